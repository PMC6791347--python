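import numpy as np
import pytest

from ortholoss.annotate import ERODED, INCONCLUSIVE, INTACT, InactivatingMutation


MYSTICETI = ["bowhead", "gray", "antarctic_minke", "minke"]
ODONTOCETI_NON_SPERM = [
    "yangtze_river_dolphin",
    "beluga",
    "finless_porpoise",
    "killer_whale",
    "pacific_white_sided_dolphin",
    "bottlenose_dolphin",
    "humpback_dolphin",
]

CETACEAN_TOPOLOGY = (
    "(human:1,(cattle:1,(hippo:1,((bowhead:1,(gray:1,(antarctic_minke:1,minke:1):1):1):1,"
    "(sperm_whale:1,(yangtze_river_dolphin:1,(beluga:1,(finless_porpoise:1,(killer_whale:1,"
    "(pacific_white_sided_dolphin:1,(bottlenose_dolphin:1,humpback_dolphin:1):1):1):1):1):1):1):1):1):1):1);"
)


@pytest.fixture(scope="session")
def cetacean_matrix():
    """Mutation matrix transcribed from the catalog of whale lesions:
    a 2-nt deletion shared by all toothed whales but the sperm whale,
    sperm-whale-private stop + 1-nt insertion, a 1-nt deletion shared
    by three baleen whales, the fourth baleen whale unknown (5' gap)."""
    from ortholoss.events import build_mutation_matrix

    muts = {t: [] for t in MYSTICETI + ODONTOCETI_NON_SPERM + ["sperm_whale", "human", "cattle", "hippo"]}
    for t in ODONTOCETI_NON_SPERM:
        muts[t].append(InactivatingMutation(kind="frameshift_deletion", ref_coord=517, length_nt=2))
    muts["sperm_whale"] = [
        InactivatingMutation(kind="premature_stop", ref_coord=703, codon_index=235),
        InactivatingMutation(kind="frameshift_insertion", ref_coord=1380, length_nt=1),
    ]
    for t in ["bowhead", "gray", "antarctic_minke"]:
        muts[t].append(InactivatingMutation(kind="frameshift_deletion", ref_coord=130, length_nt=1))
    statuses = {t: ERODED for t in ODONTOCETI_NON_SPERM + ["sperm_whale", "bowhead", "gray", "antarctic_minke"]}
    statuses.update({"minke": INCONCLUSIVE, "human": INTACT, "cattle": INTACT, "hippo": INTACT})
    return build_mutation_matrix(muts, statuses)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
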