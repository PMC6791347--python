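"""Reference-guided annotation: mapping, mutation calling, truncation,
status classification, translation alignment."""

import numpy as np
import pytest

from ortholoss.annotate import (
    ERODED,
    INCONCLUSIVE,
    INTACT,
    AnnotationError,
    NoOrthologDetected,
    ReferenceGene,
    call_inactivating_mutations,
    classify_coding_status,
    detect_truncation,
    map_reference_cds,
    translation_align,
)
from ortholoss.codons import random_sense_cds, revcomp
from ortholoss.locus import GenomicLocus
from ortholoss.simulate import LesionSpec, build_locus, inject_lesions


def make_reference(n_codons=200, seed=0, utr=100):
    rng = np.random.default_rng(seed)
    cds = random_sense_cds(n_codons - 1, rng) + "TAA"
    u5 = "".join(rng.choice(list("ACGT"), size=utr))
    u3 = "".join(rng.choice(list("ACGT"), size=utr))
    return ReferenceGene(name="ref", cds=cds, utr5=u5, utr3=u3)


def embed(seq, seed=0, strand="+", utr5="", utr3=""):
    """Locus with the mutated CDS between random flank genes; homologous
    UTRs (when given) sit adjacent to the CDS, as in a real locus."""
    locus, truth = build_locus(
        seq,
        [("u", "".join(np.random.default_rng(seed + 1).choice(list("ACGT"), 400)))],
        [("d", "".join(np.random.default_rng(seed + 2).choice(list("ACGT"), 400)))],
        strand=strand,
        utr5=utr5,
        utr3=utr3,
        seed=seed,
    )
    return locus


class TestMapping:
    def test_exact_cds_full_coverage(self):
        ref = make_reference(seed=1)
        aln = map_reference_cds(ref, embed(ref.cds, seed=1, utr5=ref.utr5, utr3=ref.utr3))
        assert aln.coverage == 1.0
        assert aln.reconstructed_cds() == ref.cds

    def test_two_nt_deletion_shows_reference_bulge(self):
        ref = make_reference(seed=2)
        mutant, truth = inject_lesions(
            ref.cds, [LesionSpec(kind="deletion", position_frac=0.4, length_nt=2)]
        )
        aln = map_reference_cds(ref, embed(mutant, seed=2, utr5=ref.utr5, utr3=ref.utr3))
        rec = aln.reconstructed_cds()
        pos = truth[0].ref_coord - 1
        assert rec[pos : pos + 2] == "--"
        assert rec.count("-") == 2

    def test_strand_symmetry(self):
        ref = make_reference(seed=3)
        plus = map_reference_cds(ref, embed(ref.cds, seed=3, strand="+", utr5=ref.utr5, utr3=ref.utr3))
        minus = map_reference_cds(ref, embed(ref.cds, seed=3, strand="-", utr5=ref.utr5, utr3=ref.utr3))
        assert plus.reconstructed_cds() == minus.reconstructed_cds()
        assert minus.strand_used == "-"

    def test_unrelated_region_no_ortholog(self):
        ref = make_reference(seed=4)
        junk = "".join(np.random.default_rng(99).choice(list("ACGT"), 2000))
        with pytest.raises(NoOrthologDetected):
            map_reference_cds(ref, GenomicLocus(name="x", seq=junk))


class TestMutationCalling:
    def test_lesion_free_target_empty_list(self):
        ref = make_reference(seed=5)
        aln = map_reference_cds(ref, embed(ref.cds, seed=5, utr5=ref.utr5, utr3=ref.utr3))
        assert call_inactivating_mutations(aln) == []

    def test_mysticeti_like_shared_and_private_lesions(self):
        """One 1-nt deletion shared by three of four taxa plus private
        insertions (2-nt and 1-nt near the 5' end) — each call matches
        its taxon's injected truth."""
        ref = make_reference(n_codons=480, seed=6)
        plans = {
            "bowhead": [LesionSpec(kind="deletion", position_frac=0.09, length_nt=1)],
            "gray": [
                LesionSpec(kind="deletion", position_frac=0.09, length_nt=1),
                LesionSpec(kind="insertion", position_frac=0.15, length_nt=1),
            ],
            "antarctic_minke": [
                LesionSpec(kind="deletion", position_frac=0.09, length_nt=1),
                LesionSpec(kind="insertion", position_frac=0.55, length_nt=2),
            ],
            "minke": [],
        }
        coords = {}
        for taxon, plan in plans.items():
            mutant, truth = inject_lesions(ref.cds, plan, seed=42)
            aln = map_reference_cds(ref, embed(mutant, seed=42, utr5=ref.utr5, utr3=ref.utr3))
            calls = call_inactivating_mutations(aln)
            assert sorted((m.kind, m.ref_coord, m.length_nt) for m in calls) == sorted(
                (t.kind, t.ref_coord, t.length_nt) for t in truth
            ), taxon
            for m in calls:
                coords.setdefault((m.kind, m.length_nt), set()).add(m.ref_coord)
        # the shared deletion projects to one coordinate in every carrier
        assert len(coords[("frameshift_deletion", 1)]) == 1

    def test_roundtrip_random_lesions(self):
        """Injected lesions >=30 nt apart are recovered with exact kind,
        length and coordinate over many random loci."""
        n_ok = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            ref = make_reference(n_codons=200, seed=1000 + seed)
            kinds = ["deletion", "insertion", "nonsense"]
            lesions, last = [], -100
            for f in sorted(rng.uniform(0.05, 0.9, size=rng.integers(0, 4))):
                pos = int(f * len(ref.cds))
                if pos - last < 40:
                    continue
                last = pos
                k = kinds[rng.integers(0, 3)]
                lesions.append(
                    LesionSpec(
                        kind=k,
                        position_frac=f,
                        length_nt=int(rng.integers(1, 3)) if k != "nonsense" else None,
                    )
                )
            mutant, truth = inject_lesions(ref.cds, lesions, seed=seed)
            aln = map_reference_cds(ref, embed(mutant, seed=seed, strand="+-"[seed % 2], utr5=ref.utr5, utr3=ref.utr3))
            calls = call_inactivating_mutations(aln)
            assert sorted((m.kind, m.ref_coord, m.length_nt) for m in calls) == sorted(
                (t.kind, t.ref_coord, t.length_nt) for t in truth
            ), seed
            n_ok += 1
        assert n_ok == 30

    def test_compensated_pair_flagged_but_reported(self):
        ref = make_reference(n_codons=300, seed=7)
        mutant, _ = inject_lesions(
            ref.cds,
            [
                LesionSpec(kind="deletion", position_frac=0.3, length_nt=1),
                LesionSpec(kind="insertion", position_frac=0.6, length_nt=1),
            ],
        )
        calls = call_inactivating_mutations(map_reference_cds(ref, embed(mutant, seed=7, utr5=ref.utr5, utr3=ref.utr3)))
        fs = [m for m in calls if m.kind.startswith("frameshift")]
        assert len(fs) == 2 and all(m.compensated for m in fs)

    def test_stops_invariant_to_utr_length(self):
        rng = np.random.default_rng(8)
        cds = random_sense_cds(199, rng) + "TAA"
        mutant, truth = inject_lesions(cds, [LesionSpec(kind="nonsense", position_frac=0.5)])
        region = embed(mutant, seed=8)
        calls = {}
        for utr in (0, 50, 200):
            pad = "".join(np.random.default_rng(utr).choice(list("ACGT"), utr))
            ref = ReferenceGene(name="r", cds=cds, utr5=pad, utr3=pad)
            ms = call_inactivating_mutations(map_reference_cds(ref, region))
            calls[utr] = [(m.kind, m.ref_coord, m.codon_index) for m in ms]
        assert calls[0] == calls[50] == calls[200]
        assert calls[0][0][2] == truth[0].codon_index

    def test_frame_restored_after_removing_frameshift_columns(self):
        """Dropping the reported frameshift columns leaves a string that
        is reference-frame consistent (length divisible by 3, stops only
        where called)."""
        ref = make_reference(n_codons=200, seed=9)
        mutant, _ = inject_lesions(
            ref.cds,
            [
                LesionSpec(kind="deletion", position_frac=0.2, length_nt=2),
                LesionSpec(kind="insertion", position_frac=0.7, length_nt=1),
            ],
        )
        aln = map_reference_cds(ref, embed(mutant, seed=9, utr5=ref.utr5, utr3=ref.utr3))
        rec = aln.reconstructed_cds()
        assert len(rec) == len(ref.cds)
        assert len(rec) % 3 == 0


class TestTruncation:
    def test_uniform_high_identity_no_call(self):
        ref = make_reference(seed=10)
        aln = map_reference_cds(ref, embed(ref.cds, seed=10, utr5=ref.utr5, utr3=ref.utr3))
        assert detect_truncation(aln) is None

    def test_random_second_half_breakpoint_near_junction(self):
        ref = make_reference(n_codons=300, seed=11)
        half = len(ref.cds) // 2
        junk = "".join(np.random.default_rng(12).choice(list("ACGT"), len(ref.cds) - half))
        region = GenomicLocus(name="t", seq=ref.cds[:half] + junk)
        aln = map_reference_cds(ref, region)
        call = detect_truncation(aln)
        assert call is not None and not call.inconclusive
        assert abs(call.ref_coord - half) <= 60  # within one window

    def test_all_n_second_half_is_inconclusive_not_truncation(self):
        ref = make_reference(n_codons=300, seed=13)
        half = len(ref.cds) // 2
        region = GenomicLocus(name="t", seq=ref.cds[:half] + "N" * (len(ref.cds) - half))
        aln = map_reference_cds(ref, region)
        call = detect_truncation(aln)
        assert call is None or call.inconclusive


class TestCodingStatus:
    def test_full_coverage_no_mutations_intact(self):
        ref = make_reference(seed=14)
        aln = map_reference_cds(ref, embed(ref.cds, seed=14, utr5=ref.utr5, utr3=ref.utr3))
        assert classify_coding_status([], aln) == INTACT

    def test_five_prime_ns_inconclusive(self):
        """A 5'-end masked by Ns leaves too little unambiguous sequence:
        the status cannot be called even without mutations."""
        ref = make_reference(n_codons=300, seed=15)
        n_mask = int(0.2 * len(ref.cds))
        region = GenomicLocus(name="t", seq="N" * n_mask + ref.cds[n_mask:])
        aln = map_reference_cds(ref, region)
        muts = call_inactivating_mutations(aln)
        assert classify_coding_status(muts, aln) == INCONCLUSIVE

    def test_single_frameshift_erodes(self):
        ref = make_reference(seed=16)
        mutant, _ = inject_lesions(
            ref.cds, [LesionSpec(kind="deletion", position_frac=0.1, length_nt=1)]
        )
        aln = map_reference_cds(ref, embed(mutant, seed=16, utr5=ref.utr5, utr3=ref.utr3))
        muts = call_inactivating_mutations(aln)
        assert classify_coding_status(muts, aln) == ERODED

    def test_monotone_in_mutations(self):
        ref = make_reference(seed=17)
        aln = map_reference_cds(ref, embed(ref.cds, seed=17, utr5=ref.utr5, utr3=ref.utr3))
        assert classify_coding_status([], aln) == INTACT
        from ortholoss.annotate import InactivatingMutation

        extra = [InactivatingMutation(kind="premature_stop", ref_coord=10, codon_index=4)]
        assert classify_coding_status(extra, aln) == ERODED


class TestTranslationAlign:
    def test_identical_sequences_gap_free(self):
        cds = random_sense_cds(100, np.random.default_rng(18))
        aln = translation_align({"a": cds, "b": cds, "c": cds})
        assert aln.n_codons == 100
        assert all("-" not in s for s in aln.seqs)

    def test_stops_become_missing(self):
        cds = "ATGAAATAAGGGCCC"
        aln = translation_align({"a": cds})
        assert aln.seqs[0][6:9] == "???"

    def test_pairwise_identity_matches_column_count_oracle(self):
        rng = np.random.default_rng(19)
        a = random_sense_cds(80, rng)
        b = list(a)
        for i in rng.choice(len(a), size=12, replace=False):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        b = "".join(b)
        aln = translation_align({"x": a, "y": b})
        sa, sb = aln.sequence("x"), aln.sequence("y")
        same = sum(
            1 for p, q in zip(sa, sb) if p == q and p in "ACGT" and q in "ACGT"
        )
        tot = sum(1 for p, q in zip(sa, sb) if p in "ACGT" and q in "ACGT")
        assert aln.pairwise_identity("x", "y") == pytest.approx(same / tot)

    def test_frame_inconsistent_input_names_taxon(self):
        with pytest.raises(AnnotationError, match="badtaxon"):
            translation_align({"ok": "ATGAAA", "badtaxon": "ATGAA"})

    def test_eroded_set_average_identity_stays_high(self):
        """Reconstructed CDSs of related taxa with lesions removed align
        at high average pairwise identity (the conserved-pseudogene
        regime in which a selection analysis is meaningful)."""
        from ortholoss.fixtures import make_cetacea
        from ortholoss.annotate import map_reference_cds as mrc

        bundle = make_cetacea(seed=0)
        ref = ReferenceGene(
            name="ref",
            cds=bundle.reference_cds,
            utr5=bundle.reference_utr5,
            utr3=bundle.reference_utr3,
        )
        recon = {}
        for taxon in ("cattle", "human", "killer_whale", "bowhead", "sperm_whale"):
            aln = mrc(ref, bundle.loci[taxon])
            recon[taxon] = aln.reconstructed_cds()
        caln = translation_align(recon)
        assert caln.mean_pairwise_identity() > 0.8
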