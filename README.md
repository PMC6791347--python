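# ortholoss

Inference of gene loss from genome assemblies.

Comparative genomics keeps turning up protein-coding genes that one
lineage has quietly abandoned: the locus is still there, flanked by its
usual neighbors, but the reading frame is broken by small indels,
premature stop codons, or outright truncation.  Establishing that such
a gene is genuinely dead — and counting how many times it died
independently across a clade — takes more than spotting one suspicious
annotation.  `ortholoss` packages that whole argument as a reusable,
tested pipeline:

1. **Synteny** — locus orthology from neighbor genes and anchor pairs
   (affine-gap local alignment, best hit by query coverage then
   identity), returning the inter-anchor candidate region.
2. **Annotation** — a UTR-flanked single-exon reference gene is mapped
   onto the region (local affine alignment, N as wildcard) and the
   target CDS is reconstructed in the reference frame.  Frameshift
   indels (length ≢ 0 mod 3), in-frame premature stop codons, and
   abrupt identity-collapse truncations are called at
   reference-projected coordinates; loci hidden behind assembly gaps
   (N runs) are classified *inconclusive* rather than over-called.
3. **Read validation** — every called lesion is scored against raw
   sequencing reads by aligning each read to the mutant and the
   reverted haplotype (edit distance); verdicts are
   confirmed / refuted / polymorphic / no-data, so segregating loss
   alleles (≈50% read support) are recognized as such.
4. **Loss events** — lesions shared across taxa (identical kind,
   coordinate and length) are merged and placed on a rooted species
   tree under Dollo parsimony; the distinct most-basal lesion-bearing
   branches are the independent inactivation events.
5. **Selection** — a Goldman–Yang (GY94) codon substitution model with
   per-branch-category dN/dS (ω), F3x4 codon frequencies, and
   Felsenstein-pruning likelihoods.  Each branch category is tested
   against neutrality (ω = 1) by a χ² likelihood-ratio test, the
   classic signature being purifying selection (ω ≪ 1) before the
   loss and ω ≈ 1 after it.

A first-class synthetic-data module generates loci with known ground
truth — CDSs evolved on a tree under GY94 with per-branch ω, injected
1–2 nt frameshifts and nonsense substitutions, anchored loci with N
runs, and reads drawn from one or a mixture of alleles — so every stage
is testable without downloading anything.

## The model at the core

GY94 rates between sense codons *i* → *j* differing at one position:

    q_ij ∝ π_j · κ^[transition] · ω^[nonsynonymous]

with π the 61 F3x4 sense-codon frequencies and the generator scaled to
one expected substitution per codon per unit branch length.  Branches
carry category labels (codeml-style `#tag` suffixes in Newick); each
category has its own ω.  `CodonBranchModel(alignment, tree)` is the
model object; `.fit()` maximizes the likelihood over κ, the free ω's
and all branch lengths (bounded L-BFGS-B on log parameters, three
deterministic ω starts) and returns a results object with `summary()`;
`fit_two_ratio(category)` runs the focal-ω-free vs ω=1 pair of nested
fits and the df=1 LRT.  Codons containing gaps, N or `?`, and stop
codons, are fully ambiguous (all 61 states), matching the convention
of including ambiguous sites with stops recorded as missing.

## Worked example

```sh
ortholoss fixture cetacea --out-dir demo
ortholoss run-all --config demo/config.yaml --run-dir demo/run
```

prints (fixture seed 0):

```
stages completed: synteny, annotate, validate, events, selection
independent loss events: 3
cetacean_stem                omega=0.057  p=0.0007
functional                   omega=0.103  p=0.0000
mysticeti                    omega=0.977  p=0.9402
mysticeti_stem               omega=0.891  p=0.8153
odontoceti                   omega=0.315  p=0.0001
odontoceti_stem              omega=1.748  p=0.6198
sperm_whale_ancestor         omega=1.297  p=0.6861
```

Reading this: the bundled whale-like fixture carries a 2-nt deletion
shared by all toothed whales except the sperm whale, a private
mid-gene stop plus a 1-nt insertion in the sperm whale, and a 1-nt
deletion shared by three of the four baleen whales (the fourth is
5'-fragmented by Ns and comes out *inconclusive*).  Dollo placement
turns that catalog into **3 independent loss events** — the baleen-whale
stem, the toothed-whales-minus-sperm-whale stem, and the sperm-whale
branch.  The selection table shows strong purifying selection where
the gene is (or was) functional — the outgroup branches (ω = 0.10,
p < 0.05) and the pre-loss common cetacean stem (ω = 0.06,
p = 0.0007) — while the post-loss stems are indistinguishable from
neutral evolution (p ≫ 0.05), exactly the pattern the fixture was
built to contain.  Per-stage artifacts (mutation table, verdicts,
mutation matrix, event list, codon alignment, ω/LRT table,
machine-readable `summary.json`) land in `demo/run/`.

The library surface mirrors the CLI: `simulate_cds_evolution`,
`inject_lesions`, `build_locus`, `simulate_reads`;
`best_hit` / `build_synteny_map` / `locate_target_region`;
`map_reference_cds` / `call_inactivating_mutations` /
`detect_truncation` / `classify_coding_status` / `translation_align`;
`validate_mutation` / `validate_all`; `build_mutation_matrix` /
`count_independent_losses` / `label_branch_categories`;
`CodonBranchModel` / `fit_branch_model` / `lrt_neutral`.

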