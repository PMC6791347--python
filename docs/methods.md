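# Methods

This note records the models, conventions and numerical choices behind
`ortholoss`, and what the synthetic-data tests do and do not establish
about real data.

## Sequence evolution model

Coding sequences evolve on a rooted tree under the Goldman–Yang codon
substitution process over the 61 sense codons.  For codons differing at
exactly one position the instantaneous rate is
`q_ij = π_j · κ^[transition] · ω^[nonsynonymous]`; multi-position
changes have rate zero; the diagonal closes each row.  The generator is
rescaled so that `Σ_i π_i Σ_{j≠i} q_ij = 1`, making branch lengths
expected substitutions per codon.  The chain is reversible, so the
symmetrized generator `D^{1/2} Q D^{-1/2}` (D = diag π) is
eigendecomposed once per (κ, ω) pair and every transition matrix
`P(t) = exp(Qt)` is two 61×61 products — this is what makes hundreds of
maximum-likelihood fits affordable in the test suite.

Equilibrium frequencies default to F3x4: nucleotide frequencies are
counted separately at the three codon positions over unambiguous
characters, each codon's frequency is the product of its positional
frequencies, stop-codon mass is removed and the rest renormalized.

The simulator (`simulate_cds_evolution`) draws the root from a supplied
stop-free sequence and samples each site down the tree from the exact
per-branch `P(t)` — transition matrices rather than event-by-event
simulation, which is simpler and exactly sufficient for testing
estimators.  Stop codons can never arise because they are not states of
the chain.  All randomness flows from one `numpy` generator per call,
seeded explicitly.

## Likelihood, fitting, and the two-ratio test

Likelihoods use Felsenstein pruning over 61 states with per-site
rescaling.  A codon containing a gap, `?`, or N — and any stop codon —
is fully ambiguous: its leaf partial vector is all ones, so ambiguous
sites are included rather than deleted (stops recorded as missing).
This is the permissive convention appropriate for eroded sequences,
where the informative signal of the remaining intact codons should not
be discarded.

`CodonBranchModel.fit()` maximizes over κ, the free category ω's and
every branch length jointly, on log scale, with bounds
ω ∈ [1e-4, 10], κ ∈ [0.1, 20], t ∈ [1e-6, 50], using L-BFGS-B
(finite-difference gradients; convergence at ftol 1e-8).  Branch
lengths start from the input tree.  Three deterministic ω starts
(0.1, 1, 2) are scored by likelihood at the start point and the best is
polished to convergence; running one polished optimization instead of
three full ones keeps a 400-fit calibration suite inside its time
budget while still guarding against the coarse local-optimum failure
mode (starting a strongly purifying data set at ω = 2 and vice versa).
The root placement is taken as given; for this reversible model the
likelihood is root-invariant (checked by a pulley-principle test), the
two root-child branch lengths being identifiable only through their
sum.

Each branch category is tested against neutrality by its own two-ratio
pair: the focal category's ω free versus fixed at 1, all other branches
sharing one free background ω in both fits; branch lengths and κ are
re-estimated in each fit; `2Δℓ` (clamped at zero for boundary noise) is
referred to χ² with df = 1.  Testing categories one at a time, against
a single shared background, is the conventional branch-model layout
when a table reports one ω and one p-value per category.

## Locus annotation

The reference is an intact single-exon gene, optionally UTR-flanked.
Mapping uses affine local alignment (match 1, mismatch −2, gap open 12,
extend 3, N matches anything at zero) on both strands, the better
strand winning.  Local — rather than reference-global — alignment is
deliberate: non-homologous flanking sequence, truncation junk, and
fragmented ends are clipped instead of force-aligned, which would
otherwise shed spurious gaps into the CDS edges.  The tolerance of
these scores is roughly 20–25% divergence, comfortable for
within-order comparisons like whales against cattle.

The target CDS is reconstructed **in the reference frame**: for every
reference CDS position the aligned target base, `-` for an internal
deletion, `?` where the alignment does not reach.  Frameshift indels
(length ≢ 0 mod 3) are reported with left-normalized (VCF-style)
coordinates, so placements inside homopolymer runs are canonical and
comparable across taxa; the injector normalizes its truth records the
same way, which is what makes exact round-trip coordinate checks
meaningful.  Premature stops are read from the reference-frame codons
of the reconstruction — equivalently, in the running frame after the
reported frameshift columns are removed, which restores the reference
frame.  Codons touched by gaps, Ns or uncovered positions are never
stop calls.  A stop in the terminal reference codon position is never
premature.  Pairs of indels whose cumulative offset returns to 0 mod 3
are flagged `compensated` but still reported.

Truncation detection slides a 60 nt window at 15 nt steps over the
reference CDS and looks for an identity collapse: two consecutive
windows below 30% after any window at or above 70%, with no later
recovery above 70%.  The breakpoint is the first low window's start.
Low windows explained by Ns — either N-aligned columns or an unaligned
region tail that is mostly N — are reported as inconclusive rather
than as truncation.  Defaults (60/15/70/30) reproduce the qualitative
mid-gene collapse fixture and are CLI-configurable.

Coding status: *eroded* if a truncation was called (the lost span is
demonstrably replaced by unrelated sequence, not missing); otherwise
*inconclusive* if under 90% of the reference CDS aligns to real
(non-N) bases — the fragmented-assembly case; otherwise *eroded* with
any lesion, else *intact*.

The codon alignment for selection analysis is built by translating the
reference-frame reconstructions (frameshift columns removed; `-`, `?`,
N and stops becoming the missing codon `???`) and aligning the
proteins progressively under BLOSUM62 along a neighbor-joining guide
tree of pairwise p-distances, profile-to-profile with affine gaps,
then back-threading codons (protein gap → `---`).

## Read validation

Each read (and its reverse complement) is aligned, by edit distance in
infix mode, to the two haplotypes of the called site: the region as
assembled (mutant) and the region with the lesion reverted to the
reference allele.  A read is informative if its best placement spans
the site with at least half the flank (default flank 30 nt, so 15 nt)
anchored on each side and its distance is strictly better on one
haplotype.  With fewer than 3 informative reads the verdict is
no-data; support fraction ≥ 0.8 confirms, ≤ 0.2 refutes, and the band
between is polymorphic — wide enough that a 50/50 segregating allele
is called polymorphic with high probability at realistic depths.
Across read sets, the consensus confirms only if no set refutes and at
least one confirms; confirm/refute disagreement is flagged as
conflict.  Haplotype-window scoring replaces mapping-plus-pileup; for
the 1–2 nt indels and single-codon substitutions in scope it is exact
and dependency-free.

## Loss events

Lesions are merged across taxa on exact identity (kind, left-normalized
reference coordinate, length); no tolerance window is applied by
default, since homologous lesions project to identical reference
coordinates under a shared reference.  Taxa with inconclusive status
are *unknown* at coordinates outside their covered intervals.  Under
Dollo parsimony (a lesion arises once, never reverts) each lesion is
placed on the stem of the smallest clade containing all its carriers
after pruning unknown taxa — so an N-fragmented taxon nested inside a
carrier clade does not break the clade, and a stem event can include
it.  Non-monophyletic carriers split into per-maximal-subclade
origins.  The root itself is never an origin (an event needs a
branch).  A leaf's inactivation branch is the most basal
lesion-bearing branch on its root path; the set of distinct
inactivation branches is the event set.  On small trees this placement
is checked against exhaustive enumeration of Dollo-consistent origin
assignments.

Branch categories for the selection stage are assigned by ordered
selectors (crown / stem / terminal; later entries override earlier
ones; unlabeled branches form the background).  The bundled cetacean
scheme produces seven categories: crown Mysticeti, crown Odontoceti,
both parvorder stems (Odontoceti stem excluding the sperm whale), the
common cetacean stem, the sperm-whale branch, and a functional
background covering the outgroups.

## Synthetic data: what it does and does not emulate

The generator produces the statistical structure the analysis assumes:
GY94-evolved CDSs with per-category ω, 1–2 nt frameshifts and
minimal-substitution nonsense changes (tie broken to TAA for
determinism), anchored loci with intergenic spacers and N runs, and
uniform-coverage single-end reads with substitution-only errors.  The
bundled `cetacea` fixture (480 codons, 15 taxa, branch lengths 0.005–
0.08 substitutions/codon) mirrors a characteristic whale-like erosion
catalog: a shared 2-nt deletion in the non-sperm toothed whales, a
private mid-gene stop plus near-end 1-nt insertion in the sperm whale,
a shared 1-nt deletion in three of four baleen whales with the fourth
5'-fragmented — three independent losses by construction, with
purifying ω (0.1) on functional branches and relaxed ω after loss.

Deliberately not emulated: assembly error processes, quality-score
realism, paired-end geometry, indel sequencing errors (optional
substitution errors only), multi-exon gene structure, and alignment
ambiguity between highly diverged (>25%) sequences.  Passing tests
therefore demonstrate correctness of the inference machinery under the
assumed generative process, not robustness to assembly artifacts or
deep-divergence alignment failure; on real data the read-validation
stage is the guard against the former.

## Problem sizes and runtime choices

The test suite runs simulation studies at sizes chosen to give stable
statistics on one CPU: LRT calibration uses 200 neutral replicates
(300 codons, 8 taxa) and 40 power replicates (500 codons, foreground
ω = 0.1); ω recovery uses 50 replicates per setting at 500 codons on 6
taxa; pruning is checked against enumeration on 200 instances of ≤4
taxa and ≤10 codons; round-trip annotation covers 110 seeded loci.
`scripts/acceptance.py` recomputes the same quantities at moderately
reduced replicate counts (reported in its output as `n`).

## Known limitations

- Exact-coordinate lesion homology can split a genuinely shared lesion
  if alignment noise shifts its projection in some carriers; the
  matrix builder keeps such lesions distinct (a warning is emitted for
  same-coordinate kind conflicts), and Dollo placement then infers
  extra events.  The bundled fixtures are constructed within the
  divergence range where projections are stable.
- The two root-child branch lengths are not separately identifiable;
  only their sum is meaningful in fitted parameters.
- p-values assume the χ²_1 reference distribution; for focal ω near
  the boundary it is conservative.
- The truncation detector reports the first collapse only; multiple
  independent breakpoints in one locus are summarized by the first.
- Branch-model fits are not designed for saturated alignments (tree
  lengths far above ~5 substitutions/codon); bounds will truncate
  rather than diagnose saturation.
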