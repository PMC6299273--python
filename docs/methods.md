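# Methods

This note documents the models and procedures implemented in `mitoarch`,
the defaults chosen where the design was genuinely open, and what the
synthetic-data validation does and does not establish.

## Data model and coordinates

`GeneFeature` stores 1-based inclusive coordinates, the convention of
GenBank flat files and published gene tables; `end < start` marks a
feature spanning the origin of a circular genome. All internal arithmetic
(gap computation, frame phases, codon scanning) converts to 0-based
offsets modulo the genome length, which removes off-by-one hazards in
circular bookkeeping. Translation uses NCBI table 5 (invertebrate
mitochondrial: AGA/AGG → Ser, ATA → Met, TGA → Trp; stops TAA/TAG) via
Biopython's codon tables. Ambiguous bases (`N`) translate to `X` and are
excluded from composition counts so that percentages remain interpretable.

## Annotation curation

The curation pass applies, in order: duplicate resolution, start-codon
selection, stop-codon resolution, and overlap-legality checks. The
reasoning behind each rule:

- **Starts.** Both mitochondrial strands are transcribed as polycistronic
  RNA, so a PCG is assumed to begin at the first eligible in-frame start
  codon nearest to the preceding gene without overlapping it. The eligible
  start set defaults to {ATG, ATA, ATT, ATC, GTG} (configurable; non-ATG
  starts must be reachable — *atp6* in *M. neritoides* genuinely starts
  with ATT). Candidates are enumerated from the upstream gene boundary
  inward, in the annotated reading frame, up to 90 nt into the annotated
  gene (a window wide enough for typical annotator overshoot while never
  reaching a downstream gene). A candidate is accepted if the ORF it opens
  reaches a stop (see below) and, when reference genomes are supplied, the
  protein length falls within ±10% of the reference mean for that gene.
  Since each candidate position carries exactly one codon, position order
  (nearest-to-upstream first) fully determines the choice and no
  same-position tie between codons can occur.
- **Stops.** Scanning in frame from the (fixed) start, the gene ends at
  the first full TAA/TAG. If none occurs before the downstream gene, an
  abbreviated stop is accepted when the remaining 1–2 nt flush against the
  downstream feature read `T` or `TA` (recorded as `T--`/`TA-`,
  "subsequently completed with A by polyadenylation" of the transcript).
  Candidate ORF validation during start selection uses this same scan —
  deliberately not the currently annotated 3' end, so a record corrupted
  in both boundaries is still recoverable.
- **Overlaps.** Two same-strand PCGs overlapping in the same reading frame
  are physically impossible on a shared transcript and are reported as
  violations (never auto-edited); different frames or opposite strands
  pass. Frame congruence is start-phase arithmetic: on the plus strand,
  `(start_a − start_b) mod 3 == 0`; on the minus strand the analogous test
  on ends. A 7-nt overlap (as between *nad4l* and *nad4*) is automatically
  legal because 7 is not a codon multiple.
- **Duplicates.** Among same-named candidates the highest annotation
  quality wins; ties keep the earliest coordinate and emit a warning.
- **tRNA/rRNA boundaries** are trusted as given (re-prediction is out of
  scope) and never extended toward flanking genes. Reference genomes
  contribute a per-gene length-delta report only; reference annotations
  are never propagated automatically, and unresolvable genes are flagged,
  never deleted.

Gene geometry counts one gap per adjacent pair on the circle, including
the wrap-around junction, so Σ gaps + Σ feature lengths equals the genome
length exactly — a conservation identity enforced in tests.

## Composition and codon usage

Skews are (A−T)/(A+T) and (G−C)/(G+C). Per-gene rows are computed on the
plus strand as the printed coordinates define the region, with a
coding-strand option. Values are kept at full precision internally and
rounded half-up only at report time (1 decimal for percentages, 3 for
skews). One known artefact: recomputing a whole-genome GC skew from
percentages rounded to 1 decimal can disagree with a skew computed from
raw counts in the third decimal; the bundled published percentages give
+0.015 where the full-sequence value is +0.012.

RSCU follows the standard definition RSCU(c) = k·n_c/Σ n over the 22
synonymous families of the invertebrate mitochondrial code (9 four-fold,
13 two-fold; the six-codon amino acids of the standard code split into
Leu1 = CUN / Leu2 = UUR and Ser1 = AGN / Ser2 = UCN, and Ile is two-fold
because AUA encodes Met). Families with zero usage get missing-flagged
RSCU rather than zeros.

Species comparisons run one chi-square test per codon family: observed =
focal counts; expected = the focal family total distributed by the pooled
two-species proportions ("the count if this codon was equally used in the
two species"). This one-row formulation is not invariant to rescaling one
species' counts — that is a property of the pooled definition, not a bug —
and a 2×k contingency variant is available via `contingency=True`.
Families with any expected count < 5 are flagged, not excluded; untestable
families (pooled total 0) are reported as such. All testable families are
tested and both the family count and the testable count are reported.
Multiple testing uses Holm's step-down (sequential Bonferroni): reject
p(i) ≤ α/(m−i+1) in ascending order, stopping at the first failure.

## Codon model and branch fits

The substitution model is the Goldman–Yang codon model over the 62 sense
codons: single-nucleotide steps only, with rate π_j multiplied by κ for
transitions and ω for non-synonymous changes, scaled to one expected
substitution per codon at stationarity. Codon frequencies default to F3x4
(position-specific nucleotide frequencies estimated from the alignment,
with a small guard count against unobserved bases); empirical or uniform
vectors can be passed explicitly. Gap- or ambiguity-containing codon
columns are removed alignment-wide (complete deletion); stop-containing
columns are an error.

Likelihoods are computed by Felsenstein pruning on site patterns with
per-node rescaling. P(t) = exp(Qt) comes from the eigendecomposition of
the π^(1/2)-symmetrized generator (the model is reversible), with a
scipy `expm` fallback if conditioning fails; P(0) = I holds to < 1e-12.
Trees with a bifurcating root are derooted before fitting, since under a
reversible model only the sum of the two root edges is identifiable — a
4-taxon tree therefore has 5 branches and the free-ratios model 5 ω's.

Branch models (one-ratio, two-ratios with a named foreground branch,
free-ratios) are fitted with bounded L-BFGS-B on log-transformed
parameters (κ ∈ [0.05, 100], branch lengths ∈ [1e-6, 50], ω ∈ [1e-4,
999] — the wide ω ceiling accommodates extreme estimates) with seeded
random restarts (default 3). Passing a nested model's fit as `init` seeds
the first start at its optimum, which guarantees the likelihood nesting
inequality between successive fits; the LRT clamps small negative
statistics at 0 and warns below −1e-6. Degrees of freedom are parameter-
count differences; frequencies are counted as empirical, not free
parameters (the usual convention for F3x4-style fits).

The Nei–Gojobori counting estimator (equal-weight pathway averaging,
mutations to stop codons excluded from site counts, Jukes–Cantor
correction) is implemented independently of the ML machinery and serves
as a cross-check: purifying-selection simulations must yield counting
ω < 1.

Published branch-model ω values for the littorinid radiation (0.1361 …
16.8910) require the *Littorina* genome sequences and optimizer parity
with CODEML (whose codon-frequency setting is not stated in the source
analyses); they are treated as external-data conformance checks, not test
anchors. Validation instead uses parameter recovery and LRT calibration
on simulated data (below).

## Gene-order distances

Orders are circular signed permutations, canonicalized by rotating the
anchor gene (default *cox1*) to the front with positive sign, reflecting
the circle if needed. Breakpoints are counted fully circularly: an
adjacency (x, y) of one order is matched in the other by (x, y) or by its
opposite-orientation reading (−y, −x); an order and its reverse
complement therefore have distance 0. Common intervals are counted on the
anchor-linearized orders, signs ignored, over block sizes 2..n, with an
O(n²) running-min/max counter validated against an O(n³) exhaustive
oracle. Because published interval counts from other tools depend on an
unpublished convention (circular vs linearized, inclusion of size-n
blocks), absolute counts are comparable within this package but may
differ from such tools by a convention constant; published values
(398/74/84 intervals, 24/22/11/12 breakpoints) are conformance context,
not anchors. Comparisons default to 13-PCG orders; any gene set works as
long as the two orders share it.

## Branch Length Test

For a rooted tree, δᵢ = dᵢ − mean(d) over the root-to-tip distances dᵢ;
Σδ = 0 by construction and δ is invariant to a constant root edge.
Positive δ marks a faster-than-average lineage — the sign convention
follows how accelerated lineages are conventionally reported (δ = +1.06
for the fastest taxa), although the defining sentence in the original
method description reads "average minus distance"; the ambiguity is noted
here deliberately. The mean is unweighted over leaves.

Standard errors come from a nonparametric site bootstrap (default 1000
replicates, seeded): multinomial site weights, Jukes–Cantor distances,
then branch lengths re-fitted on the fixed topology by ordinary least
squares (the original tool was itself distance-based, so a distance
refit is the closest desk-scale analogue to its analytic variance, which
is not reproduced here). The two child edges of a bifurcating root are
collinear in leaf-path space and are merged into a single OLS parameter,
re-split in the input tree's proportion for root-to-tip reconstruction.
CP = 1 − p with p the two-sided normal tail of δ/SE; CP ≥ 0.99 flags the
1% level. Fewer than 50 bootstrap replicates triggers a warning; without
an alignment or supplied SEs, CP is reported as missing.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed). The genome generator
lays out genes and spacers on a circle; PCGs are a start codon, random
sense codons and a stop, so the true annotation satisfies every curation
rule. Spacers are drawn from a C/G-only alphabet: every eligible start
codon contains A or T, so spacers cannot harbour spurious upstream
in-frame starts and the truth is an exact fixed point of curation by
construction. Corruption switches shift starts in-frame into the gene,
extend stops past the true terminus, inject low-quality duplicate tRNA
calls, and create frame-congruent PCG overlaps. This emulates the error
modes the curation rules address — it does not emulate sequencing error,
mis-assembly, biased base composition or genes whose true start is absent
from the candidate set, so perfect round-trip recovery on synthetic data
bounds only the logic, not real-annotation accuracy.

The codon simulator uses exact matrix-exponential transition
probabilities per branch (matching the likelihood model being tested, by
design — recovery tests therefore validate the estimator, not model
adequacy). The clock-tree generator builds a random-join ultrametric tree
and rescales pendant edges so a designated leaf's root-to-tip path equals
depth × factor; its nucleotide companion simulates Jukes–Cantor sites.

## Problem sizes and tolerances

Validation uses, as the package's own choices: 4-taxon alignments of
200–800 codons for the selection machinery (ω-recovery median relative
error ≤ 25% at ω ∈ {0.2, 1, 5} over seeded replicates; two-ratios LRT
type-I rate within [0.5%, 10.5%] of the nominal 5% over 200 null
simulations; power against ω = 5 foreground at 800 codons), 500 random
signed permutations of n ≤ 10 for the interval-counter oracle, 100 seeds
for curation round-trips, and 6-taxon / 2000-site clock simulations with
a 3× accelerated lineage for the BLT (detection at CP ≥ 99%). Likelihood
convergence tolerance is 1e-6 on the log-likelihood; nesting inequalities
are asserted to the same tolerance.

## Known limitations

- Site models and branch-site models are not implemented; selection
  inference is branch-wise only.
- The curation start-codon search assumes the annotated frame; a gene
  annotated in the wrong frame entirely is flagged unresolved rather than
  re-discovered.
- Common-interval counts are convention-dependent (see above).
- The BLT bootstrap refits branch lengths under Jukes–Cantor distances
  regardless of the model that produced the input tree; SEs are
  approximate when substitution processes are strongly heterogeneous.
- The bundled reference record is coordinates-only (all-N sequence);
  sequence-derived statistics (composition from raw sequence, RSCU of the
  real genome) require the user to supply the deposited GenBank file.
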