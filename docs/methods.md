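# Methods

## Data model and units

All analyses run on transcript-level quantifications of a two-group,
seven-stage, replicated design. Counts are integer fragment counts per
transcript and sample; FPKM is computed by the closed formula

    fpkm[t, s] = counts[t, s] / ((length_bp[t] / 1e3) * (library_size[s] / 1e6))

with the effective length taken as the annotated exonic length (overlapping
exons within a transcript merged first; no fragment-length correction). This
deterministic definition stands in for assembler-reported FPKM and makes
normalization exactly invertible and testable. Expression filtering keeps
transcripts with FPKM strictly above 1 in at least one sample.

Wherever expression enters a linear model (time-course regression, SVD axes)
the transform is `log2(FPKM + 1)`. The source analyses do not state their
unit or pseudocount; this choice stabilizes variance, maps zero to zero, and
is used consistently so the two modules see the same geometry.

Stages are encoded as days from onset of incubation — E10→10, E14→14,
E18→18, D1→22, W1→28, W3→42, W5→56 (hatch at day 21) — a monotone,
physiologically ordered scale. The encoding is a parameter everywhere it is
used.

## Developmental axes (SVD)

Per group, `X` (transcripts x samples, transformed, rows mean-centered by
default) is decomposed by SVD. Row centering gives variance fractions
`λ_α²/Σλ²` their PCA meaning; a flag disables it for a raw-matrix reading.
Conventions differ on which SVD factor is read as the trajectory; this
package fixes one: *axis vectors* are the length-s right singular vectors
(the developmental axis over samples), *feature vectors* are the length-g
left singular vectors (per-transcript loadings).

Sign indeterminacy is resolved by orienting each axis so its Pearson
correlation with numeric time is non-negative (fallback: first nonzero axis
entry positive), making runs bit-stable and axes comparable between groups
without any cross-group subspace alignment. Axis curves are smoothed against
time by a tricube-weighted local-quadratic regression (span 0.75 of the
points per window, at least four points required). A degree-2 local fit is
used because the axes are themselves modelled as quadratic-in-time
trajectories; no installed Python smoother offers degree-2 LOESS with a
span parameter, so the ~30-line weighted fit is implemented here and tested
against its polynomial-reproduction property.

Contributors of a component are the `ceil(0.10 * g)` transcripts of largest
absolute loading (fraction configurable), ranked with lexicographic
transcript-id tie-breaks; the loading sign gives the up/down direction.
Group-specific contributors are the union over that group's leading
components minus the union over the other group's. Which components are
"development-related" is a user decision, typically made by GO inspection
of each component's contributors; the pipeline default takes the top four
per group, which carry > 80% of the variance under the emulated conditions.

## Stage-wise differential expression (NB GLM)

Counts are modelled as NB2 (`variance = μ + φμ²`) with a log link and a
`log(library_size)` offset; no TMM-style factor is applied, as library-size
offsets are the simplest defensible normalization when the upstream
normalization is unspecified. Dispersion is estimated by per-transcript
method-of-moments on library-size-rescaled counts
(`φ̂ = max(0, (s² − m̄)/m̄²)`, pooled across groups), trimmed-mean common
value, and a 50/50 shrunk combination used by default; the test then treats
φ as fixed. Fixed-φ likelihood-ratio testing (group model vs. shared-mean
model, 1 df, χ² reference) is stable at n = 3 per group and independently
checkable against a scalar-optimizer oracle. Fitting is single-parameter
Fisher scoring per group, vectorized across transcripts; all-zero
transcripts are excluded with p = 1.

DET calling uses strict thresholds, `|log2FC| > 1` and `q < 0.05`, with
Benjamini–Hochberg families formed per stage across tested transcripts.
Fold changes are experimental over reference (`AA` over `LS` by default).

Measured calibration (seeded Monte Carlo, also recomputed by
`scripts/acceptance.py`): on 2000 null transcripts (φ = 0.1, 3 vs 3) the
q < 0.05 fraction is ≤ 0.05 + 3·SE; planted four-fold effects at mean 500,
φ = 0.05 are detected with sensitivity ≥ 0.7 and median |log2FC − 2| < 0.3.

## Two-group time-course model

`y = β0 + β1 t + β2 t² + β3 z + β4 t z + β5 t² z + ε` with `z = 0` for the
reference group; the degree is fixed at 2. The global F-test compares the
full six-term model with intercept-only; constant responses get p = 1.
Transcripts significant after BH (α = 0.05) undergo backward elimination:
the least-significant candidate term (two-sided t-test p > 0.05) is removed
iteratively, the intercept always kept; a transcript is retained when the
selected model reaches R² ≥ 0.6. Retained fitted profiles (mean fitted
value per group x stage) are z-scored and clustered by average-linkage
agglomerative clustering on 1 − Pearson correlation, cut at k = 9;
transcripts are processed in lexicographic order so distance ties resolve
deterministically.

## Dominant isoforms and switch events

At each group x stage, within each gene having ≥ 2 *quantified* isoforms,
the candidate is the isoform with the highest mean FPKM over replicates
(lexicographic tie-break; ties cannot be dominant). It is dominant when:

* zero rule — every sibling's mean FPKM is exactly 0 and the candidate's is
  ≥ 1 FPKM. The expression floor is this package's guard: without it a
  single stray read in an otherwise silent gene would be declared dominant,
  and two groups' stray reads routinely land on different isoforms,
  manufacturing spurious same-stage disagreements; or
* pairwise tests — the candidate beats *every* sibling with `log2FC > 1`
  and `q < 0.05` (strict) in the NB LRT, with BH across all pairwise tests
  of that group x stage family.

The pairwise test uses `log(library_size × transcript_length)` offsets so
the tested fold change is on the FPKM scale — the same scale on which the
candidate was chosen; cross-group DET tests use library-size offsets only,
where both sides share a length. The statistical procedure behind the
original isoform q-values is unstated; this package documents its own (the
NB LRT above). An optional per-sample mode calls dominance as highest FPKM
with > 2-fold over every sibling, no test.

Cross-group classification (class I takes precedence; the classes are
mutually exclusive per gene): **class I** — the groups' defined dominants
disagree at some stage; **class II** — no same-stage disagreement, but a
defined dominant of one group at one stage differs from a defined dominant
of the other group at another stage. Undefined calls (no dominant) never
count as disagreement. The "differs across any two stages" wording in the
source is ambiguous; the cross-stage-disagreement reading adopted here is
one consistent operational definition and is what the tests verify.
Within-group events are genes with ≥ 2 distinct defined dominants across
stages in one group.

## Integration

Group-specific axis contributors ∩ stage-wise upregulated DETs → candidate
transcripts/genes; an optional gene→term filter keeps genes annotated to a
user-supplied term list (term lists are parameters — no ontology is bundled
or downloaded); the Venn of DET genes, cross-group switch genes and
candidates yields the triple intersection as the headline set.
Over-representation is the upper-tail hypergeometric
`P(X ≥ overlap)` per term with BH across terms, with the expressed gene set
as the default universe. The wet-lab utilities implement
`2^-(corrected − control mean)` per well (group value = arithmetic mean)
and `2^-ΔΔCT`.

The pipeline driver runs normalize → timecourse → per-group axes →
per-stage DET → dominance/switches → integration, writes headered TSVs plus
a JSON manifest (version, parameters, record counts — no timestamps), and
is byte-identical across reruns; any stage failure aborts naming the stage.

## Synthetic data generator

The generator emulates the study conditions: 500 genes (1–4 isoforms,
probabilities 0.35/0.35/0.20/0.10), 2 groups × 7 stages × 3 replicates,
library size ~2×10⁷ with 5% lognormal jitter, NB dispersion φ = 0.05
(typical of bulk RNA-seq biological replicates). Gene-level expected FPKM
follows `exp(b0 + b1 τ + b2 τ²)` on scaled time τ∈[0,1] with
`b0 ~ N(3, 1)` (≈20 FPKM median) and `b1, b2 ~ N(0, 2)`. Expected counts
are `usage × gene FPKM × length/1e3 × library/1e6`; counts are
gamma–Poisson draws (Poisson at φ = 0).

Planted structure: a 10% fraction of genes receives a ±4-fold group effect
at one random stage (DET truth); 60% of unassigned multi-isoform genes get
a stable dominant isoform carrying an exact 0.85 usage share (others split
the remainder equally; background genes draw a single Dirichlet(2) share
vector shared across all cells). Switch events move the heavy share:
class I — one group changes its heavy isoform at a switch stage while the
other does not; class II — both groups share an identical pattern that
changes at one stage (so dominants disagree across stages but never at the
same stage); within-group-only — one group switches while the other has
balanced usage everywhere (no dominant), which is the only way a
within-group switch can avoid creating a cross-group event. A subset of the
class-I genes additionally gets post-hatch AA upregulation, a strong
AA-specific exponential trend (flat in LS), and the synthetic
muscle-development term in the emitted gene→term map; these are the planted
"candidate" genes the integration layer should recover through its
term-based reduction step.

Switch truth is *derived* from the planted dominance map by directly
applying the operational class definitions (an independent, enumerative
implementation inside the generator), so recovery tests compare the caller
against exactly the events the planted pattern implies — including the
within-group events that class I/II planting necessarily creates.

What the generator does not emulate: positional/GC biases, correlated
isoform usage noise (usage shares are deterministic per cell), assembler
quantification uncertainty (counts are per-transcript, not read-assigned),
and gene–gene correlation beyond the shared trajectory family. Passing
recovery tests therefore demonstrates correctness of the inference logic
under the declared noise model, not robustness to quantification artifacts.

## Numerical choices and degenerate inputs

* NB fitting: single-parameter Fisher scoring, step clipped to ±5,
  intercept floored at −30 (handles all-zero groups); LRT clipped at 0.
* OLS via `numpy.linalg.lstsq`; constant responses ⇒ p = 1, R² = 0; perfect
  fits ⇒ p = 0. Stepwise t-tests use pinv-based standard errors.
* Clustering: correlation of a zero-variance profile is treated as 0
  (distance 1); input sorted by transcript id before linkage.
* All rankings break ties lexicographically by transcript id.
* Problem sizes in the shipped tests and the acceptance script (500-gene
  simulations, 2000-transcript null panels, 3 replicates) are chosen to
  estimate every reported rate with comfortable Monte-Carlo error while the
  whole suite completes in well under a minute of compute per component.

## Known limitations

* Exactly two groups; quadratic time polynomial only; no covariates.
* Fixed-dispersion LRT, not profile-likelihood or quasi-likelihood; at
  n = 3 the method-of-moments tagwise dispersion is noisy, hence the shrunk
  default.
* The dominance q-value procedure and the class II definition are this
  package's documented operationalizations of definitions that admit more
  than one reading.
* No particular real dataset's gene lists are reproduced here: real-data
  analyses require the original transcript quantifications as input, which
  this package deliberately does not bundle.
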