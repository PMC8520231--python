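# Methods

This note records the models, conventions and free choices behind each
module — what the code assumes, why defaults are what they are, and what
the synthetic data do and do not establish about real data.

## Identity scoring (`sigscore`)

**Expression filter.** Genes are kept when their mean normalized count
across *all* samples is strictly greater than `min_avg_count`
(default 10). The inequality is strict: a gene averaging exactly 10 is
dropped.

**Signature derivation.** For a two-population reference, per-gene
fold-change A/B plus an unpaired Welch *t*-test. Two significance
cutoffs exist because published signature lists of this kind are quoted
sometimes with a raw-p rule (p < 0.05) and sometimes with an FDR rule
(FDR < 0.01); the default applies both, and either can be disabled by
setting it to `None` in `SignatureThresholds`. FDR is always
Benjamini–Hochberg across the genes tested in one contrast. For
development-staged references (`mode="multi_stage"`), a per-gene one-way
ANOVA across stages must reject *and* the Šidák-adjusted pairwise Welch
comparison of the first vs last stage must reject (adjustment family =
all stage pairs); fold-change is taken first-vs-last. The pairwise
family is a package choice — stage-resolved references are usually
summarised by their extremes, and the Šidák factor makes the pairwise
test conservative with respect to the number of stages.

**Trend concordance.** The baseline for a group's fold-change is a free
parameter because no single choice is canonical: the default is the
pooled mean over all study samples; any named group can be substituted.
Significance is a Welch test of the group's samples against the baseline
samples (against all remaining samples under the pooled default), with
BH FDR over the signature genes. A signature gene is concordant with its
population when FC > 1.5 (strict) and FDR ≤ 0.01; the unspecified window
[0.6667, 1.500] is closed, so a gene at exactly 1.500 is unspecified.
Zero-baseline genes are flagged unspecified with a warning. Genes absent
from the filtered study matrix are reported `not_expressed`, and for
every group the four call classes partition the full listed set.

Note a structural consequence of the elevation-based rule: a group can
only show concordance with population X if the baseline expresses X's
signature genes *less* than the group does. With a pooled baseline over
a study dominated by B-like groups, B-scores of those groups are near
zero (their B genes cannot exceed a baseline they dominate — the
fold-change is capped at 4/3 with three of four groups B-like). Scoring
microglia-likeness of microglia-dominated studies therefore calls for a
monocyte-like (e.g. engrafted) baseline group, as shown in
`examples/identity_scoring.py`.

**Scores.** `score = round(100·n/denominator)`, rounded half away from
zero, denominator = the full defined list size by default
(`listed_total`), because a similarity expressed as "percent of the
defined list" must count non-expressed listed genes in the denominator;
`expressed_only` is available for sensitivity analysis.

**Matrices and clustering.** Pearson correlation over log2(count + 1)
(the transform is a package convention; correlations of strongly
expressed profiles are insensitive to the +1 offset). Clustering is
agglomerative under distance 1 − r with average linkage (complete
selectable); leaves are sorted lexicographically before linkage so tie
handling is deterministic. Zero-variance profiles yield NaN correlations
with a warning and are a hard error for clustering.

## Differential expression (`diffexpr`)

Per-gene Welch + BH contrasts; the DE flag combines the fold-change
window with the configured significance rule. The *radiation-only* set
is pure set algebra: DE in the irradiated-vs-sham contrast on control
diet and *not* DE in the same contrast under inhibitor treatment —
deliberately the weakest reading of "not changed" (no equivalence
testing). The overrepresentation test is a flat hypergeometric
upper-tail per term with BH across terms and fold enrichment
observed/expected; annotation maps carry no ontology hierarchy and no
propagation is attempted.

## Sholl morphometry (`morphometry`)

The circle of radius r pixels is defined as the unit-width annulus
(r − ½)² ≤ dy² + dx² < (r + ½)², ordered by angle; an intersection is a
maximal contiguous foreground run along it, runs across the angular wrap
joined. Radii start at `step` (2 µm) and stop at `r_max` (60 µm) — 30
radii at defaults; radius 0 (the soma) is not counted. Circles leaving
the image are scored on the in-bounds arc and flagged. Two independent
implementations of the same contract exist — a vectorised one and an
exhaustive pure-Python per-pixel scan (`sholl_oracle`) — and the suite
holds them to exact agreement on random cells. The per-radius group
comparison is an unadjusted Welch test per radius (the conventional
reporting for Sholl curves); the output carries an explicit
`p_adjusted = False` column so downstream users cannot miss it.
Pixel-level caveat: profiles are exactly invariant under 90° rotation
and under pixel-size rescaling of the same geometry, except at radii
that coincide with a structure boundary (e.g. the soma edge), where
rasterisation at different resolutions may legitimately differ by one
count.

## Flow synaptometry (`cytometry`)

Size is inferred from forward scatter alone: bead classes (1, 2, 3,
6 µm) are summarised by their median FSC-A, the map interpolates
log-scatter vs log-size piecewise-linearly through those knots (so bead
medians map back to nominal sizes exactly) and extrapolates linearly
with a warning outside the bead range. Non-monotone bead medians are a
hard calibration error. The synaptosome gate is the closed interval
[1 µm, 3 µm] on mapped size, beads excluded; gating is idempotent. MFI
is the arithmetic channel mean. Engulfment positivity defaults to the
99.9th percentile of a negative-control population because no numeric
cutoff is canonical. Spillover compensation and doublet discrimination
are out of scope.

## Behavior (`behavior`)

DI = (T_novel − T_familiar)/(T_novel + T_familiar); antisymmetric under
swapping objects and invariant under common scaling of both times. The
insufficient-exploration exclusion removes trials with total time below
3 s by default — a conventional threshold, exposed as a parameter, with
every removal logged. Dose arithmetic: ppm × 10⁻⁶ × g/day × 1000 mg/g
(1200 ppm × 4 g/day = 4.8 mg/day).

## Shared statistics (`stats`)

Welch t with Satterthwaite df (p = 1 convention when both samples are
constant and equal); BH step-up FDR; two-way ANOVA with interaction
using type-II sums of squares so unbalanced cells (9–12 per group in the
motivating design; error df = N − 4) are handled, coinciding with the
classical decomposition when balanced. Tukey HSD or Dunnett-vs-control
post-hocs operate on the four cell labels; Dunnett critical values come
from the multivariate-t implementation in scipy.

## Synthetic data (`synthdata`)

All generators draw multiplicative log-normal replicate noise with the
mean correction exp(σz − σ²/2), so every generated value has exactly its
configured expectation and the zero-dispersion limit is deterministic.
One global seed expands into named per-stream child seeds; adding a
generator never perturbs another's draws.

* **Reference counts** — log-normal baseline means (median ≈ 100 counts,
  well above the expression floor), `n_sig_a`/`n_sig_b` genes elevated
  `effect_fc`-fold in their population (default 4, a clear but not
  extreme marker-gene separation), 4 replicates per population (the
  replicate count of sorted-population bulk designs is rarely larger),
  dispersion 0.2 by default (≈20% CV, typical of biological replicates);
  property tests that state "low dispersion" use 0.05. `effect_fc = 1`
  is allowed as the explicit null. A staged variant elevates A-genes in
  the first stage and B-genes in the last.
* **Study counts** — group means are exact affine mixtures
  π·A + (1 − π)·B of the reference profiles; the default places the
  engrafted group at π = 0.5 and the three microglia groups at π = 0.
* **Radiation study** — a separate generator plants an up/down response
  (defaults 117/87 genes, 4-fold) only in the irradiated control-diet
  group, groups under inhibitor treatment staying at sham levels.
* **Cell masks** — a filled soma disk (4 µm default) plus evenly spaced
  straight rays a few pixels wide, clipped to the nominal ray length;
  the soma is excluded from the intersection ground truth.
* **Flow events** — monotone log-linear size→scatter map
  (FSC = 1000·size^1.5) with multiplicative noise; only monotonicity
  matters for gating correctness. Beads carry their nominal class;
  100 000 particle events by default.
* **NOR trials** — per-mouse DI = preference + noise, clipped to
  [−1, 1], times back-computed from a clipped-normal total.

**What passing on synthetic data shows — and does not.** The generators
reproduce the *statistical structure* the pipeline assumes (directional
planted effects, affine mixtures, monotone scatter, configured
preferences) with independent log-normal noise per gene and event. Real
data add gene–gene correlation, library-size and batch effects,
count-discreteness at low expression, heavy-tailed scatter populations,
doublets, and segmentation error in masks — none of which are emulated.
Green tests certify the computations and their contracts, not robustness
to those artefacts.

## Problem sizes in the test suite

The suites run on 1 000–2 000-gene matrices, 50 random masks, 10⁵-event
flow tables, a few hundred NOR trials, and 400 null-ANOVA replicates for
type-I-error calibration (3-SE binomial band) — sizes at which every
statistical bound asserted has comfortable margin while the whole suite
stays fast.
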