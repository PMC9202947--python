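# Methods

This note records the statistical conventions `refstab` implements, the
choices made where the methods literature leaves room, and what the
synthetic-data generator does and does not emulate.

## Data model and QC

A Ct table is gene × sample × technical replicate, each sample labelled
with a group (two groups; `egg`/`cortex` are defaults, any labels work)
and a template kind (`total` or `polyA`); analyses run on one template
kind at a time, and total-RNA and poly(A) analyses are independent runs
over disjoint samples. Technical replicates are collapsed by the
arithmetic mean on the Ct scale — Ct is already a log-quantity, so this
is a geometric mean of quantities — and every estimator consumes the
per-sample mean Ct. Replicate spread (max − min) at or above 0.5 cycles
raises a QC flag; flags warn and never exclude, because a complete
gene × sample matrix is an assumption of all five estimators. For the
same reason missing cells are load-time errors, not imputation targets.
Ct values must be finite and positive; the practical instrument range
(~5–40 cycles) is documented but not enforced.

## Amplification efficiency

`fit_standard_curve` regresses mean Ct on log10(relative input) by
ordinary least squares (replicates within a dilution point are averaged
first; a flag fits raw replicates instead). Efficiency is reported in
percent, `E = (10^(−1/slope) − 1)·100`, so 100 % is perfect doubling and
the quantity base used elsewhere is `1 + E/100`. A slope ≥ 0 is rejected
as an invalid curve. The acceptance window is the closed interval
[90, 110] % — boundary values pass — and is configurable. Regressing Ct
on log input (not the reverse) is the universal standard-curve
convention.

## Relative quantities

All ratio-based estimators work on
`Q_{g,s} = B_g^(min_s Ct_{g,s} − Ct_{g,s})`, which puts each gene's
most-abundant sample at Q = 1. The base defaults to 2 for every gene;
per-gene efficiency-corrected bases are available but off by default,
since published stability analyses in this setting use base 2.
Rescaling by the per-gene minimum is a per-gene additive constant on the
log scale and cancels in every dispersion, so it affects nothing but
numerical convenience.

## The five estimators

All scores are "ascending is better"; every SD uses the n − 1
denominator (the convention of the methods' reference tools); rank ties
break alphabetically so results are deterministic.

**BestKeeper.** Score = sample SD of per-sample mean Ct; CV% =
100·SD/mean Ct is reported alongside, and SD ≤ 1 cycle marks a gene
acceptable. The original BestKeeper spreadsheet's dispersion — mean
absolute deviation around the geometric mean Ct — is available as
`variant="mad_geo"`; which of the two a given published analysis used is
often unstated, so both are kept.

**CV.** Score = 100·SD(Q)/mean(Q) on the linear quantity scale. Note
this is the only estimator besides BestKeeper that reacts to per-sample
loading shifts, since Q is not a ratio between genes.

**ΔCt (comparative).** For every unordered gene pair, the SD over
samples of the per-sample Ct difference; a gene's score is the mean over
the pairs that contain it. Requires ≥ 3 genes.

**geNorm.** `V_jk = SD_s(log2 Q_j − log2 Q_k)`,
`M_j = mean_{k≠j} V_jk`; the gene with the largest M is removed and M
recomputed until two genes remain. Those two are mutually unrankable —
the algorithm's own property — so they occupy ranking positions 1–2 (in
alphabetical order) and both carry their mutual V as score; other genes
carry the M from their elimination round. Ties at the maximum M remove
the lexicographically later gene id. M ≤ 0.5 flags a usable reference.
Removing the highest-M gene can never raise the survivors' mean M (a
consequence of the max exceeding the mean); the test suite asserts this
per round. The pairwise-variation curve uses
`NF_{n,s} = geometric mean of Q` of the n top-ranked genes;
`V_{n/n+1} = SD_s log2(NF_n/NF_{n+1})`, and the recommended number of
reference genes is the smallest n with V below 0.15 (all k candidates
if none qualifies).

**NormFinder.** On `y = log2 Q`, per group g with n_g samples and k
genes: residuals are double-centred within the group,
`z = y − gene mean − sample mean + group mean`;
`s²_ig = Σ_j z²/(n_g − 1)` and the bias-corrected intragroup variance is

    σ̂²_ig = (k/(k−2)) · (s²_ig − s̄²_g/(k−1)),  truncated at 0,

which follows from the fact that subtracting the sample mean mixes 1/k
of every gene's noise into each residual. The intergroup difference
`d_ig` is the gene-centred group mean minus the gene-centred grand mean
(summing to zero over genes within a group). With
`var(d̂_ig) = σ̂²_ig/n_g` and the across-gene spread
`γ² = Σ d̂²/(G(k−1)) − mean(var(d̂))` (truncated at 0), d is shrunk by
`γ²/(γ² + var(d̂))` and the stability value is

    ρ_ig = |d̃_ig| + sqrt(var(d̂_ig)·γ²/(γ² + var(d̂_ig))),

averaged over the two groups. When γ̂² = 0 the data carry no detectable
intergroup component and the shrinkage formula would tie every gene at
zero; the implementation then falls back to `ρ_ig = sqrt(var(d̂_ig))`,
i.e. ranks by intragroup variance alone, which is the γ → 0 limit of
the model's information content. The best two-gene combination
minimises the same criterion applied to the pair average (d averaged,
variance quartered). Exactly two groups with ≥ 2 samples each are
required; the pair criterion is two-group by construction.

## Rank aggregation

The methods × positions matrix mirrors the usual summary table in
reference-gene studies, with geNorm's pair in a merged "1–2" cell. The
consensus ordering — geometric mean of per-method ranks, pair members
counted as 1.5 — is this package's explicit formalization of the usual
qualitative "top-3 across methods" reading, and is labelled as such in
output. It is invariant to method order and reduces to any ranking all
methods agree on.

## Comparative Ct (2^−ΔΔCt)

`ΔCt_s = Ct_goi,s − mean(Ct of normalizers in s)`; averaging normalizer
Ct arithmetically equals the geometric mean of normalizer quantities,
the recommended multi-reference normalization factor.
`ΔΔCt_s = ΔCt_s − mean ΔCt over the calibrator group`, per-sample fold
`2^−ΔΔCt_s`, group fold `2^−(group mean ΔΔCt)` (a geometric-style mean;
per-sample folds are reported so other summaries can be formed), with
`fold_lo/hi = 2^−(mean ± SD of ΔCt)` as the dispersion band. The
calibrator group's fold is 1 by construction; swapping the calibrator
inverts group folds; adding any per-sample constant to all genes (a
loading shift) cancels exactly. The group comparison is a two-tailed
unpaired t-test on ΔCt — the log-scale, approximately normal quantity —
with pooled variance by default and Welch as an option; testing fold
values instead would tangle the inference with the calibrator choice.
Pfaffl-style efficiency-corrected ΔΔCt is available via per-gene
efficiencies and off by default.

## FPKM candidate screens

Reference candidates: `min(FPKM_A, FPKM_B) ≥ min_fpkm` (default 1000)
and `max(A/B, B/A) ≤ max_fold` (default 1.5). Gene-of-interest
candidates: both FPKM > 0.5 and `B/A ≥ min_fold` (default 2), sorted by
fold. These fold thresholds are explicit proxies for a replicate-level
differential-expression call, which cannot be reproduced from a
two-column FPKM table; they are configurable and documented as proxies.
The abundance floor makes pseudocounts unnecessary. The built-in
egg/cortex panel (four transcripts with their published FPKM values)
exercises both screens in examples and the acceptance script.

## Synthetic data

The Ct generator draws

    Ct_{g,s,r} = μ_g + δ_g·[s ∈ group B] + L_s + b_{g,s} + τ_{g,s,r}

with loading shifts `L_s ~ N(0, σ_load²)` shared across genes (they
cancel in every ratio-based statistic and in ΔΔCt), biological noise
`b ~ N(0, σ_bio,g²)` independent per gene × sample, and technical noise
`τ ~ N(0, σ_tech²)` per replicate. Gaussian noise on the Ct scale is
the standard qPCR error model. A group shift of δ cycles is a quantity
fold of 2^−δ in group B. Defaults: σ_tech = 0.15 cycles (keeps
triplicate spreads under the 0.5-cycle QC bound in ≈ 95 % of cells),
σ_load = 0.05 (equal-input loading), 3 + 3 samples, triplicates. Every
simulation returns its ground truth (per-gene fold, designed most- and
least-stable genes), and a fixed seed gives bit-identical output.

**The `sea-urchin-7gene` preset.** Baseline means follow the real
panel's abundance ordering (28S most abundant at ~15.6 cycles, GAPDH
least at ~28). The designed most-stable gene, Ubb, has zero group shift
and the smallest biological SD (0.03 cycles). The other candidates
carry egg-vs-cortex shifts of 0.6–3.5 cycles, alternating in sign and
summing to zero, with biological SDs of 0.10–0.60 cycles; 28S combines
the largest shift with the largest noise (designed least stable, with a
realized Ct range of ≈ 5 cycles as rRNA shows in real total-RNA data),
and Ebr1 is a mildly shifted, low-noise partner so that a genuinely
co-varying best *pair* exists for the pair-based methods. The gene of
interest, Daglb-2, is 2-fold enriched in cortices (δ = −1).

This layout is deliberate. With three biological replicates per group a
sample SD has five degrees of freedom, so rankings that differ only
through noise SDs are unstable: chance low-variance draws and chance
between-gene correlations flip pairwise comparisons with probabilities
in the several-percent range, and geNorm in particular will adopt any
pair of genes whose draws happen to co-vary. Encoding instability
mainly as *group shifts* — which are nearly deterministic contrasts at
this sample size — makes the designed ground truth identifiable by all
five estimators in ≈ 96–100 % of seeded experiments, which is what a
ground-truth benchmark needs. The shifts sum to zero so that the
designed stable gene sits at the panel's consensus (NormFinder measures
deviation from it), and they are mutually separated so no two unstable
genes form a spuriously co-regulated pair. The price is that the preset
exaggerates between-gene heterogeneity relative to a well-chosen real
candidate panel; it emulates the *structure* of an egg/cortex
comparison (composition shifts between compartments are large — rRNA
alone shifts severalfold between total-RNA samples of eggs and
cortices), not the modest noise levels of a panel that has already been
pre-screened for stability.

What the generator does not emulate: amplification-curve artefacts
(the model starts at Ct values), inter-run batch effects, non-Gaussian
outliers, replicate-count imbalance, and transcript-level correlation
beyond the shared loading shift. Passing the simulation-based tests
therefore demonstrates correctness and power of the estimators under
the additive Gaussian model, not robustness to instrument pathology.

## Numerical conventions and degenerate inputs

Sample SDs use ddof = 1 throughout. geNorm M-ties remove the
lexicographically later gene; ranking ties sort alphabetically.
NormFinder truncates negative variance estimates and γ̂² at zero.
Constant tables give all-zero scores for every estimator (for
NormFinder through the γ = 0 fallback). Fewer than three genes,
single-sample tables, single-sample groups, more than two groups for
NormFinder, rising standard curves and sub-three-point dilution series
are rejected with descriptive errors rather than propagating NaNs.

## Problem sizes

The verification suite and the acceptance script run at the study's own
scale — 7 + 1 genes, 3 + 3 samples, technical triplicates — using 200
seeded experiments for recovery rates and Monte-Carlo intervals, 100
seeds for noisy efficiency recovery, and 3–7 gene × 4–12 sample random
matrices for oracle-equivalence and invariance checks; the whole suite
completes in well under a minute on one core.

## Known limitations

* NormFinder's published description leaves details of its sampling
  variance `var(d̂)` to its supplementary material; this implementation
  uses `σ̂²_ig/n_g` and documents the γ = 0 fallback explicitly. Scores
  are therefore comparable between runs of this package, and the
  ranking logic matches the published estimator, but third-party
  NormFinder ports may differ in the last decimals of ρ.
* The candidate screens are threshold filters, not a differential
  expression model; with replicate-level counts a dedicated DE tool is
  the right instrument.
* More than two groups are out of scope throughout (NormFinder's pair
  criterion and the egg/cortex design are two-group).
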