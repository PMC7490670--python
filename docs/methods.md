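# Methods

This note documents the statistical procedures implemented in `refstab`,
their assumptions, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and known limitations.

## Data model and missing-data policy

A dataset is a genes × samples matrix of threshold cycles (Ct; the crossing
point Cp is treated as the same quantity) with per-sample metadata (group,
tissue, time point) and a per-gene role (candidate reference vs target).
Ct is a negative log2 expression scale: one cycle ≈ one doubling at ideal
amplification efficiency E = 2. Validation requires every present Ct to lie
in (0, 50) — headroom around standard 40–45-cycle instruments — and warns
(without rejecting) above 35 cycles, the common low-expression convention.
At least 2 genes and 3 samples are required.

All stability analyses and ΔΔCt normalization run on **complete cases over
the gene panel in use**: the BestKeeper index and GeNorm normalization
factors are sample-wise products across genes, so pairwise-complete
handling would mix incompatible sample sets. Dropped sample ids are logged.
One Ct per (gene, sample) is stored; technical replicates are assumed
averaged upstream.

## GeNorm

Relative quantities are `Q = E^(minCt_gene − Ct)`, so each gene's highest
expressor has Q = 1 (the conventional input scaling; M is invariant to it,
and normalization factors change only by a constant that cancels in
log-ratios). Efficiency defaults to 2.0 — a single global value, no
per-assay correction — and is accepted in [1.6, 2.2].

For genes j, k the pairwise variation `V_jk` is the standard deviation over
samples of `log2(Q_j/Q_k)`; `M_j` is the mean of `V_jk` over partners.
Because a shared per-sample shift cancels in every ratio, M responds only
to genes that move *relative to* the panel. All standard deviations in the
package use the n−1 denominator; the historical spreadsheet's convention is
not documented anywhere authoritative, so the statistical default is used
throughout and stated here.

Stepwise exclusion recomputes M on the surviving panel and removes the
largest-M gene (ties broken by input order, for determinism) until two
remain; those two share their final M by construction and tie at fractional
rank 1.5. Both the per-gene M at exclusion (`M_final`) and the single-pass
full-panel M are reported, since published tables do not always say which
variant they show.

Suitability thresholds: M < 0.5 for homogeneous sample panels, M < 1.5 for
heterogeneous ones (the default here, matching multi-condition designs).
The threshold used is recorded in the result.

The pairwise-variation curve uses nested normalization factors
`NF_n = geometric mean of Q over the top-n genes`;
`V_n/n+1 = SD[log2(NF_n/NF_{n+1})]`. The optimal count is the smallest n
with `V_n/n+1 < 0.15`, comparison strict on unrounded values; an
`cutoff_inclusive` option admits V exactly at the cutoff, since published
analyses sometimes accept a rounded boundary value. If no n passes, all
genes are kept and a warning is raised.

## NormFinder

Ct enters directly as log2-scale expression with no sign flip: every
statistic below depends only on variances and centered deviations, which
are sign-invariant. Genes are first centered on their grand means. Per
group g the two-way additive fit (gene + sample effects) gives residuals
`r = y − rowmean − colmean + grand`; the intra-group variance is
`s²_ig = L/(L−1) · Σ_j r²_igj / (n_g−1)` — the L/(L−1) factor compensates
the sum-to-zero constraint across the L genes — floored at zero. The
inter-group deviation is `d̂_ig = ȳ_ig − ȳ_g` (zero-sum over genes per
group), with sampling variance
`v_ig = ((L−1)/L)² s²_ig/n_g + (1/L²) Σ_{i'≠i} s²_{i'g}/n_g`.

The common inter-group variance is estimated by method of moments with
G·(L−1) effective degrees of freedom,
`γ̂² = max(0, Σ d̂²/(G(L−1)) − mean v)`, and deviations are shrunk,
`d̃ = d̂·γ̂²/(γ̂²+v)`. The stability value is
`sv_i = mean_g [ |d̃_ig| + √(γ̂² v_ig/(γ̂²+v_ig)) ]`; lower is more stable.
When γ̂² = 0 (no detectable inter-group signal) all sv collapse to zero;
the ranking then falls back to the mean sampling SD `mean_g √v_ig` with a
warning, so a usable ordering is always produced. With a single group, sv
is the residual SD `√s²_i` from the same two-way fit on the whole panel.

Grouped mode requires ≥ 2 groups with ≥ 2 samples each and ≥ 3 genes.
Bit-for-bit parity with the original Excel macro is *not* claimed — its
small-sample conventions are not published — the contract is the estimator
above plus the property suite (zero-sum constraints, least-squares
equivalence of s², invariances, planted-effect recovery).

## BestKeeper

The per-sample index is the geometric mean of the candidate panel's Ct
values (targets excluded). Per gene: geometric/arithmetic mean, min, max,
SD, CV (% of the arithmetic mean), and the Pearson correlation r with the
index, with a two-sided p from the t distribution on n−2 df. `sd` defaults
to the sample standard deviation about the arithmetic mean; because
reimplementations of the original tool differ, a `mad-geomean` variant
(mean absolute deviation about the geometric mean) is provided and off by
default. A zero-variance gene has undefined r: it is flagged, not raised,
and sorts after all defined-r genes (input order among themselves). Both
rank orders (descending r, ascending SD) are emitted.

## Comparative delta-Ct and consensus

The comparative delta-Ct stability of gene i is the mean over partners k of
the SD of `Ct_i − Ct_k` — algebraically the full-panel GeNorm M at E = 2,
an identity the test suite checks to 1e−12 (the two are still computed by
separate code paths).

The rank table holds fractional average ranks per method; BestKeeper
contributes its two printed statistics (r and SD) as separate columns. The
**final rank** is the re-ranked sum of the NormFinder, GeNorm and two
BestKeeper rank columns — summing both BestKeeper columns mirrors the two
statistics such summaries typically print; the set is configurable. The
**RefFinder-style score** is the geometric mean of the delta-Ct,
NormFinder, GeNorm and one BestKeeper rank (default the SD rank,
configurable); it is labelled "-style" because the web tool's internal
conventions (its BestKeeper column, grouped vs ungrouped NormFinder) are
not published. The recommended set is the top `optimal_n` genes by final
rank, ties broken by RefFinder-style score then input order; genes failing
the GeNorm suitability flag are kept with a warning rather than dropped,
because the V curve, not the flag, sizes the set.

## ΔΔCt normalization and group tests

With several references the per-sample reference aggregate is the
arithmetic mean of their Ct — the geometric mean of their quantities, the
standard multi-gene convention. `ΔCt = Ct_target − aggregate`; `ΔΔCt`
centers ΔCt on the **arithmetic mean** of the control group's ΔCt (not the
median), which makes the geometric mean of `rq = E^(−ΔΔCt)` over control
samples exactly 1. The alternative reading — normalize per individual
reference, then average the relative quantities — is available as
`aggregate="rq_mean"`.

Each non-control group is compared with control by a two-sided
Mann–Whitney U test, reporting `U = min(U_a, U_b)`. The exact null
distribution is used when both samples have ≤ 8 observations and no ties;
otherwise the normal approximation with tie and continuity corrections.
No multiple-testing correction is applied by default (per-group tests vs
control at p < 0.05 is the workflow this mirrors). A Shapiro–Wilk check is
available purely as annotation; the pipeline stays nonparametric
regardless of its outcome. Constant input yields an undefined-W flag.

## Synthetic-data generator

`Ct_is = baseline_i + shift_s + effect_ig + ε_is`, with a shared per-sample
technical shift `N(0, technical_shift_sd²)` (RNA input / RT variability —
the component every stability statistic must cancel, and the key structure
the invariance tests exploit), Gaussian gene-level noise on the Ct scale
(the homoscedastic log-scale assumption underlying all four methods), and
deterministic group effects (a fold change F is a Ct shift of −log2 F).
Missing cells, off by default, are masked completely at random. Randomness
comes from `numpy.random.default_rng` (PCG64), so a seed pins the dataset.

Defaults encode a four-arm rodent multi-trauma design: groups control /
Fx (fracture) / TBI (brain injury) / TBI+Fx, n = 6 per group and time
point, five routinely used candidate housekeepers with baselines 17–24
cycles, noise SD 0.3, technical shift SD 0.5, and a planted dysregulation
of 1.5 cycles in the insult-carrying groups (*Actb*-like in
fracture groups for the bone preset; *B2m*-like in TBI groups for the
hypothalamus preset). The WAT preset carries ten candidates with a mildly
unstable *Gapdh*-like gene (0.4–0.9-cycle group shifts, elevated noise);
the neutral preset has no planted effects and noise SD 0.1. Magnitudes are
stylized — chosen to be realistic for tissue qPCR panels — not fitted to
any published variance components.

What the generator does **not** emulate: amplification-curve shape and
per-assay efficiency differences, plate/batch effects, heteroscedastic
noise at high Ct, informative missingness, and correlated biological
regulation among candidates. Passing tests therefore demonstrate that the
estimators recover the structure they model — not that any particular real
tissue behaves this way.

## Numerical choices and degenerate inputs

* Standard deviations: ddof = 1 everywhere.
* GeNorm exclusion ties and all rank ties: input order / fractional
  average ranks, for determinism.
* Negative variance estimates (NormFinder s², γ̂²) floored at 0.
* Zero-variance genes: BestKeeper flags r undefined; GeNorm/delta-Ct
  return M = 0 contributions (a constant difference has SD 0).
* Exact Mann–Whitney switches to the asymptotic path in the presence of
  any tie, at any n.
* Validation errors name the offending gene/sample where possible.

## Problem sizes used in the self-checks

Oracle equivalences run on 100 random matrices of 4–8 genes × 6–30
samples; recovery rates use 200 seeded draws of the 4 × 6 design;
Mann–Whitney exactness is checked exhaustively over all achievable U
values for all size pairs up to 7 vs 7, and null calibration over 2000
draws at 6 vs 6. These sizes make the whole evaluation run in seconds
while leaving the binomial noise on a 200-draw rate at about ±3%.

## Known limitations

* No efficiency estimation from dilution series; E is a single global
  constant.
* No inter-run calibration, plate-layout handling, or instrument-file
  ingestion.
* NormFinder confidence intervals and REML-based mixed-model variants are
  out of scope.
* Numeric parity with the original GeNorm/NormFinder/BestKeeper
  spreadsheets and the RefFinder web service is not claimed; agreement is
  at the level of the documented estimators and rankings.
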