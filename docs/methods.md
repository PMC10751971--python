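# Methods

## Scope and model

`cytonet` implements a correlation-network analysis for multiplex
cytokine panels measured on conditioned media from mechanically loaded
intervertebral-disc (functional spine unit) organ cultures. The study
design it mirrors has two arms: a loading arm (unloaded control, dynamic
compression, static compression, each compression mode with and without
the TRPV4 antagonist GSK205) sampled at one analysis timepoint, and a
pharmacological activation arm (repeated TRPV4 agonist exposure, sampled
at day 3 and day 7). Each sample is a 44-analyte panel of concentrations
in pg/mL with a per-analyte lower limit of detection (LLOD) in the
assay's printed 0.3–30.6 pg/mL sensitivity range.

Within one condition the analysis is:

1. **Detection filter.** An analyte censored (below LLOD) in more than
   `max_censored_fraction` (default 0.5) of the condition's samples is
   excluded; surviving censored cells are substituted by LLOD/√2 by
   default. Filtering is per condition, so an analyte can be a node in
   one condition's network and absent from another's.
2. **Correlation.** Sample Pearson correlation for every unordered
   analyte pair.
3. **Thresholding.** An edge wherever |r| strictly exceeds the
   condition's cutoff — 0.9 ("very strong") for the compression-arm
   conditions, 0.7 ("strong") for the activation arm — with the sign of
   r kept as an edge attribute, so inverse relationships (e.g. LIF and
   IL-16 vs VEGFA in unloaded tissue) stay visible.
4. **Centrality.** Eigenvector centrality C_λ of the binary (unsigned)
   adjacency: the leading eigenvector, made non-negative
   (Perron–Frobenius) and normalized by its maximum entry. C_λ lives on
   [0, 1]; isolated nodes score exactly 0 and the best-connected node
   scores exactly 1 (a complete graph scores 1 everywhere).

Conditions are compared edge-by-edge under canonical analyte naming
(chemokines by CCL/CXCL name): edges present in both networks are
**conserved** (with a **sign-flipped** subset when the correlation sign
differs), edges only in the second are **gained**, only in the first
**lost**, and overlap is summarized by the Jaccard index of edge sets
(defined as 1 for two empty networks — identical emptiness). A
sign-flipped edge is reported as conserved-with-flip; whether that counts
as "preserved" is left to the caller. Edge identity ignores r magnitude;
the strength delta is reported separately.

Per-analyte group statistics mirror the figure-level comparisons:
two-sample pooled t-tests, one-way ANOVA, two-way ANOVA with
interaction, and Tukey(-Kramer) HSD post-hoc contrasts from the pooled
within-group mean square, flagged at α = 0.05.

## Synthetic panel generator

The study's raw tables are not deposited, so the generator stands in for
them. Concentrations are multivariate log-normal: for each condition,
log10 concentrations are drawn from a multivariate normal with
per-analyte means and SDs and a condition-specific correlation matrix,
exponentiated to pg/mL, and left-censored at the LLOD (censored cells
are recorded *at* the LLOD and flagged, keeping the table rectangular;
downstream substitution is the preprocessing policy's job). A
log-normal is used because immunoassay concentrations are positive and
right-skewed, and it makes the Pearson structure on the log scale
directly controllable.

Defaults (one choice, stated here, not tuned per analysis):

| parameter | default | rationale |
| --- | --- | --- |
| baseline log10 mean | 2.0 (100 pg/mL) | mid-assay working range |
| log10 SD | 0.3 (≈2-fold spread) | typical biological CV for secreted cytokines |
| planted block ρ | 0.95 | must survive an \|r\| > 0.9 cutoff at n = 6–10 with high probability |
| fold change up / down | 3× / 0.33× | "elevated"/"decreased" bars without published effect sizes |
| LLODs | log-spaced 0.3–30.6 pg/mL in panel order | per-analyte sensitivities live in an external assay protocol; only the range is printed |
| group sizes | control 6, dynamic 6, dynamic+GSK205 6, static 6, static+GSK205 7, activation day3/day7 10 | the study's reported ns |

Condition templates plant the qualitative structure as signed
correlation blocks (within a block ρ_ij = s_i·s_j·0.95): the control
condition has an IL-6-family hub block (IL-6, LIF, IL-11, IL-1β)
intercorrelated with CXCL1, CXCL2, GCSF and GMCSF, with IL-16 in the
block and VEGFA anti-correlated with all of it; dynamic compression
drops IL-6 from the block and adds IL-1α and CXCL5 (whose means are
elevated, along with CXCL1 and IL-1β); the static template equals
control with VEGFA's sign reversed (the LIF/IL-16–VEGFA inversion
becomes positive); the inhibitor templates keep only the pairs the
study describes as maintained (LIF:GCSF and CCL4:GMCSF under dynamic
inhibition; positive LIF/IL-6–VEGFA with a weakened LIF–IL-6 link and
an IL-16–CCL22 pair under static inhibition); the activation templates
pair IL-16:CCL17 and IL-15:IL-12p70 at both timepoints, add
VEGFA-linked and day-7-specific pairs, and shift the IL-6-family means
up and the monocyte/T-cell chemokine means down. Because the static
template is defined as "control with VEGFA reversed", the whole block's
VEGFA edges flip, not only LIF's and IL-16's; and the dynamic and
static templates share the control backbone, so their overlap is larger
than the study's near-disjoint drawn networks.

Sign-consistent blocks are rank-one patterns and hence positive
semidefinite by construction; templates with extra hand-planted entries
(static+GSK205's {LIF, IL-6, VEGFA} triangle) are indefinite and are
projected to the nearest valid correlation matrix (Higham alternating
projections, via `nearest_valid_correlation`) before sampling; the
projection's maximum entry-wise change is reported and surfaced as a
pipeline warning. The sampler factorizes the correlation by
eigen-decomposition with negative eigenvalues clipped at zero, which
handles singular targets exactly: two analytes planted at ρ = 1 with
equal moments yield bit-identical columns.

Seeding: one master seed; each group draws from a child seed derived
from the group's position (`SeedSequence(seed, spawn_key=(i,))`), so
adding a condition leaves earlier conditions' draws unchanged. Two
single-group configs built from the *same* master seed share their
latent draws; cross-condition simulations should therefore merge
templates into one multi-group config to get independent samples.

What the generator does **not** emulate: plate/batch effects, standard
curves, bead-count failures, heteroscedastic assay noise, outliers, or
any dependence between censoring and the correlation structure beyond
what the marginals imply. Passing recovery tests therefore demonstrate
that the pipeline's inference chain is correct and calibrated under the
generative model, not that the thresholds are optimal for real Luminex
data.

## Correlation scale: raw vs log10

The library computes Pearson correlations on raw pg/mL concentrations
by default, with a log10 pre-transform available everywhere
(`log10_transform=True`). The recovery analyses, the analysis scripts,
and the acceptance script use the log10 scale, for a structural reason:
the generator's planted correlations live on the log scale, and the
Pearson correlation of log-normal variables is attenuated on the raw
scale — severely so for negative correlations, whose raw-scale
magnitude is bounded. At σ_log10 = 0.3, a planted log-scale ρ = −0.95
yields a raw-scale correlation of only about −0.60 and can never cross
an |r| > 0.9 cutoff, while ρ = +0.95 attenuates mildly to ≈ 0.94.
Correlating log10 concentrations recovers the planted structure
symmetrically in sign and is standard practice for right-skewed assay
data.

## Numerical and design choices

- **Centrality** is computed by dense symmetric eigen-decomposition
  (deterministic; no iteration tolerance). In a disconnected graph the
  global leading eigenvector localizes on the spectrally dominant
  component and other components score ≈ 0 — documented behavior, with
  a `per_component=True` mode that scores each connected component
  independently. A numerically degenerate top eigenvalue (e.g. two
  disjoint identical components) attaches a warning; the solver's
  deterministic output is used.
- **Edges carry no p-values**: thresholding is on magnitude only,
  matching the analysis being reproduced; the null tail of r is instead
  used as a *calibration check* (at n = 6, P(|r| > 0.9) = 0.0145 under
  independence, from the density ∝ (1 − r²)^((n−4)/2)).
- **Tukey HSD** uses the studentized-range distribution with the
  Tukey–Kramer standard error; for two groups this reduces to the
  pooled t-test exactly (q = t√2), which scipy's distribution reproduces
  to ~1e-14.
- **Two-way ANOVA** uses Type II sums of squares (OLS fit), which
  coincides with the classical partition for balanced designs and is a
  deliberate choice for the unbalanced activation design (n = 6 vehicle
  vs n = 10 agonist). Degenerate limits: an effect with zero sum of
  squares gets F = 0, p = 1 (noise-free additive data has interaction
  F = 0); a positive effect over a zero residual gets the perfect
  separation limit F = ∞, p = 0; fully constant data is an error.
- **No multiple-testing correction by default** across the 44-analyte
  panel, matching raw per-analyte reporting; a Benjamini–Hochberg
  column is opt-in.
- **Detection-filter default** `max_censored_fraction = 0.5`: an
  analyte measurable in a majority of samples carries usable
  correlation signal; 0.0 reproduces a strict "any censoring excludes"
  reading. Substitution default LLOD/√2, the standard left-censoring
  replacement for log-normal-ish data; `at_llod` gives the rawest
  reading. Whether exclusion should be per condition or panel-wide is
  not specified by the source analysis; per condition is the default,
  `panel_wide=True` the alternative.
- **Thresholds per condition**: the methods text assigns r > 0.7 to the
  activation networks while the corresponding figure caption says
  r > 0.9; the pipeline follows the methods text, parameterizes r_min
  per condition, and records the discrepancy as a manifest warning.
- **CSV round-trips are bit-exact**: floats are written as `%.17g` and
  parsed with round-trip precision, so write∘read is the identity and
  report bundles are byte-reproducible from config + seed alone (the
  manifest echoes both; the output directory is excluded as a
  non-scientific parameter).

## Problem sizes

The test suite and acceptance script use: 1000 random 8×10 matrices for
the correlation oracle; 200 random graphs (≤ 44 nodes) against a
power-iteration centrality oracle (graphs with a near-degenerate top
eigenvalue are excluded — ties are solver-determined); 10 000
independent pairs at n = 6 for null-edge calibration; 200 seeds at
n = 8 for planted-block recovery against a brute-force re-simulation;
50 seeds at n = 8 for the control-vs-static LIF–VEGFA sign-flip rate
(bivariate detection oracle: P(|r| > 0.9 | ρ = 0.95, n = 8) ≈ 0.857,
so both-network detection ≈ 0.73); 1000 simulations for p-value
uniformity; and two full seven-condition runs for byte determinism.

## Limitations

- Correlation networks at n = 6–10 are noisy; the planted-recovery
  rates above (≈86–88% of ρ = 0.95 edges at n = 8, with ≈0.2% spurious
  pairs) quantify exactly how noisy under the model.
- Left-censoring is handled by substitution, not by a likelihood-based
  (Tobit) model; heavy censoring biases correlations toward zero.
- No statistical test is attached to network differences; conserved /
  gained / lost / flipped sets are descriptive, as in the analysis being
  reproduced.
- The generator's planted effect sizes (ρ = 0.95, 3× folds) are
  stand-ins for unpublished values; absolute recovery rates depend on
  them.
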