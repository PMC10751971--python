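# cytonet

Signed Pearson correlation networks, eigenvector centrality, and
differential network comparison for multiplex cytokine panels — with a
synthetic panel generator for end-to-end validation.

## The problem

Mechanically loaded intervertebral-disc organ cultures secrete dozens of
cytokines and chemokines into their media. Multiplex bead assays measure
a 44-analyte panel per sample, and the scientific questions are
relational: which cytokines rise and fall *together* under dynamic vs
static compression, what happens to those relationships when the
mechanosensitive ion channel TRPV4 is inhibited or activated, and which
analytes sit at the hub of each condition's co-secretion network. This
package turns wide concentration tables (samples × analytes, pg/mL, with
per-analyte detection limits) into per-condition networks and their
differences, for researchers analyzing conditioned-media or serum panel
data with small group sizes.

## The method

For each condition with samples *x* and analytes *j, k*:

- **Filter:** analytes below the lower limit of detection (LLOD) in more
  than half the condition's samples are excluded; remaining censored
  cells are substituted by LLOD/√2.
- **Network:** compute the sample Pearson correlation r_jk for every
  pair; draw an edge when |r_jk| > r_min (0.9 for the compression-arm
  conditions, 0.7 for TRPV4-activation timepoints), keeping the sign of
  r on the edge so inverse relationships stay visible.
- **Centrality:** score each node by eigenvector centrality C_λ — the
  leading eigenvector of the binary adjacency, max-normalized to [0, 1],
  where 0 means no connections and 1 the best-connected analyte.
- **Compare:** two condition networks are diffed by edge identity into
  conserved / gained / lost sets, with sign-flipped edges (present in
  both with opposite sign) called out and overlap summarized by the
  Jaccard index.
- **Group statistics:** per-analyte t-tests, one-/two-way ANOVA and
  Tukey HSD contrasts at α = 0.05.

Because the study it emulates deposits no raw tables, the
`cytonet.synthetic` module generates panels with the same statistical
skeleton — multivariate log-normal concentrations, planted
condition-specific correlation blocks (e.g. an IL-6/LIF/IL-11/IL-1β hub
block whose LIF–VEGFA and IL-16–VEGFA edges are negative in the control
condition and positive under static compression), fold-change effects,
and LLOD censoring — so every stage is testable end to end. See
`docs/methods.md` for the model, defaults, and design choices.

## Worked example

The analysis is organized as numbered drivers over the library:

```sh
python analysis/01_simulate_panels.py --seed 1   # panel CSVs -> results/panels/
python analysis/02_build_networks.py             # networks   -> results/networks/
python analysis/03_compare_conditions.py         # diffs      -> results/diffs/
python analysis/04_group_statistics.py           # stats      -> results/stats/
```

With seed 1 the comparison step prints (abridged):

```
control vs dynamic: conserved=32 gained=26 lost=38 flipped=0 jaccard=0.333
    LIF neighborhood: gained [CXCL5–LIF, IL-1α–LIF]; lost [CXCL2–LIF, GCSF–LIF, IL-10–LIF, IL-6–LIF]
control vs static: conserved=45 gained=19 lost=25 flipped=9 jaccard=0.506
    sign flip: IL-16–VEGFA (r -0.97 -> +1.00)
    sign flip: LIF–VEGFA (r -0.99 -> +0.99)
activation_day3 vs activation_day7: conserved=2 gained=21 lost=28 flipped=0 jaccard=0.039
```

Reading this: under dynamic loading LIF gains edges to IL-1α and CXCL5
and loses its IL-6 edge; static loading reverses the inverse LIF/IL-16
vs VEGFA relationships of the unloaded control to positive (9 VEGFA
edges flip, LIF–VEGFA and IL-16–VEGFA among them); and only the two
planted pairs (IL-16:CCL17, IL-15:IL-12p70) survive both activation
timepoints. These recover exactly the planted structure of the
templates.

The same pipeline runs in one shot (`cytonet run --config cfg.yaml`),
and the `simulate` / `network` / `compare` / `stats` subcommands expose
the individual stages; real panel data enters as the same three-CSV
bundle (`panel_data.csv`, `panel_analytes.csv`, optional
`panel_censored.csv`).

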