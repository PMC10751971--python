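"""Per-analyte group statistics across the panel.

Runs a one-way ANOVA over the compression-arm conditions and a two-sample
t-test between the two TRPV4-activation timepoints for every analyte
(log10 concentrations), flagging p < 0.05 without multiple-testing
correction; tables land under results/stats/.
"""

import argparse
from pathlib import Path

from cytonet import StatDesign, panel_sweep, read_panel
from cytonet.panel_io import PanelFileBundle


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--panels", type=Path, default=Path("results/panels"))
    parser.add_argument("--out", type=Path, default=Path("results/stats"))
    args = parser.parse_args()

    dataset = read_panel(PanelFileBundle(
        args.panels / "panel_data.csv",
        args.panels / "panel_analytes.csv",
        args.panels / "panel_censored.csv",
    ))
    args.out.mkdir(parents=True, exist_ok=True)

    loading = [g for g in dataset.groups if not g.startswith("activation")]
    activation = [g for g in dataset.groups if g.startswith("activation")]

    designs = []
    if len(loading) >= 2:
        designs.append(("loading_one_way", StatDesign(kind="one_way", groups=loading)))
    if len(activation) == 2:
        designs.append(("activation_t_test", StatDesign(kind="t_test", groups=activation)))

    for name, design in designs:
        table = panel_sweep(dataset, design, log10_transform=True)
        table.to_csv(args.out / f"{name}.csv", index=False, encoding="utf-8")
        sig = table.loc[table["significant"], "analyte"].tolist()
        print(f"{name}: {len(sig)}/{len(table)} analytes at p < 0.05: "
              + (", ".join(sig[:10]) + ("…" if len(sig) > 10 else "") if sig else "none"))


if __name__ == "__main__":
    main()
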