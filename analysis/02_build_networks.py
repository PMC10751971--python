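"""Build the per-condition signed correlation networks.

Reads the simulated panel bundle, applies the below-detection filter per
condition, computes all-pairs Pearson correlations of log10
concentrations, thresholds at the condition's cutoff (r > 0.9 for the
compression arm, r > 0.7 for the activation arm), and scores eigenvector
centrality. Outputs per condition under results/networks/.
"""

import argparse
from pathlib import Path

from cytonet import (
    FilterPolicy,
    apply_detection_filter,
    eigenvector_centrality,
    pearson_matrix,
    read_panel,
    threshold_network,
)
from cytonet.network import write_edgelist_csv, write_graphml
from cytonet.panel_io import PanelFileBundle
from cytonet.pipeline import default_r_min


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--panels", type=Path, default=Path("results/panels"))
    parser.add_argument("--out", type=Path, default=Path("results/networks"))
    args = parser.parse_args()

    dataset = read_panel(PanelFileBundle(
        args.panels / "panel_data.csv",
        args.panels / "panel_analytes.csv",
        args.panels / "panel_censored.csv",
    ))
    for cond in dataset.groups:
        filtered = apply_detection_filter(dataset, cond, FilterPolicy())
        corr = pearson_matrix(filtered, log10_transform=True)
        r_min = default_r_min(cond)
        net = threshold_network(corr, r_min, source_condition=cond)
        cent = eigenvector_centrality(net)

        out = args.out / cond
        out.mkdir(parents=True, exist_ok=True)
        corr.to_dataframe().to_csv(out / "correlation.csv", encoding="utf-8")
        write_edgelist_csv(net, out / "edges.csv")
        write_graphml(net, out / "network.graphml")
        cent.to_dataframe().to_csv(out / "centrality.csv", index=False, encoding="utf-8")

        top = sorted(cent.scores.items(), key=lambda kv: -kv[1])[:3]
        top_str = ", ".join(f"{a}={v:.2f}" for a, v in top)
        print(f"{cond:>16}: r_min={r_min}, {len(net.edges):3d} edges, "
              f"{len(filtered.excluded)} excluded analytes; top C_lambda: {top_str}")


if __name__ == "__main__":
    main()
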