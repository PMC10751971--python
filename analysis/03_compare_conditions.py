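"""Compare condition networks edge-by-edge.

Diffs the narrative condition pairs (control vs dynamic, dynamic vs its
TRPV4-inhibited arm, control vs static, static vs its inhibited arm,
dynamic vs static, and activation day 3 vs day 7), reporting conserved,
gained, lost, and sign-flipped edges plus the Jaccard overlap. The
headline check: the planted LIF/IL-16 vs VEGFA inversion of the control
condition reverses to positive under static compression, which the diff
reports as sign-flipped edges.
"""

import argparse
from pathlib import Path

from cytonet.compare import diff_networks, node_neighborhood_change
from cytonet.network import read_edgelist_csv
from cytonet.pipeline import NARRATIVE_PAIRS, default_r_min


def load(net_dir: Path, cond: str):
    return read_edgelist_csv(
        net_dir / cond / "edges.csv", r_min=default_r_min(cond), source_condition=cond
    )


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--networks", type=Path, default=Path("results/networks"))
    parser.add_argument("--out", type=Path, default=Path("results/diffs"))
    args = parser.parse_args()

    for a, b in NARRATIVE_PAIRS:
        if not (args.networks / a).is_dir() or not (args.networks / b).is_dir():
            continue
        diff = diff_networks(load(args.networks, a), load(args.networks, b),
                             label_a=a, label_b=b)
        out = args.out / f"{a}__vs__{b}"
        out.mkdir(parents=True, exist_ok=True)
        diff.to_dataframe().to_csv(out / "diff.csv", index=False, encoding="utf-8")
        print(f"{a} vs {b}: conserved={len(diff.conserved)} gained={len(diff.gained)} "
              f"lost={len(diff.lost)} flipped={len(diff.sign_flipped)} "
              f"jaccard={diff.jaccard:.3f}")
        if (a, b) == ("control", "static"):
            for pair in sorted(diff.sign_flipped):
                print(f"    sign flip: {pair[0]}–{pair[1]} "
                      f"(r {diff.r_a[pair]:+.2f} -> {diff.r_b[pair]:+.2f})")
        if (a, b) == ("control", "dynamic") and "LIF" in diff.nodes:
            nd = node_neighborhood_change(diff, "LIF")
            gained = ", ".join("–".join(p) for p in sorted(nd.gained)) or "none"
            lost = ", ".join("–".join(p) for p in sorted(nd.lost)) or "none"
            print(f"    LIF neighborhood: gained [{gained}]; lost [{lost}]")


if __name__ == "__main__":
    main()
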