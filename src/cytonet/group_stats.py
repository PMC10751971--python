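"""Per-analyte group statistics: t-tests, one-/two-way ANOVA, Tukey HSD.

Comparisons are computed on raw pg/mL concentrations by default (the
figures they mirror plot linear-scale bars); a log10 transform is
available by flag. Significance is flagged at α = 0.05 with no
multiple-testing correction across the panel by default; a
Benjamini–Hochberg column is available opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .panel_io import PanelDataset

__all__ = [
    "EffectResult",
    "AnovaResult",
    "TukeyTable",
    "StatDesign",
    "one_way_anova",
    "two_way_anova",
    "tukey_hsd",
    "two_sample_t",
    "panel_sweep",
]

ALPHA = 0.05


@dataclass
class EffectResult:
    name: str
    f: float
    df_num: float
    df_den: float
    p: float


@dataclass
class AnovaResult:
    kind: str  # "one_way" | "two_way"
    effects: list[EffectResult]
    residual_df: float
    analyte: str | None = None

    def effect(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def p(self) -> float:
        """p-value of the first (primary) effect."""
        return self.effects[0].p


@dataclass
class TukeyTable:
    """Tukey-adjusted pairwise contrasts; one row per unordered group pair."""

    rows: pd.DataFrame  # columns: group_i, group_j, mean_diff, p_adj
    analyte: str | None = None


def _group_arrays(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    out: dict[str, np.ndarray] = {}
    for g in groups:
        if g not in out:
            out[g] = values[groups == g]
    return out


def _one_way_ss(by_group: dict[str, np.ndarray]) -> tuple[float, float, int, int]:
    """Between/within sums of squares and their dfs."""
    all_vals = np.concatenate(list(by_group.values()))
    grand = all_vals.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in by_group.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in by_group.values())
    df_b = len(by_group) - 1
    df_w = len(all_vals) - len(by_group)
    return float(ssb), float(ssw), df_b, df_w


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way ANOVA: F = MSB/MSW with p from the F distribution."""
    by_group = _group_arrays(values, groups)
    if len(by_group) < 2:
        raise ValueError("one_way_anova requires at least 2 groups")
    for g, v in by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has a single sample; at least 2 required")
    ssb, ssw, df_b, df_w = _one_way_ss(by_group)
    if ssw == 0.0:
        raise ValueError("zero within-group variance everywhere; F is undefined")
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(
        kind="one_way",
        effects=[EffectResult("group", float(f), df_b, df_w, p)],
        residual_df=df_w,
    )


def two_way_anova(values, factor_a, factor_b) -> AnovaResult:
    """Two-way ANOVA with interaction.

    Balanced designs reduce to the classical partitioning; unbalanced
    designs use Type II sums of squares. Every factor-level cell must be
    non-empty.
    """
    values = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a).astype(str)
    fb = np.asarray(factor_b).astype(str)
    if not (len(values) == len(fa) == len(fb)):
        raise ValueError("values and factors must have the same length")
    levels_a, levels_b = sorted(set(fa)), sorted(set(fb))
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("both factors need at least 2 levels")
    for la in levels_a:
        for lb in levels_b:
            if not np.any((fa == la) & (fb == lb)):
                raise ValueError(f"empty design cell: ({la!r}, {lb!r})")
    total_ss = float(((values - values.mean()) ** 2).sum())
    if total_ss == 0.0:
        raise ValueError("data constant everywhere; no variance to partition")
    df = pd.DataFrame({"y": values, "a": fa, "b": fb})
    fit = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # anova_lm divides by a zero SSR itself
        table = sm.stats.anova_lm(fit, typ=2)
    resid_df = float(table.loc["Residual", "df"])
    ssr = float(table.loc["Residual", "sum_sq"])
    ss_tol = 1e-12 * total_ss

    # F/p from the Type II sums of squares, taking limits in the noise-free
    # cases: a vanishing effect SS gives F = 0 regardless of the residual
    # (e.g. the interaction of perfectly additive data); a non-vanishing
    # effect over a zero residual gives the perfect-separation limit.
    effects = []
    for row_name, eff_name in [("C(a)", "factor_a"), ("C(b)", "factor_b"),
                               ("C(a):C(b)", "interaction")]:
        ss = float(table.loc[row_name, "sum_sq"])
        df_num = float(table.loc[row_name, "df"])
        if ss <= ss_tol:
            f_stat, p = 0.0, 1.0
        elif ssr <= ss_tol or resid_df == 0:
            f_stat, p = float("inf"), 0.0
        else:
            f_stat = (ss / df_num) / (ssr / resid_df)
            p = float(stats.f.sf(f_stat, df_num, resid_df))
        effects.append(EffectResult(eff_name, f_stat, df_num, resid_df, p))
    return AnovaResult(kind="two_way", effects=effects, residual_df=resid_df)


def tukey_hsd(values, groups) -> TukeyTable:
    """Tukey(-Kramer) HSD pairwise contrasts.

    Uses the pooled within-group mean square from the one-way fit and the
    studentized-range distribution: q = |ȳᵢ − ȳⱼ| / √(MSW/2 · (1/nᵢ + 1/nⱼ)),
    p = P(Q_{k, df_w} ≥ q). For two groups this reduces exactly to the
    pooled-variance two-sample t-test (q = t·√2).
    """
    by_group = _group_arrays(values, groups)
    if len(by_group) < 2:
        raise ValueError("tukey_hsd requires at least 2 groups")
    for g, v in by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has a single sample; at least 2 required")
    _, ssw, _, df_w = _one_way_ss(by_group)
    if ssw == 0.0:
        raise ValueError("zero within-group variance everywhere; q is undefined")
    msw = ssw / df_w
    k = len(by_group)
    rows = []
    for gi, gj in combinations(by_group, 2):
        vi, vj = by_group[gi], by_group[gj]
        diff = float(vi.mean() - vj.mean())
        se = np.sqrt(msw / 2.0 * (1.0 / len(vi) + 1.0 / len(vj)))
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_w))
        rows.append({"group_i": gi, "group_j": gj, "mean_diff": diff, "p_adj": min(p, 1.0)})
    return TukeyTable(rows=pd.DataFrame(rows, columns=["group_i", "group_j", "mean_diff", "p_adj"]))


def two_sample_t(values, groups) -> tuple[float, float]:
    """Pooled-variance two-sample t-test; returns (t, p)."""
    by_group = _group_arrays(values, groups)
    if len(by_group) != 2:
        raise ValueError("two_sample_t requires exactly 2 groups")
    a, b = by_group.values()
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


@dataclass
class StatDesign:
    """Which comparison to run across the panel.

    ``kind`` is one of ``one_way`` (factor: group), ``two_way`` (factors:
    group metadata columns, default group × timepoint), or ``t_test``
    (exactly two groups). ``groups`` optionally restricts to a subset of
    condition labels.
    """

    kind: str = "one_way"
    groups: list[str] | None = None
    factors: tuple[str, str] = ("group", "timepoint")

    def __post_init__(self):
        if self.kind not in {"one_way", "two_way", "t_test"}:
            raise ValueError(f"unknown design kind {self.kind!r}")


def panel_sweep(
    dataset: PanelDataset,
    design: StatDesign,
    *,
    alpha: float = ALPHA,
    bh: bool = False,
    log10_transform: bool = False,
    with_tukey: bool = False,
) -> pd.DataFrame:
    """Run the design's comparison for every analyte in the panel.

    Returns one row per analyte with the primary-effect statistic and
    p-value, a significance flag at ``alpha``, and the per-analyte error
    message when a comparison is undefined (errors are collected, not
    fatal). ``bh=True`` adds a Benjamini–Hochberg adjusted column (and a
    flag at the same alpha); the default mirrors raw per-analyte
    reporting. ``with_tukey`` attaches the Tukey table per analyte in a
    ``tukey`` column (one_way designs only).
    """
    meta = dataset.sample_meta
    if design.groups is not None:
        missing = set(design.groups) - set(meta["group"])
        if missing:
            raise ValueError(f"design references unknown groups: {sorted(missing)}")
        mask = meta["group"].isin(design.groups).to_numpy()
    else:
        mask = np.ones(len(meta), dtype=bool)
    sub_meta = meta.loc[mask]
    sub_conc = dataset.concentrations.loc[mask]

    rows = []
    for analyte in dataset.analytes:
        vals = sub_conc[analyte].to_numpy(dtype=float)
        if log10_transform:
            vals = np.log10(vals)
        row: dict = {"analyte": analyte, "test": design.kind, "statistic": np.nan,
                     "p": np.nan, "error": None}
        try:
            if design.kind == "one_way":
                res = one_way_anova(vals, sub_meta["group"].to_numpy())
                row["statistic"], row["p"] = res.effects[0].f, res.p
                if with_tukey:
                    row["tukey"] = tukey_hsd(vals, sub_meta["group"].to_numpy())
            elif design.kind == "t_test":
                t, p = two_sample_t(vals, sub_meta["group"].to_numpy())
                row["statistic"], row["p"] = t, p
            else:
                fa = sub_meta[design.factors[0]].to_numpy()
                fb = sub_meta[design.factors[1]].to_numpy()
                res = two_way_anova(vals, fa, fb)
                for e in res.effects:
                    row[f"F_{e.name}"] = e.f
                    row[f"p_{e.name}"] = e.p
                # primary effect: first factor's main effect
                row["statistic"], row["p"] = res.effects[0].f, res.effects[0].p
        except ValueError as exc:
            row["error"] = str(exc)
        rows.append(row)

    table = pd.DataFrame(rows)
    table["significant"] = (table["p"] < alpha).fillna(False)
    if bh:
        ok = table["p"].notna()
        adj = np.full(len(table), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
        table["p_bh"] = adj
        table["significant_bh"] = (table["p_bh"] < alpha).fillna(False)
    return table
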