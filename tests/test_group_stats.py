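"""ANOVA, Tukey HSD, t-tests, and the per-analyte panel sweep."""

import numpy as np
import pytest
from scipy import stats as sps

from cytonet.group_stats import (
    StatDesign,
    one_way_anova,
    panel_sweep,
    tukey_hsd,
    two_sample_t,
    two_way_anova,
)
from cytonet.synthetic import SynthConfig, simulate_panel


def one_way_oracle(groups_values):
    """Brute-force sum-of-squares partition, independent of the library."""
    allv = [v for g in groups_values for v in g]
    grand = sum(allv) / len(allv)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups_values)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups_values)
    df_b = len(groups_values) - 1
    df_w = len(allv) - len(groups_values)
    f = (ssb / df_b) / (ssw / df_w)
    return f, float(sps.f.sf(f, df_b, df_w))


def labelled(groups_values):
    values = np.concatenate([np.asarray(g, float) for g in groups_values])
    labels = np.concatenate(
        [np.full(len(g), f"g{i}") for i, g in enumerate(groups_values)]
    )
    return values, labels


class TestOneWay:
    def test_equal_group_means_give_f_zero(self):
        values, labels = labelled([[1, 2, 3], [2, 3, 1], [3, 1, 2]])
        res = one_way_anova(values, labels)
        assert res.effects[0].f == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        values, labels = labelled([[1, 2, 3], [4, 5, 6]])
        res = one_way_anova(values, labels)
        eff = res.effects[0]
        assert eff.f == pytest.approx(13.5, abs=1e-12)
        assert (eff.df_num, eff.df_den) == (1, 4)

    def test_matches_brute_force_oracle_and_scipy(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = [rng.normal(size=rng.integers(3, 8)).tolist() for _ in range(k)]
            values, labels = labelled(groups)
            res = one_way_anova(values, labels)
            f_o, p_o = one_way_oracle(groups)
            assert res.effects[0].f == pytest.approx(f_o, abs=1e-10)
            assert res.p == pytest.approx(p_o, abs=1e-10)
            f_s, p_s = sps.f_oneway(*groups)
            assert res.effects[0].f == pytest.approx(f_s, rel=1e-10)

    def test_two_group_f_is_t_squared(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=6), rng.normal(1.0, 1.0, size=8)
        values, labels = labelled([a.tolist(), b.tolist()])
        res = one_way_anova(values, labels)
        t, p = two_sample_t(values, labels)
        assert res.effects[0].f == pytest.approx(t**2, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_shift_invariance(self):
        values, labels = labelled([[1.0, 2.0, 3.5], [4.0, 5.5, 6.0]])
        res1 = one_way_anova(values, labels)
        res2 = one_way_anova(values + 1234.5, labels)
        assert res1.effects[0].f == pytest.approx(res2.effects[0].f, rel=1e-9)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError, match="zero within-group variance"):
            one_way_anova([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="single sample"):
            one_way_anova([1.0, 2.0, 3.0], ["a", "a", "b"])
        with pytest.raises(ValueError, match="at least 2 groups"):
            one_way_anova([1.0, 2.0], ["a", "a"])


def two_way_oracle_balanced(cells):
    """Classical balanced two-way partition. cells[(i, j)] = list of values."""
    la = sorted({a for a, _ in cells})
    lb = sorted({b for _, b in cells})
    n = len(next(iter(cells.values())))
    allv = [v for vs in cells.values() for v in vs]
    grand = np.mean(allv)
    mean_a = {a: np.mean([v for (x, _), vs in cells.items() if x == a for v in vs]) for a in la}
    mean_b = {b: np.mean([v for (_, y), vs in cells.items() if y == b for v in vs]) for b in lb}
    cell_mean = {k: np.mean(vs) for k, vs in cells.items()}
    ss_a = n * len(lb) * sum((mean_a[a] - grand) ** 2 for a in la)
    ss_b = n * len(la) * sum((mean_b[b] - grand) ** 2 for b in lb)
    ss_ab = n * sum(
        (cell_mean[(a, b)] - mean_a[a] - mean_b[b] + grand) ** 2 for a in la for b in lb
    )
    ss_r = sum((v - cell_mean[k]) ** 2 for k, vs in cells.items() for v in vs)
    df_r = len(allv) - len(la) * len(lb)
    out = {}
    for name, ss, df in [("factor_a", ss_a, len(la) - 1),
                         ("factor_b", ss_b, len(lb) - 1),
                         ("interaction", ss_ab, (len(la) - 1) * (len(lb) - 1))]:
        f = (ss / df) / (ss_r / df_r)
        out[name] = (f, float(sps.f.sf(f, df, df_r)))
    return out


class TestTwoWay:
    def _flatten(self, cells):
        values, fa, fb = [], [], []
        for (a, b), vs in cells.items():
            values.extend(vs)
            fa.extend([a] * len(vs))
            fb.extend([b] * len(vs))
        return np.array(values), fa, fb

    def test_perfectly_additive_data_has_zero_interaction(self):
        cells = {("a1", "b1"): [0.0, 0.0], ("a1", "b2"): [1.0, 1.0],
                 ("a2", "b1"): [2.0, 2.0], ("a2", "b2"): [3.0, 3.0]}
        res = two_way_anova(*self._flatten(cells))
        assert res.effect("interaction").f == 0.0
        assert res.effect("interaction").p == 1.0

    def test_constant_data_errors(self):
        cells = {("a1", "b1"): [5.0, 5.0], ("a1", "b2"): [5.0, 5.0],
                 ("a2", "b1"): [5.0, 5.0], ("a2", "b2"): [5.0, 5.0]}
        with pytest.raises(ValueError, match="constant"):
            two_way_anova(*self._flatten(cells))

    def test_empty_cell_errors_naming_cell(self):
        values = [1.0, 2.0, 3.0, 4.0]
        fa = ["a1", "a1", "a2", "a2"]
        fb = ["b1", "b2", "b1", "b1"]
        with pytest.raises(ValueError, match="a2.*b2"):
            two_way_anova(values, fa, fb)

    def test_balanced_design_matches_classical_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            cells = {
                (a, b): rng.normal(loc=rng.normal(), size=3).tolist()
                for a in ["a1", "a2"] for b in ["b1", "b2"]
            }
            res = two_way_anova(*self._flatten(cells))
            oracle = two_way_oracle_balanced(cells)
            for name in ("factor_a", "factor_b", "interaction"):
                assert res.effect(name).f == pytest.approx(oracle[name][0], abs=1e-10)
                assert res.effect(name).p == pytest.approx(oracle[name][1], abs=1e-10)

    def test_unbalanced_design_runs_with_valid_output(self):
        # vehicle n=6 vs agonist n=10, two timepoints
        rng = np.random.default_rng(8)
        values, fa, fb = [], [], []
        for treat, n in [("vehicle", 6), ("agonist", 10)]:
            for day in ["d3", "d7"]:
                values.extend(rng.normal(size=n // 2 + 2).tolist())
                fa.extend([treat] * (n // 2 + 2))
                fb.extend([day] * (n // 2 + 2))
        res = two_way_anova(np.array(values), fa, fb)
        for e in res.effects:
            assert e.f >= 0
            assert 0 <= e.p <= 1


class TestTukey:
    def test_two_groups_reduce_to_pooled_t(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            a = rng.normal(size=int(rng.integers(3, 9)))
            b = rng.normal(0.8, 1.0, size=int(rng.integers(3, 9)))
            values, labels = labelled([a.tolist(), b.tolist()])
            table = tukey_hsd(values, labels)
            _, p_t = two_sample_t(values, labels)
            assert table.rows["p_adj"].iloc[0] == pytest.approx(p_t, abs=1e-10)

    def test_identical_group_means_give_p_one(self):
        values, labels = labelled([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [0.0, 2.0, 4.0]])
        table = tukey_hsd(values, labels)
        row = table.rows[(table.rows.group_i == "g0") & (table.rows.group_j == "g1")]
        assert row["mean_diff"].iloc[0] == 0.0
        assert row["p_adj"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_adjusted_p_not_below_pairwise_t(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            groups = [rng.normal(size=5).tolist() for _ in range(4)]
            values, labels = labelled(groups)
            table = tukey_hsd(values, labels)
            for _, row in table.rows.iterrows():
                i = int(row.group_i[1:])
                j = int(row.group_j[1:])
                _, p_raw = sps.ttest_ind(groups[i], groups[j], equal_var=True)
                assert row.p_adj >= p_raw - 1e-12

    def test_matches_scipy_tukey(self):
        rng = np.random.default_rng(29)
        groups = [rng.normal(size=6).tolist() for _ in range(3)]
        values, labels = labelled(groups)
        table = tukey_hsd(values, labels)
        ref = sps.tukey_hsd(*[np.asarray(g) for g in groups])
        for _, row in table.rows.iterrows():
            i = int(row.group_i[1:])
            j = int(row.group_j[1:])
            assert row.p_adj == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_one_pair_per_unordered_group_pair(self):
        values, labels = labelled([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 5.0]])
        table = tukey_hsd(values, labels)
        assert len(table.rows) == 6


def shifted_panel_config(seed, p=44, shift_analyte=0, log10_shift=1.0, n=6):
    analytes = [f"a{i}" for i in range(p)]
    mean_x = np.full(p, 2.0)
    mean_y = np.full(p, 2.0)
    mean_y[shift_analyte] += log10_shift
    return SynthConfig(
        analytes=analytes,
        groups=[("x", n), ("y", n)],
        log10_mean={"x": mean_x, "y": mean_y},
        log10_sd=np.full(p, 0.3),
        correlation={"x": np.eye(p), "y": np.eye(p)},
        llod=np.full(p, 1e-9),
        seed=seed,
    )


class TestPanelSweep:
    def test_planted_shift_flagged_and_null_rate_calibrated(self):
        n_seeds = 200
        planted_hits = 0
        false_flags = 0
        null_tests = 0
        for seed in range(n_seeds):
            ds = simulate_panel(shifted_panel_config(seed))
            table = panel_sweep(ds, StatDesign(kind="one_way"), log10_transform=True)
            table = table.set_index("analyte")
            planted_hits += bool(table.loc["a0", "significant"])
            nulls = table.drop(index="a0")
            false_flags += int(nulls["significant"].sum())
            null_tests += len(nulls)
        # log10 shift of 1.0 vs sd 0.3 is a huge effect; allow a rare miss
        assert planted_hits >= n_seeds - 2
        rate = false_flags / null_tests
        se = np.sqrt(0.05 * 0.95 / null_tests)
        assert abs(rate - 0.05) < 3 * se

    def test_bh_column_controls_global_null(self):
        n_seeds = 50
        any_bh = 0
        for seed in range(n_seeds):
            ds = simulate_panel(shifted_panel_config(seed + 1000, p=20, log10_shift=0.0))
            table = panel_sweep(
                ds, StatDesign(kind="one_way"), bh=True, log10_transform=True
            )
            any_bh += bool(table["significant_bh"].any())
        assert any_bh < n_seeds / 2  # expected ~5% of seeds

    def test_single_group_collects_errors_without_flagging(self):
        ds = simulate_panel(
            SynthConfig(
                analytes=["A", "B"],
                groups=[("only", 6)],
                log10_mean={"only": np.array([1.0, 1.0])},
                log10_sd=np.array([0.2, 0.2]),
                correlation={"only": np.eye(2)},
                llod=np.array([1e-9, 1e-9]),
                seed=0,
            )
        )
        table = panel_sweep(ds, StatDesign(kind="one_way"))
        assert table["error"].notna().all()
        assert not table["significant"].any()

    def test_unknown_design_group_errors(self):
        ds = simulate_panel(shifted_panel_config(0, p=3))
        with pytest.raises(ValueError, match="unknown groups"):
            panel_sweep(ds, StatDesign(kind="one_way", groups=["x", "zzz"]))

    def test_t_test_design(self):
        ds = simulate_panel(shifted_panel_config(1, p=5))
        table = panel_sweep(ds, StatDesign(kind="t_test"), log10_transform=True)
        assert table.set_index("analyte").loc["a0", "significant"]
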