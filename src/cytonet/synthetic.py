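"""Synthetic multiplex cytokine panel generator.

Concentrations are modelled as multivariate log-normal: for each
experimental group, log10 concentrations are drawn from a multivariate
normal with per-analyte means and standard deviations and a per-group
correlation matrix, then exponentiated to pg/mL and left-censored at each
analyte's lower limit of detection (LLOD). Censored cells are recorded at
the LLOD and flagged, keeping the table rectangular.

Condition templates plant the qualitative correlation structure of an
ex vivo intervertebral-disc loading study — an IL-6-family hub block
(IL-6, LIF, IL-11, IL-1β) with neutrophil-chemokine partners in the
control condition, loading-specific rewiring of the LIF neighbourhood,
and a LIF/IL-16 vs VEGFA sign reversal between unloaded and statically
loaded tissue — as explicit correlation entries at a configurable
planting level (default ρ = 0.95, chosen so planted edges survive an
|r| > 0.9 cutoff at n = 6–10 with high probability).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import yaml
from statsmodels.stats.correlation_tools import corr_nearest

from .panel_io import PanelDataset, panel_catalog

import pandas as pd

__all__ = [
    "SynthConfig",
    "TEMPLATE_NAMES",
    "build_condition_template",
    "merge_configs",
    "nearest_valid_correlation",
    "simulate_panel",
    "default_llods",
]

#: Printed sensitivity range of the assay panel, pg/mL.
LLOD_RANGE = (0.3, 30.6)

#: Default planting level for "highly correlated" blocks.
DEFAULT_PLANT_RHO = 0.95

#: Default fold changes for elevated / depressed analytes.
DEFAULT_FOLD_UP = 3.0
DEFAULT_FOLD_DOWN = 1.0 / 3.0

#: Baseline marginals on the log10 pg/mL scale.
BASE_LOG10_MEAN = 2.0
BASE_LOG10_SD = 0.3


def default_llods(analytes: list[str] | None = None) -> np.ndarray:
    """Per-analyte detection limits, evenly log-spaced over the panel's
    printed 0.3–30.6 pg/mL sensitivity range, in panel order."""
    if analytes is None:
        analytes = panel_catalog()
    lo, hi = LLOD_RANGE
    llod = np.logspace(np.log10(lo), np.log10(hi), len(analytes))
    llod[0], llod[-1] = lo, hi  # pin endpoints against log/exp round-off
    return llod


@dataclass
class SynthConfig:
    """Full specification of a synthetic panel draw.

    ``log10_mean`` and ``correlation`` are per-group; ``log10_sd`` and
    ``llod`` are shared per-analyte vectors. ``timepoints`` maps each group
    to its collection timepoint label (metadata only).
    """

    analytes: list[str]
    groups: list[tuple[str, int]]
    log10_mean: dict[str, np.ndarray]
    log10_sd: np.ndarray
    correlation: dict[str, np.ndarray]
    llod: np.ndarray
    seed: int = 0
    timepoints: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.log10_sd = np.asarray(self.log10_sd, dtype=float)
        self.llod = np.asarray(self.llod, dtype=float)
        self.log10_mean = {g: np.asarray(m, dtype=float) for g, m in self.log10_mean.items()}
        self.correlation = {g: np.asarray(c, dtype=float) for g, c in self.correlation.items()}

    def validate(self) -> None:
        p = len(self.analytes)
        if len(set(self.analytes)) != p:
            raise ValueError("duplicate analyte names")
        if not self.groups:
            raise ValueError("at least one group required")
        for g, n in self.groups:
            if n < 3:
                raise ValueError(f"group {g!r}: n_samples must be >= 3, got {n}")
            if g not in self.log10_mean or g not in self.correlation:
                raise ValueError(f"group {g!r}: missing mean or correlation")
            if self.log10_mean[g].shape != (p,):
                raise ValueError(f"group {g!r}: log10_mean has wrong length")
            c = self.correlation[g]
            if c.shape != (p, p):
                raise ValueError(f"group {g!r}: correlation has wrong shape")
            _check_correlation_form(c)
        if self.log10_sd.shape != (p,) or np.any(self.log10_sd <= 0):
            raise ValueError("log10_sd must be positive, one per analyte")
        if self.llod.shape != (p,) or np.any(self.llod <= 0):
            raise ValueError("llod must be positive, one per analyte")

    def analyte_index(self, name: str) -> int:
        return self.analytes.index(name)

    def with_valid_correlations(self, tol: float = 1e-10) -> "SynthConfig":
        """Return a copy whose per-group correlation matrices are projected
        to the nearest valid (PSD, unit-diagonal) correlation matrix."""
        fixed = {g: nearest_valid_correlation(c, tol=tol).matrix
                 for g, c in self.correlation.items()}
        return SynthConfig(
            analytes=list(self.analytes),
            groups=list(self.groups),
            log10_mean={g: m.copy() for g, m in self.log10_mean.items()},
            log10_sd=self.log10_sd.copy(),
            correlation=fixed,
            llod=self.llod.copy(),
            seed=self.seed,
            timepoints=dict(self.timepoints),
        )

    # -- plain-text serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "analytes": list(self.analytes),
            "groups": [[g, int(n)] for g, n in self.groups],
            "log10_mean": {g: [float(x) for x in m] for g, m in self.log10_mean.items()},
            "log10_sd": [float(x) for x in self.log10_sd],
            "correlation": {g: [[float(x) for x in row] for row in c]
                            for g, c in self.correlation.items()},
            "llod": [float(x) for x in self.llod],
            "seed": int(self.seed),
            "timepoints": dict(self.timepoints),
        }

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, allow_unicode=True, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        return cls(
            analytes=list(d["analytes"]),
            groups=[(g, int(n)) for g, n in d["groups"]],
            log10_mean={g: np.asarray(m, float) for g, m in d["log10_mean"].items()},
            log10_sd=np.asarray(d["log10_sd"], float),
            correlation={g: np.asarray(c, float) for g, c in d["correlation"].items()},
            llod=np.asarray(d["llod"], float),
            seed=int(d.get("seed", 0)),
            timepoints=dict(d.get("timepoints", {})),
        )

    @classmethod
    def from_yaml(cls, path: Path | str) -> "SynthConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


class ProjectionResult(NamedTuple):
    matrix: np.ndarray
    max_change: float


def _check_correlation_form(c: np.ndarray, tol: float = 1e-8) -> None:
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    if np.max(np.abs(c - c.T)) > tol:
        raise ValueError("correlation matrix must be symmetric")
    if np.max(np.abs(np.diag(c) - 1.0)) > tol:
        raise ValueError("correlation matrix must have unit diagonal")
    off = c - np.diag(np.diag(c))
    if np.max(np.abs(off)) > 1.0 + tol:
        bad = float(np.max(np.abs(off)))
        raise ValueError(f"off-diagonal correlation magnitude exceeds 1: {bad}")


def nearest_valid_correlation(target: np.ndarray, tol: float = 1e-10) -> ProjectionResult:
    """Project a symmetric unit-diagonal matrix to the nearest valid
    correlation matrix (positive semidefinite, unit diagonal).

    Hand-planted block matrices need not be PSD; this projection (Higham
    alternating projections with eigenvalue clipping) makes them usable as
    sampling targets. An already-PSD input is returned unchanged.

    Returns
    -------
    ProjectionResult
        ``matrix`` — the PSD correlation matrix; ``max_change`` — the
        maximum absolute entry-wise difference from the input.
    """
    c = np.asarray(target, dtype=float)
    _check_correlation_form(c)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)

    w = np.linalg.eigvalsh(c)
    if w[0] >= -tol:
        return ProjectionResult(c, float(np.max(np.abs(c - target))))

    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import IterationLimitWarning

    with _warnings.catch_warnings():
        # PSD-ness is verified explicitly below, so the projector's own
        # iteration-limit warning is redundant noise.
        _warnings.simplefilter("ignore", IterationLimitWarning)
        fixed = corr_nearest(c, threshold=1e-7, n_fact=200)
    fixed = np.asarray((fixed + fixed.T) / 2.0)
    np.fill_diagonal(fixed, 1.0)
    w = np.linalg.eigvalsh(fixed)
    if w[0] < -tol:  # pragma: no cover - corr_nearest guarantees this
        raise RuntimeError(f"projection failed to reach PSD: min eigenvalue {w[0]}")
    return ProjectionResult(fixed, float(np.max(np.abs(fixed - target))))


# ---------------------------------------------------------------------------
# Condition templates
# ---------------------------------------------------------------------------

TEMPLATE_NAMES = (
    "control",
    "dynamic",
    "dynamic_gsk205",
    "static",
    "static_gsk205",
    "activation_day3",
    "activation_day7",
)

# Signed correlation blocks: within a block, rho(i, j) = sign_i * sign_j * level.
# Sign-consistent blocks are rank-one patterns and therefore PSD by
# construction; extra pairwise entries may make a template indefinite, in
# which case simulate_panel requires a nearest_valid_correlation pass.
_CONTROL_BLOCK = {
    "IL-6": +1, "LIF": +1, "IL-11": +1, "IL-1β": +1,
    "CXCL1": +1, "CXCL2": +1, "GCSF": +1, "GMCSF": +1,
    "IL-16": +1, "VEGFA": -1,
}

_TEMPLATES: dict[str, dict] = {
    # Unloaded control: IL-6-family hub block intercorrelated with the
    # neutrophil chemokines CXCL1/CXCL2 (and GCSF/GMCSF); LIF and IL-16
    # inversely correlated with VEGFA.
    "control": {
        "n": 6,
        "timepoint": "day2",
        "blocks": [_CONTROL_BLOCK],
        "entries": [],
        "up": [],
        "down": [],
    },
    # Dynamic compression: LIF keeps CXCL1/CXCL2/GCSF/GMCSF, gains IL-1α
    # and CXCL5, loses IL-6; IL-1 and neutrophil chemokines elevated.
    "dynamic": {
        "n": 6,
        "timepoint": "day2",
        "blocks": [{
            "LIF": +1, "IL-11": +1, "IL-1β": +1,
            "CXCL1": +1, "CXCL2": +1, "GCSF": +1, "GMCSF": +1,
            "IL-1α": +1, "CXCL5": +1, "IL-16": +1, "VEGFA": -1,
        }],
        "entries": [],
        "up": ["CXCL1", "CXCL5", "IL-1α", "IL-1β"],
        "down": [],
    },
    # TRPV4 inhibition during dynamic loading: only LIF:GCSF and
    # CCL4:GMCSF survive; the loading-induced elevations are blunted.
    "dynamic_gsk205": {
        "n": 6,
        "timepoint": "day2",
        "blocks": [{"LIF": +1, "GCSF": +1}, {"CCL4": +1, "GMCSF": +1}],
        "entries": [],
        "up": [],
        "down": [],
    },
    # Static compression: identical block structure to control except the
    # LIF–VEGFA and IL-16–VEGFA relationships reverse to positive.
    "static": {
        "n": 6,
        "timepoint": "day2",
        "blocks": [{**_CONTROL_BLOCK, "VEGFA": +1}],
        "entries": [],
        "up": [],
        "down": [],
    },
    # TRPV4 inhibition during static loading: positive LIF–VEGFA and
    # IL-6–VEGFA maintained while LIF–IL-6 decouples; IL-16–CCL22 kept.
    "static_gsk205": {
        "n": 7,
        "timepoint": "day2",
        "blocks": [{"IL-16": +1, "CCL22": +1}],
        "entries": [("LIF", "VEGFA", None), ("IL-6", "VEGFA", None), ("LIF", "IL-6", 0.6)],
        "up": [],
        "down": [],
    },
    # TRPV4 agonist, day 3: IL-6-family elevated, monocyte/T-cell
    # chemokines depressed; IL-11/LIF correlate with VEGFA.
    "activation_day3": {
        "n": 10,
        "timepoint": "day3",
        "blocks": [
            {"IL-16": +1, "CCL17": +1},
            {"IL-15": +1, "IL-12p70": +1},
            {"IL-11": +1, "LIF": +1, "VEGFA": +1},
        ],
        "entries": [],
        "up": ["IL-6", "IL-11", "LIF", "IL-16"],
        "down": ["CCL2", "CCL12", "CCL3", "CCL4"],
    },
    # TRPV4 agonist, day 7: IL-1β/LIF stay elevated, a broader chemokine
    # set is depressed; IL-6 inversely related to CXCL10, IL-16 with IL-11.
    "activation_day7": {
        "n": 10,
        "timepoint": "day7",
        "blocks": [
            {"IL-16": +1, "CCL17": +1, "IL-11": +1},
            {"IL-15": +1, "IL-12p70": +1},
            {"IL-6": +1, "CXCL10": -1},
        ],
        "entries": [],
        "up": ["IL-1β", "LIF"],
        "down": ["CCL2", "CCL12", "CCL3", "CCL4", "CCL17", "CCL20", "CCL22", "CXCL10"],
    },
}


def build_condition_template(
    template_name: str,
    *,
    n_samples: int | None = None,
    plant_rho: float = DEFAULT_PLANT_RHO,
    fold_up: float = DEFAULT_FOLD_UP,
    fold_down: float = DEFAULT_FOLD_DOWN,
    seed: int = 0,
) -> SynthConfig:
    """Build the single-group :class:`SynthConfig` for a study condition.

    Parameters
    ----------
    template_name :
        One of :data:`TEMPLATE_NAMES`.
    n_samples :
        Override the condition's default group size.
    plant_rho :
        Magnitude at which block correlations are planted.
    fold_up, fold_down :
        Concentration-scale fold changes applied to the condition's
        elevated / depressed analytes relative to baseline.
    """
    if template_name not in _TEMPLATES:
        raise ValueError(
            f"unknown template {template_name!r}; valid templates: "
            + ", ".join(TEMPLATE_NAMES)
        )
    spec = _TEMPLATES[template_name]
    analytes = panel_catalog()
    p = len(analytes)
    idx = {a: i for i, a in enumerate(analytes)}

    corr = np.eye(p)
    for block in spec["blocks"]:
        members = list(block)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                rho = block[a] * block[b] * plant_rho
                corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    for a, b, level in spec["entries"]:
        rho = plant_rho if level is None else level
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho

    mean = np.full(p, BASE_LOG10_MEAN)
    for a in spec["up"]:
        mean[idx[a]] += np.log10(fold_up)
    for a in spec["down"]:
        mean[idx[a]] += np.log10(fold_down)

    n = spec["n"] if n_samples is None else int(n_samples)
    return SynthConfig(
        analytes=analytes,
        groups=[(template_name, n)],
        log10_mean={template_name: mean},
        log10_sd=np.full(p, BASE_LOG10_SD),
        correlation={template_name: corr},
        llod=default_llods(analytes),
        seed=seed,
        timepoints={template_name: spec["timepoint"]},
    )


def merge_configs(configs: list[SynthConfig], seed: int | None = None) -> SynthConfig:
    """Merge single-group configs (e.g. several templates) into one
    multi-group config sharing analytes, sds, and detection limits."""
    if not configs:
        raise ValueError("no configs to merge")
    first = configs[0]
    merged = SynthConfig(
        analytes=list(first.analytes),
        groups=[],
        log10_mean={},
        log10_sd=first.log10_sd.copy(),
        correlation={},
        llod=first.llod.copy(),
        seed=first.seed if seed is None else seed,
        timepoints={},
    )
    for cfg in configs:
        if cfg.analytes != merged.analytes:
            raise ValueError("configs use different analyte panels")
        for g, n in cfg.groups:
            if g in dict(merged.groups):
                raise ValueError(f"duplicate group {g!r}")
            merged.groups.append((g, n))
            merged.log10_mean[g] = cfg.log10_mean[g].copy()
            merged.correlation[g] = cfg.correlation[g].copy()
            merged.timepoints[g] = cfg.timepoints.get(g, "t0")
    return merged


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

#: Relative eigenvalue tolerance below which a correlation matrix is
#: rejected as non-PSD at sampling time.
_PSD_TOL = 1e-8


def _factor(corr: np.ndarray) -> np.ndarray:
    """Square-root factor L with L @ L.T == corr, via eigen-decomposition.

    Handles singular matrices (planted duplicates at rho = 1 give exactly
    identical draws). Small negative eigenvalues within tolerance are
    clipped to zero.
    """
    w, v = np.linalg.eigh(corr)
    scale = max(w[-1], 1.0)
    if w[0] < -_PSD_TOL * scale:
        raise ValueError(
            "correlation matrix is not positive semidefinite "
            f"(min eigenvalue {w[0]:.3g}); apply nearest_valid_correlation first"
        )
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_panel(config: SynthConfig, *, return_raw: bool = False):
    """Draw a :class:`PanelDataset` from a :class:`SynthConfig`.

    For each group, ``n_samples`` vectors are drawn from a multivariate
    normal on the log10 scale, exponentiated to pg/mL, and left-censored:
    values below the analyte's LLOD are recorded at the LLOD with
    ``censored = True``. Draws are reproducible for a fixed config seed;
    each group uses a child seed derived from its position, so adding a
    group leaves earlier groups' draws unchanged.

    With ``return_raw=True`` also returns the pre-censoring concentration
    table (for diagnostics and tests).
    """
    config.validate()
    rows, cens_rows, meta_rows, ids = [], [], [], []
    for gi, (gname, n) in enumerate(config.groups):
        L = _factor(config.correlation[gname])
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(gi,)))
        z = rng.standard_normal((n, len(config.analytes)))
        log10_vals = config.log10_mean[gname] + config.log10_sd * (z @ L.T)
        conc = 10.0 ** log10_vals
        censored = conc < config.llod
        rows.append(conc)
        cens_rows.append(censored)
        tp = config.timepoints.get(gname, "t0")
        for i in range(n):
            ids.append(f"{gname}_{i + 1:02d}")
            meta_rows.append((gname, tp))

    raw = np.vstack(rows)
    cens = np.vstack(cens_rows)
    conc = raw.copy()
    conc[cens] = np.broadcast_to(config.llod, conc.shape)[cens]

    index = pd.Index(ids, name="sample_id")
    dataset = PanelDataset(
        concentrations=pd.DataFrame(conc, index=index, columns=config.analytes),
        censored=pd.DataFrame(cens, index=index, columns=config.analytes),
        sample_meta=pd.DataFrame(meta_rows, index=index, columns=["group", "timepoint"]),
        analyte_meta=pd.DataFrame(
            {"llod_pg_ml": config.llod}, index=pd.Index(config.analytes, name="analyte")
        ),
    )
    if return_raw:
        raw_df = pd.DataFrame(raw, index=index, columns=config.analytes)
        return dataset, raw_df
    return dataset
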