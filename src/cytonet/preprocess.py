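"""Detection-limit filtering and censored-value imputation.

Analytes that are below the assay's detectable threshold in too large a
fraction of a condition's samples carry no usable correlation signal and
are excluded from that condition's network. Surviving left-censored cells
are substituted by a simple function of the detection limit. Filtering is
per condition by default, so an analyte may enter one condition's network
and be excluded from another's; a ``panel_wide`` flag evaluates the
censored fraction over all samples instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .panel_io import PanelDataset

__all__ = [
    "FilterPolicy",
    "FilteredGroupMatrix",
    "ExcludedAnalyte",
    "apply_detection_filter",
    "impute_censored",
    "IMPUTATION_METHODS",
]

# Censored-cell substitution: value = llod / divisor.
IMPUTATION_METHODS = {
    "llod_over_sqrt2": math.sqrt(2.0),
    "llod_over_2": 2.0,
    "at_llod": 1.0,
}


@dataclass
class FilterPolicy:
    """Below-detection exclusion and imputation policy.

    ``max_censored_fraction=0.5`` keeps analytes measurable in a majority
    of samples; 0.0 reproduces a strict "any censoring excludes" reading.
    ``llod_over_sqrt2`` is the standard left-censoring substitution for
    right-skewed assay data; ``at_llod`` reproduces the rawest reading.
    """

    max_censored_fraction: float = 0.5
    imputation: str = "llod_over_sqrt2"
    min_samples: int = 3
    panel_wide: bool = False

    def __post_init__(self):
        if not 0.0 <= self.max_censored_fraction <= 1.0:
            raise ValueError("max_censored_fraction must be in [0, 1]")
        if self.imputation not in IMPUTATION_METHODS:
            raise ValueError(
                f"unknown imputation {self.imputation!r}; "
                f"valid: {sorted(IMPUTATION_METHODS)}"
            )
        if self.min_samples < 3:
            raise ValueError("min_samples must be >= 3")


class ExcludedAnalyte(NamedTuple):
    analyte: str
    reason: str  # "below_detection" | "constant"
    censored_fraction: float


@dataclass
class FilteredGroupMatrix:
    """Analysis-ready samples × retained-analytes matrix for one condition."""

    group: str
    values: pd.DataFrame
    retained: list[str]
    excluded: list[ExcludedAnalyte]

    @property
    def n_samples(self) -> int:
        return len(self.values)


def impute_censored(
    values: np.ndarray,
    censored: np.ndarray,
    llod: float,
    method: str = "llod_over_sqrt2",
) -> np.ndarray:
    """Replace censored positions by ``llod / √2``, ``llod / 2`` or
    ``llod`` per ``method``; uncensored positions are untouched."""
    values = np.asarray(values, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    if values.shape != censored.shape:
        raise ValueError("values and censored must have the same shape")
    if llod <= 0:
        raise ValueError("llod must be positive")
    if method not in IMPUTATION_METHODS:
        raise ValueError(
            f"unknown imputation method {method!r}; valid: {sorted(IMPUTATION_METHODS)}"
        )
    out = values.copy()
    out[censored] = llod / IMPUTATION_METHODS[method]
    return out


def apply_detection_filter(
    dataset: PanelDataset,
    group: str,
    policy: FilterPolicy | None = None,
) -> FilteredGroupMatrix:
    """Produce the analysis-ready matrix for one condition.

    Analytes whose censored fraction (within the group, or panel-wide when
    ``policy.panel_wide``) exceeds ``max_censored_fraction`` are excluded
    with reason ``"below_detection"``; surviving censored cells are imputed
    per policy; analytes left with zero variance are excluded with reason
    ``"constant"`` so correlation is always defined downstream.
    """
    policy = policy or FilterPolicy()
    mask = dataset.group_mask(group)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"group {group!r} not present in dataset")
    if n < policy.min_samples:
        raise ValueError(
            f"group {group!r} has {n} samples; at least {policy.min_samples} required"
        )

    conc = dataset.concentrations.loc[mask]
    cens = dataset.censored.loc[mask]
    frac_src = dataset.censored if policy.panel_wide else cens
    censored_fraction = frac_src.mean(axis=0)

    retained: list[str] = []
    excluded: list[ExcludedAnalyte] = []
    cols: dict[str, np.ndarray] = {}
    for analyte in dataset.analytes:
        frac = float(censored_fraction[analyte])
        if frac > policy.max_censored_fraction:
            excluded.append(ExcludedAnalyte(analyte, "below_detection", frac))
            continue
        llod = float(dataset.analyte_meta.loc[analyte, "llod_pg_ml"])
        col = impute_censored(
            conc[analyte].to_numpy(),
            cens[analyte].to_numpy(),
            llod,
            policy.imputation,
        )
        if np.ptp(col) == 0.0:
            excluded.append(ExcludedAnalyte(analyte, "constant", frac))
            continue
        retained.append(analyte)
        cols[analyte] = col

    values = pd.DataFrame(cols, index=conc.index, columns=retained)
    return FilteredGroupMatrix(group=group, values=values, retained=retained, excluded=excluded)
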