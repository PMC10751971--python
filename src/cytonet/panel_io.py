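"""Reading, validating, and writing multiplex cytokine panel tables.

The interchange format is a pair (optionally a triple) of UTF-8 CSV files:

* a wide data file — one row per sample with ``sample_id``, ``group``,
  ``timepoint`` columns followed by one concentration column (pg/mL) per
  analyte;
* an analyte metadata file with columns ``analyte`` and ``llod_pg_ml``
  (the assay's lower limit of detection for that analyte);
* an optional boolean censoring file mirroring the concentration block,
  marking values that fell below the detection limit.

When no censoring file is supplied, flags are inferred as
``concentration < llod``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PanelDataset",
    "PanelFileBundle",
    "PanelValidationError",
    "panel_catalog",
    "canonical_name",
    "read_panel",
    "write_panel",
]

# The 44-analyte mouse cytokine/chemokine discovery panel, in printed kit
# order (32-plex followed by the 12-analyte second kit). Chemokines are
# carried under their systematic CCL/CXCL names.
_PANEL_32 = [
    "CCL11", "GCSF", "GMCSF", "IFN-γ", "IL-1α", "IL-1β", "IL-2", "IL-3",
    "IL-4", "IL-5", "IL-6", "IL-7", "IL-9", "IL-10", "IL-12p40", "IL-12p70",
    "IL-13", "IL-15", "IL-17", "CXCL10", "CXCL1", "LIF", "CXCL5", "CCL2",
    "MCSF", "CXCL9", "CCL3", "CCL4", "CXCL2", "CCL5", "TNF-α", "VEGFA",
]
_PANEL_12 = [
    "CCL21", "CX3CL1", "IFN-β1", "IL-11", "IL-16", "IL-20", "CCL12",
    "CCL22", "CCL20", "CCL19", "CCL17", "TIMP-1",
]
_PANEL = _PANEL_32 + _PANEL_12

# Common immunology names mapped to the systematic CCL/CXCL nomenclature
# (plus a few spelling variants for input tolerance).
_ALIASES = {
    "Eotaxin": "CCL11",
    "KC": "CXCL1",
    "IP-10": "CXCL10",
    "LIX": "CXCL5",
    "MCP-1": "CCL2",
    "MIG": "CXCL9",
    "MIP-1α": "CCL3",
    "MIP-1a": "CCL3",
    "MIP-1β": "CCL4",
    "MIP-1b": "CCL4",
    "MIP-2": "CXCL2",
    "RANTES": "CCL5",
    "6Ckine": "CCL21",
    "Exodus2": "CCL21",
    "Fractalkine": "CX3CL1",
    "MCP-5": "CCL12",
    "MDC": "CCL22",
    "MIP-3α": "CCL20",
    "MIP-3a": "CCL20",
    "MIP-3β": "CCL19",
    "MIP-3b": "CCL19",
    "TARC": "CCL17",
    "VEGF": "VEGFA",
    "IL-12 (p40)": "IL-12p40",
    "IL-12 (p70)": "IL-12p70",
}


def panel_catalog() -> list[str]:
    """Return the 44 canonical analyte names of the panel, in kit order."""
    return list(_PANEL)


def canonical_name(name: str) -> str:
    """Resolve a common analyte name to its canonical panel name.

    Chemokines resolve to their CCL/CXCL name (``"MCP-1"`` → ``"CCL2"``);
    names without an alias (e.g. ``"IL-6"``) are returned unchanged.
    Resolution is idempotent.
    """
    return _ALIASES.get(name, name)


class PanelValidationError(ValueError):
    """Raised when a panel table violates its contract.

    Carries the full list of problems found, not just the first one.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            f"{len(self.problems)} validation problem(s):\n  "
            + "\n  ".join(self.problems)
        )


@dataclass
class PanelFileBundle:
    """Paths of the on-disk representation of a :class:`PanelDataset`."""

    data_path: Path
    meta_path: Path
    censor_path: Path | None = None

    def __post_init__(self):
        self.data_path = Path(self.data_path)
        self.meta_path = Path(self.meta_path)
        if self.censor_path is not None:
            self.censor_path = Path(self.censor_path)


@dataclass
class PanelDataset:
    """A samples × analytes concentration table with censoring flags.

    Attributes
    ----------
    concentrations :
        Samples × analytes table of concentrations in pg/mL, indexed by
        ``sample_id``. Values below the analyte's detection limit are
        recorded at the limit and flagged in ``censored``.
    censored :
        Boolean table of the same shape marking left-censored cells.
    sample_meta :
        Per-sample metadata (``group``, ``timepoint``), indexed by
        ``sample_id`` in the same order as ``concentrations``.
    analyte_meta :
        Per-analyte metadata (``llod_pg_ml``), indexed by analyte name in
        the same order as the concentration columns.
    """

    concentrations: pd.DataFrame
    censored: pd.DataFrame
    sample_meta: pd.DataFrame
    analyte_meta: pd.DataFrame

    @property
    def analytes(self) -> list[str]:
        return list(self.concentrations.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.concentrations.index)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.sample_meta["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def group_mask(self, group: str) -> np.ndarray:
        return (self.sample_meta["group"] == group).to_numpy()

    def validate(self) -> None:
        problems: list[str] = []
        conc, cens = self.concentrations, self.censored
        if list(conc.columns) != list(cens.columns) or list(conc.index) != list(cens.index):
            problems.append("concentrations and censored tables are not aligned")
        if conc.index.duplicated().any():
            dups = sorted(set(conc.index[conc.index.duplicated()]))
            problems.append(f"duplicate sample_id(s): {dups}")
        if conc.columns.duplicated().any():
            dups = sorted(set(conc.columns[conc.columns.duplicated()]))
            problems.append(f"duplicate analyte name(s): {dups}")
        if list(self.analyte_meta.index) != list(conc.columns):
            a, b = set(self.analyte_meta.index), set(conc.columns)
            if a != b:
                problems.append(
                    f"analyte mismatch between data and metadata: "
                    f"data-only={sorted(b - a)} metadata-only={sorted(a - b)}"
                )
            else:
                problems.append("analyte order differs between data and metadata")
        if list(self.sample_meta.index) != list(conc.index):
            problems.append("sample_meta index does not match concentration rows")

        vals = conc.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            for i, sid in enumerate(conc.index):
                for j, an in enumerate(conc.columns):
                    if not isinstance(vals[i, j], (int, float, np.number)) or (
                        isinstance(vals[i, j], float) and math.isnan(vals[i, j])
                    ):
                        problems.append(f"non-numeric concentration at ({sid!r}, {an!r})")
        else:
            bad = np.argwhere(~np.isfinite(vals) | (vals < 0))
            for i, j in bad:
                problems.append(
                    f"negative or non-finite concentration at "
                    f"({conc.index[i]!r}, {conc.columns[j]!r}): {vals[i, j]}"
                )
            if not problems:
                llod = self.analyte_meta["llod_pg_ml"].to_numpy(dtype=float)
                below = np.argwhere((vals < llod[None, :]) & ~cens.to_numpy())
                for i, j in below:
                    problems.append(
                        f"uncensored concentration below detection limit at "
                        f"({conc.index[i]!r}, {conc.columns[j]!r}): "
                        f"{vals[i, j]} < {llod[j]}"
                    )
        if problems:
            raise PanelValidationError(problems)

    def equals(self, other: "PanelDataset") -> bool:
        return (
            self.concentrations.equals(other.concentrations)
            and self.censored.equals(other.censored)
            and self.sample_meta.equals(other.sample_meta)
            and self.analyte_meta.equals(other.analyte_meta)
        )


_META_COLUMNS = ["sample_id", "group", "timepoint"]


def read_panel(bundle: PanelFileBundle) -> PanelDataset:
    """Read and validate a panel dataset from its CSV bundle.

    Censoring flags are taken from ``bundle.censor_path`` when present and
    otherwise inferred as ``concentration < llod``. A missing ``timepoint``
    column is tolerated and filled with a single pseudo-timepoint ``"t0"``.
    Validation reports every offending cell/column, not just the first.
    """
    # round_trip parsing keeps concentrations bit-exact across write/read
    data = pd.read_csv(bundle.data_path, float_precision="round_trip")
    meta = pd.read_csv(bundle.meta_path, float_precision="round_trip")

    problems: list[str] = []
    if "sample_id" not in data.columns:
        raise PanelValidationError(["data file has no 'sample_id' column"])
    if "group" not in data.columns:
        problems.append("data file has no 'group' column")
    if "timepoint" not in data.columns:
        data = data.copy()
        data["timepoint"] = "t0"
    if not {"analyte", "llod_pg_ml"} <= set(meta.columns):
        problems.append("metadata file must have 'analyte' and 'llod_pg_ml' columns")
    if problems:
        raise PanelValidationError(problems)

    analyte_cols = [c for c in data.columns if c not in _META_COLUMNS]
    meta_analytes = list(meta["analyte"])
    if set(analyte_cols) != set(meta_analytes):
        raise PanelValidationError(
            [
                "analyte mismatch between data and metadata: "
                f"data-only={sorted(set(analyte_cols) - set(meta_analytes))} "
                f"metadata-only={sorted(set(meta_analytes) - set(analyte_cols))}"
            ]
        )

    data = data.set_index("sample_id")
    if data.index.duplicated().any():
        dups = sorted(set(data.index[data.index.duplicated()]))
        raise PanelValidationError([f"duplicate sample_id(s): {dups}"])

    # Align data columns to metadata row order so the metadata file owns
    # the panel ordering.
    conc = data[meta_analytes].copy()
    for col in meta_analytes:
        conc[col] = pd.to_numeric(conc[col], errors="coerce")
    raw = data[meta_analytes]
    coerced_na = conc.isna() & raw.notna()
    for sid, an in zip(*np.where(coerced_na.to_numpy())):
        problems.append(
            f"non-numeric concentration at ({conc.index[sid]!r}, {meta_analytes[an]!r}): "
            f"{raw.iloc[sid, an]!r}"
        )
    vals = conc.to_numpy(dtype=float)
    bad = np.argwhere(np.isfinite(vals) & (vals < 0))
    for i, j in bad:
        problems.append(
            f"negative concentration at ({conc.index[i]!r}, {meta_analytes[j]!r}): "
            f"{vals[i, j]}"
        )
    if problems:
        raise PanelValidationError(problems)
    conc = conc.astype(float)

    analyte_meta = meta.set_index("analyte")[["llod_pg_ml"]].astype(float)
    sample_meta = data[["group", "timepoint"]].copy()

    if bundle.censor_path is not None:
        cens = pd.read_csv(bundle.censor_path).set_index("sample_id")
        cens = cens[meta_analytes].astype(bool)
        cens = cens.reindex(index=conc.index)
    else:
        llod = analyte_meta["llod_pg_ml"].to_numpy()
        cens = conc.lt(llod, axis=1)
    cens = cens.astype(bool)

    ds = PanelDataset(
        concentrations=conc,
        censored=cens,
        sample_meta=sample_meta,
        analyte_meta=analyte_meta,
    )
    ds.validate()
    return ds


def write_panel(dataset: PanelDataset, out_dir: Path | str) -> PanelFileBundle:
    """Write a dataset as its three-CSV bundle under ``out_dir``.

    Columns are emitted in deterministic order (``sample_id``, ``group``,
    ``timepoint``, then the analytes in panel order) at full floating-point
    precision, so write → read round-trips bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    data_path = out_dir / "panel_data.csv"
    meta_path = out_dir / "panel_analytes.csv"
    censor_path = out_dir / "panel_censored.csv"

    data = pd.concat([dataset.sample_meta, dataset.concentrations], axis=1)
    data.index.name = "sample_id"
    # %.17g round-trips double precision exactly
    data.to_csv(data_path, encoding="utf-8", float_format="%.17g")

    meta = dataset.analyte_meta.copy()
    meta.index.name = "analyte"
    meta.to_csv(meta_path, encoding="utf-8", float_format="%.17g")

    cens = dataset.censored.copy()
    cens.index.name = "sample_id"
    cens.to_csv(censor_path, encoding="utf-8")

    return PanelFileBundle(data_path=data_path, meta_path=meta_path, censor_path=censor_path)
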