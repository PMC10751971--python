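import numpy as np
import pandas as pd
import pytest

from cytonet.panel_io import PanelDataset


def make_dataset(
    values: dict[str, list[float]],
    groups: list[str],
    llod: dict[str, float] | float = 0.001,
    censored: dict[str, list[bool]] | None = None,
    timepoints: list[str] | None = None,
) -> PanelDataset:
    """Assemble a small PanelDataset from per-analyte value lists."""
    analytes = list(values)
    n = len(groups)
    index = pd.Index([f"s{i + 1:02d}" for i in range(n)], name="sample_id")
    conc = pd.DataFrame({a: np.asarray(v, float) for a, v in values.items()}, index=index)
    if isinstance(llod, (int, float)):
        llod = {a: float(llod) for a in analytes}
    meta = pd.DataFrame(
        {"llod_pg_ml": [llod[a] for a in analytes]},
        index=pd.Index(analytes, name="analyte"),
    )
    if censored is None:
        cens = conc.lt(meta["llod_pg_ml"], axis=1)
    else:
        cens = pd.DataFrame({a: np.asarray(v, bool) for a, v in censored.items()}, index=index)
    sample_meta = pd.DataFrame(
        {"group": groups, "timepoint": timepoints or ["t0"] * n}, index=index
    )
    return PanelDataset(
        concentrations=conc, censored=cens, sample_meta=sample_meta, analyte_meta=meta
    )


@pytest.fixture
def tiny_dataset() -> PanelDataset:
    """Two groups × three analytes, everything above detection."""
    return make_dataset(
        values={
            "IL-6": [10.0, 12.0, 14.0, 20.0, 22.0, 24.0],
            "LIF": [5.0, 6.0, 7.0, 8.0, 9.0, 10.0],
            "VEGFA": [7.0, 5.0, 3.0, 9.0, 11.0, 13.0],
        },
        groups=["control"] * 3 + ["static"] * 3,
    )
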