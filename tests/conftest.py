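"""Shared fixtures: small spectral objects and the default synthetic run.

The heavy seed-1 default acquisition (two organs, 200 sites per class per
organ) is generated once per session and shared by the end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import drsmargin as dm


@pytest.fixture()
def analysis_grid() -> dm.WavelengthGrid:
    return dm.WavelengthGrid(468.0, 720.0, 0.5)


@pytest.fixture()
def full_grid() -> dm.WavelengthGrid:
    return dm.default_acquisition_grid()


@pytest.fixture()
def flat_calibration(full_grid):
    """Calibration with constant white/dark so reflectance = (S-100)/900."""
    white = dm.Spectrum(full_grid, np.full(full_grid.n_samples, 1000.0))
    dark = dm.Spectrum(full_grid, np.full(full_grid.n_samples, 100.0))
    return dm.CalibrationPair(white, dark)


def make_reflectance_dataset(
    values: np.ndarray,
    patients: list[str] | None = None,
    classes: list[str] | None = None,
    grid: dm.WavelengthGrid | None = None,
) -> dm.SpectralDataset:
    """Reflectance dataset straight from an (n_sites, n_wl) array."""
    grid = grid or dm.WavelengthGrid(468.0, 720.0, 0.5)
    n = values.shape[0]
    meta = pd.DataFrame(
        {
            "site_id": [f"s{i:04d}" for i in range(n)],
            "patient_id": patients if patients is not None else ["p0"] * n,
            "organ": ["stomach"] * n,
            "tissue_class": classes if classes is not None else ["normal"] * n,
            "timestamp_s": np.arange(n, dtype=float),
        }
    )
    return dm.SpectralDataset(grid, values, meta, kind="reflectance")


@pytest.fixture(scope="session")
def default_run():
    """Seed-1 default acquisition taken through calibration, crop and QC."""
    syn = dm.generate_spectra(dm.SpectraGenConfig(seed=1))
    refl = dm.calibrate_dataset(syn.site_mean_dataset(), syn.calibration)
    crop = dm.crop_to_analysis_range(refl)
    with pytest.warns(UserWarning):
        qc_ds, qc_report = dm.run_qc(crop)
    return {"syn": syn, "cropped": crop, "qc_ds": qc_ds, "qc_report": qc_report}


@pytest.fixture(scope="session")
def stomach_table(default_run) -> dm.FeatureTable:
    qc_ds = default_run["qc_ds"]
    sto = qc_ds.select((qc_ds.meta["organ"] == "stomach").to_numpy())
    return dm.build_feature_table(sto)


@pytest.fixture(scope="session")
def stomach_benchmark(stomach_table) -> dm.EvaluationReport:
    return dm.run_benchmark(stomach_table, dm.CVPlan(seed=1))
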