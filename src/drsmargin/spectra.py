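"""Core spectral types and acquisition-geometry operations.

A diffuse-reflectance acquisition produces raw intensity frames (counts vs
wavelength) at ~80 frames/s.  Twenty consecutive frames per probed tissue
site are averaged into a site mean, which is normalised against a white
reflectance standard and a dark-field reading,

    R(lambda) = (S(lambda) - D(lambda)) / (W(lambda) - D(lambda)),

yielding unitless reflectance.  Analysis is restricted to the 468-720 nm
band of the spectrometer grid (0.5 nm spacing, 505 retained samples); the
blue and near-infrared edges are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    ConfigError,
    GridAlignmentError,
    GridMismatchError,
    InsufficientFramesError,
    UnusableCalibrationError,
)

# Spectrum kinds
RAW_FRAME = "raw_frame"
SITE_MEAN = "site_mean"
REFLECTANCE = "reflectance"
KINDS = (RAW_FRAME, SITE_MEAN, REFLECTANCE)

#: Retained analysis band (nm), inclusive on both ends.
ANALYSIS_LO_NM = 468.0
ANALYSIS_HI_NM = 720.0

#: Frames averaged per tissue site by the acquisition protocol.
FRAMES_PER_SITE = 20

#: Minimum point measurements per tissue class required by the protocol.
MIN_SITES_PER_CLASS = 200

#: Acquisition rate of the spectrometer, frames per second.
FRAME_RATE_HZ = 80.0

_GRID_TOL_NM = 1e-6


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform, inclusive wavelength grid in nanometres."""

    start_nm: float
    stop_nm: float
    step_nm: float

    def __post_init__(self) -> None:
        if not (self.start_nm < self.stop_nm):
            raise ConfigError("grid start must be below stop")
        if not (self.step_nm > 0):
            raise ConfigError("grid step must be positive")
        span = self.stop_nm - self.start_nm
        k = span / self.step_nm
        if abs(k - round(k)) > 1e-9 * max(1.0, k):
            raise ConfigError(
                f"grid span {span} nm is not an integer multiple of "
                f"step {self.step_nm} nm"
            )

    @property
    def n_samples(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_samples)

    def index_of(self, nm: float, tol: float = _GRID_TOL_NM) -> int:
        """Index of a wavelength that must land on a grid point."""
        k = (nm - self.start_nm) / self.step_nm
        i = int(round(k))
        if i < 0 or i >= self.n_samples or abs(k - i) * self.step_nm > tol:
            raise GridAlignmentError(
                f"{nm} nm is not a grid point of [{self.start_nm}, "
                f"{self.stop_nm}] @ {self.step_nm} nm"
            )
        return i

    def subgrid(self, lo_nm: float, hi_nm: float) -> "WavelengthGrid":
        i, j = self.index_of(lo_nm), self.index_of(hi_nm)
        if j <= i:
            raise GridAlignmentError("subgrid bounds out of order")
        return WavelengthGrid(
            self.start_nm + i * self.step_nm,
            self.start_nm + j * self.step_nm,
            self.step_nm,
        )


def default_acquisition_grid() -> WavelengthGrid:
    """Full spectrometer grid: 420-1000 nm at 0.5 nm (1161 samples)."""
    return WavelengthGrid(420.0, 1000.0, 0.5)


@dataclass
class SpectrumMeta:
    """Acquisition metadata attached to one spectrum."""

    patient_id: str = ""
    organ: str = ""  # "stomach" | "esophagus"
    site_id: str = ""
    timestamp_s: float = 0.0
    tissue_class: str = "unknown"  # "normal" | "tumor" | "unknown"


@dataclass
class Spectrum:
    """One wavelength-indexed intensity vector plus metadata.

    ``mask`` marks wavelengths that survived calibration; masked entries
    hold 0 and must be ignored downstream.  ``mask is None`` means all
    wavelengths are valid.
    """

    grid: WavelengthGrid
    intensities: np.ndarray
    kind: str = RAW_FRAME
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ConfigError("intensities must be a 1-D vector")
        if len(self.intensities) != self.grid.n_samples:
            raise GridMismatchError(
                f"{len(self.intensities)} intensities on a "
                f"{self.grid.n_samples}-point grid"
            )
        if self.kind not in KINDS:
            raise ConfigError(f"unknown spectrum kind {self.kind!r}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.intensities.shape:
                raise GridMismatchError("mask length differs from grid")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths()


@dataclass
class CalibrationPair:
    """White-reference and dark-field spectra on a shared grid."""

    white: Spectrum
    dark: Spectrum

    def __post_init__(self) -> None:
        if self.white.grid != self.dark.grid:
            raise GridMismatchError("white and dark are on different grids")
        if np.any(self.white.intensities < self.dark.intensities):
            raise CalibrationError(
                "white reference below dark field at some wavelength"
            )

    @property
    def grid(self) -> WavelengthGrid:
        return self.white.grid


class SpectralDataset:
    """Labelled collection of same-kind spectra on one grid.

    Stored columnar: an (n_sites, n_wavelengths) intensity matrix plus a
    site-level metadata frame with columns
    ``site_id, patient_id, organ, tissue_class, timestamp_s``.
    """

    META_COLUMNS = ["site_id", "patient_id", "organ", "tissue_class", "timestamp_s"]

    def __init__(
        self,
        grid: WavelengthGrid,
        intensities: np.ndarray,
        meta: pd.DataFrame,
        kind: str = SITE_MEAN,
        mask: np.ndarray | None = None,
    ) -> None:
        intensities = np.asarray(intensities, dtype=float)
        if intensities.ndim != 2 or intensities.shape[1] != grid.n_samples:
            raise GridMismatchError("intensity matrix does not match grid")
        if len(meta) != intensities.shape[0]:
            raise ConfigError("metadata rows do not match spectra count")
        missing = [c for c in self.META_COLUMNS if c not in meta.columns]
        if missing:
            raise ConfigError(f"metadata missing columns {missing}")
        if meta["site_id"].duplicated().any():
            raise ConfigError("duplicate site_id in dataset")
        self.grid = grid
        self.intensities = intensities
        meta = meta.reset_index(drop=True)
        self.meta = meta.assign(timestamp_s=meta["timestamp_s"].astype(float))
        self.kind = kind
        self.mask = None if mask is None else np.asarray(mask, dtype=bool)

    def __len__(self) -> int:
        return self.intensities.shape[0]

    @property
    def site_ids(self) -> np.ndarray:
        return self.meta["site_id"].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.meta["tissue_class"].to_numpy()

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectralDataset":
        if not spectra:
            raise ConfigError("empty spectrum list")
        grid, kind = spectra[0].grid, spectra[0].kind
        for s in spectra:
            if s.grid != grid:
                raise GridMismatchError("spectra on different grids")
            if s.kind != kind:
                raise ConfigError("mixed spectrum kinds in one dataset")
        meta = pd.DataFrame(
            {
                "site_id": [s.meta.site_id for s in spectra],
                "patient_id": [s.meta.patient_id for s in spectra],
                "organ": [s.meta.organ for s in spectra],
                "tissue_class": [s.meta.tissue_class for s in spectra],
                "timestamp_s": [s.meta.timestamp_s for s in spectra],
            }
        )
        mask = spectra[0].mask
        return cls(grid, np.vstack([s.intensities for s in spectra]), meta, kind, mask)

    def spectrum(self, i: int) -> Spectrum:
        row = self.meta.iloc[i]
        return Spectrum(
            self.grid,
            self.intensities[i].copy(),
            self.kind,
            SpectrumMeta(
                patient_id=row["patient_id"],
                organ=row["organ"],
                site_id=row["site_id"],
                timestamp_s=float(row["timestamp_s"]),
                tissue_class=row["tissue_class"],
            ),
            mask=None if self.mask is None else self.mask.copy(),
        )

    def select(self, keep: np.ndarray) -> "SpectralDataset":
        """Row-subset by boolean mask or integer index array."""
        keep = np.asarray(keep)
        return SpectralDataset(
            self.grid,
            self.intensities[keep],
            self.meta.iloc[keep].reset_index(drop=True),
            self.kind,
            self.mask,
        )

    def select_sites(self, site_ids: Iterable[str]) -> "SpectralDataset":
        wanted = set(site_ids)
        keep = self.meta["site_id"].isin(wanted).to_numpy()
        return self.select(keep)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def average_frames(
    frames: Sequence[Spectrum], n_required: int = FRAMES_PER_SITE
) -> Spectrum:
    """Average the first ``n_required`` raw frames (timestamp order) of a site.

    The acquisition protocol records 20 frames per probed site and displays
    their mean; later frames beyond the protocol count are ignored so site
    means stay comparable.
    """
    if not frames:
        raise InsufficientFramesError("no frames supplied")
    grid = frames[0].grid
    site = frames[0].meta.site_id
    for f in frames:
        if f.grid != grid:
            raise GridMismatchError(f"frame grid mismatch at site {site!r}")
        if f.meta.site_id != site:
            raise GridMismatchError("frames from different sites")
    if len(frames) < n_required:
        raise InsufficientFramesError(
            f"site {site!r}: {len(frames)} frames < required {n_required}"
        )
    ordered = sorted(frames, key=lambda f: f.meta.timestamp_s)[:n_required]
    mean = np.mean([f.intensities for f in ordered], axis=0)
    return Spectrum(grid, mean, SITE_MEAN, replace(ordered[0].meta))


def calibrate(
    raw: Spectrum,
    cal: CalibrationPair,
    floor_eps: float = 1e-3,
    clip_max: float = 2.0,
    smooth_window: int = 0,
) -> Spectrum:
    """Normalise raw counts to reflectance with a white/dark pair.

    R = (S - D) / (W - D).  Wavelengths whose denominator falls below
    ``floor_eps * max(W - D)`` are masked (set to 0, mask=False) — the
    spectrometer has no usable sensitivity there and division would only
    amplify noise.  The result is clipped to [0, clip_max]; specular glints
    can push R above 1 but unbounded values destabilise features.

    ``smooth_window`` > 1 applies a centred moving average after division
    (optional noise reduction; off by default).
    """
    if raw.grid != cal.grid:
        raise GridMismatchError("spectrum and calibration on different grids")
    denom = cal.white.intensities - cal.dark.intensities
    if denom.max() <= 0:
        raise UnusableCalibrationError("white equals dark at every wavelength")
    valid = denom >= floor_eps * denom.max()
    if not valid.any():
        raise UnusableCalibrationError("all wavelengths masked by floor")
    refl = np.zeros_like(denom)
    refl[valid] = (raw.intensities[valid] - cal.dark.intensities[valid]) / denom[valid]
    refl = np.clip(refl, 0.0, clip_max)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        sm = np.convolve(refl, kernel, mode="same")
        # edges: renormalise by actual kernel coverage
        cov = np.convolve(np.ones_like(refl), kernel, mode="same")
        refl = sm / cov
    mask = None if valid.all() else valid
    return Spectrum(raw.grid, refl, REFLECTANCE, replace(raw.meta), mask=mask)


def calibrate_dataset(
    ds: SpectralDataset,
    cal: CalibrationPair,
    floor_eps: float = 1e-3,
    clip_max: float = 2.0,
) -> SpectralDataset:
    """Vectorised :func:`calibrate` over every site of a dataset."""
    if ds.grid != cal.grid:
        raise GridMismatchError("dataset and calibration on different grids")
    denom = cal.white.intensities - cal.dark.intensities
    if denom.max() <= 0:
        raise UnusableCalibrationError("white equals dark at every wavelength")
    valid = denom >= floor_eps * denom.max()
    if not valid.any():
        raise UnusableCalibrationError("all wavelengths masked by floor")
    refl = np.zeros_like(ds.intensities)
    refl[:, valid] = (
        ds.intensities[:, valid] - cal.dark.intensities[valid]
    ) / denom[valid]
    refl = np.clip(refl, 0.0, clip_max)
    mask = None if valid.all() else valid
    return SpectralDataset(ds.grid, refl, ds.meta.copy(), REFLECTANCE, mask)


def crop_to_analysis_range(
    s: "Spectrum | SpectralDataset",
    lo_nm: float = ANALYSIS_LO_NM,
    hi_nm: float = ANALYSIS_HI_NM,
):
    """Restrict to the inclusive [lo_nm, hi_nm] band (default 468-720 nm).

    Bounds must land exactly on grid points — there is deliberately no
    interpolation; off-grid requests raise :class:`GridAlignmentError`.
    """
    grid = s.grid
    i, j = grid.index_of(lo_nm), grid.index_of(hi_nm)
    if j <= i:
        raise GridAlignmentError("crop bounds out of order")
    sub = grid.subgrid(lo_nm, hi_nm)
    sl = slice(i, j + 1)
    if isinstance(s, SpectralDataset):
        return SpectralDataset(
            sub,
            s.intensities[:, sl],
            s.meta.copy(),
            s.kind,
            None if s.mask is None else s.mask[sl],
        )
    return Spectrum(
        sub,
        s.intensities[sl].copy(),
        s.kind,
        replace(s.meta),
        mask=None if s.mask is None else s.mask[sl],
    )


@dataclass
class ValidationReport:
    """Per-class site counts against the protocol minimum."""

    counts: dict[str, int]
    min_sites_per_class: int
    flagged: list[str]

    @property
    def ok(self) -> bool:
        return not self.flagged


def validate_dataset(
    ds: SpectralDataset, min_sites_per_class: int = MIN_SITES_PER_CLASS
) -> ValidationReport:
    """Check the protocol's minimum site count per tissue class.

    Reporting only — never mutates the dataset.  A class absent from the
    dataset counts as zero and is flagged.
    """
    if len(ds) == 0:
        raise ConfigError("empty dataset")
    counts = ds.meta["tissue_class"].value_counts().to_dict()
    for cls_name in ("normal", "tumor"):
        counts.setdefault(cls_name, 0)
    flagged = sorted(c for c, n in counts.items() if n < min_sites_per_class)
    return ValidationReport(counts, min_sites_per_class, flagged)


# ---------------------------------------------------------------------------
# I/O — long-form CSV for spectra, wide CSV for calibration pairs
# ---------------------------------------------------------------------------

LONG_COLUMNS = [
    "patient_id",
    "organ",
    "site_id",
    "tissue_class",
    "kind",
    "timestamp_s",
    "wavelength_nm",
    "intensity",
]


def dataset_to_csv(ds: SpectralDataset, path) -> None:
    """Write a dataset as long-form CSV (one row per site x wavelength)."""
    wl = ds.grid.wavelengths()
    n_wl = len(wl)
    rep = ds.meta.loc[ds.meta.index.repeat(n_wl)].reset_index(drop=True)
    frame = pd.DataFrame(
        {
            "patient_id": rep["patient_id"],
            "organ": rep["organ"],
            "site_id": rep["site_id"],
            "tissue_class": rep["tissue_class"],
            "kind": ds.kind,
            "timestamp_s": rep["timestamp_s"],
            "wavelength_nm": np.tile(wl, len(ds)),
            "intensity": ds.intensities.ravel(),
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def dataset_from_csv(path) -> SpectralDataset:
    """Read a long-form CSV written by :func:`dataset_to_csv`.

    Intensities round-trip bit-exactly (written at full double precision).
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LONG_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigError(f"spectra CSV missing columns {missing}")
    wl = np.sort(frame["wavelength_nm"].unique())
    if len(wl) < 2:
        raise ConfigError("need at least two wavelengths")
    steps = np.diff(wl)
    step = steps[0]
    if not np.allclose(steps, step, atol=1e-9):
        raise ConfigError("non-uniform wavelength grid in CSV")
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(step))
    kinds = frame["kind"].unique()
    if len(kinds) != 1:
        raise ConfigError("mixed spectrum kinds in CSV")
    pivot = frame.pivot_table(
        index="site_id", columns="wavelength_nm", values="intensity", sort=False
    )
    pivot = pivot.reindex(columns=wl)
    meta = (
        frame.drop_duplicates("site_id")
        .set_index("site_id")
        .loc[pivot.index]
        .reset_index()[SpectralDataset.META_COLUMNS]
    )
    return SpectralDataset(grid, pivot.to_numpy(), meta, str(kinds[0]))


def calibration_to_csv(cal: CalibrationPair, path) -> None:
    """Two-row wide CSV keyed by wavelength: rows 'white' and 'dark'."""
    wl = cal.grid.wavelengths()
    frame = pd.DataFrame(
        [cal.white.intensities, cal.dark.intensities],
        index=pd.Index(["white", "dark"], name="reference"),
        columns=[f"{w:.6g}" for w in wl],
    )
    frame.to_csv(path, float_format="%.17g")


def calibration_from_csv(path) -> CalibrationPair:
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    wl = frame.columns.to_numpy(dtype=float)
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(wl[1] - wl[0]))
    white = Spectrum(grid, frame.loc["white"].to_numpy(), RAW_FRAME)
    dark = Spectrum(grid, frame.loc["dark"].to_numpy(), RAW_FRAME)
    return CalibrationPair(white, dark)
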