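"""Synthetic DRS acquisitions and probe-video scenes with ground truth.

No study data were deposited, so every stage of the pipeline is exercised
on simulated inputs that reproduce the statistical structure the method
assumes:

* two tissue classes whose mean reflectance differs most inside the
  600-700 nm band, on the spectrometer's 420-1000 nm grid at 0.5 nm;
* 20 raw frames per probed site at 80 frames/s, averaged to a site mean;
* a white/dark calibration pair such that calibration recovers the
  designed reflectance exactly in the noise-free limit;
* per-patient baseline offsets and spectral tilt (inter-patient
  variability), per-site jitter, and per-frame noise;
* injected acquisition artifacts — no-contact sites (near-dark frames)
  and outlier sites (amplitude spikes) — at configurable rates, all
  recorded in the ground truth.

The tissue model is parametric, not a real chromophore table: a broad
scattering baseline with two haemoglobin-like Gaussian absorption dips
(540 and 575 nm) and, for tumor tissue, an added Gaussian contrast band
centred in 600-700 nm.  The tumor contrast interacts with the patient
baseline offset (patients with below-average baseline show attenuated
contrast), which builds a nonlinear class boundary: threshold-based
ensembles can condition on the overall level while a single linear rule
cannot.

Generation is a pure function of (config, seed): identical configs give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .overlay import ClassifiedSite
from .spectra import (
    ANALYSIS_HI_NM,
    ANALYSIS_LO_NM,
    FRAME_RATE_HZ,
    RAW_FRAME,
    SITE_MEAN,
    CalibrationPair,
    SpectralDataset,
    Spectrum,
    SpectrumMeta,
    default_acquisition_grid,
)

ORGANS = ("stomach", "esophagus")


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectraGenConfig:
    """Study conditions for the spectral simulator (defaults = protocol scale
    at desk size: 8 patients/organ x 25 sites/class -> 200 sites per class
    per organ, the protocol's minimum)."""

    organs: tuple[str, ...] = ORGANS
    n_patients_per_organ: int = 8
    sites_per_class_per_patient: int = 25
    contrast_amplitude: float = 0.12  # reflectance units
    contrast_band_nm: tuple[float, float] = (600.0, 700.0)
    interpatient_sd: float = 0.04  # flat baseline offset per patient
    tilt_sd: float = 0.02  # per-patient spectral slope amplitude
    site_jitter_sd: float = 0.008  # SD of smooth site-to-site variation
    frame_noise_sd: float = 0.02  # per-frame noise, reflectance units
    no_contact_fraction: float = 0.05
    outlier_fraction: float = 0.05
    outlier_spike_amplitude: float = 0.6
    weak_contrast_factor: float = -0.6  # tumor contrast scale for low-offset patients
    nonlinear_boundary: bool = True
    frames_per_site: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.no_contact_fraction, self.outlier_fraction):
            if not (0.0 <= f <= 1.0):
                raise ConfigError("artifact fractions must lie in [0, 1]")
        if self.contrast_amplitude < 0:
            raise ConfigError("contrast amplitude must be >= 0")
        lo, hi = self.contrast_band_nm
        if not (ANALYSIS_LO_NM <= lo < hi <= ANALYSIS_HI_NM):
            raise ConfigError(
                f"contrast band {self.contrast_band_nm} outside the analysis "
                f"range [{ANALYSIS_LO_NM}, {ANALYSIS_HI_NM}] nm"
            )
        if self.frames_per_site < 1:
            raise ConfigError("frames_per_site must be >= 1")


@dataclass
class GroundTruth:
    """Generator-side truth for one synthetic spectra run."""

    sites: pd.DataFrame  # site_id, patient_id, organ, tissue_class, artifact
    designed_reflectance: np.ndarray  # (n_sites, n_wavelengths), pre-noise
    grid: object

    @property
    def artifact_site_ids(self) -> np.ndarray:
        return self.sites.loc[
            self.sites["artifact"] != "none", "site_id"
        ].to_numpy()

    def class_mean(self, tissue_class: str, organ: str | None = None) -> np.ndarray:
        """Designed mean reflectance of a class (artifact sites excluded)."""
        sel = (self.sites["tissue_class"] == tissue_class) & (
            self.sites["artifact"] == "none"
        )
        if organ is not None:
            sel &= self.sites["organ"] == organ
        return self.designed_reflectance[sel.to_numpy()].mean(axis=0)


class SyntheticSpectra:
    """Raw frames + calibration pair + ground truth from one generator run."""

    def __init__(
        self,
        grid,
        raw_frames: np.ndarray,  # (n_sites, frames_per_site, n_wl), counts
        meta: pd.DataFrame,
        timestamps: np.ndarray,  # (n_sites, frames_per_site), seconds
        calibration: CalibrationPair,
        truth: GroundTruth,
    ) -> None:
        self.grid = grid
        self.raw_frames = raw_frames
        self.meta = meta
        self.timestamps = timestamps
        self.calibration = calibration
        self.truth = truth

    def __len__(self) -> int:
        return self.raw_frames.shape[0]

    def site_frames(self, i: int) -> list[Spectrum]:
        """The raw frames of one site as Spectrum objects, timestamp order."""
        row = self.meta.iloc[i]
        return [
            Spectrum(
                self.grid,
                self.raw_frames[i, j],
                RAW_FRAME,
                SpectrumMeta(
                    patient_id=row["patient_id"],
                    organ=row["organ"],
                    site_id=row["site_id"],
                    timestamp_s=float(self.timestamps[i, j]),
                    tissue_class=row["tissue_class"],
                ),
            )
            for j in range(self.raw_frames.shape[1])
        ]

    def site_mean_dataset(self) -> SpectralDataset:
        """Frame-averaged site means (the protocol's 20-frame mean)."""
        means = self.raw_frames.mean(axis=1)
        return SpectralDataset(self.grid, means, self.meta.copy(), SITE_MEAN)


def _tissue_baseline(wl: np.ndarray) -> np.ndarray:
    """Scattering baseline with haemoglobin-like dips at 540 and 575 nm."""
    base = 0.28 + 0.42 * np.exp(-((wl - 650.0) ** 2) / (2 * 55.0**2))
    dip1 = 0.08 * np.exp(-((wl - 540.0) ** 2) / (2 * 12.0**2))
    dip2 = 0.07 * np.exp(-((wl - 575.0) ** 2) / (2 * 12.0**2))
    return base - dip1 - dip2


def _lamp_white(wl: np.ndarray) -> np.ndarray:
    return 3500.0 * np.exp(-(((wl - 680.0) / 300.0) ** 2)) + 600.0


def _dark_field(wl: np.ndarray) -> np.ndarray:
    return 150.0 + 0.02 * wl


def generate_spectra(cfg: SpectraGenConfig | None = None) -> SyntheticSpectra:
    """Simulate one ex vivo acquisition session."""
    cfg = cfg or SpectraGenConfig()
    rng = np.random.default_rng(cfg.seed)
    grid = default_acquisition_grid()
    wl = grid.wavelengths()
    n_wl = grid.n_samples

    lo, hi = cfg.contrast_band_nm
    band_center = 0.5 * (lo + hi)
    band_sigma = (hi - lo) / 4.0  # band covers +/- 2 sigma
    contrast_shape = np.exp(-((wl - band_center) ** 2) / (2 * band_sigma**2))
    tilt_shape = (wl - wl.mean()) / (wl.max() - wl.min())  # -0.5 .. 0.5
    # within-patient site-to-site variation: a smooth wavelength-correlated
    # perturbation (local vascularity / chromophore density varies smoothly
    # in wavelength), correlation length ~8 nm on the 0.5 nm grid
    from scipy.ndimage import gaussian_filter1d

    _smooth_sigma = 16.0  # grid samples
    _impulse = np.zeros(8 * int(_smooth_sigma) + 1)
    _impulse[len(_impulse) // 2] = 1.0
    _kernel_norm = np.sqrt(
        np.sum(gaussian_filter1d(_impulse, _smooth_sigma) ** 2)
    )

    def _site_variation(r):
        white_noise = r.normal(0.0, 1.0, n_wl)
        return (
            cfg.site_jitter_sd
            * gaussian_filter1d(white_noise, _smooth_sigma, mode="nearest")
            / _kernel_norm
        )

    baseline = _tissue_baseline(wl)
    rows, designed, tstamps = [], [], []
    t_cursor = 0.0
    for organ in cfg.organs:
        for p in range(cfg.n_patients_per_organ):
            patient = f"{organ}_pat{p:02d}"
            offset = rng.normal(0.0, cfg.interpatient_sd)
            tilt = rng.normal(0.0, cfg.tilt_sd)
            if cfg.nonlinear_boundary:
                amp = cfg.contrast_amplitude * (
                    1.0 if offset >= 0 else cfg.weak_contrast_factor
                )
            else:
                amp = cfg.contrast_amplitude
            for tissue in ("normal", "tumor"):
                for s in range(cfg.sites_per_class_per_patient):
                    r = baseline + offset + tilt * tilt_shape + _site_variation(rng)
                    if tissue == "tumor":
                        r = r + amp * contrast_shape
                    designed.append(r)
                    rows.append(
                        {
                            "site_id": f"{organ}_p{p:02d}_{tissue}_{s:03d}",
                            "patient_id": patient,
                            "organ": organ,
                            "tissue_class": tissue,
                            "timestamp_s": t_cursor,
                        }
                    )
                    tstamps.append(
                        t_cursor + np.arange(cfg.frames_per_site) / FRAME_RATE_HZ
                    )
                    t_cursor += cfg.frames_per_site / FRAME_RATE_HZ + 0.25
    meta = pd.DataFrame(rows)
    designed = np.asarray(designed)
    tstamps = np.asarray(tstamps)
    n_sites = len(meta)

    # artifact injection: disjoint no-contact and outlier site sets
    artifact = np.array(["none"] * n_sites, dtype=object)
    n_nc = int(round(cfg.no_contact_fraction * n_sites))
    n_out = int(round(cfg.outlier_fraction * n_sites))
    chosen = rng.choice(n_sites, size=min(n_nc + n_out, n_sites), replace=False)
    nc_idx, out_idx = chosen[:n_nc], chosen[n_nc:]
    artifact[nc_idx] = "no_contact"
    artifact[out_idx] = "outlier"
    for i in out_idx:
        center = rng.uniform(500.0, 700.0)
        designed[i] = designed[i] + cfg.outlier_spike_amplitude * np.exp(
            -((wl - center) ** 2) / (2 * 10.0**2)
        )
    meta["artifact"] = artifact  # kept only in the truth frame below

    white, dark = _lamp_white(wl), _dark_field(wl)
    gain = white - dark
    refl_frames = (
        designed[:, None, :]
        + rng.normal(0.0, cfg.frame_noise_sd, (n_sites, cfg.frames_per_site, n_wl))
        if cfg.frame_noise_sd > 0
        else np.repeat(designed[:, None, :], cfg.frames_per_site, axis=1)
    )
    # no-contact sites: the probe collects (almost) nothing above dark
    if len(nc_idx):
        nc_level = np.abs(
            rng.normal(0.0, 0.004, (len(nc_idx), cfg.frames_per_site, n_wl))
        )
        refl_frames[nc_idx] = nc_level
        designed[nc_idx] = 0.0
    raw = dark + refl_frames * gain

    cal = CalibrationPair(
        Spectrum(grid, white, RAW_FRAME, SpectrumMeta(site_id="white_ref")),
        Spectrum(grid, dark, RAW_FRAME, SpectrumMeta(site_id="dark_ref")),
    )
    truth = GroundTruth(
        sites=meta[
            ["site_id", "patient_id", "organ", "tissue_class", "artifact"]
        ].copy(),
        designed_reflectance=designed,
        grid=grid,
    )
    return SyntheticSpectra(
        grid,
        raw,
        meta.drop(columns=["artifact"]),
        tstamps,
        cal,
        truth,
    )


# ---------------------------------------------------------------------------
# Probe-video scenes
# ---------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """A textured tissue-coloured background with a moving green marker."""

    frame_height: int = 240
    frame_width: int = 320
    n_frames: int = 200
    marker_radius: float = 6.0
    marker_hue_deg: float = 120.0
    marker_sat: float = 0.75
    marker_val: float = 0.85
    trajectory: str = "sinusoid"  # "sinusoid" | "linear" | "static"
    start: tuple[float, float] = (160.0, 120.0)  # (x, y) px
    velocity: tuple[float, float] = (2.0, 0.0)  # linear, px/frame
    amplitude: tuple[float, float] = (90.0, 60.0)  # sinusoid, px
    period_frames: tuple[float, float] = (120.0, 80.0)
    occlusion: tuple[tuple[int, int], ...] = ()  # half-open [start, stop)
    texture_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if 2 * self.marker_radius >= min(self.frame_height, self.frame_width):
            raise ConfigError("marker larger than the frame")
        for a, b in self.occlusion:
            if not (0 <= a < b <= self.n_frames):
                raise ConfigError(f"occlusion interval ({a}, {b}) out of range")


@dataclass
class SceneTruth:
    """Per-frame true marker centroid and occlusion flag."""

    frames: pd.DataFrame = field(default_factory=pd.DataFrame)  # frame, cx, cy, occluded


def _trajectory(cfg: SceneConfig) -> np.ndarray:
    t = np.arange(cfg.n_frames, dtype=float)
    x0, y0 = cfg.start
    if cfg.trajectory == "static":
        x, y = np.full_like(t, x0), np.full_like(t, y0)
    elif cfg.trajectory == "linear":
        x, y = x0 + cfg.velocity[0] * t, y0 + cfg.velocity[1] * t
    elif cfg.trajectory == "sinusoid":
        ax, ay = cfg.amplitude
        px, py = cfg.period_frames
        x = x0 + ax * np.sin(2 * np.pi * t / px)
        y = y0 + ay * np.sin(2 * np.pi * t / py + np.pi / 3)
    else:
        raise ConfigError(f"unknown trajectory {cfg.trajectory!r}")
    return np.column_stack([x, y])


def generate_scene(
    cfg: SceneConfig | None = None,
) -> tuple[list[np.ndarray], SceneTruth]:
    """Render a synthetic probe video; truth centroids for every frame
    (including occluded ones, where the marker simply is not drawn)."""
    import colorsys

    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    traj = _trajectory(cfg)
    h, w, r = cfg.frame_height, cfg.frame_width, cfg.marker_radius
    if (
        traj[:, 0].min() < r
        or traj[:, 0].max() > w - 1 - r
        or traj[:, 1].min() < r
        or traj[:, 1].max() > h - 1 - r
    ):
        raise ConfigError("trajectory leaves the frame bounds")

    occluded = np.zeros(cfg.n_frames, dtype=bool)
    for a, b in cfg.occlusion:
        occluded[a:b] = True

    # static tissue-coloured texture (reddish, away from the marker hue)
    from scipy.ndimage import gaussian_filter

    base = np.array([0.55, 0.30, 0.28])
    texture = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=6.0)
    texture = cfg.texture_sd * texture / max(texture.std(), 1e-12)
    background = np.clip(base[None, None, :] + texture[..., None], 0.0, 1.0)

    marker_rgb = np.array(
        colorsys.hsv_to_rgb(
            cfg.marker_hue_deg / 360.0, cfg.marker_sat, cfg.marker_val
        )
    )
    yy, xx = np.mgrid[0:h, 0:w]
    frames = []
    for i in range(cfg.n_frames):
        img = background + rng.normal(0.0, 0.005, (h, w, 1))
        if not occluded[i]:
            cx, cy = traj[i]
            disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
            img[disc] = marker_rgb
        frames.append(
            np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
        )
    truth = SceneTruth(
        pd.DataFrame(
            {
                "frame": np.arange(cfg.n_frames),
                "cx": traj[:, 0],
                "cy": traj[:, 1],
                "occluded": occluded,
            }
        )
    )
    return frames, truth


def generate_classified_sites(
    n_sites: int,
    frame_height: int = 240,
    frame_width: int = 320,
    min_separation: float = 14.0,
    seed: int = 0,
) -> tuple[list[ClassifiedSite], list[str]]:
    """Random non-overlapping sampled sites with known classes.

    Positions are drawn on a jittered grid so circles of the default
    overlay radius never overlap; returns (sites, true hard labels).
    """
    rng = np.random.default_rng(seed)
    step = int(np.ceil(min_separation))
    margin = step // 2 + 1
    xs = np.arange(margin, frame_width - margin, step)
    ys = np.arange(margin, frame_height - margin, step)
    grid_pts = [(float(x), float(y)) for y in ys for x in xs]
    if len(grid_pts) < n_sites:
        raise ConfigError("frame too small for that many separated sites")
    chosen = rng.choice(len(grid_pts), size=n_sites, replace=False)
    sites, labels = [], []
    for k, gi in enumerate(chosen):
        x, y = grid_pts[gi]
        p = float(rng.uniform(0.0, 1.0))
        sites.append(ClassifiedSite(frame_index=k, x=x, y=y, p_tumor=p))
        labels.append("tumor" if p >= 0.5 else "normal")
    return sites, labels
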