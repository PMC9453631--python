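"""Probe-tip tracking: HSV marker segmentation + constant-velocity Kalman.

The probe tip carries a green tape marker chosen to contrast with the hue
distribution of biological tissue.  Each video frame is segmented in HSV
space; the centroid of the largest connected green component is the
measurement.  A 4-state (x, y, vx, vy) Kalman filter with
white-acceleration process noise smooths the trajectory and coasts through
detection gaps (occlusion), so the sampled-site coordinates are known for
every frame.

Coordinates are pixel-centred: origin at the centre of the top-left pixel,
x rightward, y downward; velocities in px/frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import ConfigError, NoTrackError, NumericStateError

_PSD_TOL = -1e-9


@dataclass
class HSVRange:
    """Hue band in degrees (wraparound allowed), sat/val bands in [0, 1]."""

    hue_lo: float = 90.0
    hue_hi: float = 150.0
    sat_lo: float = 0.4
    sat_hi: float = 1.0
    val_lo: float = 0.2
    val_hi: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.hue_lo < 360 and 0 <= self.hue_hi < 360):
            raise ConfigError("hue bounds must lie in [0, 360)")
        if self.sat_lo > self.sat_hi or self.val_lo > self.val_hi:
            raise ConfigError("sat/val bounds out of order")

    def contains(self, h_deg, s, v):
        """Vectorised membership; handles the hue wraparound."""
        if self.hue_lo <= self.hue_hi:
            hue_ok = (h_deg >= self.hue_lo) & (h_deg <= self.hue_hi)
        else:  # e.g. red: 350..10
            hue_ok = (h_deg >= self.hue_lo) | (h_deg <= self.hue_hi)
        return (
            hue_ok
            & (s >= self.sat_lo)
            & (s <= self.sat_hi)
            & (v >= self.val_lo)
            & (v <= self.val_hi)
        )


def _as_float_rgb(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] < 3:
        raise ConfigError("expected an RGB image (H, W, 3)")
    frame = frame[..., :3]
    if frame.dtype == np.uint8 or frame.max() > 1.0:
        return frame.astype(float) / 255.0
    return frame.astype(float)


def segment_marker(
    frame: np.ndarray,
    hsv: HSVRange | None = None,
    min_area: float = 25.0,
) -> tuple[float, float] | None:
    """Centroid (x, y) of the largest in-range component, or None.

    Components use 4-connectivity; a component counts only if its area is
    at least ``min_area`` px².  Absence of the marker is a valid outcome,
    not an error.
    """
    hsv = hsv or HSVRange()
    rgb = _as_float_rgb(frame)
    if rgb.size == 0:
        raise ConfigError("empty frame")
    hsv_img = rgb2hsv(rgb)
    mask = hsv.contains(hsv_img[..., 0] * 360.0, hsv_img[..., 1], hsv_img[..., 2])
    if not mask.any():
        return None
    labels = cc_label(mask, connectivity=1)
    regions = regionprops(labels)
    best = max(regions, key=lambda r: r.area)
    if best.area < min_area:
        return None
    cy, cx = best.centroid  # row, col
    return float(cx), float(cy)


@dataclass
class KalmanConfig:
    q: float = 0.3  # white-acceleration variance, px²/frame⁴
    r: float = 2.0  # measurement variance, px²
    init_pos_var: float = 25.0
    init_vel_var: float = 100.0

    def __post_init__(self) -> None:
        if self.q < 0 or self.r < 0:
            raise ConfigError("noise variances must be non-negative")


# Constant-velocity model, dt = 1 frame.
_F = np.array(
    [[1.0, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]]
)
_G = np.array([[0.5, 0], [0, 0.5], [1.0, 0], [0, 1.0]])
_H = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])


@dataclass
class KalmanState:
    """State (x, y, vx, vy) with covariance; PSD enforced on entry."""

    state: np.ndarray
    covariance: np.ndarray
    q: float = 0.3
    r: float = 2.0

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=float).reshape(4)
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(4, 4)
        _check_psd(self.covariance)

    @property
    def position(self) -> np.ndarray:
        return self.state[:2]

    @property
    def velocity(self) -> np.ndarray:
        return self.state[2:]


def _check_psd(P: np.ndarray) -> None:
    if not np.allclose(P, P.T, atol=1e-6):
        raise NumericStateError("covariance not symmetric")
    if np.linalg.eigvalsh(P).min() < _PSD_TOL:
        raise NumericStateError("covariance not positive semidefinite")


def kalman_predict(ks: KalmanState) -> KalmanState:
    """Propagate one frame under the constant-velocity model."""
    Q = ks.q * (_G @ _G.T)
    state = _F @ ks.state
    P = _F @ ks.covariance @ _F.T + Q
    P = 0.5 * (P + P.T)
    return KalmanState(state, P, ks.q, ks.r)


def kalman_update(ks: KalmanState, measurement: Sequence[float]) -> KalmanState:
    """Position-only measurement update (Joseph-form covariance)."""
    z = np.asarray(measurement, dtype=float).reshape(2)
    if not np.isfinite(z).all():
        raise NumericStateError("non-finite measurement")
    R = ks.r * np.eye(2)
    S = _H @ ks.covariance @ _H.T + R
    if np.linalg.cond(S) > 1e12:
        raise NumericStateError("singular innovation covariance")
    K = ks.covariance @ _H.T @ np.linalg.inv(S)
    state = ks.state + K @ (z - _H @ ks.state)
    IKH = np.eye(4) - K @ _H
    P = IKH @ ks.covariance @ IKH.T + K @ R @ K.T
    P = 0.5 * (P + P.T)
    return KalmanState(state, P, ks.q, ks.r)


def init_state(
    measurement: Sequence[float], cfg: KalmanConfig | None = None
) -> KalmanState:
    """Weakly informative start at the first detection, zero velocity."""
    cfg = cfg or KalmanConfig()
    z = np.asarray(measurement, dtype=float)
    P = np.diag(
        [cfg.init_pos_var, cfg.init_pos_var, cfg.init_vel_var, cfg.init_vel_var]
    )
    return KalmanState(np.array([z[0], z[1], 0.0, 0.0]), P, cfg.q, cfg.r)


@dataclass
class Track:
    """Per-frame tip estimates aligned to the input frames."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["frame", "x", "y", "found", "meas_x", "meas_y", "cov_trace"]
        )
    )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def positions(self) -> np.ndarray:
        return self.frame[["x", "y"]].to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Track":
        return cls(pd.read_csv(path))


def track_video(
    frames: Iterable[np.ndarray],
    hsv: HSVRange | None = None,
    kcfg: KalmanConfig | None = None,
    min_area: float = 25.0,
) -> Track:
    """Track the marker through an image sequence.

    Per frame: Kalman predict, then update if segmentation found the
    marker, else coast on the prediction and flag the gap.  The filter is
    initialised at the first detection; earlier frames are flagged
    undetected with NaN estimates.  Raises :class:`NoTrackError` if the
    marker is never detected.
    """
    hsv = hsv or HSVRange()
    kcfg = kcfg or KalmanConfig()
    rows = []
    ks: KalmanState | None = None
    n = 0
    for i, frame in enumerate(frames):
        n += 1
        meas = segment_marker(frame, hsv, min_area)
        if ks is None:
            if meas is None:
                rows.append(
                    dict(
                        frame=i, x=np.nan, y=np.nan, found=False,
                        meas_x=np.nan, meas_y=np.nan, cov_trace=np.nan,
                    )
                )
                continue
            ks = init_state(meas, kcfg)
        else:
            ks = kalman_predict(ks)
            if meas is not None:
                ks = kalman_update(ks, meas)
        rows.append(
            dict(
                frame=i,
                x=float(ks.state[0]),
                y=float(ks.state[1]),
                found=meas is not None,
                meas_x=meas[0] if meas else np.nan,
                meas_y=meas[1] if meas else np.nan,
                cov_trace=float(np.trace(ks.covariance)),
            )
        )
    if n == 0:
        raise ConfigError("no frames supplied")
    if ks is None:
        raise NoTrackError("marker never detected in the sequence")
    return Track(pd.DataFrame(rows))
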