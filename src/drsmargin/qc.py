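"""Automated quality control of calibrated reflectance datasets.

Two deterministic filters run before feature extraction:

1. Contact-artifact removal — a site where the probe lost tissue contact
   collects almost no diffusely reflected light, so its reflectance is near
   zero across the band.  A site is dropped when the fraction of wavelengths
   below ``contact_floor`` exceeds ``contact_fraction``.

2. Outlier removal — erroneous measurements (air interference, specular
   spikes) are flagged by a robust distance rule *within each
   (patient, tissue class) group*, which respects inter-patient variability:
   a site is dropped when its Euclidean distance to the group's pointwise
   median spectrum exceeds median(d) + k * 1.4826 * MAD(d).

Filters only exclude sites; intensity values are never modified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, PreconditionError
from .spectra import REFLECTANCE, SpectralDataset

#: Consistency constant making MAD an unbiased sigma estimate under normality.
MAD_SCALE = 1.4826

#: Groups smaller than this are skipped by the outlier filter.
MIN_GROUP_SIZE = 5


@dataclass
class QCConfig:
    contact_floor: float = 0.02  # reflectance below this counts as "dark"
    contact_fraction: float = 0.8  # fraction of dark wavelengths that rejects
    outlier_k: float = 3.5  # MAD multiplier
    max_removal_fraction: float = 0.1  # per-group cap for the outlier filter

    def __post_init__(self) -> None:
        if not (0 < self.contact_fraction <= 1):
            raise ConfigError("contact_fraction must be in (0, 1]")
        if self.outlier_k <= 0:
            raise ConfigError("outlier_k must be positive")
        if not (0 < self.max_removal_fraction < 1):
            raise ConfigError("max_removal_fraction must be in (0, 1)")


@dataclass
class QCReport:
    """Removal decisions; the three id sets partition the input sites."""

    removed_contact: list[str] = field(default_factory=list)
    removed_outlier: list[str] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)
    scores: pd.DataFrame | None = None  # site_id, decision, score
    warnings: list[str] = field(default_factory=list)

    def merged_with(self, other: "QCReport") -> "QCReport":
        kept = [s for s in self.kept if s in set(other.kept)]
        scores = pd.concat(
            [f for f in (self.scores, other.scores) if f is not None],
            ignore_index=True,
        )
        return QCReport(
            removed_contact=self.removed_contact + other.removed_contact,
            removed_outlier=self.removed_outlier + other.removed_outlier,
            kept=kept,
            scores=scores,
            warnings=self.warnings + other.warnings,
        )

    def to_csv(self, path) -> None:
        self.scores.to_csv(path, index=False)


def _require_reflectance(ds: SpectralDataset) -> None:
    if ds.kind != REFLECTANCE:
        raise PreconditionError(
            f"QC expects calibrated reflectance, got kind {ds.kind!r}"
        )


def remove_contact_artifacts(
    ds: SpectralDataset, cfg: QCConfig | None = None
) -> tuple[SpectralDataset, QCReport]:
    """Drop sites whose spectra indicate lack of probe-tissue contact."""
    cfg = cfg or QCConfig()
    _require_reflectance(ds)
    x = ds.intensities
    if ds.mask is not None:
        x = x[:, ds.mask]
    dark_frac = np.mean(x < cfg.contact_floor, axis=1)
    removed = dark_frac > cfg.contact_fraction
    ids = ds.site_ids
    scores = pd.DataFrame(
        {
            "site_id": ids,
            "decision": np.where(removed, "removed_contact", "kept"),
            "score": dark_frac,
            "filter": "contact",
        }
    )
    report = QCReport(
        removed_contact=list(ids[removed]),
        kept=list(ids[~removed]),
        scores=scores,
    )
    return ds.select(~removed), report


def remove_outliers(
    ds: SpectralDataset, cfg: QCConfig | None = None
) -> tuple[SpectralDataset, QCReport]:
    """Drop robust-distance outliers within each (patient, class) group.

    Never removes more than ``max_removal_fraction`` of a group: if the
    threshold would exceed the cap, only the worst offenders up to the cap
    are removed and a warning is recorded.  Groups smaller than
    :data:`MIN_GROUP_SIZE` are skipped (warned, nothing removed).
    Decisions do not depend on the ordering of sites in the input.
    """
    cfg = cfg or QCConfig()
    _require_reflectance(ds)
    x = ds.intensities
    if ds.mask is not None:
        x = x[:, ds.mask]
    ids = ds.site_ids
    remove = np.zeros(len(ds), dtype=bool)
    distance = np.full(len(ds), np.nan)
    notes: list[str] = []
    groups = ds.meta.groupby(["patient_id", "tissue_class"], sort=True).indices
    for (patient, tissue), idx in sorted(groups.items()):
        idx = np.sort(np.asarray(idx))
        if len(idx) < MIN_GROUP_SIZE:
            msg = (
                f"outlier filter skipped group ({patient}, {tissue}): "
                f"only {len(idx)} sites"
            )
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        cap = int(np.floor(cfg.max_removal_fraction * len(idx)))
        live = np.ones(len(idx), dtype=bool)
        # iterate the rule to a fixed point (statistics recomputed on the
        # survivors) so a rerun at the same config removes nothing more;
        # the cap is cumulative over the iterations
        while True:
            med = np.median(x[idx[live]], axis=0)
            d_live = np.linalg.norm(x[idx[live]] - med, axis=1)
            distance[idx[live]] = d_live
            mad = np.median(np.abs(d_live - np.median(d_live)))
            thr = np.median(d_live) + cfg.outlier_k * MAD_SCALE * mad
            flag = d_live > thr
            budget = cap - int((~live).sum())
            if flag.sum() > budget:
                msg = (
                    f"group ({patient}, {tissue}): {int(flag.sum())} outliers "
                    f"exceed cap {cap}; removing only the worst {budget}"
                )
                notes.append(msg)
                warnings.warn(msg, stacklevel=2)
                worst = np.argsort(-d_live, kind="stable")[:budget]
                flag = np.zeros_like(flag)
                flag[worst] = True
                live[np.flatnonzero(live)[flag]] = False
                break
            if not flag.any():
                break
            live[np.flatnonzero(live)[flag]] = False
        remove[idx[~live]] = True
    scores = pd.DataFrame(
        {
            "site_id": ids,
            "decision": np.where(remove, "removed_outlier", "kept"),
            "score": distance,
            "filter": "outlier",
        }
    )
    report = QCReport(
        removed_outlier=list(ids[remove]),
        kept=list(ids[~remove]),
        scores=scores,
        warnings=notes,
    )
    return ds.select(~remove), report


def run_qc(
    ds: SpectralDataset, cfg: QCConfig | None = None
) -> tuple[SpectralDataset, QCReport]:
    """Contact filter followed by outlier filter; merged report."""
    cfg = cfg or QCConfig()
    ds1, rep1 = remove_contact_artifacts(ds, cfg)
    ds2, rep2 = remove_outliers(ds1, cfg)
    return ds2, rep1.merged_with(rep2)
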