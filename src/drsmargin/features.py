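"""Peak-based spectral features and feature-selection methods.

Each QC-passed reflectance spectrum is summarised by its two most prominent
peaks (topographic prominence on the 1-D signal): for each peak the peak
wavelength and the mean reflectance in a symmetric window around it, plus
the mean reflectance over the whole analysis band — five features per
spectrum at the default configuration.

Three selection methods rank or filter features: permutation importance on
a held-out split, recursive feature elimination, and the Boruta
all-relevant procedure (shadow features + Bonferroni-corrected binomial
hit tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import binomtest

from .errors import (
    ConfigError,
    DegenerateSplitError,
    PreconditionError,
    UnsupportedEstimatorError,
)
from .estimators import feature_importances, make_estimator
from .spectra import REFLECTANCE, SpectralDataset, Spectrum

POSITIVE_CLASS = "tumor"


@dataclass
class PeakFeatureConfig:
    n_peaks: int = 2
    window_halfwidth_nm: float = 10.0
    min_prominence: float = 0.05  # fraction of the spectrum's value range
    include_peak_wavelength: bool = True

    def __post_init__(self) -> None:
        if self.n_peaks < 1:
            raise ConfigError("n_peaks must be >= 1")
        if self.window_halfwidth_nm <= 0:
            raise ConfigError("window_halfwidth_nm must be positive")
        if not (0 < self.min_prominence < 1):
            raise ConfigError("min_prominence must be in (0, 1)")


def extract_peak_features(
    s: Spectrum, cfg: PeakFeatureConfig | None = None
) -> tuple[dict[str, float], int]:
    """Feature vector of one spectrum: peaks + window means + overall mean.

    Returns ``(features, n_missing)`` where ``n_missing`` counts peak slots
    that had to be filled because fewer than ``n_peaks`` qualifying peaks
    exist (filled with the overall mean — a constant spectrum has no peaks
    and exercises this path rather than raising).

    Peaks are ranked by topographic prominence; ties break toward the lower
    wavelength.  Masked wavelengths (failed calibration) are excluded.
    """
    cfg = cfg or PeakFeatureConfig()
    wl = s.grid.wavelengths()
    x = s.intensities
    if s.mask is not None:
        wl, x = wl[s.mask], x[s.mask]
    if len(x) == 0:
        raise PreconditionError("spectrum fully masked")
    overall_mean = float(np.mean(x))
    value_range = float(np.ptp(x))

    if value_range > 0:
        idx, props = find_peaks(x, prominence=cfg.min_prominence * value_range)
        order = sorted(
            range(len(idx)), key=lambda k: (-props["prominences"][k], idx[k])
        )
        chosen = [idx[k] for k in order[: cfg.n_peaks]]
    else:
        chosen = []

    feats: dict[str, float] = {}
    n_missing = cfg.n_peaks - len(chosen)
    for p in range(cfg.n_peaks):
        if p < len(chosen):
            i = chosen[p]
            lam = float(wl[i])
            window = np.abs(wl - lam) <= cfg.window_halfwidth_nm
            wwl, wx = wl[window], x[window]
            if len(wwl) > 1:
                # continuous mean over the window (trapezoidal), so the
                # feature approximates the band-average intensity rather
                # than a sample-count-dependent sum
                wmean = float(np.trapezoid(wx, wwl) / (wwl[-1] - wwl[0]))
            else:
                wmean = float(wx[0])
        else:
            lam = overall_mean  # fill policy: overall mean in every slot
            wmean = overall_mean
        if cfg.include_peak_wavelength:
            feats[f"peak{p + 1}_wavelength_nm"] = lam
        feats[f"peak{p + 1}_window_mean"] = wmean
    feats["overall_mean"] = overall_mean
    return feats, n_missing


class FeatureTable:
    """Per-site feature matrix with binary labels and patient groups."""

    def __init__(
        self,
        features: pd.DataFrame,
        labels: np.ndarray,
        groups: np.ndarray,
        site_ids: np.ndarray | None = None,
    ) -> None:
        if features.isna().any().any():
            raise ConfigError("feature table contains missing values")
        labels = np.asarray(labels)
        uniq = set(np.unique(labels))
        if not uniq <= {"normal", "tumor"}:
            raise ConfigError(f"labels must be normal/tumor, got {sorted(uniq)}")
        if len(features) != len(labels) or len(features) != len(groups):
            raise ConfigError("features, labels and groups differ in length")
        self.features = features.reset_index(drop=True)
        self.labels = labels
        self.groups = np.asarray(groups)
        self.site_ids = (
            np.asarray(site_ids)
            if site_ids is not None
            else np.arange(len(labels)).astype(str)
        )

    def __len__(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Binary target, tumor = 1 (positive class)."""
        return (self.labels == POSITIVE_CLASS).astype(int)

    def subset(self, rows: np.ndarray) -> "FeatureTable":
        rows = np.asarray(rows)
        return FeatureTable(
            self.features.iloc[rows],
            self.labels[rows],
            self.groups[rows],
            self.site_ids[rows],
        )

    def to_csv(self, path) -> None:
        out = self.features.copy()
        out.insert(0, "site_id", self.site_ids)
        out["tissue_class"] = self.labels
        out["patient_id"] = self.groups
        out.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path, float_precision="round_trip")
        meta_cols = ["site_id", "tissue_class", "patient_id"]
        feats = frame.drop(columns=meta_cols)
        return cls(
            feats,
            frame["tissue_class"].to_numpy(),
            frame["patient_id"].to_numpy(),
            frame["site_id"].to_numpy(),
        )


def build_feature_table(
    ds: SpectralDataset,
    cfg: PeakFeatureConfig | None = None,
    include_fill_flag: bool = False,
) -> FeatureTable:
    """Peak features for every site of a QC-passed reflectance dataset.

    ``include_fill_flag`` appends a 0/1 column counting spectra whose peak
    slots were filled, keeping the table rectangular when some spectra lack
    the requested number of peaks.
    """
    if ds.kind != REFLECTANCE:
        raise PreconditionError("feature extraction expects reflectance spectra")
    cfg = cfg or PeakFeatureConfig()
    rows, flags = [], []
    for i in range(len(ds)):
        feats, n_missing = extract_peak_features(ds.spectrum(i), cfg)
        rows.append(feats)
        flags.append(1 if n_missing else 0)
    frame = pd.DataFrame(rows)
    if include_fill_flag:
        frame["peak_fill_flag"] = flags
    return FeatureTable(
        frame,
        ds.meta["tissue_class"].to_numpy(),
        ds.meta["patient_id"].to_numpy(),
        ds.site_ids,
    )


def raw_intensity_table(ds: SpectralDataset) -> FeatureTable:
    """Alternative feature source: the raw per-wavelength intensities."""
    if ds.kind != REFLECTANCE:
        raise PreconditionError("expected reflectance spectra")
    wl = ds.grid.wavelengths()
    cols = [f"r_{w:g}nm" for w in wl]
    x = ds.intensities
    if ds.mask is not None:
        cols = [c for c, m in zip(cols, ds.mask) if m]
        x = x[:, ds.mask]
    frame = pd.DataFrame(x, columns=cols)
    return FeatureTable(
        frame,
        ds.meta["tissue_class"].to_numpy(),
        ds.meta["patient_id"].to_numpy(),
        ds.site_ids,
    )


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Outcome of one selection method; one row per input feature."""

    method: str  # "permutation" | "rfe" | "boruta"
    table: pd.DataFrame  # columns: feature, plus rank/decision/score
    seed: int | None = None

    @property
    def selected(self) -> list[str]:
        if self.method == "rfe":
            return list(self.table.loc[self.table["rank"] == 1, "feature"])
        if self.method == "boruta":
            return list(
                self.table.loc[self.table["decision"] == "confirmed", "feature"]
            )
        return list(
            self.table.sort_values("score", ascending=False)["feature"]
        )

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(1, "method", self.method)
        out.to_csv(path, index=False)


def permutation_importance(
    model,
    table: FeatureTable,
    n_permutations: int = 30,
    seed: int = 0,
) -> SelectionResult:
    """Held-out permutation importance of an already-fitted classifier.

    importance(f) = accuracy(model, X) − mean over shuffles of
    accuracy(model, X with column f permuted); all shuffling happens
    within the held-out table only.
    """
    y = table.y
    if len(np.unique(y)) < 2:
        raise DegenerateSplitError("held-out split contains a single class")
    rng = np.random.default_rng(seed)
    X = table.X
    baseline = float(np.mean(model.predict(X) == y))
    scores = []
    for j, name in enumerate(table.feature_names):
        accs = np.empty(n_permutations)
        for p in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            accs[p] = np.mean(model.predict(Xp) == y)
        scores.append(baseline - float(accs.mean()))
    out = pd.DataFrame({"feature": table.feature_names, "score": scores})
    out["rank"] = out["score"].rank(ascending=False, method="first").astype(int)
    return SelectionResult("permutation", out, seed)


def recursive_feature_elimination(
    table: FeatureTable,
    estimator="lgbm",
    n_keep: int = 1,
    seed: int = 0,
) -> SelectionResult:
    """Backward elimination: repeatedly drop the least important feature.

    Importance is the coefficient magnitude for linear models and the gain
    for tree ensembles.  ``rank`` 1 marks the ``n_keep`` survivors; larger
    ranks record the elimination order (last eliminated = rank 2).
    """
    n_features = len(table.feature_names)
    if n_features <= n_keep:
        if n_features < n_keep:
            raise ConfigError("n_keep exceeds the number of features")
        out = pd.DataFrame(
            {"feature": table.feature_names, "rank": 1, "score": np.nan}
        )
        return SelectionResult("rfe", out, seed)
    from sklearn.feature_selection import RFE

    est = make_estimator(estimator, seed)
    rfe = RFE(est, n_features_to_select=n_keep, step=1)
    try:
        rfe.fit(table.X, table.y)
    except ValueError as exc:  # sklearn: no coef_/feature_importances_
        raise UnsupportedEstimatorError(str(exc)) from exc
    out = pd.DataFrame(
        {
            "feature": table.feature_names,
            "rank": rfe.ranking_.astype(int),
            "score": np.nan,
        }
    )
    return SelectionResult("rfe", out, seed)


def boruta(
    table: FeatureTable,
    estimator="lgbm",
    max_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> SelectionResult:
    """Boruta all-relevant feature selection.

    Each iteration appends a shadow copy of every live feature with rows
    independently shuffled, fits the estimator on a bootstrap sample of the
    augmented matrix, and scores a *hit* for features whose importance
    exceeds the best shadow importance.  Two-sided binomial tests (hits out
    of iterations, p=0.5) with Bonferroni correction confirm
    clearly-better-than-shadow features and reject clearly-worse ones;
    rejected features leave the model.  Features undecided after
    ``max_iter`` iterations are tentative.

    The per-iteration row bootstrap plays the role the random forest's
    bagging plays in the original procedure: it decorrelates successive
    importance draws, so a noise feature whose fixed spurious association
    happens to be strong cannot beat the shadow maximum consistently.
    """
    if max_iter < 10:
        raise ConfigError("boruta needs max_iter >= 10")
    names = table.feature_names
    n_features = len(names)
    if n_features < 2:
        raise ConfigError("boruta needs at least 2 features")
    y = table.y
    if len(np.unique(y)) < 2:
        raise ConfigError("boruta needs both classes present")
    rng = np.random.default_rng(seed)
    X = table.X
    bonf_alpha = alpha / n_features

    decision = {n: "tentative" for n in names}
    hits = dict.fromkeys(names, 0)
    tested = dict.fromkeys(names, 0)
    live = list(names)  # tentative + confirmed stay in the model

    n_rows = len(X)
    for _ in range(max_iter):
        cols = [names.index(n) for n in live]
        Xl = X[:, cols]
        shadows = np.column_stack(
            [Xl[rng.permutation(n_rows), j] for j in range(Xl.shape[1])]
        )
        while True:  # bootstrap rows, keeping both classes present
            rows = rng.integers(0, n_rows, n_rows)
            if len(np.unique(y[rows])) == 2:
                break
        est = make_estimator(estimator, int(rng.integers(2**31)))
        est.fit(np.hstack([Xl, shadows])[rows], y[rows])
        imp = feature_importances(est)
        shadow_max = imp[len(cols):].max()
        for k, n in enumerate(live):
            if decision[n] != "tentative":
                continue
            tested[n] += 1
            if imp[k] > shadow_max:
                hits[n] += 1
        for n in list(live):
            if decision[n] != "tentative":
                continue
            test = binomtest(hits[n], tested[n], 0.5)
            if test.pvalue < bonf_alpha:
                if hits[n] > tested[n] / 2:
                    decision[n] = "confirmed"
                else:
                    decision[n] = "rejected"
                    live.remove(n)
        if all(d != "tentative" for d in decision.values()):
            break

    out = pd.DataFrame(
        {
            "feature": names,
            "decision": [decision[n] for n in names],
            "score": [
                hits[n] / tested[n] if tested[n] else np.nan for n in names
            ],
        }
    )
    return SelectionResult("boruta", out, seed)
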