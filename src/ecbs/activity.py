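"""Post-assay activity modeling.

Competitive binding assays report, for each compound at each concentration,
the percent of control (POC): the fraction of kinase still captured on the
solid support.  Low POC means the test compound displaced the immobilized
ligand, i.e. bound strongly.  This module converts POC readouts into
activity values (100 − POC), fits dissociation constants (Kd) to
dose–response curves with the Hill equation, and implements the secondary
activity-modeling loop used to rescore virtual-screening candidates: an
activity/uncertainty representation, log-scale activity rescaling, a
transparent weighted-ridge QSAR surrogate over molecular descriptors,
Fisher-randomization model validation, and the combined similarity ×
predicted-activity decision rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold


@dataclass
class DoseResponse:
    """Paired concentration (nM) / POC series for one compound–target pair."""

    concentrations_nM: np.ndarray
    responses_poc: np.ndarray
    compound_id: str = ""
    target_id: str = ""

    def __post_init__(self) -> None:
        self.concentrations_nM = np.asarray(self.concentrations_nM, dtype=float)
        self.responses_poc = np.asarray(self.responses_poc, dtype=float)
        if self.concentrations_nM.shape != self.responses_poc.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(self.concentrations_nM <= 0):
            raise ValueError("concentrations must be strictly positive")


@dataclass
class HillFit:
    kd_nM: float
    hill_coefficient: float
    top: float
    bottom: float
    rss: float
    converged: bool


@dataclass
class ActivityRecord:
    """One compound's activity value with multiplicative uncertainty u >= 1."""

    compound_id: str
    activity: float
    uncertainty: float = 3.0
    source: str = "poc"  # or "kd"

    def __post_init__(self) -> None:
        if self.uncertainty < 1:
            raise ValueError("uncertainty must be >= 1")


def poc_to_activity(poc: float) -> float:
    """Activity value from a POC readout: 100 − POC.

    POC 0 (complete displacement) maps to activity 100; POC 100 (no
    binding) maps to 0.  Readouts outside [0, 100] — possible under assay
    noise — pass through with a warning.
    """
    if not np.isfinite(poc):
        raise ValueError(f"POC must be finite, got {poc}")
    if poc < 0 or poc > 100:
        warnings.warn(f"POC {poc} outside [0, 100]; passing through", UserWarning)
    return 100.0 - poc


def hill_poc(c: np.ndarray, kd_nM: float, h: float,
             top: float = 100.0, bottom: float = 0.0) -> np.ndarray:
    """Hill-equation POC curve: bottom + (top − bottom) / (1 + (c/Kd)^h)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / kd_nM) ** h)


def fit_hill(dr: DoseResponse,
             initial: tuple[float, float, float, float] | None = None) -> HillFit:
    """Fit Kd from a dose–response curve by least squares in log-dose space.

    The model is POC(c) = bottom + (top − bottom)/(1 + (c/Kd)^h) with Kd
    parameterized as log10(Kd); top and bottom are free within [−10, 120]
    POC units for robustness to assay drift, and h within [0.2, 5].
    Initialization takes Kd from the dose whose response is closest to the
    data midpoint, unless an explicit ``initial`` (log10 Kd, h, top, bottom)
    is given.  Non-convergence is reported honestly via ``converged``.
    """
    c = dr.concentrations_nM
    y = dr.responses_poc
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct concentrations to fit")
    if np.allclose(y, y[0]):
        raise ValueError("responses are constant across doses: no signal to fit")

    logc = np.log10(c)

    def model(logc_, log_kd, h, top, bottom):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (h * (logc_ - log_kd)))

    if initial is None:
        top0, bottom0 = float(np.max(y)), float(np.min(y))
        mid = (top0 + bottom0) / 2.0
        log_kd0 = float(logc[np.argmin(np.abs(y - mid))])
        p0 = [log_kd0, 1.0, top0, bottom0]
    else:
        p0 = list(initial)
    bounds = ([logc.min() - 3, 0.2, -10.0, -10.0],
              [logc.max() + 3, 5.0, 120.0, 120.0])
    p0 = np.clip(p0, bounds[0], bounds[1]).tolist()
    try:
        popt, _ = curve_fit(model, logc, y, p0=p0, bounds=bounds, maxfev=20000)
        resid = y - model(logc, *popt)
        rss = float(np.sum(resid**2))
        converged = bool(np.isfinite(rss))
    except RuntimeError:
        popt = p0
        rss = float("inf")
        converged = False
    log_kd, h, top, bottom = popt
    return HillFit(kd_nM=float(10.0 ** log_kd), hill_coefficient=float(h),
                   top=float(top), bottom=float(bottom), rss=rss,
                   converged=converged)


def uncertainty_bounds(activity: float, u: float) -> tuple[float, float]:
    """Active range implied by a multiplicative uncertainty: (a/u, a·u).

    E.g. activity 0.001 with uncertainty 3.0 brackets the true value between
    0.001/3.0 ≈ 0.00033 and 0.001×3.0 = 0.003.
    """
    if not activity > 0:
        raise ValueError("activity must be positive")
    if u < 1:
        raise ValueError("uncertainty must be >= 1")
    return activity / u, activity * u


def rescale_activities(values: Sequence[float], span_orders: float = 4.0) -> np.ndarray:
    """Affine rescale in log10 space so the output spans 10**span_orders.

    The minimum maps to 1 and the maximum to 10**span_orders; rank order is
    preserved.  Requires at least two distinct positive values and a
    positive span.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("activities must be positive for log rescaling")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise ValueError("need at least two distinct values to rescale")
    if not span_orders > 0:
        raise ValueError("span_orders must be positive")
    logv = np.log10(v)
    scaled = (logv - np.log10(lo)) / (np.log10(hi) - np.log10(lo)) * span_orders
    return 10.0 ** scaled


@dataclass
class QSARSurrogate:
    """Transparent stand-in for a pharmacophore-hypothesis regressor.

    A weighted ridge regression on log10(activity) over molecular descriptor
    vectors.  Narrower uncertainty intervals get larger weights:
    w = 1 / (1 + log10(u))**2, so u = 1 weighs 1 and u = 10 weighs 0.25.
    """

    coefficients: np.ndarray
    intercept: float
    training_ids: list[str] = field(default_factory=list)
    significance: float | None = None  # percent, set by Fisher validation

    def predict_log_activity(self, descriptors: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(descriptors, dtype=float))
        if X.shape[1] != len(self.coefficients):
            raise ValueError(
                f"descriptor length {X.shape[1]} != model length "
                f"{len(self.coefficients)}")
        return X @ self.coefficients + self.intercept

    def predict_activity(self, descriptors: np.ndarray) -> np.ndarray:
        return 10.0 ** self.predict_log_activity(descriptors)


def _uncertainty_weights(records: Sequence[ActivityRecord]) -> np.ndarray:
    return np.array([1.0 / (1.0 + np.log10(r.uncertainty)) ** 2 for r in records])


def fit_qsar_surrogate(
    descriptors: np.ndarray,
    activities: Sequence[ActivityRecord],
    seed: int = 0,
    alpha: float = 1e-6,
) -> QSARSurrogate:
    """Weighted regularized linear fit of log-activity on descriptors.

    Ridge regularization keeps rank-deficient inputs well-posed; the tiny
    default alpha leaves well-conditioned fits essentially unbiased.
    Deterministic for fixed inputs.
    """
    X = np.asarray(descriptors, dtype=float)
    if X.ndim != 2:
        raise ValueError("descriptors must be a 2-D matrix")
    if X.shape[0] != len(activities):
        raise ValueError("one activity record per descriptor row required")
    if X.shape[0] < 4:
        raise ValueError("need at least 4 compounds to fit")
    y = np.log10(np.array([r.activity for r in activities], dtype=float))
    w = _uncertainty_weights(activities)
    model = Ridge(alpha=alpha, random_state=seed)
    model.fit(X, y, sample_weight=w)
    return QSARSurrogate(
        coefficients=np.asarray(model.coef_, dtype=float),
        intercept=float(model.intercept_),
        training_ids=[r.compound_id for r in activities],
    )


def cv_correlation(descriptors: np.ndarray, activities: Sequence[ActivityRecord],
                   n_splits: int = 4, seed: int = 0) -> float:
    """Cross-validated Pearson correlation of predicted vs observed log-activity."""
    X = np.asarray(descriptors, dtype=float)
    y = np.log10(np.array([r.activity for r in activities], dtype=float))
    preds = np.empty_like(y)
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    records = list(activities)
    for train_idx, test_idx in kf.split(X):
        sub = fit_qsar_surrogate(X[train_idx], [records[i] for i in train_idx],
                                 seed=seed)
        preds[test_idx] = sub.predict_log_activity(X[test_idx])
    if np.std(preds) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(preds, y)[0, 1])


def training_correlation(descriptors: np.ndarray,
                         activities: Sequence[ActivityRecord],
                         seed: int = 0) -> float:
    """Pearson correlation of the fitted model on its own training data."""
    X = np.asarray(descriptors, dtype=float)
    y = np.log10(np.array([r.activity for r in activities], dtype=float))
    fit = fit_qsar_surrogate(X, activities, seed=seed)
    pred = fit.predict_log_activity(X)
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(pred, y)[0, 1])


def fisher_randomization(
    fit_and_score: Callable[[np.ndarray, Sequence[ActivityRecord], int], float],
    descriptors: np.ndarray,
    activities: Sequence[ActivityRecord],
    level: int = 95,
    seed: int = 0,
) -> tuple[bool, list[float]]:
    """Permutation validation of a QSAR fit at a 90% or 95% confidence level.

    Activity labels are permuted and the model refitted; the number of
    permutations is ceil(100/(100−level)) − 1 — 9 for 90% and 19 for 95%,
    the standard Fisher-randomization reading of those levels.  The model is
    significant iff the unpermuted fit's score strictly exceeds every
    permuted score; a permutation whose fit fails is counted as beating the
    true model (conservative).  Returns the verdict and the null scores.
    """
    if level not in (90, 95):
        raise ValueError("confidence level must be 90 or 95")
    n_perm = int(np.ceil(100.0 / (100 - level))) - 1
    rng = np.random.default_rng(seed)
    records = list(activities)
    true_score = fit_and_score(descriptors, records, int(rng.integers(2**31)))
    null_scores: list[float] = []
    values = np.array([r.activity for r in records])
    for _ in range(n_perm):
        perm = rng.permutation(len(records))
        permuted = [
            ActivityRecord(r.compound_id, float(values[j]), r.uncertainty, r.source)
            for r, j in zip(records, perm)
        ]
        try:
            s = fit_and_score(descriptors, permuted, int(rng.integers(2**31)))
            if not np.isfinite(s):
                s = float("inf")
        except Exception:
            s = float("inf")
        null_scores.append(float(s))
    significant = all(true_score > s for s in null_scores)
    return significant, null_scores


def combined_decision(
    ecbs_score: float,
    predicted_activity: float,
    score_cutoff: float = 0.7,
    activity_cutoff: float = 50.0,
) -> str:
    """Joint prioritization: similarity screen AND predicted-activity screen.

    A compound is prioritized only when its binding-similarity score passes
    the primary cutoff (default 0.7, inclusive) and its predicted activity —
    on the 100 − POC scale, where higher means stronger binding — passes the
    activity cutoff (default 50, inclusive).  Otherwise it is rejected.
    """
    for name, v in (("ecbs_score", ecbs_score),
                    ("predicted_activity", predicted_activity)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    if ecbs_score >= score_cutoff and predicted_activity >= activity_cutoff:
        return "prioritize"
    return "reject"


def load_dose_responses(path) -> list[DoseResponse]:
    """Read a CSV with columns compound_id, target_id, concentration_nM, poc."""
    df = pd.read_csv(path)
    required = {"compound_id", "target_id", "concentration_nM", "poc"}
    if not required <= set(df.columns):
        raise ValueError(f"dose-response table must have columns {sorted(required)}")
    out = []
    for (cid, tid), grp in df.groupby(["compound_id", "target_id"], sort=True):
        out.append(DoseResponse(
            concentrations_nM=grp["concentration_nM"].to_numpy(float),
            responses_poc=grp["poc"].to_numpy(float),
            compound_id=str(cid), target_id=str(tid),
        ))
    return out
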