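"""Regression, backward stepwise AIC selection, and ROC/Youden machinery.

These are the statistics used to compare overlap predictors of parotid mean
dose and to calibrate the decision threshold:

* ordinary least squares with intercept, reporting R², slope t-test
  p-values, and AIC under the full Gaussian convention
  ``AIC = n ln(2π) + n ln(RSS/n) + n + 2 (p + 2)``
  (σ counted as a parameter, so values match mainstream statistics
  software, e.g. R's ``AIC(lm(...))``);
* backward stepwise deletion driven by AIC, starting from the full model
  and stopping when no single deletion lowers AIC;
* an explicit-threshold ROC: candidate thresholds are −∞, midpoints between
  consecutive distinct scores, and +∞; a record is called positive iff its
  score is strictly greater than the threshold; AUC by the trapezoid rule
  (equal to the Mann–Whitney pair statistic with ties counted ½);
* the Youden-optimal operating point (max sensitivity + specificity − 1),
  ties resolved to the smallest threshold — the highest-sensitivity choice,
  which is the conservative one for toxicity screening.

Outcome labels follow the tolerance convention: a parotid is "positive" iff
its D_mean is strictly greater than 26 Gy; exactly 26 Gy is negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dosimetry import PAROTID_TOLERANCE_GY

__all__ = [
    "ParotidRecord",
    "RegressionFit",
    "RocCurve",
    "OperatingPoint",
    "fit_linear",
    "backward_stepwise_aic",
    "roc_curve",
    "optimal_operating_point",
    "records_to_frame",
    "frame_to_records",
    "OLV_COLUMNS",
]

OLV_COLUMNS = ("olv_ct", "olv_ct05", "olv_ct10", "olv_hd", "olv_hd05",
               "olv_im", "olv_ld")


@dataclass
class ParotidRecord:
    """One parotid's overlap statistics, volume, and (optional) mean dose.

    OLV fields are fractions of the parotid volume overlapped by: the
    combined PTV and its 5/10 mm expansions (ct/ct05/ct10), the high-dose
    PTV and its 5 mm expansion (hd/hd05), and the intermediate/low-dose
    PTVs (im/ld).
    """

    plan_id: str
    side: str  # "L" / "R"
    volume_cc: float
    olv_ct: float
    olv_ct05: float
    olv_ct10: float
    olv_hd: float
    olv_hd05: float
    olv_im: float
    olv_ld: float
    d_mean: float | None = None

    def __post_init__(self) -> None:
        eps = 1e-9
        for name in OLV_COLUMNS:
            v = float(getattr(self, name))
            if not (-eps <= v <= 1 + eps):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
            setattr(self, name, min(max(v, 0.0), 1.0))
        if not (self.olv_ct <= self.olv_ct05 + eps and self.olv_ct05 <= self.olv_ct10 + eps):
            raise ValueError(
                f"expansion monotonicity violated: olv_ct={self.olv_ct} "
                f"olv_ct05={self.olv_ct05} olv_ct10={self.olv_ct10}"
            )
        if self.olv_hd > self.olv_hd05 + eps:
            raise ValueError(
                f"expansion monotonicity violated: olv_hd={self.olv_hd} > "
                f"olv_hd05={self.olv_hd05}"
            )
        if self.d_mean is not None:
            self.d_mean = float(self.d_mean)

    @property
    def positive(self) -> bool:
        """True iff D_mean strictly exceeds the 26 Gy sparing tolerance."""
        if self.d_mean is None:
            raise ValueError(f"record {self.plan_id}/{self.side} has no D_mean")
        return self.d_mean > PAROTID_TOLERANCE_GY


def records_to_frame(records: Sequence[ParotidRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"plan_id": r.plan_id, "side": r.side, "volume_cc": r.volume_cc}
        row.update({c: getattr(r, c) for c in OLV_COLUMNS})
        row["d_mean"] = r.d_mean
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[ParotidRecord]:
    recs = []
    for _, row in df.iterrows():
        recs.append(ParotidRecord(
            plan_id=str(row["plan_id"]), side=str(row["side"]),
            volume_cc=float(row["volume_cc"]),
            d_mean=None if pd.isna(row.get("d_mean")) else float(row["d_mean"]),
            **{c: float(row[c]) for c in OLV_COLUMNS},
        ))
    return recs


# ---------------------------------------------------------------------------
# Linear regression and stepwise AIC
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    predictors: tuple[str, ...]
    coefficients: np.ndarray  # intercept first, then slopes in predictor order
    r_squared: float
    aic: float
    n: int
    slope_pvalues: tuple[float, ...] = ()
    slope_standard_errors: tuple[float, ...] = ()

    @property
    def p_value(self) -> float | None:
        """Two-sided p-value of the slope, for the univariate case."""
        return self.slope_pvalues[0] if len(self.slope_pvalues) == 1 else None


def _as_matrix(X, names: Sequence[str] | None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(str(c) for c in X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("X must be 1-D or 2-D")
    if names is None:
        names = tuple(f"x{i + 1}" for i in range(arr.shape[1]))
    return arr, tuple(names)


def fit_linear(y, X, names: Sequence[str] | None = None) -> RegressionFit:
    """OLS with intercept; R², AIC (Gaussian, σ counted), slope t p-values.

    ``X`` may have zero columns (intercept-only model).  Rank deficiency is
    an error naming the dependent columns.
    """
    y = np.asarray(y, dtype=float).ravel()
    Xm, pred_names = _as_matrix(X, names)
    if Xm.shape[1] == 0:
        Xm = np.empty((len(y), 0))
        pred_names = ()
    n, p = len(y), Xm.shape[1]
    if Xm.shape[0] != n:
        raise ValueError(f"X has {Xm.shape[0]} rows but y has {n}")
    if n < p + 2:
        raise ValueError(f"need n >= p + 2 observations, got n={n}, p={p}")

    design = np.column_stack([np.ones(n), Xm]) if p else np.ones((n, 1))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that add no rank, in order
        dep = []
        cur = design[:, :1]
        for j in range(p):
            cand = np.column_stack([cur, Xm[:, j]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                dep.append(pred_names[j])
            else:
                cur = cand
        raise ValueError(f"design matrix is rank deficient; dependent columns: {dep}")

    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if tss == 0.0 else 1.0 - rss / tss
    r2 = min(max(r2, 0.0), 1.0)

    if rss <= 0.0:
        aic = -math.inf
    else:
        aic = n * math.log(2 * math.pi) + n * math.log(rss / n) + n + 2 * (p + 2)

    pvals: tuple[float, ...] = ()
    ses: tuple[float, ...] = ()
    dof = n - p - 1
    if p and dof > 0 and rss > 0:
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov))[1:]
        t = beta[1:] / se
        pvals = tuple(float(2 * stats.t.sf(abs(ti), dof)) for ti in t)
        ses = tuple(float(s) for s in se)
    elif p:
        pvals = tuple(0.0 for _ in range(p))
        ses = tuple(0.0 for _ in range(p))

    return RegressionFit(pred_names, beta, r2, aic, n, pvals, ses)


def backward_stepwise_aic(y, X: pd.DataFrame) -> tuple[list[str], RegressionFit]:
    """Backward deletion from the full model, one variable per step.

    Each step removes the single variable whose deletion lowers AIC the
    most; selection stops when no deletion lowers AIC.  The intercept is
    never removed.  Equal-AIC ties are broken by removing the
    lexicographically last name, so the path is deterministic.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float),
                         columns=[f"x{i + 1}" for i in range(np.asarray(X).shape[1])])
    current = [str(c) for c in X.columns]
    fit = fit_linear(y, X[current]) if current else fit_linear(y, np.empty((len(y), 0)))
    while current:
        candidates = []
        for name in current:
            kept = [c for c in current if c != name]
            sub = fit_linear(y, X[kept]) if kept else fit_linear(
                y, np.empty((len(y), 0)))
            candidates.append((sub.aic, name, sub))
        best_aic = min(c[0] for c in candidates)
        if best_aic >= fit.aic:
            break
        # among ties at best_aic, drop the lexicographically last name
        tied = [c for c in candidates if c[0] == best_aic]
        _, drop, fit = max(tied, key=lambda c: c[1])
        current = [c for c in current if c != drop]
    return current, fit


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    """Sensitivity/specificity at every candidate threshold, plus AUC.

    Thresholds ascend from −∞ to +∞; a score is called positive iff it is
    strictly greater than the threshold, so the curve runs from
    (sens 1, spec 0) to (sens 0, spec 1).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_positive: int = 0
    n_negative: int = 0

    def __post_init__(self) -> None:
        for arr in (self.sensitivity, self.specificity):
            if np.any((arr < -1e-12) | (arr > 1 + 1e-12)):
                raise ValueError("sensitivity/specificity must lie in [0, 1]")
        if not (-1e-12 <= self.auc <= 1 + 1e-12):
            raise ValueError("AUC must lie in [0, 1]")


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def roc_curve(scores, labels) -> RocCurve:
    """ROC sweep of ``positive iff score > threshold`` over all cut points."""
    s = np.asarray(scores, dtype=float).ravel()
    lab = np.asarray(labels).astype(bool).ravel()
    if s.shape != lab.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"ROC needs both classes; got {n_pos} positive / {n_neg} negative"
        )
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thr = np.concatenate(([-np.inf], mids, [np.inf]))
    pred = s[None, :] > thr[:, None]
    sens = (pred & lab[None, :]).sum(axis=1) / n_pos
    spec = (~pred & ~lab[None, :]).sum(axis=1) / n_neg
    fpr = 1.0 - spec
    # thresholds ascend => fpr and sens descend; reverse for the integral
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    return RocCurve(thr, sens.astype(float), spec.astype(float), auc, n_pos, n_neg)


def optimal_operating_point(rc: RocCurve) -> OperatingPoint:
    """Maximize Youden J; among ties prefer the smallest threshold
    (highest sensitivity — the conservative choice for screening)."""
    j = rc.sensitivity + rc.specificity - 1.0
    best = j.max()
    idx = int(np.flatnonzero(j >= best - 1e-12)[0])
    return OperatingPoint(float(rc.thresholds[idx]),
                          float(rc.sensitivity[idx]),
                          float(rc.specificity[idx]))
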