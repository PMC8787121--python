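"""Metric-evaluation harness: logistic mapping and the five indices.

Objective scores are first aligned to the subjective scale with a
five-parameter logistic curve; SROCC/KROCC are computed on the raw
scores, PLCC/RMSE/MAE on the mapped ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .io_fixtures import ImagePlane, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LogisticParams:
    """The five curve parameters (tau1..tau5)."""

    tau: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.tau) != 5:
            raise ValidationError("exactly five logistic parameters required")
        if not all(np.isfinite(self.tau)):
            raise ValidationError("logistic parameters must be finite")


@dataclass
class EvalReport:
    """Five performance indices plus the fitted curve and sample count.

    ``mae`` is the mean absolute error (some IQA tables abbreviate this
    column "MSE"; the key here is always ``mae``).
    """

    srocc: float
    krocc: float
    plcc: float
    rmse: float
    mae: float
    logistic: LogisticParams
    n: int

    def to_dict(self) -> dict:
        return {
            "srocc": self.srocc, "krocc": self.krocc, "plcc": self.plcc,
            "rmse": self.rmse, "mae": self.mae,
            "tau": list(self.logistic.tau), "n": self.n,
        }


def logistic_map(q, params: LogisticParams):
    """S(q) = tau1*(1/2 - 1/(1 + exp((q - tau3)/tau2))) + q*tau4 + tau5."""
    t1, t2, t3, t4, t5 = params.tau
    if t2 == 0:
        raise ValidationError("tau2 must be nonzero")
    q = np.asarray(q, dtype=np.float64)
    z = np.clip((q - t3) / t2, -500.0, 500.0)
    out = t1 * (0.5 - 1.0 / (1.0 + np.exp(z))) + q * t4 + t5
    return float(out) if out.ndim == 0 else out


def _as_pair(a, b, min_n: int):
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size != b.size:
        raise ValidationError("input lists must have equal length")
    if a.size < min_n:
        raise ValidationError(f"need at least {min_n} samples, got {a.size}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("inputs must be finite")
    return a, b


def _curve_rmse(obj: np.ndarray, subj: np.ndarray, params: LogisticParams) -> float:
    return float(np.sqrt(np.mean((logistic_map(obj, params) - subj) ** 2)))


def fit_logistic(objective, subjective) -> LogisticParams:
    """Least-squares fit of the five-parameter logistic curve.

    Deterministic: two analytic starts (the documented initialization and
    the same with tau2 negated) are each refined with Levenberg-Marquardt;
    the candidate — refined or raw start — with the lowest RMSE wins, so
    the result never degrades the best initialization.
    """
    obj, subj = _as_pair(objective, subjective, 5)
    if np.ptp(obj) == 0:
        raise ValidationError("objective scores are all equal; cannot fit")

    spread = subj.max() - subj.min()
    slope_sign = 1.0
    if np.std(subj) > 0:
        r = np.corrcoef(obj, subj)[0, 1]
        if np.isfinite(r) and r < 0:
            slope_sign = -1.0
    t2 = max(np.std(obj) / 4.0, 1e-6) * slope_sign
    base = np.array([spread, t2, np.median(obj), 0.0, subj.mean()])
    starts = [base, base * np.array([1, -1, 1, 1, 1])]

    def residuals(tau):
        return logistic_map(obj, LogisticParams(tuple(tau))) - subj

    candidates = [LogisticParams(tuple(s)) for s in starts]
    for s in starts:
        try:
            sol = optimize.least_squares(residuals, s, method="lm", max_nfev=5000)
            candidates.append(LogisticParams(tuple(sol.x)))
            if not sol.success:
                logger.info("logistic fit did not fully converge: %s", sol.message)
        except Exception as exc:  # noqa: BLE001 - fall back to the raw start
            logger.warning("logistic fit attempt failed: %s", exc)

    best = min(candidates, key=lambda p: _curve_rmse(obj, subj, p))
    return best


def srocc(a, b) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    a, b = _as_pair(a, b, 3)
    for name, v in (("first", a), ("second", b)):
        if np.unique(v).size < 2:
            raise ValidationError(f"{name} input has zero rank variance")
    return float(stats.spearmanr(a, b).statistic)


def krocc(a, b) -> float:
    """Kendall rank correlation, tau-b (tie-corrected)."""
    a, b = _as_pair(a, b, 3)
    for name, v in (("first", a), ("second", b)):
        if np.unique(v).size < 2:
            raise ValidationError(f"{name} input has zero rank variance")
    return float(stats.kendalltau(a, b, variant="b").statistic)


def plcc_rmse_mae(mapped, subjective) -> tuple[float, float, float]:
    """Pearson correlation plus RMSE and MAE of mapped vs subjective.

    With zero variance in either input PLCC is undefined: it is returned
    as NaN with a warning while RMSE/MAE are still computed.
    """
    m, s = _as_pair(mapped, subjective, 2)
    rmse = float(np.sqrt(np.mean((m - s) ** 2)))
    mae = float(np.mean(np.abs(m - s)))
    if np.std(m) == 0 or np.std(s) == 0:
        logger.warning("zero variance input: PLCC undefined, returned as NaN")
        return float("nan"), rmse, mae
    plcc = float(stats.pearsonr(m, s).statistic)
    return plcc, rmse, mae


def evaluate_metric(objective, dmos) -> EvalReport:
    """Full report: rank indices on raw scores, logistic fit, then
    PLCC/RMSE/MAE on the mapped scores."""
    obj, subj = _as_pair(objective, dmos, 5)
    r_s = srocc(obj, subj)
    r_k = krocc(obj, subj)
    params = fit_logistic(obj, subj)
    mapped = logistic_map(obj, params)
    plcc, rmse, mae = plcc_rmse_mae(mapped, subj)
    return EvalReport(srocc=r_s, krocc=r_k, plcc=plcc, rmse=rmse, mae=mae,
                      logistic=params, n=int(obj.size))


def baseline_scores(reference: ImagePlane, distorted: ImagePlane) -> tuple[float, float]:
    """Benchmark (MSE, PSNR); identical planes give PSNR = +inf."""
    if (reference.height, reference.width) != (distorted.height, distorted.width):
        raise ValidationError("reference and distorted dimensions must match")
    diff = reference.pixels - distorted.pixels
    mse = float(np.mean(diff * diff))
    if mse == 0:
        return 0.0, float("inf")
    psnr = float(10.0 * np.log10(reference.dynamic_range**2 / mse))
    return mse, psnr
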