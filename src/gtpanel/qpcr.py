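"""qPCR host-DNA quantification and genotyping-success screening.

Noninvasive (scat) extracts carry mostly non-host DNA; a single-locus qPCR
assay against a standard dilution series estimates the host-specific
concentration, and a binary logistic regression of genotyping success on
concentration sets the minimum concentration worth sequencing.  "Success"
is genotyping at least a chosen fraction of panel loci (50%, 25% or 10%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit


@dataclass
class StandardCurve:
    """Least-squares Cq = intercept + slope * log10(concentration)."""

    points: list[tuple[float, float]]  # (known conc ng/uL, Cq)
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency; 1.0 means perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Fit a qPCR standard curve from (concentration, Cq) pairs.

    Needs >= 3 distinct positive concentrations.  A non-negative slope
    (Cq should fall as template rises... i.e. slope must be negative) is
    flagged with an INVALID_CURVE warning but still returned.
    """
    if len(points) < 3:
        raise ValueError("standard curve needs >= 3 points")
    conc = np.array([p[0] for p in points], dtype=float)
    cq = np.array([p[1] for p in points], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("standard concentrations must be > 0")
    if len(np.unique(conc)) < 3:
        raise ValueError("standard concentrations must be distinct")
    res = stats.linregress(np.log10(conc), cq)
    if res.slope >= 0:
        warnings.warn("INVALID_CURVE: standard-curve slope is non-negative", stacklevel=2)
    return StandardCurve(
        points=list(points),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def quantify(cq: float | None, curve: StandardCurve) -> float:
    """Concentration (ng/uL) for an observed Cq; undetermined -> 0."""
    if cq is None or (isinstance(cq, float) and np.isnan(cq)):
        return 0.0
    return float(10.0 ** ((cq - curve.intercept) / curve.slope))


@dataclass
class ScreenModel:
    """Binary logistic model of genotyping success vs DNA concentration."""

    success_threshold: float  # fraction of loci genotyped counting as success
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    scale: str = "linear"  # or "log10"
    converged: bool = True
    separation: bool = False
    n_obs: int = 0
    n_success: int = 0

    def predict(self, concentration: np.ndarray | float) -> np.ndarray | float:
        x = np.log10(concentration) if self.scale == "log10" else np.asarray(concentration, dtype=float)
        return expit(self.intercept + self.slope * x)


def _firth_logistic(x: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Jeffreys-prior penalized logistic fit (handles complete separation)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        XtW = X.T * w
        info = XtW @ X
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w  # hat diagonal
        score = X.T @ (y - mu + h * (0.5 - mu))
        delta = info_inv @ score
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            break
    se = np.sqrt(np.diag(np.linalg.pinv(info)))
    return beta, se


def fit_screen_model(
    samples: pd.DataFrame,
    success_threshold: float = 0.5,
    scale: str = "linear",
    include_zero_conc: bool = False,
) -> ScreenModel:
    """Fit the concentration -> genotyping-success logistic model.

    ``samples`` needs columns ``concentration`` (ng/uL) and
    ``pct_loci_genotyped`` (fraction or percent; percents are detected and
    rescaled).  Outcome is 1 when the genotyped fraction reaches
    ``success_threshold``.  A ``success_prob`` column, when present,
    switches to a grouped-proportion fit (binomial GLM with that column as
    the response) — useful for fitting exact success probabilities.
    Zero-concentration samples are excluded by default, matching the
    screening use where only qPCR-positive extracts proceed.  Complete
    separation falls back to a Firth-type penalized fit and is flagged.
    """
    import statsmodels.api as sm

    df = samples.copy()
    proportions = "success_prob" in df.columns
    if proportions:
        df["_success"] = df["success_prob"].astype(float)
    else:
        pct = df["pct_loci_genotyped"].astype(float)
        if pct.max() > 1.0:
            pct = pct / 100.0
        df["_success"] = (pct >= success_threshold).astype(int)
    if not include_zero_conc:
        df = df[df["concentration"] > 0]
    if scale == "log10":
        if (df["concentration"] <= 0).any():
            raise ValueError("log10 scale requires positive concentrations")
        x = np.log10(df["concentration"].to_numpy(dtype=float))
    else:
        x = df["concentration"].to_numpy(dtype=float)
    y = df["_success"].to_numpy(dtype=float)
    if len(df) < 10:
        raise ValueError("need >= 10 observations for the screen model")
    if proportions:
        X = sm.add_constant(x)
        with warnings.catch_warnings():
            # exact proportions legitimately trip the separation detector
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        return ScreenModel(success_threshold, float(fit.params[0]), float(fit.params[1]),
                           float(fit.bse[0]), float(fit.bse[1]), scale, True, False,
                           len(y), int(np.round(y.sum())))
    y = y.astype(int)
    if y.min() == y.max():
        warnings.warn("screen model: single outcome class; Firth fallback", stacklevel=2)
        beta, se = _firth_logistic(x, y)
        return ScreenModel(success_threshold, float(beta[0]), float(beta[1]),
                           float(se[0]), float(se[1]), scale, True, True,
                           len(y), int(y.sum()))
    X = sm.add_constant(x)
    separation = False
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        beta = fit.params
        se = fit.bse
        if np.any(np.abs(beta) > 50) or np.any(~np.isfinite(se)) or np.any(se > 1e3):
            raise RuntimeError("separation suspected")
    except Exception:
        separation = True
        beta, se = _firth_logistic(x, y)
    return ScreenModel(
        success_threshold=success_threshold,
        intercept=float(beta[0]),
        slope=float(beta[1]),
        intercept_se=float(se[0]),
        slope_se=float(se[1]),
        scale=scale,
        converged=converged,
        separation=separation,
        n_obs=len(y),
        n_success=int(y.sum()),
    )


def concentration_for_probability(model: ScreenModel, p: float) -> float:
    """Concentration at which P(success) = p under the fitted model."""
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    if model.slope <= 0:
        raise ValueError("NONINFORMATIVE: slope <= 0; model cannot be inverted")
    x = (logit(p) - model.intercept) / model.slope
    return float(10.0**x) if model.scale == "log10" else float(x)
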