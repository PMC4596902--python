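"""Agreement between manual counts O and image-analysis counts E.

Error metrics::

    RMSE = sqrt( sum (E_i - O_i)^2 / n )
    MAE  = sum |E_i - O_i| / n
    MBE  = sum (E_i - O_i) / n            (signed bias)
    MSE  = sum (E_i - O_i)^2 / n          (= RMSE^2)

The coefficient of determination is taken against the identity line,

    R^2 = 1 - sum (O_i - E_i)^2 / sum (O_i - Obar)^2,

which penalises miscalibration and is therefore never larger than the
squared Pearson correlation.  ``identity_regression_test`` additionally fits
E on O by OLS and F-tests the slope against 1 and the intercept against 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "error_metrics",
    "r_squared",
    "identity_regression_test",
    "AgreementReport",
    "agreement_report",
]


def _as_pair(O, E) -> tuple[np.ndarray, np.ndarray]:
    O = np.asarray(O, dtype=np.float64).ravel()
    E = np.asarray(E, dtype=np.float64).ravel()
    if O.shape != E.shape:
        raise ValueError("O and E must have equal length")
    if O.size < 2:
        raise ValueError("need at least 2 paired observations")
    return O, E


def error_metrics(O, E) -> dict:
    """RMSE, MAE, signed MBE and MSE of paired counts."""
    O, E = _as_pair(O, E)
    d = E - O
    mse = float((d**2).mean())
    return {
        "RMSE": float(np.sqrt(mse)),
        "MAE": float(np.abs(d).mean()),
        "MBE": float(d.mean()),
        "MSE": mse,
    }


def r_squared(O, E) -> float:
    """Identity-line coefficient of determination (not squared correlation)."""
    O, E = _as_pair(O, E)
    sst = float(((O - O.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("undefined R²: O is constant")
    return 1.0 - float(((O - E) ** 2).sum()) / sst


def identity_regression_test(O, E) -> dict:
    """OLS of E on O with F tests of slope = 1 and intercept = 0.

    Returns slope, intercept, the two p-values, Pearson r and its p-value.
    A perfect fit (zero residual variance) is a logged special case with
    both p-values set to 1.
    """
    O, E = _as_pair(O, E)
    if O.size < 3:
        raise ValueError("need at least 3 pairs for regression tests")
    if np.var(O) == 0:
        raise ValueError("degenerate variance: O is constant")
    res = sm.OLS(E, sm.add_constant(O)).fit()
    intercept, slope = res.params
    se_int, se_slope = res.bse
    df = res.df_resid
    if res.ssr <= 1e-12 * max(1.0, float((E**2).sum())):
        logger.info("zero residual variance: identity-test p-values set to 1")
        p_slope, p_int = 1.0, 1.0
    else:
        f_slope = ((slope - 1.0) / se_slope) ** 2
        f_int = (intercept / se_int) ** 2
        p_slope = float(stats.f.sf(f_slope, 1, df))
        p_int = float(stats.f.sf(f_int, 1, df))
    if np.var(E) == 0:
        r, p_r = 0.0, 1.0
    else:
        r, p_r = stats.pearsonr(O, E)
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "p_slope_vs_1": p_slope,
        "p_intercept_vs_0": p_int,
        "r": float(r),
        "p_r": float(p_r),
    }


@dataclass
class AgreementReport:
    """Manual-vs-estimated count agreement in the style of a per-species
    accuracy row: correlation, identity-line regression tests, error
    metrics and identity-line R^2."""

    n: int
    r: float
    p_r: float
    slope: float
    p_slope_vs_1: float
    intercept: float
    p_intercept_vs_0: float
    RMSE: float
    MAE: float
    MBE: float
    MSE: float
    R2: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])

    def summary(self) -> str:
        d = self.to_dict()
        width = max(len(k) for k in d)
        lines = ["Method agreement (E vs O)"]
        for k, v in d.items():
            lines.append(f"  {k:<{width}} : {v:.4f}" if isinstance(v, float) else f"  {k:<{width}} : {v}")
        return "\n".join(lines)

    def plot(self, O, E, ax=None):
        """Scatter of E against O with the identity line and the OLS fit."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        O = np.asarray(O, float)
        ax.scatter(O, E, s=12, alpha=0.7, label="bunches")
        lim = [0, max(float(np.max(O)), float(np.max(E))) * 1.05]
        ax.plot(lim, lim, "k--", lw=1, label="identity")
        xs = np.linspace(lim[0], lim[1], 2)
        ax.plot(xs, self.intercept + self.slope * xs, "r-", lw=1,
                label=f"OLS: {self.slope:.2f}·O {self.intercept:+.1f}")
        ax.set_xlabel("manual count O")
        ax.set_ylabel("image-analysis count E")
        ax.legend(frameon=False)
        return ax


def agreement_report(O, E) -> AgreementReport:
    """Full agreement report for paired manual / estimated counts."""
    O_, E_ = _as_pair(O, E)
    metrics = error_metrics(O_, E_)
    reg = identity_regression_test(O_, E_)
    return AgreementReport(
        n=int(O_.size),
        r=reg["r"],
        p_r=reg["p_r"],
        slope=reg["slope"],
        p_slope_vs_1=reg["p_slope_vs_1"],
        intercept=reg["intercept"],
        p_intercept_vs_0=reg["p_intercept_vs_0"],
        RMSE=metrics["RMSE"],
        MAE=metrics["MAE"],
        MBE=metrics["MBE"],
        MSE=metrics["MSE"],
        R2=r_squared(O_, E_),
    )
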