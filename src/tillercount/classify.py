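"""Shoot / non-shoot object classification.

The segmented objects of a bunch photograph are not all shoot tips: cut
leaves and soil debris survive the size filter.  A two-class Fisher linear
discriminant on the morphometric descriptors separates them.  Before the
fit, collinear descriptors are removed by stepwise variance-inflation-factor
(VIF) deletion (threshold 10), and an optional backward elimination drops
variables whose F-to-remove falls below a threshold.  Per-variable
diagnostics (tolerance T, F-to-remove, Wilks' lambda of the reduced model)
are reported for every fitted model.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging, morphometry

logger = logging.getLogger(__name__)

__all__ = [
    "SHOOT",
    "NON_SHOOT",
    "compute_vif",
    "vif_prune",
    "ShootClassifier",
    "fit_lda",
    "lda_diagnostics",
    "classify_objects",
    "count_tillers",
]

SHOOT = "shoot"
NON_SHOOT = "non-shoot"

#: R^2 above which a predictor is treated as exactly collinear.
_R2_SINGULAR = 1.0 - 1e-12


def _r_squared_on_others(X: np.ndarray, j: int) -> float:
    """R^2 of column j regressed (with intercept) on the remaining columns."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError(f"feature column {j} has zero variance")
    return 1.0 - float((resid**2).sum()) / sst


def compute_vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors VIF_j = 1 / (1 - R^2_j).

    ``R^2_j`` comes from regressing feature j on all other features with an
    intercept.  Exactly collinear features get ``inf``.
    """
    X = pd.DataFrame(X)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than features for VIF")
    arr = X.to_numpy(dtype=np.float64)
    if X.shape[1] == 1:
        return pd.Series([1.0], index=X.columns, name="VIF")
    out = []
    for j in range(arr.shape[1]):
        r2 = _r_squared_on_others(arr, j)
        out.append(np.inf if r2 >= _R2_SINGULAR else 1.0 / (1.0 - r2))
    return pd.Series(out, index=X.columns, name="VIF")


def vif_prune(
    X: pd.DataFrame, threshold: float = 10.0
) -> tuple[list[str], pd.DataFrame]:
    """Stepwise deletion of the largest-VIF feature until all VIF <= threshold.

    Returns the surviving feature names in original column order and a trace
    frame (step, feature, VIF at deletion).  Ties delete the later column.
    Raises if fewer than 2 features would survive.
    """
    X = pd.DataFrame(X)
    cols = list(X.columns)
    trace: list[dict] = []
    step = 0
    while True:
        vif = compute_vif(X[cols])
        vmax = vif.max()
        if not (vmax > threshold):
            break
        # ties broken toward the later column
        worst = [c for c in cols if vif[c] == vmax][-1]
        step += 1
        trace.append({"step": step, "feature": worst, "VIF": float(vmax)})
        logger.info("VIF prune step %d: dropping %s (VIF=%.2f)", step, worst, vmax)
        cols.remove(worst)
        if len(cols) < 2:
            raise ValueError("over-pruned feature set: fewer than 2 survivors")
    return cols, pd.DataFrame(trace, columns=["step", "feature", "VIF"])


def _class_split(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    shoots = X[y]
    others = X[~y]
    if len(shoots) == 0 or len(others) == 0:
        raise ValueError("both classes must be non-empty")
    return shoots, others


def _pooled_cov(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n1, n0 = len(a), len(b)
    s1 = np.cov(a, rowvar=False, bias=False) if n1 > 1 else np.zeros((a.shape[1],) * 2)
    s0 = np.cov(b, rowvar=False, bias=False) if n0 > 1 else np.zeros((b.shape[1],) * 2)
    return ((n1 - 1) * np.atleast_2d(s1) + (n0 - 1) * np.atleast_2d(s0)) / (n1 + n0 - 2)


def _mahalanobis_sq(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Mahalanobis distance between class means under pooled cov.

    Uses a least-squares solve so that diagnostics stay finite on
    near-singular covariances (the model fit itself still refuses them).
    """
    W = _pooled_cov(a, b)
    d = a.mean(axis=0) - b.mean(axis=0)
    x, *_ = np.linalg.lstsq(W, d, rcond=None)
    return float(abs(d @ x))


def _wilks_lambda(d_sq: float, n1: int, n0: int) -> float:
    """Two-class Wilks' lambda from the Mahalanobis D^2.

    Lambda = 1 / (1 + n1*n0/((n1+n0)(n1+n0-2)) * D^2); equals 1 when the
    class means coincide and shrinks toward 0 with separation.
    """
    n = n1 + n0
    return 1.0 / (1.0 + (n1 * n0) / (n * (n - 2.0)) * d_sq)


def lda_diagnostics(
    X: pd.DataFrame, y: np.ndarray, features: list[str] | None = None
) -> pd.DataFrame:
    """Per-variable tolerance, F-to-remove and Wilks' lambda.

    For each selected variable j: ``T_j`` is 1 minus the R^2 of j on the
    other selected variables (near 0 flags collinearity); ``Lambda_j`` is the
    Wilks' lambda of the model with j removed; and the partial F-to-remove is

        F_j = (n - p - 1) * (Lambda_j / Lambda_full - 1)

    which for p = 1 reduces to the two-sample squared t statistic.
    """
    X = pd.DataFrame(X)
    feats = list(features) if features is not None else list(X.columns)
    y = _as_bool_labels(y)
    arr = X[feats].to_numpy(dtype=np.float64)
    a, b = _class_split(arr, y)
    n1, n0 = len(a), len(b)
    n, p = n1 + n0, len(feats)
    if n - p - 1 <= 0:
        logger.warning("too few observations for F-to-remove; diagnostics omitted")
        return pd.DataFrame(columns=["T", "F", "Lambda"], index=feats)
    lam_full = _wilks_lambda(_mahalanobis_sq(a, b), n1, n0)
    rows = {}
    for j, name in enumerate(feats):
        tol = 1.0 - _r_squared_on_others(arr, j) if p > 1 else 1.0
        if p > 1:
            red = np.delete(arr, j, axis=1)
            lam_j = _wilks_lambda(_mahalanobis_sq(red[y], red[~y]), n1, n0)
        else:
            lam_j = 1.0
        f_rm = (n - p - 1.0) * (lam_j / lam_full - 1.0)
        rows[name] = {"T": tol, "F": f_rm, "Lambda": lam_j}
    return pd.DataFrame.from_dict(rows, orient="index")[["T", "F", "Lambda"]]


def _as_bool_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "USO":
        return y == SHOOT
    return y.astype(bool)


@dataclass
class ShootClassifier:
    """Fitted two-class Fisher discriminant for shoot recognition.

    ``score(x) = coef . x + intercept``; objects with score >= 0 are called
    shoots (boundary ties resolve to shoot: under-counting is the costlier
    error in breeding use).  Holds the per-variable diagnostics and the VIF
    deletion trace for reporting.
    """

    features: list[str]
    coef: np.ndarray
    intercept: float
    priors: tuple[float, float]  # (P(shoot), P(non-shoot))
    diagnostics: pd.DataFrame
    vif_trace: pd.DataFrame = field(default_factory=pd.DataFrame)
    species: str | None = None
    wilks_lambda: float = float("nan")

    def decision_scores(self, feats: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in feats.columns]
        if missing:
            raise ValueError(f"missing feature column: {missing[0]}")
        return feats[self.features].to_numpy(np.float64) @ self.coef + self.intercept

    def summary(self) -> str:
        lines = [
            "Shoot classifier (two-class Fisher LDA)",
            f"  species key : {self.species or '-'}",
            f"  features    : {', '.join(self.features)}",
            f"  priors      : shoot={self.priors[0]:.3f}, non-shoot={self.priors[1]:.3f}",
            f"  Wilks' lambda (full model): {self.wilks_lambda:.4f}",
            "",
            self.diagnostics.round(4).to_string(),
        ]
        if len(self.vif_trace):
            lines += ["", "VIF deletions:", self.vif_trace.round(2).to_string(index=False)]
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species": self.species,
            "features": self.features,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "priors": list(self.priors),
            "wilks_lambda": self.wilks_lambda,
            "diagnostics": self.diagnostics.reset_index()
            .rename(columns={"index": "feature"})
            .to_dict(orient="records"),
            "vif_trace": self.vif_trace.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ShootClassifier":
        d = json.loads(Path(path).read_text())
        diag = pd.DataFrame(d["diagnostics"])
        if len(diag):
            diag = diag.set_index("feature")[["T", "F", "Lambda"]]
        return cls(
            features=d["features"],
            coef=np.asarray(d["coef"], dtype=np.float64),
            intercept=float(d["intercept"]),
            priors=tuple(d["priors"]),
            diagnostics=diag,
            vif_trace=pd.DataFrame(d.get("vif_trace", [])),
            species=d.get("species"),
            wilks_lambda=float(d.get("wilks_lambda", float("nan"))),
        )


def fit_lda(
    X: pd.DataFrame,
    y,
    *,
    priors: str | tuple[float, float] = "empirical",
    species: str | None = None,
    stepwise: bool = True,
    f_remove_threshold: float = 1.0,
    min_features: int = 2,
    vif_trace: pd.DataFrame | None = None,
) -> ShootClassifier:
    """Fit the two-class Fisher discriminant, optionally with backward
    elimination of weak variables.

    The discriminant direction is ``w = W^-1 (mu_shoot - mu_nonshoot)`` with
    ``W`` the pooled within-class covariance; the cut sits at the midpoint of
    the projected class means shifted by the log prior ratio.  With
    ``stepwise=True`` the variable with the smallest F-to-remove is dropped
    repeatedly while that F stays below ``f_remove_threshold`` (never going
    below ``min_features`` variables).
    """
    X = pd.DataFrame(X)
    yb = _as_bool_labels(y)
    feats = list(X.columns)
    if X.isna().any().any():
        raise ValueError("training features contain missing values")
    if len(X) < len(feats) + 2:
        raise ValueError("need n >= p + 2 training objects")
    if stepwise:
        while len(feats) > min_features:
            diag = lda_diagnostics(X, yb, feats)
            weakest = diag["F"].idxmin()
            if diag.loc[weakest, "F"] >= f_remove_threshold:
                break
            logger.info(
                "stepwise LDA: removing %s (F-to-remove=%.3f)",
                weakest,
                diag.loc[weakest, "F"],
            )
            feats.remove(weakest)
    arr = X[feats].to_numpy(np.float64)
    a, b = _class_split(arr, yb)
    n1, n0 = len(a), len(b)
    if priors == "empirical":
        pri = (n1 / (n1 + n0), n0 / (n1 + n0))
    elif priors == "equal":
        pri = (0.5, 0.5)
    else:
        pri = (float(priors[0]), float(priors[1]))
    W = _pooled_cov(a, b)
    delta = a.mean(axis=0) - b.mean(axis=0)
    try:
        coef = np.linalg.solve(W, delta)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled covariance; prune collinear features first"
        ) from exc
    intercept = float(-coef @ (a.mean(axis=0) + b.mean(axis=0)) / 2.0
                      + math.log(pri[0] / pri[1]))
    diag = lda_diagnostics(X, yb, feats)
    lam = _wilks_lambda(_mahalanobis_sq(a, b), n1, n0)
    return ShootClassifier(
        features=feats,
        coef=coef,
        intercept=intercept,
        priors=pri,
        diagnostics=diag,
        vif_trace=vif_trace if vif_trace is not None else pd.DataFrame(),
        species=species,
        wilks_lambda=lam,
    )


def classify_objects(
    model: ShootClassifier, feats: pd.DataFrame
) -> tuple[np.ndarray, int]:
    """Label each object shoot / non-shoot and count the shoots.

    Objects exactly on the discriminant boundary are assigned to shoot
    (logged).  Returns ``(labels, E)`` with E the shoot count.
    """
    if len(feats) == 0:
        return np.array([], dtype=object), 0
    scores = model.decision_scores(feats)
    on_boundary = scores == 0.0
    if on_boundary.any():
        logger.info("%d objects exactly on the boundary -> shoot", on_boundary.sum())
    labels = np.where(scores >= 0.0, SHOOT, NON_SHOOT).astype(object)
    return labels, int((scores >= 0.0).sum())


def count_tillers(
    image: str | Path | np.ndarray,
    model: ShootClassifier,
    *,
    band: str = "blue",
    min_area: int = 200,
    opening_radius: int = 1,
    mm_per_px: float | None = None,
) -> dict:
    """Run the full pipeline on one photograph and report the tiller count.

    Stages: band split -> maximum-contrast threshold -> opening + area
    filter -> morphometry -> LDA classification.  Errors are re-raised with
    the failing stage named.  The report is JSON-serialisable.
    """
    name = None
    if isinstance(image, (str, Path)):
        name = Path(image).name
        image = imaging.read_image(image)
    stage = "band extraction"
    try:
        grey = imaging.to_blue_band(image, band=band)
        stage = "thresholding"
        threshold, mask = imaging.max_contrast_threshold(grey)
        stage = "labelling"
        objects = imaging.open_and_label(mask, min_area=min_area, opening_radius=opening_radius)
        stage = "morphometry"
        feats = morphometry.compute_feature_table(objects, mm_per_px=mm_per_px)
        stage = "classification"
        labels, e_count = classify_objects(model, feats)
    except ValueError as exc:
        raise ValueError(f"{stage}: {exc}") from exc
    report = {
        "threshold": int(threshold),
        "n_objects": objects.n_objects,
        "E": e_count,
        "labels": list(map(str, labels)),
        "object_ids": [int(i) for i in feats["id"]] if len(feats) else [],
    }
    if name is not None:
        report = {"image": name, **report}
    return report
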