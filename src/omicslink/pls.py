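"""Partial least squares regression (NIPALS, orthogonal scores) with
cross-validated prediction-error curves.

PLS builds the linear model Y = XB + E through a sequence of latent
variables: each component extracts a score t = Xw maximizing covariance with
the responses, regresses both blocks on t, and deflates X before the next
extraction.  The collected matrices are the classical T (X-scores), W
(X-weights), P (X-loadings), U (Y-scores) and Q (Y-loadings); regression
coefficients for a components are B_a = W_a (P_a' W_a)^{-1} Q_a'.  (The
uncorrected product W Q' is exact only without deflation; with deflation the
(P'W)^{-1} correction is required and is what this implementation uses —
recorded in the result metadata.)

Unlike CCA, PLS tolerates collinear predictors and n < p, which is why it
serves as the second engine on the same functional groups.  Component choice
is guided by cross-validation: for each response and component count the
root mean squared error of prediction (RMSEP), its square (MSEP) and an R²
against the cross-validated mean-only baseline are computed under
leave-one-out or seeded k-fold schemes.
"""

from __future__ import annotations

import enum
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, LeaveOneOut

from .io import OmicsMatrix

__all__ = [
    "PLSResult",
    "CVResult",
    "CVScheme",
    "fit_pls",
    "predict",
    "cross_validate",
    "write_pls_reports",
]

NIPALS_TOL = 1e-12
NIPALS_MAX_ITER = 500


@dataclass
class PLSResult:
    """Fitted PLS model (orthogonal-scores NIPALS).

    ``coefficients`` has shape (ncomp, p, m): ``coefficients[a - 1]`` is the
    regression matrix using the first ``a`` latent variables, on the
    centered/scaled training scale.  ``explained_x`` / ``explained_y`` are
    cumulative percentages of block variance captured per component count.
    """

    ncomp: int
    x_features: list[str]
    y_features: list[str]
    sample_ids: list[str]
    x_scores: np.ndarray      # T, n × A
    x_weights: np.ndarray     # W, p × A
    x_loadings: np.ndarray    # P, p × A
    y_scores: np.ndarray      # U, n × A
    y_loadings: np.ndarray    # Q, m × A
    coefficients: np.ndarray  # A × p × m
    x_residuals: np.ndarray   # unexplained part of X (scaled space)
    y_residuals: np.ndarray   # unexplained part of Y (scaled space)
    explained_x: np.ndarray   # cumulative %, length A
    explained_y: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    scaled: bool
    n_iterations: list[int] = field(default_factory=list)
    notes: str = (
        "coefficients use the deflation-corrected form B = W (P'W)^{-1} Q'"
    )


def _check_xy(X: OmicsMatrix, Y: OmicsMatrix) -> None:
    if X.sample_ids != Y.sample_ids:
        raise ValueError("X and Y must share the same samples in the same order")


def _center_scale(values: np.ndarray, scale: bool, what: str, features: list[str]):
    mean = values.mean(axis=0)
    if scale:
        sd = values.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            bad = [f for f, z in zip(features, zero) if z]
            raise ValueError(f"zero-variance {what} column(s): {bad}")
    else:
        sd = np.ones(values.shape[1])
    return (values - mean) / sd, mean, sd


def _nipals(Xs: np.ndarray, Ys: np.ndarray, ncomp: int):
    """Core NIPALS extraction on already centered/scaled arrays."""
    E = Xs.copy()
    F = Ys.copy()
    n, p = E.shape
    m = F.shape[1]
    T = np.empty((n, ncomp))
    W = np.empty((p, ncomp))
    P = np.empty((p, ncomp))
    U = np.empty((n, ncomp))
    Q = np.empty((m, ncomp))
    iters: list[int] = []
    for a in range(ncomp):
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        t = np.zeros(n)
        for it in range(1, NIPALS_MAX_ITER + 1):
            w = E.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise np.linalg.LinAlgError(
                    f"component {a + 1}: X carries no covariance with Y residuals"
                )
            w /= norm
            t_new = E @ w
            q = F.T @ t_new / (t_new @ t_new)
            if m == 1 or np.linalg.norm(t_new - t) <= NIPALS_TOL * np.linalg.norm(t_new):
                t = t_new
                break
            u = F @ q / (q @ q)
            t = t_new
        iters.append(it)
        tt = t @ t
        p_a = E.T @ t / tt
        q_a = F.T @ t / tt
        E -= np.outer(t, p_a)
        F -= np.outer(t, q_a)
        T[:, a], W[:, a], P[:, a], Q[:, a], U[:, a] = t, w, p_a, q_a, u
    return T, W, P, Q, U, E, F, iters


def fit_pls(
    X: OmicsMatrix, Y: OmicsMatrix, ncomp: int, scale: bool = True
) -> PLSResult:
    """Fit a PLS regression of Y on X with ``ncomp`` latent variables.

    Centering is always applied; unit-variance scaling (default on, since
    omics blocks live on heterogeneous scales) can be switched off.  Valid
    component counts are 1 ≤ ncomp ≤ min(n − 1, p); n < p is explicitly
    supported.  Zero-variance response columns are a hard error (they carry
    no signal and break scaling).
    """
    _check_xy(X, Y)
    res = _fit_arrays(X.values, Y.values, ncomp, scale, X.feature_ids, Y.feature_ids)
    res.x_features = list(X.feature_ids)
    res.y_features = list(Y.feature_ids)
    res.sample_ids = list(X.sample_ids)
    return res


def _fit_arrays(
    Xv: np.ndarray,
    Yv: np.ndarray,
    ncomp: int,
    scale: bool,
    x_features: list[str] | None = None,
    y_features: list[str] | None = None,
) -> PLSResult:
    n, p = Xv.shape
    m = Yv.shape[1]
    x_features = x_features or [f"x{j}" for j in range(p)]
    y_features = y_features or [f"y{j}" for j in range(m)]
    limit = min(n - 1, p)
    if not 1 <= ncomp <= limit:
        raise ValueError(
            f"ncomp must be in [1, {limit}] for n = {n}, p = {p}; got {ncomp}"
        )
    sd_y = Yv.std(axis=0, ddof=1)
    if np.any(sd_y == 0):
        bad = [f for f, s in zip(y_features, sd_y) if s == 0]
        raise ValueError(f"zero-variance response column(s): {bad}")
    Xs, x_mean, x_scale = _center_scale(Xv, scale, "predictor", x_features)
    Ys, y_mean, y_scale = _center_scale(Yv, scale, "response", y_features)
    T, W, P, Q, U, E, F, iters = _nipals(Xs, Ys, ncomp)
    # per-component coefficient matrices, deflation-corrected
    B = np.empty((ncomp, p, m))
    for a in range(1, ncomp + 1):
        PtW = P[:, :a].T @ W[:, :a]
        B[a - 1] = W[:, :a] @ np.linalg.solve(PtW, Q[:, :a].T)
    ss_x = float((Xs**2).sum())
    ss_y = float((Ys**2).sum())
    tt = (T**2).sum(axis=0)
    explained_x = 100.0 * np.cumsum(tt * (P**2).sum(axis=0)) / ss_x
    explained_y = 100.0 * np.cumsum(tt * (Q**2).sum(axis=0)) / ss_y
    return PLSResult(
        ncomp=ncomp,
        x_features=x_features,
        y_features=y_features,
        sample_ids=[str(i) for i in range(n)],
        x_scores=T,
        x_weights=W,
        x_loadings=P,
        y_scores=U,
        y_loadings=Q,
        coefficients=B,
        x_residuals=E,
        y_residuals=F,
        explained_x=explained_x,
        explained_y=explained_y,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        scaled=scale,
        n_iterations=iters,
    )


def predict(
    res: PLSResult, X_new: OmicsMatrix | np.ndarray, ncomp: int | None = None
) -> np.ndarray:
    """Predict responses for new samples using the first ``ncomp`` components.

    ``ncomp = 0`` returns the training response means for every sample (the
    cross-validation baseline).  For an :class:`~omicslink.io.OmicsMatrix`
    input the feature set must match the training features exactly.
    """
    if ncomp is None:
        ncomp = res.ncomp
    if not 0 <= ncomp <= res.ncomp:
        raise ValueError(f"ncomp must be in [0, {res.ncomp}], got {ncomp}")
    if isinstance(X_new, OmicsMatrix):
        if list(X_new.feature_ids) != list(res.x_features):
            missing = set(res.x_features) - set(X_new.feature_ids)
            extra = set(X_new.feature_ids) - set(res.x_features)
            raise ValueError(
                f"feature mismatch with training X: missing {sorted(missing)}, "
                f"extra {sorted(extra)}"
            )
        Xv = X_new.values
    else:
        Xv = np.asarray(X_new, dtype=float)
    if Xv.shape[1] != len(res.x_features):
        raise ValueError(
            f"expected {len(res.x_features)} features, got {Xv.shape[1]}"
        )
    if ncomp == 0:
        return np.tile(res.y_mean, (Xv.shape[0], 1))
    Xs = (Xv - res.x_mean) / res.x_scale
    return Xs @ res.coefficients[ncomp - 1] * res.y_scale + res.y_mean


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


class CVKind(str, enum.Enum):
    LOO = "loo"
    KFOLD = "kfold"


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation scheme: LOO (default) or seeded k-fold."""

    kind: CVKind = CVKind.LOO
    k: int | None = None
    seed: int | None = None

    @classmethod
    def parse(cls, text: str) -> "CVScheme":
        """Parse ``"loo"`` or ``"kfold:<k>:<seed>"``."""
        if text == "loo":
            return cls(CVKind.LOO)
        m = re.fullmatch(r"kfold:(\d+):(\d+)", text)
        if m is None:
            raise ValueError(f"unrecognized CV scheme {text!r}")
        return cls(CVKind.KFOLD, int(m.group(1)), int(m.group(2)))

    def __str__(self) -> str:
        if self.kind is CVKind.LOO:
            return "loo"
        return f"kfold:{self.k}:{self.seed}"

    def splits(self, n: int):
        if self.kind is CVKind.LOO:
            return LeaveOneOut().split(np.arange(n))
        if self.k is None or not 2 <= self.k <= n:
            raise ValueError(f"k-fold needs 2 <= k <= n = {n}, got k = {self.k}")
        return KFold(n_splits=self.k, shuffle=True, random_state=self.seed).split(
            np.arange(n)
        )


@dataclass
class CVResult:
    """Prediction-error curves per response and component count.

    Arrays have shape (m, max_ncomp + 1); column 0 is the mean-only
    baseline.  ``r2`` is 1 − PRESS_a / PRESS_0, i.e. skill relative to the
    cross-validated training-fold mean.
    """

    scheme: CVScheme
    responses: list[str]
    ncomps: np.ndarray
    rmsep: np.ndarray
    msep: np.ndarray
    r2: np.ndarray

    def best_ncomp(self) -> int:
        """Component count minimizing mean RMSEP over responses."""
        return int(np.argmin(self.rmsep.mean(axis=0)))


def cross_validate(
    X: OmicsMatrix,
    Y: OmicsMatrix,
    max_ncomp: int,
    scheme: CVScheme | str = CVScheme(),
    scale: bool = True,
) -> CVResult:
    """Cross-validated RMSEP/MSEP/R² curves for 0 … ``max_ncomp`` components.

    Every fold refits from scratch with the same centering/scaling policy as
    training, so the error estimates honestly include the preprocessing.
    """
    _check_xy(X, Y)
    if isinstance(scheme, str):
        scheme = CVScheme.parse(scheme)
    n, p = X.values.shape
    m = Y.values.shape[1]
    min_train = (
        n - 1 if scheme.kind is CVKind.LOO else n - int(np.ceil(n / (scheme.k or 2)))
    )
    if max_ncomp > min(min_train - 1, p) or max_ncomp < 1:
        raise ValueError(
            f"max_ncomp = {max_ncomp} infeasible: the smallest training fold "
            f"({min_train} samples, {p} predictors) supports at most "
            f"{min(min_train - 1, p)} components"
        )
    press = np.zeros((m, max_ncomp + 1))
    for train, test in scheme.splits(n):
        fit = _fit_arrays(
            X.values[train], Y.values[train], max_ncomp, scale,
            list(X.feature_ids), list(Y.feature_ids),
        )
        for a in range(max_ncomp + 1):
            pred = predict(fit, X.values[test], a)
            press[:, a] += ((Y.values[test] - pred) ** 2).sum(axis=0)
    msep = press / n
    rmsep = np.sqrt(msep)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - press / press[:, [0]]
    return CVResult(
        scheme=scheme,
        responses=list(Y.feature_ids),
        ncomps=np.arange(max_ncomp + 1),
        rmsep=rmsep,
        msep=msep,
        r2=r2,
    )


def write_pls_reports(
    res: PLSResult, out_dir: str | os.PathLike, cv: CVResult | None = None
) -> list[str]:
    """Write TSVs for every fitted matrix, the explained-variance profile and
    (optionally) the cross-validation curves; returns the file paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths: list[str] = []
    lv = [f"LV{a + 1}" for a in range(res.ncomp)]

    def _write(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(out_dir, name)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
        paths.append(path)

    _write("scores.tsv", pd.DataFrame(res.x_scores, columns=lv).assign(
        sample_id=res.sample_ids)[["sample_id"] + lv])
    _write("weights.tsv", pd.DataFrame(res.x_weights, columns=lv).assign(
        feature=res.x_features)[["feature"] + lv])
    _write("loadings.tsv", pd.DataFrame(res.x_loadings, columns=lv).assign(
        feature=res.x_features)[["feature"] + lv])
    _write("Yscores.tsv", pd.DataFrame(res.y_scores, columns=lv).assign(
        sample_id=res.sample_ids)[["sample_id"] + lv])
    _write("Yloadings.tsv", pd.DataFrame(res.y_loadings, columns=lv).assign(
        response=res.y_features)[["response"] + lv])
    coef = pd.concat(
        [
            pd.DataFrame(res.coefficients[a], columns=res.y_features).assign(
                ncomp=a + 1, predictor=res.x_features
            )
            for a in range(res.ncomp)
        ],
        ignore_index=True,
    )
    _write("coefficients.tsv", coef[["ncomp", "predictor"] + res.y_features])
    _write(
        "explained_variance.tsv",
        pd.DataFrame(
            {
                "component": lv,
                "cum_explained_x_pct": res.explained_x,
                "cum_explained_y_pct": res.explained_y,
            }
        ),
    )
    if cv is not None:
        rows = []
        for j, resp in enumerate(cv.responses):
            for a in cv.ncomps:
                rows.append(
                    {
                        "response": resp,
                        "ncomp": int(a),
                        "rmsep": cv.rmsep[j, a],
                        "msep": cv.msep[j, a],
                        "r2": cv.r2[j, a],
                    }
                )
        _write("cv_curves.tsv", pd.DataFrame(rows))
    return paths
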