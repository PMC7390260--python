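"""Canonical correlation analysis with full diagnostics.

Given two sample-aligned matrices X (n × p) and Y (n × q), CCA finds pairs
of linear combinations u_i = X a_i, v_i = Y b_i maximizing cor(u_i, v_i)
subject to each new pair being uncorrelated with the previous ones.  Both
blocks are standardized (mean 0, sd 1) first, so weights are on the
comparable standardized-variable scale.

Computation is by singular value decomposition of the whitened cross-
correlation matrix R_xx^{-1/2} R_xy R_yy^{-1/2}: the singular values are the
canonical correlations and the whitened singular vectors give the weights.
This route is numerically symmetric in the two blocks and avoids forming the
non-symmetric product matrix whose eigendecomposition is less stable.

The diagnostic suite mirrors the classical reporting conventions:

* **loadings** — correlations of each original variable with each canonical
  variate (squared loading = fraction of that variable's variance explained);
* **adequacy** — mean squared loading of a set on one of its own variates;
* **communality** — per-variable sum of squared loadings over all variates;
* **redundancy** — fraction of one set's total variance explained by a
  variate of the *other* set: r_i² × (mean squared loading of the set on its
  own i-th variate);
* **Bartlett's sequential chi-squared test** — for each index i, tests
  H0: r_i = … = r_k = 0 via χ²_i = −[n − 1 − (p + q + 1)/2]·ln Λ_i with
  Λ_i = Π_{j≥i} (1 − r_j²) and df_i = (p − i + 1)(q − i + 1).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import OmicsMatrix

__all__ = ["CCAResult", "fit_cca", "bartlett_test", "helio_data", "write_cca_reports"]

SINGULARITY_TOL = 1e-10  # minimum eigenvalue of a within-set correlation matrix
SAMPLE_SIZE_FACTOR = 20  # classical n >= 20 * max(p, q) guideline


class SingularCorrelationError(np.linalg.LinAlgError):
    """Within-set correlation matrix is (numerically) singular."""


@dataclass
class CCAResult:
    """All canonical pairs with weights, variates and diagnostics.

    Shapes: ``correlations`` (k,), ``x_weights`` (p, k), ``y_weights``
    (q, k), ``x_variates``/``y_variates`` (n, k), loadings (p, k)/(q, k),
    adequacies and redundancies (k,), communalities (p,)/(q,).  Redundancy
    ``y_redundancies[i]`` is the fraction of Y's total variance explained by
    the X-side variate u_i (and symmetrically for ``x_redundancies``).
    """

    n: int
    p: int
    q: int
    k: int
    x_features: list[str]
    y_features: list[str]
    sample_ids: list[str]
    correlations: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray
    x_variates: np.ndarray
    y_variates: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_adequacies: np.ndarray
    y_adequacies: np.ndarray
    x_communalities: np.ndarray
    y_communalities: np.ndarray
    x_redundancies: np.ndarray
    y_redundancies: np.ndarray
    bartlett: pd.DataFrame = field(repr=False, default=None)


def _standardize(values: np.ndarray, what: str, features: list[str]) -> np.ndarray:
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [f for f, s in zip(features, sd) if s == 0]
        raise SingularCorrelationError(
            f"zero-variance {what} column(s) {bad}: correlation matrix singular; "
            "run the decorrelation (prune) step first"
        )
    return (values - values.mean(axis=0)) / sd


def _inv_sqrt(R: np.ndarray, what: str) -> np.ndarray:
    w, V = np.linalg.eigh(R)
    if w.min() < SINGULARITY_TOL:
        raise SingularCorrelationError(
            f"within-set correlation matrix of {what} is singular or nearly so "
            f"(min eigenvalue {w.min():.3e}); remove collinear columns with the "
            "decorrelation (prune) step first"
        )
    return V @ np.diag(1.0 / np.sqrt(w)) @ V.T


def fit_cca(X: OmicsMatrix, Y: OmicsMatrix) -> CCAResult:
    """Fit canonical correlation analysis between two sample-aligned sets.

    Requires the same samples in the same order in both matrices and
    n > max(p, q) + 1; below the classical guideline of 20 samples per
    variable a warning is emitted (small-n canonical correlations are
    strongly inflated).  Signs are fixed so that, for each canonical pair,
    the largest-magnitude loading across both blocks is positive.
    """
    if X.sample_ids != Y.sample_ids:
        raise ValueError("X and Y must share the same samples in the same order")
    n, p = X.values.shape
    q = Y.values.shape[1]
    if n <= max(p, q) + 1:
        raise ValueError(
            f"n = {n} samples cannot support CCA with p = {p}, q = {q} "
            f"(need n > max(p, q) + 1)"
        )
    if n < SAMPLE_SIZE_FACTOR * max(p, q):
        warnings.warn(
            f"n = {n} is below the {SAMPLE_SIZE_FACTOR}x-variables guideline "
            f"(max(p, q) = {max(p, q)}); canonical correlations will be inflated",
            stacklevel=2,
        )
    Zx = _standardize(X.values, "X", X.feature_ids)
    Zy = _standardize(Y.values, "Y", Y.feature_ids)
    Rxx = Zx.T @ Zx / (n - 1)
    Ryy = Zy.T @ Zy / (n - 1)
    Rxy = Zx.T @ Zy / (n - 1)
    Wx = _inv_sqrt(Rxx, "X")
    Wy = _inv_sqrt(Ryy, "Y")
    U, s, Vt = np.linalg.svd(Wx @ Rxy @ Wy)
    k = min(p, q)
    r = np.clip(s[:k], 0.0, 1.0)
    a = Wx @ U[:, :k]
    b = Wy @ Vt.T[:, :k]
    # loadings on standardized data are exactly R @ weights
    lx = Rxx @ a
    ly = Ryy @ b
    # sign convention: largest-|loading| entry across both blocks positive
    for i in range(k):
        stacked = np.concatenate([lx[:, i], ly[:, i]])
        if stacked[np.argmax(np.abs(stacked))] < 0:
            a[:, i] *= -1
            b[:, i] *= -1
            lx[:, i] *= -1
            ly[:, i] *= -1
    u = Zx @ a
    v = Zy @ b
    x_adeq = (lx**2).mean(axis=0)
    y_adeq = (ly**2).mean(axis=0)
    return CCAResult(
        n=n, p=p, q=q, k=k,
        x_features=list(X.feature_ids),
        y_features=list(Y.feature_ids),
        sample_ids=list(X.sample_ids),
        correlations=r,
        x_weights=a,
        y_weights=b,
        x_variates=u,
        y_variates=v,
        x_loadings=lx,
        y_loadings=ly,
        x_adequacies=x_adeq,
        y_adequacies=y_adeq,
        x_communalities=(lx**2).sum(axis=1),
        y_communalities=(ly**2).sum(axis=1),
        x_redundancies=r**2 * x_adeq,
        y_redundancies=r**2 * y_adeq,
        bartlett=_bartlett_allowing_degenerate(r, n, p, q),
    )


def _bartlett_allowing_degenerate(
    r: np.ndarray, n: int, p: int, q: int
) -> pd.DataFrame:
    """Bartlett table that tolerates numerically perfect correlations.

    A canonical correlation of 1 drives Λ to 0, so the chi-squared statistic
    diverges; the correct limit (chi² = inf, p = 0) is reported for every
    index whose tail contains such a correlation."""
    degenerate = r >= 1 - 1e-12
    if not degenerate.any():
        return bartlett_test(r, n, p, q)
    table = bartlett_test(np.where(degenerate, 0.0, r), n, p, q)
    last_degenerate = int(np.max(np.nonzero(degenerate)))
    table.loc[: last_degenerate, "chi_squared"] = np.inf
    table.loc[: last_degenerate, "p_value"] = 0.0
    table["canonical_correlation"] = r
    return table


def bartlett_test(
    correlations: np.ndarray, n: int, p: int, q: int
) -> pd.DataFrame:
    """Sequential chi-squared tests of H0: r_i = … = r_k = 0.

    Uses the classic multiplier −[n − 1 − (p + q + 1)/2]; for test index i,
    Λ_i = Π_{j=i..k} (1 − r_j²), χ²_i = multiplier · ln Λ_i and
    df_i = (p − i + 1)(q − i + 1); p-values come from the chi-squared
    upper tail.
    """
    r = np.asarray(correlations, dtype=float)
    if np.any((r < 0) | (r >= 1)):
        raise ValueError(f"canonical correlations must lie in [0, 1): {r}")
    mult = n - 1 - (p + q + 1) / 2
    if mult <= 0:
        raise ValueError(
            f"n = {n} too small for Bartlett's test with p = {p}, q = {q} "
            f"(need n > (p + q + 3)/2)"
        )
    k = len(r)
    rows = []
    for i in range(1, k + 1):
        lam = float(np.prod(1.0 - r[i - 1 :] ** 2))
        chi2 = -mult * np.log(lam)
        df = (p - i + 1) * (q - i + 1)
        rows.append(
            {
                "index": i,
                "canonical_correlation": r[i - 1],
                "chi_squared": chi2,
                "df": df,
                "p_value": float(stats.chi2.sf(chi2, df)),
            }
        )
    return pd.DataFrame(rows)


def helio_data(res: CCAResult, cv_index: int) -> pd.DataFrame:
    """Plot-ready table for a helio (circular bar) plot of one variate.

    One row per variable of either block: its structural loading on the
    chosen canonical variate (positive bars point outward, negative inward)
    and an evenly-spaced angular position in degrees.  ``cv_index`` is
    1-based.
    """
    if not 1 <= cv_index <= res.k:
        raise ValueError(f"cv_index must be in [1, {res.k}], got {cv_index}")
    i = cv_index - 1
    variables = list(res.x_features) + list(res.y_features)
    sets = ["X"] * res.p + ["Y"] * res.q
    loadings = np.concatenate([res.x_loadings[:, i], res.y_loadings[:, i]])
    total = res.p + res.q
    angles = 360.0 * np.arange(total) / total
    return pd.DataFrame(
        {
            "variable": variables,
            "set": sets,
            "loading": loadings,
            "angle_deg": angles,
        }
    )


def write_cca_reports(res: CCAResult, out_dir: str | os.PathLike) -> list[str]:
    """Write one TSV per diagnostic block; returns the file paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []

    def _write(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(out_dir, name)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
        paths.append(path)

    cv_names = [f"CV{i + 1}" for i in range(res.k)]
    _write("correlations_bartlett.tsv", res.bartlett)
    _write(
        "weights.tsv",
        pd.DataFrame(
            np.vstack([res.x_weights, res.y_weights]),
            columns=cv_names,
        ).assign(
            variable=res.x_features + res.y_features,
            set=["X"] * res.p + ["Y"] * res.q,
        )[["variable", "set"] + cv_names],
    )
    _write(
        "loadings.tsv",
        pd.DataFrame(
            np.vstack([res.x_loadings, res.y_loadings]), columns=cv_names
        ).assign(
            variable=res.x_features + res.y_features,
            set=["X"] * res.p + ["Y"] * res.q,
        )[["variable", "set"] + cv_names],
    )
    _write(
        "adequacies.tsv",
        pd.DataFrame(
            {
                "variate": cv_names,
                "x_adequacy": res.x_adequacies,
                "y_adequacy": res.y_adequacies,
            }
        ),
    )
    _write(
        "communalities.tsv",
        pd.DataFrame(
            {
                "variable": res.x_features + res.y_features,
                "set": ["X"] * res.p + ["Y"] * res.q,
                "communality": np.concatenate(
                    [res.x_communalities, res.y_communalities]
                ),
            }
        ),
    )
    _write(
        "redundancies.tsv",
        pd.DataFrame(
            {
                "variate": cv_names,
                "x_variance_explained_by_v": res.x_redundancies,
                "y_variance_explained_by_u": res.y_redundancies,
            }
        ),
    )
    _write("helio_cv1.tsv", helio_data(res, 1))
    return paths
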