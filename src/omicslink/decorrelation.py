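"""Within-set correlation pruning.

Classical CCA breaks down when either variable set carries strongly
collinear columns (the within-set correlation matrix becomes singular or
badly conditioned), so before the statistics stage each set is reduced to a
subset of mutually weakly-correlated representatives.  The rule is a greedy
scan in input column order: the first column is always kept; each subsequent
column is dropped if its absolute correlation with any already-kept column
reaches the threshold, and the kept column with the largest |r| is recorded
as its representative.  Dropped features are never silently lost — they
remain in the result for reporting and later biological interpretation.
"""

from __future__ import annotations

import enum
import os
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import OmicsMatrix

__all__ = ["CorrelationMethod", "DroppedFeature", "PruneResult", "prune_correlated",
           "write_prune_report"]


class CorrelationMethod(str, enum.Enum):
    PEARSON = "pearson"
    SPEARMAN = "spearman"


@dataclass(frozen=True)
class DroppedFeature:
    feature_id: str
    representative_id: str | None  # None for zero-variance columns
    correlation: float  # |r| with the representative; NaN for constants


@dataclass
class PruneResult:
    kept: list[str]
    dropped: list[DroppedFeature]
    threshold: float
    method: CorrelationMethod

    @property
    def kept_set(self) -> set[str]:
        return set(self.kept)


def _correlation_matrix(values: np.ndarray, method: CorrelationMethod) -> np.ndarray:
    if method is CorrelationMethod.SPEARMAN:
        ranked = stats.rankdata(values, axis=0)
        return np.corrcoef(ranked, rowvar=False)
    return np.corrcoef(values, rowvar=False)


def prune_correlated(
    m: OmicsMatrix,
    threshold: float,
    method: CorrelationMethod | str = CorrelationMethod.PEARSON,
) -> PruneResult:
    """Greedily select mutually weakly-correlated feature representatives.

    Parameters
    ----------
    m
        Input matrix; column order determines scan order and hence the
        outcome — the rule is deterministic given the file's column order.
    threshold
        Features with |r| ≥ ``threshold`` against a kept column are dropped;
        must lie in (0, 1].  At 1.0 only exact duplicates (and constants)
        are removed.
    method
        ``pearson`` (default — CCA and PLS are linear methods) or
        ``spearman``.

    Zero-variance columns have undefined correlations; they are dropped with
    no representative and a warning.
    """
    method = CorrelationMethod(method)
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    p = m.n_features
    if p == 1:
        return PruneResult(kept=list(m.feature_ids), dropped=[], threshold=threshold,
                           method=method)
    constant = np.ptp(m.values, axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = _correlation_matrix(m.values, method)
    kept_idx: list[int] = []
    dropped: list[DroppedFeature] = []
    for j in range(p):
        fid = m.feature_ids[j]
        if constant[j]:
            warnings.warn(
                f"feature {fid!r} has zero variance; dropped (correlation undefined)",
                stacklevel=2,
            )
            dropped.append(DroppedFeature(fid, None, float("nan")))
            continue
        if kept_idx:
            rs = np.abs(corr[j, kept_idx])
            if np.nanmax(rs) >= threshold:
                best = kept_idx[int(np.nanargmax(rs))]
                dropped.append(
                    DroppedFeature(fid, m.feature_ids[best], float(np.nanmax(rs)))
                )
                continue
        kept_idx.append(j)
    return PruneResult(
        kept=[m.feature_ids[j] for j in kept_idx],
        dropped=dropped,
        threshold=threshold,
        method=method,
    )


def write_prune_report(res: PruneResult, path: str | os.PathLike) -> None:
    """TSV report: feature_id, status, representative, abs_correlation."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("feature_id\tstatus\trepresentative\tabs_correlation\n")
        for fid in res.kept:
            fh.write(f"{fid}\tkept\t\t\n")
        for d in res.dropped:
            rep = d.representative_id or ""
            r = "" if np.isnan(d.correlation) else f"{d.correlation:.6f}"
            fh.write(f"{d.feature_id}\tdropped\t{rep}\t{r}\n")
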