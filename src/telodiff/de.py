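"""Filtering, log transform, two-sample Student's t-test and BH FDR control.

The filter cascade is applied in order: (1) transcripts with all values
exactly zero are removed; (2) among the remainder, the bottom quintile by
mean expression across all samples is removed (floor(0.2 n) lowest means,
ties broken by stable input order); (3) transcripts with mean expression
below a threshold (default 0.05) are removed. Testing is a pooled-variance,
two-sided, independent two-sample Student's t on log2-transformed values
with Benjamini–Hochberg adjustment; significance is q < alpha (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger("telodiff")


@dataclass
class FilterReport:
    n_input: int
    n_zero_removed: int
    n_quintile_removed: int
    n_below_mean_threshold: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (
            self.n_zero_removed
            + self.n_quintile_removed
            + self.n_below_mean_threshold
            + self.n_retained
        )
        if total != self.n_input:
            raise ValidationError(
                f"filter counts do not sum to input: {total} != {self.n_input}"
            )


@dataclass
class DESummary:
    """Counts and direction fractions of a differential-expression run.

    ``frac_down_significant`` and ``frac_down_all`` are ``None`` when their
    denominator is empty.
    """

    n_analyzed: int
    n_significant: int
    n_down: int
    n_up: int
    frac_down_significant: Optional[float]
    frac_down_all: Optional[float]

    @classmethod
    def from_counts(
        cls, n_analyzed: int, n_down: int, n_up: int, n_down_all: int | None = None
    ) -> "DESummary":
        n_sig = n_down + n_up
        return cls(
            n_analyzed=n_analyzed,
            n_significant=n_sig,
            n_down=n_down,
            n_up=n_up,
            frac_down_significant=(n_down / n_sig) if n_sig else None,
            frac_down_all=(n_down_all / n_analyzed)
            if (n_down_all is not None and n_analyzed)
            else None,
        )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_transcripts(
    m: ExpressionMatrix, mean_threshold: float = 0.05
) -> tuple[ExpressionMatrix, FilterReport]:
    """Apply the zero / bottom-quintile / mean-threshold cascade in order."""
    values = m.values
    n_input = len(values)
    means = values.mean(axis=1).to_numpy()

    all_zero = (values.to_numpy() == 0).all(axis=1)
    n_zero = int(all_zero.sum())
    keep1 = values.index[~all_zero]
    means1 = means[~all_zero]

    n_quintile = int(np.floor(0.2 * len(keep1)))
    order = np.argsort(means1, kind="stable")
    drop_q = set(order[:n_quintile])
    keep2_mask = np.array([i not in drop_q for i in range(len(keep1))])
    keep2 = keep1[keep2_mask]
    means2 = means1[keep2_mask]

    below = means2 < mean_threshold
    n_below = int(below.sum())
    keep3 = keep2[~below]

    if len(keep3) < 5:
        raise ValidationError(
            f"only {len(keep3)} transcripts remain after filtering; need >= 5"
        )
    report = FilterReport(
        n_input=n_input,
        n_zero_removed=n_zero,
        n_quintile_removed=n_quintile,
        n_below_mean_threshold=n_below,
        n_retained=len(keep3),
    )
    logger.info(
        "filter: %d input, %d all-zero, %d bottom-quintile, %d below mean %.3g, "
        "%d retained",
        n_input, n_zero, n_quintile, n_below, mean_threshold, len(keep3),
    )
    return m.subset_transcripts(keep3), report


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount), elementwise; monotone and finite."""
    if pseudocount < 0:
        raise ValidationError(f"pseudocount must be >= 0, got {pseudocount}")
    return ExpressionMatrix(np.log2(m.values + pseudocount), dict(m.group_of))


# ---------------------------------------------------------------------------
# Optional quality control (off by default)
# ---------------------------------------------------------------------------


def qc_remove_outlier_samples(
    m: ExpressionMatrix, k: float = 5.0
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop samples farther than ``k`` MADs from the centroid on PC1/PC2.

    A disclosed, explicit stand-in for per-sample quality screening; requires
    at least 3 samples per group to act, and never empties a group below 2.
    """
    from sklearn.decomposition import PCA

    X = m.values.to_numpy().T  # samples x transcripts
    Xc = X - X.mean(axis=0)
    coords = PCA(n_components=2).fit_transform(Xc)
    d = np.linalg.norm(coords - np.median(coords, axis=0), axis=1)
    mad = np.median(np.abs(d - np.median(d)))
    if mad == 0:
        return m, []
    outliers = [s for s, di in zip(m.sample_ids, d) if di > k * mad]
    kept = [s for s in m.sample_ids if s not in outliers]
    for label in ("case", "control"):
        if sum(1 for s in kept if m.group_of[s] == label) < 2:
            logger.warning("outlier removal would empty group %r; skipped", label)
            return m, []
    if outliers:
        logger.info("removed outlier samples: %s", ", ".join(outliers))
        return (
            ExpressionMatrix(m.values[kept], {s: m.group_of[s] for s in kept}),
            outliers,
        )
    return m, []


def qc_remove_abundant_transcripts(
    m: ExpressionMatrix, max_fraction: float = 0.05
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop transcripts capturing more than ``max_fraction`` of any sample's
    total signal (a normalization-artifact guard)."""
    totals = m.values.sum(axis=0)
    share = m.values / totals.replace(0, np.nan)
    bad = share.max(axis=1) > max_fraction
    dropped = list(m.values.index[bad.fillna(False)])
    if dropped:
        logger.info("removed overly abundant transcripts: %s", ", ".join(dropped))
        keep = [t for t in m.transcript_ids if t not in set(dropped)]
        return m.subset_transcripts(keep), dropped
    return m, []


# ---------------------------------------------------------------------------
# Testing
# ---------------------------------------------------------------------------


def student_t_two_sample(x, y) -> tuple[float, float]:
    """Pooled-variance two-sample Student's t with two-sided p.

    df = n1 + n2 - 2. Degenerate zero-variance input: equal means give
    (t=0, p=1); unequal means give p=0 (the caller should treat this as a
    flagged degenerate case).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least 2 values")
    t, p, _ = _t_rows(x[None, :], y[None, :])
    return float(t[0]), float(p[0])


def _t_rows(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised pooled t over rows. Returns (t, p, degenerate_mask)."""
    n1, n2 = X.shape[1], Y.shape[1]
    mx, my = X.mean(axis=1), Y.mean(axis=1)
    vx = X.var(axis=1, ddof=1)
    vy = Y.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * vx + (n2 - 1) * vy) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = mx - my
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, diff / np.where(se == 0, 1.0, se))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero pooled variance: equal means -> t=0, p=1; unequal -> p=0
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate & (diff != 0), np.sign(diff) * np.inf, t)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    return t, p, degenerate & (diff != 0)


def _welch_rows(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n1, n2 = X.shape[1], Y.shape[1]
    mx, my = X.mean(axis=1), Y.mean(axis=1)
    vx = X.var(axis=1, ddof=1) / n1
    vy = Y.var(axis=1, ddof=1) / n2
    se2 = vx + vy
    diff = mx - my
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, diff / np.sqrt(np.where(se2 == 0, 1.0, se2)))
        df = np.where(
            degenerate,
            1.0,
            se2**2 / (vx**2 / (n1 - 1) + vy**2 / (n2 - 1) + 1e-300),
        )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate & (diff != 0), np.sign(diff) * np.inf, t)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    return t, p, degenerate & (diff != 0)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order.

    q(i) = min_{j >= i} p(j) * m / j over the ascending sort, clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def run_de(
    m: ExpressionMatrix, alpha: float = 0.05, welch: bool = False
) -> tuple[pd.DataFrame, DESummary]:
    """Per-transcript t-test + BH over a filtered, log-transformed matrix.

    Returns a DataFrame indexed by transcript id with columns
    (log2_ratio, t_stat, p_raw, q_value, direction, significant, degenerate)
    and a DESummary. ``log2_ratio`` is case mean minus control mean of the
    (already log2) values; ``direction`` is down/up for significant
    transcripts and ``none`` otherwise.
    """
    case = m.samples_in_group("case")
    control = m.samples_in_group("control")
    X = m.values[case].to_numpy()
    Y = m.values[control].to_numpy()
    t, p, degenerate = (_welch_rows if welch else _t_rows)(X, Y)
    if degenerate.any():
        logger.warning(
            "%d transcript(s) with zero within-group variance and unequal means "
            "(p set to 0, flagged degenerate)",
            int(degenerate.sum()),
        )
    q = bh_adjust(p)
    log2_ratio = X.mean(axis=1) - Y.mean(axis=1)
    significant = q < alpha
    direction = np.where(
        significant, np.where(log2_ratio < 0, "down", "up"), "none"
    )
    table = pd.DataFrame(
        {
            "log2_ratio": log2_ratio,
            "t_stat": t,
            "p_raw": p,
            "q_value": q,
            "direction": direction,
            "significant": significant,
            "degenerate": degenerate,
        },
        index=pd.Index(m.transcript_ids, name="transcript_id"),
    )
    n_down = int((significant & (log2_ratio < 0)).sum())
    n_up = int((significant & (log2_ratio >= 0)).sum())
    summary = DESummary.from_counts(
        n_analyzed=len(table),
        n_down=n_down,
        n_up=n_up,
        n_down_all=int((log2_ratio < 0).sum()),
    )
    logger.info(
        "DE: %d analyzed, %d significant at q<%g (%d down / %d up)",
        summary.n_analyzed, summary.n_significant, alpha, n_down, n_up,
    )
    return table, summary
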