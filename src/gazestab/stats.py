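"""The study-style statistical procedures, implemented at the formula level.

Includes iterative two-sided Grubbs outlier screening, two-tailed paired
t-tests with no corrections, one-way repeated-measures ANOVA (sphericity
assumed) with Holm-adjusted pairwise follow-ups, and lag-aligned Pearson
correlation.  p-values come from the exact t/F cumulative distributions
(scipy.stats); the test statistics themselves are computed from their
closed forms so the arithmetic is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as _sps

from .core import (
    InsufficientDataError,
    InvalidParameterError,
    UndefinedResultError,
)

__all__ = [
    "StatResult",
    "grubbs_filter",
    "paired_t",
    "holm_adjust",
    "rm_anova",
    "lagged_pearson",
]


@dataclass
class StatResult:
    """A test statistic with its degrees of freedom and two-tailed p-value."""

    statistic: float
    df: tuple[float, ...]
    p_two_tailed: float
    n: int
    kind: str = "t"
    adjusted_p: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_tailed <= 1.0:
            raise InvalidParameterError("p must lie in [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p_two_tailed - 1e-12:
            raise InvalidParameterError("adjusted p cannot be below the raw p")


def _grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha) from the t quantile."""
    t2 = _sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def grubbs_filter(
    values, alpha: float = 0.05, max_removed_fraction: float = 0.2
) -> tuple[list[float], list[float]]:
    """Iterative two-sided Grubbs outlier screen.

    At each step the point farthest from the mean (in SD units,
    ``G = max|x - mean| / sd``) is removed if G exceeds the critical value,
    until no rejection occurs, fewer than 3 points remain, or the removal cap
    (default 20% of the input) is hit.  Returns ``(kept, flagged)`` with the
    input order preserved within ``kept``.
    """
    vals = [float(v) for v in values]
    if len(vals) < 3:
        raise InsufficientDataError("Grubbs test needs n >= 3")
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must be in (0, 1)")
    max_removed = int(np.floor(max_removed_fraction * len(vals)))
    keep = list(range(len(vals)))
    flagged_idx: list[int] = []
    while len(keep) >= 3 and len(flagged_idx) < max_removed:
        arr = np.array([vals[i] for i in keep])
        sd = arr.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(arr - arr.mean())
        j = int(np.argmax(dev))
        g = dev[j] / sd
        if g > _grubbs_critical(len(arr), alpha):
            flagged_idx.append(keep.pop(j))
        else:
            break
    kept = [vals[i] for i in keep]
    flagged = [vals[i] for i in sorted(flagged_idx)]
    return kept, flagged


def paired_t(a, b) -> StatResult:
    """Two-tailed paired t-test with no corrections.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``d = a - b`` and ``df = n - 1``;
    the p-value is twice the upper tail of the t distribution.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("paired samples must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise InsufficientDataError("paired t-test needs n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise UndefinedResultError("zero-variance differences: t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * _sps.t.sf(abs(t), n - 1))
    return StatResult(t, (float(n - 1),), p, n, kind="t")


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment.

    Sorted ascending, ``p_(i)`` is multiplied by ``m - i`` (1-based ranks give
    the factor m, m-1, ...), running maxima enforce monotonicity, and results
    are clipped at 1 and returned in the original order.
    """
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(scaled)
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def rm_anova(data) -> tuple[StatResult, list[StatResult]]:
    """One-way repeated-measures ANOVA plus Holm-adjusted pairwise paired t-tests.

    ``data`` is a complete subjects x levels matrix.  The F statistic uses
    the classical partition: treatment SS against the subject-by-treatment
    interaction SS, with df ``(k - 1, (k - 1)(s - 1))``.  Sphericity is
    assumed (no correction applied); that assumption is recorded in the
    result metadata.
    """
    x = np.asarray(data, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InvalidParameterError("need a subjects x levels matrix, >=2 each")
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("incomplete design: missing cells")
    s, k = x.shape
    grand = x.mean()
    ss_treat = s * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_treat - ss_subj
    df_treat = k - 1
    df_err = (k - 1) * (s - 1)
    ms_treat = ss_treat / df_treat
    ms_err = ss_err / df_err
    if ms_err == 0:
        f = 0.0 if ms_treat == 0 else np.inf
        p = 1.0 if ms_treat == 0 else 0.0
    else:
        f = float(ms_treat / ms_err)
        p = float(_sps.f.sf(f, df_treat, df_err))
    omnibus = StatResult(
        f, (float(df_treat), float(df_err)), p, s, kind="F",
        meta={"sphericity_correction": "none (assumed)"},
    )

    pairs = list(combinations(range(k), 2))
    raw = []
    for i, j in pairs:
        try:
            raw.append(paired_t(x[:, i], x[:, j]))
        except UndefinedResultError:
            raw.append(StatResult(0.0, (float(s - 1),), 1.0, s, kind="t"))
    adj = holm_adjust([r.p_two_tailed for r in raw])
    pairwise = [
        StatResult(
            r.statistic, r.df, r.p_two_tailed, r.n, kind="t",
            adjusted_p=float(ap), meta={"levels": (i, j)},
        )
        for r, ap, (i, j) in zip(raw, adj, pairs)
    ]
    return omnibus, pairwise


def lagged_pearson(x, y, lag_frames: int = 0) -> StatResult:
    """Pearson correlation after shifting ``x`` forward by ``lag_frames``.

    ``r`` is computed on the overlap of ``x[i]`` with ``y[i + lag]`` (so a
    positive lag correlates earlier x with later y, e.g. eye positions offset
    forward in time to match tail-movement onset); ``df = n_overlap - 2``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim != 1 or y.ndim != 1:
        raise InvalidParameterError("series must be 1-D")
    lag = int(lag_frames)
    if lag >= 0:
        xs, ys = x[: x.size - lag] if lag else x, y[lag:]
    else:
        xs, ys = x[-lag:], y[: y.size + lag]
    n = min(xs.size, ys.size)
    xs, ys = xs[:n], ys[:n]
    if n < 10:
        raise InsufficientDataError("overlap after shift must be >= 10 samples")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise UndefinedResultError("constant series: correlation undefined")
    r, p = _sps.pearsonr(xs, ys)
    return StatResult(float(r), (float(n - 2),), float(p), n, kind="r")
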