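"""Hand-authored statistical procedures used by the perception and gaze analyses.

Four procedures are implemented from first principles — one-sample t,
one-way within-subject (repeated-measures) ANOVA with Bonferroni post hocs,
Spearman rank correlation, and the Wilcoxon signed-rank test — plus the
head-vs-rest gaze contrast built on the paired t.  Only the reference
distributions (t, F, normal) come from :mod:`scipy.stats`; sums of squares,
ranking, enumeration and the exact signed-rank distribution are computed
here and validated against brute-force oracles in the test suite.

Conventions: all p values are two-sided; ties receive mid-ranks; zero
differences in the signed-rank test are excluded (Wilcoxon's original
treatment, matching SPSS-era reporting).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _dist

__all__ = [
    "DegenerateSampleError",
    "PairedSample",
    "TestResult",
    "one_sample_t",
    "paired_t",
    "rm_anova_oneway",
    "bonferroni_pairwise",
    "spearman",
    "wilcoxon_signed_rank",
    "head_vs_rest_contrast",
]


class DegenerateSampleError(ValueError):
    """Raised when a sample carries no usable variation (e.g. all ties)."""


@dataclass(frozen=True)
class PairedSample:
    """Two equal-length measurement lists paired by position."""

    a: Sequence[float]
    b: Sequence[float]
    unit_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("paired samples must have equal length")
        if len(self.a) < 1:
            raise ValueError("paired samples must be non-empty")
        if self.unit_ids is not None and len(self.unit_ids) != len(self.a):
            raise ValueError("unit_ids must match the sample length")

    def differences(self) -> np.ndarray:
        return np.asarray(self.a, dtype=np.float64) - np.asarray(self.b, dtype=np.float64)


@dataclass
class TestResult:
    """Outcome of one statistical test.

    ``df`` is a single number for t-type tests, a ``(df1, df2)`` pair for
    F-type tests and ``None`` for nonparametric tests.  ``extra`` carries
    method-specific detail (rank sums, z values, comparison labels).
    """

    method: str
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None
    effect_size: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p value outside [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p_value": self.p_value,
            "effect_size": self.effect_size,
        }
        d.update(self.extra)
        return d


def _clean_1d(x, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def one_sample_t(x, mu0: float = 0.0) -> TestResult:
    """Two-sided one-sample t-test of ``mean(x) == mu0``.

    ``t = (mean - mu0) / (sd / sqrt(n))`` with ``df = n - 1``; sd is the
    n-1 sample standard deviation.
    """
    arr = _clean_1d(x)
    n = arr.size
    if n < 2:
        raise ValueError("one-sample t-test needs at least two observations")
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        raise DegenerateSampleError("zero sample variance")
    mean = float(np.mean(arr))
    t = (mean - mu0) / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * float(_dist.t.sf(abs(t), df))
    return TestResult(
        method="one-sample-t",
        statistic=t,
        p_value=min(p, 1.0),
        df=float(df),
        effect_size=(mean - mu0) / sd,  # Cohen's d
        extra={"mean": mean, "sd": sd, "n": n, "mu0": mu0},
    )


def paired_t(a, b) -> TestResult:
    """Two-sided paired t-test: one-sample t on the within-pair differences."""
    a = _clean_1d(a, "a")
    b = _clean_1d(b, "b")
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    res = one_sample_t(a - b, 0.0)
    res.method = "paired-t"
    return res


def _scores_matrix(scores) -> np.ndarray:
    """Coerce a judge x condition table to a 2-D float array, no missing cells."""
    try:
        import pandas as pd

        if isinstance(scores, pd.DataFrame):
            scores = scores.to_numpy()
    except ImportError:  # pragma: no cover
        pass
    arr = np.asarray(scores, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("scores must be a 2-D judge x condition table")
    if not np.all(np.isfinite(arr)):
        raise ValueError("scores table has missing or non-finite cells")
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    return arr


def rm_anova_oneway(scores) -> TestResult:
    """One-way within-subject ANOVA on a complete judge x condition table.

    Classical decomposition: ``F = MS_condition / MS_(condition x subject)``
    with ``df = (k - 1, (k - 1)(n - 1))``.  No sphericity correction is
    applied, matching the uncorrected integer dfs conventionally reported.
    """
    arr = _scores_matrix(scores)
    n, k = arr.shape
    grand = arr.mean()
    col_means = arr.mean(axis=0)
    row_means = arr.mean(axis=1)
    ss_cond = n * float(np.sum((col_means - grand) ** 2))
    ss_subj = k * float(np.sum((row_means - grand) ** 2))
    ss_total = float(np.sum((arr - grand) ** 2))
    # interaction (error) SS computed directly from residuals, not by
    # subtraction, to avoid negative rounding artifacts
    resid = arr - row_means[:, None] - col_means[None, :] + grand
    ss_err = float(np.sum(resid**2))
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    tiny = 1e-12 * max(ss_total, 1.0)
    if ss_cond <= tiny and ss_err <= tiny:
        if ss_total <= tiny:
            raise DegenerateSampleError("no variation in the scores table")
        f, p = 0.0, 1.0  # all columns identical up to rounding
    elif ms_err <= tiny:
        f = math.inf
        p = 0.0
    else:
        f = ms_cond / ms_err
        p = float(_dist.f.sf(f, df1, df2))
    # partial eta squared: condition SS relative to condition + error SS
    eta_p = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else float("nan")
    return TestResult(
        method="rm-anova-oneway",
        statistic=f,
        p_value=p,
        df=(float(df1), float(df2)),
        effect_size=eta_p,
        extra={"ss_condition": ss_cond, "ss_subject": ss_subj, "ss_error": ss_err},
    )


def bonferroni_pairwise(scores, labels: Sequence[str] | None = None) -> list[TestResult]:
    """Bonferroni-corrected paired t-tests for every condition pair.

    Raw two-sided p values are multiplied by the number of pairs
    ``k(k-1)/2`` and clamped to 1.  A pair with zero-variance differences
    yields a placeholder result flagged ``extra["error"]`` so the remaining
    comparisons are unaffected.
    """
    arr = _scores_matrix(scores)
    k = arr.shape[1]
    if labels is None:
        labels = [f"cond{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels must match the number of conditions")
    n_pairs = k * (k - 1) // 2
    out: list[TestResult] = []
    for i, j in itertools.combinations(range(k), 2):
        tag = f"{labels[i]}-vs-{labels[j]}"
        try:
            res = paired_t(arr[:, i], arr[:, j])
        except DegenerateSampleError as exc:
            out.append(
                TestResult(
                    method="paired-t-bonferroni",
                    statistic=float("nan"),
                    p_value=float("nan"),
                    extra={"comparison": tag, "error": str(exc)},
                )
            )
            continue
        res.method = "paired-t-bonferroni"
        res.extra["comparison"] = tag
        res.extra["p_uncorrected"] = res.p_value
        res.extra["n_comparisons"] = n_pairs
        res.p_value = min(1.0, res.p_value * n_pairs)
        out.append(res)
    return out


def _midranks(v: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by the average of the tied positions."""
    v = np.asarray(v, dtype=np.float64)
    order = np.argsort(v, kind="mergesort")
    sv = v[order]
    ranks = np.empty(v.size, dtype=np.float64)
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman(x, y, *, exact: bool = False) -> TestResult:
    """Spearman rank correlation with a two-sided p value.

    ``rs`` is the Pearson correlation of the mid-ranks.  The p value uses
    the t approximation ``t = rs * sqrt((n - 2) / (1 - rs^2))`` on ``n - 2``
    df; ``rs = +/-1`` gives ``p = 0``.  ``exact=True`` (n <= 8 only)
    enumerates all permutations of one variable instead.
    """
    xa = _clean_1d(x, "x")
    ya = _clean_1d(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 observations")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise DegenerateSampleError("constant input has no rank correlation")
    rx = _midranks(xa)
    ry = _midranks(ya)
    rs = float(np.corrcoef(rx, ry)[0, 1])
    rs = max(-1.0, min(1.0, rs))
    if exact:
        if n > 8:
            raise ValueError("exact permutation p limited to n <= 8")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
            if abs(r) >= abs(rs) - 1e-12:
                count += 1
            total += 1
        return TestResult(
            method="spearman-exact",
            statistic=rs,
            p_value=count / total,
            df=None,
            effect_size=rs,
            extra={"n": n},
        )
    if abs(rs) >= 1.0 - 1e-12:
        rs = math.copysign(1.0, rs)
        p = 0.0
    else:
        t = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
        p = min(1.0, 2.0 * float(_dist.t.sf(abs(t), n - 2)))
    return TestResult(
        method="spearman",
        statistic=rs,
        p_value=p,
        df=None,
        effect_size=rs,
        extra={"n": n},
    )


def _signed_rank_exact_p(ranks: np.ndarray, w_min: float) -> float:
    """Exact two-sided p for the signed-rank statistic via a count DP.

    Works with mid-ranks (multiples of 1/2) by doubling all ranks to
    integers and convolving the distribution of the positive rank sum over
    all 2^n equally likely sign assignments.  ``p = min(1, 2 P(W+ <= w_min))``
    by the symmetry of the null distribution.
    """
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for d in doubled:
        shifted = np.zeros_like(counts)
        shifted[d:] = counts[: counts.size - d]
        counts = counts + shifted
    w2 = int(np.rint(2.0 * w_min))
    p = 2.0 * counts[: w2 + 1].sum() / (2.0 ** len(ranks))
    return min(1.0, p)


def wilcoxon_signed_rank(
    sample: PairedSample | Sequence[float],
    b: Sequence[float] | None = None,
    *,
    exact_max_n: int = 25,
) -> TestResult:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are excluded before ranking; absolute differences are
    ranked with mid-ranks for ties; the statistic is ``W = min(W+, W-)``.
    For ``n <= exact_max_n`` non-zero pairs the two-sided p value is exact
    (full distribution of the 2^n sign assignments, computed by dynamic
    programming); beyond that the normal approximation with tie correction
    and a 0.5 continuity correction is used and the statistic reported is
    the signed ``Z``.  Effect size is ``r = |Z| / sqrt(n)``.
    """
    if isinstance(sample, PairedSample):
        d = sample.differences()
    else:
        if b is None:
            raise ValueError("provide a PairedSample or two sequences")
        a_arr = _clean_1d(sample, "a")
        b_arr = _clean_1d(b, "b")
        if a_arr.size != b_arr.size:
            raise ValueError("paired samples must have equal length")
        d = a_arr - b_arr
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateSampleError("all paired differences are zero")
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    # Normal approximation (always computed: it supplies Z and the effect size)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        raise DegenerateSampleError("no rank variation after tie correction")
    sigma = math.sqrt(var)
    dev = w_plus - mu
    z = 0.0 if dev == 0.0 else (dev - 0.5 * math.copysign(1.0, dev)) / sigma
    p_normal = min(1.0, 2.0 * float(_dist.norm.sf(abs(z))))

    if n <= exact_max_n:
        p = _signed_rank_exact_p(ranks, w)
        statistic = w
        method = "wilcoxon-signed-rank-exact"
    else:
        p = p_normal
        statistic = z
        method = "wilcoxon-signed-rank-normal"
    return TestResult(
        method=method,
        statistic=statistic,
        p_value=p,
        df=None,
        effect_size=abs(z) / math.sqrt(n),
        extra={
            "w_plus": w_plus,
            "w_minus": w_minus,
            "w": w,
            "z": z,
            "p_normal": p_normal,
            "n_nonzero": n,
        },
    )


def head_vs_rest_contrast(gaze, region_labels: Sequence[str] | None = None) -> TestResult:
    """Head-vs-other-regions contrast on a judge x region duration table.

    For each judge the contrast is ``head - mean(other regions)``; a paired
    t-test against zero is squared into ``F = t^2`` with ``df = (1, n - 1)``.
    Accepts a DataFrame with a ``head`` column or an array plus labels.
    """
    try:
        import pandas as pd

        if isinstance(gaze, pd.DataFrame):
            region_labels = list(gaze.columns)
            gaze = gaze.to_numpy()
    except ImportError:  # pragma: no cover
        pass
    arr = np.asarray(gaze, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a judge x region table with head and >= 1 other region")
    if region_labels is None:
        raise ValueError("region_labels required for array input")
    labels = [str(r) for r in region_labels]
    if "head" not in labels:
        raise ValueError("regions must include 'head'")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 judges")
    head_ix = labels.index("head")
    others = [i for i in range(arr.shape[1]) if i != head_ix]
    contrast = arr[:, head_ix] - arr[:, others].mean(axis=1)
    n = arr.shape[0]
    if np.all(contrast == 0.0):
        # head exactly balances the other regions for every judge
        return TestResult(
            method="head-vs-rest-F",
            statistic=0.0,
            p_value=1.0,
            df=(1.0, float(n - 1)),
            effect_size=0.0,
            extra={"t": 0.0, "mean_contrast": 0.0},
        )
    res = one_sample_t(contrast, 0.0)  # raises DegenerateSampleError on zero variance
    t = res.statistic
    f = t * t
    return TestResult(
        method="head-vs-rest-F",
        statistic=f,
        p_value=res.p_value,
        df=(1.0, float(n - 1)),
        effect_size=res.effect_size,
        extra={"t": t, "mean_contrast": float(np.mean(contrast))},
    )
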