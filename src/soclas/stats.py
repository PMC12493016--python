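"""Paired Wilcoxon tests, running pointwise comparisons with FDR control,
and sleep-architecture metrics.

The signed-rank test drops zero differences (Wilcoxon's original
treatment), assigns mid-ranks to tied absolute differences, uses the exact
permutation null (all 2^n sign assignments, evaluated by convolution) for
n ≤ 15 and a tie-corrected normal approximation above.  Running tests
apply the paired Wilcoxon independently at every point of a time grid and
report both the raw p < 0.05 mask and the Benjamini–Hochberg FDR mask at
q = 0.05, mirroring the dual (uncorrected/corrected) display convention of
the CLAS literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .core import Hypnogram, SLEEP_STAGES


class WilcoxonResult(NamedTuple):
    statistic: float  # W+: sum of ranks of positive differences
    pvalue: float  # two-sided
    degenerate: bool = False  # all differences zero


@dataclass
class RunningTestResult:
    time_s: np.ndarray
    p_raw: np.ndarray
    significant_raw: np.ndarray  # p < alpha
    significant_fdr: np.ndarray  # BH at q
    n_pairs: int
    alpha: float = 0.05
    q: float = 0.05


@dataclass
class SleepArchitecture:
    tst_min: float
    waso_min: float
    sleep_efficiency_pct: float
    time_in_bed_min: float
    stage_minutes: dict[str, float]
    stage_pct_tst: dict[str, float]
    rem_first_half_min: float
    rem_second_half_min: float


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _exact_distribution(ranks2: tuple[int, ...]) -> np.ndarray:
    """Counts of W+ (doubled scale) over all sign assignments, by convolution."""
    total = sum(ranks2)
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


@lru_cache(maxsize=128)
def _exact_distribution_cached(ranks2: tuple[int, ...]) -> np.ndarray:
    return _exact_distribution(ranks2)


def _exact_pvalue(ranks2: tuple[int, ...], w2: int) -> float:
    counts = _exact_distribution_cached(tuple(sorted(ranks2)))
    total = counts.sum()
    cdf = counts[: w2 + 1].sum() / total
    sf = counts[w2:].sum() / total
    return float(min(1.0, 2.0 * min(cdf, sf)))


EXACT_N_MAX = 15  # enumeration switch point (2^15 outcomes)


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float]
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; tied absolute differences get mid-ranks.
    For ≤ 15 non-zero pairs the p-value is exact over all sign
    assignments; beyond that a tie-corrected normal approximation is used.
    If every difference is zero the result is degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size == 0:
        raise ValueError("need at least one pair")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, pvalue=1.0, degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        ranks2 = tuple(int(round(2 * r)) for r in ranks)
        p = _exact_pvalue(ranks2, int(round(2 * w_pos)))
        return WilcoxonResult(statistic=w_pos, pvalue=p)
    # normal approximation with tie correction
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_pos - mean) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(statistic=w_pos, pvalue=p)


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def benjamini_hochberg(
    p_values: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Step-up FDR control: (adjusted p-values, rejection mask).

    Rejects hypotheses i ≤ k in the p-sorted order where
    k = max{i : p(i) ≤ i·q/m}; adjusted p(i) = min_{j ≥ i} m·p(j)/j,
    capped at 1, returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    scaled = ranked * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    passes = ranked <= np.arange(1, m + 1) * q / m
    reject_sorted = np.zeros(m, dtype=bool)
    if passes.any():
        k = int(np.flatnonzero(passes)[-1])
        reject_sorted[: k + 1] = True
    adjusted = np.empty(m)
    reject = np.empty(m, dtype=bool)
    adjusted[order] = adjusted_sorted
    reject[order] = reject_sorted
    return adjusted, reject


# ---------------------------------------------------------------------------
# running pointwise tests
# ---------------------------------------------------------------------------

def running_wilcoxon(
    traces_a: np.ndarray,
    traces_b: np.ndarray,
    time_s: Sequence[float] | None = None,
    alpha: float = 0.05,
    q: float = 0.05,
) -> RunningTestResult:
    """Pointwise paired Wilcoxon across subjects along a shared time grid.

    ``traces_a``/``traces_b`` are (n_subjects, n_times) stacks in the same
    subject order.  Columns with no ties among non-zero |differences| use a
    vectorized exact-null lookup; degenerate or tied columns fall back to
    the scalar test.
    """
    a = np.atleast_2d(np.asarray(traces_a, dtype=float))
    b = np.atleast_2d(np.asarray(traces_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("trace stacks must share subject order and time grid")
    n_sub, n_t = a.shape
    if n_sub < 5:
        raise ValueError("need at least 5 subjects for the running test")
    if time_s is None:
        time_s = np.arange(n_t, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    if time_s.size != n_t:
        raise ValueError("time grid does not match the traces")

    d = a - b
    p_raw = np.empty(n_t)
    # fast path: no zeros, no ties -> single cached null distribution
    nz = d != 0
    simple = nz.all(axis=0)
    if simple.any() and n_sub <= EXACT_N_MAX:
        ranks = sps.rankdata(np.abs(d[:, simple]), axis=0)
        tied = (np.sort(ranks, axis=0) != np.arange(1, n_sub + 1)[:, None]).any(axis=0)
        cols = np.flatnonzero(simple)
        clean = cols[~tied]
        if clean.size:
            w2 = (2 * ranks[:, ~tied] * (d[:, clean] > 0)).sum(axis=0).astype(int)
            ranks2 = tuple(2 * r for r in range(1, n_sub + 1))
            counts = _exact_distribution_cached(ranks2)
            total = counts.sum()
            cdf = np.cumsum(counts) / total
            sf = np.cumsum(counts[::-1])[::-1] / total
            p_raw[clean] = np.minimum(1.0, 2.0 * np.minimum(cdf[w2], sf[w2]))
        rest = set(cols[tied])
    else:
        rest = set(np.flatnonzero(simple))
    rest |= set(np.flatnonzero(~simple))
    for j in rest:
        p_raw[j] = wilcoxon_signed_rank(a[:, j], b[:, j]).pvalue

    _, sig_fdr = benjamini_hochberg(p_raw, q)
    return RunningTestResult(
        time_s=time_s,
        p_raw=p_raw,
        significant_raw=p_raw < alpha,
        significant_fdr=sig_fdr,
        n_pairs=n_sub,
        alpha=alpha,
        q=q,
    )


# ---------------------------------------------------------------------------
# sleep architecture
# ---------------------------------------------------------------------------

def sleep_architecture(hypnogram: Hypnogram) -> SleepArchitecture:
    """TST, WASO, efficiency, per-stage minutes/% and the REM night-half split.

    WASO counts Wake epochs after the first sleep epoch; efficiency is
    100·TST / time in bed; the night-half split is at the midpoint of time
    in bed.
    """
    if hypnogram.n_epochs == 0:
        raise ValueError("empty hypnogram")
    epl_min = hypnogram.epoch_length_s / 60.0
    stages = np.array(hypnogram.stages)
    is_sleep = np.array([s in SLEEP_STAGES for s in stages])
    tib_min = hypnogram.n_epochs * epl_min
    tst_min = float(is_sleep.sum() * epl_min)
    if is_sleep.any():
        onset = int(np.flatnonzero(is_sleep)[0])
        waso_min = float(((stages[onset:] == "Wake")).sum() * epl_min)
    else:
        waso_min = 0.0
    stage_minutes = {
        s: float((stages == s).sum() * epl_min) for s in ("Wake", "N1", "N2", "N3", "REM")
    }
    stage_pct = {
        s: (100.0 * stage_minutes[s] / tst_min if tst_min > 0 else float("nan"))
        for s in ("N1", "N2", "N3", "REM")
    }
    mid = hypnogram.n_epochs // 2
    rem_first = float((stages[:mid] == "REM").sum() * epl_min)
    rem_second = float((stages[mid:] == "REM").sum() * epl_min)
    return SleepArchitecture(
        tst_min=tst_min,
        waso_min=waso_min,
        sleep_efficiency_pct=100.0 * tst_min / tib_min,
        time_in_bed_min=tib_min,
        stage_minutes=stage_minutes,
        stage_pct_tst=stage_pct,
        rem_first_half_min=rem_first,
        rem_second_half_min=rem_second,
    )
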