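"""Independent brute-force oracles used to pin down expected values.

These deliberately use naive per-position loops and textbook formulas,
independent of the vectorised implementations they check.
"""

from typing import Dict, List, Sequence, Tuple

import numpy as np


def brute_force_tracts(seq: str, min_len: int) -> List[Tuple[int, int, str]]:
    """Per-position run enumerator for T ('+') and A ('−') runs."""
    out = []
    for strand, ch in (("+", "T"), ("-", "A")):
        i = 0
        n = len(seq)
        while i < n:
            if seq[i] == ch:
                j = i
                while j < n and seq[j] == ch:
                    j += 1
                if j - i >= min_len:
                    out.append((i, j, strand))
                i = j
            else:
                i += 1
    return sorted(out)


def quantile_linear(values: Sequence[float], q: float) -> float:
    """Empirical quantile, linear interpolation between order statistics."""
    v = sorted(values)
    n = len(v)
    h = (n - 1) * q
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    if lo == hi:
        return v[lo]
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def brute_force_rt(
    oriented: np.ndarray,
    threshold: float,
    window_bp: int,
    step_bp: int,
    max_gap_bp: int,
) -> Tuple[int, int, bool]:
    """Enumerate every window, mark bases, merge runs; returns
    (rt_length, n_fragments, empty) for a downstream-oriented signal."""
    L = len(oriented)
    marked = np.zeros(L, dtype=bool)
    offsets = []
    if L > 0:
        if L <= window_bp:
            offsets = [0]
        else:
            o = 0
            while o + window_bp <= L:
                offsets.append(o)
                o += step_bp
            if offsets[-1] != L - window_bp:
                offsets.append(L - window_bp)
    any_marked = False
    for o in offsets:
        end = min(o + window_bp, L)
        total = 0.0
        for i in range(o, end):
            total += float(oriented[i])
        if total > threshold:
            marked[o:end] = True
            any_marked = True
    if not any_marked:
        return 0, 0, True
    # marked base runs
    runs = []
    i = 0
    while i < L:
        if marked[i]:
            j = i
            while j < L and marked[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    # close small gaps
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= max_gap_bp:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return merged[-1][1], len(merged), False


def binned_means_trapezoid(arr: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin means by explicit per-base fractional overlap accumulation."""
    L = len(arr)
    edges = [i * L / n_bins for i in range(n_bins + 1)]
    out = np.zeros(n_bins)
    for k in range(n_bins):
        a, b = edges[k], edges[k + 1]
        total = 0.0
        for i in range(int(np.floor(a)), int(np.ceil(b))):
            lo = max(a, i)
            hi = min(b, i + 1)
            if hi > lo:
                total += arr[i] * (hi - lo)
        out[k] = total / (b - a)
    return out


def kruskal_h(groups: Dict[str, Sequence[float]]) -> float:
    """Kruskal-Wallis H from the rank formula with tie correction."""
    all_vals = []
    for name, vals in groups.items():
        all_vals.extend((float(v), name) for v in vals)
    all_vals.sort()
    n = len(all_vals)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and all_vals[j][0] == all_vals[i][0]:
            j += 1
        avg = (i + 1 + j) / 2.0  # average of ranks i+1 .. j
        ranks[i:j] = avg
        i = j
    rank_sums: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    for r, (_, name) in zip(ranks, all_vals):
        rank_sums[name] = rank_sums.get(name, 0.0) + r
        counts[name] = counts.get(name, 0) + 1
    h = 12.0 / (n * (n + 1)) * sum(
        rank_sums[g] ** 2 / counts[g] for g in rank_sums
    ) - 3 * (n + 1)
    # tie correction
    tie_sum = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and all_vals[j][0] == all_vals[i][0]:
            j += 1
        t = j - i
        tie_sum += t ** 3 - t
        i = j
    correction = 1.0 - tie_sum / (n ** 3 - n)
    return h / correction


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson r from the covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank-then-Pearson computation of Spearman rho."""
    def ranks(v):
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        v = np.asarray(v, float)
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            r[order[i:j]] = (i + 1 + j) / 2.0
            i = j
        return r

    return pearson_r(ranks(x), ranks(y))
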