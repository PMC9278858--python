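"""Per-gene termination statistics and condition contrasts.

The central quantity is the RT index: the signal over the called
read-through region expressed as a percentage of the signal over the gene
region (5′ end through the primary tract 3′ edge).  On top of it this module
builds fold-change tracks, scaled metagene/heatmap matrices, a ranking of
genes by mutant-dependency with quartile assignment, and the rank-based
group tests used to compare quartiles and conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from polterm.coverage import CoverageTrack
from polterm.genome_annotation import TerminatorAnnotation
from polterm.rt_calling import RTRegion

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


@dataclass
class TerminationSummary:
    """RT statistics for one gene in one condition."""

    gene_id: str
    condition: str
    gene_body_signal: float
    rt_signal: float
    rt_index: Optional[float]  # percent; None when gene_body_signal == 0
    rt_length_bp: int
    primary_tract_len: int
    n_weak_secondary: int
    n_strong_secondary: int


@dataclass(frozen=True)
class QuartileAssignment:
    gene_id: str
    dependency_score: float
    quartile: str  # Q1..Q4, Q1 = most mutant-dependent


@dataclass
class FoldChangeTrack:
    """Per-base log2 ratio track (values may be negative)."""

    strand: str
    data: Dict[str, np.ndarray]


def gene_body_interval(anno: TerminatorAnnotation) -> Tuple[int, int]:
    """Plus-strand interval from the gene 5′ end through the primary tract 3′ edge."""
    if anno.primary is None:
        raise StatsError(f"gene {anno.gene_id}: no primary terminator")
    gene = anno.gene
    if gene.strand == "+":
        return gene.start, anno.primary.end
    return anno.primary.start, gene.end


def _track(plus: CoverageTrack, minus: CoverageTrack, strand: str) -> CoverageTrack:
    return plus if strand == "+" else minus


def rt_index(
    plus: CoverageTrack,
    minus: CoverageTrack,
    anno: TerminatorAnnotation,
    region: RTRegion,
    condition: str = "other",
) -> TerminationSummary:
    """RT-region signal as a percentage of gene-body signal.

    A gene with zero body signal gets ``rt_index=None`` (flagged); callers
    exclude such genes from aggregate statistics and log the count.
    """
    body_start, body_end = gene_body_interval(anno)
    track = _track(plus, minus, anno.gene.strand)
    body = float(track.data[anno.gene.chrom][body_start:body_end].sum())
    rt = 0.0
    if not region.empty and region.end > region.start:
        rt = float(track.data[region.chrom][region.start:region.end].sum())
    index = 100.0 * rt / body if body > 0 else None
    if index is None:
        logger.info("gene %s: zero gene-body signal, RT index undefined", anno.gene_id)
    return TerminationSummary(
        gene_id=anno.gene_id,
        condition=condition,
        gene_body_signal=body,
        rt_signal=rt,
        rt_index=index,
        rt_length_bp=region.rt_length_bp,
        primary_tract_len=anno.primary.length,
        n_weak_secondary=anno.n_weak_secondary,
        n_strong_secondary=anno.n_strong_secondary,
    )


def fixed_window_rt_index(
    plus: CoverageTrack,
    minus: CoverageTrack,
    anno: TerminatorAnnotation,
    downstream_bp: int = 700,
) -> Optional[float]:
    """Sensitivity variant: downstream fixed window / gene body, in percent."""
    body_start, body_end = gene_body_interval(anno)
    track = _track(plus, minus, anno.gene.strand)
    chrom_len = len(track.data[anno.gene.chrom])
    if anno.gene.strand == "+":
        ds = track.data[anno.gene.chrom][body_end:min(chrom_len, body_end + downstream_bp)]
    else:
        ds = track.data[anno.gene.chrom][max(0, body_start - downstream_bp):body_start]
    body = float(track.data[anno.gene.chrom][body_start:body_end].sum())
    return 100.0 * float(ds.sum()) / body if body > 0 else None


def estimate_readthrough_fraction(
    plus: CoverageTrack,
    minus: CoverageTrack,
    anno: TerminatorAnnotation,
    probe_bp: int = 15,
) -> Optional[float]:
    """Estimate the fraction of polymerases that pass the primary terminator.

    Under a dwell model where every initiated polymerase traverses the gene
    body and a fraction f continues past the primary tract, the per-base
    signal immediately downstream of the tract is f times the per-base
    signal over the body.  Medians are used on both sides so isolated pause
    peaks do not bias the ratio.  Returns None when the body median is 0.
    """
    if anno.primary is None:
        raise StatsError(f"gene {anno.gene_id}: no primary terminator")
    gene = anno.gene
    track = _track(plus, minus, gene.strand)
    chrom = track.data[gene.chrom]
    if gene.strand == "+":
        body = chrom[gene.start:anno.primary.start]
        probe = chrom[anno.primary.end:min(len(chrom), anno.primary.end + probe_bp)]
    else:
        body = chrom[anno.primary.end:gene.end]
        probe = chrom[max(0, anno.primary.start - probe_bp):anno.primary.start]
    body_med = float(np.median(body)) if body.size else 0.0
    if body_med <= 0 or probe.size == 0:
        return None
    return float(np.median(probe)) / body_med


def log2_fold_change_track(
    mutant: CoverageTrack, wt: CoverageTrack, pseudocount: float = 1.0
) -> FoldChangeTrack:
    """Per-base log2((mutant + pc) / (wt + pc)) track."""
    if pseudocount < 0:
        raise StatsError(f"pseudocount must be >= 0, got {pseudocount}")
    if mutant.strand != wt.strand:
        raise StatsError("fold change: strand mismatch")
    if mutant.chrom_sizes != wt.chrom_sizes:
        raise StatsError("fold change: chromosome sizes differ")
    data = {
        c: np.log2((mutant.data[c] + pseudocount) / (wt.data[c] + pseudocount))
        for c in mutant.data
    }
    return FoldChangeTrack(mutant.strand, data)


# ---------------------------------------------------------------------------
# Scaled matrices


def _binned_means(arr: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean per equal-width bin with fractional base weighting at edges."""
    L = arr.size
    if L == 0:
        return np.zeros(n_bins)
    prefix = np.concatenate(([0.0], np.cumsum(arr)))

    def integral(x: float) -> float:
        i = int(np.floor(x))
        if i >= L:
            return prefix[L]
        return prefix[i] + (x - i) * arr[i]

    edges = np.linspace(0.0, float(L), n_bins + 1)
    out = np.empty(n_bins)
    for k in range(n_bins):
        width = edges[k + 1] - edges[k]
        out[k] = (integral(edges[k + 1]) - integral(edges[k])) / width
    return out


def _oriented(data: Dict[str, np.ndarray], chrom: str, start: int, end: int,
              strand: str) -> np.ndarray:
    arr = data[chrom][max(0, start):max(0, end)]
    return arr if strand == "+" else arr[::-1]


def metagene_matrix(
    plus_data: Dict[str, np.ndarray],
    minus_data: Dict[str, np.ndarray],
    annos: Sequence[TerminatorAnnotation],
    body_bins: int = 100,
    flank_bp: int = 0,
) -> pd.DataFrame:
    """Genes × bins matrix of mean per-bin signal with scaled gene bodies.

    The gene body (5′ end through primary tract 3′ edge) is scaled to
    *body_bins* bins; optional fixed-width (1-bp) flank bins are added on
    both sides.  Minus-strand genes are mirrored so column 0 is always the
    5′-most position.  Rows are genes with a primary terminator.
    """
    rows, index = [], []
    for anno in annos:
        if anno.primary is None:
            continue
        gene = anno.gene
        data = plus_data if gene.strand == "+" else minus_data
        body_start, body_end = gene_body_interval(anno)
        body = _binned_means(
            _oriented(data, gene.chrom, body_start, body_end, gene.strand), body_bins
        )
        if flank_bp > 0:
            n = len(data[gene.chrom])
            if gene.strand == "+":
                up = data[gene.chrom][max(0, body_start - flank_bp):body_start]
                down = data[gene.chrom][body_end:min(n, body_end + flank_bp)]
            else:
                up = data[gene.chrom][body_end:min(n, body_end + flank_bp)][::-1]
                down = data[gene.chrom][max(0, body_start - flank_bp):body_start][::-1]
            up = np.concatenate((np.zeros(flank_bp - up.size), up))
            down = np.concatenate((down, np.zeros(flank_bp - down.size)))
            row = np.concatenate((up, body, down))
        else:
            row = body
        rows.append(row)
        index.append(anno.gene_id)
    cols = (
        [f"up_{i}" for i in range(-flank_bp, 0)]
        + [f"body_{i}" for i in range(body_bins)]
        + [f"down_{i}" for i in range(1, flank_bp + 1)]
    )
    return pd.DataFrame(rows, index=index, columns=cols)


def heatmap_matrix(
    fc_plus: FoldChangeTrack,
    fc_minus: FoldChangeTrack,
    annos: Sequence[TerminatorAnnotation],
    body_bins: int = 100,
    flank_bp: int = 0,
) -> pd.DataFrame:
    """Metagene-style matrix on a fold-change track, rows sorted by
    descending row mean (the ordering reused for quartiles)."""
    mat = metagene_matrix(fc_plus.data, fc_minus.data, annos, body_bins, flank_bp)
    order = mat.mean(axis=1).sort_values(ascending=False, kind="mergesort").index
    return mat.loc[order]


# ---------------------------------------------------------------------------
# Dependency ranking and group comparisons


def rank_by_dependency(
    fc_plus: FoldChangeTrack,
    fc_minus: FoldChangeTrack,
    annos: Sequence[TerminatorAnnotation],
    downstream_window_bp: int = 700,
) -> List[QuartileAssignment]:
    """Rank genes by mean log2 fold change downstream of the primary tract.

    Quartiles are assigned by rank: Q1 holds the top 25% (highest
    dependency), ties broken by gene_id for determinism; remainders when the
    gene count is not divisible by 4 are assigned by rank order.
    """
    usable = [a for a in annos if a.primary is not None]
    if len(usable) < 4:
        raise StatsError("rank_by_dependency: need >= 4 genes with primary terminator")
    scores = []
    for anno in usable:
        fc = fc_plus if anno.gene.strand == "+" else fc_minus
        chrom = fc.data[anno.gene.chrom]
        if anno.gene.strand == "+":
            s = anno.primary.end
            window = chrom[s:min(len(chrom), s + downstream_window_bp)]
        else:
            e = anno.primary.start
            window = chrom[max(0, e - downstream_window_bp):e]
        scores.append((float(window.mean()), anno.gene_id))
    order = sorted(range(len(scores)), key=lambda i: (-scores[i][0], scores[i][1]))
    bounds = np.cumsum([len(chunk) for chunk in np.array_split(order, 4)])
    out: List[QuartileAssignment] = []
    for rank, idx in enumerate(order):
        q = int(np.searchsorted(bounds, rank, side="right")) + 1
        out.append(QuartileAssignment(scores[idx][1], scores[idx][0], f"Q{q}"))
    return out


def terminators_per_quartile(
    quartiles: Sequence[QuartileAssignment],
    annos: Sequence[TerminatorAnnotation],
) -> pd.DataFrame:
    """Mean ± SE of weak/strong secondary-terminator counts per quartile."""
    by_id = {a.gene_id: a for a in annos}
    rows = []
    for q in ("Q1", "Q2", "Q3", "Q4"):
        members = [by_id[qa.gene_id] for qa in quartiles if qa.quartile == q]
        if not members:
            raise StatsError(f"empty quartile {q}")
        for kind, getter in (
            ("weak", lambda a: a.n_weak_secondary),
            ("strong", lambda a: a.n_strong_secondary),
        ):
            vals = np.array([getter(a) for a in members], dtype=float)
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
            rows.append({"quartile": q, "kind": kind, "mean": float(vals.mean()),
                         "se": se, "n": len(vals)})
    return pd.DataFrame(rows)


def group_tests(groups: Dict[str, Sequence[float]]) -> Dict[str, object]:
    """Kruskal-Wallis omnibus plus pairwise two-sided Mann-Whitney tests.

    Returns NaN statistics (flagged via ``defined``) when every observation
    is identical, where the tests are undefined.
    """
    names = list(groups)
    if len(names) < 2 or any(len(groups[n]) == 0 for n in names):
        raise StatsError("group_tests: need >= 2 nonempty groups")
    all_vals = np.concatenate([np.asarray(groups[n], dtype=float) for n in names])
    if np.all(all_vals == all_vals[0]):
        return {"kruskal_H": float("nan"), "kruskal_p": float("nan"),
                "pairwise": {}, "defined": False}
    H, p = stats.kruskal(*(groups[n] for n in names))
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = np.asarray(groups[a], float), np.asarray(groups[b], float)
            joint = np.concatenate((va, vb))
            if np.all(joint == joint[0]):
                pairwise[(a, b)] = float("nan")
            else:
                pairwise[(a, b)] = float(
                    stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue
                )
    return {"kruskal_H": float(H), "kruskal_p": float(p),
            "pairwise": pairwise, "defined": True}


def paired_wilcoxon(a: Sequence[float], b: Sequence[float]) -> Dict[str, float]:
    """Two-sided Wilcoxon signed-rank test on per-gene pairs."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise StatsError("paired_wilcoxon: length mismatch")
    if np.all(a == b):
        return {"statistic": float("nan"), "pvalue": float("nan")}
    res = stats.wilcoxon(a, b)
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}


def cluster_by_terminator_length(
    summaries: Sequence[TerminationSummary], pool_from: int = 8
) -> pd.DataFrame:
    """Mean RT index ± SE per primary-tract-length class.

    Lengths >= *pool_from* are pooled into one class.  Genes with undefined
    RT index are excluded (logged); empty classes are dropped.
    """
    usable = [s for s in summaries if s.rt_index is not None]
    dropped = len(summaries) - len(usable)
    if dropped:
        logger.info("cluster_by_terminator_length: %d genes with undefined RT "
                    "index excluded", dropped)
    classes: Dict[str, List[float]] = {}
    for s in usable:
        label = f">={pool_from}" if s.primary_tract_len >= pool_from else str(s.primary_tract_len)
        classes.setdefault(label, []).append(s.rt_index)
    rows = []
    for label in sorted(classes, key=lambda x: int(x.lstrip(">="))):
        vals = np.asarray(classes[label])
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        rows.append({"tract_len": label, "mean_rt_index": float(vals.mean()),
                     "se": se, "n": len(vals)})
    return pd.DataFrame(rows)


def correlate_conditions(
    summaries_a: Sequence[TerminationSummary],
    summaries_b: Sequence[TerminationSummary],
    metric: str = "rt_index",
) -> Dict[str, object]:
    """Pearson correlation of a per-gene metric between two conditions."""
    if metric not in ("rt_index", "rt_length"):
        raise StatsError(f"unknown metric {metric!r}")
    attr = "rt_index" if metric == "rt_index" else "rt_length_bp"
    b_by_id = {s.gene_id: s for s in summaries_b}
    xs, ys, ids = [], [], []
    for sa in summaries_a:
        sb = b_by_id.get(sa.gene_id)
        if sb is None:
            continue
        va, vb = getattr(sa, attr), getattr(sb, attr)
        if va is None or vb is None:
            continue
        xs.append(float(va))
        ys.append(float(vb))
        ids.append(sa.gene_id)
    xs, ys = np.asarray(xs), np.asarray(ys)
    if len(xs) < 3:
        raise StatsError("correlate_conditions: need >= 3 paired genes")
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return {"r": float("nan"), "pvalue": float("nan"), "n": len(xs),
                "defined": False, "pairs": pd.DataFrame({"gene_id": ids, "a": xs, "b": ys})}
    r, p = stats.pearsonr(xs, ys)
    return {"r": float(r), "pvalue": float(p), "n": len(xs), "defined": True,
            "pairs": pd.DataFrame({"gene_id": ids, "a": xs, "b": ys})}


def exclude_outliers_iqr(values: Sequence[float], k: float = 1.5) -> np.ndarray:
    """Mask values beyond k×IQR from the quartiles (display filtering only)."""
    v = np.asarray(values, float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return v[(v >= q1 - k * iqr) & (v <= q3 + k * iqr)]


def summaries_to_frame(summaries: Sequence[TerminationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in summaries],
            "condition": [s.condition for s in summaries],
            "gene_body_signal": [s.gene_body_signal for s in summaries],
            "rt_signal": [s.rt_signal for s in summaries],
            "rt_index": [s.rt_index if s.rt_index is not None else np.nan
                         for s in summaries],
            "rt_length_bp": [s.rt_length_bp for s in summaries],
            "primary_tract_len": [s.primary_tract_len for s in summaries],
            "n_weak_secondary": [s.n_weak_secondary for s in summaries],
            "n_strong_secondary": [s.n_strong_secondary for s in summaries],
        }
    )
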