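"""Background thresholding and read-through (RT) region calling.

The background threshold is the 95% quantile (configurable) of total signal
in 20-bp nonoverlapping windows tiled over protein-coding genes.  RT regions
are then called over the 1-kb span immediately downstream of each gene's
primary terminator: overlapping 20-bp windows are scored, windows with total
signal strictly above the threshold are merged into fragments, fragments
separated by small gaps are unioned, and the RT region is the bounding
interval from the first base after the primary tract to the 3′-most retained
fragment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from polterm.coverage import CoverageTrack
from polterm.genome_annotation import GeneModel, TerminatorAnnotation

logger = logging.getLogger(__name__)


class RTCallingError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdModel:
    """Empirical background threshold on per-window total signal."""

    window_bp: int
    quantile: float
    threshold_value: float
    n_windows_used: int


@dataclass(frozen=True)
class RTRegion:
    """Called read-through region downstream of a gene's primary terminator.

    ``start``/``end`` are plus-strand half-open coordinates; for an empty
    region they collapse to the span's 5′ boundary.  ``rt_length_bp`` is the
    orientation-aware distance from the primary tract 3′ edge to the region
    3′ edge (0 iff empty).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    rt_length_bp: int
    fragments_merged: int
    empty: bool


def _strand_track(plus: CoverageTrack, minus: CoverageTrack, strand: str) -> CoverageTrack:
    return plus if strand == "+" else minus


def background_threshold(
    plus: CoverageTrack,
    minus: CoverageTrack,
    coding_genes: Sequence[GeneModel],
    window_bp: int = 20,
    quantile: float = 0.95,
) -> ThresholdModel:
    """Quantile of per-window total signal over protein-coding genes.

    Genes are tiled with nonoverlapping windows of *window_bp*; windows
    truncated at gene ends are discarded.  The threshold is the empirical
    quantile with linear interpolation between order statistics.
    """
    if not (0 < quantile < 1):
        raise RTCallingError(f"quantile must be in (0,1), got {quantile}")
    totals: List[float] = []
    for gene in coding_genes:
        track = _strand_track(plus, minus, gene.strand)
        arr = track.data[gene.chrom][gene.start:gene.end]
        n_windows = len(arr) // window_bp
        if n_windows == 0:
            continue
        trimmed = arr[: n_windows * window_bp].reshape(n_windows, window_bp)
        totals.extend(trimmed.sum(axis=1))
    if not totals:
        raise RTCallingError(
            "no complete background windows (are the coding genes shorter "
            f"than {window_bp} bp?)"
        )
    value = float(np.quantile(np.asarray(totals), quantile))
    return ThresholdModel(window_bp, quantile, value, len(totals))


def window_offsets(span_len: int, window_bp: int, step_bp: int) -> List[int]:
    """Offsets of windows tiled over a span, anchoring the final window.

    Windows start at 0, step, 2*step, ...; a final window flush with the span
    end is added when the stride does not land on it, so the whole span is
    covered.  A span shorter than one window yields a single truncated
    window at offset 0.
    """
    if span_len <= 0:
        return []
    if span_len <= window_bp:
        return [0]
    offsets = list(range(0, span_len - window_bp + 1, step_bp))
    if offsets[-1] != span_len - window_bp:
        offsets.append(span_len - window_bp)
    return offsets


def _merge_marked(
    marked: List[Tuple[int, int]], max_gap_bp: int
) -> List[Tuple[int, int]]:
    """Union overlapping/adjacent intervals, then close gaps <= max_gap_bp."""
    if not marked:
        return []
    marked = sorted(marked)
    fragments = [list(marked[0])]
    for s, e in marked[1:]:
        if s <= fragments[-1][1]:
            fragments[-1][1] = max(fragments[-1][1], e)
        else:
            fragments.append([s, e])
    merged = [fragments[0]]
    for s, e in fragments[1:]:
        if s - merged[-1][1] <= max_gap_bp:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def call_rt_region(
    plus: CoverageTrack,
    minus: CoverageTrack,
    anno: TerminatorAnnotation,
    threshold: ThresholdModel,
    span_bp: int = 1000,
    window_bp: int = 20,
    step_bp: int = 19,
    max_gap_bp: int = 20,
) -> RTRegion:
    """Call the RT region downstream of *anno*'s primary terminator.

    Windows with total signal strictly greater than the threshold value are
    merged; the region runs from the first base after the primary tract to
    the 3′ edge of the last retained fragment.  Fragments disconnected from
    the terminator by more than *max_gap_bp* are still included (the region
    is the union's bounding interval).  A span extending past the chromosome
    end is truncated with a logged warning.
    """
    if anno.primary is None:
        raise RTCallingError(f"gene {anno.gene_id}: no primary terminator")
    primary = anno.primary
    strand = primary.strand
    track = _strand_track(plus, minus, strand)
    chrom_len = len(track.data[primary.chrom])

    if strand == "+":
        span_start = primary.end
        span_end = primary.end + span_bp
        if span_end > chrom_len:
            logger.warning(
                "gene %s: RT span truncated at chromosome end (%d > %d)",
                anno.gene_id, span_end, chrom_len)
            span_end = chrom_len
        oriented = track.data[primary.chrom][span_start:span_end]
    else:
        span_end = primary.start
        span_start = primary.start - span_bp
        if span_start < 0:
            logger.warning(
                "gene %s: RT span truncated at chromosome start (%d < 0)",
                anno.gene_id, span_start)
            span_start = 0
        oriented = track.data[primary.chrom][span_start:span_end][::-1]

    span_len = len(oriented)
    marked: List[Tuple[int, int]] = []
    for off in window_offsets(span_len, window_bp, step_bp):
        w_end = min(off + window_bp, span_len)
        if oriented[off:w_end].sum() > threshold.threshold_value:
            marked.append((off, w_end))
    fragments = _merge_marked(marked, max_gap_bp)

    if not fragments:
        rel_end = 0
        empty = True
    else:
        rel_end = fragments[-1][1]
        empty = False

    if strand == "+":
        start, end = span_start, span_start + rel_end
    else:
        start, end = span_end - rel_end, span_end
    return RTRegion(
        gene_id=anno.gene_id,
        chrom=primary.chrom,
        start=start,
        end=end,
        strand=strand,
        rt_length_bp=rel_end,
        fragments_merged=len(fragments),
        empty=empty,
    )


def rt_length(region: RTRegion) -> int:
    """RT length in bp: distance from primary tract 3′ edge to region 3′ edge."""
    return region.rt_length_bp


def write_rt_bed(regions: Sequence[RTRegion], path: str) -> None:
    """BED6 of RT regions: name = gene_id, score = rt_length."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t"
                     f"{r.rt_length_bp}\t{r.strand}\n")


def write_rt_tsv(regions: Sequence[RTRegion], path: str,
                 threshold: Optional[ThresholdModel] = None) -> None:
    with open(path, "w") as fh:
        if threshold is not None:
            fh.write(f"# threshold_value={threshold.threshold_value:.6g} "
                     f"window_bp={threshold.window_bp} "
                     f"quantile={threshold.quantile} "
                     f"n_windows={threshold.n_windows_used}\n")
        fh.write("gene_id\tchrom\tstart\tend\tstrand\trt_length_bp\t"
                 "fragments_merged\tempty\n")
        for r in regions:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t"
                     f"{r.rt_length_bp}\t{r.fragments_merged}\t{int(r.empty)}\n")
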