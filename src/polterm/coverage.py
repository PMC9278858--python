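"""Strand-specific per-base coverage tracks.

Tracks are dense per-chromosome float arrays.  bedGraph (4-column,
whitespace-separated) is the canonical on-disk format; minus-strand files
store nonnegative values, the strand being carried by the file role rather
than by a sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from polterm.genome_annotation import GeneModel


class CoverageError(ValueError):
    pass


def read_chrom_sizes(path: str) -> Dict[str, int]:
    """Read a 2-column ``chrom.sizes`` TSV."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    if not sizes:
        raise CoverageError(f"{path}: no chromosomes")
    return sizes


@dataclass
class CoverageTrack:
    """Per-base nonnegative signal for one strand of one sample."""

    sample_id: str
    strand: str
    data: Dict[str, np.ndarray]
    condition: str = "other"
    total_raw_reads: Optional[float] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise CoverageError(f"bad strand {self.strand!r}")
        for chrom, arr in self.data.items():
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise CoverageError(f"track {self.sample_id}: non-finite or "
                                    f"negative values on {chrom}")

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}

    def total(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))

    @classmethod
    def zeros(cls, sample_id: str, strand: str, chrom_sizes: Dict[str, int],
              condition: str = "other") -> "CoverageTrack":
        data = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
        return cls(sample_id, strand, data, condition)


def load_bedgraph(path: str, chrom_sizes: Dict[str, int]) -> Dict[str, np.ndarray]:
    """Parse a bedGraph file into dense per-chromosome arrays.

    Positions absent from the file are 0.  Overlapping intervals and unknown
    chromosomes are errors.
    """
    data = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise CoverageError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in data:
                raise CoverageError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= chrom_sizes[chrom]):
                raise CoverageError(
                    f"{path}:{lineno}: interval [{start},{end}) outside "
                    f"{chrom} (length {chrom_sizes[chrom]})"
                )
            if covered[chrom][start:end].any():
                raise CoverageError(f"{path}:{lineno}: overlapping bedGraph interval")
            covered[chrom][start:end] = True
            data[chrom][start:end] = value
    return data


def write_bedgraph(data: Dict[str, np.ndarray], path: str) -> None:
    """Write dense arrays as bedGraph, run-length-merging equal values.

    Zero runs are omitted (absent positions read back as 0), so the
    round trip through :func:`load_bedgraph` is lossless.
    """
    with open(path, "w") as fh:
        for chrom in data:
            arr = data[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def load_coverage(
    plus_file: str,
    minus_file: str,
    chrom_sizes: Dict[str, int],
    sample_id: str = "sample",
    condition: str = "other",
) -> Tuple[CoverageTrack, CoverageTrack]:
    """Load a strand pair of bedGraph files into dense tracks."""
    plus = CoverageTrack(sample_id, "+", load_bedgraph(plus_file, chrom_sizes), condition)
    minus = CoverageTrack(sample_id, "-", load_bedgraph(minus_file, chrom_sizes), condition)
    return plus, minus


def normalize_cpm(
    plus: CoverageTrack, minus: CoverageTrack
) -> Tuple[CoverageTrack, CoverageTrack]:
    """CPM-normalise a strand pair by their joint raw total.

    Each value is scaled by 1e6 / (joint total), so the normalised pair sums
    to 1e6 over both strands.
    """
    total = plus.total() + minus.total()
    if total <= 0:
        raise CoverageError("normalize_cpm: zero total signal")
    factor = 1e6 / total
    out = []
    for track in (plus, minus):
        out.append(
            CoverageTrack(
                track.sample_id,
                track.strand,
                {c: a * factor for c, a in track.data.items()},
                track.condition,
                total_raw_reads=total,
            )
        )
    return out[0], out[1]


@dataclass(frozen=True)
class RegionSignal:
    region_id: str
    total: float
    mean: float
    max: float
    length: int


def region_signal(track: CoverageTrack, chrom: str, start: int, end: int,
                  region_id: str = "") -> RegionSignal:
    """Sum/mean/max of the track over [start, end)."""
    if chrom not in track.data:
        raise CoverageError(f"unknown chromosome {chrom!r}")
    n = len(track.data[chrom])
    if not (0 <= start < end <= n):
        raise CoverageError(
            f"region [{start},{end}) invalid or outside {chrom} (length {n})"
        )
    window = track.data[chrom][start:end]
    return RegionSignal(region_id, float(window.sum()), float(window.mean()),
                        float(window.max()), end - start)


def average_replicates(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Per-base arithmetic mean of replicate tracks (same strand and sizes)."""
    if not tracks:
        raise CoverageError("average_replicates: no tracks")
    first = tracks[0]
    for t in tracks[1:]:
        if t.strand != first.strand:
            raise CoverageError("average_replicates: mixed strands")
        if t.chrom_sizes != first.chrom_sizes:
            raise CoverageError("average_replicates: chromosome sizes differ")
    data = {
        c: np.mean([t.data[c] for t in tracks], axis=0) for c in first.data
    }
    return CoverageTrack(
        sample_id="+".join(t.sample_id for t in tracks),
        strand=first.strand,
        data=data,
        condition=first.condition,
    )


def gene_flank_means(
    plus: CoverageTrack,
    minus: CoverageTrack,
    genes: Sequence[GeneModel],
    flank_bp: int = 500,
) -> np.ndarray:
    """Per-gene mean signal over gene ± *flank_bp*, strand-matched."""
    values = []
    for gene in genes:
        track = plus if gene.strand == "+" else minus
        n = len(track.data[gene.chrom])
        s = max(0, gene.start - flank_bp)
        e = min(n, gene.end + flank_bp)
        values.append(region_signal(track, gene.chrom, s, e, gene.gene_id).mean)
    return np.asarray(values)


def correlate_samples(
    pair_a: Tuple[CoverageTrack, CoverageTrack],
    pair_b: Tuple[CoverageTrack, CoverageTrack],
    genes: Sequence[GeneModel],
    flank_bp: int = 500,
) -> Dict[str, float]:
    """Spearman correlation of per-gene mean signals between two samples.

    The per-gene statistic is the mean signal over the gene extended by
    *flank_bp* on both sides, on the gene's strand.  Constant vectors make
    the correlation undefined and are flagged rather than reported as 0.
    """
    if len(genes) < 3:
        raise CoverageError("correlate_samples: need >= 3 genes")
    va = gene_flank_means(*pair_a, genes, flank_bp)
    vb = gene_flank_means(*pair_b, genes, flank_bp)
    if np.all(va == va[0]) or np.all(vb == vb[0]):
        return {"rho": float("nan"), "pvalue": float("nan"),
                "n": len(genes), "defined": False}
    rho, p = stats.spearmanr(va, vb)
    return {"rho": float(rho), "pvalue": float(p), "n": len(genes), "defined": True}
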