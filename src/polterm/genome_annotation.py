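"""T-tract scanning and per-gene terminator annotation.

All coordinates are 0-based, half-open (BED convention).  "Downstream" and
"3′" are always taken in the transcription orientation of the feature at
hand: for a '+' strand gene the 3′ end is ``gene.end`` and downstream means
increasing coordinates; for a '−' strand gene the 3′ end is ``gene.start``
and downstream means decreasing coordinates.

A T-tract is a maximal run of T residues on the sense strand.  On the plus
strand this is a run of ``T`` in the reference sequence; on the minus strand
a run of ``A`` in the reference (which reads as T on the minus strand).
``N`` residues terminate runs.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

VALID_RESIDUES = frozenset("ACGTN")

WEAK = "weak"
STRONG = "strong"

#: Tracts of 4 or 5 Ts are weak terminators; 6 or more Ts are strong.
STRONG_MIN_LEN = 6
MIN_TRACT_LEN = 4


class AnnotationError(ValueError):
    """Raised on invalid sequences, coordinates or annotation state."""


@dataclass(frozen=True)
class GenomeSequence:
    """Genome as per-chromosome residue strings over {A, C, G, T, N}."""

    chroms: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.chroms:
            raise AnnotationError("genome is empty: no chromosomes")
        for name, seq in self.chroms.items():
            if not name:
                raise AnnotationError("empty chromosome name")
            bad = re.search(r"[^ACGTN]", seq)
            if bad:
                raise AnnotationError(
                    f"invalid residue {seq[bad.start()]!r} at "
                    f"{name}:{bad.start()} (expected one of A,C,G,T,N)"
                )

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeSequence":
        chroms = {}
        for rec in SeqIO.parse(path, "fasta"):
            if rec.id in chroms:
                raise AnnotationError(f"duplicate chromosome name {rec.id!r}")
            chroms[rec.id] = str(rec.seq).upper()
        return cls(chroms)


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with strand and class ('tRNA-like' or 'coding')."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_class: str = "tRNA-like"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"gene {self.gene_id}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def three_prime(self) -> int:
        """3′ end as a plus-strand coordinate boundary (half-open edge)."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True, order=True)
class TTract:
    """Maximal run of sense-strand Ts: T-run on '+', A-run on '−'."""

    chrom: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """5′ edge in transcription orientation (plus-strand boundary coordinate)."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        """3′ edge in transcription orientation (plus-strand boundary coordinate)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class TerminatorAnnotation:
    """Primary terminator, spacer and secondary terminators of one gene."""

    gene_id: str
    gene: GeneModel
    primary: Optional[TTract] = None
    spacer_bp: Optional[int] = None
    secondary: List[TTract] = field(default_factory=list)

    @property
    def has_primary(self) -> bool:
        return self.primary is not None

    @property
    def n_weak_secondary(self) -> int:
        return sum(1 for t in self.secondary if classify_terminator(t) == WEAK)

    @property
    def n_strong_secondary(self) -> int:
        return sum(1 for t in self.secondary if classify_terminator(t) == STRONG)


def find_t_tracts(genome: GenomeSequence, min_len: int = MIN_TRACT_LEN) -> List[TTract]:
    """Find all maximal T-tracts on both strands of *genome*.

    Plus-strand tracts are runs of ``T``; minus-strand tracts are runs of
    ``A`` in the plus-strand sequence.  ``N`` breaks runs.  Returns tracts
    with run length >= *min_len* sorted by (chrom, start, strand).
    """
    if min_len < 1:
        raise AnnotationError(f"min_len must be >= 1, got {min_len}")
    tracts: List[TTract] = []
    pat = {"+" : re.compile(r"T{%d,}" % min_len), "-": re.compile(r"A{%d,}" % min_len)}
    for chrom in genome.chroms:
        seq = genome.chroms[chrom]
        for strand, rx in pat.items():
            for m in rx.finditer(seq):
                tracts.append(TTract(chrom, m.start(), m.end(), strand))
    tracts.sort(key=lambda t: (t.chrom, t.start, t.strand))
    return tracts


def assign_primary_terminator(
    gene: GeneModel,
    tracts: Sequence[TTract],
    max_search_bp: int = 1000,
) -> TerminatorAnnotation:
    """Assign the first same-strand T-tract downstream of the gene 3′ end.

    The primary terminator is the eligible tract with the smallest
    orientation-aware distance (spacer) from the gene 3′ end; the spacer must
    be >= 0 and <= *max_search_bp*.  A tract whose 5′ edge coincides with the
    3′ end counts with spacer 0.  If no tract qualifies the annotation is
    returned with ``primary=None`` (flagged, never silently dropped).
    """
    best: Optional[TTract] = None
    best_spacer: Optional[int] = None
    for tract in tracts:
        if tract.chrom != gene.chrom or tract.strand != gene.strand:
            continue
        if gene.strand == "+":
            spacer = tract.start - gene.end
        else:
            spacer = gene.start - tract.end
        if spacer < 0 or spacer > max_search_bp:
            continue
        if best_spacer is None or spacer < best_spacer:
            best, best_spacer = tract, spacer
    return TerminatorAnnotation(
        gene_id=gene.gene_id, gene=gene, primary=best, spacer_bp=best_spacer
    )


def annotate_secondary_terminators(
    anno: TerminatorAnnotation,
    tracts: Sequence[TTract],
    window_bp: int = 700,
) -> TerminatorAnnotation:
    """Collect same-strand tracts in the window downstream of the primary.

    Membership is by the tract 5′ edge falling in the half-open window of
    width *window_bp* starting at the base immediately after the primary
    tract 3′ edge.  Tracts are ordered 5′→3′ in transcription orientation.
    Requires a primary terminator.
    """
    if anno.primary is None:
        raise AnnotationError(
            f"gene {anno.gene_id} has no primary terminator; "
            "call assign_primary_terminator first"
        )
    primary = anno.primary
    strand = primary.strand
    hits: List[TTract] = []
    for tract in tracts:
        if tract.chrom != primary.chrom or tract.strand != strand:
            continue
        if tract == primary:
            continue
        if strand == "+":
            offset = tract.start - primary.end
        else:
            offset = primary.start - tract.end
        if 0 <= offset < window_bp:
            hits.append(tract)
    hits.sort(key=lambda t: t.start if strand == "+" else -t.end)
    anno.secondary = hits
    return anno


def classify_terminator(tract: TTract) -> str:
    """Classify a tract: 4–5 Ts → 'weak', >=6 Ts → 'strong'."""
    if tract.length < MIN_TRACT_LEN:
        raise AnnotationError(
            f"tract of length {tract.length} is not a terminator (< {MIN_TRACT_LEN})"
        )
    return STRONG if tract.length >= STRONG_MIN_LEN else WEAK


def spacer_statistics(
    annos: Iterable[TerminatorAnnotation], cutoff_bp: int = 7
) -> Dict[str, object]:
    """Summarise spacer lengths over a set of terminator annotations.

    Returns the number of genes whose spacer is <= *cutoff_bp*, the number
    with a primary terminator at all, the total gene count, and the full
    spacer histogram.
    """
    annos = list(annos)
    if not annos:
        raise AnnotationError("spacer_statistics: empty annotation list")
    spacers = [a.spacer_bp for a in annos if a.has_primary]
    hist = Counter(spacers)
    return {
        "n_genes": len(annos),
        "n_with_primary": len(spacers),
        "n_spacer_le_cutoff": sum(1 for s in spacers if s <= cutoff_bp),
        "cutoff_bp": cutoff_bp,
        "spacer_histogram": dict(sorted(hist.items())),
    }


def tract_orientation_counts(
    regions: Sequence[GeneModel], tracts: Sequence[TTract]
) -> Dict[str, Tuple[int, int]]:
    """Count, per region, tracts in sense vs antisense orientation.

    A tract counts for a region if it overlaps the region interval by at
    least one base; it is *sense* if its strand matches the region strand.
    """
    out: Dict[str, Tuple[int, int]] = {}
    for region in regions:
        sense = antisense = 0
        for tract in tracts:
            if tract.chrom != region.chrom:
                continue
            if tract.start < region.end and tract.end > region.start:
                if tract.strand == region.strand:
                    sense += 1
                else:
                    antisense += 1
        out[region.gene_id] = (sense, antisense)
    return out


# ---------------------------------------------------------------------------
# BED / TSV I/O


def read_genes_bed(path: str, gene_class: str = "tRNA-like") -> List[GeneModel]:
    """Read a BED6 file of genes (score column ignored; strand required)."""
    genes: List[GeneModel] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise AnnotationError(
                    f"{path}:{lineno}: expected BED6 (6 columns), got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            if name in seen:
                raise AnnotationError(f"{path}:{lineno}: duplicate gene_id {name!r}")
            seen.add(name)
            genes.append(
                GeneModel(name, chrom, int(start), int(end), strand, gene_class)
            )
    return genes


def write_tracts_bed(tracts: Sequence[TTract], path: str) -> None:
    """Write tracts as BED6 with name ``T<length>`` and score = length."""
    with open(path, "w") as fh:
        for t in tracts:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\tT{t.length}\t{t.length}\t{t.strand}\n"
            )


def write_annotations_tsv(annos: Sequence[TerminatorAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tchrom\tstrand\tprimary_start\tprimary_end\tprimary_len\t"
            "spacer_bp\tn_weak_secondary\tn_strong_secondary\n"
        )
        for a in annos:
            if a.primary is None:
                fh.write(f"{a.gene_id}\t{a.gene.chrom}\t{a.gene.strand}\t"
                         "NA\tNA\tNA\tNA\tNA\tNA\n")
            else:
                fh.write(
                    f"{a.gene_id}\t{a.gene.chrom}\t{a.gene.strand}\t"
                    f"{a.primary.start}\t{a.primary.end}\t{a.primary.length}\t"
                    f"{a.spacer_bp}\t{a.n_weak_secondary}\t{a.n_strong_secondary}\n"
                )
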