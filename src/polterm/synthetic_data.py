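"""Stochastic polymerase-elongation simulator with known ground truth.

The simulator builds a synthetic genome in which every terminator is placed
by design (the random background is generated tract-free), then walks
polymerases gene by gene:

- every initiated polymerase traverses the gene body, the spacer and the
  primary tract;
- at the primary tract 3′ edge it is released with probability
  ``p_term(L)``, increasing in tract length L;
- survivors continue into the 1-kb downstream window, where they can be
  released at designed secondary-tract 3′ edges (with ``p_term`` of that
  tract, plus the condition-dependent fail-safe probability) and at random
  pause sites (fail-safe probability only);
- polymerases reaching the window boundary run off: they contribute dwell
  over the bases they traversed but no termination event.

Occupancy at a base is the summed dwell of all polymerases over it (dwell 1
at ordinary bases, ``dwell_pause`` at pause sites and tract 3′ edges), which
is what a cross-linking 3′-end protocol samples.  Identical seed and config
give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from polterm.coverage import CoverageTrack, write_bedgraph
from polterm.genome_annotation import (
    GeneModel,
    GenomeSequence,
    TTract,
    write_tracts_bed,
)


class SimulationError(ValueError):
    pass


#: Default length-dependent release probability at a tract 3′ edge.
#: Qualitative profile: T4 nearly never releases, T5 intermediate, T6 very
#: efficient, longer tracts marginally better; non-decreasing in length.
DEFAULT_P_TERM: Dict[int, float] = {
    4: 0.05, 5: 0.5, 6: 0.9, 7: 0.93, 8: 0.95,
    9: 0.95, 10: 0.96, 11: 0.97, 12: 0.98,
}

CONDITIONS = ("WT", "mutant")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 24
    gene_length: Tuple[int, int] = (70, 120)
    spacer_range: Tuple[int, int] = (0, 8)
    primary_len_choices: Tuple[int, ...] = (4, 5, 6, 7, 8)
    #: explicit per-gene primary tract lengths (overrides primary_len_choices)
    primary_lengths: Optional[Sequence[int]] = None
    weak_secondary_range: Tuple[int, int] = (0, 3)
    strong_secondary_range: Tuple[int, int] = (0, 2)
    weak_secondary_counts: Optional[Sequence[int]] = None
    strong_secondary_counts: Optional[Sequence[int]] = None
    p_term: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_P_TERM))
    p_failsafe_wt: float = 0.5
    p_failsafe_mut: float = 0.05
    pause_site_rate: float = 0.02
    dwell_pause: float = 4.0
    initiations_per_gene: float = 500.0
    poisson_initiations: bool = True
    #: None → write exact occupancy; int → sample that many reads from it
    reads_total: Optional[int] = None
    background_noise_rate: float = 0.01
    strand_balance: bool = True
    n_coding_genes: int = 8
    coding_gene_length: int = 1000
    downstream_bp: int = 1000
    secondary_window_bp: int = 700
    # optional stall-without-release at the proximal part of long tracts
    stall_long_tracts: bool = False
    p_stall: float = 0.5
    stall_min_len: int = 9

    def __post_init__(self) -> None:
        for name in ("p_failsafe_wt", "p_failsafe_mut", "pause_site_rate",
                     "p_stall"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationError(f"{name}={v} outside [0,1]")
        lengths = sorted(self.p_term)
        for a, b in zip(lengths, lengths[1:]):
            if self.p_term[b] < self.p_term[a]:
                raise SimulationError("p_term must be non-decreasing in tract length")
        for L, p in self.p_term.items():
            if not (0.0 <= p <= 1.0):
                raise SimulationError(f"p_term[{L}]={p} outside [0,1]")
        if self.n_genes < 1:
            raise SimulationError("n_genes must be >= 1")

    def release_prob(self, tract_len: int) -> float:
        """p_term for a tract length, clamped to the configured range."""
        keys = sorted(self.p_term)
        if tract_len <= keys[0]:
            return self.p_term[keys[0]]
        if tract_len >= keys[-1]:
            return self.p_term[keys[-1]]
        if tract_len in self.p_term:
            return self.p_term[tract_len]
        below = max(k for k in keys if k < tract_len)
        return self.p_term[below]

    def failsafe(self, condition: str) -> float:
        if condition == "WT":
            return self.p_failsafe_wt
        if condition == "mutant":
            return self.p_failsafe_mut
        raise SimulationError(f"unknown condition {condition!r}")


@dataclass
class GeneDesign:
    """Ground-truth design of one simulated gene (oriented coordinates)."""

    gene: GeneModel
    primary: TTract
    spacer_bp: int
    primary_len: int
    secondary: List[TTract]
    #: 3′-edge offsets of secondary tracts, relative to primary tract 3′ edge
    secondary_edge_offsets: List[int]
    secondary_lengths: List[int]
    #: pause-site offsets relative to primary tract 3′ edge (1-based bases in)
    pause_offsets: List[int]
    n_weak: int
    n_strong: int


@dataclass
class SimulatedGenome:
    genome: GenomeSequence
    genes: List[GeneModel]
    coding_genes: List[GeneModel]
    designs: Dict[str, GeneDesign]

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return self.genome.lengths

    @property
    def tracts(self) -> List[TTract]:
        out = []
        for d in self.designs.values():
            out.append(d.primary)
            out.extend(d.secondary)
        return sorted(out)


@dataclass
class GeneTruth:
    gene_id: str
    condition: str
    n_initiated: int
    released_primary: int
    released_downstream: int
    stalled: int
    run_off: int
    true_rt_fraction: float  # 1 - p_term(primary length)
    #: realized termination counts keyed by offset from primary 3′ edge
    downstream_release_positions: Dict[int, int]


@dataclass
class SimTruth:
    condition: str
    genes: Dict[str, GeneTruth]


_BASES = np.array(list("ACGT"))


def _tract_free_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random sequence with no T- or A-run of length >= 4 on either strand."""
    arr = rng.choice(_BASES, size=n)
    for base, repl in (("T", "C"), ("A", "G")):
        idx = np.flatnonzero(arr == base)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [idx.size - 1]))
        for rs, re_ in zip(run_starts, run_ends):
            start, end = idx[rs], idx[re_]
            if end - start + 1 >= 4:
                arr[np.arange(start + 3, end + 1, 4)] = repl
    return arr


def _write_tract(seq: np.ndarray, start: int, length: int, strand: str) -> None:
    """Overwrite a designed tract, guarding flanks so the run stays maximal."""
    char, flank = ("T", "C") if strand == "+" else ("A", "G")
    seq[start:start + length] = char
    if start > 0:
        seq[start - 1] = flank
    if start + length < len(seq):
        seq[start + length] = flank


def _place_secondary(
    rng: np.random.Generator, n_weak: int, n_strong: int, window_bp: int
) -> List[Tuple[int, int]]:
    """Sample non-overlapping (offset, length) pairs in the secondary window.

    Offsets are measured from the base after the primary tract; a 25-bp
    buffer after the primary keeps the immediate downstream probe clean.
    """
    lengths = [int(rng.integers(4, 6)) for _ in range(n_weak)]
    lengths += [int(rng.integers(6, 8)) for _ in range(n_strong)]
    rng.shuffle(lengths)
    placed: List[Tuple[int, int]] = []
    for L in lengths:
        for _ in range(200):
            off = int(rng.integers(25, window_bp - L - 2))
            if all(off + L + 2 <= s or off >= s + sl + 2 for s, sl in placed):
                placed.append((off, L))
                break
        else:
            raise SimulationError(
                "could not place secondary tracts without overlap; "
                "reduce their number"
            )
    return sorted(placed)


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Build the synthetic genome, gene models and designed terminators.

    The layout is one chromosome of consecutive gene blocks (pad, gene body,
    spacer, primary tract, downstream window) followed by tract-free
    protein-coding "background genes" used for threshold estimation.  All
    randomness comes from ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 101])
    pad = 200
    segments: List[np.ndarray] = []
    genes: List[GeneModel] = []
    designs: Dict[str, GeneDesign] = {}
    pos = 0
    chrom = "chrS"

    if config.primary_lengths is not None:
        if len(config.primary_lengths) != config.n_genes:
            raise SimulationError("primary_lengths must have n_genes entries")
        primary_lengths = list(config.primary_lengths)
    else:
        primary_lengths = [int(rng.choice(config.primary_len_choices))
                           for _ in range(config.n_genes)]

    def counts(explicit, lo_hi, i):
        if explicit is not None:
            return int(explicit[i])
        return int(rng.integers(lo_hi[0], lo_hi[1] + 1))

    for i in range(config.n_genes):
        gene_id = f"sim_tRNA_{i:04d}"
        strand = ("+" if i % 2 == 0 else "-") if config.strand_balance else \
            ("+" if rng.random() < 0.5 else "-")
        body_len = int(rng.integers(config.gene_length[0], config.gene_length[1] + 1))
        spacer = int(rng.integers(config.spacer_range[0], config.spacer_range[1] + 1))
        plen = primary_lengths[i]
        n_weak = counts(config.weak_secondary_counts, config.weak_secondary_range, i)
        n_strong = counts(config.strong_secondary_counts, config.strong_secondary_range, i)
        sec_placed = _place_secondary(rng, n_weak, n_strong,
                                      config.secondary_window_bp)

        block_len = pad + body_len + spacer + plen + config.downstream_bp
        block = _tract_free_sequence(rng, block_len)

        if strand == "+":
            body_start = pos + pad
            body_end = body_start + body_len
            tract_start = body_end + spacer
            _write_tract(block, pad + body_len + spacer, plen, "+")
            primary = TTract(chrom, tract_start, tract_start + plen, "+")
            secondary = []
            for off, L in sec_placed:
                rel = pad + body_len + spacer + plen + off
                _write_tract(block, rel, L, "+")
                s = tract_start + plen + off
                secondary.append(TTract(chrom, s, s + L, "+"))
        else:
            # mirrored block: downstream window first, then tract, spacer, body
            body_end = pos + block_len
            body_start = body_end - body_len
            tract_end = body_start - spacer
            rel_tract = block_len - body_len - spacer - plen
            _write_tract(block, rel_tract, plen, "-")
            primary = TTract(chrom, tract_end - plen, tract_end, "-")
            secondary = []
            for off, L in sec_placed:
                s_end = primary.start - off
                _write_tract(block, s_end - L - pos, L, "-")
                secondary.append(TTract(chrom, s_end - L, s_end, "-"))

        gene = GeneModel(gene_id, chrom, body_start, body_end, strand, "tRNA-like")
        pause = np.flatnonzero(
            rng.random(config.downstream_bp) < config.pause_site_rate
        ) + 1  # offsets are 1-based bases after the tract 3′ edge
        tract_cover = set()
        for off, L in sec_placed:
            tract_cover.update(range(off + 1, off + L + 1))
        pause_offsets = [int(p) for p in pause if int(p) not in tract_cover]

        genes.append(gene)
        designs[gene_id] = GeneDesign(
            gene=gene,
            primary=primary,
            spacer_bp=spacer,
            primary_len=plen,
            secondary=secondary,
            secondary_edge_offsets=[off + L for off, L in sec_placed],
            secondary_lengths=[L for _, L in sec_placed],
            pause_offsets=pause_offsets,
            n_weak=n_weak,
            n_strong=n_strong,
        )
        segments.append(block)
        pos += block_len

    coding_genes: List[GeneModel] = []
    for j in range(config.n_coding_genes):
        block = _tract_free_sequence(rng, config.coding_gene_length + pad)
        start = pos + pad // 2
        coding_genes.append(
            GeneModel(f"sim_coding_{j:04d}", chrom, start,
                      start + config.coding_gene_length,
                      "+" if j % 2 == 0 else "-", "coding")
        )
        segments.append(block)
        pos += len(block)

    seq = "".join("".join(s) for s in segments)
    genome = GenomeSequence({chrom: seq})
    return SimulatedGenome(genome, genes, coding_genes, designs)


def simulate_transcription(
    sim: SimulatedGenome,
    config: SimulationConfig,
    condition: str,
) -> Tuple[CoverageTrack, CoverageTrack, SimTruth]:
    """Walk polymerases through every gene and return occupancy tracks.

    Returns raw-count (or exact-occupancy) tracks for both strands plus the
    per-gene ground truth for *condition*.
    """
    cond_key = {"WT": 1, "mutant": 2}.get(condition)
    if cond_key is None:
        raise SimulationError(f"condition must be one of {CONDITIONS}, "
                              f"got {condition!r}")
    rng = np.random.default_rng([config.seed, 211, cond_key])
    p_failsafe = config.failsafe(condition)
    sizes = sim.chrom_sizes
    occ = {
        "+": {c: np.zeros(n) for c, n in sizes.items()},
        "-": {c: np.zeros(n) for c, n in sizes.items()},
    }
    truths: Dict[str, GeneTruth] = {}
    total_init = 0

    for gene in sim.genes:
        design = sim.designs[gene.gene_id]
        body_len = gene.end - gene.start
        plen = design.primary_len
        pre_len = body_len + design.spacer_bp + plen  # through the tract
        path_len = pre_len + config.downstream_bp
        primary_edge = pre_len - 1  # oriented index of the tract's last base

        if config.poisson_initiations:
            n_init = int(rng.poisson(config.initiations_per_gene))
        else:
            n_init = int(round(config.initiations_per_gene))
        total_init += n_init

        # release events ordered along the path
        events: List[Tuple[int, float, str]] = []
        if config.stall_long_tracts and plen >= config.stall_min_len:
            events.append((pre_len - plen, config.p_stall, "stall"))
        events.append((primary_edge, config.release_prob(plen), "primary"))
        for edge_off, L in zip(design.secondary_edge_offsets,
                               design.secondary_lengths):
            p_rel = 1.0 - (1.0 - config.release_prob(L)) * (1.0 - p_failsafe)
            events.append((pre_len + edge_off - 1, p_rel, "secondary"))
        for off in design.pause_offsets:
            events.append((pre_len + off - 1, p_failsafe, "pause"))
        events.sort()

        dwell = np.ones(path_len)
        drops = np.zeros(path_len + 1)
        n_active = n_init
        released_primary = released_downstream = stalled = 0
        positions: Dict[int, int] = {}
        for pos_, p_rel, kind in events:
            if kind != "stall":
                dwell[pos_] = config.dwell_pause
            if n_active == 0 or p_rel == 0.0:
                continue
            k = int(rng.binomial(n_active, p_rel))
            if k == 0:
                continue
            drops[pos_ + 1] += k
            n_active -= k
            if kind == "primary":
                released_primary += k
            elif kind == "stall":
                stalled += k
            else:
                released_downstream += k
                off = pos_ - primary_edge
                positions[off] = positions.get(off, 0) + k
        run_off = n_active

        reach = n_init - np.cumsum(drops)[:path_len]
        gene_occ = reach * dwell

        if gene.strand == "+":
            start = gene.start
            occ["+"][gene.chrom][start:start + path_len] += gene_occ
        else:
            end = gene.end
            occ["-"][gene.chrom][end - path_len:end] += gene_occ[::-1]

        truths[gene.gene_id] = GeneTruth(
            gene_id=gene.gene_id,
            condition=condition,
            n_initiated=n_init,
            released_primary=released_primary,
            released_downstream=released_downstream,
            stalled=stalled,
            run_off=run_off,
            true_rt_fraction=1.0 - config.release_prob(plen),
            downstream_release_positions=positions,
        )

    if total_init == 0:
        raise SimulationError("zero initiations overall; raise "
                              "initiations_per_gene")

    if config.reads_total is not None:
        flat = np.concatenate([occ[s][c] for s in ("+", "-") for c in sizes])
        total = flat.sum()
        if total <= 0:
            raise SimulationError("no occupancy to sample reads from")
        counts = rng.multinomial(config.reads_total, flat / total).astype(float)
        offset = 0
        for s in ("+", "-"):
            for c in sizes:
                n = sizes[c]
                occ[s][c] = counts[offset:offset + n]
                offset += n

    if config.background_noise_rate > 0:
        for s in ("+", "-"):
            for c, n in sizes.items():
                occ[s][c] += rng.poisson(config.background_noise_rate, n)

    plus = CoverageTrack(f"sim_{condition}", "+", occ["+"], condition)
    minus = CoverageTrack(f"sim_{condition}", "-", occ["-"], condition)
    return plus, minus, SimTruth(condition, truths)


# ---------------------------------------------------------------------------
# File emission


def write_genes_bed(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_truth_tsv(truth: SimTruth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcondition\tn_initiated\treleased_primary\t"
                 "released_downstream\tstalled\trun_off\ttrue_rt_fraction\n")
        for t in truth.genes.values():
            fh.write(f"{t.gene_id}\t{t.condition}\t{t.n_initiated}\t"
                     f"{t.released_primary}\t{t.released_downstream}\t"
                     f"{t.stalled}\t{t.run_off}\t{t.true_rt_fraction:.6g}\n")


def emit_coverage(
    sim: SimulatedGenome,
    config: SimulationConfig,
    outdir: str,
    conditions: Sequence[str] = CONDITIONS,
) -> Dict[str, Dict[str, str]]:
    """Run the simulation for each condition and write all pipeline inputs.

    Writes FASTA, gene/coding/tract BED files, chrom.sizes, a raw-count
    bedGraph pair per condition, a truth TSV per condition and a config
    echo.  Returns the map condition → written coverage file paths.
    """
    import os

    import yaml

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "genome.fa"), "w") as fh:
        for chrom, seq in sim.genome.chroms.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
        for chrom, n in sim.chrom_sizes.items():
            fh.write(f"{chrom}\t{n}\n")
    write_genes_bed(sim.genes, os.path.join(outdir, "genes.bed"))
    write_genes_bed(sim.coding_genes, os.path.join(outdir, "coding.bed"))
    write_tracts_bed(sim.tracts, os.path.join(outdir, "designed_tracts.bed"))

    paths: Dict[str, Dict[str, str]] = {}
    for condition in conditions:
        plus, minus, truth = simulate_transcription(sim, config, condition)
        p = os.path.join(outdir, f"{condition}_plus.bedgraph")
        m = os.path.join(outdir, f"{condition}_minus.bedgraph")
        write_bedgraph(plus.data, p)
        write_bedgraph(minus.data, m)
        write_truth_tsv(truth, os.path.join(outdir, f"{condition}_truth.tsv"))
        paths[condition] = {"plus": p, "minus": m}

    echo = dataclasses.asdict(config)
    echo["p_term"] = {int(k): float(v) for k, v in config.p_term.items()}
    with open(os.path.join(outdir, "sim_config.yaml"), "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=True)
    return paths
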