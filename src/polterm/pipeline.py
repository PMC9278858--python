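"""Stage orchestration behind the CLI subcommands.

Each ``run_*`` function composes the module-level operations, writes its
output files under ``config.outdir`` and logs one structured line with the
stage counts (genes in, genes flagged, threshold value, ...), so exclusions
stay visible.
"""

from __future__ import annotations

import hashlib
import logging
import os
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from polterm import __version__
from polterm.config import PipelineConfig
from polterm.coverage import (
    CoverageTrack,
    load_coverage,
    normalize_cpm,
    read_chrom_sizes,
)
from polterm.genome_annotation import (
    GenomeSequence,
    TerminatorAnnotation,
    annotate_secondary_terminators,
    assign_primary_terminator,
    find_t_tracts,
    read_genes_bed,
    spacer_statistics,
    write_annotations_tsv,
    write_tracts_bed,
)
from polterm.rt_calling import (
    RTRegion,
    background_threshold,
    call_rt_region,
    write_rt_bed,
    write_rt_tsv,
)
from polterm import termination_stats as ts

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def _ensure_outdir(config: PipelineConfig) -> str:
    os.makedirs(config.outdir, exist_ok=True)
    return config.outdir


def _file_checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_provenance(config: PipelineConfig, stage: str) -> None:
    """Config echo + tool version + input checksums, one file per stage."""
    outdir = _ensure_outdir(config)
    lines = [f"tool_version\t{__version__}", f"stage\t{stage}"]
    for name in ("genome_fasta", "genes_bed", "coding_bed", "chrom_sizes"):
        path = getattr(config, name)
        if path and os.path.exists(path):
            lines.append(f"input\t{name}\t{path}\t{_file_checksum(path)}")
    for cond, files in config.coverage.items():
        for strand, path in files.items():
            if os.path.exists(path):
                lines.append(f"input\tcoverage.{cond}.{strand}\t{path}\t"
                             f"{_file_checksum(path)}")
    with open(os.path.join(outdir, f"provenance_{stage}.tsv"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    config.to_yaml(os.path.join(outdir, f"config_echo_{stage}.yaml"))


def build_annotations(config: PipelineConfig) -> List[TerminatorAnnotation]:
    """Scan the genome and annotate every gene's terminators."""
    if not config.genome_fasta or not os.path.exists(config.genome_fasta):
        raise FileNotFoundError(f"genome FASTA not found: {config.genome_fasta!r}")
    if not config.genes_bed or not os.path.exists(config.genes_bed):
        raise FileNotFoundError(f"genes BED not found: {config.genes_bed!r}")
    genome = GenomeSequence.from_fasta(config.genome_fasta)
    genes = read_genes_bed(config.genes_bed)
    tracts = find_t_tracts(genome, config.min_tract_len)
    annos = []
    for gene in genes:
        anno = assign_primary_terminator(gene, tracts, config.max_search_bp)
        if anno.primary is not None:
            annotate_secondary_terminators(anno, tracts, config.secondary_window)
        annos.append(anno)
    n_flagged = sum(1 for a in annos if a.primary is None)
    logger.info("annotate: genes_in=%d genes_flagged_no_primary=%d tracts=%d",
                len(genes), n_flagged, len(tracts))
    return annos


def run_annotate(config: PipelineConfig) -> Dict[str, str]:
    """``annotate`` stage: tract BED + annotation TSV + spacer summary."""
    annos = build_annotations(config)
    genome = GenomeSequence.from_fasta(config.genome_fasta)
    tracts = find_t_tracts(genome, config.min_tract_len)
    outdir = _ensure_outdir(config)
    write_provenance(config, "annotate")
    tract_bed = os.path.join(outdir, "t_tracts.bed")
    anno_tsv = os.path.join(outdir, "terminators.tsv")
    write_tracts_bed(tracts, tract_bed)
    write_annotations_tsv(annos, anno_tsv)
    stats = spacer_statistics(annos, config.spacer_cutoff)
    spacer_tsv = os.path.join(outdir, "spacer_stats.tsv")
    with open(spacer_tsv, "w") as fh:
        fh.write("key\tvalue\n")
        for key in ("n_genes", "n_with_primary", "n_spacer_le_cutoff", "cutoff_bp"):
            fh.write(f"{key}\t{stats[key]}\n")
        for spacer, count in stats["spacer_histogram"].items():
            fh.write(f"spacer_{spacer}\t{count}\n")
    return {"tracts": tract_bed, "annotations": anno_tsv, "spacer": spacer_tsv}


def load_condition_tracks(
    config: PipelineConfig, condition: str
) -> Tuple[CoverageTrack, CoverageTrack]:
    """Load and CPM-normalise the bedGraph pair of one condition."""
    if condition not in config.coverage:
        raise FileNotFoundError(f"no coverage files configured for condition "
                                f"{condition!r}")
    files = config.coverage[condition]
    sizes = read_chrom_sizes(config.chrom_sizes)
    plus, minus = load_coverage(files["plus"], files["minus"], sizes,
                                sample_id=condition, condition=condition)
    return normalize_cpm(plus, minus)


def run_rt(config: PipelineConfig, condition: str) -> Dict[str, object]:
    """``rt-call`` stage for one condition: threshold + per-gene RT regions."""
    annos = build_annotations(config)
    plus, minus = load_condition_tracks(config, condition)
    outdir = _ensure_outdir(config)
    write_provenance(config, f"rt_{condition}")
    coding = read_genes_bed(config.coding_bed, gene_class="coding")
    threshold = background_threshold(plus, minus, coding, config.window,
                                     config.quantile)
    regions: List[RTRegion] = []
    for anno in annos:
        if anno.primary is None:
            continue
        regions.append(
            call_rt_region(plus, minus, anno, threshold, config.rt_span,
                           config.window, config.step, config.max_gap)
        )
    n_empty = sum(1 for r in regions if r.empty)
    logger.info(
        "rt-call[%s]: genes_in=%d genes_called=%d genes_empty=%d threshold=%.6g",
        condition, len(annos), len(regions), n_empty, threshold.threshold_value)
    bed = os.path.join(outdir, f"rt_regions_{condition}.bed")
    tsv = os.path.join(outdir, f"rt_regions_{condition}.tsv")
    write_rt_bed(regions, bed)
    write_rt_tsv(regions, tsv, threshold)
    return {"bed": bed, "tsv": tsv, "threshold": threshold, "regions": regions,
            "annotations": annos}


def compute_condition_summaries(
    config: PipelineConfig,
    condition: str,
    annos: Optional[Sequence[TerminatorAnnotation]] = None,
) -> List[ts.TerminationSummary]:
    if annos is None:
        annos = build_annotations(config)
    plus, minus = load_condition_tracks(config, condition)
    coding = read_genes_bed(config.coding_bed, gene_class="coding")
    threshold = background_threshold(plus, minus, coding, config.window,
                                     config.quantile)
    summaries = []
    for anno in annos:
        if anno.primary is None:
            continue
        region = call_rt_region(plus, minus, anno, threshold, config.rt_span,
                                config.window, config.step, config.max_gap)
        summaries.append(ts.rt_index(plus, minus, anno, region, condition))
    return summaries


def run_stats(
    config: PipelineConfig,
    wt: str = "WT",
    mutant: str = "mutant",
    figures: bool = False,
) -> Dict[str, object]:
    """``stats`` stage: summaries, matrices, quartiles and group tests."""
    annos = build_annotations(config)
    outdir = _ensure_outdir(config)
    write_provenance(config, "stats")
    with_primary = [a for a in annos if a.primary is not None]

    summaries = {
        cond: compute_condition_summaries(config, cond, annos)
        for cond in (wt, mutant)
    }
    frame = pd.concat(
        [ts.summaries_to_frame(summaries[c]) for c in (wt, mutant)],
        ignore_index=True,
    )
    summary_tsv = os.path.join(outdir, "termination_summary.tsv")
    frame.to_csv(summary_tsv, sep="\t", index=False)

    wt_plus, wt_minus = load_condition_tracks(config, wt)
    mut_plus, mut_minus = load_condition_tracks(config, mutant)
    fc_plus = ts.log2_fold_change_track(mut_plus, wt_plus, config.pseudocount)
    fc_minus = ts.log2_fold_change_track(mut_minus, wt_minus, config.pseudocount)

    meta = {
        cond: ts.metagene_matrix(p.data, m.data, with_primary, config.body_bins)
        for cond, (p, m) in {wt: (wt_plus, wt_minus),
                             mutant: (mut_plus, mut_minus)}.items()
    }
    for cond, mat in meta.items():
        mat.to_csv(os.path.join(outdir, f"metagene_{cond}.tsv"), sep="\t")
    heat = ts.heatmap_matrix(fc_plus, fc_minus, with_primary, config.body_bins)
    heat.to_csv(os.path.join(outdir, "heatmap_log2fc.tsv"), sep="\t")

    quartiles = ts.rank_by_dependency(fc_plus, fc_minus, with_primary,
                                      config.dependency_window)
    qframe = pd.DataFrame(
        {"gene_id": [q.gene_id for q in quartiles],
         "dependency_score": [q.dependency_score for q in quartiles],
         "quartile": [q.quartile for q in quartiles]}
    )
    qframe.to_csv(os.path.join(outdir, "quartiles.tsv"), sep="\t", index=False)

    per_quartile = ts.terminators_per_quartile(quartiles, with_primary)
    per_quartile.to_csv(os.path.join(outdir, "terminators_per_quartile.tsv"),
                        sep="\t", index=False)

    by_id = {a.gene_id: a for a in with_primary}
    tests = {}
    for kind in ("weak", "strong"):
        groups = {
            q: [getattr(by_id[qa.gene_id], f"n_{kind}_secondary")
                for qa in quartiles if qa.quartile == q]
            for q in ("Q1", "Q2", "Q3", "Q4")
        }
        tests[kind] = ts.group_tests(groups)
    test_rows = []
    for kind, res in tests.items():
        test_rows.append({"metric": f"{kind}_secondary", "test": "kruskal",
                          "statistic": res["kruskal_H"], "pvalue": res["kruskal_p"]})
        for (a, b), p in res["pairwise"].items():
            test_rows.append({"metric": f"{kind}_secondary",
                              "test": f"mannwhitney_{a}_vs_{b}",
                              "statistic": np.nan, "pvalue": p})
    paired = {}
    wt_by_id = {s.gene_id: s for s in summaries[wt]}
    for metric, attr in (("rt_index", "rt_index"), ("rt_length", "rt_length_bp")):
        xs, ys = [], []
        for s in summaries[mutant]:
            o = wt_by_id.get(s.gene_id)
            if o is None:
                continue
            a, b = getattr(o, attr), getattr(s, attr)
            if a is None or b is None:
                continue
            xs.append(float(a))
            ys.append(float(b))
        res = ts.paired_wilcoxon(xs, ys)
        paired[metric] = res
        test_rows.append({"metric": metric, "test": "wilcoxon_paired_wt_vs_mut",
                          "statistic": res["statistic"], "pvalue": res["pvalue"]})
    pd.DataFrame(test_rows).to_csv(os.path.join(outdir, "group_tests.tsv"),
                                   sep="\t", index=False)

    by_len = {
        cond: ts.cluster_by_terminator_length(summaries[cond])
        for cond in (wt, mutant)
    }
    for cond, table in by_len.items():
        table.to_csv(os.path.join(outdir, f"rt_index_by_tract_length_{cond}.tsv"),
                     sep="\t", index=False)

    if figures:
        _write_figures(outdir, meta, heat)

    logger.info("stats: genes_in=%d genes_with_primary=%d", len(annos),
                len(with_primary))
    return {"summaries": summaries, "quartiles": quartiles, "tests": tests,
            "paired": paired, "heatmap": heat, "metagene": meta,
            "per_quartile": per_quartile, "by_length": by_len,
            "summary_tsv": summary_tsv}


def _write_figures(outdir: str, meta, heat) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        logger.warning("matplotlib unavailable; skipping figures")
        return
    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, mat in meta.items():
        ax.plot(mat.mean(axis=0).to_numpy(), label=cond)
    ax.set_xlabel("scaled position (bins)")
    ax.set_ylabel("mean signal")
    ax.legend()
    fig.savefig(os.path.join(outdir, "metagene.svg"))
    plt.close(fig)
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(heat.to_numpy(), aspect="auto", cmap="RdBu_r")
    fig.colorbar(im, ax=ax, label="log2 FC")
    ax.set_xlabel("scaled position (bins)")
    ax.set_ylabel("genes (ranked)")
    fig.savefig(os.path.join(outdir, "heatmap.svg"))
    plt.close(fig)
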