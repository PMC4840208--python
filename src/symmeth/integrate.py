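"""Methylation-expression integration, window profiles, and the pipeline.

The candidate list is the intersection rule of the study: a gene is a
candidate for methylation-mediated regulation iff it has at least one
methylation state change (coding or upstream) between conditions AND a
significant expression change (BH-adjusted p below the alpha convention).
"""
from __future__ import annotations

import json
import logging
import math
import re
from contextlib import contextmanager
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import percent
from .diffmeth import (
    GeneAssignment,
    assign_to_genes,
    diff_sites,
    diff_to_frame,
    gene_methylation_to_frame,
    regional_tally,
    summaries_to_frame,
    summarize_motif,
    tally_to_frame,
)
from .expression import (
    DE_ALPHA,
    DEFAULT_D0,
    collapse_spots,
    differential_expression,
    median_center,
    quantile_normalize,
    read_expression,
)
from .genome import (
    GenomicRegion,
    WindowProfile,
    gc_windows,
    load_annotation,
    load_annotation_gff3,
    load_genome,
    rotate_to_origin,
    upstream_regions,
    window_starts,
    write_bedgraph,
)
from .modcalls import SiteState, assign_states, qc_filter, read_modifications
from .motifs import default_motifs, load_motifs, scan_all

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntegrationCounts:
    """Headline counts of the methylation-expression intersection."""

    n_genes: int
    n_candidates_genome: int
    n_candidates_island: int
    n_island_genes: int
    pct_island: Optional[float]
    n_up_in_a: int
    n_up_in_b: int
    n_symbiosis_candidates: int


class PipelineError(RuntimeError):
    pass


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage {name!r}: {e}") from e


def integrate(
    gene_meth: GeneAssignment | Sequence,
    de: pd.DataFrame,
    genes: Sequence,
    island: GenomicRegion,
) -> pd.DataFrame:
    """One summary row per annotated gene, joining methylation-change counts
    with differential expression; genes missing from either input default to
    zero changes / non-significant (counts logged)."""
    per_gene = gene_meth.per_gene if isinstance(gene_meth, GeneAssignment) else list(gene_meth)
    meth = {g.gene_id: g for g in per_gene}
    gene_ids = [g.gene_id for g in genes]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids in annotation")
    de_idx = de.set_index("gene_id")
    if de_idx.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression results")
    n_no_de = sum(1 for g in gene_ids if g not in de_idx.index)
    if n_no_de:
        logger.info("%d genes missing from expression results", n_no_de)
    extra_meth = set(meth) - set(gene_ids)
    if extra_meth:
        raise ValueError(f"methylation records for unannotated genes: {sorted(extra_meth)[:5]}")
    rows = []
    for g in genes:
        gm = meth.get(g.gene_id)
        changes_coding = gm.changes_coding if gm else 0
        changes_upstream = gm.changes_upstream if gm else 0
        motifs_changed = sorted(gm.motifs_changed) if gm else []
        if g.gene_id in de_idx.index:
            log_fc = float(de_idx.at[g.gene_id, "log_fc"])
            adj_p = float(de_idx.at[g.gene_id, "adj_p"])
            significant = bool(de_idx.at[g.gene_id, "significant"])
        else:
            log_fc, adj_p, significant = 0.0, 1.0, False
        meth_changes = changes_coding + changes_upstream
        rows.append(
            {
                "gene_id": g.gene_id,
                "in_island": island.contains(g.start),
                "meth_changes": meth_changes,
                "changes_coding": changes_coding,
                "changes_upstream": changes_upstream,
                "motifs_changed": ";".join(motifs_changed),
                "log_fc": log_fc,
                "adj_p": adj_p,
                "de_significant": significant,
                "candidate": bool(meth_changes >= 1 and significant),
                "is_symbiosis_gene": g.is_symbiosis_gene,
                "product": g.product,
            }
        )
    return pd.DataFrame(rows)


def integration_counts(
    summaries: pd.DataFrame, island_gene_count: Optional[int] = None
) -> IntegrationCounts:
    """Headline candidate counts and the island percentage (1 decimal)."""
    cand = summaries[summaries["candidate"]]
    n_island_genes = (
        int(summaries["in_island"].sum())
        if island_gene_count is None
        else int(island_gene_count)
    )
    n_candidates_island = int((cand["in_island"]).sum())
    if n_island_genes == 0:
        if n_candidates_island > 0:
            raise ValueError("island candidates reported but zero island genes")
        pct_island = None
    else:
        pct_island = percent(n_candidates_island, n_island_genes, 1)
    return IntegrationCounts(
        n_genes=len(summaries),
        n_candidates_genome=int(len(cand)),
        n_candidates_island=n_candidates_island,
        n_island_genes=n_island_genes,
        pct_island=pct_island,
        n_up_in_a=int((cand["log_fc"] > 0).sum()),
        n_up_in_b=int((cand["log_fc"] < 0).sum()),
        n_symbiosis_candidates=int(cand["is_symbiosis_gene"].sum()),
    )


def annotated_fraction(n_annotated: int, n_total: int) -> float:
    """Percent of genes carrying an annotation, 1 decimal, half-up."""
    if n_total <= 0:
        raise ValueError("total gene count must be positive")
    if n_annotated > n_total:
        raise ValueError("annotated count exceeds total")
    return percent(n_annotated, n_total, 1)


def methylation_windows(
    states: Sequence[SiteState],
    genome_length: int,
    circular: bool = True,
    window: int = 1000,
    step: int = 100,
) -> list[WindowProfile]:
    """Fraction of methylated sites per overlapping sliding window for one
    motif and condition.  Windows containing no sites carry NaN (a 0/0
    proportion is undefined, not zero)."""
    starts = window_starts(genome_length, window, step, circular)
    pos = np.array([s.site.position for s in states], dtype=np.int64)
    meth = np.array([1 if s.methylated else 0 for s in states], dtype=np.int64)
    order = np.argsort(pos, kind="stable")
    pos, meth = pos[order], meth[order]
    if circular:
        pos = np.concatenate([pos, pos + genome_length])
        meth = np.concatenate([meth, meth])
    cum = np.concatenate([[0], np.cumsum(meth)])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + window - 1, side="right")
    out = []
    for s, i, j in zip(starts, lo, hi):
        n = int(j - i)
        value = float(cum[j] - cum[i]) / n if n > 0 else math.nan
        out.append(WindowProfile(int(s), window, value, n_sites=n))
    return out


def _safe_name(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "", name.replace("(N)", "N"))


_CONFIG_DEFAULTS = {
    "circular": True,
    "rotate_to_origin": False,
    "condition_a": "free_living",
    "condition_b": "bacteroid",
    "motifs": None,
    "include_m4c": False,
    "min_coverage": 25,
    "min_qv": 30,
    "window_size": 1000,
    "window_step": 100,
    "upstream_max_len": 500,
    "de_alpha": DE_ALPHA,
    "d0": DEFAULT_D0,
    "quantile_normalize": True,
    "median_center": True,
    "counting_mode": "per_strand",
    "arrays": None,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """End-to-end run: scan, per-condition states, differential methylation,
    expression testing, integration, window tracks, run log.

    Returns the output directory.  Reruns with identical config and inputs
    produce byte-identical tables.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = dict(_CONFIG_DEFAULTS)
    cfg.update(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("load_genome"):
        genome = load_genome(cfg["genome_fasta"], circular=cfg["circular"])
        if cfg["rotate_to_origin"]:
            genome = rotate_to_origin(genome)
    with _stage("load_annotation"):
        if "annotation_gff3" in cfg and cfg.get("annotation_gff3"):
            genes = load_annotation_gff3(cfg["annotation_gff3"], genome)
        else:
            genes = load_annotation(cfg["annotation"], genome)
        upstream = upstream_regions(genes, genome, cfg["upstream_max_len"])
    with _stage("island"):
        island = GenomicRegion(
            int(cfg["island_start"]), int(cfg["island_end"]), "symbiosis_island"
        )
        if island.end > len(genome):
            raise ValueError("island outside genome")
    with _stage("motifs"):
        motifs = load_motifs(cfg["motifs"]) if cfg["motifs"] else default_motifs()
        diff_motifs = [
            m for m in motifs if cfg["include_m4c"] or m.mod_type == "m6A"
        ]
    with _stage("scan"):
        sites = scan_all(genome, motifs)

    cond_a, cond_b = cfg["condition_a"], cfg["condition_b"]
    states: dict[str, dict[str, list[SiteState]]] = {}
    for cond, key in ((cond_a, "mods_a"), (cond_b, "mods_b")):
        with _stage(f"modifications[{cond}]"):
            if key not in cfg:
                raise ValueError(f"config missing {key!r}")
            raw = read_modifications(cfg[key])
            kept = qc_filter(raw, cfg["min_coverage"], cfg["min_qv"])
            rejected = [r for r in raw if r not in kept]
            flat_sites = [s for m in motifs for s in sites[m.name]]
            assigned = assign_states(flat_sites, kept, cond, motifs, rejected)
            by_motif: dict[str, list[SiteState]] = {m.name: [] for m in motifs}
            for st in assigned:
                by_motif[st.site.motif_name].append(st)
            states[cond] = by_motif

    with _stage("motif_summary"):
        summary_rows = []
        summaries = {}
        for cond in (cond_a, cond_b):
            for m in motifs:
                s = summarize_motif(states[cond][m.name], m)
                summaries[(cond, m.name)] = s
                summary_rows.append((cond, s))
        summary_df = summaries_to_frame(summary_rows)
        _write_tsv(summary_df, out / "motif_summary.tsv")

    with _stage("differential_methylation"):
        states_a = [s for m in diff_motifs for s in states[cond_a][m.name]]
        states_b = [s for m in diff_motifs for s in states[cond_b][m.name]]
        diff = diff_sites(states_a, states_b)
        _write_tsv(diff_to_frame(diff), out / "diff_sites.tsv")
        assignment = assign_to_genes(diff, genes, upstream)
        _write_tsv(gene_methylation_to_frame(assignment), out / "gene_methylation.tsv")
        tallies = regional_tally(diff, island, genes, upstream, len(genome))
        _write_tsv(tally_to_frame(tallies), out / "regional_tally.tsv")

    with _stage("expression"):
        arrays = cfg["arrays"]
        if arrays is None:
            header = pd.read_csv(cfg["expression"], sep="\t", nrows=0)
            arrays = {}
            for col in header.columns:
                if col in ("gene_id", "spot_id"):
                    continue
                if col.startswith(cond_a):
                    arrays[col] = cond_a
                elif col.startswith(cond_b):
                    arrays[col] = cond_b
                else:
                    raise ValueError(
                        f"array {col!r} matches neither condition; supply 'arrays'"
                    )
        matrix = read_expression(cfg["expression"], arrays)
        if cfg["median_center"]:
            matrix = median_center(matrix)
        if cfg["quantile_normalize"]:
            matrix = quantile_normalize(matrix)
        matrix = collapse_spots(matrix)
        de = differential_expression(
            matrix, cond_a, cond_b, alpha=cfg["de_alpha"], d0=cfg["d0"]
        )
        _write_tsv(de, out / "de_results.tsv")

    with _stage("integration"):
        gene_summaries = integrate(assignment, de, genes, island)
        _write_tsv(gene_summaries, out / "gene_summaries.tsv")
        counts = integration_counts(gene_summaries)
        with open(out / "integration_counts.json", "w") as fh:
            json.dump(asdict(counts), fh, indent=1, sort_keys=True)

    with _stage("windows"):
        wdir = out / "windows"
        wdir.mkdir(exist_ok=True)
        gc = gc_windows(genome, cfg["window_size"], cfg["window_step"])
        write_bedgraph(gc, wdir / "gc.bedgraph", genome.name, len(genome), "GC")
        for cond in (cond_a, cond_b):
            for m in diff_motifs:
                prof = methylation_windows(
                    states[cond][m.name],
                    len(genome),
                    genome.circular,
                    cfg["window_size"],
                    cfg["window_step"],
                )
                fname = f"meth_{_safe_name(m.name)}_{_safe_name(cond)}.bedgraph"
                write_bedgraph(
                    prof, wdir / fname, genome.name, len(genome),
                    f"{m.name} {cond}",
                )

    with _stage("run_log"):
        with open(out / "run_log.txt", "w") as fh:
            fh.write(f"symmeth {__version__}\n")
            for k in sorted(cfg):
                fh.write(f"{k} = {cfg[k]!r}\n")
            fh.write(f"genome_length = {len(genome)}\n")
            fh.write(f"n_genes = {len(genes)}\n")
            fh.write(f"n_diff_sites = {len(diff)}\n")
            fh.write(
                f"n_changed = {sum(1 for d in diff if d.changed)}\n"
            )
            fh.write(f"intergenic_changes = {assignment.n_intergenic}\n")
            fh.write(f"n_candidates = {int(gene_summaries['candidate'].sum())}\n")
    return out


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
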