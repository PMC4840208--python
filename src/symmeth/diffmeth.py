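"""Differential methylation between two conditions.

Per-site state comparison (gain / loss / unchanged), Table-style per-motif
summaries, per-gene change counts over coding and upstream compartments, and
regional tallies (whole genome / symbiosis island / remainder) with per-kb
normalisation.  A "methylation change" is a per-site state flip between
conditions; call magnitudes are deliberately not used.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from ._util import percent
from .genome import GeneAnnotation, GenomicRegion
from .modcalls import SiteState
from .motifs import MotifSite, MotifSpec


@dataclass(frozen=True)
class DiffSite:
    """Methylation state of one site in both conditions."""

    site: MotifSite
    state_a: str
    state_b: str

    @property
    def change(self) -> str:
        if self.state_a == self.state_b:
            return "unchanged"
        return "gain" if self.state_b == "methylated" else "loss"

    @property
    def changed(self) -> bool:
        return self.state_a != self.state_b


@dataclass(frozen=True)
class MotifSummary:
    """One row of the per-motif methylation summary table."""

    motif_name: str
    modified_position: int
    mod_type: str
    n_motifs: int
    n_methylated: int
    pct_methylated: Optional[float]
    mean_qv: Optional[float]
    mean_coverage: Optional[float]
    mean_ipd: Optional[float]


@dataclass(frozen=True)
class RegionalTally:
    """Changed/methylated site counts in one region x compartment x motif."""

    region_label: str     # genome | island | rest
    compartment: str      # coding | upstream | all
    motif_name: str
    n_sites: int
    n_methylated_a: int
    n_methylated_b: int
    n_changed: int
    compartment_bp: int
    sites_per_kb: Optional[float]
    changed_per_kb: Optional[float]


@dataclass
class GeneMethylation:
    """Per-gene methylation-change record."""

    gene_id: str
    changes_coding: int = 0
    changes_upstream: int = 0
    motifs_changed: set[str] = field(default_factory=set)

    @property
    def total_changes(self) -> int:
        return self.changes_coding + self.changes_upstream


@dataclass(frozen=True)
class GeneAssignment:
    per_gene: list[GeneMethylation]
    n_intergenic: int


def _site_key(s: MotifSite) -> tuple[str, int, str]:
    return (s.motif_name, s.position, s.strand)


def diff_sites(
    states_a: Sequence[SiteState], states_b: Sequence[SiteState]
) -> list[DiffSite]:
    """Pair the two per-condition state vectors site by site."""
    a = {_site_key(s.site): s for s in states_a}
    b = {_site_key(s.site): s for s in states_b}
    if set(a) != set(b):
        only_a = len(set(a) - set(b))
        only_b = len(set(b) - set(a))
        raise ValueError(
            f"site sets differ between conditions ({only_a} only in A, "
            f"{only_b} only in B)"
        )
    out = [
        DiffSite(site=a[k].site, state_a=a[k].state, state_b=b[k].state)
        for k in sorted(a)
    ]
    return out


def summarize_motif(states: Sequence[SiteState], motif: MotifSpec) -> MotifSummary:
    """Counts, percent methylated (2 decimals) and QC means over methylated
    sites of one motif in one condition."""
    for s in states:
        if s.site.motif_name != motif.name:
            raise ValueError(
                f"state for {s.site.motif_name!r} passed to summary of {motif.name!r}"
            )
    n = len(states)
    meth = [s for s in states if s.methylated]
    if n == 0:
        return MotifSummary(
            motif.name, motif.modified_offset, motif.mod_type, 0, 0,
            None, None, None, None,
        )
    recs = [s.record for s in meth]
    mean = lambda xs: (sum(xs) / len(xs)) if xs else None
    return MotifSummary(
        motif_name=motif.name,
        modified_position=motif.modified_offset,
        mod_type=motif.mod_type,
        n_motifs=n,
        n_methylated=len(meth),
        pct_methylated=percent(len(meth), n, 2),
        mean_qv=mean([r.mod_qv for r in recs]),
        mean_coverage=mean([float(r.coverage) for r in recs]),
        mean_ipd=mean([r.ipd_ratio for r in recs]),
    )


def methylation_loss(summary_a: MotifSummary, summary_b: MotifSummary) -> int:
    """Signed drop in methylated-site count from condition A to B."""
    if summary_a.motif_name != summary_b.motif_name:
        raise ValueError("summaries are for different motifs")
    if summary_a.n_motifs != summary_b.n_motifs:
        raise ValueError("summaries cover different site universes")
    return summary_a.n_methylated - summary_b.n_methylated


def _compartment_trees(
    genes: Sequence[GeneAnnotation],
    upstream: dict[str, Optional[GenomicRegion]],
) -> IntervalTree:
    tree = IntervalTree()
    for g in genes:
        tree.addi(g.start, g.end + 1, (g.gene_id, "coding"))
    for gid, region in upstream.items():
        if region is not None:
            tree.addi(region.start, region.end + 1, (gid, "upstream"))
    return tree


def assign_to_genes(
    diff: Sequence[DiffSite],
    genes: Sequence[GeneAnnotation],
    upstream: dict[str, Optional[GenomicRegion]],
) -> GeneAssignment:
    """Attribute each changed site to every gene whose coding or upstream
    region contains it (shared intergenic gaps count toward both flanking
    genes); sites in no region are tallied as intergenic."""
    tree = _compartment_trees(genes, upstream)
    per_gene: dict[str, GeneMethylation] = {}
    n_intergenic = 0
    for d in diff:
        if not d.changed:
            continue
        hits = tree[d.site.position]
        if not hits:
            n_intergenic += 1
            continue
        for iv in hits:
            gid, compartment = iv.data
            gm = per_gene.setdefault(gid, GeneMethylation(gid))
            if compartment == "coding":
                gm.changes_coding += 1
            else:
                gm.changes_upstream += 1
            gm.motifs_changed.add(d.site.motif_name)
    ordered = [per_gene[g.gene_id] for g in genes if g.gene_id in per_gene]
    return GeneAssignment(per_gene=ordered, n_intergenic=n_intergenic)


def _merged_length(intervals: list[tuple[int, int]], clip: GenomicRegion) -> int:
    """Total bp of the union of inclusive intervals clipped to a region."""
    clipped = sorted(
        (max(s, clip.start), min(e, clip.end))
        for s, e in intervals
        if s <= clip.end and e >= clip.start
    )
    total, cur_s, cur_e = 0, None, None
    for s, e in clipped:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def regional_tally(
    diff: Sequence[DiffSite],
    island: GenomicRegion,
    genes: Sequence[GeneAnnotation],
    upstream: dict[str, Optional[GenomicRegion]],
    genome_length: int,
) -> list[RegionalTally]:
    """Tallies for genome/island/rest x coding/upstream/all x motif.

    The 'all' compartment covers every site in the region, including
    intergenic ones; per-kb values are normalised by the merged compartment
    length inside the region.
    """
    if island.end > genome_length:
        raise ValueError("island outside genome")
    regions = {
        "genome": GenomicRegion(1, genome_length, "genome"),
        "island": island,
        # 'rest' handled by exclusion below
    }
    coding_iv = [(g.start, g.end) for g in genes]
    upstream_iv = [(r.start, r.end) for r in upstream.values() if r is not None]
    tree = _compartment_trees(genes, upstream)
    motif_names = sorted({d.site.motif_name for d in diff})

    def in_region(pos: int, label: str) -> bool:
        if label == "genome":
            return True
        if label == "island":
            return island.contains(pos)
        return not island.contains(pos)

    def region_bp(label: str, intervals: list[tuple[int, int]]) -> int:
        if label == "rest":
            whole = _merged_length(intervals, GenomicRegion(1, genome_length))
            return whole - _merged_length(intervals, island)
        return _merged_length(intervals, regions[label])

    out: list[RegionalTally] = []
    for label in ("genome", "island", "rest"):
        for compartment in ("coding", "upstream", "all"):
            if compartment == "coding":
                bp = region_bp(label, coding_iv)
            elif compartment == "upstream":
                bp = region_bp(label, upstream_iv)
            else:
                if label == "rest":
                    bp = genome_length - island.length_bp
                else:
                    bp = regions[label].length_bp
            for motif in motif_names:
                n_sites = n_a = n_b = n_changed = 0
                for d in diff:
                    if d.site.motif_name != motif:
                        continue
                    pos = d.site.position
                    if not in_region(pos, label):
                        continue
                    if compartment != "all":
                        hits = tree[pos]
                        if not any(h.data[1] == compartment for h in hits):
                            continue
                    n_sites += 1
                    n_a += d.state_a == "methylated"
                    n_b += d.state_b == "methylated"
                    n_changed += d.changed
                out.append(
                    RegionalTally(
                        region_label=label,
                        compartment=compartment,
                        motif_name=motif,
                        n_sites=n_sites,
                        n_methylated_a=n_a,
                        n_methylated_b=n_b,
                        n_changed=n_changed,
                        compartment_bp=bp,
                        sites_per_kb=(1000.0 * n_sites / bp) if bp > 0 else None,
                        changed_per_kb=(1000.0 * n_changed / bp) if bp > 0 else None,
                    )
                )
    return out


def gain_loss_binomtest(diff: Sequence[DiffSite]) -> Optional[float]:
    """Optional extra (off by default in the pipeline): two-sided binomial
    test of gain/loss symmetry among changed sites."""
    from scipy.stats import binomtest

    gains = sum(1 for d in diff if d.change == "gain")
    losses = sum(1 for d in diff if d.change == "loss")
    if gains + losses == 0:
        return None
    return binomtest(gains, gains + losses, 0.5).pvalue


def summaries_to_frame(
    summaries: Iterable[tuple[str, MotifSummary]]
) -> pd.DataFrame:
    """Rows (condition, summary) -> table shaped like the published motif summary."""
    rows = []
    for condition, s in summaries:
        rows.append(
            {
                "condition": condition,
                "motif": s.motif_name,
                "modified_position": s.modified_position,
                "mod_type": s.mod_type,
                "pct_methylated": s.pct_methylated,
                "n_methylated": s.n_methylated,
                "n_motifs": s.n_motifs,
                "mean_qv": s.mean_qv,
                "mean_coverage": s.mean_coverage,
                "mean_ipd_ratio": s.mean_ipd,
            }
        )
    return pd.DataFrame(rows)


def diff_to_frame(diff: Sequence[DiffSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": d.site.motif_name,
                "position": d.site.position,
                "strand": d.site.strand,
                "state_a": d.state_a,
                "state_b": d.state_b,
                "change": d.change,
            }
            for d in diff
        ]
    )


def gene_methylation_to_frame(assignment: GeneAssignment) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "changes_coding": g.changes_coding,
                "changes_upstream": g.changes_upstream,
                "total_changes": g.total_changes,
                "motifs_changed": ";".join(sorted(g.motifs_changed)),
            }
            for g in assignment.per_gene
        ]
    )


def tally_to_frame(tallies: Sequence[RegionalTally]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in tallies])
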