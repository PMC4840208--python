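"""Synthetic data with full ground truth for every pipeline stage.

The generator emulates the study system: a GC-rich (~64%) circular genome
carrying a lower-GC island, planted occurrences of the five methylated
motifs, two-condition per-site methylation states drawn from the published
per-motif rates (including a condition-exclusive motif methylated only in
the endosymbiotic state), modification calls with realistic coverage/modQV
noise, and a two-condition spotted expression matrix with planted log2 fold
changes recycled from the published candidate-gene effect sizes.

Everything derives deterministically from (seed, config): identical inputs
give byte-identical output files.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diffmeth import DiffSite, assign_to_genes
from .expression import ExpressionMatrix, write_expression
from .genome import (
    GeneAnnotation,
    GenomeSequence,
    GenomicRegion,
    upstream_regions,
    write_annotation,
    write_genome,
)
from .modcalls import ModificationRecord, write_modifications
from .motifs import (
    IUPAC_CLASSES,
    MotifSite,
    MotifSpec,
    default_motifs,
    scan,
    scan_all,
)

#: Published per-motif methylation probabilities, free-living condition.
RATES_FREE_LIVING = {
    "GANTC": 0.9977,
    "CRAGGAT": 0.9995,
    "GAGA(N)6RTG": 1.0,
    "CAY(N)6TCTC": 0.9995,
    "CCTTGAG": 0.0,
}

#: Published per-motif methylation probabilities, bacteroid condition.
RATES_BACTEROID = {
    "GANTC": 0.9746,
    "CRAGGAT": 0.8749,
    "GAGA(N)6RTG": 0.8260,
    "CAY(N)6TCTC": 0.8606,
    "CCTTGAG": 0.8006,
}

#: Published candidate-gene log2 fold changes, recycled as planted effects.
DE_EFFECTS = (3.06, 5.49, 4.60, 5.06, 4.55, 1.23, 0.89, 5.73, 0.78)


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_len: int = 100_000
    gc_background: float = 0.64
    island_start: int = 30_001
    island_end: int = 45_000
    gc_island: float = 0.59
    gene_len: int = 900
    gene_gap: int = 300
    condition_a: str = "free_living"
    condition_b: str = "bacteroid"
    motif_rates_a: dict = field(default_factory=lambda: dict(RATES_FREE_LIVING))
    motif_rates_b: dict = field(default_factory=lambda: dict(RATES_BACTEROID))
    # Explicit planting keeps rare 7-13-mer motifs at usable site counts on a
    # 100-kb genome (the i.i.d. expectation is only ~10-20 sites).
    min_sites_per_motif: int = 400
    coverage_mean_a: float = 130.0
    coverage_mean_b: float = 64.0
    qv_mean_a: float = 136.0
    qv_mean_b: float = 85.0
    qv_noise: float = 15.0
    ipd_mean: float = 4.5
    ipd_sd: float = 0.5
    subthreshold_frac: float = 0.0
    arrays_per_condition: int = 3
    spots_per_gene: int = 2
    expression_baseline_mean: float = 8.0
    expression_baseline_sd: float = 1.5
    expression_sigma: float = 0.25
    de_fraction: float = 0.3
    de_effects: tuple = DE_EFFECTS
    de_sign_balanced: bool = True
    upstream_max_len: int = 500
    # Planted effects below this magnitude are kept out of the expected
    # candidate set: at the default design (3 arrays/condition, sigma 0.25)
    # they are not reliably detectable at adjusted p < 0.001.
    truth_min_lfc: float = 2.0

    def __post_init__(self) -> None:
        if not (1 <= self.island_start <= self.island_end <= self.genome_len):
            raise ValueError("island must lie within the genome")
        for rates in (self.motif_rates_a, self.motif_rates_b):
            for name, p in rates.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"rate for {name} outside [0, 1]")

    @property
    def island(self) -> GenomicRegion:
        return GenomicRegion(self.island_start, self.island_end, "symbiosis_island")


@dataclass
class GroundTruth:
    """Planted truth, keyed by 'motif|position|strand' site strings."""

    site_states: dict  # condition -> {site_key: bool methylated}
    subthreshold: dict  # condition -> [site_key, ...]
    gene_effects: dict  # gene_id -> planted log2 fold change (A minus B)
    expected_candidates: list  # detectable planted candidates (power screen)
    candidates_all: list  # every planted meth-change x DE gene
    meth_changed_genes: list

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeSequence
    genes: list
    motifs: list
    sites: dict  # motif name -> list[MotifSite]
    records: dict  # condition -> list[ModificationRecord]
    expression: ExpressionMatrix
    truth: GroundTruth


def site_key(site: MotifSite) -> str:
    return f"{site.motif_name}|{site.position}|{site.strand}"


def _sample_bases(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)


def _realize(iupac: str, rng: np.random.Generator) -> str:
    return "".join(
        c if len(IUPAC_CLASSES[c]) == 1 else IUPAC_CLASSES[c][rng.integers(len(IUPAC_CLASSES[c]))]
        for c in iupac
    )


def simulate_genome(
    config: SimulationConfig,
    rng: np.random.Generator,
    plant: bool = True,
) -> tuple[GenomeSequence, list[GeneAnnotation]]:
    """I.i.d. bases at the background GC outside the island and the island GC
    inside it, optional motif planting, and a non-overlapping gene tiling."""
    L = config.genome_len
    arr = _sample_bases(L, config.gc_background, rng)
    isl = config.island
    arr[isl.start - 1 : isl.end] = _sample_bases(
        isl.length_bp, config.gc_island, rng
    )
    genome = GenomeSequence("sim", arr.tobytes().decode("ascii"), circular=True)

    if plant and config.min_sites_per_motif > 0:
        genome = _plant_motifs(genome, config, rng)
        genome = _remove_shared_bases(genome, rng)

    genes: list[GeneAnnotation] = []
    pos = config.gene_gap + 1
    i = 0
    while pos + config.gene_len - 1 <= L:
        i += 1
        strand = "+" if rng.integers(2) == 0 else "-"
        start, end = pos, pos + config.gene_len - 1
        in_island = isl.contains(start)
        symbiosis = bool(in_island and rng.random() < 0.3)
        prefix = "blr" if strand == "+" else "bll"
        product = (
            "nodulation protein" if symbiosis
            else ("hypothetical protein" if rng.random() < 0.5 else "putative enzyme")
        )
        genes.append(
            GeneAnnotation(
                gene_id=f"{prefix}{i:04d}",
                start=start,
                end=end,
                strand=strand,
                product=product,
                is_symbiosis_gene=symbiosis,
            )
        )
        pos = end + config.gene_gap + 1
    return genome, genes


def _plant_motifs(
    genome: GenomeSequence, config: SimulationConfig, rng: np.random.Generator
) -> GenomeSequence:
    """Overwrite random well-spaced loci with concrete motif realisations
    until every motif reaches min_sites_per_motif strand-specific sites.

    One planted GANTC occurrence contributes a site on each strand
    (palindrome); one planted GAGA(N)6RTG occurrence contributes one
    GAGA(N)6RTG site and one CAY(N)6TCTC site (two strands of one duplex
    motif); the asymmetric 7-mers contribute one site each.
    """
    motifs = {m.name: m for m in default_motifs(include_m4c=False)}
    target = config.min_sites_per_motif
    counts = {name: len(scan(genome, m)) for name, m in motifs.items()}
    need: list[tuple[str, int]] = []  # (iupac to plant, occurrences)
    gantc_deficit = max(0, target - counts["GANTC"])
    need.append(("GANTC", (gantc_deficit + 1) // 2))
    need.append(("CRAGGAT", max(0, target - counts["CRAGGAT"])))
    bipartite = max(
        max(0, target - counts["GAGA(N)6RTG"]),
        max(0, target - counts["CAY(N)6TCTC"]),
    )
    need.append(("GAGANNNNNNRTG", bipartite))
    need.append(("CCTTGAG", max(0, target - counts["CCTTGAG"])))

    total = sum(n for _, n in need)
    if total == 0:
        return genome
    spacing = 25
    slots = np.arange(0, config.genome_len - spacing, spacing)
    if total > len(slots):
        raise ValueError("genome too small for requested motif planting")
    chosen = rng.choice(slots, size=total, replace=False)
    arr = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8).copy()
    k = 0
    for iupac, n_occ in need:
        for _ in range(n_occ):
            s0 = int(chosen[k])
            k += 1
            word = _realize(iupac, rng).encode("ascii")
            arr[s0 : s0 + len(word)] = np.frombuffer(word, dtype=np.uint8)
    return GenomeSequence(genome.name, arr.tobytes().decode("ascii"), circular=True)


#: Which motif keeps its occurrence when two motifs' methylatable bases
#: coincide (rarer, planted motifs win; the abundant palindrome yields).
_KEEP_PRIORITY = {
    "CCTTGAG": 0,
    "GAGA(N)6RTG": 1,
    "CAY(N)6TCTC": 1,
    "CRAGGAT": 2,
    "CRAGGAT-m4C": 2,
    "GANTC": 3,
}


def _remove_shared_bases(
    genome: GenomeSequence, rng: np.random.Generator, max_iter: int = 30
) -> GenomeSequence:
    """Mutate the genome until no two motifs share a methylatable base.

    A genomic base carries a single methylation state, so per-motif rates are
    only well defined when motif site sets are disjoint at the base level.
    Chance overlaps (e.g. CCTTGAGTC embeds a GANTC whose adenine is the
    CCTTGAG target) are resolved by point-mutating the lower-priority
    occurrence at a position that is degenerate (or absent) in every other
    occurrence, then re-scanning.
    """
    from .motifs import reverse_complement

    motifs = default_motifs(include_m4c=True)
    spec = {m.name: m for m in motifs}
    L = len(genome)
    seq = genome.sequence
    for _ in range(max_iter):
        g = GenomeSequence(genome.name, seq, circular=True)
        sites = scan_all(g, motifs)
        by_base: dict[tuple[int, str, str], list[MotifSite]] = {}
        for m in motifs:
            for s in sites[m.name]:
                by_base.setdefault((s.position, s.strand, m.mod_type), []).append(s)
        collided = {
            k: v for k, v in by_base.items() if len({s.motif_name for s in v}) > 1
        }
        if not collided:
            return g

        # One genomic word can back several site records (both strands of a
        # palindrome, both mod types of CRAGGAT, both strands of the
        # bipartite duplex); identify occurrences by their forward-projected
        # pattern and start so a word never blocks its own mutation.
        def word(s: MotifSite) -> tuple[str, int]:
            pat = spec[s.motif_name].iupac
            if s.strand == "-":
                pat = reverse_complement(pat)
            return (pat, s.match_start)

        # positions where some occurrence requires a specific base class
        specific: dict[int, set[tuple[str, int]]] = {}
        for m in motifs:
            for s in sites[m.name]:
                pat, start = word(s)
                for i, c in enumerate(pat):
                    if len(IUPAC_CLASSES[c]) < 4:
                        p = (start + i - 1) % L + 1
                        specific.setdefault(p, set()).add((pat, start))
        arr = bytearray(seq.encode("ascii"))
        dirty: set[int] = set()
        for key in sorted(collided):
            group = sorted(
                collided[key],
                key=lambda s: (_KEEP_PRIORITY.get(s.motif_name, 9), s.motif_name),
            )
            victim = group[-1]
            pat, start = word(victim)
            span = [((start + i - 1) % L + 1) for i in range(len(pat))]
            if any(p in dirty for p in span):
                continue  # resolved (or re-checked) next iteration
            for i, p in enumerate(span):
                cls = IUPAC_CLASSES[pat[i]]
                if len(cls) == 4:
                    continue  # spacer position cannot break the pattern
                others = specific.get(p, set()) - {(pat, start)}
                if others:
                    continue  # would damage another occurrence
                choices = [b for b in "ACGT" if b not in cls]
                arr[p - 1] = ord(choices[rng.integers(len(choices))])
                dirty.update(span)
                break
        seq = arr.decode("ascii")
    return GenomeSequence(genome.name, seq, circular=True)


def simulate_modifications(
    sites: dict[str, list[MotifSite]],
    motifs: Sequence[MotifSpec],
    config: SimulationConfig,
    condition: str,
    rng: np.random.Generator,
) -> tuple[list[ModificationRecord], dict[str, bool], list[str]]:
    """Draw per-site methylation states and emit one call per methylated base.

    Returns (records, truth states keyed by site string, sub-threshold site
    keys).  Sites of different motifs that share a genomic base (overlapping
    occurrences, same modification type) are drawn once and share one record.
    """
    if condition == config.condition_a:
        rates, cov_mean, qv_mean = (
            config.motif_rates_a, config.coverage_mean_a, config.qv_mean_a,
        )
    elif condition == config.condition_b:
        rates, cov_mean, qv_mean = (
            config.motif_rates_b, config.coverage_mean_b, config.qv_mean_b,
        )
    else:
        raise ValueError(f"unknown condition {condition!r}")
    mod_type_of = {m.name: m.mod_type for m in motifs}

    by_base: dict[tuple[int, str, str], list[MotifSite]] = {}
    for name in sorted(sites):
        for s in sites[name]:
            by_base.setdefault((s.position, s.strand, mod_type_of[name]), []).append(s)

    records: list[ModificationRecord] = []
    truth: dict[str, bool] = {}
    sub: list[str] = []
    for key in sorted(by_base):
        group = by_base[key]
        rate = rates.get(group[0].motif_name, 0.0)
        methylated = bool(rng.random() < rate)
        for s in group:
            truth[site_key(s)] = methylated
        if not methylated:
            continue
        subthreshold = bool(rng.random() < config.subthreshold_frac)
        if subthreshold:
            qv = float(rng.uniform(5.0, 29.0))
            coverage = int(rng.integers(5, 25))
            for s in group:
                sub.append(site_key(s))
        else:
            qv = max(0.0, float(rng.normal(qv_mean, config.qv_noise)))
            coverage = max(1, int(round(rng.normal(cov_mean, 0.2 * cov_mean))))
        ipd = max(1.01, float(rng.normal(config.ipd_mean, config.ipd_sd)))
        pos, strand, mod_type = key
        records.append(
            ModificationRecord(pos, strand, mod_type, round(qv), coverage, ipd)
        )
    return records, truth, sub


def simulate_expression(
    gene_ids: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, dict[str, float]]:
    """Spotted log2 intensities for two conditions with planted fold changes.

    Baselines ~ N(8, 1.5); a de_fraction of genes receive additive effects
    recycled from the published candidate logFC values, split symmetrically
    between conditions (+lfc/2 in A, -lfc/2 in B) with alternating signs when
    balanced.  Per-spot, per-array noise ~ N(0, expression_sigma).
    """
    n = len(gene_ids)
    arrays = [f"{config.condition_a}_{i + 1}" for i in range(config.arrays_per_condition)]
    arrays += [f"{config.condition_b}_{i + 1}" for i in range(config.arrays_per_condition)]
    conditions = {
        a: (config.condition_a if a.startswith(config.condition_a) else config.condition_b)
        for a in arrays
    }
    baseline = rng.normal(
        config.expression_baseline_mean, config.expression_baseline_sd, size=n
    )
    lfc = np.zeros(n)
    k = int(round(config.de_fraction * n))
    if k > 0:
        chosen = np.sort(rng.choice(n, size=k, replace=False))
        effects = [config.de_effects[i % len(config.de_effects)] for i in range(k)]
        signs = [1.0 if (i % 2 == 0 or not config.de_sign_balanced) else -1.0 for i in range(k)]
        lfc[chosen] = np.array(effects) * np.array(signs)
    half = {a: (lfc / 2 if conditions[a] == config.condition_a else -lfc / 2) for a in arrays}
    rows = []
    index = []
    for gi, gid in enumerate(gene_ids):
        for spot in range(config.spots_per_gene):
            index.append((gid, f"s{spot + 1}"))
            rows.append(
                [
                    baseline[gi] + half[a][gi] + rng.normal(0, config.expression_sigma)
                    for a in arrays
                ]
            )
    values = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["gene_id", "spot_id"]),
        columns=arrays,
    )
    effects_map = {
        gid: float(lfc[i]) for i, gid in enumerate(gene_ids) if lfc[i] != 0.0
    }
    return ExpressionMatrix(values=values, conditions=conditions), effects_map


def _truth_diff(
    sites: dict[str, list[MotifSite]],
    truth_a: dict[str, bool],
    truth_b: dict[str, bool],
    sub_a: set[str],
    sub_b: set[str],
) -> list[DiffSite]:
    """Diff sites implied by the planted truth after the QC filter (a planted
    sub-threshold call can never be counted methylated)."""
    out = []
    for name in sorted(sites):
        for s in sites[name]:
            key = site_key(s)
            ma = truth_a[key] and key not in sub_a
            mb = truth_b[key] and key not in sub_b
            out.append(
                DiffSite(
                    site=s,
                    state_a="methylated" if ma else "unmethylated",
                    state_b="methylated" if mb else "unmethylated",
                )
            )
    return out


def simulate_dataset(
    config: Optional[SimulationConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> SimulatedDataset:
    """Generate one complete synthetic study; optionally write all files.

    Emits genome.fasta, annotation.tsv, mods_<condition>.gff (x2),
    expression.tsv and truth.json when out_dir is given.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    genome, genes = simulate_genome(config, rng)
    motifs = default_motifs(include_m4c=True)
    m6a = [m for m in motifs if m.mod_type == "m6A"]
    sites = scan_all(genome, motifs)
    sites_m6a = {m.name: sites[m.name] for m in m6a}
    rec_a, truth_a, sub_a = simulate_modifications(
        sites_m6a, m6a, config, config.condition_a, rng
    )
    rec_b, truth_b, sub_b = simulate_modifications(
        sites_m6a, m6a, config, config.condition_b, rng
    )
    gene_ids = [g.gene_id for g in genes]
    expression, effects = simulate_expression(gene_ids, config, rng)

    diff = _truth_diff(sites_m6a, truth_a, truth_b, set(sub_a), set(sub_b))
    upstream = upstream_regions(genes, genome, config.upstream_max_len)
    assignment = assign_to_genes(diff, genes, upstream)
    meth_genes = {g.gene_id for g in assignment.per_gene if g.total_changes > 0}
    all_cand = sorted(meth_genes & set(effects))
    expected = sorted(
        g for g in all_cand if abs(effects[g]) >= config.truth_min_lfc
    )
    truth = GroundTruth(
        site_states={config.condition_a: truth_a, config.condition_b: truth_b},
        subthreshold={config.condition_a: sub_a, config.condition_b: sub_b},
        gene_effects=effects,
        expected_candidates=expected,
        candidates_all=all_cand,
        meth_changed_genes=sorted(meth_genes),
    )
    ds = SimulatedDataset(
        config=config,
        genome=genome,
        genes=genes,
        motifs=motifs,
        sites=sites,
        records={config.condition_a: rec_a, config.condition_b: rec_b},
        expression=expression,
        truth=truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genome(genome, out / "genome.fasta")
        write_annotation(genes, out / "annotation.tsv")
        write_modifications(rec_a, out / f"mods_{config.condition_a}.gff", genome.name)
        write_modifications(rec_b, out / f"mods_{config.condition_b}.gff", genome.name)
        write_expression(expression, out / "expression.tsv")
        truth.to_json(out / "truth.json")
    return ds
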