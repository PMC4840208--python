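"""Circular-genome model: sequence, gene annotation, regions and GC windows.

Coordinates are 1-based with inclusive ends (GFF convention) throughout the
package.  The genome is a single replicon, optionally circular; sliding-window
profiles wrap across the origin junction on circular genomes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

IUPAC_CHARS = set("ACGTRYSWKMBDHVN")

#: Canonical DnaA box used to set the origin of replication at position 1.
DNAA_BOX = "TGTTTCACG"


@dataclass(frozen=True)
class GenomeSequence:
    """A single replicon, uppercased, 1-based coordinates."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.sequence) - IUPAC_CHARS
        if bad:
            raise ValueError(f"non-IUPAC characters in genome: {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def gc_fraction(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene, inclusive 1-based coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    is_symbiosis_gene: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomicRegion:
    """Inclusive 1-based interval with a label."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("region end < start")

    @property
    def length_bp(self) -> int:
        """Inclusive length (end - start + 1)."""
        return self.end - self.start + 1

    @property
    def span_bp(self) -> int:
        """Coordinate span (end - start); the convention behind printed
        round-number island sizes such as 681 kb."""
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class WindowProfile:
    """One sliding-window value (GC fraction or methylated fraction)."""

    window_start: int
    window_size: int
    value: float
    n_sites: Optional[int] = None


def fraction_of_genome(part_bp: int, genome_bp: int, ndigits: int = 2) -> float:
    """Percentage of the genome occupied by a region, half-up rounded."""
    from ._util import percent

    return percent(part_bp, genome_bp, ndigits)


def load_genome(fasta_path: str | Path, circular: bool = True) -> GenomeSequence:
    """Read a single-replicon FASTA; multi-record input is an error."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"{fasta_path}: no FASTA records (empty file?)")
    if len(records) > 1:
        raise ValueError(
            f"{fasta_path}: expected single replicon, found {len(records)} records"
        )
    rec = records[0]
    return GenomeSequence(name=rec.id, sequence=str(rec.seq).upper(), circular=circular)


def write_genome(genome: GenomeSequence, fasta_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.name}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def rotate_to_origin(genome: GenomeSequence, box: str = DNAA_BOX) -> GenomeSequence:
    """Rotate a circular genome so the first forward-strand occurrence of the
    DnaA box starts at position 1.  Reverse-strand occurrences are ignored."""
    if not genome.circular:
        raise ValueError("rotate_to_origin requires a circular genome")
    idx = genome.sequence.find(box)
    if idx < 0:
        raise ValueError(f"DnaA box {box!r} not found on forward strand")
    seq = genome.sequence[idx:] + genome.sequence[:idx]
    return GenomeSequence(name=genome.name, sequence=seq, circular=True)


def upstream_region(
    gene: GeneAnnotation,
    genome: GenomeSequence,
    all_genes: Sequence[GeneAnnotation],
    max_len: int = 500,
) -> Optional[GenomicRegion]:
    """The intergenic interval 5' of a gene on its own strand.

    Truncated at max_len and at the nearest neighbouring gene boundary; returns
    None when the interval is empty (abutting or overlapping neighbours).
    Wrap-around across the origin is not extended: the window is clipped at the
    sequence ends.
    """
    if max_len <= 0:
        return None
    if gene.strand == "+":
        lo = max(1, gene.start - max_len)
        hi = gene.start - 1
        for g in all_genes:
            if g.gene_id == gene.gene_id:
                continue
            if g.start <= hi and g.end >= lo:
                lo = max(lo, g.end + 1)
        if lo > hi:
            return None
        return GenomicRegion(lo, hi, label=f"upstream:{gene.gene_id}")
    lo = gene.end + 1
    hi = min(len(genome), gene.end + max_len)
    for g in all_genes:
        if g.gene_id == gene.gene_id:
            continue
        if g.start <= hi and g.end >= lo:
            hi = min(hi, g.start - 1)
    if hi < lo:
        return None
    return GenomicRegion(lo, hi, label=f"upstream:{gene.gene_id}")


def upstream_regions(
    genes: Sequence[GeneAnnotation], genome: GenomeSequence, max_len: int = 500
) -> dict[str, Optional[GenomicRegion]]:
    """Upstream interval per gene id (None where empty)."""
    return {g.gene_id: upstream_region(g, genome, genes, max_len) for g in genes}


def window_starts(length: int, window: int, step: int, circular: bool) -> np.ndarray:
    """1-based start coordinates of sliding windows over the replicon."""
    if window <= 0:
        raise ValueError("window size must be positive")
    if step <= 0:
        raise ValueError("window step must be positive")
    if window > length:
        raise ValueError("window larger than genome")
    if circular:
        return np.arange(1, length + 1, step, dtype=np.int64)
    return np.arange(1, length - window + 2, step, dtype=np.int64)


def gc_windows(
    genome: GenomeSequence, window: int = 1000, step: int = 100
) -> list[WindowProfile]:
    """GC fraction in overlapping sliding windows, wrapping if circular."""
    L = len(genome)
    starts = window_starts(L, window, step, genome.circular)
    seq = genome.sequence
    if genome.circular:
        seq = seq + seq[: window - 1]
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    cum = np.concatenate([[0], np.cumsum(is_gc)])
    vals = (cum[starts - 1 + window] - cum[starts - 1]) / window
    return [
        WindowProfile(int(s), window, float(v)) for s, v in zip(starts, vals)
    ]


def write_bedgraph(
    profiles: Iterable[WindowProfile],
    path: str | Path,
    chrom: str,
    chrom_length: int,
    track_name: str = "",
) -> None:
    """Export window profiles as bedGraph (0-based half-open).

    Windows wrapping past the origin are clipped at the chromosome end;
    windows with undefined values (no sites) are omitted.
    """
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        for p in profiles:
            if p.value is None or math.isnan(p.value):
                continue
            start0 = p.window_start - 1
            end0 = min(start0 + p.window_size, chrom_length)
            fh.write(f"{chrom}\t{start0}\t{end0}\t{p.value:.6g}\n")


_ANNOT_COLUMNS = ["gene_id", "start", "end", "strand", "product"]


def load_annotation(
    tsv_path: str | Path, genome: Optional[GenomeSequence] = None
) -> list[GeneAnnotation]:
    """Read the tab-delimited gene table.

    Required columns: gene_id, start, end, strand, product; an optional
    symbiosis_role column (truthy/``1``/``yes``) sets is_symbiosis_gene.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in _ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{tsv_path}: missing annotation columns {missing}")
    genes: list[GeneAnnotation] = []
    truthy = {"1", "true", "yes", "y"}
    for row in df.itertuples(index=False):
        role = getattr(row, "symbiosis_role", "")
        genes.append(
            GeneAnnotation(
                gene_id=str(row.gene_id),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                product="" if pd.isna(row.product) else str(row.product),
                is_symbiosis_gene=str(role).strip().lower() in truthy,
            )
        )
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene ids in annotation: {dupes}")
    if genome is not None:
        for g in genes:
            if g.start < 1 or g.end > len(genome):
                raise ValueError(f"{g.gene_id}: coordinates outside genome")
    return genes


def write_annotation(genes: Sequence[GeneAnnotation], tsv_path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "product": [g.product for g in genes],
            "symbiosis_role": [int(g.is_symbiosis_gene) for g in genes],
        }
    )
    df.to_csv(tsv_path, sep="\t", index=False)


def load_annotation_gff3(
    gff_path: str | Path, genome: Optional[GenomeSequence] = None
) -> list[GeneAnnotation]:
    """Optional convenience: map GFF3 ``gene`` features onto GeneAnnotation."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        product = feat.attributes.get("product", [""])[0]
        genes.append(
            GeneAnnotation(
                gene_id=gid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                product=product,
            )
        )
    if genome is not None:
        for g in genes:
            if g.start < 1 or g.end > len(genome):
                raise ValueError(f"{g.gene_id}: coordinates outside genome")
    return genes
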