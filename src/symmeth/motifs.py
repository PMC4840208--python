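"""Degenerate-motif scanning.

Enumerates every strand-specific methylatable position of an IUPAC motif
(including bipartite spacer motifs such as GAGA(N)6RTG) on both strands of a
linear or circular genome.  A site is identified by the genomic coordinate of
the methylated base itself plus the strand; all overlapping occurrences are
reported, and circular genomes are scanned across the origin junction.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome import GenomeSequence

#: IUPAC ambiguity classes.  The spacer letter N deliberately matches only the
#: four unambiguous bases, so ambiguity characters in a reference can never
#: host a motif site.
IUPAC_CLASSES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_SPACER_RE = re.compile(r"\(N\)_?(\d+)_?")


def expand_spacers(iupac: str) -> str:
    """Expand spacer notation: ``GAGA(N)6RTG`` / ``GAGA(N)_6_RTG`` -> GAGANNNNNNRTG."""
    return _SPACER_RE.sub(lambda m: "N" * int(m.group(1)), iupac)


def reverse_complement(iupac: str) -> str:
    """Reverse complement of a degenerate DNA string."""
    try:
        return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(iupac))
    except KeyError as e:
        raise ValueError(f"not an IUPAC base: {e.args[0]!r}") from None


@dataclass(frozen=True)
class MotifSpec:
    """A degenerate motif with the position of its methylatable base.

    modified_offset is 1-based within the motif; mod_type is the base
    modification written by the cognate methyltransferase (m6A on adenine,
    m4C on cytosine).
    """

    name: str
    iupac: str
    modified_offset: int
    mod_type: str

    def __post_init__(self) -> None:
        pat = expand_spacers(self.iupac.upper())
        object.__setattr__(self, "iupac", pat)
        bad = set(pat) - set(IUPAC_CLASSES)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC letters {sorted(bad)}")
        if not 1 <= self.modified_offset <= len(pat):
            raise ValueError(f"{self.name}: modified_offset outside motif")
        if self.mod_type not in {"m6A", "m4C"}:
            raise ValueError(f"{self.name}: unknown mod_type {self.mod_type!r}")
        target = "A" if self.mod_type == "m6A" else "C"
        if target not in IUPAC_CLASSES[pat[self.modified_offset - 1]]:
            raise ValueError(
                f"{self.name}: base at offset {self.modified_offset} "
                f"cannot carry {self.mod_type}"
            )

    def __len__(self) -> int:
        return len(self.iupac)

    def regex(self) -> str:
        return "".join(
            c if len(IUPAC_CLASSES[c]) == 1 else "[" + IUPAC_CLASSES[c] + "]"
            for c in self.iupac
        )

    def is_palindromic(self) -> bool:
        return reverse_complement(self.iupac) == self.iupac


@dataclass(frozen=True, order=True)
class MotifSite:
    """One strand-specific methylatable genomic position.

    position is the 1-based forward-strand coordinate of the methylated base;
    match_start is the forward-strand coordinate where the motif occurrence
    begins (for minus-strand sites, of the occurrence's reverse complement).
    """

    motif_name: str
    position: int
    strand: str
    match_start: int


def default_motifs(include_m4c: bool = True) -> list[MotifSpec]:
    """The five methylated motifs of the B. diazoefficiens methylome.

    CRAGGAT carries both an m6A (offset 6) and a weakly supported m4C
    (offset 1); GAGA(N)6RTG / CAY(N)6TCTC are the two strands of one bipartite
    Type I duplex motif; CCTTGAG is the symbiosis-exclusive motif.
    """
    specs = [
        MotifSpec("GANTC", "GANTC", 2, "m6A"),
        MotifSpec("CRAGGAT", "CRAGGAT", 6, "m6A"),
        MotifSpec("CRAGGAT-m4C", "CRAGGAT", 1, "m4C"),
        MotifSpec("GAGA(N)6RTG", "GAGA(N)6RTG", 4, "m6A"),
        MotifSpec("CAY(N)6TCTC", "CAY(N)6TCTC", 2, "m6A"),
        MotifSpec("CCTTGAG", "CCTTGAG", 6, "m6A"),
    ]
    if not include_m4c:
        specs = [m for m in specs if m.mod_type != "m4C"]
    return specs


def _wrap(pos: int, length: int) -> int:
    return (pos - 1) % length + 1


def scan(genome: GenomeSequence, motif: MotifSpec) -> list[MotifSite]:
    """All strand-specific sites of a motif, both strands, origin-aware.

    Forward-strand occurrences yield '+' sites at match_start+offset-1.
    Occurrences of the motif's reverse complement on the forward strand are
    minus-strand occurrences; their methylated base sits offset positions from
    the occurrence's 3' end in forward coordinates.
    """
    L = len(genome)
    mlen = len(motif)
    if mlen > L:
        raise ValueError("motif longer than genome")
    seq = genome.sequence
    if genome.circular and mlen > 1:
        seq = seq + genome.sequence[: mlen - 1]
    sites: list[MotifSite] = []
    fwd = re.compile(f"(?=({motif.regex()}))")
    for m in fwd.finditer(seq):
        s0 = m.start()
        if s0 >= L:
            break
        start1 = s0 + 1
        sites.append(
            MotifSite(
                motif.name,
                _wrap(start1 + motif.modified_offset - 1, L),
                "+",
                start1,
            )
        )
    rc_spec = reverse_complement(motif.iupac)
    rev = re.compile(
        "(?=("
        + "".join(
            c if len(IUPAC_CLASSES[c]) == 1 else "[" + IUPAC_CLASSES[c] + "]"
            for c in rc_spec
        )
        + "))"
    )
    for m in rev.finditer(seq):
        s0 = m.start()
        if s0 >= L:
            break
        start1 = s0 + 1
        sites.append(
            MotifSite(
                motif.name,
                _wrap(start1 + mlen - motif.modified_offset, L),
                "-",
                start1,
            )
        )
    sites.sort(key=lambda s: (s.match_start, s.strand))
    return sites


def scan_all(
    genome: GenomeSequence, motifs: Sequence[MotifSpec]
) -> dict[str, list[MotifSite]]:
    return {m.name: scan(genome, m) for m in motifs}


def count_sites(sites: Iterable[MotifSite], mode: str = "per_strand") -> int:
    """per_strand counts (position, strand) pairs; per_duplex collapses the
    two strands of one match locus (palindromic double counting)."""
    sites = list(sites)
    if mode == "per_strand":
        return len({(s.position, s.strand) for s in sites})
    if mode == "per_duplex":
        return len({s.match_start for s in sites})
    raise ValueError(f"unknown counting mode {mode!r}")


def load_motifs(tsv_path: str | Path) -> list[MotifSpec]:
    """Read a motif table: columns name, iupac, modified_offset, mod_type."""
    df = pd.read_csv(tsv_path, sep="\t")
    required = ["name", "iupac", "modified_offset", "mod_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{tsv_path}: missing motif columns {missing}")
    return [
        MotifSpec(str(r.name_), str(r.iupac), int(r.modified_offset), str(r.mod_type))
        for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def write_sites(sites: Iterable[MotifSite], tsv_path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.motif_name, s.position, s.strand, s.match_start) for s in sites],
        columns=["motif", "position", "strand", "match_start"],
    )
    df.to_csv(tsv_path, sep="\t", index=False)
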