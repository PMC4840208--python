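"""Per-base modification calls: parsing, QC filtering, site-state assignment.

Input is the PacBio-style modifications GFF dialect: one 9-column record per
called base, with the Phred-like modification quality in the score column and
``coverage=``/``IPDRatio=`` key-value attributes.  A motif site is called
methylated in a condition iff a QC-passing record of the right modification
type exists at exactly its (position, strand); absence of a call is
unmethylated (no explicit unmethylated records are expected).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .motifs import MotifSite, MotifSpec

logger = logging.getLogger(__name__)

#: Default QC thresholds (both inclusive), the platform-recommended minima.
MIN_COVERAGE = 25
MIN_QV = 30


@dataclass(frozen=True)
class ModificationRecord:
    """One called modified base with its QC metadata."""

    position: int
    strand: str
    mod_type: str
    mod_qv: float
    coverage: int
    ipd_ratio: float

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if self.ipd_ratio <= 0:
            raise ValueError("IPD ratio must be > 0")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.strand, self.mod_type)


@dataclass(frozen=True)
class SiteState:
    """Methylation status of one motif site in one condition."""

    site: MotifSite
    condition: str
    state: str  # "methylated" | "unmethylated"
    record: Optional[ModificationRecord] = None

    def __post_init__(self) -> None:
        if self.state not in {"methylated", "unmethylated"}:
            raise ValueError(f"bad state {self.state!r}")
        if (self.state == "methylated") != (self.record is not None):
            raise ValueError("methylated iff a supporting record is present")

    @property
    def methylated(self) -> bool:
        return self.state == "methylated"


def _parse_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_modifications(gff_path: str | Path) -> list[ModificationRecord]:
    """Parse a modifications GFF file; malformed lines raise with line number."""
    records: list[ModificationRecord] = []
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 9:
                raise ValueError(
                    f"{gff_path}:{lineno}: expected 9 GFF columns, got {len(fields)}"
                )
            _, _, mod_type, start, end, score, strand, _, attrs = fields[:9]
            try:
                position = int(start)
                mod_qv = float(score)
                attr = _parse_attributes(attrs)
                coverage = int(float(attr["coverage"]))
                ipd = float(attr["IPDRatio"])
            except (ValueError, KeyError) as e:
                raise ValueError(f"{gff_path}:{lineno}: malformed record ({e})") from None
            if strand not in {"+", "-"}:
                raise ValueError(f"{gff_path}:{lineno}: unknown strand {strand!r}")
            records.append(
                ModificationRecord(position, strand, mod_type, mod_qv, coverage, ipd)
            )
    return records


def write_modifications(
    records: Iterable[ModificationRecord], gff_path: str | Path, seqid: str = "genome"
) -> None:
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            fh.write(
                f"{seqid}\tkinModCall\t{r.mod_type}\t{r.position}\t{r.position}\t"
                f"{r.mod_qv:.0f}\t{r.strand}\t.\t"
                f"coverage={r.coverage};IPDRatio={r.ipd_ratio:.2f}\n"
            )


def qc_filter(
    records: Iterable[ModificationRecord],
    min_coverage: int = MIN_COVERAGE,
    min_qv: float = MIN_QV,
) -> list[ModificationRecord]:
    """Keep records with coverage >= min_coverage and modQV >= min_qv
    (both boundaries inclusive)."""
    return [
        r for r in records if r.coverage >= min_coverage and r.mod_qv >= min_qv
    ]


def partition_records(
    sites: Sequence[MotifSite],
    records: Sequence[ModificationRecord],
    motifs: Sequence[MotifSpec],
) -> tuple[dict[tuple[int, str, str], ModificationRecord], list[ModificationRecord]]:
    """Split records into a lookup for on-motif calls and the off-motif rest.

    Duplicate records at one (position, strand, mod_type) are ambiguous input
    and raise.
    """
    by_key: dict[tuple[int, str, str], ModificationRecord] = {}
    for r in records:
        if r.key in by_key:
            raise ValueError(f"duplicate modification record at {r.key}")
        by_key[r.key] = r
    mod_type_of = {m.name: m.mod_type for m in motifs}
    site_keys = set()
    for s in sites:
        try:
            site_keys.add((s.position, s.strand, mod_type_of[s.motif_name]))
        except KeyError:
            raise ValueError(f"site references unknown motif {s.motif_name!r}") from None
    off = [r for k, r in by_key.items() if k not in site_keys]
    return by_key, off


def assign_states(
    sites: Sequence[MotifSite],
    records: Sequence[ModificationRecord],
    condition: str,
    motifs: Sequence[MotifSpec],
    rejected: Optional[Sequence[ModificationRecord]] = None,
) -> list[SiteState]:
    """One SiteState per input site; records are expected to be QC-filtered.

    Off-motif records (no matching site) are counted and logged.  If the
    pre-QC rejects are supplied, sites that are unmethylated only because
    their call failed QC (undecidable rather than unmethylated) are counted
    and logged as well.
    """
    by_key, off = partition_records(sites, records, motifs)
    mod_type_of = {m.name: m.mod_type for m in motifs}
    states: list[SiteState] = []
    for s in sites:
        key = (s.position, s.strand, mod_type_of[s.motif_name])
        rec = by_key.get(key)
        if rec is not None:
            states.append(SiteState(s, condition, "methylated", rec))
        else:
            states.append(SiteState(s, condition, "unmethylated"))
    if off:
        logger.info("%s: %d off-motif modification calls ignored", condition, len(off))
    if rejected:
        rej_keys = {r.key for r in rejected}
        undecidable = sum(
            1
            for st in states
            if not st.methylated
            and (st.site.position, st.site.strand, mod_type_of[st.site.motif_name])
            in rej_keys
        )
        if undecidable:
            logger.info(
                "%s: %d sites unmethylated only for lack of a QC-passing call",
                condition,
                undecidable,
            )
    return states
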