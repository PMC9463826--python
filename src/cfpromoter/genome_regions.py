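"""TSS annotation parsing and construction of the 2 kb promoter windows.

The feature space of the whole pipeline is the set of primary-TSS (pTSS)
windows: for each gene, the interval ``[tss - 1000, tss + 1000)`` around its
primary transcription start site.  All coordinates are 0-based half-open
internally; conversions from 1-based GTF happen only at the file boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "TssRecord",
    "PtssRegion",
    "read_tss_annotations",
    "select_primary_tss",
    "build_ptss_regions",
    "write_regions_bed",
    "read_regions_bed",
]


@dataclass(frozen=True)
class TssRecord:
    gene_id: str
    chrom: str
    strand: str
    tss_position: int  # 0-based
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.tss_position < 0:
            raise ValueError("tss_position must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")


@dataclass(frozen=True)
class PtssRegion:
    """A promoter window; always exactly 2 * flank bp long (2000 by default)."""

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid region [{self.start}, {self.end})")


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_line(line: str, lineno: int) -> TssRecord | None:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 9:
        raise ValueError(f"line {lineno}: GTF needs 9 tab-separated fields")
    chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
    if feature not in ("transcript", "mRNA"):
        return None
    if strand not in ("+", "-"):
        raise ValueError(f"line {lineno}: unknown strand {strand!r}")
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinates") from exc
    attr = dict(_GTF_ATTR.findall(attrs))
    gene_id = attr.get("gene_id")
    if not gene_id:
        raise ValueError(f"line {lineno}: missing gene_id attribute")
    # GTF is 1-based inclusive; the TSS is the 5'-most transcribed base.
    tss = start_i - 1 if strand == "+" else end_i - 1
    return TssRecord(gene_id, chrom, strand, tss, attr.get("transcript_id"))


def _parse_bed_line(line: str, lineno: int) -> TssRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise ValueError(f"line {lineno}: BED6 needs >= 6 fields (strand required)")
    chrom, start, end, name, _score, strand = fields[:6]
    if strand not in ("+", "-"):
        raise ValueError(f"line {lineno}: unknown strand {strand!r}")
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinates") from exc
    tss = start_i if strand == "+" else end_i - 1
    return TssRecord(name, chrom, strand, tss)


def read_tss_annotations(path: str | Path, fmt: str | None = None) -> list[TssRecord]:
    """Read TSS records from a BED6 or GTF file.

    ``fmt`` is ``"bed"`` or ``"gtf"``; if None it is inferred from the suffix.
    Malformed lines raise ValueError naming the line number.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "bed"
    fmt = fmt.lower()
    if fmt not in ("bed", "gtf"):
        raise ValueError(f"unknown annotation format {fmt!r}")
    records: list[TssRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            rec = _parse_gtf_line(line, lineno) if fmt == "gtf" else _parse_bed_line(line, lineno)
            if rec is not None:
                records.append(rec)
    records.sort(key=lambda r: (r.chrom, r.tss_position))
    return records


def select_primary_tss(records: Iterable[TssRecord]) -> list[TssRecord]:
    """Keep one record per gene: the 5'-most TSS in gene orientation.

    On "+" the smallest coordinate wins, on "-" the largest; ties break by
    transcript_id lexicographic order so the choice is deterministic.
    """
    records = list(records)
    if not records:
        raise ValueError("no TSS records")
    by_gene: dict[str, TssRecord] = {}
    for rec in records:
        cur = by_gene.get(rec.gene_id)
        if cur is None:
            by_gene[rec.gene_id] = rec
            continue
        key_new = (rec.tss_position if rec.strand == "+" else -rec.tss_position,
                   rec.transcript_id or "")
        key_cur = (cur.tss_position if cur.strand == "+" else -cur.tss_position,
                   cur.transcript_id or "")
        if key_new < key_cur:
            by_gene[rec.gene_id] = rec
    out = list(by_gene.values())
    out.sort(key=lambda r: (r.chrom, r.tss_position))
    return out


def build_ptss_regions(
    tss_records: Iterable[TssRecord],
    chrom_lengths: Mapping[str, int],
    flank: int = 1000,
) -> list[PtssRegion]:
    """Build ``[tss - flank, tss + flank)`` windows; drop (never clip) edge genes.

    Dropping keeps every window exactly ``2 * flank`` bp so the normalization
    denominator is a constant; dropped genes are logged.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    regions: list[PtssRegion] = []
    dropped: list[str] = []
    for rec in tss_records:
        if rec.chrom not in chrom_lengths:
            raise KeyError(f"no chromosome length for {rec.chrom!r}")
        start, end = rec.tss_position - flank, rec.tss_position + flank
        if start < 0 or end > chrom_lengths[rec.chrom]:
            dropped.append(rec.gene_id)
            continue
        regions.append(PtssRegion(rec.gene_id, rec.chrom, start, end))
    if dropped:
        logger.warning(
            "dropped %d gene(s) whose promoter window crosses a chromosome edge: %s",
            len(dropped),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    return regions


def regions_from_genome(genome, flank: int = 1000) -> list[PtssRegion]:
    """Promoter windows for a :class:`~cfpromoter.synthetic_cfdna.ToyGenome`."""
    recs = [TssRecord(g.gene_id, genome.chrom_name, g.strand, g.tss) for g in genome.genes]
    return build_ptss_regions(recs, {genome.chrom_name: genome.chrom_length}, flank=flank)


def write_regions_bed(regions: Iterable[PtssRegion], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\n")
    return path


def read_regions_bed(path: str | Path) -> list[PtssRegion]:
    regions: list[PtssRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: region BED needs 4 fields")
            chrom, start, end, gene_id = fields[:4]
            regions.append(PtssRegion(gene_id, chrom, int(start), int(end)))
    return regions
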