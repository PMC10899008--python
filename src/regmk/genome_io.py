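"""Interval I/O and interval algebra shared by the whole pipeline.

All coordinates are 0-based, half-open ([start, end)) internally.  BED and
narrowPeak files are already in that convention; GFF3 (1-based, inclusive)
is converted at the parsing boundary and converted back on write.

Evolutionary strata -- blocks of the sex chromosomes that stopped
recombining at different times -- are carried as labels on intervals and
assigned from a plain-text boundary table, so that every downstream
statistic can be split by stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class Stratum(str, Enum):
    """Stratum label for a position on a sex chromosome.

    S1 is the oldest stratum (highest X-Y divergence), S3 the youngest.
    PAR marks the still-recombining pseudoautosomal region.
    """

    S1 = "S1"
    S2 = "S2"
    S3 = "S3"
    PAR = "PAR"
    AUTOSOME = "AUTOSOME"
    NA = "NA"


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    label: str = ""
    stratum: Stratum = Stratum.NA

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in interval {self.label!r}: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval {self.label!r} has end <= start ({self.end} <= {self.start})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Gene:
    """Gene interval with strand; the TSS is start on '+' and end-1 on '-'."""

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id} has end <= start")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.gene_id)


@dataclass
class AnnotationSet:
    """Genes, repeats and ACRs for one or more chromosomes.

    Interval lists are kept sorted per chromosome; ``chrom_lengths`` bounds
    every interval.
    """

    genes: list[Gene] = field(default_factory=list)
    repeats: list[GenomicInterval] = field(default_factory=list)
    acrs: list[GenomicInterval] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.chrom, g.start, g.end))
        self.repeats = sorted(self.repeats, key=lambda i: (i.chrom, i.start, i.end))
        self.acrs = sorted(self.acrs, key=lambda i: (i.chrom, i.start, i.end))
        for name, itvs in (("gene", self.genes), ("repeat", self.repeats), ("acr", self.acrs)):
            for itv in itvs:
                length = self.chrom_lengths.get(itv.chrom)
                if length is not None and itv.end > length:
                    raise ValueError(
                        f"{name} interval on {itv.chrom} ends at {itv.end}, "
                        f"beyond chromosome length {length}"
                    )


# ---------------------------------------------------------------------------
# Parsing


def _parse_bed_line(fields: list[str], lineno: int, path: str) -> GenomicInterval:
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
    label = fields[3] if len(fields) > 3 else ""
    try:
        return GenomicInterval(fields[0], start, end, label)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: {exc}") from exc


def _parse_gff_line(fields: list[str], lineno: int, path: str) -> GenomicInterval:
    if len(fields) < 9:
        raise ValueError(f"{path}:{lineno}: GFF line has fewer than 9 columns")
    try:
        start1, end1 = int(fields[3]), int(fields[4])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
    attrs = parse_gff_attributes(fields[8])
    label = attrs.get("ID", attrs.get("Parent", ""))
    try:
        # GFF is 1-based inclusive; convert to 0-based half-open.
        return GenomicInterval(fields[0], start1 - 1, end1, label)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: {exc}") from exc


def parse_gff_attributes(attr_field: str) -> dict[str, str]:
    """Minimal GFF3 column-9 parsing: ID and Parent only."""
    out: dict[str, str] = {}
    for item in attr_field.strip().split(";"):
        if "=" in item:
            key, value = item.split("=", 1)
            if key.strip() in ("ID", "Parent"):
                out[key.strip()] = value.strip()
    return out


def read_intervals(path: str | Path, fmt: str = "BED") -> list[GenomicInterval]:
    """Read intervals from a BED, narrowPeak or GFF file.

    narrowPeak is BED6+4; only the first four columns are retained.  Malformed
    lines raise ``ValueError`` naming the offending line number.
    """
    fmt = fmt.upper()
    if fmt not in ("BED", "NARROWPEAK", "GFF"):
        raise ValueError(f"unknown interval format: {fmt}")
    parse = _parse_gff_line if fmt == "GFF" else _parse_bed_line
    intervals: list[GenomicInterval] = []
    path = Path(path)
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            intervals.append(parse(line.split("\t"), lineno, str(path)))
    return sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as handle:
        for itv in intervals:
            name = itv.label or "."
            handle.write(f"{itv.chrom}\t{itv.start}\t{itv.end}\t{name}\n")


def read_strata_table(path: str | Path) -> list[GenomicInterval]:
    """Read a strata boundary table: TSV of chrom, start, end, stratum."""
    out: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            out.append(
                GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]), stratum=Stratum(fields[3])
                )
            )
    return sorted(out, key=lambda i: (i.chrom, i.start))


def write_strata_table(bounds: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as handle:
        for itv in bounds:
            handle.write(f"{itv.chrom}\t{itv.start}\t{itv.end}\t{itv.stratum.value}\n")


def assign_stratum(
    chrom: str, pos: int, bounds: Sequence[GenomicInterval]
) -> Stratum:
    """Stratum of a position, a pure function of (chrom, pos) given the table."""
    for itv in bounds:
        if itv.chrom == chrom and itv.start <= pos < itv.end:
            return itv.stratum
    return Stratum.NA


def label_strata(
    intervals: Iterable[GenomicInterval], bounds: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Attach a stratum to each interval from the stratum of its midpoint."""
    return [
        replace(itv, stratum=assign_stratum(itv.chrom, int(itv.midpoint), bounds))
        for itv in intervals
    ]


# ---------------------------------------------------------------------------
# Interval algebra


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals per chromosome, as sorted disjoint intervals."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for itv in intervals:
        by_chrom.setdefault(itv.chrom, []).append(itv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        current_start = current_end = None
        for itv in sorted(by_chrom[chrom], key=lambda i: i.start):
            if current_start is None:
                current_start, current_end = itv.start, itv.end
            elif itv.start <= current_end:
                current_end = max(current_end, itv.end)
            else:
                merged.append(GenomicInterval(chrom, current_start, current_end))
                current_start, current_end = itv.start, itv.end
        if current_start is not None:
            merged.append(GenomicInterval(chrom, current_start, current_end))
    return merged


def complement(
    intervals: Iterable[GenomicInterval], chrom: str, chrom_length: int
) -> list[GenomicInterval]:
    """Complement of the union of ``intervals`` within [0, chrom_length)."""
    merged = [i for i in merge_intervals(intervals) if i.chrom == chrom]
    out: list[GenomicInterval] = []
    cursor = 0
    for itv in merged:
        if itv.start > cursor:
            out.append(GenomicInterval(chrom, cursor, itv.start))
        cursor = max(cursor, itv.end)
    if cursor < chrom_length:
        out.append(GenomicInterval(chrom, cursor, chrom_length))
    return out


def intergenic_space(annotations: AnnotationSet, chrom: str) -> list[GenomicInterval]:
    """Intergenic space: everything outside genes, repeats and ACRs.

    Returns the complement, within [0, chrom_length), of the union of all
    annotated functional intervals on ``chrom``.
    """
    if chrom not in annotations.chrom_lengths:
        raise KeyError(f"unknown chromosome: {chrom}")
    annotated = (
        [g.interval for g in annotations.genes if g.chrom == chrom]
        + [i for i in annotations.repeats if i.chrom == chrom]
        + [i for i in annotations.acrs if i.chrom == chrom]
    )
    return complement(annotated, chrom, annotations.chrom_lengths[chrom])


def assign_acr_to_gene(
    acrs: Sequence[GenomicInterval],
    genes: Sequence[Gene],
    max_dist: int = 50_000,
    anchor: str = "midpoint",
) -> dict[str, str | None]:
    """Assign each ACR to the closest gene TSS within ``max_dist`` bp.

    ``anchor`` selects the ACR-side reference point: "midpoint" (default)
    or "edge" (distance from the nearest ACR edge to the TSS; zero if the
    TSS falls inside the ACR).  Ties on distance are broken by the lower
    TSS coordinate, then lexicographic gene id.  Returns a map keyed by
    ACR label ("chrom:start-end" when the label is empty); ACRs with no
    gene in range map to None.
    """
    if anchor not in ("midpoint", "edge"):
        raise ValueError("anchor must be 'midpoint' or 'edge'")
    assignment: dict[str, str | None] = {}
    for acr in acrs:
        key = acr.label or f"{acr.chrom}:{acr.start}-{acr.end}"
        best: tuple[float, int, str] | None = None
        for gene in genes:
            if gene.chrom != acr.chrom:
                continue
            if anchor == "midpoint":
                dist = abs(acr.midpoint - gene.tss)
            else:
                if acr.start <= gene.tss < acr.end:
                    dist = 0.0
                else:
                    dist = float(min(abs(gene.tss - (acr.end - 1)), abs(gene.tss - acr.start)))
            cand = (dist, gene.tss, gene.gene_id)
            if dist <= max_dist and (best is None or cand < best):
                best = cand
        assignment[key] = best[2] if best is not None else None
    return assignment


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(i) for i in intervals)
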