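"""Exon target regions: BED input, merging of close targets, GC content.

Coordinates are 0-based half-open internally (BED convention).  Printed
genomic coordinates of the form ``chrN:a-b`` are treated as 1-based
inclusive when converted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

__all__ = [
    "ExonRegion",
    "read_bed",
    "write_bed",
    "sort_regions",
    "merge_close_exons",
    "filter_autosomes",
    "gc_content",
    "attach_gc",
    "AUTOSOMES",
]

AUTOSOMES = frozenset(
    [str(i) for i in range(1, 23)] + [f"chr{i}" for i in range(1, 23)]
)


@dataclass(frozen=True)
class ExonRegion:
    """A single capture target interval.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based inclusive start.
    end : int
        0-based exclusive end; must exceed ``start``.
    id : str
        Stable label; defaults to ``chrom:start-end``.
    gc : float or None
        GC content in percent (0-100), or None if unknown.
    """

    chrom: str
    start: int
    end: int
    id: str = ""
    gc: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"region end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.gc is not None and not (0.0 <= self.gc <= 100.0):
            raise ValueError(f"GC content out of [0, 100]: {self.gc}")
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _chrom_sort_key(chrom: str):
    base = chrom[3:] if chrom.startswith("chr") else chrom
    return (0, int(base)) if base.isdigit() else (1, base)


def sort_regions(regions: Iterable[ExonRegion]) -> list[ExonRegion]:
    """Sort by chromosome (numeric-aware) then start coordinate."""
    return sorted(regions, key=lambda r: (_chrom_sort_key(r.chrom), r.start, r.end))


def _check_sorted(regions: Sequence[ExonRegion]) -> None:
    for prev, cur in zip(regions, regions[1:]):
        if prev.chrom == cur.chrom and cur.start < prev.start:
            raise ValueError(
                f"regions not sorted: {cur.id} follows {prev.id}; "
                "sort per chromosome before merging"
            )


def merge_close_exons(
    regions: Sequence[ExonRegion], gap_bp: int = 50
) -> list[ExonRegion]:
    """Merge consecutive same-chromosome regions separated by < ``gap_bp``.

    Capture targets closer than ~50 bp cannot be distinguished by fragment
    midpoints, so they are collapsed into their union.  Overlapping regions
    (negative gap) are always merged.  The operation is idempotent and
    never discards covered bases.

    GC of a merged region is the length-weighted mean of the inputs when
    all inputs carry GC, else None.
    """
    if gap_bp < 0:
        raise ValueError("gap_bp must be >= 0")
    regions = list(regions)
    _check_sorted(regions)
    if not regions:
        return []
    out: list[ExonRegion] = []
    cur = regions[0]
    for nxt in regions[1:]:
        if nxt.chrom == cur.chrom and nxt.start - cur.end < gap_bp:
            new_end = max(cur.end, nxt.end)
            if cur.gc is not None and nxt.gc is not None:
                w = cur.length * cur.gc + nxt.length * nxt.gc
                gc = w / (cur.length + nxt.length)
            else:
                gc = None
            cur = ExonRegion(
                cur.chrom, cur.start, new_end,
                id=f"{cur.chrom}:{cur.start}-{new_end}", gc=gc,
            )
        else:
            out.append(cur)
            cur = nxt
    out.append(cur)
    return out


def filter_autosomes(
    regions: Sequence[ExonRegion], allow_all: bool = False
) -> list[ExonRegion]:
    """Keep autosomal regions (chr1-22); warn about anything dropped.

    Sex chromosomes are excluded by default because male and female
    samples would need separate handling; pass ``allow_all=True`` to keep
    every chromosome.
    """
    if allow_all:
        return list(regions)
    kept = [r for r in regions if r.chrom in AUTOSOMES]
    n_dropped = len(regions) - len(kept)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} non-autosomal region(s); "
            "pass allow_all=True to keep them",
            stacklevel=2,
        )
    return kept


def read_bed(path) -> list[ExonRegion]:
    """Read a BED3+ file into ExonRegion records (name column kept if present)."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) >= 4 else ""
            regions.append(ExonRegion(chrom, start, end, id=name))
    return regions


def write_bed(regions: Iterable[ExonRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")


def gc_content(region: ExonRegion, genome) -> float | None:
    """GC percentage of a region from an indexed FASTA.

    ``genome`` is a ``pyfaidx.Fasta`` (or any mapping of name ->
    sliceable sequence).  Ambiguous bases are excluded from numerator and
    denominator; returns None when no unambiguous base remains.
    """
    if region.chrom not in genome:
        raise KeyError(f"chromosome {region.chrom!r} not in genome")
    seq = genome[region.chrom]
    if region.end > len(seq):
        raise ValueError(
            f"region {region.id} extends past end of {region.chrom} ({len(seq)} bp)"
        )
    sub = str(seq[region.start : region.end]).upper()
    gc = sub.count("G") + sub.count("C")
    at = sub.count("A") + sub.count("T")
    if gc + at == 0:
        return None
    return 100.0 * gc / (gc + at)


def attach_gc(regions: Sequence[ExonRegion], genome) -> list[ExonRegion]:
    """Return regions with the ``gc`` field filled from a FASTA."""
    return [replace(r, gc=gc_content(r, genome)) for r in regions]
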