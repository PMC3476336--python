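"""Per-exon fragment counts: the CountMatrix container, FPKM, TSV I/O and
optional BAM/SAM fragment counting.

A *fragment* is a consistent read pair: both mates mapped to the same
chromosome, in convergent orientation, spanning < 1000 bp, with mapping
quality >= 20.  Each fragment is counted once, at the exon containing the
midpoint of [leftmost start, rightmost end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import ExonRegion, sort_regions

__all__ = ["CountMatrix", "count_fragments", "FragmentStats"]


@dataclass
class CountMatrix:
    """Exons x samples integer fragment counts.

    ``counts[i, s]`` is the number of fragments assigned to ``regions[i]``
    in ``samples[s]``.  Column sums are exposed as ``total_per_sample``.
    """

    regions: list[ExonRegion]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.regions)} regions x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample names")
        if self.regions != sort_regions(self.regions):
            raise ValueError("regions must be in genomic sort order")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def total_per_sample(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(
                f"sample {sample!r} not in matrix (have {self.samples})"
            ) from None

    def column(self, sample: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample)]

    def aggregate(self, samples: Sequence[str]) -> np.ndarray:
        """Per-exon sum of counts over the given samples (aggregate reference)."""
        idx = [self.sample_index(s) for s in samples]
        if not idx:
            raise ValueError("aggregate needs at least one sample")
        return self.counts[:, idx].sum(axis=1)

    def region_lengths(self) -> np.ndarray:
        return np.array([r.length for r in self.regions], dtype=np.int64)

    def fpkm(self) -> np.ndarray:
        """Fragments per kilobase of exon per million mapped fragments.

        fpkm[i, s] = counts[i, s] / (length_kb[i] * total[s] / 1e6).
        Invariant under rescaling of a sample's counts.
        """
        totals = self.total_per_sample
        zero = np.flatnonzero(totals == 0)
        if zero.size:
            bad = ", ".join(self.samples[i] for i in zero)
            raise ValueError(f"sample(s) with zero total fragments: {bad}")
        len_kb = self.region_lengths() / 1000.0
        return self.counts / (len_kb[:, None] * (totals[None, :] / 1e6))

    # ---------------------------------------------------------------- I/O
    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
            }
        )
        for j, s in enumerate(self.samples):
            df[s] = self.counts[:, j]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t")
        required = ["chrom", "start", "end"]
        if list(df.columns[:3]) != required:
            raise ValueError(
                f"count TSV must start with columns {required}, got "
                f"{list(df.columns[:3])}"
            )
        samples = list(df.columns[3:])
        if not samples:
            raise ValueError("count TSV has no sample columns")
        regions = [
            ExonRegion(str(c), int(s), int(e))
            for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ]
        counts = df[samples].to_numpy()
        return cls(regions=regions, samples=samples, counts=counts)


@dataclass
class FragmentStats:
    """Tally of fragment filtering during counting."""

    retained: int = 0
    skipped_unpaired: int = 0
    filtered_mapq: int = 0
    filtered_insert: int = 0
    filtered_orientation: int = 0
    outside_regions: int = 0
    extra: dict = field(default_factory=dict)


def _region_lookup(regions: Sequence[ExonRegion]):
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, ([], [], []))  # type: ignore[arg-type]
    starts: dict[str, list] = {c: [] for c in by_chrom}
    ends: dict[str, list] = {c: [] for c in by_chrom}
    idx: dict[str, list] = {c: [] for c in by_chrom}
    for i, r in enumerate(regions):
        starts[r.chrom].append(r.start)
        ends[r.chrom].append(r.end)
        idx[r.chrom].append(i)
    return {
        c: (np.asarray(starts[c]), np.asarray(ends[c]), np.asarray(idx[c]))
        for c in starts
    }


def count_fragments(
    alignments,
    regions: Sequence[ExonRegion],
    min_mapq: int = 20,
    max_insert: int = 1000,
) -> tuple[np.ndarray, FragmentStats]:
    """Count consistent read-pair fragments per exon.

    Parameters
    ----------
    alignments : str | pysam.AlignmentFile
        Path to a SAM/BAM/CRAM file, or an open ``pysam.AlignmentFile``.
    regions : sequence of ExonRegion
        Sorted, non-overlapping target regions.
    min_mapq : int
        Minimum Phred-scaled mapping quality for both mates.
    max_insert : int
        Mates spanning >= this many bases are discarded.

    Returns
    -------
    counts : int array, one entry per region
    stats : FragmentStats

    A fragment is assigned to the unique region whose half-open interval
    contains the midpoint ``(leftmost_start + rightmost_end) // 2``;
    fragments whose midpoint falls between regions are dropped.
    """
    import pysam

    close = False
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        alignments = pysam.AlignmentFile(str(alignments))
        close = True

    lookup = _region_lookup(regions)
    counts = np.zeros(len(regions), dtype=np.int64)
    stats = FragmentStats()
    pending: dict[str, object] = {}

    try:
        for read in alignments:
            if read.is_secondary or read.is_supplementary:
                continue
            if not read.is_paired or read.is_unmapped or read.mate_is_unmapped:
                stats.skipped_unpaired += 1
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            _count_pair(mate, read, lookup, counts, stats, min_mapq, max_insert)
        stats.skipped_unpaired += len(pending)
    finally:
        if close:
            alignments.close()
    return counts, stats


def _count_pair(r1, r2, lookup, counts, stats, min_mapq, max_insert) -> None:
    if r1.reference_name != r2.reference_name:
        stats.filtered_orientation += 1
        return
    if min(r1.mapping_quality, r2.mapping_quality) < min_mapq:
        stats.filtered_mapq += 1
        return
    left, right = (r1, r2) if r1.reference_start <= r2.reference_start else (r2, r1)
    # convergent: leftmost mate on forward strand, rightmost on reverse
    if left.is_reverse or not right.is_reverse:
        stats.filtered_orientation += 1
        return
    lo = left.reference_start
    hi = max(left.reference_end, right.reference_end)
    if hi - lo >= max_insert:
        stats.filtered_insert += 1
        return
    mid = (lo + hi) // 2
    entry = lookup.get(r1.reference_name)
    if entry is None:
        stats.outside_regions += 1
        return
    starts, ends, idx = entry
    k = int(np.searchsorted(starts, mid, side="right")) - 1
    if k >= 0 and mid < ends[k]:
        counts[idx[k]] += 1
        stats.retained += 1
    else:
        stats.outside_regions += 1
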