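"""Post-processing and evaluation of RLFS predictions.

Covers coordinate remapping onto a genomic anchor, clustering of overlapping
predictions, base-pair-overlap comparison against experimentally defined
R-loop regions (e.g. DRIP-seq intervals), confusion-matrix metrics from
present/absent call tables, and random sampling of signal-free negative
regions for specificity estimation.

"Overlap" always means at least one shared base in 0-based half-open
coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np
from intervaltree import IntervalTree

from .scan import RlfsRecord


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware interval on a named sequence (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )

    @classmethod
    def from_one_based_inclusive(
        cls, chrom: str, start: int, end: int, strand: str = "."
    ) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (UCSC browser style)."""
        return cls(chrom, start - 1, end, strand)

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RlfsCluster:
    """A maximal set of >= 2 mutually connected overlapping predictions."""

    members: tuple[RlfsRecord, ...]
    span: GenomicInterval

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def remap_records(
    records: Sequence[RlfsRecord], anchor: tuple[str, int, str]
) -> list[RlfsRecord]:
    """Re-express local record coordinates on a chromosome.

    ``anchor`` is ``(chrom, 1-based inclusive start, strand)`` describing
    where the scanned sequence sits in the genome.  For a '-' anchor the
    local axis runs antiparallel to the chromosome: intervals are mirrored
    within the anchored span and record strands flip.
    """
    chrom, start1, astrand = anchor
    if start1 < 1:
        raise ValueError("anchor start is 1-based and must be >= 1")
    if astrand not in ("+", "-"):
        raise ValueError("anchor strand must be '+' or '-'")
    offset = start1 - 1
    out: list[RlfsRecord] = []
    for rec in records:
        if rec.source is None:
            raise ValueError("record lacks source sequence; cannot remap")
        seq_len = len(rec.source.residues)
        if rec.start < 0 or rec.end > seq_len:
            raise ValueError(
                f"record [{rec.start},{rec.end}) exceeds the anchored span "
                f"of length {seq_len}"
            )
        if astrand == "+":
            def shift(s: int, e: int) -> tuple[int, int]:
                return offset + s, offset + e
            strand = rec.strand
        else:
            def shift(s: int, e: int) -> tuple[int, int]:
                return offset + seq_len - e, offset + seq_len - s
            strand = "-" if rec.strand == "+" else "+"
        riz = shift(rec.riz_start, rec.riz_end)
        rez = shift(rec.rez_start, rec.rez_end)
        out.append(
            replace(
                rec,
                chrom=chrom,
                strand=strand,
                riz_start=riz[0],
                riz_end=riz[1],
                rez_start=rez[0],
                rez_end=rez[1],
            )
        )
    return out


def cluster_records(
    records: Sequence[RlfsRecord], per_strand: bool = True
) -> list[RlfsCluster]:
    """Group records into clusters of >= 2 connected overlapping predictions.

    Clusters are the connected components of the >= 1-base overlap graph,
    computed per reference name and (by default) per strand; singleton
    components are not clusters.
    """
    groups: dict[tuple, list[RlfsRecord]] = {}
    for rec in records:
        key = (rec.ref_name, rec.strand if per_strand else ".")
        groups.setdefault(key, []).append(rec)

    clusters: list[RlfsCluster] = []
    for (name, strand), group in sorted(groups.items()):
        group = sorted(group, key=lambda r: (r.start, r.end))
        component: list[RlfsRecord] = []
        comp_end = -1
        def flush() -> None:
            if len(component) >= 2:
                span = GenomicInterval(
                    name,
                    min(r.start for r in component),
                    max(r.end for r in component),
                    strand,
                )
                clusters.append(RlfsCluster(tuple(component), span))
        for rec in group:
            if component and rec.start < comp_end:
                component.append(rec)
                comp_end = max(comp_end, rec.end)
            else:
                flush()
                component = [rec]
                comp_end = rec.end
        flush()
    return clusters


def _trees_by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def overlap_count(
    predicted: Sequence[GenomicInterval], reference: Sequence[GenomicInterval]
) -> tuple[int, int]:
    """Count reference intervals hit by >= 1 base of any prediction.

    Strand is ignored (experimental hybrid regions are strand-agnostic).
    Returns ``(n_reference, n_reference_hit)``.
    """
    trees = _trees_by_chrom(predicted)
    hit = 0
    for ref in reference:
        tree = trees.get(ref.chrom)
        if tree is not None and tree.overlaps(ref.start, ref.end):
            hit += 1
    return len(reference), hit


PRESENT, ABSENT = "present", "absent"


def confusion_metrics(
    calls: Sequence[tuple[str, str]]
) -> tuple[ConfusionTable, float, float, float]:
    """Confusion table and accuracy/sensitivity/specificity from call pairs.

    ``calls`` holds ``(experimental, predicted)`` pairs of 'present'/'absent'.
    Sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), accuracy =
    (tp+tn)/total; a metric with zero denominator is returned as NaN.
    """
    if not calls:
        raise ValueError("empty call list")
    tp = fp = tn = fn = 0
    for expt, pred in calls:
        if expt not in (PRESENT, ABSENT) or pred not in (PRESENT, ABSENT):
            raise ValueError(f"calls must be 'present'/'absent', got {(expt, pred)!r}")
        if expt == PRESENT:
            if pred == PRESENT:
                tp += 1
            else:
                fn += 1
        else:
            if pred == PRESENT:
                fp += 1
            else:
                tn += 1
    table = ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn)
    sens = tp / (tp + fn) if (tp + fn) else math.nan
    spec = tn / (tn + fp) if (tn + fp) else math.nan
    acc = (tp + tn) / table.total
    return table, acc, sens, spec


def sample_negative_regions(
    chrom_sizes: Sequence[tuple[str, int]],
    exclude: Sequence[GenomicInterval],
    n_regions: int,
    region_lengths: Sequence[int],
    replicates: int,
    seed: int,
    max_attempts: int = 10_000,
) -> list[list[GenomicInterval]]:
    """Sample replicate sets of random regions avoiding excluded signal.

    Each replicate holds ``n_regions`` intervals whose lengths are drawn with
    replacement from ``region_lengths`` (matching the reference set's length
    distribution), placed uniformly on the genome defined by ``chrom_sizes``
    and rejected while they share any base with an excluded interval.
    Identical seeds give identical output.
    """
    if n_regions <= 0 or replicates <= 0:
        raise ValueError("n_regions and replicates must be positive")
    if not region_lengths:
        raise ValueError("region_lengths is empty")
    rng = np.random.default_rng(seed)
    trees = _trees_by_chrom(exclude)
    names = [c for c, _ in chrom_sizes]
    sizes = np.array([s for _, s in chrom_sizes], dtype=np.int64)
    lengths_arr = np.asarray(region_lengths, dtype=np.int64)
    if (lengths_arr > sizes.max()).any():
        raise ValueError("a requested region length exceeds every chromosome")

    out: list[list[GenomicInterval]] = []
    for rep in range(replicates):
        regions: list[GenomicInterval] = []
        for _ in range(n_regions):
            L = int(lengths_arr[rng.integers(len(lengths_arr))])
            placed = False
            for _attempt in range(max_attempts):
                # chromosomes weighted by the feasible placement space
                space = np.maximum(sizes - L + 1, 0)
                total = space.sum()
                if total == 0:
                    break
                ci = int(rng.choice(len(names), p=space / total))
                start = int(rng.integers(space[ci]))
                tree = trees.get(names[ci])
                if tree is not None and tree.overlaps(start, start + L):
                    continue
                regions.append(GenomicInterval(names[ci], start, start + L))
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"replicate {rep}: could not place a {L}-nt region after "
                    f"{max_attempts} attempts (exclusions too dense)"
                )
        out.append(regions)
    return out


def read_bed(source: Union[str, Path, IO[str]]) -> list[GenomicInterval]:
    """Read a BED (3+ column) interval list; track/browser/# lines skipped."""
    close = False
    if isinstance(source, (str, Path)):
        handle: IO[str] = open(source)
        close = True
    else:
        handle = source
    try:
        intervals: list[GenomicInterval] = []
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if (
                not line
                or line.startswith("#")
                or line.startswith("track")
                or line.startswith("browser")
            ):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 columns")
            strand = fields[5] if len(fields) >= 6 else "."
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
        return intervals
    finally:
        if close:
            handle.close()


_CALL_ALIASES = {
    "present": PRESENT, "+": PRESENT, "1": PRESENT, "yes": PRESENT,
    "absent": ABSENT, "-": ABSENT, "0": ABSENT, "no": ABSENT,
}


def read_calls_table(
    source: Union[str, Path, IO[str]]
) -> list[tuple[str, str, str]]:
    """Read a tab-separated (locus, experimental, predicted) call table.

    Calls may be spelled present/absent, +/-, 1/0 or yes/no (case-
    insensitive).  A header line whose second and third columns are not
    recognizable calls is skipped.  Malformed rows raise an error listing
    every offending line.
    """
    close = False
    if isinstance(source, (str, Path)):
        handle: IO[str] = open(source)
        close = True
    else:
        handle = source
    try:
        rows: list[tuple[str, str, str]] = []
        bad: list[str] = []
        first_data_line = True
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                bad.append(f"line {lineno}: fewer than 3 columns")
                first_data_line = False
                continue
            locus = fields[0].strip()
            expt = _CALL_ALIASES.get(fields[1].strip().lower())
            pred = _CALL_ALIASES.get(fields[2].strip().lower())
            if expt is None or pred is None:
                if first_data_line:
                    first_data_line = False
                    continue  # header row
                bad.append(f"line {lineno}: unrecognized call labels {fields[1:3]}")
                continue
            first_data_line = False
            rows.append((locus, expt, pred))
        if bad:
            raise ValueError("malformed call table:\n" + "\n".join(bad))
        if not rows:
            raise ValueError("call table holds no data rows")
        return rows
    finally:
        if close:
            handle.close()
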