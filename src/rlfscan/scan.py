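"""RLFS structural models and the scanning algorithm.

An R-loop forming sequence (RLFS) is modelled as three consecutive elements on
the strand whose transcript would form the RNA-DNA hybrid:

* **RIZ** (R-loop initiation zone): a compact G-cluster region.  Model ``m1``
  needs at least three G-tracts of >= 3 contiguous G's; model ``m2`` needs at
  least two G-tracts of >= 4 contiguous G's.  Consecutive tracts are separated
  by 1-10 nt spacers of unconstrained composition, and the whole RIZ must be
  at least 50% G.
* **linker**: 0-50 nt of unconstrained composition.
* **REZ** (R-loop elongation zone): a 100-2000 nt window with at least 40% G.
  Among all qualifying (linker, window) combinations only the longest REZ is
  kept, so each RIZ yields at most one RLFS.

Scanning the minus strand means scanning the reverse complement and mapping
the hits back to forward-strand coordinates.  All intervals are 0-based,
half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .sequence_io import InputSequence, reverse_complement

MODELS = ("m1", "m2")
STRANDS = ("+", "-")


@dataclass(frozen=True)
class SearchParams:
    """Tunable parameters of the structural models.

    Defaults are the models' published values; changing them redefines the
    grammar (e.g. ``min_tract_m1`` is the minimum per-tract G-run length n1).
    """

    min_tract_m1: int = 3
    min_tract_m2: int = 4
    min_clusters_m1: int = 3
    min_clusters_m2: int = 2
    gap_min: int = 1
    gap_max: int = 10
    linker_min: int = 0
    linker_max: int = 50
    rez_min: int = 100
    rez_max: int = 2000
    riz_g_min: float = 0.50
    rez_g_min: float = 0.40
    models: tuple[str, ...] = MODELS
    strands: tuple[str, ...] = STRANDS

    def __post_init__(self) -> None:
        if self.min_tract_m1 < 3:
            raise ValueError("min_tract_m1 must be >= 3 (model m1 definition)")
        if self.min_tract_m2 < 4:
            raise ValueError("min_tract_m2 must be >= 4 (model m2 definition)")
        if not (1 <= self.gap_min <= self.gap_max):
            raise ValueError("need 1 <= gap_min <= gap_max")
        if not (0 <= self.linker_min <= self.linker_max):
            raise ValueError("need 0 <= linker_min <= linker_max")
        if not (0 < self.rez_min <= self.rez_max):
            raise ValueError("need 0 < rez_min <= rez_max")
        if not (0 < self.riz_g_min <= 1 and 0 < self.rez_g_min <= 1):
            raise ValueError("G-content thresholds must lie in (0, 1]")
        bad = set(self.models) - set(MODELS)
        if bad or not self.models:
            raise ValueError(f"models must be a non-empty subset of {MODELS}")
        bad = set(self.strands) - set(STRANDS)
        if bad or not self.strands:
            raise ValueError(f"strands must be a non-empty subset of {STRANDS}")

    def min_tract(self, model: str) -> int:
        return self.min_tract_m1 if model == "m1" else self.min_tract_m2

    def min_clusters(self, model: str) -> int:
        return self.min_clusters_m1 if model == "m1" else self.min_clusters_m2


@dataclass(frozen=True)
class RizMatch:
    """A candidate R-loop initiation zone on the scanned strand."""

    start: int
    end: int
    model: str
    n_clusters: int
    g_fraction: float


@dataclass(frozen=True)
class RlfsRecord:
    """One predicted RLFS; all intervals in forward-strand coordinates.

    For ``strand == '-'`` the REZ lies left of the RIZ on the forward strand
    (elements read RIZ-linker-REZ on the scanned reverse complement).
    ``chrom`` is set once the record has been remapped onto a chromosome
    anchor; ``source`` gives writers access to the underlying residues.
    """

    seq_name: str
    strand: str
    model: str
    riz_start: int
    riz_end: int
    n_clusters: int
    riz_g_fraction: float
    linker_length: int
    rez_start: int
    rez_end: int
    rez_g_fraction: float
    chrom: Optional[str] = None
    source: Optional[InputSequence] = field(default=None, repr=False, compare=False)

    @property
    def start(self) -> int:
        """RLFS start (leftmost base of RIZ/REZ on the forward strand)."""
        return min(self.riz_start, self.rez_start)

    @property
    def end(self) -> int:
        return max(self.riz_end, self.rez_end)

    @property
    def riz_length(self) -> int:
        return self.riz_end - self.riz_start

    @property
    def rez_length(self) -> int:
        return self.rez_end - self.rez_start

    @property
    def ref_name(self) -> str:
        """Name to report coordinates against (chromosome once remapped)."""
        return self.chrom if self.chrom is not None else self.seq_name

    def feature_interval(self, feature: str) -> tuple[int, int]:
        if feature == "RLFS":
            return self.start, self.end
        if feature == "RIZ":
            return self.riz_start, self.riz_end
        if feature == "REZ":
            return self.rez_start, self.rez_end
        raise ValueError(f"unknown feature {feature!r}")


def g_fraction(residues: str, start: int, end: int) -> float:
    """Fraction of 'G' in ``residues[start:end)``; N counts as non-G."""
    if not (0 <= start < end <= len(residues)):
        raise ValueError(f"invalid interval [{start}, {end}) for length {len(residues)}")
    return residues.count("G", start, end) / (end - start)


_G_RUN_RE = re.compile(r"G+")


def _g_runs(residues: str) -> list[tuple[int, int]]:
    """Maximal runs of contiguous G as (start, end) pairs."""
    return [(m.start(), m.end()) for m in _G_RUN_RE.finditer(residues)]


def find_riz(residues: str, model: str, params: SearchParams) -> list[RizMatch]:
    """Find every maximal RIZ match of ``model`` in normalized residues.

    A tract is a maximal G-run of at least the model's minimum length; a
    chain of tracts qualifies when consecutive tracts are separated by
    ``gap_min..gap_max`` intervening characters (which may contain shorter
    G-runs but never a tract).  Chains are extended greedily to the maximum
    number of tracts, so matches are maximal and never nested; chains with
    fewer clusters than the model requires, or with overall G content below
    ``riz_g_min``, are discarded.
    """
    min_tract = params.min_tract(model)
    min_clusters = params.min_clusters(model)
    tracts = [(s, e) for s, e in _g_runs(residues) if e - s >= min_tract]
    matches: list[RizMatch] = []
    i = 0
    while i < len(tracts):
        # grow a chain while the inter-tract gap stays in [gap_min, gap_max]
        j = i
        while (
            j + 1 < len(tracts)
            and params.gap_min <= tracts[j + 1][0] - tracts[j][1] <= params.gap_max
        ):
            j += 1
        if j - i + 1 >= min_clusters:
            start, end = tracts[i][0], tracts[j][1]
            frac = g_fraction(residues, start, end)
            if frac >= params.riz_g_min:
                matches.append(
                    RizMatch(
                        start=start,
                        end=end,
                        model=model,
                        n_clusters=j - i + 1,
                        g_fraction=frac,
                    )
                )
        i = j + 1
    return matches


def _g_prefix(residues: str) -> np.ndarray:
    """prefix[i] = number of G's in residues[:i]."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    prefix = np.zeros(len(residues) + 1, dtype=np.int64)
    np.cumsum(arr == ord("G"), out=prefix[1:])
    return prefix


def find_best_rez(
    residues: str,
    riz_end: int,
    params: SearchParams,
    _gprefix: Optional[np.ndarray] = None,
) -> Optional[tuple[int, int, int, float]]:
    """Search linker/window space downstream of a RIZ for the longest REZ.

    Enumerates every linker length in ``[linker_min, linker_max]`` and every
    window length in ``[rez_min, min(rez_max, remaining)]`` starting at
    ``riz_end + linker``; among windows whose G fraction meets ``rez_g_min``
    returns the one maximizing window length, breaking ties by the smallest
    linker.  Returns ``(linker_length, rez_start, rez_end, rez_g_fraction)``
    or ``None`` when no combination qualifies.
    """
    if not (0 <= riz_end <= len(residues)):
        raise ValueError("riz_end out of range")
    prefix = _g_prefix(residues) if _gprefix is None else _gprefix
    n = len(residues)
    best: Optional[tuple[int, int, int, float]] = None
    best_z = params.rez_min - 1
    for linker in range(params.linker_min, params.linker_max + 1):
        start = riz_end + linker
        z_cap = min(params.rez_max, n - start)
        if z_cap < params.rez_min:
            break  # remaining length only shrinks as the linker grows
        # scan down from the cap; stop once no window could beat the best
        for z in range(z_cap, best_z, -1):
            g = int(prefix[start + z] - prefix[start])
            frac = g / z
            if frac >= params.rez_g_min:
                best = (linker, start, start + z, frac)
                best_z = z
                break
    return best


def _mirror(start: int, end: int, length: int) -> tuple[int, int]:
    return length - end, length - start


def assemble_rlfs(seq: InputSequence, params: SearchParams = SearchParams()) -> list[RlfsRecord]:
    """Run the full RIZ -> linker/REZ search on both strands of a sequence.

    Each RIZ contributes at most one record (paired with its longest REZ);
    minus-strand hits are reported in forward-strand coordinates with strand
    '-'.  Records identical in both intervals across models are deduplicated
    in favor of m1.  Output is sorted by (strand, start).
    """
    records: list[RlfsRecord] = []
    length = len(seq.residues)
    for strand in STRANDS:
        if strand not in params.strands:
            continue
        scanned = seq.residues if strand == "+" else reverse_complement(seq.residues)
        prefix = _g_prefix(scanned)
        seen: set[tuple[int, int, int, int]] = set()
        for model in MODELS:  # m1 first so deduplication keeps m1
            if model not in params.models:
                continue
            for riz in find_riz(scanned, model, params):
                hit = find_best_rez(scanned, riz.end, params, _gprefix=prefix)
                if hit is None:
                    continue
                linker, rez_s, rez_e, rez_frac = hit
                riz_s, riz_e = riz.start, riz.end
                if strand == "-":
                    riz_s, riz_e = _mirror(riz.start, riz.end, length)
                    rez_s, rez_e = _mirror(rez_s, rez_e, length)
                key = (riz_s, riz_e, rez_s, rez_e)
                if key in seen:
                    continue
                seen.add(key)
                records.append(
                    RlfsRecord(
                        seq_name=seq.name,
                        strand=strand,
                        model=model,
                        riz_start=riz_s,
                        riz_end=riz_e,
                        n_clusters=riz.n_clusters,
                        riz_g_fraction=riz.g_fraction,
                        linker_length=linker,
                        rez_start=rez_s,
                        rez_end=rez_e,
                        rez_g_fraction=rez_frac,
                        source=seq,
                    )
                )
    records.sort(key=lambda r: (0 if r.strand == "+" else 1, r.start, r.end, r.model))
    return records


def scan_records(
    sequences: Sequence[InputSequence], params: SearchParams = SearchParams()
) -> list[RlfsRecord]:
    """Scan several sequences, concatenating their record lists in order."""
    out: list[RlfsRecord] = []
    for seq in sequences:
        out.extend(assemble_rlfs(seq, params))
    return out
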