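"""Synthetic sequences with known planted RLFS structure.

The generator builds guaranteed-negative backgrounds (no G- or C-run of
length 3 or more, and every 100-nt window below the REZ G-content threshold
on either strand, so neither structural model can fire on either strand) and
splices RIZ-linker-REZ constructs with exact
tract/gap geometry and a controlled REZ G content into them.  Every construct
records its ground truth, so scanner recovery can be asserted without any
external data.

Recovery is containment/overlap based, not equality based: the scanner may
legitimately extend a planted tract with adjacent background guanines on the
left, or extend a planted REZ into flanking sequence while the window still
clears the G-content threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Optional, Sequence

import numpy as np

from .scan import SearchParams
from .sequence_io import reverse_complement

_NON_G = "ATC"


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of one planted construct (forward-strand coordinates)."""

    sequence: str
    model: str
    strand: str
    riz_start: int
    riz_end: int
    n_clusters: int
    linker_length: int
    rez_start: int
    rez_end: int
    rez_g_target: float
    n_g_planted: int
    seed: Optional[int] = None

    @property
    def start(self) -> int:
        return min(self.riz_start, self.rez_start)

    @property
    def end(self) -> int:
        return max(self.riz_end, self.rez_end)


def make_background(
    length: int,
    g_ceiling: float,
    seed: int,
    params: SearchParams = SearchParams(),
) -> str:
    """Random sequence in which no structural model can fire.

    Guarantees (deterministically, not just in expectation), on *both*
    strands: no run of 3 or more consecutive G, and every 100-nt window has
    G fraction strictly below ``params.rez_g_min``.  Since the minus strand
    reads C as G, the constraints are applied symmetrically to G and C.
    ``g_ceiling`` sets the marginal G (and C) probability and must lie below
    ``params.rez_g_min``; at 0 the sequence is A/T only.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0 <= g_ceiling < params.rez_g_min):
        raise ValueError(
            f"g_ceiling must lie in [0, rez_g_min={params.rez_g_min}); "
            f"got {g_ceiling} (constraints infeasible)"
        )
    rng = np.random.default_rng(seed)
    window = 100
    # strict inequality: at most ceil(window * rez_g_min) - 1 G (or C) per window
    max_per_window = int(np.ceil(window * params.rez_g_min)) - 1
    chars: list[str] = []
    counts = {"G": 0, "C": 0}
    for i in range(length):
        if i >= window:
            old = chars[i - window]
            if old in counts:
                counts[old] -= 1
        allowed = {
            base: not (
                (len(chars) >= 2 and chars[-1] == base and chars[-2] == base)
                or counts[base] >= max_per_window
            )
            for base in ("G", "C")
        }
        r = rng.random()
        if r < g_ceiling and allowed["G"]:
            base = "G"
        elif r < 2 * g_ceiling and allowed["C"]:
            base = "C"
        else:
            base = "AT"[rng.integers(2)]
        chars.append(base)
        if base in counts:
            counts[base] += 1
    return "".join(chars)


def _validate_riz_spec(
    model: str,
    tract_lengths: Sequence[int],
    gap_lengths: Sequence[int],
    params: SearchParams,
) -> None:
    if model not in ("m1", "m2"):
        raise ValueError(f"unknown model {model!r}")
    if len(gap_lengths) != len(tract_lengths) - 1:
        raise ValueError("need exactly one gap between consecutive tracts")
    if len(tract_lengths) < params.min_clusters(model):
        raise ValueError(
            f"model {model} needs >= {params.min_clusters(model)} G-tracts"
        )
    min_tract = params.min_tract(model)
    if any(t < min_tract for t in tract_lengths):
        raise ValueError(f"model {model} tracts must each be >= {min_tract} G")
    if any(not (params.gap_min <= g <= params.gap_max) for g in gap_lengths):
        raise ValueError(
            f"gaps must lie in [{params.gap_min}, {params.gap_max}]"
        )
    total = sum(tract_lengths) + sum(gap_lengths)
    if sum(tract_lengths) / total < params.riz_g_min:
        raise ValueError(
            "tract/gap geometry puts RIZ G content below riz_g_min"
        )


def plant_rlfs(
    background: str,
    position: int,
    riz_spec: tuple[str, Sequence[int], Sequence[int]],
    linker_length: int,
    rez_length: int,
    rez_g_target: float,
    strand: str = "+",
    seed: int = 0,
    params: SearchParams = SearchParams(),
) -> tuple[str, PlantedTruth]:
    """Splice a RIZ-linker-REZ construct into a background sequence.

    ``riz_spec`` is ``(model, tract_lengths, gap_lengths)``; the grammar is
    validated before any generation.  The REZ receives
    ``round(rez_g_target * rez_length)`` guanines at random positions
    (sub-threshold targets are allowed so threshold sharpness can be probed).
    On strand '-' the reverse complement of the construct is spliced, so the
    motif reads RIZ-linker-REZ on the minus strand.  Returns the modified
    sequence and the ground truth in forward-strand coordinates.
    """
    model, tract_lengths, gap_lengths = riz_spec
    _validate_riz_spec(model, tract_lengths, gap_lengths, params)
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    if not (params.linker_min <= linker_length <= params.linker_max):
        raise ValueError("linker_length outside model bounds")
    if rez_length < params.rez_min:
        raise ValueError(f"rez_length must be >= {params.rez_min}")
    if not (0 <= rez_g_target <= 1):
        raise ValueError("rez_g_target must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    parts: list[str] = []
    for k, tract in enumerate(tract_lengths):
        parts.append("G" * tract)
        if k < len(gap_lengths):
            parts.append(
                "".join(_NON_G[rng.integers(3)] for _ in range(gap_lengths[k]))
            )
    riz = "".join(parts)
    linker = "".join("AT"[rng.integers(2)] for _ in range(linker_length))

    n_g = int(round(rez_g_target * rez_length))
    # keep the REZ head G-free when the linker is short enough that a leading
    # REZ tract could chain onto the RIZ and dilute its G content
    guard = params.gap_max + 1 if linker_length <= params.gap_max else 0
    if rez_length - guard < n_g:
        raise ValueError("rez_g_target too high for the guarded REZ layout")
    rez_chars = [_NON_G[rng.integers(3)] for _ in range(rez_length)]
    g_positions = rng.choice(np.arange(guard, rez_length), size=n_g, replace=False)
    for p in g_positions:
        rez_chars[int(p)] = "G"
    rez = "".join(rez_chars)

    construct = riz + linker + rez
    if position < 0 or position + len(construct) > len(background):
        raise ValueError("construct does not fit in the background at position")
    forward = construct if strand == "+" else reverse_complement(construct)
    sequence = (
        background[:position] + forward + background[position + len(construct):]
    )
    if strand == "+":
        riz_iv = (position, position + len(riz))
        rez_iv = (position + len(riz) + linker_length,
                  position + len(construct))
    else:
        rez_iv = (position, position + rez_length)
        riz_iv = (position + rez_length + linker_length,
                  position + len(construct))
    truth = PlantedTruth(
        sequence=sequence,
        model=model,
        strand=strand,
        riz_start=riz_iv[0],
        riz_end=riz_iv[1],
        n_clusters=len(tract_lengths),
        linker_length=linker_length,
        rez_start=rez_iv[0],
        rez_end=rez_iv[1],
        rez_g_target=rez_g_target,
        n_g_planted=n_g,
        seed=seed,
    )
    return sequence, truth


def random_planted(
    seed: int,
    model: Optional[str] = None,
    strand: Optional[str] = None,
    background_length: int = 1200,
    g_ceiling: float = 0.2,
    params: SearchParams = SearchParams(),
) -> tuple[str, PlantedTruth]:
    """One random valid construct in a random negative background.

    Geometry (tract count/lengths, gaps, linker, REZ length and G target) is
    drawn uniformly within the model grammar; the REZ G target stays in a
    threshold-adjacent band just above ``rez_g_min``.
    """
    rng = np.random.default_rng(seed)
    model = model or ("m1", "m2")[rng.integers(2)]
    strand = strand or "+-"[rng.integers(2)]
    n_tracts = int(rng.integers(params.min_clusters(model),
                                params.min_clusters(model) + 3))
    tracts = [int(rng.integers(params.min_tract(model),
                               params.min_tract(model) + 4))
              for _ in range(n_tracts)]
    # keep gaps compatible with the >= 50% RIZ G-content rule
    max_total_gap = max(1, sum(tracts))  # G fraction >= sum(tracts)/(2*sum) = 0.5
    gaps = []
    budget = max_total_gap - (n_tracts - 1) * params.gap_min
    for _ in range(n_tracts - 1):
        hi = min(params.gap_max, params.gap_min + max(budget, 0))
        g = int(rng.integers(params.gap_min, hi + 1))
        budget -= g - params.gap_min
        gaps.append(g)
    linker = int(rng.integers(params.linker_min, params.linker_max + 1))
    rez_length = int(rng.integers(params.rez_min, 3 * params.rez_min))
    rez_target = float(params.rez_g_min + rng.uniform(0.0, 0.05))
    background = make_background(background_length, g_ceiling,
                                 int(rng.integers(2**31)), params)
    construct_len = sum(tracts) + sum(gaps) + linker + rez_length
    position = int(rng.integers(0, background_length - construct_len + 1))
    return plant_rlfs(
        background, position, (model, tracts, gaps), linker, rez_length,
        rez_target, strand, seed=int(rng.integers(2**31)), params=params,
    )


def write_truth_tsv(truths: Iterable[PlantedTruth], sink: IO[str]) -> int:
    """Write a truth sidecar table for fixture FASTA files."""
    cols = (
        "model", "strand", "riz_start", "riz_end", "n_clusters",
        "linker_length", "rez_start", "rez_end", "rez_g_target",
    )
    sink.write("\t".join(cols) + "\n")
    n = 0
    for t in truths:
        sink.write(
            "\t".join(
                str(v)
                for v in (
                    t.model, t.strand, t.riz_start, t.riz_end, t.n_clusters,
                    t.linker_length, t.rez_start, t.rez_end, t.rez_g_target,
                )
            )
            + "\n"
        )
        n += 1
    return n
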