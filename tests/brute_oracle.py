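"""Independent brute-force reference for the RIZ/REZ search.

Deliberately naive: RIZ matches are found by enumerating candidate
substrings and checking the tract/gap grammar directly, keeping only
substrings not contained in a larger match; the REZ search enumerates every
(linker, window) pair.  Shares no code with the package's scanner beyond the
grammar definition itself.
"""

from __future__ import annotations

import re
from bisect import bisect_left

_RUN_RE = re.compile(r"G+")


def g_runs(s: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in _RUN_RE.finditer(s)]


def substring_matches_grammar(
    sub: str, min_tract: int, min_clusters: int, gap_min: int, gap_max: int
) -> bool:
    """Does the whole substring match tract(gap tract)+ with model bounds?

    Tracts are maximal G-runs of at least ``min_tract``; the substring must
    begin with the first base of a tract and end with the last base of a
    tract; gaps between consecutive tracts (which may contain shorter G-runs)
    must have lengths in [gap_min, gap_max].
    """
    runs = g_runs(sub)
    if not runs:
        return False
    if runs[0][0] != 0 or runs[0][1] - runs[0][0] < min_tract:
        return False
    if runs[-1][1] != len(sub) or runs[-1][1] - runs[-1][0] < min_tract:
        return False
    tracts = [(s, e) for s, e in runs if e - s >= min_tract]
    if len(tracts) < min_clusters:
        return False
    for (s1, e1), (s2, e2) in zip(tracts, tracts[1:]):
        if not (gap_min <= s2 - e1 <= gap_max):
            return False
    return True


def brute_find_riz(residues: str, model: str, params) -> list[tuple[int, int, int, float]]:
    """All maximal RIZ matches as (start, end, n_clusters, g_fraction)."""
    min_tract = params.min_tract(model)
    min_clusters = params.min_clusters(model)
    n = len(residues)
    # candidate boundaries must touch G; min length bounds prune the search
    g_at = [i for i in range(n) if residues[i] == "G"]
    min_len = min_clusters * min_tract + (min_clusters - 1) * params.gap_min
    matches: list[tuple[int, int]] = []
    for s in g_at:
        lo = bisect_left(g_at, s + min_len - 1)
        for e_minus_1 in g_at[lo:]:
            sub = residues[s : e_minus_1 + 1]
            if substring_matches_grammar(
                sub, min_tract, min_clusters, params.gap_min, params.gap_max
            ):
                matches.append((s, e_minus_1 + 1))
    # containment sweep: sorted by (start, -end), a match is maximal iff its
    # end exceeds every end seen at an earlier-or-equal start
    maximal = []
    max_end = -1
    for s, e in sorted(set(matches), key=lambda iv: (iv[0], -iv[1])):
        if e > max_end:
            maximal.append((s, e))
            max_end = e
    out = []
    for s, e in sorted(maximal):
        frac = residues.count("G", s, e) / (e - s)
        if frac >= params.riz_g_min:
            sub = residues[s:e]
            n_clusters = sum(
                1 for rs, re_ in g_runs(sub) if re_ - rs >= min_tract
            )
            out.append((s, e, n_clusters, frac))
    return out


def brute_find_best_rez(residues: str, riz_end: int, params):
    """Exhaustive (linker, window) enumeration keeping the longest REZ."""
    n = len(residues)
    best = None  # (z, -linker) preference encoded by explicit comparison
    for linker in range(params.linker_min, params.linker_max + 1):
        start = riz_end + linker
        for z in range(params.rez_min, min(params.rez_max, n - start) + 1):
            g = residues.count("G", start, start + z)
            if g / z >= params.rez_g_min:
                if best is None or z > best[0]:
                    best = (z, linker, start, start + z, g / z)
    if best is None:
        return None
    _, linker, s, e, frac = best
    return (linker, s, e, frac)


def brute_assemble(residues: str, params, revcomp) -> list[tuple]:
    """Full search on both strands; forward-strand coordinates.

    Returns tuples (strand, model, riz_start, riz_end, n_clusters,
    linker, rez_start, rez_end) with identical-interval cross-model
    duplicates resolved in favor of m1, sorted by (strand, start).
    """
    length = len(residues)
    chosen: dict[tuple, tuple] = {}
    for strand in params.strands:
        scanned = residues if strand == "+" else revcomp(residues)
        for model in [m for m in ("m1", "m2") if m in params.models]:
            for s, e, n_clusters, _frac in brute_find_riz(scanned, model, params):
                hit = brute_find_best_rez(scanned, e, params)
                if hit is None:
                    continue
                linker, rs, re_, _rfrac = hit
                if strand == "-":
                    s, e, rs, re_ = length - e, length - s, length - re_, length - rs
                key = (strand, s, e, rs, re_)
                if key not in chosen:  # m1 visited first
                    chosen[key] = (strand, model, s, e, n_clusters, linker, rs, re_)
    return sorted(
        chosen.values(),
        key=lambda t: (0 if t[0] == "+" else 1, min(t[2], t[6]), max(t[3], t[7]), t[1]),
    )
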