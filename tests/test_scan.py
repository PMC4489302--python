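import dataclasses

import numpy as np
import pytest

from conftest import as_input, random_sequence
from rlfscan import (
    InputSequence,
    SearchParams,
    assemble_rlfs,
    find_best_rez,
    find_riz,
    g_fraction,
    reverse_complement,
)


class TestGFraction:
    @pytest.mark.parametrize(
        "residues,start,end,expected",
        [("GGGA", 0, 4, 0.75), ("TTTT", 0, 4, 0.0), ("GNGN", 0, 4, 0.5)],
    )
    def test_known_values(self, residues, start, end, expected):
        assert g_fraction(residues, start, end) == expected

    @pytest.mark.parametrize("start,end", [(2, 2), (3, 1), (-1, 2), (0, 9)])
    def test_degenerate_intervals_rejected(self, start, end):
        with pytest.raises(ValueError):
            g_fraction("ACGTACGT", start, end)


class TestFindRiz:
    def test_three_tract_m1_match(self, params):
        (m,) = find_riz("GGGAGGGTGGG", "m1", params)
        assert (m.start, m.end, m.n_clusters) == (0, 11, 3)
        assert m.g_fraction == pytest.approx(9 / 11)

    def test_gap_above_maximum_breaks_the_chain(self, params):
        assert find_riz("GGGG" + "T" * 11 + "GGGG", "m2", params) == []

    def test_no_guanine_no_match(self, params):
        assert find_riz("A" * 200, "m1", params) == []
        assert find_riz("A" * 200, "m2", params) == []

    def test_single_tract_fails_cluster_count(self, params):
        assert find_riz("GGGG", "m2", params) == []

    def test_low_g_content_match_is_discarded(self, params):
        # three minimal tracts with maximal gaps: 9 G over 29 nt < 50%
        s = "GGG" + "AT" * 5 + "GGG" + "AT" * 5 + "GGG"
        assert find_riz(s, "m1", params) == []

    def test_greedy_extension_counts_all_tracts(self, params):
        s = "GGGA" * 5 + "GGG"
        (m,) = find_riz(s, "m1", params)
        assert m.n_clusters == 6 and (m.start, m.end) == (0, len(s))

    def test_short_runs_live_inside_gaps(self, params):
        # GG runs are not m1 tracts; they sit inside the 1-10 nt gaps
        s = "GGGAGGAGGGAGGAGGG"
        (m,) = find_riz(s, "m1", params)
        assert m.n_clusters == 3

    def test_widening_gap_bounds_only_merges_or_preserves_candidates(self, rng):
        # every pre-%G-filter match under the narrow gap range is contained
        # in a match under the wider range
        loose = {"riz_g_min": 1e-9}
        narrow = SearchParams(gap_min=1, gap_max=6, **loose)
        wide = SearchParams(gap_min=1, gap_max=10, **loose)
        for _ in range(25):
            s = random_sequence(rng, max_len=300)
            for model in ("m1", "m2"):
                wide_ivs = [(m.start, m.end) for m in find_riz(s, model, wide)]
                for m in find_riz(s, model, narrow):
                    assert any(ws <= m.start and m.end <= we for ws, we in wide_ivs)


class TestFindBestRez:
    def test_insufficient_remaining_length(self, params):
        residues = "A" * 60  # riz_end 10 leaves 50 nt < rez_min
        assert find_best_rez(residues, 10, params) is None

    def test_exact_threshold_window_is_kept(self, params):
        # 40 G in the first 100 nt after riz_end, then all T: the 100-nt
        # window passes at exactly 40% and no longer window keeps 40%
        residues = "A" * 10 + "G" * 40 + "T" * 60 + "T" * 200
        assert find_best_rez(residues, 10, params) == (0, 10, 110, pytest.approx(0.40))

    def test_window_capped_at_rez_max(self, params):
        residues = "A" * 5 + "G" * 2500
        linker, start, end, frac = find_best_rez(residues, 5, params)
        assert (linker, start, end - start, frac) == (0, 5, 2000, 1.0)

    def test_ties_prefer_the_smallest_linker(self, params):
        # all-G tail: every linker reaches the same capped window length
        residues = "G" * 400
        linker, start, end, _ = find_best_rez(residues, 0, params)
        assert linker == 0 and (start, end) == (0, 400)

    def test_one_below_threshold_fails(self, params):
        residues = "A" * 10 + "G" * 39 + "T" * 61
        assert find_best_rez(residues, 10, params) is None


def _planted_sequence():
    """RIZ + 5 nt linker + 150 nt REZ at 40% G, flanked by A/T."""
    riz = "GGGAGGGTGGG"
    linker = "ATATA"
    rez = "GGTTT" * 30  # 40% G, no run of 3
    return "TATA" * 10 + riz + linker + rez + "ATTA" * 30, len("TATA" * 10)


class TestAssemble:
    def test_all_a_sequence_yields_nothing(self, params):
        assert assemble_rlfs(as_input("A" * 500), params) == []

    def test_planted_motif_recovered_on_plus_strand_only(self, params):
        s, offset = _planted_sequence()
        records = assemble_rlfs(as_input(s), params)
        plus = [r for r in records if r.strand == "+"]
        assert len(plus) >= 1
        rec = plus[0]
        assert rec.riz_start == offset and rec.riz_end == offset + 11
        assert rec.rez_end - rec.rez_start >= 150
        assert rec.rez_g_fraction >= params.rez_g_min

    def test_strand_symmetry(self, params, rng):
        for _ in range(10):
            s = random_sequence(rng, max_len=400)
            fwd = assemble_rlfs(as_input(s), params)
            rev = assemble_rlfs(as_input(reverse_complement(s)), params)
            L = len(s)
            mirrored = sorted(
                ("+-"[r.strand == "+"], r.model,
                 L - r.riz_end, L - r.riz_start, L - r.rez_end, L - r.rez_start)
                for r in rev
            )
            original = sorted(
                (r.strand, r.model,
                 r.riz_start, r.riz_end, r.rez_start, r.rez_end)
                for r in fwd
            )
            assert original == mirrored

    def test_internal_g_clusters_do_not_truncate_the_rez(self, params):
        # a second RIZ planted inside the REZ must stay inside the REZ span
        s, offset = _planted_sequence()
        inner = "GGGAGGGAGGG"
        inner_at = offset + 11 + 5 + 60
        s = s[:inner_at] + inner + s[inner_at + len(inner):]
        records = assemble_rlfs(as_input(s), params)
        outer = [r for r in records if r.riz_start == offset]
        assert outer, "outer RIZ lost"
        assert outer[0].rez_end >= inner_at + len(inner)

    def test_emitted_records_satisfy_model_invariants(self, params, rng):
        checked = 0
        for _ in range(30):
            s = random_sequence(rng, max_len=500)
            seq = as_input(s)
            for rec in assemble_rlfs(seq, params):
                checked += 1
                assert 0 <= rec.start < rec.end <= len(s)
                assert params.rez_min <= rec.rez_length <= params.rez_max
                assert rec.rez_g_fraction >= params.rez_g_min
                assert rec.riz_g_fraction >= params.riz_g_min
                assert rec.n_clusters >= params.min_clusters(rec.model)
                scanned = s if rec.strand == "+" else reverse_complement(s)
                L = len(s)
                if rec.strand == "+":
                    riz = (rec.riz_start, rec.riz_end)
                    rez = (rec.rez_start, rec.rez_end)
                else:
                    riz = (L - rec.riz_end, L - rec.riz_start)
                    rez = (L - rec.rez_end, L - rec.rez_start)
                assert scanned[riz[0]] == "G" and scanned[riz[1] - 1] == "G"
                assert riz[1] + rec.linker_length == rez[0]
        assert checked > 0, "stress inputs produced no records at all"

    def test_raising_rez_threshold_only_shrinks_the_record_set(self, rng):
        base = SearchParams()
        strict = SearchParams(rez_g_min=0.5)
        for _ in range(15):
            s = random_sequence(rng, max_len=400)
            loose_keys = {
                (r.strand, r.model, r.riz_start, r.riz_end)
                for r in assemble_rlfs(as_input(s), base)
            }
            strict_keys = {
                (r.strand, r.model, r.riz_start, r.riz_end)
                for r in assemble_rlfs(as_input(s), strict)
            }
            assert strict_keys <= loose_keys

    def test_output_sorted_by_strand_then_start(self, params, rng):
        for _ in range(10):
            records = assemble_rlfs(as_input(random_sequence(rng)), params)
            keys = [(0 if r.strand == "+" else 1, r.start) for r in records]
            assert keys == sorted(keys)


class TestSearchParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_tract_m1": 2},
            {"min_tract_m2": 3},
            {"gap_min": 0},
            {"gap_min": 5, "gap_max": 4},
            {"linker_min": -1},
            {"rez_min": 0},
            {"riz_g_min": 0.0},
            {"rez_g_min": 1.5},
            {"models": ()},
            {"strands": ("x",)},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SearchParams(**kwargs)

    def test_params_are_immutable(self, params):
        with pytest.raises(dataclasses.FrozenInstanceError):
            params.gap_max = 12
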