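"""Encoding, ISSL index recall, and off-target scoring."""
from __future__ import annotations

import numpy as np
import pytest

from conftest import naive_hamming, naive_hamming_ball, random_dna

from crisprdesk.fixtures import mutate_spacer
from crisprdesk.offtarget_index import (
    EncodedSpacer,
    EncodingError,
    ISSLIndex,
    IndexConfigError,
    SliceConfig,
    assess_offtarget,
    build_index,
    decode_spacer,
    encode_spacer,
    hamming_distance,
    hit_score,
    mismatch_positions,
    specificity_score,
)


class TestEncoding:
    @pytest.mark.parametrize(
        "spacer,value",
        [
            ("A" * 20, 0),
            ("T" * 20, 4**20 - 1),  # 1,099,511,627,775
            ("C" + "A" * 19, 4**19),  # 274,877,906,944
        ],
    )
    def test_known_codes(self, spacer, value):
        assert encode_spacer(spacer) == value

    def test_decode_inverts_encode(self, rng):
        for _ in range(100):
            s = random_dna(rng, 20)
            assert decode_spacer(encode_spacer(s)) == s

    @pytest.mark.parametrize("bad", ["A" * 19, "A" * 21, "AAAAANAAAAAAAAAAAAAA"])
    def test_invalid_spacers_rejected(self, bad):
        with pytest.raises(EncodingError):
            encode_spacer(bad)

    def test_bitwise_hamming_matches_string_comparison(self, rng):
        for _ in range(200):
            a, b = random_dna(rng, 20), random_dna(rng, 20)
            assert hamming_distance(encode_spacer(a), encode_spacer(b)) == naive_hamming(a, b)

    def test_mismatch_positions_match_string_scan(self, rng):
        for _ in range(100):
            a, b = random_dna(rng, 20), random_dna(rng, 20)
            expected = {i + 1 for i in range(20) if a[i] != b[i]}
            assert mismatch_positions(encode_spacer(a), encode_spacer(b)) == expected


class TestSliceConfig:
    def test_default_is_five_by_four(self):
        cfg = SliceConfig()
        assert (cfg.num_slices, cfg.slice_width_bases) == (5, 4)

    @pytest.mark.parametrize("n", [0, 3, 7, 21])
    def test_non_divisors_rejected(self, n):
        with pytest.raises(IndexConfigError):
            SliceConfig(num_slices=n)

    def test_signatures_cover_the_code(self):
        cfg = SliceConfig(num_slices=5)
        value = encode_spacer("ACGTACGTACGTACGTACGT")
        rebuilt = 0
        for p in range(5):
            rebuilt = (rebuilt << 8) | cfg.signature(value, p)
        assert rebuilt == value


class TestBuildIndex:
    def test_single_spacer_in_every_slice_table(self):
        idx = build_index({"ACGT" * 5: 1})
        assert idx.num_distinct == 1 and idx.num_sites == 1
        for table in idx.slices:
            assert sum(len(v) for v in table.values()) == 1

    def test_near_identical_spacers_share_four_of_five_buckets(self):
        a = "ACGT" * 5
        b = "T" + a[1:]  # differ only at base 1 (first slice)
        idx = build_index({a: 1, b: 1})
        shared = 0
        for p, table in enumerate(idx.slices):
            sigs = {idx.config.signature(encode_spacer(s), p) for s in (a, b)}
            if len(sigs) == 1:
                shared += 1
        assert shared == 4

    def test_counts_aggregate(self):
        idx = build_index({"ACGT" * 5: 3})
        assert idx.num_sites == 3 and idx.num_distinct == 1

    def test_empty_input_rejected(self):
        with pytest.raises(IndexConfigError):
            build_index({})


class TestQueryNeighbours:
    def test_self_match(self):
        s = "ACGT" * 5
        idx = build_index({s: 1})
        assert idx.query_neighbours(s) == [(EncodedSpacer(encode_spacer(s), 1), 0)]

    @pytest.mark.parametrize("dist,found", [(4, True), (5, False)])
    def test_planted_neighbour_at_boundary_distance(self, rng, dist, found):
        query = random_dna(rng, 20)
        planted = mutate_spacer(query, dist, rng)
        assert naive_hamming(query, planted) == dist
        idx = build_index({planted: 1})
        hits = idx.query_neighbours(query, max_mm=4)
        if found:
            assert hits == [(EncodedSpacer(encode_spacer(planted), 1), dist)]
        else:
            assert hits == []

    def test_recall_bound_enforced(self):
        idx = build_index({"A" * 20: 1})
        with pytest.raises(IndexConfigError):
            idx.query_neighbours("A" * 20, max_mm=5)

    def test_exhaustive_recall_on_random_spacer_set(self, rng):
        # pigeonhole guarantee: the slice-gathered set, after verification,
        # equals the brute-force Hamming ball for every max_mm
        spacers = {random_dna(rng, 20): int(rng.integers(1, 4)) for _ in range(300)}
        idx = build_index(spacers)
        queries = [random_dna(rng, 20) for _ in range(10)]
        queries += [mutate_spacer(rng.choice(list(spacers)), d, rng) for d in (0, 1, 2, 3, 4)]
        for q in queries:
            for max_mm in range(5):
                got = {(n.spacer, d) for n, d in idx.query_neighbours(q, max_mm=max_mm)}
                assert got == naive_hamming_ball(spacers, q, max_mm)

    def test_monotone_in_max_mm(self, rng):
        spacers = {random_dna(rng, 20): 1 for _ in range(100)}
        idx = build_index(spacers)
        q = mutate_spacer(list(spacers)[0], 3, rng)
        previous: set = set()
        for max_mm in range(5):
            current = {n.value for n, _ in idx.query_neighbours(q, max_mm=max_mm)}
            assert previous <= current
            previous = current

    def test_results_sorted_by_distance_then_value(self, rng):
        spacers = {random_dna(rng, 20): 1 for _ in range(200)}
        idx = build_index(spacers)
        hits = idx.query_neighbours(list(spacers)[0], max_mm=4)
        keys = [(d, n.value) for n, d in hits]
        assert keys == sorted(keys)


class TestSerialization:
    def test_save_load_round_trip_queries(self, rng, tmp_path):
        spacers = {random_dna(rng, 20): int(rng.integers(1, 5)) for _ in range(150)}
        idx = build_index(spacers)
        path = tmp_path / "genome.issl"
        idx.save(path)
        back = ISSLIndex.load(path)
        assert back.num_distinct == idx.num_distinct
        assert back.num_sites == idx.num_sites
        for _ in range(20):
            q = random_dna(rng, 20)
            assert back.query_neighbours(q) == idx.query_neighbours(q)

    def test_text_dump_lists_every_spacer(self, rng):
        spacers = {random_dna(rng, 20): 1 for _ in range(10)}
        idx = build_index(spacers)
        dump = idx.dump_text()
        for s in spacers:
            assert s in dump


class TestHitScore:
    @pytest.mark.parametrize(
        "positions,expected",
        [((), 100.0), ((5,), 50.0), ((1, 2), 25.0), ((3, 9, 17), 12.5)],
    )
    def test_uniform_closed_forms(self, positions, expected):
        assert hit_score(positions, "uniform") == pytest.approx(expected)

    def test_literature_weights_penalize_pam_proximal_more(self):
        # position 20 sits against the PAM; mismatches there are better
        # tolerated metrics-wise than seed-distal ones under these weights
        assert hit_score([20], "literature") < hit_score([1], "literature")

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            hit_score([0], "uniform")
        with pytest.raises(ValueError):
            hit_score([21], "uniform")


class TestSpecificity:
    def test_clean_guide_scores_100(self):
        s = "ACGT" * 5
        idx = build_index({s: 1})
        res = assess_offtarget(idx, s)
        assert res.specificity == pytest.approx(100.0)
        assert res.neighbour_counts[0] == 1

    def test_one_exact_duplicate_halves_score(self):
        s = "ACGT" * 5
        idx = build_index({s: 2})
        assert assess_offtarget(idx, s).specificity == pytest.approx(50.0)

    def test_two_exact_duplicates(self):
        s = "ACGT" * 5
        idx = build_index({s: 3})
        assert assess_offtarget(idx, s).specificity == pytest.approx(10000 / 300)

    def test_query_absent_from_index_has_no_self_hit(self, rng):
        s = "A" * 20
        dup = "C" * 20
        idx = build_index({dup: 1})
        res = assess_offtarget(idx, s)
        # nothing within 4 mismatches at all
        assert res.specificity == pytest.approx(100.0)
        assert res.neighbour_counts[0] == 0

    def test_adding_offtargets_never_raises_specificity(self, rng):
        s = random_dna(rng, 20)
        base = {s: 1}
        idx = build_index(base)
        score = assess_offtarget(idx, s).specificity
        for d in (1, 2, 3, 4):
            base[mutate_spacer(s, d, rng)] = 1
            new_score = assess_offtarget(build_index(base), s).specificity
            assert new_score <= score + 1e-12
            score = new_score

    def test_neighbour_counts_weighted_by_occurrences(self, rng):
        s = "ACGT" * 5
        near = mutate_spacer(s, 2, np.random.default_rng(0))
        idx = build_index({s: 1, near: 4})
        res = assess_offtarget(idx, s)
        assert res.neighbour_counts[0] == 1
        assert res.neighbour_counts[2] == 4
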