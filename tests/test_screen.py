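"""The TE-CNE extraction screen: overlap arithmetic, strict thresholds,
equivalence with the brute-force oracle, and monotonicity."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coopte.model import GenomicInterval
from coopte.screen import filter_family, overlap_length, screen_te_cnes

from _oracles import overlap_per_base, screen_all_pairs
from conftest import mk_element, mk_repeat


def random_instance(rng, n_rep, n_el, span=50_000, chroms=("chr1", "chr2")):
    repeats = []
    for i in range(n_rep):
        start = int(rng.integers(0, span))
        length = int(rng.integers(20, 600))
        name = rng.choice(["AmnSINE1", "X6b_DNA", "MER117", "MIR", "(TA)n"])
        cls = "Simple_repeat" if name == "(TA)n" else "SINE/Deu"
        repeats.append(
            mk_repeat(
                chrom=str(rng.choice(chroms)), start=start, end=start + length,
                name=str(name), repeat_class=cls, join_id=i + 1,
            )
        )
    elements = []
    for _ in range(n_el):
        start = int(rng.integers(0, span))
        length = int(rng.integers(20, 500))
        lod = int(rng.integers(0, 400))
        elements.append(
            mk_element(
                chrom=str(rng.choice(chroms)), start=start,
                end=start + length, lod=lod,
            )
        )
    return repeats, elements


class TestOverlapLength:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("chr1", 100, 200), ("chr1", 150, 250), 50),
            (("chr1", 100, 200), ("chr1", 200, 300), 0),  # abutting
            (("chr1", 100, 200), ("chr2", 100, 200), 0),  # other chrom
            (("chr1", 100, 200), ("chr1", 120, 150), 30),  # containment
        ],
    )
    def test_examples(self, a, b, expected):
        ia, ib = GenomicInterval(*a), GenomicInterval(*b)
        assert overlap_length(ia, ib) == expected
        assert overlap_length(ib, ia) == expected  # symmetric

    def test_equals_per_base_intersection_on_random_pairs(self, rng):
        for _ in range(1000):
            a = GenomicInterval(
                "chr1", int(rng.integers(0, 500)),
                int(rng.integers(501, 1000)),
            )
            b = GenomicInterval(
                str(rng.choice(["chr1", "chr2"])),
                int(rng.integers(0, 500)), int(rng.integers(501, 1000)),
            )
            assert overlap_length(a, b) == overlap_per_base(a, b)


class TestScreenThresholds:
    def test_overlap_boundary_is_strict(self):
        element = mk_element(start=170, end=300, lod=500)
        at_30 = mk_repeat(start=140, end=200)  # overlap exactly 30
        at_31 = mk_repeat(start=140, end=201)  # overlap 31
        assert screen_te_cnes([at_30], [element]) == []
        (hit,) = screen_te_cnes([at_31], [element])
        assert hit.overlap_bp == 31

    def test_lod_boundary_is_strict(self):
        repeat = mk_repeat(start=0, end=300)
        at_100 = mk_element(start=0, end=200, lod=100)
        at_101 = mk_element(start=0, end=200, lod=101)
        assert screen_te_cnes([repeat], [at_100]) == []
        (hit,) = screen_te_cnes([repeat], [at_101])
        assert hit.max_lod == 101

    def test_overlap_summed_across_fragmented_elements(self):
        # two 20-bp conserved blocks: fails per-element, passes summed
        repeat = mk_repeat(start=0, end=100)
        blocks = [
            mk_element(start=10, end=30, lod=500),
            mk_element(start=60, end=80, lod=500),
        ]
        (hit,) = screen_te_cnes(repeat and [repeat], blocks)
        assert hit.overlap_bp == 40
        assert screen_te_cnes([repeat], blocks, per_element=True) == []

    def test_non_te_classes_excluded_by_default(self):
        simple = mk_repeat(start=0, end=100, name="(TA)n",
                           repeat_class="Simple_repeat")
        element = mk_element(start=0, end=100, lod=500)
        assert screen_te_cnes([simple], [element]) == []
        assert len(screen_te_cnes([simple], [element], include_non_te=True)) == 1

    def test_empty_inputs_give_empty_result(self):
        assert screen_te_cnes([], [mk_element()]) == []
        assert screen_te_cnes([mk_repeat()], []) == []


class TestScreenOracleEquivalence:
    def test_matches_all_pairs_reference_on_random_instances(self, rng):
        for _ in range(60):
            repeats, elements = random_instance(
                rng, int(rng.integers(0, 120)), int(rng.integers(0, 60))
            )
            got = screen_te_cnes(repeats, elements)
            expected = screen_all_pairs(repeats, elements)
            got_keys = {
                (t.chrom, t.start, t.end, t.repeat.join_id) for t in got
            }
            exp_keys = {
                (
                    repeats[i].interval.chrom,
                    repeats[i].interval.start,
                    repeats[i].interval.end,
                    repeats[i].join_id,
                )
                for i in expected
            }
            assert got_keys == exp_keys
            by_key = {
                (t.chrom, t.start, t.end, t.repeat.join_id): t for t in got
            }
            for i, (ov, lod, ids) in expected.items():
                r = repeats[i]
                t = by_key[
                    (r.interval.chrom, r.interval.start, r.interval.end,
                     r.join_id)
                ]
                assert (t.overlap_bp, t.max_lod, t.element_ids) == (ov, lod, ids)

    def test_raising_thresholds_never_adds_hits(self, rng):
        repeats, elements = random_instance(rng, 150, 80)

        def keyset(result):
            return {(t.chrom, t.start, t.end, t.repeat.join_id) for t in result}

        base = keyset(screen_te_cnes(repeats, elements, 30, 100))
        assert keyset(screen_te_cnes(repeats, elements, 60, 100)) <= base
        assert keyset(screen_te_cnes(repeats, elements, 30, 200)) <= base
        assert keyset(screen_te_cnes(repeats, elements, 60, 200)) <= base

    def test_screening_is_idempotent(self, rng):
        repeats, elements = random_instance(rng, 150, 80)
        once = screen_te_cnes(repeats, elements)
        twice = screen_te_cnes([t.repeat for t in once], elements)
        assert twice == once

    def test_output_sorted_by_position(self, rng):
        repeats, elements = random_instance(rng, 200, 80)
        out = screen_te_cnes(repeats, elements)
        keys = [(t.chrom, t.start, t.end) for t in out]
        assert keys == sorted(keys)


class TestFilterFamily:
    def _mixed(self):
        repeats = [
            mk_repeat(start=i * 1000, end=i * 1000 + 100, name=n)
            for i, n in enumerate(["AmnSINE1", "MER117", "MER130", "AmnSINE1"])
        ]
        element = mk_element(start=0, end=10_000, lod=500)
        return screen_te_cnes(repeats, [element])

    def test_exact_name(self):
        out = filter_family(self._mixed(), "AmnSINE1")
        assert [t.repeat_name for t in out] == ["AmnSINE1", "AmnSINE1"]

    def test_star_is_identity(self):
        tecnes = self._mixed()
        assert filter_family(tecnes, "*") == tecnes

    def test_single_char_glob(self):
        # MER11? matches MER117 but not MER130
        out = filter_family(self._mixed(), "MER11?")
        assert [t.repeat_name for t in out] == ["MER117"]

    @given(st.sampled_from(["AmnSINE1", "MER117", "MER130", "X6b_DNA"]))
    @settings(derandomize=True, max_examples=20)
    def test_exact_pattern_agrees_with_equality(self, name):
        tecnes = self._mixed()
        assert filter_family(tecnes, name) == [
            t for t in tecnes if t.repeat_name == name
        ]
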