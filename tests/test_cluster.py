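"""Proximity chaining into composite loci and companion statistics."""

from __future__ import annotations

import numpy as np
import pytest

from coopte.cluster import chain_proximal, companion_stats

from _oracles import cluster_union_find
from conftest import mk_tecne


def random_tecnes(rng, n, span=100_000):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(50, 500))
        out.append(
            mk_tecne(
                chrom=str(rng.choice(["chr1", "chr2"])),
                start=start,
                end=start + length,
                name=str(rng.choice(["AmnSINE1", "X6b_DNA", "MER117", "MIR"])),
            )
        )
    return out


class TestChainProximal:
    def test_three_te_arrangement_chains_into_one_locus(self):
        # the flagship pattern: SINE + two DNA transposons, gaps 0 and 45
        a = mk_tecne(start=1000, end=1100, name="AmnSINE1")
        b = mk_tecne(start=1100, end=1500, name="X6b_DNA")
        c = mk_tecne(start=1545, end=1900, name="MER117")
        (locus,) = chain_proximal([a, b, c])
        assert [m.repeat_name for m in locus.members] == [
            "AmnSINE1", "X6b_DNA", "MER117"
        ]
        assert locus.gaps == (0, 45)
        assert (locus.span.start, locus.span.end) == (1000, 1900)
        assert locus.is_composite

    def test_gap_boundary_is_strict(self):
        a = mk_tecne(start=0, end=100)
        at_600 = mk_tecne(start=700, end=800, name="MER117")
        at_599 = mk_tecne(start=699, end=800, name="MER117")
        assert len(chain_proximal([a, at_600])) == 2
        assert len(chain_proximal([a, at_599])) == 1

    def test_overlapping_members_have_gap_zero(self):
        a = mk_tecne(start=0, end=200)
        b = mk_tecne(start=100, end=300, name="MER117")
        (locus,) = chain_proximal([a, b])
        assert locus.gaps == (0,)

    def test_chaining_is_transitive_single_linkage(self):
        # a-b and b-c pass, a-c alone would not: all three share a locus
        a = mk_tecne(start=0, end=100)
        b = mk_tecne(start=500, end=600, name="X6b_DNA")
        c = mk_tecne(start=1000, end=1100, name="MER117")
        assert max(0, c.start - a.end) >= 600
        (locus,) = chain_proximal([a, b, c])
        assert locus.n_members == 3

    def test_different_chromosomes_never_chain(self):
        a = mk_tecne(chrom="chr1", start=0, end=100)
        b = mk_tecne(chrom="chr2", start=100, end=200)
        assert len(chain_proximal([a, b])) == 2

    def test_partition_matches_union_find_oracle(self, rng):
        for _ in range(40):
            tecnes = random_tecnes(rng, int(rng.integers(0, 120)))
            loci = chain_proximal(tecnes)
            idx = {id(t): i for i, t in enumerate(tecnes)}
            got = {
                frozenset(idx[id(m)] for m in locus.members) for locus in loci
            }
            assert got == cluster_union_find(tecnes)

    def test_partition_preserves_member_multiset(self, rng):
        tecnes = random_tecnes(rng, 200)
        loci = chain_proximal(tecnes)
        members = [m for l in loci for m in l.members]
        assert sorted(members, key=lambda t: (t.chrom, t.start, t.end, id(t))) \
            == sorted(tecnes, key=lambda t: (t.chrom, t.start, t.end, id(t)))

    def test_wider_gap_threshold_never_increases_locus_count(self, rng):
        tecnes = random_tecnes(rng, 150)
        counts = [
            len(chain_proximal(tecnes, max_gap_bp=g))
            for g in (100, 300, 600, 1200, 5000)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCompanionStats:
    def test_printed_percentage_convention(self):
        # 54 accompanied out of 626 focal elements prints as 8.6
        singles = [
            mk_tecne(chrom="chr1", start=i * 10_000, end=i * 10_000 + 300)
            for i in range(572)
        ]
        pairs = []
        for i in range(54):
            base = 10_000_000 + i * 10_000
            pairs.append(mk_tecne(chrom="chr2", start=base, end=base + 300))
            pairs.append(
                mk_tecne(chrom="chr2", start=base + 400, end=base + 700,
                         name="MER117", repeat_class="DNA/hAT-Charlie")
            )
        loci = chain_proximal(singles + pairs)
        stats = companion_stats(loci, "AmnSINE1")
        assert (stats.n_focal, stats.n_accompanied) == (626, 54)
        assert stats.pct_accompanied == 8.6

    def test_rounding_is_half_up(self):
        # 1 of 8 = 12.5 -> 12.5; 1 of 16 = 6.25 -> 6.3 (half-up)
        singles = [
            mk_tecne(start=i * 10_000, end=i * 10_000 + 100) for i in range(15)
        ]
        pair = [
            mk_tecne(chrom="chr2", start=0, end=100),
            mk_tecne(chrom="chr2", start=200, end=300, name="MER117"),
        ]
        stats = companion_stats(chain_proximal(singles + pair), "AmnSINE1")
        assert stats.n_focal == 16
        assert stats.pct_accompanied == 6.3

    def test_all_singletons_give_zero(self):
        singles = [
            mk_tecne(start=i * 10_000, end=i * 10_000 + 100) for i in range(5)
        ]
        stats = companion_stats(chain_proximal(singles), "AmnSINE1")
        assert (stats.n_accompanied, stats.pct_accompanied) == (0, 0.0)

    def test_same_family_fragments_do_not_count_as_companions(self):
        two_fragments = [
            mk_tecne(start=0, end=100),
            mk_tecne(start=200, end=300),
        ]
        stats = companion_stats(chain_proximal(two_fragments), "AmnSINE1")
        assert stats.n_focal == 2
        assert stats.n_accompanied == 0

    def test_no_focal_elements_is_defined_not_an_error(self):
        loci = chain_proximal([mk_tecne(name="MER117")])
        stats = companion_stats(loci, "AmnSINE1")
        assert stats.n_focal == 0
        assert stats.pct_accompanied is None

    def test_counts_equal_direct_per_locus_recount(self, rng):
        tecnes = random_tecnes(rng, 250)
        loci = chain_proximal(tecnes)
        stats = companion_stats(loci, "AmnSINE1")
        n_focal = sum(
            1 for l in loci for m in l.members if m.repeat_name == "AmnSINE1"
        )
        n_acc = sum(
            1
            for l in loci
            for m in l.members
            if m.repeat_name == "AmnSINE1"
            and any(x.repeat_name != "AmnSINE1" for x in l.members)
        )
        assert (stats.n_focal, stats.n_accompanied) == (n_focal, n_acc)
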