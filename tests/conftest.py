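from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pytest

from coopte.model import (
    ConservedElement,
    GenomicInterval,
    RepeatAnnotation,
    TeCne,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def mk_repeat(
    chrom="chr1",
    start=0,
    end=100,
    name="AmnSINE1",
    repeat_class="SINE/Deu",
    strand="+",
    join_id=1,
    sw_score=500,
):
    return RepeatAnnotation(
        interval=GenomicInterval(chrom, start, end, strand),
        repeat_name=name,
        repeat_class=repeat_class,
        sw_score=sw_score,
        pct_div=10.0,
        pct_del=0.0,
        pct_ins=0.0,
        cons_begin=1,
        cons_end=max(1, end - start),
        cons_left=0,
        join_id=join_id,
    )


def mk_element(chrom="chr1", start=0, end=100, lod=300):
    return ConservedElement(
        interval=GenomicInterval(chrom, start, end), lod=lod, name=f"lod={lod}"
    )


def mk_tecne(chrom="chr1", start=0, end=100, name="AmnSINE1",
             repeat_class="SINE/Deu", overlap_bp=None, max_lod=300):
    return TeCne(
        repeat=mk_repeat(chrom, start, end, name, repeat_class),
        overlap_bp=overlap_bp if overlap_bp is not None else (end - start),
        max_lod=max_lod,
        element_ids=(f"{chrom}:{start}-{end}",),
    )


def mammal_tree() -> dendropy.Tree:
    """(platypus,(opossum,(mouse,human))) with labelled internal clades."""
    tree = dendropy.Tree.get(
        data="(platypus,(opossum,(mouse,human)Eutheria)Theria)Mammalia;",
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = True
    return tree


def random_rooted_tree(rng: np.random.Generator, n_leaves: int) -> dendropy.Tree:
    """Random rooted binary-ish topology over leaves s0..s{n-1}."""
    labels = [f"s{i}" for i in range(n_leaves)]

    def build(names: list[str]) -> str:
        if len(names) == 1:
            return names[0]
        k = int(rng.integers(1, len(names)))
        return f"({build(names[:k])},{build(names[k:])})"

    order = [labels[i] for i in rng.permutation(n_leaves)]
    tree = dendropy.Tree.get(
        data=build(order) + ";",
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = True
    return tree
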