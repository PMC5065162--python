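"""Chaining proximal TE-CNEs into composite candidate enhancer loci.

The motivating arrangement is a conserved locus built from three distinct
TEs inserted side-by-side (a SINE plus two DNA-transposon relics acting as
one distal enhancer).  Candidates for that pattern are chains of TE-derived
CNEs whose neighbour gaps are strictly below a proximity threshold
(default 600 bp).  Chaining is single-linkage and therefore transitive: a
chain may span more than the threshold overall, which is intended — the
flagship locus itself is ~800 bp of TEs inside a 1.2-kb conserved element.

Proximity is measured between the repeat intervals themselves, not between
the conserved elements they overlap.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fnmatch import fnmatchcase
from typing import Sequence

from ._util import round_half_up
from .model import CompositeLocus, GenomicInterval, TeCne

__all__ = ["chain_proximal", "companion_stats", "CompanionStats"]


def _gap(prev: TeCne, nxt: TeCne) -> int:
    return max(0, nxt.start - prev.end)


def chain_proximal(
    tecnes: Sequence[TeCne], max_gap_bp: int = 600
) -> list[CompositeLocus]:
    """Partition TE-CNEs into single-linkage chains of proximal elements.

    Two elements are linked when they are on the same chromosome and the gap
    between their repeat intervals is strictly below ``max_gap_bp``
    (overlapping repeats have gap 0).  Linkage is transitive.  Every input
    element lands in exactly one locus; singletons are loci of one member.

    Returns loci sorted by (chrom, start).
    """
    if max_gap_bp <= 0:
        raise ValueError("max_gap_bp must be positive")
    ordered = sorted(tecnes, key=lambda t: (t.chrom, t.start, t.end))
    loci: list[CompositeLocus] = []
    cluster: list[TeCne] = []
    cluster_max_end = 0

    def flush() -> None:
        if not cluster:
            return
        gaps = tuple(
            _gap(cluster[i], cluster[i + 1]) for i in range(len(cluster) - 1)
        )
        span = GenomicInterval(
            cluster[0].chrom, cluster[0].start, max(m.end for m in cluster)
        )
        loci.append(CompositeLocus(members=tuple(cluster), span=span, gaps=gaps))

    for t in ordered:
        if (
            cluster
            and t.chrom == cluster[0].chrom
            and max(0, t.start - cluster_max_end) < max_gap_bp
        ):
            cluster.append(t)
            cluster_max_end = max(cluster_max_end, t.end)
        else:
            flush()
            cluster = [t]
            cluster_max_end = t.end
    flush()
    return loci


@dataclass(frozen=True)
class CompanionStats:
    """Summary of how often a focal TE family is accompanied by other TEs."""

    focal_family: str
    n_focal: int
    n_accompanied: int
    pct_accompanied: float | None  # None when n_focal == 0
    companion_families: dict[str, int] = field(default_factory=dict)
    companion_classes: dict[str, int] = field(default_factory=dict)
    n_loci: int = 0
    n_composite_loci: int = 0


def companion_stats(
    loci: Sequence[CompositeLocus], focal_family: str
) -> CompanionStats:
    """Count focal-family TE-CNEs accompanied by conserved TEs of other families.

    A focal element is "accompanied" when its locus contains at least one
    member of a *different* repeat family — two fragments of the same family
    do not make a composite.  The percentage is rounded half-up to one
    decimal place, matching how such fractions are quoted (e.g. 54 of 626
    prints as 8.6).
    """
    if not focal_family:
        raise ValueError("focal_family must be non-empty")
    n_focal = 0
    n_accompanied = 0
    fam_counter: Counter[str] = Counter()
    cls_counter: Counter[str] = Counter()
    n_composite = 0
    for locus in loci:
        if locus.is_composite:
            n_composite += 1
        focal_members = [
            m for m in locus.members if fnmatchcase(m.repeat_name, focal_family)
        ]
        n_focal += len(focal_members)
        if not focal_members:
            continue
        companions = [
            m
            for m in locus.members
            if m.repeat_name != focal_members[0].repeat_name
        ]
        accompanied = [
            m
            for m in focal_members
            if any(c.repeat_name != m.repeat_name for c in locus.members)
        ]
        n_accompanied += len(accompanied)
        if accompanied:
            for c in companions:
                fam_counter[c.repeat_name] += 1
                cls_counter[c.repeat.repeat_class] += 1
    pct = (
        round_half_up(100.0 * n_accompanied / n_focal, 1) if n_focal else None
    )
    return CompanionStats(
        focal_family=focal_family,
        n_focal=n_focal,
        n_accompanied=n_accompanied,
        pct_accompanied=pct,
        companion_families=dict(fam_counter),
        companion_classes=dict(cls_counter),
        n_loci=len(loci),
        n_composite_loci=n_composite,
    )
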