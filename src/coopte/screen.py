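"""Extraction of TE-derived conserved non-coding elements (TE-CNEs).

A repeat annotation qualifies when its total overlap with conserved elements
whose LOD score strictly exceeds ``min_lod`` strictly exceeds
``min_overlap_bp`` (defaults 100 and 30 bp).  Both inequalities are strict.
Overlap is summed over all qualifying conserved elements per repeat, because
conservation tracks fragment arbitrarily while the biological unit of
interest is the TE copy; ``per_element=True`` instead requires a single
conserved element to clear the threshold on its own.

Simple repeats, low-complexity runs and other non-TE annotation classes are
excluded by default — they are repeats, not transposable elements.
"""

from __future__ import annotations

from collections import defaultdict
from fnmatch import fnmatchcase
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .model import (
    ConservedElement,
    GenomicInterval,
    RepeatAnnotation,
    TeCne,
)

__all__ = ["overlap_length", "screen_te_cnes", "filter_family", "merge_joins", "subtract_bed"]


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two half-open intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_joins(repeats: Sequence[RepeatAnnotation]) -> list[RepeatAnnotation]:
    """Merge fragments sharing a join ID into one spanning annotation.

    RepeatMasker splits interrupted insertions into several rows linked by the
    ID column.  The merged record spans from the first fragment's start to the
    last fragment's end, takes identity fields from the highest-scoring
    fragment, and unions the consensus span.
    """
    groups: dict[tuple[str, int], list[RepeatAnnotation]] = defaultdict(list)
    for r in repeats:
        groups[(r.interval.chrom, r.join_id)].append(r)
    merged: list[RepeatAnnotation] = []
    for frags in groups.values():
        if len(frags) == 1:
            merged.append(frags[0])
            continue
        best = max(frags, key=lambda r: r.sw_score)
        start = min(r.interval.start for r in frags)
        end = max(r.interval.end for r in frags)
        merged.append(
            RepeatAnnotation(
                interval=GenomicInterval(
                    best.interval.chrom, start, end, best.interval.strand
                ),
                repeat_name=best.repeat_name,
                repeat_class=best.repeat_class,
                sw_score=best.sw_score,
                pct_div=best.pct_div,
                pct_del=best.pct_del,
                pct_ins=best.pct_ins,
                cons_begin=min(r.cons_begin for r in frags),
                cons_end=max(r.cons_end for r in frags),
                cons_left=min(r.cons_left for r in frags),
                join_id=best.join_id,
                overlapped=any(r.overlapped for r in frags),
                query_left=min(r.query_left for r in frags),
            )
        )
    merged.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    return merged


def subtract_bed(
    elements: Sequence[ConservedElement],
    mask: Sequence[GenomicInterval],
) -> list[ConservedElement]:
    """Remove masked sub-intervals (e.g. exons) from conserved elements.

    Each conserved element is clipped against the mask; surviving pieces keep
    the parent's LOD.  Used for optional exon exclusion ahead of the screen.
    """
    by_chrom: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in mask:
        by_chrom[iv.chrom].addi(iv.start, iv.end)
    out: list[ConservedElement] = []
    for e in elements:
        tree = by_chrom.get(e.interval.chrom)
        if not tree:
            out.append(e)
            continue
        pieces = [(e.interval.start, e.interval.end)]
        for hit in sorted(tree.overlap(e.interval.start, e.interval.end)):
            next_pieces = []
            for s, t in pieces:
                if hit.end <= s or hit.begin >= t:
                    next_pieces.append((s, t))
                    continue
                if s < hit.begin:
                    next_pieces.append((s, hit.begin))
                if hit.end < t:
                    next_pieces.append((hit.end, t))
            pieces = next_pieces
        for s, t in pieces:
            out.append(
                ConservedElement(
                    interval=GenomicInterval(e.interval.chrom, s, t),
                    lod=e.lod,
                    name=e.name,
                )
            )
    out.sort(key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end))
    return out


def screen_te_cnes(
    repeats: Iterable[RepeatAnnotation],
    elements: Iterable[ConservedElement],
    min_overlap_bp: int = 30,
    min_lod: int = 100,
    *,
    per_element: bool = False,
    include_non_te: bool = False,
) -> list[TeCne]:
    """Extract every TE annotation overlapping conserved elements.

    Parameters
    ----------
    repeats, elements
        Parsed annotation rows and conserved-track records.
    min_overlap_bp
        Strict lower bound on the overlap in bp (default 30: an overlap of
        exactly 30 bp does NOT qualify).
    min_lod
        Strict lower bound on the conserved element's LOD score (default
        100: LOD exactly 100 does NOT qualify).
    per_element
        Require a single conserved element to exceed ``min_overlap_bp`` on
        its own instead of summing across elements.
    include_non_te
        Also screen simple/low-complexity repeat classes.

    Returns
    -------
    list of TeCne sorted by (chrom, start), one per qualifying repeat.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    lods: dict[tuple[str, int, int], tuple[int, str]] = {}
    for e in elements:
        if e.lod > min_lod:
            iv = e.interval
            trees[iv.chrom].addi(iv.start, iv.end, e)
    out: list[TeCne] = []
    for r in repeats:
        if not include_non_te and not r.is_te:
            continue
        tree = trees.get(r.interval.chrom)
        if not tree:
            continue
        total = 0
        best_single = 0
        max_lod = 0
        ids: list[str] = []
        for hit in tree.overlap(r.interval.start, r.interval.end):
            ov = min(r.interval.end, hit.end) - max(r.interval.start, hit.begin)
            if ov <= 0:
                continue
            total += ov
            best_single = max(best_single, ov)
            max_lod = max(max_lod, hit.data.lod)
            ids.append(hit.data.element_id)
        qualifying = best_single if per_element else total
        if qualifying > min_overlap_bp:
            out.append(
                TeCne(
                    repeat=r,
                    overlap_bp=min(total, r.interval.length),
                    max_lod=max_lod,
                    element_ids=tuple(sorted(ids)),
                )
            )
    out.sort(key=lambda t: (t.chrom, t.start, t.end))
    return out


def filter_family(tecnes: Sequence[TeCne], family_pattern: str) -> list[TeCne]:
    """Restrict screened TE-CNEs to a focal subfamily.

    ``family_pattern`` is matched case-sensitively against ``repeat_name``
    as an exact name or shell-style glob (``*``, ``?``, ``[...]``).
    """
    return [t for t in tecnes if fnmatchcase(t.repeat_name, family_pattern)]
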