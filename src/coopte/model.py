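"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)`` everywhere
inside the package; conversion from the 1-based inclusive conventions of
RepeatMasker ``.out`` files (and from any other external dialect) happens at
the I/O boundary only.  Consensus coordinates, by contrast, are kept 1-based
inclusive because that is how repeat libraries and the literature quote them
(e.g. "positions 391-501 of the consensus").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fnmatch import fnmatchcase
from typing import Iterable, Mapping, Sequence

import numpy as np

#: repeat_class values that RepeatMasker emits but that are not transposable
#: elements; the screen excludes them by default.
NON_TE_CLASSES = frozenset(
    {
        "Simple_repeat",
        "Low_complexity",
        "Satellite",
        "rRNA",
        "tRNA",
        "snRNA",
        "scRNA",
        "srpRNA",
        "RNA",
        "Unknown",
        "ARTEFACT",
    }
)


def _class_is_te(repeat_class: str) -> bool:
    # class strings look like "SINE/MIR", "DNA/hAT-Charlie", "Simple_repeat"
    head = repeat_class.split("/", 1)[0]
    return head not in NON_TE_CLASSES


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class RepeatAnnotation:
    """One RepeatMasker ``.out`` row, coordinate-normalized.

    ``cons_begin``/``cons_end`` are 1-based inclusive on the consensus and are
    normalized so ``cons_begin <= cons_end`` regardless of strand (the raw
    file swaps the column order for complement-strand hits).  ``cons_left`` is
    the number of consensus bases beyond ``cons_end``; ``query_left`` the
    bases remaining on the query contig (kept so files round-trip).
    """

    interval: GenomicInterval
    repeat_name: str
    repeat_class: str
    sw_score: int
    pct_div: float
    pct_del: float
    pct_ins: float
    cons_begin: int
    cons_end: int
    cons_left: int = 0
    join_id: int = 0
    overlapped: bool = False  # "*" flag: overlapped by a higher-scoring hit
    query_left: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.cons_begin <= self.cons_end):
            raise ValueError(
                f"invalid consensus span {self.cons_begin}-{self.cons_end} "
                f"for {self.repeat_name}"
            )
        for name in ("pct_div", "pct_del", "pct_ins"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.sw_score < 0:
            raise ValueError(f"sw_score={self.sw_score} < 0")

    @property
    def is_te(self) -> bool:
        """Whether the repeat class denotes a transposable element."""
        return _class_is_te(self.repeat_class)


@dataclass(frozen=True)
class ConservedElement:
    """One conserved-track record (phastCons-style) with its LOD score."""

    interval: GenomicInterval
    lod: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.lod < 0:
            raise ValueError(f"lod={self.lod} < 0")

    @property
    def element_id(self) -> str:
        return str(self.interval)


@dataclass(frozen=True)
class TeCne:
    """A repeat annotation certified as overlapping conserved elements.

    Produced by the screen; carries the summed overlap with qualifying
    conserved elements, the maximum LOD among them and their identifiers.
    """

    repeat: RepeatAnnotation
    overlap_bp: int
    max_lod: int
    element_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.overlap_bp <= 0:
            raise ValueError("overlap_bp must be positive")
        if self.overlap_bp > self.repeat.interval.length:
            raise ValueError("overlap_bp exceeds repeat length")

    @property
    def interval(self) -> GenomicInterval:
        return self.repeat.interval

    @property
    def chrom(self) -> str:
        return self.repeat.interval.chrom

    @property
    def start(self) -> int:
        return self.repeat.interval.start

    @property
    def end(self) -> int:
        return self.repeat.interval.end

    @property
    def repeat_name(self) -> str:
        return self.repeat.repeat_name


@dataclass(frozen=True)
class CompositeLocus:
    """An ordered chain of proximal TE-derived CNEs on one chromosome."""

    members: tuple[TeCne, ...]
    span: GenomicInterval
    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a locus needs at least one member")
        if len(self.gaps) != len(self.members) - 1:
            raise ValueError("need exactly len(members)-1 gaps")
        chroms = {m.chrom for m in self.members}
        if len(chroms) != 1:
            raise ValueError("locus members span multiple chromosomes")
        starts = [m.start for m in self.members]
        if starts != sorted(starts):
            raise ValueError("members must be sorted by start")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def is_composite(self) -> bool:
        return len(self.members) >= 2

    @property
    def distinct_families(self) -> frozenset[str]:
        return frozenset(m.repeat_name for m in self.members)

    def contains_family(self, pattern: str) -> bool:
        """True if any member's repeat_name matches the exact-or-glob pattern."""
        return any(fnmatchcase(m.repeat_name, pattern) for m in self.members)


@dataclass(frozen=True)
class ConsensusMatch:
    """Best local alignment of a genomic sub-element to a TE consensus.

    ``cons_span`` is 1-based inclusive on the consensus.  ``locus_start`` /
    ``locus_end`` are 0-based half-open offsets into the query sequence as
    given (forward orientation even when the reverse complement aligned,
    with ``strand`` recording the orientation).
    """

    element_name: str
    pct_identity: float
    cons_span: tuple[int, int] | None
    locus_start: int
    locus_end: int
    strand: str
    score: float
    n_columns: int
    n_matches: int
    n_gap_columns: int

    def __post_init__(self) -> None:
        if self.n_matches > self.n_columns or self.n_gap_columns > self.n_columns:
            raise ValueError("alignment column accounting is inconsistent")
        if self.cons_span is not None:
            b, e = self.cons_span
            if not (1 <= b <= e):
                raise ValueError(f"invalid consensus span {self.cons_span}")


@dataclass
class PresenceMatrix:
    """Element x species boolean occurrence table."""

    species: list[str]
    elements: list[str]
    present: np.ndarray  # shape (n_elements, n_species), bool

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.elements), len(self.species)):
            raise ValueError("presence table shape does not match labels")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species in presence table")
        if len(set(self.elements)) != len(self.elements):
            raise ValueError("duplicate elements in presence table")
        if self.elements and not self.present.any(axis=1).all():
            bad = [
                e for e, row in zip(self.elements, self.present) if not row.any()
            ]
            raise ValueError(
                f"element(s) absent in every species: {', '.join(bad)}"
            )

    def row(self, element: str) -> dict[str, bool]:
        """Presence of one element as a species -> bool mapping."""
        i = self.elements.index(element)
        return dict(zip(self.species, (bool(v) for v in self.present[i])))


@dataclass(frozen=True)
class GainAssignment:
    """A TE sub-element's inferred branch of integration on the species tree."""

    element: str
    clade_name: str
    n_losses: int
    present_species: tuple[str, ...]
    gain_node: object = field(default=None, compare=False, hash=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_losses < 0:
            raise ValueError("n_losses < 0")


def sorted_by_position(items: Iterable, key=lambda x: x.interval) -> list:
    """Sort annotation-like objects by (chrom, start, end)."""
    return sorted(items, key=lambda x: (key(x).chrom, key(x).start, key(x).end))
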