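"""Readers and writers for every external format the pipeline touches.

Coordinate conventions are converted here and nowhere else:

* RepeatMasker ``.out`` query coordinates are 1-based inclusive on disk and
  become 0-based half-open in memory.  Complement-strand rows list their
  consensus columns as ``(left) end begin``; they are normalized at parse time
  so downstream code always sees ``cons_begin <= cons_end``.
* BED is already 0-based half-open and is kept as such.  The conserved-element
  dialect carries the LOD score in the name field as ``lod=N`` (UCSC style),
  falling back to the score column.
* Presence tables are TSV with a header line of species names; newick trees are
  parsed with dendropy and FASTA with Biopython.

Output tables produced by the pipeline are TSV with one commented header line.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import validate_dna
from .model import (
    ConservedElement,
    GenomicInterval,
    PresenceMatrix,
    RepeatAnnotation,
)

__all__ = [
    "ParseError",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_conserved_bed",
    "write_conserved_bed",
    "read_presence_table",
    "write_presence_table",
    "read_species_tree",
    "read_fasta",
    "write_fasta",
    "write_table",
    "read_table",
]


class ParseError(ValueError):
    """Malformed input file; message carries file and line number."""


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def _parse_paren(token: str, path: str, lineno: int) -> int:
    if token.startswith("(") and token.endswith(")"):
        token = token[1:-1]
    try:
        return int(token)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: non-numeric coordinate field {token!r}"
        ) from None


def _parse_int(token: str, path: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: non-numeric coordinate field {token!r}"
        ) from None


def read_repeatmasker_out(path: str | Path) -> list[RepeatAnnotation]:
    """Parse a RepeatMasker ``.out`` annotation file.

    Header lines (anything before the first row starting with an integer
    Smith-Waterman score) are skipped.  Rows flagged with a trailing ``*``
    (overlapped by a higher-scoring hit) are retained and marked.
    """
    path = Path(path)
    out: list[RepeatAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                sw_score = int(tokens[0])
            except ValueError:
                # header / ruler line
                continue
            if len(tokens) not in (15, 16):
                raise ParseError(
                    f"{path}:{lineno}: expected 15 or 16 columns, "
                    f"got {len(tokens)}"
                )
            try:
                pct_div, pct_del, pct_ins = (float(t) for t in tokens[1:4])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric percentage field"
                ) from None
            chrom = tokens[4]
            q_begin = _parse_int(tokens[5], str(path), lineno)
            q_end = _parse_int(tokens[6], str(path), lineno)
            q_left = _parse_paren(tokens[7], str(path), lineno)
            strand_raw = tokens[8]
            if strand_raw not in ("+", "C"):
                raise ParseError(
                    f"{path}:{lineno}: strand must be '+' or 'C', "
                    f"got {strand_raw!r}"
                )
            repeat_name = tokens[9]
            repeat_class = tokens[10]
            c1, c2, c3 = tokens[11:14]
            if strand_raw == "+":
                cons_begin = _parse_int(c1, str(path), lineno)
                cons_end = _parse_int(c2, str(path), lineno)
                cons_left = _parse_paren(c3, str(path), lineno)
                strand = "+"
            else:
                # complement rows store (left) end begin
                cons_left = _parse_paren(c1, str(path), lineno)
                cons_end = _parse_int(c2, str(path), lineno)
                cons_begin = _parse_int(c3, str(path), lineno)
                strand = "-"
            join_id = _parse_int(tokens[14], str(path), lineno)
            overlapped = len(tokens) == 16 and tokens[15] == "*"
            interval = GenomicInterval(chrom, q_begin - 1, q_end, strand)
            out.append(
                RepeatAnnotation(
                    interval=interval,
                    repeat_name=repeat_name,
                    repeat_class=repeat_class,
                    sw_score=sw_score,
                    pct_div=pct_div,
                    pct_del=pct_del,
                    pct_ins=pct_ins,
                    cons_begin=cons_begin,
                    cons_end=cons_end,
                    cons_left=cons_left,
                    join_id=join_id,
                    overlapped=overlapped,
                    query_left=q_left,
                )
            )
    return out


def write_repeatmasker_out(
    annotations: Iterable[RepeatAnnotation], path: str | Path
) -> None:
    """Write annotations back to RepeatMasker ``.out`` layout."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for a in annotations:
            iv = a.interval
            if iv.strand == "-":
                strand = "C"
                cons_cols = (f"({a.cons_left})", str(a.cons_end), str(a.cons_begin))
            else:
                strand = "+"
                cons_cols = (str(a.cons_begin), str(a.cons_end), f"({a.cons_left})")
            fields = [
                str(a.sw_score),
                f"{a.pct_div:.1f}",
                f"{a.pct_del:.1f}",
                f"{a.pct_ins:.1f}",
                iv.chrom,
                str(iv.start + 1),
                str(iv.end),
                f"({a.query_left})",
                strand,
                a.repeat_name,
                a.repeat_class,
                *cons_cols,
                str(a.join_id),
            ]
            if a.overlapped:
                fields.append("*")
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# conserved-element BED

def read_conserved_bed(path: str | Path) -> list[ConservedElement]:
    """Parse a conserved-element BED track with ``lod=N`` names.

    The LOD score is taken from the name field when it has the ``lod=N``
    form, else from the score column (the UCSC score column is capped at
    1000 and is only a fallback).  Records with end <= start are rejected
    with a warning; output is sorted by (chrom, start).
    """
    path = Path(path)
    out: list[ConservedElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            tokens = line.split()
            if len(tokens) < 3:
                raise ParseError(
                    f"{path}:{lineno}: BED needs at least 3 columns"
                )
            chrom = tokens[0]
            try:
                start, end = int(tokens[1]), int(tokens[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric BED coordinate"
                ) from None
            if end <= start:
                warnings.warn(
                    f"{path}:{lineno}: rejecting record with end <= start"
                )
                continue
            name = tokens[3] if len(tokens) > 3 else ""
            lod: int | None = None
            if name.startswith("lod=") or "lod=" in name:
                try:
                    lod = int(name.split("lod=", 1)[1].split(";")[0])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: malformed lod= field {name!r}"
                    ) from None
            elif len(tokens) > 4:
                try:
                    lod = int(float(tokens[4]))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric score column"
                    ) from None
            if lod is None:
                raise ParseError(
                    f"{path}:{lineno}: no 'lod=' name and no score column"
                )
            out.append(
                ConservedElement(
                    interval=GenomicInterval(chrom, start, end),
                    lod=lod,
                    name=name,
                )
            )
    out.sort(key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end))
    return out


def write_conserved_bed(
    elements: Iterable[ConservedElement], path: str | Path
) -> None:
    """Write conserved elements as BED5 with ``lod=N`` names."""
    with open(path, "w") as fh:
        for e in elements:
            iv = e.interval
            score = min(e.lod, 1000)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tlod={e.lod}\t{score}\n")


# ---------------------------------------------------------------------------
# presence table / tree / FASTA

def read_presence_table(path: str | Path) -> PresenceMatrix:
    """Read an element x species 0/1 TSV with a species header line."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    if df.empty or df.shape[1] == 0:
        raise ParseError(f"{path}: empty presence table")
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: presence value {values[i, j]!r} for element "
            f"{df.index[i]!r} / species {df.columns[j]!r} is not 0 or 1"
        )
    return PresenceMatrix(
        species=[str(c) for c in df.columns],
        elements=[str(i) for i in df.index],
        present=values.astype(bool),
    )


def write_presence_table(matrix: PresenceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.present.astype(int), index=matrix.elements, columns=matrix.species
    )
    df.index.name = "element"
    df.to_csv(path, sep="\t")


def read_species_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted newick species tree; leaf labels must be unique."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ParseError(f"{path}: duplicate leaf label: {exc}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ParseError(
            f"{path}: duplicate leaf label(s): {', '.join(sorted(dupes))}"
        )
    return tree


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered name -> uppercase-sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = validate_dna(str(rec.seq), label=rec.id)
    if not out:
        raise ParseError(f"{path}: no FASTA records")
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# generic TSV tables with a commented header

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with a '#'-commented header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(str(c) for c in df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ParseError(f"{path}: missing commented header line")
        columns = header[1:].rstrip("\n").split("\t")
        df = pd.read_csv(fh, sep="\t", header=None, names=columns)
    return df
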