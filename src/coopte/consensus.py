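"""Percent identity of a genomic sub-element against its TE consensus.

TE relics are measured by the best *local* alignment to the subfamily
consensus: a decayed copy often matches only an internal consensus slice, so
global alignment would misstate both identity and span.  Scoring is affine:
match +2, mismatch -3, and a gap of length k costs ``gap_open + k *
gap_extend`` (defaults -5 and -2, so a 1-bp gap costs -7).  ``N`` never
counts as a match.

Percent identity is, by default, matches over *all* alignment columns
including gap columns — the conservative convention.  The
``aligned-bases`` denominator (matches over substitution columns only,
the RepeatMasker-style 100 - %div reading) is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from ._util import revcomp, round_half_up, validate_dna
from .model import ConsensusMatch

__all__ = ["Scoring", "align_to_consensus", "identity_summary", "IdentitySummary"]

_MAX_ENUMERATED_OPTIMA = 32


@dataclass(frozen=True)
class Scoring:
    """Affine alignment scoring; gap of length k costs open + k*extend."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


def _build_aligner(scoring: Scoring, mode: str = "local") -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            if a == b and a != "N":
                matrix[a, b] = scoring.match
            else:
                matrix[a, b] = scoring.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix
    # PairwiseAligner's open_gap_score is the score of the FIRST gap base
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _alignment_stats(alignment, consensus: str, query: str) -> dict:
    cons_blocks, query_blocks = alignment.aligned
    if len(cons_blocks) == 0:
        return dict(n_columns=0, n_matches=0, n_gap_columns=0, cons_span=None,
                    q_start=0, q_end=0)
    t_start, t_end = cons_blocks[0][0], cons_blocks[-1][1]
    q_start, q_end = query_blocks[0][0], query_blocks[-1][1]
    diag = sum(int(e) - int(b) for b, e in cons_blocks)
    n_columns = (t_end - t_start) + (q_end - q_start) - diag
    n_matches = 0
    for (tb, te), (qb, qe) in zip(cons_blocks, query_blocks):
        for i in range(te - tb):
            c, q = consensus[tb + i], query[qb + i]
            if c == q and c != "N":
                n_matches += 1
    return dict(
        n_columns=int(n_columns),
        n_matches=n_matches,
        n_gap_columns=int(n_columns - diag),
        cons_span=(int(t_start) + 1, int(t_end)),
        q_start=int(q_start),
        q_end=int(q_end),
    )


def _best_alignment(aligner, consensus: str, query: str):
    """Pick one optimal alignment, applying the documented tie-break.

    Among co-optimal alignments (when few enough to enumerate) the one with
    the most alignment columns wins, then the one starting earliest on the
    consensus; otherwise the aligner's first optimum, which is deterministic.
    """
    alignments = aligner.align(consensus, query)
    try:
        n = len(alignments)
    except OverflowError:
        n = _MAX_ENUMERATED_OPTIMA + 1
    if n == 0:
        return None, None
    if n <= _MAX_ENUMERATED_OPTIMA:
        candidates = [
            (a, _alignment_stats(a, consensus, query)) for a in alignments
        ]
        candidates.sort(
            key=lambda pair: (
                -pair[1]["n_columns"],
                pair[1]["cons_span"] or (1, 0),
            )
        )
        return candidates[0]
    first = alignments[0]
    return first, _alignment_stats(first, consensus, query)


def align_to_consensus(
    locus_seq: str,
    consensus_seq: str,
    scoring: Scoring = Scoring(),
    strand_mode: str = "forward",
    element_name: str = "",
    identity_denominator: str = "all-columns",
    mode: str = "local",
) -> ConsensusMatch:
    """Best local alignment of a genomic sequence to a TE consensus.

    Parameters
    ----------
    locus_seq, consensus_seq
        DNA over {A,C,G,T,N}; validated, errors name the offending position.
    strand_mode
        ``"forward"`` aligns as given; ``"both"`` also tries the reverse
        complement of ``locus_seq`` and reports the higher-scoring
        orientation (forward wins ties).
    identity_denominator
        ``"all-columns"`` (default) counts gap columns as non-matches;
        ``"aligned-bases"`` divides by substitution columns only.
    mode
        ``"local"`` (default) fits decayed relics matching internal
        consensus slices.  ``"global"`` scores the full sequences end to
        end: local alignment trims poorly matching ends and therefore
        overstates per-site identity slightly, so global mode is the
        unbiased instrument when a copy is known to be full-length (used
        for divergence calibration of the synthetic model).

    Returns a :class:`ConsensusMatch`; ``locus_start``/``locus_end`` are
    offsets on the forward orientation of ``locus_seq`` regardless of the
    reported strand.
    """
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"strand_mode must be 'forward' or 'both', got {strand_mode!r}")
    if identity_denominator not in ("all-columns", "aligned-bases"):
        raise ValueError(f"unknown identity denominator {identity_denominator!r}")
    if mode not in ("local", "global"):
        raise ValueError(f"mode must be 'local' or 'global', got {mode!r}")
    locus_seq = validate_dna(locus_seq, label="locus sequence")
    consensus_seq = validate_dna(consensus_seq, label="consensus sequence")

    aligner = _build_aligner(scoring, mode)
    orientations = [("+", locus_seq)]
    if strand_mode == "both":
        orientations.append(("-", revcomp(locus_seq)))

    best = None
    for strand, query in orientations:
        alignment, stats = _best_alignment(aligner, consensus_seq, query)
        if alignment is None:
            continue
        score = float(alignment.score)
        if best is None or score > best[0]:
            best = (score, strand, query, stats)

    if best is None or best[3]["n_columns"] == 0:
        return ConsensusMatch(
            element_name=element_name,
            pct_identity=0.0,
            cons_span=None,
            locus_start=0,
            locus_end=0,
            strand="+",
            score=0.0,
            n_columns=0,
            n_matches=0,
            n_gap_columns=0,
        )

    score, strand, query, stats = best
    q_start, q_end = stats["q_start"], stats["q_end"]
    if strand == "-":
        # map offsets on the reverse complement back to forward coordinates
        q_start, q_end = len(locus_seq) - q_end, len(locus_seq) - q_start
    if identity_denominator == "all-columns":
        denom = stats["n_columns"]
    else:
        denom = stats["n_columns"] - stats["n_gap_columns"]
    pct = round_half_up(100.0 * stats["n_matches"] / denom, 1) if denom else 0.0
    return ConsensusMatch(
        element_name=element_name,
        pct_identity=pct,
        cons_span=stats["cons_span"],
        locus_start=q_start,
        locus_end=q_end,
        strand=strand,
        score=score,
        n_columns=stats["n_columns"],
        n_matches=stats["n_matches"],
        n_gap_columns=stats["n_gap_columns"],
    )


@dataclass(frozen=True)
class IdentitySummary:
    """Coverage of the consensus by a match, with a full-length flag."""

    consensus_coverage: float
    full_length: bool


def identity_summary(
    match: ConsensusMatch,
    consensus_len: int,
    full_length_threshold: float = 0.9,
) -> IdentitySummary:
    """Fraction of the consensus covered by the matched span.

    Distinguishes partial-consensus relics (an internal slice, e.g. positions
    391-501 of a 550-nt consensus, coverage ~0.2) from copies matching the
    full-length consensus (coverage >= ``full_length_threshold``).
    """
    if match.cons_span is None:
        return IdentitySummary(consensus_coverage=0.0, full_length=False)
    begin, end = match.cons_span
    if consensus_len < end:
        raise ValueError(
            f"consensus_len={consensus_len} shorter than matched span end {end}"
        )
    coverage = (end - begin + 1) / consensus_len
    return IdentitySummary(
        consensus_coverage=coverage,
        full_length=coverage >= full_length_threshold,
    )
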