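# Methods

## Coordinate conventions

All coordinates are 0-based half-open internally; conversion happens only at
I/O boundaries. RepeatMasker `.out` query coordinates (1-based inclusive)
are converted on read, and the complement-strand consensus columns —
written as `(left) end begin` rather than `begin end (left)` — are
normalized at parse time so `cons_begin <= cons_end` always holds
downstream. Consensus coordinates stay 1-based inclusive, matching how
repeat libraries are quoted. BED input is already half-open and untouched.
Rows flagged `*` (overlapped by a higher-scoring hit) are parsed and
marked, not dropped. Annotation classes that are repeats but not
transposable elements (`Simple_repeat`, `Low_complexity`, satellites,
structural RNAs) are tagged and excluded from the screen by default.

## The screen

A repeat qualifies as a TE-derived CNE when the sum of its overlaps with
conserved elements of LOD **strictly greater than 100** is **strictly
greater than 30 bp**. Both thresholds are configurable; both inequalities
are strict because that is how the bounds are conventionally printed
(">30 bp", ">100"). Overlap is summed across conserved elements per repeat:
conservation tracks fragment arbitrarily, while the unit of biological
interest is the TE copy, so a repeat split across two 20-bp conserved
blocks passes. A `per_element` mode requiring one element to clear the
threshold alone is provided for sensitivity analysis. Overlap is computed
per annotation row (RepeatMasker's native unit); `merge_joins` first merges
fragments sharing a join ID into one spanning record. Strand is ignored —
conservation tracks are unstranded. If overlapping conserved elements
double-cover part of a repeat the summed overlap is capped at the repeat
length (the qualification test itself uses the uncapped sum). An optional
BED subtraction can mask exons from the track before screening; it is off
by default because the upstream conserved-element lists used in practice
are not consistently exon-filtered.

## Composite chaining

TE-derived CNEs on one chromosome are chained by single linkage on the
relation *gap < 600 bp*, where the gap is measured between **repeat
intervals** (overlapping repeats have gap 0). Chaining is transitive, so a
locus may span more than 600 bp overall — intended, since a composite
enhancer of three TEs routinely exceeds the pairwise bound. The output is a
partition: every element belongs to exactly one locus; singletons are loci
of one member. Proximity between the conserved elements instead of the
repeats would be a small variant; repeat-interval distance is used because
the candidate unit is the TE arrangement itself.

Companion statistics count, among loci, the focal-family members whose
locus contains at least one member of a **different** repeat family; two
fragments of one family never make a composite. Percentages are rounded
half-up to one decimal (54/626 → 8.6), the convention used when such
fractions are printed.

## Consensus identity

Each sub-element is aligned to its subfamily consensus by local affine-gap
alignment (Gotoh, via Biopython's `PairwiseAligner`): match +2, mismatch
−3, and a gap of length *k* costs −5 − 2*k*. `N` never counts as a match.
Local alignment is the default because decayed relics often match only an
internal consensus slice. Percent identity is matches over **all**
alignment columns, gap columns included — the conservative convention; an
`aligned-bases` denominator (the RepeatMasker-style 100 − %div reading) is
available for comparison. Rounding is half-up to one decimal. Among
co-optimal alignments the one with more columns, then the earlier
consensus start, is reported when the co-optimal set is small enough to
enumerate (≤ 32); otherwise the aligner's first optimum, which is
deterministic, is used.

Two known measurement properties are worth stating. First, local alignment
trims mismatch-rich ends and therefore *overstates* per-site identity of a
full-length copy by about one percentage point at 30% divergence. Second,
even end-to-end alignment slightly exceeds naive per-site identity because
maximum-score alignments can buy chance matches with gaps. For calibrating
the synthetic divergence dial (below) the package therefore measures
identity in `mode="global"`, the least-biased instrument for copies known
to be full length; the screening default remains local.

## Integration dating

TE insertions at orthologous positions are effectively homoplasy-free, so
a single-gain (Dollo) model is hard-coded: the gain branch is the MRCA of
all species carrying the ortholog, and the minimal loss count is the
number of maximal all-absent subtrees below it — computed bottom-up, and
equal to zero exactly when every descendant is present. An element absent
everywhere is an error, not a root gain. Relative order between elements
follows from proper ancestry of gain nodes; gains that are equal or
incomparable (sister clades) are merged into tie groups rather than
silently ordered, because an order claim is only supported by strict clade
nesting. Presence can be called from ortholog percent-identity tables with
a configurable cutoff, **default 60%** — a pragmatic rule, and the single
most consequential free parameter when starting from alignments rather
than curated presence data.

## Synthetic data

The generator plants evolved consensus copies in uniform-random background
DNA and writes every real file format so parsers and pipeline are tested
end-to-end. Defaults define the flagship scenario and were fixed once:

| parameter | default | why |
|---|---|---|
| consensus lengths | 550 / 400 / 350 nt | SINE-like and DNA-transposon-like sizes |
| focal truncation | consensus 391–501 | an internal-slice relic, the hardest case |
| per-copy divergence | 0.27 | the ~71–74% identity of well-preserved exapted relics |
| composites | 20 × (SINE, DNA, hAT) | ≥ 20 planted three-member arrangements |
| composite gaps | uniform 0–550 bp | strictly below the 600-bp chaining bound |
| unit spacing | ≥ 2000 bp | distinct planted units must never chain |
| conserved LOD | lognormal ≈ 300, clamped > 100 | clears the screen threshold |
| background LOD | lognormal ≈ 50, clamped ≤ 100 | never clears it: separated distributions |
| conserved probability | 1.0 composite / 0.9 standalone | composites are the conserved story; strays test specificity |
| genome | 2 × 150 kb | exercises multi-chromosome handling at desk scale |
| per-edge loss probability | 0.1 | visible losses without erasing clades |

Copies are substitution-only by default (each site mutated with probability
*p* to a uniformly chosen *different* base, so expected identity is exactly
100·(1−*p*)); an indel process is available but off, which keeps planted
coordinates exactly bracketing the planted sequence. Presence rows are
generated by one gain on the family's configured clade followed by
independent per-edge losses; rows are redrawn (bounded retries) until at
least one presence survives in two child clades of the gain node
(`require_recoverable_gains`, default on), so the recorded ground-truth
gain branch actually describes the emitted data — without this, a loss of
an entire basal clade silently relabels the truth. The raw unconditioned
process is available by turning the flag off.

What the generator does **not** emulate: realistic nucleotide composition,
CpG decay, per-branch sequence evolution along the tree, nested or
fragmented insertions, or overlapping repeat annotations. Passing tests
therefore demonstrate correctness of the screen's logic and bookkeeping
under its stated model, not performance on the idiosyncrasies of real
annotation tracks.

## Determinism and numerics

Every random draw flows from one `numpy` Generator seeded from the config;
fixed seed means byte-identical output files and pipeline tables (the run
manifest differs only in its timestamp). Alignment scores are exact floats
from integer-valued scoring; percentage rounding is half-up via `decimal`.
Ties in chaining cannot arise (sorting by chrom/start/end is total);
alignment ties resolve as described above.

## Problem sizes

The test suite and acceptance script run at desk scale by design: random
screen instances up to 500 repeats × 200 elements, chaining sets up to 300
elements, alignment oracle pairs up to 60 nt, 500 random trees up to 10
leaves, 200 calibration replicates of a 500-nt consensus, and five
replicate runs of the 300-kb scenario. These sizes give tight oracle
comparisons while keeping a full run in seconds; the pipeline itself is
linear-logarithmic in annotation count and handles genome-scale inputs.

## Known limitations

* Headline numbers from any real genome-wide application depend on the
  annotation and conservation-track versions; published identity figures
  for specific loci (e.g. 71.4% over consensus 391–501) additionally
  depend on the exact consensus library, so they are integration checks
  against external data, not unit tests.
* The companion statistic conditions on the focal family matching by name;
  a glob pattern that spans multiple families blurs the "different family"
  definition.
* Dollo inference reports the MRCA; it cannot place a gain above the MRCA
  even when losses would make that equally parsimonious on an edge with no
  sampled outgroup descendants, and it does not model parallel gains.
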