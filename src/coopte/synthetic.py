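"""Synthetic genomes with planted TE relics and known ground truth.

The generator emulates the statistical structure the screen assumes: a
random background genome carrying planted TE copies — some standalone, some
arranged as ordered multi-TE composites with sub-threshold gaps (the
three-TE side-by-side arrangement of a SINE plus two DNA-transposon relics)
— a conservation track whose high-LOD elements cover the conserved planted
copies and whose background elements sit well below the LOD threshold, a
consensus library, and an ortholog presence matrix generated by a single
gain on a known branch with per-edge losses.

Every output is written in the real on-disk format (RepeatMasker ``.out``,
BED, FASTA, TSV, newick) so parsers, screen and CLI are exercised
end-to-end; format dialects are the pipeline's main failure mode.

Defaults mirror the flagship scenario: three distinct TE families whose
clades of origin are strictly nested (all mammals / therians / placentals),
per-copy divergence 0.27 (the ~71-74% identity level of well-preserved
exapted relics), composite gaps strictly below the 600-bp proximity
threshold, and planted units spaced far enough apart that distinct units
never chain together.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import yaml

from ._util import revcomp
from .io_formats import (
    write_conserved_bed,
    write_fasta,
    write_presence_table,
    write_repeatmasker_out,
)
from .model import (
    ConservedElement,
    GenomicInterval,
    PresenceMatrix,
    RepeatAnnotation,
)

__all__ = [
    "ConsensusSpec",
    "InsertionSpec",
    "CompositeSpec",
    "ConservationModel",
    "SimulationConfig",
    "GroundTruth",
    "TrueComposite",
    "SimulatedDataset",
    "evolve_copy",
    "simulate_dataset",
    "default_config",
    "default_species_tree_newick",
    "config_from_yaml",
    "config_to_yaml",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: 12 mammals with the nested clades used to date integrations.
DEFAULT_TREE = (
    "((platypus,echidna)Monotremata,"
    "((opossum,wallaby)Marsupialia,"
    "(((mouse,rat)Glires,(human,chimp)Primates)Euarchontoglires,"
    "((dog,cat)Carnivora,(cow,pig)Cetartiodactyla)Laurasiatheria"
    ")Eutheria)Theria)Mammalia;"
)


def default_species_tree_newick() -> str:
    return DEFAULT_TREE


@dataclass(frozen=True)
class ConsensusSpec:
    """One TE subfamily: name, consensus length, clade of origin.

    ``truncation`` (1-based inclusive consensus span) is the slice planted
    copies derive from; None means the full-length consensus.
    """

    name: str
    length: int
    clade: str
    truncation: tuple[int, int] | None = None


@dataclass(frozen=True)
class InsertionSpec:
    """Standalone insertions: family, copy count, per-site divergence."""

    consensus: str
    count: int
    divergence: float
    truncation: tuple[int, int] | None = None


@dataclass(frozen=True)
class CompositeSpec:
    """Ordered TE tuples planted side-by-side with gaps from a range."""

    members: tuple[str, ...]
    count: int
    gap_range: tuple[int, int] = (0, 550)  # inclusive bounds, keep < 600
    divergence: float = 0.27


@dataclass(frozen=True)
class ConservationModel:
    """Conservation-track emission model.

    Conserved planted TEs are covered by an element padded by up to
    ``padding`` bp per side with lognormal LOD around ``lod_conserved_mean``
    (clamped above the screening threshold); background elements get LOD
    around ``lod_background_mean`` clamped to at most 100, so the two
    distributions are separated and the default thresholds are exercised
    from both sides.
    """

    conserved_prob: float = 0.9
    composite_conserved_prob: float = 1.0
    lod_conserved_mean: float = 300.0
    lod_background_mean: float = 50.0
    lod_sigma: float = 0.3
    background_per_chrom: int = 20
    padding: int = 25


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_length: int = 300_000
    n_chroms: int = 2
    consensus_specs: tuple[ConsensusSpec, ...] = ()
    insertion_specs: tuple[InsertionSpec, ...] = ()
    composite_specs: tuple[CompositeSpec, ...] = ()
    conservation: ConservationModel = field(default_factory=ConservationModel)
    species_tree: str = DEFAULT_TREE
    loss_prob: float = 0.1
    unit_spacing: int = 2000
    indel_rate: float = 0.0
    #: redraw presence rows until the gain branch is identifiable (at least
    #: one surviving presence in two child clades of the gain node), so the
    #: ground-truth gain labels describe the emitted data.  Disable to get
    #: the raw unconditioned loss process.
    require_recoverable_gains: bool = True

    def __post_init__(self) -> None:
        for p in (self.loss_prob, self.indel_rate,
                  self.conservation.conserved_prob,
                  self.conservation.composite_conserved_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        for spec in self.insertion_specs:
            if spec.count < 0:
                raise ValueError("insertion count < 0")
            if not (0.0 <= spec.divergence <= 1.0):
                raise ValueError("divergence outside [0, 1]")
        for spec in self.composite_specs:
            if spec.count < 0:
                raise ValueError("composite count < 0")


@dataclass(frozen=True)
class TrueComposite:
    """Ground-truth record of one planted composite."""

    chrom: str
    member_names: tuple[str, ...]
    member_starts: tuple[int, ...]
    member_ends: tuple[int, ...]
    gaps: tuple[int, ...]


@dataclass
class GroundTruth:
    planted_repeats: list[RepeatAnnotation]
    true_composites: list[TrueComposite]
    true_gain_branches: dict[str, str]
    conserved_planted: list[int]  # indices into planted_repeats


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    repeats: list[RepeatAnnotation]
    elements: list[ConservedElement]
    consensi: dict[str, str]
    presence: PresenceMatrix
    tree: dendropy.Tree
    truth: GroundTruth
    paths: dict[str, Path] = field(default_factory=dict)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _evolve(
    seq: str, divergence_p: float, indel_rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    """Substitute/indel a consensus copy; returns (sequence, n_substitutions)."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < divergence_p
    n_sub = int(hit.sum())
    if n_sub:
        # shift each hit base by 1-3 in the ACGT cycle: always a different base
        idx = np.flatnonzero(hit)
        base_idx = np.searchsorted(_BASES, arr[idx])
        shift = rng.integers(1, 4, size=n_sub)
        arr[idx] = _BASES[(base_idx + shift) % 4]
    out = arr.tobytes().decode()
    if indel_rate > 0:
        pieces: list[str] = []
        i = 0
        for i, c in enumerate(out):
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            pieces.append(c)
            if r > 1 - indel_rate / 2:
                pieces.append(_random_dna(rng, int(rng.integers(1, 4))))
        out = "".join(pieces)
    return out, n_sub


def evolve_copy(
    consensus_seq: str,
    divergence_p: float,
    indel_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Evolve one copy of a consensus: per-site substitution probability
    ``divergence_p`` (to a uniformly chosen *different* base), optional
    indels at ``indel_rate``.  Seeded and reproducible."""
    if not (0.0 <= divergence_p <= 1.0):
        raise ValueError("divergence_p outside [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return _evolve(consensus_seq, divergence_p, indel_rate, rng)[0]


def _simulate_presence_row(
    gain: dendropy.Node,
    all_species: list[str],
    loss_prob: float,
    rng: np.random.Generator,
    require_recoverable: bool = False,
) -> dict[str, bool] | None:
    """One gain at ``gain``, then independent per-edge losses below it.

    With ``require_recoverable`` the draw is rejected unless the surviving
    presences pin the gain to its true branch (some presence in at least
    two child clades of ``gain``, trivially true for a leaf gain).
    """
    lost: set[int] = set()
    for node in gain.preorder_iter():
        if node is gain:
            continue
        if id(node.parent_node) in lost or id(node) in lost:
            lost.add(id(node))
            continue
        if rng.random() < loss_prob:
            lost.add(id(node))
    present_leaves = {
        l.taxon.label for l in gain.leaf_iter() if id(l) not in lost
    }
    if not present_leaves:
        return None
    if require_recoverable and not gain.is_leaf():
        children_with_presence = sum(
            1
            for child in gain.child_nodes()
            if any(id(l) not in lost for l in child.leaf_iter())
        )
        if children_with_presence < 2:
            return None
    return {sp: sp in present_leaves for sp in all_species}


def _find_clade_node(tree: dendropy.Tree, clade: str) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.is_leaf() else node.label
        if label == clade:
            return node
    raise ValueError(f"clade {clade!r} not found in species tree")


def simulate_dataset(
    config: SimulationConfig, outdir: str | Path
) -> SimulatedDataset:
    """Generate one dataset and write every file in its real format.

    Writes ``genome.fa``, ``repeats.out``, ``conserved.bed``,
    ``consensi.fa``, ``presence.tsv``, ``species.nwk`` and
    ``ground_truth.json`` under ``outdir``; byte-identical across runs for
    a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cons_by_name = {c.name: c for c in config.consensus_specs}
    consensi = {
        c.name: _random_dna(rng, c.length) for c in config.consensus_specs
    }

    tree = dendropy.Tree.get(
        data=config.species_tree,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = True
    species = [l.taxon.label for l in tree.leaf_node_iter()]

    # --- build the planted units -------------------------------------------
    def make_copy(family: str, divergence: float,
                  truncation: tuple[int, int] | None):
        spec = cons_by_name[family]
        trunc = truncation or spec.truncation or (1, spec.length)
        b, e = trunc
        if not (1 <= b <= e <= spec.length):
            raise ValueError(
                f"truncation {trunc} outside consensus {family} (len {spec.length})"
            )
        slice_seq = consensi[family][b - 1 : e]
        evolved, n_sub = _evolve(slice_seq, divergence, config.indel_rate, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        return dict(
            family=family,
            seq=evolved if strand == "+" else revcomp(evolved),
            strand=strand,
            cons_begin=b,
            cons_end=e,
            cons_left=spec.length - e,
            n_sub=n_sub,
            slice_len=len(slice_seq),
            divergence=divergence,
        )

    # each unit: list of (copy dict, gap-after) placed contiguously
    units: list[tuple[str, list[dict], list[int]]] = []
    for spec in config.composite_specs:
        for _ in range(spec.count):
            copies = [make_copy(m, spec.divergence, None) for m in spec.members]
            lo, hi = spec.gap_range
            gaps = [int(rng.integers(lo, hi + 1)) for _ in copies[:-1]]
            units.append(("composite", copies, gaps))
    for spec in config.insertion_specs:
        for _ in range(spec.count):
            units.append(
                ("single", [make_copy(spec.consensus, spec.divergence,
                                      spec.truncation)], [])
            )
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    # --- place units on chromosomes ----------------------------------------
    chrom_len = config.genome_length // config.n_chroms
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    per_chrom: dict[str, list] = {c: [] for c in chrom_names}
    for i, unit in enumerate(units):
        per_chrom[chrom_names[i % config.n_chroms]].append(unit)

    genome: dict[str, str] = {}
    repeats: list[RepeatAnnotation] = []
    elements: list[ConservedElement] = []
    truth_composites: list[TrueComposite] = []
    conserved_idx: list[int] = []
    join_id = 0
    cmodel = config.conservation

    for chrom in chrom_names:
        chrom_units = per_chrom[chrom]
        unit_lens = [
            sum(len(c["seq"]) for c in copies) + sum(gaps)
            for _, copies, gaps in chrom_units
        ]
        n_units = len(chrom_units)
        needed = sum(unit_lens) + config.unit_spacing * (n_units + 1)
        if needed > chrom_len:
            raise ValueError(
                f"cannot place {n_units} units in {chrom_len} bp on {chrom}; "
                "increase genome_length or reduce counts"
            )
        leftover = chrom_len - needed
        extra = (
            rng.multinomial(leftover, [1.0 / (n_units + 1)] * (n_units + 1))
            if n_units
            else np.array([leftover])
        )
        seq = np.frombuffer(_random_dna(rng, chrom_len).encode(), dtype="S1").copy()
        pos = 0
        for u, (kind, copies, gaps) in enumerate(chrom_units):
            pos += config.unit_spacing + int(extra[u])
            member_starts: list[int] = []
            member_ends: list[int] = []
            member_idx: list[int] = []
            for k, copy in enumerate(copies):
                start = pos
                end = start + len(copy["seq"])
                seq[start:end] = np.frombuffer(copy["seq"].encode(), dtype="S1")
                join_id += 1
                L = copy["slice_len"]
                pct_div = min(100.0, round(100.0 * copy["n_sub"] / L, 1))
                sw = max(0, 2 * (L - copy["n_sub"]) - 3 * copy["n_sub"])
                repeats.append(
                    RepeatAnnotation(
                        interval=GenomicInterval(chrom, start, end, copy["strand"]),
                        repeat_name=copy["family"],
                        repeat_class=_family_class(copy["family"]),
                        sw_score=sw,
                        pct_div=pct_div,
                        pct_del=0.0,
                        pct_ins=0.0,
                        cons_begin=copy["cons_begin"],
                        cons_end=copy["cons_end"],
                        cons_left=copy["cons_left"],
                        join_id=join_id,
                        query_left=chrom_len - end,
                    )
                )
                member_idx.append(len(repeats) - 1)
                member_starts.append(start)
                member_ends.append(end)
                pos = end
                if k < len(gaps):
                    pos += gaps[k]
            if kind == "composite":
                truth_composites.append(
                    TrueComposite(
                        chrom=chrom,
                        member_names=tuple(c["family"] for c in copies),
                        member_starts=tuple(member_starts),
                        member_ends=tuple(member_ends),
                        gaps=tuple(gaps),
                    )
                )
                p_cons = cmodel.composite_conserved_prob
            else:
                p_cons = cmodel.conserved_prob
            for idx, start, end in zip(member_idx, member_starts, member_ends):
                if rng.random() < p_cons:
                    conserved_idx.append(idx)
                    pad_l = int(rng.integers(0, cmodel.padding + 1))
                    pad_r = int(rng.integers(0, cmodel.padding + 1))
                    lod = max(
                        101,
                        int(rng.lognormal(np.log(cmodel.lod_conserved_mean),
                                          cmodel.lod_sigma)),
                    )
                    elements.append(
                        ConservedElement(
                            interval=GenomicInterval(
                                chrom,
                                max(0, start - pad_l),
                                min(chrom_len, end + pad_r),
                            ),
                            lod=lod,
                            name=f"lod={lod}",
                        )
                    )
        # background conserved elements: low LOD, anywhere
        for _ in range(cmodel.background_per_chrom):
            length = int(rng.integers(50, 300))
            start = int(rng.integers(0, max(1, chrom_len - length)))
            lod = min(100, max(1, int(rng.lognormal(
                np.log(cmodel.lod_background_mean), cmodel.lod_sigma))))
            elements.append(
                ConservedElement(
                    interval=GenomicInterval(chrom, start, start + length),
                    lod=lod,
                    name=f"lod={lod}",
                )
            )
        genome[chrom] = seq.tobytes().decode()

    elements.sort(key=lambda e: (e.interval.chrom, e.interval.start,
                                 e.interval.end))
    repeats.sort(key=lambda r: (r.interval.chrom, r.interval.start,
                                r.interval.end))

    # --- presence matrix: one gain on the family's clade, per-edge losses ---
    families = [c.name for c in config.consensus_specs]
    gain_branches = {c.name: c.clade for c in config.consensus_specs}
    rows = []
    for fam in families:
        gain = _find_clade_node(tree, gain_branches[fam])
        row = None
        for _ in range(100):
            row = _simulate_presence_row(
                gain, species, config.loss_prob, rng,
                require_recoverable=config.require_recoverable_gains,
            )
            if row is not None:
                break
        if row is None:
            raise ValueError(
                f"could not simulate a surviving presence row for {fam}"
            )
        rows.append([row[sp] for sp in species])
    presence = PresenceMatrix(
        species=list(species),
        elements=list(families),
        present=np.array(rows, dtype=bool).reshape(len(families), len(species)),
    )

    truth = GroundTruth(
        planted_repeats=list(repeats),
        true_composites=truth_composites,
        true_gain_branches=gain_branches,
        conserved_planted=sorted(conserved_idx),
    )

    paths = {
        "genome": outdir / "genome.fa",
        "repeats": outdir / "repeats.out",
        "conserved": outdir / "conserved.bed",
        "consensi": outdir / "consensi.fa",
        "presence": outdir / "presence.tsv",
        "tree": outdir / "species.nwk",
        "truth": outdir / "ground_truth.json",
    }
    write_fasta(genome, paths["genome"])
    write_repeatmasker_out(repeats, paths["repeats"])
    write_conserved_bed(elements, paths["conserved"])
    write_fasta(consensi, paths["consensi"])
    write_presence_table(presence, paths["presence"])
    paths["tree"].write_text(config.species_tree + "\n")
    paths["truth"].write_text(
        json.dumps(
            {
                "true_composites": [
                    dataclasses.asdict(t) for t in truth_composites
                ],
                "true_gain_branches": gain_branches,
                "n_planted_repeats": len(repeats),
                "conserved_planted": truth.conserved_planted,
            },
            indent=2,
        )
        + "\n"
    )

    return SimulatedDataset(
        config=config,
        genome=genome,
        repeats=repeats,
        elements=elements,
        consensi=consensi,
        presence=presence,
        tree=tree,
        truth=truth,
        paths=paths,
    )


def _family_class(family: str) -> str:
    classes = {
        "AmnSINE1": "SINE/Deu",
        "X6b_DNA": "DNA",
        "MER117": "DNA/hAT-Charlie",
    }
    return classes.get(family, "SINE")


def default_config(seed: int = 0) -> SimulationConfig:
    """The flagship three-TE scenario with nested clades of origin."""
    return SimulationConfig(
        seed=seed,
        genome_length=300_000,
        n_chroms=2,
        consensus_specs=(
            ConsensusSpec("AmnSINE1", 550, "Mammalia", truncation=(391, 501)),
            ConsensusSpec("X6b_DNA", 400, "Theria"),
            ConsensusSpec("MER117", 350, "Eutheria"),
        ),
        insertion_specs=(
            InsertionSpec("AmnSINE1", 8, 0.27),
            InsertionSpec("X6b_DNA", 8, 0.27),
            InsertionSpec("MER117", 8, 0.27),
        ),
        composite_specs=(
            CompositeSpec(
                members=("AmnSINE1", "X6b_DNA", "MER117"),
                count=20,
                gap_range=(0, 550),
                divergence=0.27,
            ),
        ),
    )


# ---------------------------------------------------------------------------
# YAML round-trip for the CLI

def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))


def _tuplify(spec_cls, d: dict):
    d = dict(d)
    for k in ("truncation", "gap_range", "members"):
        if k in d and d[k] is not None:
            d[k] = tuple(d[k])
    return spec_cls(**d)


def config_from_yaml(path: str | Path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text())
    raw = dict(raw)
    raw["consensus_specs"] = tuple(
        _tuplify(ConsensusSpec, d) for d in raw.get("consensus_specs", ())
    )
    raw["insertion_specs"] = tuple(
        _tuplify(InsertionSpec, d) for d in raw.get("insertion_specs", ())
    )
    raw["composite_specs"] = tuple(
        _tuplify(CompositeSpec, d) for d in raw.get("composite_specs", ())
    )
    if "conservation" in raw and isinstance(raw["conservation"], dict):
        raw["conservation"] = ConservationModel(**raw["conservation"])
    return SimulationConfig(**raw)
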