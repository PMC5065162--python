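"""End-to-end orchestration: simulate/ingest -> screen -> cluster -> align ->
phylo -> report, with a manifest so every threshold a result depends on is
auditable.  Re-running with the same config and inputs reproduces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cluster import CompanionStats, chain_proximal, companion_stats
from .consensus import Scoring, align_to_consensus, identity_summary
from .io_formats import (
    read_conserved_bed,
    read_fasta,
    read_presence_table,
    read_repeatmasker_out,
    read_species_tree,
    write_table,
)
from .phylo import infer_gains, integration_order
from .screen import merge_joins as _merge_joins
from .screen import screen_te_cnes, subtract_bed
from .synthetic import SimulationConfig, simulate_dataset

__all__ = ["RunConfig", "RunResult", "run_pipeline", "PipelineError"]

logger = logging.getLogger("coopte")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """All inputs and thresholds for one pipeline run.

    Either the five input paths or ``sim_config`` must be provided; with
    ``sim_config`` the synthetic dataset is generated under
    ``outdir/simulated`` first and then consumed through its on-disk files
    like any other input.
    """

    outdir: Path
    repeats_path: Path | None = None
    conserved_path: Path | None = None
    genome_path: Path | None = None
    consensus_path: Path | None = None
    presence_path: Path | None = None
    tree_path: Path | None = None
    exclude_bed: Path | None = None
    sim_config: SimulationConfig | None = None
    min_overlap_bp: int = 30
    min_lod: int = 100
    max_gap_bp: int = 600
    presence_threshold: float = 60.0
    identity_denominator: str = "all-columns"
    focal_family: str = "AmnSINE1"
    strand_mode: str = "both"
    merge_joins: bool = False
    per_element: bool = False
    seed: int = 0


@dataclass
class RunResult:
    tecnes: list
    loci: list
    stats: CompanionStats
    matches: pd.DataFrame
    gains: pd.DataFrame
    order: list[list[str]]
    manifest: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _md5(path: Path) -> str:
    h = hashlib.md5()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunResult:
    """Run every stage and write the report bundle under ``config.outdir``.

    Outputs: ``tecnes.tsv``, ``loci.tsv``, ``stats.tsv``, ``matches.tsv``,
    ``gains.tsv`` and ``manifest.json``.  Any stage error removes the
    partial outputs of this run and raises :class:`PipelineError` naming
    the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        if config.sim_config is not None:
            stage = "simulate"
            logger.info("[simulate] generating synthetic dataset")
            ds = simulate_dataset(config.sim_config, outdir / "simulated")
            in_paths = {
                "repeats": ds.paths["repeats"],
                "conserved": ds.paths["conserved"],
                "genome": ds.paths["genome"],
                "consensi": ds.paths["consensi"],
                "presence": ds.paths["presence"],
                "tree": ds.paths["tree"],
            }
        else:
            in_paths = {
                "repeats": config.repeats_path,
                "conserved": config.conserved_path,
                "genome": config.genome_path,
                "consensi": config.consensus_path,
                "presence": config.presence_path,
                "tree": config.tree_path,
            }
            missing = [k for k, v in in_paths.items() if v is None]
            if missing:
                raise PipelineError(
                    f"[setup] missing inputs: {', '.join(missing)} "
                    "(provide paths or a simulation config)"
                )
            in_paths = {k: Path(v) for k, v in in_paths.items()}

        stage = "read"
        logger.info("[read] parsing inputs")
        repeats = read_repeatmasker_out(in_paths["repeats"])
        elements = read_conserved_bed(in_paths["conserved"])
        genome = read_fasta(in_paths["genome"])
        consensi = read_fasta(in_paths["consensi"])
        presence = read_presence_table(in_paths["presence"])
        tree = read_species_tree(in_paths["tree"])
        if config.exclude_bed is not None:
            mask = [e.interval for e in read_conserved_bed(config.exclude_bed)]
            elements = subtract_bed(elements, mask)
        if config.merge_joins:
            repeats = _merge_joins(repeats)

        stage = "screen"
        logger.info(
            "[screen] overlap > %d bp with LOD > %d elements",
            config.min_overlap_bp, config.min_lod,
        )
        tecnes = screen_te_cnes(
            repeats,
            elements,
            min_overlap_bp=config.min_overlap_bp,
            min_lod=config.min_lod,
            per_element=config.per_element,
        )
        logger.info("[screen] %d TE-derived CNEs", len(tecnes))
        tecne_df = pd.DataFrame(
            [
                dict(
                    chrom=t.chrom, start=t.start, end=t.end,
                    strand=t.interval.strand, repeat_name=t.repeat_name,
                    repeat_class=t.repeat.repeat_class,
                    overlap_bp=t.overlap_bp, max_lod=t.max_lod,
                    element_ids=",".join(t.element_ids),
                )
                for t in tecnes
            ],
            columns=["chrom", "start", "end", "strand", "repeat_name",
                     "repeat_class", "overlap_bp", "max_lod", "element_ids"],
        )
        p = outdir / "tecnes.tsv"
        write_table(tecne_df, p)
        written.append(p)

        stage = "cluster"
        logger.info("[cluster] chaining with gap < %d bp", config.max_gap_bp)
        loci = chain_proximal(tecnes, max_gap_bp=config.max_gap_bp)
        stats = companion_stats(loci, config.focal_family)
        logger.info(
            "[cluster] %d loci, %d composite; focal %s accompanied: %s/%s",
            stats.n_loci, stats.n_composite_loci, config.focal_family,
            stats.n_accompanied, stats.n_focal,
        )
        loci_df = pd.DataFrame(
            [
                dict(
                    locus_id=i + 1,
                    chrom=l.span.chrom, start=l.span.start, end=l.span.end,
                    n_members=l.n_members,
                    members=",".join(m.repeat_name for m in l.members),
                    member_coords=",".join(
                        f"{m.start}-{m.end}" for m in l.members
                    ),
                    gaps=",".join(str(g) for g in l.gaps),
                    composite=int(l.is_composite),
                )
                for i, l in enumerate(loci)
            ],
            columns=["locus_id", "chrom", "start", "end", "n_members",
                     "members", "member_coords", "gaps", "composite"],
        )
        p = outdir / "loci.tsv"
        write_table(loci_df, p)
        written.append(p)
        stats_rows = [
            ("focal_family", stats.focal_family),
            ("n_focal", stats.n_focal),
            ("n_accompanied", stats.n_accompanied),
            ("pct_accompanied",
             "NA" if stats.pct_accompanied is None else stats.pct_accompanied),
            ("n_loci", stats.n_loci),
            ("n_composite_loci", stats.n_composite_loci),
        ]
        for fam, cnt in sorted(stats.companion_families.items()):
            stats_rows.append((f"companion_family:{fam}", cnt))
        for cls, cnt in sorted(stats.companion_classes.items()):
            stats_rows.append((f"companion_class:{cls}", cnt))
        p = outdir / "stats.tsv"
        write_table(pd.DataFrame(stats_rows, columns=["key", "value"]), p)
        written.append(p)

        stage = "align"
        logger.info("[align] members of %d loci vs consensus library", len(loci))
        match_rows = []
        scoring = Scoring()
        for i, locus in enumerate(loci):
            for m in locus.members:
                cons = consensi.get(m.repeat_name)
                if cons is None:
                    continue
                seq = genome[m.chrom][m.start:m.end]
                match = align_to_consensus(
                    seq, cons, scoring=scoring,
                    strand_mode=config.strand_mode,
                    element_name=m.repeat_name,
                    identity_denominator=config.identity_denominator,
                )
                cov = identity_summary(match, len(cons))
                b, e = match.cons_span if match.cons_span else (0, 0)
                match_rows.append(
                    dict(
                        locus_id=i + 1, chrom=m.chrom,
                        start=m.start + match.locus_start,
                        end=m.start + match.locus_end,
                        element=m.repeat_name,
                        pct_identity=match.pct_identity,
                        cons_begin=b, cons_end=e, strand=match.strand,
                        score=match.score,
                        consensus_coverage=round(cov.consensus_coverage, 3),
                        full_length=int(cov.full_length),
                    )
                )
        matches_df = pd.DataFrame(
            match_rows,
            columns=["locus_id", "chrom", "start", "end", "element",
                     "pct_identity", "cons_begin", "cons_end", "strand",
                     "score", "consensus_coverage", "full_length"],
        )
        p = outdir / "matches.tsv"
        write_table(matches_df, p)
        written.append(p)

        stage = "phylo"
        logger.info("[phylo] inferring gain branches for %d elements",
                    len(presence.elements))
        assignments = infer_gains(presence, tree)
        order = integration_order(assignments, tree)
        rank = {
            el: r + 1 for r, group in enumerate(order) for el in group
        }
        gains_df = pd.DataFrame(
            [
                dict(
                    element=a.element, gain_clade=a.clade_name,
                    n_losses=a.n_losses, order_rank=rank[a.element],
                    tie_group="|".join(
                        g for g in order[rank[a.element] - 1]
                    ),
                )
                for a in assignments
            ],
            columns=["element", "gain_clade", "n_losses", "order_rank",
                     "tie_group"],
        )
        p = outdir / "gains.tsv"
        write_table(gains_df, p)
        written.append(p)

        stage = "manifest"
        manifest = {
            "coopte_version": __version__,
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "seed": config.seed,
            "thresholds": {
                "min_overlap_bp": config.min_overlap_bp,
                "min_lod": config.min_lod,
                "max_gap_bp": config.max_gap_bp,
                "presence_threshold": config.presence_threshold,
                "identity_denominator": config.identity_denominator,
                "strand_mode": config.strand_mode,
                "merge_joins": config.merge_joins,
                "per_element": config.per_element,
                "focal_family": config.focal_family,
            },
            "inputs": {
                k: {"path": str(v), "md5": _md5(v)}
                for k, v in in_paths.items()
            },
            "outputs": [p.name for p in written],
            "simulated": config.sim_config is not None,
        }
        p = outdir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(p)
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"[{stage}] {exc}") from exc

    return RunResult(
        tecnes=tecnes,
        loci=loci,
        stats=stats,
        matches=matches_df,
        gains=gains_df,
        order=order,
        manifest=manifest,
        paths={p.name.split(".")[0]: p for p in written},
    )
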