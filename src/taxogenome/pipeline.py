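"""End-to-end orchestration: simulate/load -> metrics -> core genome ->
level statistics -> thresholds -> cluster -> classify -> report.

Every run is driven by a single :class:`PipelineConfig`; all randomness
flows from its one seed, and a rerun with identical config and inputs
reproduces identical artifacts.  Stage events (timings, counts) are
appended to a JSON-lines run log for auditability.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aligner import AlignerParams
from .core_genome import (
    RBHParams,
    build_core_alignment,
    find_ortholog_families,
    shared_gene_fraction,
    write_families,
)
from .genome_io import (
    GenomeRecord,
    Metric,
    SimilarityMatrix,
    genome_summary,
    read_genome,
    read_metadata,
    write_matrix,
    write_metadata,
)
from .metrics import MetricParams, build_matrix
from .synthetic_data import SimulatedClade, SimulationConfig, simulate_clade, write_clade
from .taxonomy import (
    ThresholdSet,
    assignments_to_frame,
    classify_strains,
    cluster_strains,
    derive_all_thresholds,
    format_thresholds,
    summarize_levels,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Exactly one of ``genomes_dir`` (with ``metadata``) or ``simulation``
    must be supplied."""

    output_dir: str | Path = "taxogenome_out"
    genomes_dir: str | Path | None = None
    metadata: str | Path | None = None
    simulation: SimulationConfig | None = None
    metric_params: MetricParams = field(default_factory=MetricParams)
    aligner_params: AlignerParams = field(default_factory=AlignerParams)
    rbh_params: RBHParams = field(default_factory=RBHParams)
    classify_metric: Metric = Metric.ANIB_G
    species_threshold_override: float | None = None
    genus_threshold_override: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        has_inputs = self.genomes_dir is not None
        has_sim = self.simulation is not None
        if has_inputs == has_sim:
            raise ValueError(
                "exactly one of genomes_dir or simulation must be supplied"
            )
        if has_inputs and self.metadata is None:
            raise ValueError("genomes_dir requires a metadata table")
        self.classify_metric = Metric(self.classify_metric)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_genomes(genomes_dir: str | Path, metadata_path: str | Path) -> list[GenomeRecord]:
    """Load every strain listed in the metadata from ``genomes_dir``
    (``<strain_id>.fasta`` plus optional ``<strain_id>.gff``)."""
    genomes_dir = Path(genomes_dir)
    meta = read_metadata(metadata_path)
    genomes = []
    for _, row in meta.iterrows():
        sid = row["strain_id"]
        fasta = genomes_dir / f"{sid}.fasta"
        if not fasta.exists():
            raise FileNotFoundError(f"missing genome FASTA {fasta}")
        gff = genomes_dir / f"{sid}.gff"
        genomes.append(
            read_genome(fasta, gff if gff.exists() else None, row.to_dict())
        )
    return genomes


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def event(self, stage: str, **info) -> None:
        rec = {"stage": stage, "elapsed_s": None, **info}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def build_nj_tree(matrix: SimilarityMatrix) -> str:
    """Neighbor-joining tree (Newick) from a similarity matrix.

    Distances are ``100 - similarity`` on the symmetrized matrix; negative
    branch lengths are clamped to zero.  Requires >= 3 strains and no NA.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    sym = matrix.symmetrized()
    if sym.n < 3:
        raise ValueError("neighbor joining needs at least 3 strains")
    if np.isnan(sym.values).any():
        raise ValueError("matrix contains NA; cannot build a tree")
    dist = 100.0 - sym.values
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    dm = DistanceMatrix(dist, ids=sym.strain_ids)
    tree = nj(dm)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        log.info("NJ tree: clamped %d negative branch lengths to 0", clamped)
    return str(tree).strip()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns a result bundle and writes every
    artifact (matrices, thresholds, partitions, tree, report) to
    ``cfg.output_dir``."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    runlog = _RunLog(out / "run_log.jsonl")
    t0 = time.monotonic()

    clade: SimulatedClade | None = None
    if cfg.simulation is not None:
        sim_cfg = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        clade = simulate_clade(sim_cfg)
        write_clade(clade, out / "simulated")
        genomes = clade.genomes
        labels = clade.truth
        runlog.event("simulate", n_genomes=len(genomes), seed=cfg.seed)
    else:
        genomes = load_genomes(cfg.genomes_dir, cfg.metadata)
        labels = read_metadata(cfg.metadata)
        runlog.event("load", n_genomes=len(genomes))

    matrices: dict[Metric, SimilarityMatrix] = {}
    for metric in Metric:
        t = time.monotonic()
        m = build_matrix(
            genomes, metric, cfg.metric_params, cfg.aligner_params, cfg.rbh_params
        )
        matrices[metric] = m
        write_matrix(m, out / f"matrix_{metric.value.lower()}.tsv")
        runlog.event(
            "matrix", metric=metric.value, seconds=round(time.monotonic() - t, 2)
        )

    families = find_ortholog_families(genomes, cfg.rbh_params)
    write_families(families, out / "families.tsv")
    core = build_core_alignment(families, genomes)
    with open(out / "core_alignment.fasta", "w") as fh:
        for sid, seq in core.concatenated.items():
            fh.write(f">{sid}\n{seq}\n")
    runlog.event(
        "core_genome",
        n_families=len(families),
        n_core=core.n_core_genes,
        columns_stripped=core.n_columns_removed,
    )

    # Fig-4-style genome summary triplets
    summaries = []
    by_group: dict[str, list[GenomeRecord]] = {}
    lab = labels.set_index("strain_id")
    for g in genomes:
        grp = lab.loc[g.strain_id, "group"]
        by_group.setdefault(str(grp), []).append(g)
    for g in genomes:
        grp = str(lab.loc[g.strain_id, "group"])
        members = by_group[grp]
        frac = (
            shared_gene_fraction(g, members, families)
            if len(members) >= 2
            else np.nan
        )
        s = genome_summary(g)
        summaries.append(
            {
                "strain_id": s.strain_id,
                "group": grp,
                "genome_size": s.genome_size,
                "gc_mol_percent": None if s.gc_content is None else round(s.gc_content, 2),
                "shared_gene_fraction": None if np.isnan(frac) else round(frac, 4),
            }
        )
    pd.DataFrame(summaries).to_csv(out / "genome_summaries.tsv", sep="\t", index=False)

    level_stats = {}
    thresholds: dict[Metric, ThresholdSet] = {}
    for metric, m in matrices.items():
        stats = summarize_levels(m, labels)
        level_stats[metric] = stats
        if len(stats) == 3:
            thresholds[metric] = derive_all_thresholds(stats)
    with open(out / "thresholds.json", "w") as fh:
        json.dump(
            {
                metric.value: {
                    **format_thresholds(ts),
                    "species_threshold_raw": ts.species_threshold,
                    "genus_threshold_raw": ts.genus_threshold,
                    "buffer_species": list(ts.buffer_species),
                    "buffer_genus": list(ts.buffer_genus),
                    "levels": {
                        s.level.value: {
                            "mean": s.mean,
                            "sd": s.sd,
                            "n_pairs": s.n_pairs,
                        }
                        for s in level_stats[metric]
                    },
                }
                for metric, ts in thresholds.items()
            }
            | {
                "_provenance": {
                    "package_version": __version__,
                    "seed": cfg.seed,
                    "matrix_sha256": {
                        metric.value: _sha256(out / f"matrix_{metric.value.lower()}.tsv")
                        for metric in matrices
                    },
                }
            },
            fh,
            indent=2,
        )
    runlog.event("thresholds", metrics=[m.value for m in thresholds])

    cls_metric = cfg.classify_metric
    if cls_metric not in thresholds and (
        cfg.species_threshold_override is None
        or cfg.genus_threshold_override is None
    ):
        raise RuntimeError(
            f"no thresholds derivable for metric {cls_metric.value}; "
            "supply overrides"
        )
    ts = thresholds.get(cls_metric)
    sp_thr = (
        cfg.species_threshold_override
        if cfg.species_threshold_override is not None
        else ts.species_threshold
    )
    ge_thr = (
        cfg.genus_threshold_override
        if cfg.genus_threshold_override is not None
        else ts.genus_threshold
    )
    use_ts = ThresholdSet(
        metric=cls_metric,
        species_threshold=sp_thr,
        genus_threshold=ge_thr,
        buffer_species=ts.buffer_species if ts else (sp_thr, sp_thr),
        buffer_genus=ts.buffer_genus if ts else (ge_thr, ge_thr),
    )
    cls_matrix = matrices[cls_metric]
    species_partition = cluster_strains(cls_matrix, use_ts.species_threshold)
    group_partition = cluster_strains(cls_matrix, use_ts.genus_threshold)
    partition = pd.DataFrame(
        {
            "strain_id": species_partition.index,
            "species_cluster": species_partition.values,
            "group_cluster": group_partition.reindex(species_partition.index).values,
        }
    )
    partition.to_csv(out / "partition.tsv", sep="\t", index=False)
    assignments = classify_strains(cls_matrix, use_ts, labels)
    assignments_to_frame(assignments).to_csv(
        out / "assignments.tsv", sep="\t", index=False
    )
    runlog.event(
        "classify",
        metric=cls_metric.value,
        n_species_clusters=species_partition.nunique(),
        n_group_clusters=group_partition.nunique(),
    )

    tree_newick = build_nj_tree(cls_matrix)
    (out / "tree.nwk").write_text(tree_newick + "\n")

    _write_report(
        out,
        cfg,
        genomes,
        level_stats,
        thresholds,
        partition,
        assignments,
    )
    runlog.event("done", seconds=round(time.monotonic() - t0, 2))
    return {
        "genomes": genomes,
        "matrices": matrices,
        "families": families,
        "core_alignment": core,
        "level_stats": level_stats,
        "thresholds": thresholds,
        "partition": partition,
        "assignments": assignments,
        "tree": tree_newick,
        "clade": clade,
    }


def _write_report(out, cfg, genomes, level_stats, thresholds, partition, assignments):
    lines = ["# Taxogenomic report", ""]
    lines.append(f"Strains analysed: {len(genomes)}")
    lines.append("")
    lines.append("## Level statistics (mean ± sd)")
    for metric, stats in level_stats.items():
        lines.append(f"### {metric.value}")
        for s in stats:
            lines.append(f"- {s.level.value}: {s}")
        lines.append("")
    lines.append("## Derived rank boundaries")
    for metric, ts in thresholds.items():
        fmt = format_thresholds(ts)
        lines.append(
            f"- {metric.value}: species {fmt['species_threshold']} "
            f"(buffer {ts.buffer_species[0]:.2f}-{ts.buffer_species[1]:.2f}), "
            f"genus {fmt['genus_threshold']} "
            f"(buffer {ts.buffer_genus[0]:.2f}-{ts.buffer_genus[1]:.2f})"
        )
    lines.append("")
    n_species = partition["species_cluster"].nunique()
    n_groups = partition["group_cluster"].nunique()
    lines.append(
        f"## Partition: {n_species} species clusters in {n_groups} groups "
        f"({len(partition)} strains)"
    )
    flagged = [a for a in assignments if a.flags]
    lines.append("")
    lines.append(f"## Flagged strains ({len(flagged)})")
    for a in flagged:
        lines.append(
            f"- {a.strain_id}: {', '.join(sorted(f.value for f in a.flags))}"
        )
    (out / "report.md").write_text("\n".join(lines) + "\n")
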