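"""Simulation of hierarchical genome clades with known ground truth.

The simulator evolves a random ancestral chromosome along a fixed
star-within-star topology: a root ancestor spawns ``n_genera`` genus
ancestors, each genus ancestor spawns ``species_per_genus`` species
ancestors, and each species ancestor spawns ``strains_per_species`` leaf
strains.  Every branch applies independent Jukes-Cantor-style substitutions
(each substituted site moves to one of the three alternative bases,
uniformly) at a per-branch probability chosen so that the *pairwise*
divergence realized at each taxonomic level matches the configured targets:

* two strains of the same species differ at ``divergence_within_species``
  of sites in expectation,
* two strains of the same genus but different species at
  ``divergence_within_genus``,
* two strains of different genera at ``divergence_between_genera``.

Substitution probabilities compose along a lineage as
``c(a, b) = a + b - (4/3) a b`` under this model, which makes the expected
pairwise identity at every level an explicit closed form
(:func:`expected_identity`) -- exactly what threshold-recovery tests need.

Protein-coding genes are laid out as non-overlapping loci (ATG ... TAA, no
internal stops) on the forward strand; substitutions that would create a
premature stop codon are resampled, and indels never fall inside a CDS so
reading frames are preserved by construction.  Whole genes are deleted per
*species* lineage with ``gene_loss_prob_per_species``, so core-genome size
and shared-gene fractions vary across the clade while every surviving gene
keeps its ancestral family identity in the truth tables.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .genome_io import GeneLocus, GenomeRecord, write_genome, write_metadata

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA in A=0,C=1,G=2,T=3


def _compose(a: float, b: float) -> float:
    """Pairwise divergence of two lineages with divergences a and b."""
    return a + b - (4.0 / 3.0) * a * b


def _branch_from_pairwise(d: float) -> float:
    """Per-lineage divergence p with c(p, p) = d."""
    if not 0 <= d < 0.75:
        raise ValueError(f"pairwise divergence {d} outside [0, 0.75)")
    return 0.75 * (1.0 - math.sqrt(1.0 - (4.0 / 3.0) * d))


def _decompose(total: float, known: float) -> float:
    """Solve c(x, known) = total for x."""
    x = (total - known) / (1.0 - (4.0 / 3.0) * known)
    if x < 0:
        raise ValueError("divergence levels are not strictly increasing")
    return x


def expected_identity(
    lineage1: float | Iterable[float], lineage2: float | Iterable[float]
) -> float:
    """Expected percent identity between two lineages.

    Each argument is a per-branch substitution probability or an iterable of
    them (composed root-to-leaf).  Returns ``100 * (1 - p_observed)`` with
    ``p_observed = p1 + p2 - (4/3) p1 p2``.
    """

    def _lineage(p: float | Iterable[float]) -> float:
        if isinstance(p, (int, float)):
            return float(p)
        total = 0.0
        for branch in p:
            total = _compose(total, float(branch))
        return total

    p1, p2 = _lineage(lineage1), _lineage(lineage2)
    return 100.0 * (1.0 - _compose(p1, p2))


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of a simulated clade.

    Divergence values are target *pairwise* per-site substitution fractions
    between strains at each level; defaults put within-species identity near
    98%, within-genus near 85% and between-genus near 72%, mirroring the
    similarity bands that separate prokaryotic species and genera.
    """

    seed: int = 0
    ancestor_length: int = 20_000
    n_genera: int = 3
    species_per_genus: int = 2
    strains_per_species: int = 3
    divergence_within_species: float = 0.02
    divergence_within_genus: float = 0.15
    divergence_between_genera: float = 0.28
    indel_rate: float = 2e-4
    indel_length_mean: float = 3.0
    n_genes: int = 12
    gene_length: int = 600
    gene_loss_prob_per_species: float = 0.1
    gc_target: float = 0.62

    def __post_init__(self) -> None:
        if self.ancestor_length <= 0:
            raise ValueError("ancestor_length must be positive")
        if self.gene_length % 3 != 0:
            raise ValueError("gene_length must be a multiple of 3")
        if not (
            0
            <= self.divergence_within_species
            < self.divergence_within_genus
            < self.divergence_between_genera
            < 0.5
        ):
            raise ValueError(
                "divergences must satisfy within_species < within_genus "
                "< between_genera, all in [0, 0.5)"
            )
        for name in ("indel_rate", "gene_loss_prob_per_species", "gc_target"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_genes * self.gene_length > self.ancestor_length:
            raise ValueError(
                f"gene layout impossible: {self.n_genes} x {self.gene_length} bp "
                f"> ancestor_length {self.ancestor_length}"
            )

    def branch_probabilities(self) -> tuple[float, float, float]:
        """Per-branch substitution probabilities (genus, species, strain)."""
        p_strain = _branch_from_pairwise(self.divergence_within_species)
        sp_lineage = _branch_from_pairwise(self.divergence_within_genus)
        p_species = _decompose(sp_lineage, p_strain)
        ge_lineage = _branch_from_pairwise(self.divergence_between_genera)
        p_genus = _decompose(ge_lineage, _compose(p_species, p_strain))
        return p_genus, p_species, p_strain


@dataclass
class SimulatedClade:
    """A simulated clade plus its ground truth."""

    genomes: list[GenomeRecord]
    truth: pd.DataFrame  # strain_id, species, group
    ortholog_map: dict[tuple[str, str], str]  # (strain_id, gene_id) -> family id
    pairwise_true_divergence: pd.DataFrame  # strain x strain substitution fraction
    config: SimulationConfig


@dataclass
class _Lineage:
    seq: np.ndarray  # uint8 codes over ancestral coordinates
    keep: np.ndarray  # bool, False where deleted
    insertions: dict[int, np.ndarray]  # anchor position -> inserted codes
    genes_present: list[int]  # surviving family indices


def _sample_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _layout_genes(
    rng: np.random.Generator, cfg: SimulationConfig
) -> list[tuple[int, int]]:
    """Non-overlapping gene intervals with at least 2 bp between/around genes."""
    min_gap = 2
    slack = cfg.ancestor_length - cfg.n_genes * cfg.gene_length
    n_gaps = cfg.n_genes + 1
    if slack < n_gaps * min_gap:
        raise ValueError(
            "gene layout impossible: not enough intergenic room "
            f"({slack} bp slack for {n_gaps} gaps)"
        )
    extra = rng.multinomial(slack - n_gaps * min_gap, np.full(n_gaps, 1 / n_gaps))
    gaps = extra + min_gap
    intervals = []
    pos = 0
    for gi in range(cfg.n_genes):
        pos += int(gaps[gi])
        intervals.append((pos, pos + cfg.gene_length))
        pos += cfg.gene_length
    return intervals


def _write_gene(
    rng: np.random.Generator, seq: np.ndarray, start: int, end: int
) -> None:
    """Fill [start, end) with ATG, random non-stop codons, TAA."""
    # start codon ATG
    seq[start] = 0
    seq[start + 1] = 3
    seq[start + 2] = 2
    for cpos in range(start + 3, end - 3, 3):
        while True:
            codon = rng.integers(0, 4, size=3)
            if tuple(codon) not in _STOPS:
                break
        seq[cpos : cpos + 3] = codon
    # stop codon TAA
    seq[end - 3] = 3
    seq[end - 2] = 0
    seq[end - 1] = 0


def _apply_substitutions(
    lineage: _Lineage,
    p: float,
    rng: np.random.Generator,
    intervals: list[tuple[int, int]],
) -> None:
    seq, keep = lineage.seq, lineage.keep
    if p <= 0:
        return
    hit = (rng.random(seq.size) < p) & keep
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return
    offsets = rng.integers(1, 4, size=idx.size).astype(np.uint8)
    old = seq[idx].copy()
    seq[idx] = (seq[idx] + offsets) % 4
    # repair substitutions that created premature stop codons inside a CDS
    present = set(lineage.genes_present)
    for fam, (start, end) in enumerate(intervals):
        if fam not in present:
            continue
        lo = np.searchsorted(idx, start)
        hi = np.searchsorted(idx, end - 3)  # final (stop) codon exempt
        if lo == hi:
            continue
        for pos in idx[lo:hi]:
            cstart = start + ((pos - start) // 3) * 3
            codon = seq[cstart : cstart + 3]
            if tuple(codon) in _STOPS:
                original = old[np.searchsorted(idx, pos)]
                fixed = False
                for alt in range(4):
                    if alt == original:
                        continue
                    trial = codon.copy()
                    trial[pos - cstart] = alt
                    if tuple(trial) not in _STOPS:
                        seq[pos] = alt
                        fixed = True
                        break
                if not fixed:  # pragma: no cover - impossible with 3 stop codons
                    seq[pos] = original


def _apply_indels(
    lineage: _Lineage,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    cds_mask: np.ndarray,
) -> None:
    if cfg.indel_rate <= 0:
        return
    candidates = np.flatnonzero(lineage.keep & ~cds_mask)
    if candidates.size == 0:
        return
    n_events = rng.binomial(candidates.size, cfg.indel_rate)
    for _ in range(n_events):
        pos = int(candidates[rng.integers(candidates.size)])
        length = int(rng.geometric(1.0 / cfg.indel_length_mean))
        if rng.random() < 0.5:  # deletion, truncated at the next CDS boundary
            stop = pos
            limit = lineage.seq.size
            while stop < limit and stop - pos < length and not cds_mask[stop]:
                lineage.keep[stop] = False
                stop += 1
        else:  # insertion anchored after pos
            ins = _sample_bases(rng, length, cfg.gc_target)
            prev = lineage.insertions.get(pos)
            lineage.insertions[pos] = (
                ins if prev is None else np.concatenate([prev, ins])
            )


def _finalize(
    lineage: _Lineage,
    strain_id: str,
    species: str,
    group: str,
    intervals: list[tuple[int, int]],
) -> tuple[GenomeRecord, dict[str, str]]:
    keep = lineage.keep
    L = keep.size
    ins_len = np.zeros(L, dtype=np.int64)
    for pos, ins in lineage.insertions.items():
        if keep[pos]:
            ins_len[pos] = ins.size
    # new coordinate of ancestral position i = kept bases before i
    #                                        + insertions anchored before i
    shift = np.concatenate([[0], np.cumsum(keep.astype(np.int64) + ins_len)])

    parts: list[bytes] = []
    anchors = sorted(p for p in lineage.insertions if keep[p])
    prev = 0
    kept_seq = lineage.seq[keep]
    kept_pos = np.cumsum(keep) - 1  # ancestral -> kept index
    for pos in anchors:
        upto = kept_pos[pos] + 1
        parts.append(_BASES[kept_seq[prev:upto]].tobytes())
        parts.append(_BASES[lineage.insertions[pos]].tobytes())
        prev = upto
    parts.append(_BASES[kept_seq[prev:]].tobytes())
    contig = b"".join(parts).decode()

    genes: list[GeneLocus] = []
    ortho: dict[str, str] = {}
    for fam in lineage.genes_present:
        start, end = intervals[fam]
        new_start = int(shift[start])
        gene_id = f"g{fam:04d}"
        genes.append(
            GeneLocus(
                gene_id=gene_id,
                contig_index=0,
                start=new_start,
                end=new_start + (end - start),
                strand="+",
                is_cds=True,
            )
        )
        ortho[gene_id] = f"F{fam:04d}"
    record = GenomeRecord(
        strain_id=strain_id,
        contigs=[contig],
        genes=genes,
        declared_species=species,
        declared_group=group,
    )
    return record, ortho


def simulate_clade(cfg: SimulationConfig) -> SimulatedClade:
    """Simulate a clade of genomes under ``cfg``; identical cfg+seed gives
    byte-identical output."""
    rng = np.random.default_rng(cfg.seed)
    p_genus, p_species, p_strain = cfg.branch_probabilities()

    ancestor = _sample_bases(rng, cfg.ancestor_length, cfg.gc_target)
    intervals = _layout_genes(rng, cfg)
    for start, end in intervals:
        _write_gene(rng, ancestor, start, end)
    cds_mask = np.zeros(cfg.ancestor_length, dtype=bool)
    for start, end in intervals:
        cds_mask[start:end] = True

    root = _Lineage(
        seq=ancestor,
        keep=np.ones(cfg.ancestor_length, dtype=bool),
        insertions={},
        genes_present=list(range(cfg.n_genes)),
    )

    genomes: list[GenomeRecord] = []
    ortholog_map: dict[tuple[str, str], str] = {}
    truth_rows = []
    leaf_states: list[_Lineage] = []

    def _copy(lin: _Lineage) -> _Lineage:
        return _Lineage(
            seq=lin.seq.copy(),
            keep=lin.keep.copy(),
            insertions={k: v.copy() for k, v in lin.insertions.items()},
            genes_present=list(lin.genes_present),
        )

    for gi in range(cfg.n_genera):
        group = f"G{gi + 1}"
        genus = _copy(root)
        _apply_substitutions(genus, p_genus, rng, intervals)
        _apply_indels(genus, cfg, rng, cds_mask)
        for si in range(cfg.species_per_genus):
            species = f"{group}.S{si + 1}"
            sp = _copy(genus)
            # lineage-specific gene loss happens once per species
            survivors = []
            for fam in sp.genes_present:
                if rng.random() < cfg.gene_loss_prob_per_species:
                    start, end = intervals[fam]
                    sp.keep[start:end] = False
                else:
                    survivors.append(fam)
            sp.genes_present = survivors
            _apply_substitutions(sp, p_species, rng, intervals)
            _apply_indels(sp, cfg, rng, cds_mask)
            for ti in range(cfg.strains_per_species):
                strain_id = f"{species}.T{ti + 1}"
                leaf = _copy(sp)
                _apply_substitutions(leaf, p_strain, rng, intervals)
                _apply_indels(leaf, cfg, rng, cds_mask)
                record, ortho = _finalize(leaf, strain_id, species, group, intervals)
                genomes.append(record)
                leaf_states.append(leaf)
                for gene_id, fam_id in ortho.items():
                    ortholog_map[(strain_id, gene_id)] = fam_id
                truth_rows.append(
                    {"strain_id": strain_id, "species": species, "group": group}
                )

    ids = [g.strain_id for g in genomes]
    n = len(ids)
    div = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = leaf_states[i].keep & leaf_states[j].keep
            m = int(both.sum())
            d = (
                float(np.mean(leaf_states[i].seq[both] != leaf_states[j].seq[both]))
                if m
                else np.nan
            )
            div[i, j] = div[j, i] = d

    return SimulatedClade(
        genomes=genomes,
        truth=pd.DataFrame(truth_rows),
        ortholog_map=ortholog_map,
        pairwise_true_divergence=pd.DataFrame(div, index=ids, columns=ids),
        config=cfg,
    )


def write_clade(clade: SimulatedClade, outdir: str | Path) -> None:
    """Emit per-strain FASTA + GFF, metadata TSV, truth tables and config."""
    outdir = Path(outdir)
    genomes_dir = outdir / "genomes"
    genomes_dir.mkdir(parents=True, exist_ok=True)
    for genome in clade.genomes:
        write_genome(
            genome,
            genomes_dir / f"{genome.strain_id}.fasta",
            genomes_dir / f"{genome.strain_id}.gff",
        )
    write_metadata(clade.truth, outdir / "metadata.tsv")
    pd.DataFrame(
        [
            {"strain_id": sid, "gene_id": gid, "family_id": fam}
            for (sid, gid), fam in sorted(clade.ortholog_map.items())
        ]
    ).to_csv(outdir / "ortholog_map.tsv", sep="\t", index=False)
    clade.pairwise_true_divergence.to_csv(
        outdir / "true_divergence.tsv", sep="\t", float_format="%.6f"
    )
    (outdir / "config.json").write_text(
        json.dumps(dataclasses.asdict(clade.config), indent=2) + "\n"
    )
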