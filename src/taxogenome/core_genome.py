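"""Core-genome extraction by reciprocal best hits (RBH).

Orthology is inferred from an all-vs-all comparison of CDS translations:
for each genome pair, genes a and b form an RBH when each is the other's
best-scoring global-alignment match with protein identity >= 40% and
mutual coverage >= 70%.  Families are the connected components of the RBH
graph.  A family is *core* when it covers every genome exactly once; any
within-genome duplication disqualifies it (the concatenation step needs a
strict 1:1 mapping).

The concatenated core alignment follows the classical codon-stripping
recipe: per family the translations are aligned and the alignment is
back-threaded onto the nucleotide sequences codon-by-codon; the start and
stop codons are removed from every gene; and after concatenation any codon
column containing a gap or N in any genome is stripped, leaving a
missing-data-free matrix whose length is divisible by 3.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from Bio.Align import PairwiseAligner

from .genome_io import GenomeRecord, translate_cds

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RBHParams:
    """Reciprocal-best-hit acceptance thresholds."""

    min_identity: float = 40.0  # percent over alignment columns
    min_coverage: float = 0.7  # aligned residues / protein length, both ways


@dataclass
class OrthologFamily:
    """A putative ortholog family; ``members`` maps genome id to gene ids."""

    family_id: str
    members: dict[str, list[str]]
    single_copy: bool
    is_core: bool


@dataclass
class CoreAlignment:
    """Per-family codon alignments plus their codon-stripped concatenation."""

    families: list[dict[str, str]]  # per family: strain_id -> aligned nt
    concatenated: dict[str, str]  # strain_id -> stripped concatenation
    n_core_genes: int
    n_columns_removed: int  # codon columns stripped for gaps/Ns


_PROT_ALIGNER = PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def _alignment_stats(a: str, b: str) -> tuple[float, float, float, float]:
    """(score, identity%, coverage_a, coverage_b) of the global alignment."""
    aln = _PROT_ALIGNER.align(a, b)[0]
    counts = aln.counts()
    aligned_pairs = counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / aln.length
    return (
        float(aln.score),
        identity,
        aligned_pairs / len(a),
        aligned_pairs / len(b),
    )


def _translations(genome: GenomeRecord) -> dict[str, str]:
    prots = {}
    for gene in genome.cds:
        prots[gene.gene_id] = translate_cds(
            genome.gene_sequence(gene), gene_id=f"{genome.strain_id}:{gene.gene_id}"
        )
    return prots


def find_ortholog_families(
    genomes: list[GenomeRecord], params: RBHParams | None = None
) -> list[OrthologFamily]:
    """Infer ortholog families across ``genomes`` by reciprocal best hits."""
    params = params or RBHParams()
    for g in genomes:
        if not g.cds:
            raise ValueError(f"genome {g.strain_id!r} has no CDS")
    prots = {g.strain_id: _translations(g) for g in genomes}
    ids = [g.strain_id for g in genomes]

    graph = nx.Graph()
    for sid in ids:
        for gid in prots[sid]:
            graph.add_node((sid, gid))

    # Reciprocal best hits with ties: a gene's "best hits" are all genes
    # within score ties of its maximum, so identical within-genome
    # duplicates land in one family and get flagged rather than silently
    # splitting into single-copy families.
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            sa, sb = ids[ai], ids[bi]
            stats = {
                (ga, gb): _alignment_stats(pa, pb)
                for ga, pa in prots[sa].items()
                for gb, pb in prots[sb].items()
            }
            best_a = {
                ga: max(stats[(ga, gb)][0] for gb in prots[sb])
                for ga in prots[sa]
            }
            best_b = {
                gb: max(stats[(ga, gb)][0] for ga in prots[sa])
                for gb in prots[sb]
            }
            for (ga, gb), (score, identity, cov_a, cov_b) in stats.items():
                if score < best_a[ga] or score < best_b[gb]:
                    continue
                if (
                    identity >= params.min_identity
                    and cov_a >= params.min_coverage
                    and cov_b >= params.min_coverage
                ):
                    graph.add_edge((sa, ga), (sb, gb))

    n_genomes = len(ids)
    families = []
    components = sorted(
        nx.connected_components(graph), key=lambda c: sorted(c)[0]
    )
    for fi, component in enumerate(components):
        members: dict[str, list[str]] = {}
        for sid, gid in sorted(component):
            members.setdefault(sid, []).append(gid)
        single_copy = all(len(v) == 1 for v in members.values())
        families.append(
            OrthologFamily(
                family_id=f"FAM{fi:05d}",
                members=members,
                single_copy=single_copy,
                is_core=single_copy and len(members) == n_genomes,
            )
        )
    log.info(
        "%d families, %d core, across %d genomes",
        len(families),
        sum(f.is_core for f in families),
        n_genomes,
    )
    return families


def _gene_nt(genome: GenomeRecord, gene_id: str) -> str:
    locus = next(g for g in genome.genes if g.gene_id == gene_id)
    return genome.gene_sequence(locus)


def _mafft_align(seqs: dict[str, str]) -> dict[str, str]:
    """Protein multiple alignment via mafft (only needed for unequal lengths)."""
    if shutil.which("mafft") is None:  # pragma: no cover - environment guard
        raise RuntimeError("mafft not found on PATH; needed for gapped families")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.faa"
        with open(fin, "w") as fh:
            for sid, seq in seqs.items():
                fh.write(f">{sid}\n{seq}\n")
        res = subprocess.run(
            ["mafft", "--auto", "--quiet", "--anysymbol", str(fin)],
            capture_output=True,
            text=True,
            check=True,
        )
    aligned: dict[str, str] = {}
    current = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            current = line[1:].strip()
            aligned[current] = ""
        elif current is not None:
            aligned[current] += line.strip()
    return {sid: aligned[sid].upper() for sid in seqs}


def _backthread(prot_aln: str, nt: str) -> str:
    """Map an aligned protein back onto codons; gaps become '---'."""
    out = []
    pos = 0
    for aa in prot_aln:
        if aa == "-":
            out.append("---")
        else:
            out.append(nt[pos : pos + 3])
            pos += 3
    return "".join(out)


def build_core_alignment(
    families: list[OrthologFamily], genomes: list[GenomeRecord]
) -> CoreAlignment:
    """Concatenated codon-stripped core alignment over ``genomes``."""
    by_id = {g.strain_id: g for g in genomes}
    core = [f for f in families if f.is_core]
    if not core:
        raise ValueError("no core families to align")
    ids = [g.strain_id for g in genomes]

    family_alignments: list[dict[str, str]] = []
    for fam in core:
        nts = {}
        for sid in ids:
            nt = _gene_nt(by_id[sid], fam.members[sid][0])
            if len(nt) % 3 != 0:
                raise ValueError(
                    f"family {fam.family_id}: gene {fam.members[sid][0]!r} in "
                    f"{sid!r} has length {len(nt)} not divisible by 3"
                )
            # remove start and stop codons before alignment
            nts[sid] = nt[3:-3]
        lengths = {len(v) for v in nts.values()}
        if lengths == {0}:
            raise ValueError(f"family {fam.family_id}: genes of 2 codons or fewer")
        if len(lengths) == 1:
            aligned = dict(nts)  # equal lengths align column-for-column
        else:
            prots = {
                sid: translate_cds(nt + "TAA", gene_id=f"{fam.family_id}:{sid}")
                for sid, nt in nts.items()
            }
            prot_aln = _mafft_align(prots)
            aligned = {sid: _backthread(prot_aln[sid], nts[sid]) for sid in ids}
        family_alignments.append(aligned)

    concat = {sid: "".join(fam[sid] for fam in family_alignments) for sid in ids}
    total = len(next(iter(concat.values())))
    if any(len(v) != total for v in concat.values()):
        raise RuntimeError("core alignment rows differ in length")
    arr = np.array([list(concat[sid]) for sid in ids])
    codons = arr.reshape(len(ids), -1, 3)
    bad = ((codons == "-") | (codons == "N")).any(axis=(0, 2))
    kept = codons[:, ~bad, :].reshape(len(ids), -1)
    stripped = {sid: "".join(kept[i]) for i, sid in enumerate(ids)}
    n_removed = int(bad.sum())
    log.info(
        "core alignment: %d genes, %d codon columns stripped, %d nt remain",
        len(core),
        n_removed,
        kept.shape[1],
    )
    return CoreAlignment(
        families=family_alignments,
        concatenated=stripped,
        n_core_genes=len(core),
        n_columns_removed=n_removed,
    )


def shared_gene_fraction(
    genome: GenomeRecord,
    group_genomes: list[GenomeRecord],
    families: list[OrthologFamily] | None = None,
    params: RBHParams | None = None,
) -> float:
    """Fraction of the genome's CDS in families present in every member of
    its group.  ``group_genomes`` must include ``genome`` or it is added."""
    members = list(group_genomes)
    if all(g.strain_id != genome.strain_id for g in members):
        members.append(genome)
    if len(members) < 2:
        raise ValueError("shared_gene_fraction needs a group of at least 2 genomes")
    if families is None:
        families = find_ortholog_families(members, params)
    group_ids = {g.strain_id for g in members}
    shared = 0
    for fam in families:
        if group_ids <= set(fam.members):
            shared += len(fam.members.get(genome.strain_id, []))
    n_cds = len(genome.cds)
    if n_cds == 0:
        raise ValueError(f"genome {genome.strain_id!r} has no CDS")
    return shared / n_cds


def write_families(families: list[OrthologFamily], path: str | Path) -> None:
    """Families as TSV: family_id, genome_id, gene_id, single_copy, is_core."""
    with open(path, "w") as fh:
        fh.write("family_id\tgenome_id\tgene_id\tsingle_copy\tis_core\n")
        for fam in families:
            for sid, gene_ids in sorted(fam.members.items()):
                for gid in gene_ids:
                    fh.write(
                        f"{fam.family_id}\t{sid}\t{gid}\t"
                        f"{int(fam.single_copy)}\t{int(fam.is_core)}\n"
                    )
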