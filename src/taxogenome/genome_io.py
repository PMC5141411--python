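"""Core record types and I/O for genomes, annotations, metadata and matrices.

Conventions used throughout the package:

* All genomic coordinates are 0-based, half-open ``[start, end)``.
* Contig sequences are upper-case strings over the alphabet ``A C G T N``;
  any other character (IUPAC ambiguity codes included) is coerced to ``N``
  on ingestion and the coercion count is logged.
* Similarity matrices hold values on a 0-100 scale; undefined comparisons
  are ``NaN`` in memory and ``NA`` on disk.  Directed matrices are stored
  as-is together with a JSON sidecar recording the ``directed`` flag and
  metric name, so that symmetrization is always reproducible.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

#: NCBI translation table used for all CDS translations (bacterial).
CODON_TABLE = 11

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class Metric(str, Enum):
    """The four pairwise similarity metrics of the framework."""

    FBS = "FBS"
    ANIB_G = "ANIB_G"
    ANIB_C = "ANIB_C"
    AAI = "AAI"


@dataclass(frozen=True)
class GeneLocus:
    """A gene on a contig; coordinates are 0-based half-open."""

    gene_id: str
    contig_index: int
    start: int
    end: int
    strand: str = "+"
    is_cds: bool = True

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if self.is_cds and (self.end - self.start) % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id!r}: CDS length {self.end - self.start} "
                "not divisible by 3"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A strain's assembly (one or more contigs) plus gene annotation."""

    strain_id: str
    contigs: list[str]
    genes: list[GeneLocus] = field(default_factory=list)
    declared_species: str | None = None
    declared_group: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.contigs or all(len(c) == 0 for c in self.contigs):
            raise ValueError(f"genome {self.strain_id!r} has no sequence")
        for i, contig in enumerate(self.contigs):
            bad = set(contig) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"genome {self.strain_id!r} contig {i}: invalid characters {bad}"
                )
        seen: set[str] = set()
        for gene in self.genes:
            if gene.gene_id in seen:
                raise ValueError(
                    f"genome {self.strain_id!r}: duplicate gene id {gene.gene_id!r}"
                )
            seen.add(gene.gene_id)
            if gene.contig_index < 0 or gene.contig_index >= len(self.contigs):
                raise ValueError(
                    f"gene {gene.gene_id!r}: contig index {gene.contig_index} "
                    f"out of range for genome {self.strain_id!r}"
                )
            clen = len(self.contigs[gene.contig_index])
            if gene.end > clen:
                raise ValueError(
                    f"gene {gene.gene_id!r}: end {gene.end} beyond contig "
                    f"length {clen} in genome {self.strain_id!r}"
                )

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def gene_sequence(self, gene: GeneLocus) -> str:
        """Return the gene's nucleotide sequence in reading orientation."""
        seq = self.contigs[gene.contig_index][gene.start : gene.end]
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    @property
    def cds(self) -> list[GeneLocus]:
        return [g for g in self.genes if g.is_cds]


@dataclass(frozen=True)
class GenomeSummary:
    """Per-genome summary: size, GC mol% and shared-gene fraction."""

    strain_id: str
    genome_size: int
    gc_content: float | None
    shared_gene_fraction: float | None = None


@dataclass
class SimilarityMatrix:
    """An n x n matrix of pairwise similarity values in [0, 100].

    ``values[i, j]`` is the similarity of query ``strain_ids[i]`` against
    target ``strain_ids[j]``.  Undefined comparisons are NaN.  Fragment-based
    metrics (FBS, ANIb-G) are directed; core-gene metrics are symmetric.
    """

    metric: Metric
    strain_ids: list[str]
    values: np.ndarray
    directed: bool = True

    def __post_init__(self) -> None:
        self.metric = Metric(self.metric)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.strain_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} strain ids"
            )
        with np.errstate(invalid="ignore"):
            defined = ~np.isnan(self.values)
            if np.any((self.values[defined] < 0) | (self.values[defined] > 100)):
                raise ValueError("similarity values must lie in [0, 100]")

    @property
    def n(self) -> int:
        return len(self.strain_ids)

    def symmetrized(self) -> "SimilarityMatrix":
        """Return the symmetrized view S'(i,j) = mean(S(i,j), S(j,i)).

        When only one direction is defined that value is used; when neither
        is defined the cell stays NaN.
        """
        if not self.directed:
            return SimilarityMatrix(
                self.metric, list(self.strain_ids), self.values.copy(), directed=False
            )
        stacked = np.stack([self.values, self.values.T])
        with np.errstate(all="ignore"):
            sym = np.nanmean(stacked, axis=0)
        return SimilarityMatrix(self.metric, list(self.strain_ids), sym, directed=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strain_ids, columns=self.strain_ids)


def _normalize_sequence(raw: str, where: str) -> str:
    seq = raw.upper()
    n_coerced = len(_NON_ACGTN.findall(seq))
    if n_coerced:
        log.info("%s: coerced %d non-ACGTN characters to N", where, n_coerced)
        seq = _NON_ACGTN.sub("N", seq)
    return seq


_GFF_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def _read_gff_subset(path: Path, contig_ids: Sequence[str]) -> list[GeneLocus]:
    """Parse the honoured GFF3 subset: seqid, type CDS/gene, start, end, strand, ID."""
    index_of = {cid: i for i, cid in enumerate(contig_ids)}
    loci: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns")
            seqid, _source, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype not in ("CDS", "gene"):
                continue
            if seqid not in index_of:
                raise ValueError(
                    f"{path}:{lineno}: unknown seqid {seqid!r} (not in FASTA)"
                )
            m = _GFF_ID.search(attrs)
            if not m:
                raise ValueError(f"{path}:{lineno}: feature without ID attribute")
            loci.append(
                GeneLocus(
                    gene_id=m.group(1),
                    contig_index=index_of[seqid],
                    start=int(start) - 1,  # GFF is 1-based inclusive
                    end=int(end),
                    strand=strand,
                    is_cds=(ftype == "CDS"),
                )
            )
    return loci


def read_genome(
    fasta_path: str | Path,
    annotation_path: str | Path | None = None,
    metadata_row: Mapping[str, object] | None = None,
) -> GenomeRecord:
    """Read a genome from FASTA (+ optional GFF3-subset annotation).

    Lowercase input is normalized to uppercase and characters outside
    A/C/G/T/N are mapped to N (logged).  The strain id defaults to the FASTA
    file stem and may be overridden via ``metadata_row['strain_id']``.
    """
    fasta_path = Path(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"{fasta_path}: no FASTA records found")
    contigs = [
        _normalize_sequence(str(r.seq), f"{fasta_path.name}:{r.id}") for r in records
    ]
    contig_ids = [r.id for r in records]

    genes: list[GeneLocus] = []
    if annotation_path is not None:
        genes = _read_gff_subset(Path(annotation_path), contig_ids)

    meta = dict(metadata_row or {})

    def _opt(key: str) -> str | None:
        val = meta.get(key)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            return None
        return str(val)

    return GenomeRecord(
        strain_id=str(meta.get("strain_id", fasta_path.stem)),
        contigs=contigs,
        genes=genes,
        declared_species=_opt("species"),
        declared_group=_opt("group"),
    )


def write_genome(
    genome: GenomeRecord,
    fasta_path: str | Path,
    annotation_path: str | Path | None = None,
) -> None:
    """Write a genome as FASTA (contigs named ``<strain>|ctg<i>``) + GFF3 subset."""
    contig_ids = [f"{genome.strain_id}|ctg{i}" for i in range(len(genome.contigs))]
    records = [
        SeqRecord(Seq(seq), id=cid, description="")
        for cid, seq in zip(contig_ids, genome.contigs)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if annotation_path is not None:
        with open(annotation_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gene in genome.genes:
                ftype = "CDS" if gene.is_cds else "gene"
                fh.write(
                    "\t".join(
                        [
                            contig_ids[gene.contig_index],
                            "taxogenome",
                            ftype,
                            str(gene.start + 1),
                            str(gene.end),
                            ".",
                            gene.strand,
                            "0" if gene.is_cds else ".",
                            f"ID={gene.gene_id}",
                        ]
                    )
                    + "\n"
                )


def genome_summary(
    genome: GenomeRecord, shared_gene_count: int | None = None
) -> GenomeSummary:
    """Genome size, GC mol% (over A/C/G/T only) and shared-gene fraction.

    A genome consisting only of Ns has undefined GC content (``None``).
    """
    a = c = g = t = 0
    for contig in genome.contigs:
        a += contig.count("A")
        c += contig.count("C")
        g += contig.count("G")
        t += contig.count("T")
    acgt = a + c + g + t
    if acgt == 0:
        log.warning("genome %s: only Ns, GC content undefined", genome.strain_id)
        gc: float | None = None
    else:
        gc = 100.0 * (g + c) / acgt
    frac: float | None = None
    if shared_gene_count is not None:
        n_cds = len(genome.cds)
        if n_cds == 0:
            raise ValueError(
                f"genome {genome.strain_id!r}: shared_gene_count given but no CDS"
            )
        frac = shared_gene_count / n_cds
    return GenomeSummary(genome.strain_id, genome.length, gc, frac)


def translate_cds(nt: str, gene_id: str = "?") -> str:
    """Translate a CDS with the bacterial code; trailing stop removed.

    Raises ``ValueError`` naming the gene when an internal stop codon is
    present or the length is not a codon multiple.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"gene {gene_id!r}: CDS length {len(nt)} not divisible by 3")
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    if codons and codons[-1] in _STOP_CODONS:
        codons = codons[:-1]
    for idx, codon in enumerate(codons):
        if codon in _STOP_CODONS:
            raise ValueError(f"gene {gene_id!r}: internal stop codon at codon {idx}")
    return str(Seq("".join(codons)).translate(table=CODON_TABLE))


# ---------------------------------------------------------------------------
# matrix and metadata I/O
# ---------------------------------------------------------------------------

_MATRIX_DECIMALS = 4


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_matrix(matrix: SimilarityMatrix, path: str | Path) -> None:
    """Write a similarity matrix as TSV plus a JSON sidecar.

    The TSV stores directed values rounded to 4 decimals with strain ids as
    header row and column; undefined cells are ``NA``.  The sidecar records
    the metric and the ``directed`` flag so symmetrization is reproducible.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["strain_id", *matrix.strain_ids])
        for sid, row in zip(matrix.strain_ids, matrix.values):
            writer.writerow(
                [sid]
                + [
                    "NA" if np.isnan(v) else f"{v:.{_MATRIX_DECIMALS}f}"
                    for v in row
                ]
            )
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "metric": matrix.metric.value,
                "directed": matrix.directed,
                "strain_ids": matrix.strain_ids,
            },
            indent=2,
        )
        + "\n"
    )


def read_matrix(path: str | Path) -> SimilarityMatrix:
    """Read a similarity matrix written by :func:`write_matrix`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing matrix sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    with open(path) as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    header = rows[0][1:]
    n = len(header)
    values = np.full((n, n), np.nan)
    body = rows[1:]
    if len(body) != n:
        raise ValueError(f"{path}: {len(body)} data rows for {n} columns")
    row_ids = []
    for i, row in enumerate(body):
        if len(row) != n + 1:
            raise ValueError(f"{path}: ragged row {i + 2}")
        row_ids.append(row[0])
        values[i] = [np.nan if v == "NA" else float(v) for v in row[1:]]
    if row_ids != header:
        raise ValueError(f"{path}: header/row strain ids disagree")
    return SimilarityMatrix(
        metric=Metric(meta["metric"]),
        strain_ids=row_ids,
        values=values,
        directed=bool(meta["directed"]),
    )


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the strain metadata TSV (strain_id, species, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "strain_id" not in df.columns:
        raise ValueError(f"{path}: metadata must have a 'strain_id' column")
    for col in ("species", "group"):
        if col not in df.columns:
            df[col] = None
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
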