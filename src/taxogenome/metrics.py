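"""The four pairwise similarity metrics: FBS, ANIb-G, ANIb-C and AAI.

ANIb-G fragments the query genome into 1020 bp windows, locally aligns each
window to the target, keeps matches with identity > 30% and alignable
length >= 70% of the fragment, and averages the retained identities.  FBS
uses 500 bp windows and averages each fragment's best local score
normalized by its self-score (fragment length x match reward), counting
fragments without a hit as 0.  Both are directed: query->target and
target->query generally differ, and the matrix builder computes both.

ANIb-C and AAI are symmetric core-genome metrics: per single-copy core gene
family the two genomes' genes (nucleotide, or translated protein) are
globally aligned and the identity averaged over families.  Identity always
counts gap columns in the denominator -- one consistent definition across
all four metrics.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner

from . import core_genome
from .aligner import AlignerParams, GenomeIndex, best_local_match, fragment_genome
from .genome_io import GenomeRecord, Metric, SimilarityMatrix, translate_cds

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricParams:
    """Fragment sizes and ANIb hit filters."""

    fbs_fragment_length: int = 500
    anib_fragment_length: int = 1020
    anib_min_identity: float = 30.0  # retained when identity strictly above
    anib_min_alignable: float = 0.7

    def __post_init__(self) -> None:
        if self.fbs_fragment_length <= 0 or self.anib_fragment_length <= 0:
            raise ValueError("fragment lengths must be positive")
        if not 0 < self.anib_min_identity <= 100:
            raise ValueError("anib_min_identity must be in (0, 100]")
        if not 0 < self.anib_min_alignable <= 1:
            raise ValueError("anib_min_alignable must be in (0, 1]")


def _target_index(
    target: GenomeRecord | GenomeIndex, aligner_params: AlignerParams
) -> GenomeIndex:
    if isinstance(target, GenomeIndex):
        return target
    return GenomeIndex(target, aligner_params)


def anib_pair(
    query: GenomeRecord,
    target: GenomeRecord | GenomeIndex,
    params: MetricParams | None = None,
    aligner_params: AlignerParams | None = None,
) -> float | None:
    """Directed ANIb-G(query -> target) in percent, or ``None`` when no
    fragment passes the identity/coverage filters."""
    params = params or MetricParams()
    aligner_params = aligner_params or AlignerParams()
    index = _target_index(target, aligner_params)
    fragments = fragment_genome(query, params.anib_fragment_length)
    if not fragments:
        raise ValueError(f"genome {query.strain_id!r} yields no ANIb fragments")
    identities = []
    for frag in fragments:
        hit = best_local_match(frag.sequence, index, aligner_params)
        if hit is None:
            continue
        if (
            hit.identity > params.anib_min_identity
            and hit.alignable_fraction >= params.anib_min_alignable
        ):
            identities.append(hit.identity)
    if not identities:
        log.info(
            "ANIb %s -> %s undefined: no fragment passed filters",
            query.strain_id,
            index.genome.strain_id,
        )
        return None
    return float(np.mean(identities))


def fbs_pair(
    query: GenomeRecord,
    target: GenomeRecord | GenomeIndex,
    params: MetricParams | None = None,
    aligner_params: AlignerParams | None = None,
) -> float:
    """Directed fragmented-BLAST similarity score in [0, 100].

    Mean over non-overlapping fragments of ``100 * best local score /
    self-score``; fragments with no hit (or below the score floor)
    contribute 0.
    """
    params = params or MetricParams()
    aligner_params = aligner_params or AlignerParams()
    index = _target_index(target, aligner_params)
    fragments = fragment_genome(query, params.fbs_fragment_length)
    if not fragments:
        raise ValueError(f"genome {query.strain_id!r} yields no FBS fragments")
    self_score = params.fbs_fragment_length * aligner_params.match
    total = 0.0
    for frag in fragments:
        hit = best_local_match(frag.sequence, index, aligner_params)
        if hit is not None:
            total += 100.0 * max(0.0, hit.score) / self_score
    return total / len(fragments)


# ---------------------------------------------------------------------------
# core-gene metrics
# ---------------------------------------------------------------------------

_NT_ALIGNER = PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)
_AA_ALIGNER = PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def global_identity(a: str, b: str, protein: bool = False) -> float:
    """Percent identity of the global alignment of a and b.

    Matches / alignment columns, gap columns counted in the denominator.
    """
    aligner = _AA_ALIGNER if protein else _NT_ALIGNER
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def core_gene_sequences(
    genomes: list[GenomeRecord],
    families: list["core_genome.OrthologFamily"] | None = None,
) -> list[dict[str, str]]:
    """Nucleotide sequences of core genes: one dict strain_id -> CDS per
    core family.  Families are computed by reciprocal best hits when not
    supplied."""
    if families is None:
        families = core_genome.find_ortholog_families(genomes)
    by_id = {g.strain_id: g for g in genomes}
    out = []
    for fam in families:
        if not fam.is_core:
            continue
        seqs = {}
        for strain_id, gene_ids in fam.members.items():
            genome = by_id[strain_id]
            locus = next(g for g in genome.genes if g.gene_id == gene_ids[0])
            seqs[strain_id] = genome.gene_sequence(locus)
        out.append(seqs)
    if not out:
        raise ValueError("no core gene families among these genomes")
    return out


def anib_core(core_nt: list[dict[str, str]], i: str, j: str) -> float:
    """ANIb-C(i, j): mean pairwise nucleotide identity over core families."""
    if not core_nt:
        raise ValueError("empty core family list")
    vals = []
    for fam in core_nt:
        if i not in fam or j not in fam:
            raise ValueError(f"core family missing genome {i!r} or {j!r}")
        vals.append(global_identity(fam[i], fam[j], protein=False))
    return float(np.mean(vals))


def aai_core(core_nt: list[dict[str, str]], i: str, j: str) -> float:
    """AAI(i, j): mean pairwise amino-acid identity over translated core
    families (bacterial code, stop codon excluded)."""
    if not core_nt:
        raise ValueError("empty core family list")
    vals = []
    for fidx, fam in enumerate(core_nt):
        if i not in fam or j not in fam:
            raise ValueError(f"core family missing genome {i!r} or {j!r}")
        pi = translate_cds(fam[i], gene_id=f"family{fidx}:{i}")
        pj = translate_cds(fam[j], gene_id=f"family{fidx}:{j}")
        vals.append(global_identity(pi, pj, protein=True))
    return float(np.mean(vals))


def build_matrix(
    genomes: list[GenomeRecord],
    metric: Metric | str,
    params: MetricParams | None = None,
    aligner_params: AlignerParams | None = None,
    rbh_params: "core_genome.RBHParams | None" = None,
) -> SimilarityMatrix:
    """All-pairs similarity matrix for one metric.

    FBS and ANIb-G compute every ordered pair (directed matrix); ANIb-C and
    AAI every unordered pair (symmetric).  Diagonals are set to 100;
    undefined pairs are stored as NaN.
    """
    metric = Metric(metric)
    params = params or MetricParams()
    aligner_params = aligner_params or AlignerParams()
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    ids = [g.strain_id for g in genomes]
    n = len(ids)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)

    if metric in (Metric.FBS, Metric.ANIB_G):
        pair_fn = fbs_pair if metric is Metric.FBS else anib_pair
        indices = [GenomeIndex(g, aligner_params) for g in genomes]
        for qi, ti in itertools.permutations(range(n), 2):
            v = pair_fn(genomes[qi], indices[ti], params, aligner_params)
            values[qi, ti] = np.nan if v is None else v
            log.debug("%s %s -> %s: %s", metric.value, ids[qi], ids[ti], v)
        directed = True
    else:
        families = core_genome.find_ortholog_families(genomes, rbh_params)
        core_nt = core_gene_sequences(genomes, families)
        pair_core = anib_core if metric is Metric.ANIB_C else aai_core
        for qi, ti in itertools.combinations(range(n), 2):
            v = pair_core(core_nt, ids[qi], ids[ti])
            values[qi, ti] = values[ti, qi] = v
            log.debug("%s %s ~ %s: %.4f", metric.value, ids[qi], ids[ti], v)
        directed = False
    return SimilarityMatrix(metric, ids, values, directed=directed)
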