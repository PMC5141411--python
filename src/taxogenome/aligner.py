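"""Seed-and-extend local alignment: the search engine behind FBS and ANIb.

A fragment is searched against a target genome on both strands.  Exact
k-mer seeds (default k=15) are located with a sorted k-mer index of the
target, clustered by diagonal, and each cluster is extended by banded
affine-gap Smith-Waterman dynamic programming (numba-compiled).  The band
is widened and the cell recomputed whenever the optimal traceback touches
a band edge, so at the divergences the similarity metrics operate in the
returned score equals the unbanded Smith-Waterman optimum.

Scoring (fixed defaults, configurable): match +1, mismatch -2, gap open -4
for the first gap column and -1 per additional column.  There is no
E-value model: a minimum score floor of ``2 k`` stands in for significance
filtering, with the metric-level identity/coverage filters doing the real
work.  When no seed of length k exists, seeding is retried once at a
shorter fallback k before declaring a no-hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from numba import njit

from .genome_io import GenomeRecord

log = logging.getLogger(__name__)

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENC[_c] = _i
for _i, _c in enumerate(b"acgt"):
    _ENC[_c] = _i

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_NEG = -(2**28)


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0-3; anything else (N) as 4, which never matches."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement_codes(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr[::-1]]


@dataclass(frozen=True)
class AlignerParams:
    """Seed-and-extend parameters; scores are integers."""

    k: int = 15
    fallback_k: int = 8
    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1
    band: int = 32
    max_clusters: int = 50
    min_score: int | None = None  # defaults to 2 * k

    @property
    def score_floor(self) -> int:
        return 2 * self.k if self.min_score is None else self.min_score


class MatchResult(NamedTuple):
    """Best local alignment of a fragment against a target genome."""

    identity: float  # percent of alignment columns that are matches
    alignable_fraction: float  # aligned fragment positions / fragment length
    score: float
    target_contig: int
    target_start: int
    strand: str  # '+' fragment forward, '-' reverse complement


class Fragment(NamedTuple):
    sequence: str
    contig_index: int
    offset: int


def fragment_genome(genome: GenomeRecord, fragment_length: int) -> list[Fragment]:
    """Cut each contig into consecutive non-overlapping windows of exactly
    ``fragment_length``; trailing windows shorter than that are discarded."""
    if fragment_length <= 0:
        raise ValueError("fragment_length must be positive")
    fragments: list[Fragment] = []
    for ci, contig in enumerate(genome.contigs):
        n_full = len(contig) // fragment_length
        for w in range(n_full):
            off = w * fragment_length
            fragments.append(Fragment(contig[off : off + fragment_length], ci, off))
    if not fragments:
        log.info(
            "genome %s shorter than fragment length %d: no fragments",
            genome.strain_id,
            fragment_length,
        )
    return fragments


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (positions, packed codes) of all N-free k-mers in arr."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k).astype(np.int64)
    valid = (windows < 4).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = windows @ powers
    pos = np.flatnonzero(valid)
    return pos, codes[pos]


class GenomeIndex:
    """Sorted k-mer index over the contigs of a target genome.

    Built once per target and reused across queries; the fallback-k index is
    built lazily on first use.
    """

    def __init__(self, genome: GenomeRecord, params: AlignerParams | None = None):
        self.params = params or AlignerParams()
        self.genome = genome
        self.contig_codes = [encode(c) for c in genome.contigs]
        self._indices: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
        self._build(self.params.k)

    def _build(self, k: int) -> None:
        per_contig = []
        for arr in self.contig_codes:
            pos, codes = _kmer_codes(arr, k)
            order = np.argsort(codes, kind="stable")
            per_contig.append((codes[order], pos[order]))
        self._indices[k] = per_contig

    def seeds(self, frag: np.ndarray, k: int, contig: int) -> tuple[np.ndarray, np.ndarray]:
        """All (qpos, tpos) exact k-mer seed hits of frag in one contig."""
        if k not in self._indices:
            self._build(k)
        codes_sorted, pos_sorted = self._indices[k][contig]
        qpos, qcodes = _kmer_codes(frag, k)
        if qcodes.size == 0 or codes_sorted.size == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        lo = np.searchsorted(codes_sorted, qcodes, side="left")
        hi = np.searchsorted(codes_sorted, qcodes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        q_out = np.repeat(qpos, counts)
        t_out = np.empty(total, np.int64)
        at = 0
        for i in np.flatnonzero(counts):
            c = counts[i]
            t_out[at : at + c] = pos_sorted[lo[i] : hi[i]]
            at += c
        return q_out, t_out


@njit(cache=True)
def _banded_sw(q, t, dlo, dhi, ma, mi, go, ge):  # pragma: no cover - numba
    """Banded affine local alignment of q vs t on diagonals [dlo, dhi].

    Returns (score, qbeg, qend, tbeg, tend, matches, columns, touched),
    where touched means the optimal traceback ran along a band edge.
    """
    n = q.size
    m = t.size
    w = dhi - dlo + 1
    H = np.full((n + 1, w), _NEG, np.int32)
    E = np.full((n + 1, w), _NEG, np.int32)  # gap in query (left move)
    F = np.full((n + 1, w), _NEG, np.int32)  # gap in target (up move)
    for b in range(w):
        j = dlo + b
        if 0 <= j <= m:
            H[0, b] = 0
    best = 0
    bi = -1
    bb = -1
    for i in range(1, n + 1):
        for b in range(w):
            j = i + dlo + b
            if j < 0 or j > m:
                continue
            if j == 0:
                H[i, b] = 0
                continue
            e = _NEG
            if b - 1 >= 0:
                if H[i, b - 1] > _NEG:
                    e = H[i, b - 1] + go
                if E[i, b - 1] > _NEG and E[i, b - 1] + ge > e:
                    e = E[i, b - 1] + ge
            f = _NEG
            if b + 1 < w:
                if H[i - 1, b + 1] > _NEG:
                    f = H[i - 1, b + 1] + go
                if F[i - 1, b + 1] > _NEG and F[i - 1, b + 1] + ge > f:
                    f = F[i - 1, b + 1] + ge
            d = _NEG
            if H[i - 1, b] > _NEG:
                s = ma if (q[i - 1] == t[j - 1] and q[i - 1] < 4) else mi
                d = H[i - 1, b] + s
            h = 0
            if d > h:
                h = d
            if e > h:
                h = e
            if f > h:
                h = f
            E[i, b] = e
            F[i, b] = f
            H[i, b] = h
            if h > best:
                best = h
                bi = i
                bb = b
    if best <= 0 or bi < 0:
        return 0, 0, 0, 0, 0, 0, 0, False
    # traceback, preferring diagonal, then query-gap, then target-gap moves
    i = bi
    b = bb
    matches = 0
    columns = 0
    touched = False
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        j = i + dlo + b
        if b == 0 or b == w - 1:
            touched = True
        if state == 0:
            v = H[i, b]
            if v == 0:
                break
            diag = _NEG
            if i >= 1 and j >= 1 and H[i - 1, b] > _NEG:
                s = ma if (q[i - 1] == t[j - 1] and q[i - 1] < 4) else mi
                diag = H[i - 1, b] + s
            if v == diag:
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    matches += 1
                columns += 1
                i -= 1
            elif v == E[i, b]:
                state = 1
            else:
                state = 2
        elif state == 1:
            v = E[i, b]
            columns += 1
            prev_h = H[i, b - 1] if b - 1 >= 0 else _NEG
            if prev_h > _NEG and v == prev_h + go:
                state = 0
            b -= 1
        else:
            v = F[i, b]
            columns += 1
            prev_h = H[i - 1, b + 1] if b + 1 < w else _NEG
            if prev_h > _NEG and v == prev_h + go:
                state = 0
            i -= 1
            b += 1
    qbeg = i
    tbeg = i + dlo + b
    tend = bi + dlo + bb
    return best, qbeg, bi, tbeg, tend, matches, columns, touched


def _cluster_diagonals(diags: np.ndarray, merge_gap: int) -> list[tuple[int, int, int]]:
    """Group sorted unique diagonals closer than merge_gap; returns
    (dmin, dmax, n_seeds) per cluster, heaviest first."""
    uniq, counts = np.unique(diags, return_counts=True)
    clusters = []
    start = 0
    for i in range(1, uniq.size + 1):
        if i == uniq.size or uniq[i] - uniq[i - 1] > merge_gap:
            clusters.append(
                (int(uniq[start]), int(uniq[i - 1]), int(counts[start:i].sum()))
            )
            start = i
    clusters.sort(key=lambda c: (-c[2], c[0]))
    return clusters


def _extend_clusters(
    frag: np.ndarray,
    target: np.ndarray,
    clusters: list[tuple[int, int, int]],
    params: AlignerParams,
):
    """Run banded DP on each seed cluster; return the best raw hit tuple."""
    n, m = frag.size, target.size
    pad = params.band // 2
    best = None
    for dmin, dmax, _count in clusters[: params.max_clusters]:
        dlo = max(dmin - pad, -(n - 1))
        dhi = min(dmax + pad, m - 1)
        while True:
            res = _banded_sw(
                frag,
                target,
                dlo,
                dhi,
                params.match,
                params.mismatch,
                params.gap_open,
                params.gap_extend,
            )
            score, qbeg, qend, tbeg, tend, matches, columns, touched = res
            full = dlo <= -(n - 1) and dhi >= m - 1
            if not touched or full:
                break
            dlo = max(dlo - params.band, -(n - 1))
            dhi = min(dhi + params.band, m - 1)
        if score <= 0:
            continue
        if best is None or (score, -tbeg) > (best[0], -best[3]):
            best = res
    return best


def best_local_match(
    fragment: str,
    target: GenomeRecord | GenomeIndex,
    params: AlignerParams | None = None,
) -> MatchResult | None:
    """Best local alignment of ``fragment`` in ``target`` or ``None`` (no hit).

    Both strands are searched (the reverse complement of the fragment
    against the forward target).  Ties are broken by higher score, then
    lower target coordinate, then forward strand.
    """
    params = params or AlignerParams()
    if isinstance(target, GenomeIndex):
        index = target
    else:
        index = GenomeIndex(target, params)
    genome = index.genome
    if genome.length == 0:
        raise ValueError("empty target genome")
    if len(fragment) < params.k:
        raise ValueError(
            f"fragment length {len(fragment)} shorter than seed length {params.k}"
        )
    frag_fwd = encode(fragment)
    frag_rev = reverse_complement_codes(frag_fwd)

    best: tuple[tuple[int, int, int, int], tuple, str] | None = None
    for k in (params.k, params.fallback_k):
        if k is None or k <= 0:
            continue
        any_seed = False
        for ci, target_codes in enumerate(index.contig_codes):
            for strand, frag_arr in (("+", frag_fwd), ("-", frag_rev)):
                qpos, tpos = index.seeds(frag_arr, k, ci)
                if qpos.size == 0:
                    continue
                any_seed = True
                clusters = _cluster_diagonals(tpos - qpos, params.band)
                hit = _extend_clusters(frag_arr, target_codes, clusters, params)
                if hit is None:
                    continue
                score, qbeg, qend, tbeg, tend, matches, columns, _t = hit
                # sort key: higher score, lower (contig, tbeg), '+' before '-'
                key = (-score, ci, tbeg, 0 if strand == "+" else 1)
                if best is None or key < best[0]:
                    best = (key, hit, strand)
        if any_seed:
            break  # no fallback reseeding once k-mer seeds existed
    if best is None:
        return None
    _key, (score, qbeg, qend, tbeg, tend, matches, columns, _t), strand = best
    if score < params.score_floor:
        return None
    ci = _key[1]
    return MatchResult(
        identity=100.0 * matches / columns,
        alignable_fraction=(qend - qbeg) / len(fragment),
        score=float(score),
        target_contig=ci,
        target_start=tbeg,
        strand=strand,
    )
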