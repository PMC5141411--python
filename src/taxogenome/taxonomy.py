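"""Level statistics, rank boundaries, clustering and strain classification.

Pairwise similarities are summarized at three taxonomic levels: within
species, within species-group *excluding* same-species pairs, and between
groups.  The rank boundary between two adjacent levels is the midpoint of
the finer level's (mean - 1 SD) and the coarser level's (mean + 1 SD); the
open interval between those two bounds is the *buffer zone*, where
assignments are flagged as uncertain rather than decided.  Applied to the
published Rhodococcus level statistics this rule yields species boundaries
of 66.75 (FBS), ~94 (ANIb-G), 96.88 (ANIb-C) and 98.41 (AAI), and genus
boundaries of 6.9 (FBS) and 74.8 (ANIb-G).

Strains are partitioned by single-linkage at a threshold: connected
components of the graph with an edge wherever the symmetrized similarity
meets the threshold.  Classification compares each strain's best
similarity to its declared species' members (and groups) against the
thresholds, flagging misclassified strains, putative novel species/genera
and buffer-zone calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .genome_io import Metric, SimilarityMatrix

log = logging.getLogger(__name__)


class Level(str, Enum):
    WITHIN_SPECIES = "WITHIN_SPECIES"
    WITHIN_GROUP = "WITHIN_GROUP"  # same group, different species
    BETWEEN_GROUP = "BETWEEN_GROUP"


class Flag(str, Enum):
    MISCLASSIFIED = "MISCLASSIFIED"
    NOVEL_SPECIES = "NOVEL_SPECIES"
    NOVEL_GENUS = "NOVEL_GENUS"
    BUFFER_ZONE = "BUFFER_ZONE"


@dataclass(frozen=True)
class LevelStats:
    """Mean +- population SD of pairwise similarities at one level."""

    metric: Metric
    level: Level
    mean: float
    sd: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")

    def __str__(self) -> str:  # Fig-3 style presentation
        return f"{self.mean:.2f} ± {self.sd:.2f} (n={self.n_pairs})"


@dataclass(frozen=True)
class ThresholdSet:
    """Species and genus boundaries for one metric, with buffer zones."""

    metric: Metric
    species_threshold: float
    genus_threshold: float
    buffer_species: tuple[float, float]
    buffer_genus: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.genus_threshold < self.species_threshold:
            raise ValueError("genus threshold must lie below species threshold")


@dataclass
class TaxonAssignment:
    strain_id: str
    assigned_species: str
    assigned_group: str
    declared_species: str | None = None
    flags: set[Flag] = field(default_factory=set)


def _check_labels(matrix: SimilarityMatrix, labels: pd.DataFrame) -> pd.DataFrame:
    labels = labels.set_index("strain_id") if "strain_id" in labels.columns else labels
    missing = [sid for sid in matrix.strain_ids if sid not in labels.index]
    if missing:
        raise ValueError(f"strains without labels: {missing}")
    return labels


def summarize_levels(
    matrix: SimilarityMatrix, labels: pd.DataFrame
) -> list[LevelStats]:
    """Three LevelStats (one per level) from a matrix and species/group labels.

    The matrix is symmetrized first; self-pairs are excluded, NA pairs are
    dropped with a logged count, and levels with zero pairs are omitted with
    a warning.  SD is the population SD (divisor n).
    """
    labels = _check_labels(matrix, labels)
    sym = matrix.symmetrized()
    species = [labels.loc[sid, "species"] for sid in sym.strain_ids]
    group = [labels.loc[sid, "group"] for sid in sym.strain_ids]
    buckets: dict[Level, list[float]] = {lv: [] for lv in Level}
    n_na = 0
    n = sym.n
    for i in range(n):
        for j in range(i + 1, n):
            v = sym.values[i, j]
            if np.isnan(v):
                n_na += 1
                continue
            if species[i] == species[j]:
                buckets[Level.WITHIN_SPECIES].append(v)
            elif group[i] == group[j]:
                buckets[Level.WITHIN_GROUP].append(v)
            else:
                buckets[Level.BETWEEN_GROUP].append(v)
    if n_na:
        log.info("summarize_levels(%s): %d NA pairs excluded", sym.metric.value, n_na)
    out = []
    for level, vals in buckets.items():
        if not vals:
            log.warning(
                "summarize_levels(%s): level %s has no pairs; omitted",
                sym.metric.value,
                level.value,
            )
            continue
        arr = np.asarray(vals)
        out.append(
            LevelStats(
                metric=sym.metric,
                level=level,
                mean=float(arr.mean()),
                sd=float(arr.std(ddof=0)),
                n_pairs=arr.size,
            )
        )
    return out


def derive_threshold(upper: LevelStats, lower: LevelStats) -> float:
    """Rank boundary between a finer (upper) and coarser (lower) level:
    midpoint of ``upper.mean - upper.sd`` and ``lower.mean + lower.sd``."""
    if upper.mean <= lower.mean:
        raise ValueError(
            f"upper level mean {upper.mean} must exceed lower level mean {lower.mean}"
        )
    return ((upper.mean - upper.sd) + (lower.mean + lower.sd)) / 2.0


def buffer_interval(upper: LevelStats, lower: LevelStats) -> tuple[float, float]:
    """Buffer zone (lower.mean + sd, upper.mean - sd); inverted intervals
    (overlapping level distributions) collapse to the threshold point and
    are logged."""
    lo = lower.mean + lower.sd
    hi = upper.mean - upper.sd
    if lo >= hi:
        t = derive_threshold(upper, lower)
        log.warning(
            "buffer interval inverted for %s (%s vs %s): (%.4f, %.4f)",
            upper.metric.value,
            upper.level.value,
            lower.level.value,
            lo,
            hi,
        )
        return (t, t)
    return (lo, hi)


def derive_all_thresholds(stats: list[LevelStats]) -> ThresholdSet:
    """Species and genus boundaries for one metric from its three levels.

    Rounding happens only at report time (2 decimals for species, 1 for
    genus, matching conventional printed precision); the returned values
    are unrounded.
    """
    metrics = {s.metric for s in stats}
    if len(metrics) != 1:
        raise ValueError("level statistics must all belong to one metric")
    by_level = {s.level: s for s in stats}
    for level in Level:
        if level not in by_level:
            raise ValueError(f"missing level {level.value}")
    ws, wg, bg = (
        by_level[Level.WITHIN_SPECIES],
        by_level[Level.WITHIN_GROUP],
        by_level[Level.BETWEEN_GROUP],
    )
    return ThresholdSet(
        metric=metrics.pop(),
        species_threshold=derive_threshold(ws, wg),
        genus_threshold=derive_threshold(wg, bg),
        buffer_species=buffer_interval(ws, wg),
        buffer_genus=buffer_interval(wg, bg),
    )


def format_thresholds(ts: ThresholdSet) -> dict[str, float]:
    """Report-time rounding: species to 2 decimals, genus to 1."""
    return {
        "species_threshold": round(ts.species_threshold, 2),
        "genus_threshold": round(ts.genus_threshold, 1),
    }


def cluster_strains(matrix: SimilarityMatrix, threshold: float) -> pd.Series:
    """Single-linkage partition at ``threshold``.

    Connected components of the graph with an edge where the symmetrized
    similarity >= threshold; NA pairs count as below threshold (logged).
    Returns a Series strain_id -> cluster id ("C1", "C2", ... in input
    order).
    """
    sym = matrix.symmetrized()
    values = sym.values
    n = sym.n
    n_na = int(np.isnan(values[np.triu_indices(n, 1)]).sum())
    if n_na:
        log.info("cluster_strains: %d NA pairs treated as below threshold", n_na)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            v = values[i, j]
            if not np.isnan(v) and v >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    roots: dict[int, str] = {}
    out = []
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = f"C{len(roots) + 1}"
        out.append(roots[r])
    return pd.Series(out, index=sym.strain_ids, name="cluster")


def _in_buffer(v: float, interval: tuple[float, float]) -> bool:
    lo, hi = interval
    return lo < v < hi


def classify_strains(
    matrix: SimilarityMatrix,
    thresholds: ThresholdSet,
    labels: pd.DataFrame,
) -> list[TaxonAssignment]:
    """Assign strains to species/group clusters and flag anomalies.

    * MISCLASSIFIED: declared species exists (other labeled members) but the
      strain's best similarity to them falls below the species threshold.
    * NOVEL_SPECIES: singleton species cluster inside a group with other
      members.
    * NOVEL_GENUS: best similarity to every named group's members falls
      below the genus threshold.
    * BUFFER_ZONE: a decisive similarity lies inside a buffer interval.
    """
    labels = _check_labels(matrix, labels)
    sym = matrix.symmetrized()
    ids = sym.strain_ids
    values = sym.values
    idx = {sid: i for i, sid in enumerate(ids)}
    species_clusters = cluster_strains(sym, thresholds.species_threshold)
    group_clusters = cluster_strains(sym, thresholds.genus_threshold)

    declared_species = {sid: labels.loc[sid, "species"] for sid in ids}
    declared_group = {sid: labels.loc[sid, "group"] for sid in ids}

    species_members: dict[str, list[str]] = {}
    for sid, sp in declared_species.items():
        if sp is not None and not (isinstance(sp, float) and np.isnan(sp)):
            species_members.setdefault(sp, []).append(sid)
    group_members: dict[str, list[str]] = {}
    for sid, gr in declared_group.items():
        if gr is not None and not (isinstance(gr, float) and np.isnan(gr)):
            group_members.setdefault(gr, []).append(sid)

    def _best_to(sid: str, member_ids: list[str]) -> float:
        i = idx[sid]
        vals = [
            values[i, idx[m]]
            for m in member_ids
            if m != sid and not np.isnan(values[i, idx[m]])
        ]
        return max(vals) if vals else float("-inf")

    out = []
    sp_sizes = species_clusters.value_counts()
    gr_sizes = group_clusters.value_counts()
    for sid in ids:
        flags: set[Flag] = set()
        sp_label = declared_species[sid]
        if sp_label in species_members and len(species_members[sp_label]) > 1:
            decisive = _best_to(sid, species_members[sp_label])
            if decisive < thresholds.species_threshold:
                flags.add(Flag.MISCLASSIFIED)
            if np.isfinite(decisive) and _in_buffer(
                decisive, thresholds.buffer_species
            ):
                flags.add(Flag.BUFFER_ZONE)
        if (
            sp_sizes[species_clusters[sid]] == 1
            and gr_sizes[group_clusters[sid]] > 1
        ):
            flags.add(Flag.NOVEL_SPECIES)
        best_group = float("-inf")
        for gr, members in group_members.items():
            best_group = max(best_group, _best_to(sid, members))
        if group_members and best_group < thresholds.genus_threshold:
            flags.add(Flag.NOVEL_GENUS)
        if np.isfinite(best_group) and _in_buffer(best_group, thresholds.buffer_genus):
            flags.add(Flag.BUFFER_ZONE)
        out.append(
            TaxonAssignment(
                strain_id=sid,
                assigned_species=species_clusters[sid],
                assigned_group=group_clusters[sid],
                declared_species=None
                if sp_label is None or (isinstance(sp_label, float) and np.isnan(sp_label))
                else str(sp_label),
                flags=flags,
            )
        )
    return out


def assignments_to_frame(assignments: list[TaxonAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain_id": a.strain_id,
                "assigned_species": a.assigned_species,
                "assigned_group": a.assigned_group,
                "declared_species": a.declared_species,
                "flags": ",".join(sorted(f.value for f in a.flags)),
            }
            for a in assignments
        ]
    )
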