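"""Taxonomy: level statistics, boundary rule, clustering, classification."""

import numpy as np
import pandas as pd
import pytest

from taxogenome.genome_io import Metric, SimilarityMatrix
from taxogenome.taxonomy import (
    Flag,
    Level,
    LevelStats,
    ThresholdSet,
    buffer_interval,
    classify_strains,
    cluster_strains,
    derive_all_thresholds,
    derive_threshold,
    format_thresholds,
    summarize_levels,
)


def LS(level, mean, sd, metric=Metric.FBS, n=10):
    return LevelStats(metric, level, mean, sd, n)


def _labels(rows):
    return pd.DataFrame(rows, columns=["strain_id", "species", "group"])


def _sym_matrix(ids, values, metric=Metric.ANIB_G):
    return SimilarityMatrix(metric, ids, np.asarray(values, float), directed=False)


class TestSummarizeLevels:
    def test_single_pair_within_species(self):
        m = _sym_matrix(["a", "b"], [[100, 98], [98, 100]])
        labels = _labels([("a", "sp1", "g1"), ("b", "sp1", "g1")])
        stats = summarize_levels(m, labels)
        assert len(stats) == 1
        s = stats[0]
        assert s.level is Level.WITHIN_SPECIES
        assert (s.mean, s.sd, s.n_pairs) == (98.0, 0.0, 1)

    def test_hand_computed_four_strain_case(self):
        # a,b: species sp1; c: sp2 (same group g1); d: sp3 in group g2
        ids = ["a", "b", "c", "d"]
        vals = [
            [100, 98, 85, 70],
            [98, 100, 83, 72],
            [85, 83, 100, 74],
            [70, 72, 74, 100],
        ]
        labels = _labels(
            [("a", "sp1", "g1"), ("b", "sp1", "g1"), ("c", "sp2", "g1"),
             ("d", "sp3", "g2")]
        )
        stats = {s.level: s for s in summarize_levels(_sym_matrix(ids, vals), labels)}
        assert stats[Level.WITHIN_SPECIES].mean == 98.0
        wg = stats[Level.WITHIN_GROUP]
        assert wg.n_pairs == 2 and wg.mean == pytest.approx(84.0)
        assert wg.sd == pytest.approx(1.0)  # population SD of {85, 83}
        bg = stats[Level.BETWEEN_GROUP]
        assert bg.n_pairs == 3 and bg.mean == pytest.approx(72.0)
        assert bg.sd == pytest.approx(np.std([70, 72, 74]))

    def test_all_singleton_species_omits_within_species(self):
        m = _sym_matrix(["a", "b"], [[100, 80], [80, 100]])
        labels = _labels([("a", "sp1", "g1"), ("b", "sp2", "g1")])
        levels = {s.level for s in summarize_levels(m, labels)}
        assert Level.WITHIN_SPECIES not in levels

    def test_na_pairs_excluded(self):
        m = _sym_matrix(["a", "b", "c"], [[100, 98, np.nan],
                                          [98, 100, 97],
                                          [np.nan, 97, 100]])
        labels = _labels([(s, "sp1", "g1") for s in "abc"])
        (s,) = summarize_levels(m, labels)
        assert s.n_pairs == 2

    def test_unlabeled_strain_errors(self):
        m = _sym_matrix(["a", "b"], [[100, 98], [98, 100]])
        with pytest.raises(ValueError, match="without labels"):
            summarize_levels(m, _labels([("a", "sp1", "g1")]))


class TestDeriveThreshold:
    """The boundary rule against the six published Rhodococcus values."""

    @pytest.mark.parametrize(
        "upper,lower,expected",
        [
            ((83.45, 6.91), (32.67, 24.29), 66.75),   # FBS species
            ((98.02, 0.84), (83.47, 7.30), 93.975),   # ANIb-G species (~94)
            ((32.67, 24.29), (3.64, 1.86), 6.94),     # FBS genus (prints 6.9)
            ((83.47, 7.30), (71.63, 1.86), 74.83),    # ANIb-G genus (prints 74.8)
            ((99.11, 0.42), (89.28, 5.79), 96.88),    # ANIb-C species
            ((99.44, 0.76), (93.92, 4.22), 98.41),    # AAI species
        ],
    )
    def test_published_boundaries(self, upper, lower, expected):
        got = derive_threshold(
            LS(Level.WITHIN_SPECIES, *upper), LS(Level.WITHIN_GROUP, *lower)
        )
        assert got == pytest.approx(expected, abs=1e-9)

    def test_equal_means_error(self):
        with pytest.raises(ValueError, match="must exceed"):
            derive_threshold(
                LS(Level.WITHIN_SPECIES, 50, 0), LS(Level.WITHIN_GROUP, 50, 0)
            )

    def test_buffer_interval_and_inversion(self):
        up, lo = LS(Level.WITHIN_SPECIES, 98, 1), LS(Level.WITHIN_GROUP, 85, 5)
        assert buffer_interval(up, lo) == (90.0, 97.0)
        up2, lo2 = LS(Level.WITHIN_SPECIES, 90, 10), LS(Level.WITHIN_GROUP, 85, 10)
        lo_b, hi_b = buffer_interval(up2, lo2)
        assert lo_b == hi_b  # inverted interval collapses to the threshold

    def test_derive_all_and_report_rounding(self):
        stats = [
            LS(Level.WITHIN_SPECIES, 83.45, 6.91),
            LS(Level.WITHIN_GROUP, 32.67, 24.29),
            LS(Level.BETWEEN_GROUP, 3.64, 1.86),
        ]
        ts = derive_all_thresholds(stats)
        fmt = format_thresholds(ts)
        assert fmt == {"species_threshold": 66.75, "genus_threshold": 6.9}
        assert ts.buffer_species[0] < ts.species_threshold < ts.buffer_species[1]
        assert ts.genus_threshold < ts.species_threshold

    def test_missing_level_errors(self):
        with pytest.raises(ValueError, match="missing level"):
            derive_all_thresholds([LS(Level.WITHIN_SPECIES, 98, 1)])


class TestClusterStrains:
    def test_all_connected_single_cluster(self):
        m = _sym_matrix(["a", "b", "c"], np.full((3, 3), 99.0))
        assert cluster_strains(m, 95).nunique() == 1

    def test_two_block_matrix(self):
        ids = list("abcde")
        v = np.full((5, 5), 60.0)
        for i in (0, 1):
            for j in (0, 1):
                v[i, j] = 99
        for i in (2, 3, 4):
            for j in (2, 3, 4):
                v[i, j] = 99
        part = cluster_strains(_sym_matrix(ids, v), 95)
        assert part["a"] == part["b"] != part["c"]
        assert part["c"] == part["d"] == part["e"]

    def test_single_linkage_chain(self):
        v = [[100, 96, 80], [96, 100, 96], [80, 96, 100]]
        part = cluster_strains(_sym_matrix(list("abc"), v), 95)
        assert part.nunique() == 1

    def test_invariant_under_reordering(self, rng):
        ids = list("abcdef")
        v = rng.uniform(50, 100, size=(6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 100)
        part = cluster_strains(_sym_matrix(ids, v), 80)
        order = [3, 1, 5, 0, 2, 4]
        part2 = cluster_strains(
            _sym_matrix([ids[i] for i in order], v[np.ix_(order, order)]), 80
        )
        for a in ids:
            for b in ids:
                assert (part[a] == part[b]) == (part2[a] == part2[b])

    def test_monotone_coarsening(self, rng):
        """Genus-level clusters are unions of species-level clusters."""
        ids = [f"s{i}" for i in range(8)]
        v = rng.uniform(60, 100, size=(8, 8))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 100)
        m = _sym_matrix(ids, v)
        fine = cluster_strains(m, 90)
        coarse = cluster_strains(m, 75)
        for a in ids:
            for b in ids:
                if fine[a] == fine[b]:
                    assert coarse[a] == coarse[b]


class TestClassifyStrains:
    _TS = ThresholdSet(
        metric=Metric.ANIB_G,
        species_threshold=94.0,
        genus_threshold=74.8,
        buffer_species=(90.8, 97.2),
        buffer_genus=(73.5, 76.2),
    )

    def test_conspecific_assignment_no_flags(self):
        m = _sym_matrix(["a", "b"], [[100, 98], [98, 100]])
        labels = _labels([("a", "spX", "g1"), ("b", "spX", "g1")])
        (ra, rb) = classify_strains(m, self._TS, labels)
        assert ra.assigned_species == rb.assigned_species
        assert not ra.flags and not rb.flags

    def test_misclassified_plus_novel_species(self):
        # q declared spX: 90 to both X members (below 94) but 80 to the group
        ids = ["x1", "x2", "q"]
        v = [[100, 98, 90], [98, 100, 90], [90, 90, 100]]
        labels = _labels([("x1", "spX", "g1"), ("x2", "spX", "g1"),
                          ("q", "spX", "g1")])
        res = {a.strain_id: a for a in classify_strains(
            _sym_matrix(ids, v), self._TS, labels)}
        assert Flag.MISCLASSIFIED in res["q"].flags
        assert Flag.NOVEL_SPECIES in res["q"].flags
        assert res["q"].assigned_group == res["x1"].assigned_group

    def test_novel_genus_flag(self):
        ids = ["a", "b", "z"]
        v = [[100, 98, 60], [98, 100, 60], [60, 60, 100]]
        labels = _labels([("a", "spA", "g1"), ("b", "spA", "g1"),
                          ("z", None, None)])
        res = {a.strain_id: a for a in classify_strains(
            _sym_matrix(ids, v), self._TS, labels)}
        assert Flag.NOVEL_GENUS in res["z"].flags

    def test_buffer_zone_flag(self):
        ids = ["a", "b", "q"]
        v = [[100, 98, 95], [98, 100, 95], [95, 95, 100]]
        labels = _labels([("a", "spA", "g1"), ("b", "spA", "g1"),
                          ("q", "spA", "g1")])
        res = {a.strain_id: a for a in classify_strains(
            _sym_matrix(ids, v), self._TS, labels)}
        # 95 is above the species threshold but inside the buffer (90.8, 97.2)
        assert Flag.MISCLASSIFIED not in res["q"].flags
        assert Flag.BUFFER_ZONE in res["q"].flags

    def test_recovers_simulated_truth(self, small_clade):
        from taxogenome import build_matrix

        m = build_matrix(small_clade.genomes, Metric.ANIB_G)
        stats = summarize_levels(m, small_clade.truth)
        ts = derive_all_thresholds(stats)
        res = classify_strains(m, ts, small_clade.truth)
        tr = small_clade.truth.set_index("strain_id")
        by_assigned: dict[str, set] = {}
        for a in res:
            # BUFFER_ZONE only marks uncertainty; no hard anomaly flags here
            assert not a.flags - {Flag.BUFFER_ZONE}, (
                f"{a.strain_id} unexpectedly flagged: {a.flags}"
            )
            by_assigned.setdefault(a.assigned_species, set()).add(
                tr.loc[a.strain_id, "species"]
            )
        # each recovered species cluster maps to exactly one true species
        assert all(len(v) == 1 for v in by_assigned.values())
        assert len(by_assigned) == tr["species"].nunique()
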