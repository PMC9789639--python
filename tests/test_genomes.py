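"""MAG filtering, enrichment scoring, genomospecies, recruitment, RPKG."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aromdeg import (
    MAGRecord,
    comparative_marker_census,
    filter_best_hits,
    filter_mags,
    genomospecies,
    mag_pathway_scores,
    rpkg,
    select_enriched_mags,
)
from aromdeg.pathways import Pathway, PathwayCatalog, Reaction


def _mag(mag_id="M1", completeness=80.0, contamination=2.0, ecs=(), kos=(), size=2000.0):
    return MAGRecord(mag_id, completeness, contamination, size, tuple(ecs), tuple(kos))


class TestQualityFilter:
    @pytest.mark.parametrize(
        "completeness,contamination,kept",
        [
            (30.0, 5.0, False),   # boundary: strictly greater than 30 required
            (95.0, 2.0, True),
            (50.0, 10.0, False),  # boundary: strictly less than 10 required
            (30.1, 9.9, True),
        ],
    )
    def test_strict_thresholds(self, completeness, contamination, kept):
        out = filter_mags([_mag(completeness=completeness, contamination=contamination)])
        assert (len(out) == 1) is kept


class TestPathwayScores:
    @pytest.fixture
    def catalog(self):
        def pwy(pid, n_rxn, klass="funneling"):
            return Pathway(pid, pid, klass, reactions=[
                Reaction(f"{pid}_R{i}", f"{pid}.{i}", ("other",)) for i in range(n_rxn)
            ])
        return PathwayCatalog([pwy("F1", 5), pwy("F2", 3), pwy("F3", 2),
                               pwy("RF1", 3, "ring_fission")])

    def test_normalized_score_formula(self, catalog):
        # 1 of 5 reactions present, completeness 50% -> raw 0.2, normalized 0.4
        mag = _mag(completeness=50.0, ecs=["F1.0"])
        scores, _ = mag_pathway_scores(mag, catalog)
        assert scores["F1"] == pytest.approx(0.4)

    def test_complete_pathway_full_completeness(self, catalog):
        mag = _mag(completeness=100.0, ecs=["F3.0", "F3.1"])
        scores, _ = mag_pathway_scores(mag, catalog)
        assert scores["F3"] == pytest.approx(1.0)

    def test_cap_at_one_for_low_completeness(self, catalog):
        mag = _mag(completeness=40.0, ecs=["F3.0", "F3.1"])
        scores, _ = mag_pathway_scores(mag, catalog)
        assert scores["F3"] == 1.0
        uncapped, _ = mag_pathway_scores(mag, catalog, cap=False)
        assert uncapped["F3"] == pytest.approx(2.5)

    def test_median_includes_zero_pathways(self, catalog):
        mag = _mag(completeness=100.0, ecs=["F1.0"])
        _, med = mag_pathway_scores(mag, catalog)
        assert med == 0.0  # two of three funneling pathways absent

    def test_ring_fission_pathways_excluded(self, catalog):
        mag = _mag(ecs=["RF1.0", "RF1.1", "RF1.2"])
        scores, med = mag_pathway_scores(mag, catalog)
        assert "RF1" not in scores.index
        assert med == 0.0

    def test_zero_completeness_rejected(self, catalog):
        with pytest.raises(ValueError):
            mag_pathway_scores(_mag(completeness=0.0), catalog)


class TestEnrichmentSelection:
    @pytest.fixture
    def catalog(self):
        return PathwayCatalog([
            Pathway("F1", "f1", "funneling",
                    reactions=[Reaction("R1", "1.1", ("other",))]),
        ])

    def test_strict_threshold_boundary(self, catalog):
        over = _mag("hi", completeness=100.0, ecs=["1.1"])       # median 1.0
        under = _mag("lo", completeness=100.0, ecs=[])           # median 0.0
        selected, table = select_enriched_mags([over, under], catalog)
        assert selected == ["hi"]
        # exact-boundary median is not selected (strictly greater required)
        assert table.loc["lo", "median_score"] == 0.0

    def test_monotone_in_annotations(self):
        cat = PathwayCatalog([
            Pathway("F1", "f1", "funneling", reactions=[
                Reaction("R1", "1.1", ("other",)), Reaction("R2", "1.2", ("other",))
            ]),
        ])
        base = _mag("m", completeness=80.0, ecs=["1.1"])
        more = _mag("m", completeness=80.0, ecs=["1.1", "1.2"])
        s1, _ = select_enriched_mags([base], cat)
        s2, _ = select_enriched_mags([more], cat)
        assert set(s1) <= set(s2)


class TestGenomospecies:
    def test_transitive_closure(self):
        ani = pd.DataFrame(
            [[100, 96, 94], [96, 100, 96], [94, 96, 100]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        labels = genomospecies(ani)
        assert labels.nunique() == 1

    def test_all_below_threshold_are_singletons(self):
        ani = pd.DataFrame(
            [[100, 90, 80], [90, 100, 85], [80, 85, 100]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        assert genomospecies(ani).nunique() == 3

    def test_exact_95_is_no_edge(self):
        ani = pd.DataFrame([[100.0, 95.0], [95.0, 100.0]], index=list("AB"),
                           columns=list("AB"))
        assert genomospecies(ani).nunique() == 2

    def test_asymmetric_matrix_rejected(self):
        ani = pd.DataFrame([[100.0, 96.0], [94.0, 100.0]], index=list("AB"),
                           columns=list("AB"))
        with pytest.raises(ValueError):
            genomospecies(ani)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(2, 20), st.integers(0, 2**31 - 1))
    def test_matches_union_find_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(75, 100, size=(n, n))
        a = np.triu(a, 1)
        a = a + a.T
        np.fill_diagonal(a, 100.0)

        # independent union-find oracle
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if a[i, j] > 95.0:
                    parent[find(i)] = find(j)
        oracle = [find(i) for i in range(n)]
        ours = genomospecies(a)
        # same partition up to relabeling
        pairs_same_oracle = {(i, j) for i in range(n) for j in range(n)
                             if oracle[i] == oracle[j]}
        pairs_same_ours = {(i, j) for i in range(n) for j in range(n)
                           if ours.iloc[i] == ours.iloc[j]}
        assert pairs_same_oracle == pairs_same_ours


class TestBestHits:
    def _hits(self, rows):
        return pd.DataFrame(
            rows, columns=["read_id", "target_id", "aln_len_bp", "pct_identity", "bitscore"]
        )

    def test_maximal_bitscore_wins(self):
        hits = self._hits([("r1", "X", 150, 99.0, 50.0), ("r1", "Y", 150, 99.0, 60.0)])
        out = filter_best_hits(hits)
        assert list(out["target_id"]) == ["Y"]

    def test_short_alignment_discarded(self):
        hits = self._hits([("r1", "X", 99, 99.0, 50.0)])
        assert filter_best_hits(hits).empty

    def test_inclusive_boundaries_kept(self):
        hits = self._hits([("r1", "X", 100, 98.0, 50.0)])
        out = filter_best_hits(hits)
        assert len(out) == 1

    def test_tie_broken_lexicographically_and_flagged(self):
        hits = self._hits([("r1", "Z", 150, 99.0, 50.0), ("r1", "A", 150, 99.0, 50.0)])
        out = filter_best_hits(hits)
        assert list(out["target_id"]) == ["A"]
        assert bool(out["tie"].iloc[0])

    def test_filter_applied_after_best_hit(self):
        # best hit fails the filter: the read is dropped, not reassigned
        hits = self._hits([("r1", "X", 90, 99.0, 60.0), ("r1", "Y", 150, 99.0, 50.0)])
        assert filter_best_hits(hits).empty


class TestRPKG:
    def test_formula(self):
        out = rpkg(pd.Series({"m": 500}), pd.Series({"m": 1000.0}), 5.0)
        assert out["m"] == pytest.approx(0.1)

    def test_zero_reads(self):
        assert rpkg(pd.Series({"m": 0}), pd.Series({"m": 1000.0}), 5.0)["m"] == 0.0

    def test_linearity_and_library_scaling(self):
        base = rpkg(pd.Series({"m": 100}), pd.Series({"m": 500.0}), 2.0)["m"]
        assert rpkg(pd.Series({"m": 200}), pd.Series({"m": 500.0}), 2.0)["m"] == \
            pytest.approx(2 * base)
        assert rpkg(pd.Series({"m": 100}), pd.Series({"m": 500.0}), 4.0)["m"] == \
            pytest.approx(base / 2)

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            rpkg(pd.Series({"m": 1}), pd.Series({"m": 0.0}), 1.0)


class TestMarkerCensus:
    def test_copy_numbers_and_contrast(self):
        markers = {"P1": ("1.1", "K1"), "P2": ("2.2", "K2")}
        a = _mag("arctic1", kos=["K1", "K1", "K1"])
        b = _mag("ref1", kos=["K2"])
        census, contrast = comparative_marker_census(
            {"arctic": [a], "reference": [b]}, markers, pairing={"arctic1": "ref1"}
        )
        assert census.loc["arctic1", "K1"] == 3
        assert census.loc["ref1", "K1"] == 0
        assert contrast.loc[0, "arctic_only"] == "K1"
        assert contrast.loc[0, "reference_only"] == "K2"

    def test_unpaired_mag_rejected(self):
        markers = {"P1": ("1.1", "K1")}
        with pytest.raises(ValueError):
            comparative_marker_census(
                {"a": [_mag("x")], "b": [_mag("y")]}, markers, pairing={"x": "missing"}
            )
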