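import itertools

import numpy as np
import pandas as pd
import pytest

from barcodekit.distances import DistanceMatrix
from barcodekit.identification import (
    NoDensityMinimumError,
    OUTCOMES,
    optimal_threshold,
    run_identification_panel,
    simulate_identifications,
    summarize_outcomes,
    threshold_cumulative_error,
    threshold_density_minimum,
)

from conftest import random_distance_matrix


def _dm(ids, d):
    d = np.asarray(d, float)
    return DistanceMatrix(ids=ids, d=d, model="K2P", comparable_sites=np.full(d.shape, 658))


def three_seq_library(d_a1a2, d_a1b1, d_a2b1=None):
    ids = ["a1", "a2", "b1"]
    d_a2b1 = d_a1b1 if d_a2b1 is None else d_a2b1
    d = np.array([[0, d_a1a2, d_a1b1], [d_a1a2, 0, d_a2b1], [d_a1b1, d_a2b1, 0]])
    labels = {"a1": "sp A", "a2": "sp A", "b1": "sp B"}
    return _dm(ids, d), labels


def brute_force_outcome(dm, labels, query, criterion, threshold):
    """Independent re-statement of the criterion definitions by enumeration."""
    cands = [
        (dm.loc(query, other), other)
        for other in dm.ids
        if other != query and labels.get(other) and not np.isnan(dm.loc(query, other))
    ]
    qsp = labels[query]
    if criterion == "BM":
        dmin = min(d for d, _ in cands)
        tied_sp = {labels[o] for d, o in cands if d == dmin}
        if tied_sp == {qsp}:
            return "correct"
        return "ambiguous" if len(tied_sp) >= 2 else "incorrect"
    within = [(d, o) for d, o in cands if d <= threshold]
    if not within:
        return "no_identification"
    if criterion == "BCM":
        dmin = min(d for d, _ in within)
        tied_sp = {labels[o] for d, o in within if d == dmin}
        if tied_sp == {qsp}:
            return "correct"
        return "ambiguous" if len(tied_sp) >= 2 else "incorrect"
    species = {labels[o] for _, o in within}
    if species == {qsp}:
        return "correct"
    return "ambiguous" if len(species) >= 2 else "incorrect"


class TestCriteria:
    def test_bcm_correct_within_threshold(self):
        dm, labels = three_seq_library(0.003, 0.05)
        out = simulate_identifications(dm, labels, "BCM", 0.01).set_index("query_id")
        assert out.loc["a1", "outcome"] == "correct"

    def test_bcm_unidentified_but_bm_correct_when_conspecific_far(self):
        dm, labels = three_seq_library(0.02, 0.05)
        bcm = simulate_identifications(dm, labels, "BCM", 0.01).set_index("query_id")
        bm = simulate_identifications(dm, labels, "BM").set_index("query_id")
        assert bcm.loc["a1", "outcome"] == "no_identification"
        assert bm.loc["a1", "outcome"] == "correct"

    def test_bic_ambiguous_when_two_species_within_threshold(self):
        dm, labels = three_seq_library(0.003, 0.008)
        bic = simulate_identifications(dm, labels, "BIC", 0.01).set_index("query_id")
        bcm = simulate_identifications(dm, labels, "BCM", 0.01).set_index("query_id")
        assert bic.loc["a1", "outcome"] == "ambiguous"
        assert bcm.loc["a1", "outcome"] == "correct"

    def test_bm_tie_across_species_is_ambiguous(self):
        ids = ["a1", "a2", "b1"]
        d = np.array([[0, 0.01, 0.01], [0.01, 0, 0.02], [0.01, 0.02, 0]])
        labels = {"a1": "sp A", "a2": "sp A", "b1": "sp B"}
        out = simulate_identifications(_dm(ids, d), labels, "BM").set_index("query_id")
        assert out.loc["a1", "outcome"] == "ambiguous"

    def test_bm_tie_among_conspecifics_only_is_correct(self):
        ids = ["a1", "a2", "a3", "b1"]
        d = np.full((4, 4), 0.05)
        np.fill_diagonal(d, 0)
        d[0, 1] = d[1, 0] = d[0, 2] = d[2, 0] = 0.01
        labels = {"a1": "sp A", "a2": "sp A", "a3": "sp A", "b1": "sp B"}
        out = simulate_identifications(_dm(ids, d), labels, "BM").set_index("query_id")
        assert out.loc["a1", "outcome"] == "correct"

    def test_singletons_and_unlabeled_are_not_queries(self):
        ids = ["a1", "a2", "b1", "u1"]
        d = np.full((4, 4), 0.05)
        np.fill_diagonal(d, 0)
        labels = {"a1": "sp A", "a2": "sp A", "b1": "sp B", "u1": ""}
        out = simulate_identifications(_dm(ids, d), labels, "BM")
        assert set(out["query_id"]) == {"a1", "a2"}

    def test_threshold_required_for_bcm_and_bic(self):
        dm, labels = three_seq_library(0.003, 0.05)
        with pytest.raises(ValueError, match="threshold"):
            simulate_identifications(dm, labels, "BIC")


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_small_libraries(self):
        """Implementation agrees with direct enumeration of the criterion
        definitions over random <=8-sequence libraries, all criteria and
        several thresholds."""
        rng = np.random.default_rng(42)
        thresholds = [0.002, 0.005, 0.01, 0.02, 0.05]
        n_checked = 0
        for _ in range(50):
            n = int(rng.integers(4, 9))
            dm = random_distance_matrix(rng, n)
            n_sp = int(rng.integers(2, 4))
            labels = {sid: f"sp{rng.integers(0, n_sp)}" for sid in dm.ids}
            for crit in ("BM", "BCM", "BIC"):
                for t in [None] if crit == "BM" else thresholds:
                    got = simulate_identifications(dm, labels, crit, t)
                    for _, row in got.iterrows():
                        expect = brute_force_outcome(dm, labels, row["query_id"], crit, t)
                        assert row["outcome"] == expect
                        n_checked += 1
        assert n_checked > 500


class TestInvariants:
    def test_outcome_conservation(self, default_dm, default_sim):
        ds, _ = default_sim
        labels = ds.species_map()
        for crit, t in [("BM", None), ("BCM", 0.01), ("BIC", 0.01)]:
            out = simulate_identifications(default_dm, labels, crit, t)
            s = summarize_outcomes(out)
            assert s["count"].sum() == len(out)
            assert s["percent"].sum() == pytest.approx(100.0)

    def test_raising_threshold_never_increases_unidentified(self, default_dm, default_sim):
        ds, _ = default_sim
        labels = ds.species_map()
        prev = None
        for t in [0.002, 0.005, 0.01, 0.02, 0.05]:
            out = simulate_identifications(default_dm, labels, "BCM", t)
            n_unid = (out["outcome"] == "no_identification").sum()
            if prev is not None:
                assert n_unid <= prev
            prev = n_unid

    def test_bic_correct_implies_bcm_correct(self, default_dm, default_sim):
        ds, _ = default_sim
        labels = ds.species_map()
        t = 0.015
        bic = simulate_identifications(default_dm, labels, "BIC", t).set_index("query_id")
        bcm = simulate_identifications(default_dm, labels, "BCM", t).set_index("query_id")
        for q in bic.index:
            if bic.loc[q, "outcome"] == "correct":
                assert bcm.loc[q, "outcome"] == "correct"

    def test_bm_perfect_when_conspecifics_mutually_nearest(self):
        dm, labels = three_seq_library(0.003, 0.05)
        out = simulate_identifications(dm, labels, "BM")
        assert (out["outcome"] == "correct").all()


class TestThresholdProcedures:
    def test_zero_error_band_inside_clean_gap(self):
        ids = ["a1", "a2", "b1", "b2", "c1", "c2"]
        d = np.full((6, 6), 0.07)
        np.fill_diagonal(d, 0)
        for i, j in [(0, 1), (2, 3), (4, 5)]:
            d[i, j] = d[j, i] = 0.002
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"}
        dm = _dm(ids, d)
        minimizers, curve = threshold_cumulative_error(dm, labels)
        assert curve.loc[curve["threshold"].isin(minimizers), "cumulative_error"].eq(0).all()
        assert np.all(minimizers > 0.002 - 1e-12)
        assert np.all(minimizers < 0.07)
        assert 0.002 < optimal_threshold(minimizers) < 0.07

    def test_threshold_below_all_distances_makes_all_queries_false_negative(self):
        dm, labels = three_seq_library(0.003, 0.05)
        _, curve = threshold_cumulative_error(dm, labels, grid=[1e-6])
        assert curve.iloc[0]["false_negative"] == 2  # both A members unidentifiable
        assert curve.iloc[0]["false_positive"] == 0

    def test_density_minimum_falls_between_modes(self):
        rng = np.random.default_rng(7)
        n = 40
        ids = [f"s{i}" for i in range(n)]
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals = np.where(rng.random(iu[0].size) < 0.5,
                        rng.normal(0.005, 0.001, iu[0].size),
                        rng.normal(0.07, 0.01, iu[0].size))
        d[iu] = np.abs(vals)
        d = d + d.T
        t = threshold_density_minimum(_dm(ids, d))
        assert 0.005 < t < 0.07

    def test_unimodal_pool_signals_no_minimum(self):
        rng = np.random.default_rng(7)
        n = 20
        ids = [f"s{i}" for i in range(n)]
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = np.abs(rng.normal(0.05, 0.005, iu[0].size))
        d = d + d.T
        with pytest.raises(NoDensityMinimumError):
            threshold_density_minimum(_dm(ids, d))


class TestPanel:
    def test_panel_columns_conserve_queries(self, toy_ds, toy_dm):
        labels = toy_ds.species_map()
        panel = run_identification_panel(toy_dm, labels, {"q95": 0.01, "bold_1pct": 0.01})
        assert (panel.counts.sum(axis=0) == panel.n_queries).all()
        assert np.allclose(panel.percents.sum(axis=0), 100.0)

    def test_clean_library_panel_all_correct_above_intra_max(self):
        ids = ["a1", "a2", "b1", "b2"]
        d = np.array(
            [[0, 0.002, 0.06, 0.06], [0.002, 0, 0.06, 0.06], [0.06, 0.06, 0, 0.002], [0.06, 0.06, 0.002, 0]]
        )
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        panel = run_identification_panel(_dm(ids, d), labels, {"t": 0.01})
        assert (panel.counts.loc["correct"] == panel.n_queries).all()
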