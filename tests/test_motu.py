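import numpy as np
import pytest

from barcodekit.distances import DistanceMatrix, distance_matrix
from barcodekit.motu import (
    ABGDClusterer,
    RESLClusterer,
    TCSClusterer,
    abgd_partition,
    abgd_recursive,
    abgd_scan,
    parsimony_connection_limit,
    parsimony_probability,
    resl_like_cluster,
    single_linkage_components,
    tcs_cluster,
)
from barcodekit.seqio import BarcodeDataset, SpecimenRecord
from barcodekit.synthetic import SimulationSpec, generate_dataset


def _dm(d, ids=None):
    d = np.asarray(d, float)
    ids = ids or [f"s{i}" for i in range(d.shape[0])]
    return DistanceMatrix(ids=ids, d=d, model="K2P", comparable_sites=np.full(d.shape, 658))


def brute_force_components(d, threshold):
    """Union-find over pairs with d <= threshold (independent oracle)."""
    n = d.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if not np.isnan(d[i, j]) and d[i, j] <= threshold:
                parent[find(i)] = find(j)
    roots = {}
    return [roots.setdefault(find(i), len(roots)) for i in range(n)]


def two_cluster_matrix(rng, n1=5, n2=5, intra=0.004, inter=0.09):
    n = n1 + n2
    d = rng.uniform(0, intra, (n, n))
    d = np.triu(d, 1)
    d[:n1, n1:] = rng.uniform(inter, inter * 1.2, (n1, n2))
    d = d + d.T
    np.fill_diagonal(d, 0)
    return d


class TestParsimonyLimit:
    def test_probability_decreases_with_steps(self):
        probs = [parsimony_probability(j, 658) for j in range(1, 30)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))
        assert probs[0] == 1.0

    def test_connection_limit_frozen_value_for_barcode_length(self):
        """Straight-line evaluation of the parsimony probability at m=658:
        prod(1 - i/658) for i<j stays >= 0.95 up to j=8 and drops below at 9
        (frozen oracle value computed by direct multiplication)."""
        p, j = 1.0, 1
        while True:
            nxt = p * (1 - j / 658)
            if nxt < 0.95:
                break
            p, j = nxt, j + 1
        assert j == 8  # frozen from the straight-line recursion
        assert parsimony_connection_limit(658, 0.95) == 8

    def test_limit_near_one_forces_minimum(self):
        assert parsimony_connection_limit(658, 0.999999) == 1

    @pytest.mark.parametrize("length", [200, 658, 1200])
    def test_j_non_increasing_in_limit(self, length):
        limits = np.arange(0.90, 1.00, 0.01)
        js = [parsimony_connection_limit(length, float(l)) for l in limits]
        assert all(a >= b for a, b in zip(js, js[1:]))


def _seq_ds(seqs, species=None):
    species = species or [f"sp{i}" for i in range(len(seqs))]
    recs = [
        SpecimenRecord(f"s{i}", species[i], "G", "F", s) for i, s in enumerate(seqs)
    ]
    return BarcodeDataset(records=recs)


class TestTCS:
    def test_boundary_at_connection_limit(self):
        J = parsimony_connection_limit(658, 0.95)
        base = "A" * 658
        at_limit = "G" * J + base[J:]
        over_limit = "G" * (J + 1) + base[J + 1 :]
        ds = _seq_ds([base, at_limit])
        assert tcs_cluster(ds, 0.95).n_motus == 1
        ds2 = _seq_ds([base, over_limit])
        assert tcs_cluster(ds2, 0.95).n_motus == 2

    def test_chain_links_through_intermediate_haplotype(self):
        J = parsimony_connection_limit(658, 0.95)
        base = "A" * 658
        b = "G" * J + base[J:]
        c = "G" * (2 * J) + base[2 * J :]
        ds = _seq_ds([base, b, c])
        # d(a,c) = 2J > J, but both link to b
        assert tcs_cluster(ds, 0.95).n_motus == 1

    def test_motu_count_monotone_in_limit(self, default_sim):
        ds, _ = default_sim
        n90 = tcs_cluster(ds, 0.90).n_motus
        n99 = tcs_cluster(ds, 0.99).n_motus
        assert n90 <= n99

    def test_requires_alignment_not_matrix(self, toy_dm):
        with pytest.raises(TypeError):
            TCSClusterer().fit(toy_dm)


class TestABGD:
    def test_two_clean_clusters_found(self):
        rng = np.random.default_rng(0)
        d = two_cluster_matrix(rng)
        part = abgd_partition(_dm(d), P=0.01, X=1.5)
        assert part.n_motus == 2
        assert not part.flags["no_gap"]
        labels = [part.assignment[f"s{i}"] for i in range(10)]
        assert len({labels[i] for i in range(5)}) == 1
        assert len({labels[i] for i in range(5, 10)}) == 1

    def test_all_identical_is_single_motu(self):
        d = np.zeros((4, 4))
        part = abgd_partition(_dm(d), P=0.01)
        assert part.n_motus == 1

    def test_prior_above_all_distances_flags_no_gap(self):
        rng = np.random.default_rng(0)
        d = two_cluster_matrix(rng)
        part = abgd_partition(_dm(d), P=0.5)
        assert part.n_motus == 1
        assert part.flags["no_gap"]

    def test_recursive_finds_secondary_gap(self):
        """Three-level structure: a global gap at ~8% plus a secondary gap at
        ~2% inside one group; the initial partition sees 2 MOTUs, the
        recursive one 3."""
        rng = np.random.default_rng(1)
        n = 12
        d = rng.uniform(0.0005, 0.003, (n, n))
        d = np.triu(d, 1)
        # sub-lineage: members 4..7 sit 2% from members 0..3
        d[0:4, 4:8] = rng.uniform(0.02, 0.022, (4, 4))
        # distinct cluster: members 8..11 at 8%
        d[0:8, 8:12] = rng.uniform(0.08, 0.085, (8, 4))
        d = d + d.T
        np.fill_diagonal(d, 0)
        initial = abgd_partition(_dm(d), P=0.03, X=1.5)
        recursive = abgd_recursive(_dm(d), P=0.005, X=1.5)
        assert initial.n_motus == 2
        assert recursive.n_motus >= 3
        assert recursive.n_motus >= initial.n_motus

    def test_groups_below_min_size_never_resplit(self):
        d = np.array([[0, 0.001, 0.05], [0.001, 0, 0.05], [0.05, 0.05, 0]])
        part = ABGDClusterer(prior=0.0001, recursive=True, min_group_size=3).fit(_dm(d)).partition_()
        # the 2-member group cannot split further regardless of its spread
        assert part.n_motus <= 2

    def test_scan_stability_window_on_clean_data(self):
        rng = np.random.default_rng(2)
        d = two_cluster_matrix(rng)
        grid = [0.005, 0.01, 0.02, 0.04]
        scan = abgd_scan(_dm(d), grid, X_values=(1.5,))
        initial = scan[scan["mode"] == "initial"]
        assert (initial["n_motus"] == 2).all()
        assert initial["stability_window"].nunique() == 1

    def test_motu_count_non_increasing_in_prior(self, default_dm):
        grid = [0.001, 0.003, 0.01, 0.03, 0.08]
        counts = [abgd_partition(default_dm, P=P).n_motus for P in grid]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_grid_is_error(self, default_dm):
        with pytest.raises(ValueError, match="empty"):
            abgd_scan(default_dm, [])

    def test_recovers_true_species_on_clean_gap_data(self):
        ds, truth = generate_dataset(
            SimulationSpec(seed=5, n_species=20, ambiguity_rate=0.0,
                           min_interspecific_divergence=0.03)
        )
        dm = distance_matrix(ds)
        part = abgd_partition(dm, P=0.02, X=1.5)
        by_motu = {}
        for sid, m in part.assignment.items():
            by_motu.setdefault(m, set()).add(truth.species_of[sid])
        # every MOTU is one species and species count equals MOTU count
        assert all(len(sps) == 1 for sps in by_motu.values())
        assert part.n_motus == len(set(truth.species_of.values()))


class TestRESL:
    def test_separate_clusters_stay_separate(self):
        rng = np.random.default_rng(3)
        d = two_cluster_matrix(rng, intra=0.003, inter=0.05)
        part = resl_like_cluster(_dm(d))
        assert part.n_motus == 2

    def test_refinement_splits_sub_lineages(self):
        rng = np.random.default_rng(4)
        n = 10
        d = rng.uniform(0.0005, 0.003, (n, n))
        d = np.triu(d, 1)
        d[0:5, 5:10] = rng.uniform(0.018, 0.0185, (5, 5))  # two lineages 1.8% apart
        d = d + d.T
        np.fill_diagonal(d, 0)
        est = RESLClusterer().fit(_dm(d).d)
        assert len(set(est.labels_)) == 2
        assert est.refinements_ and est.refinements_[0]["silhouette"] > 0.5

    def test_uniform_component_not_split(self):
        n = 8
        d = np.full((n, n), 0.01)
        np.fill_diagonal(d, 0)
        part = resl_like_cluster(_dm(d))
        assert part.n_motus == 1

    def test_seed_threshold_must_cover_refine_range(self):
        with pytest.raises(ValueError):
            RESLClusterer(seed_threshold=0.01, refine_low=0.007, refine_high=0.022).fit(
                np.zeros((3, 3))
            )


class TestPartitionInvariants:
    def test_every_partition_is_total_and_disjoint(self, default_sim, default_dm):
        ds, _ = default_sim
        for part in [
            abgd_partition(default_dm, P=0.01),
            tcs_cluster(ds, 0.95),
            resl_like_cluster(default_dm),
        ]:
            assert set(part.assignment) == set(ds.ids)
            assert part.n_motus == len(set(part.assignment.values()))

    def test_single_linkage_nesting(self, default_dm):
        l1 = single_linkage_components(default_dm.d, 0.005)
        l2 = single_linkage_components(default_dm.d, 0.02)
        # t1-partition refines t2-partition: equal l1-labels imply equal l2-labels
        for a in range(len(l1)):
            for b in range(a + 1, len(l1)):
                if l1[a] == l1[b]:
                    assert l2[a] == l2[b]

    def test_components_match_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 11))
            d = np.triu(rng.uniform(0, 0.05, (n, n)), 1)
            d = d + d.T
            t = float(rng.uniform(0.01, 0.04))
            got = single_linkage_components(d, t)
            expect = brute_force_components(d, t)
            # same partition up to relabeling (both canonicalized by first appearance)
            assert list(got) == expect

    def test_tcs_matches_brute_force_on_small_alignments(self):
        rng = np.random.default_rng(6)
        base = np.zeros(658, dtype=int)
        for _ in range(10):
            n = int(rng.integers(4, 10))
            seqs = []
            for _ in range(n):
                s = base.copy()
                k = int(rng.integers(0, 25))
                sites = rng.choice(658, size=k, replace=False)
                s[sites] = rng.integers(1, 4, size=k)
                seqs.append("".join("ACGT"[c] for c in s))
            ds = _seq_ds(seqs)
            part = tcs_cluster(ds, 0.95)
            J = parsimony_connection_limit(658, 0.95)
            diffs = np.array(
                [[sum(a != b for a, b in zip(x, y)) for y in seqs] for x in seqs], float
            )
            expect = brute_force_components(diffs, J)
            got = [part.assignment[f"s{i}"] for i in range(n)]
            assert got == expect
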