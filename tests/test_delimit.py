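"""Nearest-neighbour screening, discrimination verdicts, deep-divergence
flags, subcluster partitioning and per-genus calibration."""

import numpy as np
import pytest

import barcode_audit as ba
from conftest import toy_matrix, toy_taxonomy


@pytest.fixture()
def three_species():
    tax = toy_taxonomy({
        "a1": ("A", "G", "F", "O"), "a2": ("A", "G", "F", "O"),
        "b1": ("B", "G", "F", "O"),
        "c1": ("C", "G", "F", "O"),
    })
    dm = toy_matrix(
        ["a1", "a2", "b1", "c1"],
        {
            ("a1", "a2"): 0.002,
            ("a1", "b1"): 0.010, ("a2", "b1"): 0.015,
            ("a1", "c1"): 0.040, ("a2", "c1"): 0.045,
            ("b1", "c1"): 0.030,
        },
    )
    return dm, tax


class TestNearestNeighbor:
    def test_mutual_nearest_neighbours(self, three_species):
        dm, tax = three_species
        rows = {r.species: r for r in ba.nearest_neighbor_table(dm, tax)}
        assert rows["A"].nearest == "B" and rows["A"].nnd_pct == pytest.approx(1.0)
        assert rows["B"].nearest == "A" and rows["B"].nnd_pct == pytest.approx(1.0)
        assert rows["C"].nearest == "B" and rows["C"].nnd_pct == pytest.approx(3.0)

    def test_matches_exhaustive_oracle(self, sim_dm, sim_taxonomy):
        rows = {r.species: r for r in ba.nearest_neighbor_table(sim_dm, sim_taxonomy)}
        species_of = sim_taxonomy["species"]
        for sp, row in list(rows.items())[:10]:
            best = np.inf
            for i, a in enumerate(sim_dm.labels):
                if species_of[a] != sp:
                    continue
                for j, b in enumerate(sim_dm.labels):
                    if species_of[b] == sp:
                        continue
                    d = sim_dm.values[i, j]
                    if np.isfinite(d) and d < best:
                        best = d
            assert row.nnd_pct == pytest.approx(best * 100.0, abs=1e-9)


class TestLowDivergencePairs:
    def test_strict_cutoff(self, three_species):
        dm, tax = three_species
        pairs = ba.low_divergence_pairs(dm, tax, cutoff=0.02)
        assert [(p[0], p[1]) for p in pairs] == [("A", "B")]
        assert pairs[0][2] == pytest.approx(1.0)
        assert ba.low_divergence_pairs(dm, tax, cutoff=0.0) == []

    def test_monotone_in_cutoff(self, sim_dm, sim_taxonomy):
        prev = -1
        for cutoff in (0.0, 0.01, 0.02, 0.05, np.inf):
            n = len(ba.low_divergence_pairs(sim_dm, sim_taxonomy, cutoff=cutoff))
            assert n >= prev
            prev = n

    def test_infinite_cutoff_returns_all_pairs(self, three_species):
        dm, tax = three_species
        assert len(ba.low_divergence_pairs(dm, tax, cutoff=np.inf)) == 3

    def test_shared_haplotype_species_always_screened(self, sim_dm, sim_taxonomy, sim_dataset):
        shared = {s for p in sim_dataset.truth.shared_pairs for s in p[:2]}
        pairs = ba.low_divergence_pairs(sim_dm, sim_taxonomy, cutoff=1e-6)
        screened = {s for p in pairs for s in p[:2]}
        assert shared <= screened


class TestDiscrimination:
    def test_shared_haplotype_fails_both(self):
        tax = toy_taxonomy({
            "a1": ("A", "G", "F", "O"), "b1": ("B", "G", "F", "O"),
            "c1": ("C", "G", "F", "O"), "d1": ("D", "G", "F", "O"),
        })
        dm = toy_matrix(
            ["a1", "b1", "c1", "d1"],
            {("a1", "b1"): 0.0, ("a1", "c1"): 0.05, ("a1", "d1"): 0.06,
             ("b1", "c1"): 0.05, ("b1", "d1"): 0.06, ("c1", "d1"): 0.04},
        )
        tree = ba.nj(dm)
        verdicts, success = ba.discrimination_status(dm, tree, tax)
        by = {v.species: v for v in verdicts}
        assert by["A"].failure_mode == "shared_haplotype" and by["A"].offending == ["B"]
        assert by["B"].failure_mode == "shared_haplotype"
        assert by["C"].discriminated and by["D"].discriminated
        assert success == pytest.approx(0.5)

    def test_well_separated_species_all_discriminated(self, three_species):
        dm, tax = three_species
        tree = ba.nj(dm)
        verdicts, success = ba.discrimination_status(dm, tree, tax)
        assert success == 1.0
        assert all(v.failure_mode == "none" for v in verdicts)

    def test_injected_shared_pair_recovered(self, sim_dataset, sim_dm, sim_taxonomy, sim_tree):
        verdicts, success = ba.discrimination_status(sim_dm, sim_tree, sim_taxonomy)
        failed = {v.species for v in verdicts if not v.discriminated}
        truth = {s for p in sim_dataset.truth.shared_pairs for s in p[:2]}
        assert failed == truth
        n_species = sim_taxonomy["species"].nunique()
        assert success == pytest.approx((n_species - len(truth)) / n_species)


class TestDeepDivergence:
    def test_flagging_is_strict(self):
        tax = toy_taxonomy({
            "a1": ("A", "G", "F", "O"), "a2": ("A", "G", "F", "O"),
            "b1": ("B", "G", "F", "O"), "b2": ("B", "G", "F", "O"),
        })
        dm = toy_matrix(
            ["a1", "a2", "b1", "b2"],
            {("a1", "a2"): 0.005, ("b1", "b2"): 0.04,
             ("a1", "b1"): 0.08, ("a1", "b2"): 0.08,
             ("a2", "b1"): 0.08, ("a2", "b2"): 0.08},
        )
        flags = ba.deep_divergence_flags(dm, tax, cutoff=0.02)
        assert list(flags["species"]) == ["B"]
        assert flags["max_intraspecific_pct"].iloc[0] == pytest.approx(4.0)
        # a species exactly at the cutoff is not flagged (strict >)
        dm2 = toy_matrix(
            ["a1", "a2", "b1", "b2"],
            {("a1", "a2"): 0.02, ("b1", "b2"): 0.04,
             ("a1", "b1"): 0.08, ("a1", "b2"): 0.08,
             ("a2", "b1"): 0.08, ("a2", "b2"): 0.08},
        )
        assert list(ba.deep_divergence_flags(dm2, tax)["species"]) == ["B"]


class TestSubclusterPartition:
    def test_two_tight_groups(self):
        tax = toy_taxonomy({f"a{i}": ("A", "G", "F", "O") for i in range(1, 5)})
        dm = toy_matrix(
            ["a1", "a2", "a3", "a4"],
            {("a1", "a2"): 0.002, ("a3", "a4"): 0.002,
             ("a1", "a3"): 0.04, ("a1", "a4"): 0.041,
             ("a2", "a3"): 0.042, ("a2", "a4"): 0.04},
        )
        part = ba.subcluster_partition(dm, "A", tax, linkage_cutoff=0.02)
        assert part.n_subclusters == 2
        assert part.assignment["a1"] == part.assignment["a2"]
        assert part.assignment["a3"] == part.assignment["a4"]
        assert part.between_pct[(1, 2)][0] == pytest.approx(4.0)
        assert part.intra_means_pct[1] == pytest.approx(0.2)

    def test_all_below_cutoff_single_cluster(self):
        tax = toy_taxonomy({f"a{i}": ("A", "G", "F", "O") for i in range(1, 4)})
        dm = toy_matrix(
            ["a1", "a2", "a3"],
            {("a1", "a2"): 0.001, ("a1", "a3"): 0.002, ("a2", "a3"): 0.003},
        )
        assert ba.subcluster_partition(dm, "A", tax).n_subclusters == 1

    def test_singleton_species(self):
        tax = toy_taxonomy({"a1": ("A", "G", "F", "O"), "b1": ("B", "G", "F", "O")})
        dm = toy_matrix(["a1", "b1"], {("a1", "b1"): 0.05})
        part = ba.subcluster_partition(dm, "A", tax)
        assert part.n_subclusters == 1 and part.assignment == {"a1": 1}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_equals_connected_components_oracle(self, seed):
        from scipy.sparse.csgraph import connected_components

        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        vals = rng.uniform(0, 0.06, size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        labels = [f"x{i}" for i in range(n)]
        tax = toy_taxonomy({l: ("X", "G", "F", "O") for l in labels})
        dm = ba.DistanceMatrix(labels, vals)
        part = ba.subcluster_partition(dm, "X", tax, linkage_cutoff=0.02)
        _, comp = connected_components(vals < 0.02, directed=False)
        ours = [part.assignment[l] for l in labels]
        # same partition up to relabelling
        assert len(set(zip(ours, comp))) == len(set(ours)) == len(set(comp))

    def test_largest_gap_mode_recovers_shallow_split(self):
        tax = toy_taxonomy({f"a{i}": ("A", "G", "F", "O") for i in range(1, 5)})
        # split at 1.5%, below the 2% default cutoff
        dm = toy_matrix(
            ["a1", "a2", "a3", "a4"],
            {("a1", "a2"): 0.002, ("a3", "a4"): 0.002,
             ("a1", "a3"): 0.015, ("a1", "a4"): 0.016,
             ("a2", "a3"): 0.016, ("a2", "a4"): 0.015},
        )
        assert ba.subcluster_partition(dm, "A", tax, linkage_cutoff=0.02).n_subclusters == 1
        part = ba.subcluster_partition(dm, "A", tax, mode="largest-gap")
        assert part.n_subclusters == 2


class TestGenusCalibration:
    def test_overlap_flag(self):
        tax = toy_taxonomy({
            "a1": ("A", "G1", "F", "O"), "a2": ("A", "G1", "F", "O"),
            "b1": ("B", "G1", "F", "O"),
            "c1": ("C", "G1", "F", "O"),
        })
        # species A polymorphic beyond the genus' minimum interspecific gap
        dm = toy_matrix(
            ["a1", "a2", "b1", "c1"],
            {("a1", "a2"): 0.02,
             ("a1", "b1"): 0.01, ("a2", "b1"): 0.03,
             ("a1", "c1"): 0.05, ("a2", "c1"): 0.06,
             ("b1", "c1"): 0.04},
        )
        table = ba.genus_calibration_table(dm, tax, min_species=3)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["genus"] == "G1" and row["n_species"] == 3
        assert row["inter_min_pct"] == pytest.approx(1.0)
        assert row["inter_max_pct"] == pytest.approx(6.0)
        assert bool(row["overlap"])  # max intra 2.0 > min inter 1.0

    def test_genus_threshold(self, sim_dm, sim_taxonomy):
        table = ba.genus_calibration_table(sim_dm, sim_taxonomy, min_species=3)
        counts = sim_taxonomy.groupby("genus")["species"].nunique()
        assert set(table["genus"]) == set(counts[counts >= 3].index)
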