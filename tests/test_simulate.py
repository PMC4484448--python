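"""The ground-truthed synthetic secretome generator."""

import math

import numpy as np
import pytest

from spectracount import (
    SimulationConfig,
    generate_truth,
    simulate_interaction_network,
    simulate_psm_table,
    write_fixture_bundle,
)
from spectracount import io as sc_io


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(frac_differential=1.5),
        dict(decoy_fraction=-0.1),
        dict(module_size=50, n_proteins=40),
        dict(fold_range=(0.5, 3.0)),
        dict(leakage_fraction_per_sample=(0.1, 1.2)),
        dict(n_proteins=0),
    ])
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_zero_depth_rejected_at_simulation(self, small_truth, small_config):
        from dataclasses import replace
        bad = replace(small_config, total_spectra_per_sample=0)
        with pytest.raises(ValueError):
            simulate_psm_table(small_truth, bad)


class TestGenerateTruth:
    def test_seeded_determinism(self, small_config, small_truth):
        again = generate_truth(small_config)
        assert again.proteins == small_truth.proteins
        assert np.array_equal(again.baseline, small_truth.baseline)
        assert np.array_equal(again.fold, small_truth.fold)
        assert again.categories == small_truth.categories

    def test_null_planting(self):
        truth = generate_truth(SimulationConfig(n_proteins=200,
                                                frac_differential=0.0, seed=3))
        assert np.all(truth.fold == 1.0)

    @pytest.mark.parametrize("n,frac,expected", [
        (1000, 0.2, 200), (900, 0.3, 270), (150, 0.0, 0),
    ])
    def test_exact_differential_count(self, n, frac, expected):
        truth = generate_truth(SimulationConfig(n_proteins=n,
                                                frac_differential=frac, seed=9))
        assert truth.n_differential == expected

    def test_module_members_share_category_and_are_up_in_B(self, small_truth,
                                                           small_config):
        idx = np.flatnonzero(small_truth.module_member)
        assert len(idx) == small_config.module_size
        for i in idx:
            cats = small_truth.categories[small_truth.proteins[i]]
            assert small_config.module_category in cats
        assert np.all(small_truth.fold[idx] >= small_config.module_fold_range[0])

    def test_contaminants_are_null_and_annotated(self, small_truth):
        idx = np.flatnonzero(small_truth.contaminant)
        assert np.all(small_truth.fold[idx] == 1.0)
        for i in idx:
            cats = set(small_truth.categories[small_truth.proteins[i]])
            assert cats & {"DNA binding", "RNA binding"}


class TestSimulatePsmTable:
    def test_target_depth_and_no_decoys_when_disabled(self):
        config = SimulationConfig(n_proteins=100, total_spectra_per_sample=500,
                                  decoy_fraction=0.0, seed=5)
        psms = simulate_psm_table(generate_truth(config), config)
        for table in psms.values():
            assert not table["is_decoy"].any()
            assert len(table) == 500

    def test_target_psm_total_is_exactly_the_depth(self, small_psms, small_config):
        for table in small_psms.values():
            assert (~table["is_decoy"]).sum() == small_config.total_spectra_per_sample

    def test_decoy_scores_mostly_below_threshold(self, small_psms):
        decoys = [t[t["is_decoy"]] for t in small_psms.values()]
        frac_sig = np.mean(
            [np.mean(d["score"] > d["identity_threshold"]) for d in decoys]
        )
        assert frac_sig < 0.25

    def test_planted_high_fold_protein_up_in_B(self):
        """A protein planted at ~8-fold with median-range abundance receives
        more spectra in sample B than A in >= 95% of seeded replicates."""
        wins = tries = 0
        for seed in range(100):
            config = SimulationConfig(n_proteins=300,
                                      total_spectra_per_sample=2000, seed=seed)
            truth = generate_truth(config)
            median = np.median(truth.baseline)
            candidates = np.flatnonzero(
                (truth.fold >= 6) & (truth.fold <= 10)
                & (truth.baseline > 0.5 * median) & (truth.baseline < 2 * median)
            )
            if len(candidates) == 0:
                continue
            protein = truth.proteins[candidates[0]]
            psms = simulate_psm_table(truth, config)
            a, b = (
                (t["protein"] == protein).sum() for t in psms.values()
            )
            tries += 1
            wins += b > a
        assert tries >= 50
        assert wins / tries >= 0.95

    def test_leakage_shifts_contaminant_spectra(self):
        config = SimulationConfig(n_proteins=300, total_spectra_per_sample=5000,
                                  leakage_fraction_per_sample=(0.2, 0.0), seed=2)
        truth = generate_truth(config)
        contaminants = {
            truth.proteins[i] for i in np.flatnonzero(truth.contaminant)
        }
        psms = simulate_psm_table(truth, config)
        sample_a, sample_b = config.sample_names
        in_a = psms[sample_a]["protein"].isin(contaminants).sum()
        in_b = psms[sample_b]["protein"].isin(contaminants).sum()
        assert in_a == 1000  # 20% of 5000 diverted to leakage
        assert in_b == 0

    def test_some_proteins_have_single_peptide_inventory(self, small_psms):
        table = next(iter(small_psms.values()))
        targets = table[~table["is_decoy"]]
        n_peptides = targets.groupby("protein")["peptide"].nunique()
        assert (n_peptides == 1).any()


class TestInteractionNetwork:
    def test_module_internal_edge_count_is_planted(self, small_truth, small_config):
        edges = simulate_interaction_network(small_truth, small_config)
        members = {
            small_truth.proteins[i]
            for i in np.flatnonzero(small_truth.module_member)
        }
        internal = sum(1 for a, b in edges if a in members and b in members)
        m = small_config.module_size
        assert internal >= math.ceil(small_config.module_density * m * (m - 1) / 2)

    def test_no_self_loops_or_duplicates(self, small_truth, small_config):
        edges = simulate_interaction_network(small_truth, small_config)
        assert all(a != b for a, b in edges)
        canonical = {tuple(sorted(e)) for e in edges}
        assert len(canonical) == len(edges)


class TestFixtureBundle:
    def test_round_trip_and_byte_identity(self, small_truth, small_psms,
                                          small_config, tmp_path):
        first = write_fixture_bundle(small_truth, small_psms, tmp_path / "a",
                                     config=small_config)
        second = write_fixture_bundle(small_truth, small_psms, tmp_path / "b",
                                      config=small_config)
        for key in first:
            assert first[key].read_bytes() == second[key].read_bytes()

        sample = small_config.sample_names[0]
        loaded = sc_io.read_psm_table(first[f"psms:{sample}"])
        original = small_psms[sample]
        assert len(loaded) == len(original)
        assert list(loaded["peptide"]) == list(original["peptide"])
        assert list(loaded["is_decoy"]) == list(original["is_decoy"])
        assert np.allclose(loaded["score"], original["score"])

    def test_gmt_line_count_matches_distinct_categories(self, small_truth,
                                                        small_psms, small_config,
                                                        tmp_path):
        written = write_fixture_bundle(small_truth, small_psms, tmp_path,
                                      config=small_config)
        distinct = {c for cats in small_truth.categories.values() for c in cats}
        lines = [
            line for line in written["gmt"].read_text().splitlines() if line.strip()
        ]
        assert len(lines) == len(distinct)

    def test_truth_table_round_trip(self, small_truth, small_psms, small_config,
                                    tmp_path):
        written = write_fixture_bundle(small_truth, small_psms, tmp_path,
                                      config=small_config)
        frame = sc_io.read_truth_table(written["truth"])
        assert list(frame["protein"]) == list(small_truth.proteins)
        assert np.array_equal(
            frame["module"].astype(bool), small_truth.module_member
        )
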