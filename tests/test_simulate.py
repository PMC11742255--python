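"""Generator contracts: round trips, determinism, noise propagation, closure."""

import numpy as np
import pandas as pd
import pytest

from soilcue.chemistry import process_chemistry_table
from soilcue.isotope import process_incubation_table
from soilcue.simulate import (
    BasisCorrelationSpec,
    GroupEffects,
    StudyDesign,
    default_basis_spec,
    default_design,
    planted_pairs_correlation,
    simulate_fumigation,
    simulate_incubation,
    simulate_otu_table,
    simulate_study,
)


def truth_frame(n, growth=100.0, respiration=300.0, mbc=300.0):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "growth": growth,
            "respiration": respiration,
            "MBC": mbc,
        }
    )


class TestSimulateIncubation:
    def test_noise_free_round_trip_identity(self):
        records = simulate_incubation(truth_frame(5), noise_cv=0.0, seed=0)
        rates = process_incubation_table(records)
        assert np.allclose(rates["growth"], 100.0, rtol=1e-12)
        assert np.allclose(rates["respiration"], 300.0, rtol=1e-12)
        assert np.allclose(rates["cue"], 0.25, rtol=1e-12)

    def test_blank_corrected_co2_matches_dimensional_inverse(self):
        # respiration 380.97 ng C g-1 h-1 under default config <-> ~1000 ppm
        records = simulate_incubation(
            truth_frame(1, respiration=380.9682), noise_cv=0.0, seed=0
        )
        rs = records.loc[0, "co2_ppm"] - records.loc[0, "blank_ppm_mean"]
        assert rs == pytest.approx(1000.0, abs=0.1)

    def test_noise_propagates_into_growth_cv(self):
        # growth is a product of two noisy readings (O content, at% excess):
        # at cv = 0.1 the recomputed growth CV lands in the 0.10-0.15 band
        records = simulate_incubation(truth_frame(1000), noise_cv=0.1, seed=5)
        rates = process_incubation_table(records)
        cv = rates["growth"].std() / rates["growth"].mean()
        assert 0.08 < cv < 0.18

    def test_rejects_nonpositive_truth(self):
        bad = truth_frame(3).assign(growth=[-1.0, 10.0, 10.0])
        with pytest.raises(ValueError):
            simulate_incubation(bad)

    def test_rejects_impossible_labelling(self):
        # absurd growth would push the labelled at% beyond the soil water level
        with pytest.raises(ValueError):
            simulate_incubation(truth_frame(1, growth=1e9), noise_cv=0.0, seed=0)


class TestSimulateFumigation:
    def test_conversion_identities(self):
        truth = pd.DataFrame(
            {"sample_id": ["a"], "MBC": [200.0], "MBN": [50.0], "DOC": [60.0], "TDN": [10.0]}
        )
        pairs = simulate_fumigation(truth, noise_cv=0.0, seed=0)
        assert pairs.loc[0, "doc_fumigated"] == pytest.approx(150.0)  # 60 + 0.45*200
        assert pairs.loc[0, "tdn_fumigated"] == pytest.approx(37.0)   # 10 + 0.54*50
        chem = process_chemistry_table(pairs)
        assert chem.loc[0, "MBC"] == pytest.approx(200.0)
        assert chem.loc[0, "MBN"] == pytest.approx(50.0)

    def test_mean_recovery_under_noise(self):
        # multiplicative mean-one noise: recovered MBC is unbiased
        truth = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(1000)],
                "MBC": 200.0,
                "MBN": 50.0,
                "DOC": 60.0,
                "TDN": 10.0,
            }
        )
        chem = process_chemistry_table(simulate_fumigation(truth, noise_cv=0.05, seed=3))
        assert chem["MBC"].mean() == pytest.approx(200.0, rel=0.02)

    def test_rejects_negative_truth(self):
        truth = pd.DataFrame(
            {"sample_id": ["a"], "MBC": [-1.0], "MBN": [1.0], "DOC": [1.0], "TDN": [1.0]}
        )
        with pytest.raises(ValueError):
            simulate_fumigation(truth)


class TestSimulateOtuTable:
    def spec(self, n_taxa=10, depth=5000, pairs=()):
        rng = np.random.default_rng(0)
        return BasisCorrelationSpec(
            n_taxa=n_taxa,
            correlation_matrix=planted_pairs_correlation(n_taxa, list(pairs)),
            log_mean_abundances=rng.normal(0, 1, n_taxa),
            log_sd=np.ones(n_taxa),
            sequencing_depth=depth,
        )

    def test_compositional_closure(self):
        table = simulate_otu_table(self.spec(), n_samples=20, seed=1)
        assert (table.counts.sum(axis=0) == 5000).all()

    def test_planted_pair_dominates_pearson_log_counts(self):
        table = simulate_otu_table(
            self.spec(n_taxa=8, depth=30000, pairs=[(0, 1, 0.9)]), n_samples=150, seed=2
        )
        logs = np.log(table.counts.values + 1.0)
        c = np.corrcoef(logs)
        np.fill_diagonal(c, 0.0)
        assert np.unravel_index(np.argmax(np.abs(c)), c.shape) in {(0, 1), (1, 0)}

    def test_zero_depth_errors(self):
        with pytest.raises(ValueError):
            simulate_otu_table(self.spec(depth=0), n_samples=10, seed=0)

    def test_non_psd_correlation_errors(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError):
            BasisCorrelationSpec(3, bad, np.zeros(3), np.ones(3), 100)


class TestSimulateStudy:
    def test_design_arithmetic(self, noise_free_study):
        # 15 species x 2 positions x 5 replicates
        assert len(noise_free_study.metadata) == 150
        assert len(noise_free_study.incubation) == 150
        assert len(noise_free_study.fumigation) == 150
        assert noise_free_study.bacteria.n_samples == 150
        assert noise_free_study.fungi.n_samples == 150

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        design = default_design(noise_cv=0.15)
        a = simulate_study(design, seed=9)
        b = simulate_study(design, seed=9)
        pa = a.write(tmp_path / "a")
        pb = b.write(tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes()

    def test_planted_cue_contrast_present(self, noise_free_study):
        truth = noise_free_study.truth
        grouped = truth.groupby(["mycorrhizal_type", "position"])["cue"].mean()
        diff = grouped[("ECM", "non_rhizosphere")] - grouped[("AM", "non_rhizosphere")]
        assert diff == pytest.approx(0.2, abs=1e-6)

    def test_design_validation(self):
        with pytest.raises(ValueError):
            StudyDesign([("x", "AM")], 0, {})
        with pytest.raises(ValueError):
            GroupEffects(1.0, 1.0, -5.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            default_design(noise_cv=-0.1)

    def test_default_basis_specs_valid(self):
        b = default_basis_spec("bacteria")
        f = default_basis_spec("fungi")
        assert b.n_taxa == 60 and f.n_taxa == 30
        assert np.linalg.eigvalsh(b.correlation_matrix).min() > -1e-8
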