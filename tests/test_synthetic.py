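import warnings

import numpy as np
import pandas as pd
import pytest

import inktqsar as iq
from inktqsar.synthetic import ConfigurationError, REFERENCE_BASELINE

REF = "CPD-001"


class TestChemicalSpace:
    def test_exact_constant_column_count(self):
        config = iq.GeneratorConfig(n_compounds=40, n_descriptors=20, n_constant=5,
                                    seed=3)
        matrix, _ = iq.generate_chemical_space(config)
        n_const = int((matrix.var(axis=0, ddof=1) <= 1e-12).sum())
        assert n_const == 5

    def test_same_seed_gives_identical_output(self):
        config = iq.GeneratorConfig(seed=7)
        m1, t1 = iq.generate_chemical_space(config)
        m2, t2 = iq.generate_chemical_space(config)
        pd.testing.assert_frame_equal(m1, m2)
        assert t1.informative_indices == t2.informative_indices

    def test_informative_block_is_correlated(self):
        config = iq.GeneratorConfig(n_compounds=200, n_descriptors=30,
                                    n_informative=6, block_correlation=0.8, seed=1)
        matrix, truth = iq.generate_chemical_space(config)
        block = matrix.iloc[:, truth.informative_indices]
        corr = block.corr().abs().to_numpy()
        off_diag = corr[np.triu_indices_from(corr, k=1)]
        assert off_diag.mean() > 0.5

    def test_reference_has_zero_informative_descriptors(self):
        matrix, truth = iq.generate_chemical_space(iq.GeneratorConfig(seed=2))
        ref_row = matrix.loc[truth.reference_compound_id]
        assert (ref_row.iloc[truth.informative_indices] == 0).all()

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            iq.generate_chemical_space(
                iq.GeneratorConfig(n_descriptors=5, n_informative=4, n_constant=3))


class TestResponseStudies:
    def test_noiseless_null_model_equals_baseline(self):
        config = iq.GeneratorConfig(n_compounds=10, n_descriptors=6,
                                    n_informative=0, n_constant=0,
                                    study_noise_cv=0.0, measure_prob=1.0, seed=4)
        descriptors, truth = iq.generate_chemical_space(config)
        records = iq.generate_response_studies(descriptors, truth, config)
        # zero coefficients + no noise: every analogue matches the reference
        # baseline profile at every dose
        ref_at = records[records.compound_id == REF].set_index(
            ["study_id", "marker", "dose"])["value"]
        others = records[records.compound_id != REF]
        ratios = others["value"].to_numpy() / ref_at.loc[
            list(zip(others["study_id"], others["marker"], others["dose"]))
        ].to_numpy()
        assert np.allclose(ratios, 1.0)
        middle = records[(records.compound_id != REF) & (records.dose == 1.0)]
        assert np.allclose(middle["value"], REFERENCE_BASELINE)

    def test_noiseless_normalized_response_is_exp_x_beta(self):
        config = iq.GeneratorConfig(n_compounds=15, n_descriptors=8,
                                    study_noise_cv=0.0, measure_prob=1.0,
                                    n_studies_min=2, n_studies_max=2, seed=5)
        descriptors, records, truth = iq.generate_dataset(config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normalized = iq.normalize_to_reference(
                iq.read_response_table(records), REF)
            matrix = iq.aggregate_replicates(normalized, REF)
        for system, marker in [("mice/in-vivo", "IFN-γ"),
                               ("human/in-vitro/cell-cell", "IL-4")]:
            expected = np.exp(descriptors.to_numpy()
                              @ truth.coefficients[(system, marker)])
            got = matrix.cell(system, marker)
            mask = got.notna()
            assert np.allclose(got[mask],
                               expected[[descriptors.index.get_loc(c)
                                         for c in got.index[mask]]])

    def test_replicate_rsd_matches_noise_cv(self):
        # lognormal ratio noise at cv=0.5 should reproduce ~50% per-compound RSD
        config = iq.GeneratorConfig(n_compounds=1001, n_descriptors=4,
                                    n_informative=0, n_constant=0,
                                    study_noise_cv=0.5, measure_prob=1.0,
                                    n_studies_min=4, n_studies_max=4, seed=6,
                                    systems=("mice/in-vivo",), markers=("IFN-γ",))
        descriptors, records, _ = iq.generate_dataset(config)
        normalized = iq.normalize_to_reference(iq.read_response_table(records), REF)
        reps = {cid: grp["normalized"].to_numpy() for cid, grp in
                normalized[normalized.compound_id != REF].groupby("compound_id")}
        rsd = iq.intra_rsd(reps)
        assert abs(rsd.mean() - 50.0) < 15.0

    def test_measurement_frequency_matches_missingness(self):
        config = iq.GeneratorConfig(n_compounds=501, n_descriptors=4,
                                    n_informative=0, n_constant=0,
                                    study_noise_cv=0.0, measure_prob=0.6,
                                    n_studies_min=1, n_studies_max=1, seed=8)
        descriptors, records, _ = iq.generate_dataset(config)
        cells = records[records.compound_id != REF].drop_duplicates(
            ["compound_id", "species", "setting", "presentation", "marker"])
        n_possible = 500 * 20
        assert abs(len(cells) / n_possible - 0.6) < 0.03

    def test_reference_missing_from_descriptors_is_an_error(self):
        config = iq.GeneratorConfig(n_compounds=10, n_descriptors=4,
                                    n_informative=2, n_constant=0, seed=1)
        descriptors, truth = iq.generate_chemical_space(config)
        with pytest.raises(ValueError, match="reference"):
            iq.generate_response_studies(descriptors.drop(index=REF), truth, config)


class TestFixtureSuite:
    def test_fixture_suite_deterministic_and_complete(self, tmp_path):
        m1 = iq.generate_fixture_suite(tmp_path / "a", seed=1)
        m2 = iq.generate_fixture_suite(tmp_path / "b", seed=1)
        assert m1["files"] == m2["files"]
        for name in m1["files"]:
            assert (tmp_path / "a" / name).exists()

    def test_assay_count_fixture_totals(self, tmp_path):
        iq.generate_fixture_suite(tmp_path, seed=2)
        counts = pd.read_csv(tmp_path / "assay_counts.csv")
        assert counts["count"].sum() == 851

    def test_ground_truth_roundtrip(self, tmp_path):
        iq.generate_fixture_suite(tmp_path, seed=3)
        truth = iq.GroundTruth.from_json(
            (tmp_path / "ground_truth.json").read_text(encoding="utf-8"))
        assert truth.reference_compound_id == REF
        beta = truth.coefficients[("mice/in-vivo", "IFN-γ")]
        assert (beta[truth.informative_indices] != 0).all()
        # Th1/Th2 polarity: IL-4 coefficients oppose IFN-γ
        beta_il4 = truth.coefficients[("mice/in-vivo", "IL-4")]
        assert np.all(beta_il4[truth.informative_indices]
                      * beta[truth.informative_indices] < 0)
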