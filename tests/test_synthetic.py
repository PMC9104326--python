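import numpy as np
import pytest

from conftest import brute_force_auc
from disbench.evaluation import roc_auc
from disbench.predictors import dsspp_predict
from disbench.synthetic import (GeneratorConfig, binormal_auc,
                                generate_backbone, generate_cohort,
                                generate_coverage, generate_labels,
                                generate_plddt, generate_predictor_files,
                                generate_ss)


def flat(arrays):
    return np.concatenate(list(arrays))


class TestLabels:
    def test_boundary_fractions(self):
        rng = np.random.default_rng(0)
        cfg = GeneratorConfig(n_proteins=5, disorder_fraction=0.0)
        assert flat(generate_labels(cfg, rng)).sum() == 0
        cfg = GeneratorConfig(n_proteins=5, disorder_fraction=1.0)
        labs = flat(generate_labels(GeneratorConfig(
            n_proteins=5, disorder_fraction=1.0), rng))
        assert labs.min() == 1

    def test_cohort_fraction_near_target(self):
        cfg = GeneratorConfig(n_proteins=200, length_range=(100, 300),
                              disorder_fraction=0.3, seed=5)
        labs = flat(generate_labels(cfg, np.random.default_rng(cfg.seed)))
        # segments of mean length L give ~n/L independent clusters
        n_segments = len(labs) / cfg.mean_segment_length
        se = np.sqrt(0.3 * 0.7 / n_segments)
        assert labs.mean() == pytest.approx(0.3, abs=3 * se)

    def test_labels_come_in_segments(self):
        cfg = GeneratorConfig(n_proteins=20, length_range=(200, 300),
                              mean_segment_length=30, seed=2)
        labs = generate_labels(cfg, np.random.default_rng(2))
        switches = sum(int(np.abs(np.diff(l)).sum()) for l in labs)
        total = sum(len(l) for l in labs)
        # switch rate far below i.i.d. labelling (~0.42 at d=0.3)
        assert switches / total < 0.15

    def test_tiny_segment_length_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(mean_segment_length=1)


class TestPlddt:
    def test_degenerate_noise_gives_step_profiles(self):
        cfg = GeneratorConfig(n_proteins=3, plddt_ordered=(90, 1e-9),
                              plddt_disordered=(40, 1e-9),
                              smoothing_window=1, seed=1)
        rng = np.random.default_rng(1)
        labels = generate_labels(cfg, rng)
        plddt = generate_plddt(labels, cfg, rng)
        for lab, p in zip(labels, plddt):
            np.testing.assert_allclose(p, np.where(lab == 1, 40.0, 90.0),
                                       atol=1e-6)

    def test_smoothing_window_one_is_identity(self):
        cfg1 = GeneratorConfig(n_proteins=2, smoothing_window=1, seed=3)
        cfg5 = GeneratorConfig(n_proteins=2, smoothing_window=5, seed=3)
        rng = np.random.default_rng(9)
        labels = generate_labels(cfg1, rng)
        raw = generate_plddt(labels, cfg1, np.random.default_rng(4))
        smooth = generate_plddt(labels, cfg5, np.random.default_rng(4))
        assert any((a != b).any() for a, b in zip(raw, smooth))
        again = generate_plddt(labels, cfg1, np.random.default_rng(4))
        for a, b in zip(raw, again):
            np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("d_prime", [0.5, 1.0, 2.0, 4.0])
    def test_binormal_auc_calibration(self, d_prime):
        """Unsmoothed tpLD AUC matches Phi(d'/sqrt 2) within 0.02."""
        sigma = 8.0
        mu = 55.0
        cfg = GeneratorConfig(
            n_proteins=60, length_range=(150, 250), disorder_fraction=0.5,
            plddt_ordered=(mu + d_prime * sigma / 2, sigma),
            plddt_disordered=(mu - d_prime * sigma / 2, sigma),
            smoothing_window=1, seed=17)
        rng = np.random.default_rng(cfg.seed)
        labels = generate_labels(cfg, rng)
        plddt = generate_plddt(labels, cfg, rng)
        auc = roc_auc(flat(labels), 1 - flat(plddt) / 100).summary
        assert auc == pytest.approx(binormal_auc(d_prime), abs=0.02)


class TestSecondaryStructure:
    def test_zero_rates_make_dsspp_exact(self):
        cfg = GeneratorConfig(n_proteins=10, transient_helix_rate=0.0,
                              confident_coil_rate=0.0, seed=6)
        rng = np.random.default_rng(6)
        labels = generate_labels(cfg, rng)
        ss = generate_ss(labels, cfg, rng)
        for lab, (ss8, _red) in zip(labels, ss):
            np.testing.assert_array_equal(dsspp_predict(ss8).calls, lab)

    def test_transient_helices_make_dsspp_miss_disorder(self):
        cfg = GeneratorConfig(n_proteins=40, transient_helix_rate=0.3,
                              confident_coil_rate=0.0, seed=8)
        rng = np.random.default_rng(8)
        labels = generate_labels(cfg, rng)
        ss = generate_ss(labels, cfg, rng)
        calls = flat(dsspp_predict(s8).calls for s8, _ in ss)
        labs = flat(labels)
        missed = ((calls == 0) & (labs == 1)).sum() / (labs == 1).sum()
        assert missed == pytest.approx(0.3, abs=0.1)

    def test_all_ordered_protein_is_structured_string(self):
        cfg = GeneratorConfig(n_proteins=3, disorder_fraction=0.0,
                              confident_coil_rate=0.0, seed=4)
        rng = np.random.default_rng(4)
        labels = generate_labels(cfg, rng)
        for ss8, red in generate_ss(labels, cfg, rng):
            assert set(ss8) <= set("HET")
            assert set(red) <= set("HET")


class TestCoverage:
    def test_full_and_zero_coverage(self):
        cfg = GeneratorConfig(n_proteins=5, coverage_fraction_ordered=1.0,
                              coverage_fraction_disordered=1.0, seed=2)
        rng = np.random.default_rng(2)
        labels = generate_labels(cfg, rng)
        cov = generate_coverage(labels, cfg, rng)
        for lab, iv in zip(labels, cov):
            assert iv == [(1, len(lab))]
        cfg0 = GeneratorConfig(n_proteins=5, coverage_fraction_ordered=0.0,
                               coverage_fraction_disordered=0.0, seed=2)
        cov0 = generate_coverage(labels, cfg0, rng)
        assert all(iv == [] for iv in cov0)


class TestEmulatedPredictors:
    @pytest.mark.parametrize("target_auc", [0.5, 0.9])
    def test_measured_auc_matches_configured(self, target_auc, rng):
        labels = [rng.integers(0, 2, 2000) for _ in range(5)]
        files = generate_predictor_files(labels, target_auc, rng)
        labs = flat(labels)
        scores = flat(f.scores for f in files)
        assert roc_auc(labs, scores).summary == pytest.approx(target_auc,
                                                              abs=0.02)
        # trapezoidal AUC agrees with pairwise concordance on a subset
        assert roc_auc(labs[:1000], scores[:1000]).summary == \
            pytest.approx(brute_force_auc(labs[:1000], scores[:1000]),
                          abs=1e-12)

    def test_perfect_predictor_degenerates_to_labels(self, rng):
        labels = [rng.integers(0, 2, 100)]
        files = generate_predictor_files(labels, 1.0, rng)
        np.testing.assert_array_equal(files[0].scores, labels[0])


class TestBackbone:
    def test_ideal_bond_lengths(self):
        model = generate_backbone("HHHHHHHH", seed=0)
        res = model.residues
        for r in res:
            assert np.linalg.norm(r.coord("CA") - r.coord("N")) == \
                pytest.approx(1.458, abs=1e-6)
            assert np.linalg.norm(r.coord("C") - r.coord("CA")) == \
                pytest.approx(1.525, abs=1e-6)
        for a, b in zip(res, res[1:]):
            assert np.linalg.norm(b.coord("N") - a.coord("C")) == \
                pytest.approx(1.329, abs=1e-6)

    def test_coil_deterministic_given_seed(self):
        a = generate_backbone("C" * 20, seed=12)
        b = generate_backbone("C" * 20, seed=12)
        for ra, rb in zip(a.residues, b.residues):
            np.testing.assert_array_equal(ra.coord("CA"), rb.coord("CA"))

    def test_no_steric_collapse_in_coils(self):
        for seed in range(5):
            model = generate_backbone("C" * 40, seed=seed)
            ca = np.array([r.coord("CA") for r in model.residues])
            d = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
            iu = np.triu_indices(len(ca), k=2)
            assert d[iu].min() >= 2.0


class TestDeterminism:
    def test_identical_config_identical_cohort(self):
        cfg = GeneratorConfig(n_proteins=10, seed=21)
        a = generate_cohort(cfg, predictor_aucs={"p": 0.8})
        b = generate_cohort(cfg, predictor_aucs={"p": 0.8})
        assert a.ss8 == b.ss8
        for x, y in zip(a.plddt, b.plddt):
            np.testing.assert_array_equal(x, y)
        for x, y in zip(a.predictor_files["p"], b.predictor_files["p"]):
            np.testing.assert_array_equal(x.scores, y.scores)
        assert a.disorder_intervals == b.disorder_intervals

    def test_written_cohort_byte_identical(self, tmp_path):
        from disbench.synthetic import write_cohort
        cfg = GeneratorConfig(n_proteins=6, length_range=(60, 100), seed=33)
        for sub in ("a", "b"):
            write_cohort(generate_cohort(cfg, predictor_aucs={"p": 0.8}),
                         tmp_path / sub)
        for name in ("disorder.tsv", "coverage.tsv", "tpld.caid",
                     "pred_p.caid", "ss.tsv", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()
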