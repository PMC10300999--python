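import json

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

from readiff.difficulty import summarize_errors
from readiff.errors import ConfigurationError, InputError
from readiff.synthetic import (SyntheticConfig, generate_case, generate_cohort,
                               responses_frame, simulate_reader_panel,
                               truth_frame, write_cohort)


class TestConfig:
    def test_image_too_small_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(image_size=32)

    @pytest.mark.parametrize("kw", [{"n_normal": 0}, {"n_cancer": 0}, {"n_readers": 0}])
    def test_counts_must_be_positive(self, kw):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(**kw)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(blob_sigma_range=(8.0, 2.0))


class TestGenerateCase:
    def test_same_seed_same_index_bit_identical(self):
        cfg = SyntheticConfig(n_normal=2, n_cancer=1, image_size=96, seed=3)
        a = generate_case(cfg, 1)
        b = generate_case(cfg, 1)
        for view in a.views:
            assert np.array_equal(a.views[view], b.views[view])

    def test_different_seed_differs(self):
        cfg1 = SyntheticConfig(n_normal=2, n_cancer=1, image_size=96, seed=3)
        cfg2 = SyntheticConfig(n_normal=2, n_cancer=1, image_size=96, seed=4)
        assert not np.array_equal(generate_case(cfg1, 0).views["LCC"],
                                  generate_case(cfg2, 0).views["LCC"])

    def test_lesion_inside_silhouette_of_both_views(self, small_cohort):
        _, cases, _ = small_cohort
        cancer = [c for c in cases if c.cancer]
        assert cancer
        for case in cancer:
            assert len(case.lesion_coords) == 2
            assert set(case.lesion_coords) == {f"{case.lesion_side}CC", f"{case.lesion_side}MLO"}
            for view, (r, c) in case.lesion_coords.items():
                assert case.silhouettes[view][r, c]

    def test_collapsed_sigma_range_zero_variance(self):
        cfg = SyntheticConfig(n_normal=50, n_cancer=1, image_size=96,
                              blob_sigma_range=(4.0, 4.0), seed=5)
        sigmas = [generate_case(cfg, i).mean_blob_sigma for i in range(50)]
        assert np.var(sigmas) == 0.0

    def test_mlo_views_carry_wedge(self, small_cohort):
        _, cases, _ = small_cohort
        for case in cases:
            assert case.wedges["LMLO"].any() and case.wedges["RMLO"].any()
            assert not case.wedges["LCC"].any()

    def test_index_out_of_range(self):
        cfg = SyntheticConfig(n_normal=1, n_cancer=1, image_size=96)
        with pytest.raises(InputError):
            generate_case(cfg, 2)


class TestGroundTruth:
    def test_probabilities_monotone_in_difficulty(self, small_cohort):
        _, _, truths = small_cohort
        by_d = sorted(truths, key=lambda t: t.latent_difficulty)
        probs = [list(t.expected_error_prob.values())[0] for t in by_d]
        assert all(a <= b + 1e-12 for a, b in zip(probs, probs[1:]))
        assert all(0 <= p <= 1 for p in probs)

    def test_beta_zero_flat_probabilities(self):
        cfg = SyntheticConfig(n_normal=5, n_cancer=2, image_size=96,
                              error_link_slope=0.0, seed=2)
        _, truths = generate_cohort(cfg)
        probs = {p for t in truths for p in t.expected_error_prob.values()}
        assert len(probs) == 1


class TestReaderPanel:
    def test_beta_zero_error_rate_matches_intercept(self):
        """With beta=0 and no reader bias, errors are Bernoulli(0.3)."""
        cfg = SyntheticConfig(n_normal=50, n_cancer=1, image_size=96,
                              n_readers=100, error_link_slope=0.0,
                              error_link_intercept=float(logit(0.3)),
                              reader_bias_sd=0.0, seed=9)
        cases, truths = generate_cohort(cfg)
        resp = responses_frame(simulate_reader_panel(cases, truths, cfg))
        summ = summarize_errors(resp, truth_frame(cases), "FP", radius=cfg.loc_radius)
        mean_prop = np.mean([s.proportion for s in summ])
        se = np.sqrt(0.3 * 0.7 / (100 * 50))
        assert abs(mean_prop - 0.3) < 3 * se

    def test_beta_large_errors_track_difficulty(self):
        """Spearman(d_c, FP proportion) > 0.8 at beta=5 with 30 readers."""
        cfg = SyntheticConfig(n_normal=50, n_cancer=1, image_size=96,
                              n_readers=30, error_link_slope=5.0, seed=10)
        cases, truths = generate_cohort(cfg)
        resp = responses_frame(simulate_reader_panel(cases, truths, cfg))
        summ = {s.case_id: s.proportion
                for s in summarize_errors(resp, truth_frame(cases), "FP", radius=cfg.loc_radius)}
        d = [t.latent_difficulty for t in truths if t.case_id in summ]
        p = [summ[t.case_id] for t in truths if t.case_id in summ]
        rho = stats.spearmanr(d, p).statistic
        assert rho > 0.8

    def test_panel_is_deterministic(self):
        cfg = SyntheticConfig(n_normal=3, n_cancer=2, image_size=96, n_readers=4, seed=6)
        cases, truths = generate_cohort(cfg)
        a = simulate_reader_panel(cases, truths, cfg)
        b = simulate_reader_panel(cases, truths, cfg)
        assert a == b

    def test_rating_conventions(self, small_cohort):
        cfg, cases, truths = small_cohort
        resp = responses_frame(simulate_reader_panel(cases, truths, cfg))
        truth = truth_frame(cases)
        normal_ids = set(truth.loc[~truth["cancer"], "case_id"])
        normals = resp[resp["case_id"].isin(normal_ids)]
        # negative calls on normals carry no annotation
        negs = normals[normals["rating"] <= 2]
        assert negs["view"].isna().all()
        # positive calls always carry an annotation
        pos = resp[resp["rating"] >= 3]
        assert pos["view"].notna().all() and pos["x"].notna().all()

    def test_localization_errors_beyond_radius(self):
        """Mislocalized annotations land outside the correct radius, on-breast."""
        cfg = SyntheticConfig(n_normal=1, n_cancer=10, image_size=128, n_readers=20,
                              error_link_intercept=20.0, error_link_slope=0.0,
                              localization_error_fraction=1.0, reader_bias_sd=0.0, seed=11)
        cases, truths = generate_cohort(cfg)
        resp = responses_frame(simulate_reader_panel(cases, truths, cfg))
        by_case = {c.case_id: c for c in cases}
        checked = 0
        for row in resp.itertuples():
            case = by_case[row.case_id]
            if not case.cancer or row.rating <= 2:
                continue
            lr, lc = case.lesion_coords[row.view]
            dist = np.hypot(row.y - lr, row.x - lc)
            assert dist > cfg.loc_radius
            assert case.silhouettes[row.view][int(row.y), int(row.x)]
            checked += 1
        assert checked > 50

    def test_mismatched_truth_rejected(self, small_cohort):
        cfg, cases, truths = small_cohort
        with pytest.raises(InputError):
            simulate_reader_panel(cases, truths[:-1], cfg)


class TestIo:
    def test_write_cohort_artifacts(self, tmp_path, small_cohort):
        cfg, cases, truths = small_cohort
        responses = simulate_reader_panel(cases, truths, cfg)
        manifest = write_cohort(tmp_path, cases, truths, responses, cfg)
        assert (tmp_path / "truth.csv").exists()
        assert (tmp_path / "responses.csv").exists()
        pngs = list((tmp_path / "images").glob("*.png"))
        assert len(pngs) == 4 * len(cases)
        import imageio.v3 as iio

        img = iio.imread(tmp_path / "images" / "case000_LCC.png")
        assert img.dtype == np.uint16 and img.shape == (cfg.image_size,) * 2
        loaded = json.loads((tmp_path / "manifest.json").read_text())
        assert loaded["config"]["seed"] == cfg.seed
        assert manifest["n_responses"] == len(responses)
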