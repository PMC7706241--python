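"""Metric oracles, volumetrics, and agreement statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chdseg.evaluation import (bland_altman, chamber_volume, clinical_indices,
                               contour_distance_metrics, contour_points,
                               evaluate_cohort, fisher_icc, icc_category,
                               overlap_metrics, paired_t_test, r2_vol)


def brute_force_overlap(pred, truth):
    """Independent oracle: explicit pixel loops."""
    tp = fp = fn = tn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_force_contour_distances(a_mask, b_mask, spacing=1.0):
    """All-pairs oracle with an independently coded boundary rule."""
    def boundary(m):
        pts = []
        h, w = m.shape
        for i in range(h):
            for j in range(w):
                if not m[i, j]:
                    continue
                nbrs = [(i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)]
                if any(not (0 <= x < h and 0 <= y < w) or not m[x, y]
                       for x, y in nbrs):
                    pts.append((i, j))
        return pts

    A, B = boundary(a_mask), boundary(b_mask)
    d_ab = [min(np.hypot(ax - bx, ay - by) for bx, by in B) for ax, ay in A]
    d_ba = [min(np.hypot(bx - ax, by - ay) for ax, ay in A) for bx, by in B]
    hd = max(max(d_ab), max(d_ba)) * spacing
    mcd = float(np.mean(d_ab + d_ba)) * spacing
    return hd, mcd


class TestOverlap:
    def test_identical_nonempty_masks(self):
        m = np.zeros((8, 8), np.uint8)
        m[2:5, 2:5] = 1
        rec = overlap_metrics(m, m)
        assert rec["dice_pct"] == 100.0 and rec["jaccard_pct"] == 100.0
        assert rec["sensitivity_pct"] == 100.0 and rec["ppv_pct"] == 100.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8), np.uint8)
        b = np.zeros((8, 8), np.uint8)
        a[0, 0] = 1
        b[7, 7] = 1
        rec = overlap_metrics(a, b)
        assert rec["dice_pct"] == 0.0 and rec["jaccard_pct"] == 0.0
        assert rec["ppv_pct"] == 0.0

    def test_counting_example_on_4x4_grid(self):
        # |P| = 4, |T| = 6, |P∩T| = 3 -> Dice 60%, Jaccard 3/7
        pred = np.zeros((4, 4), np.uint8)
        truth = np.zeros((4, 4), np.uint8)
        pred.reshape(-1)[[0, 1, 2, 8]] = 1
        truth.reshape(-1)[[0, 1, 2, 3, 4, 5]] = 1
        rec = overlap_metrics(pred, truth)
        assert rec["dice_pct"] == pytest.approx(60.0)
        assert rec["jaccard_pct"] == pytest.approx(100 * 3 / 7)

    def test_both_empty_convention_and_missing_ratios(self):
        z = np.zeros((4, 4), np.uint8)
        rec = overlap_metrics(z, z)
        assert rec["dice_pct"] == 100.0 and rec["jaccard_pct"] == 100.0
        assert np.isnan(rec["sensitivity_pct"])  # TP+FN = 0 -> missing
        assert np.isnan(rec["ppv_pct"])

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError):
            overlap_metrics(np.full((2, 2), 2), np.zeros((2, 2)))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_and_dice_jaccard_identity(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.random((8, 8)) < 0.4).astype(np.uint8)
        truth = (rng.random((8, 8)) < 0.4).astype(np.uint8)
        rec = overlap_metrics(pred, truth)
        tp, fp, fn, tn = brute_force_overlap(pred, truth)
        if tp + fp + fn:
            assert rec["dice_pct"] == pytest.approx(100 * 2 * tp / (2 * tp + fp + fn))
            j = rec["jaccard_pct"]
            assert rec["dice_pct"] == pytest.approx(200 * j / (100 + j))
        if tp + fn:
            assert rec["sensitivity_pct"] == pytest.approx(100 * tp / (tp + fn))
        if tn + fp:
            assert rec["specificity_pct"] == pytest.approx(100 * tn / (tn + fp))

    def test_symmetry_relations(self):
        rng = np.random.default_rng(5)
        a = (rng.random((10, 10)) < 0.4).astype(np.uint8)
        b = (rng.random((10, 10)) < 0.4).astype(np.uint8)
        ab, ba = overlap_metrics(a, b), overlap_metrics(b, a)
        assert ab["dice_pct"] == ba["dice_pct"]
        assert ab["jaccard_pct"] == ba["jaccard_pct"]
        assert ab["sensitivity_pct"] == ba["ppv_pct"]


class TestContourDistances:
    def test_identical_masks_zero(self):
        m = np.zeros((8, 8), np.uint8)
        m[2:6, 2:6] = 1
        rec = contour_distance_metrics(m, m, 1.7)
        assert rec["hd_mm"] == 0.0 and rec["mcd_mm"] == 0.0

    def test_single_pixel_pair_with_spacing(self):
        a = np.zeros((8, 8), np.uint8)
        b = np.zeros((8, 8), np.uint8)
        a[2, 2] = 1
        b[2, 5] = 1  # 3 px apart, 2 mm spacing -> 6 mm
        rec = contour_distance_metrics(a, b, 2.0)
        assert rec["hd_mm"] == pytest.approx(6.0)
        assert rec["mcd_mm"] == pytest.approx(6.0)

    def test_concentric_squares_match_all_pairs_oracle(self):
        a = np.zeros((16, 16), np.uint8)
        b = np.zeros((16, 16), np.uint8)
        a[3:12, 3:12] = 1   # 9x9
        b[5:10, 5:10] = 1   # 5x5
        rec = contour_distance_metrics(a, b, 1.0)
        hd, mcd = brute_force_contour_distances(a, b)
        assert rec["hd_mm"] == pytest.approx(hd, abs=1e-9)
        assert rec["mcd_mm"] == pytest.approx(mcd, abs=1e-9)

    def test_empty_mask_reported_missing(self):
        m = np.zeros((8, 8), np.uint8)
        n = m.copy()
        n[1, 1] = 1
        rec = contour_distance_metrics(m, n, 1.0)
        assert np.isnan(rec["hd_mm"]) and rec["reason"] == "empty_mask"

    def test_hd_bounds_mcd_and_scales_with_spacing(self):
        rng = np.random.default_rng(3)
        a = np.zeros((20, 20), np.uint8)
        b = np.zeros((20, 20), np.uint8)
        a[4:12, 4:12] = 1
        b[8:17, 6:15] = 1
        r1 = contour_distance_metrics(a, b, 1.0)
        r2 = contour_distance_metrics(a, b, 2.5)
        assert r1["hd_mm"] >= r1["mcd_mm"] >= 0
        assert r2["hd_mm"] == pytest.approx(2.5 * r1["hd_mm"])
        assert r2["mcd_mm"] == pytest.approx(2.5 * r1["mcd_mm"])

    def test_contour_is_4_neighbor_boundary(self):
        m = np.zeros((5, 5), np.uint8)
        m[1:4, 1:4] = 1
        pts = contour_points(m)
        assert len(pts) == 8  # 3x3 block minus interior pixel


class TestVolumes:
    def test_unit_arithmetic(self):
        stack = np.zeros((1, 40, 40), np.uint8)
        stack[0].reshape(-1)[:1000] = 1
        assert chamber_volume(stack, 1.0, 10.0) == pytest.approx(10.0)

    def test_empty_stack_zero(self):
        assert chamber_volume(np.zeros((0, 4, 4)), 1.0, 8.0) == 0.0

    def test_additivity_over_slices(self):
        rng = np.random.default_rng(0)
        stack = (rng.random((5, 16, 16)) < 0.3).astype(np.uint8)
        total = chamber_volume(stack, 1.3, 7.0)
        per_slice = sum(chamber_volume(s[None], 1.3, 7.0) for s in stack)
        assert total == pytest.approx(per_slice)

    def test_phantom_volume_within_2pct_of_analytic_disks(self, default_study):
        st_ = default_study
        for ph in ("ED", "ES"):
            shrink = 1.0 if ph == "ED" else 0.6
            analytic_px = sum(np.pi * (r * shrink) ** 2
                              for r in st_.geometry["lv_radii_ed"])
            analytic_ml = (analytic_px * st_.pixel_spacing_mm ** 2
                           * st_.slice_thickness_mm / 1000.0)
            measured = chamber_volume(st_.masks[("LV", ph)],
                                      st_.pixel_spacing_mm,
                                      st_.slice_thickness_mm)
            assert abs(measured - analytic_ml) / analytic_ml < 0.02

    def test_negative_spacing_rejected(self):
        with pytest.raises(ValueError):
            chamber_volume(np.zeros((1, 4, 4)), -1.0, 8.0)


class TestClinicalIndices:
    def test_basic_and_degenerate(self):
        rec = clinical_indices(150.0, 50.0)
        assert rec["sv_ml"] == 100.0
        assert rec["ef_pct"] == pytest.approx(200 / 3)
        rec = clinical_indices(100.0, 100.0)
        assert rec["sv_ml"] == 0.0 and rec["ef_pct"] == 0.0
        assert np.isnan(clinical_indices(0.0, 0.0)["ef_pct"])

    def test_cohort_mean_arithmetic(self):
        # LV cohort means EDV 91.72 / ESV 35.16 mL -> SV 56.56, EF ~61.7%
        rec = clinical_indices(91.72, 35.16)
        assert rec["sv_ml"] == pytest.approx(56.56)
        assert rec["ef_pct"] == pytest.approx(61.66, abs=0.05)

    def test_esv_above_edv_warns(self):
        with pytest.warns(UserWarning):
            rec = clinical_indices(50.0, 60.0)
        assert rec["sv_ml"] == -10.0


class TestPairedTTest:
    def test_identical_vectors_pass_by_convention(self):
        x = np.arange(10.0)
        rec = paired_t_test(x, x)
        assert rec["p_value"] == 1.0 and rec["passed"] and rec["degenerate"]

    def test_constant_offset_fails_textbook_t(self):
        rng = np.random.default_rng(0)
        y = rng.normal(50, 5, 20)
        x = y + 10 + rng.normal(0, 0.5, 20)
        rec = paired_t_test(x, y)
        d = x - y
        t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy.stats import t as tdist
        p_manual = 2 * (1 - tdist.cdf(abs(t_stat), len(d) - 1))
        assert rec["p_value"] == pytest.approx(p_manual, abs=1e-12)
        assert rec["p_value"] < 0.05 and not rec["passed"]

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0, 2.0])


class TestFisherICC:
    def test_perfect_agreement_is_exactly_one(self):
        x = np.arange(1.0, 60.0)
        rec = fisher_icc(x, x)
        assert rec["icc"] == pytest.approx(1.0, abs=1e-12)
        assert rec["category"] == "excellent"

    def test_symmetric_anticorrelation_is_minus_one(self):
        x = np.arange(1.0, 21.0)
        y = -x + 2 * x.mean()
        rec = fisher_icc(x, y)
        assert rec["icc"] == pytest.approx(-1.0, abs=1e-12)

    def test_recovers_simulated_intraclass_rho(self):
        rho, n = 0.8, 10_000
        rng = np.random.default_rng(12)
        a = rng.normal(0, np.sqrt(rho), n)
        x = a + rng.normal(0, np.sqrt(1 - rho), n)
        y = a + rng.normal(0, np.sqrt(1 - rho), n)
        rec = fisher_icc(x, y)
        assert rec["icc"] == pytest.approx(rho, abs=0.02)
        assert rec["category"] == "good"

    @pytest.mark.parametrize("icc,cat", [
        (0.49, "poor"), (0.5, "moderate"), (0.74, "moderate"),
        (0.75, "good"), (0.89, "good"), (0.90, "excellent"), (0.97, "excellent")])
    def test_koo_li_bins(self, icc, cat):
        assert icc_category(icc) == cat

    def test_constant_input_flagged(self):
        rec = fisher_icc([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert np.isnan(rec["icc"]) and rec["category"] == "undefined"


class TestBlandAltman:
    def test_identity_gives_zero_band(self):
        x = np.arange(5.0)
        rec = bland_altman(x, x)
        assert rec["bias"] == 0.0
        assert rec["loa_low"] == 0.0 and rec["loa_high"] == 0.0

    def test_plus_minus_one_hand_computation(self):
        rec = bland_altman([1.0, -1.0], [0.0, 0.0])
        assert rec["bias"] == 0.0
        assert rec["sd"] == pytest.approx(np.sqrt(2.0))
        assert rec["loa_high"] == pytest.approx(1.96 * np.sqrt(2.0))
        assert rec["loa_low"] == pytest.approx(-1.96 * np.sqrt(2.0))

    def test_translation_shifts_bias_exactly(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 3, 30)
        x = y + rng.normal(0, 1, 30)
        b0 = bland_altman(x, y)["bias"]
        b7 = bland_altman(x + 7.0, y)["bias"]
        assert b7 - b0 == pytest.approx(7.0)


class TestR2:
    def test_identity_and_scale_invariance(self):
        y = np.arange(1.0, 20.0)
        assert r2_vol(y, y) == pytest.approx(100.0)
        assert r2_vol(2 * y, y) == pytest.approx(100.0)

    def test_known_correlation_recovered(self):
        rng = np.random.default_rng(2)
        n = 200_000
        y = rng.normal(0, 1, n)
        x = 0.5 * y + rng.normal(0, np.sqrt(0.75), n)  # rho^2 = 0.25
        assert r2_vol(x, y) == pytest.approx(25.0, abs=2.0)

    def test_identity_line_variant_penalizes_scale(self):
        y = np.arange(1.0, 20.0)
        assert r2_vol(y, y, method="identity") == pytest.approx(100.0)
        assert r2_vol(2 * y, y, method="identity") < 100.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            r2_vol([1.0, 1.0], [1.0, 2.0])


class TestEvaluateCohort:
    @staticmethod
    def _cohort(n_subjects=5, seed=0):
        from chdseg.phantom import PhantomConfig, generate_cohort
        cfg = PhantomConfig(n_slices=4, source_size=128, noise_sd=0.02,
                            lv_radius_range_px=(14, 18), wall_thickness_px=4,
                            rv_thickness_px=5, center_jitter_px=4,
                            apical_empty_slice=False)
        cohort = generate_cohort(n_subjects, seed, cfg)
        truth, spacing = {}, {}
        for st_ in cohort:
            spacing[st_.study_id] = (st_.pixel_spacing_mm, st_.slice_thickness_mm)
            for key, m in st_.masks.items():
                truth[(st_.study_id, *key)] = m
        return truth, spacing

    def test_identity_cohort_is_perfect(self):
        truth, spacing = self._cohort()
        report = evaluate_cohort(truth, truth, spacing)
        assert (report.metrics.dice_pct == 100.0).all()
        assert (report.metrics.hd_mm == 0.0).all()
        assert report.agreement.t_passed.all()
        assert (report.agreement.icc > 0.999).all()
        assert (report.agreement.icc_category == "excellent").all()
        assert (report.agreement.ba_bias == 0.0).all()
        wide = report.volumetrics
        assert (wide.edv_abs_diff == 0.0).all()

    def test_eroded_predictions_underestimate(self):
        from scipy import ndimage
        truth, spacing = self._cohort()
        pred = {k: np.stack([ndimage.binary_erosion(s).astype(np.uint8)
                             for s in v]) for k, v in truth.items()}
        report = evaluate_cohort(pred, truth, spacing)
        assert (report.metrics.dice_pct < 100.0).all()
        vol = report.volumetrics.pivot_table(
            index=["subject", "chamber"], columns="source", values="edv_ml")
        assert (vol["predicted"] < vol["manual"]).all()

    def test_shuffled_predictions_degrade_icc(self):
        truth, spacing = self._cohort(n_subjects=6)
        subjects = sorted({k[0] for k in truth})
        rolled = {subjects[i]: subjects[(i + 1) % len(subjects)]
                  for i in range(len(subjects))}
        pred = {(rolled[s], ch, ph): v for (s, ch, ph), v in truth.items()}
        report = evaluate_cohort(pred, truth, spacing)
        identity = evaluate_cohort(truth, truth, spacing)
        assert report.agreement.icc.mean() < identity.agreement.icc.mean()

    def test_missing_prediction_key_raises(self):
        truth, spacing = self._cohort(n_subjects=3)
        pred = dict(truth)
        pred.pop(sorted(pred)[0])
        with pytest.raises(KeyError):
            evaluate_cohort(pred, truth, spacing)

    def test_sv_ef_identities_hold_in_table(self):
        truth, spacing = self._cohort()
        vol = evaluate_cohort(truth, truth, spacing).volumetrics
        np.testing.assert_allclose(vol.sv_ml, vol.edv_ml - vol.esv_ml)
        nonzero = vol.edv_ml > 0
        np.testing.assert_allclose(vol.ef_pct[nonzero],
                                   100 * vol.sv_ml[nonzero] / vol.edv_ml[nonzero])
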