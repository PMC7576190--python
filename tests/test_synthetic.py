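"""Synthetic plexus generator: ground-truth self-consistency and lesions."""

import numpy as np
import pytest
from scipy.integrate import quad

import octamorph as om
from octamorph.synthetic import (polyline_arc_length, rasterize_polyline,
                                 sinusoid_polyline)


class TestSinusoidCenterline:
    def test_zero_amplitude_is_straight(self):
        poly = sinusoid_polyline((0, 0), (0, 40), 0.0, 10.0)
        assert polyline_arc_length(poly) == pytest.approx(40.0)

    def test_arc_length_matches_quadrature_oracle(self):
        # y = a sin(k pi x / L): compare the polyline's arc length with
        # numerical quadrature of sqrt(1 + y'^2)
        L, lam, a = 200.0, 50.0, 5.0
        k = round(2 * L / lam)
        poly = sinusoid_polyline((0, 0), (0, L), a, lam, samples_per_px=20)
        expect, _ = quad(lambda x: np.sqrt(
            1 + (a * k * np.pi / L * np.cos(k * np.pi * x / L)) ** 2), 0, L,
            limit=200)
        assert polyline_arc_length(poly) == pytest.approx(expect, rel=1e-4)

    def test_endpoints_exact(self):
        poly = sinusoid_polyline((3, 4), (40, 30), 4.0, 15.0)
        assert np.allclose(poly[0], (3, 4))
        assert np.allclose(poly[-1], (40, 30))

    def test_rasterized_chain_is_8_connected(self):
        poly = sinusoid_polyline((2, 2), (50, 60), 3.0, 12.0)
        chain = rasterize_polyline(poly)
        d = np.abs(np.diff(np.asarray(chain), axis=0))
        assert d.max() == 1
        assert not np.any((d == 0).all(axis=1))


class TestGeneratePlexus:
    def test_deterministic_given_seed(self):
        a1, m1, t1 = om.generate_plexus(om.dcp_params(), seed=9)
        a2, m2, t2 = om.generate_plexus(om.dcp_params(), seed=9)
        assert np.array_equal(a1.pixels, a2.pixels)
        assert np.array_equal(m1.pixels, m2.pixels)
        assert all(b1.chain == b2.chain
                   for b1, b2 in zip(t1.branches, t2.branches))

    def test_zero_amplitude_truth_is_straight(self):
        params = om.dcp_params(tort_amplitude_um=0.0)
        _, _, truth = om.generate_plexus(params, seed=2)
        for b in truth.branches:
            assert b.arc_um == pytest.approx(
                float(np.hypot(*(b.polyline[-1] - b.polyline[0])))
                * params.scale_um_per_px, rel=1e-9)
        # chain-level VT stays near 1 (only chain-code digitization above it)
        assert truth.metrics("full")["vt"] < 1.06

    def test_truth_self_consistent(self, dcp_plexus):
        _, mask, truth = dcp_plexus
        m = truth.metrics("full")
        bl = [b.bl_um for b in truth.branches]
        el = [b.el_um for b in truth.branches]
        assert m["branch_number"] == len(bl) == truth.params.target_branch_count
        assert m["sum_bl_mm"] == pytest.approx(sum(bl) / 1000)
        assert m["vt"] == pytest.approx(sum(bl) / sum(el))
        assert m["vd"] == mask.pixels.mean()
        assert all(b >= e - 1e-9 for b, e in zip(bl, el))

    def test_halves_partition_truth(self, dcp_plexus):
        _, _, truth = dcp_plexus
        n_sup = truth.metrics("superior")["branch_number"]
        n_inf = truth.metrics("inferior")["branch_number"]
        assert n_sup + n_inf == truth.metrics("full")["branch_number"]

    def test_unreachable_target_rejected(self):
        params = om.dcp_params(shape=(64, 64), scale_um_per_px=5.86,
                               target_branch_count=400)
        with pytest.raises(ValueError, match="branch"):
            om.generate_plexus(params, seed=0)

    def test_grayscale_levels(self, dcp_plexus):
        image, mask, _ = dcp_plexus
        assert image.pixels[mask.pixels > 0].min() >= 150
        assert image.pixels[mask.pixels == 0].max() <= 80


class TestLesions:
    def test_zero_dropout_is_identity(self, dcp_plexus):
        _, mask, truth = dcp_plexus
        m2, t2 = om.apply_lesion(truth, om.LesionParams(0.0), seed=1)
        assert np.array_equal(m2.pixels, mask.pixels)
        assert len(t2.branches) == len(truth.branches)

    def test_full_superior_dropout_empties_half_only(self, dcp_plexus):
        _, _, truth = dcp_plexus
        m2, t2 = om.apply_lesion(
            truth, om.LesionParams(1.0, "uniform", "superior"), seed=2)
        assert t2.metrics("superior")["branch_number"] == 0
        assert t2.metrics("inferior")["branch_number"] == \
            truth.metrics("inferior")["branch_number"]

    def test_preferential_dropout_raises_true_mean_bl(self, dcp_plexus):
        _, _, truth = dcp_plexus
        base = truth.metrics("full")["mean_bl_um"]
        _, t2 = om.apply_lesion(
            truth, om.LesionParams(0.3, "short_branch_preferential", "both"),
            seed=3)
        assert t2.metrics("full")["mean_bl_um"] > base

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            om.LesionParams(1.5)
        with pytest.raises(ValueError):
            om.LesionParams(0.2, "weird")
        with pytest.raises(ValueError):
            om.LesionParams(0.2, "uniform", "left")


class TestCohort:
    def test_noiseless_cohort_recovers_beta_exactly(self):
        clin, met, _ = om.generate_cohort({"BRVO_eye": 12}, {"vd": -3.0},
                                          noise_sigma=0.0, seed=4)
        tab = met[met.region.isin(["affected", "superior"])].merge(clin, on="eye_id")
        r = om.adjusted_univariate_regression(tab, "vd", "va_1yr")
        assert r.beta == pytest.approx(-3.0, rel=1e-6)

    def test_schema_matches_pipeline_tables(self):
        clin, met, truths = om.generate_cohort({"control": 2, "CRVO_eye": 2},
                                               seed=6)
        assert {"eye_id", "patient_id", "group", "age", "sex", "va_baseline",
                "va_octa_day", "va_1yr", "cmt_um", "n_injections"} <= set(clin.columns)
        assert {"eye_id", "layer", "region", "branch_number", "vt", "vd"} <= \
            set(met.columns)
        # three regions per eye
        assert met.groupby("eye_id").size().eq(3).all()

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            om.generate_cohort({"control": 1}, seed=0)
        with pytest.raises(ValueError, match="unknown group"):
            om.generate_cohort({"patients": 5}, seed=0)

    def test_brvo_affected_half_depleted(self):
        clin, met, _ = om.generate_cohort(
            {"BRVO_eye": 8}, dropout_ranges={"BRVO_eye": (0.3, 0.3)}, seed=8)
        wide = met.pivot_table(index="eye_id", columns="region", values="vd")
        ok = (wide["affected"] < wide["nonaffected"]).mean()
        assert ok >= 0.9
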