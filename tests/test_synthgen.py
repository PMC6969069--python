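"""Generator contracts: determinism, geometry, and sampling rates."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi
from scipy import stats

from cinquant.synthgen import (
    DefectModel,
    FieldSpec,
    PlacementError,
    SpreadPopulationSpec,
    deletion_code_probs,
    generate_cna_matrix,
    generate_field,
    generate_spread_set,
    generate_survival_cohort,
)

SMALL = dict(image_size=(600, 600), pixel_size=0.5, n_cells=25)


class TestFields:
    def test_empty_field(self):
        image, gt = generate_field(FieldSpec(**SMALL | {"n_cells": 0}, seed=1))
        assert gt.empty
        assert image.pixels.shape == (600, 600)

    def test_seeded_determinism_is_bit_identical(self):
        spec = FieldSpec(**SMALL, mn_rate=0.3, seed=7)
        a_img, a_gt = generate_field(spec)
        b_img, b_gt = generate_field(spec)
        assert np.array_equal(a_img.pixels, b_img.pixels)
        pd.testing.assert_frame_equal(a_gt, b_gt)

    def test_different_seeds_differ(self):
        a, _ = generate_field(FieldSpec(**SMALL, seed=1))
        b, _ = generate_field(FieldSpec(**SMALL, seed=2))
        assert not np.array_equal(a.pixels, b.pixels)

    def test_micronuclei_reference_existing_nuclei_outside_owner(self):
        spec = FieldSpec(**SMALL, mn_rate=0.5, seed=3)
        _, gt = generate_field(spec)
        nuclei = gt[gt.kind == "nucleus"].set_index("object_id")
        mns = gt[gt.kind == "micronucleus"]
        assert len(mns) > 0
        for _, m in mns.iterrows():
            owner = nuclei.loc[m.owner_id]
            centre_dist = np.hypot(m.cx_um - owner.cx_um, m.cy_um - owner.cy_um)
            # outside the owner's boundary but within its cell-body reach
            assert centre_dist > owner.diameter_um / 2.0
            assert centre_dist < owner.diameter_um / 2.0 + 12.0

    def test_border_flag_matches_centroid_distance(self):
        spec = FieldSpec(**SMALL, border_fraction=0.4, seed=9)
        image, gt = generate_field(spec)
        hx, wx = image.extent_um
        edge = np.minimum.reduce(
            [gt.cx_um, gt.cy_um, wx - gt.cx_um, hx - gt.cy_um]
        )
        assert ((edge <= spec.border_margin) == gt.border).all()
        assert gt[gt.kind == "nucleus"].border.any()

    def test_ground_truth_matches_brute_force_pixel_scan(self):
        """Re-measuring each object from the image reproduces the recorded
        diameter within one pixel and the intensity within 5%."""
        spec = FieldSpec(**SMALL, mn_rate=0.3, seed=11)
        image, gt = generate_field(spec)
        mid = (spec.background_intensity[0] + spec.foreground_intensity[0]) / 2.0
        labels, n = ndi.label(image.pixels > mid)
        assert n == len(gt)
        ps = image.pixel_size
        for _, row in gt.iterrows():
            lab = labels[int(round(row.cy_um / ps)), int(round(row.cx_um / ps))]
            assert lab > 0
            area = (labels == lab).sum() * ps * ps
            d = np.sqrt(4 * area / np.pi)
            assert abs(d - row.diameter_um) <= ps + 1e-9
            mean = image.pixels[labels == lab].mean()
            assert abs(mean - row.mean_intensity) / row.mean_intensity < 0.05

    def test_mn_rate_within_poisson_interval(self):
        total_cells = total_mn = 0
        for s in range(8):
            spec = FieldSpec(**SMALL | {"n_cells": 70, "image_size": (900, 900)},
                             mn_rate=0.2, seed=100 + s)
            _, gt = generate_field(spec)
            total_cells += (gt.kind == "nucleus").sum()
            total_mn += (gt.kind == "micronucleus").sum()
        assert total_cells >= 500
        lam = 0.2 * total_cells
        lo, hi = stats.poisson.ppf(0.005, lam), stats.poisson.ppf(0.995, lam)
        assert lo <= total_mn <= hi

    def test_silenced_vs_control_fold_setpoint(self):
        """A 19.6x configured micronucleus rate is recovered within the
        Poisson interval of the simulated counts (3 replicates/condition)."""
        counts = {0.015: [0, 0], 0.015 * 19.6: [0, 0]}  # rate -> [mn, cells]
        for rep in range(3):
            for rate in counts:
                spec = FieldSpec(**SMALL | {"n_cells": 60, "image_size": (900, 900)},
                                 mn_rate=rate, seed=500 + rep)
                _, gt = generate_field(spec)
                counts[rate][0] += (gt.kind == "micronucleus").sum()
                counts[rate][1] += (gt.kind == "nucleus").sum()
        (c_mn, c_n), (t_mn, t_n) = counts[0.015], counts[0.015 * 19.6]
        # exact Poisson 99% intervals on each rate -> interval on the ratio
        c_lo, c_hi = stats.chi2.ppf(0.005, 2 * c_mn) / 2, stats.chi2.ppf(0.995, 2 * (c_mn + 1)) / 2
        t_lo, t_hi = stats.chi2.ppf(0.005, 2 * t_mn) / 2, stats.chi2.ppf(0.995, 2 * (t_mn + 1)) / 2
        lo = (t_lo / t_n) / (c_hi / c_n)
        hi = (t_hi / t_n) / (max(c_lo, 1e-9) / c_n)
        assert lo <= 19.6 <= hi

    def test_impossible_placement_raises(self):
        spec = FieldSpec(image_size=(220, 220), pixel_size=0.5, n_cells=40,
                         max_retries=50, seed=0)
        with pytest.raises(PlacementError):
            generate_field(spec)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            FieldSpec(apoptotic_fraction=1.5).validate()
        with pytest.raises(ValueError):
            FieldSpec(pixel_size=0.0).validate()


class TestSpreads:
    def test_all_zero_defect_model(self):
        df = generate_spread_set(SpreadPopulationSpec(n_spreads=50, seed=1))
        assert (df.defective_chromosomes == 0).all()
        assert not df.severe_spread.any()

    def test_degenerate_noise_gives_modal_count(self):
        df = generate_spread_set(
            SpreadPopulationSpec(n_spreads=120, modal_count=45, seed=2)
        )
        assert (df.chromosome_count == 45).all()

    def test_tetraploid_fraction_within_binomial_interval(self):
        spec = SpreadPopulationSpec(
            n_spreads=1000, modal_count=45, tetraploid_fraction=0.2, seed=3
        )
        df = generate_spread_set(spec)
        n_tetra = (df.chromosome_count > 67).sum()
        lo = stats.binom.ppf(0.005, 1000, 0.2)
        hi = stats.binom.ppf(0.995, 1000, 0.2)
        assert lo <= n_tetra <= hi

    def test_defective_never_exceeds_count(self):
        spec = SpreadPopulationSpec(
            n_spreads=300,
            defect_model=DefectModel(defect_rate=0.7, mean_defective=8, p_severe=0.2),
            seed=4,
        )
        df = generate_spread_set(spec)
        assert (df.defective_chromosomes <= df.chromosome_count).all()

    def test_determinism(self):
        spec = SpreadPopulationSpec(n_spreads=40, tetraploid_fraction=0.3, seed=5)
        pd.testing.assert_frame_equal(generate_spread_set(spec), generate_spread_set(spec))

    def test_bad_noise_distribution_rejected(self):
        with pytest.raises(ValueError):
            SpreadPopulationSpec(count_noise={0: 0.5, 1: 0.2}).validate()


class TestCNA:
    def test_all_diploid(self):
        m = generate_cna_matrix(3, 20, [[0, 0, 1, 0, 0]], seed=1)
        assert (m.to_numpy() == 0).all()

    def test_all_deep_deletion(self):
        m = generate_cna_matrix(1, 15, [[1, 0, 0, 0, 0]], seed=1)
        assert (m.to_numpy() == -2).all()

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            generate_cna_matrix(2, 10, [[0.5, 0.2, 0.1, 0, 0]], seed=1)

    def test_cumulative_setpoint_within_binomial_interval(self):
        """Per-gene deletion mass tuned for 95% cumulative frequency."""
        p_gene = 1 - (1 - 0.95) ** (1 / 10)  # 1-(1-p)^10 = 0.95
        m = generate_cna_matrix(10, 600, deletion_code_probs(p_gene), seed=6)
        hit = (m.to_numpy() <= -1).any(axis=0).sum()
        lo = stats.binom.ppf(0.005, 600, 0.95)
        hi = stats.binom.ppf(0.995, 600, 0.95)
        assert lo <= hit <= hi


class TestSurvival:
    def test_zero_censoring_all_events(self):
        df = generate_survival_cohort(100, 50, 2.0, 0.0, seed=1)
        assert (df.event == 1).all()

    def test_censor_rate_within_binomial_interval(self):
        df = generate_survival_cohort(1500, 50, 2.5, 0.3, seed=2)
        n_cens = int((df.event == 0).sum())
        lo = stats.binom.ppf(0.005, 1500, 0.3)
        hi = stats.binom.ppf(0.995, 1500, 0.3)
        assert lo <= n_cens <= hi

    def test_null_hazard_ratio_uniform_pvalues(self):
        """With no true effect the log-rank p across seeds behaves like a
        uniform variate: rejection rate at alpha=0.05 within the exact
        binomial 99% interval of 5%."""
        from cinquant.genomics import km_logrank

        rejections = 0
        n_sims = 200
        for s in range(n_sims):
            df = generate_survival_cohort(120, 50, 1.0, 0.2, seed=3000 + s)
            low = df[df.expression < df.expression.median()]
            high = df[df.expression >= df.expression.median()]
            res = km_logrank(low, high)
            if res.p_value < 0.05:
                rejections += 1
        lo = stats.binom.ppf(0.005, n_sims, 0.05)
        hi = stats.binom.ppf(0.995, n_sims, 0.05)
        assert lo <= rejections <= hi

    def test_precondition_validation(self):
        with pytest.raises(ValueError):
            generate_survival_cohort(1, 50, 2.0, 0.1)
        with pytest.raises(ValueError):
            generate_survival_cohort(50, 0, 2.0, 0.1)
        with pytest.raises(ValueError):
            generate_survival_cohort(50, 50, -1.0, 0.1)
        with pytest.raises(ValueError):
            generate_survival_cohort(50, 50, 2.0, 1.0)
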