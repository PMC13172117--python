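"""Phantom generation, cohort quotas, and the fixed benchmark cohort."""

import numpy as np
import pytest

import cribmap as cm
from cribmap.synthetic import _quota_counts, cohort_to_dataframe, records_from_dataframe


class TestGeneratePhantom:
    def test_no_lesions_all_background(self, small_config):
        ph = cm.generate_phantom(
            small_config, {"crib_positive": False, "n_lesions": 0, "patient_id": "p0"}
        )
        assert not ph.record.crib_positive
        assert ph.record.max_crib_diameter_mm == 0.0
        assert not ph.lesion_labels.any()
        # mask voxels drawn from the background distribution only
        vals = ph.adc.data[ph.mask.data]
        mean, sd = small_config.background_adc
        assert abs(vals.mean() - mean) < 3 * sd / np.sqrt(vals.size)

    def test_six_mm_crib_lesion_diameter_and_area(self, small_config):
        """The measured in-plane diameter sits within one in-plane voxel of
        the requested 6 mm, and the voxel count per slice is within 25% of
        the analytic circle area (lattice-point oracle)."""
        ph = cm.generate_phantom(
            small_config,
            {"crib_positive": True, "crib_diameter_mm": 6.0, "n_lesions": 1},
        )
        dx = small_config.voxel_spacing[0]
        assert abs(ph.record.max_crib_diameter_mm - 6.0) <= dx
        crib = ph.lesion_labels == int(cm.LesionClass.GP4_CRIB_POS)
        # equator slice: the densest one
        z = np.argmax(crib.sum(axis=(0, 1)))
        count = crib[:, :, z].sum()
        analytic = np.pi * 3.0**2 / (dx * small_config.voxel_spacing[1])
        assert abs(count - analytic) / analytic < 0.25

    def test_same_seed_bit_identical(self, small_config):
        spec = {"crib_positive": True, "n_lesions": 2, "patient_id": "p"}
        a = cm.generate_phantom(small_config, dict(spec))
        b = cm.generate_phantom(small_config, dict(spec))
        assert np.array_equal(a.adc.data, b.adc.data)
        assert np.array_equal(a.lesion_labels, b.lesion_labels)
        assert a.record == b.record

    def test_lesions_inside_mask_and_crib_flag_consistent(self, small_config):
        rng = np.random.default_rng(77)
        for _ in range(10):
            ph = cm.generate_phantom(small_config, rng=rng)
            assert np.all(ph.mask.data[ph.lesion_labels > 0])
            has_crib = bool(
                (ph.lesion_labels == int(cm.LesionClass.GP4_CRIB_POS)).any()
            )
            assert ph.record.crib_positive == has_crib
            if has_crib:
                assert ph.record.max_crib_diameter_mm > 0

    def test_class_means_recovered_from_voxels(self, small_config):
        """Pooled lesion voxels recover the class ADC mean within 3 SE
        (>= 1,000 voxels per class, aggregated over phantoms)."""
        import dataclasses

        cfg = dataclasses.replace(small_config, lesion_diameter_range=(4.0, 6.0))
        pooled = {cls: [] for cls in cm.LesionClass}
        rng = np.random.default_rng(123)
        for _ in range(45):
            ph = cm.generate_phantom(
                cfg,
                {"crib_positive": True, "crib_diameter_mm": 8.0, "n_lesions": 3},
                rng=rng,
            )
            for cls in cm.LesionClass:
                pooled[cls].append(ph.adc.data[ph.lesion_labels == int(cls)])
        for cls, (mean, sd) in small_config.lesion_adc.items():
            vals = np.concatenate(pooled[cls])
            assert vals.size >= 1000
            assert abs(vals.mean() - mean) < 3 * sd / np.sqrt(vals.size)

    def test_contradictory_spec_raises(self, small_config):
        with pytest.raises(ValueError):
            cm.generate_phantom(
                small_config, {"crib_positive": False, "crib_diameter_mm": 5.0}
            )

    def test_impossible_placement_raises_explicitly(self, small_config):
        with pytest.raises(RuntimeError, match="could not place"):
            cm.generate_phantom(
                small_config,
                {"crib_positive": True, "crib_diameter_mm": 30.0, "n_lesions": 1},
            )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):  # cribriform mean above GP3 mean
            cm.PhantomConfig(
                lesion_adc={
                    cm.LesionClass.GP3: (900.0, 100.0),
                    cm.LesionClass.GP4_CRIB_NEG: (900.0, 100.0),
                    cm.LesionClass.GP4_CRIB_POS: (1200.0, 100.0),
                }
            )
        with pytest.raises(ValueError):
            cm.PhantomConfig(noise_sigma=-1.0)
        with pytest.raises(ValueError):
            cm.PhantomConfig(lesion_diameter_range=(5.0, 3.0))

    @pytest.mark.parametrize("noise_model", ["gaussian", "rician"])
    def test_noise_models_apply(self, small_config, noise_model):
        import dataclasses

        cfg = dataclasses.replace(
            small_config, noise_model=noise_model, noise_sigma=50.0
        )
        quiet = cm.generate_phantom(small_config, {"crib_positive": False, "n_lesions": 0})
        noisy = cm.generate_phantom(cfg, {"crib_positive": False, "n_lesions": 0})
        assert noisy.adc.data[noisy.mask.data].std() > quiet.adc.data[quiet.mask.data].std()
        assert np.all(noisy.adc.data >= 0)


class TestGenerateCohort:
    MIX = {(2, True): 0.41, (2, False): 0.59}

    def test_exact_quota_hits_requested_counts(self, small_config):
        counts = _quota_counts(200, np.array([0.41, 0.59]), True, np.random.default_rng(0))
        assert list(counts) == [82, 118]

    def test_exact_quota_cohort_realises_prevalence(self, small_config):
        phantoms = cm.generate_cohort(20, small_config, {(2, True): 0.4, (2, False): 0.6}, seed=5)
        assert sum(p.record.crib_positive for p in phantoms) == 8
        assert all(p.record.cpg == 2 for p in phantoms)

    def test_multinomial_counts_within_binomial_bounds(self):
        """Multinomial mode at n = 10,000 stays within the 99% binomial band."""
        from scipy.stats import binom

        rng = np.random.default_rng(11)
        p = np.array([0.41, 0.59])
        counts = _quota_counts(10_000, p, False, rng)
        lo, hi = binom.ppf([0.005, 0.995], 10_000, 0.41)
        assert lo <= counts[0] <= hi

    def test_cpg1_cells_forced_to_gg1_low_psa(self, small_config):
        phantoms = cm.generate_cohort(10, small_config, {(1, False): 1.0}, seed=2)
        for ph in phantoms:
            r = ph.record
            assert r.biopsy_gg == 1 and r.psa < 10 and r.clinical_t_stage <= 2
            assert r.cpg == 1

    def test_different_seeds_same_quota_different_images(self, small_config):
        a = cm.generate_cohort(8, small_config, self.MIX, seed=1)
        b = cm.generate_cohort(8, small_config, self.MIX, seed=2)
        assert sum(p.record.crib_positive for p in a) == sum(
            p.record.crib_positive for p in b
        )
        assert not np.array_equal(a[0].adc.data, b[0].adc.data)

    def test_seed_determinism_byte_for_byte(self, small_config):
        a = cm.generate_cohort(6, small_config, self.MIX, seed=9)
        b = cm.generate_cohort(6, small_config, self.MIX, seed=9)
        assert cohort_to_dataframe(a).to_csv() == cohort_to_dataframe(b).to_csv()
        for x, y in zip(a, b):
            assert np.array_equal(x.adc.data, y.adc.data)

    def test_bad_mix_rejected(self, small_config):
        with pytest.raises(ValueError, match="sum to 1"):
            cm.generate_cohort(5, small_config, {(1, False): 0.4, (2, False): 0.4})


class TestFixtureCohort:
    def test_printed_marginals(self, fixture_cohort):
        recs = fixture_cohort
        by_cpg = {c: [r for r in recs if r.cpg == c] for c in (1, 2, 3)}
        # the nine published marginal counts
        assert len(recs) == 127
        assert (len(by_cpg[1]), len(by_cpg[2]), len(by_cpg[3])) == (26, 72, 29)
        crib = {c: sum(r.crib_positive for r in by_cpg[c]) for c in (1, 2, 3)}
        assert (crib[1], crib[2], crib[3]) == (3, 33, 16)
        gg3 = {c: sum(r.prostatectomy_gg >= 3 for r in by_cpg[c]) for c in (1, 2, 3)}
        assert (gg3[1], gg3[2], gg3[3]) == (0, 12, 10)

    def test_headline_totals(self, fixture_cohort):
        assert sum(r.crib_positive for r in fixture_cohort) == 52
        assert sum(r.prostatectomy_gg >= 3 for r in fixture_cohort) == 22

    def test_cpg12_subset(self, fixture_cohort):
        sub = cm.select_cohort(fixture_cohort, "cpg12")
        assert len(sub) == 98
        assert sum(r.crib_positive for r in sub) == 36

    def test_cpg1_mostly_crib_negative(self, fixture_cohort):
        cpg1 = [r for r in fixture_cohort if r.cpg == 1]
        assert sum(not r.crib_positive for r in cpg1) == 23

    def test_cpg_consistent_with_assignment_rule(self, fixture_cohort):
        for r in fixture_cohort:
            assert cm.assign_cpg(r.psa, r.biopsy_gg, r.clinical_t_stage) == r.cpg

    def test_crib_diameters_above_detectability_cutoff(self, fixture_cohort):
        assert all(
            r.max_crib_diameter_mm >= 1.5
            for r in fixture_cohort
            if r.crib_positive
        )

    def test_deterministic_and_round_trips_through_csv(self, fixture_cohort, tmp_path):
        df = cohort_to_dataframe(fixture_cohort)
        assert df.to_csv() == cohort_to_dataframe(cm.build_fixture_cohort()).to_csv()
        path = tmp_path / "fixture.csv"
        df.to_csv(path, index=False)
        import pandas as pd

        back = records_from_dataframe(pd.read_csv(path))
        assert back == fixture_cohort
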