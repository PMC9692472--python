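"""Generators: construction exactness, determinism, forward-model physics."""

import numpy as np
import pytest

from pdxmet.exchange import simulate_two_site
from pdxmet.synthetic import (DWIGroundTruth, ExchangeModelParams,
                              GroupSpec, NMRGroundTruth, PhantomSpec,
                              add_noise, make_cohort, make_dwi_series,
                              make_hp_dynamics, make_nmr_tables,
                              make_t2w_phantom)

from conftest import fine_step_two_site


def exact_spec(**kw):
    """Phantom spec with every intensity SD at zero: exact construction."""
    return PhantomSpec(kidney_sd=0, tumor_sd=0, cyst_sd=0, necrosis_sd=0,
                       background_sd=0, noise_sd=0, **kw)


class TestT2wPhantom:
    def test_exact_class_counts(self):
        _, _, truth = make_t2w_phantom(exact_spec(cystic_fraction=0.10, seed=1))
        assert truth.n_tumor == 1000
        assert truth.n_cystic == 100
        assert truth.n_necrotic == 0

    def test_no_extreme_classes_all_voxels_at_tumor_mean(self):
        vol, rois, _ = make_t2w_phantom(exact_spec(seed=2))
        assert np.all(vol.data[rois.tumor] == 100.0)

    def test_seed_determinism_bit_identical(self):
        spec = PhantomSpec(cystic_fraction=0.2, necrotic_fraction=0.1,
                           noise_sd=3.0, seed=9)
        v1, _, t1 = make_t2w_phantom(spec)
        v2, _, t2 = make_t2w_phantom(spec)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(t1.labels, t2.labels)

    def test_overlapping_masks_rejected(self):
        spec = exact_spec()
        spec.tumor_box = spec.kidney_box
        with pytest.raises(ValueError, match="overlap"):
            make_t2w_phantom(spec)

    def test_fraction_invariants_rejected(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            make_t2w_phantom(exact_spec(cystic_fraction=0.7,
                                        necrotic_fraction=0.5))


class TestDWI:
    def test_forward_signal_matches_monoexponential(self):
        truth = DWIGroundTruth(adc=np.full((1, 1, 1), 1.0e-3),
                               s0=np.full((1, 1, 1), 1000.0),
                               bvalues=[0.0, 1000.0])
        series = make_dwi_series(truth)
        assert series.signal[0, 0, 0, 0] == pytest.approx(1000.0)
        assert series.signal[0, 0, 0, 1] == pytest.approx(367.879441, abs=1e-6)

    def test_zero_adc_gives_flat_signal(self):
        truth = DWIGroundTruth(adc=np.zeros((2, 2, 1)),
                               s0=np.full((2, 2, 1), 500.0))
        series = make_dwi_series(truth)
        assert np.allclose(series.signal, 500.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            DWIGroundTruth(adc=np.zeros((1, 1, 1)), s0=np.ones((1, 1, 1)),
                           noise_sd=-1.0)

    def test_rician_noise_is_upward_biased(self, rng):
        # magnitude of a complex Gaussian exceeds the noiseless value in
        # expectation; Monte-Carlo oracle at both high and low SNR
        for s0 in (1000.0, 20.0):
            noisy = add_noise(np.full(100_000, s0), 20.0, rng, "rician")
            assert noisy.mean() > s0

    def test_bvalue_validation(self):
        with pytest.raises(ValueError, match="include b = 0"):
            DWIGroundTruth(adc=np.zeros((1, 1, 1)), s0=np.ones((1, 1, 1)),
                           bvalues=[100.0, 200.0])


class TestExchangeDynamics:
    def test_zero_kpl_means_zero_lactate(self):
        grid = make_hp_dynamics(ExchangeModelParams(kpl=0.0, noise_sd=0.0))
        assert np.all(grid.lactate == 0.0)
        assert grid.pyruvate.max() > 0

    def test_protocol_timing(self):
        grid = make_hp_dynamics(ExchangeModelParams())
        assert grid.times.size == 15
        assert grid.times[0] == pytest.approx(10.0)
        assert np.allclose(np.diff(grid.times), 4.2)

    def test_delta_bolus_auc_ratio_tends_to_kpl_t1l(self):
        # analytic limit of the linear system: integral ratio = kPL * T1L
        kpl, t1l = 0.03, 33.0
        times = np.arange(0.0, 8 * 43.0, 2.0)
        p, l = simulate_two_site(times, kpl, 43.0, t1l, bolus="delta",
                                 bolus_arrival=0.0)
        ratio = np.trapezoid(l, times) / np.trapezoid(p, times)
        assert ratio == pytest.approx(kpl * t1l, rel=0.02)

    def test_gamma_bolus_matches_independent_rk4_oracle(self):
        times = np.arange(10.0, 70.0, 4.2)
        p, l = simulate_two_site(times, 0.05, 43.0, 33.0, bolus="gamma",
                                 bolus_arrival=0.0)
        p_ref, l_ref = fine_step_two_site(times, 0.05, 43.0, 33.0,
                                          bolus="gamma")
        assert np.allclose(p, p_ref, rtol=1e-3)
        assert np.allclose(l, l_ref, rtol=1e-3)

    def test_ratio_monotone_in_kpl_against_ode_oracle(self):
        times = np.arange(10.0, 73.0, 4.2)
        ratios = []
        for kpl in (0.01, 0.02, 0.05, 0.1):
            p, l = fine_step_two_site(times, kpl, 43.0, 33.0, bolus="gamma")
            ratios.append(np.trapezoid(l, times) / np.trapezoid(p, times))
        assert np.all(np.diff(ratios) > 0)
        # package gives the same ordering
        pk = [simulate_two_site(times, k, 43.0, 33.0, bolus="gamma")
              for k in (0.01, 0.02, 0.05, 0.1)]
        pkg_ratios = [np.trapezoid(l, times) / np.trapezoid(p, times)
                      for p, l in pk]
        assert np.all(np.diff(pkg_ratios) > 0)

    def test_mass_conservation_without_decay(self):
        # T1 -> inf, no flip loss, delta bolus: P + L constant after arrival
        times = np.linspace(1.0, 200.0, 50)
        p, l = simulate_two_site(times, 0.05, 1e9, 1e9, bolus="delta",
                                 bolus_arrival=0.0)
        assert np.allclose(p + l, 1.0, rtol=1e-6)

    def test_invalid_t1_rejected(self):
        with pytest.raises(ValueError, match="T1"):
            make_hp_dynamics(ExchangeModelParams(t1_pyruvate=-1.0))


class TestNMRTables:
    def test_hsqc_over_total_recovers_fe(self):
        truth = NMRGroundTruth(seed=0)
        truth.metabolites = {"lactate": truth.metabolites["lactate"]}
        truth.metabolites["lactate"].pool = 10.0
        truth.metabolites["lactate"].fe = 0.25
        tables = make_nmr_tables(truth)
        labeled = tables.hsqc["labeled_nmol_mg"].iloc[0]
        assert labeled / 10.0 == pytest.approx(0.25)

    def test_zero_fe_gives_zero_hsqc_entry(self):
        tables = make_nmr_tables(NMRGroundTruth())
        taurine = tables.hsqc[tables.hsqc["metabolite"] == "taurine"]
        assert taurine["labeled_nmol_mg"].iloc[0] == 0.0

    def test_zero_tsp_area_rejected(self):
        with pytest.raises(ValueError, match="TSP"):
            make_nmr_tables(NMRGroundTruth(tsp_area=0.0))

    def test_multiplet_fractions_sum_to_one(self):
        tables = make_nmr_tables(NMRGroundTruth(area_noise_cv=0.05, seed=4))
        sums = tables.multiplets.groupby("carbon")["fraction"].sum()
        assert np.allclose(sums, 1.0)


class TestCohort:
    def test_layout_and_manifest(self, tmp_path):
        groups = [GroupSpec(name="a", n_tumors=3),
                  GroupSpec(name="b", n_tumors=3, kpl_mean=0.06)]
        manifest = make_cohort(groups, tmp_path / "c", seed=5)
        assert len(manifest) == 6
        tumor_dirs = [p for p in (tmp_path / "c").iterdir() if p.is_dir()]
        assert len(tumor_dirs) == 6
        for td in tumor_dirs:
            assert (td / "t2w.nii").exists()
            assert (td / "dwi.bvals.json").exists()
            assert (td / "hp_dynamics.timing.json").exists()
            assert (td / "nmr_multiplets.csv").exists()

    def test_same_seed_identical_manifest(self, tmp_path):
        m1 = make_cohort(None, tmp_path / "c1", seed=6)
        m2 = make_cohort(None, tmp_path / "c2", seed=6)
        assert m1.equals(m2)

    def test_group_kpl_means_differ_as_prescribed(self, tmp_path):
        groups = [GroupSpec(name="a", n_tumors=6, kpl_mean=0.02, kpl_sd=0.002),
                  GroupSpec(name="b", n_tumors=6, kpl_mean=0.06, kpl_sd=0.002)]
        manifest = make_cohort(groups, tmp_path / "c", seed=7)
        means = manifest.groupby("group")["true_kpl_s"].mean()
        assert means["a"] == pytest.approx(0.02, abs=0.005)
        assert means["b"] == pytest.approx(0.06, abs=0.005)
        assert means["b"] > means["a"]
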