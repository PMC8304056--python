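"""Reflectivity kernels: Fresnel, Parratt, Abelès, Born, smearing, Bragg analysis."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memscatter import (
    DisorderSpec,
    SldValue,
    abeles_reflectivity,
    apply_scale_background,
    born_reflectivity,
    critical_q,
    fresnel_interface,
    incoherent_mean,
    jitter_ensemble,
    locate_bragg_peaks,
    parratt_reflectivity,
    profile_to_slabs,
    smear_resolution,
    tile_unit_cell,
)
from memscatter.assembly import Slab, SlabStack
from memscatter.fixtures import make_slab_profile
from memscatter.reflectivity import ReflectivityCurve

from conftest import D2O, SI

QC_SI_D2O = critical_q(SldValue(SI), SldValue(D2O))


def reflect(profile, q):
    return parratt_reflectivity(profile_to_slabs(profile, coarsen_tolerance=1e-9), q)


class TestFresnel:
    def test_total_reflection_below_critical_edge(self):
        q = np.linspace(0.2 * QC_SI_D2O, 0.999 * QC_SI_D2O, 50)
        r, _ = fresnel_interface(q, SI, D2O)
        np.testing.assert_allclose(np.abs(r) ** 2, 1.0, atol=1e-12)

    def test_closed_form_at_twice_critical_q(self):
        r, _ = fresnel_interface(np.array([2.0 * QC_SI_D2O]), SI, D2O)
        expected = ((2 - math.sqrt(3)) / (2 + math.sqrt(3))) ** 2
        assert np.abs(r[0]) ** 2 == pytest.approx(expected, rel=1e-10)

    def test_matched_media_transmit_everything(self):
        q = np.array([0.01, 0.1])
        r, t = fresnel_interface(q, D2O, D2O)
        np.testing.assert_allclose(r, 0.0)
        np.testing.assert_allclose(t, 1.0)


def random_stack(rng, n_slabs, with_roughness=False):
    slabs = [
        Slab(
            rng.uniform(5.0, 80.0),
            rng.uniform(-1e-6, 8e-6),
            rng.uniform(0.0, 3.0) if with_roughness else 0.0,
        )
        for _ in range(n_slabs)
    ]
    return SlabStack(
        rng.uniform(-1e-6, 8e-6),
        slabs,
        rng.uniform(-1e-6, 8e-6),
        backing_roughness=rng.uniform(0.0, 3.0) if with_roughness else 0.0,
    )


class TestExactKernels:
    def test_bare_interface_reproduces_fresnel_decay(self):
        q = np.linspace(0.001, 0.1, 500)
        curve = parratt_reflectivity(SlabStack(SI, [], D2O), q)
        r, _ = fresnel_interface(q, SI, D2O)
        np.testing.assert_allclose(curve.R, np.abs(r) ** 2, rtol=1e-12)
        assert np.all(curve.R[q <= QC_SI_D2O] == pytest.approx(1.0, abs=1e-12))

    def test_kiessig_fringe_spacing_of_single_slab(self):
        stack = SlabStack(0.0, [Slab(50.0, 4e-6)], D2O)
        q = np.linspace(0.15, 0.45, 20000)
        curve = parratt_reflectivity(stack, q)
        from scipy.signal import find_peaks

        minima, _ = find_peaks(-np.log10(curve.R))
        spacings = np.diff(q[minima])
        assert spacings.mean() == pytest.approx(2 * math.pi / 50.0, rel=0.01)

    def test_zero_contrast_slab_is_invisible(self):
        q = np.linspace(0.005, 0.3, 300)
        base = SlabStack(SI, [Slab(30.0, 4e-6)], D2O)
        padded = SlabStack(SI, [Slab(25.0, SI), Slab(30.0, 4e-6)], D2O)
        np.testing.assert_allclose(
            parratt_reflectivity(base, q).R,
            parratt_reflectivity(padded, q).R,
            rtol=1e-12,
        )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        n_slabs=st.integers(1, 20),
        rough=st.booleans(),
    )
    def test_parratt_equals_abeles_and_unitarity(self, seed, n_slabs, rough):
        """The two exact kernels agree to 1e-10 and 0 ≤ R ≤ 1 (no absorption)."""
        rng = np.random.default_rng(seed)
        stack = random_stack(rng, n_slabs, with_roughness=rough)
        q = np.geomspace(1e-3, 0.5, 60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rp = parratt_reflectivity(stack, q).R
            ra = abeles_reflectivity(stack, q).R
        np.testing.assert_allclose(rp, ra, rtol=1e-10, atol=1e-14)
        assert np.all(rp >= 0.0)
        assert np.all(rp <= 1.0 + 1e-10)

    def test_nevot_croce_vanishing_sigma_limit_is_exact(self):
        q = np.linspace(0.005, 0.4, 200)
        sharp = SlabStack(SI, [Slab(40.0, 4e-6)], D2O)
        rough = SlabStack(
            SI, [Slab(40.0, 4e-6, roughness=0.0)], D2O, backing_roughness=0.0
        )
        np.testing.assert_array_equal(
            parratt_reflectivity(sharp, q).R, parratt_reflectivity(rough, q).R
        )
        # and any σ > 0 strictly damps the high-Q reflectivity
        damped = SlabStack(SI, [Slab(40.0, 4e-6, roughness=2.0)], D2O,
                           backing_roughness=2.0)
        assert np.all(
            parratt_reflectivity(damped, q).R[q > 0.05]
            < parratt_reflectivity(sharp, q).R[q > 0.05]
        )

    def test_fresnel_asymptote(self):
        """R · (2Q/Qc)⁴ → 1 far above the critical edge."""
        q = np.array([50.0 * QC_SI_D2O])
        r = parratt_reflectivity(SlabStack(SI, [], D2O), q).R[0]
        assert r * (2 * q[0] / QC_SI_D2O) ** 4 == pytest.approx(1.0, rel=0.01)

    def test_symmetric_stack_reversal_invariance(self):
        q = np.linspace(0.01, 0.3, 200)
        slabs = [Slab(20.0, 4e-6), Slab(30.0, 1e-6), Slab(20.0, 4e-6)]
        stack = SlabStack(D2O, slabs, D2O)
        np.testing.assert_allclose(
            parratt_reflectivity(stack, q).R,
            parratt_reflectivity(stack.reversed(), q).R,
            rtol=1e-10,
        )

    def test_thin_slab_roughness_triggers_validity_warning(self):
        stack = SlabStack(SI, [Slab(6.0, 4e-6, roughness=4.0)], D2O)
        with pytest.warns(UserWarning, match="roughness"):
            parratt_reflectivity(stack, np.array([0.05]))


class TestBorn:
    def test_sharp_interface_equals_fresnel_exactly(self):
        prof = make_slab_profile([(20.0, SI)], bin_width=0.5, fronting=SI, backing=D2O)
        q = np.linspace(0.02, 0.3, 100)
        born = born_reflectivity(prof, q)
        r, _ = fresnel_interface(q, SI, D2O)
        np.testing.assert_allclose(born.R, np.abs(r) ** 2, rtol=1e-10)

    def test_weak_contrast_high_q_agrees_with_parratt(self):
        prof = make_slab_profile(
            [(50.0, 0.2e-6)], bin_width=0.5, fronting=0.0, backing=0.1e-6
        )
        qc = critical_q(SldValue(0.0), SldValue(0.1e-6))
        q = np.linspace(10 * qc, 0.3, 100)
        born = born_reflectivity(prof, q).R
        exact = parratt_reflectivity(profile_to_slabs(prof, 1e-12), q).R
        np.testing.assert_allclose(born, exact, rtol=0.05)

    def test_invalid_region_is_flagged(self):
        prof = make_slab_profile([(20.0, SI)], bin_width=0.5, fronting=SI, backing=D2O)
        q = np.linspace(0.005, 0.05, 50)
        born = born_reflectivity(prof, q)
        qc = born.metadata["invalid_below_q"]
        assert qc == pytest.approx(QC_SI_D2O, rel=1e-6)
        assert np.any(born.R[q < qc] > 1.0)  # the documented failure mode

    def test_zero_total_contrast_rejected(self):
        prof = make_slab_profile([(20.0, 4e-6)], bin_width=0.5, fronting=D2O, backing=D2O)
        with pytest.raises(ValueError, match="contrast"):
            born_reflectivity(prof, np.array([0.1]))


class TestInstrumentEffects:
    def test_zero_resolution_is_identity(self):
        q = np.linspace(0.01, 0.3, 200)
        curve = parratt_reflectivity(SlabStack(SI, [], D2O), q)
        out = smear_resolution(curve, 0.0)
        np.testing.assert_array_equal(out.R, curve.R)

    def test_surf_resolution_lowers_contrast_of_fringes(self):
        q = np.linspace(0.01, 0.3, 1000)
        curve = parratt_reflectivity(SlabStack(SI, [Slab(50.0, 4e-6)], D2O), q)
        smeared = smear_resolution(curve, 0.035)
        # fringes persist but their log-contrast is reduced
        span = slice(400, 900)
        raw = np.ptp(np.log10(curve.R[span]))
        sm = np.ptp(np.log10(smeared.R[span]))
        assert sm < raw
        assert smeared.metadata["dq_over_q"] == 0.035

    def test_smearing_conserves_integrated_peak_area(self):
        """A Δλ/λ = 10% Gaussian kernel lowers a Bragg-like peak but conserves
        its integrated area over ±5 FWHM within 1%."""
        q0, height, width = 0.095, 1e-3, 0.001
        q = np.linspace(0.05, 0.14, 6001)
        base = 1e-6
        R = base + height * np.exp(-0.5 * ((q - q0) / width) ** 2)
        curve = ReflectivityCurve(q, R)
        smeared = smear_resolution(curve, 0.10)
        fwhm = 0.10 * q0
        win = (q > q0 - 5 * fwhm) & (q < q0 + 5 * fwhm)
        area_raw = np.trapezoid(curve.R[win] - base, q[win])
        area_sm = np.trapezoid(smeared.R[win] - base, q[win])
        assert smeared.R.max() < curve.R.max()
        assert area_sm == pytest.approx(area_raw, rel=0.01)

    def test_scale_and_background(self):
        q = np.linspace(0.005, 0.3, 300)
        curve = parratt_reflectivity(SlabStack(SI, [], D2O), q)
        ident = apply_scale_background(curve, 1.0, 0.0)
        np.testing.assert_array_equal(ident.R, curve.R)
        shifted = apply_scale_background(curve, 1.0, 1e-4)
        np.testing.assert_allclose(shifted.R, curve.R + 1e-4)
        # the background dominates the high-Q plateau
        assert shifted.R[-1] == pytest.approx(1e-4, rel=0.01)
        # a 0.9 normalization error is visible on the total-reflection plateau
        scaled = apply_scale_background(curve, 0.9, 0.0)
        plateau = q < 0.9 * QC_SI_D2O
        np.testing.assert_allclose(scaled.R[plateau], 0.9, atol=1e-12)


class TestIncoherentAveraging:
    def test_mean_of_identical_curves_is_identity(self):
        q = np.linspace(0.01, 0.3, 50)
        curve = parratt_reflectivity(SlabStack(SI, [], D2O), q)
        out = incoherent_mean([curve, curve, curve])
        np.testing.assert_allclose(out.R, curve.R)

    def test_mean_is_bounded_by_ensemble_envelope(self, unit_cell):
        q = np.linspace(0.05, 0.25, 400)
        ens = jitter_ensemble(unit_cell, 8, DisorderSpec(3.0, n_realizations=8, seed=3))
        curves = [reflect(p, q) for p in ens]
        mean = incoherent_mean(curves)
        lo = np.min([c.R for c in curves], axis=0)
        hi = np.max([c.R for c in curves], axis=0)
        assert np.all(mean.R >= lo - 1e-15)
        assert np.all(mean.R <= hi + 1e-15)

    def test_disorder_damps_second_order_bragg_more(self, unit_cell):
        """Interlamellar disorder leaves the first Bragg peak but suppresses the
        second-order peak contrast, Debye–Waller-like."""
        q = np.linspace(0.05, 0.25, 2000)
        ordered = smear_resolution(reflect(tile_unit_cell(unit_cell, 12), q), 0.03)
        ens = jitter_ensemble(
            unit_cell, 12, DisorderSpec(3.0, n_realizations=32, seed=9)
        )
        mean = smear_resolution(
            incoherent_mean([reflect(p, q) for p in ens]), 0.03
        )

        def order2_contrast(curve):
            band = (q > 0.16) & (q < 0.22)  # around Q2 = 2·2π/66 ≈ 0.19
            return np.log10(curve.R[band].max()) - np.log10(curve.R[band].min())

        assert order2_contrast(mean) < order2_contrast(ordered)


class TestBraggLocation:
    def test_lamellar_stack_first_peak_at_unit_cell_spacing(self, unit_cell):
        q = np.linspace(0.03, 0.3, 3000)
        tiled = tile_unit_cell(unit_cell, 36)
        tiled.fronting = SI
        curve = smear_resolution(reflect(tiled, q), 0.05)
        peaks = locate_bragg_peaks(curve, q_min=0.05)
        assert peaks, "expected at least one Bragg peak"
        d = peaks[0][1]
        assert d == pytest.approx(66.0, abs=1.0)

    def test_featureless_fresnel_curve_has_no_peaks(self):
        q = np.linspace(0.02, 0.3, 500)
        curve = parratt_reflectivity(SlabStack(SI, [], D2O), q)
        assert locate_bragg_peaks(curve, q_min=0.05) == []

    def test_asymmetric_gaps_add_half_order_peak(self):
        """Alternating unequal water layers double the lattice constant: an
        extra peak appears at half the first-order Bragg position."""
        q = np.linspace(0.02, 0.3, 4000)
        bil = [(6.5, 1.8e-6), (11.0, -0.4e-6), (6.5, 1.8e-6)]
        unit = make_slab_profile(
            [(16.0, D2O)] + bil + [(52.0, D2O)] + bil + [(16.0, D2O)],
            bin_width=0.5,
            backing=D2O,
        )
        tiled = tile_unit_cell(unit, 18, allow_asymmetry=True)
        tiled.fronting = SI
        curve = smear_resolution(reflect(tiled, q), 0.05)
        peaks = locate_bragg_peaks(curve, q_min=0.03)
        assert len(peaks) >= 2
        ratio = peaks[0][0] / peaks[1][0]
        assert ratio == pytest.approx(0.50, abs=0.02)
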