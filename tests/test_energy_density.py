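"""The tensor engine: amplitudes, regularization, fields, gauges, slices."""

from dataclasses import replace

import numpy as np
import pytest

from mpacdens.energy_density import (
    EnergyDensityEngine,
    a_gauge_shift,
    compute_amplitudes,
    correlation_bar_from_tensors,
    correlation_density,
    exchange_density,
    integrate_field,
    interaction_density,
    pair_density_slice,
    regularize_amplitudes,
)
from mpacdens.grids import build_grid
from mpacdens.oracles import conventional_mo_eris, mp2_energies
from mpacdens.reference import MoleculeSpec, build_reference


class TestAmplitudes:
    def test_permutational_symmetry(self, ne_ref):
        amps = compute_amplitudes(ne_ref)
        np.testing.assert_allclose(
            amps.T, amps.T.transpose(1, 0, 3, 2), atol=1e-12
        )

    def test_amplitudes_match_conventional_integral_contraction(self, he_min_ref):
        """T_{ijab} = (ia|jb)/Delta, checked against four-center integrals."""
        amps = compute_amplitudes(he_min_ref)
        eri = conventional_mo_eris(he_min_ref)
        o = he_min_ref.n_occ
        ovov_conv = eri[:o, o:, :o, o:].transpose(0, 2, 1, 3)
        T_conv = ovov_conv / amps.delta
        # agreement limited only by the density-fitting error of (ia|jb)
        assert np.abs(amps.T - T_conv).max() < 5e-5

    def test_energy_from_amplitudes_matches_mp2_oracle(self, be_engine):
        split = mp2_energies(be_engine.ref)
        assert be_engine.amps.channel_energy("total") == pytest.approx(
            split["total"], abs=1e-10
        )

    def test_regularizer_limits_and_bounds(self, he_engine):
        amps = he_engine.amps
        zero = regularize_amplitudes(amps, 0.0)
        assert np.all(zero.T * zero.regularizer == 0.0)
        tight = regularize_amplitudes(amps, 50.0)
        assert np.abs(tight.T * tight.regularizer - amps.T).max() < 1e-12
        mid = regularize_amplitudes(amps, 1.4)
        reg = mid.regularizer
        # mathematically in [0, 1); rounds to exactly 1.0 for core excitations
        assert np.all((reg >= 0.0) & (reg <= 1.0))
        assert reg.min() < 1.0
        assert np.all(np.abs(mid.T * reg) <= np.abs(amps.T) + 1e-300)

    def test_negative_kappa_rejected(self, he_engine):
        with pytest.raises(ValueError):
            regularize_amplitudes(he_engine.amps, -1.0)

    def test_regularized_energy_monotone_in_kappa(self, he_engine):
        energies = [
            replace(he_engine.amps, kappa=k).channel_energy("total")
            for k in (0.5, 1.0, 1.4, 2.0, 4.0)
        ]
        assert np.all(np.diff(energies) <= 1e-14)  # nonincreasing


class TestFields:
    def test_dual_route_identity_improves_with_grid(self, he_ref):
        rels = []
        for level in (0, 2):
            grid = build_grid(he_ref.mol, level)
            eng = EnergyDensityEngine(he_ref, grid)
            e_grid = float(np.dot(grid.weights, eng.correlation_bar("total", 2.0)))
            e_tens = replace(eng.amps, kappa=2.0).channel_energy("total")
            rels.append(abs(e_grid - e_tens) / abs(e_tens))
        assert rels[-1] < 1e-6
        assert rels[-1] < rels[0]

    def test_channel_additivity_pointwise_and_integrated(self, be_engine):
        tot = be_engine.correlation_bar("total", 2.0)
        os_ = be_engine.correlation_bar("os", 2.0)
        ss = be_engine.correlation_bar("ss", 2.0)
        np.testing.assert_allclose(os_ + ss, tot, atol=1e-10)

    def test_helium_ss_channel_vanishes(self, he_engine):
        """Two electrons in one spatial orbital carry no same-spin pairs."""
        ss = he_engine.correlation_bar("ss", np.inf)
        assert np.abs(ss).max() < 1e-14
        e_os = float(np.dot(he_engine.grid.weights,
                            he_engine.correlation_bar("os", np.inf)))
        assert e_os == pytest.approx(mp2_energies(he_engine.ref)["total"],
                                     rel=1e-8)

    def test_field_values_finite_with_small_far_tail(self, ne_engine):
        f = correlation_density(ne_engine.ref, ne_engine.amps,
                                ne_engine.grid, "total", engine=ne_engine)
        assert np.all(np.isfinite(f.values))
        r = np.linalg.norm(ne_engine.grid.points, axis=1)
        far = r > 10.0
        # per-particle values are floored to zero where rho underflows
        assert np.abs(f.values[far] * f.rho[far]).max() < 1e-10

    def test_exchange_integrates_to_hf_exchange(self, h2_engine):
        fx = exchange_density(h2_engine.ref, h2_engine.grid, engine=h2_engine)
        ex = integrate_field(fx)
        assert ex == pytest.approx(h2_engine.ref.e_exchange, rel=1e-5)

    def test_exchange_nonpositive_and_single_orbital_identity(self, he_engine):
        """He: e_x = -(1/2) x Coulomb self-energy of the density."""
        fx = exchange_density(he_engine.ref, he_engine.grid, engine=he_engine)
        assert np.max(fx.values) <= 1e-12
        ex = integrate_field(fx)
        # (rho|rho) of the doubly occupied orbital from the fitted factors
        b_oo = he_engine.ref.b_mo[:1, :1, :]
        J_rho = 4.0 * float(np.einsum("ijP,klP->", b_oo, b_oo))
        assert ex == pytest.approx(-J_rho / 4.0, rel=1e-5)  # = -(1/2) E_Hartree

    def test_integrate_field_linearity_and_normalization(self, he_engine):
        f = correlation_density(he_engine.ref, he_engine.amps,
                                he_engine.grid, "total", engine=he_engine)
        zero = replace(f, values=np.zeros_like(f.values))
        assert integrate_field(zero) == 0.0
        const = replace(f, values=np.ones_like(f.values) * 0.25)
        assert integrate_field(const) == pytest.approx(
            0.25 * he_engine.ref.mol.n_electrons, rel=1e-6
        )

    def test_density_weighted_conversion_roundtrip(self, he_engine):
        f = correlation_density(he_engine.ref, he_engine.amps,
                                he_engine.grid, "total", engine=he_engine)
        fw = f.density_weighted()
        np.testing.assert_allclose(fw.values, f.values * f.rho, atol=1e-300)
        back = fw.per_particle()
        mask = f.rho > 1e-12
        np.testing.assert_allclose(back.values[mask], f.values[mask], rtol=1e-12)


class TestGaugeShift:
    def test_identity_at_zero(self, ne_engine):
        f = correlation_density(ne_engine.ref, ne_engine.amps,
                                ne_engine.grid, "total", engine=ne_engine)
        assert a_gauge_shift(f, 0.0, ne_engine.orbital_values()) is f

    @pytest.mark.parametrize("a", [-0.1, 0.1])
    def test_shift_preserves_integrated_energy(self, ne_engine, a):
        f = correlation_density(ne_engine.ref, ne_engine.amps,
                                ne_engine.grid, "total", engine=ne_engine)
        e0 = integrate_field(f)
        fa = a_gauge_shift(f, a, ne_engine.orbital_values())
        assert abs(integrate_field(fa) - e0) < 1e-4 * abs(e0)

    def test_shift_term_changes_sign_across_shells(self, ne_engine):
        f = correlation_density(ne_engine.ref, ne_engine.amps,
                                ne_engine.grid, "total", engine=ne_engine)
        fa = a_gauge_shift(f, 0.1, ne_engine.orbital_values())
        shift = fa.values - f.values
        mask = f.rho > 1e-6
        assert (shift[mask] > 1e-10).any() and (shift[mask] < -1e-10).any()


class TestScalingConsistency:
    @pytest.mark.parametrize("lam", [0.5, 2.0])
    def test_uniform_scaling_identity(self, he_engine, rng, lam):
        """e_c on lambda-scaled tensors at r equals original e_c at lambda*r.

        phi -> lam^{3/2} phi(lam r), integrals -> lam (ia|jb),
        Delta -> lam^2 Delta, potentials -> lam v(lam r).
        """
        eng = he_engine
        o = eng.ref.n_occ
        pts = rng.normal(size=(25, 3))
        spts = lam * pts
        ov = eng.orbital_values(spts)
        v_ov = eng.pair_potentials(spts)
        amps = eng.amps
        # original route evaluated at lambda*r
        ebar_orig = correlation_bar_from_tensors(
            amps.ovov, amps.delta, ov.mo[:, :o], ov.mo[:, o:], v_ov
        )
        rho_orig = ov.rho
        # scaled tensors evaluated at r
        ebar_scaled = correlation_bar_from_tensors(
            lam * amps.ovov,
            lam ** 2 * amps.delta,
            lam ** 1.5 * ov.mo[:, :o],
            lam ** 1.5 * ov.mo[:, o:],
            lam * v_ov,
        )
        rho_scaled = lam ** 3 * rho_orig
        e_orig = ebar_orig / rho_orig
        e_scaled = ebar_scaled / rho_scaled
        np.testing.assert_allclose(e_scaled, e_orig, atol=1e-8)


class TestPairDensity:
    def test_slice_carries_no_net_charge(self, he_engine):
        """int P2(r0, r') dr' = 0 (occ x virt overlaps vanish)."""
        grid = he_engine.grid
        sl = pair_density_slice(he_engine, np.array([0.3, 0.1, -0.2]),
                                grid.points, kappa=2.0)
        assert abs(float(np.dot(grid.weights, sl.values))) < 1e-6

    def test_electrostatic_self_consistency(self, he_engine, rng):
        """(1/4) int P2(r0,r')/|r0-r'| dr' reproduces ebar_c(r0)."""
        grid = he_engine.grid
        for _ in range(5):
            r0 = rng.normal(size=3) * 0.7
            sl = pair_density_slice(he_engine, r0, grid.points, kappa=2.0)
            dist = np.linalg.norm(grid.points - r0, axis=1)
            dist = np.maximum(dist, 1e-10)
            lhs = 0.25 * float(np.dot(grid.weights, sl.values / dist))
            rhs = float(he_engine.correlation_bar("total", 2.0,
                                                  points=r0.reshape(1, 3))[0])
            assert lhs == pytest.approx(rhs, rel=2e-2, abs=1e-7)


class TestInteractionPairDensity:
    def test_dispersion_polarization_pattern_in_he2(self):
        """Fix the reference electron near one He; around the far atom the
        interaction pair-density correction shows a negative lobe on the
        near side and a positive lobe beyond (the dipolar polarization
        responsible for dispersion binding)."""
        from mpacdens.systems import get_fixture, run_interaction

        res = run_interaction(get_fixture("he2_5.6"), method="MP2")
        r0 = np.array([0.0, 0.0, 0.7])
        z = np.linspace(3.5, 8.0, 60)
        probes = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        dp2 = pair_density_slice(res["complex_engine"], r0, probes).values.copy()
        for eng in res["fragment_engines"]:
            dp2 -= pair_density_slice(eng, r0, probes).values
        near_side = (z > 4.3) & (z < 5.6)
        beyond = (z > 5.6) & (z < 7.0)
        assert dp2[near_side].mean() < 0
        assert dp2[beyond].mean() > 0


class TestInteraction:
    def test_fragment_mismatch_rejected(self, he_engine, h2_engine):
        with pytest.raises(ValueError, match="fragment atoms"):
            interaction_density(h2_engine, [he_engine], np.zeros((1, 3)))

    def test_noninteracting_dimer_is_superposition(self):
        """ebar_c of two He at 50 bohr equals the monomer sum pointwise."""
        R = 50.0
        cplx = build_reference(MoleculeSpec(
            symbols=("He", "He"), coords=((0, 0, 0), (0, 0, R)), label="He2far"))
        frags = [
            build_reference(MoleculeSpec(symbols=("He",), coords=((0, 0, 0),))),
            build_reference(MoleculeSpec(symbols=("He",), coords=((0, 0, R),))),
        ]
        z = np.linspace(-2.0, R + 2.0, 40)
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        delta = interaction_density(
            EnergyDensityEngine(cplx), [EnergyDensityEngine(f) for f in frags],
            pts, kappa=np.inf,
        )
        assert np.abs(delta).max() < 1e-8
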