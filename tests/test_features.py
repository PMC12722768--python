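"""Descriptor stack: closed forms, limits, invariances, table contract."""

import numpy as np
import pytest

from mpacdens.features import (
    ML2_FEATURES,
    MLS2_FEATURES,
    alpha_kinetic,
    assemble_feature_table,
    fod_feature,
    normalized_correlation_features,
    reduced_gradient,
    reduced_laplacian,
    spin_polarization,
    wigner_seitz,
)
from mpacdens.grids import build_grid
from mpacdens.orbitals import evaluate_orbitals_on_points
from mpacdens.reference import MoleculeSpec, build_reference


class TestClosedForms:
    def test_uniform_density_limits(self):
        """Flat density: s = 0, q = 0, alpha = 1 by construction."""
        rho = np.array([0.5, 1.0, 2.0])
        zero_grad = np.zeros((3, 3))
        assert np.all(reduced_gradient(rho, zero_grad) == 0.0)
        assert np.all(reduced_laplacian(rho, np.zeros(3)) == 0.0)
        tau_unif = 0.3 * (3 * np.pi ** 2) ** (2 / 3) * rho ** (5 / 3)
        np.testing.assert_allclose(
            alpha_kinetic(rho, zero_grad, tau_unif), 1.0, atol=1e-10
        )

    def test_wigner_seitz_closed_form(self):
        assert wigner_seitz(np.array([3.0 / (4.0 * np.pi)]))[0] == pytest.approx(1.0)

    def test_spin_polarization_bounds_and_cases(self):
        assert spin_polarization(np.array([1.0]), np.array([1.0]))[0] == 0.0
        assert spin_polarization(np.array([1.0]), np.array([0.0]))[0] == 1.0

    def test_scaling_invariance_of_dimensionless_features(self, rng):
        """s, q, alpha are invariant under rho -> lam^3 rho(lam r)."""
        lam = 1.7
        rho = rng.uniform(0.1, 2.0, 20)
        grad = rng.normal(size=(20, 3))
        lap = rng.normal(size=20)
        tau = np.einsum("gx,gx->g", grad, grad) / (8 * rho) + rng.uniform(0.01, 1, 20)
        s0, q0 = reduced_gradient(rho, grad), reduced_laplacian(rho, lap)
        a0 = alpha_kinetic(rho, grad, tau)
        rho_s, grad_s, lap_s, tau_s = (
            lam ** 3 * rho, lam ** 4 * grad, lam ** 5 * lap, lam ** 5 * tau,
        )
        np.testing.assert_allclose(reduced_gradient(rho_s, grad_s), s0, rtol=1e-12)
        np.testing.assert_allclose(reduced_laplacian(rho_s, lap_s), q0, rtol=1e-12)
        np.testing.assert_allclose(alpha_kinetic(rho_s, grad_s, tau_s), a0, rtol=1e-12)


class TestAlphaOnSystems:
    def test_single_orbital_region_iso_orbital_limit(self, he_engine):
        """He: tau = tau_W everywhere, so alpha vanishes."""
        ov = he_engine.orbital_values()
        alpha = alpha_kinetic(ov.rho, ov.rho_grad, ov.tau)
        mask = ov.rho > 1e-8
        assert np.max(alpha[mask]) < 1e-6

    def test_shell_structure_gives_positive_alpha(self, ne_engine):
        ov = ne_engine.orbital_values()
        alpha = alpha_kinetic(ov.rho, ov.rho_grad, ov.tau)
        assert np.percentile(alpha[ov.rho > 1e-4], 90) > 0.1


class TestFOD:
    def test_vanishes_at_zero_temperature_limit(self, he_engine):
        f = fod_feature(he_engine.ref, he_engine.orbital_values(), 1.0)
        assert np.abs(f).max() < 1e-12

    def test_grows_with_temperature(self, be_engine):
        ov = be_engine.orbital_values()
        w = be_engine.grid.weights * ov.rho
        f1 = fod_feature(be_engine.ref, ov, 10_000.0)
        f2 = fod_feature(be_engine.ref, ov, 25_000.0)
        assert np.dot(w, f2) > np.dot(w, f1) >= 0.0

    def test_stretched_bond_flags_static_correlation(self):
        """Restricted H2 at 5 bohr: FOD far above the equilibrium value."""
        vals = []
        for R in (1.401, 5.0):
            ref = build_reference(MoleculeSpec(
                symbols=("H", "H"), coords=((0, 0, 0), (0, 0, R)),
                label=f"H2@{R}"))
            grid = build_grid(ref.mol, 0)
            ov = evaluate_orbitals_on_points(ref, grid.points)
            f = fod_feature(ref, ov, 10_000.0)
            vals.append(np.dot(grid.weights * ov.rho, f))
        assert vals[1] > 10.0 * vals[0]


class TestNormalizedCorrelation:
    def test_zero_field_maps_to_zero(self):
        out = normalized_correlation_features(
            np.zeros(4), np.full(4, -0.5), np.ones(4))
        assert np.all(out == 0.0)

    def test_two_electron_identity_xos_equals_xc(self, he_ref):
        grid = build_grid(he_ref.mol, 1)
        table = assemble_feature_table(he_ref, grid, MLS2_FEATURES)
        np.testing.assert_allclose(table.column("xos"), table.column("xc"),
                                   atol=1e-12)


class TestAssembly:
    def test_ml2_columns_exact(self, he_ref):
        grid = build_grid(he_ref.mol, 0)
        table = assemble_feature_table(he_ref, grid, ML2_FEATURES)
        assert table.columns == ("s", "q", "alpha", "f1", "f2")
        assert table.values.shape[1] == 5
        assert np.all(np.isfinite(table.values))

    def test_mls2_adds_density_and_ratio_columns(self, he_ref):
        grid = build_grid(he_ref.mol, 0)
        table = assemble_feature_table(he_ref, grid, MLS2_FEATURES)
        assert set(table.columns) - set(ML2_FEATURES) == {"rs", "xc", "xos"}

    def test_deterministic_bitwise(self, he_ref):
        grid = build_grid(he_ref.mol, 0)
        t1 = assemble_feature_table(he_ref, grid, ML2_FEATURES)
        t2 = assemble_feature_table(he_ref, grid, ML2_FEATURES)
        assert np.array_equal(t1.values, t2.values)

    def test_zeta_closed_shell_is_zero(self, he_ref):
        grid = build_grid(he_ref.mol, 0)
        table = assemble_feature_table(he_ref, grid, ("s", "zeta"))
        assert np.all(table.column("zeta") == 0.0)

    def test_invariant_bounds(self, ne_engine):
        table = assemble_feature_table(
            ne_engine.ref, ne_engine.grid, MLS2_FEATURES, engine=ne_engine)
        assert np.all(table.column("s") >= 0)
        assert np.all(table.column("alpha") >= 0)
        assert np.all(table.column("rs") > 0)
        assert np.all((table.column("f1") >= 0) & (table.column("f1") <= 1))
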