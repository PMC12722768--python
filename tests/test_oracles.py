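"""Brute-force oracles against the optimized engine and closed forms."""

import numpy as np
import pytest

from mpacdens.energy_density import EnergyDensityEngine
from mpacdens.oracles import (
    ci_correlation_energy,
    conventional_mo_eris,
    mp2_energies,
    oracle_energies,
    spin_orbital_oracle_density,
)
from mpacdens.reference import MoleculeSpec


class TestMP2Split:
    def test_decomposition_identity(self, ne_ref):
        split = mp2_energies(ne_ref)
        assert split["os"] + split["ss"] == pytest.approx(split["total"], abs=1e-12)

    def test_two_electron_system_has_no_same_spin_pairs(self, he_ref):
        split = mp2_energies(he_ref)
        assert split["ss"] == pytest.approx(0.0, abs=1e-14)
        assert split["os"] < 0

    def test_one_electron_correlation_vanishes(self):
        res = oracle_energies(
            MoleculeSpec(symbols=("H",), coords=((0, 0, 0),), label="H")
        )
        assert res == {"total": 0.0, "os": 0.0, "ss": 0.0}

    def test_df_against_conventional_integrals(self, he_min_ref):
        df = mp2_energies(he_min_ref, use_df=True)
        conv = mp2_energies(he_min_ref, use_df=False)
        assert df["total"] == pytest.approx(conv["total"], abs=2e-5)


class TestSpinOrbitalOracle:
    @pytest.mark.parametrize("channel", ["total", "os", "ss"])
    @pytest.mark.parametrize("kappa", [np.inf, 2.0])
    def test_matches_engine_on_shared_integrals(self, he_min_ref, h2_min_ref,
                                                rng, channel, kappa):
        """Independent spin-orbital loops vs the closed-shell engine.

        On the same fitted integrals the two routes must agree to machine
        precision: this pins the closed-shell spin prefactors.
        """
        pts = rng.normal(size=(25, 3))
        for ref in (he_min_ref, h2_min_ref):
            eng = EnergyDensityEngine(ref)
            oracle = spin_orbital_oracle_density(ref, pts, kappa=kappa,
                                                 channel=channel, use_df=True)
            engine = eng.correlation_bar(channel, kappa, points=pts)
            np.testing.assert_allclose(oracle, engine, atol=1e-12)

    def test_conventional_route_within_fitting_error(self, he_min_ref, rng):
        """Fully independent route (4-center integrals, exact potentials)."""
        from mpacdens import integrals

        pts = rng.normal(size=(25, 3))
        eng = EnergyDensityEngine(he_min_ref)
        oracle = spin_orbital_oracle_density(he_min_ref, pts, channel="total")
        engine = eng.correlation_bar("total", np.inf, points=pts)
        # bound the discrepancy by the measured DF integral error
        eri = integrals.eri_conventional(he_min_ref.basis_set)
        b = integrals.int3c2e(he_min_ref.basis_set, he_min_ref.aux_basis_set)
        b = b @ he_min_ref.aux_metric_inv_sqrt
        df_err = np.abs(np.einsum("mnP,lsP->mnls", b, b) - eri).max()
        assert np.abs(oracle - engine).max() < 50.0 * df_err

    def test_one_electron_field_identically_zero(self, h_atom_ref, rng):
        pts = rng.normal(size=(50, 3))
        field = spin_orbital_oracle_density(h_atom_ref, pts, kappa=2.0)
        assert np.abs(field).max() == 0.0

    def test_pair_class_partition(self, h2_min_ref, rng):
        """os and ss pair-class loops add up to the total."""
        pts = rng.normal(size=(20, 3))
        tot = spin_orbital_oracle_density(h2_min_ref, pts, channel="total")
        os_ = spin_orbital_oracle_density(h2_min_ref, pts, channel="os")
        ss = spin_orbital_oracle_density(h2_min_ref, pts, channel="ss")
        np.testing.assert_allclose(os_ + ss, tot, atol=1e-14)

    def test_size_guard(self, ne_ref):
        with pytest.raises(ValueError, match="guard"):
            spin_orbital_oracle_density(ne_ref, np.zeros((1, 3)))


class TestCI:
    def test_two_orbital_ci_matches_explicit_matrix(self, he_min_ref):
        """He in a 2-orbital window vs an explicit 4-determinant matrix.

        One alpha and one beta electron in two spatial orbitals: the four
        determinants |a b| give a Hamiltonian small enough to write down
        term by term (no shared code with the CI solver's matrix-element
        machinery beyond the integrals themselves).
        """
        res = ci_correlation_energy(he_min_ref, n_active=2)
        h, eri = _mo_h_and_eri(he_min_ref)
        dets = [(0, 0), (0, 1), (1, 0), (1, 1)]  # (alpha orb, beta orb)

        def hval(d1, d2):
            a1, b1 = d1
            a2, b2 = d2
            if a1 == a2 and b1 == b2:
                return h[a1, a1] + h[b1, b1] + eri[a1, a1, b1, b1]
            if a1 != a2 and b1 == b2:  # alpha single
                return h[a1, a2] + eri[a1, a2, b1, b1]
            if a1 == a2 and b1 != b2:  # beta single
                return h[b1, b2] + eri[a1, a1, b1, b2]
            return eri[a1, a2, b1, b2]  # opposite-spin double

        H = np.array([[hval(d1, d2) for d2 in dets] for d1 in dets])
        e0 = np.linalg.eigvalsh(H)[0] + he_min_ref.mol.nuclear_repulsion
        assert res.e_tot == pytest.approx(e0, abs=1e-10)

    def test_ci_below_hf_and_mp2_reasonable(self, he_ref):
        res = ci_correlation_energy(he_ref)
        assert res.e_corr < 0
        mp2 = mp2_energies(he_ref)["total"]
        # CI recovers more correlation than MP2 for He and stays same order
        assert res.e_corr < mp2 < 0.5 * res.e_corr

    def test_determinant_guard(self, ne_ref):
        with pytest.raises(ValueError, match="guard"):
            ci_correlation_energy(ne_ref, max_determinants=10)


def _mo_h_and_eri(ref):
    from mpacdens import integrals

    h_ao = integrals.kinetic(ref.basis_set) + integrals.nuclear_attraction(
        ref.basis_set, ref.mol.charges, ref.mol.coords_array
    )
    C = ref.mo_coeff
    return C.T @ h_ao @ C, conventional_mo_eris(ref)
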