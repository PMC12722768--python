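"""Independent brute-force oracles.

Everything here is deliberately naive: conventional four-center integrals,
explicit spin-orbital loops, determinant-space configuration interaction.
The optimized density-fitted closed-shell engine is validated against these
paths; none of them is used in production evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from . import integrals
from .reference import MoleculeSpec, SCFReference, build_reference

__all__ = [
    "conventional_mo_eris",
    "mp2_energies",
    "spin_orbital_oracle_density",
    "ci_correlation_energy",
    "oracle_energies",
]


def conventional_mo_eris(ref: SCFReference, max_nbf: int = 72) -> np.ndarray:
    """(pq|rs) in the MO basis from conventional four-center integrals."""
    eri_ao = integrals.eri_conventional(ref.basis_set, max_nbf=max_nbf)
    C = ref.mo_coeff
    tmp = np.einsum("mnls,mp->pnls", eri_ao, C, optimize=True)
    tmp = np.einsum("pnls,nq->pqls", tmp, C, optimize=True)
    tmp = np.einsum("pqls,lr->pqrs", tmp, C, optimize=True)
    return np.einsum("pqrs,st->pqrt", tmp, C, optimize=True)


def mp2_energies(
    ref: SCFReference, kappa: float = np.inf, use_df: bool = True
) -> dict[str, float]:
    """Standard (regularized) MP2 correlation energy and os/ss split.

    Closed-shell spatial-orbital formulas:
        E_os = -sum (ia|jb)^2 * g / Delta
        E_ss = -sum (ia|jb)[(ia|jb) - (ib|ja)] * g / Delta
    with g the kappa multiplier (1 - exp(-kappa Delta))^2.
    """
    o = ref.n_occ
    eps = ref.mo_energy
    if use_df:
        b_ov = ref.b_mo[:o, o:, :]
        ovov = np.einsum("iaP,jbP->ijab", b_ov, b_ov, optimize=True)
    else:
        mo_eri = conventional_mo_eris(ref)
        ovov = mo_eri[:o, o:, :o, o:].transpose(0, 2, 1, 3)
    delta = (
        eps[None, None, o:, None]
        + eps[None, None, None, o:]
        - eps[:o, None, None, None]
        - eps[None, :o, None, None]
    )
    g = np.ones_like(delta) if np.isinf(kappa) else (1.0 - np.exp(-kappa * delta)) ** 2
    e_os = -float(np.einsum("ijab,ijab->", ovov, ovov * g / delta))
    e_ss = -float(
        np.einsum("ijab,ijab->", ovov, (ovov - ovov.transpose(0, 1, 3, 2)) * g / delta)
    )
    return {"os": e_os, "ss": e_ss, "total": e_os + e_ss}


# --- spin-orbital brute force --------------------------------------------

def spin_orbital_oracle_density(
    ref: SCFReference,
    points: np.ndarray,
    kappa: float = np.inf,
    channel: str = "total",
    max_spin_orbitals: int = 22,
    use_df: bool = False,
) -> np.ndarray:
    """Density-weighted correlation field by explicit spin-orbital loops.

    Accepts restricted and single-determinant open-shell (e.g. one-electron)
    references.  Returns ebar_c at the given points; identically zero for
    one-electron systems.  With use_df=False (default) conventional
    four-center integrals and exact pair potentials are used, making the
    route fully independent of the density-fitted engine; use_df=True runs
    the same naive loops on the fitted integrals, isolating the algebraic
    bookkeeping from the fitting error.
    """
    nmo = ref.mo_coeff.shape[1]
    if 2 * nmo > max_spin_orbitals:
        raise ValueError(
            f"spin-orbital oracle guard: {2 * nmo} spin orbitals > {max_spin_orbitals}"
        )
    if channel not in ("total", "os", "ss"):
        raise ValueError(f"unknown channel '{channel}'")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    npts = points.shape[0]
    n_alpha = ref.n_occ if ref.restricted else ref.n_occ
    n_beta = ref.n_occ if ref.restricted else 0
    if n_alpha + n_beta < 2:
        return np.zeros(npts)

    eps = ref.mo_energy
    C = ref.mo_coeff
    if use_df:
        mo_eri = np.einsum("pqP,rsP->pqrs", ref.b_mo, ref.b_mo, optimize=True)
        Vaux = integrals.potential_at_points(ref.aux_basis_set, points)
        Vt = Vaux @ ref.aux_metric_inv_sqrt
        Vmo = np.einsum("pqP,gP->gpq", ref.b_mo, Vt, optimize=True)
    else:
        mo_eri = conventional_mo_eris(ref)
        Vao = integrals.pair_potential_at_points(ref.basis_set, points)
        Vmo = np.einsum("mp,gmn,nq->gpq", C, Vao, C, optimize=True)
    ao = integrals.ao_values(ref.basis_set, points, deriv=0)[0]
    phi = ao @ C  # (npts, nmo)

    # spin orbitals: even index alpha, odd beta, energy ordering by spatial
    so = [(p, s) for p in range(nmo) for s in (0, 1)]
    occ = [2 * p + s for p in range(nmo) for s in (0, 1)
           if (s == 0 and p < n_alpha) or (s == 1 and p < n_beta)]
    vir = [i for i in range(2 * nmo) if i not in occ]

    def spatial(i):
        return so[i][0]

    def spin(i):
        return so[i][1]

    ebar = np.zeros(npts)
    for i in occ:
        for j in occ:
            for a in vir:
                for b in vir:
                    si, sj, sa, sb = spin(i), spin(j), spin(a), spin(b)
                    pi, pj, pa, pb = spatial(i), spatial(j), spatial(a), spatial(b)
                    d1 = (si == sa) and (sj == sb)
                    d2 = (si == sb) and (sj == sa)
                    if not (d1 or d2):
                        continue
                    g1 = mo_eri[pi, pa, pj, pb] if d1 else 0.0
                    g2 = mo_eri[pi, pb, pj, pa] if d2 else 0.0
                    gij = g1 - g2  # <ij||ab>
                    if gij == 0.0:
                        continue
                    denom = eps[pi] + eps[pj] - eps[pa] - eps[pb]
                    delta = -denom
                    reg = 1.0 if np.isinf(kappa) else (1.0 - np.exp(-kappa * delta)) ** 2
                    t = gij / denom * reg
                    is_os = si != sj
                    if channel == "os" and not is_os:
                        continue
                    if channel == "ss" and is_os:
                        continue
                    # pointwise representation of <ij||ab>
                    X = np.zeros(npts)
                    if d1:
                        X += 0.5 * (
                            phi[:, pi] * phi[:, pa] * Vmo[:, pj, pb]
                            + phi[:, pj] * phi[:, pb] * Vmo[:, pi, pa]
                        )
                    if d2:
                        X -= 0.5 * (
                            phi[:, pi] * phi[:, pb] * Vmo[:, pj, pa]
                            + phi[:, pj] * phi[:, pa] * Vmo[:, pi, pb]
                        )
                    ebar += 0.25 * t * X
    return ebar


# --- determinant configuration interaction --------------------------------

@dataclass
class CIResult:
    e_tot: float
    e_corr: float
    n_determinants: int


def ci_correlation_energy(
    ref: SCFReference,
    n_active: int | None = None,
    n_frozen: int = 0,
    max_determinants: int = 4096,
) -> CIResult:
    """Full CI (optionally in an active orbital window) by dense
    diagonalization over Slater determinants.

    Exact within the basis for two-electron systems; the package's
    high-level correlation reference for small fixtures.
    """
    from itertools import combinations

    nmo = ref.mo_coeff.shape[1]
    na = ref.n_occ - n_frozen
    nb = (ref.n_occ if ref.restricted else 0) - n_frozen
    if na < 0 or nb < 0:
        raise ValueError("frozen count exceeds occupation")
    norb = min(n_active or (nmo - n_frozen), nmo - n_frozen)

    h_full, eri_full = _mo_hamiltonian(ref)
    # fold frozen core into an effective one-body term and constant
    core = list(range(n_frozen))
    act = list(range(n_frozen, n_frozen + norb))
    e_core = ref.mol.nuclear_repulsion
    h = h_full.copy()
    for i in core:
        e_core += 2.0 * h_full[i, i]
        for j in core:
            e_core += 2.0 * eri_full[i, i, j, j] - eri_full[i, j, j, i]
    if core:
        h = h + 2.0 * np.einsum("pqii->pq", eri_full[:, :, core, :][:, :, :, core]) \
            - np.einsum("piiq->pq", eri_full[:, core, :, :][:, :, core, :])
    h = h[np.ix_(act, act)]
    eri = eri_full[np.ix_(act, act, act, act)]

    alpha_dets = list(combinations(range(norb), na))
    beta_dets = list(combinations(range(norb), nb))
    ndet = len(alpha_dets) * len(beta_dets)
    if ndet > max_determinants:
        raise ValueError(f"CI guard: {ndet} determinants > {max_determinants}")
    dets = [(a, b) for a in alpha_dets for b in beta_dets]
    H = np.zeros((ndet, ndet))
    for I in range(ndet):
        for J in range(I + 1):
            HIJ = _slater_condon(dets[I], dets[J], h, eri)
            H[I, J] = H[J, I] = HIJ
    w = eigh(H, eigvals_only=True, subset_by_index=[0, 0])
    e_tot = float(w[0] + e_core)
    return CIResult(e_tot=e_tot, e_corr=e_tot - ref.e_tot, n_determinants=ndet)


def _mo_hamiltonian(ref: SCFReference):
    basis = ref.basis_set
    mol = ref.mol
    h_ao = integrals.kinetic(basis) + integrals.nuclear_attraction(
        basis, mol.charges, mol.coords_array
    )
    C = ref.mo_coeff
    h = C.T @ h_ao @ C
    eri = conventional_mo_eris(ref)
    return h, eri


def _slater_condon(det1, det2, h, eri):
    a1, b1 = det1
    a2, b2 = det2
    da = set(a1) ^ set(a2)
    db = set(b1) ^ set(b2)
    nex = (len(da) + len(db)) // 2
    if nex > 2:
        return 0.0
    if nex == 0:
        e = sum(h[p, p] for p in a1) + sum(h[p, p] for p in b1)
        for p in a1:
            for q in a1:
                e += 0.5 * (eri[p, p, q, q] - eri[p, q, q, p])
        for p in b1:
            for q in b1:
                e += 0.5 * (eri[p, p, q, q] - eri[p, q, q, p])
        for p in a1:
            for q in b1:
                e += eri[p, p, q, q]
        return e
    if nex == 1:
        if da:
            (hole,), (part,) = (
                tuple(set(a1) - set(a2)),
                tuple(set(a2) - set(a1)),
            )
            sign = _single_phase(a1, hole, part)
            e = h[hole, part]
            for p in a1:
                if p == hole:
                    continue
                e += eri[hole, part, p, p] - eri[hole, p, p, part]
            for p in b1:
                e += eri[hole, part, p, p]
            return sign * e
        (hole,), (part,) = (
            tuple(set(b1) - set(b2)),
            tuple(set(b2) - set(b1)),
        )
        sign = _single_phase(b1, hole, part)
        e = h[hole, part]
        for p in b1:
            if p == hole:
                continue
            e += eri[hole, part, p, p] - eri[hole, p, p, part]
        for p in a1:
            e += eri[hole, part, p, p]
        return sign * e
    # nex == 2
    if len(da) == 4:  # both in alpha
        h1, h2 = sorted(set(a1) - set(a2))
        p1, p2 = sorted(set(a2) - set(a1))
        sign = _double_phase(a1, (h1, h2), (p1, p2))
        return sign * (eri[h1, p1, h2, p2] - eri[h1, p2, h2, p1])
    if len(db) == 4:  # both in beta
        h1, h2 = sorted(set(b1) - set(b2))
        p1, p2 = sorted(set(b2) - set(b1))
        sign = _double_phase(b1, (h1, h2), (p1, p2))
        return sign * (eri[h1, p1, h2, p2] - eri[h1, p2, h2, p1])
    # one alpha, one beta
    (ha,), (pa,) = tuple(set(a1) - set(a2)), tuple(set(a2) - set(a1))
    (hb,), (pb,) = tuple(set(b1) - set(b2)), tuple(set(b2) - set(b1))
    sign = _single_phase(a1, ha, pa) * _single_phase(b1, hb, pb)
    return sign * eri[ha, pa, hb, pb]


def _single_phase(det: tuple, hole: int, part: int) -> int:
    """Sign from reordering after a single hole->part substitution."""
    d = [x for x in det if x != hole]
    # position hole occupied in det, and insertion position of part
    i = det.index(hole)
    j = 0
    while j < len(d) and d[j] < part:
        j += 1
    return -1 if (i + j) % 2 else 1


def _double_phase(det: tuple, holes, parts) -> int:
    d = list(det)
    sign = 1
    for h, p in zip(holes, parts):
        i = d.index(h)
        d.pop(i)
        j = 0
        while j < len(d) and d[j] < p:
            j += 1
        d.insert(j, p)
        if (i + j) % 2:
            sign = -sign
    return sign


def ci_reference(ref: SCFReference, max_determinants: int = 4096) -> CIResult:
    """Bounded-window CI correlation reference for desk-scale training.

    Freezes all but the two highest occupied spatial orbitals and truncates
    the virtual space so the determinant count stays within the guard;
    exact (full CI) for two-electron systems.
    """
    n_frozen = max(0, ref.n_occ - 2)
    nmo = ref.mo_coeff.shape[1]
    n_active = min(11, nmo - n_frozen)  # C(11,2)^2 = 3025 determinants
    return ci_correlation_energy(
        ref, n_active=n_active, n_frozen=n_frozen,
        max_determinants=max_determinants,
    )


def oracle_energies(
    mol: MoleculeSpec, method: str = "MP2", kappa: float = np.inf
) -> dict[str, float]:
    """Scalar reference energies for a molecule.

    method: 'MP2' (total + os/ss split, optionally kappa-regularized) or
    'CI' (determinant CI correlation, small systems only).
    """
    if mol.n_electrons == 1:
        return {"total": 0.0, "os": 0.0, "ss": 0.0}
    ref = build_reference(mol)
    if method.upper() in ("MP2", "SCS-COMPONENTS"):
        return mp2_energies(ref, kappa=kappa)
    if method.upper() == "CI":
        res = ci_reference(ref)
        return {"total": res.e_corr}
    raise ValueError(f"unknown method '{method}'")
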