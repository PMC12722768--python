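"""Hartree-Fock reference states.

The correlation functionals in this package are functionals of the
Hartree-Fock density (MPAC framework): every downstream quantity --
energy densities, features, ML models -- is built from a converged
restricted HF reference.  This module owns the molecule description,
the SCF driver (density-fitted Coulomb/exchange builds, DIIS), and the
one-electron "reference" pathway used by the brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import eigh

from . import integrals
from .basis import BasisSet, make_auxiliary_basis, make_basis

__all__ = ["MoleculeSpec", "SCFReference", "build_reference", "SCFConfig"]

BOHR_PER_ANGSTROM = 1.8897259886

ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr",
]
ATOMIC_NUMBER = {s: z for z, s in enumerate(ELEMENTS)}


@dataclass(frozen=True)
class MoleculeSpec:
    """Geometry / charge / multiplicity / basis bundle identifying a system.

    Coordinates are stored in bohr.
    """

    symbols: tuple[str, ...]
    coords: tuple[tuple[float, float, float], ...]
    charge: int = 0
    multiplicity: int = 1
    basis: str = "desk-dz"
    aux_basis_corr: str = "auto"
    aux_basis_jk: str = "auto"
    label: str = ""

    def __post_init__(self):
        arr = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("coordinates must be finite")
        if len(self.symbols) == 0:
            raise ValueError("empty molecule")
        if self.n_electrons < 1:
            raise ValueError("molecule must carry at least one electron")

    @property
    def coords_array(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBER[s] for s in self.symbols], dtype=float)

    @property
    def n_electrons(self) -> int:
        return int(self.charges.sum()) - self.charge

    @property
    def nuclear_repulsion(self) -> float:
        z = self.charges
        xyz = self.coords_array
        e = 0.0
        for i in range(len(z)):
            for j in range(i):
                e += z[i] * z[j] / np.linalg.norm(xyz[i] - xyz[j])
        return e

    def with_label(self, label: str) -> "MoleculeSpec":
        return replace(self, label=label)


@dataclass
class SCFConfig:
    conv_tol: float = 1e-10  # on energy change
    conv_tol_grad: float = 1e-7  # on DIIS error norm
    max_cycle: int = 200
    metric_cutoff: float = 1e-10  # pseudo-inverse cutoff on Coulomb metric
    overlap_cutoff: float = 1e-9  # canonical orthogonalization cutoff
    level_shift: float = 0.0


@dataclass
class SCFReference:
    """Converged restricted HF solution plus DF machinery."""

    mol: MoleculeSpec
    basis_set: BasisSet
    aux_basis_set: BasisSet
    mo_coeff: np.ndarray  # (nao, nmo)
    mo_energy: np.ndarray  # (nmo,), ascending
    n_occ: int
    e_tot: float
    e_exchange: float
    converged: bool
    restricted: bool = True
    overlap: np.ndarray | None = None
    b_mo: np.ndarray | None = field(default=None, repr=False)  # (nmo,nmo,naux) J^-1/2 fitted
    aux_metric_inv_sqrt: np.ndarray | None = field(default=None, repr=False)
    metric_cond: float = np.nan

    @property
    def n_virt(self) -> int:
        return self.mo_coeff.shape[1] - self.n_occ

    @property
    def homo_lumo_gap(self) -> float:
        if self.n_virt == 0:
            return np.inf
        return float(self.mo_energy[self.n_occ] - self.mo_energy[self.n_occ - 1])

    def orthonormality_residual(self) -> float:
        smo = self.mo_coeff.T @ self.overlap @ self.mo_coeff
        return float(np.max(np.abs(smo - np.eye(smo.shape[0]))))


def _metric_inv_sqrt(J: np.ndarray, cutoff: float) -> tuple[np.ndarray, float]:
    w, U = eigh(J)
    cond = float(w[-1] / max(w[0], 1e-300))
    keep = w > cutoff * w[-1]
    Jih = (U[:, keep] / np.sqrt(w[keep])) @ U[:, keep].T
    return Jih, cond


def build_reference(
    mol: MoleculeSpec, scf_config: SCFConfig | None = None,
    dm0: np.ndarray | None = None,
) -> SCFReference:
    """Converge a restricted HF reference with density-fitted J/K.

    `dm0` optionally seeds the initial density matrix (scan continuation).
    """
    cfg = scf_config or SCFConfig()
    if mol.n_electrons % 2 != 0 or mol.multiplicity != 1:
        raise ValueError(
            "restricted pathway requires an even electron count and "
            "multiplicity 1; use the one-electron/spin-orbital oracle path "
            "for open shells"
        )
    basis = make_basis(list(mol.symbols), mol.coords_array, mol.basis)
    aux = make_auxiliary_basis(basis)
    S = integrals.overlap(basis)
    T = integrals.kinetic(basis)
    V = integrals.nuclear_attraction(basis, mol.charges, mol.coords_array)
    hcore = T + V
    eri3 = integrals.int3c2e(basis, aux)
    J2 = integrals.int2c2e(aux)
    Jih, cond = _metric_inv_sqrt(J2, cfg.metric_cutoff)
    b = eri3 @ Jih  # (nao, nao, naux): (mn|P) J^{-1/2}

    # canonical orthogonalization
    sw, su = eigh(S)
    keep = sw > cfg.overlap_cutoff * sw[-1]
    X = su[:, keep] / np.sqrt(sw[keep])

    nocc = mol.n_electrons // 2

    def fock(D):
        cP = np.einsum("mnP,mn->P", b, D)
        Jm = np.einsum("mnP,P->mn", b, cP)
        # exchange via occupied half-transform happens outside; here full D
        return Jm

    def solve(F):
        Fo = X.T @ F @ X
        w, c = eigh(Fo)
        C = X @ c
        return w, C

    w, C = solve(hcore) if dm0 is None else (None, None)
    if dm0 is None:
        Cocc = C[:, :nocc]
        D = 2.0 * Cocc @ Cocc.T
    else:
        D = dm0.copy()

    diis_F, diis_E = [], []
    e_old = 0.0
    converged = False
    e_tot = np.nan
    for cycle in range(cfg.max_cycle):
        cP = np.einsum("mnP,mn->P", b, D)
        Jm = np.einsum("mnP,P->mn", b, cP)
        # K from density eigen-decomposition (works for any symmetric D >= 0)
        dw, dU = eigh(D)
        occ_idx = dw > 1e-12
        L = dU[:, occ_idx] * np.sqrt(dw[occ_idx])  # D = L L^T
        bl = np.einsum("mnP,ni->miP", b, L)
        Km = np.einsum("miP,niP->mn", bl, bl)
        F = hcore + Jm - 0.5 * Km
        e_elec = np.einsum("mn,mn->", D, hcore) + 0.5 * np.einsum(
            "mn,mn->", D, Jm - 0.5 * Km
        )
        e_tot = e_elec + mol.nuclear_repulsion
        err = F @ D @ S - S @ D @ F
        err = X.T @ err @ X
        diis_F.append(F.copy())
        diis_E.append(err.ravel())
        if len(diis_F) > 8:
            diis_F.pop(0)
            diis_E.pop(0)
        if len(diis_F) > 1:
            nd = len(diis_F)
            Bm = np.empty((nd + 1, nd + 1))
            Bm[-1, :] = -1.0
            Bm[:, -1] = -1.0
            Bm[-1, -1] = 0.0
            for i in range(nd):
                for j in range(nd):
                    Bm[i, j] = np.dot(diis_E[i], diis_E[j])
            rhs = np.zeros(nd + 1)
            rhs[-1] = -1.0
            try:
                coef = np.linalg.solve(Bm, rhs)[:nd]
                F = sum(c * Fi for c, Fi in zip(coef, diis_F))
            except np.linalg.LinAlgError:
                pass
        if cfg.level_shift and cycle < 20:
            F = F + cfg.level_shift * (S - S @ D @ S / 2.0)
        w, C = solve(F)
        Cocc = C[:, :nocc]
        D = 2.0 * Cocc @ Cocc.T
        de = abs(e_tot - e_old)
        gnorm = np.linalg.norm(diis_E[-1])
        if de < cfg.conv_tol and gnorm < cfg.conv_tol_grad:
            converged = True
            break
        e_old = e_tot
    if not converged:
        raise RuntimeError(
            f"SCF failed to converge for '{mol.label or mol.symbols}': "
            f"last dE={de:.3e}, |err|={gnorm:.3e}"
        )
    # final energy and exchange with converged density
    cP = np.einsum("mnP,mn->P", b, D)
    Jm = np.einsum("mnP,P->mn", b, cP)
    bl = np.einsum("mnP,ni->miP", b, C[:, :nocc])
    Km = 2.0 * np.einsum("miP,niP->mn", bl, bl)
    e_x = -0.25 * np.einsum("mn,mn->", D, Km)
    e_tot = (
        np.einsum("mn,mn->", D, hcore)
        + 0.5 * np.einsum("mn,mn->", D, Jm - 0.5 * Km)
        + mol.nuclear_repulsion
    )
    # MO-basis fitted factors for all pairs
    b_mo = np.einsum("mp,mnP,nq->pqP", C, b, C, optimize=True)
    return SCFReference(
        mol=mol,
        basis_set=basis,
        aux_basis_set=aux,
        mo_coeff=C,
        mo_energy=w,
        n_occ=nocc,
        e_tot=float(e_tot),
        e_exchange=float(e_x),
        converged=converged,
        overlap=S,
        b_mo=b_mo,
        aux_metric_inv_sqrt=Jih,
        metric_cond=cond,
    )


def df_fit_pairs(ref: SCFReference, pair_block: str = "ov") -> np.ndarray:
    """Fitted pair factors for an MO pair block.

    pair_block 'ov' (occupied x virtual) or 'oo' (occupied x occupied);
    returned factors b^P satisfy (pq|rs) ~= sum_P b^P_pq b^P_rs (the
    Coulomb-metric J^{-1/2} convention).
    """
    o = ref.n_occ
    if pair_block == "ov":
        return ref.b_mo[:o, o:, :]
    if pair_block == "oo":
        return ref.b_mo[:o, :o, :]
    raise ValueError("pair_block must be 'ov' or 'oo'")


def one_electron_reference(mol: MoleculeSpec) -> SCFReference:
    """Exact single-electron 'HF' reference (no SCF needed).

    Used by the spin-orbital oracle pathway; HF is exact here and all
    correlation quantities must vanish identically.
    """
    if mol.n_electrons != 1:
        raise ValueError("one_electron_reference requires exactly one electron")
    basis = make_basis(list(mol.symbols), mol.coords_array, mol.basis)
    aux = make_auxiliary_basis(basis)
    S = integrals.overlap(basis)
    h = integrals.kinetic(basis) + integrals.nuclear_attraction(
        basis, mol.charges, mol.coords_array
    )
    sw, su = eigh(S)
    keep = sw > 1e-9 * sw[-1]
    X = su[:, keep] / np.sqrt(sw[keep])
    w, c = eigh(X.T @ h @ X)
    C = X @ c
    eri3 = integrals.int3c2e(basis, aux)
    J2 = integrals.int2c2e(aux)
    Jih, cond = _metric_inv_sqrt(J2, 1e-10)
    b = eri3 @ Jih
    b_mo = np.einsum("mp,mnP,nq->pqP", C, b, C, optimize=True)
    return SCFReference(
        mol=mol,
        basis_set=basis,
        aux_basis_set=aux,
        mo_coeff=C,
        mo_energy=w,
        n_occ=1,  # one spatial orbital singly occupied (spin handled by caller)
        e_tot=float(w[0] + mol.nuclear_repulsion),
        e_exchange=0.0,
        converged=True,
        restricted=False,
        overlap=S,
        b_mo=b_mo,
        aux_metric_inv_sqrt=Jih,
        metric_cond=cond,
    )
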