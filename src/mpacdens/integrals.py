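"""Molecular integrals over Cartesian Gaussians (McMurchie-Davidson scheme).

Provides overlap, kinetic, nuclear attraction, two-/three-/four-center
Coulomb integrals, Coulomb potentials of auxiliary functions at arbitrary
points, and orbital values/gradients/Laplacians on grids.  Everything is
plain numpy; shell-pair loops run in Python, inner work is vectorized.

Conventions: chemists' notation (pq|rs); all quantities in Hartree atomic
units.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc, gammaln

from .basis import BasisSet, Shell

__all__ = [
    "overlap",
    "kinetic",
    "nuclear_attraction",
    "eri_conventional",
    "int3c2e",
    "int2c2e",
    "potential_at_points",
    "ao_values",
]


# --- Boys function --------------------------------------------------------

def boys(nmax: int, T: np.ndarray) -> np.ndarray:
    """F_n(T) for n = 0..nmax; returns array (nmax+1, *T.shape)."""
    T = np.asarray(T, dtype=float)
    out = np.empty((nmax + 1,) + T.shape)
    small = T < 1e-13
    Ts = np.where(small, 1.0, T)
    n = nmax + 0.5
    # F_nmax via regularized lower incomplete gamma
    fn = 0.5 * np.exp(gammaln(n)) * gammainc(n, Ts) / Ts ** n
    out[nmax] = np.where(small, 1.0 / (2 * nmax + 1), fn)
    if nmax > 0:
        expT = np.exp(-T)
        for m in range(nmax - 1, -1, -1):
            out[m] = (2.0 * T * out[m + 1] + expT) / (2 * m + 1)
        # downward recursion is stable; small-T limit handled by it as well
    return out


# --- Hermite expansion coefficients --------------------------------------

def _e_coeffs(l1: int, l2: int, a: float, b: float, AB: float) -> np.ndarray:
    """E[i,j,t] connecting x^i_A x^j_B exp to Hermite Gaussians, one dim."""
    p = a + b
    mu = a * b / p
    E = np.zeros((l1 + 1, l2 + 1, l1 + l2 + 1))
    E[0, 0, 0] = np.exp(-mu * AB * AB)
    PA = -b / p * AB  # P - A with AB = A - B
    PB = a / p * AB  # P - B
    for i in range(1, l1 + 1):
        for t in range(i + 1):
            val = 0.0
            if t > 0:
                val += E[i - 1, 0, t - 1] / (2 * p)
            val += PA * E[i - 1, 0, t]
            if t + 1 <= i - 1:
                val += (t + 1) * E[i - 1, 0, t + 1]
            E[i, 0, t] = val
    for j in range(1, l2 + 1):
        for i in range(l1 + 1):
            for t in range(i + j + 1):
                val = 0.0
                if t > 0:
                    val += E[i, j - 1, t - 1] / (2 * p)
                val += PB * E[i, j - 1, t]
                if t + 1 <= i + j - 1:
                    val += (t + 1) * E[i, j - 1, t + 1]
                E[i, j, t] = val
    return E


def _pair_hermite(sh1: Shell, sh2: Shell):
    """Hermite expansion data for a (contracted) shell pair.

    Returns (p, P, H) with, per primitive pair k: p[k] total exponent,
    P[k] composite center, and H[k, comp1, comp2, t, u, v] Hermite
    coefficients including contraction coefficients and component norms.
    """
    A, B = sh1.center, sh2.center
    AB = A - B
    l1, l2 = sh1.l, sh2.l
    comps1, comps2 = sh1.components, sh2.components
    n1, n2 = sh1.component_norms(), sh2.component_norms()
    ps, Ps, Hs = [], [], []
    for a, ca in zip(sh1.exps, sh1.coefs):
        for b, cb in zip(sh2.exps, sh2.coefs):
            p = a + b
            P = (a * A + b * B) / p
            Ex = _e_coeffs(l1, l2, a, b, AB[0])
            Ey = _e_coeffs(l1, l2, a, b, AB[1])
            Ez = _e_coeffs(l1, l2, a, b, AB[2])
            H = np.zeros(
                (len(comps1), len(comps2), l1 + l2 + 1, l1 + l2 + 1, l1 + l2 + 1)
            )
            for i1, (x1, y1, z1) in enumerate(comps1):
                for i2, (x2, y2, z2) in enumerate(comps2):
                    cc = ca * cb * n1[i1] * n2[i2]
                    H[i1, i2, : x1 + x2 + 1, : y1 + y2 + 1, : z1 + z2 + 1] = (
                        cc
                        * Ex[x1, x2, : x1 + x2 + 1, None, None]
                        * Ey[y1, y2, None, : y1 + y2 + 1, None]
                        * Ez[z1, z2, None, None, : z1 + z2 + 1]
                    )
            ps.append(p)
            Ps.append(P)
            Hs.append(H)
    return np.array(ps), np.array(Ps), Hs


# --- one-electron integrals ----------------------------------------------

def overlap(basis: BasisSet) -> np.ndarray:
    n = basis.nbf
    S = np.zeros((n, n))
    sl = basis.shell_slices()
    for isl, sh1 in enumerate(basis.shells):
        for jsl in range(isl + 1):
            sh2 = basis.shells[jsl]
            S[sl[isl], sl[jsl]] = _overlap_block(sh1, sh2)
    iu = np.triu_indices(n, 1)
    S[iu] = S.T[iu]
    return S


def _overlap_block(sh1: Shell, sh2: Shell) -> np.ndarray:
    ps, Ps, Hs = _pair_hermite(sh1, sh2)
    out = np.zeros((sh1.ncart, sh2.ncart))
    for p, H in zip(ps, Hs):
        out += (np.pi / p) ** 1.5 * H[:, :, 0, 0, 0]
    return out


def kinetic(basis: BasisSet) -> np.ndarray:
    """Kinetic energy via -1/2 Laplacian acting on the ket.

    T_{mu nu} = -1/2 <mu| d2/dx2+d2/dy2+d2/dz2 |nu>; assembled from overlap
    integrals with shifted ket angular momenta using the Gaussian derivative
    identity, applied per primitive of the ket shell.
    """
    n = basis.nbf
    T = np.zeros((n, n))
    sl = basis.shell_slices()
    for isl, sh1 in enumerate(basis.shells):
        for jsl, sh2 in enumerate(basis.shells):
            T[sl[isl], sl[jsl]] = _kinetic_block(sh1, sh2)
    return T


def _kinetic_block(sh1: Shell, sh2: Shell) -> np.ndarray:
    out = np.zeros((sh1.ncart, sh2.ncart))
    comps2 = sh2.components
    n2 = sh2.component_norms()
    for b, cb in zip(sh2.exps, sh2.coefs):
        # expand Laplacian of primitive Cartesian Gaussian into shifted l
        # d2/dx2 [x^l e] = l(l-1) x^{l-2} e - 2b(2l+1) x^l e + 4b^2 x^{l+2} e
        for i2, (lx, ly, lz) in enumerate(comps2):
            terms: list[tuple[float, tuple[int, int, int]]] = []
            for axis, lax in enumerate((lx, ly, lz)):
                shift = [0, 0, 0]
                if lax >= 2:
                    shift[axis] = -2
                    terms.append(
                        (lax * (lax - 1), (lx + shift[0], ly + shift[1], lz + shift[2]))
                    )
                terms.append((-2.0 * b * (2 * lax + 1), (lx, ly, lz)))
                shift = [0, 0, 0]
                shift[axis] = 2
                terms.append((4.0 * b * b, (lx + shift[0], ly + shift[1], lz + shift[2])))
            col = np.zeros(sh1.ncart)
            for coef, lmn in terms:
                col += coef * _overlap_with_monomial(sh1, sh2.center, b, lmn)
            out[:, i2] += -0.5 * cb * n2[i2] * col
    return out


def _overlap_with_monomial(
    sh1: Shell, center2: np.ndarray, b: float, lmn: tuple[int, int, int]
) -> np.ndarray:
    """<sh1_components | x^lx y^ly z^lz e^{-b r2} at center2> (unnormalized ket)."""
    A, B = sh1.center, center2
    AB = A - B
    l1 = sh1.l
    l2 = sum(lmn) if max(lmn) >= 0 else 0
    l2 = max(lmn[0], 0) + max(lmn[1], 0) + max(lmn[2], 0)
    lx, ly, lz = lmn
    comps1 = sh1.components
    n1 = sh1.component_norms()
    out = np.zeros(sh1.ncart)
    for a, ca in zip(sh1.exps, sh1.coefs):
        p = a + b
        Ex = _e_coeffs(l1, max(lx, 0), a, b, AB[0])
        Ey = _e_coeffs(l1, max(ly, 0), a, b, AB[1])
        Ez = _e_coeffs(l1, max(lz, 0), a, b, AB[2])
        for i1, (x1, y1, z1) in enumerate(comps1):
            out[i1] += (
                ca
                * n1[i1]
                * (np.pi / p) ** 1.5
                * Ex[x1, lx, 0]
                * Ey[y1, ly, 0]
                * Ez[z1, lz, 0]
            )
    return out


# --- Hermite Coulomb recursion -------------------------------------------

def _hermite_coulomb(tmax: int, umax: int, vmax: int, p, PC: np.ndarray):
    """R_{tuv}(p, PC) for all t<=tmax, u<=umax, v<=vmax.

    PC may be (3,) or (npts, 3); p may be a scalar or an (npts,) array
    (one effective exponent per row).  Returns dict[(t,u,v)] -> (npts,).
    """
    PC = np.atleast_2d(PC)
    p_arr = np.broadcast_to(np.asarray(p, dtype=float), (PC.shape[0],))
    T = p_arr * np.einsum("gi,gi->g", PC, PC)
    nmax = tmax + umax + vmax
    F = boys(nmax, T)
    pow_neg2p = (-2.0 * p_arr) ** np.arange(nmax + 1)[:, None]
    base = F * pow_neg2p  # R^n_000
    # recursion: R^n_{t+1,u,v} = t*R^{n+1}_{t-1,u,v} + X * R^{n+1}_{t,u,v}
    R: dict[tuple[int, int, int], np.ndarray] = {}
    # build R^n tables progressively: store R^n_{tuv} for needed n
    table: dict[tuple[int, int, int, int], np.ndarray] = {}
    for nn in range(nmax + 1):
        table[(0, 0, 0, nn)] = base[nn]
    X, Y, Z = PC[:, 0], PC[:, 1], PC[:, 2]

    def get(t: int, u: int, v: int, nn: int) -> np.ndarray:
        key = (t, u, v, nn)
        if key in table:
            return table[key]
        if t > 0:
            val = X * get(t - 1, u, v, nn + 1)
            if t > 1:
                val = val + (t - 1) * get(t - 2, u, v, nn + 1)
        elif u > 0:
            val = Y * get(t, u - 1, v, nn + 1)
            if u > 1:
                val = val + (u - 1) * get(t, u - 2, v, nn + 1)
        else:
            val = Z * get(t, u, v - 1, nn + 1)
            if v > 1:
                val = val + (v - 1) * get(t, u, v - 2, nn + 1)
        table[key] = val
        return val

    for t in range(tmax + 1):
        for u in range(umax + 1):
            for v in range(vmax + 1):
                R[(t, u, v)] = get(t, u, v, 0)
    return R


def nuclear_attraction(
    basis: BasisSet, charges: np.ndarray, coords: np.ndarray
) -> np.ndarray:
    """V_{mu nu} = -sum_C Z_C <mu| 1/|r-C| |nu>."""
    n = basis.nbf
    V = np.zeros((n, n))
    sl = basis.shell_slices()
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    for isl, sh1 in enumerate(basis.shells):
        for jsl in range(isl + 1):
            sh2 = basis.shells[jsl]
            block = np.zeros((sh1.ncart, sh2.ncart))
            ps, Ps, Hs = _pair_hermite(sh1, sh2)
            L = sh1.l + sh2.l
            for p, P, H in zip(ps, Ps, Hs):
                R = _hermite_coulomb(L, L, L, p, (P - coords))
                acc = np.zeros((sh1.ncart, sh2.ncart))
                for t in range(L + 1):
                    for u in range(L + 1):
                        for v in range(L + 1):
                            Htuv = H[:, :, t, u, v]
                            if not Htuv.any():
                                continue
                            acc += Htuv * np.dot(R[(t, u, v)], charges)
                block += (2.0 * np.pi / p) * acc
            V[sl[isl], sl[jsl]] -= block
    iu = np.triu_indices(n, 1)
    V[iu] = V.T[iu]
    return V


# --- two-electron integrals ----------------------------------------------

def _contract_bra_hermite(
    Hb: np.ndarray, Rsub: np.ndarray
) -> np.ndarray:
    """Contract bra Hermite coefficients with an R block.

    Hb: (n1, n2, t, u, v); Rsub: (t, u, v, ...) -> (n1, n2, ...)
    """
    return np.tensordot(Hb, Rsub, axes=([2, 3, 4], [0, 1, 2]))


def eri_conventional(basis: BasisSet, max_nbf: int = 72) -> np.ndarray:
    """Full (pq|rs) tensor.  Guarded: meant for small oracle systems."""
    n = basis.nbf
    if n > max_nbf:
        raise ValueError(
            f"conventional ERI guard: {n} basis functions > {max_nbf}"
        )
    sl = basis.shell_slices()
    pairs = []
    for i, shi in enumerate(basis.shells):
        for j in range(i + 1):
            pairs.append((i, j))
    eri = np.zeros((n, n, n, n))
    # precompute pair data
    pair_data = {}
    for (i, j) in pairs:
        pair_data[(i, j)] = _pair_hermite(basis.shells[i], basis.shells[j])
    for ip, (i, j) in enumerate(pairs):
        shi, shj = basis.shells[i], basis.shells[j]
        Lb = shi.l + shj.l
        psb, Psb, Hsb = pair_data[(i, j)]
        for (k, l) in pairs[: ip + 1]:
            shk, shl = basis.shells[k], basis.shells[l]
            Lk = shk.l + shl.l
            psk, Psk, Hsk = pair_data[(k, l)]
            block = np.zeros((shi.ncart, shj.ncart, shk.ncart, shl.ncart))
            for pb, Pb, Hb in zip(psb, Psb, Hsb):
                for pk, Pk, Hk in zip(psk, Psk, Hsk):
                    alpha = pb * pk / (pb + pk)
                    R = _hermite_coulomb(Lb + Lk, Lb + Lk, Lb + Lk, alpha, Pb - Pk)
                    fac = (
                        2.0 * np.pi ** 2.5 / (pb * pk * np.sqrt(pb + pk))
                    )
                    # assemble R tensor indexed by (t+tau, u+nu, v+phi)
                    Rarr = np.zeros((Lb + Lk + 1,) * 3)
                    for t in range(Lb + Lk + 1):
                        for u in range(Lb + Lk + 1):
                            for v in range(Lb + Lk + 1):
                                Rarr[t, u, v] = R[(t, u, v)][0]
                    for tau in range(Lk + 1):
                        for nu in range(Lk + 1):
                            for phi in range(Lk + 1):
                                Hket = Hk[:, :, tau, nu, phi]
                                if not Hket.any():
                                    continue
                                sign = (-1.0) ** (tau + nu + phi)
                                Rsub = Rarr[
                                    tau : tau + Lb + 1,
                                    nu : nu + Lb + 1,
                                    phi : phi + Lb + 1,
                                ]
                                bra = _contract_bra_hermite(Hb, Rsub)
                                block += (
                                    fac * sign * bra[:, :, None, None] * Hket[None, None]
                                )
            _fill_eri(eri, block, sl[i], sl[j], sl[k], sl[l])
    return eri


def _fill_eri(eri, block, si, sj, sk, slc):
    eri[si, sj, sk, slc] = block
    eri[sj, si, sk, slc] = block.transpose(1, 0, 2, 3)
    eri[si, sj, slc, sk] = block.transpose(0, 1, 3, 2)
    eri[sj, si, slc, sk] = block.transpose(1, 0, 3, 2)
    eri[sk, slc, si, sj] = block.transpose(2, 3, 0, 1)
    eri[slc, sk, si, sj] = block.transpose(3, 2, 0, 1)
    eri[sk, slc, sj, si] = block.transpose(2, 3, 1, 0)
    eri[slc, sk, sj, si] = block.transpose(3, 2, 1, 0)


def _aux_groups(aux: BasisSet):
    """Group single-primitive aux shells by (center, l) for vectorization.

    Returns list of dicts with exps (nk,), H (nk, ncart, l+1, l+1, l+1),
    center (3,), l, and the flat aux-function indices (nk * ncart,).
    """
    asl = aux.shell_slices()
    groups: dict[tuple, dict] = {}
    for ka, sh in enumerate(aux.shells):
        if len(sh.exps) != 1:
            raise NotImplementedError("aux grouping expects uncontracted shells")
        key = (tuple(np.round(sh.center, 12)), sh.l)
        g = groups.setdefault(
            key, {"center": sh.center, "l": sh.l, "exps": [], "coefs": [], "idx": []}
        )
        g["exps"].append(sh.exps[0])
        g["coefs"].append(sh.coefs[0])
        g["idx"].append(asl[ka])
    out = []
    for g in groups.values():
        l = g["l"]
        ncart = (l + 1) * (l + 2) // 2
        comps = [
            (lx, ly, l - lx - ly)
            for lx in range(l, -1, -1)
            for ly in range(l - lx, -1, -1)
        ]
        nk = len(g["exps"])
        H = np.zeros((nk, ncart, l + 1, l + 1, l + 1))
        norms = _component_norms(l)
        for k, (a, c) in enumerate(zip(g["exps"], g["coefs"])):
            Ex = _e_coeffs(l, 0, a, 0.0, 0.0)
            Ey, Ez = Ex, Ex
            for ic, (lx, ly, lz) in enumerate(comps):
                H[k, ic, : lx + 1, : ly + 1, : lz + 1] = (
                    c * norms[ic]
                    * Ex[lx, 0, : lx + 1, None, None]
                    * Ey[ly, 0, None, : ly + 1, None]
                    * Ez[lz, 0, None, None, : lz + 1]
                )
        idx = np.concatenate(
            [np.arange(s.start, s.stop) for s in g["idx"]]
        ).reshape(nk, ncart)
        out.append(
            {
                "center": g["center"],
                "l": l,
                "exps": np.asarray(g["exps"]),
                "H": H,
                "idx": idx,
            }
        )
    return out


def _component_norms(l: int) -> np.ndarray:
    ref = _double_factorial_local(2 * l - 1)
    comps = [
        (lx, ly, l - lx - ly)
        for lx in range(l, -1, -1)
        for ly in range(l - lx, -1, -1)
    ]
    return np.array(
        [
            np.sqrt(
                ref
                / (
                    _double_factorial_local(2 * lx - 1)
                    * _double_factorial_local(2 * ly - 1)
                    * _double_factorial_local(2 * lz - 1)
                )
            )
            for (lx, ly, lz) in comps
        ]
    )


def _double_factorial_local(n: int) -> float:
    if n <= 0:
        return 1.0
    out = 1.0
    while n > 0:
        out *= n
        n -= 2
    return out


def int3c2e(basis: BasisSet, aux: BasisSet) -> np.ndarray:
    """(mu nu | P) Coulomb three-center integrals, shape (nbf, nbf, naux).

    Vectorized over auxiliary exponents sharing a center and angular
    momentum: only the Boys-function base of the Hermite-Coulomb recursion
    depends on the exponent.
    """
    n, na = basis.nbf, aux.nbf
    out = np.zeros((n, n, na))
    sl = basis.shell_slices()
    groups = _aux_groups(aux)
    for i, shi in enumerate(basis.shells):
        for j in range(i + 1):
            shj = basis.shells[j]
            Lb = shi.l + shj.l
            psb, Psb, Hsb = _pair_hermite(shi, shj)
            for g in groups:
                Lk = g["l"]
                exps = g["exps"]  # (nk,)
                nk = exps.size
                Hk = g["H"]  # (nk, ncart, Lk+1, Lk+1, Lk+1)
                block = np.zeros((shi.ncart, shj.ncart, nk, Hk.shape[1]))
                for pb, Pb, Hb in zip(psb, Psb, Hsb):
                    alpha = pb * exps / (pb + exps)
                    PC = np.broadcast_to(Pb - g["center"], (nk, 3))
                    R = _hermite_coulomb(Lb + Lk, Lb + Lk, Lb + Lk, alpha, PC)
                    fac = 2.0 * np.pi ** 2.5 / (pb * exps * np.sqrt(pb + exps))
                    L = Lb + Lk
                    Rarr = np.empty((L + 1, L + 1, L + 1, nk))
                    for t in range(L + 1):
                        for u in range(L + 1):
                            for v in range(L + 1):
                                Rarr[t, u, v] = R[(t, u, v)]
                    for tau in range(Lk + 1):
                        for nu in range(Lk + 1):
                            for phi in range(Lk + 1):
                                Hket = Hk[:, :, tau, nu, phi]  # (nk, ncart)
                                if not Hket.any():
                                    continue
                                sign = (-1.0) ** (tau + nu + phi)
                                Rsub = Rarr[
                                    tau : tau + Lb + 1,
                                    nu : nu + Lb + 1,
                                    phi : phi + Lb + 1,
                                ]  # (Lb+1, Lb+1, Lb+1, nk)
                                bra = np.tensordot(
                                    Hb, Rsub, axes=([2, 3, 4], [0, 1, 2])
                                )  # (n1, n2, nk)
                                block += sign * np.einsum(
                                    "abk,k,kc->abkc", bra, fac, Hket
                                )
                flat = g["idx"]  # (nk, ncart)
                out[sl[i], sl[j], flat.ravel()] += block.reshape(
                    shi.ncart, shj.ncart, -1
                )
                if i != j:
                    out[sl[j], sl[i], flat.ravel()] += block.transpose(
                        1, 0, 2, 3
                    ).reshape(shj.ncart, shi.ncart, -1)
    return out


def _unit_s_shell(center: np.ndarray) -> Shell:
    """Dummy s 'shell' with zero exponent and unit coefficient.

    Pairing any shell with it leaves the shell's own Hermite expansion;
    used to reuse the pair machinery for single-shell (aux) expansions.
    """
    sh = Shell.__new__(Shell)
    sh.l = 0
    sh.center = np.asarray(center, dtype=float)
    sh.exps = np.array([0.0])
    sh.coefs = np.array([1.0])
    sh.atom_index = -1
    return sh


def int2c2e(aux: BasisSet) -> np.ndarray:
    """(P|Q) two-center Coulomb metric."""
    na = aux.nbf
    out = np.zeros((na, na))
    asl = aux.shell_slices()
    for i, shi in enumerate(aux.shells):
        psb, Psb, Hsb = _pair_hermite(shi, _unit_s_shell(shi.center))
        Lb = shi.l
        for j in range(i + 1):
            shj = aux.shells[j]
            Lk = shj.l
            psk, Psk, Hsk = _pair_hermite(shj, _unit_s_shell(shj.center))
            block = np.zeros((shi.ncart, shj.ncart))
            for pb, Pb, Hb in zip(psb, Psb, Hsb):
                for pk, Pk, Hk in zip(psk, Psk, Hsk):
                    alpha = pb * pk / (pb + pk)
                    R = _hermite_coulomb(Lb + Lk, Lb + Lk, Lb + Lk, alpha, Pb - Pk)
                    fac = 2.0 * np.pi ** 2.5 / (pb * pk * np.sqrt(pb + pk))
                    Rarr = np.zeros((Lb + Lk + 1,) * 3)
                    for t in range(Lb + Lk + 1):
                        for u in range(Lb + Lk + 1):
                            for v in range(Lb + Lk + 1):
                                Rarr[t, u, v] = R[(t, u, v)][0]
                    for tau in range(Lk + 1):
                        for nu in range(Lk + 1):
                            for phi in range(Lk + 1):
                                Hket = Hk[:, 0, tau, nu, phi]
                                if not Hket.any():
                                    continue
                                sign = (-1.0) ** (tau + nu + phi)
                                Rsub = Rarr[
                                    tau : tau + Lb + 1,
                                    nu : nu + Lb + 1,
                                    phi : phi + Lb + 1,
                                ]
                                bra = np.tensordot(
                                    Hb[:, 0], Rsub, axes=([1, 2, 3], [0, 1, 2])
                                )
                                block += fac * sign * np.outer(bra, Hket)
            out[asl[i], asl[j]] = block
    iu = np.triu_indices(na, 1)
    out[iu] = out.T[iu]
    return out


def potential_at_points(aux: BasisSet, points: np.ndarray) -> np.ndarray:
    """V_P(r_g) = int chi_P(r') / |r_g - r'| dr', shape (npts, naux).

    For a normalized s Gaussian this reduces to erf(sqrt(a) r)/r.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    npts = points.shape[0]
    out = np.zeros((npts, aux.nbf))
    asl = aux.shell_slices()
    for ka, sha in enumerate(aux.shells):
        ps, Ps, Hs = _pair_hermite(sha, _unit_s_shell(sha.center))
        L = sha.l
        block = np.zeros((npts, sha.ncart))
        for p, P, H in zip(ps, Ps, Hs):
            R = _hermite_coulomb(L, L, L, p, P[None, :] - points)
            for t in range(L + 1):
                for u in range(L + 1):
                    for v in range(L + 1):
                        Htuv = H[:, 0, t, u, v]
                        if not Htuv.any():
                            continue
                        block += (2.0 * np.pi / p) * R[(t, u, v)][:, None] * Htuv[None]
        out[:, asl[ka]] = block
    return out


def pair_potential_at_points(basis: BasisSet, points: np.ndarray) -> np.ndarray:
    """V_{mu nu}(r_g) = int chi_mu chi_nu / |r_g - r'| dr', (npts, nbf, nbf).

    Conventional (fitting-free) pair potentials; cost grows as nbf^2 * npts,
    intended for small oracle systems only.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    npts = points.shape[0]
    n = basis.nbf
    out = np.zeros((npts, n, n))
    sl = basis.shell_slices()
    for i, shi in enumerate(basis.shells):
        for j in range(i + 1):
            shj = basis.shells[j]
            L = shi.l + shj.l
            ps, Ps, Hs = _pair_hermite(shi, shj)
            block = np.zeros((npts, shi.ncart, shj.ncart))
            for p, P, H in zip(ps, Ps, Hs):
                R = _hermite_coulomb(L, L, L, p, P[None, :] - points)
                for t in range(L + 1):
                    for u in range(L + 1):
                        for v in range(L + 1):
                            Htuv = H[:, :, t, u, v]
                            if not Htuv.any():
                                continue
                            block += (2.0 * np.pi / p) * (
                                R[(t, u, v)][:, None, None] * Htuv[None]
                            )
            out[:, sl[i], sl[j]] = block
            if i != j:
                out[:, sl[j], sl[i]] = block.transpose(0, 2, 1)
    return out


# --- orbital values on points --------------------------------------------

def ao_values(basis: BasisSet, points: np.ndarray, deriv: int = 2):
    """AO values (and optionally gradient, Laplacian) at points.

    Returns (vals,) or (vals, grad) or (vals, grad, lap) with
    vals (npts, nbf), grad (npts, 3, nbf), lap (npts, nbf).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    npts = points.shape[0]
    n = basis.nbf
    vals = np.zeros((npts, n))
    grad = np.zeros((npts, 3, n)) if deriv >= 1 else None
    lap = np.zeros((npts, n)) if deriv >= 2 else None
    sl = basis.shell_slices()
    for isl, sh in enumerate(basis.shells):
        d = points - sh.center  # (npts, 3)
        r2 = np.einsum("gi,gi->g", d, d)
        comps = sh.components
        norms = sh.component_norms()
        vblock = np.zeros((npts, sh.ncart))
        gblock = np.zeros((npts, 3, sh.ncart)) if deriv >= 1 else None
        lblock = np.zeros((npts, sh.ncart)) if deriv >= 2 else None
        for a, c in zip(sh.exps, sh.coefs):
            e = np.exp(-a * r2)
            for ic, (lx, ly, lz) in enumerate(comps):
                mono = d[:, 0] ** lx * d[:, 1] ** ly * d[:, 2] ** lz
                f = c * norms[ic]
                vblock[:, ic] += f * mono * e
                if deriv >= 1:
                    lvec = (lx, ly, lz)
                    for axis in range(3):
                        la = lvec[axis]
                        others = [0, 1, 2]
                        others.remove(axis)
                        mono_others = (
                            d[:, others[0]] ** lvec[others[0]]
                            * d[:, others[1]] ** lvec[others[1]]
                        )
                        term = -2.0 * a * d[:, axis] ** (la + 1)
                        if la > 0:
                            term = term + la * d[:, axis] ** (la - 1)
                        gblock[:, axis, ic] += f * mono_others * term * e
                if deriv >= 2:
                    lvec = (lx, ly, lz)
                    lap_term = np.zeros(npts)
                    for axis in range(3):
                        la = lvec[axis]
                        others = [0, 1, 2]
                        others.remove(axis)
                        mono_others = (
                            d[:, others[0]] ** lvec[others[0]]
                            * d[:, others[1]] ** lvec[others[1]]
                        )
                        term = (
                            4.0 * a * a * d[:, axis] ** (la + 2)
                            - 2.0 * a * (2 * la + 1) * d[:, axis] ** la
                        )
                        if la > 1:
                            term = term + la * (la - 1) * d[:, axis] ** (la - 2)
                        lap_term += mono_others * term
                    lblock[:, ic] += f * lap_term * e
        vals[:, sl[isl]] = vblock
        if deriv >= 1:
            grad[:, :, sl[isl]] = gblock
        if deriv >= 2:
            lap[:, sl[isl]] = lblock
    if deriv == 0:
        return (vals,)
    if deriv == 1:
        return vals, grad
    return vals, grad, lap
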