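"""Correlation and exchange energy densities in real space.

The correlation energy per particle adopted here is the electrostatic
potential of the second-order correction to the pair density (the gauge of
the Moller-Plesset adiabatic connection): in closed-shell spatial orbitals

    ebar_c(r) = sum_{ijab} G_{ijab} * phi_i(r) phi_a(r) v_jb(r),

with v_jb(r) the Coulomb potential of the occupied x virtual product
density (evaluated through a density-fitting expansion), and channel
coefficient tensors

    total:          G_{ijab} = T^k_{ijba} - 2 T^k_{ijab}
    opposite-spin:  G_{ijab} = -T^k_{ijab}

where T_{ijab} = (ia|jb) / (eps_a + eps_b - eps_i - eps_j) is the partial
doubles amplitude and T^k its kappa-regularized counterpart (multiplier
(1 - exp(-kappa*Delta))^2).  The same-spin channel is the difference
total - os.  The spin prefactors are pinned by the requirement that the
channel fields integrate to the standard MP2 opposite-/same-spin split; a
spin-orbital brute-force oracle confirms them pointwise.

Exchange is treated on the same footing (potential of the exchange-hole
pair density): ebar_x(r) = - sum_{ij occ} phi_i phi_j(r) v_ij(r).

Per-particle fields e(r) = ebar(r)/rho(r) are the ML training targets;
density-weighted fields ebar(r) integrate directly to energies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import integrals
from .grids import QuadratureGrid
from .orbitals import OrbitalValues, evaluate_orbitals_on_points
from .reference import SCFReference

__all__ = [
    "AmplitudeSet",
    "EnergyDensityField",
    "PairDensitySlice",
    "compute_amplitudes",
    "regularize_amplitudes",
    "correlation_density",
    "exchange_density",
    "integrate_field",
    "a_gauge_shift",
    "interaction_density",
    "pair_density_slice",
    "EnergyDensityEngine",
]

RHO_FLOOR = 1e-12
DENOMINATOR_FLOOR = 1e-8

CHANNELS = ("total", "os", "ss")


@dataclass
class AmplitudeSet:
    """Partial MP2 doubles amplitudes T_{ijab} over occ,occ,virt,virt."""

    T: np.ndarray  # (o, o, v, v)
    delta: np.ndarray  # eps_a + eps_b - eps_i - eps_j, same shape
    ovov: np.ndarray  # (ia|jb) as [i, j, a, b]
    kappa: float = np.inf  # inf = unregularized
    small_denominator: bool = False  # any |delta| below floor (diagnostic)

    @property
    def regularizer(self) -> np.ndarray:
        if np.isinf(self.kappa):
            return np.ones_like(self.delta)
        return (1.0 - np.exp(-self.kappa * self.delta)) ** 2

    def channel_coefficients(self, channel: str) -> np.ndarray:
        """G_{ijab} multiplying phi_i phi_a v_jb in the density expansion."""
        Tk = self.T * self.regularizer
        if channel == "total":
            return Tk.transpose(0, 1, 3, 2) - 2.0 * Tk
        if channel == "os":
            return -Tk
        if channel == "ss":
            return self.channel_coefficients("total") - self.channel_coefficients("os")
        raise ValueError(f"unknown channel '{channel}'; expected one of {CHANNELS}")

    def channel_energy(self, channel: str) -> float:
        """Tensor-route (grid-free) correlation energy of a channel."""
        return float(np.einsum("ijab,ijab->", self.channel_coefficients(channel), self.ovov))


@dataclass
class EnergyDensityField:
    values: np.ndarray  # (npts,)
    channel: str  # total | os | ss | exchange
    kappa: float
    gauge: str = "mpac"  # or "a-shifted(a)"
    normalization: str = "per_particle"  # or "density_weighted"
    grid: QuadratureGrid | None = None
    rho: np.ndarray | None = None

    def density_weighted(self) -> "EnergyDensityField":
        if self.normalization == "density_weighted":
            return self
        return replace(
            self,
            values=self.values * self.rho,
            normalization="density_weighted",
        )

    def per_particle(self) -> "EnergyDensityField":
        if self.normalization == "per_particle":
            return self
        vals = np.where(self.rho > RHO_FLOOR, self.values / np.maximum(self.rho, RHO_FLOOR), 0.0)
        return replace(self, values=vals, normalization="per_particle")


@dataclass
class PairDensitySlice:
    r0: np.ndarray
    probe_points: np.ndarray
    values: np.ndarray  # P2(r0, r') at the probes
    kappa: float
    channel: str = "total"


def compute_amplitudes(ref: SCFReference) -> AmplitudeSet:
    """Partial doubles amplitudes T_{ijab} = (ia|jb)/Delta from DF factors."""
    o, nmo = ref.n_occ, ref.mo_coeff.shape[1]
    if o < 1 or nmo - o < 1:
        raise ValueError("need at least one occupied and one virtual orbital")
    b_ov = ref.b_mo[:o, o:, :]
    ovov = np.einsum("iaP,jbP->ijab", b_ov, b_ov, optimize=True)
    eps = ref.mo_energy
    delta = (
        eps[None, None, o:, None]
        + eps[None, None, None, o:]
        - eps[:o, None, None, None]
        - eps[None, :o, None, None]
    )
    small = bool(np.any(np.abs(delta) < DENOMINATOR_FLOOR))
    safe = np.where(np.abs(delta) < DENOMINATOR_FLOOR,
                    np.sign(delta) * DENOMINATOR_FLOOR + (delta == 0) * DENOMINATOR_FLOOR,
                    delta)
    T = ovov / safe
    return AmplitudeSet(T=T, delta=delta, ovov=ovov, kappa=np.inf, small_denominator=small)


def regularize_amplitudes(amps: AmplitudeSet, kappa: float) -> AmplitudeSet:
    """Tag the set with a kappa; the multiplier (1-exp(-k*Delta))^2 is applied lazily."""
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    return replace(amps, kappa=float(kappa))


class EnergyDensityEngine:
    """Caches grid-dependent tensors for one reference + grid pair."""

    def __init__(self, ref: SCFReference, grid: QuadratureGrid | None = None):
        self.ref = ref
        self.grid = grid
        self.amps = compute_amplitudes(ref) if ref.n_occ < ref.mo_coeff.shape[1] else None
        self._cache: dict = {}

    # -- cached grid quantities --
    def orbital_values(self, points=None) -> OrbitalValues:
        if points is None:
            key = "ov_grid"
            if key not in self._cache:
                self._cache[key] = evaluate_orbitals_on_points(self.ref, self.grid.points)
            return self._cache[key]
        return evaluate_orbitals_on_points(self.ref, points)

    def aux_potentials(self, points=None) -> np.ndarray:
        """J^{-1/2}-transformed auxiliary Coulomb potentials at points."""
        if points is None:
            key = "vt_grid"
            if key not in self._cache:
                V = integrals.potential_at_points(self.ref.aux_basis_set, self.grid.points)
                self._cache[key] = V @ self.ref.aux_metric_inv_sqrt
            return self._cache[key]
        V = integrals.potential_at_points(self.ref.aux_basis_set, points)
        return V @ self.ref.aux_metric_inv_sqrt

    # -- fields --
    def correlation_bar(
        self, channel: str = "total", kappa: float = np.inf, points=None
    ) -> np.ndarray:
        """Density-weighted correlation field ebar_c at grid or given points."""
        if self.amps is None:
            npts = self.grid.size if points is None else np.atleast_2d(points).shape[0]
            return np.zeros(npts)
        amps = replace(self.amps, kappa=float(kappa))
        G = amps.channel_coefficients(channel)
        o = self.ref.n_occ
        b_ov = self.ref.b_mo[:o, o:, :]
        D = np.einsum("ijab,jbP->iaP", G, b_ov, optimize=True)
        ov = self.orbital_values(points)
        Vt = self.aux_potentials(points)
        phi_occ = ov.mo[:, :o]
        phi_vir = ov.mo[:, o:]
        # ebar(g) = phi_i(g) phi_a(g) D_iaP Vt_gP, chunked over grid points
        out = np.empty(phi_occ.shape[0])
        chunk = 4096
        for s in range(0, out.shape[0], chunk):
            sl = slice(s, s + chunk)
            M = np.einsum("iaP,gP->gia", D, Vt[sl], optimize=True)
            out[sl] = np.einsum("gi,ga,gia->g", phi_occ[sl], phi_vir[sl], M, optimize=True)
        return out

    def pair_potentials(self, points) -> np.ndarray:
        """Fitted occ x virt pair potentials v_jb(r) at points, (npts, o, v)."""
        o = self.ref.n_occ
        Vt = self.aux_potentials(points)
        return np.einsum("jbP,gP->gjb", self.ref.b_mo[:o, o:, :], Vt, optimize=True)

    def exchange_bar(self, points=None) -> np.ndarray:
        o = self.ref.n_occ
        b_oo = self.ref.b_mo[:o, :o, :]
        ov = self.orbital_values(points)
        Vt = self.aux_potentials(points)
        phi_occ = ov.mo[:, :o]
        # spin factor: restricted closed shell has 2 electrons per orbital,
        # E_x = -sum_ij (ij|ij); one-electron references carry no exchange pair
        if not self.ref.restricted:
            return np.zeros(phi_occ.shape[0])
        out = np.empty(phi_occ.shape[0])
        chunk = 4096
        for s in range(0, out.shape[0], chunk):
            sl = slice(s, s + chunk)
            v_ij = np.einsum("ijP,gP->gij", b_oo, Vt[sl], optimize=True)
            out[sl] = -np.einsum("gi,gj,gij->g", phi_occ[sl], phi_occ[sl], v_ij, optimize=True)
        return out


def correlation_bar_from_tensors(
    ovov: np.ndarray,
    delta: np.ndarray,
    phi_occ: np.ndarray,
    phi_vir: np.ndarray,
    v_ov: np.ndarray,
    kappa: float = np.inf,
    channel: str = "total",
) -> np.ndarray:
    """Assemble ebar_c(r) directly from raw tensors.

    Inputs: MO-pair integrals (ia|jb) as [i,j,a,b], orbital-energy
    differences Delta_{ijab}, orbital values phi at the evaluation points,
    and pair potentials v_jb at the same points.  Used to check algebraic
    identities (e.g. uniform-scaling consistency) on explicitly transformed
    tensors, independent of the density-fitting pipeline.
    """
    T = ovov / delta
    if not np.isinf(kappa):
        T = T * (1.0 - np.exp(-kappa * delta)) ** 2
    if channel == "total":
        G = T.transpose(0, 1, 3, 2) - 2.0 * T
    elif channel == "os":
        G = -T
    elif channel == "ss":
        G = T.transpose(0, 1, 3, 2) - T
    else:
        raise ValueError(f"unknown channel '{channel}'")
    return np.einsum(
        "ijab,gi,ga,gjb->g", G, phi_occ, phi_vir, v_ov, optimize=True
    )


def _engine(ref, grid) -> EnergyDensityEngine:
    # lightweight per-call engine; callers wanting caching hold their own
    return EnergyDensityEngine(ref, grid)


def correlation_density(
    ref: SCFReference,
    amps: AmplitudeSet | None,
    grid: QuadratureGrid,
    channel: str = "total",
    engine: EnergyDensityEngine | None = None,
) -> EnergyDensityField:
    """Per-particle correlation energy density e_c(r) on the grid."""
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel '{channel}'")
    eng = engine or _engine(ref, grid)
    kappa = amps.kappa if amps is not None else np.inf
    ebar = eng.correlation_bar(channel, kappa)
    rho = eng.orbital_values().rho
    vals = np.where(rho > RHO_FLOOR, ebar / np.maximum(rho, RHO_FLOOR), 0.0)
    return EnergyDensityField(
        values=vals, channel=channel, kappa=kappa, grid=grid, rho=rho
    )


def exchange_density(
    ref: SCFReference,
    grid: QuadratureGrid,
    engine: EnergyDensityEngine | None = None,
) -> EnergyDensityField:
    """Per-particle exchange energy density (hole-potential gauge)."""
    eng = engine or _engine(ref, grid)
    ebar = eng.exchange_bar()
    rho = eng.orbital_values().rho
    vals = np.where(rho > RHO_FLOOR, ebar / np.maximum(rho, RHO_FLOOR), 0.0)
    return EnergyDensityField(
        values=vals, channel="exchange", kappa=np.inf, grid=grid, rho=rho
    )


def integrate_field(field: EnergyDensityField, grid: QuadratureGrid | None = None) -> float:
    """E = int e(r) rho(r) dr (per-particle) or int ebar(r) dr (weighted)."""
    g = grid or field.grid
    if g is None:
        raise ValueError("no grid attached to field")
    if field.normalization == "per_particle":
        if field.rho is None:
            raise ValueError("per-particle field requires rho for integration")
        return float(np.dot(g.weights, field.values * field.rho))
    return float(np.dot(g.weights, field.values))


def a_gauge_shift(
    field: EnergyDensityField, a: float, orbital_values: OrbitalValues
) -> EnergyDensityField:
    """Gauge transform e^a(r) = e(r) + a q(r) rho^{2/3}(r).

    q is the reduced density Laplacian; the shift integrates (against rho)
    to a multiple of int lap(rho) dr = 0, leaving the energy unchanged for
    exponentially decaying densities.
    """
    if field.normalization != "per_particle":
        raise ValueError("gauge shift is defined on per-particle fields")
    if a == 0.0:
        return field
    rho = orbital_values.rho
    lap = orbital_values.rho_lap
    q = lap / (4.0 * (3.0 * np.pi ** 2) ** (2.0 / 3.0) * np.maximum(rho, RHO_FLOOR) ** (5.0 / 3.0))
    shift = a * q * np.maximum(rho, 0.0) ** (2.0 / 3.0)
    shift = np.where(rho > RHO_FLOOR, shift, 0.0)
    return replace(field, values=field.values + shift, gauge=f"a-shifted({a})")


def interaction_density(
    complex_engine: EnergyDensityEngine,
    fragment_engines: list[EnergyDensityEngine],
    eval_points: np.ndarray,
    kappa: float = np.inf,
    channel: str = "total",
) -> np.ndarray:
    """Delta ebar_c(r) = ebar_c^complex(r) - sum_frag ebar_c^frag(r).

    Fragments must be positioned in the complex frame; evaluation is
    analytic at arbitrary points (no grid interpolation).
    """
    csyms = sorted(complex_engine.ref.mol.symbols)
    fsyms = sorted(s for e in fragment_engines for s in e.ref.mol.symbols)
    if csyms != fsyms:
        raise ValueError("fragment atoms do not match the complex geometry")
    pts = np.asarray(eval_points, dtype=float).reshape(-1, 3)
    out = complex_engine.correlation_bar(channel, kappa, points=pts)
    for eng in fragment_engines:
        out = out - eng.correlation_bar(channel, kappa, points=pts)
    return out


def pair_density_slice(
    engine: EnergyDensityEngine,
    r0: np.ndarray,
    probe_points: np.ndarray,
    kappa: float = np.inf,
    channel: str = "total",
) -> PairDensitySlice:
    """Second-order pair-density correction P2(r0, r') at probe points.

    P2(r, r') = 4 sum_{ijab} G_{ijab} phi_i phi_a(r) phi_j phi_b(r'),
    normalized so that (1/4) int P2(r0, r')/|r0-r'| dr' = ebar_c(r0).
    """
    ref = engine.ref
    amps = replace(engine.amps, kappa=float(kappa))
    G = amps.channel_coefficients(channel)
    o = ref.n_occ
    r0 = np.asarray(r0, dtype=float).reshape(1, 3)
    probes = np.asarray(probe_points, dtype=float).reshape(-1, 3)
    ov0 = engine.orbital_values(r0)
    ovp = engine.orbital_values(probes)
    A = ov0.mo[0, :o, None] * ov0.mo[0, None, o:]  # (o, v) at r0
    B = np.einsum("gi,ga->gia", ovp.mo[:, :o], ovp.mo[:, o:])  # probes
    coef = np.einsum("ijab,ia->jb", G, A, optimize=True)
    vals = 4.0 * np.einsum("jb,gjb->g", coef, B, optimize=True)
    return PairDensitySlice(
        r0=r0[0], probe_points=probes, values=vals, kappa=kappa, channel=channel
    )
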