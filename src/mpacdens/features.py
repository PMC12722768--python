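"""Dimensionless per-point descriptors feeding the neural functionals.

The ML2 feature stack {s, q, alpha, f1, f2} is invariant under uniform
density scaling rho_lambda(r) = lambda^3 rho(lambda r), matching the
scaling invariance of the regularized MP2 energy per particle it learns.
The MLS2 stack adds density-magnitude and energy-ratio features
{r_s, x_c, x_os} (the true correlation energy is not scale invariant),
and optionally the spin polarization zeta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy_density import RHO_FLOOR, EnergyDensityEngine
from .grids import QuadratureGrid
from .occupations import fermi_occupations
from .orbitals import OrbitalValues
from .reference import SCFReference

__all__ = [
    "FeatureTable",
    "reduced_gradient",
    "reduced_laplacian",
    "alpha_kinetic",
    "fod_feature",
    "wigner_seitz",
    "spin_polarization",
    "normalized_correlation_features",
    "assemble_feature_table",
    "ML2_FEATURES",
    "MLS2_FEATURES",
]

ML2_FEATURES = ("s", "q", "alpha", "f1", "f2")
MLS2_FEATURES = ("s", "q", "alpha", "f1", "f2", "rs", "xc", "xos")

FOD_T1 = 10_000.0  # K
FOD_T2 = 25_000.0  # K

_ALPHA_ETA = 1e-3  # regularization of the alpha kinetic variable
_CAP_S = 1e3
_CAP_Q = 1e3
_CAP_F = 1.0

_CF = (3.0 * np.pi ** 2) ** (1.0 / 3.0)


def _floored(rho: np.ndarray) -> np.ndarray:
    return np.maximum(rho, RHO_FLOOR)


def reduced_gradient(rho: np.ndarray, rho_grad: np.ndarray) -> np.ndarray:
    """s = |grad rho| / (2 (3 pi^2)^{1/3} rho^{4/3})."""
    gnorm = np.linalg.norm(rho_grad, axis=-1) if rho_grad.ndim > 1 else np.abs(rho_grad)
    s = gnorm / (2.0 * _CF * _floored(rho) ** (4.0 / 3.0))
    return np.minimum(s, _CAP_S)


def reduced_laplacian(rho: np.ndarray, rho_lap: np.ndarray) -> np.ndarray:
    """q = lap rho / (4 (3 pi^2)^{2/3} rho^{5/3}); sign follows lap rho."""
    q = rho_lap / (4.0 * _CF ** 2 * _floored(rho) ** (5.0 / 3.0))
    return np.clip(q, -_CAP_Q, _CAP_Q)


def alpha_kinetic(rho: np.ndarray, rho_grad: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """alpha = (tau - tau_W) / (tau_unif + eta tau_W), clamped nonnegative."""
    g2 = np.einsum("gx,gx->g", rho_grad, rho_grad)
    tau_w = g2 / (8.0 * _floored(rho))
    tau_unif = 0.3 * _CF ** 2 * _floored(rho) ** (5.0 / 3.0)
    alpha = (tau - tau_w) / (tau_unif + _ALPHA_ETA * tau_w)
    return np.minimum(np.maximum(alpha, 0.0), _CAP_S)


def fod_feature(
    ref: SCFReference, orbital_values: OrbitalValues, temperature: float
) -> np.ndarray:
    """Fractional-occupation-number-weighted density, divided by rho.

    rho_FOD(r) = sum_{i<=F} (n_max - n_i^T) |phi_i|^2
               + sum_{i>F} n_i^T |phi_i|^2,  f(r) = rho_FOD(r)/rho(r).
    """
    nmo = ref.mo_coeff.shape[1]
    per_orb = 2.0 if ref.restricted else 1.0
    n_elec = int(per_orb) * ref.n_occ
    f = fermi_occupations(ref.mo_energy, temperature, n_elec, spin_factor=per_orb)
    n_t = per_orb * f
    n_max = np.zeros(nmo)
    n_max[: ref.n_occ] = per_orb
    w = np.where(np.arange(nmo) < ref.n_occ, n_max - n_t, n_t)
    rho_fod = np.einsum("p,gp->g", w, orbital_values.mo ** 2)
    out = rho_fod / _floored(orbital_values.rho)
    return np.minimum(np.maximum(out, 0.0), _CAP_F)


def wigner_seitz(rho: np.ndarray) -> np.ndarray:
    """r_s = (3 / (4 pi rho))^{1/3} (bohr)."""
    return (3.0 / (4.0 * np.pi * _floored(rho))) ** (1.0 / 3.0)


def spin_polarization(rho_alpha: np.ndarray, rho_beta: np.ndarray) -> np.ndarray:
    """zeta = (rho_a - rho_b) / rho, in [-1, 1]."""
    tot = _floored(rho_alpha + rho_beta)
    return np.clip((rho_alpha - rho_beta) / tot, -1.0, 1.0)


def normalized_correlation_features(
    e_c: np.ndarray, e_x: np.ndarray, rho: np.ndarray
) -> np.ndarray:
    """x = e_c / (rho^{-1/3} e_x), guarded where the carrier is tiny."""
    carrier = e_x * _floored(rho) ** (-1.0 / 3.0)
    return np.where(np.abs(carrier) > 1e-10, e_c / np.where(np.abs(carrier) > 1e-10, carrier, 1.0), 0.0)


@dataclass
class FeatureTable:
    columns: tuple[str, ...]
    values: np.ndarray  # (npts, ncols)
    rho: np.ndarray
    kappa: float = np.nan
    metadata: dict = field(default_factory=dict)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]


def assemble_feature_table(
    ref: SCFReference,
    grid: QuadratureGrid,
    feature_spec: tuple[str, ...] = ML2_FEATURES,
    engine: EnergyDensityEngine | None = None,
    kappa: float = 2.0,
) -> FeatureTable:
    """Evaluate the requested descriptor columns on the grid.

    Column order follows `feature_spec` exactly; the result is NaN-free and
    deterministic.  Correlation-ratio columns (xc, xos) and zeta raise if
    the reference cannot supply them.
    """
    eng = engine or EnergyDensityEngine(ref, grid)
    ov = eng.orbital_values()
    rho = ov.rho
    cols = {}
    needed = set(feature_spec)
    if "s" in needed:
        cols["s"] = reduced_gradient(rho, ov.rho_grad)
    if "q" in needed:
        cols["q"] = reduced_laplacian(rho, ov.rho_lap)
    if "alpha" in needed:
        cols["alpha"] = alpha_kinetic(rho, ov.rho_grad, ov.tau)
    if "f1" in needed:
        cols["f1"] = fod_feature(ref, ov, FOD_T1)
    if "f2" in needed:
        cols["f2"] = fod_feature(ref, ov, FOD_T2)
    if "rs" in needed:
        cols["rs"] = wigner_seitz(rho)
    if {"xc", "xos"} & needed:
        e_x = eng.exchange_bar() / _floored(rho)
        if "xc" in needed:
            e_c = eng.correlation_bar("total", kappa) / _floored(rho)
            cols["xc"] = normalized_correlation_features(e_c, e_x, rho)
        if "xos" in needed:
            e_os = eng.correlation_bar("os", kappa) / _floored(rho)
            cols["xos"] = normalized_correlation_features(e_os, e_x, rho)
    if "zeta" in needed:
        if not ref.restricted and ref.n_occ >= 1:
            # one-electron pathway: fully spin polarized
            cols["zeta"] = np.ones_like(rho)
        elif ref.restricted:
            cols["zeta"] = np.zeros_like(rho)
        else:
            raise ValueError("zeta requires spin densities")
    missing = needed - set(cols)
    if missing:
        raise ValueError(f"cannot compute features: {sorted(missing)}")
    values = np.column_stack([cols[name] for name in feature_spec])
    if not np.all(np.isfinite(values)):
        raise FloatingPointError("non-finite feature values")
    return FeatureTable(
        columns=tuple(feature_spec),
        values=values,
        rho=rho,
        kappa=kappa,
        metadata={
            "rho_floor": RHO_FLOOR,
            "caps": {"s": _CAP_S, "q": _CAP_Q, "f": _CAP_F},
            "alpha_eta": _ALPHA_ETA,
            "fod_temperatures_K": (FOD_T1, FOD_T2),
            "basis": ref.mol.basis,
            "grid_level": grid.level,
        },
    )
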