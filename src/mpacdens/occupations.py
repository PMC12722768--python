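"""Finite-temperature Fermi occupations of fixed HF orbital energies.

Used for the fractional-occupation-number-weighted density (FOD) features:
occupations are smeared over the converged ground-state orbital energies
(non-self-consistently) at a given electronic temperature, with the
chemical potential solved by bisection so the particle number is conserved
exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fermi_occupations", "KELVIN_TO_HARTREE"]

KELVIN_TO_HARTREE = 3.166811563e-6  # Boltzmann constant in Eh/K


def fermi_occupations(
    mo_energy: np.ndarray, temperature: float, n_elec: int, tol: float = 1e-12,
    spin_factor: float = 2.0,
) -> np.ndarray:
    """Fractional occupations f_i in [0, 1] per spatial orbital and spin.

    Returns f such that spin_factor * sum(f) = n_elec (spin-summed,
    restricted convention; spin_factor=1 for the single-spin pathway).
    f is monotone nonincreasing in orbital energy.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    eps = np.asarray(mo_energy, dtype=float)
    kt = temperature * KELVIN_TO_HARTREE

    def total(mu: float) -> float:
        x = np.clip((eps - mu) / kt, -500, 500)
        return float(spin_factor * np.sum(1.0 / (1.0 + np.exp(x))))

    lo, hi = eps.min() - 50.0 * kt - 10.0, eps.max() + 50.0 * kt + 10.0
    if not (total(lo) <= n_elec <= total(hi)):
        raise RuntimeError("chemical-potential bisection bracket failure")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if total(mid) < n_elec:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15 * max(1.0, abs(mid)):
            break
    mu = 0.5 * (lo + hi)
    x = np.clip((eps - mu) / kt, -500, 500)
    f = 1.0 / (1.0 + np.exp(x))
    # polish normalization to solver tolerance
    s = spin_factor * f.sum()
    if abs(s - n_elec) > tol and s > 0:
        f = f * (n_elec / s)
    return f
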