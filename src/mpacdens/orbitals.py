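"""Molecular-orbital values and density derivatives on point sets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import integrals
from .reference import SCFReference

__all__ = ["OrbitalValues", "evaluate_orbitals_on_points"]


@dataclass
class OrbitalValues:
    """MO values phi_p(r), gradients and Laplacians, plus density derivatives.

    occupations are spin-summed (2 per spatial orbital for restricted
    references, 1 for the one-electron pathway).
    """

    mo: np.ndarray  # (npts, nmo)
    mo_grad: np.ndarray  # (npts, 3, nmo)
    mo_lap: np.ndarray  # (npts, nmo)
    occupations: np.ndarray  # (nmo,)

    @property
    def rho(self) -> np.ndarray:
        return np.einsum("p,gp->g", self.occupations, self.mo ** 2)

    @property
    def rho_grad(self) -> np.ndarray:
        return 2.0 * np.einsum(
            "p,gp,gxp->gx", self.occupations, self.mo, self.mo_grad
        )

    @property
    def rho_lap(self) -> np.ndarray:
        return 2.0 * np.einsum(
            "p,gxp,gxp->g", self.occupations, self.mo_grad, self.mo_grad
        ) + 2.0 * np.einsum("p,gp,gp->g", self.occupations, self.mo, self.mo_lap)

    @property
    def tau(self) -> np.ndarray:
        """Positive kinetic energy density tau = 1/2 sum_i n_i |grad phi_i|^2."""
        return 0.5 * np.einsum(
            "p,gxp,gxp->g", self.occupations, self.mo_grad, self.mo_grad
        )

    @property
    def tau_weizsacker(self) -> np.ndarray:
        g2 = np.einsum("gx,gx->g", self.rho_grad, self.rho_grad)
        return g2 / np.maximum(8.0 * self.rho, 1e-300)


def evaluate_orbitals_on_points(
    ref: SCFReference, points: np.ndarray, occupations: np.ndarray | None = None
) -> OrbitalValues:
    """Analytic MO values/gradients/Laplacians at arbitrary points."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")
    ao, ao_grad, ao_lap = integrals.ao_values(ref.basis_set, points, deriv=2)
    C = ref.mo_coeff
    if occupations is None:
        occupations = np.zeros(C.shape[1])
        occupations[: ref.n_occ] = 2.0 if ref.restricted else 1.0
    return OrbitalValues(
        mo=ao @ C,
        mo_grad=np.einsum("gxm,mp->gxp", ao_grad, C),
        mo_lap=ao_lap @ C,
        occupations=np.asarray(occupations, dtype=float),
    )
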