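"""Machine-learned correlation functionals (ML2 and MLS2).

ML2 rescales the exchange energy density pointwise,

    e_c^{ML2}(r) = w_c(r) * e_x(r) * rho^{-1/3}(r),    w_c in [-1, 1],

with w_c produced by a small network over scale-invariant descriptors.
MLS2 generalizes spin-component scaling to real space,

    e_c^{MLS2}(r) = w_os(r) e_os^{kMP2}(r) + w_ss(r) e_ss^{kMP2}(r),

with w in [0, 10]; it is exact for one-electron systems regardless of the
weights because both channel fields vanish there.

Training minimizes one of:
  LES     mean_s int |e_ref - e_ml| rho dr       (pointwise, per particle)
  LES2    mean_s int (e_ref - e_ml)^2 rho dr
  GES     mean_s |E_ref - E_ml|                  (one number per system)
  direct  mean_s int |ebar_ref - ebar_ml| dr     (density-weighted target)
  combined  lam_tot * GES(totals) + lam_int * GES(interaction energies)

Estimators follow the scikit-learn protocol: hyperparameters in
``__init__``, fitted state in trailing-underscore attributes, and
``get_params``/``set_params`` for composition with sklearn tooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .energy_density import RHO_FLOOR, EnergyDensityEngine
from .features import ML2_FEATURES, MLS2_FEATURES, assemble_feature_table
from .grids import build_grid
from .nn import MLP, Adam, MLPSpec, lr_schedule
from .reference import MoleculeSpec, SCFReference, build_reference

__all__ = [
    "SystemData",
    "InteractionData",
    "prepare_system",
    "compute_loss",
    "ML2Model",
    "MLS2Model",
    "train_seed_ensemble",
]

LOSS_MODES = ("les", "les2", "ges", "direct", "combined")


@dataclass
class SystemData:
    """Precomputed training/evaluation bundle for one system."""

    label: str
    features: np.ndarray  # (n, d)
    columns: tuple[str, ...]
    weights: np.ndarray  # quadrature weights (n,)
    rho: np.ndarray  # (n,)
    e_ref: np.ndarray  # reference e_c^{kappa MP2} per particle (n,)
    carrier: np.ndarray  # e_x * rho^{-1/3} (n,)
    e_os: np.ndarray  # os channel per particle (n,)
    e_ss: np.ndarray  # ss channel per particle (n,)
    kappa: float
    n_elec: int
    e_ref_scalar: float = np.nan  # scalar target; defaults to integral of e_ref

    def __post_init__(self):
        if np.isnan(self.e_ref_scalar):
            self.e_ref_scalar = float(
                np.dot(self.weights * self.rho, self.e_ref)
            )

    @property
    def wrho(self) -> np.ndarray:
        return self.weights * self.rho


@dataclass
class InteractionData:
    """Interaction-energy datum: complex minus positioned fragments."""

    label: str
    complex: SystemData
    fragments: list[SystemData]
    de_ref: float  # reference interaction correlation energy (hartree)


def prepare_system(
    mol_or_ref: MoleculeSpec | SCFReference,
    kappa: float = 2.0,
    grid_level: int = 2,
    feature_spec: tuple[str, ...] = ML2_FEATURES,
    e_ref_scalar: float = np.nan,
    prune_weight: float = 1e-14,
    gauge_a: float = 0.0,
) -> SystemData:
    """Run the pipeline HF -> grid -> densities -> features for one system.

    Grid points with negligible rho-weight are dropped; they carry no
    measurable contribution to any density-weighted loss or integral.
    `gauge_a` shifts the per-particle training target into the a-dependent
    gauge e^a = e + a q rho^{2/3} (same integrated energy).
    """
    ref = (
        mol_or_ref
        if isinstance(mol_or_ref, SCFReference)
        else build_reference(mol_or_ref)
    )
    grid = build_grid(ref.mol, grid_level)
    eng = EnergyDensityEngine(ref, grid)
    ov = eng.orbital_values()
    rho = ov.rho
    keep = np.abs(grid.weights) * rho > prune_weight
    table = assemble_feature_table(ref, grid, feature_spec, engine=eng, kappa=kappa)
    ebar = eng.correlation_bar("total", kappa)
    ebar_os = eng.correlation_bar("os", kappa)
    ebar_x = eng.exchange_bar()
    rho_safe = np.maximum(rho, RHO_FLOOR)
    e_ref = np.where(rho > RHO_FLOOR, ebar / rho_safe, 0.0)
    if gauge_a != 0.0:
        q = ov.rho_lap / (
            4.0 * (3.0 * np.pi ** 2) ** (2.0 / 3.0) * rho_safe ** (5.0 / 3.0)
        )
        e_ref = e_ref + np.where(
            rho > RHO_FLOOR, gauge_a * q * rho_safe ** (2.0 / 3.0), 0.0
        )
    e_os = np.where(rho > RHO_FLOOR, ebar_os / rho_safe, 0.0)
    e_ss = np.where(rho > RHO_FLOOR, (ebar - ebar_os) / rho_safe, 0.0)
    carrier = np.where(rho > RHO_FLOOR, ebar_x / rho_safe, 0.0) * rho_safe ** (
        -1.0 / 3.0
    )
    return SystemData(
        label=ref.mol.label or "-".join(ref.mol.symbols),
        features=table.values[keep],
        columns=table.columns,
        weights=grid.weights[keep],
        rho=rho[keep],
        e_ref=e_ref[keep],
        carrier=carrier[keep],
        e_os=e_os[keep],
        e_ss=e_ss[keep],
        kappa=kappa,
        n_elec=ref.mol.n_electrons,
        e_ref_scalar=e_ref_scalar,
    )


def prepare_one_electron_system(
    mol: MoleculeSpec,
    kappa: float = 2.0,
    grid_level: int = 2,
    feature_spec: tuple[str, ...] = MLS2_FEATURES,
) -> SystemData:
    """System bundle for a one-electron reference (spin-orbital pathway).

    All doubles amplitudes vanish, so every correlation channel is
    identically zero; the spin-scaled functional is therefore exact
    (E_c = 0) for arbitrary weight fields.  Features are evaluated on the
    singly occupied orbital; correlation-ratio columns are zero by
    construction.
    """
    from .features import (
        alpha_kinetic,
        fod_feature,
        reduced_gradient,
        reduced_laplacian,
        wigner_seitz,
        FOD_T1,
        FOD_T2,
    )
    from .orbitals import evaluate_orbitals_on_points
    from .oracles import spin_orbital_oracle_density
    from .reference import one_electron_reference

    ref = one_electron_reference(mol)
    grid = build_grid(mol, grid_level)
    ov = evaluate_orbitals_on_points(ref, grid.points)
    rho = ov.rho
    ebar = spin_orbital_oracle_density(ref, grid.points, kappa=kappa)
    cols = {
        "s": reduced_gradient(rho, ov.rho_grad),
        "q": reduced_laplacian(rho, ov.rho_lap),
        "alpha": alpha_kinetic(rho, ov.rho_grad, ov.tau),
        "f1": fod_feature(ref, ov, FOD_T1),
        "f2": fod_feature(ref, ov, FOD_T2),
        "rs": wigner_seitz(rho),
        "xc": np.zeros_like(rho),
        "xos": np.zeros_like(rho),
        "zeta": np.ones_like(rho),
    }
    zeros = np.zeros_like(rho)
    keep = np.abs(grid.weights) * rho > 1e-14
    return SystemData(
        label=mol.label or mol.symbols[0],
        features=np.column_stack([cols[c] for c in feature_spec])[keep],
        columns=tuple(feature_spec),
        weights=grid.weights[keep],
        rho=rho[keep],
        e_ref=np.where(rho > RHO_FLOOR, ebar / np.maximum(rho, RHO_FLOOR), 0.0)[keep],
        carrier=zeros[keep],
        e_os=zeros[keep],
        e_ss=zeros[keep],
        kappa=kappa,
        n_elec=1,
        e_ref_scalar=0.0,
    )


# --- losses ---------------------------------------------------------------

def compute_loss(
    mode: str,
    predicted: list[np.ndarray],
    systems: list[SystemData],
    interactions: list[tuple[float, float]] | None = None,
    lam_tot: float = 1.0,
    lam_int: float = 1.0,
) -> float:
    """Scalar loss for per-point predictions e_ml (per particle) per system.

    For 'combined', `interactions` carries (de_pred, de_ref) pairs.
    """
    if mode not in LOSS_MODES:
        raise ValueError(f"unknown loss mode '{mode}'")
    if mode == "combined":
        terms = [
            abs(s.e_ref_scalar - float(np.dot(s.wrho, e)))
            for s, e in zip(systems, predicted)
        ]
        tot = np.mean(terms) if terms else 0.0
        inter = (
            np.mean([abs(dp - dr) for dp, dr in interactions])
            if interactions
            else 0.0
        )
        return lam_tot * tot + lam_int * inter
    terms = []
    for s, e_ml in zip(systems, predicted):
        if mode == "les":
            terms.append(float(np.dot(s.wrho, np.abs(s.e_ref - e_ml))))
        elif mode == "les2":
            terms.append(float(np.dot(s.wrho, (s.e_ref - e_ml) ** 2)))
        elif mode == "ges":
            terms.append(abs(s.e_ref_scalar - float(np.dot(s.wrho, e_ml))))
        elif mode == "direct":
            # density-weighted target learned directly
            terms.append(
                float(np.dot(s.weights, np.abs(s.rho * s.e_ref - e_ml)))
            )
    return float(np.mean(terms))


# --- estimators -----------------------------------------------------------

# fixed bounded input map applied ahead of the first network layer: the
# physical descriptors are unbounded (s, alpha, r_s grow without bound in
# density tails) and would saturate tanh units; x/(1+x) compresses each to
# an order-one range while keeping small-feature behavior linear
_SQUASH = {
    "s": lambda x: x / (1.0 + x),
    "q": lambda x: x / (1.0 + np.abs(x)),
    "alpha": lambda x: x / (1.0 + x),
    "f1": lambda x: x,
    "f2": lambda x: x,
    "rs": lambda x: x / (1.0 + x),
    "xc": lambda x: x / (1.0 + np.abs(x)),
    "xos": lambda x: x / (1.0 + np.abs(x)),
    "zeta": lambda x: x,
}


def _squash_features(X: np.ndarray, columns: tuple[str, ...]) -> np.ndarray:
    out = np.empty_like(X)
    for k, name in enumerate(columns):
        out[:, k] = _SQUASH[name](X[:, k])
    return out


class _NeuralFunctional(BaseEstimator):
    """Shared fit loop: full-system batches, Adam, warm-up + decay."""

    def _net_inputs(self, system: SystemData) -> np.ndarray:
        cached = getattr(system, "_squashed", None)
        if cached is None:
            cached = _squash_features(system.features, system.columns)
            system._squashed = cached
        return cached

    def _spec(self, n_inputs: int) -> MLPSpec:  # overridden
        raise NotImplementedError

    def _model_output_and_grad(self, net, system):
        """Return (e_ml, pullback) where pullback maps dL/de_ml to flat grads."""
        raise NotImplementedError

    def _check_systems(self, systems):
        cols = systems[0].columns
        for s in systems:
            if s.columns != cols:
                raise ValueError("inconsistent feature columns across systems")
        expected = tuple(self.feature_spec)
        if cols != expected:
            raise ValueError(
                f"feature columns {cols} do not match model spec {expected}"
            )

    def fit(self, systems: list[SystemData], validation_systems=None):
        self._check_systems(systems)
        rng = np.random.default_rng(self.seed)
        spec = self._spec(len(systems[0].columns))
        net = MLP(spec, rng)
        params = net.get_flat()
        opt = Adam(params.size)
        history = []
        val_history = []
        for epoch in range(self.epochs):
            loss, grad = self._loss_and_grad(net, systems)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            lr = lr_schedule(
                epoch, self.epochs, self.learning_rate, self.warmup_frac, self.decay_to
            )
            params = opt.step(params, grad, lr)
            net.set_flat(params)
            history.append(loss)
            if validation_systems and (epoch % 50 == 0 or epoch == self.epochs - 1):
                preds = [self._model_output_and_grad(net, s)[0] for s in validation_systems]
                val_history.append(
                    (epoch, compute_loss(self._base_mode(), preds, validation_systems))
                )
        self.net_ = net
        self.spec_ = spec
        self.loss_history_ = np.asarray(history)
        self.validation_history_ = val_history
        self.feature_columns_ = systems[0].columns
        self.kappa_ = systems[0].kappa
        return self

    def _base_mode(self):
        return self.loss if self.loss != "combined" else "ges"

    def _loss_and_grad(self, net, systems):
        n_sys = len(systems)
        loss_terms = []
        grad = np.zeros(net.get_flat().size)
        for s in systems:
            e_ml, pullback = self._model_output_and_grad(net, s, need_cache=True)
            mode = self.loss
            if mode == "les":
                r = s.e_ref - e_ml
                loss_terms.append(float(np.dot(s.wrho, np.abs(r))))
                dL = -s.wrho * np.sign(r)
            elif mode == "les2":
                r = s.e_ref - e_ml
                loss_terms.append(float(np.dot(s.wrho, r * r)))
                dL = -2.0 * s.wrho * r
            elif mode == "ges" or mode == "combined":
                E_ml = float(np.dot(s.wrho, e_ml))
                r = s.e_ref_scalar - E_ml
                loss_terms.append(abs(r))
                dL = -np.sign(r) * s.wrho
            elif mode == "direct":
                r = s.rho * s.e_ref - e_ml
                loss_terms.append(float(np.dot(s.weights, np.abs(r))))
                dL = -s.weights * np.sign(r)
            else:
                raise ValueError(f"unknown loss mode '{mode}'")
            grad += pullback(dL) / n_sys
        return float(np.mean(loss_terms)), grad

    # -- prediction --
    def predict(self, system: SystemData) -> np.ndarray:
        """Per-particle model correlation energy density on system points."""
        e_ml, _ = self._model_output_and_grad(self.net_, system)
        return e_ml

    def predict_energy(self, system: SystemData) -> float:
        return float(np.dot(system.wrho, self.predict(system)))


class ML2Model(_NeuralFunctional):
    """LES/GES-trainable rescaling of the exchange energy density."""

    feature_spec = ML2_FEATURES

    def __init__(
        self,
        loss: str = "les",
        epochs: int = 5000,
        learning_rate: float = 0.1,
        warmup_frac: float = 0.05,
        decay_to: float = 0.03,
        seed: int = 0,
        hidden: tuple[int, ...] = (16, 16, 16),
    ):
        self.loss = loss
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.warmup_frac = warmup_frac
        self.decay_to = decay_to
        self.seed = seed
        self.hidden = hidden

    def _spec(self, n_inputs):
        return MLPSpec(
            n_inputs=n_inputs,
            hidden=tuple(self.hidden),
            output_activation="tanh",
            n_outputs=1,
            output_scale=1.0,
        )

    def _model_output_and_grad(self, net, system, need_cache=False):
        # under the 'direct' loss the same functional form is read as the
        # density-weighted field ebar_ml; the loss accounts for that
        carrier = system.carrier
        out, cache = net.forward(self._net_inputs(system), need_cache=True)
        w_c = out[:, 0]
        e_ml = w_c * carrier

        def pullback(dL):
            dout = (dL * carrier)[:, None]
            return net.backward(cache, dout)

        return e_ml, pullback


class MLS2Model(_NeuralFunctional):
    """Real-space spin-component scaling of regularized MP2 channels."""

    feature_spec = MLS2_FEATURES

    def __init__(
        self,
        loss: str = "combined",
        epochs: int = 1000,
        learning_rate: float = 0.003,
        warmup_frac: float = 0.05,
        decay_to: float = 0.01,
        seed: int = 0,
        hidden: tuple[int, ...] = (64, 64, 64, 64),
        lam_tot: float = 1.0,
        lam_int: float = 1.0,
    ):
        self.loss = loss
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.warmup_frac = warmup_frac
        self.decay_to = decay_to
        self.seed = seed
        self.hidden = hidden
        self.lam_tot = lam_tot
        self.lam_int = lam_int

    def _spec(self, n_inputs):
        return MLPSpec(
            n_inputs=n_inputs,
            hidden=tuple(self.hidden),
            output_activation="sigmoid",
            n_outputs=2,
            output_scale=10.0,
        )

    def _model_output_and_grad(self, net, system, need_cache=False):
        out, cache = net.forward(self._net_inputs(system), need_cache=True)
        w_os, w_ss = out[:, 0], out[:, 1]
        e_ml = w_os * system.e_os + w_ss * system.e_ss

        def pullback(dL):
            dout = np.stack([dL * system.e_os, dL * system.e_ss], axis=1)
            return net.backward(cache, dout)

        return e_ml, pullback

    def fit(self, systems, validation_systems=None, interactions: list[InteractionData] | None = None):
        if self.loss != "combined" or not interactions:
            return super().fit(systems, validation_systems)
        self._check_systems(systems)
        rng = np.random.default_rng(self.seed)
        spec = self._spec(len(systems[0].columns))
        net = MLP(spec, rng)
        params = net.get_flat()
        opt = Adam(params.size)
        history = []
        n_sys = len(systems)
        n_int = len(interactions)
        for epoch in range(self.epochs):
            grad = np.zeros(params.size)
            # total-energy GES term
            tot_terms = []
            for s in systems:
                e_ml, pullback = self._model_output_and_grad(net, s)
                r = s.e_ref_scalar - float(np.dot(s.wrho, e_ml))
                tot_terms.append(abs(r))
                grad += self.lam_tot * pullback(-np.sign(r) * s.wrho) / n_sys
            # interaction-energy GES term
            int_terms = []
            for job in interactions:
                parts = [(job.complex, 1.0)] + [(f, -1.0) for f in job.fragments]
                de = 0.0
                pullbacks = []
                for s, sgn in parts:
                    e_ml, pb = self._model_output_and_grad(net, s)
                    de += sgn * float(np.dot(s.wrho, e_ml))
                    pullbacks.append((s, sgn, pb))
                r = job.de_ref - de
                int_terms.append(abs(r))
                for s, sgn, pb in pullbacks:
                    grad += self.lam_int * pb(-np.sign(r) * sgn * s.wrho) / n_int
            loss = self.lam_tot * np.mean(tot_terms) + (
                self.lam_int * np.mean(int_terms) if int_terms else 0.0
            )
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            lr = lr_schedule(
                epoch, self.epochs, self.learning_rate, self.warmup_frac, self.decay_to
            )
            params = opt.step(params, grad, lr)
            net.set_flat(params)
            history.append(float(loss))
        self.net_ = net
        self.spec_ = spec
        self.loss_history_ = np.asarray(history)
        self.validation_history_ = []
        self.feature_columns_ = systems[0].columns
        self.kappa_ = systems[0].kappa
        return self


def train_seed_ensemble(
    model_factory, systems, seeds, validation_systems, **fit_kwargs
):
    """Train one model per seed; return (best_model, all_models).

    Selection by final validation loss (ties by seed order); the optional
    workflow for picking a production model out of several inits.
    """
    models = []
    scores = []
    for seed in seeds:
        m = model_factory(seed)
        m.fit(systems, validation_systems=validation_systems, **fit_kwargs)
        preds = [m.predict(s) for s in validation_systems]
        scores.append(compute_loss(m._base_mode(), preds, validation_systems))
        models.append(m)
    best = models[int(np.argmin(scores))]
    return best, models
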