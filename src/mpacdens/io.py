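"""Readers and writers for every artifact the toolkit touches.

XYZ (angstrom, standard dialect), Gaussian cube volumes (bohr, z-fastest
ordering), CSV tables with annotated headers, and model checkpoints
(JSON metadata + npz weight arrays, bitwise round-trip).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import MLP, MLPSpec
from .reference import BOHR_PER_ANGSTROM, MoleculeSpec, ATOMIC_NUMBER

__all__ = [
    "read_xyz",
    "write_xyz",
    "write_cube",
    "write_table",
    "save_checkpoint",
    "load_checkpoint",
]


def read_xyz(path, charge: int = 0, multiplicity: int = 1,
             basis: str = "desk-dz") -> MoleculeSpec:
    """Read a standard XYZ file (coordinates in angstrom)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}:1: empty XYZ file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}:1: expected atom count") from None
    symbols, coords = [], []
    for ln, line in enumerate(lines[2 : 2 + natoms], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: expected 'symbol x y z'")
        sym = parts[0].capitalize()
        if sym not in ATOMIC_NUMBER:
            raise ValueError(f"{path}:{ln}: unknown element '{parts[0]}'")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ValueError(f"{path}:{ln}: malformed coordinate") from None
        symbols.append(sym)
        coords.append([c * BOHR_PER_ANGSTROM for c in xyz])
    if len(symbols) != natoms:
        raise ValueError(f"{path}: header declares {natoms} atoms, found {len(symbols)}")
    label = lines[1].strip() if len(lines) > 1 else ""
    return MoleculeSpec(
        symbols=tuple(symbols), coords=tuple(map(tuple, coords)),
        charge=charge, multiplicity=multiplicity, basis=basis, label=label,
    )


def write_xyz(mol: MoleculeSpec, path) -> None:
    lines = [str(len(mol.symbols)), mol.label or ""]
    for sym, xyz in zip(mol.symbols, mol.coords_array):
        x, y, z = xyz / BOHR_PER_ANGSTROM
        lines.append(f"{sym} {x:.12f} {y:.12f} {z:.12f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_cube(
    path,
    mol: MoleculeSpec,
    evaluate,  # callable points(N,3 bohr) -> values (N,)
    origin=None,
    lengths=(10.0, 10.0, 10.0),
    shape=(40, 40, 40),
    comment: str = "density-weighted field (hartree/bohr^3)",
) -> None:
    """Write a Gaussian cube file by evaluating a field on a regular lattice.

    Cube files here always carry density-weighted (volume-integrable)
    fields; per-particle fields go to point tables instead.
    """
    coords = mol.coords_array
    if origin is None:
        origin = coords.mean(axis=0) - 0.5 * np.asarray(lengths)
    origin = np.asarray(origin, dtype=float)
    nx, ny, nz = shape
    steps = np.asarray(lengths, dtype=float) / (np.asarray(shape) - 1)
    xs = origin[0] + steps[0] * np.arange(nx)
    ys = origin[1] + steps[1] * np.arange(ny)
    zs = origin[2] + steps[2] * np.arange(nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    vals = np.asarray(evaluate(pts)).reshape(nx, ny, nz)
    with open(path, "w") as fh:
        fh.write("mpacdens cube\n")
        fh.write(comment + "\n")
        fh.write(f"{len(mol.symbols):5d} {origin[0]:12.6f} {origin[1]:12.6f} {origin[2]:12.6f}\n")
        fh.write(f"{nx:5d} {steps[0]:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{ny:5d} {0.0:12.6f} {steps[1]:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {steps[2]:12.6f}\n")
        for sym, xyz in zip(mol.symbols, coords):
            Zn = ATOMIC_NUMBER[sym]
            fh.write(f"{Zn:5d} {float(Zn):12.6f} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}\n")
        for ix in range(nx):
            for iy in range(ny):
                row = vals[ix, iy]
                for k in range(0, nz, 6):
                    fh.write("".join(f"{v:13.5e}" for v in row[k : k + 6]) + "\n")


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """CSV with '#'-prefixed metadata header lines."""
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def save_checkpoint(model, path) -> None:
    """Persist a fitted functional model to a directory."""
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    net: MLP = model.net_
    spec: MLPSpec = model.spec_
    meta = {
        "class": type(model).__name__,
        "params": model.get_params(),
        "spec": {
            "n_inputs": spec.n_inputs,
            "hidden": list(spec.hidden),
            "output_activation": spec.output_activation,
            "n_outputs": spec.n_outputs,
            "output_scale": spec.output_scale,
        },
        "feature_columns": list(model.feature_columns_),
        "kappa": model.kappa_,
    }
    (p / "metadata.json").write_text(json.dumps(meta, indent=2, default=_jsonable))
    np.savez(p / "weights.npz", flat=net.get_flat())
    np.savetxt(p / "loss_history.csv", model.loss_history_,
               header="loss", comments="")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_checkpoint(path):
    from . import models as _models

    p = Path(path)
    meta = json.loads((p / "metadata.json").read_text())
    cls = getattr(_models, meta["class"])
    model = cls(**{k: tuple(v) if isinstance(v, list) else v
                   for k, v in meta["params"].items()})
    spec = MLPSpec(
        n_inputs=meta["spec"]["n_inputs"],
        hidden=tuple(meta["spec"]["hidden"]),
        output_activation=meta["spec"]["output_activation"],
        n_outputs=meta["spec"]["n_outputs"],
        output_scale=meta["spec"]["output_scale"],
    )
    rng = np.random.default_rng(0)
    net = MLP(spec, rng)
    net.set_flat(np.load(p / "weights.npz")["flat"])
    model.net_ = net
    model.spec_ = spec
    model.feature_columns_ = tuple(meta["feature_columns"])
    model.kappa_ = meta["kappa"]
    model.loss_history_ = np.loadtxt(p / "loss_history.csv", skiprows=1, ndmin=1)
    model.validation_history_ = []
    return model


def load_run_config(path) -> dict:
    """Structured YAML run configuration.

    Recognized keys: system (fixture/xyz/charge/multiplicity), basis,
    aux settings, grid_level, kappa, model.preset, loss.mode,
    train.{epochs,seed,lr,warmup_frac,decay}, output.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level of a run config must be a mapping")
    return cfg
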