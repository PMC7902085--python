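"""File formats: CA-only PDB structures, trajectory archives, model documents.

Structures are exchanged as standard PDB files carrying one CA record per
residue; chains map to the complex's A/B labels.  Trajectories go to a
compressed array container (.npz) with a JSON sidecar of parameters.
Models serialize to human-diffable JSON documents with a type tag and
format version; numeric fields round-trip bit-exactly via full-precision
repr, and a reloaded Markov model re-verifies its stationary vector
against its transition matrix on load.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .boundstate import BiexpFit, RcutScan
from .features import TICAModel
from .model import CGComplex
from .msm import CountMatrix, MarkovModel
from .simulate import LangevinParams, RunResult, UmbrellaBias
from .tram import TRAMModel

__all__ = [
    "read_structure",
    "write_structure",
    "save_run",
    "load_run",
    "save_model",
    "load_model",
]

FORMAT_VERSION = 1


def read_structure(path) -> dict[str, np.ndarray]:
    """Read a CA-only PDB; returns chain id -> (n, 3) coordinates (file order)."""
    pdb = pdbio.PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    ca = atoms[atoms.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ValueError(f"no CA records in {path}")
    chains: dict[str, np.ndarray] = {}
    for cid in np.unique(ca.chain_id):
        chains[str(cid)] = ca.coord[ca.chain_id == cid].astype(float)
    return chains


def write_structure(cplx: CGComplex, path) -> None:
    """Write the reference pose as a CA-only PDB (chains A and B)."""
    n = cplx.n_beads
    atoms = struc.AtomArray(n)
    atoms.coord = cplx.reference.astype(np.float32)
    atoms.chain_id = np.array(["A" if c == 0 else "B" for c in cplx.chain_ids])
    res_ids = np.empty(n, dtype=int)
    res_ids[cplx.idx_A] = np.arange(1, cplx.n_A + 1)
    res_ids[cplx.idx_B] = np.arange(1, cplx.n_B + 1)
    atoms.res_id = res_ids
    atoms.res_name = np.full(n, "GLY")
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    pdb = pdbio.PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def write_contact_table(contacts, path) -> None:
    """Write Go contacts as whitespace-delimited iA iB r_min epsilon."""
    with open(path, "w") as fh:
        fh.write("# iA iB r_min epsilon\n")
        for c in contacts:
            row = (c.index_A, c.index_B, c.r_min, c.epsilon) if hasattr(c, "r_min") else c
            fh.write("{} {} {!r} {!r}\n".format(*row))


def read_contact_table(path) -> list[tuple[int, int, float, float]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].replace(",", " ").strip()
            if not line:
                continue
            ia, ib, rmin, eps = line.split()
            rows.append((int(ia), int(ib), float(rmin), float(eps)))
    return rows


def save_run(run: RunResult, path) -> None:
    """Archive a trajectory: arrays in .npz, parameters in a JSON sidecar."""
    path = Path(path)
    arrays = {
        "frames": run.frames,
        "frame_times": run.frame_times,
        "chain_ids": run.chain_ids,
        "masses": run.masses,
    }
    if run.bias_energies is not None:
        arrays["bias_energies"] = run.bias_energies
    np.savez_compressed(path, **arrays)
    side = {
        "format_version": FORMAT_VERSION,
        "params": asdict(run.params),
        "window": asdict(run.window) if run.window else None,
    }
    path.with_suffix(".json").write_text(json.dumps(side, indent=1))


def load_run(path) -> RunResult:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    data = np.load(path)
    side = json.loads(path.with_suffix(".json").read_text())
    if side["format_version"] != FORMAT_VERSION:
        raise ValueError(f"unsupported archive version {side['format_version']}")
    return RunResult(
        frames=data["frames"],
        frame_times=data["frame_times"],
        params=LangevinParams(**side["params"]),
        chain_ids=data["chain_ids"],
        masses=data["masses"],
        window=UmbrellaBias(**side["window"]) if side["window"] else None,
        bias_energies=data["bias_energies"] if "bias_energies" in data else None,
    )


def write_xyz(run: RunResult, path) -> None:
    """Plain XYZ export (element C for every bead)."""
    with open(path, "w") as fh:
        for t, frame in enumerate(run.frames):
            fh.write(f"{len(frame)}\nframe {t} t={run.frame_times[t]!r} ns\n")
            for x, y, z in frame:
                fh.write(f"C {x:.6f} {y:.6f} {z:.6f}\n")


def _arr(x):
    return np.asarray(x).tolist()


def save_model(model, path) -> None:
    """Serialize a supported model to a versioned JSON document."""
    if isinstance(model, MarkovModel):
        doc = {
            "type": "MarkovModel",
            "T": _arr(model.T),
            "pi": _arr(model.pi),
            "lag_time": model.lag_time,
            "eigenvalues": _arr(model.eigenvalues),
            "active_set": _arr(model.active_set),
            "reversible": model.reversible,
        }
    elif isinstance(model, TICAModel):
        doc = {
            "type": "TICAModel",
            "mean": _arr(model.mean),
            "C0": _arr(model.C0),
            "Ctau": _arr(model.Ctau),
            "lag": model.lag,
            "eigenvectors": _arr(model.eigenvectors),
            "eigenvalues": _arr(model.eigenvalues),
            "timescales": _arr(np.where(np.isfinite(model.timescales), model.timescales, -1.0)),
            "frame_interval": model.frame_interval,
        }
    elif isinstance(model, TRAMModel):
        doc = {
            "type": "TRAMModel",
            "state_free_energies": _arr(model.state_free_energies),
            "unbiased_pi": _arr(model.unbiased_pi),
            "transition_matrices": _arr(model.transition_matrices),
            "active_set": _arr(model.active_set),
            "lag": model.lag,
            "converged": model.converged,
            "final_increment": model.final_increment,
            "n_iterations": model.n_iterations,
        }
    elif isinstance(model, RcutScan):
        doc = {
            "type": "RcutScan",
            "grid": _arr(model.grid),
            "fits": [asdict(f) if f is not None else None for f in model.fits],
            "optimal_rcut": model.optimal_rcut,
        }
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    doc["format_version"] = FORMAT_VERSION
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path):
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported document version {doc.get('format_version')}")
    t = doc.get("type")
    if t == "MarkovModel":
        # MarkovModel.__post_init__ re-verifies pi T = pi (integrity check)
        return MarkovModel(
            T=np.array(doc["T"]),
            lag_time=doc["lag_time"],
            pi=np.array(doc["pi"]),
            eigenvalues=np.array(doc["eigenvalues"]),
            active_set=np.array(doc["active_set"], dtype=int),
            reversible=doc["reversible"],
        )
    if t == "TICAModel":
        ts = np.array(doc["timescales"])
        return TICAModel(
            mean=np.array(doc["mean"]),
            C0=np.array(doc["C0"]),
            Ctau=np.array(doc["Ctau"]),
            lag=doc["lag"],
            eigenvectors=np.array(doc["eigenvectors"]),
            eigenvalues=np.array(doc["eigenvalues"]),
            timescales=np.where(ts < 0, np.inf, ts),
            frame_interval=doc["frame_interval"],
        )
    if t == "TRAMModel":
        return TRAMModel(
            state_free_energies=np.array(doc["state_free_energies"]),
            unbiased_pi=np.array(doc["unbiased_pi"]),
            transition_matrices=np.array(doc["transition_matrices"]),
            active_set=np.array(doc["active_set"], dtype=int),
            lag=doc["lag"],
            converged=doc["converged"],
            final_increment=doc["final_increment"],
            n_iterations=doc["n_iterations"],
        )
    if t == "RcutScan":
        fits = [BiexpFit(**f) if f is not None else None for f in doc["fits"]]
        return RcutScan(grid=np.array(doc["grid"]), fits=fits, optimal_rcut=doc["optimal_rcut"])
    raise ValueError(f"unknown model type tag {t!r}")
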