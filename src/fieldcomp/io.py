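"""Reading and writing probe arrays, phase/k time-series and models.

Two on-disk forms are supported:

* an HDF5 container with groups ``/probes``, ``/phase``, ``/k`` and
  ``/compression`` (units and order labels stored as attributes);
* portable text formats — probe arrays and k time-courses as CSV, and
  compression models as JSON (singular spectrum and C_high inlined).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .harmonics import HarmonicIndexing, ProbeArray
from .fitting import KCoefficients, PhaseData
from .compression import CompressionModel

__all__ = [
    "read_probes_csv", "write_probes_csv",
    "write_k_csv", "read_k_csv",
    "save_container", "load_container",
    "save_model_json", "load_model_json",
]


# -- CSV ---------------------------------------------------------------------

def write_probes_csv(path, probes: ProbeArray) -> None:
    df = pd.DataFrame({
        "probe_id": np.arange(probes.n_probes),
        "x_m": probes.positions[:, 0],
        "y_m": probes.positions[:, 1],
        "z_m": probes.positions[:, 2],
        "weight": probes.weights if probes.weights is not None
                  else np.ones(probes.n_probes),
    })
    df.to_csv(path, index=False)


def read_probes_csv(path) -> ProbeArray:
    df = pd.read_csv(path)
    pos = df[["x_m", "y_m", "z_m"]].to_numpy(float)
    w = df["weight"].to_numpy(float) if "weight" in df else None
    if w is not None and np.allclose(w, 1.0):
        w = None
    return ProbeArray(pos, w)


def write_k_csv(path, k: KCoefficients) -> None:
    """k time-courses as CSV: time + segment columns, one column per basis."""
    cols = {"time_s": k.time, "segment": k.segment_labels}
    for i, (l, m) in enumerate(k.indexing.index_map):
        cols[f"k_l{l}_m{m}"] = k.k[i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_k_csv(path) -> KCoefficients:
    df = pd.read_csv(path)
    kcols = [c for c in df.columns if c.startswith("k_l")]
    max_order = int(np.sqrt(len(kcols))) - 1
    indexing = HarmonicIndexing(max_order)
    k = np.stack([df[f"k_l{l}_m{m}"].to_numpy(float)
                  for l, m in indexing.index_map])
    return KCoefficients(k=k, indexing=indexing,
                         time=df["time_s"].to_numpy(float),
                         segment_labels=df["segment"].to_numpy(int))


# -- HDF5 container ----------------------------------------------------------

def save_container(path, probes: ProbeArray | None = None,
                   phase: PhaseData | None = None,
                   k: KCoefficients | None = None,
                   model: CompressionModel | None = None) -> None:
    with h5py.File(path, "w") as f:
        if probes is not None:
            g = f.create_group("probes")
            g.create_dataset("positions", data=probes.positions)
            g["positions"].attrs["units"] = "m"
            if probes.weights is not None:
                g.create_dataset("weights", data=probes.weights)
        if phase is not None:
            g = f.create_group("phase")
            g.create_dataset("phi", data=phase.phi)
            g["phi"].attrs["units"] = "rad"
            g.create_dataset("time", data=phase.time)
            g.create_dataset("segment_labels", data=phase.segment_labels)
        if k is not None:
            g = f.create_group("k")
            g.create_dataset("k", data=k.k)
            g["k"].attrs["units"] = "rad/m^l"
            g["k"].attrs["orders"] = k.indexing.orders
            g.attrs["max_order"] = k.indexing.max_order
            g.create_dataset("time", data=k.time)
            g.create_dataset("segment_labels", data=k.segment_labels)
        if model is not None:
            g = f.create_group("compression")
            g.create_dataset("C_high", data=model.C_high)
            g.create_dataset("singular_values", data=model.singular_values)
            g.attrs["gamma_base"] = model.gamma_base
            g.attrs["max_order"] = model.max_order
            g.attrs["L"] = model.L


def load_container(path) -> dict:
    """Load whichever groups are present; returns a dict of objects."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        if "probes" in f:
            g = f["probes"]
            w = g["weights"][()] if "weights" in g else None
            out["probes"] = ProbeArray(g["positions"][()], w)
        if "phase" in f:
            g = f["phase"]
            out["phase"] = PhaseData(phi=g["phi"][()], time=g["time"][()],
                                     segment_labels=g["segment_labels"][()])
        if "k" in f:
            g = f["k"]
            indexing = HarmonicIndexing(int(g.attrs["max_order"]))
            out["k"] = KCoefficients(k=g["k"][()], indexing=indexing,
                                     time=g["time"][()],
                                     segment_labels=g["segment_labels"][()])
        if "compression" in f:
            g = f["compression"]
            indexing = HarmonicIndexing(int(g.attrs["max_order"]))
            out["model"] = CompressionModel(
                indexing=indexing, C_high=g["C_high"][()],
                singular_values=g["singular_values"][()],
                gamma_base=float(g.attrs["gamma_base"]))
    return out


# -- JSON model sidecar ------------------------------------------------------

def save_model_json(path, model: CompressionModel) -> None:
    payload = {
        "max_order": model.max_order,
        "gamma_base": model.gamma_base,
        "L": model.L,
        "singular_values": model.singular_values.tolist(),
        "C_high": model.C_high.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model_json(path) -> CompressionModel:
    payload = json.loads(Path(path).read_text())
    return CompressionModel(
        indexing=HarmonicIndexing(int(payload["max_order"])),
        C_high=np.asarray(payload["C_high"], float),
        singular_values=np.asarray(payload["singular_values"], float),
        gamma_base=float(payload["gamma_base"]))
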