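"""File formats: NIfTI volumes and maps, delimited-text AIFs, NPZ SOM models,
and provenance records."""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np

from .kinetics import AIF, TimeGrid
from .pnms import PNMSModel
from .som import HitMaps, KohonenSOM, NeuronProbabilities

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_aif_text",
    "load_aif_text",
    "save_pnms_model",
    "load_pnms_model",
    "write_provenance",
]


def save_nifti(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_aif_text(path, aif: AIF, time_unit: str = "min") -> None:
    """Two-column delimited text (time, concentration) with a unit header."""

    t = aif.grid.t * 60.0 if time_unit == "s" else aif.grid.t
    header = f"time_unit: {time_unit}\nn_baseline: {aif.grid.n_baseline}\ntime concentration"
    np.savetxt(str(path), np.column_stack([t, aif.c]), header=header)


def load_aif_text(path, n_baseline: int | None = None) -> AIF:
    """Load a two-column AIF; a ``time_unit: s`` header converts to minutes."""

    path = Path(path)
    unit = "min"
    nb = 20
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            stripped = line.lstrip("#").strip()
            if stripped.startswith("time_unit:"):
                unit = stripped.split(":", 1)[1].strip()
            elif stripped.startswith("n_baseline:"):
                nb = int(stripped.split(":", 1)[1])
    data = np.loadtxt(str(path))
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path} is not a 2-column AIF file")
    t = data[:, 0] / 60.0 if unit == "s" else data[:, 0]
    grid = TimeGrid(t, n_baseline=nb if n_baseline is None else n_baseline)
    return AIF(grid, data[:, 1])


def save_pnms_model(path, model: PNMSModel) -> None:
    """Serialize a fitted probability model (SOM weights, hits, P) to NPZ."""

    som = model.som_
    np.savez(
        str(path),
        weights=som.weights_,
        positions=som.positions_,
        hits=model.hits_.counts,
        P=model.neuron_probabilities_.P,
        empty_mask=model.neuron_probabilities_.empty_mask,
        config=np.array(json.dumps(model.get_params()), dtype=object),
    )


def load_pnms_model(path) -> PNMSModel:
    with np.load(str(path), allow_pickle=True) as z:
        params = json.loads(str(z["config"]))
        model = PNMSModel(**params)
        som = KohonenSOM(
            **{k: params[k] for k in (
                "rows", "cols", "topology", "initial_neighborhood",
                "cover_steps", "max_epochs", "tol", "random_state",
            )}
        )
        som.weights_ = z["weights"]
        som.positions_ = z["positions"]
        som.n_features_in_ = som.weights_.shape[1]
        diff = som.positions_[:, None, :] - som.positions_[None, :, :]
        som.lattice_distances_ = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        som.n_iter_ = 0
        model.som_ = som
        model.hits_ = HitMaps(z["hits"])
        model.neuron_probabilities_ = NeuronProbabilities(
            P=z["P"], empty_mask=z["empty_mask"], scaling=params.get("scaling", "normalized")
        )
    return model


def write_provenance(outdir, config: dict) -> Path:
    """Record enough to re-run bit-identically: config, seeds, code version."""

    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"version": __version__, **config}
    blob = json.dumps(payload, indent=2, sort_keys=True, default=str)
    payload["config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    path = outdir / "provenance.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path
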