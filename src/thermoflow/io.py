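"""Feature-trajectory I/O, checkpoint loading and run manifests.

Features travel either as CSV/TSV (header row naming the feature columns,
metadata in leading ``#`` comment lines) or as an npz array container that
round-trips bit-exactly, including raw coordinates and segment bounds.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import FeatureTrajectory

__all__ = ["read_features", "write_features", "load_checkpoint",
           "write_manifest", "load_config"]


def write_features(traj: FeatureTrajectory, path):
    path = Path(path)
    if path.suffix == ".npz":
        arrays = {"frames": traj.frames,
                  "frame_interval": np.array(traj.frame_interval),
                  "temperature_tag": np.array(traj.temperature_tag),
                  "segment_bounds": traj.segment_bounds}
        if traj.coords is not None:
            arrays["coords"] = traj.coords
        if traj.labels is not None:
            arrays["labels"] = traj.labels
        np.savez(path, **arrays)
        return
    sep = "\t" if path.suffix == ".tsv" else ","
    with open(path, "w") as fh:
        fh.write(f"# frame_interval={traj.frame_interval!r}\n")
        fh.write(f"# temperature_tag={traj.temperature_tag!r}\n")
        fh.write(f"# segment_bounds={','.join(map(str, traj.segment_bounds))}\n")
        cols = [f"f{i}" for i in range(traj.n_features)]
        fh.write(sep.join(cols) + "\n")
        np.savetxt(fh, traj.frames, delimiter=sep, fmt="%.17g")


def read_features(path) -> FeatureTrajectory:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature file not found: {path}")
    if path.suffix == ".npz":
        with np.load(path) as z:
            return FeatureTrajectory(
                z["frames"],
                frame_interval=float(z["frame_interval"]),
                temperature_tag=float(z["temperature_tag"]),
                segment_bounds=z["segment_bounds"],
                coords=z["coords"] if "coords" in z else None,
                labels=z["labels"] if "labels" in z else None,
            )
    sep = "\t" if path.suffix == ".tsv" else ","
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, sep=sep, skiprows=skip)
    frames = df.to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(frames))
    if len(bad):
        r, c = bad[0]
        raise ValueError(f"non-numeric/NaN cell at data row {r}, column {df.columns[c]!r}")
    if "frame_interval" not in meta:
        warnings.warn("no frame_interval metadata; defaulting to 1.0")
    if "temperature_tag" not in meta:
        warnings.warn("no temperature_tag metadata; defaulting to 1.0")
    bounds = None
    if "segment_bounds" in meta:
        bounds = np.array([int(x) for x in meta["segment_bounds"].split(",")])
    return FeatureTrajectory(
        frames,
        frame_interval=float(meta.get("frame_interval", 1.0)),
        temperature_tag=float(meta.get("temperature_tag", 1.0)),
        segment_bounds=bounds,
    )


def load_checkpoint(path):
    """Rebuild a results object from a checkpoint archive."""
    from .flow import RealNVP
    from .model import SPIBResults, ThermoFlowModel, ThermoFlowResults, SPIBModel
    from .spib import EncoderDecoder, StateAssignment

    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        if header.get("format") != "thermoflow-checkpoint":
            raise ValueError(f"{path} is not a thermoflow checkpoint")
        arrays = {k: z[k] for k in z.files if k != "header"}

    mean, std = arrays["mean"], arrays["std"]
    net = EncoderDecoder(len(mean), header["n_states"],
                         latent_dim=header["latent_dim"],
                         encoder_hidden=tuple(header["encoder_hidden"]),
                         decoder_hidden=tuple(header["decoder_hidden"]))
    n_enc = len(net.encoder.state_arrays())
    net.encoder.load_arrays([arrays[f"enc_{i}"] for i in range(n_enc)])
    n_dec = len(net.decoder.state_arrays())
    net.decoder.load_arrays([arrays[f"dec_{i}"] for i in range(n_dec)])
    net.log_sigma.data = arrays["log_sigma"]
    flow = RealNVP(header["latent_dim"], header["flow_blocks"],
                   tuple(header["flow_hidden"]), s_max=header["s_max"])
    n_flow = len(flow.state_arrays())
    flow.load_arrays([arrays[f"flow_{i}"] for i in range(n_flow)])

    # minimal stand-in model: carries the scaler and hyperparameters; the
    # training frames themselves are not stored in a checkpoint
    stub_frames = np.zeros((2, len(mean)))
    cls = ThermoFlowModel if header["joint"] else SPIBModel
    model = cls.__new__(cls)
    model.lag = header["lag"]; model.tau = header["tau"]
    model.beta = header["beta"]; model.latent_dim = header["latent_dim"]
    model.encoder_hidden = tuple(header["encoder_hidden"])
    model.decoder_hidden = tuple(header["decoder_hidden"])
    model.flow_blocks = header["flow_blocks"]
    model.flow_hidden = tuple(header["flow_hidden"])
    model.s_max = header["s_max"]
    model._mean, model._std = mean, std
    model._X = stub_frames
    model.steerable_T = np.array([1.0])
    res_cls = ThermoFlowResults if header["joint"] else SPIBResults
    assign = StateAssignment.from_labels(arrays["labels"], compact=False)
    return res_cls(model=model, net=net, flow=flow,
                   pseudo_inputs=arrays["pseudo"], assignment=assign,
                   history=pd.DataFrame(), config=None, seed=header["seed"])


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(outdir, config: dict, seed: int, inputs=(), outputs=()):
    """Plain-text manifest making every CLI run reproducible."""
    from . import __version__

    outdir = Path(outdir)
    manifest = {
        "package_version": __version__,
        "seed": int(seed),
        "config": config,
        "inputs": {str(p): _digest(p) for p in inputs if Path(p).exists()},
        "outputs": {str(p): _digest(p) for p in outputs if Path(p).exists()},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg
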