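"""File interfaces: OBJ surfaces, TSV arrays, lead-field/basis persistence.

Lengths are metres internally; the TSV array interface is labelled in
millimetres.  CSV outputs written by the experiment recipes carry a
provenance comment (``# opmarray <version> config=<sha1>``) as their first
line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from opmarray.geometry import SensorArray, Surface

__all__ = ["write_surface_obj", "read_surface_obj", "write_array_tsv",
           "read_array_tsv", "save_leadfield", "load_leadfield",
           "save_basis", "config_hash", "write_csv_with_provenance"]


def write_surface_obj(surface: Surface, path) -> None:
    mesh = trimesh.Trimesh(surface.vertices, surface.faces, process=False)
    Path(path).write_text(trimesh.exchange.obj.export_obj(mesh, include_normals=False))


def read_surface_obj(path) -> Surface:
    """Load an OBJ surface; vertex normals are recomputed from the mesh."""
    mesh = trimesh.load(str(path), file_type="obj", process=False)
    normals = np.asarray(mesh.vertex_normals, float)
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    return Surface(np.asarray(mesh.vertices, float),
                   np.asarray(mesh.faces, np.int64), normals)


def write_array_tsv(array: SensorArray, path) -> None:
    sid = array.channel_to_sensor
    pos_mm = array.sensor_positions[sid] * 1000.0
    df = pd.DataFrame(dict(
        sensor_id=sid,
        channel_id=np.arange(array.n_channels),
        axis_index=np.arange(array.n_channels) % array.n_axes,
        x_mm=pos_mm[:, 0], y_mm=pos_mm[:, 1], z_mm=pos_mm[:, 2],
        ox=array.channel_orientations[:, 0],
        oy=array.channel_orientations[:, 1],
        oz=array.channel_orientations[:, 2],
    ))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_array_tsv(path) -> SensorArray:
    df = pd.read_csv(path, sep="\t")
    n_axes = int(df["axis_index"].max()) + 1
    sensors = df.drop_duplicates("sensor_id").sort_values("sensor_id")
    positions = sensors[["x_mm", "y_mm", "z_mm"]].to_numpy() / 1000.0
    df = df.sort_values("channel_id")
    return SensorArray(positions, df[["ox", "oy", "oz"]].to_numpy(),
                       df["sensor_id"].to_numpy(), n_axes)


def save_leadfield(leadfield, path_stem) -> None:
    """Binary matrix (.npy) plus a JSON sidecar with shape/mask/provenance."""
    stem = Path(path_stem)
    np.save(stem.with_suffix(".npy"), leadfield.matrix)
    sidecar = dict(shape=list(leadfield.matrix.shape),
                   source_mask=leadfield.source_mask.astype(int).tolist(),
                   meta={k: (v.tolist() if isinstance(v, np.ndarray) else v)
                         for k, v in leadfield.meta.items()})
    stem.with_suffix(".json").write_text(json.dumps(sidecar))


def load_leadfield(path_stem):
    from opmarray.forward import LeadField
    stem = Path(path_stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    return LeadField(np.load(stem.with_suffix(".npy")),
                     np.asarray(sidecar["source_mask"], bool) ,
                     meta=sidecar.get("meta", {}))


def save_basis(basis, path_stem) -> None:
    stem = Path(path_stem)
    np.save(stem.with_suffix(".npy"), basis.matrix)
    stem.with_suffix(".json").write_text(json.dumps(dict(
        kind=basis.kind, order=basis.order, origin=basis.origin.tolist(),
        term_index=[list(t) for t in basis.term_index])))


def config_hash(config_dict) -> str:
    return hashlib.sha1(json.dumps(config_dict, sort_keys=True,
                                   default=str).encode()).hexdigest()[:12]


def write_csv_with_provenance(df: pd.DataFrame, path, config_dict) -> None:
    from opmarray import __version__
    with open(path, "w") as fh:
        fh.write(f"# opmarray {__version__} config={config_hash(config_dict)}\n")
        df.to_csv(fh, index=False, float_format="%.8g")
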