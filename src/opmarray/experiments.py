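"""Config-driven experiment recipes chaining the library modules.

Each public ``run_*`` function reproduces one study: the attenuation sweep
(signal loss vs channel count and external order), neural-space saturation
(harmonic order vs offset), the lead-field eigenspectrum sweep, the
leverage-vs-distance diagnostic, and the radial/triaxial SNIR grid.  Every
recipe takes an :class:`ExperimentConfig`, is deterministic for a given
seed, and returns plain DataFrames / dicts; ``write=`` writes the CSV/JSON
artifacts with a provenance header.  The thin command-line layer in
:mod:`opmarray.cli` maps one command onto each recipe.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import opmarray.snir as snir
from opmarray import diagnostics, forward, geometry, io, projection, subspace
from opmarray.harmonics import build_basis, n_terms

__all__ = ["ExperimentConfig", "build_head", "build_array",
           "run_attenuation_sweep", "run_order_sweep", "run_saturation",
           "run_eigenspectrum", "run_leverage", "run_snir", "make_fixtures"]

log = logging.getLogger("opmarray")


@dataclass
class ExperimentConfig:
    """Geometry, sweep and threshold settings for the experiment recipes."""

    scalp_semi_axes: tuple = geometry.DEFAULT_SCALP["semi_axes"]
    scalp_center: tuple = geometry.DEFAULT_SCALP["center"]
    scalp_cut_height: float = geometry.DEFAULT_SCALP["cut_height"]
    scalp_mesh_resolution: int = geometry.DEFAULT_SCALP["mesh_resolution"]
    cortex_base_radius: float = geometry.DEFAULT_CORTEX["base_radius"]
    cortex_corrugation_amplitude: float = geometry.DEFAULT_CORTEX["corrugation_amplitude"]
    cortex_corrugation_frequency: float = geometry.DEFAULT_CORTEX["corrugation_frequency"]
    cortex_n_vertices: int = geometry.DEFAULT_CORTEX["n_vertices"]
    spacings_mm: tuple = tuple(range(85, 10, -5))     # 85 -> 15 in 5 mm steps
    n_axes_list: tuple = (1, 2, 3)
    offset_mm: float = 6.5
    squid_offset_mm: float = 24.0
    interference_orders: tuple = (1, 2, 3)
    order_sweep_max: int = 12
    saturation_L_max: int = 15
    ve_threshold: float = 0.99
    fraction_threshold: float = 0.95
    floor_fraction: float = 0.05
    snir_w: float = 2.5
    snir_sf_range_db: tuple = (1.0, 40.0)
    snir_a_range: tuple = (0.0, 20.0)
    seed: int = 0
    output_dir: str = "results"

    @property
    def thresholds(self):
        return (self.ve_threshold, self.fraction_threshold)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise KeyError(f"unknown config field {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def build_head(config: ExperimentConfig):
    """The synthetic scalp and corrugated cortical source space."""
    scalp = geometry.make_scalp_surface(config.scalp_semi_axes, config.scalp_center,
                                        config.scalp_cut_height,
                                        config.scalp_mesh_resolution)
    cortex = geometry.make_cortical_source_space(
        config.cortex_base_radius, config.cortex_corrugation_amplitude,
        config.cortex_corrugation_frequency, config.cortex_n_vertices,
        center=config.scalp_center)
    return scalp, cortex


def build_array(config: ExperimentConfig, n_axes: int, spacing_mm=None,
                n_sensors=None, offset_mm=None, scalp=None):
    if scalp is None:
        scalp, _ = build_head(config)
    return geometry.build_array(scalp, n_axes, spacing_mm=spacing_mm,
                                n_sensors=n_sensors,
                                offset_mm=config.offset_mm if offset_mm is None else offset_mm,
                                seed=config.seed)


def _leadfield(config, array, cortex):
    lf = forward.compute_leadfield(array, cortex)
    return forward.filter_weak_sources(lf, config.floor_fraction)


def _timed(name):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            log.info("%s finished in %.1f s", name, time.perf_counter() - self.t0)
    return _T()


def run_attenuation_sweep(config: ExperimentConfig, write: bool = False) -> pd.DataFrame:
    """Signal-loss sweep over spacings x axis counts x low external orders."""
    scalp, cortex = build_head(config)
    with _timed("attenuation sweep"):
        df = projection.attenuation_sweep(
            scalp, cortex, spacings=config.spacings_mm,
            n_axes_list=config.n_axes_list, orders=config.interference_orders,
            offset_mm=config.offset_mm, seed=config.seed,
            floor_fraction=config.floor_fraction)
    if write:
        _write(df, config, "attenuation_sweep.csv")
    return df


def run_order_sweep(config: ExperimentConfig, n_sensors=(60, 400),
                    write: bool = False) -> pd.DataFrame:
    """Attenuation vs external order 1..``order_sweep_max`` at fixed sensor counts.

    Contrasts the statistical limit (regressor count approaching channel
    count, realistic 60-sensor array) with the physical limit (ideal
    400-sensor array where regressors never approach channels).
    """
    scalp, cortex = build_head(config)
    rows = []
    with _timed("order sweep"):
        for n in n_sensors:
            for n_axes in config.n_axes_list:
                array = build_array(config, n_axes, n_sensors=n, scalp=scalp)
                lf = _leadfield(config, array, cortex)
                basis = build_basis(array, config.order_sweep_max, "external",
                                    geometry.expansion_origin_for(scalp))
                for L in range(1, config.order_sweep_max + 1):
                    with np.errstate(invalid="ignore"):
                        M = projection.external_projector(basis.truncated(L))
                    res = projection.leadfield_attenuation(M, lf, order=L)
                    rows.append(dict(sensors=n, n_axes=n_axes,
                                     channels=array.n_channels, order=L,
                                     n_regressors=n_terms(L),
                                     median_db=res.median_db,
                                     q2p5_db=res.q2p5_db))
    df = pd.DataFrame(rows)
    if write:
        _write(df, config, "order_sweep.csv")
    return df


def run_saturation(config: ExperimentConfig, spacing_mm: float = 15.0,
                   write: bool = False) -> dict:
    """Saturation order of the internal basis at on-scalp and SQUID offsets."""
    scalp, cortex = build_head(config)
    out = {}
    with _timed("saturation"):
        for label, offset in (("opm", config.offset_mm),
                              ("squid", config.squid_offset_mm)):
            per_axis = {}
            for n_axes in config.n_axes_list:
                array = build_array(config, n_axes, spacing_mm=spacing_mm,
                                    offset_mm=offset, scalp=scalp)
                lf = _leadfield(config, array, cortex)
                res = subspace.saturation_order(
                    array, lf, config.saturation_L_max, config.thresholds,
                    origin=geometry.expansion_origin_for(scalp))
                per_axis[n_axes] = res
                log.info("%s offset, %d axes: saturation order %s", label,
                         n_axes, res.order_or_count)
            out[label] = per_axis
    if write:
        rows = [dict(system=label, n_axes=n_axes, order=L, fraction_passing=f)
                for label, per_axis in out.items()
                for n_axes, res in per_axis.items()
                for L, f in zip(res.steps, res.ve_curve)]
        _write(pd.DataFrame(rows), config, "saturation_curves.csv")
        summary = {label: {n_axes: res.order_or_count
                           for n_axes, res in per_axis.items()}
                   for label, per_axis in out.items()}
        _write_json(summary, config, "saturation_summary.json")
    return out


def run_eigenspectrum(config: ExperimentConfig, write: bool = False) -> pd.DataFrame:
    """Required eigenvector count over the spacing grid and axis counts."""
    scalp, cortex = build_head(config)
    rows = []
    with _timed("eigenspectrum sweep"):
        for spacing in config.spacings_mm:
            for n_axes in config.n_axes_list:
                array = build_array(config, n_axes, spacing_mm=spacing, scalp=scalp)
                lf = _leadfield(config, array, cortex)
                res = subspace.required_eigenvectors(lf, config.thresholds)
                rows.append(dict(spacing=spacing, n_axes=n_axes,
                                 sensors=array.n_sensors,
                                 channels=array.n_channels,
                                 k_required=res.order_or_count))
    df = pd.DataFrame(rows)
    if write:
        _write(df, config, "eigenspectrum.csv")
    return df


def run_leverage(config: ExperimentConfig, orders=(1, 6, 12), spacing_mm=15.0,
                 write: bool = False) -> pd.DataFrame:
    """Leverage vs distance-to-origin, on the scalp array and a sphere control."""
    scalp, _ = build_head(config)
    rows = []
    with _timed("leverage"):
        for label, arr in (("scalp", build_array(config, 1, spacing_mm=spacing_mm,
                                                 scalp=scalp)),
                           ("sphere", _sphere_array(config, spacing_mm))):
            origin = geometry.expansion_origin_for(scalp if label == "scalp"
                                                   else _sphere_surface(config))
            basis = build_basis(arr, max(orders), "internal", origin)
            for L in orders:
                res = diagnostics.leverage(basis.truncated(L), arr, origin)
                for ch in range(arr.n_channels):
                    rows.append(dict(surface=label, channel_id=ch,
                                     distance_mm=res.distance_to_origin[ch] * 1000,
                                     order=L, leverage=res.leverage[ch],
                                     relative_leverage=res.relative_leverage[ch]))
    df = pd.DataFrame(rows)
    if write:
        _write(df, config, "leverage.csv")
    return df


def _sphere_array(config, spacing_mm):
    r = float(np.mean(config.scalp_semi_axes))
    sphere = geometry.make_scalp_surface((r, r, r), (0, 0, 0), cut_height=None,
                                         mesh_resolution=config.scalp_mesh_resolution)
    return geometry.build_array(sphere, 1, spacing_mm=spacing_mm,
                                offset_mm=config.offset_mm, seed=config.seed)


def run_snir(config: ExperimentConfig, n_sensors: int = 60,
             write: bool = False) -> dict:
    """Radial/triaxial SNIR grids at external orders 1..3.

    Amplitude attenuation factors come from the median lead-field loss of
    the ``n_sensors`` radial and triaxial arrays at each order.
    """
    scalp, cortex = build_head(config)
    grids = {}
    with _timed("snir"):
        att = {}
        for n_axes in (1, 3):
            array = build_array(config, n_axes, n_sensors=n_sensors, scalp=scalp)
            lf = _leadfield(config, array, cortex)
            basis = build_basis(array, max(config.interference_orders), "external",
                                geometry.expansion_origin_for(scalp))
            for L in config.interference_orders:
                M = projection.external_projector(basis.truncated(L))
                att[(n_axes, L)] = projection.leadfield_attenuation(M, lf).median_db
        for L in config.interference_orders:
            grids[L] = snir.snir_grid(
                w=config.snir_w, sf_range_db=config.snir_sf_range_db,
                a_range=config.snir_a_range,
                att_rad=float(snir.attenuation_db_to_factor(att[(1, L)])),
                att_tri=float(snir.attenuation_db_to_factor(att[(3, L)])),
                order=L)
    if write:
        df = pd.concat([g.to_frame().assign(order=L) for L, g in grids.items()])
        _write(df, config, "snir_grid.csv")
    return grids


def make_fixtures(seed: int = 0):
    """Small deterministic geometry bundle for unit tests and examples.

    12-sensor triaxial array, 200-vertex cortex, and the matching filtered
    lead field.
    """
    config = ExperimentConfig(cortex_n_vertices=200, scalp_mesh_resolution=3,
                              seed=seed)
    scalp, cortex = build_head(config)
    array = geometry.build_array(scalp, 3, n_sensors=12, seed=seed)
    lf = _leadfield(config, array, cortex)
    return dict(config=config, scalp=scalp, cortex=cortex, array=array,
                leadfield=lf)


def _outdir(config) -> Path:
    p = Path(config.output_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _write(df, config, name):
    io.write_csv_with_provenance(df, _outdir(config) / name, config.as_dict())
    log.info("wrote %s", _outdir(config) / name)


def _write_json(obj, config, name):
    import json
    (_outdir(config) / name).write_text(json.dumps(obj, indent=2, default=str))
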