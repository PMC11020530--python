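"""Configuration, file export and experiment orchestration.

Meshes, label fields and density maps export as legacy-VTK structured
points (plain ASCII, one scalar array per field) so they open directly in
ParaView; tabular outputs (EGM summaries, densities, convergence traces,
metrics) are CSV with explicit headers.  Experiment configuration
round-trips through YAML and every stochastic element carries an explicit
seed, recorded in the run manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .electrogram import ElectrodeSet, SurfaceFieldMap
from .geometry import VoxelMesh

__all__ = [
    "ExperimentConfig",
    "write_vtk_structured_points",
    "write_egm_summary",
    "read_egm_summary",
    "write_segment_counts",
    "run_experiment",
]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    geometry: dict = field(default_factory=lambda: {
        "kind": "slab", "dims": [40, 40, 48], "fiber_direction": [1, 0, 0],
        "spacing": 0.1,
    })
    fibrosis: dict = field(default_factory=lambda: {
        "mode": "pattern", "pattern": "transmural", "segment": 1, "seed": 1234,
    })
    solver: dict = field(default_factory=lambda: {
        "d_long": 1.0, "d_trans": 1.0, "dt": 0.0015, "dr": 0.1,
        "t_end": 9.0, "sample_every": 25,
    })
    electrodes: dict = field(default_factory=lambda: {
        "n_endo": 72, "n_epi": 81, "seed_endo": 11, "seed_epi": 12,
    })
    optimizer: dict = field(default_factory=lambda: {
        "eps": 0.01, "d_min": 0.01, "max_cycles": 10, "seed": 77,
    })
    out_dir: str = "results"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls()
        for k, v in (data or {}).items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            base = getattr(cfg, k)
            if isinstance(base, dict):
                base.update(v)
            else:
                setattr(cfg, k, v)
        return cfg


# ---------------------------------------------------------------------------
# VTK / CSV export
# ---------------------------------------------------------------------------

def write_vtk_structured_points(
    path: str | Path,
    mesh: VoxelMesh,
    fields: dict[str, np.ndarray],
    title: str = "fibrograd export",
) -> None:
    """ASCII legacy-VTK structured-points file with one scalar array per
    entry of ``fields`` (arrays of shape mesh.dims; NaN allowed)."""
    nx, ny, nz = mesh.dims
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        "ORIGIN 0 0 0",
        f"SPACING {mesh.spacing} {mesh.spacing} {mesh.spacing}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in fields.items():
        a = np.asarray(arr)
        if a.shape != tuple(mesh.dims):
            raise ValueError(f"field {name!r} shape {a.shape} != mesh dims")
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        # VTK structured points iterate x fastest
        flat = np.transpose(a, (2, 1, 0)).ravel()
        lines.extend(" ".join(f"{v:.6g}" for v in flat[i:i + 9])
                     for i in range(0, flat.size, 9))
    Path(path).write_text("\n".join(lines) + "\n")


def write_egm_summary(
    path: str | Path,
    electrodes: ElectrodeSet,
    lat: np.ndarray,
    ptp: np.ndarray,
) -> None:
    """Per-electrode summary table; also the input format for
    reconstruction-only runs."""
    df = pd.DataFrame({
        "electrode_id": np.arange(electrodes.n),
        "x": electrodes.positions[:, 0],
        "y": electrodes.positions[:, 1],
        "z": electrodes.positions[:, 2],
        "surface": electrodes.surface,
        "lat_model_time": lat,
        "ptp_model_units": ptp,
    })
    df.to_csv(path, index=False)


def read_egm_summary(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"electrode_id", "x", "y", "z", "surface",
                "lat_model_time", "ptp_model_units"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"EGM summary missing columns: {sorted(missing)}")
    return df


def write_segment_counts(path: str | Path, h, level: int = 17) -> None:
    labels = {17: h.labels_17, 68: h.labels_68, 204: h.labels_204}[level]
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    pd.DataFrame({"segment": ids, "n_nodes": counts}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

def _build_geometry(cfg: ExperimentConfig) -> VoxelMesh:
    from . import geometry as G
    g = cfg.geometry
    if g["kind"] == "slab":
        return G.build_slab_mesh(tuple(g["dims"]), tuple(g["fiber_direction"]),
                                 spacing=g.get("spacing", 0.1))
    if g["kind"] == "lv":
        return G.build_ellipsoid_lv(
            tuple(g["outer_radii"]), g["wall_thickness"], tuple(g["dims"]),
            base_cut=g.get("base_cut", 0.0), spacing=g.get("spacing", 0.1),
            helix_angles=tuple(g.get("helix_angles", (-60.0, 60.0))))
    raise ValueError(f"unknown geometry kind {g['kind']!r}")


def run_experiment(config: ExperimentConfig, stages: tuple[str, ...] = ("simulate", "reconstruct", "evaluate")) -> dict:
    """Run simulate -> reconstruct -> evaluate per the config, writing all
    artifacts (VTK fields, CSV tables, manifest) into ``config.out_dir``.

    Partial failures leave completed stages' outputs in place; the
    manifest records per-stage status.
    """
    from . import geometry as G
    from .electrogram import place_electrodes, surface_measurements
    from .fibrosis import (interpolate_density_3d, make_pattern,
                           sample_fibrosis, synth_histology_maps)
    from .reconstruction import (ForwardEvaluator, evaluate_reconstruction,
                                 prepare_baseline, reconstruct)
    from .simulation import APParams, run_simulation, sinus_protocol

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": {},
                      "config": asdict(config)}
    mpath = out / "manifest.json"

    try:
        mesh = _build_geometry(config)
        if config.geometry["kind"] == "lv":
            h = G.split_layers(G.subdivide_segments(G.segment_aha17(mesh), mesh), mesh)
        else:
            h = G.single_segment_hierarchy(mesh)
        s = config.solver
        params = APParams(d_long=s["d_long"], d_trans=s["d_trans"],
                          dt=s["dt"], dr=s["dr"])
        e = config.electrodes
        endo_e = place_electrodes(mesh, "endo", e["n_endo"], e["seed_endo"])
        epi_e = place_electrodes(mesh, "epi", e["n_epi"], e["seed_epi"])

        f = config.fibrosis
        if f["mode"] == "pattern":
            target_density = make_pattern(f.get("segment", 1), f["pattern"], h, mesh)
        elif f["mode"] == "histology":
            maps = synth_histology_maps(seed=f["seed"], **f.get("generator", {}))
            kk = np.nonzero(mesh.myocardium_mask)[2]
            maps.slice_z = np.round(np.linspace(kk.min(), kk.max(),
                                                maps.grids.shape[0])).astype(int)
            target_density = interpolate_density_3d(maps, mesh)
        else:
            raise ValueError(f"unknown fibrosis mode {f['mode']!r}")

        target_real = sample_fibrosis(target_density, f["seed"], mesh)
        manifest["stages"]["setup"] = "ok"

        tfields = None
        if "simulate" in stages:
            rec = run_simulation(mesh, target_real, params,
                                 sinus_protocol(mesh, target_real),
                                 s["t_end"], sample_every=s["sample_every"])
            tfields = surface_measurements(rec, endo_e, epi_e)
            write_vtk_structured_points(
                out / "target_density.vtk", mesh,
                {"fibrosis_density": target_density.values,
                 "non_conductive": target_real.non_conductive_mask.astype(float)})
            pd.DataFrame({
                "surface": ["endo"] * tfields.endo_nodes.size + ["epi"] * tfields.epi_nodes.size,
                "node": np.concatenate([tfields.endo_nodes, tfields.epi_nodes]),
                "lat": np.concatenate([tfields.lat_endo, tfields.lat_epi]),
                "ptp": np.concatenate([tfields.ptp_endo, tfields.ptp_epi]),
            }).to_csv(out / "surface_fields.csv", index=False)
            manifest["stages"]["simulate"] = "ok"

        result = None
        if "reconstruct" in stages and tfields is not None:
            o = config.optimizer
            ev = ForwardEvaluator(mesh, params, endo_e, epi_e, seed=o["seed"],
                                  t_end=s["t_end"], sample_every=s["sample_every"])
            base = prepare_baseline(ev)
            result = reconstruct(tfields, ev, h, baseline=base,
                                 eps=o["eps"], d_min=o["d_min"],
                                 max_cycles=o["max_cycles"])
            rows = [{"level": 204, "segment": c, "density": d}
                    for c, d in sorted(result.d204.items())]
            pd.DataFrame(rows).to_csv(out / "densities.csv", index=False)
            pd.DataFrame(result.convergence).to_csv(out / "convergence.csv", index=False)
            manifest["stages"]["reconstruct"] = "ok"
            manifest["n_forward"] = result.n_forward

        if "evaluate" in stages and result is not None:
            metrics = evaluate_reconstruction(result, target_density, h, mesh)
            metrics.to_csv(out / "metrics.csv", index=False)
            manifest["stages"]["evaluate"] = "ok"
    except Exception as exc:  # record the failure stage, keep earlier outputs
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        mpath.write_text(json.dumps(manifest, indent=2))
        raise
    mpath.write_text(json.dumps(manifest, indent=2))
    return manifest
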