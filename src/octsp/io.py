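"""Plain-text serialization: one directory per eye with a float grid per
channel and a JSON sidecar, a cohort manifest CSV, and atlas directories."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import BundlePaths, NormativeAtlas
from .grid import GridSpec
from .synthetic import Defect, EyePhenotype, RnflMapSet, SyntheticEye

_CHANNELS = ("thickness", "reflectivity", "vessel_mask", "disc_mask")


def _grid_meta(grid: GridSpec) -> dict:
    return {
        "n": grid.n,
        "spacing_um": grid.spacing_um,
        "disc_center": list(grid.center),
        "disc_radius_mm": grid.disc_radius_mm,
        "axial_um": grid.axial_um,
    }


def _grid_from_meta(meta: dict) -> GridSpec:
    return GridSpec(
        n=meta["n"],
        spacing_um=meta["spacing_um"],
        disc_center=tuple(meta["disc_center"]),
        disc_radius_mm=meta["disc_radius_mm"],
        axial_um=meta.get("axial_um", 2.0),
    )


def save_eye(eye: SyntheticEye, path) -> None:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    m = eye.maps
    np.savetxt(p / "thickness.txt", m.thickness, fmt="%.4f")
    np.savetxt(p / "reflectivity.txt", m.reflectivity, fmt="%.5f")
    np.savetxt(p / "vessel_mask.txt", m.vessel_mask.astype(int), fmt="%d")
    np.savetxt(p / "disc_mask.txt", m.disc_mask.astype(int), fmt="%d")
    meta = {
        "grid": _grid_meta(m.grid),
        "phenotype": {
            "group": eye.truth.group,
            "bundle_angles": list(eye.truth.bundle_angles),
            "global_thinning": eye.truth.global_thinning,
            "vessel_seed": eye.truth.vessel_seed,
            "defects": [asdict(d) for d in eye.truth.defects],
        },
    }
    (p / "meta.json").write_text(json.dumps(meta, indent=2))


def load_eye(path) -> SyntheticEye:
    p = Path(path)
    meta = json.loads((p / "meta.json").read_text())
    grid = _grid_from_meta(meta["grid"])
    ph = meta["phenotype"]
    truth = EyePhenotype(
        group=ph["group"],
        bundle_angles=tuple(ph["bundle_angles"]),
        defects=tuple(Defect(**d) for d in ph["defects"]),
        vessel_seed=ph["vessel_seed"],
        global_thinning=ph["global_thinning"],
    )
    maps = RnflMapSet(
        thickness=np.loadtxt(p / "thickness.txt"),
        reflectivity=np.loadtxt(p / "reflectivity.txt"),
        vessel_mask=np.loadtxt(p / "vessel_mask.txt").astype(bool),
        disc_mask=np.loadtxt(p / "disc_mask.txt").astype(bool),
        grid=grid,
    )
    return SyntheticEye(maps=maps, truth=truth)


def save_cohort(eyes, root) -> Path:
    """Eye directories plus a manifest CSV; returns the manifest path."""
    root = Path(root)
    rows = []
    for i, eye in enumerate(eyes):
        eid = f"eye{i:04d}"
        save_eye(eye, root / eid)
        rows.append({"eye_id": eid, "group": eye.truth.group, "path": eid})
    manifest = root / "cohort.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest) -> list[SyntheticEye]:
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    return [load_eye(manifest.parent / row.path) for row in df.itertuples()]


def save_atlas(atlas: NormativeAtlas, path) -> None:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    np.savetxt(p / "mean.txt", atlas.mean_map, fmt="%.4f")
    np.savetxt(p / "sd.txt", atlas.sd_map, fmt="%.5f")
    meta = {
        "n_eyes": atlas.n_eyes,
        "grid": _grid_meta(atlas.grid),
        "reference_paths": {
            "radii_px": atlas.reference_paths.radii_px.tolist(),
            "superior_deg": atlas.reference_paths.superior_deg.tolist(),
            "inferior_deg": atlas.reference_paths.inferior_deg.tolist(),
        },
    }
    (p / "meta.json").write_text(json.dumps(meta, indent=2))


def load_atlas(path) -> NormativeAtlas:
    p = Path(path)
    meta = json.loads((p / "meta.json").read_text())
    rp = meta["reference_paths"]
    return NormativeAtlas(
        mean_map=np.loadtxt(p / "mean.txt"),
        sd_map=np.loadtxt(p / "sd.txt"),
        reference_paths=BundlePaths(
            np.array(rp["radii_px"]),
            np.array(rp["superior_deg"]),
            np.array(rp["inferior_deg"]),
        ),
        n_eyes=meta["n_eyes"],
        grid=_grid_from_meta(meta["grid"]),
    )
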