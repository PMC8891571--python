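"""Writers and readers: trace CSV, run-summary JSON, snapshots, VTK export.

Snapshots are compressed NumPy archives (owner grid, type grid, the three
fields, and the cell table); a legacy-ASCII VTK structured-points export is
provided for visualization tools.  The run summary records the seed and a
SHA-256 hash of the configuration so a run can be tied to its inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import lattice as lat
from .fields import FieldSet
from .lattice import CellLattice, CellRecord

__all__ = ["cell_table", "save_snapshot", "load_snapshot", "write_vtk",
           "config_hash", "write_outputs"]


def cell_table(lattice: CellLattice) -> pd.DataFrame:
    """Cell registry as a DataFrame (id, type, volume, centroid, state)."""
    rows = []
    if lattice.cells:
        idx = {cid: i for i, cid in enumerate(lattice.cells)}
        sums = np.zeros((len(idx), 3))
        counts = np.zeros(len(idx))
        vox = np.argwhere(lattice.site_owner > 0)
        owners = lattice.site_owner[vox[:, 0], vox[:, 1], vox[:, 2]]
        for (x, y, z), cid in zip(vox, owners):
            i = idx.get(int(cid))
            if i is None:
                continue
            sums[i] += (x, y, z)
            counts[i] += 1
        for cid, rec in lattice.cells.items():
            i = idx[cid]
            c = sums[i] / counts[i] if counts[i] else (np.nan, np.nan, np.nan)
            rows.append({
                "id": cid,
                "type": lat.TYPE_NAMES[rec.type],
                "volume": rec.volume,
                "target_volume": rec.target_volume,
                "cx": c[0], "cy": c[1], "cz": c[2],
                "cum_drug": rec.cum_drug,
                "ec_activated": rec.ec_activated,
                "phenotype": f"{rec.phenotype_code:04d}",
            })
    return pd.DataFrame(rows, columns=[
        "id", "type", "volume", "target_volume", "cx", "cy", "cz",
        "cum_drug", "ec_activated", "phenotype"])


def save_snapshot(path: str | Path, lattice: CellLattice,
                  fields: FieldSet | None = None) -> Path:
    """Write lattice (+fields) to a compressed array archive."""
    path = Path(path)
    cells = lattice.cells
    ids = np.array(sorted(cells), dtype=np.int64)
    arrays = {
        "site_owner": lattice.site_owner,
        "voxel_size": np.array([lattice.voxel_size]),
        "next_id": np.array([lattice._next_id]),
        "cell_ids": ids,
        "cell_type": np.array([cells[i].type for i in ids], dtype=np.int64),
        "cell_volume": np.array([cells[i].volume for i in ids], dtype=np.int64),
        "cell_tvol": np.array([cells[i].target_volume for i in ids]),
        "cell_gamma": np.array([cells[i].elasticity for i in ids]),
        "cell_chi": np.array([cells[i].chi for i in ids]),
        "cell_chem": np.array([cells[i].chem_field for i in ids], dtype=np.int64),
        "cell_init_vol": np.array([cells[i].initial_volume for i in ids], dtype=np.int64),
        "cell_cum_drug": np.array([cells[i].cum_drug for i in ids]),
        "cell_hypoxia": np.array([cells[i].hypoxia_minutes for i in ids]),
        "cell_necrosis": np.array([cells[i].necrosis_minutes for i in ids]),
        "cell_drug_q": np.array([cells[i].drug_quiescent for i in ids], dtype=np.int64),
        "cell_ec_act": np.array([cells[i].ec_activated for i in ids], dtype=np.int64),
    }
    if fields is not None:
        arrays |= {"nutrient": fields.nutrient, "vegf": fields.vegf,
                   "drug": fields.drug}
    np.savez_compressed(path, **arrays)
    return path


def load_snapshot(path: str | Path) -> tuple[CellLattice, FieldSet | None]:
    with np.load(Path(path)) as z:
        lattice = CellLattice(z["site_owner"].shape, float(z["voxel_size"][0]))
        lattice.site_owner = z["site_owner"].copy()
        lattice._next_id = int(z["next_id"][0])
        for k, cid in enumerate(z["cell_ids"]):
            rec = CellRecord(
                id=int(cid), type=int(z["cell_type"][k]),
                volume=int(z["cell_volume"][k]),
                target_volume=float(z["cell_tvol"][k]),
                elasticity=float(z["cell_gamma"][k]),
                chi=float(z["cell_chi"][k]),
                chem_field=int(z["cell_chem"][k]),
                initial_volume=int(z["cell_init_vol"][k]),
                cum_drug=float(z["cell_cum_drug"][k]),
                hypoxia_minutes=float(z["cell_hypoxia"][k]),
                necrosis_minutes=float(z["cell_necrosis"][k]),
                drug_quiescent=bool(z["cell_drug_q"][k]),
                ec_activated=bool(z["cell_ec_act"][k]),
            )
            lattice.cells[int(cid)] = rec
        fields = None
        if "nutrient" in z:
            fields = FieldSet(nutrient=z["nutrient"].copy(),
                              vegf=z["vegf"].copy(), drug=z["drug"].copy())
    return lattice, fields


def write_vtk(path: str | Path, array: np.ndarray, name: str = "field",
              spacing: float = 1.0) -> Path:
    """Legacy-ASCII VTK structured-points export of one scalar grid."""
    path = Path(path)
    nx, ny, nz = array.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{name}\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {spacing} {spacing} {spacing}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        flat = array.transpose(2, 1, 0).ravel()  # VTK expects x fastest
        for i in range(0, flat.size, 9):
            fh.write(" ".join(f"{v:g}" for v in flat[i:i + 9]) + "\n")
    return path


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_outputs(trace, outdir: str | Path, lattice: CellLattice | None = None,
                  fields: FieldSet | None = None, vtk: bool = False,
                  classification: str | None = None) -> dict:
    """Write trace CSV, run-summary JSON and optional snapshot/VTK files."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        trace_path = outdir / "trace.csv"
        trace.data.to_csv(trace_path, index=False)
        summary = {
            "seed": trace.seed,
            "config_hash": config_hash(trace.config),
            "overflow": trace.overflow,
            "therapy_start_day": trace.therapy_start_day,
            "therapy_end_day": trace.therapy_end_day,
            "final_day": (float(trace.days[-1]) if len(trace.data) else None),
            "final_tumor_voxels": (int(trace.volumes[-1]) if len(trace.data) else None),
        }
        if classification is not None:
            summary["classification"] = classification
        summary_path = outdir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2))
        written = {"trace": trace_path, "summary": summary_path}
        (outdir / "config.json").write_text(
            json.dumps(trace.config, indent=2, default=str))
        if lattice is not None:
            written["snapshot"] = save_snapshot(outdir / "snapshot.npz",
                                               lattice, fields)
            if vtk:
                written["vtk"] = write_vtk(outdir / "owner.vtk",
                                           lattice.site_owner.astype(float),
                                           "owner", lattice.voxel_size)
        return written
    except OSError as exc:
        raise OSError(f"failed writing outputs under {outdir}: {exc}") from exc
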