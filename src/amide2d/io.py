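"""On-disk containers for libraries and feature frames.

A library directory holds a JSON manifest, the structure table (CSV) and
one delimited matrix file per spectrum with ``#pump:`` / ``#probe:`` header
lines listing the axes.  Feature frames round-trip through either CSV (with
``pump|probe`` column labels) or a compact ``.npz`` container.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .formatting import FeatureFrame
from .simulate import SpectralLibrary, Spectrum2DIR
from .structures import read_structure_table, write_structure_table

__all__ = ["write_library", "read_library", "save_frame", "load_frame"]

_MANIFEST = "manifest.json"
_STRUCTURES = "structures.csv"


def _write_spectrum(sp: Spectrum2DIR, path: Path) -> None:
    # 17 significant digits round-trip float64 exactly
    with open(path, "w") as fh:
        fh.write("#pump: " + " ".join(f"{v:.17g}" for v in sp.pump_axis) + "\n")
        fh.write("#probe: " + " ".join(f"{v:.17g}" for v in sp.probe_axis) + "\n")
        np.savetxt(fh, sp.amplitude, fmt="%.17g", delimiter="\t")


def _read_spectrum(path: Path, meta: dict) -> Spectrum2DIR:
    with open(path) as fh:
        pump_line = fh.readline()
        probe_line = fh.readline()
        if not pump_line.startswith("#pump:") or not probe_line.startswith("#probe:"):
            raise ValueError(f"{path} is not a spectrum matrix file")
        pump = np.array([float(v) for v in pump_line.split(":", 1)[1].split()])
        probe = np.array([float(v) for v in probe_line.split(":", 1)[1].split()])
        amplitude = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return Spectrum2DIR(pump, probe, amplitude, dict(meta))


def write_library(library: SpectralLibrary, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_structure_table(list(library.structures.values()), out / _STRUCTURES)
    entries = []
    for i, sp in enumerate(library.spectra):
        name = f"spectrum_{i:05d}.tsv"
        _write_spectrum(sp, out / name)
        entries.append({"file": name, "meta": sp.meta})
    manifest = {"n_spectra": len(library.spectra), "spectra": entries,
                "groups": {k: list(v) for k, v in library.groups.items()}}
    (out / _MANIFEST).write_text(json.dumps(manifest, indent=1))


def read_library(in_dir) -> SpectralLibrary:
    src = Path(in_dir)
    manifest = json.loads((src / _MANIFEST).read_text())
    structures = {s.protein_id: s for s in read_structure_table(src / _STRUCTURES)}
    spectra = [_read_spectrum(src / e["file"], e["meta"]) for e in manifest["spectra"]]
    groups = {k: [int(i) for i in v] for k, v in manifest["groups"].items()}
    return SpectralLibrary(spectra, structures, groups)


def save_frame(frame: FeatureFrame, path) -> None:
    """Save a feature frame; format chosen by extension (.csv or .npz)."""
    path = Path(path)
    if path.suffix == ".csv":
        cols = [f"{p:.6g}|{r:.6g}" for p, r in frame.feature_coords]
        df = pd.concat(
            [frame.meta.reset_index(drop=True),
             pd.DataFrame(frame.X, columns=cols)], axis=1
        )
        df.to_csv(path, index=False)
        meta_path = path.with_suffix(".frame.json")
        meta_path.write_text(json.dumps({"mode": frame.mode,
                                         "meta_columns": list(frame.meta.columns)}))
    else:
        np.savez_compressed(
            path,
            X=frame.X,
            feature_coords=frame.feature_coords,
            meta_json=np.array(frame.meta.to_json(orient="split")),
            mode=np.array(frame.mode),
        )


def load_frame(path) -> FeatureFrame:
    path = Path(path)
    if path.suffix == ".csv":
        info = json.loads(path.with_suffix(".frame.json").read_text())
        df = pd.read_csv(path)
        meta = df[info["meta_columns"]]
        feat = df.drop(columns=info["meta_columns"])
        coords = np.array([[float(v) for v in c.split("|")] for c in feat.columns])
        return FeatureFrame(feat.to_numpy(float), coords, meta, info["mode"])
    with np.load(path, allow_pickle=False) as z:
        meta = pd.read_json(__import__("io").StringIO(str(z["meta_json"])), orient="split")
        return FeatureFrame(z["X"], z["feature_coords"], meta, str(z["mode"]))
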