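"""Plain-text interchange formats: frame CSVs with JSON sidecars, scan
directories, parameter-map CSV/TIFF twins and mask PNGs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .optics import WavelengthGrid
from .scan import Frame, ParameterMap, RasterPlan


def write_frame_csv(frame: Frame, grid: WavelengthGrid, path) -> None:
    """Columns: wavelength_nm, ch01..ch49, sc1, sc2; metadata sidecar JSON."""
    path = Path(path)
    cols = {"wavelength_nm": grid.values}
    for ch in range(49):
        cols[f"ch{ch + 1:02d}"] = frame.spectra[ch]
    cols["sc1"] = frame.sc_odd
    cols["sc2"] = frame.sc_even
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {
        "offset_ix": frame.offset_index[0],
        "offset_iy": frame.offset_index[1],
        "offset_x_mm": frame.offset_mm[0],
        "offset_y_mm": frame.offset_mm[1],
        "parity": "odd+even",
    }
    for k, v in frame.metadata.items():
        if isinstance(v, np.ndarray):
            meta[k] = v.tolist()
        elif isinstance(v, (int, float, str, bool)):
            meta[k] = v
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_frame_csv(path) -> tuple[Frame, WavelengthGrid]:
    path = Path(path)
    df = pd.read_csv(path)
    grid = WavelengthGrid(df["wavelength_nm"].to_numpy(float))
    spectra = np.stack([df[f"ch{ch + 1:02d}"].to_numpy(float) for ch in range(49)])
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if "on_tissue" in meta:
        meta["on_tissue"] = np.asarray(meta["on_tissue"], dtype=bool)
    ij = (int(meta.get("offset_ix", 0)), int(meta.get("offset_iy", 0)))
    frame = Frame(
        spectra=spectra,
        sc_odd=df["sc1"].to_numpy(float),
        sc_even=df["sc2"].to_numpy(float),
        offset_index=ij,
        offset_mm=(float(meta.get("offset_x_mm", 0.0)), float(meta.get("offset_y_mm", 0.0))),
        metadata=meta,
    )
    return frame, grid


def write_scan_dir(scan, outdir) -> Path:
    """Layout: <outdir>/<ix>_<iy>/frame.csv (+ frame.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for fr in scan.frames:
        sub = outdir / f"{fr.offset_index[0]}_{fr.offset_index[1]}"
        sub.mkdir(exist_ok=True)
        write_frame_csv(fr, scan.grid, sub / "frame.csv")
    (outdir / "scan.json").write_text(json.dumps({
        "upsample_factor": scan.plan.upsample_factor,
        "pitch_mm": scan.plan.pitch_mm,
        "seed": scan.seed,
    }, indent=1))
    return outdir


def read_scan_dir(indir):
    """Returns (frames, grid, plan)."""
    indir = Path(indir)
    info = json.loads((indir / "scan.json").read_text())
    plan = RasterPlan(int(info["upsample_factor"]), float(info["pitch_mm"]))
    frames = []
    grid = None
    for sub in sorted(indir.iterdir()):
        f = sub / "frame.csv"
        if not f.exists():
            continue
        frame, grid = read_frame_csv(f)
        frames.append(frame)
    if grid is None:
        raise FileNotFoundError(f"no frames found under {indir}")
    return frames, grid, plan


def write_map(pmap: ParameterMap, path_base) -> None:
    """32-bit TIFF plus a CSV twin (text deliverable)."""
    base = Path(path_base)
    pd.DataFrame(pmap.values).to_csv(base.with_suffix(".csv"), index=False, header=False)
    try:
        import tifffile

        tifffile.imwrite(base.with_suffix(".tif"), pmap.values.astype(np.float32))
    except ImportError:  # pragma: no cover
        pass


def read_map_csv(path, pitch_mm: float, label: str = "") -> ParameterMap:
    values = pd.read_csv(path, header=None).to_numpy(float)
    return ParameterMap(values, pitch_mm=pitch_mm, label=label)


def write_mask_png(mask: np.ndarray, path) -> None:
    from PIL import Image

    Image.fromarray((mask.astype(np.uint8)) * 255).save(path)
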