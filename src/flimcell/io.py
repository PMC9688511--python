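"""On-disk interchange: TIFF stacks + JSON sidecars, label masks, CSV tables.

A FLIM stack is stored as a multi-page TIFF, one page per TCSPC time bin
(unsigned 16-bit counts; float32 for noise-free expected stacks), with a
JSON sidecar holding the acquisition configuration and, for phantoms, the
full generation manifest. Label masks are single-page unsigned 16-bit
TIFFs with 0 as background.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .core import AcquisitionConfig, DecayCurve, DecaySpec, FLIMStack, LabelMask
from .synthetic import PhantomScene

__all__ = [
    "write_stack",
    "read_stack",
    "write_mask",
    "read_mask",
    "write_scene",
    "read_scene",
    "write_curve_csv",
    "read_curve_csv",
]


def write_stack(path, stack: FLIMStack, manifest: Optional[dict] = None) -> None:
    """Write a FLIM stack as (time, y, x) TIFF pages plus a JSON sidecar."""
    path = Path(path)
    data = stack.data
    if np.issubdtype(data.dtype, np.integer):
        pages = data.transpose(2, 0, 1).astype(np.uint16)
    else:
        pages = data.transpose(2, 0, 1).astype(np.float32)
    tifffile.imwrite(path, pages)
    sidecar = {"config": stack.config.to_dict(), "channel": stack.channel}
    if manifest is not None:
        sidecar["manifest"] = manifest
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_stack(path) -> FLIMStack:
    path = Path(path)
    pages = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = AcquisitionConfig.from_dict(sidecar["config"])
    return FLIMStack(
        data=np.asarray(pages).transpose(1, 2, 0),
        config=cfg,
        channel=sidecar.get("channel", "main"),
    )


def write_mask(path, mask: LabelMask) -> None:
    tifffile.imwrite(Path(path), mask.labels.astype(np.uint16))


def read_mask(path, kind: str = "cell", provenance: str = "external") -> LabelMask:
    labels = tifffile.imread(Path(path)).astype(np.int32)
    return LabelMask(labels, kind=kind, provenance=provenance)


def write_scene(scene: PhantomScene, directory) -> Path:
    """Write a phantom scene (stacks, truth masks, manifest) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ch, stack in scene.stacks.items():
        write_stack(directory / f"stack_{ch}.tif", stack)
    write_mask(directory / "truth_cells.tif", scene.cell_mask)
    write_mask(directory / "truth_nuclei.tif", scene.nucleus_mask)
    (directory / "manifest.json").write_text(json.dumps(scene.manifest, indent=1))
    return directory


def read_scene(directory) -> PhantomScene:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    stacks = {}
    for ch in manifest["channels"]:
        stacks[ch] = read_stack(directory / f"stack_{ch}.tif")
    truth_decays = {
        f"{ch}/{comp}": DecaySpec.from_dict(spec_d)
        for ch, comps in manifest["channels"].items()
        for comp, spec_d in comps.items()
    }
    return PhantomScene(
        stacks=stacks,
        cell_mask=read_mask(directory / "truth_cells.tif", "cell", "ground-truth"),
        nucleus_mask=read_mask(directory / "truth_nuclei.tif", "nucleus", "ground-truth"),
        truth_decays=truth_decays,
        manifest=manifest,
    )


def write_curve_csv(path, curve: DecayCurve) -> None:
    """Two-column (time_ns, counts) export of a decay curve."""
    df = pd.DataFrame({"time_ns": curve.axis, "counts": curve.counts})
    df.to_csv(Path(path), index=False)


def read_curve_csv(path, config: AcquisitionConfig, roi_id=("", "")) -> DecayCurve:
    df = pd.read_csv(Path(path))
    return DecayCurve(counts=df["counts"].to_numpy(), config=config, roi_id=roi_id)
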