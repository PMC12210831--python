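"""Readers and writers for every format the pipeline touches.

Images are multi-channel TIFF with a JSON description embedding channel
order and pixel size; masks are 16-bit label TIFF.  Tables are CSV with a
``#``-prefixed metadata block (column units, coordinate convention) before
the header row, so they stay grep-able and language-neutral.  A JSON run
manifest records inputs, parameters, seed and package version — and no
timestamps, so reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .segmentation import LabelMask
from .spots import ImageStack, Spot

COORD_NOTE = "coordinates 0-based; x=column, y=row; pixel centers at integers"


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as float32 TIFF with channel metadata in the description."""
    meta = {
        "axes": "CZYX",
        "channel_names": list(stack.channel_names),
        "pixel_size_nm": stack.pixel_size_nm,
    }
    tifffile.imwrite(
        str(path),
        stack.voxels.astype(np.float32),
        description=json.dumps(meta),
        photometric="minisblack",
        planarconfig="contig",
    )


def read_stack(path: str | Path) -> ImageStack:
    with tifffile.TiffFile(str(path)) as tif:
        voxels = tif.asarray().astype(float)
        desc = tif.pages[0].description
    meta = json.loads(desc)
    return ImageStack(
        voxels=voxels,
        pixel_size_nm=float(meta["pixel_size_nm"]),
        channel_names=tuple(meta["channel_names"]),
    )


def write_mask(path: str | Path, mask: LabelMask) -> None:
    if mask.n_labels > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels do not fit a 16-bit mask")
    tifffile.imwrite(str(path), mask.labels.astype(np.uint16))


def read_mask(path: str | Path, provenance: str = "provided") -> LabelMask:
    return LabelMask(tifffile.imread(str(path)).astype(np.int32), provenance=provenance)


def write_table(path: str | Path, df: pd.DataFrame, meta: Mapping[str, str] | None = None) -> None:
    """CSV with a '#'-prefixed metadata block before the header row."""
    lines = [f"# {k}: {v}" for k, v in (meta or {}).items()]
    body = df.to_csv(index=False, lineterminator="\n")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else "") + body)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def spots_to_frame(spots: Sequence[Spot]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spot_id": s.spot_id,
                "channel": s.channel,
                "z_plane": s.z_plane,
                "x": s.x,
                "y": s.y,
                "amplitude": s.amplitude,
                "sigma_px": s.sigma_px,
                "background": s.background,
                "residual_norm": s.residual_norm,
                "nucleus_id": -1 if s.nucleus_id is None else s.nucleus_id,
            }
            for s in spots
        ],
        columns=[
            "spot_id", "channel", "z_plane", "x", "y", "amplitude",
            "sigma_px", "background", "residual_norm", "nucleus_id",
        ],
    )


def frame_to_spots(df: pd.DataFrame) -> list[Spot]:
    spots = []
    for row in df.itertuples(index=False):
        nid = int(row.nucleus_id)
        spots.append(
            Spot(
                spot_id=int(row.spot_id),
                channel=str(row.channel),
                z_plane=int(row.z_plane),
                center_xy=(float(row.x), float(row.y)),
                amplitude=float(row.amplitude),
                sigma_px=float(row.sigma_px),
                background=float(row.background),
                residual_norm=float(row.residual_norm),
                nucleus_id=None if nid < 0 else nid,
            )
        )
    return spots


def write_manifest(path: str | Path, manifest: Mapping) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
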