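"""File formats: multi-page TIFF stacks with CSV sidecars, versioned CSV tables.

Conventions: 16-bit grayscale TIFF, one page per frame; timestamps in a
``timestamps.csv`` sidecar (frame, channel, t_seconds); all CSV tables
start with a schema comment line; coordinates 0-based (row, col); times
in seconds; rate constants in min^-1.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from crrc.simulate import ImageStack

SCHEMA_HEADER = "# crrc schema v1\n"


def write_stack(stack: ImageStack, tif_path: str | Path, timestamps_csv: str | Path | None = None) -> None:
    """Write a stack as 16-bit multi-page TIFF (+ append its timestamps sidecar).

    Float frames are rounded and clipped into the uint16 range.
    """
    frames = stack.frames
    if not np.issubdtype(frames.dtype, np.integer):
        frames = np.clip(np.round(frames), 0, 65535)
    tifffile.imwrite(tif_path, frames.astype(np.uint16), photometric="minisblack")
    if timestamps_csv is not None:
        df = pd.DataFrame(
            {
                "frame": np.arange(stack.n_frames),
                "channel": stack.channel,
                "t_seconds": stack.timestamps,
            }
        )
        path = Path(timestamps_csv)
        if path.exists():
            existing = read_table(path)
            df = pd.concat([existing[existing["channel"] != stack.channel], df], ignore_index=True)
        write_table(df, path)


def read_stack(
    tif_path: str | Path,
    timestamps_csv: str | Path,
    channel: str,
    pixel_size: float,
) -> ImageStack:
    """Read a multi-page TIFF plus its timestamps sidecar into an ImageStack."""
    frames = tifffile.imread(tif_path)
    if frames.ndim == 2:
        frames = frames[None, ...]
    ts = read_table(timestamps_csv)
    ts = ts[ts["channel"] == channel].sort_values("frame")
    if len(ts) != frames.shape[0]:
        raise ValueError(
            f"{tif_path}: {frames.shape[0]} pages but {len(ts)} '{channel}' timestamps"
        )
    return ImageStack(frames, channel, ts["t_seconds"].to_numpy(), pixel_size)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """CSV with the schema version as a leading comment line."""
    with open(path, "w") as fh:
        fh.write(SCHEMA_HEADER)
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
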