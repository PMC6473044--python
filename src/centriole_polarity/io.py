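"""File I/O: label masks, centriole tables, group maps, density grids.

All CSVs use the coordinate convention x = column, y = row, 0-based,
pixel-centre origin; the convention is written into every output header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

_COORD_NOTE = "# coordinates: x = image column, y = image row, 0-based, pixel-centre origin\n"


def read_mask(path: str | Path) -> np.ndarray:
    """Read a label mask from 16-bit TIFF or PNG (background 0)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D label mask")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: label mask must be integer-typed")
    return arr


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    path = Path(path)
    arr = np.asarray(mask)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr.astype(np.uint16))
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr.astype(np.uint16))


def read_centrioles(path: str | Path) -> pd.DataFrame:
    """Centriole detections CSV with columns x, y (optional group)."""
    df = pd.read_csv(path, comment="#")
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    """Write a CSV with the coordinate-convention header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_COORD_NOTE)
        df.to_csv(fh, index=False)


def read_group_map(path: str | Path) -> dict[int, str]:
    """CSV with columns label, group -> {label: group}."""
    df = pd.read_csv(path, comment="#")
    missing = {"label", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return dict(zip(df["label"].astype(int), df["group"].astype(str)))


def write_group_map(path: str | Path, mapping: Mapping[int, str]) -> None:
    df = pd.DataFrame(
        {"label": list(mapping.keys()), "group": list(mapping.values())}
    )
    write_table(path, df)


def write_density_grid(path: str | Path, grid: np.ndarray) -> None:
    """Density grid as CSV (one row per raster row) or 32-bit float TIFF."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, np.asarray(grid, dtype=np.float32))
    else:
        np.savetxt(path, np.asarray(grid), delimiter=",")


def write_provenance(path: str | Path, payload: dict) -> None:
    """Machine-readable run record (config echo, seed, software version)."""
    from . import __version__

    record = {"software": "centriole-polarity", "version": __version__, **payload}
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")


def render_density_png(
    path: str | Path, density_maps, titles=None, cmap: str = "inferno"
) -> None:
    """Side-by-side heat-map rendering with the reference hexagon outline."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    maps = list(density_maps)
    fig, axes = plt.subplots(1, len(maps), figsize=(4.2 * len(maps), 4), squeeze=False)
    for ax, dm, title in zip(
        axes[0], maps, titles or [dm.group or "" for dm in maps]
    ):
        R = dm.frame.circumradius
        ax.imshow(
            dm.grid, extent=[-R, R, R, -R], cmap=cmap, interpolation="nearest"
        )
        verts = dm.frame.vertices()
        closed = np.vstack([verts, verts[:1]])
        ax.plot(closed[:, 0], closed[:, 1], color="white", lw=1.2)
        ax.set_title(f"{title} (n={dm.n_centrioles})")
        ax.set_xlabel("u (distal →)")
        ax.set_ylabel("v")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
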