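"""Format round-tripping: TIFF images, CSV tables, JSON results.

All tabular interchange uses UTF-8 comma-separated files with
unit-suffixed column names; images travel as single- or multi-page TIFF
with the pixel size stored in the X/Y resolution tags.  JSON results
embed the toolkit version and the configuration hash.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .contour_geometry import Contour, CurvatureProfile
from .segmentation import Image2D
from .tension import AspirationRamp, PipetteGeometry

__all__ = [
    "write_tiff",
    "read_tiff",
    "write_contours_csv",
    "read_contours_csv",
    "write_curvature_csv",
    "read_curvature_csv",
    "write_ground_truth_csv",
    "write_ramp_csv",
    "read_ramp_csv",
    "read_geometry_json",
    "write_results_json",
    "read_layout_csv",
    "write_layout_csv",
]


def write_tiff(path: str | Path, images: Image2D | list[Image2D]) -> None:
    """Write one image or a stack as TIFF, recording the pixel size."""
    if isinstance(images, Image2D):
        images = [images]
    px = images[0].pixel_size_um
    stack = np.stack([im.pixels for im in images])
    # resolution tag is in pixels per unit; unit um -> micrometres (code 1: none
    # is unreliable across readers, so also store it in the description)
    tifffile.imwrite(
        path,
        stack if len(images) > 1 else stack[0],
        resolution=(1.0 / px, 1.0 / px),
        metadata={"pixel_size_um": px},
    )


def read_tiff(
    path: str | Path, channel: int | None = None, pixel_size_um: float | None = None
) -> list[Image2D]:
    """Read a (multi-page) TIFF into a list of frames.

    The pixel size is recovered from the metadata written by
    :func:`write_tiff` when present; otherwise ``pixel_size_um`` must be
    given.  For multi-channel pages, ``channel`` selects the channel axis
    index.
    """
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta_px = None
        if tf.shaped_metadata:
            meta_px = tf.shaped_metadata[0].get("pixel_size_um")
        elif tf.imagej_metadata:
            meta_px = tf.imagej_metadata.get("pixel_size_um")
    px = pixel_size_um or meta_px
    if px is None:
        raise ValueError("pixel size not recorded in TIFF; pass pixel_size_um")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4:
        if channel is None:
            raise ValueError("multi-channel TIFF: a channel index is required")
        arr = arr[:, channel]
    return [
        Image2D(pixels=frame, pixel_size_um=float(px), meta={"frame_index": i})
        for i, frame in enumerate(arr)
    ]


def write_contours_csv(path: str | Path, contours: list[Contour]) -> None:
    rows = []
    for c in contours:
        for j, (x, y) in enumerate(c.points):
            rows.append(
                {"frame": c.frame_index, "point_index": j, "x_um": x, "y_um": y}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contours_csv(path: str | Path) -> list[Contour]:
    df = pd.read_csv(path)
    out = []
    for frame, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("point_index")
        pts = grp[["x_um", "y_um"]].to_numpy()
        out.append(Contour(pts, frame_index=int(frame)))
    return out


def write_curvature_csv(path: str | Path, profiles: list[CurvatureProfile]) -> None:
    rows = []
    for p in profiles:
        radius = p.radius_of_curvature
        for th, (x, y), k, r in zip(p.theta, p.points, p.kappa, radius):
            rows.append(
                {
                    "frame": p.frame_index,
                    "theta_rad": th,
                    "x_um": x,
                    "y_um": y,
                    "kappa_per_um": k,
                    "radius_um": r,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_curvature_csv(path: str | Path) -> list[CurvatureProfile]:
    df = pd.read_csv(path)
    out = []
    for frame, grp in df.groupby("frame", sort=True):
        pts = grp[["x_um", "y_um"]].to_numpy()
        contour = Contour(pts, frame_index=int(frame))
        out.append(
            CurvatureProfile(
                theta=grp["theta_rad"].to_numpy(),
                kappa=grp["kappa_per_um"].to_numpy(),
                points=pts,
                centroid=contour.centroid(),
                frame_index=int(frame),
            )
        )
    return out


def write_ground_truth_csv(
    path: str | Path, theta: np.ndarray, points: np.ndarray, kappa: np.ndarray
) -> None:
    pd.DataFrame(
        {
            "theta_rad": theta,
            "x_um": points[:, 0],
            "y_um": points[:, 1],
            "kappa_per_um": kappa,
        }
    ).to_csv(path, index=False)


def write_ramp_csv(path: str | Path, ramp: AspirationRamp) -> None:
    entered = (
        ramp.entered
        if ramp.entered is not None
        else np.zeros(len(ramp.pressures_pa), dtype=bool)
    )
    cap = (
        ramp.cap_radii_um
        if ramp.cap_radii_um is not None
        else np.full(len(ramp.pressures_pa), np.nan)
    )
    pd.DataFrame(
        {
            "dP_pa": ramp.pressures_pa,
            "Rc_um": cap,
            "entered": entered.astype(int),
        }
    ).to_csv(path, index=False)


def read_ramp_csv(path: str | Path) -> AspirationRamp:
    df = pd.read_csv(path)
    entered = df["entered"].to_numpy().astype(bool) if "entered" in df else None
    cap = df["Rc_um"].to_numpy() if "Rc_um" in df else None
    return AspirationRamp(
        pressures_pa=df["dP_pa"].to_numpy(), cap_radii_um=cap, entered=entered
    )


def read_geometry_json(path: str | Path) -> PipetteGeometry:
    data = json.loads(Path(path).read_text())
    return PipetteGeometry(R_P_um=data["R_P_um"], R_D_um=data["R_D_um"])


def write_results_json(
    path: str | Path, payload: dict, config=None
) -> None:
    out = {"toolkit_version": __version__}
    if config is not None:
        out["config_sha256"] = config.sha256()
    out.update(payload)
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")


def read_layout_csv(path: str | Path, window_um: float = 700.0):
    """Read channel layouts from a long-format CSV.

    Expected columns: channel_id, condition, kind in {droplet, cell},
    position_um.
    """
    from .population import ChannelLayout

    df = pd.read_csv(path)
    layouts = []
    for (cid, cond), grp in df.groupby(["channel_id", "condition"], sort=True):
        droplets = grp.loc[grp["kind"] == "droplet", "position_um"].to_numpy()
        cells = grp.loc[grp["kind"] == "cell", "position_um"].to_numpy()
        layouts.append(
            ChannelLayout(
                droplet_positions_um=droplets,
                cell_positions_um=cells,
                window_um=window_um,
                channel_id=str(cid),
                condition=str(cond),
            )
        )
    return layouts


def write_layout_csv(path: str | Path, layouts) -> None:
    rows = []
    for lay in layouts:
        for pos in lay.droplet_positions_um:
            rows.append(
                {
                    "channel_id": lay.channel_id,
                    "condition": lay.condition,
                    "kind": "droplet",
                    "position_um": pos,
                }
            )
        for pos in lay.cell_positions_um:
            rows.append(
                {
                    "channel_id": lay.channel_id,
                    "condition": lay.condition,
                    "kind": "cell",
                    "position_um": pos,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
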