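"""End-to-end chain: image stack -> contours -> curvature -> stress.

The pipeline executes segment -> resample -> low-pass filter -> curvature
-> stress for the frames named in a pairing manifest, writing every
intermediate as CSV plus a results JSON.  Outputs are staged in a
temporary directory and moved into place only on success, so a failing
run leaves no partial files behind.
"""

from __future__ import annotations

import logging
import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io
from .config import PipelineConfig
from .contour_geometry import curvature_profile, fft_lowpass, resample_closed
from .segmentation import segment_droplet
from .stress import DropletState, cohort_stress, contact_stress, match_states

__all__ = ["PipelineError", "run_pipeline", "contour_to_profile"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised with the failing stage name when a pipeline stage fails."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def contour_to_profile(contour, config: PipelineConfig):
    """Resample, low-pass filter, and differentiate one contour."""
    c = resample_closed(contour, config.resample_n)
    c = fft_lowpass(c, config.fft_harmonics)
    return curvature_profile(c)


@dataclass
class PipelineResult:
    measurements: list
    cohort: object
    out_dir: Path


def run_pipeline(
    config: PipelineConfig,
    tiff_path: str | Path,
    manifest: dict,
    out_dir: str | Path,
) -> PipelineResult:
    """Run the full stress pipeline on a droplet time-lapse.

    ``manifest`` maps droplets to frames::

        {"droplets": [{"id": "d0", "resting_frame": 0, "deformed_frame": 1}],
         "gamma_mN_per_m": 8.4,            # optional, default from config
         "window_rad": [0.0, 3.14159]}     # optional, default from config

    Returns the per-droplet stress measurements and the cohort summary;
    writes contours.csv, curvature.csv and results.json into ``out_dir``.
    """
    out_dir = Path(out_dir)
    gamma = manifest.get("gamma_mN_per_m", config.gamma_mN_per_m)
    window = tuple(manifest.get("window_rad", config.contact_window_rad))

    try:
        frames = io.read_tiff(tiff_path, pixel_size_um=config.pixel_size_um)
    except Exception as e:  # noqa: BLE001 - surfaced with stage name
        raise PipelineError("read", f"{tiff_path}: {e}") from e

    needed: set[int] = set()
    for d in manifest.get("droplets", []):
        needed.update((int(d["resting_frame"]), int(d["deformed_frame"])))
    missing = [i for i in needed if not 0 <= i < len(frames)]
    if missing:
        raise PipelineError(
            "read", f"{tiff_path}: frame indices {missing} out of range 0..{len(frames) - 1}"
        )

    contours, profiles = {}, {}
    for i in sorted(needed):
        try:
            contours[i] = segment_droplet(
                frames[i],
                median_radius_px=config.median_radius_px,
                upscale=config.upscale,
                snake=config.snake_params(),
            )
            contours[i].frame_index = i
        except Exception as e:  # noqa: BLE001
            raise PipelineError("segment", f"frame {i}: {e}") from e
        try:
            prof = contour_to_profile(contours[i], config)
            prof.frame_index = i
            profiles[i] = prof
        except Exception as e:  # noqa: BLE001
            raise PipelineError("curvature", f"frame {i}: {e}") from e

    measurements = []
    for d in manifest.get("droplets", []):
        ri, di = int(d["resting_frame"]), int(d["deformed_frame"])
        states = [
            DropletState(contours[ri], profiles[ri], "resting", ri),
            DropletState(contours[di], profiles[di], "deformed", di),
        ]
        try:
            pairs = match_states(states)
            for rest, deform in pairs:
                m = contact_stress(gamma, rest.profile, deform.profile, window)
                m.meta["droplet_id"] = d.get("id", f"{ri}->{di}")
                measurements.append(m)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("stress", f"droplet {d.get('id')}: {e}") from e

    cohort = cohort_stress(measurements) if measurements else None

    tmp = Path(tempfile.mkdtemp(prefix="dropstress-"))
    try:
        io.write_contours_csv(tmp / "contours.csv", list(contours.values()))
        io.write_curvature_csv(tmp / "curvature.csv", list(profiles.values()))
        payload = {
            "gamma_mN_per_m": gamma,
            "window_rad": list(window),
            "measurements": [
                {
                    "droplet_id": m.meta.get("droplet_id"),
                    "theta_star_rad": m.theta_star_rad,
                    "kappa_rest_per_um": m.kappa_rest_per_um,
                    "kappa_def_min_per_um": m.kappa_def_min_per_um,
                    "delta_sigma_pa": m.delta_sigma_pa,
                    "delta_sigma_pn_per_um2": m.delta_sigma_pn_per_um2,
                }
                for m in measurements
            ],
        }
        if cohort is not None:
            payload["cohort"] = {
                "mean_pa": cohort.mean_pa,
                "sd_pa": cohort.sd_pa,
                "n": cohort.n,
            }
        io.write_results_json(tmp / "results.json", payload, config=config)
        out_dir.mkdir(parents=True, exist_ok=True)
        for f in tmp.iterdir():
            shutil.move(str(f), out_dir / f.name)
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
    logger.info("pipeline finished: %d measurement(s) -> %s", len(measurements), out_dir)
    return PipelineResult(measurements=measurements, cohort=cohort, out_dir=out_dir)
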