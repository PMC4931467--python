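"""Channel-invasion statistics: cells before vs after the first droplet.

Each microchannel holds a few immobilized droplet obstacles and a number
of migrating cells.  Within a fixed counting window from the loading well
(700 um by default) every cell is classified as *before* or *after* the
first droplet; a population that cannot squeeze past the obstacle piles
up before it.  Channels are the experimental unit: per-channel
percentages are averaged per condition and conditions are compared with a
permutation test by default (t-test and Mann-Whitney available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChannelLayout",
    "CellCounts",
    "filter_channels",
    "classify_cells",
    "invasion_summary",
    "DEFAULT_WINDOW_UM",
    "DEFAULT_CELL_RADIUS_UM",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_UM = 700.0
# half a typical cell diameter; cells closer than this to the droplet are
# "at the obstacle" and cannot be attributed to either side
DEFAULT_CELL_RADIUS_UM = 6.5
MAX_DROPLETS_PER_CHANNEL = 3


@dataclass
class ChannelLayout:
    """Axial positions (um from the loading well) in one microchannel."""

    droplet_positions_um: np.ndarray
    cell_positions_um: np.ndarray
    window_um: float = DEFAULT_WINDOW_UM
    channel_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.droplet_positions_um = np.sort(
            np.atleast_1d(np.asarray(self.droplet_positions_um, dtype=float))
        )
        self.cell_positions_um = np.atleast_1d(
            np.asarray(self.cell_positions_um, dtype=float)
        )
        if self.window_um <= 0:
            raise ValueError("window_um must be positive")
        for arr, name in (
            (self.droplet_positions_um, "droplet"),
            (self.cell_positions_um, "cell"),
        ):
            if arr.size and arr.min() < 0:
                raise ValueError(f"{name} positions must be >= 0")

    def droplets_in_window(self) -> np.ndarray:
        d = self.droplet_positions_um
        return d[d <= self.window_um]


@dataclass
class CellCounts:
    n_before: int
    n_after: int
    n_at_obstacle: int = 0

    @property
    def n_classified(self) -> int:
        return self.n_before + self.n_after


def filter_channels(layouts: list[ChannelLayout]) -> list[ChannelLayout]:
    """Keep channels with 1 to 3 droplets inside the counting window.

    Channels with four or more droplets are too crowded to attribute the
    blocking to a single obstacle; channels with none offer no obstacle to
    classify against, leaving the before/after partition undefined.
    """
    kept = []
    for lay in layouts:
        n = len(lay.droplets_in_window())
        if 1 <= n <= MAX_DROPLETS_PER_CHANNEL:
            kept.append(lay)
    return kept


def classify_cells(
    layout: ChannelLayout, exclusion_um: float = DEFAULT_CELL_RADIUS_UM
) -> CellCounts:
    """Count cells before/after the first droplet within the window.

    Cells beyond the window are ignored.  Cells within ``exclusion_um``
    (half a cell diameter) of the first droplet are in mechanical contact
    with it and are flagged "at obstacle" rather than forced to a side.
    """
    droplets = layout.droplets_in_window()
    if droplets.size == 0:
        raise ValueError("layout has no droplet inside the window; filter first")
    first = droplets[0]
    cells = layout.cell_positions_um
    cells = cells[cells <= layout.window_um]
    at_obstacle = np.abs(cells - first) <= exclusion_um
    before = (cells < first) & ~at_obstacle
    after = (cells > first) & ~at_obstacle
    return CellCounts(
        n_before=int(before.sum()),
        n_after=int(after.sum()),
        n_at_obstacle=int(at_obstacle.sum()),
    )


def _permutation_pvalue(
    a: np.ndarray, b: np.ndarray, n_permutations: int, seed: int | None
) -> float:
    """Two-sided permutation test on the difference of group means."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    na = len(a)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        diff = abs(perm[:na].mean() - perm[na:].mean())
        if diff >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_permutations + 1)


def invasion_summary(
    layouts: list[ChannelLayout],
    exclusion_um: float = DEFAULT_CELL_RADIUS_UM,
    test: str = "permutation",
    n_permutations: int = 999,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-condition invasion percentages and a between-condition test.

    Channels that fail the droplet-count filter or contain no classified
    cell are excluded (the latter with a logged warning).  Per channel the
    before/after percentages are computed among classified cells; the
    condition summary is the mean of per-channel percentages.  With
    exactly two conditions, the per-channel percent-after values are
    compared with the chosen test ('permutation', 't' or 'mannwhitney').
    """
    rows = []
    for lay in filter_channels(layouts):
        counts = classify_cells(lay, exclusion_um)
        if counts.n_classified == 0:
            logger.warning(
                "channel %r: no classified cells in window, excluded", lay.channel_id
            )
            continue
        rows.append(
            {
                "channel_id": lay.channel_id,
                "condition": lay.condition,
                "n_before": counts.n_before,
                "n_after": counts.n_after,
                "n_at_obstacle": counts.n_at_obstacle,
                "percent_before": 100.0 * counts.n_before / counts.n_classified,
                "percent_after": 100.0 * counts.n_after / counts.n_classified,
            }
        )
    if not rows:
        raise ValueError("no usable channels after filtering")
    per_channel = pd.DataFrame(rows)
    summary = (
        per_channel.groupby("condition")
        .agg(
            percent_before=("percent_before", "mean"),
            percent_after=("percent_after", "mean"),
            n_channels=("channel_id", "size"),
        )
        .reset_index()
    )
    comparison: dict = {"test": None, "p_value": None}
    conditions = sorted(per_channel["condition"].unique())
    if len(conditions) == 2:
        a = per_channel.loc[
            per_channel["condition"] == conditions[0], "percent_after"
        ].to_numpy()
        b = per_channel.loc[
            per_channel["condition"] == conditions[1], "percent_after"
        ].to_numpy()
        if test == "permutation":
            p = _permutation_pvalue(a, b, n_permutations, seed)
        elif test == "t":
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        elif test == "mannwhitney":
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        comparison = {
            "test": test,
            "p_value": p,
            "conditions": conditions,
            "mean_percent_after": [float(a.mean()), float(b.mean())],
        }
    return per_channel, {"summary": summary, "comparison": comparison}
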