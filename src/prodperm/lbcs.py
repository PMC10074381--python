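"""Liposome formulability classification in the (log K, log Perm) plane.

The liposome biochemical classification system (LBCS) partitions the
partitioning/permeability plane into five bins:

* yellow -- membrane-trapped lipophiles (log K above a threshold);
* gray   -- too permeable for liposome retention;
* blue   -- too permeable as the neutral form, but rescuable by
            ionization inside the liposome cavity (user-supplied flag);
* green  -- permeability and partitioning both inside the window that
            allows encapsulation *and* thermally induced release;
* red    -- retained but too slow for thermal release.

Yellow takes precedence (a membrane-trapped compound is classified by
its partitioning first), then the too-permeable bins, then green.  The
numeric boundaries are calibration inputs, not measured constants, and
every classification carries them explicitly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = ["LBCSBin", "LBCSBoundaries", "default_boundaries", "classify", "plot_lbcs"]

from enum import Enum


class LBCSBin(str, Enum):
    GRAY = "gray"
    BLUE = "blue"
    GREEN = "green"
    RED = "red"
    YELLOW = "yellow"


@dataclass(frozen=True)
class LBCSBoundaries:
    """Thresholds partitioning the (log K, log Perm) plane."""

    logPerm_too_fast: float
    logPerm_too_slow: float
    logK_membrane_trapped: float
    logK_green_min: float
    logK_green_max: float

    def __post_init__(self) -> None:
        if not self.logPerm_too_slow < self.logPerm_too_fast:
            raise ValueError("logPerm_too_slow must lie below logPerm_too_fast")
        if not self.logK_green_min < self.logK_green_max <= self.logK_membrane_trapped:
            raise ValueError(
                "need logK_green_min < logK_green_max <= logK_membrane_trapped"
            )

    @classmethod
    def from_mapping(cls, data: dict) -> "LBCSBoundaries":
        return cls(**{k: float(data[k]) for k in (
            "logPerm_too_fast", "logPerm_too_slow", "logK_membrane_trapped",
            "logK_green_min", "logK_green_max")})

    @classmethod
    def from_file(cls, path: str | Path) -> "LBCSBoundaries":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_mapping(data)


def default_boundaries() -> LBCSBoundaries:
    """Packaged default boundaries (calibration values, see data/boundaries.yaml)."""
    ref = resources.files("prodperm.data").joinpath("boundaries.yaml")
    return LBCSBoundaries.from_mapping(yaml.safe_load(ref.read_text()))


def classify(
    logK: float,
    logPerm: float,
    ionizable_in_cavity: bool = False,
    boundaries: LBCSBoundaries | None = None,
) -> LBCSBin:
    """Assign one LBCS bin to a finite (log K, log Perm) point.

    Precedence: yellow (membrane-trapped) > gray/blue (too permeable;
    blue iff ionizable in the cavity) > green (inside both windows) >
    red (everything retained but slow).  Total on finite inputs.
    """
    if not (math.isfinite(logK) and math.isfinite(logPerm)):
        raise ValueError("classify requires finite logK and logPerm")
    b = boundaries if boundaries is not None else default_boundaries()
    if logK > b.logK_membrane_trapped:
        return LBCSBin.YELLOW
    if logPerm > b.logPerm_too_fast:
        return LBCSBin.BLUE if ionizable_in_cavity else LBCSBin.GRAY
    if logPerm >= b.logPerm_too_slow and b.logK_green_min <= logK <= b.logK_green_max:
        return LBCSBin.GREEN
    return LBCSBin.RED


_BIN_COLORS = {
    LBCSBin.GRAY: "0.6",
    LBCSBin.BLUE: "tab:blue",
    LBCSBin.GREEN: "tab:green",
    LBCSBin.RED: "tab:red",
    LBCSBin.YELLOW: "gold",
}


def plot_lbcs(
    points: Sequence[tuple[str, float, float]],
    boundaries: LBCSBoundaries | None = None,
    path: str | Path | None = None,
    xlim: tuple[float, float] = (-4.0, 10.0),
    ylim: tuple[float, float] = (-20.0, 4.0),
):
    """Scatter labelled (name, logK, logPerm) points over shaded LBCS bins."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    b = boundaries if boundaries is not None else default_boundaries()
    fig, ax = plt.subplots(figsize=(7, 5))
    # shade by classifying a coarse background grid
    import numpy as np
    xs = np.linspace(*xlim, 200)
    ys = np.linspace(*ylim, 200)
    order = list(LBCSBin)
    grid = np.array(
        [[order.index(classify(x, y, boundaries=b)) for x in xs] for y in ys]
    )
    from matplotlib.colors import ListedColormap
    ax.pcolormesh(xs, ys, grid, alpha=0.25, shading="auto",
                  cmap=ListedColormap([_BIN_COLORS[k] for k in order]),
                  vmin=0, vmax=len(order) - 1)
    for name, k, p in points:
        ax.scatter([k], [p], c="k", s=18, zorder=3)
        ax.annotate(name, (k, p), fontsize=7, xytext=(3, 3),
                    textcoords="offset points")
    ax.set_xlabel("log K (mol/mol)")
    ax.set_ylabel("log Perm (cm/s)")
    ax.set_xlim(*xlim)
    ax.set_ylim(*ylim)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
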