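"""Choropleth rendering of the district vulnerability map."""

from __future__ import annotations

from typing import Mapping

import pandas as pd
from shapely.geometry import Polygon

LEVEL_COLORS = {"low": "#2c9e4b", "medium": "#f2c744", "high": "#d63b2f"}


def plot_choropleth(
    polygons: Mapping[str, Polygon],
    levels: pd.Series,
    ax=None,
    title: str = "Under-five pneumonia vulnerability",
):
    """Fill each district polygon by its risk level. Returns the axes."""
    import matplotlib.pyplot as plt  # deferred: headless imports stay cheap
    from matplotlib.patches import Patch

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 8))
    for district_id, poly in polygons.items():
        geoms = poly.geoms if hasattr(poly, "geoms") else [poly]
        color = LEVEL_COLORS.get(str(levels.get(district_id)), "#cccccc")
        for geom in geoms:
            xs, ys = geom.exterior.xy
            ax.fill(xs, ys, facecolor=color, edgecolor="black", linewidth=0.5)
        c = poly.representative_point()
        ax.annotate(district_id, (c.x, c.y), ha="center", fontsize=6)
    ax.set_aspect("equal")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_title(title)
    handles = [
        Patch(facecolor=c, edgecolor="black", label=lev)
        for lev, c in LEVEL_COLORS.items()
    ]
    ax.legend(handles=handles, loc="lower right", fontsize=8)
    return ax
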