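"""Pavement-cell shape morphometrics and group comparison.

Cell shape is summarized by three descriptors computed per labelled cell:

area
    pixel count times the pixel area (um^2);
circularity
    4*pi*area / perimeter^2, 1 for a circle and decreasing as the boundary
    becomes more convoluted (i.e. as lobes form);
solidity
    area divided by the area of the convex hull, decreasing as lobes deepen.

Perimeter uses the 4-direction Crofton estimator (the common Fiji dialect);
an exact polygon oracle (:func:`measure_polygon`) computes the same
descriptors analytically from boundary vertices, which is used to validate
raster measurements on synthetic cells.

Group comparison aggregates to per-plant means first (the plant is the
experimental unit), runs pairwise two-tailed Welch t tests with
Benjamini-Hochberg adjustment, and summarizes the outcome as a compact
letter display: groups sharing a letter do not differ at the chosen alpha.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull
from skimage.measure import regionprops
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_MIN_CELL_PX = 10


def measure_cells(label_mask: np.ndarray, pixel_size_um: float) -> pd.DataFrame:
    """Per-cell morphometrics from an integer label mask.

    Area is pixel count times pixel area; perimeter is the 4-direction
    Crofton estimate on the cell contour; solidity uses the convex hull of
    the cell's pixels.  Circularity values marginally above 1 (possible for
    near-circular rasterized cells because the perimeter estimator is not
    exact) are clamped to 1 with the raw value kept in
    ``circularity_raw``.  Labels touching the image border are marked
    ``touches_border`` and labels below 10 px are excluded with a log entry.

    Returns a table with columns cell_id, area_um2, circularity,
    circularity_raw, solidity, touches_border.
    """
    label_mask = np.asarray(label_mask)
    if not np.issubdtype(label_mask.dtype, np.integer):
        raise ValueError("label_mask must be an integer label image")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    if label_mask.max() == 0:
        raise ValueError("label mask is empty (no labels)")

    h, w = label_mask.shape
    rows = []
    for rp in regionprops(label_mask):
        if rp.area < _MIN_CELL_PX:
            logger.info("excluding label %d: only %d px", rp.label, rp.area)
            continue
        area_um2 = rp.area * pixel_size_um**2
        perimeter_um = rp.perimeter_crofton * pixel_size_um
        if perimeter_um == 0:
            logger.info("excluding label %d: zero perimeter", rp.label)
            continue
        circ_raw = 4 * np.pi * area_um2 / perimeter_um**2
        if circ_raw > 1:
            logger.info(
                "label %d: raw circularity %.5f clamped to 1", rp.label, circ_raw
            )
        minr, minc, maxr, maxc = rp.bbox
        rows.append(
            {
                "cell_id": int(rp.label),
                "area_um2": float(area_um2),
                "circularity": float(min(circ_raw, 1.0)),
                "circularity_raw": float(circ_raw),
                "solidity": float(min(rp.solidity, 1.0)),
                "touches_border": bool(
                    minr == 0 or minc == 0 or maxr == h or maxc == w
                ),
            }
        )
    return pd.DataFrame(rows)


def measure_polygon(
    vertices_um: np.ndarray,
) -> tuple[float, float, float, float]:
    """Exact (area, perimeter, circularity, solidity) of a simple polygon.

    Area by the shoelace formula, perimeter as the sum of segment lengths,
    circularity as 4*pi*A/P^2, solidity as A over the exact convex-hull
    area.  Raises for polygons with fewer than 3 vertices or with
    self-intersections.
    """
    v = np.asarray(vertices_um, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError("need an (n >= 3) x 2 vertex array")
    x, y = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(np.sum(x * y2 - x2 * y))
    if area == 0 or _self_intersects(v):
        raise ValueError("polygon is degenerate or self-intersecting")
    perimeter = float(np.sum(np.hypot(x2 - x, y2 - y)))
    circularity = 4 * np.pi * area / perimeter**2
    hull = ConvexHull(v)
    solidity = area / hull.volume  # 2D: .volume is the hull area
    return float(area), perimeter, float(circularity), float(solidity)


def _self_intersects(v: np.ndarray) -> bool:
    """Brute-force check for crossing of non-adjacent polygon edges."""
    n = len(v)
    segs = [(v[i], v[(i + 1) % n]) for i in range(n)]

    def _ccw(a, b, c):
        return (c[1] - a[1]) * (b[0] - a[0]) - (b[1] - a[1]) * (c[0] - a[0])

    for i in range(n):
        a, b = segs[i]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through the closing edge
            c, d = segs[j]
            if (_ccw(a, b, c) * _ccw(a, b, d) < 0) and (
                _ccw(c, d, a) * _ccw(c, d, b) < 0
            ):
                return True
    return False


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def _letter_display(
    groups: list[str], means: dict[str, float], different: set[tuple[str, str]]
) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm."""
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in different:
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                letter_sets.extend([s - {a}, s - {b}])
        # absorb sets contained in another
        letter_sets = [
            s
            for s in letter_sets
            if s and not any(s < t for t in letter_sets)
        ]
        # deduplicate
        uniq = []
        for s in letter_sets:
            if s not in uniq:
                uniq.append(s)
        letter_sets = uniq
    order = sorted(groups, key=lambda g: -means[g])
    letter_sets.sort(key=lambda s: min(order.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in s:
            out[g] += letter
    return {g: "".join(sorted(v)) for g, v in out.items()}


def compare_shape_groups(
    records: pd.DataFrame,
    metric: str = "circularity",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise group comparison of a shape metric with letter display.

    ``records`` must hold columns ``group``, ``plant_id`` and the metric
    (plus optionally ``touches_border``, which excludes flagged cells).
    Cell values are first averaged per plant so the plant is the
    experimental unit; pairwise two-tailed Welch t tests on the plant means
    are Benjamini-Hochberg adjusted, and a compact letter display is built
    at ``alpha``.  A group with a single plant triggers a logged fallback to
    per-cell units for every test involving it.

    Returns one row per group: group, n_plants, n_cells, mean, letters; the
    pairwise p-values are attached as ``DataFrame.attrs['pairwise']``.
    """
    required = {"group", "plant_id", metric}
    if not required <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    df = records.copy()
    if "touches_border" in df.columns:
        df = df[~df["touches_border"].astype(bool)]
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    counts = df.groupby("group")[metric].size()
    if (counts < 5).any():
        raise ValueError("every group needs at least 5 cells")

    plant_means = (
        df.groupby(["group", "plant_id"])[metric].mean().reset_index()
    )
    n_plants = plant_means.groupby("group")["plant_id"].size()
    fallback = set(n_plants[n_plants < 2].index)
    if fallback:
        logger.warning(
            "groups %s have a single plant; falling back to per-cell units "
            "(pseudo-replication caveat applies)", sorted(fallback)
        )

    def _units(g: str) -> np.ndarray:
        # consistent units across all tests: any single-plant group forces
        # the per-cell fallback everywhere
        if fallback:
            return df.loc[df["group"] == g, metric].to_numpy()
        return plant_means.loc[plant_means["group"] == g, metric].to_numpy()

    pairs = list(itertools.combinations(groups, 2))
    p_raw = []
    for a, b in pairs:
        xa, xb = _units(a), _units(b)
        if np.var(xa) == 0 and np.var(xb) == 0:
            p = 1.0 if np.mean(xa) == np.mean(xb) else 0.0
        else:
            p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        p_raw.append(p)
    _, p_bh, _, _ = multipletests(p_raw, method="fdr_bh")
    different = {
        (a, b) for (a, b), p in zip(pairs, p_bh) if p < alpha
    }

    means = {g: float(df.loc[df["group"] == g, metric].mean()) for g in groups}
    letters = _letter_display(groups, means, different)
    out = pd.DataFrame(
        {
            "group": groups,
            "n_plants": [int(n_plants.get(g, 0)) for g in groups],
            "n_cells": [int(counts[g]) for g in groups],
            "mean": [means[g] for g in groups],
            "letters": [letters[g] for g in groups],
        }
    )
    out.attrs["pairwise"] = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "p_raw": p_raw,
            "p_bh": p_bh,
            "different": [(a, b) in different for a, b in pairs],
        }
    )
    return out
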