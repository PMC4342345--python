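"""Between/within-population segments and their land-cover composition.

A segment is the rectangle of a given width whose axis joins two sample
sites. Segments joining the closest qualifying site pair of two
different populations are "B" (between); each population contributes at
most one "W" (within) segment whose length most closely matches the
B-segment length that joins it (or a study-wide fallback length when no
B segment touches it). Composition is the proportional area of each of
the nine land-cover classes among raster pixels whose centers fall in
the rectangle, evaluated at a series of widths.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    DEFAULT_FALLBACK_W_LENGTH,
    DEFAULT_WIDTHS,
    LANDCOVER_CLASSES,
    LandCoverRaster,
    MembershipSurface,
    PopulationPartition,
    SampleSite,
    Segment,
    validate_widths,
)

logger = logging.getLogger(__name__)

__all__ = [
    "within_median",
    "find_b_segments",
    "find_w_segments",
    "build_segments",
    "segment_pixels",
    "composition",
    "mean_membership",
    "segment_table",
]

#: geometric tolerance (meters) for rectangle-membership ties
_TOL = 1e-6


def _dist(a: SampleSite, b: SampleSite) -> float:
    return math.hypot(b.x - a.x, b.y - a.y)


def _site_map(sites: Iterable[SampleSite]) -> dict[str, SampleSite]:
    return {s.id: s for s in sites}


def _within_pairs(partition: PopulationPartition, sites_by_id, pops) -> list[tuple[str, str, float]]:
    out = []
    for p in pops:
        members = [sid for sid in partition.sites_of(p) if sid in sites_by_id]
        for a, b in itertools.combinations(sorted(members), 2):
            out.append((a, b, _dist(sites_by_id[a], sites_by_id[b])))
    return out


def within_median(
    partition: PopulationPartition,
    sites: Sequence[SampleSite],
    scope: str = "global",
    pops: tuple[int, int] | None = None,
) -> float:
    """Median within-population pairwise site distance.

    Populations holding a single site contribute no distances. With
    ``scope="global"`` (default) the median pools every multi-site
    population; with ``scope="pair"`` only the two populations in
    ``pops`` are pooled — the two readings of "the median distance of
    sample sites within those populations".
    """
    sites_by_id = _site_map(sites)
    if scope == "global":
        use = range(1, partition.k + 1)
    elif scope == "pair":
        if pops is None:
            raise ValueError("scope='pair' requires pops=(p1, p2)")
        use = pops
    else:
        raise ValueError(f"unknown scope {scope!r}")
    dists = [d for _, _, d in _within_pairs(partition, sites_by_id, use)]
    if not dists:
        raise ValueError("no population holds two or more sites; median undefined")
    return float(np.median(dists))


def find_b_segments(
    partition: PopulationPartition,
    sites: Sequence[SampleSite],
    threshold: float,
) -> list[Segment]:
    """At most one B segment per population pair.

    For every unordered pair of populations, the minimum-distance site
    pair is located; if that minimum is strictly below ``threshold``
    (populations closer than expected from within-population spread,
    implying a barrier rather than distance alone) a B segment joins
    those two sites. Ties are broken toward the lexicographically
    smallest (site_a, site_b) id pair.
    """
    sites_by_id = _site_map(sites)
    out: list[Segment] = []
    for p1, p2 in itertools.combinations(range(1, partition.k + 1), 2):
        best: tuple[float, str, str] | None = None
        for a in partition.sites_of(p1):
            for b in partition.sites_of(p2):
                if a not in sites_by_id or b not in sites_by_id:
                    continue
                lo, hi = sorted((a, b))
                d = _dist(sites_by_id[a], sites_by_id[b])
                key = (d, lo, hi)
                if best is None or key < best:
                    best = key
        if best is not None and best[0] < threshold:
            sa, sb = sites_by_id[best[1]], sites_by_id[best[2]]
            pa = partition.site_to_pop[best[1]]
            pb = partition.site_to_pop[best[2]]
            out.append(Segment(site_a=sa, site_b=sb, category="B", pop_a=pa, pop_b=pb))
    return out


def find_w_segments(
    partition: PopulationPartition,
    sites: Sequence[SampleSite],
    b_segments: Sequence[Segment],
    fallback_length: float = DEFAULT_FALLBACK_W_LENGTH,
) -> list[Segment]:
    """Exactly one W segment per multi-site population.

    The chosen pair is the within-population site pair whose length is
    closest to the length of a B segment joining that population (the
    smallest mismatch over all joining B segments); populations touched
    by no B segment use ``fallback_length`` (default 776 m, the
    study-wide mean B-segment length) as the target. Single-site
    populations yield no W segment.
    """
    sites_by_id = _site_map(sites)
    targets: dict[int, list[float]] = {}
    for seg in b_segments:
        targets.setdefault(seg.pop_a, []).append(seg.length)
        targets.setdefault(seg.pop_b, []).append(seg.length)

    out: list[Segment] = []
    for p in range(1, partition.k + 1):
        pairs = _within_pairs(partition, sites_by_id, [p])
        if not pairs:
            logger.info("population %d has fewer than two sites; no W segment", p)
            continue
        goal = targets.get(p, [fallback_length])
        best = min(pairs, key=lambda t: (min(abs(t[2] - g) for g in goal), t[0], t[1]))
        a, b, _ = best
        out.append(Segment(site_a=sites_by_id[a], site_b=sites_by_id[b],
                           category="W", pop_a=p, pop_b=p))
    return out


def build_segments(
    partition: PopulationPartition,
    sites: Sequence[SampleSite],
    scope: str = "global",
    fallback_length: float = DEFAULT_FALLBACK_W_LENGTH,
) -> list[Segment]:
    """Full B/W classification for one study cell."""
    if partition.k < 2:
        median = None
        b_segs: list[Segment] = []
    else:
        try:
            median = within_median(partition, sites, scope="global")
        except ValueError:
            median = None
        b_segs = []
        if median is not None:
            if scope == "global":
                b_segs = find_b_segments(partition, sites, median)
            else:
                for p1, p2 in itertools.combinations(range(1, partition.k + 1), 2):
                    try:
                        thr = within_median(partition, sites, scope="pair", pops=(p1, p2))
                    except ValueError:
                        continue
                    sub = PopulationPartition(
                        k=partition.k,
                        site_to_pop={s: q for s, q in partition.site_to_pop.items() if q in (p1, p2)},
                    )
                    b_segs.extend(find_b_segments(sub, sites, thr))
    w_segs = find_w_segments(partition, sites, b_segs, fallback_length=fallback_length)
    return b_segs + w_segs


# ------------------------------------------------------------- geometry

def segment_pixels(
    seg: Segment,
    width: float,
    raster: LandCoverRaster,
) -> np.ndarray:
    """Raster pixels whose centers fall in the segment's rectangle.

    The rectangle runs exactly site-to-site (no end caps) with the given
    cross-axis width. Membership is by pixel center: closed along the
    axis, half-open across it (the +side boundary included, the -side
    excluded) so an axis through pixel centers selects exactly
    width/resolution rows. Never empty: a rectangle thinner than the
    pixel grid falls back to the two endpoint pixels. Returns an (m, 2)
    array of (row, col) indices.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    ax, ay, bx, by = seg.site_a.x, seg.site_a.y, seg.site_b.x, seg.site_b.y
    length = seg.length
    ux, uy = (bx - ax) / length, (by - ay) / length
    nx, ny = -uy, ux
    half = width / 2.0

    corners_x = [ax + sx * nx * half for sx in (-1, 1)] + [bx + sx * nx * half for sx in (-1, 1)]
    corners_y = [ay + sy * ny * half for sy in (-1, 1)] + [by + sy * ny * half for sy in (-1, 1)]
    xmin_r, ymin_r, xmax_r, ymax_r = raster.extent
    if min(corners_x) < xmin_r or max(corners_x) > xmax_r or min(corners_y) < ymin_r or max(corners_y) > ymax_r:
        warnings.warn("segment rectangle extends beyond the raster; clipped", stacklevel=2)

    res = raster.resolution
    c_lo = max(0, int(np.floor((min(corners_x) - raster.origin_x) / res)) - 1)
    c_hi = min(raster.n_cols - 1, int(np.ceil((max(corners_x) - raster.origin_x) / res)) + 1)
    r_lo = max(0, int(np.floor((raster.origin_y - max(corners_y)) / res)) - 1)
    r_hi = min(raster.n_rows - 1, int(np.ceil((raster.origin_y - min(corners_y)) / res)) + 1)
    if c_hi < c_lo or r_hi < r_lo:
        return _endpoint_pixels(seg, raster)

    rows = np.arange(r_lo, r_hi + 1)
    cols = np.arange(c_lo, c_hi + 1)
    RR, CC = np.meshgrid(rows, cols, indexing="ij")
    px, py = raster.pixel_center(RR, CC)
    dx, dy = px - ax, py - ay
    t = dx * ux + dy * uy
    s = dx * nx + dy * ny
    inside = (t >= -_TOL) & (t <= length + _TOL) & (s > -half + _TOL) & (s <= half + _TOL)
    if not inside.any():
        return _endpoint_pixels(seg, raster)
    return np.column_stack([RR[inside], CC[inside]])


def _endpoint_pixels(seg: Segment, raster: LandCoverRaster) -> np.ndarray:
    pix = {raster.index_of(seg.site_a.x, seg.site_a.y),
           raster.index_of(seg.site_b.x, seg.site_b.y)}
    pix = {(max(0, min(raster.n_rows - 1, r)), max(0, min(raster.n_cols - 1, c)))
           for r, c in pix}
    return np.array(sorted(pix), dtype=int)


def composition(seg: Segment, width: float, raster: LandCoverRaster) -> np.ndarray:
    """Proportional area of each of the nine classes within the segment."""
    pix = segment_pixels(seg, width, raster)
    codes = raster.classes[pix[:, 0], pix[:, 1]]
    counts = np.bincount(codes, minlength=len(LANDCOVER_CLASSES) + 1)[1:]
    return counts / counts.sum()


def mean_membership(
    seg: Segment,
    width: float,
    modal_grid: np.ndarray,
    surf: MembershipSurface,
    raster: LandCoverRaster,
) -> float:
    """Mean modal membership probability over the segment's pixels.

    Each land-cover pixel center in the segment looks up its
    nearest-neighbor pixel on the 100x100 surface grid; centers outside
    the surface bounding box clamp to the nearest edge pixel (logged).
    """
    pix = segment_pixels(seg, width, raster)
    x, y = raster.pixel_center(pix[:, 0], pix[:, 1])
    outside = (x < surf.xmin) | (x > surf.xmax) | (y < surf.ymin) | (y > surf.ymax)
    if outside.any():
        logger.info("%d/%d segment pixels outside the surface box; edge values used",
                    int(outside.sum()), len(pix))
    row, col = surf.index_of(x, y)
    return float(modal_grid[row, col].mean())


def segment_table(
    segments: Sequence[Segment],
    raster: LandCoverRaster,
    modal_grid: np.ndarray | None = None,
    surf: MembershipSurface | None = None,
    widths: Sequence[float] = DEFAULT_WIDTHS,
) -> pd.DataFrame:
    """Tidy table: one row per segment x width, with the nine class
    proportions and (when a surface is supplied) the mean membership
    probability. Also fills each segment's per-width caches."""
    widths = validate_widths(widths)
    rows = []
    for i, seg in enumerate(segments):
        for w in widths:
            comp = composition(seg, w, raster)
            seg.composition[w] = comp
            rec = {
                "segment": i,
                "site_a": seg.site_a.id,
                "site_b": seg.site_b.id,
                "category": seg.category,
                "length": seg.length,
                "width": w,
                **{name: comp[j] for j, name in enumerate(LANDCOVER_CLASSES)},
            }
            if modal_grid is not None and surf is not None:
                mm = mean_membership(seg, w, modal_grid, surf, raster)
                seg.mean_membership[w] = mm
                rec["membership"] = mm
            rows.append(rec)
    return pd.DataFrame(rows)
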