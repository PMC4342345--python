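"""Synthetic landscape scenarios with known habitat effects.

Everything downstream (segments, regressions, validation) is exercised
on scenarios produced here: a patch-mosaic land-cover raster, contiguous
genetic territories grown with elevated cost across barrier habitat,
stratified-random sample sites, diploid microsatellite-style genotypes
under a correlated-drift (F-model) process, and a membership-probability
surface whose local composition dependence is controlled by true,
configurable coefficients.

The defaults emulate a fragmented agricultural mosaic: ~88% agriculture
and ~8% forest, study cells of ~23 km^2 (4.8 km sides, 30 m pixels), at
most 45 sample sites per cell placed disproportionally in natural cover
(forest/grassland/water 27.8% of sites each, urban 13.9%, agriculture
2.8%), and 12 polymorphic loci.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .types import (
    CLASS_CODES,
    LANDCOVER_CLASSES,
    ConfigurationError,
    GenotypeMatrix,
    LandCoverRaster,
    PopulationPartition,
    MembershipSurface,
    SampleSite,
)

__all__ = [
    "ScenarioConfig",
    "SyntheticScenario",
    "stage_rng",
    "largest_remainder",
    "generate_landcover",
    "generate_partition",
    "place_sites",
    "simulate_genotypes",
    "simulate_surface",
    "generate_scenario",
    "simulate_segment_dataset",
]

DEFAULT_CLASS_MIX: dict[str, float] = {
    "agriculture": 0.88,
    "forest": 0.08,
    # remaining 4% split evenly across the seven minor classes
    "non_treed_corridor": 0.04 / 7,
    "treed_corridor": 0.04 / 7,
    "grassland": 0.04 / 7,
    "shrubland": 0.04 / 7,
    "water": 0.04 / 7,
    "urban": 0.04 / 7,
    "road": 0.04 / 7,
}

#: site strata and their target share of sites (stratified-random design)
SITE_STRATA: dict[str, float] = {
    "forest": 0.278,
    "grassland": 0.278,
    "water": 0.278,
    "urban": 0.139,
    "agriculture": 0.028,
}

#: growth-cost multipliers for territory expansion across barrier habitat
DEFAULT_BARRIER_COSTS: dict[str, float] = {"water": 25.0, "road": 10.0, "urban": 5.0}

#: expected land-cover mix of segment rectangles. Segments join sample
#: sites placed disproportionately in natural cover, so natural classes
#: are strongly enriched relative to the landscape mix even though the
#: matrix in between stays agriculture-dominated.
SEGMENT_BASE_MIX: dict[str, float] = {
    "forest": 0.22,
    "non_treed_corridor": 0.02,
    "treed_corridor": 0.02,
    "grassland": 0.14,
    "shrubland": 0.02,
    "water": 0.08,
    "urban": 0.06,
    "road": 0.02,
    "agriculture": 0.42,
}


@dataclass
class ScenarioConfig:
    """Complete parameterisation of one synthetic study cell."""

    seed: int = 0
    cell_side: float = 4800.0  # meters; ~23 km^2 cell
    resolution: float = 30.0
    k_true: int = 2
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    n_sites: int = 36
    n_loci: int = 12
    alleles_per_locus: int = 8
    theta_drift: float = 0.1
    individuals_per_site: int = 5
    effect_coefficients: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.2
    patch_cells: int = 6  # mosaic lattice coarseness, in pixels
    barrier_costs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BARRIER_COSTS)
    )
    surface_scale: float = 300.0  # softmax distance decay, meters

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(f"class_mix sums to {total}, expected 1")
        unknown = set(self.class_mix) - set(LANDCOVER_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown land-cover classes: {sorted(unknown)}")
        if self.k_true < 1:
            raise ConfigurationError("k_true must be >= 1")
        if not 0.0 < self.theta_drift < 1.0:
            raise ConfigurationError("theta_drift must lie in (0, 1)")
        if self.n_sites > 45:
            raise ConfigurationError("at most 45 sample sites per cell")
        if self.k_true > 1 and self.n_sites < 2 * self.k_true:
            raise ConfigurationError("need n_sites >= 2*k_true for multi-cluster cells")
        if self.alleles_per_locus < 2:
            raise ConfigurationError("alleles_per_locus must be >= 2")

    @property
    def n_pixels(self) -> int:
        return int(round(self.cell_side / self.resolution))


@dataclass
class SyntheticScenario:
    """A fully realised scenario plus its generating truth."""

    raster: LandCoverRaster
    territory_map: np.ndarray  # (rows, cols) true cluster ids 1..k
    sites: list[SampleSite]
    genotypes: GenotypeMatrix
    partition: PopulationPartition
    surface: MembershipSurface
    config: ScenarioConfig


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the master seed.

    Stages are independent streams, so rerunning one stage in isolation
    reproduces its output regardless of what ran before it.
    """
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])


def largest_remainder(n: int, weights: Mapping[str, float]) -> dict[str, int]:
    """Integer quotas summing to n, apportioned by the largest-remainder rule."""
    keys = list(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    if w.sum() <= 0:
        raise ConfigurationError("weights must have positive sum")
    exact = n * w / w.sum()
    quotas = np.floor(exact).astype(int)
    remainder = exact - quotas
    # ties broken by declaration order (stable argsort of -remainder)
    for idx in np.argsort(-remainder, kind="stable")[: n - quotas.sum()]:
        quotas[idx] += 1
    return dict(zip(keys, quotas.tolist()))


def generate_landcover(cfg: ScenarioConfig, rng: np.random.Generator | None = None) -> LandCoverRaster:
    """Patch-mosaic raster matching the target class mix.

    Patch nuclei sit on a jittered coarse lattice; every pixel takes the
    class of its nearest nucleus, giving contiguous patches whose realised
    area fractions track ``cfg.class_mix`` (nucleus classes are assigned
    by largest-remainder quota, then shuffled).
    """
    rng = rng if rng is not None else stage_rng(cfg.seed, "landcover")
    n = cfg.n_pixels
    step = max(1, cfg.patch_cells)
    grid = np.arange(step / 2, n, step)
    jitter = rng.uniform(-step / 2, step / 2, size=(grid.size, grid.size, 2))
    rr, cc = np.meshgrid(grid, grid, indexing="ij")
    seeds = np.stack([rr + jitter[..., 0], cc + jitter[..., 1]], axis=-1).reshape(-1, 2)

    quotas = largest_remainder(len(seeds), cfg.class_mix)
    codes = np.concatenate(
        [np.full(q, CLASS_CODES[name], dtype=np.int16) for name, q in quotas.items()]
    )
    rng.shuffle(codes)

    pr, pc = np.meshgrid(np.arange(n) + 0.5, np.arange(n) + 0.5, indexing="ij")
    _, nearest = cKDTree(seeds).query(np.column_stack([pr.ravel(), pc.ravel()]))
    classes = codes[nearest].reshape(n, n)
    return LandCoverRaster(origin_x=0.0, origin_y=n * cfg.resolution,
                           resolution=cfg.resolution, classes=classes)


def _cost_surface(raster: LandCoverRaster, barrier_costs: Mapping[str, float]) -> np.ndarray:
    cost = np.ones(raster.classes.shape, dtype=float)
    for name, mult in barrier_costs.items():
        cost[raster.classes == CLASS_CODES[name]] = mult
    return cost


def generate_partition(
    raster: LandCoverRaster,
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
    seed_pixels: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Territory map: k contiguous territories grown by cost-weighted flood fill.

    Seeds are spaced at least ``cell_side / (2 k)`` apart; growth cost is
    elevated across barrier classes so territory boundaries tend to
    co-locate with barrier habitat. Pixels unreachable under infinite
    barrier cost inherit the label of the nearest labelled pixel.
    """
    rng = rng if rng is not None else stage_rng(cfg.seed, "partition")
    rows, cols = raster.classes.shape
    k = cfg.k_true
    if k == 1:
        return np.ones((rows, cols), dtype=np.int16)

    if seed_pixels is not None:
        if len(seed_pixels) != k:
            raise ConfigurationError("need exactly k seed pixels")
        seeds = [tuple(s) for s in seed_pixels]
    else:
        min_sep_px = (min(rows, cols)) / (2.0 * k)
        seeds = []
        for _ in range(10_000):
            cand = (int(rng.integers(rows)), int(rng.integers(cols)))
            if all(math.hypot(cand[0] - s[0], cand[1] - s[1]) >= min_sep_px for s in seeds):
                seeds.append(cand)
                if len(seeds) == k:
                    break
        else:
            raise ConfigurationError(
                f"could not place {k} territory seeds with separation {min_sep_px:.0f} px"
            )

    cost = _cost_surface(raster, cfg.barrier_costs)
    n = rows * cols
    idx = np.arange(n).reshape(rows, cols)
    # 4-neighbour graph; edge weight = mean of endpoint entry costs
    right_w = (cost[:, :-1] + cost[:, 1:]).ravel() / 2
    down_w = (cost[:-1, :] + cost[1:, :]).ravel() / 2
    src = np.concatenate([idx[:, :-1].ravel(), idx[:-1, :].ravel()])
    dst = np.concatenate([idx[:, 1:].ravel(), idx[1:, :].ravel()])
    wts = np.concatenate([right_w, down_w])
    finite = np.isfinite(wts)
    graph = sparse.csr_matrix((wts[finite], (src[finite], dst[finite])), shape=(n, n))

    source_idx = np.array([idx[r, c] for r, c in seeds])
    dist, _, nearest_source = dijkstra(
        graph, directed=False, indices=source_idx, min_only=True,
        return_predecessors=True,
    )
    territory = (nearest_source + 1).astype(np.int32)
    labels = np.empty(n, dtype=np.int16)
    reachable = np.isfinite(dist)
    # map source node index -> territory id 1..k
    src_to_pop = {int(s): i + 1 for i, s in enumerate(source_idx)}
    labels[reachable] = [src_to_pop[int(s)] for s in nearest_source[reachable]]
    if not reachable.all():
        lab2d = labels.reshape(rows, cols).copy()
        unreachable = ~reachable.reshape(rows, cols)
        _, (ir, ic) = ndimage.distance_transform_edt(unreachable, return_indices=True)
        lab2d[unreachable] = lab2d[ir[unreachable], ic[unreachable]]
        return lab2d
    return labels.reshape(rows, cols)


FOREST_PATCH_BOUNDS_HA = (5.0, 50.0)  # small < 5 ha, medium 5-50 ha, large > 50 ha


def place_sites(
    raster: LandCoverRaster,
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> list[SampleSite]:
    """Stratified-random site placement at pixel centers.

    Quotas per habitat stratum follow the design proportions (natural
    classes 27.8% each, urban 13.9%, agriculture 2.8%) via the
    largest-remainder rule; forest sites are further stratified by patch
    size (small/medium/large) where such patches exist. A stratum with
    no available pixels has its quota reallocated proportionally.
    """
    rng = rng if rng is not None else stage_rng(cfg.seed, "sites")
    if cfg.n_sites > 45:
        raise ConfigurationError("at most 45 sites per cell")

    available = {s: np.argwhere(raster.classes == CLASS_CODES[s]) for s in SITE_STRATA}
    weights = dict(SITE_STRATA)
    empty = [s for s, px in available.items() if len(px) == 0]
    if empty:
        warnings.warn(f"empty site strata reallocated: {empty}", stacklevel=2)
        for s in empty:
            weights.pop(s)
        if not weights:
            raise ConfigurationError("no stratum has available pixels")
    quotas = largest_remainder(cfg.n_sites, weights)

    sites: list[SampleSite] = []

    def _add(stratum: str, pixels: np.ndarray, count: int) -> None:
        count = min(count, len(pixels))
        chosen = pixels[rng.choice(len(pixels), size=count, replace=False)]
        for r, c in chosen:
            x, y = raster.pixel_center(np.array(r), np.array(c))
            sites.append(SampleSite(id=f"s{len(sites) + 1:03d}", x=float(x), y=float(y),
                                    habitat_class=stratum))

    for stratum, quota in quotas.items():
        if quota == 0:
            continue
        if stratum == "forest":
            _place_forest(raster, available[stratum], quota, rng, _add)
        else:
            _add(stratum, available[stratum], quota)
    return sites


def _place_forest(raster, forest_pixels, quota, rng, add) -> None:
    """Split the forest quota across patch-size classes that exist."""
    mask = raster.classes == CLASS_CODES["forest"]
    labels, n_patches = ndimage.label(mask)
    if n_patches == 0:
        return
    ha_per_pixel = raster.resolution**2 / 10_000.0
    sizes_ha = np.bincount(labels.ravel())[1:] * ha_per_pixel
    lo, hi = FOREST_PATCH_BOUNDS_HA
    size_class = np.where(sizes_ha < lo, 0, np.where(sizes_ha <= hi, 1, 2))
    groups = {}
    for cls_idx, name in enumerate(("small", "medium", "large")):
        patch_ids = np.flatnonzero(size_class == cls_idx) + 1
        if len(patch_ids):
            groups[name] = np.argwhere(np.isin(labels, patch_ids))
    sub = largest_remainder(quota, {name: 1.0 for name in groups})
    for name, q in sub.items():
        add("forest", groups[name], q)


def simulate_genotypes(
    partition: PopulationPartition,
    cfg: ScenarioConfig,
    individual_sites: Mapping[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Diploid genotypes under the F-model of correlated drift.

    Per locus, ancestral allele frequencies are symmetric-Dirichlet(1);
    each population's frequencies are Dirichlet-distributed around the
    ancestral vector with concentration (1 - theta)/theta, so theta_drift
    is the expected Weir-Cockerham differentiation. Individuals draw two
    alleles per locus from their population's frequencies.
    """
    rng = rng if rng is not None else stage_rng(cfg.seed, "genotypes")
    if cfg.alleles_per_locus < 2:
        raise ConfigurationError("alleles_per_locus must be >= 2")
    individuals = sorted(partition.individual_to_pop)
    if not individuals:
        raise ConfigurationError("partition has no individuals")
    pop_of = np.array([partition.individual_to_pop[i] - 1 for i in individuals])
    n_ind, k, A = len(individuals), partition.k, cfg.alleles_per_locus
    conc = (1.0 - cfg.theta_drift) / cfg.theta_drift

    calls = np.empty((n_ind, cfg.n_loci, 2), dtype=np.int32)
    for l in range(cfg.n_loci):
        ancestral = rng.dirichlet(np.ones(A))
        pop_freqs = np.vstack([rng.dirichlet(np.maximum(ancestral * conc, 1e-9)) for _ in range(k)])
        for p in range(k):
            members = np.flatnonzero(pop_of == p)
            if members.size:
                draws = rng.choice(A, size=(members.size, 2), p=pop_freqs[p])
                calls[members, l, :] = draws + 1  # codes are 1-based; 0 = missing
    site_ids = [individual_sites.get(i, "") if individual_sites else "" for i in individuals]
    return GenotypeMatrix(individuals=individuals, site_ids=site_ids,
                          loci=[f"L{l + 1:02d}" for l in range(cfg.n_loci)], calls=calls)


def simulate_surface(
    territory_map: np.ndarray,
    raster: LandCoverRaster,
    sites: list[SampleSite],
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> MembershipSurface:
    """Membership surface whose modal logit carries habitat effects.

    Per pixel of the 100x100 grid over the site bounding box, cluster
    logits decay with distance to each territory; the true (modal)
    cluster's logit is additionally shifted by the local land-cover
    composition weighted by ``cfg.effect_coefficients``, plus Gaussian
    noise of sd ``cfg.noise_sd``. Softmax renormalises per pixel.
    """
    rng = rng if rng is not None else stage_rng(cfg.seed, "surface")
    k = int(territory_map.max())
    xs = np.array([s.x for s in sites])
    ys = np.array([s.y for s in sites])
    xmin, xmax, ymin, ymax = xs.min(), xs.max(), ys.min(), ys.max()
    G = MembershipSurface.GRID
    gx = xmin + (np.arange(G) + 0.5) * max(xmax - xmin, 1e-9) / G
    gy = ymax - (np.arange(G) + 0.5) * max(ymax - ymin, 1e-9) / G
    GX, GY = np.meshgrid(gx, gy, indexing="xy")  # row = y index (north first)
    col = np.clip(((GX - raster.origin_x) / raster.resolution).astype(int), 0, raster.n_cols - 1)
    row = np.clip(((raster.origin_y - GY) / raster.resolution).astype(int), 0, raster.n_rows - 1)

    logits = np.empty((G, G, k))
    for t in range(1, k + 1):
        dist_px = ndimage.distance_transform_edt(territory_map != t)
        logits[:, :, t - 1] = -dist_px[row, col] * raster.resolution / cfg.surface_scale

    modal = territory_map[row, col] - 1
    if cfg.effect_coefficients:
        shift = np.zeros((G, G))
        for name, coef in cfg.effect_coefficients.items():
            onehot = (raster.classes == CLASS_CODES[name]).astype(float)
            local = ndimage.uniform_filter(onehot, size=3)
            shift += coef * local[row, col]
        logits[np.arange(G)[:, None], np.arange(G)[None, :], modal] += shift
    if cfg.noise_sd > 0:
        logits[np.arange(G)[:, None], np.arange(G)[None, :], modal] += rng.normal(
            0.0, cfg.noise_sd, size=(G, G)
        )
    logits -= logits.max(axis=2, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=2, keepdims=True)
    return MembershipSurface(probs=probs, xmin=xmin, ymin=ymin, xmax=xmax, ymax=ymax)


def generate_scenario(cfg: ScenarioConfig) -> SyntheticScenario:
    """Run every generation stage and assemble a consistent scenario."""
    raster = generate_landcover(cfg)
    territory = generate_partition(raster, cfg)
    sites = place_sites(raster, cfg)

    site_to_pop: dict[str, int] = {}
    for s in sites:
        r, c = raster.index_of(s.x, s.y)
        site_to_pop[s.id] = int(territory[r, c])
    individual_to_pop: dict[str, int] = {}
    individual_sites: dict[str, str] = {}
    for s in sites:
        for j in range(cfg.individuals_per_site):
            ind = f"{s.id}_i{j + 1}"
            individual_to_pop[ind] = site_to_pop[s.id]
            individual_sites[ind] = s.id
    partition = PopulationPartition(
        k=cfg.k_true, site_to_pop=site_to_pop, individual_to_pop=individual_to_pop
    )
    genotypes = simulate_genotypes(partition, cfg, individual_sites)
    surface = simulate_surface(territory, raster, sites, cfg)
    return SyntheticScenario(raster=raster, territory_map=territory, sites=sites,
                             genotypes=genotypes, partition=partition,
                             surface=surface, config=cfg)


def simulate_segment_dataset(
    n_segments: int = 70,
    coefficients: Mapping[str, float] | None = None,
    intercept: float | None = None,
    target_w_fraction: float = 47 / 70,
    noise_sd: float = 0.2,
    membership_coefficients: Mapping[str, float] | None = None,
    membership_noise_sd: float = 0.1,
    composition_sd: float = 1.25,
    seed: int = 0,
):
    """Segment-level dataset with known habitat effects.

    Draws each segment's 9-class composition as an endpoint-anchored
    mixture (see below), then assigns the B/W category by a liability
    threshold: W iff ``intercept + sum(coef * prop) + eps > 0`` with
    ``eps ~ N(0, noise_sd)``. Segment category in the emulated system
    is a geometric fact — whether a genetic boundary crosses the
    corridor — so it is near-deterministic in habitat composition;
    ``noise_sd`` controls how often segments near the boundary are
    mislabelled, not an independent coin flip per segment. When
    ``intercept`` is None it is calibrated so the realised W fraction
    matches ``target_w_fraction`` (47 W vs 23 B in a 70-segment
    analysis set). A membership probability is generated on the
    arcsine-square-root scale from ``membership_coefficients``
    (defaults to the logistic coefficients scaled down) plus Gaussian
    noise, then back-transformed.

    Returns a pandas DataFrame with the nine composition columns,
    ``category`` ("B"/"W") and ``membership``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    coefficients = dict(coefficients or {"forest": 2.5, "grassland": 8.5})

    # Each rectangle is anchored at two stratified sample sites, whose
    # habitat dominates the ends, with a logistic-normal matrix mixture
    # in between: a forest-to-forest segment is roughly half forest even
    # when the intervening matrix is agriculture.
    strata = list(SITE_STRATA)
    probs = np.array([SITE_STRATA[s] for s in strata])
    probs /= probs.sum()
    end_idx = np.array([LANDCOVER_CLASSES.index(s) for s in strata])
    ends = rng.choice(end_idx, size=(n_segments, 2), p=probs)
    anchor = np.zeros((n_segments, len(LANDCOVER_CLASSES)))
    np.add.at(anchor, (np.arange(n_segments), ends[:, 0]), 0.5)
    np.add.at(anchor, (np.arange(n_segments), ends[:, 1]), 0.5)

    base = np.array([SEGMENT_BASE_MIX[c] for c in LANDCOVER_CLASSES])
    z = np.log(base) + rng.normal(0.0, composition_sd, size=(n_segments, base.size))
    matrix = np.exp(z)
    matrix /= matrix.sum(axis=1, keepdims=True)
    end_weight = rng.uniform(0.3, 0.7, size=(n_segments, 1))
    comp = end_weight * anchor + (1.0 - end_weight) * matrix
    coef_vec = np.array([coefficients.get(c, 0.0) for c in LANDCOVER_CLASSES])
    signal = comp @ coef_vec
    if intercept is None:
        # place the threshold at the B-fraction quantile of the signal
        intercept = -float(np.quantile(signal, 1.0 - target_w_fraction))
    liability = intercept + signal + rng.normal(0.0, noise_sd, size=n_segments)
    y = liability > 0

    m_coefs = dict(membership_coefficients) if membership_coefficients else {
        c: v / 10.0 for c, v in coefficients.items()
    }
    m_vec = np.array([m_coefs.get(c, 0.0) for c in LANDCOVER_CLASSES])
    t = 0.9 + comp @ m_vec + rng.normal(0.0, membership_noise_sd, size=n_segments)
    t = np.clip(t, 0.0, math.pi / 2)
    membership = np.sin(t) ** 2

    df = pd.DataFrame(comp, columns=list(LANDCOVER_CLASSES))
    df["category"] = np.where(y, "W", "B")
    df["membership"] = membership
    return df
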