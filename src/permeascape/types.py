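"""Core domain containers shared across the pipeline.

The land-cover legend is fixed at nine classes. Class codes are the
1-based positions in :data:`LANDCOVER_CLASSES`; 0 never appears in a
valid raster. The regression predictor set excludes agriculture, which
acts as the reference matrix class (it is almost perfectly negatively
correlated with forest in agriculture-dominated mosaics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

LANDCOVER_CLASSES: tuple[str, ...] = (
    "forest",
    "non_treed_corridor",
    "treed_corridor",
    "grassland",
    "shrubland",
    "water",
    "urban",
    "road",
    "agriculture",
)

#: name -> 1-based integer class code used in rasters
CLASS_CODES: dict[str, int] = {name: i + 1 for i, name in enumerate(LANDCOVER_CLASSES)}

#: regression predictors: the eight classes excluding agriculture
PREDICTOR_CLASSES: tuple[str, ...] = (
    "forest",
    "non_treed_corridor",
    "road",
    "grassland",
    "shrubland",
    "treed_corridor",
    "urban",
    "water",
)

DEFAULT_WIDTHS: tuple[float, ...] = (3.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0, 1000.0)

#: fallback target length (m) for W segments in populations not joined by a
#: B segment: the study-wide mean B-segment length.
DEFAULT_FALLBACK_W_LENGTH: float = 776.0


class ConfigurationError(ValueError):
    """Raised when a configuration violates a documented invariant."""


@dataclass
class LandCoverRaster:
    """Categorical land-cover grid.

    ``classes`` holds 1-based codes into :data:`LANDCOVER_CLASSES`,
    indexed row-major from the top-left corner: row 0 is the northern
    edge, column 0 the western edge. ``origin_x``/``origin_y`` are the
    coordinates of the top-left *corner* in projected meters.
    """

    origin_x: float
    origin_y: float
    resolution: float
    classes: np.ndarray  # (n_rows, n_cols) int

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int16)
        if self.resolution <= 0:
            raise ConfigurationError("raster resolution must be positive")
        if self.classes.ndim != 2:
            raise ConfigurationError("raster class array must be 2-D")
        vals = np.unique(self.classes)
        if vals.min() < 1 or vals.max() > len(LANDCOVER_CLASSES):
            raise ConfigurationError("raster codes must lie in 1..9")

    @property
    def n_rows(self) -> int:
        return self.classes.shape[0]

    @property
    def n_cols(self) -> int:
        return self.classes.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.resolution,
            self.origin_x + self.n_cols * self.resolution,
            self.origin_y,
        )

    def pixel_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin_x + (np.asarray(col) + 0.5) * self.resolution
        y = self.origin_y - (np.asarray(row) + 0.5) * self.resolution
        return x, y

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the pixel containing point (x, y)."""
        col = int(np.floor((x - self.origin_x) / self.resolution))
        row = int(np.floor((self.origin_y - y) / self.resolution))
        return row, col

    def class_fractions(self) -> dict[str, float]:
        counts = np.bincount(self.classes.ravel(), minlength=len(LANDCOVER_CLASSES) + 1)
        total = self.classes.size
        return {name: counts[code] / total for name, code in CLASS_CODES.items()}


@dataclass(frozen=True)
class SampleSite:
    """A trapping location in projected meters."""

    id: str
    x: float
    y: float
    cell_id: str = "cell0"
    habitat_class: str | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ConfigurationError(f"site {self.id}: non-finite coordinates")


@dataclass
class PopulationPartition:
    """Assignment of sites and individuals to genetic clusters 1..k."""

    k: int
    site_to_pop: dict[str, int]
    individual_to_pop: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError("cluster count k must be >= 1")
        for mapping in (self.site_to_pop, self.individual_to_pop):
            for key, pop in mapping.items():
                if not 1 <= pop <= self.k:
                    raise ConfigurationError(f"{key}: cluster id {pop} outside 1..{self.k}")

    def sites_of(self, pop: int) -> list[str]:
        return sorted(s for s, p in self.site_to_pop.items() if p == pop)


@dataclass
class GenotypeMatrix:
    """Diploid multilocus genotypes; allele code 0 means missing.

    ``calls`` has shape (n_individuals, n_loci, 2); both alleles of a
    call are present or both are missing.
    """

    individuals: list[str]
    site_ids: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n, l = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, l, 2):
            raise ConfigurationError(
                f"calls shape {self.calls.shape} != ({n}, {l}, 2)"
            )
        if self.calls.min() < 0:
            raise ConfigurationError("allele codes must be nonnegative")
        half_missing = (self.calls == 0).sum(axis=2) == 1
        if half_missing.any():
            raise ConfigurationError("both alleles of a call must be typed or missing")
        if len(self.site_ids) != n:
            raise ConfigurationError("one site id per individual required")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)


@dataclass
class MembershipSurface:
    """Per-pixel posterior membership probabilities on a fixed 100x100 grid.

    The grid spans the bounding box of the sample sites ("bound by the
    outer sample points"); ``probs`` has shape (100, 100, k) with row 0
    at the northern edge, and every pixel's vector sums to one.
    """

    probs: np.ndarray  # (100, 100, k)
    xmin: float
    ymin: float
    xmax: float
    ymax: float

    GRID: int = 100

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[:2] != (self.GRID, self.GRID):
            raise ConfigurationError("surface grid must be 100x100xk")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ConfigurationError("probabilities outside [0, 1]")
        if not np.allclose(self.probs.sum(axis=2), 1.0, atol=1e-6):
            raise ConfigurationError("per-pixel probabilities must sum to 1")
        if not (self.xmax >= self.xmin and self.ymax >= self.ymin):
            raise ConfigurationError("invalid bounding box")

    @property
    def k(self) -> int:
        return self.probs.shape[2]

    @property
    def pixel_width(self) -> float:
        return max(self.xmax - self.xmin, 1e-12) / self.GRID

    @property
    def pixel_height(self) -> float:
        return max(self.ymax - self.ymin, 1e-12) / self.GRID

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.xmin + (np.arange(self.GRID) + 0.5) * self.pixel_width
        ys = self.ymax - (np.arange(self.GRID) + 0.5) * self.pixel_height
        return xs, ys

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-pixel (row, col) lookup, clamped to the grid edge."""
        col = np.floor((np.asarray(x) - self.xmin) / self.pixel_width).astype(int)
        row = np.floor((self.ymax - np.asarray(y)) / self.pixel_height).astype(int)
        return np.clip(row, 0, self.GRID - 1), np.clip(col, 0, self.GRID - 1)


@dataclass
class Segment:
    """A rectangular corridor joining two sample sites.

    ``category`` is "B" (endpoints in different clusters) or "W" (same
    cluster). Composition and mean membership are filled per width by
    the segment builder.
    """

    site_a: SampleSite
    site_b: SampleSite
    category: str
    pop_a: int
    pop_b: int
    composition: dict[float, np.ndarray] = field(default_factory=dict)
    mean_membership: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in ("B", "W"):
            raise ConfigurationError("segment category must be 'B' or 'W'")
        if self.category == "B" and self.pop_a == self.pop_b:
            raise ConfigurationError("B segment endpoints must lie in different clusters")
        if self.category == "W" and self.pop_a != self.pop_b:
            raise ConfigurationError("W segment endpoints must lie in the same cluster")
        if self.length <= 0:
            raise ConfigurationError("segment length must be positive")

    @property
    def length(self) -> float:
        return math.hypot(self.site_b.x - self.site_a.x, self.site_b.y - self.site_a.y)


def validate_widths(widths: Sequence[float]) -> tuple[float, ...]:
    w = tuple(float(v) for v in widths)
    if any(v <= 0 for v in w) or any(b <= a for a, b in zip(w, w[1:])):
        raise ConfigurationError("widths must be strictly positive and increasing")
    return w


def composition_vector(counts: Mapping[str, float]) -> np.ndarray:
    """Order a class->proportion mapping into the canonical 9-vector."""
    return np.array([counts.get(name, 0.0) for name in LANDCOVER_CLASSES], dtype=float)
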