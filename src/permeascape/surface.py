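"""Membership-probability surfaces from individual assignment vectors.

A deterministic, allele-frequency-based stand-in for the per-pixel
posterior surface a spatially explicit Bayesian clustering run would
produce: individuals get leave-one-out assignment posteriors under each
population's allele frequencies, and the 100x100 surface over the site
bounding box interpolates those vectors by inverse-distance weighting.
"""

from __future__ import annotations

import numpy as np

from .types import GenotypeMatrix, MembershipSurface, PopulationPartition

__all__ = ["assign_posteriors", "build_surface", "modal_surface", "population_weights"]


def assign_posteriors(
    G: GenotypeMatrix,
    partition: PopulationPartition,
    pseudo: float = 1.0,
) -> tuple[np.ndarray, list[str]]:
    """Leave-one-out assignment posteriors under per-population frequencies.

    Population allele frequencies are estimated with an additive
    pseudo-count per allele; the focal individual's own alleles are
    removed from its population's counts before its likelihood is
    evaluated. Returns an (n_individuals, k) array of posteriors under a
    uniform prior over the k populations, plus the ids of individuals
    with no typed locus (assigned the uniform vector 1/k).
    """
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    k = partition.k
    n, L = G.n_individuals, G.n_loci
    pop_of = np.array([partition.individual_to_pop[i] - 1 for i in G.individuals])

    log_post = np.zeros((n, k))
    for l in range(L):
        calls = G.calls[:, l, :]
        typed = calls[:, 0] > 0
        if not typed.any():
            continue
        n_alleles = int(calls.max())
        counts = np.zeros((k, n_alleles + 1))
        for p in range(k):
            sub = calls[(pop_of == p) & typed]
            counts[p] += np.bincount(sub.ravel(), minlength=n_alleles + 1)
        counts[:, 1:] += pseudo
        counts[:, 0] = 0.0

        for i in np.flatnonzero(typed):
            a, b = calls[i]
            cnt = counts.copy()
            cnt[pop_of[i], a] -= 1
            cnt[pop_of[i], b] -= 1
            cnt = np.maximum(cnt, 1e-12)
            freqs = cnt[:, 1:] / cnt[:, 1:].sum(axis=1, keepdims=True)
            if a == b:
                ll = 2.0 * np.log(freqs[:, a - 1])
            else:
                ll = np.log(2.0 * freqs[:, a - 1] * freqs[:, b - 1])
            log_post[i] += ll

    flagged = []
    probs = np.empty((n, k))
    for i in range(n):
        if (G.calls[i, :, 0] == 0).all():
            probs[i] = 1.0 / k
            flagged.append(G.individuals[i])
            continue
        z = log_post[i] - log_post[i].max()
        w = np.exp(z)
        probs[i] = w / w.sum()
    return probs, flagged


def population_weights(partition: PopulationPartition, individuals: list[str]) -> np.ndarray:
    """Per-individual weights equalising each population's total mass.

    Plain IDW lets a densely sampled population dominate the surface far
    beyond its territory simply by contributing more terms; weighting
    each individual by the inverse of its population's sample count
    removes that artifact without changing the interpolation locally.
    """
    pops = np.array([partition.individual_to_pop[i] for i in individuals])
    counts = {p: int((pops == p).sum()) for p in np.unique(pops)}
    return np.array([1.0 / counts[p] for p in pops])


def build_surface(
    assignments: np.ndarray,
    coords: np.ndarray,
    k: int | None = None,
    weights: np.ndarray | None = None,
) -> MembershipSurface:
    """Inverse-distance-weighted (power 2) surface over the site bounding box.

    A pixel coincident with an individual takes that individual's vector
    exactly (the IDW limit); coincident individuals are averaged. The
    grid is fixed at 100x100 pixels spanning the bounding box of the
    coordinates, per-pixel vectors renormalised onto the simplex.
    Optional per-individual ``weights`` multiply the IDW weights (see
    :func:`population_weights`).
    """
    assignments = np.asarray(assignments, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if assignments.ndim != 2 or len(assignments) != len(coords):
        raise ValueError("one assignment vector per coordinate pair required")
    if k is not None and assignments.shape[1] != k:
        raise ValueError("assignment vectors inconsistent with k")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(coords),) or np.any(weights <= 0):
            raise ValueError("weights must be positive, one per individual")
    xmin, ymin = coords.min(axis=0)
    xmax, ymax = coords.max(axis=0)
    G = MembershipSurface.GRID
    px = xmin + (np.arange(G) + 0.5) * max(xmax - xmin, 1e-9) / G
    py = ymax - (np.arange(G) + 0.5) * max(ymax - ymin, 1e-9) / G
    PX, PY = np.meshgrid(px, py, indexing="xy")
    pts = np.column_stack([PX.ravel(), PY.ravel()])

    d2 = ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    exact = d2 < 1e-18
    with np.errstate(divide="ignore"):
        w = 1.0 / d2
    if weights is not None:
        w = w * weights[None, :]
    has_exact = exact.any(axis=1)
    w[has_exact] = exact[has_exact].astype(float)  # IDW limit at coincident points
    vals = w @ assignments / w.sum(axis=1, keepdims=True)
    probs = (vals / vals.sum(axis=1, keepdims=True)).reshape(G, G, assignments.shape[1])
    return MembershipSurface(probs=probs, xmin=float(xmin), ymin=float(ymin),
                             xmax=float(xmax), ymax=float(ymax))


def modal_surface(surface: MembershipSurface) -> np.ndarray:
    """Per-pixel modal membership probability (maximum over the k clusters).

    This is the single-valued reduction averaged over segment pixels
    downstream; values lie in [1/k, 1]. An alternative focal-cluster
    slice can be taken directly from ``surface.probs`` when a named
    cluster is of interest.
    """
    return surface.probs.max(axis=2)
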