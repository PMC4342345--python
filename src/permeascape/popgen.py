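"""Population-genetic summaries: diversity, F_IS, pairwise F_ST, Mantel IBD.

F_ST uses the Weir & Cockerham (1984) variance-components estimator
theta-hat, combined across alleles and loci as a ratio of sums (the
standard multilocus form). Permutation p-values everywhere use the
(b + 1)/(m + 1) estimator so an empirical p of exactly zero cannot occur.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import GenotypeMatrix, PopulationPartition

__all__ = [
    "DiversitySummary",
    "FstMatrix",
    "MantelResult",
    "diversity_summary",
    "allelic_richness",
    "weir_cockerham_theta",
    "pairwise_fst",
    "mantel",
    "mantel_ibd",
]


@dataclass
class FstMatrix:
    populations: list[int]
    theta: np.ndarray  # symmetric, nan diagonal
    p_value: np.ndarray
    n_permutations: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, index=self.populations, columns=self.populations)


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    n_pairs: int


@dataclass
class DiversitySummary:
    table: pd.DataFrame  # one row per locus x population


# ---------------------------------------------------------------- diversity

def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allelic_richness(allele_counts: np.ndarray, g: int) -> float:
    """Expected allele count in a random subsample of g genes.

    Hypergeometric rarefaction: sum over alleles of the probability that
    the allele appears at least once among g genes drawn without
    replacement from the 2N observed.
    """
    counts = np.asarray(allele_counts, dtype=float)
    counts = counts[counts > 0]
    total = counts.sum()
    if g > total:
        raise ValueError(f"rarefaction size g={g} exceeds {int(total)} sampled genes")
    absent = np.where(
        total - counts >= g,
        np.exp(_log_comb(total - counts, g) - _log_comb(np.array(total), g)),
        0.0,
    )
    return float(np.sum(1.0 - absent))


def _locus_pop_stats(calls: np.ndarray) -> tuple[int, np.ndarray, float]:
    """(N typed, allele count vector, observed heterozygosity) for one locus/pop."""
    typed = calls[calls[:, 0] > 0]
    n = len(typed)
    if n == 0:
        return 0, np.zeros(0), np.nan
    counts = np.bincount(typed.ravel())[1:]
    ho = float(np.mean(typed[:, 0] != typed[:, 1]))
    return n, counts, ho


def diversity_summary(
    G: GenotypeMatrix,
    partition: PopulationPartition,
    g: int | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> DiversitySummary:
    """Per locus x population diversity metrics with permutation F_IS CIs.

    He is the small-sample-corrected (unbiased) expected heterozygosity
    2N/(2N-1) * (1 - sum p^2); F_IS = 1 - Ho/He, undefined (NaN) at
    monomorphic loci. The 95% CI comes from ``n_perm`` permutations of
    alleles among individuals within the population, which breaks the
    within-individual allele association while preserving frequencies.
    When ``g`` is None it defaults to twice the smallest per-population
    typed sample over loci.
    """
    rng = np.random.default_rng(seed)
    pop_of = np.array([partition.individual_to_pop[i] for i in G.individuals])
    pops = sorted(set(pop_of.tolist()))

    if g is None:
        mins = []
        for p in pops:
            sub = G.calls[pop_of == p]
            typed = (sub[:, :, 0] > 0).sum(axis=0)
            mins.append(typed[typed > 0].min() if (typed > 0).any() else 0)
        g = 2 * int(min(m for m in mins if m > 0))

    rows = []
    for p in pops:
        sub = G.calls[pop_of == p]
        for l, locus in enumerate(G.loci):
            n, counts, ho = _locus_pop_stats(sub[:, l, :])
            if n == 0:
                rows.append(dict(population=p, locus=locus, N=0, Na=0, Ho=np.nan,
                                 He=np.nan, AR=np.nan, Fis=np.nan,
                                 Fis_lo=np.nan, Fis_hi=np.nan))
                continue
            freqs = counts / counts.sum()
            he = 2 * n / (2 * n - 1) * (1.0 - float(np.sum(freqs**2)))
            na = int((counts > 0).sum())
            ar = allelic_richness(counts, g) if g <= 2 * n else np.nan
            if he <= 0:
                fis = lo = hi = np.nan
            else:
                fis = 1.0 - ho / he
                typed = sub[:, l, :][sub[:, l, 0] > 0]
                pool = typed.ravel().copy()
                perm_fis = np.empty(n_perm)
                for b in range(n_perm):
                    rng.shuffle(pool)
                    pairs = pool.reshape(-1, 2)
                    ho_b = np.mean(pairs[:, 0] != pairs[:, 1])
                    perm_fis[b] = 1.0 - ho_b / he
                lo, hi = np.percentile(perm_fis, [2.5, 97.5])
            rows.append(dict(population=p, locus=locus, N=n, Na=na, Ho=ho, He=he,
                             AR=ar, Fis=fis, Fis_lo=lo, Fis_hi=hi))
    return DiversitySummary(table=pd.DataFrame(rows))


# ------------------------------------------------------------------- F_ST

def _wc_components(calls_l: np.ndarray, pop_idx: np.ndarray) -> tuple[float, float]:
    """Weir-Cockerham (a, a+b+c) summed over alleles for one locus.

    ``calls_l`` is (n, 2) allele codes (0 = missing), ``pop_idx`` the
    0-based population index per individual.
    """
    typed = calls_l[:, 0] > 0
    calls_l, pop_idx = calls_l[typed], pop_idx[typed]
    pops = np.unique(pop_idx)
    r = len(pops)
    if r < 2 or calls_l.size == 0:
        return 0.0, 0.0
    n_i = np.array([(pop_idx == p).sum() for p in pops], dtype=float)
    nbar = n_i.mean()
    if nbar <= 1:
        return 0.0, 0.0
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    if nc <= 0:
        return 0.0, 0.0

    n_codes = int(calls_l.max()) + 1
    het_ind = calls_l[:, 0] != calls_l[:, 1]
    # per-population allele frequencies and heterozygote-carrier rates,
    # vectorised over allele codes
    p_i = np.zeros((r, n_codes))
    h_i = np.zeros((r, n_codes))
    for ridx, p in enumerate(pops):
        sub = calls_l[pop_idx == p]
        p_i[ridx] = np.bincount(sub.ravel(), minlength=n_codes) / (2 * n_i[ridx])
        hets = sub[het_ind[pop_idx == p]]
        h_i[ridx] = np.bincount(hets.ravel(), minlength=n_codes) / n_i[ridx]

    pbar = (n_i[:, None] * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h_i).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    seen = pbar > 0
    return float(a[seen].sum()), float((a + b + c)[seen].sum())


def weir_cockerham_theta(calls: np.ndarray, pop_idx: np.ndarray) -> float:
    """Multilocus theta-hat as the ratio of summed variance components."""
    num = den = 0.0
    for l in range(calls.shape[1]):
        a, abc = _wc_components(calls[:, l, :], pop_idx)
        num += a
        den += abc
    return num / den if den != 0 else np.nan


def pairwise_fst(
    G: GenotypeMatrix,
    partition: PopulationPartition,
    n_perm: int = 1200,
    seed: int = 0,
) -> FstMatrix:
    """Pairwise multilocus theta-hat with permutation significance.

    For each population pair, individuals are shuffled between the two
    populations ``n_perm`` times; p is the (+1-corrected) fraction of
    permuted theta-hat values at least as large as the observed one.
    """
    rng = np.random.default_rng(seed)
    pop_of = np.array([partition.individual_to_pop[i] for i in G.individuals])
    pops = sorted(set(pop_of.tolist()))
    m = len(pops)
    theta = np.full((m, m), np.nan)
    pval = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            mask = (pop_of == pops[i]) | (pop_of == pops[j])
            calls = G.calls[mask]
            labels = (pop_of[mask] == pops[j]).astype(int)
            typed_any = (calls[:, :, 0] > 0).any(axis=1)
            if typed_any[labels == 0].sum() < 2 or typed_any[labels == 1].sum() < 2:
                continue  # a population with (almost) no data: pair stays missing
            obs = weir_cockerham_theta(calls, labels)
            if np.isnan(obs):
                continue
            exceed = 0
            perm = labels.copy()
            for _ in range(n_perm):
                rng.shuffle(perm)
                t = weir_cockerham_theta(calls, perm)
                if not np.isnan(t) and t >= obs:
                    exceed += 1
            theta[i, j] = theta[j, i] = obs
            pval[i, j] = pval[j, i] = (exceed + 1) / (n_perm + 1)
    return FstMatrix(populations=pops, theta=theta, p_value=pval, n_permutations=n_perm)


# ------------------------------------------------------------------ Mantel

def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(mat, k=1)
    return mat[iu]


def mantel(
    m1: np.ndarray,
    m2: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Simple Mantel test: Pearson r of upper triangles, one-sided p.

    Rows/columns of ``m1`` are permuted simultaneously; entries that are
    non-finite in either matrix (e.g. an infinite F_ST linearisation)
    are excluded pair-wise, with the exclusion mask recomputed under
    each permutation.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.shape[0] != m1.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices_from(m1, k=1)

    def corr(a: np.ndarray) -> float:
        v1, v2 = a[iu], m2[iu]
        ok = np.isfinite(v1) & np.isfinite(v2)
        if ok.sum() < 3:
            return np.nan
        return float(np.corrcoef(v1[ok], v2[ok])[0, 1])

    r_obs = corr(m1)
    n = m1.shape[0]
    exceed = 0
    for _ in range(n_perm):
        order = rng.permutation(n)
        r_p = corr(m1[np.ix_(order, order)])
        if not np.isnan(r_p) and r_p >= r_obs:
            exceed += 1
    n_pairs = int(np.sum(np.isfinite(m1[iu]) & np.isfinite(m2[iu])))
    return MantelResult(r=r_obs, p=(exceed + 1) / (n_perm + 1),
                        n_permutations=n_perm, n_pairs=n_pairs)


def mantel_ibd(
    fst: FstMatrix | np.ndarray,
    coords: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Isolation-by-distance test: F_ST/(1-F_ST) versus Euclidean distance.

    ``coords`` is an (n, 2) array of site or cell centroids matching the
    order of the F_ST matrix labels. Pairs whose theta-hat equals 1
    (infinite linearisation) are excluded with a warning.
    """
    theta = fst.theta if isinstance(fst, FstMatrix) else np.asarray(fst, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lin = theta / (1.0 - theta)
    if np.any(np.isinf(lin)):
        warnings.warn("theta-hat of 1 linearises to infinity; pair(s) excluded", stacklevel=2)
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    geo = np.sqrt((diff**2).sum(axis=2))
    return mantel(lin, geo, n_perm=n_perm, seed=seed)
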