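"""Regression machinery: logistic and linear fits, stepwise AIC, bootstrap.

Two model families share one bootstrap/selection harness:

* logistic — response is segment category (B = 0, W = 1), predictors the
  eight land-cover proportions excluding agriculture; reports deviances
  and percent deviance explained;
* linear — response is the arcsine-square-root-transformed mean
  membership probability; reports R^2 / adjusted R^2 and the overall F
  test.

Stepwise selection starts from the full model and applies, at each
step, the single variable addition or removal that most lowers AIC
(previously removed variables may re-enter), stopping at a local AIC
optimum with the intercept always retained. The bootstrap refits
full-model-then-stepwise on each of B resamples and summarises
retention counts, coefficient distributions and fit statistics; a
variable is "selected" when retained in at least ``retain`` of the B
iterations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import ConfigurationError, PREDICTOR_CLASSES

__all__ = [
    "ModelDesign",
    "FittedModel",
    "BootstrapSummary",
    "arcsine_sqrt",
    "anderson_darling",
    "design_from_table",
    "fit_logistic",
    "fit_linear",
    "fit_model",
    "stepwise_aic",
    "percent_deviance",
    "bootstrap_models",
]

_MAX_IRLS_ITER = 100
# proportion predictors legitimately carry large coefficients (1/units of
# proportion), so separation is diagnosed from a collapsing deviance or a
# truly diverging fit, never from moderately large coefficients
_SEPARATION_COEF = 500.0
# a binomial deviance this small means the sample is (quasi-)separated;
# iterating further only inflates the coefficients
_DEV_FLOOR = 1e-3


def arcsine_sqrt(p):
    """Variance-stabilising transform arcsin(sqrt(p)) for proportions."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def anderson_darling(x) -> tuple[float, float]:
    """Anderson-Darling normality test with estimated mean and variance.

    Returns the small-sample-adjusted statistic
    A* = A^2 (1 + 0.75/n + 2.25/n^2) and its p-value from the standard
    case-3 approximation (both parameters estimated).
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 observations")
    s = x.std(ddof=1)
    if s == 0:
        return math.inf, 0.0
    z = (x - x.mean()) / s
    cdf = stats.norm.cdf(z)
    cdf = np.clip(cdf, 1e-300, 1 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log(1 - cdf[::-1])))
    a_star = a2 * (1 + 0.75 / n + 2.25 / n**2)
    if a_star >= 0.6:
        p = math.exp(1.2937 - 5.709 * a_star + 0.0186 * a_star**2)
    elif a_star >= 0.34:
        p = math.exp(0.9177 - 4.279 * a_star - 1.38 * a_star**2)
    elif a_star >= 0.2:
        p = 1 - math.exp(-8.318 + 42.796 * a_star - 59.938 * a_star**2)
    else:
        p = 1 - math.exp(-13.436 + 101.14 * a_star - 223.73 * a_star**2)
    return float(a_star), float(min(max(p, 0.0), 1.0))


@dataclass
class ModelDesign:
    """Rows (segments at one width) by predictors, plus the response."""

    X: np.ndarray  # (n, p) predictor matrix WITHOUT intercept column
    y: np.ndarray
    names: list[str]
    kind: str  # "logistic" | "linear"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.kind not in ("logistic", "linear"):
            raise ConfigurationError("kind must be 'logistic' or 'linear'")
        if "agriculture" in self.names:
            raise ConfigurationError("agriculture is excluded from all models")
        if self.X.shape != (len(self.y), len(self.names)):
            raise ConfigurationError("X shape inconsistent with y/names")
        if not np.isfinite(self.X).all() or not np.isfinite(self.y).all():
            raise ConfigurationError("design contains non-finite values")
        if self.kind == "logistic" and not np.isin(self.y, (0.0, 1.0)).all():
            raise ConfigurationError("logistic response must be coded 0/1")

    @property
    def n(self) -> int:
        return len(self.y)

    def subset(self, rows: np.ndarray | None = None, cols: list[int] | None = None) -> "ModelDesign":
        rows = np.arange(self.n) if rows is None else rows
        cols = list(range(len(self.names))) if cols is None else cols
        return ModelDesign(X=self.X[np.ix_(rows, cols)], y=self.y[rows],
                           names=[self.names[c] for c in cols], kind=self.kind)


def design_from_table(table: pd.DataFrame, kind: str, width: float | None = None) -> ModelDesign:
    """Build a design from a segment table (one row per segment x width).

    Logistic response: category B -> 0, W -> 1. Linear response:
    arcsin(sqrt(mean membership)).
    """
    df = table if width is None else table[table["width"] == width]
    X = df[list(PREDICTOR_CLASSES)].to_numpy(dtype=float)
    if kind == "logistic":
        y = (df["category"] == "W").to_numpy(dtype=float)
    else:
        y = arcsine_sqrt(df["membership"].to_numpy(dtype=float))
    return ModelDesign(X=X, y=y, names=list(PREDICTOR_CLASSES), kind=kind)


@dataclass
class FittedModel:
    kind: str
    names: list[str]  # included predictors (intercept implicit, first coef)
    coef: np.ndarray  # (p+1,) intercept first
    se: np.ndarray
    p_values: np.ndarray
    aic: float
    converged: bool
    n: int
    separated: bool = False  # logistic: fitted probabilities pinned at 0/1
    # logistic
    deviance: float = math.nan
    null_deviance: float = math.nan
    # linear
    r2: float = math.nan
    adj_r2: float = math.nan
    f_pvalue: float = math.nan
    sigma2: float = math.nan
    df_resid: int = 0
    xtx_inv: np.ndarray | None = field(default=None, repr=False)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.names):
            raise ValueError(f"expected columns {self.names}")
        return self.coef[0] + X @ self.coef[1:]

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        """Fitted probability of the W class (logistic models)."""
        if self.kind != "logistic":
            raise ValueError("probability prediction is for logistic fits")
        from scipy.special import expit

        return expit(self.linear_predictor(X))


def _with_intercept(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def fit_logistic(design: ModelDesign) -> FittedModel:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    AIC = deviance + 2 * (number of coefficients). Complete or
    quasi-complete separation (deviance collapsing toward 0 with
    diverging coefficients) is flagged via ``separated``; the fit
    itself still terminates on the numerical deviance criterion, the
    way standard GLM software proceeds, so separated fits classify but
    their coefficients and standard errors are not interpretable.
    """
    if design.kind != "logistic":
        raise ConfigurationError("design is not logistic")
    y = design.y
    if y.min() == y.max():
        raise ConfigurationError("logistic fit needs both response classes")
    from scipy.special import expit

    Xd = _with_intercept(design.X)
    n, p = Xd.shape
    beta = np.zeros(p)
    dev = _binomial_deviance(y, np.full(n, 0.5))
    converged = False
    for _ in range(_MAX_IRLS_ITER):
        mu = expit(Xd @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        try:
            delta = np.linalg.solve(Xd.T @ (Xd * w[:, None]), Xd.T @ (y - mu))
        except np.linalg.LinAlgError:
            # singular information (aliased or saturated resample):
            # minimum-norm Newton step
            delta, _, _, _ = np.linalg.lstsq(Xd.T @ (Xd * w[:, None]),
                                             Xd.T @ (y - mu), rcond=None)
        # step-halving keeps the deviance monotone on ill-conditioned resamples
        step = 1.0
        new_dev = _binomial_deviance(y, expit(Xd @ (beta + delta)))
        while new_dev > dev + 1e-8 and step > 1e-4:
            step /= 2.0
            new_dev = _binomial_deviance(y, expit(Xd @ (beta + step * delta)))
        beta = beta + step * delta
        if abs(new_dev - dev) < 1e-8 * (abs(dev) + 1e-8) or new_dev < _DEV_FLOOR:
            dev = new_dev
            converged = True
            break
        dev = new_dev
    separated = dev < _DEV_FLOOR or np.max(np.abs(beta)) > _SEPARATION_COEF
    if not converged and separated:
        # quasi-separation: the deviance crawls toward its infimum while
        # coefficients diverge; terminate as GLM software does
        converged = True
    mu = expit(Xd @ beta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    try:
        cov = np.linalg.inv(Xd.T @ (Xd * w[:, None]))
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    zval = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zval))
    ybar = y.mean()
    null_dev = _binomial_deviance(y, np.full(n, ybar))
    return FittedModel(kind="logistic", names=list(design.names), coef=beta, se=se,
                       p_values=pvals, aic=dev + 2 * p,
                       converged=converged, separated=separated, n=n,
                       deviance=dev, null_deviance=null_dev)


def fit_linear(design: ModelDesign) -> FittedModel:
    """Ordinary least squares with aliased-column handling.

    Rank-deficient designs have aliased columns dropped (with a
    warning); dropped variables report NaN coefficients. AIC uses the
    profiled-variance Gaussian log-likelihood:
    n ln(2 pi RSS/n) + n + 2 * (number of coefficients).
    """
    if design.kind != "linear":
        raise ConfigurationError("design is not linear")
    y = design.y
    Xd = _with_intercept(design.X)
    n, p_full = Xd.shape

    # detect aliased columns via pivoted QR
    from scipy.linalg import qr

    _, R, piv = qr(Xd, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xd.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    if 0 not in keep:  # never drop the intercept
        keep = np.concatenate([[0], keep[keep != 0][: rank - 1]])
    if rank < p_full:
        dropped = [design.names[i - 1] for i in range(1, p_full) if i not in keep]
        warnings.warn(f"aliased columns dropped: {dropped}", stacklevel=2)
    Xk = Xd[:, keep]
    p = Xk.shape[1]
    if n <= p:
        raise ConfigurationError("need more rows than estimated coefficients")

    xtx_inv = np.linalg.inv(Xk.T @ Xk)
    beta_k = xtx_inv @ Xk.T @ y
    resid = y - Xk @ beta_k
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    df_resid = n - p
    sigma2 = rss / df_resid if df_resid > 0 else math.nan
    se_k = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta_k / se_k
    pvals_k = 2 * stats.t.sf(np.abs(tvals), df_resid)

    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    adj_r2 = 1.0 - (1 - r2) * (n - 1) / df_resid if tss > 0 else math.nan
    if p > 1 and tss > 0 and rss > 0:
        f_stat = ((tss - rss) / (p - 1)) / (rss / df_resid)
        f_pvalue = float(stats.f.sf(f_stat, p - 1, df_resid))
    else:
        f_pvalue = math.nan
    aic = n * math.log(2 * math.pi * max(rss, 1e-300) / n) + n + 2 * p

    beta = np.full(p_full, np.nan)
    se = np.full(p_full, np.nan)
    pv = np.full(p_full, np.nan)
    beta[keep], se[keep], pv[keep] = beta_k, se_k, pvals_k
    return FittedModel(kind="linear", names=list(design.names), coef=beta, se=se,
                       p_values=pv, aic=aic, converged=True, n=n,
                       r2=r2, adj_r2=adj_r2, f_pvalue=f_pvalue, sigma2=sigma2,
                       df_resid=df_resid, xtx_inv=xtx_inv if rank == p_full else None)


def fit_model(design: ModelDesign) -> FittedModel:
    return fit_logistic(design) if design.kind == "logistic" else fit_linear(design)


def _candidate_aic(Xd: np.ndarray, y: np.ndarray, kind: str) -> float | None:
    """AIC of one candidate model, skipping inference statistics.

    Used only inside the stepwise search; returns None when the
    candidate cannot be scored (singular or non-converged).
    """
    n, p = Xd.shape
    if kind == "linear":
        if n <= p:
            return None
        beta, _, _, _ = np.linalg.lstsq(Xd, y, rcond=None)
        resid = y - Xd @ beta
        rss = float(resid @ resid)
        # parameters counted per column (aliased columns still pay the
        # AIC penalty, so duplicates are stepped out one by one)
        return n * math.log(2 * math.pi * max(rss, 1e-300) / n) + n + 2 * p
    from scipy.special import expit

    beta = np.zeros(p)
    dev = _binomial_deviance(y, np.full(n, 0.5))
    converged = False
    for _ in range(_MAX_IRLS_ITER):
        mu = expit(Xd @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        try:
            delta = np.linalg.solve(Xd.T @ (Xd * w[:, None]), Xd.T @ (y - mu))
        except np.linalg.LinAlgError:
            delta, _, _, _ = np.linalg.lstsq(Xd.T @ (Xd * w[:, None]), Xd.T @ (y - mu),
                                             rcond=None)
        step = 1.0
        new_dev = _binomial_deviance(y, expit(Xd @ (beta + delta)))
        while new_dev > dev + 1e-8 and step > 1e-4:
            step /= 2.0
            new_dev = _binomial_deviance(y, expit(Xd @ (beta + step * delta)))
        beta = beta + step * delta
        if abs(new_dev - dev) < 1e-8 * (abs(dev) + 1e-8) or new_dev < _DEV_FLOOR:
            dev = new_dev
            converged = True
            break
        dev = new_dev
    if not converged and np.max(np.abs(beta)) <= _SEPARATION_COEF:
        return None
    return dev + 2 * p


def percent_deviance(null_dev: float, resid_dev: float) -> float:
    """Percent deviance explained, 100 (D0 - D) / D0."""
    if null_dev == 0:
        raise ValueError("null deviance is zero; percent deviance undefined")
    if resid_dev > null_dev * (1 + 1e-9) + 1e-9:
        warnings.warn("residual deviance exceeds null deviance", stacklevel=2)
    return 100.0 * (null_dev - resid_dev) / null_dev


def stepwise_aic(
    design: ModelDesign,
    full: FittedModel | None = None,
    skip_separated: bool = False,
) -> FittedModel:
    """Bidirectional stepwise AIC selection starting from the full model.

    At each step every single-variable removal (and re-addition of a
    previously removed variable) is scored; the move with the largest
    AIC decrease is taken, terminating when no move lowers AIC. The
    intercept is always retained. Non-converged candidate fits are
    always skipped; separated-but-converged fits are usable unless
    ``skip_separated``.
    """
    p = len(design.names)
    current = sorted(range(p))
    Xd = _with_intercept(design.X)
    y = design.y

    def score(cols: list[int]) -> float | None:
        if skip_separated:
            try:
                fit = fit_model(design.subset(cols=cols))
            except (ConfigurationError, np.linalg.LinAlgError):
                return None
            if not fit.converged or fit.separated:
                return None
            return fit.aic
        return _candidate_aic(Xd[:, [0] + [c + 1 for c in cols]], y, design.kind)

    best_aic = score(current)
    if best_aic is None:
        raise ConfigurationError("full model cannot be scored; check the design")
    max_moves = max(2 * p * p, 10)
    for _ in range(max_moves):
        candidates: list[list[int]] = [[c for c in current if c != j] for j in current]
        candidates += [sorted(current + [j]) for j in range(p) if j not in current]
        best_move: tuple[float, list[int]] | None = None
        for cols in candidates:
            aic = score(cols)
            if aic is None:
                continue
            if aic < best_aic - 1e-10 and (best_move is None or aic < best_move[0]):
                best_move = (aic, cols)
        if best_move is None:
            if full is not None and current == sorted(range(p)):
                return full
            return fit_model(design.subset(cols=current))
        best_aic, current = best_move
    raise RuntimeError("stepwise selection exceeded its move cap without converging")


@dataclass
class BootstrapSummary:
    """Bootstrap x stepwise selection summary at one segment width."""

    kind: str
    names: list[str]
    B: int
    retain: int
    inclusion: np.ndarray  # (B, p) bool
    coefs: np.ndarray  # (B, p+1) with NaN where excluded; intercept col 0
    p_values: np.ndarray  # (B, p+1)
    fit_stats: pd.DataFrame  # per-iteration aic/deviance/r2...
    iteration_rows: np.ndarray  # (B, n) resampled row indices
    n_redraws: int = 0
    n_separated: int = 0

    @property
    def retention(self) -> pd.Series:
        return pd.Series(self.inclusion.sum(axis=0), index=self.names, name="retention")

    @property
    def selected(self) -> list[str]:
        return [n for n, c in self.retention.items() if c >= self.retain]

    def variable_table(self) -> pd.DataFrame:
        """Per-variable retention, conditional mean/SE of beta, 95% CI, mean p."""
        rows = []
        for j, name in enumerate(["intercept"] + self.names):
            col = self.coefs[:, j]
            inc = ~np.isnan(col)
            rows.append(dict(
                variable=name,
                retention=int(inc.sum()),
                mean_beta=float(np.nanmean(col)) if inc.any() else math.nan,
                se_beta=float(np.nanstd(col, ddof=1)) if inc.sum() > 1 else math.nan,
                ci_lower=float(np.nanpercentile(col, 2.5)) if inc.any() else math.nan,
                ci_upper=float(np.nanpercentile(col, 97.5)) if inc.any() else math.nan,
                mean_p=float(np.nanmean(self.p_values[:, j])) if inc.any() else math.nan,
                selected=(name != "intercept" and int(inc.sum()) >= self.retain),
            ))
        return pd.DataFrame(rows)

    def fit_summary(self) -> dict[str, float]:
        out = {"mean_aic": float(self.fit_stats["aic"].mean())}
        if self.kind == "logistic":
            out["mean_residual_deviance"] = float(self.fit_stats["deviance"].mean())
            out["mean_null_deviance"] = float(self.fit_stats["null_deviance"].mean())
            out["mean_percent_deviance"] = float(self.fit_stats["percent_deviance"].mean())
        else:
            out["mean_r2"] = float(self.fit_stats["r2"].mean())
            out["mean_adj_r2"] = float(self.fit_stats["adj_r2"].mean())
        return out


def bootstrap_models(
    design: ModelDesign,
    B: int = 1000,
    retain: int = 900,
    seed: int = 0,
    stratified: bool = False,
    redraw_separated: bool = False,
) -> BootstrapSummary:
    """Bootstrap-wrapped stepwise selection.

    Each iteration resamples the n segments with replacement
    (unstratified by default, matching resampling of the full dataset;
    ``stratified=True`` resamples within B and W separately for
    degenerate small-n cases), fits the full model, then runs stepwise
    AIC. Iterations whose resample has a single response class or whose
    full fit fails to converge are redrawn, up to 10 B total attempts.
    Separated logistic resamples are accepted (and counted in
    ``n_separated``) by default; ``redraw_separated=True`` redraws them
    instead, which is only feasible when the data are far from
    separable.
    """
    if retain > B:
        raise ConfigurationError("retain threshold cannot exceed B")
    if design.kind == "logistic" and (design.y.sum() < 1 or (1 - design.y).sum() < 1):
        raise ConfigurationError("both segment categories required")
    rng = np.random.default_rng(seed)
    n, p = design.n, len(design.names)
    if n < 10:
        warnings.warn("fewer than 10 segments; bootstrap summaries will be fragile",
                      stacklevel=2)
    name_to_idx = {nm: i for i, nm in enumerate(design.names)}

    inclusion = np.zeros((B, p), dtype=bool)
    coefs = np.full((B, p + 1), np.nan)
    pvals = np.full((B, p + 1), np.nan)
    rows_out = np.zeros((B, n), dtype=np.int32)
    stats_rows = []
    attempts = 0
    n_separated = 0
    b = 0
    classes = (design.y > 0.5) if design.kind == "logistic" else None
    while b < B:
        if attempts >= 10 * B:
            raise RuntimeError(f"exceeded {10 * B} bootstrap attempts at iteration {b}")
        attempts += 1
        if stratified and classes is not None:
            idx0 = np.flatnonzero(~classes)
            idx1 = np.flatnonzero(classes)
            rows = np.concatenate([rng.choice(idx0, size=len(idx0), replace=True),
                                   rng.choice(idx1, size=len(idx1), replace=True)])
        else:
            rows = rng.integers(0, n, size=n)
        sub = design.subset(rows=rows)
        if design.kind == "logistic" and (sub.y.min() == sub.y.max()):
            continue
        try:
            full = fit_model(sub)
        except (ConfigurationError, np.linalg.LinAlgError):
            continue
        if not full.converged or (redraw_separated and full.separated):
            continue
        n_separated += int(full.separated)
        sel = stepwise_aic(sub, full=full, skip_separated=redraw_separated)
        rows_out[b] = rows
        coefs[b, 0] = sel.coef[0]
        pvals[b, 0] = sel.p_values[0]
        for nm, cf, pv in zip(sel.names, sel.coef[1:], sel.p_values[1:]):
            j = name_to_idx[nm]
            if not np.isnan(cf):
                inclusion[b, j] = True
                coefs[b, j + 1] = cf
                pvals[b, j + 1] = pv
        rec = {"aic": sel.aic}
        if design.kind == "logistic":
            rec.update(deviance=sel.deviance, null_deviance=sel.null_deviance,
                       percent_deviance=percent_deviance(sel.null_deviance, sel.deviance))
        else:
            rec.update(r2=sel.r2, adj_r2=sel.adj_r2)
        stats_rows.append(rec)
        b += 1

    return BootstrapSummary(kind=design.kind, names=list(design.names), B=B,
                            retain=retain, inclusion=inclusion, coefs=coefs,
                            p_values=pvals, fit_stats=pd.DataFrame(stats_rows),
                            iteration_rows=rows_out, n_redraws=attempts - B,
                            n_separated=n_separated)
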