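"""Bayesian model averaging over covariate subsets for trend projection.

Every subset of the candidate covariates (including the empty model)
defines a linear regression on a transformed response; models are weighted
by their marginal likelihood under a Zellner g-prior with unit information
(g = n) and a uniform prior over the model space.  The space is enumerated
exactly for k <= 20 covariates; a Metropolis sampler over inclusion masks
(MC3) with configurable burn-in and iteration counts covers larger spaces.

Responses bounded in (0, 1) (probabilities, prevalences) are modelled on
the logit scale and rates on the log scale; projections are transformed
back, which keeps forecasts in range by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

__all__ = ["BMAConfig", "BMAFit", "enumerate_models", "fit_bma", "project_bma"]

_ENUM_LIMIT = 20
_TRANSFORMS = {
    "logit": (lambda y: logit(np.clip(y, 1e-12, 1 - 1e-12)), expit),
    "log": (lambda y: np.log(np.maximum(y, 1e-300)), np.exp),
    "identity": (lambda y: y, lambda y: y),
}


@dataclass(frozen=True)
class BMAConfig:
    covariate_labels: tuple[str, ...]
    model_prior: str = "uniform"
    burn_in: int = 5000
    iterations: int = 20000
    sampler: str = "enumerate"
    transform: str = "logit"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.covariate_labels)) != len(self.covariate_labels):
            raise ValueError("covariate labels must be unique")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.sampler not in ("enumerate", "mc3"):
            raise ValueError("sampler must be 'enumerate' or 'mc3'")
        if self.model_prior != "uniform":
            raise ValueError("only the uniform model prior is supported")
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class BMAFit:
    config: BMAConfig
    models: list[tuple[int, ...]]          # covariate index subsets
    model_weights: np.ndarray
    inclusion_probability: pd.Series       # per covariate label
    coefficients: list[np.ndarray]         # posterior slope means per model
    years: np.ndarray = field(default=None)  # years the fit conditioned on
    _X: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _g: float = field(repr=False, default=None)

    @property
    def model_space_size(self) -> int:
        return len(self.models)


def enumerate_models(k: int) -> list[tuple[int, ...]]:
    """All 2**k covariate subsets, ordered by inclusion bitmask.

    Bit i of the mask selects covariate i; the empty model is first.
    """
    if not 1 <= k <= _ENUM_LIMIT:
        raise ValueError(
            f"enumeration supports 1 <= k <= {_ENUM_LIMIT}; use the mc3 sampler beyond that")
    return [tuple(i for i in range(k) if mask >> i & 1) for mask in range(2 ** k)]


def _log_marginal(X: np.ndarray, y: np.ndarray, subset: tuple[int, ...], g: float) -> tuple[float, np.ndarray]:
    """Log marginal likelihood (up to a model-constant) and OLS slopes.

    Zellner g-prior with a flat prior on intercept and log-variance:
    ``ml ∝ (1+g)^((n-1-p)/2) * (1 + g (1 - R^2))^(-(n-1)/2)``.
    Rank-deficient designs get -inf (weight zero).
    """
    n = y.size
    yc = y - y.mean()
    tss = float(yc @ yc)
    if not subset:
        return 0.0, np.zeros(0)
    Xs = X[:, subset]
    Xc = Xs - Xs.mean(axis=0)
    beta, _, rank, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    if rank < len(subset):
        logger.debug("rank-deficient design for subset %s; weight set to 0", subset)
        return -np.inf, np.zeros(len(subset))
    resid = yc - Xc @ beta
    r2 = 0.0 if tss == 0 else 1.0 - float(resid @ resid) / tss
    r2 = min(max(r2, 0.0), 1.0 - 1e-15)
    p = len(subset)
    lml = 0.5 * (n - 1 - p) * np.log1p(g) - 0.5 * (n - 1) * np.log1p(g * (1.0 - r2))
    return float(lml), beta


def _design(response: pd.Series, covariates: pd.DataFrame, config: BMAConfig):
    fwd, _ = _TRANSFORMS[config.transform]
    joined = covariates.loc[response.index, list(config.covariate_labels)]
    if joined.isna().any().any():
        raise ValueError("covariates missing for some response years")
    y = fwd(response.to_numpy(dtype=float))
    X = joined.to_numpy(dtype=float)
    return X, y


def fit_bma(response: pd.Series, covariates: pd.DataFrame, config: BMAConfig) -> BMAFit:
    """Weight all covariate-subset regressions by marginal likelihood.

    ``response`` is indexed by year; ``covariates`` is a year-indexed frame
    containing every label in the config.  Requires at least 8 observed
    time points.
    """
    if len(response) < 8:
        raise ValueError("need at least 8 observed time points")
    X, y = _design(response, covariates, config)
    n, k = X.shape
    g = float(n)
    rng = np.random.default_rng(config.seed)

    if config.sampler == "enumerate":
        models = enumerate_models(k)
        lml = np.empty(len(models))
        betas = []
        for i, subset in enumerate(models):
            lml[i], beta = _log_marginal(X, y, subset, g)
            betas.append(beta)
        n_deficient = int(np.sum(~np.isfinite(lml)))
        if n_deficient:
            logger.warning("%d of %d models dropped (rank-deficient designs)",
                           n_deficient, len(models))
        w = np.exp(lml - np.max(lml[np.isfinite(lml)]))
        w[~np.isfinite(w)] = 0.0
        weights = w / w.sum()
    else:
        cache: dict[int, tuple[float, np.ndarray]] = {}

        def score(mask: int):
            if mask not in cache:
                subset = tuple(i for i in range(k) if mask >> i & 1)
                cache[mask] = _log_marginal(X, y, subset, g)
            return cache[mask]

        mask = 0
        counts: dict[int, int] = {}
        cur, _ = score(mask)
        for it in range(config.iterations):
            flip = int(rng.integers(k))
            prop = mask ^ (1 << flip)
            cand, _ = score(prop)
            if np.log(rng.random()) < cand - cur:
                mask, cur = prop, cand
            if it >= config.burn_in:
                counts[mask] = counts.get(mask, 0) + 1
        visited = sorted(counts)
        models = [tuple(i for i in range(k) if m >> i & 1) for m in visited]
        weights = np.array([counts[m] for m in visited], dtype=float)
        weights /= weights.sum()
        betas = [score(m)[1] for m in visited]

    pip = np.zeros(k)
    for subset, w in zip(models, weights):
        for i in subset:
            pip[i] += w
    return BMAFit(
        config=config,
        models=models,
        model_weights=weights,
        inclusion_probability=pd.Series(pip, index=list(config.covariate_labels)),
        coefficients=betas,
        years=np.asarray(response.index, dtype=int),
        _X=X, _y=y, _g=g,
    )


def project_bma(fit: BMAFit, covariate_projections: pd.DataFrame, horizon_year: int,
                draws: int = 2000, seed: int | None = None) -> pd.DataFrame:
    """Posterior-predictive projection of the fitted series to the horizon.

    ``covariate_projections`` must be year-indexed and cover every year up
    to ``horizon_year``.  Returns a frame indexed by year with columns
    (value, ui_low, ui_high, provenance); the fitted years are flagged
    ``observed`` and later years ``projected``.  Point forecasts are the
    weight-averaged per-model least-squares predictions (the g-prior enters
    the weights only), intervals come from mixture posterior-predictive
    draws on the transformed scale, back-transformed.
    """
    cfg = fit.config
    _, back = _TRANSFORMS[cfg.transform]
    years = np.arange(int(covariate_projections.index.min()), horizon_year + 1)
    missing = [int(yv) for yv in years if yv not in covariate_projections.index]
    if missing:
        raise ValueError(f"covariate projections missing years {missing}")
    Xnew = covariate_projections.loc[years, list(cfg.covariate_labels)].to_numpy(dtype=float)

    X, y = fit._X, fit._y
    n = y.size
    ybar = float(y.mean())
    xbar = X.mean(axis=0)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    mean_acc = np.zeros(years.size)
    draw_acc = np.empty((draws, years.size))
    n_models = len(fit.models)
    model_idx = rng.choice(n_models, size=draws, p=fit.model_weights)
    counts = np.bincount(model_idx, minlength=n_models)
    pos = 0
    for mi, (subset, w, beta) in enumerate(zip(fit.models, fit.model_weights, fit.coefficients)):
        Xc_new = Xnew[:, subset] - xbar[list(subset)] if subset else np.zeros((years.size, 0))
        mu = ybar + (Xc_new @ beta if subset else 0.0)
        mean_acc += w * mu
        m = counts[mi]
        if m == 0:
            continue
        yc = y - ybar
        if subset:
            Xc = X[:, subset] - xbar[list(subset)]
            gram_inv = np.linalg.pinv(Xc.T @ Xc)
            rss = float((yc - Xc @ beta) @ (yc - Xc @ beta))
            dof = max(n - 1 - len(subset), 1)
        else:
            gram_inv = np.zeros((0, 0))
            rss = float(yc @ yc)
            dof = n - 1
        s2 = max(rss, 1e-12)
        sigma2 = s2 / rng.chisquare(dof, size=m)
        for j, s_draw in enumerate(sigma2):
            if subset:
                cov = s_draw * 0.5 * (gram_inv + gram_inv.T)
                b = rng.multivariate_normal(beta, cov, check_valid="ignore")
                mu_d = ybar + Xc_new @ b
                lev = np.einsum("ij,jk,ik->i", Xc_new, gram_inv, Xc_new)
            else:
                mu_d = np.full(years.size, ybar)
                lev = np.zeros(years.size)
            pred_sd = np.sqrt(s_draw * (1.0 + 1.0 / n + lev))
            draw_acc[pos + j] = rng.normal(mu_d, pred_sd)
        pos += m

    lo, hi = np.percentile(draw_acc, [2.5, 97.5], axis=0)
    fitted_years = set(int(v) for v in np.asarray(fit.years))
    out = pd.DataFrame({
        "value": back(mean_acc),
        "ui_low": back(np.minimum(lo, mean_acc)),
        "ui_high": back(np.maximum(hi, mean_acc)),
        "provenance": ["observed" if int(yv) in fitted_years else "projected" for yv in years],
    }, index=pd.Index(years, name="year"))
    return out
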