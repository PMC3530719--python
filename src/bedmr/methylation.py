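"""Trinary methylation calls from hybridization log-ratios.

Fragment-level methylation log-ratios are modeled as a three-component 1-D
Gaussian mixture (low / intermediate / high methylation) fitted by
expectation-maximization over the pooled fragment x sample values. A value
is called +1 when the posterior probability of the high component reaches
``posterior_cutoff`` (default 0.8), -1 symmetrically for the low component,
and 0 otherwise — ambiguous values stay uncalled rather than being forced
into a tail state. Non-finite inputs yield missing calls.

Pipelines whose input already carries trinary calls bypass this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

DEFAULT_POSTERIOR_CUTOFF = 0.8


class EMConvergenceWarning(UserWarning):
    pass


@dataclass
class TrinaryMixtureModel:
    """Fitted 1-D Gaussian mixture; components ordered by ascending mean."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    posterior_cutoff: float = DEFAULT_POSTERIOR_CUTOFF
    converged: bool = True
    degenerate: bool = False
    n_iter: int = 0
    log_likelihoods: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (0.5 < self.posterior_cutoff <= 1.0):
            raise ValueError("posterior_cutoff must be in (0.5, 1]")
        if (self.sds <= 0).any():
            raise ValueError("component sds must be positive")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("component weights must sum to 1")
        if not np.all(np.diff(self.means) >= 0):
            raise ValueError("component means must be ordered ascending")


def _log_gauss(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd * np.sqrt(2.0 * np.pi))


def _kmeans_1d(x: np.ndarray, k: int, max_iter: int = 50) -> np.ndarray:
    """Deterministic 1-D Lloyd iteration seeded from evenly spaced quantiles."""
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    for _ in range(max_iter):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array([
            x[assign == j].mean() if (assign == j).any() else centers[j] for j in range(k)
        ])
        if np.allclose(new, centers):
            break
        centers = new
    return np.sort(centers)


def fit_trinary_em(
    logratios,
    n_components: int = 3,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    posterior_cutoff: float = DEFAULT_POSTERIOR_CUTOFF,
    var_floor: float | None = None,
) -> TrinaryMixtureModel:
    """Maximum-likelihood Gaussian mixture fit by EM on the pooled values.

    Initialization is a deterministic 1-D k-means from quantile seeds, so
    the fit is reproducible regardless of ``seed`` (kept for API symmetry
    with the stochastic stages). The log-likelihood is non-decreasing across
    iterations; a variance floor guards against components collapsing onto
    duplicated values, and hitting it flags the model ``degenerate``.
    """
    x = np.asarray(logratios, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 3 * n_components:
        raise ValueError(
            f"need at least {3 * n_components} finite values, got {x.size}"
        )
    spread = x.max() - x.min()
    if var_floor is None:
        var_floor = max((1e-3 * spread) ** 2, 1e-12)

    means = _kmeans_1d(x, n_components)
    sds = np.full(n_components, max(x.std(), np.sqrt(var_floor)))
    weights = np.full(n_components, 1.0 / n_components)

    degenerate = False
    loglik = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        log_comp = np.stack(
            [np.log(weights[j]) + _log_gauss(x, means[j], sds[j]) for j in range(n_components)]
        )  # (k, n)
        log_norm = logsumexp(log_comp, axis=0)
        ll = float(log_norm.sum())
        loglik.append(ll)
        resp = np.exp(log_comp - log_norm)  # responsibilities (k, n)
        # M-step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        means = (resp @ x) / nk
        var = (resp @ (x[:, None] ** 2)).ravel() / nk - means**2
        if (var < var_floor).any():
            degenerate = True
        var = np.maximum(var, var_floor)
        sds = np.sqrt(var)
        weights = nk / x.size
        if len(loglik) > 1 and abs(loglik[-1] - loglik[-2]) <= tol * (1 + abs(loglik[-2])):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations; returning best-so-far model",
            EMConvergenceWarning,
        )
    order = np.argsort(means, kind="stable")
    return TrinaryMixtureModel(
        means=means[order],
        sds=sds[order],
        weights=weights[order],
        posterior_cutoff=posterior_cutoff,
        converged=converged,
        degenerate=degenerate,
        n_iter=it,
        log_likelihoods=np.asarray(loglik),
    )


def posteriors(model: TrinaryMixtureModel, logratios) -> np.ndarray:
    """Posterior component probabilities, shape (n, n_components)."""
    x = np.asarray(logratios, dtype=float).ravel()
    log_comp = np.stack(
        [
            np.log(model.weights[j]) + _log_gauss(x, model.means[j], model.sds[j])
            for j in range(len(model.means))
        ]
    )
    return np.exp(log_comp - logsumexp(log_comp, axis=0)).T


def call_state(model: TrinaryMixtureModel, logratios) -> np.ndarray:
    """Trinary calls: +1 / -1 when the top/bottom component posterior reaches
    the cutoff, 0 otherwise, NaN for non-finite input. Returns float array
    (or scalar for scalar input)."""
    x = np.asarray(logratios, dtype=float)
    flat = x.ravel()
    out = np.full(flat.shape, np.nan)
    ok = np.isfinite(flat)
    if ok.any():
        post = posteriors(model, flat[ok])
        calls = np.zeros(post.shape[0])
        calls[post[:, -1] >= model.posterior_cutoff] = 1.0
        calls[post[:, 0] >= model.posterior_cutoff] = -1.0
        out[ok] = calls
    out = out.reshape(x.shape)
    if np.isscalar(logratios) or x.ndim == 0:
        return float(out)
    return out


def call_matrix(model: TrinaryMixtureModel, logratios: np.ndarray) -> np.ndarray:
    """Vectorized calls for a fragments x samples log-ratio matrix."""
    return call_state(model, np.asarray(logratios, dtype=float))
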