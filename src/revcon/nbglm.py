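"""Negative-binomial generalized log-linear models, vectorised across genes.

The model for gene g in sample i is

    y_gi ~ NB(mu_gi, phi),    log mu_gi = x_i' beta_g + o_i,

with variance mu + phi * mu^2 (size = 1/phi; phi = 0 is the Poisson limit).
Offsets o_i are log effective library sizes.  Coefficients are fit by
iteratively reweighted least squares with working weights mu/(1 + phi*mu),
vectorised over genes (and over contrasts, when a batch of one-vs-rest
designs shares the same design matrix).  A single common dispersion is
estimated by maximising the profile log-likelihood summed over genes, with
beta re-fit at every candidate phi: a log-spaced grid search refined by
golden section.

Inference on nested designs uses the likelihood-ratio test against the
chi-square reference, and multiplicity is handled with Benjamini-Hochberg
FDR (one signature at a time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

_ETA_CLIP = 30.0
_MAX_ITER = 50
_REL_TOL = 1e-8

LN2 = np.log(2.0)


@dataclass
class NBFit:
    """Per-gene NB GLM fit on one shared design."""

    beta: np.ndarray          # (..., p)
    mu: np.ndarray            # (..., n)
    dispersion: float
    loglik: np.ndarray        # (...,)
    converged: np.ndarray     # (...,) bool
    design: np.ndarray        # (n, p)
    colnames: tuple


def _check_full_rank(X: np.ndarray, colnames=None) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = colnames or [f"col{j}" for j in range(X.shape[1])]
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-10]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Log-likelihood summed over the last (observation) axis."""
    mu = np.maximum(mu, 1e-300)
    if phi == 0.0:
        return stats.poisson.logpmf(y, mu).sum(axis=-1)
    r = 1.0 / phi
    return stats.nbinom.logpmf(y, r, r / (r + mu)).sum(axis=-1)


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    mu = np.maximum(mu, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    if phi == 0.0:
        return 2.0 * (t1 - (y - mu)).sum(axis=-1)
    t2 = (y + 1.0 / phi) * np.log((1.0 + phi * y) / (1.0 + phi * mu))
    return 2.0 * (t1 - t2).sum(axis=-1)


def irls(
    y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    phi: float,
    max_iter: int = _MAX_ITER,
    tol: float = _REL_TOL,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit beta for every unit along the leading axes of ``y``.

    ``y`` has shape (..., n) with a shared design X of shape (n, p);
    ``offsets`` broadcasts against y.  Starting values come from a least
    squares fit to log(y + 0.5) - offset, which is deterministic and robust.
    Returns (beta, mu, converged).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    offsets = np.broadcast_to(np.asarray(offsets, dtype=float), y.shape)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)

    z0 = np.log(y + 0.5) - offsets
    beta = np.einsum("...n,np->...p", z0, X) @ xtx_inv

    dev = np.full(y.shape[:-1], np.inf)
    converged = np.zeros(y.shape[:-1], dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(np.einsum("...p,np->...n", beta, X) + offsets, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)
        z = (eta - offsets) + (y - mu) / mu
        A = np.einsum("...n,ni,nj->...ij", w, X, X)
        b = np.einsum("...n,ni,...n->...i", w, X, z)
        # ridge of last resort for degenerate weight configurations
        A = A + 1e-12 * np.eye(p)
        beta = np.linalg.solve(A, b[..., None])[..., 0]

        eta = np.clip(np.einsum("...p,np->...n", beta, X) + offsets, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        new_dev = nb_deviance(y, mu, phi)
        done = np.abs(new_dev - dev) / (np.abs(new_dev) + 0.1) < tol
        converged |= done
        dev = new_dev
        if converged.all():
            break
    eta = np.clip(np.einsum("...p,np->...n", beta, X) + offsets, -_ETA_CLIP, _ETA_CLIP)
    return beta, np.exp(eta), converged


def fit_nb_glm(
    counts: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray,
    phi: float,
    colnames=None,
) -> NBFit:
    """Fit the NB GLM to every gene; raises on rank-deficient designs."""
    X = np.asarray(design, dtype=float)
    _check_full_rank(X, colnames)
    beta, mu, converged = irls(counts, X, offsets, phi)
    ll = nb_loglik(np.asarray(counts, dtype=float), mu, phi)
    return NBFit(
        beta=beta, mu=mu, dispersion=phi, loglik=ll, converged=converged,
        design=X, colnames=tuple(colnames) if colnames else tuple(f"col{j}" for j in range(X.shape[1])),
    )


def _profile_loglik(counts, X, offsets, phi) -> float:
    _, mu, _ = irls(counts, X, offsets, phi)
    return float(nb_loglik(counts, mu, phi).sum())


def estimate_dispersion(
    counts: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray,
    grid=None,
) -> float:
    """Common dispersion by profile likelihood over a log grid + golden section.

    The profile re-fits every gene's beta at each candidate phi and sums the
    NB log-likelihood over genes; the maximiser is refined by golden-section
    search between the grid neighbours of the best grid point.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("cannot estimate dispersion from an all-zero matrix")
    X = np.asarray(design, dtype=float)
    if counts.shape[-1] - X.shape[1] < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    _check_full_rank(X)
    if grid is None:
        grid = np.logspace(-4, 1, 15)
    ll = np.array([_profile_loglik(counts, X, offsets, g) for g in grid])
    k = int(np.argmax(ll))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if lo == hi:
        return float(grid[k])

    # golden-section on log(phi)
    a, b = np.log(lo), np.log(hi)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _profile_loglik(counts, X, offsets, np.exp(c))
    fd = _profile_loglik(counts, X, offsets, np.exp(d))
    for _ in range(25):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _profile_loglik(counts, X, offsets, np.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _profile_loglik(counts, X, offsets, np.exp(d))
        if b - a < 1e-3:
            break
    return float(np.exp((a + b) / 2.0))


def _is_nested(full: np.ndarray, reduced: np.ndarray) -> bool:
    sol, *_ = np.linalg.lstsq(full, reduced, rcond=None)
    return bool(np.allclose(full @ sol, reduced, atol=1e-8))


def lrt(full: NBFit, reduced: NBFit, df: int) -> np.ndarray:
    """Likelihood-ratio p-values per gene against chi-square(df)."""
    if not _is_nested(full.design, reduced.design):
        raise ValueError("reduced design is not nested in the full design")
    stat = np.maximum(2.0 * (full.loglik - reduced.loglik), 0.0)
    return stats.chi2.sf(stat, df)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
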