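"""The four tumour-signature families from NB GLM contrasts.

Signature kinds:

* ``group``           — all tumour samples vs all normal samples,
* ``subtype``         — each molecular subtype's tumours vs all normals,
* ``sample``          — each single tumour sample vs all normals,
* ``normal_control``  — each normal sample vs all the other normals (the
  false-positive yardstick for the per-sample signatures).

All contrasts share one cohort-level common dispersion (a single tumour
sample cannot inform its own dispersion; fixing phi keeps the per-sample
likelihood-ratio tests well defined).  One-vs-rest contrasts share the same
two-column design, so all of a kind's fits run in one vectorised IRLS pass
over genes x contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .data import CountMatrix
from .nbglm import LN2, bh_fdr, estimate_dispersion, fit_nb_glm, lrt

logger = logging.getLogger("revcon")

SIGNATURE_KINDS = ("group", "subtype", "sample", "normal_control")


@dataclass
class Signature:
    """Per-gene (log2fc, p, fdr) for one contrast."""

    contrast_kind: str
    contrast_id: str
    table: pd.DataFrame  # index gene, columns log2fc, p, fdr
    dispersion: float

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def fdr(self) -> pd.Series:
        return self.table["fdr"]


def signature_size(sig: Signature, fdr_cutoff: float) -> int:
    """Number of genes with FDR strictly below the cutoff."""
    if not 0 < fdr_cutoff <= 1:
        raise ValueError("fdr_cutoff must be in (0, 1]")
    return int((sig.table["fdr"] < fdr_cutoff).sum())


def default_offsets(cm: CountMatrix) -> np.ndarray:
    return np.log(cm.library_sizes().to_numpy(dtype=float))


def estimate_cohort_dispersion(cm: CountMatrix, offsets: np.ndarray | None = None) -> float:
    """Common dispersion on the full cohort with a tissue-type design."""
    if offsets is None:
        offsets = default_offsets(cm)
    X = np.column_stack([
        np.ones(cm.n_samples),
        cm.tissue_mask("tumour").astype(float),
    ])
    return estimate_dispersion(cm.counts.to_numpy(dtype=float), X, offsets)


def _signature_from_arrays(genes, lfc, p, kind, cid, phi) -> Signature:
    table = pd.DataFrame({"log2fc": lfc, "p": p, "fdr": bh_fdr(p)}, index=genes)
    return Signature(contrast_kind=kind, contrast_id=str(cid), table=table, dispersion=phi)


def _two_group_contrast(counts, offsets, group_mask, phi, genes, kind, cid) -> Signature:
    """One contrast of group_mask samples vs the rest of the given columns."""
    y = counts
    Xf = np.column_stack([np.ones(y.shape[1]), group_mask.astype(float)])
    Xr = Xf[:, :1]
    full = fit_nb_glm(y, Xf, offsets, phi, colnames=("intercept", "contrast"))
    red = fit_nb_glm(y, Xr, offsets, phi, colnames=("intercept",))
    p = lrt(full, red, df=1)
    lfc = full.beta[:, 1] / LN2
    allzero = y.sum(axis=1) == 0
    lfc[allzero] = 0.0
    p[allzero] = 1.0
    return _signature_from_arrays(genes, lfc, p, kind, cid, phi)


_ETA_CLIP = 30.0


def _deviance_parts(y: np.ndarray, phi: float) -> np.ndarray:
    """Mean-independent deviance terms, precomputable per data block."""
    t = y * np.log(np.maximum(y, 1.0))
    if phi > 0:
        t = t - (y + 1.0 / phi) * np.log1p(phi * y)
    return t


def _deviance_from_eta(y, eta, pre, phi) -> np.ndarray:
    mu = np.exp(eta)
    if phi == 0.0:
        return 2.0 * (pre - y * eta - (y - mu)).sum(axis=-1)
    return 2.0 * (pre - y * eta + (y + 1.0 / phi) * np.log1p(phi * mu)).sum(axis=-1)


def intercept_nb_fit(
    y: np.ndarray,
    offsets: np.ndarray,
    phi: float,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Intercept-only NB fit along the last axis; returns (beta0, deviance).

    Scalar-update IRLS, vectorised over arbitrary leading axes; the working
    weight is mu/(1 + phi*mu) as in the general fitter.
    """
    y = np.asarray(y, dtype=float)
    offsets = np.broadcast_to(np.asarray(offsets, dtype=float), y.shape)
    pre = _deviance_parts(y, phi)
    beta = (np.log(y + 0.5) - offsets).mean(axis=-1)
    dev = np.full(y.shape[:-1], np.inf)
    converged = np.zeros(y.shape[:-1], dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(beta[..., None] + offsets, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)
        z = (eta - offsets) + (y - mu) / mu
        beta = (w * z).sum(axis=-1) / w.sum(axis=-1)
        eta = np.clip(beta[..., None] + offsets, -_ETA_CLIP, _ETA_CLIP)
        new_dev = _deviance_from_eta(y, eta, pre, phi)
        converged |= np.abs(new_dev - dev) / (np.abs(new_dev) + 0.1) < tol
        dev = new_dev
        if converged.all():
            break
    return beta, dev


def one_vs_rest_block(
    counts: np.ndarray,
    offsets: np.ndarray,
    bg_idx: np.ndarray,
    col_idx: np.ndarray,
    phi: float,
    bg_fit: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-vs-background contrasts sharing a design.

    ``bg_idx`` is (n_contrasts, n_bg) sample indices forming each contrast's
    background, ``col_idx`` the contrasted sample per contrast.  Returns
    (log2fc, p), each (n_genes, n_contrasts).  Genes with all-zero counts
    within a contrast get log2fc 0 and p 1.

    The full model solves in closed form: the indicator coefficient's score
    equation forces the contrasted sample's fitted mean onto its observed
    count (contributing zero deviance), so the intercept is the background's
    intercept-only MLE and the likelihood-ratio statistic reduces to
    ``deviance(reduced) - deviance(background)``.  ``bg_fit`` lets callers
    reuse the background fit when the background is shared (per-sample
    signatures against a fixed normal panel).
    """
    counts = np.asarray(counts, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    bg_idx = np.atleast_2d(bg_idx)
    col_idx = np.asarray(col_idx)
    n_contrasts = len(col_idx)

    shared_bg = (bg_idx.shape[0] == 1) or (bg_idx == bg_idx[0]).all()
    if bg_fit is None:
        if shared_bg:
            b0, dev_bg = intercept_nb_fit(counts[:, bg_idx[0]], offsets[bg_idx[0]], phi)
            b0 = b0[:, None]
            dev_bg = dev_bg[:, None]
        else:
            b0, dev_bg = intercept_nb_fit(counts[:, bg_idx], offsets[bg_idx], phi)
    else:
        b0, dev_bg = bg_fit
        if b0.ndim == 1:
            b0, dev_bg = b0[:, None], dev_bg[:, None]

    y_s = counts[:, col_idx]                      # (G, C)
    o_s = offsets[col_idx]
    with np.errstate(divide="ignore"):
        eta_unit = np.where(y_s > 0, np.log(np.maximum(y_s, 1e-300)) - o_s, -_ETA_CLIP)
    lfc = (eta_unit - b0) / LN2

    idx = np.concatenate([bg_idx if bg_idx.shape[0] == n_contrasts
                          else np.broadcast_to(bg_idx, (n_contrasts, bg_idx.shape[1])),
                          col_idx[:, None]], axis=1)
    _, dev_red = intercept_nb_fit(counts[:, idx], offsets[idx], phi)
    stat = np.maximum(dev_red - dev_bg, 0.0)
    p = special.chdtrc(1, stat)
    lfc = np.asarray(lfc)
    allzero = counts[:, idx].sum(axis=-1) == 0
    lfc[allzero] = 0.0
    p[allzero] = 1.0
    return lfc, p


def make_signatures(
    cm: CountMatrix,
    phi: float,
    kind: str,
    offsets: np.ndarray | None = None,
) -> list[Signature]:
    """Fit all signatures of one kind on a (filtered) cohort."""
    if kind not in SIGNATURE_KINDS:
        raise ValueError(f"kind must be one of {SIGNATURE_KINDS}")
    if offsets is None:
        offsets = default_offsets(cm)
    counts = cm.counts.to_numpy(dtype=float)
    genes = cm.genes
    tumour_mask = cm.tissue_mask("tumour")
    normal_idx = np.flatnonzero(~tumour_mask)
    tumour_idx = np.flatnonzero(tumour_mask)
    if len(normal_idx) < 2:
        raise ValueError("need at least 2 normal samples")

    if kind == "group":
        used = np.concatenate([tumour_idx, normal_idx])
        mask = np.array([True] * len(tumour_idx) + [False] * len(normal_idx))
        return [_two_group_contrast(counts[:, used], offsets[used], mask, phi,
                                    genes, kind, "all_tumours")]

    if kind == "subtype":
        sigs = []
        subtypes = cm.metadata.loc[cm.samples[tumour_idx], "subtype"]
        for st in sorted(subtypes.unique()):
            st_idx = tumour_idx[(subtypes == st).to_numpy()]
            if len(st_idx) == 0:
                logger.warning("subtype %s has no samples; skipped", st)
                continue
            used = np.concatenate([st_idx, normal_idx])
            mask = np.array([True] * len(st_idx) + [False] * len(normal_idx))
            sigs.append(_two_group_contrast(counts[:, used], offsets[used], mask,
                                            phi, genes, kind, st))
        return sigs

    if kind == "sample":
        bg = np.broadcast_to(normal_idx, (len(tumour_idx), len(normal_idx)))
        lfc, p = one_vs_rest_block(counts, offsets, bg, tumour_idx, phi)
        ids = cm.samples[tumour_idx]
    else:  # normal_control: each normal vs the other normals
        n = len(normal_idx)
        bg = np.array([np.delete(normal_idx, i) for i in range(n)])
        lfc, p = one_vs_rest_block(counts, offsets, bg, normal_idx, phi)
        ids = cm.samples[normal_idx]

    return [
        _signature_from_arrays(genes, lfc[:, j], p[:, j], kind, ids[j], phi)
        for j in range(lfc.shape[1])
    ]
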