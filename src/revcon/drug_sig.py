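"""Per-drug signatures from linear models with empirical-Bayes moderation.

Each drug's experiments (all cell lines, durations and batches pooled) are
modelled per gene by ordinary least squares with drug concentration as a
linear covariate (0 for vehicle controls) and cell line, duration (only
when more than one distinct duration is present) and batch as categorical
nuisance covariates.  Drugs without any control column, or whose design is
rank deficient or saturated, are UNPROCESSABLE.

Residual variances are shrunk across genes towards a common prior by the
scaled-F empirical-Bayes model: s^2_g | sigma^2_g ~ sigma^2_g * chi^2_d/d
with 1/sigma^2 ~ scaled chi^2 on d0 df and scale s0^2.  The hyperparameters
(d0, s0^2) are estimated by moment-matching the mean and variance of
log s^2 using digamma/trigamma identities; the posterior variance is
(d0*s0^2 + d*s^2)/(d0 + d) and the moderated t uses d0 + d degrees of
freedom.  The fraction of genes under 50% FDR (pct_deg) is the signature
quality score used throughout the downstream summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .nbglm import bh_fdr

STATUS_OK = "OK"
STATUS_UNPROCESSABLE = "UNPROCESSABLE"

D0_CLAMP = (0.1, 1e6)


class UnprocessableDrugError(ValueError):
    """The drug's design does not admit the linear model."""


@dataclass
class DrugDesign:
    matrix: np.ndarray          # (n_experiments, p)
    colnames: tuple
    conc_index: int             # column of the concentration covariate
    column_ids: tuple


@dataclass
class DrugModelFit:
    slope: np.ndarray           # (n_genes,)
    s2: np.ndarray              # residual variance per gene
    df: int                     # residual degrees of freedom
    v_slope: float              # (X'X)^-1 diagonal entry of the slope
    genes: pd.Index
    n_experiments: int
    n_cell_lines: int


@dataclass
class EBayesParams:
    d0: float                   # prior df; np.inf when variances are exchangeable
    s0_sq: float


@dataclass
class DrugSignature:
    drug_id: str
    table: pd.DataFrame         # index gene; slope, moderated_t, p, fdr
    ebayes: EBayesParams
    n_experiments: int
    n_cell_lines: int

    @property
    def moderated_t(self) -> pd.Series:
        return self.table["moderated_t"]


def _dummies(values, prefix: str) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(pd.Series(values).astype(str)))
    cols, names = [], []
    for lv in levels[1:]:  # first level by lexicographic order is the reference
        cols.append((pd.Series(values).astype(str) == lv).to_numpy(dtype=float))
        names.append(f"{prefix}[{lv}]")
    return (np.column_stack(cols) if cols else np.empty((len(values), 0))), names


def build_design(metadata: pd.DataFrame) -> DrugDesign:
    """Design matrix for one drug's experiments; raises UnprocessableDrugError.

    The duration block is included only when more than one distinct duration
    is present; single-level categorical blocks are dropped.
    """
    required = {"column_id", "concentration", "cell_line", "duration", "batch"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"experiment metadata missing columns: {sorted(missing)}")
    conc = metadata["concentration"].to_numpy(dtype=float)
    if not (conc == 0).any():
        raise UnprocessableDrugError("no control samples (all concentrations > 0)")
    if not (conc > 0).any():
        raise UnprocessableDrugError("no treated samples (all concentrations are 0)")

    blocks = [np.ones((len(metadata), 1)), conc[:, None]]
    names = ["intercept", "concentration"]
    cl, cl_names = _dummies(metadata["cell_line"], "cell_line")
    blocks.append(cl)
    names += cl_names
    if metadata["duration"].nunique() > 1:
        du, du_names = _dummies(metadata["duration"], "duration")
        blocks.append(du)
        names += du_names
    ba, ba_names = _dummies(metadata["batch"], "batch")
    blocks.append(ba)
    names += ba_names

    X = np.column_stack([b for b in blocks if b.shape[1] > 0])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise UnprocessableDrugError("design is rank deficient after dropping levels")
    return DrugDesign(
        matrix=X, colnames=tuple(names), conc_index=1,
        column_ids=tuple(metadata["column_id"]),
    )


def fit_drug_model(expr: pd.DataFrame, design: DrugDesign) -> DrugModelFit:
    """Per-gene OLS; slope is the concentration coefficient."""
    X = design.matrix
    n, p = X.shape
    df = n - p
    if df < 1:
        raise UnprocessableDrugError("no residual degrees of freedom")
    Y = expr[list(design.column_ids)].to_numpy(dtype=float)  # genes x experiments
    xtx_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ xtx_inv                                      # genes x p
    resid = Y - B @ X.T
    s2 = (resid ** 2).sum(axis=1) / df
    n_cl = int(pd.Series([c for c in design.colnames if c.startswith("cell_line")]).size) + 1
    return DrugModelFit(
        slope=B[:, design.conc_index], s2=s2, df=df,
        v_slope=float(xtx_inv[design.conc_index, design.conc_index]),
        genes=expr.index, n_experiments=n, n_cell_lines=n_cl,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_ebayes(s2: np.ndarray, df: int) -> EBayesParams:
    """Moment-match (d0, s0^2) from the ensemble of log residual variances."""
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 10:
        raise ValueError("need at least 10 genes to estimate moderation hyperparameters")
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return EBayesParams(d0=np.inf, s0_sq=float(np.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(evar)
    d0 = float(np.clip(d0, *D0_CLAMP))
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBayesParams(d0=d0, s0_sq=s0_sq)


def ebayes_moderate(
    fit: DrugModelFit,
    drug_id: str = "",
    params: EBayesParams | None = None,
) -> DrugSignature:
    """Shrink variances and emit the moderated-t drug signature.

    ``params`` may be supplied to force the hyperparameters (d0 = 0 reduces
    to the ordinary t; d0 = inf pins every posterior variance at s0^2).
    """
    if params is None:
        params = estimate_ebayes(fit.s2, fit.df)
    d0, s0_sq = params.d0, params.s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(fit.s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + fit.df * fit.s2) / (d0 + fit.df)
        df_total = d0 + fit.df
    t = fit.slope / np.sqrt(s2_post * fit.v_slope)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    table = pd.DataFrame(
        {"slope": fit.slope, "moderated_t": t, "p": p, "fdr": bh_fdr(p)},
        index=fit.genes,
    )
    return DrugSignature(
        drug_id=drug_id, table=table, ebayes=params,
        n_experiments=fit.n_experiments, n_cell_lines=fit.n_cell_lines,
    )


def pct_deg(sig: DrugSignature, fdr_cutoff: float = 0.5) -> float:
    """Percentage of signature genes under the FDR cutoff (quality score)."""
    if len(sig.table) == 0:
        raise ValueError("empty drug signature")
    return float(100.0 * (sig.table["fdr"] < fdr_cutoff).mean())


def fit_drug_panel(panel, ebayes_params: EBayesParams | None = None) -> tuple[dict, dict]:
    """Fit every drug in a panel.

    Returns (signatures, status): signatures maps drug id -> DrugSignature
    for processable drugs; status maps every drug id to OK/UNPROCESSABLE.
    """
    signatures: dict[str, DrugSignature] = {}
    status: dict[str, str] = {}
    for drug in panel.drugs:
        meta = panel.metadata[panel.metadata["drug"] == drug]
        try:
            design = build_design(meta)
            fit = fit_drug_model(panel.expression[drug], design)
            signatures[drug] = ebayes_moderate(fit, drug_id=drug, params=ebayes_params)
            status[drug] = STATUS_OK
        except UnprocessableDrugError:
            status[drug] = STATUS_UNPROCESSABLE
    return signatures, status
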