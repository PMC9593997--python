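"""Gene-trait association testing and model aggregation.

Per weight model, the gene-level statistic against GWAS summary z-scores is
the burden-type ratio ``z = (Z w) / sqrt(w' V w)`` with V the LD matrix of
the analyzed SNPs.  P-values from the models of one gene are aggregated by
the Cauchy combination test with prediction-R^2 weights,

    T = sum_j wtilde_j * tan((0.5 - p_j) * pi),   wtilde_j = R2_j / sum R2,

which is approximately standard Cauchy under the null regardless of the
dependence among the models, giving ``p = 0.5 - arctan(T)/pi``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GwasSummaryTable
from .ld import LdMatrix
from .train import WeightModel

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAssociation",
    "burden_test",
    "glm_association",
    "cauchy_combine",
    "direction_vote",
    "transcriptome_scan",
]


@dataclass
class GeneAssociation:
    gene_id: str
    families: list[str]
    z_per_model: np.ndarray
    p_per_model: np.ndarray
    combined_p: float
    direction: str  # '+', '-', or 'unknown'
    n_models: int = 0
    significant: Optional[bool] = None

    def __post_init__(self) -> None:
        self.n_models = len(self.families)


def burden_test(w_hat: np.ndarray, gwas: GwasSummaryTable | np.ndarray, V) -> tuple[float, float]:
    """Burden-type gene-level test from GWAS summary z-scores.

    Returns ``(z_tilde, p)`` with ``z_tilde = Z w / sqrt(w' V w)`` and a
    two-sided standard-normal p-value.  Invariant to positive rescaling of
    the weights.
    """
    w = np.asarray(w_hat, dtype=float)
    if not np.any(w):
        raise ValueError("all-zero weight vector; the model predicts nothing")
    z = gwas.z if isinstance(gwas, GwasSummaryTable) else np.asarray(gwas, dtype=float)
    Vm = V.values if isinstance(V, LdMatrix) else np.asarray(V, dtype=float)
    if z.shape[0] != w.shape[0] or Vm.shape != (w.shape[0], w.shape[0]):
        raise ValueError("weights, z-scores and V are not aligned")
    denom = float(w @ Vm @ w)
    if denom <= 0:
        raise ValueError(
            "w'Vw <= 0: the LD matrix is indefinite; use the shrunk (or ridged) estimator for V"
        )
    z_tilde = float(z @ w) / np.sqrt(denom)
    p = 2.0 * stats.norm.sf(abs(z_tilde))
    return z_tilde, max(p, np.finfo(float).tiny)


def glm_association(
    w_hat: np.ndarray,
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    link: str = "identity",
) -> tuple[float, float]:
    """Individual-level association of predicted expression with a trait.

    Fits ``f(E[P | C, X]) = alpha C + beta (X w)`` with an identity (linear
    regression) or logit link and returns the Wald test of beta = 0.
    """
    import statsmodels.api as sm

    x = np.asarray(genotypes, dtype=float)
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    pred = (x - mu) / sd @ np.asarray(w_hat, dtype=float)
    if pred.std() == 0:
        raise ValueError("predicted expression has zero variance")
    design = [np.ones(len(pred))]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(pred):
            cov = cov.T
        design.append(cov)
    design.append(pred[:, None])
    X = np.column_stack(design)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates in the association design")
    y = np.asarray(phenotype, dtype=float)
    if link == "identity":
        fit = sm.OLS(y, X).fit()
    elif link == "logit":
        fit = sm.Logit(y, X).fit(disp=0)
    else:
        raise ValueError(f"unsupported link {link!r}")
    return float(fit.params[-1]), float(fit.pvalues[-1])


def cauchy_combine(p_values: Sequence[float], r2_weights: Sequence[float]) -> float:
    """Cauchy combination of dependent p-values with R^2 weights.

    Weights are normalized to sum to one.  For p below 1e-15 the term
    ``tan((0.5 - p) pi)`` is replaced by its tail equivalent ``1/(p pi)``
    to avoid overflow; the same tail form maps very large |T| back to p.
    """
    p = np.asarray(p_values, dtype=float)
    w = np.asarray(r2_weights, dtype=float)
    if p.shape != w.shape or p.size == 0:
        raise ValueError("need matching, non-empty p-values and weights")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p-values must lie strictly in (0, 1)")
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    w = w / w.sum()
    small = p < 1e-15
    terms = np.empty_like(p)
    terms[~small] = np.tan((0.5 - p[~small]) * np.pi)
    terms[small] = 1.0 / (p[small] * np.pi)
    t = float(w @ terms)
    if t > 1e15:
        out = 1.0 / (t * np.pi)
    else:
        out = 0.5 - np.arctan(t) / np.pi
    return float(min(max(out, np.finfo(float).tiny), 1.0 - 1e-16))


def direction_vote(signs: Sequence[str | int | float]) -> str:
    """Majority vote over per-model association directions; ties -> unknown."""
    if len(signs) == 0:
        raise ValueError("need at least one model")
    n_pos = n_neg = 0
    for s in signs:
        if s in ("+", 1) or (isinstance(s, (int, float)) and s > 0):
            n_pos += 1
        elif s in ("-", -1) or (isinstance(s, (int, float)) and s < 0):
            n_neg += 1
    if n_pos == n_neg:
        return "unknown"
    return "+" if n_pos > n_neg else "-"


def associate_gene(
    gene_id: str,
    models: Sequence[WeightModel],
    gwas_z: np.ndarray,
    V,
    r2_attr: str = "r2_testing",
) -> GeneAssociation:
    """Burden test per model, then Cauchy-combine with prediction-R^2 weights."""
    zs, ps, fams, weights = [], [], [], []
    for m in models:
        z_t, p = burden_test(m.w_hat, gwas_z, V)
        zs.append(z_t)
        ps.append(p)
        fams.append(m.penalty.family)
        r2 = getattr(m, r2_attr)
        weights.append(r2 if r2 is not None else m.r2_tuning)
    if sum(weights) == 0:
        weights = [1.0] * len(weights)  # degenerate: fall back to flat weights
    combined = cauchy_combine(ps, weights)
    direction = direction_vote([np.sign(z) for z in zs])
    return GeneAssociation(
        gene_id=gene_id,
        families=fams,
        z_per_model=np.asarray(zs),
        p_per_model=np.asarray(ps),
        combined_p=combined,
        direction=direction,
    )


def transcriptome_scan(
    models_by_gene: dict[str, Sequence[WeightModel]],
    gwas_by_gene: dict[str, np.ndarray],
    v_by_gene: dict[str, LdMatrix],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Scan all genes with admitted models against one GWAS.

    ``gwas_by_gene`` and ``v_by_gene`` must be aligned to each gene's model
    SNP order.  Genes with no overlapping GWAS SNPs are recorded as untested
    and excluded from the Bonferroni denominator, which is the number of
    genes actually tested.  Output is sorted by combined p.
    """
    rows, untested = [], []
    for gene_id, models in models_by_gene.items():
        z = gwas_by_gene.get(gene_id)
        if z is None or len(z) == 0 or len(models) == 0:
            untested.append(gene_id)
            continue
        res = associate_gene(gene_id, models, z, v_by_gene[gene_id])
        rows.append(res)
    n_tested = len(rows)
    threshold = alpha / n_tested if n_tested else np.nan
    logger.info("transcriptome scan: %d genes tested, %d untested, threshold %.3g",
                n_tested, len(untested), threshold)
    records = [
        {
            "gene_id": r.gene_id,
            "n_models": r.n_models,
            "z_per_model": ",".join(f"{z:.4g}" for z in r.z_per_model),
            "p_per_model": ",".join(f"{p:.4g}" for p in r.p_per_model),
            "combined_p": r.combined_p,
            "direction": r.direction,
            "significant": bool(r.combined_p < threshold),
        }
        for r in rows
    ]
    for g in untested:
        records.append(
            {
                "gene_id": g,
                "n_models": 0,
                "z_per_model": "",
                "p_per_model": "",
                "combined_p": np.nan,
                "direction": "unknown",
                "significant": False,
            }
        )
    df = pd.DataFrame.from_records(records)
    if len(df):
        df = df.sort_values("combined_p", na_position="last").reset_index(drop=True)
        df.attrs["n_tested"] = n_tested
        df.attrs["threshold"] = threshold
    return df
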