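"""Generative simulation framework: LD-structured genotypes, expression,
phenotypes, derived summary statistics, and the accuracy / power / type-I
experiments.  Also serves as the repository's synthetic fixture generator.

Genotypes come from a latent-Gaussian threshold model: per-SNP minor allele
frequencies are drawn uniformly from ``maf_range``; each of two haplotypes
is a latent multivariate normal with block-AR(1) correlation, thresholded
at the MAF quantile; the genotype is the haplotype sum, so Hardy-Weinberg
holds by construction.  Expression is ``E = X w + eps_e`` with a random
causal subset of SNPs, ``w`` rescaled so the realized variance of ``X w``
equals the target expression heritability ``h_e^2`` and noise variance
``1 - h_e^2``; phenotype is ``Y = beta E + eps_p`` with ``beta`` rescaled
analogously for the phenotypic heritability ``h_p^2``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ReferencePanel, SnpRecord, EqtlSummaryTable, GwasSummaryTable
from .ld import LdMatrix, ld_from_standardized, shrink_ld
from .train import (
    TrainingConfig,
    fit_gene,
    squared_correlation,
    validate_models,
)
from .assoc import burden_test, cauchy_combine

logger = logging.getLogger(__name__)

__all__ = [
    "BlockLdModel",
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_phenotype",
    "make_summary",
    "run_accuracy_experiment",
    "run_power_experiment",
    "run_type1_experiment",
]


@dataclass(frozen=True)
class BlockLdModel:
    """Block-AR(1) latent correlation: within blocks of ``block_size`` SNPs
    the latent correlation between neighbours is rho (drawn per block from
    U(rho_min, rho_max) unless ``rho_fixed`` is set); blocks are independent.
    """

    block_size: int = 20
    rho_min: float = 0.2
    rho_max: float = 0.9
    rho_fixed: Optional[float] = None

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValueError("block size must be >= 1")
        for rho in (self.rho_min, self.rho_max, self.rho_fixed or 0.0):
            if not (-1.0 < rho < 1.0):
                raise ValueError(f"AR(1) rho {rho} outside (-1, 1): block spec not positive definite")


@dataclass
class SimulationConfig:
    """Study conditions for the simulation experiments.

    Defaults mirror a large meta-analysed blood eQTL resource: 31,684
    training samples, 369 tuning samples, 10,000 test samples, 877 cis-SNPs,
    and a genome-wide significance threshold of 0.05/20,000 = 2.5e-6.
    """

    n_train: int = 31_684
    n_tune: int = 369
    n_test: int = 10_000
    n_gwas: int = 10_000
    p_snps: int = 877
    h_e2: float = 0.1
    h_p2: float = 0.2
    p_causal: float = 0.1
    ld_model: BlockLdModel = field(default_factory=BlockLdModel)
    maf_range: tuple = (0.01, 0.5)
    n_replicates: int = 1000
    seed: int = 0
    sig_threshold: float = 2.5e-6
    h_p2_mode: str = "expression"  # or "genetic": scale beta by var(beta*Xw)
    shrink_training_ld: bool = True
    training: TrainingConfig = field(default_factory=TrainingConfig)
    spacing_bp: int = 2300  # ~877 SNPs across a 2 Mb cis window

    def __post_init__(self) -> None:
        if not (0.0 <= self.h_e2 <= 1.0 and 0.0 <= self.h_p2 <= 1.0):
            raise ValueError("heritabilities must lie in [0, 1]")
        if not (0.0 < self.p_causal <= 1.0):
            raise ValueError("p_causal must lie in (0, 1]")
        for n in (self.n_train, self.n_tune, self.n_test):
            if n < 2:
                raise ValueError("sample sizes must be >= 2")


def _latent_rho(target: float, maf: float) -> float:
    """Latent AR(1) parameter whose thresholded (phi) correlation hits target.

    Thresholding a bivariate normal at the MAF quantile attenuates the
    correlation, so the block parameter is interpreted on the genotype scale
    and mapped back to the latent scale via the tetrachoric relation.
    Inputs are rounded to 0.01 so solves can be cached.
    """
    return _latent_rho_cached(round(float(target), 2), round(float(maf), 2))


from functools import lru_cache


@lru_cache(maxsize=8192)
def _latent_rho_cached(target: float, maf: float) -> float:
    if target == 0.0:
        return 0.0
    from scipy.optimize import brentq
    from scipy.stats import multivariate_normal, norm

    h = norm.ppf(maf)
    q = maf

    def phi_minus_target(rho: float) -> float:
        p11 = multivariate_normal.cdf([h, h], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
        return (p11 - q * q) / (q * (1.0 - q)) - target

    lo, hi = (0.0, 0.999) if target > 0 else (-0.999, 0.0)
    if phi_minus_target(hi if target > 0 else lo) < 0 <= target:
        return 0.999
    return float(brentq(phi_minus_target, lo, hi, xtol=1e-4))


def _make_records(p: int, maf: np.ndarray, spacing_bp: int, cm: np.ndarray) -> list[SnpRecord]:
    start = 1_000_000
    return [
        SnpRecord(
            snp_id=f"snp{i+1}",
            chrom="1",
            pos=start + i * spacing_bp,
            ref_allele="A",
            alt_allele="G",
            maf=float(maf[i]),
            cm=float(cm[i]),
        )
        for i in range(p)
    ]


def _hotspot_cm(p: int, block_size: int, spacing_bp: int, hotspot_cm: float = 0.1,
                background_cm_per_mb: float = 0.01) -> np.ndarray:
    """Genetic positions with recombination concentrated between LD blocks.

    Real haplotype blocks exist because recombination clusters in hotspots
    at their boundaries; a map consistent with the generator's block-LD
    structure therefore accrues ~``hotspot_cm`` at each block boundary and
    only a small background rate inside blocks.  With 20-SNP blocks at
    2.3 kb spacing this averages ~1 cM/Mb, the genome-wide norm.
    """
    idx = np.arange(p)
    background = idx * spacing_bp * background_cm_per_mb * 1e-6
    return background + (idx // block_size) * hotspot_cm


def simulate_genotypes(
    n: int,
    p: int,
    ld_model: BlockLdModel = BlockLdModel(),
    maf_range: tuple = (0.01, 0.5),
    seed: int | np.random.Generator = 0,
    spacing_bp: int = 2300,
) -> ReferencePanel:
    """Draw an LD-structured genotype panel (values in {0, 1, 2}).

    Deterministic given the seed.  Realized allele frequencies match the
    drawn MAF targets up to binomial sampling error.
    """
    lo, hi = maf_range
    if not (0.01 <= lo <= hi <= 0.5):
        raise ValueError("maf_range must be within [0.01, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=p)
    thresholds = sps.norm.ppf(maf).astype(np.float32)
    # draw per-block target genotype-scale correlations, then map each to the
    # latent scale (using the block's mean MAF) so realized adjacent-pair
    # genotype LD tracks the block parameter
    block_rho = []
    start = 0
    while start < p:
        size = min(ld_model.block_size, p - start)
        rho = ld_model.rho_fixed
        if rho is None:
            rho = float(rng.uniform(ld_model.rho_min, ld_model.rho_max))
        block_rho.append((start, size, _latent_rho(rho, float(maf[start : start + size].mean()))))
        start += size
    geno = np.zeros((n, p), dtype=np.float32)
    for _hap in range(2):
        latent = np.empty((n, p), dtype=np.float32)
        for start, size, rho in block_rho:
            e = rng.standard_normal((n, size), dtype=np.float32)
            latent[:, start] = e[:, 0]
            scale = np.float32(np.sqrt(1.0 - rho * rho))
            for k in range(1, size):
                latent[:, start + k] = rho * latent[:, start + k - 1] + scale * e[:, k]
        geno += (latent < thresholds[None, :]).astype(np.float32)
    cm = _hotspot_cm(p, ld_model.block_size, spacing_bp)
    records = _make_records(p, maf, spacing_bp, cm)
    sample_ids = [f"ind{i+1}" for i in range(n)]
    return ReferencePanel(sample_ids=sample_ids, genotypes=geno, records=records)


def simulate_expression(
    x_std: np.ndarray,
    h_e2: float,
    p_causal: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate expression ``E = X w + eps`` on standardized genotypes.

    ``ceil(p_causal * p)`` causal SNPs are drawn uniformly; their effects
    start as N(0, 1) and are rescaled so the realized variance of ``X w``
    equals ``h_e2``; noise has variance ``1 - h_e2``.  Returns ``(E, w)``
    with ``w`` on the standardized-genotype scale.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x_std = np.asarray(x_std)
    n, p = x_std.shape
    if not (0.0 <= h_e2 < 1.0):
        raise ValueError("h_e2 must be in [0, 1)")
    n_causal = int(np.ceil(p_causal * p))
    if p_causal * p < 1:
        warnings.warn("p_causal * p < 1; using a single causal SNP", RuntimeWarning)
        n_causal = 1
    w = np.zeros(p)
    if h_e2 > 0.0:
        causal = rng.choice(p, size=n_causal, replace=False)
        w[causal] = rng.standard_normal(n_causal)
        g = x_std @ w
        sd = g.std()
        if sd == 0:
            raise ValueError("degenerate genetic component (all-constant genotypes?)")
        w *= np.sqrt(h_e2) / sd
    e = (x_std @ w if h_e2 > 0 else np.zeros(n)) + rng.normal(0.0, np.sqrt(1.0 - h_e2), n)
    return e, w


def simulate_phenotype(
    e_g: np.ndarray,
    h_p2: float,
    seed: int | np.random.Generator = 0,
    genetic_component: Optional[np.ndarray] = None,
    mode: str = "expression",
) -> np.ndarray:
    """Simulate the trait ``Y = beta E + eps`` with target heritability.

    In the default ``expression`` mode, beta is rescaled so the realized
    variance of ``beta * E`` equals ``h_p2`` (h_p2 = share of phenotypic
    variance explained by expression).  ``genetic`` mode instead scales by
    the variance of ``beta * (X w)`` and requires ``genetic_component``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e_g = np.asarray(e_g, dtype=float)
    if not (0.0 <= h_p2 < 1.0):
        raise ValueError("h_p2 must be in [0, 1)")
    if h_p2 == 0.0:
        return rng.normal(0.0, 1.0, e_g.shape[0])
    if mode == "expression":
        anchor = e_g
    elif mode == "genetic":
        if genetic_component is None:
            raise ValueError("genetic mode needs the genetic component X w")
        anchor = np.asarray(genetic_component, dtype=float)
    else:
        raise ValueError(f"unknown h_p2 mode {mode!r}")
    sd = anchor.std()
    if sd == 0:
        raise ValueError("zero-variance expression with h_p2 > 0")
    beta = np.sqrt(h_p2) / sd
    return beta * e_g + rng.normal(0.0, np.sqrt(1.0 - h_p2), e_g.shape[0])


def _marginal_z(x_std: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-SNP simple-regression z-statistics of y on each standardized SNP."""
    n = x_std.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for marginal regression")
    yc = y - y.mean()
    sy = yc.std()
    if sy == 0:
        raise ValueError("constant outcome")
    r = (x_std.T @ yc) / (n * sy)
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    return r * np.sqrt((n - 2.0) / (1.0 - r**2))


def make_summary(
    x_std: np.ndarray,
    y: np.ndarray,
    records: list[SnpRecord],
    gene_id: Optional[str] = None,
):
    """Summary statistics from individual-level data via per-SNP regression.

    Returns an :class:`EqtlSummaryTable` when ``gene_id`` is given, else a
    :class:`GwasSummaryTable`.  The genotype matrix must be standardized
    (monomorphic SNPs raise upstream during standardization).
    """
    x_std = np.asarray(x_std)
    sd = x_std.std(axis=0)
    if np.any(sd == 0):
        bad = records[int(np.argmax(sd == 0))].snp_id
        raise ValueError(f"SNP {bad} is monomorphic")
    z = _marginal_z(x_std, np.asarray(y, dtype=float))
    n = x_std.shape[0]
    if gene_id is not None:
        return EqtlSummaryTable(gene_id=gene_id, records=list(records), z=z, n=np.full(len(records), n))
    return GwasSummaryTable(records=list(records), z=z)


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    # float32 in large simulations, float64 otherwise; per-SNP accumulations
    # at simulation scale are well within float32 tolerance
    x = np.asarray(x)
    if x.dtype != np.float32:
        x = x.astype(np.float64)
    mu, sd = x.mean(axis=0, dtype=np.float64), x.std(axis=0, dtype=np.float64)
    sd[sd == 0] = 1.0
    return ((x - mu) / sd).astype(x.dtype)


def _training_ld(xs_train: np.ndarray, records, config: SimulationConfig) -> LdMatrix:
    ld = ld_from_standardized(xs_train, [r.snp_id for r in records])
    if config.shrink_training_ld:
        cm = np.array([r.cm for r in records])
        ld = shrink_ld(ld, cm)
    return ld


def _one_replicate(
    config: SimulationConfig,
    rng: np.random.Generator,
    with_oracle: bool = False,
    with_assoc: bool = False,
    null_gwas: bool = False,
) -> dict:
    """Simulate one full replicate: data, summary stats, fits, evaluation."""
    n_total = config.n_train + config.n_tune + config.n_test + (config.n_gwas if with_assoc else 0)
    panel = simulate_genotypes(
        n_total,
        config.p_snps,
        config.ld_model,
        config.maf_range,
        rng,
        spacing_bp=config.spacing_bp,
    )
    g = panel.genotypes
    ends = np.cumsum([config.n_train, config.n_tune, config.n_test])
    x_train, x_tune, x_test = g[: ends[0]], g[ends[0] : ends[1]], g[ends[1] : ends[2]]
    xs_train = _standardize(x_train)

    e_train, w_true = simulate_expression(xs_train, config.h_e2, config.p_causal, rng)
    xs_tune, xs_test = _standardize(x_tune), _standardize(x_test)
    noise_sd = np.sqrt(1.0 - config.h_e2)
    e_tune = xs_tune @ w_true + rng.normal(0, noise_sd, xs_tune.shape[0])
    e_test = xs_test @ w_true + rng.normal(0, noise_sd, xs_test.shape[0])

    table = make_summary(xs_train, e_train, panel.records, gene_id="simgene")
    R_tilde = _training_ld(xs_train, panel.records, config)

    models = fit_gene(table, R_tilde, (x_tune, e_tune), config.training)
    best = max(models, key=lambda m: (m.r2_tuning, -m.n_nonzero))
    out = {
        "w_true": w_true,
        "models": models,
        "best_family": best.penalty.family,
        "test_r2": squared_correlation(xs_test @ best.w_hat, e_test),
        "best_w": best.w_hat,
    }

    if with_oracle:
        # individual-level fit: exact in-sample correlations, raw LD
        r_exact = (xs_train.T @ (e_train - e_train.mean())) / (xs_train.shape[0] * e_train.std())
        R_raw = ld_from_standardized(xs_train, [r.snp_id for r in panel.records])
        oracle_models = fit_gene(table, R_raw, (x_tune, e_tune), config.training, r_tilde=r_exact)
        obest = max(oracle_models, key=lambda m: (m.r2_tuning, -m.n_nonzero))
        out["oracle_r2"] = squared_correlation(xs_test @ obest.w_hat, e_test)

    if with_assoc:
        x_gwas = g[ends[2] :]
        xs_gwas = _standardize(x_gwas)
        if null_gwas:
            y_gwas = rng.normal(0.0, 1.0, xs_gwas.shape[0])
        else:
            e_gwas = xs_gwas @ w_true + rng.normal(0, noise_sd, xs_gwas.shape[0])
            y_gwas = simulate_phenotype(
                e_gwas, config.h_p2, rng,
                genetic_component=xs_gwas @ w_true, mode=config.h_p2_mode,
            )
        gwas = make_summary(xs_gwas, y_gwas, panel.records)
        admitted = validate_models(models, (x_test, e_test), config.training.r2_min)
        if not admitted:
            out["assoc_p"] = np.nan
        else:
            # in-cohort raw LD matches the correlation of simulated z-scores
            V = ld_from_standardized(xs_gwas, [r.snp_id for r in panel.records])
            ps, r2s = [], []
            for m in admitted:
                if m.n_nonzero == 0:
                    continue
                _, p = burden_test(m.w_hat, gwas.z, V)
                ps.append(p)
                r2s.append(m.r2_testing)
            out["assoc_p"] = cauchy_combine(ps, r2s) if ps and sum(r2s) > 0 else np.nan
        out["n_admitted"] = len(admitted)
    return out


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_accuracy_experiment(
    config: SimulationConfig,
    n_replicates: Optional[int] = None,
    with_oracle: bool = False,
) -> pd.DataFrame:
    """Held-out imputation accuracy of the summary-based fit.

    Per replicate: fresh genotypes and expression, summary statistics from
    the training cohort, model fitting and tuning selection, evaluation as
    squared correlation on the held-out test cohort.  ``with_oracle`` also
    fits the same penalized model from exact individual-level statistics.
    """
    n_rep = n_replicates if n_replicates is not None else config.n_replicates
    rows = []
    for i, rng in enumerate(_spawn_rngs(config.seed, n_rep)):
        rep = _one_replicate(config, rng, with_oracle=with_oracle)
        row = {"replicate": i, "test_r2": rep["test_r2"], "family": rep["best_family"]}
        if with_oracle:
            row["oracle_r2"] = rep["oracle_r2"]
        rows.append(row)
    df = pd.DataFrame(rows)
    logger.info(
        "accuracy: h_e2=%g p_causal=%g n_train=%d -> mean test R2 %.4f over %d reps",
        config.h_e2, config.p_causal, config.n_train, df["test_r2"].mean(), n_rep,
    )
    return df


def run_power_experiment(
    config: SimulationConfig,
    n_replicates: Optional[int] = None,
) -> dict:
    """Empirical power at the genome-wide threshold, with a binomial CI.

    Each replicate trains models, admits those with held-out R^2 above the
    admission threshold, simulates an independent GWAS cohort, and tests
    with the burden statistic aggregated by the Cauchy combination.
    """
    n_rep = n_replicates if n_replicates is not None else config.n_replicates
    ps, rows = [], []
    for i, rng in enumerate(_spawn_rngs(config.seed, n_rep)):
        rep = _one_replicate(config, rng, with_assoc=True)
        ps.append(rep["assoc_p"])
        rows.append({"replicate": i, "assoc_p": rep["assoc_p"], "test_r2": rep["test_r2"]})
    p_arr = np.asarray(ps, dtype=float)
    tested = np.isfinite(p_arr)
    hits = int(np.sum(p_arr[tested] < config.sig_threshold))
    n_tested = int(tested.sum())
    power = hits / n_rep  # untestable replicates (no admitted model) count as misses
    se = np.sqrt(max(power * (1 - power), 1e-12) / n_rep)
    return {
        "power": power,
        "ci95": (max(0.0, power - 1.96 * se), min(1.0, power + 1.96 * se)),
        "n_replicates": n_rep,
        "n_tested": n_tested,
        "threshold": config.sig_threshold,
        "per_replicate": pd.DataFrame(rows),
    }


def run_type1_experiment(
    config: SimulationConfig,
    n_weight_sets: int = 100,
    n_null_per_set: int = 500,
    alphas: tuple = (0.05, 0.01, 1e-3),
) -> dict:
    """Empirical type-I error of the combined test under the global null.

    Reuses each fitted weight set across ``n_null_per_set`` null GWAS
    replicates: one GWAS genotype cohort per weight set, fresh pure-noise
    phenotypes, vectorized marginal z-scores.  Deterministic given the seed.
    """
    null_ps = []
    for rng in _spawn_rngs(config.seed, n_weight_sets):
        rep = _one_replicate(config, rng, with_assoc=True, null_gwas=True)
        admitted = [m for m in rep["models"] if m.r2_testing is not None
                    and m.r2_testing >= config.training.r2_min and m.n_nonzero > 0]
        if not admitted:
            continue
        x_gwas = simulate_genotypes(
            config.n_gwas, config.p_snps, config.ld_model, config.maf_range, rng,
            spacing_bp=config.spacing_bp,
        )
        xs = _standardize(x_gwas.genotypes)
        n = xs.shape[0]
        Y = rng.standard_normal((n, n_null_per_set))
        Yc = Y - Y.mean(axis=0)
        r = (xs.T @ Yc) / (n * Yc.std(axis=0))
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
        Z = r * np.sqrt((n - 2.0) / (1.0 - r**2))
        V = (xs.T @ xs) / n
        r2s = np.array([m.r2_testing for m in admitted], dtype=float)
        if r2s.sum() == 0:
            r2s = np.ones_like(r2s)
        P = np.empty((len(admitted), n_null_per_set))
        for k, m in enumerate(admitted):
            denom = np.sqrt(float(m.w_hat @ V @ m.w_hat))
            zt = (m.w_hat @ Z) / denom
            P[k] = np.maximum(2.0 * sps.norm.sf(np.abs(zt)), np.finfo(float).tiny)
        for b in range(n_null_per_set):
            null_ps.append(cauchy_combine(P[:, b], r2s))
    null_ps = np.asarray(null_ps)
    rates = {a: float(np.mean(null_ps < a)) for a in alphas}
    return {"rates": rates, "n_null": int(null_ps.size), "null_p": null_ps}
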