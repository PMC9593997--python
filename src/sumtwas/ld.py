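"""Reference-panel LD and the genetic-distance shrinkage estimator.

The sample LD matrix is the Pearson correlation of standardized genotype
columns.  The shrinkage estimator damps each off-diagonal entry by
``exp(-2 * N_e * c_ij / m)`` -- where ``c_ij`` is the genetic distance
between SNPs i and j in centimorgans, ``N_e`` the effective population
size, and ``m`` the sample size of the genetic-map data -- and sets the
entry to exact zero when the damping factor falls below a threshold ``c``.
Defaults (N_e = 11,400, m = 183, c = 1e-3) correspond to the 1000 Genomes
OMNI genetic maps; with them an entry is zeroed beyond
``m * ln(1/c) / (2 * N_e)`` ~ 0.0554 cM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import ReferencePanel, SnpRecord

__all__ = ["LdMatrix", "sample_ld", "shrink_ld", "interpolate_cm", "DEFAULT_N_E", "DEFAULT_M", "DEFAULT_C"]

DEFAULT_N_E = 11_400
DEFAULT_M = 183
DEFAULT_C = 1e-3


@dataclass
class LdMatrix:
    snp_ids: list[str]
    values: np.ndarray
    shrunk: bool = False
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        p = len(self.snp_ids)
        if self.values.shape != (p, p):
            raise ValueError(f"LD matrix shape {self.values.shape} does not match {p} SNPs")
        if p and not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("LD matrix is not symmetric")
        if p and not np.allclose(np.diag(self.values), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal is not 1")
        if p and (self.values.max() > 1 + 1e-8 or self.values.min() < -1 - 1e-8):
            raise ValueError("LD entries outside [-1, 1]")

    @property
    def p(self) -> int:
        return len(self.snp_ids)

    def subset(self, idx: Sequence[int]) -> "LdMatrix":
        idx = np.asarray(idx, dtype=int)
        return LdMatrix(
            snp_ids=[self.snp_ids[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
            shrunk=self.shrunk,
            params=dict(self.params),
        )

    def write_triplets(self, path) -> None:
        """Debug writer: gzipped 'snp_i snp_j r' triplets (upper triangle)."""
        iu, ju = np.triu_indices(self.p)
        df = pd.DataFrame(
            {
                "snp_i": [self.snp_ids[i] for i in iu],
                "snp_j": [self.snp_ids[j] for j in ju],
                "r": self.values[iu, ju],
            }
        )
        df.to_csv(path, sep="\t", index=False, compression="gzip")


def sample_ld(panel: ReferencePanel) -> LdMatrix:
    """Pearson correlation matrix of the panel's genotype columns."""
    if panel.n_samples < 2:
        raise ValueError("need at least 2 samples to estimate LD")
    xs = panel.standardized()  # raises naming any monomorphic SNP
    n = xs.shape[0]
    r = (xs.T @ xs) / n
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return LdMatrix(snp_ids=panel.snp_ids, values=r, shrunk=False)


def ld_from_standardized(xs: np.ndarray, snp_ids: Optional[list] = None) -> LdMatrix:
    """LD matrix from an already-standardized genotype matrix (internal)."""
    n, p = xs.shape
    r = (xs.T @ xs) / n
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return LdMatrix(snp_ids=snp_ids or [f"snp{i+1}" for i in range(p)], values=r, shrunk=False)


def shrink_ld(
    ld: LdMatrix,
    cm: np.ndarray,
    n_e: float = DEFAULT_N_E,
    m: float = DEFAULT_M,
    c: float = DEFAULT_C,
) -> LdMatrix:
    """Apply genetic-distance shrinkage to a raw sample LD matrix.

    Off-diagonal entry (i, j) is multiplied by ``exp(-2 n_e |cm_i - cm_j| / m)``
    and set to exact zero where that factor is below ``c``; the diagonal is
    untouched.
    """
    if ld.shrunk:
        raise ValueError("LD matrix is already shrunk")
    cm = np.asarray(cm, dtype=float)
    if cm.shape[0] != ld.p:
        raise ValueError("cM vector length does not match LD matrix")
    if np.any(~np.isfinite(cm)):
        raise ValueError("missing/non-finite cM values; interpolate the genetic map first")
    dist = np.abs(cm[:, None] - cm[None, :])
    factor = np.exp(-2.0 * n_e * dist / m)
    factor[factor < c] = 0.0
    values = ld.values * factor
    np.fill_diagonal(values, 1.0)
    return LdMatrix(
        snp_ids=list(ld.snp_ids),
        values=values,
        shrunk=True,
        params={"n_e": n_e, "m": m, "c": c},
    )


def interpolate_cm(
    snps: Union[Sequence[SnpRecord], np.ndarray],
    genetic_map: pd.DataFrame,
) -> np.ndarray:
    """Linearly interpolate genetic positions (cM) at SNP bp positions.

    ``genetic_map`` must have ``pos`` and ``cm`` columns sorted by position
    (as returned by :func:`sumtwas.io.read_genetic_map`).  Positions outside
    the map range are clamped to the end values.
    """
    if len(genetic_map) == 0:
        raise ValueError("empty genetic map")
    if len(snps) and isinstance(snps[0], SnpRecord):
        pos = np.array([r.pos for r in snps], dtype=float)
    else:
        pos = np.asarray(snps, dtype=float)
    return np.interp(pos, genetic_map["pos"].to_numpy(dtype=float), genetic_map["cm"].to_numpy(dtype=float))
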