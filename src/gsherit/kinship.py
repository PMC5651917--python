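"""Marker-inferred kinship: K' = (1/m) * sum_k Z_k Z_k^T and its rescaling.

The raw kinship K' averages per-locus outer products of the genotype codes
with no allele-frequency centering or VanRaden-style scaling — the trace
rescale K = n K'/tr(K') is the model's sole normalization, chosen so that
the polygenic variance sigma_A^2 is on the same per-individual scale as the
residual variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["KinshipMatrix", "compute_kinship", "rescale_kinship"]

# relative eigenvalue below which a negative eigenvalue is treated as a
# genuine PSD violation rather than round-off
_PSD_TOL = 1e-8


@dataclass(frozen=True)
class KinshipMatrix:
    values: np.ndarray
    individual_ids: tuple[str, ...]
    rescaled: bool = False

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError("kinship must be a square matrix")
        if vals.shape[0] != len(self.individual_ids):
            raise ValueError("individual_ids length mismatch")
        if not np.allclose(vals, vals.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "individual_ids", tuple(self.individual_ids))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def check_psd(self) -> "KinshipMatrix":
        """Validate positive semi-definiteness, clamping round-off negatives.

        Eigenvalues below -1e-8 times the largest eigenvalue raise; tiny
        negatives are clamped to zero and the matrix reassembled.
        """
        w, U = np.linalg.eigh(self.values)
        top = max(w[-1], 0.0)
        if w[0] < -_PSD_TOL * max(top, 1.0):
            raise ValueError(
                f"kinship is not positive semi-definite (min eigenvalue {w[0]:.3e})"
            )
        if w[0] < 0.0:
            w = np.clip(w, 0.0, None)
            vals = (U * w) @ U.T
            vals = 0.5 * (vals + vals.T)
            return KinshipMatrix(vals, self.individual_ids, self.rescaled)
        return self

    def submatrix(self, rows, cols=None) -> np.ndarray:
        """Slice values by integer index (K11, K21 blocks of the partition)."""
        rows = np.asarray(rows)
        cols = rows if cols is None else np.asarray(cols)
        return self.values[np.ix_(rows, cols)]


def compute_kinship(geno: GenotypeMatrix, *, drop_monomorphic: bool = False) -> KinshipMatrix:
    """Raw kinship K' = (1/m) sum_k Z_k Z_k^T over all loci.

    Monomorphic loci are retained by default (the defining sum makes no
    reference to allele frequencies); ``drop_monomorphic=True`` removes
    zero-variance loci before the sum.  Missing genotypes (NaN) are imputed
    to the per-locus mean of the observed codes, with a logged count.
    """
    if geno.n_loci == 0 or geno.n_individuals < 2:
        raise ValueError("need at least 2 individuals and 1 locus")
    Z = geno.values.astype(float)
    miss = np.isnan(Z)
    if miss.any():
        logger.warning("imputing %d missing genotype calls to per-locus means", miss.sum())
        mean = np.nanmean(Z, axis=0)
        Z = np.where(miss, mean[None, :], Z)
    if drop_monomorphic:
        keep = Z.std(axis=0) > 0
        if not keep.any():
            raise ValueError("all loci monomorphic")
        Z = Z[:, keep]
    m = Z.shape[1]
    K = (Z @ Z.T) / m
    K = 0.5 * (K + K.T)
    return KinshipMatrix(K, geno.individual_ids, rescaled=False)


def rescale_kinship(K_prime: KinshipMatrix) -> KinshipMatrix:
    """Trace rescale K = n K'/tr(K'), so tr(K) = n."""
    tr = float(np.trace(K_prime.values))
    if tr <= 0:
        raise ValueError("kinship trace is not positive (monomorphic panel?)")
    vals = K_prime.n * K_prime.values / tr
    return KinshipMatrix(vals, K_prime.individual_ids, rescaled=True)
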