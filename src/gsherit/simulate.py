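"""Synthetic biparental RIL populations with map-based linkage disequilibrium.

Recombinant inbred lines (RILs) are fully homozygous lines derived from a
cross of two inbred parents by repeated selfing.  At fixation, the
probability that two linked loci carry alleles from *different* parents is
the RIL recombination fraction

    R = 2r / (1 + 2r),

where ``r`` is the single-meiosis recombination fraction, obtained here from
map distance ``d`` (centimorgan) through the Haldane map function

    r = (1 - exp(-2 d / 100)) / 2          (no crossover interference).

Lines are generated directly at fixation by a left-to-right Markov walk
along each chromosome (switch parental origin with probability ``R``
between adjacent loci), rather than by simulating discrete selfing
generations; the two constructions have identical pairwise expectations and
the direct one is validated against a generation-explicit meiosis simulator
in the test suite.

Phenotypes follow the standard polygenic model: each marker effect
``gamma_k`` is drawn i.i.d. from N(0, sigma_g^2), the genetic value of line
``j`` is ``xi_j = sum_k Z_jk gamma_k``, and every replicated measurement is
``xi_j`` plus i.i.d. N(0, sigma_e^2) noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "TrueEffects",
    "PhenotypeTable",
    "simulate_ril_genotypes",
    "simulate_phenotypes",
    "average_replicates",
]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMap:
    """Marker map: chromosome label and cM position for every locus.

    Loci of one chromosome must be contiguous in the arrays and their
    positions nondecreasing; every locus belongs to exactly one chromosome.
    """

    chromosome: np.ndarray          # (m,) int chromosome index per locus
    position_cm: np.ndarray         # (m,) float map position per locus
    locus_ids: tuple[str, ...] = ()

    def __post_init__(self):
        chrom = np.asarray(self.chromosome)
        pos = np.asarray(self.position_cm, dtype=float)
        if chrom.size == 0:
            raise ValueError("genetic map must contain at least one locus")
        if chrom.shape != pos.shape:
            raise ValueError("chromosome and position arrays differ in length")
        # chromosomes must form contiguous blocks
        change = np.flatnonzero(np.diff(chrom) != 0)
        seen = chrom[np.concatenate([[0], change + 1])]
        if len(set(seen.tolist())) != len(seen):
            raise ValueError("loci of one chromosome must be contiguous")
        for c in seen:
            p = pos[chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions on chromosome {c} are not sorted")
        ids = self.locus_ids or tuple(
            f"c{c}_b{i}" for c, i in zip(chrom, _within_chrom_index(chrom))
        )
        if len(ids) != chrom.size:
            raise ValueError("locus_ids length does not match locus count")
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_cm", pos)
        object.__setattr__(self, "locus_ids", tuple(ids))

    @property
    def n_loci(self) -> int:
        return self.chromosome.size

    @property
    def n_chromosomes(self) -> int:
        return len(np.unique(self.chromosome))

    @property
    def loci_per_chromosome(self) -> dict[int, int]:
        vals, counts = np.unique(self.chromosome, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    @classmethod
    def uniform(cls, n_chromosomes: int = 12, n_loci: int = 1619,
                chrom_length_cm: float = 150.0) -> "GeneticMap":
        """Evenly spaced loci on equal-length chromosomes.

        Defaults mirror a rice-like bin map: 1619 loci over 12 chromosomes
        of 150 cM each.  A remainder that does not divide evenly is spread
        over the first chromosomes.
        """
        if n_chromosomes < 1 or n_loci < 1:
            raise ValueError("need at least one chromosome and one locus")
        base, extra = divmod(n_loci, n_chromosomes)
        chroms, pos = [], []
        for c in range(n_chromosomes):
            k = base + (1 if c < extra else 0)
            if k == 0:
                continue
            chroms.append(np.full(k, c + 1))
            pos.append(np.linspace(0.0, chrom_length_cm, k))
        return cls(np.concatenate(chroms), np.concatenate(pos))


@dataclass(frozen=True)
class GenotypeMatrix:
    """n × m marker codes: 1 = A1A1, 0 = A1A2 (heterozygote), -1 = A2A2."""

    values: np.ndarray
    individual_ids: tuple[str, ...]
    locus_ids: tuple[str, ...]

    def __post_init__(self):
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        if not np.isin(vals[~_nan_mask(vals)], (-1, 0, 1)).all():
            raise ValueError("genotype codes must be in {-1, 0, 1}")
        if vals.shape[0] != len(self.individual_ids):
            raise ValueError("individual_ids length mismatch")
        if vals.shape[1] != len(self.locus_ids):
            raise ValueError("locus_ids length mismatch")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "individual_ids", tuple(self.individual_ids))
        object.__setattr__(self, "locus_ids", tuple(self.locus_ids))

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    def subset_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[:, idx],
            self.individual_ids,
            tuple(self.locus_ids[i] for i in idx),
        )


@dataclass(frozen=True)
class TrueEffects:
    """Per-locus effects used to build a simulated trait."""

    gamma: np.ndarray               # (m,) per-locus effects
    sigma_g: float                  # effect standard deviation
    sigma_e: float                  # residual standard deviation

    def __post_init__(self):
        if self.sigma_g <= 0 or self.sigma_e <= 0:
            raise ValueError("sigma_g and sigma_e must be positive")
        object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=float))


@dataclass(frozen=True)
class PhenotypeTable:
    """Long-format phenotype records (id, replicate, value).

    ``genetic_values`` holds the true polygenic values xi, indexed by
    individual id; it is populated only for simulated data and is carried
    through replicate averaging untouched.
    """

    data: pd.DataFrame
    genetic_values: pd.Series | None = None

    def __post_init__(self):
        required = {"id", "replicate", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")
        if self.data.duplicated(["id", "replicate"]).any():
            raise ValueError("duplicate (id, replicate) records")

    @property
    def individual_ids(self) -> tuple[str, ...]:
        return tuple(self.data["id"].drop_duplicates())

    def values_for(self, ids) -> np.ndarray:
        """Phenotype vector in the order of ``ids`` (single-record tables)."""
        counts = self.data["id"].value_counts()
        if (counts > 1).any():
            raise ValueError("table has replicates; average them first")
        series = self.data.set_index("id")["value"]
        return series.loc[list(ids)].to_numpy(dtype=float)


def _nan_mask(a: np.ndarray) -> np.ndarray:
    return np.isnan(a) if np.issubdtype(a.dtype, np.floating) else np.zeros(a.shape, bool)


def _within_chrom_index(chrom: np.ndarray) -> np.ndarray:
    out = np.zeros(chrom.size, dtype=int)
    for c in np.unique(chrom):
        sel = chrom == c
        out[sel] = np.arange(1, sel.sum() + 1)
    return out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Single-meiosis recombination fraction from Haldane map distance."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_recombination(r) -> np.ndarray | float:
    """RIL-at-fixation recombination fraction R = 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


def simulate_ril_genotypes(gmap: GeneticMap, n: int, seed: int) -> GenotypeMatrix:
    """Draw ``n`` fully homozygous RIL genotypes under the given map.

    Each chromosome is a two-state Markov chain along its loci: the first
    locus is each parent's allele with probability 1/2, and parental origin
    switches between adjacent loci with probability R = 2r/(1+2r), the
    expected RIL discordance for a single meiosis fraction r derived from
    the Haldane map function.  Chromosomes are independent; codes are
    strictly in {-1, +1}.
    """
    if n < 2:
        raise ValueError("need at least 2 lines")
    rng = np.random.default_rng(seed)
    cols = []
    for c in np.unique(gmap.chromosome):
        pos = gmap.position_cm[gmap.chromosome == c]
        R = ril_recombination(haldane_r(np.diff(pos)))
        first = rng.integers(0, 2, size=n)
        if R.size:
            switches = rng.random((n, R.size)) < R[None, :]
            state = np.concatenate([first[:, None], switches], axis=1)
        else:
            state = first[:, None]
        state = np.cumsum(state, axis=1) % 2
        cols.append(np.where(state == 0, 1, -1).astype(np.int8))
    values = np.concatenate(cols, axis=1)
    ids = tuple(f"L{i + 1:04d}" for i in range(n))
    return GenotypeMatrix(values, ids, gmap.locus_ids)


def simulate_phenotypes(geno: GenotypeMatrix, sigma_g: float, sigma_e: float,
                        replicates: int, seed: int, *,
                        causal_fraction: float = 1.0,
                        zero_effects: bool = False,
                        ) -> tuple[PhenotypeTable, TrueEffects]:
    """Simulate a polygenic trait with ``replicates`` measurements per line.

    Draw order under one seeded generator, for reproducibility: (1) the m
    per-locus effects gamma_k ~ N(0, sigma_g^2); (2) if
    ``causal_fraction`` < 1, the random causal subset (effects outside it
    are set to zero — those loci are neutral); (3) residuals, replicate-
    major, eps[r, j] ~ N(0, sigma_e^2).

    With ``zero_effects`` every gamma_k is forced to zero, giving a
    pure-noise trait with Var(xi) = 0 (null simulations).
    """
    if geno.n_loci == 0:
        raise ValueError("genotype matrix has no loci")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if not 0.0 < causal_fraction <= 1.0:
        raise ValueError("causal_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    m, n = geno.n_loci, geno.n_individuals
    gamma = rng.normal(0.0, sigma_g, size=m)
    if causal_fraction < 1.0:
        n_causal = max(1, int(round(causal_fraction * m)))
        neutral = rng.permutation(m)[n_causal:]
        gamma[neutral] = 0.0
    if zero_effects:
        gamma[:] = 0.0
    xi = geno.values.astype(float) @ gamma
    eps = rng.normal(0.0, sigma_e, size=(replicates, n))
    y = xi[None, :] + eps
    frames = pd.DataFrame({
        "id": np.tile(geno.individual_ids, replicates),
        "replicate": np.repeat(np.arange(1, replicates + 1), n),
        "value": y.ravel(),
    })
    xi_series = pd.Series(xi, index=list(geno.individual_ids), name="xi")
    effects = TrueEffects(gamma, sigma_g, sigma_e)
    return PhenotypeTable(frames, xi_series), effects


def average_replicates(pheno: PhenotypeTable) -> PhenotypeTable:
    """Collapse replicated measurements to one per-line arithmetic mean."""
    if pheno.data.empty:
        raise ValueError("empty phenotype table")
    order = pheno.data["id"].drop_duplicates()
    means = pheno.data.groupby("id", sort=False)["value"].mean().loc[order]
    out = pd.DataFrame({
        "id": means.index,
        "replicate": 1,
        "value": means.to_numpy(),
    })
    return replace(pheno, data=out)
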