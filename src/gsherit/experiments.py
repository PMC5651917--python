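"""Scripted study designs: the signal-strength × replicate grid, the
replicate-count grid, and the incremental-locus association scan.

These drivers reproduce, on synthetic RIL panels, the three demonstrations
that motivate cross-validated heritability:

* ``signal_grid_experiment`` — a grid of sigma_g/sigma_e ratios with r
  technical replicates per line; H, Hcv and Pcv are computed per replicate
  column and on the replicate average, plus the ANOVA benchmark on the full
  replicated table.  Shows H > Hcv (overfitting) and Hcv ≈ Pcv.
* ``replicate_grid_experiment`` — one fixed panel and trait, increasing
  replicate counts; GS statistics on the replicate averages rise with r
  while the ANOVA heritability stays put.
* ``locus_scan`` — loci sorted by |Pearson correlation| with the phenotype,
  strongest first; H, Hcv, Pcv evaluated on nested top-fraction subsets.
  H keeps climbing as neutral loci are appended while Hcv and Pcv plateau
  once the associated loci are covered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .anova import anova_heritability
from .cv import cross_validate, naive_heritability
from .kinship import compute_kinship, rescale_kinship
from .mixed_model import MixedModelData
from .simulate import (GeneticMap, GenotypeMatrix, PhenotypeTable,
                       average_replicates, simulate_phenotypes,
                       simulate_ril_genotypes)

__all__ = [
    "panel_data",
    "signal_grid_experiment",
    "replicate_grid_experiment",
    "locus_scan",
]


def panel_data(geno: GenotypeMatrix, y: np.ndarray) -> MixedModelData:
    """Bundle a genotype panel and phenotype vector into model data,
    computing the rescaled kinship internally."""
    K = rescale_kinship(compute_kinship(geno))
    return MixedModelData(np.asarray(y, dtype=float), K,
                          individual_ids=geno.individual_ids)


def _gs_stats(geno, y, k, cv_repeats, seed, varcomp_mode="per_fold"):
    data = panel_data(geno, y)
    H = naive_heritability(data)
    summ = cross_validate(data, k=k, repeats=cv_repeats, seed=seed,
                          varcomp_mode=varcomp_mode)
    return H, summ.mean["Hcv"], summ.mean["Pcv"]


def signal_grid_experiment(ratios=(1 / 50, 1 / 20, 1 / 10), *, n: int = 210,
                           gmap: GeneticMap | None = None, sigma_e: float = 1.0,
                           replicates: int = 4, k: int = 5, cv_repeats: int = 1,
                           seed: int = 0) -> pd.DataFrame:
    """H/Hcv/Pcv per replicate column and on the average, plus the ANOVA
    heritability, for each sigma_g/sigma_e ratio.

    One genotype panel is simulated and shared across ratios (as when real
    genotypes are reused); effects and errors are redrawn per ratio.
    """
    gmap = gmap or GeneticMap.uniform()
    geno = simulate_ril_genotypes(gmap, n, seed)
    rows = []
    for i, ratio in enumerate(ratios):
        pheno, effects = simulate_phenotypes(
            geno, sigma_g=ratio * sigma_e, sigma_e=sigma_e,
            replicates=replicates, seed=seed + 1000 + i)
        for rep in range(1, replicates + 1):
            sub = pheno.data[pheno.data["replicate"] == rep]
            y = sub.set_index("id")["value"].loc[list(geno.individual_ids)].to_numpy()
            H, Hcv, Pcv = _gs_stats(geno, y, k, cv_repeats, seed + rep)
            rows.append({"ratio": ratio, "column": f"rep{rep}",
                         "sample_size": n, "H": H, "Hcv": Hcv, "Pcv": Pcv,
                         "Haov": np.nan})
        avg = average_replicates(pheno)
        y = avg.values_for(geno.individual_ids)
        H, Hcv, Pcv = _gs_stats(geno, y, k, cv_repeats, seed)
        rows.append({"ratio": ratio, "column": "average",
                     "sample_size": n * replicates, "H": H, "Hcv": Hcv,
                     "Pcv": Pcv, "Haov": np.nan})
        aov = anova_heritability(pheno)
        rows.append({"ratio": ratio, "column": "anova",
                     "sample_size": n * replicates, "H": np.nan,
                     "Hcv": np.nan, "Pcv": np.nan, "Haov": aov.Haov})
    return pd.DataFrame(rows)


def replicate_grid_experiment(replicate_grid=(10, 50, 100, 500), *,
                              n: int = 210, gmap: GeneticMap | None = None,
                              sigma_g: float = 1 / 20, sigma_e: float = 1.0,
                              k: int = 5, cv_repeats: int = 1,
                              seed: int = 0) -> pd.DataFrame:
    """ANOVA vs GS statistics as the replicate count grows.

    The panel and the per-locus effects are fixed (same trait throughout);
    only the residual draws differ with r.  GS statistics are computed on
    the replicate averages.
    """
    gmap = gmap or GeneticMap.uniform()
    geno = simulate_ril_genotypes(gmap, n, seed)
    rows = []
    for i, r in enumerate(replicate_grid):
        # same effect seed for every r -> identical xi, more averaging only
        pheno, _ = simulate_phenotypes(geno, sigma_g=sigma_g, sigma_e=sigma_e,
                                       replicates=r, seed=seed + 7)
        # r = 1 raises the documented ANOVA error (replicates are required
        # there; the GS path below would not need them)
        haov = anova_heritability(pheno).Haov
        avg = average_replicates(pheno)
        y = avg.values_for(geno.individual_ids)
        H, Hcv, Pcv = _gs_stats(geno, y, k, cv_repeats, seed + i)
        rows.append({"replicates": r, "Haov": haov, "H": H,
                     "Hcv": Hcv, "Pcv": Pcv})
    return pd.DataFrame(rows)


def locus_scan(geno: GenotypeMatrix, pheno: PhenotypeTable, *,
               step: float = 0.1, k: int = 5, cv_repeats: int = 1,
               seed: int = 0) -> pd.DataFrame:
    """Evaluate H/Hcv/Pcv on nested top-association locus subsets.

    The phenotype table must hold one record per individual (average
    replicates first).  Loci are ranked by the absolute Pearson correlation
    of their codes with the phenotype, strongest association first, then
    the top ``step``, 2·``step``, ... fractions are analysed in turn.
    """
    if not 0 < step <= 1:
        raise ValueError("step must be in (0, 1]")
    y = pheno.values_for(geno.individual_ids)
    Z = geno.values.astype(float)
    yc = y - y.mean()
    Zc = Z - Z.mean(axis=0)
    denom = np.sqrt((Zc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs((Zc.T @ yc) / denom)
    corr = np.nan_to_num(corr)          # monomorphic loci sort last
    order = np.argsort(-corr, kind="stable")

    m = geno.n_loci
    fractions = np.arange(step, 1 + 1e-9, step)
    rows = []
    for frac in fractions:
        top = order[: max(1, int(round(frac * m)))]
        sub = geno.subset_loci(np.sort(top))
        H, Hcv, Pcv = _gs_stats(sub, y, k, cv_repeats, seed)
        rows.append({"fraction": round(float(frac), 10), "n_loci": top.size,
                     "H": H, "Hcv": Hcv, "Pcv": Pcv})
    return pd.DataFrame(rows)
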