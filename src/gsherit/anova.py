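"""Line-plus-replicate ANOVA heritability, the classical benchmark.

For a balanced design of n lines × r replicates the two-way fixed-effects
decomposition gives mean squares for line, replicate and error; the
between-line variance component on a single-observation basis is

    var_line = (MS_line - MS_error) / r

and the ANOVA heritability

    Haov = var_line / (var_line + MS_error),

with a negative var_line truncated to zero (REML-like convention).  This
estimator requires replicated measurements — a single replicate leaves no
within-line variance to compare against, which is exactly the limitation
the marker-based path does not share.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .simulate import PhenotypeTable

__all__ = ["AnovaResult", "anova_heritability"]


@dataclass(frozen=True)
class AnovaResult:
    ms_line: float
    ms_replicate: float
    ms_error: float
    var_line: float
    var_error: float
    Haov: float
    n_lines: int
    n_replicates: int


def anova_heritability(pheno: PhenotypeTable) -> AnovaResult:
    """Balanced two-way ANOVA heritability from a replicated phenotype table.

    Raises on a single replicate (use the GS path, which needs none) and on
    unbalanced designs.
    """
    df = pheno.data
    counts = df.groupby("id")["value"].count()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: lines differ in replicate count")
    r = int(counts.iloc[0])
    n = counts.size
    if n < 2:
        raise ValueError("need at least 2 lines")
    if r < 2:
        raise ValueError(
            "ANOVA requires replicated measurements; with a single replicate "
            "use the marker-based GS analysis instead"
        )
    # reps must also be crossed: every replicate index appears once per line
    rep_counts = df.groupby("replicate")["value"].count()
    if rep_counts.nunique() != 1 or rep_counts.size != r:
        raise ValueError("unbalanced design: replicate indices are not crossed")

    wide = df.pivot(index="id", columns="replicate", values="value").to_numpy()
    grand = wide.mean()
    line_means = wide.mean(axis=1)
    rep_means = wide.mean(axis=0)
    ss_line = r * float(((line_means - grand) ** 2).sum())
    ss_rep = n * float(((rep_means - grand) ** 2).sum())
    ss_total = float(((wide - grand) ** 2).sum())
    ss_err = ss_total - ss_line - ss_rep

    ms_line = ss_line / (n - 1)
    ms_rep = ss_rep / (r - 1)
    ms_err = ss_err / ((n - 1) * (r - 1))

    var_line = (ms_line - ms_err) / r
    if var_line < 0:
        warnings.warn("negative between-line variance truncated to 0",
                      RuntimeWarning)
        var_line = 0.0
    denom = var_line + ms_err
    haov = var_line / denom if denom > 0 else 0.0
    return AnovaResult(
        ms_line=ms_line, ms_replicate=ms_rep, ms_error=ms_err,
        var_line=var_line, var_error=ms_err, Haov=haov,
        n_lines=n, n_replicates=r,
    )
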