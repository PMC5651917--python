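"""Cross-validated heritability (Hcv) and predictability (Pcv).

Fitting GBLUP on a panel saturated with trait-irrelevant markers inflates
the REML genetic variance, so the conventional heritability
h^2 = sigma_A^2/(sigma_A^2 + sigma^2) estimated on the full training data
("H" here) overfits.  The cross-validated alternative instead predicts each
individual's genetic value while that individual sits in the test fold, and
takes

    Vg  = Var(xi_hat_cv)                      (genetic variance)
    Vr  = Var(y_centered - xi_hat_cv)         (residual variance)
    Hcv = Vg / (Vg + Vr)

where y_centered removes each individual's fold-specific fixed-effect fit
X2 beta_hat (a per-fold mean shift under the default intercept-only
design).  Predictability is the squared Pearson correlation between
y_centered and xi_hat_cv, pooled over the whole panel for each repeat; the
two statistics agree closely when overfitting is under control.

Leak policy: variance components and beta are re-estimated within every
training fold (``varcomp_mode='per_fold'``, the default) — the only fully
leak-free reading of "the training set estimates the model parameters".  A
``'global'`` mode (components from the full data, predictions still
cross-validated) is provided for comparison but is partially leaky.  The
kinship matrix is computed once from all genotypes and sliced per fold;
genotypes carry no phenotype information, so this is not leakage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .mixed_model import MixedModelData, heritability, predict_holdout, \
    reml_fit

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "CVResult",
    "CVSummary",
    "make_folds",
    "run_cv",
    "cross_validate",
    "cv_heritability",
    "cv_heritability_alt",
    "predictability",
    "naive_heritability",
]


@dataclass(frozen=True)
class FoldPlan:
    """One repeat's fold assignment: label in [0, k) per individual."""

    k: int
    assignments: np.ndarray
    repeat_index: int = 0
    seed: int | None = None

    def __post_init__(self):
        a = np.asarray(self.assignments)
        sizes = np.bincount(a, minlength=self.k)
        if a.min() < 0 or a.max() >= self.k:
            raise ValueError("fold labels out of range")
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes differ by more than 1")
        object.__setattr__(self, "assignments", a)

    def folds(self):
        for f in range(self.k):
            test = np.flatnonzero(self.assignments == f)
            train = np.flatnonzero(self.assignments != f)
            yield f, train, test


@dataclass(frozen=True)
class CVResult:
    """Per-repeat CV output: one out-of-fold prediction per individual."""

    xi_hat_cv: np.ndarray           # out-of-fold predicted genetic values
    y_centered: np.ndarray          # y minus the fold-specific X2 beta_hat
    y: np.ndarray                   # raw phenotypes
    plan: FoldPlan
    beta_by_fold: list
    varcomp_by_fold: list

    @property
    def Hcv(self) -> float:
        return cv_heritability(self)

    @property
    def Hcv_alt(self) -> float:
        return cv_heritability_alt(self)

    @property
    def Pcv(self) -> float:
        return predictability(self)


@dataclass(frozen=True)
class CVSummary:
    """Aggregate over repeats: per-repeat statistics plus mean and sd."""

    results: tuple
    Hcv: np.ndarray
    Hcv_alt: np.ndarray
    Pcv: np.ndarray

    @property
    def mean(self) -> dict:
        return {"Hcv": float(self.Hcv.mean()),
                "Hcv_alt": float(self.Hcv_alt.mean()),
                "Pcv": float(self.Pcv.mean())}

    @property
    def sd(self) -> dict:
        ddof = 1 if len(self.Hcv) > 1 else 0
        return {"Hcv": float(self.Hcv.std(ddof=ddof)),
                "Hcv_alt": float(self.Hcv_alt.std(ddof=ddof)),
                "Pcv": float(self.Pcv.std(ddof=ddof))}


def make_folds(n: int, k: int, repeats: int = 1, seed: int = 0) -> list[FoldPlan]:
    """Random k-fold partitions, one plan per repeat, deterministic in seed.

    Each repeat permutes the n individuals uniformly and cuts the
    permutation into k contiguous blocks whose sizes differ by at most 1.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError("more folds than individuals")
    rng = np.random.default_rng(seed)
    plans = []
    for rep in range(repeats):
        perm = rng.permutation(n)
        assignments = np.empty(n, dtype=int)
        for f, block in enumerate(np.array_split(perm, k)):
            assignments[block] = f
        plans.append(FoldPlan(k=k, assignments=assignments,
                              repeat_index=rep, seed=seed))
    return plans


def run_cv(data: MixedModelData, plan: FoldPlan,
           varcomp_mode: str = "per_fold") -> CVResult:
    """One repeat of k-fold CV producing out-of-fold genetic values.

    For each fold, variance components (per_fold mode) and the fixed
    effects are estimated on the k-1 training folds only, then the test
    fold's genetic values are filled in by conditional expectation.  After
    all folds, every individual carries exactly one prediction obtained
    without its own phenotype contributing to training.
    """
    if varcomp_mode not in ("per_fold", "global"):
        raise ValueError("varcomp_mode must be 'per_fold' or 'global'")
    n = data.n
    if plan.assignments.size != n:
        raise ValueError("fold plan does not match data size")
    global_vc = reml_fit(data) if varcomp_mode == "global" else None

    xi_cv = np.full(n, np.nan)
    y_centered = np.full(n, np.nan)
    betas, vcs = [], []
    for _f, train_idx, test_idx in plan.folds():
        if train_idx.size < data.q + 1:
            raise ValueError("training folds smaller than the fixed-effect rank")
        vc = global_vc if global_vc is not None else reml_fit(data.subset(train_idx))
        pred = predict_holdout(data, train_idx, test_idx, vc)
        xi_cv[test_idx] = pred.xi2_hat
        y_centered[test_idx] = data.y[test_idx] - data.X[test_idx] @ pred.beta_hat
        betas.append(pred.beta_hat)
        vcs.append(vc)
    assert not np.isnan(xi_cv).any()
    return CVResult(xi_hat_cv=xi_cv, y_centered=y_centered, y=data.y.copy(),
                    plan=plan, beta_by_fold=betas, varcomp_by_fold=vcs)


def cross_validate(data: MixedModelData, k: int = 5, repeats: int = 1,
                   seed: int = 0, varcomp_mode: str = "per_fold") -> CVSummary:
    """k-fold CV repeated ``repeats`` times; Hcv/Hcv_alt/Pcv per repeat."""
    plans = make_folds(data.n, k, repeats, seed)
    results = tuple(run_cv(data, p, varcomp_mode) for p in plans)
    return CVSummary(
        results=results,
        Hcv=np.array([r.Hcv for r in results]),
        Hcv_alt=np.array([r.Hcv_alt for r in results]),
        Pcv=np.array([r.Pcv for r in results]),
    )


# ---------------------------------------------------------------------------
# the statistics
# ---------------------------------------------------------------------------

def cv_heritability(result: CVResult) -> float:
    """Hcv = Var(xi_hat_cv) / (Var(xi_hat_cv) + Var(y_centered - xi_hat_cv)).

    Sample variances use the n-1 denominator.
    """
    vg = float(np.var(result.xi_hat_cv, ddof=1))
    vr = float(np.var(result.y_centered - result.xi_hat_cv, ddof=1))
    if vg + vr == 0:
        raise ValueError("zero total variance")
    return vg / (vg + vr)


def cv_heritability_alt(result: CVResult) -> float:
    """Alternative ratio: Var(xi_hat_cv) / Var(y)."""
    vy = float(np.var(result.y, ddof=1))
    if vy == 0:
        raise ValueError("zero phenotypic variance")
    return float(np.var(result.xi_hat_cv, ddof=1)) / vy


def predictability(result: CVResult) -> float:
    """Pcv: squared Pearson correlation of y_centered with xi_hat_cv,
    pooled over all individuals of the repeat.

    Constant predictions give Pcv = 0 with a warning (an all-shrunk model
    predicts nothing, it is not an error).
    """
    x, y = result.xi_hat_cv, result.y_centered
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector in predictability; returning 0",
                      RuntimeWarning)
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def naive_heritability(data: MixedModelData, method: str = "REML") -> float:
    """The non-CV benchmark H: full-data REML then the variance ratio."""
    return heritability(reml_fit(data, method=method))
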