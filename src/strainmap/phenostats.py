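"""Strain-level phenotype summaries and the covariate-adjusted group test.

``strain_summary`` reports per-strain n / mean / SEM plus the panel-wide
fold range between the lowest and highest strain means. The knockout-style
comparison regresses the trait on nuisance covariates (age, body weight)
across all animals of one sex with ordinary least squares and compares the
residuals between two genotype groups with a pooled-variance Student's
t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import PhenotypeTable


@dataclass
class StrainSummary:
    trait: str
    per_strain: pd.DataFrame       # strain_id, n, mean, sem (NaN when n == 1)
    min_strain: str
    max_strain: str
    min_mean: float
    max_mean: float
    fold_range: float

    @property
    def fold_range_rounded(self) -> float:
        return round(self.fold_range, 1)


def strain_summary(pheno: PhenotypeTable, trait: str) -> StrainSummary:
    """Per-strain mean +/- SEM and the max/min fold range of strain means."""
    tf = pheno.trait_frame(trait)
    g = tf.groupby("strain_id")["value"]
    per = pd.DataFrame({
        "n": g.size(),
        "mean": g.mean(),
        "sem": g.std(ddof=1) / np.sqrt(g.size()),
    }).reset_index().sort_values("strain_id").reset_index(drop=True)
    imin = per["mean"].idxmin()
    imax = per["mean"].idxmax()
    min_mean = float(per.loc[imin, "mean"])
    max_mean = float(per.loc[imax, "mean"])
    return StrainSummary(
        trait=trait, per_strain=per,
        min_strain=str(per.loc[imin, "strain_id"]),
        max_strain=str(per.loc[imax, "strain_id"]),
        min_mean=min_mean, max_mean=max_mean,
        fold_range=max_mean / min_mean,
    )


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float                  # residual mean of group a
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    p: float
    n_a: int
    n_b: int
    residuals: np.ndarray


def adjusted_group_comparison(values: np.ndarray, covariates: np.ndarray,
                              groups: np.ndarray, group_a: str,
                              group_b: str) -> GroupComparison:
    """Residualize on covariates (OLS with intercept, all animals pooled),
    then compare residuals between two groups by two-sided pooled-variance
    t-test.

    ``covariates`` is (n, k); pass an empty (n, 0) array for an unadjusted
    comparison (the regression degenerates to centering, and the test
    equals the plain two-sample t-test on raw values).
    """
    values = np.asarray(values, float).ravel()
    groups = np.asarray(groups, dtype=object).ravel()
    cov = np.asarray(covariates, float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != values.size:
        raise ValueError("covariates and values differ in length")
    # drop constant covariate columns: they are absorbed by the intercept
    keep = [j for j in range(cov.shape[1]) if np.std(cov[:, j]) > 0]
    X = sm.add_constant(cov[:, keep] if keep else np.empty((values.size, 0)))
    resid = sm.OLS(values, X).fit().resid

    ra = resid[groups == group_a]
    rb = resid[groups == group_b]
    if len(ra) < 2 or len(rb) < 2:
        raise ValueError("each group needs at least 2 animals")
    t, p = stats.ttest_ind(ra, rb, equal_var=True)
    return GroupComparison(
        group_a=group_a, group_b=group_b,
        mean_a=float(ra.mean()), mean_b=float(rb.mean()),
        sem_a=float(ra.std(ddof=1) / np.sqrt(len(ra))),
        sem_b=float(rb.std(ddof=1) / np.sqrt(len(rb))),
        t=float(t), p=float(p), n_a=len(ra), n_b=len(rb),
        residuals=resid,
    )
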