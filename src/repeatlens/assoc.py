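"""Haplotype-dosage coding and association models.

The composite marker combines the VNTR allele class (Short/Long) with the
intron-4 SNP allele (C/T) into four phased haplotypes — Short-C, Short-T,
Long-C and Long-T — counted per sample as dosages summing to 2.  Short-C is
the reference category, so association models estimate the effect of each
of the other three haplotypes relative to it.

Models: ordinary least squares for quantitative traits, maximum-likelihood
logistic regression (with separation detection) for case/control outcomes,
a likelihood-ratio test for dosage x 5-year-age-group interaction, and the
two-sample Wilcoxon-Mann-Whitney test for copy-number comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, mannwhitneyu

logger = logging.getLogger("repeatlens")

HAPLOTYPES = ("SHORT_C", "SHORT_T", "LONG_C", "LONG_T")
REFERENCE_HAPLOTYPE = "SHORT_C"


@dataclass
class RegressionResult:
    """Per-term estimates from one fitted model."""

    terms: pd.DataFrame  # index: term; columns: beta, se, p (+ or_, ci_low, ci_high)
    loglik: float
    n: int
    separation: bool = False


@dataclass
class InteractionResult:
    main_terms: pd.DataFrame
    p_interaction: float
    bin_edges: np.ndarray
    n: int


def haplotype_dosage(vntr_classes: np.ndarray, snp_alleles: np.ndarray) -> pd.DataFrame:
    """Count the four (VNTR class, SNP allele) haplotypes per sample.

    ``vntr_classes`` is ``(n, 2)`` of "SHORT"/"LONG" and ``snp_alleles``
    ``(n, 2)`` of 0 (C) / 1 (T), both phased so column k is chromosome k.
    Dosages are non-negative integers summing to 2 for every sample.
    """
    vntr = np.asarray(vntr_classes)
    snp = np.asarray(snp_alleles)
    if vntr.shape != snp.shape or vntr.ndim != 2 or vntr.shape[1] != 2:
        raise ValueError("inputs must both be (n, 2) phased arrays")
    names = np.char.add(
        np.char.add(vntr.astype(str), "_"), np.where(snp == 1, "T", "C")
    )
    out = pd.DataFrame(
        {h: (names == h).sum(axis=1) for h in HAPLOTYPES}, dtype=int
    )
    assert (out.sum(axis=1) == 2).all()
    return out


def _design(dosages, covariates: pd.DataFrame | None, drop_reference: bool) -> pd.DataFrame:
    if isinstance(dosages, pd.DataFrame):
        X = dosages.copy()
        if drop_reference and REFERENCE_HAPLOTYPE in X.columns:
            X = X.drop(columns=[REFERENCE_HAPLOTYPE])
    else:
        X = pd.DataFrame({"dosage": np.asarray(dosages, dtype=float)})
    if covariates is not None:
        for col in covariates.columns:
            X[col] = np.asarray(covariates[col], dtype=float)
    X = sm.add_constant(X.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]}); collinear terms: "
            f"{list(X.columns)}"
        )
    return X


def linear_assoc(y, dosages, covariates: pd.DataFrame | None = None) -> RegressionResult:
    """OLS of a quantitative trait on haplotype dosages (Short-C reference).

    ``dosages`` may be a haplotype-dosage DataFrame (the reference column is
    omitted automatically) or a single genotype-dosage vector.  P-values
    are two-sided Wald tests per term.
    """
    y = np.asarray(y, dtype=float)
    X = _design(dosages, covariates, drop_reference=True)
    if len(y) <= X.shape[1]:
        raise ValueError("n must exceed the number of model terms")
    fit = sm.OLS(y, X).fit()
    terms = pd.DataFrame({"beta": fit.params, "se": fit.bse, "p": fit.pvalues})
    return RegressionResult(terms, float(fit.llf), int(fit.nobs))


def logistic_assoc(case, dosages, covariates: pd.DataFrame | None = None) -> RegressionResult:
    """Maximum-likelihood logit of a case indicator on dosages.

    Odds ratios with 95% confidence intervals are attached per term.
    Perfect separation is flagged and no estimates are reported.
    """
    case = np.asarray(case, dtype=float)
    if set(np.unique(case)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes coded 0/1")
    X = _design(dosages, covariates, drop_reference=True)
    try:
        fit = sm.Logit(case, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise np.linalg.LinAlgError("no convergence")
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        logger.warning("perfect separation detected; no estimates reported")
        return RegressionResult(pd.DataFrame(), float("nan"), len(case), separation=True)
    if np.any(np.abs(fit.params) > 15):  # quasi-separation: effectively infinite OR
        logger.warning("quasi-separation detected; no estimates reported")
        return RegressionResult(pd.DataFrame(), float("nan"), len(case), separation=True)
    ci = fit.conf_int()
    terms = pd.DataFrame(
        {
            "beta": fit.params,
            "se": fit.bse,
            "p": fit.pvalues,
            "or_": np.exp(fit.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
        }
    )
    return RegressionResult(terms, float(fit.llf), int(fit.nobs))


def _age_groups(age: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    lo = np.floor(age.min() / bin_width) * bin_width
    edges = np.arange(lo, age.max() + bin_width, bin_width)
    idx = np.clip(np.digitize(age, edges) - 1, 0, len(edges) - 1)
    # merge empty or singleton trailing bins with their left neighbour
    counts = np.bincount(idx, minlength=len(edges))
    for b in range(len(counts)):
        if counts[b] == 0 and b > 0:
            logger.warning("empty age bin %d merged with neighbour", b)
    return idx.astype(float), edges


def interaction_assoc(
    y,
    dosage,
    age,
    covariates: pd.DataFrame | None = None,
    bin_width: float = 5.0,
) -> InteractionResult:
    """Dosage x age-group interaction tested by a likelihood-ratio test.

    Ages are grouped in ``bin_width``-year bins (default 5, to avoid
    age-heaping); the full model adds a dosage x group term to the main
    effects and the LRT p-value compares it with the no-interaction model.
    """
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    age = np.asarray(age, dtype=float)
    group, edges = _age_groups(age, bin_width)
    if len(np.unique(group)) < 2:
        raise ValueError("age range must span at least 2 bins")
    base = pd.DataFrame({"dosage": dosage, "age_group": group})
    full = base.assign(dosage_x_age=dosage * group)
    X0 = _design(base, covariates, drop_reference=False)
    X1 = _design(full, covariates, drop_reference=False)
    fit0 = sm.OLS(y, X0).fit()
    fit1 = sm.OLS(y, X1).fit()
    lrt = 2.0 * (fit1.llf - fit0.llf)
    p_int = float(chi2.sf(lrt, df=X1.shape[1] - X0.shape[1]))
    terms = pd.DataFrame({"beta": fit1.params, "se": fit1.bse, "p": fit1.pvalues})
    return InteractionResult(terms, p_int, edges, int(fit1.nobs))


def mann_whitney(copies_group1, copies_group2) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test on repeat copy numbers.

    Exact null distribution for small samples (both n <= 8), tie-corrected
    normal approximation otherwise.
    """
    a = np.asarray(copies_group1, dtype=float)
    b = np.asarray(copies_group2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if max(a.size, b.size) <= 8 else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
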