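"""Tag-SNP discovery and haplotype-based VNTR allele calling.

The Long VNTR allele cannot be genotyped directly from short reads, but it
travels on a characteristic two-SNP haplotype.  This module implements the
discovery chain — minor-allele-frequency filtering, an allele-count
chi-square screen against the Short/Short vs Long/any labels, random-forest
Gini importance ranking, and induction of the phased two-SNP haplotype ->
allele-class rule — plus the validation statistics used to check the rule
(Cohen's kappa and percent agreement, hierarchical clustering of coverage
profiles, and LD r-squared).

:class:`TagHaplotypeCaller` wraps the chain as a scikit-learn style
estimator: ``fit`` learns the SNP pair and rule, ``predict`` calls
per-sample VNTR diplotypes from a phased panel.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2_contingency
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .io import MISSING, PhasedGenotypeTable
from .repeats import AlleleClass, DiploClass

logger = logging.getLogger("repeatlens")

SHORT = AlleleClass.SHORT.value
LONG = AlleleClass.LONG.value

_HAPLOTYPES = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass
class SnpScreenResult:
    snp_id: str
    maf: float
    chi2: float
    p_value: float
    passed_maf: bool
    passed_assoc: bool


@dataclass
class ImportanceRanking:
    """SNPs ordered by random-forest mean decrease in Gini impurity."""

    ranking: list  # (snp_id, importance), descending
    selected: list  # top ceil(10%) snp ids

    def __post_init__(self) -> None:
        imps = [imp for _, imp in self.ranking]
        if any(a < b for a, b in zip(imps, imps[1:])):
            raise ValueError("ranking must be in descending importance order")


@dataclass
class HaplotypeRule:
    """Mapping from each phased two-SNP haplotype to a VNTR allele class."""

    snp_ids: tuple
    mapping: dict  # (allele1, allele2) -> "SHORT" | "LONG"

    def __post_init__(self) -> None:
        if set(self.mapping) != set(_HAPLOTYPES):
            raise ValueError("mapping must cover all four haplotypes")

    def call(self, hap: tuple[int, int]) -> str:
        return self.mapping[tuple(int(a) for a in hap)]

    def to_dict(self) -> dict:
        return {
            "snp_ids": list(self.snp_ids),
            "mapping": {f"{a}{b}": v for (a, b), v in self.mapping.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HaplotypeRule":
        mapping = {(int(k[0]), int(k[1])): v for k, v in d["mapping"].items()}
        return cls(tuple(d["snp_ids"]), mapping)


@dataclass
class AgreementStats:
    kappa: float
    agreement: float
    confusion: pd.DataFrame


# ---------------------------------------------------------------------------
# screening and ranking


def screen_snps(
    panel: PhasedGenotypeTable,
    labels,
    maf_min: float = 0.05,
    alpha: float = 0.05,
) -> list[SnpScreenResult]:
    """MAF filter plus a 2x2 allele-count chi-square test against the labels.

    Each sample contributes two alleles; the contingency table crosses
    allele (0/1) with the sample-level Short/Short vs Long/any label.
    Monomorphic SNPs are excluded regardless of association.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != panel.n_samples:
        raise ValueError("labels length must match panel samples")
    is_pos = labels == DiploClass.LONG_ANY.value
    results = []
    for j in range(panel.n_variants):
        alleles = panel.alleles[:, j, :]  # (n, 2)
        valid = alleles != MISSING
        counts_alt = np.where(valid, alleles, 0).sum(axis=1)
        n_valid = valid.sum(axis=1)
        total = n_valid.sum()
        freq = counts_alt.sum() / total if total else 0.0
        maf = min(freq, 1.0 - freq)
        snp_id = panel.variants["id"].iloc[j]
        if maf == 0.0:
            results.append(SnpScreenResult(snp_id, 0.0, float("nan"), float("nan"), False, False))
            continue
        table = np.array(
            [
                [counts_alt[is_pos].sum(), n_valid[is_pos].sum() - counts_alt[is_pos].sum()],
                [counts_alt[~is_pos].sum(), n_valid[~is_pos].sum() - counts_alt[~is_pos].sum()],
            ]
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            chi2, p = float("nan"), float("nan")
        else:
            chi2, p, _, _ = chi2_contingency(table, correction=False)
        results.append(
            SnpScreenResult(
                snp_id,
                float(maf),
                float(chi2),
                float(p),
                maf > maf_min,
                bool(p < alpha) if not math.isnan(p) else False,
            )
        )
    return results


def rank_importance(
    dosages: np.ndarray,
    snp_ids,
    labels,
    n_trees: int = 500,
    seed: int = 0,
    top_frac: float = 0.10,
) -> ImportanceRanking:
    """Random-forest Gini importance ranking of dosage-coded SNPs.

    Genotypes are coded 0/1/2; the selected set is the top
    ``ceil(top_frac * n)`` SNPs by mean decrease in Gini, at least one.
    """
    dosages = np.asarray(dosages, dtype=float)
    snp_ids = list(snp_ids)
    if dosages.shape[1] != len(snp_ids):
        raise ValueError("dosage columns must match snp_ids")
    if len(snp_ids) < 2:
        raise ValueError("need at least 2 SNPs to rank")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(np.nan_to_num(dosages), np.asarray(labels))
    order = np.argsort(forest.feature_importances_)[::-1]
    ranking = [(snp_ids[k], float(forest.feature_importances_[k])) for k in order]
    n_select = max(1, math.ceil(top_frac * len(snp_ids)))
    return ImportanceRanking(ranking, [sid for sid, _ in ranking[:n_select]])


# ---------------------------------------------------------------------------
# rule induction and application


def induce_rule(
    haplotype_pairs: np.ndarray,
    chrom_classes,
    snp_ids: tuple = ("snp1", "snp2"),
) -> HaplotypeRule:
    """Map each two-SNP haplotype to LONG iff P(Long | haplotype) > 0.5.

    ``haplotype_pairs`` is ``(n_chromosomes, 2)`` of 0/1 alleles and
    ``chrom_classes`` the matching chromosome-level SHORT/LONG truth.
    Ties and haplotypes unobserved in training map to SHORT (with a
    warning for the latter).
    """
    pairs = np.asarray(haplotype_pairs, dtype=int)
    classes = np.asarray(chrom_classes)
    if pairs.shape[0] != classes.shape[0]:
        raise ValueError("haplotype_pairs and chrom_classes length mismatch")
    is_long = classes == LONG
    mapping = {}
    for hap in _HAPLOTYPES:
        mask = (pairs[:, 0] == hap[0]) & (pairs[:, 1] == hap[1])
        if not mask.any():
            logger.warning("haplotype %s unobserved in training; mapped SHORT", hap)
            mapping[hap] = SHORT
            continue
        mapping[hap] = LONG if is_long[mask].mean() > 0.5 else SHORT
    return HaplotypeRule(tuple(snp_ids), mapping)


def assign_vntr(rule: HaplotypeRule, panel: PhasedGenotypeTable) -> pd.DataFrame:
    """Call per-sample VNTR diplotypes from the two rule SNPs.

    Phased samples are called per chromosome.  For unphased samples both
    allele orderings are evaluated; if they disagree on the diplotype class
    the sample is flagged ambiguous.  Samples missing either rule SNP get
    no call.

    Returns a DataFrame with columns ``sample, hap_a, hap_b, diplo_class,
    ambiguous``.
    """
    idx = []
    for sid in rule.snp_ids:
        j = panel.variants.index[panel.variants["id"] == sid]
        if len(j) != 1:
            raise KeyError(f"rule SNP {sid!r} not found exactly once in panel")
        idx.append(int(j[0]))
    rows = []
    for i, sample in enumerate(panel.samples):
        a = panel.alleles[i, idx[0], :]  # (hapA, hapB) at SNP1
        b = panel.alleles[i, idx[1], :]
        if MISSING in a or MISSING in b:
            rows.append((sample, None, None, None, False))
            continue
        hap_a = rule.call((a[0], b[0]))
        hap_b = rule.call((a[1], b[1]))
        diplo = _diplo_from_classes(hap_a, hap_b)
        ambiguous = False
        if not panel.phased[i]:
            swapped = _diplo_from_classes(rule.call((a[0], b[1])), rule.call((a[1], b[0])))
            if swapped != diplo:
                diplo, ambiguous = None, True
        rows.append((sample, hap_a, hap_b, diplo, ambiguous))
    return pd.DataFrame(
        rows, columns=["sample", "hap_a", "hap_b", "diplo_class", "ambiguous"]
    )


def _diplo_from_classes(c1: str, c2: str) -> str:
    if LONG in (c1, c2):
        return DiploClass.LONG_ANY.value
    return DiploClass.SHORT_SHORT.value


# ---------------------------------------------------------------------------
# validation statistics


def cluster_profiles(profiles: np.ndarray, n_clusters: int = 2) -> np.ndarray:
    """Agglomerative complete-linkage clustering on Euclidean distances.

    Returns 0-based cluster labels from cutting the dendrogram at
    ``n_clusters``.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    if np.allclose(X, X[0]):
        logger.warning("all profiles identical; cluster split is arbitrary")
    Z = linkage(X, method="complete", metric="euclidean")
    return fcluster(Z, t=n_clusters, criterion="maxclust") - 1


def kappa_agreement(a, b) -> AgreementStats:
    """Cohen's kappa and percent agreement between two categorical vectors.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginal products.
    When chance agreement p_e is 1 (both raters constant and equal) kappa
    is undefined and reported as NaN.
    """
    a = pd.Series(np.asarray(a), name="a")
    b = pd.Series(np.asarray(b), name="b")
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    confusion = pd.crosstab(a, b, dropna=False)
    cats = sorted(set(confusion.index) | set(confusion.columns))
    confusion = confusion.reindex(index=cats, columns=cats, fill_value=0)
    n = confusion.to_numpy().sum()
    p_o = np.trace(confusion.to_numpy()) / n
    row = confusion.sum(axis=1).to_numpy() / n
    col = confusion.sum(axis=0).to_numpy() / n
    p_e = float(np.dot(row, col))
    if p_e >= 1.0 - 1e-12:
        logger.warning("chance agreement is 1; kappa undefined")
        kappa = float("nan")
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementStats(float(kappa), float(p_o), confusion)


def ld_r2(x, y) -> float:
    """Squared Pearson correlation of two 0/1 chromosome-level allele vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("allele vectors must be 1-D and equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("r2 undefined for a monomorphic vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# estimator


class TagHaplotypeCaller(BaseEstimator):
    """Learn a two-SNP haplotype rule for the VNTR and call diplotypes.

    ``fit(panel, y)`` runs the discovery chain: MAF + chi-square screen,
    random-forest Gini ranking, and — among the top-ranked SNPs — selection
    of the pair whose induced haplotype rule best agrees with the
    sample-level labels.  ``predict(panel)`` applies the learned rule.

    Parameters
    ----------
    maf_min, alpha : screen thresholds (MAF > 5%, chi-square p < 0.05).
    n_trees : random-forest size for the Gini ranking.
    top_frac : fraction of ranked SNPs carried into pair selection.
    max_pair_candidates : cap on SNPs combinatorially paired.
    random_state : forest seed.

    Attributes
    ----------
    screen_ : list of :class:`SnpScreenResult`
    ranking_ : :class:`ImportanceRanking`
    rule_ : :class:`HaplotypeRule`
    train_agreement_ : sample-level agreement of the rule on training data
    """

    def __init__(
        self,
        maf_min: float = 0.05,
        alpha: float = 0.05,
        n_trees: int = 500,
        top_frac: float = 0.10,
        max_pair_candidates: int = 12,
        random_state: int = 0,
    ):
        self.maf_min = maf_min
        self.alpha = alpha
        self.n_trees = n_trees
        self.top_frac = top_frac
        self.max_pair_candidates = max_pair_candidates
        self.random_state = random_state

    def fit(self, panel: PhasedGenotypeTable, y, chrom_classes=None):
        """Learn the rule from a phased panel and Short/Short vs Long/any labels.

        ``chrom_classes`` (optional, shape ``(n, 2)``) supplies
        chromosome-level SHORT/LONG truth, e.g. from assemblies or a
        simulation.  Without it, chromosomes inherit their sample's label
        (both chromosomes of a Long/any sample provisionally LONG), which
        is adequate whenever Long carriers are a minority.
        """
        y = np.asarray(y)
        self.screen_ = screen_snps(panel, y, self.maf_min, self.alpha)
        passing = [r.snp_id for r in self.screen_ if r.passed_maf and r.passed_assoc]
        if len(passing) < 2:
            raise ValueError("fewer than 2 SNPs pass the screen")
        cols = [int(panel.variants.index[panel.variants["id"] == s][0]) for s in passing]
        dosages = panel.dosage()[:, cols]
        self.ranking_ = rank_importance(
            dosages, passing, y, n_trees=self.n_trees, seed=self.random_state,
            top_frac=self.top_frac,
        )
        if chrom_classes is None:
            chrom = np.where(y == DiploClass.LONG_ANY.value, LONG, SHORT)
            chrom_classes = np.repeat(chrom[:, None], 2, axis=1)
        chrom_flat = np.asarray(chrom_classes).reshape(-1)

        candidates = self.ranking_.selected[: self.max_pair_candidates]
        best = None
        for sid1, sid2 in itertools.combinations(candidates, 2):
            j1 = int(panel.variants.index[panel.variants["id"] == sid1][0])
            j2 = int(panel.variants.index[panel.variants["id"] == sid2][0])
            pairs = np.stack(
                [panel.alleles[:, j1, :].reshape(-1), panel.alleles[:, j2, :].reshape(-1)],
                axis=1,
            )
            ok = (pairs != MISSING).all(axis=1)
            rule = induce_rule(pairs[ok], chrom_flat[ok], snp_ids=(sid1, sid2))
            calls = assign_vntr(rule, panel)
            agree = float(np.mean(calls["diplo_class"].to_numpy() == y))
            if best is None or agree > best[0]:
                best = (agree, rule)
        self.train_agreement_, self.rule_ = best
        return self

    def predict(self, panel: PhasedGenotypeTable) -> pd.DataFrame:
        check_is_fitted(self, "rule_")
        return assign_vntr(self.rule_, panel)
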