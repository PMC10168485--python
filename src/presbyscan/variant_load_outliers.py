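"""Gene-level variant-load comparison between phenotype groups.

Per-gene allele counts are totalled per group, one group's counts are
regressed on another's, and genes whose residuals fall outside
``Q3 + 6*(Q3-Q1)`` / ``Q1 - 6*(Q3-Q1)`` are flagged as outliers.  Outlier
lists are tested for hypergeometric gene-set over-representation and can be
combined/intersected across comparisons and cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .variants import MISSING

log = logging.getLogger(__name__)

IQD_MULTIPLIER = 6.0


def count_variants_per_gene(
    consensus: np.ndarray,
    variants: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    samples: Sequence[str],
    mode: str = "alleles",
) -> pd.DataFrame:
    """Genes x groups matrix of summed qualifying variant load.

    ``mode="alleles"`` counts allele dosage (het = 1, hom_alt = 2, missing =
    0); ``mode="carriers"`` counts carriers (any alt allele = 1).  Variants
    without a gene annotation are excluded with a logged count.  ``groups``
    maps sample id -> group label; samples without a label are ignored.
    """
    if mode not in ("alleles", "carriers"):
        raise ValueError("mode must be 'alleles' or 'carriers'")
    consensus = np.atleast_2d(np.asarray(consensus))
    genes = variants["gene"]
    no_gene = genes.isna() | (genes.astype(str) == "")
    if no_gene.any():
        log.info("excluding %d variant(s) without gene annotation", int(no_gene.sum()))
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups

    dosage = np.where(consensus == MISSING, 0, consensus).astype(np.int64)
    if mode == "carriers":
        dosage = (dosage > 0).astype(np.int64)

    frame = pd.DataFrame(dosage, index=variants.index, columns=list(samples))
    frame = frame.loc[~no_gene.to_numpy()]
    gene_by_sample = frame.groupby(genes[~no_gene].to_numpy()).sum()

    labels = groups.reindex(list(samples)).dropna()
    out = {}
    for group in sorted(labels.unique()):
        members = labels.index[labels == group]
        out[group] = gene_by_sample[list(members)].sum(axis=1)
    result = pd.DataFrame(out, dtype=np.int64)
    result.index.name = "gene"
    return result


def sex_stratified_groups(
    categories: Mapping[str, str] | pd.Series, sex: Mapping[str, str] | pd.Series
) -> pd.Series:
    """Combine category and sex labels into '<category>|<sex>' group labels."""
    categories = pd.Series(dict(categories)) if not isinstance(categories, pd.Series) else categories
    sex = pd.Series(dict(sex)) if not isinstance(sex, pd.Series) else sex
    return categories.str.cat(sex.reindex(categories.index), sep="|")


@dataclass
class OutlierFit:
    predictor: str
    response: str
    slope: float
    intercept: float
    residuals: pd.Series
    q1: float
    q3: float
    iqd: float
    upper_cut: float
    lower_cut: float
    high_in_response: list = field(default_factory=list)
    high_in_predictor: list = field(default_factory=list)

    def scatter_frame(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Per-gene plotting/export data for this comparison."""
        flag = pd.Series("", index=self.residuals.index)
        flag[self.residuals > self.upper_cut] = "high_in_response"
        flag[self.residuals < self.lower_cut] = "high_in_predictor"
        return pd.DataFrame(
            {
                "x": matrix[self.predictor],
                "y": matrix[self.response],
                "residual": self.residuals,
                "flag": flag,
            }
        )


def residual_cuts(residuals: Sequence[float]) -> tuple[float, float, float, float, float]:
    """(Q1, Q3, D, lower_cut, upper_cut) with linear-interpolation quantiles.

    The outlier rule is deliberately extreme: cuts sit 6 interquartile
    distances beyond the quartiles.
    """
    r = np.asarray(residuals, dtype=float)
    q1, q3 = np.quantile(r, [0.25, 0.75])  # default linear interpolation
    iqd = q3 - q1
    return float(q1), float(q3), float(iqd), float(q1 - IQD_MULTIPLIER * iqd), float(
        q3 + IQD_MULTIPLIER * iqd
    )


def fit_outliers(
    matrix: pd.DataFrame, predictor: str, response: str
) -> OutlierFit:
    """OLS of response-group counts on predictor-group counts across genes,
    then flag genes whose residuals exceed the +/-6D quantile cuts."""
    for col in (predictor, response):
        if col not in matrix.columns:
            raise KeyError(f"group {col!r} not present in the load matrix")
    if len(matrix) < 8:
        raise ValueError("need at least 8 genes to support quartile cuts")
    x = matrix[predictor].to_numpy(dtype=float)
    y = matrix[response].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"predictor group {predictor!r} has zero variance")
    slope, intercept = np.polyfit(x, y, 1)
    residuals = pd.Series(y - (slope * x + intercept), index=matrix.index,
                          name="residual")
    q1, q3, iqd, lower, upper = residual_cuts(residuals.to_numpy())
    return OutlierFit(
        predictor=predictor,
        response=response,
        slope=float(slope),
        intercept=float(intercept),
        residuals=residuals,
        q1=q1,
        q3=q3,
        iqd=iqd,
        upper_cut=upper,
        lower_cut=lower,
        high_in_response=sorted(residuals.index[residuals > upper]),
        high_in_predictor=sorted(residuals.index[residuals < lower]),
    )


@dataclass
class EnrichmentResult:
    list_size: int
    universe_size: int
    geneset_size: int
    overlap: int
    p_raw: float
    p_adjusted: float | None = None
    adjust_method: str | None = None


def enrich_geneset(
    outlier_list: Iterable[str], universe: Iterable[str], geneset: Iterable[str]
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation test.

    The gene set is intersected with the universe before testing; the outlier
    list must be a subset of the universe.  ``p = P(X >= overlap)`` for
    ``X ~ Hypergeom(universe, geneset & universe, list)``.  Empty list -> 1.
    """
    outlier_list = set(outlier_list)
    universe = set(universe)
    if not outlier_list <= universe:
        raise ValueError("outlier list must be a subset of the universe")
    gs = set(geneset) & universe
    overlap = len(outlier_list & gs)
    if not outlier_list:
        p = 1.0
    else:
        p = float(hypergeom.sf(overlap - 1, len(universe), len(gs), len(outlier_list)))
    return EnrichmentResult(
        list_size=len(outlier_list),
        universe_size=len(universe),
        geneset_size=len(gs),
        overlap=overlap,
        p_raw=min(p, 1.0),
    )


def adjust_enrichment(
    results: Sequence[EnrichmentResult], method: str = "bonferroni"
) -> list[EnrichmentResult]:
    """Adjust raw p-values across all tests in one run (default Bonferroni)."""
    n = len(results)
    if method == "bonferroni":
        adjusted = [min(1.0, r.p_raw * n) for r in results]
    elif method == "bh":
        order = np.argsort([r.p_raw for r in results])
        adjusted = [None] * n
        prev = 1.0
        for rank, idx in reversed(list(enumerate(order, start=1))):
            prev = min(prev, results[idx].p_raw * n / rank)
            adjusted[idx] = prev
    elif method == "none":
        adjusted = [r.p_raw for r in results]
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    for r, p in zip(results, adjusted):
        r.p_adjusted = float(p)
        r.adjust_method = method
    return list(results)


def combine_and_intersect(lists: Mapping[str, Iterable[str]]) -> dict:
    """Union the lists and count every intersection region (Venn-style).

    Returns ``{"combined": sorted union, "regions": {frozenset(names):
    count}, "common_to_all": sorted genes in every list}``.  Region counts
    are exclusive: a gene counts toward the exact subset of lists containing
    it.
    """
    sets = {name: set(genes) for name, genes in lists.items()}
    union = set().union(*sets.values()) if sets else set()
    regions = {}
    names = list(sets)
    for r in range(1, len(names) + 1):
        for subset in combinations(names, r):
            inside = set(union)
            for name in subset:
                inside &= sets[name]
            for name in set(names) - set(subset):
                inside -= sets[name]
            regions[frozenset(subset)] = len(inside)
    common = sorted(set.intersection(*sets.values())) if sets else []
    return {
        "combined": sorted(union),
        "regions": regions,
        "common_to_all": common,
    }


def annotate_membership(
    genes: Iterable[str], genesets: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Boolean membership table of genes against named gene sets."""
    genes = sorted(set(genes))
    return pd.DataFrame(
        {name: [g in set(gs) for g in genes] for name, gs in genesets.items()},
        index=pd.Index(genes, name="gene"),
    )
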