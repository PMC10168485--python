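"""Multi-caller genotype consensus and variant-level QC filters.

The filters mirror a combination rule tuned by resequencing: a variant is
retained when its best caller evidence is jointly supported (top-tranche
GATK pass plus at least one of BCFtools/Freebayes, or second-tranche with
BCFtools support), per-sample genotypes are merged by majority vote, and
variants showing heterozygote excess, anomalously high cohort allele
frequency, low predicted impact or high catalogue frequency are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .variants import HET, HOM_ALT, HOM_REF, MISSING, MultiCallerVariantTable

QC_FLAG_ORDER = ("fail_combination", "excess_het", "af_anomaly", "low_impact", "common")


# ---------------------------------------------------------------------------
# combination filter


def variant_combination_filter(variants: pd.DataFrame) -> pd.Series:
    """Keep/drop mask over the variant table.

    Keep iff (tranche T1 AND gatk pass AND (bcftools OR freebayes pass))
    OR (tranche T2 AND bcftools pass).  A variant with no usable GATK record
    (tranche outside T1/T2) is dropped: GATK evidence anchors both branches.
    """
    tranche = variants["tranche"].astype(str)
    t1 = (
        (tranche == "T1")
        & variants["gatk_pass"].astype(bool)
        & (variants["bcftools_pass"].astype(bool)
           | variants["freebayes_pass"].astype(bool))
    )
    t2 = (tranche == "T2") & variants["bcftools_pass"].astype(bool)
    return (t1 | t2).rename("keep")


# ---------------------------------------------------------------------------
# genotype consensus


def merge_caller_genotypes(calls: np.ndarray) -> np.ndarray:
    """Merge (n_variants, n_samples, 3) caller calls into consensus genotypes.

    Unanimous or 2-vs-1 -> majority; the three distinct non-missing states
    -> heterozygote; anything involving a missing call -> missing.  Symmetric
    in caller order by construction.
    """
    calls = np.asarray(calls, dtype=np.int8)
    if calls.ndim == 2:  # single variant convenience
        calls = calls[None, :, :]
        squeeze = True
    else:
        squeeze = False
    a, b, c = calls[..., 0], calls[..., 1], calls[..., 2]
    any_missing = (calls == MISSING).any(axis=-1)

    out = np.full(a.shape, MISSING, dtype=np.int8)
    # all three distinct non-missing must be {hom_ref, het, hom_alt} -> het
    distinct = (a != b) & (b != c) & (a != c)
    out[distinct] = HET
    pair_ab = a == b
    pair_ac = a == c
    pair_bc = b == c
    out[pair_bc] = b[pair_bc]
    out[pair_ac] = a[pair_ac]
    out[pair_ab] = a[pair_ab]
    out[any_missing] = MISSING
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# excess heterozygosity (one-sided exact Hardy-Weinberg test)


def het_excess_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact one-sided p-value for heterozygote *excess* under HWE.

    Uses the conditional (Levene-Haldane) distribution of the heterozygote
    count given the allele counts; p = P(het >= observed).  Monomorphic
    variants return 1.0 (test undefined, treated as no excess).
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n - n_alt
    if n == 0 or n_alt == 0 or n_ref == 0:
        return 1.0
    rare = min(n_alt, n_ref)
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = (
        hets * np.log(2.0)
        - gammaln((n_alt - hets) / 2.0 + 1)
        - gammaln(hets + 1.0)
        - gammaln((n_ref - hets) / 2.0 + 1)
    )
    logp -= logsumexp(logp)
    return float(np.exp(logsumexp(logp[hets >= n_het])))


def excess_het_filter(
    consensus: np.ndarray, alpha: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant keep mask and p-values for heterozygote excess.

    ``consensus`` is (n_variants, n_samples).  Default alpha is Bonferroni
    0.05 / n_variants.
    """
    consensus = np.atleast_2d(consensus)
    nv = consensus.shape[0]
    if alpha is None:
        alpha = 0.05 / max(nv, 1)
    pvals = np.array([
        het_excess_pvalue(
            int((row == HOM_REF).sum()),
            int((row == HET).sum()),
            int((row == HOM_ALT).sum()),
        )
        for row in consensus
    ])
    return pvals >= alpha, pvals


# ---------------------------------------------------------------------------
# simple per-record filters


def cohort_allele_frequency(consensus: np.ndarray) -> np.ndarray:
    """Alternate-allele frequency per variant over non-missing genotypes."""
    consensus = np.atleast_2d(consensus)
    called = consensus != MISSING
    alt = np.where(called, consensus, 0).sum(axis=1)
    denom = 2 * called.sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, alt / np.maximum(denom, 1), np.nan)


def cohort_af_filter(cohort_af, reference_maf, margin: float = 0.4):
    """Keep unless cohort AF exceeds catalogue MAF + margin (strict >)."""
    cohort_af = np.asarray(cohort_af, dtype=float)
    reference_maf = np.nan_to_num(np.asarray(reference_maf, dtype=float))
    return ~(cohort_af > reference_maf + margin)


def impact_maf_filter(impact, reference_maf, maf_cut: float = 0.1):
    """Keep iff predicted impact is high AND catalogue MAF < maf_cut (strict)."""
    impact = np.asarray(impact, dtype=object)
    reference_maf = np.nan_to_num(np.asarray(reference_maf, dtype=float))
    return (impact == "high") & (reference_maf < maf_cut)


def mito_genotype(
    vaf: float,
    depth: int,
    min_depth: int = 30,
    homoplasmy_vaf: float = 0.95,
    het_floor: float = 0.40,
) -> int:
    """Mitochondrial call from variant allele fraction and depth.

    Homoplasmic (VAF > 0.95) -> hom_alt; heteroplasmic (het_floor <= VAF
    <= 0.95) -> het; below the reliable heteroplasmy detection floor or below
    the depth minimum -> missing.
    """
    if depth < min_depth:
        return MISSING
    if vaf > homoplasmy_vaf:
        return HOM_ALT
    if vaf >= het_floor:
        return HET
    return MISSING


# ---------------------------------------------------------------------------
# composed QC


@dataclass
class QCResult:
    consensus: np.ndarray          # (n_kept, n_samples) consensus genotypes
    kept: pd.DataFrame             # variant metadata of retained records
    flags: pd.DataFrame            # per-input-variant boolean flag matrix
    drop_log: dict = field(default_factory=dict)

    @property
    def kept_ids(self) -> pd.Index:
        return self.kept.index


def apply_qc(
    table: MultiCallerVariantTable,
    het_alpha: float | None = None,
    af_margin: float = 0.4,
    maf_cut: float = 0.1,
    require_high_impact: bool = True,
) -> QCResult:
    """Run the full variant QC chain and return consensus genotypes.

    Each filter reads only immutable record fields plus the consensus
    genotypes, so the keep/drop outcome is order-independent; the drop log
    attributes each dropped variant to the first failing flag in
    :data:`QC_FLAG_ORDER` and asserts count conservation.
    """
    variants = table.variants
    nv = len(variants)
    consensus_all = merge_caller_genotypes(table.calls) if nv else \
        np.empty((0, len(table.samples)), dtype=np.int8)

    keep_comb = variant_combination_filter(variants).to_numpy() if nv else \
        np.empty(0, dtype=bool)
    # excess-het alpha is Bonferroni over the variants actually tested
    n_testable = int(keep_comb.sum())
    alpha = het_alpha if het_alpha is not None else 0.05 / max(n_testable, 1)
    keep_het, het_p = excess_het_filter(consensus_all, alpha=alpha) if nv else \
        (np.empty(0, dtype=bool), np.empty(0))

    cohort_af = cohort_allele_frequency(consensus_all) if nv else np.empty(0)
    ref_maf = variants["maf"].to_numpy(dtype=float) if nv else np.empty(0)
    keep_af = cohort_af_filter(cohort_af, ref_maf, margin=af_margin)
    impact = variants["impact"].to_numpy(dtype=object) if nv else np.empty(0, dtype=object)
    high = impact == "high"
    rare = np.nan_to_num(ref_maf) < maf_cut

    flags = pd.DataFrame(
        {
            "fail_combination": ~keep_comb,
            "excess_het": ~keep_het,
            "af_anomaly": ~keep_af,
            "low_impact": ~high if require_high_impact else np.zeros(nv, dtype=bool),
            "common": ~rare,
        },
        index=variants.index,
    )
    keep = ~flags.any(axis=1).to_numpy() if nv else np.empty(0, dtype=bool)

    drop_log = {"n_input": nv, "n_kept": int(keep.sum())}
    remaining = ~keep
    for flag in QC_FLAG_ORDER:
        first_reason = remaining & flags[flag].to_numpy() if nv else np.empty(0, bool)
        drop_log[flag] = int(first_reason.sum())
        remaining = remaining & ~flags[flag].to_numpy() if nv else remaining
    assert drop_log["n_input"] == drop_log["n_kept"] + sum(
        drop_log[f] for f in QC_FLAG_ORDER
    ), "QC drop accounting is not conserved"

    kept = variants.loc[keep].copy()
    kept["cohort_af"] = cohort_af[keep]
    kept["het_excess_p"] = het_p[keep]
    return QCResult(
        consensus=consensus_all[keep],
        kept=kept,
        flags=flags,
        drop_log=drop_log,
    )
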