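"""Per-variant audiometric threshold-difference scan with permutation testing.

For every variant, alternate-genotype carrier groups (het / hom_alt, within
all / male / female strata) are compared against the sex-matched homozygous
reference group.  A stimulus frequency passes when the group mean differs by
at least ``diff_min`` dB and the alternate group's SD is under a
frequency-banded cap; variants with two or more passing frequencies in each
ear become candidates and go to permutation testing: carriers are reassigned
at random (preserving group size and sex composition) and the variant is
rejected when more than ``reject_above`` of ``n_perm`` shufflings reproduce
the candidate criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .variants import HET, HOM_ALT, HOM_REF

CONTRASTS = ("all", "male", "female")
DECISIONS = ("not_candidate", "candidate_rejected", "detected")


@dataclass(frozen=True)
class ScanCriteria:
    """Constants of the scan; defaults are the published procedure's values."""

    min_group: int = 5
    diff_min: float = 20.0
    #: (upper frequency bound kHz inclusive, SD cap dB), ascending
    sd_caps: tuple = ((0.5, 15.0), (2.0, 20.0), (4.0, 25.0), (float("inf"), 30.0))
    min_passing_freqs: int = 2
    n_perm: int = 20_000
    reject_above: int = 1_000

    def __post_init__(self):
        if self.min_group < 1 or self.diff_min <= 0 or self.min_passing_freqs < 1:
            raise ValueError("scan criteria must be positive")
        if not 0 < self.reject_above < self.n_perm:
            raise ValueError("reject_above must lie in (0, n_perm)")

    def sd_cap(self, freq_khz: float) -> float:
        for bound, cap in self.sd_caps:
            if freq_khz <= bound:
                return cap
        raise ValueError(f"no SD cap covers frequency {freq_khz} kHz")

    def caps_for_grid(self, grid: Sequence[float]) -> np.ndarray:
        return np.array([self.sd_cap(f) for f in grid])


@dataclass
class ContrastGroup:
    variant_id: str
    contrast: str       # all | male | female
    genotype: str       # het | hom_alt | carrier
    members: np.ndarray     # participant indices of the alternate group
    reference: np.ndarray   # matched hom_ref participant indices

    def __post_init__(self):
        if np.intersect1d(self.members, self.reference).size:
            raise ValueError("alternate and reference groups overlap")


@dataclass
class ScanResult:
    group: ContrastGroup
    pass_mask: np.ndarray       # (2, n_freqs)
    mean_diff: np.ndarray       # (2, n_freqs) mean_alt - mean_ref
    candidate: bool
    similar_count: int | None = None
    decision: str = "not_candidate"
    direction: str = ""


def threshold_array(audiograms: pd.DataFrame, participant_order: Sequence[str]) -> np.ndarray:
    """Audiogram frame -> dense (n_participants, 2 ears, n_freqs) array (NaN pad)."""
    idx = pd.MultiIndex.from_product([list(participant_order), ["L", "R"]])
    arr = audiograms.reindex(idx).to_numpy(dtype=float)
    return arr.reshape(len(participant_order), 2, audiograms.shape[1])


def build_groups(
    genotypes: np.ndarray,
    sex: np.ndarray,
    criteria: ScanCriteria,
    variant_id: str = "",
    pooled: bool = False,
) -> list[ContrastGroup]:
    """Evaluable alternate-allele groups for one variant.

    Up to six groups (het/hom_alt x all/male/female); groups smaller than
    ``min_group`` are skipped.  Returns an empty list when no group is
    evaluable (the variant is then excluded from scanning).  ``pooled``
    merges het and hom_alt carriers into a single group.
    """
    genotypes = np.asarray(genotypes)
    sex = np.asarray(sex)
    geno_masks = (
        {"carrier": genotypes >= HET}
        if pooled
        else {"het": genotypes == HET, "hom_alt": genotypes == HOM_ALT}
    )
    ref_mask = genotypes == HOM_REF
    contrast_masks = {
        "all": np.ones(len(genotypes), dtype=bool),
        "male": sex == "M",
        "female": sex == "F",
    }
    groups = []
    for geno, gmask in geno_masks.items():
        for contrast, cmask in contrast_masks.items():
            members = np.nonzero(gmask & cmask)[0]
            if len(members) < criteria.min_group:
                continue
            reference = np.nonzero(ref_mask & cmask)[0]
            groups.append(ContrastGroup(variant_id, contrast, geno, members, reference))
    return groups


def _group_stats(thr: np.ndarray, idx: np.ndarray):
    sub = thr[idx]  # (k, 2, nf)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(sub, axis=0)
        count = np.isfinite(sub).sum(axis=0)
        sd = np.full(mean.shape, np.nan)
        enough = count > 1
        if enough.any():
            sd_all = np.nanstd(sub, axis=0, ddof=1)
            sd[enough] = sd_all[enough]
    return mean, sd, count


def frequency_pass(
    thr: np.ndarray,
    group: ContrastGroup,
    grid: Sequence[float],
    criteria: ScanCriteria,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-ear, per-frequency pass mask and mean difference for a group.

    Frequency f passes in ear e iff |mean_alt - mean_ref| >= diff_min AND the
    alternate group's sample SD (n-1 denominator) <= the frequency band's
    cap.  The SD cap applies to the alternate group only.  Missing thresholds
    are excluded pairwise per frequency.
    """
    caps = criteria.caps_for_grid(grid)
    mean_alt, sd_alt, _ = _group_stats(thr, group.members)
    mean_ref, _, _ = _group_stats(thr, group.reference)
    mean_diff = mean_alt - mean_ref
    with np.errstate(invalid="ignore"):
        pass_mask = (
            (np.abs(mean_diff) >= criteria.diff_min)
            & (sd_alt <= caps[None, :])
            & np.isfinite(mean_diff)
        )
    return pass_mask, mean_diff


def candidate_filter(pass_mask: np.ndarray, criteria: ScanCriteria) -> bool:
    """Candidate iff at least ``min_passing_freqs`` frequencies pass in each ear."""
    per_ear = pass_mask.sum(axis=1)
    return bool((per_ear >= criteria.min_passing_freqs).all())


def decide(similar_count: int, criteria: ScanCriteria) -> str:
    """Rejected iff strictly more than ``reject_above`` shufflings were similar."""
    return "candidate_rejected" if similar_count > criteria.reject_above else "detected"


def permutation_test(
    thr: np.ndarray,
    group: ContrastGroup,
    sex: np.ndarray,
    grid: Sequence[float],
    criteria: ScanCriteria,
    rng: np.random.Generator,
    check_composition: bool = False,
) -> tuple[int, str]:
    """Count permutations reproducing the candidate criterion.

    Pseudo-alternate groups of identical size and sex composition are drawn
    from the alternate + reference pool; a permutation is *similar* when it
    satisfies the candidate criterion under the same diff/SD rules.  Returns
    ``(similar_count, decision)``.
    """
    pool = np.concatenate([group.members, group.reference])
    sex = np.asarray(sex)
    k_total = len(group.members)
    if len(pool) <= k_total:
        raise ValueError("permutation pool smaller than the group")

    nf = len(grid)
    F = 2 * nf
    T = thr[pool].reshape(len(pool), F)
    valid = np.isfinite(T)
    T0 = np.where(valid, T, 0.0)
    tot_sum = T0.sum(axis=0)
    tot_cnt = valid.sum(axis=0)
    tot_sumsq = (T0**2).sum(axis=0)
    caps = np.tile(criteria.caps_for_grid(grid), 2)

    # strata: preserve the member sex composition exactly
    pool_sex = sex[pool]
    member_sex = sex[group.members]
    strata = []
    for sx in np.unique(pool_sex):
        positions = np.nonzero(pool_sex == sx)[0]
        k_s = int((member_sex == sx).sum())
        if k_s > len(positions):
            raise ValueError("stratum pool smaller than the group's sex count")
        strata.append((sx, positions, k_s))

    similar = 0
    n_perm = criteria.n_perm
    chunk = max(64, min(n_perm, int(2_000_000 // max(k_total * F, 1))))
    done = 0
    first = True
    while done < n_perm:
        b = min(chunk, n_perm - done)
        g_sum = np.zeros((b, F))
        g_cnt = np.zeros((b, F), dtype=np.int64)
        g_sumsq = np.zeros((b, F))
        chosen = [] if (check_composition and first) else None
        for sx, positions, k_s in strata:
            if k_s == 0:
                continue
            r = rng.random((b, len(positions)))
            pick = np.argpartition(r, k_s - 1, axis=1)[:, :k_s]
            sel = positions[pick]  # (b, k_s) positions into pool
            g_sum += T0[sel].sum(axis=1)
            g_cnt += valid[sel].sum(axis=1)
            g_sumsq += (T0[sel] ** 2).sum(axis=1)
            if chosen is not None:
                assert (sex[pool[sel]] == sx).all(), "sex composition violated"
                chosen.append(sel)
        if chosen is not None:
            sizes = {len(np.unique(np.concatenate([c[i] for c in chosen])))
                     for i in range(min(b, 8))}
            assert sizes == {k_total}, "group size not preserved"
            first = False

        with np.errstate(invalid="ignore", divide="ignore"):
            mean_alt = np.where(g_cnt > 0, g_sum / np.maximum(g_cnt, 1), np.nan)
            var = np.where(
                g_cnt > 1,
                (g_sumsq - g_sum**2 / np.maximum(g_cnt, 1)) / np.maximum(g_cnt - 1, 1),
                np.nan,
            )
            sd_alt = np.sqrt(np.maximum(var, 0.0))
            ref_cnt = tot_cnt[None, :] - g_cnt
            mean_ref = np.where(
                ref_cnt > 0, (tot_sum[None, :] - g_sum) / np.maximum(ref_cnt, 1), np.nan
            )
            diff = mean_alt - mean_ref
            pass_mask = (
                (np.abs(diff) >= criteria.diff_min)
                & (sd_alt <= caps[None, :])
                & np.isfinite(diff)
            )
        per_ear = pass_mask.reshape(b, 2, nf).sum(axis=2)
        similar += int((per_ear >= criteria.min_passing_freqs).all(axis=1).sum())
        done += b

    return similar, decide(similar, criteria)


def direction_label(mean_diff: np.ndarray, pass_mask: np.ndarray) -> str:
    """'better' iff the average passing difference is negative (lower dB HL);
    ties break toward 'worse'."""
    d = float(np.mean(mean_diff[pass_mask]))
    return "better" if d < 0 else "worse"


def scan_cohort(
    consensus: np.ndarray,
    variants: pd.DataFrame,
    audiograms: pd.DataFrame,
    metadata: pd.DataFrame,
    criteria: ScanCriteria = ScanCriteria(),
    seed: int = 0,
    pooled: bool = False,
) -> pd.DataFrame:
    """Scan every variant; returns one row per evaluable contrast group.

    Columns: variant_id, gene, contrast, genotype, n_alt, n_ref, passing_L,
    passing_R, candidate, similar_count, decision, direction.  Deterministic
    for a fixed seed (per-group child RNG streams).
    """
    consensus = np.atleast_2d(consensus)
    order = list(metadata.index)
    thr = threshold_array(audiograms, order)
    grid = [float(c) for c in audiograms.columns]
    sex = metadata["sex"].to_numpy()

    rows = []
    for vi, vid in enumerate(variants.index):
        groups = build_groups(consensus[vi], sex, criteria, str(vid), pooled=pooled)
        for gi, group in enumerate(groups):
            pass_mask, mean_diff = frequency_pass(thr, group, grid, criteria)
            cand = candidate_filter(pass_mask, criteria)
            similar, decision, direction = None, "not_candidate", ""
            if cand:
                rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(vi, gi))
                )
                similar, decision = permutation_test(
                    thr, group, sex, grid, criteria, rng
                )
                if decision == "detected":
                    direction = direction_label(mean_diff, pass_mask)
            rows.append(
                {
                    "variant_id": str(vid),
                    "gene": variants["gene"].iloc[vi] if "gene" in variants else "",
                    "contrast": group.contrast,
                    "genotype": group.genotype,
                    "n_alt": len(group.members),
                    "n_ref": len(group.reference),
                    "passing_L": int(pass_mask[0].sum()),
                    "passing_R": int(pass_mask[1].sum()),
                    "candidate": cand,
                    "similar_count": similar,
                    "decision": decision,
                    "direction": direction,
                }
            )
    columns = ["variant_id", "gene", "contrast", "genotype", "n_alt", "n_ref",
               "passing_L", "passing_R", "candidate", "similar_count",
               "decision", "direction"]
    result = pd.DataFrame(rows, columns=columns)
    result.attrs["grid"] = grid
    return result


def replicate_in_second_cohort(
    detected: pd.DataFrame,
    consensus2: np.ndarray,
    variants2: pd.DataFrame,
    audiograms2: pd.DataFrame,
    metadata2: pd.DataFrame,
    criteria: ScanCriteria = ScanCriteria(),
    seed: int = 0,
) -> pd.DataFrame:
    """Follow up detected variants in a second cohort.

    Per detected (variant, contrast, genotype): status is ``absent`` when the
    variant or carriers are missing from cohort 2, ``not_comparable`` when
    the affected sex stratum is absent there, otherwise ``similar`` /
    ``different`` by whether the average carrier-vs-reference difference over
    the shared frequency grid has the same sign as in cohort 1.  The full
    scan decision on cohort 2 is reported alongside.
    """
    consensus2 = np.atleast_2d(consensus2)
    # mean comparisons use the intersection of the two cohorts' grids
    grid1 = set(float(f) for f in detected.attrs.get("grid", audiograms2.columns))
    shared_cols = [c for c in audiograms2.columns if float(c) in grid1]
    if not shared_cols:
        raise ValueError("the two cohorts share no audiogram frequencies")
    audiograms2 = audiograms2[shared_cols]
    order2 = list(metadata2.index)
    thr2 = threshold_array(audiograms2, order2)
    grid2 = [float(c) for c in audiograms2.columns]
    sex2 = metadata2["sex"].to_numpy()
    sexes_present = set(sex2)
    vid_to_row = {str(v): i for i, v in enumerate(variants2.index)}

    out = []
    hits = detected[detected["decision"] == "detected"]
    for _, row in hits.iterrows():
        rec = {
            "variant_id": row["variant_id"],
            "contrast": row["contrast"],
            "genotype": row["genotype"],
            "n_carriers_2": 0,
            "status": "",
            "cohort2_decision": "",
        }
        vi = vid_to_row.get(row["variant_id"])
        if vi is None:
            rec["status"] = "absent"
            out.append(rec)
            continue
        needed_sex = {"male": "M", "female": "F"}.get(row["contrast"])
        if needed_sex is not None and needed_sex not in sexes_present:
            rec["status"] = "not_comparable"
            out.append(rec)
            continue
        gt2 = consensus2[vi]
        if row["genotype"] == "carrier":
            gmask = gt2 >= HET
        elif row["genotype"] == "het":
            gmask = gt2 == HET
        else:
            gmask = gt2 == HOM_ALT
        cmask = np.ones(len(gt2), dtype=bool) if needed_sex is None else sex2 == needed_sex
        members = np.nonzero(gmask & cmask)[0]
        rec["n_carriers_2"] = int(len(members))
        if len(members) == 0:
            rec["status"] = "absent"
            out.append(rec)
            continue
        reference = np.nonzero((gt2 == HOM_REF) & cmask)[0]
        group2 = ContrastGroup(row["variant_id"], row["contrast"], row["genotype"],
                               members, reference)
        _, mean_diff2 = frequency_pass(thr2, group2, grid2, criteria)
        avg2 = float(np.nanmean(mean_diff2))
        expect_better = row["direction"] == "better"
        rec["status"] = "similar" if (avg2 < 0) == expect_better else "different"
        if len(members) >= criteria.min_group:
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(vi,)))
            pm2, _ = frequency_pass(thr2, group2, grid2, criteria)
            if candidate_filter(pm2, criteria):
                _, rec["cohort2_decision"] = permutation_test(
                    thr2, group2, sex2, grid2, criteria, rng
                )
            else:
                rec["cohort2_decision"] = "not_candidate"
        out.append(rec)
    return pd.DataFrame(
        out, columns=["variant_id", "contrast", "genotype", "n_carriers_2",
                      "status", "cohort2_decision"]
    )
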