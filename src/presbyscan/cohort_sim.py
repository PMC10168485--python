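"""Synthetic cohort generator.

Produces participants with two-ear audiograms composed of scaled canonical
metabolic and sensory shapes plus Gaussian noise, multi-caller genotype
tables with configurable caller disagreement, and planted carrier threshold
shifts — everything the downstream stages need, with full ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import audiogram_phenotype as ap
from ._utils import as_float_array, float_repr
from .variants import CALLERS, MISSING, MultiCallerVariantTable, VARIANT_COLUMNS

CATEGORY_KEYS = ("OlderNormal", "Metabolic", "Sensory", "Unclassified")

#: (m, s) uniform sampling ranges per planted category, in dB.  Chosen so the
#: classification rules hold in the noiseless limit with a comfortable margin.
DEFAULT_COMPONENT_RANGES = {
    "OlderNormal": ((0.0, 6.0), (0.0, 6.0)),
    "Metabolic": ((25.0, 35.0), (2.0, 12.0)),
    "Sensory": ((2.0, 14.0), (25.0, 40.0)),
    "Unclassified": ((26.0, 36.0), (20.0, 25.0)),
}

THRESHOLD_FLOOR = -10.0  # dB HL


@dataclass(frozen=True)
class PlantedEffect:
    """A variant whose carriers get a threshold shift added to both ears."""

    variant_index: int
    shift: object  # scalar dB or per-frequency vector
    sex: str = "both"  # "both" | "M" | "F"
    maf: float | None = None  # force this variant's allele frequency

    def shift_vector(self, n_freqs: int) -> np.ndarray:
        arr = np.asarray(self.shift, dtype=float)
        if arr.ndim == 0:
            return np.full(n_freqs, float(arr))
        if len(arr) != n_freqs:
            raise ValueError("planted shift vector does not match the frequency grid")
        return arr


@dataclass
class SimConfig:
    n_participants: int = 200
    sex_ratio: float = 0.55  # fraction female
    frequency_grid: Sequence[float] = ap.DEFAULT_GRID
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "OlderNormal": 0.20, "Metabolic": 0.30, "Sensory": 0.30,
            "Unclassified": 0.20,
        }
    )
    metabolic_profile: Sequence[float] | None = None
    sensory_profile: Sequence[float] | None = None
    threshold_noise_sd: float = 3.0
    n_variants: int = 100
    maf_range: tuple = (0.01, 0.3)
    planted_effects: Sequence[PlantedEffect] = ()
    caller_disagreement_rate: float = 0.0
    seed: int = 0
    # secondary knobs (reporting realism / QC plumbing)
    age_range: tuple = (55.0, 85.0)
    noise_history_rates: Mapping[str, float] = field(
        default_factory=lambda: {"M": 0.79, "F": 0.21}
    )
    component_ranges: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_RANGES)
    )
    n_genes: int | None = None
    impact_high_fraction: float = 1.0
    tranche_probs: tuple = (0.94, 0.05, 0.01)
    caller_fail_rate: float = 0.0

    def __post_init__(self):
        grid = as_float_array(self.frequency_grid, "frequency_grid")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("frequency_grid must be strictly increasing")
        self.frequency_grid = tuple(grid)
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError("category_mix proportions must sum to 1")
        if set(self.category_mix) - set(CATEGORY_KEYS):
            raise ValueError(f"category_mix keys must be among {CATEGORY_KEYS}")
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within [0, 0.5]")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.threshold_noise_sd < 0:
            raise ValueError("threshold_noise_sd must be non-negative")
        if not 0.0 <= self.caller_disagreement_rate <= 1.0:
            raise ValueError("caller_disagreement_rate must be in [0, 1]")
        for prof, name in ((self.metabolic_profile, "metabolic_profile"),
                           (self.sensory_profile, "sensory_profile")):
            if prof is not None:
                arr = as_float_array(prof, name)
                if len(arr) != len(self.frequency_grid):
                    raise ValueError(f"{name} length does not match frequency_grid")
                if np.any(arr < 0):
                    raise ValueError(f"{name} must be non-negative")

    def basis(self) -> ap.ProfileBasis:
        if self.metabolic_profile is None and self.sensory_profile is None:
            return ap.default_basis(self.frequency_grid)
        default = ap.default_basis(self.frequency_grid)
        return ap.ProfileBasis(
            grid=np.asarray(self.frequency_grid, dtype=float),
            metabolic=(default.metabolic if self.metabolic_profile is None
                       else np.asarray(self.metabolic_profile, dtype=float)),
            sensory=(default.sensory if self.sensory_profile is None
                     else np.asarray(self.sensory_profile, dtype=float)),
        )


@dataclass
class SyntheticCohort:
    participants: pd.DataFrame  # index participant_id: sex, age, noise_history
    audiograms: pd.DataFrame    # index (participant_id, ear) x grid columns
    genotypes: MultiCallerVariantTable
    truth: dict

    def equals(self, other: "SyntheticCohort") -> bool:
        return (
            self.participants.equals(other.participants)
            and self.audiograms.equals(other.audiograms)
            and self.genotypes.equals(other.genotypes)
            and json.dumps(self.truth, sort_keys=True)
            == json.dumps(other.truth, sort_keys=True)
        )


def _rng_for(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def simulate_audiograms(config: SimConfig) -> SyntheticCohort:
    """Generate participants and their two-ear audiograms (no genotypes yet).

    Per ear, ``thresholds = m*M(f) + s*S(f) + N(0, noise_sd)``, truncated
    below at -10 dB HL, with ``(m, s)`` drawn per the planted category.
    """
    rng = _rng_for(config, 0)
    n = config.n_participants
    grid = np.asarray(config.frequency_grid)
    basis = config.basis()

    width = max(4, len(str(max(n, 1))))
    pids = [f"P{i:0{width}d}" for i in range(n)]
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    age = rng.uniform(*config.age_range, size=n)
    noise_rate = np.array([config.noise_history_rates[sx] for sx in sex])
    noise_history = (rng.random(n) < noise_rate).astype(int)

    cats = list(config.category_mix)
    probs = np.array([config.category_mix[c] for c in cats])
    categories = rng.choice(cats, size=n, p=probs) if n else np.array([], dtype=object)

    m = np.empty(n)
    s = np.empty(n)
    for cat in cats:
        mask = categories == cat
        (m_lo, m_hi), (s_lo, s_hi) = config.component_ranges[cat]
        m[mask] = rng.uniform(m_lo, m_hi, size=mask.sum())
        s[mask] = rng.uniform(s_lo, s_hi, size=mask.sum())

    clean = m[:, None] * basis.metabolic + s[:, None] * basis.sensory  # (n, nf)
    thresholds = np.empty((n, 2, len(grid)))
    for ei in range(2):
        noise = rng.normal(0.0, config.threshold_noise_sd, size=(n, len(grid))) \
            if config.threshold_noise_sd > 0 else 0.0
        thresholds[:, ei, :] = np.maximum(clean + noise, THRESHOLD_FLOOR)

    participants = pd.DataFrame(
        {"sex": sex, "age": age, "noise_history": noise_history}, index=pd.Index(pids, name="participant_id")
    )
    idx = pd.MultiIndex.from_product([pids, ["L", "R"]],
                                     names=["participant_id", "ear"])
    audiograms = pd.DataFrame(
        thresholds.reshape(n * 2, len(grid)), index=idx, columns=grid
    )
    truth = {
        "seed": config.seed,
        "categories": dict(zip(pids, categories.tolist())),
        "components": {
            pid: {"L": [m[i], s[i]], "R": [m[i], s[i]]} for i, pid in enumerate(pids)
        },
        "effect_variants": [],
    }
    empty = pd.DataFrame(columns=VARIANT_COLUMNS)
    empty.index.name = "variant_id"
    genotypes = MultiCallerVariantTable(
        variants=empty, samples=list(pids),
        calls=np.empty((0, n, 3), dtype=np.int8),
    )
    return SyntheticCohort(participants, audiograms, genotypes, truth)


def simulate_genotypes(
    config: SimConfig, participants: pd.DataFrame
) -> MultiCallerVariantTable:
    """Draw genotypes as Binomial(2, MAF) and replicate them across callers.

    At ``caller_disagreement_rate``, one caller (chosen uniformly) has its
    call replaced by one of the two other non-missing genotype states chosen
    uniformly; majority consensus therefore still recovers the truth.
    """
    rng = _rng_for(config, 1)
    nv, ns = config.n_variants, len(participants)
    # 6 dp keeps the TSV round-trip lossless
    mafs = np.round(rng.uniform(*config.maf_range, size=nv), 6)
    for eff in config.planted_effects:
        if not 0 <= eff.variant_index < nv:
            raise ValueError("planted effect variant_index out of range")
        if eff.maf is not None:
            mafs[eff.variant_index] = eff.maf

    dosage = rng.binomial(2, mafs[:, None], size=(nv, ns)).astype(np.int8) \
        if nv and ns else np.empty((nv, ns), dtype=np.int8)
    calls = np.repeat(dosage[:, :, None], len(CALLERS), axis=2)

    if config.caller_disagreement_rate > 0 and nv and ns:
        hit = rng.random((nv, ns)) < config.caller_disagreement_rate
        which = rng.integers(0, len(CALLERS), size=(nv, ns))
        # replace with one of the two other states in {0,1,2}
        offset = rng.integers(1, 3, size=(nv, ns)).astype(np.int8)
        vi, si = np.nonzero(hit)
        new = (dosage[vi, si] + offset[vi, si]) % 3
        calls[vi, si, which[vi, si]] = new

    n_genes = config.n_genes or max(1, nv // 4)
    tranche = rng.choice(np.array(["T1", "T2", "lower"]), size=nv,
                         p=np.asarray(config.tranche_probs))
    variants = pd.DataFrame(
        {
            "chrom": [str((i % 22) + 1) for i in range(nv)],
            "pos": [10_000 + 137 * i for i in range(nv)],
            "ref": ["A"] * nv,
            "alt": ["G"] * nv,
            "gene": [f"G{i % n_genes:05d}" for i in range(nv)],
            "impact": np.where(rng.random(nv) < config.impact_high_fraction,
                               "high", "other"),
            "maf": mafs,
            "tranche": tranche,
            "gatk_pass": np.ones(nv, dtype=bool),
            "bcftools_pass": rng.random(nv) >= config.caller_fail_rate,
            "freebayes_pass": rng.random(nv) >= config.caller_fail_rate,
        },
        index=pd.Index([f"var{i:05d}" for i in range(nv)], name="variant_id"),
    )
    return MultiCallerVariantTable(
        variants=variants, samples=list(participants.index), calls=calls
    )


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Full cohort: audiograms + genotypes + planted carrier effects."""
    cohort = simulate_audiograms(config)
    table = simulate_genotypes(config, cohort.participants)
    cohort.genotypes = table

    if config.planted_effects:
        from .variant_consensus_qc import merge_caller_genotypes

        consensus = merge_caller_genotypes(table.calls)
        grid_n = len(config.frequency_grid)
        sex = cohort.participants["sex"].to_numpy()
        thr = cohort.audiograms.to_numpy()
        pid_order = {p: i for i, p in enumerate(cohort.participants.index)}
        for eff in config.planted_effects:
            shift = eff.shift_vector(grid_n)
            carriers = consensus[eff.variant_index] >= 1
            if eff.sex != "both":
                carriers &= sex == eff.sex
            for pi in np.nonzero(carriers)[0]:
                pid = cohort.participants.index[pi]
                for row in (2 * pid_order[pid], 2 * pid_order[pid] + 1):
                    thr[row] = np.maximum(thr[row] + shift, THRESHOLD_FLOOR)
            cohort.truth["effect_variants"].append(
                str(table.variant_ids[eff.variant_index]))
        cohort.audiograms = pd.DataFrame(
            thr, index=cohort.audiograms.index, columns=cohort.audiograms.columns
        )
    return cohort


# ---------------------------------------------------------------------------
# fixture I/O


def _freq_label(f: float) -> str:
    return f"thr_{format(float(f), 'g')}"


def write_fixture(cohort: SyntheticCohort, directory) -> dict:
    """Write the cohort as plain-text files; returns the path map.

    Layout: ``audiograms.csv`` (participant_id, ear, thr_<kHz>...),
    ``metadata.csv``, ``variants.tsv`` (long multi-caller dialect) and
    ``truth.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "audiograms": directory / "audiograms.csv",
        "metadata": directory / "metadata.csv",
        "variants": directory / "variants.tsv",
        "truth": directory / "truth.json",
    }
    aud = cohort.audiograms.copy()
    aud.columns = [_freq_label(c) for c in aud.columns]
    aud.reset_index().to_csv(paths["audiograms"], index=False, float_format=float_repr)
    cohort.participants.reset_index().to_csv(paths["metadata"], index=False,
                                             float_format=float_repr)
    cohort.genotypes.to_tsv(paths["variants"])
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def read_fixture(directory) -> SyntheticCohort:
    from .io import read_audiograms, read_metadata

    directory = Path(directory)
    participants = read_metadata(directory / "metadata.csv")
    audiograms = read_audiograms(directory / "audiograms.csv")
    genotypes = MultiCallerVariantTable.from_tsv(directory / "variants.tsv")
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    return SyntheticCohort(participants, audiograms, genotypes, truth)
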