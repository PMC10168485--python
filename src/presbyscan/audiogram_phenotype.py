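"""Audiogram decomposition into metabolic/sensory components and phenotype rules.

Each ear's audiogram (pure-tone thresholds in dB HL over a frequency grid) is
approximated as a non-negative combination of two canonical hearing-loss
shapes: a *metabolic* shape (mildly elevated low frequencies, gently sloping)
and a *sensory* shape (normal low frequencies, steep high-frequency loss).
The fitted magnitudes ``(m, s)`` are expressed in dB (the shapes are
normalised to unit maximum) and the residual of the fit is the *line-fit
error*.  A small ordered rule set then assigns each participant to one of
five categories: OlderNormal, Metabolic, Sensory, Unclassified or Unselected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from ._utils import as_float_array

log = logging.getLogger(__name__)

CATEGORIES = ("OlderNormal", "Metabolic", "Sensory", "Unclassified", "Unselected")

#: Default canonical audiogram frequencies, kHz.
DEFAULT_GRID = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)


@dataclass(frozen=True)
class ProfileBasis:
    """Canonical metabolic and sensory audiogram shapes on a frequency grid.

    Shapes are unitless (normalised so that the fitted magnitudes are in dB);
    both must be non-negative and not collinear.
    """

    grid: np.ndarray
    metabolic: np.ndarray
    sensory: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "grid", as_float_array(self.grid, "grid"))
        object.__setattr__(self, "metabolic", as_float_array(self.metabolic, "metabolic"))
        object.__setattr__(self, "sensory", as_float_array(self.sensory, "sensory"))
        n = len(self.grid)
        if len(self.metabolic) != n or len(self.sensory) != n:
            raise ValueError("profile vectors must match the grid length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.metabolic < 0) or np.any(self.sensory < 0):
            raise ValueError("profiles must be non-negative")

    def interpolate_to(self, grid: Sequence[float]) -> "ProfileBasis":
        """Resample both shapes onto ``grid``, linear in log-frequency."""
        grid = as_float_array(grid, "grid")
        lx, lg = np.log2(grid), np.log2(self.grid)
        return ProfileBasis(
            grid=grid,
            metabolic=np.interp(lx, lg, self.metabolic),
            sensory=np.interp(lx, lg, self.sensory),
        )

    def design_matrix(self) -> np.ndarray:
        return np.column_stack([self.metabolic, self.sensory])


def default_basis(grid: Sequence[float] = DEFAULT_GRID) -> ProfileBasis:
    """Built-in placeholder basis shapes.

    Metabolic: gently sloping, half-maximal at the lowest frequency rising to
    maximal loss at 8 kHz.  Sensory: flat-normal through 1 kHz then rising
    steeply to maximal loss at 8 kHz.  Both normalised to unit maximum so the
    fitted component magnitudes are in dB HL at the worst frequency.  Real
    empirically derived shapes can be substituted via a basis YAML file.
    """
    anchor = ProfileBasis(
        grid=np.array([0.125, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0]),
        metabolic=np.array([0.48, 0.5, 0.56, 0.63, 0.71, 0.77, 0.82, 0.91, 1.0]),
        sensory=np.array([0.0, 0.0, 0.0, 0.0, 0.24, 0.40, 0.55, 0.80, 1.0]),
    )
    return anchor.interpolate_to(grid)


@dataclass(frozen=True)
class EarDecomposition:
    """Fitted metabolic/sensory magnitudes (dB) and residual line-fit error."""

    m: float
    s: float
    line_fit_error: float

    def __post_init__(self):
        if self.m < 0 or self.s < 0 or self.line_fit_error < 0:
            raise ValueError("decomposition components must be non-negative")


@dataclass(frozen=True)
class ClassificationRules:
    """Boundary constants of the ordered category rules (dB)."""

    unselected_error: float = 15.0
    normal_sum: float = 20.0
    normal_asymmetry: float = 10.0
    metabolic_min: float = 20.0
    metabolic_asymmetry: float = 15.0
    metabolic_sensory_max: float = 20.0
    sensory_min: float = 15.0
    sensory_asymmetry: float = 20.0
    sensory_metabolic_max: float = 25.0


@dataclass
class PhenotypeRecord:
    participant_id: str
    left: EarDecomposition
    right: EarDecomposition
    category: str
    rule_trace: list = field(default_factory=list)


_ERROR_METRICS = {
    "rms": lambda r: float(np.sqrt(np.mean(r**2))),
    "mae": lambda r: float(np.mean(np.abs(r))),
    "max": lambda r: float(np.max(np.abs(r))),
}


def decompose_audiogram(
    thresholds: Sequence[float],
    basis: ProfileBasis,
    error_metric: str = "rms",
) -> EarDecomposition:
    """Non-negative least-squares fit of one ear's thresholds to the basis.

    ``(m, s)`` minimise ``||thresholds - m*M - s*S||`` subject to
    ``m, s >= 0``; the line-fit error is the residual summarised by
    ``error_metric`` ("rms" default; "mae"/"max" available) over the
    non-missing grid points.
    """
    t = np.asarray(thresholds, dtype=float)
    if len(t) != len(basis.grid):
        raise ValueError(
            f"threshold vector length {len(t)} does not match grid length {len(basis.grid)}"
        )
    ok = np.isfinite(t)
    if not ok.any():
        raise ValueError("all thresholds missing; cannot decompose")
    A = basis.design_matrix()[ok]
    # Collinear shapes make (m, s) unidentifiable.
    if np.linalg.matrix_rank(A, tol=1e-10) < 2:
        raise ValueError("degenerate basis: metabolic and sensory shapes are collinear")
    coef, _ = nnls(A, t[ok])
    resid = t[ok] - A @ coef
    err = _ERROR_METRICS[error_metric](resid)
    return EarDecomposition(m=float(coef[0]), s=float(coef[1]), line_fit_error=err)


def classify_participant(
    left: EarDecomposition,
    right: EarDecomposition,
    rules: ClassificationRules = ClassificationRules(),
    participant_id: str = "",
) -> PhenotypeRecord:
    """Apply the ordered category rules to a pair of ear decompositions.

    Order is fixed: Unselected -> OlderNormal -> Metabolic -> Sensory ->
    Unclassified (first match wins).  Magnitude criteria use the across-ear
    mean of each estimate; asymmetry criteria use the absolute between-ear
    difference.  Boundary semantics are literal: the line-fit error cut is
    inclusive (>=), magnitude cuts as stated per rule.
    """
    trace = []
    m = (left.m + right.m) / 2.0
    s = (left.s + right.s) / 2.0
    dm = abs(left.m - right.m)
    ds = abs(left.s - right.s)

    unselected = (
        left.line_fit_error >= rules.unselected_error
        or right.line_fit_error >= rules.unselected_error
    )
    trace.append(("unselected: either line-fit error >= 15", unselected))
    if unselected:
        return PhenotypeRecord(participant_id, left, right, "Unselected", trace)

    older_normal = (
        (m + s) < rules.normal_sum
        and dm < rules.normal_asymmetry
        and ds < rules.normal_asymmetry
    )
    trace.append(("older-normal: m+s < 20 and both asymmetries < 10", older_normal))
    if older_normal:
        return PhenotypeRecord(participant_id, left, right, "OlderNormal", trace)

    metabolic = (
        m >= rules.metabolic_min
        and dm <= rules.metabolic_asymmetry
        and s < rules.metabolic_sensory_max
        and m > s
    )
    trace.append(("metabolic: m >= 20, |dm| <= 15, s < 20, m > s", metabolic))
    if metabolic:
        return PhenotypeRecord(participant_id, left, right, "Metabolic", trace)

    sensory = (
        s >= rules.sensory_min
        and ds <= rules.sensory_asymmetry
        and m < rules.sensory_metabolic_max
        and s > m
    )
    trace.append(("sensory: s >= 15, |ds| <= 20, m < 25, s > m", sensory))
    if sensory:
        return PhenotypeRecord(participant_id, left, right, "Sensory", trace)

    trace.append(("unclassified: no earlier rule matched", True))
    return PhenotypeRecord(participant_id, left, right, "Unclassified", trace)


def classify_cohort(
    audiograms: pd.DataFrame,
    basis: ProfileBasis,
    rules: ClassificationRules = ClassificationRules(),
    error_metric: str = "rms",
    overrides: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Decompose and classify every participant in an audiogram table.

    ``audiograms`` is indexed by ``(participant_id, ear)`` with ear in
    {"L", "R"} and one float column per grid frequency (kHz).  Participants
    missing an ear are excluded with a logged warning.  ``overrides`` maps
    participant ids to categories applied after rule-based classification
    (stand-in for manual review).

    Returns a frame indexed by participant_id with columns
    ``m_L, s_L, err_L, m_R, s_R, err_R, category``.
    """
    grid = [float(c) for c in audiograms.columns]
    fitted_basis = basis if np.allclose(grid, basis.grid) else basis.interpolate_to(grid)

    rows = {}
    for pid, sub in audiograms.groupby(level=0, sort=False):
        ears = set(sub.index.get_level_values(1))
        if not {"L", "R"} <= ears:
            log.warning("participant %s has %d ear(s); excluded from classification",
                        pid, len(ears))
            continue
        dec = {
            ear: decompose_audiogram(sub.loc[(pid, ear)].to_numpy(), fitted_basis,
                                     error_metric)
            for ear in ("L", "R")
        }
        rec = classify_participant(dec["L"], dec["R"], rules, participant_id=str(pid))
        rows[pid] = {
            "m_L": dec["L"].m, "s_L": dec["L"].s, "err_L": dec["L"].line_fit_error,
            "m_R": dec["R"].m, "s_R": dec["R"].s, "err_R": dec["R"].line_fit_error,
            "category": rec.category,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "participant_id"
    if out.empty:
        out = pd.DataFrame(
            columns=["m_L", "s_L", "err_L", "m_R", "s_R", "err_R", "category"]
        )
        out.index.name = "participant_id"
    if overrides:
        for pid, category in overrides.items():
            if category not in CATEGORIES:
                raise ValueError(f"unknown override category {category!r}")
            if pid in out.index:
                out.loc[pid, "category"] = category
    return out
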