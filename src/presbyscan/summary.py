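"""Cohort summary tables, weighted means and packaged reference tables."""

from __future__ import annotations

import json
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import percent, round_half_up
from .audiogram_phenotype import CATEGORIES


def weighted_mean(counts: Sequence[float], means: Sequence[float]) -> float:
    """Count-weighted overall mean of per-stratum means."""
    counts = np.asarray(counts, dtype=float)
    means = np.asarray(means, dtype=float)
    if counts.sum() == 0:
        return float("nan")
    return float(np.sum(counts * means) / counts.sum())


def summarize_cohort(
    classification: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Category x sex cohort summary (counts, mean ages, noise history).

    ``classification`` is indexed by participant_id with a ``category``
    column; ``metadata`` carries sex, age and noise_history.  Rows cover
    every category x sex cell plus per-sex "All" rows; columns are ``n``,
    ``mean_age`` and ``noise_pos``.
    """
    df = classification.join(metadata, how="inner")
    sexes = ["M", "F"]
    rows = []
    for sex in sexes:
        sub_all = df[df["sex"] == sex]
        rows.append(_stratum_row("All", sex, sub_all))
        for cat in CATEGORIES:
            sub = sub_all[sub_all["category"] == cat]
            rows.append(_stratum_row(cat, sex, sub))
    out = pd.DataFrame(rows, columns=["category", "sex", "n", "mean_age", "noise_pos"])
    return out.set_index(["category", "sex"])


def _stratum_row(category: str, sex: str, sub: pd.DataFrame) -> dict:
    return {
        "category": category,
        "sex": sex,
        "n": int(len(sub)),
        "mean_age": float(sub["age"].mean()) if len(sub) else float("nan"),
        "noise_pos": int(sub["noise_history"].sum()) if "noise_history" in sub else 0,
    }


def overall_mean_age(summary: pd.DataFrame, ndigits: int = 2) -> float:
    """Weighted overall mean age from the per-sex 'All' rows of a summary."""
    strata = summary.loc["All"]
    strata = strata[strata["n"] > 0]
    return round_half_up(weighted_mean(strata["n"], strata["mean_age"]), ndigits)


def summary_percentages(summary: pd.DataFrame) -> pd.DataFrame:
    """Percent noise-positive and percent-of-sex per category x sex cell."""
    out = summary.copy()
    totals = summary.loc["All", "n"]
    out["pct_noise_pos"] = [
        percent(r.noise_pos, r.n) if r.n else float("nan") for r in summary.itertuples()
    ]
    out["pct_of_sex"] = [
        percent(r.n, totals[idx[1]]) if totals[idx[1]] else float("nan")
        for idx, r in zip(summary.index, summary.itertuples())
    ]
    return out


# ---------------------------------------------------------------------------
# packaged reference tables (printed summaries of the two study cohorts)


def _data_path(name: str):
    return resources.files("presbyscan.data").joinpath(name)


def load_reference_summary(cohort: str) -> pd.DataFrame:
    """Category x sex strata (n, mean_age, noise_pos) for 'musc' / 'twinsuk'."""
    name = {"musc": "cohort_table_musc.csv", "twinsuk": "cohort_table_twinsuk.csv"}[
        cohort.lower()
    ]
    with resources.as_file(_data_path(name)) as path:
        df = pd.read_csv(path, comment="#")
    return df.set_index(["category", "sex"])


def load_reference_scan_hits() -> pd.DataFrame:
    """Bundled transcription of the primary cohort's threshold-scan hit table."""
    with resources.as_file(_data_path("scan_hits_musc.tsv")) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_reference_counts() -> dict:
    """Bundled printed count inputs (validation calls, gene-list components)."""
    return json.loads(_data_path("reference_counts.json").read_text())


def effect_direction_counts(hits: pd.DataFrame) -> dict:
    """Count scan-hit rows by printed effect direction."""
    counts = hits["effect"].str.lower().value_counts()
    return {"better": int(counts.get("better", 0)), "worse": int(counts.get("worse", 0))}
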