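"""Readers and writers for the plain-text interchange formats.

All readers skip ``#``-prefixed header comment lines so that files stamped
with run provenance headers round-trip.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .audiogram_phenotype import ProfileBasis


def read_audiograms(path) -> pd.DataFrame:
    """Audiogram CSV -> frame indexed by (participant_id, ear), float kHz columns."""
    df = pd.read_csv(path, comment="#", dtype={"participant_id": str},
                     float_precision="round_trip")
    freq_cols = [c for c in df.columns if c.startswith("thr_")]
    if not freq_cols:
        out = pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []],
                                            names=["participant_id", "ear"]))
        return out
    out = df.set_index(["participant_id", "ear"])[freq_cols]
    out.columns = [float(c[len("thr_"):]) for c in freq_cols]
    return out


def write_audiograms(audiograms: pd.DataFrame, path, header: str | None = None) -> None:
    aud = audiograms.copy()
    aud.columns = [f"thr_{format(float(c), 'g')}" for c in aud.columns]
    _write_csv(aud.reset_index(), path, header)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"participant_id": str},
                     float_precision="round_trip")
    df = df.set_index("participant_id")
    if "noise_history" in df.columns and len(df):
        df["noise_history"] = df["noise_history"].astype(int)
    return df


def write_metadata(metadata: pd.DataFrame, path, header: str | None = None) -> None:
    _write_csv(metadata.reset_index(), path, header)


def read_classification(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"participant_id": str})
    return df.set_index("participant_id")


def write_classification(classification: pd.DataFrame, path,
                         header: str | None = None) -> None:
    _write_csv(classification.reset_index(), path, header)


def read_basis(path) -> ProfileBasis:
    """Profile basis YAML with keys grid, metabolic, sensory."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ProfileBasis(
        grid=np.asarray(raw["grid"], dtype=float),
        metabolic=np.asarray(raw["metabolic"], dtype=float),
        sensory=np.asarray(raw["sensory"], dtype=float),
    )


def write_basis(basis: ProfileBasis, path) -> None:
    payload = {
        "grid": [float(x) for x in basis.grid],
        "metabolic": [float(x) for x in basis.metabolic],
        "sensory": [float(x) for x in basis.sensory],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_gene_set(path) -> set:
    """One gene symbol per line; blank lines and # comments ignored."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    return genes


def write_gene_set(genes: Iterable[str], path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_overrides(path) -> Mapping[str, str]:
    """Optional manual-review override CSV: participant_id, category."""
    df = pd.read_csv(path, comment="#", dtype=str)
    return dict(zip(df["participant_id"], df["category"]))


def _write_csv(df: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, index=False)
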