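"""Small shared helpers."""

from __future__ import annotations

import decimal
import hashlib
from typing import Iterable

import numpy as np


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (half-up), not banker's rounding.

    All percentage/age reporting in summaries uses this rule so that printed
    values match conventional table rounding.
    """
    quantum = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(value))).quantize(
        quantum, rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


def percent(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Percentage with half-up rounding; denominator 0 gives nan."""
    if denominator == 0:
        return float("nan")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def config_hash(obj) -> str:
    """Stable short hash of a (nested) plain-data configuration object."""
    import json

    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def float_repr(x) -> str:
    """Shortest exact decimal representation; keeps CSV float round-trips lossless."""
    return repr(float(x))


def as_float_array(values: Iterable, name: str) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr
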