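"""Hierarchical averaging and normalisation of MP measurements.

Measurements are nested: many MPs per dish, several dishes per animal
(BMDM preparation).  Group statistics therefore average bottom-up — MPs
within a dish first, dish means within an animal next — so that each animal
contributes exactly one data point, and the reported s.e.m. is taken over
animals.  Volume time courses are normalised per track to the first
observed timepoint (nominal minute 5), making the published "fraction of
initial volume" curves scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GroupSummary",
    "normalize_track_volume",
    "hierarchical_mean",
    "summarize_group",
]

LEVELS = ("animal", "dish")  # top-down nesting order


@dataclass
class GroupSummary:
    mean: float
    sem: float
    n: int                       # distinct top-level units (animals)
    n_dishes: int
    n_measurements: int
    per_animal: pd.Series


def normalize_track_volume(volumes) -> np.ndarray:
    """Divide a volume series by its first observed value.

    ``volumes`` is an ordered series (earliest timepoint first); NaN entries
    (detection gaps) are preserved.  The first finite value defines the
    denominator, so the output starts at 1 and the 10-minute endpoint reads
    directly as the remaining volume fraction.
    """
    v = np.asarray(volumes, dtype=float)
    finite = np.flatnonzero(np.isfinite(v))
    if len(finite) == 0:
        raise ValueError("track has no observed volumes")
    v0 = v[finite[0]]
    if v0 <= 0:
        raise ValueError("first observed volume must be positive")
    return v / v0


def hierarchical_mean(samples: pd.DataFrame, value: str = "value") -> GroupSummary:
    """Average per dish, then per animal; mean ± s.e.m. over animals.

    ``samples`` needs columns ``animal``, ``dish`` and the value column; any
    row with a missing level key is an error (every measurement must carry
    its full provenance).
    """
    for col in (*LEVELS, value):
        if col not in samples.columns:
            raise KeyError(f"missing column {col!r}")
    if samples[list(LEVELS)].isna().any().any():
        raise ValueError("incomplete level keys in samples")
    if len(samples) == 0:
        raise ValueError("no samples")
    dish_means = samples.groupby(["animal", "dish"], sort=False)[value].mean()
    per_animal = dish_means.groupby("animal", sort=False).mean()
    n = len(per_animal)
    sem = float(per_animal.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return GroupSummary(mean=float(per_animal.mean()), sem=sem, n=n,
                        n_dishes=len(dish_means), n_measurements=len(samples),
                        per_animal=per_animal)


def summarize_group(samples: pd.DataFrame, value: str = "value",
                    by: str | None = "frame") -> pd.DataFrame:
    """Per-timepoint hierarchical summary table (mean, sem, n over animals)."""
    if by is None or by not in samples.columns:
        s = hierarchical_mean(samples, value)
        return pd.DataFrame([{"mean": s.mean, "sem": s.sem, "n": s.n}])
    rows = []
    for key, grp in samples.groupby(by, sort=True):
        s = hierarchical_mean(grp, value)
        rows.append({by: key, "mean": s.mean, "sem": s.sem, "n": s.n})
    return pd.DataFrame(rows)
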