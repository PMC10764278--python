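"""Relative abundances of filament types from particle counts.

The abundance of a polymorph in a dataset is the number of extracted
particles belonging to filaments of that type, expressed as a percentage of
the *total* picked particles of the dataset — including particles from
filaments that never yielded a solved structure and picking false positives.
That remainder is reported explicitly as an ``unassigned`` row (the grey pie
segment), so every per-dataset table sums to exactly 100%.

Percentages are kept at full precision; rounding (1 decimal) happens only at
presentation time.  Note these numbers quantify particles on micrographs,
not necessarily the solution-state amounts of each filament type.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .particle_io import ParticleRecord
from .polymorph_clustering import ClusterAssignment

__all__ = [
    "UNASSIGNED",
    "particle_counts_by_cluster",
    "abundance_percentages",
    "timecourse_table",
]

UNASSIGNED = "unassigned"

_COLUMNS = ["condition", "replicate", "time_min", "cluster_id",
            "particle_count", "percent"]


def particle_counts_by_cluster(
    assignment: ClusterAssignment,
    records: Iterable[ParticleRecord] | None = None,
) -> tuple[dict[int, int], int]:
    """Particle counts per cluster plus the unassigned count.

    With ``records`` given, the unassigned count covers every picked
    particle not accounted for by a cluster: particles of unlabelled
    filaments and unusable particles of labelled ones.  Counts plus
    unassigned partition the total picked particles.
    """
    counts = dict(sorted(assignment.cluster_particle_counts.items()))
    unassigned = 0
    if records is not None:
        total_picked = sum(1 for _ in records)
        unassigned = total_picked - sum(counts.values())
        if unassigned < 0:
            raise ValueError(
                "cluster particle counts exceed the number of picked particles"
            )
    return counts, unassigned


def abundance_percentages(
    counts: Mapping,
    total_picked: int,
    condition: str = "",
    replicate: int = 1,
    time_min: float = 0.0,
) -> pd.DataFrame:
    """Abundance rows for one dataset, as percentages of total picked particles.

    Any shortfall between ``total_picked`` and the summed cluster counts is
    reported as an ``unassigned`` row, so percentages always sum to 100.
    A zero total with zero counts yields an empty table (no division).
    """
    s = sum(counts.values())
    if total_picked < s:
        raise ValueError(
            f"total_picked={total_picked} is less than summed counts {s}"
        )
    if total_picked == 0:
        return pd.DataFrame(columns=_COLUMNS)
    rows = [
        (condition, replicate, time_min, cid, int(n), 100.0 * n / total_picked)
        for cid, n in sorted(counts.items(), key=lambda kv: str(kv[0]))
    ]
    rest = total_picked - s
    if rest > 0:
        rows.append((condition, replicate, time_min, UNASSIGNED, rest,
                     100.0 * rest / total_picked))
    return pd.DataFrame(rows, columns=_COLUMNS)


def timecourse_table(per_dataset) -> pd.DataFrame:
    """Concatenate per-dataset abundance tables into one long table.

    ``per_dataset`` maps (condition, replicate, time_min) to the dataset's
    abundance table (a mapping, or an iterable of key/table pairs); the key
    overrides the labelling columns of each frame.  Duplicate keys are an
    error.  Output is sorted by (condition, replicate, time_min, cluster_id)
    and ready for pie or stacked-area plotting.
    """
    items = (per_dataset.items() if isinstance(per_dataset, Mapping)
             else per_dataset)
    seen: set[tuple[str, int, float]] = set()
    frames = []
    for (cond, rep, t), df in items:
        key = (str(cond), int(rep), float(t))
        if key in seen:
            raise ValueError(f"duplicate dataset key {key} in time course")
        seen.add(key)
        if df.empty:
            continue
        df = df.copy()
        df["condition"], df["replicate"], df["time_min"] = key
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=_COLUMNS)
    out = pd.concat(frames, ignore_index=True)[_COLUMNS]
    out["cluster_id"] = out["cluster_id"].astype(str)
    return out.sort_values(
        ["condition", "replicate", "time_min", "cluster_id"]
    ).reset_index(drop=True)
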