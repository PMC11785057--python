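"""Motif-conditioned breathing features.

Turns simulator output (breathing profiles, bubble tensors) and motif matches
into the per-sequence features the association analyses consume:

* the average flipping probability over all matched motif positions (pooled
  with multiplicity when matches overlap),
* per-position flipping probabilities in motif orientation,
* bubble calls: the tensor is sliced at the smallest grid length exceeding
  10 bp and the smallest amplitude exceeding 3.5 Å to give one bubble
  probability per position; positions above the dataset-wide 95th-percentile
  value are flagged as bubble-containing,
* bubble-near-motif indicators at edge-distance cutoffs of 5, 10 and 20 bp.

Breathing features are duplex properties and are never strand-flipped; only
per-position motif reporting is oriented by match strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .epbd import FLIP_THRESHOLD, BreathingProfile, BubbleTensor
from .motifs import MotifMatch, strongest_match

__all__ = [
    "BubbleCallConfig",
    "BubbleCalls",
    "avg_flip_over_motifs",
    "per_position_flip",
    "slice_bubble_prob",
    "dataset_percentile_threshold",
    "call_bubbles",
    "bubble_near_motif",
    "feature_table",
    "per_position_matrix",
    "flagged_intervals",
]


@dataclass(frozen=True)
class BubbleCallConfig:
    """Bubble definition: displacement > 3.5 Å sustained over > 10 bp, with a
    dataset-wide 95th-percentile significance threshold and nearby-bubble
    cutoffs of 5/10/20 bp."""

    amplitude_min: float = 3.5          # Å, exclusive
    length_min_exclusive: int = 10      # bp, exclusive
    percentile_q: float = 95.0
    near_cutoffs: tuple[int, ...] = (5, 10, 20)

    def __post_init__(self) -> None:
        if self.amplitude_min <= 0:
            raise ValueError("amplitude_min must be > 0")
        if not (0.0 < self.percentile_q < 100.0):
            raise ValueError("percentile_q must be in (0, 100)")
        if any(c <= 0 for c in self.near_cutoffs):
            raise ValueError("near cutoffs must be positive")


@dataclass
class BubbleCalls:
    """Per-position bubble probabilities after slicing, and the flag vector."""

    seq_id: str
    sliced_prob: np.ndarray
    flagged: np.ndarray
    dataset_threshold: float


def avg_flip_over_motifs(
    profile: BreathingProfile,
    matches: Sequence[MotifMatch],
    threshold: float = FLIP_THRESHOLD,
) -> float:
    """Mean flipping probability over the concatenation of all matched positions.

    Positions covered by more than one match are counted once per covering
    match (multiset semantics).  Returns NaN when there are no matches.
    """
    if not matches:
        return float("nan")
    flips = profile.flip_at(threshold)
    pool: list[np.ndarray] = []
    for m in matches:
        if m.start < 0 or m.end > flips.size:
            raise ValueError(f"match {m} out of bounds for {profile.seq_id}")
        pool.append(flips[m.start:m.end])
    return float(np.concatenate(pool).mean())


def per_position_flip(
    profile: BreathingProfile,
    match: MotifMatch,
    threshold: float = FLIP_THRESHOLD,
) -> np.ndarray:
    """Flipping probabilities at the matched positions, in motif orientation."""
    flips = profile.flip_at(threshold)
    if match.start < 0 or match.end > flips.size:
        raise ValueError(f"match {match} out of bounds for {profile.seq_id}")
    window = flips[match.start:match.end]
    return window[::-1].copy() if match.strand == "-" else window.copy()


def _grid_index_above(grid: np.ndarray, bound: float, what: str) -> int:
    idx = np.nonzero(grid > bound)[0]
    if idx.size == 0:
        raise ValueError(f"no {what} grid point strictly exceeds {bound}")
    return int(idx[0])


def slice_bubble_prob(tensor: BubbleTensor, config: BubbleCallConfig | None = None) -> np.ndarray:
    """One bubble probability per position: P[n, l*, t*] at the smallest grid
    length l* > length_min and smallest amplitude t* > amplitude_min
    (defaults select l* = 11 bp, t* = 4.0 Å on the default grids)."""
    config = config or BubbleCallConfig()
    li = _grid_index_above(tensor.length_grid.astype(float), float(config.length_min_exclusive),
                           "bubble length")
    ti = _grid_index_above(tensor.threshold_grid, config.amplitude_min, "amplitude")
    return tensor.P[:, li, ti].copy()


def dataset_percentile_threshold(all_sliced_values: np.ndarray, q: float = 95.0) -> float:
    """q-th percentile (linear interpolation) of the pooled per-position values."""
    pool = np.asarray(all_sliced_values, dtype=float).ravel()
    if pool.size == 0:
        raise ValueError("empty value pool")
    return float(np.percentile(pool, q))


def call_bubbles(seq_id: str, sliced_prob: np.ndarray, dataset_threshold: float) -> BubbleCalls:
    sliced = np.asarray(sliced_prob, dtype=float)
    return BubbleCalls(
        seq_id=seq_id,
        sliced_prob=sliced,
        flagged=sliced > dataset_threshold,
        dataset_threshold=dataset_threshold,
    )


def bubble_near_motif(calls: BubbleCalls, match: MotifMatch, cutoff: int) -> bool:
    """True iff any flagged position lies within ``cutoff`` bp of the motif edge
    (distance 0 inside [start, end); boundary distance is inclusive)."""
    flagged = np.nonzero(calls.flagged)[0]
    if flagged.size == 0:
        return False
    inside = (flagged >= match.start) & (flagged < match.end)
    if inside.any():
        return True
    dist = np.minimum(np.abs(flagged - match.start), np.abs(flagged - (match.end - 1)))
    return bool((dist <= cutoff).any())


def flagged_intervals(calls: BubbleCalls) -> list[tuple[int, int]]:
    """Maximal runs of flagged positions as half-open intervals (BED-ready)."""
    flags = np.concatenate([[False], calls.flagged, [False]]).astype(int)
    starts = np.nonzero(np.diff(flags) == 1)[0]
    ends = np.nonzero(np.diff(flags) == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def feature_table(
    profiles: Mapping[str, BreathingProfile],
    sliced: Mapping[str, np.ndarray],
    matches: Mapping[str, Sequence[MotifMatch]],
    config: BubbleCallConfig | None = None,
    flip_threshold: float = FLIP_THRESHOLD,
) -> pd.DataFrame:
    """Assemble the per-sequence feature table used by the association stage.

    ``sliced`` maps seq_id to the per-position sliced bubble probabilities; the
    dataset percentile threshold is computed over the pooled positions of every
    sequence passed here.  Motif-dependent columns are NaN when a sequence has
    no match.
    """
    config = config or BubbleCallConfig()
    ids = list(profiles.keys())
    if set(ids) != set(sliced.keys()):
        raise ValueError("profiles and sliced bubble probabilities must cover the same sequences")
    pool = np.concatenate([np.asarray(sliced[i], dtype=float) for i in ids])
    thr = dataset_percentile_threshold(pool, config.percentile_q)
    rows = []
    for sid in ids:
        seq_matches = list(matches.get(sid, ()))
        calls = call_bubbles(sid, sliced[sid], thr)
        best = strongest_match(seq_matches)
        row = {
            "seq_id": sid,
            "avg_flip_motif": avg_flip_over_motifs(profiles[sid], seq_matches, flip_threshold),
            "n_strong": sum(m.strength == "strong" for m in seq_matches),
            "n_weak": sum(m.strength == "weak" for m in seq_matches),
            "best_score": best.score if best else float("nan"),
            "best_p": best.p_value if best else float("nan"),
            "bubble_positive": bool(calls.flagged.any()),
        }
        for cut in config.near_cutoffs:
            row[f"bubble_near_{cut}"] = (
                bubble_near_motif(calls, best, cut) if best else float("nan")
            )
        rows.append(row)
    df = pd.DataFrame(rows).set_index("seq_id")
    df.attrs["dataset_threshold"] = thr
    df.attrs["flip_threshold"] = flip_threshold
    return df


def per_position_matrix(
    profiles: Mapping[str, BreathingProfile],
    matches: Mapping[str, Sequence[MotifMatch]],
    flip_threshold: float = FLIP_THRESHOLD,
) -> tuple[np.ndarray, list[str]]:
    """Per-position flipping probabilities of each sequence's strongest match.

    Returns (matrix [n x W], seq_ids); sequences without a match are omitted.
    """
    rows, ids = [], []
    width = None
    for sid, prof in profiles.items():
        best = strongest_match(list(matches.get(sid, ())))
        if best is None:
            continue
        v = per_position_flip(prof, best, flip_threshold)
        if width is None:
            width = v.size
        elif v.size != width:
            warnings.warn(f"{sid}: match width {v.size} differs from {width}; skipped")
            continue
        rows.append(v)
        ids.append(sid)
    if not rows:
        return np.empty((0, 0)), []
    return np.vstack(rows), ids
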