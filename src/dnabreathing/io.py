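"""File formats and seeding helpers.

Canonical interchange formats: FASTA for sequences, TSV for tables, BED6 for
interval exports, NPZ (with explicit axis vectors) for bubble tensors.  All
coordinates in machine-readable outputs are 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .epbd import BreathingProfile, BubbleTensor, DuplexSequence
from .motifs import MotifMatch

__all__ = [
    "SeqRecord",
    "read_fasta",
    "write_fasta",
    "subseed",
    "content_hash",
    "profile_frame",
    "write_profiles",
    "write_bubble_tensors",
    "read_bubble_tensors",
    "write_matches",
    "matches_to_bed",
]


@dataclass(frozen=True)
class SeqRecord:
    """A FASTA record before duplex validation (may still carry non-ACGT)."""

    id: str
    bases: str

    def as_duplex(self) -> DuplexSequence:
        return DuplexSequence(self.id, self.bases)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read FASTA; IDs up to first whitespace, sequences uppercased.

    Duplicate IDs and empty files are rejected.  Non-ACGT symbols are kept and
    left to downstream layers to handle.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence ID {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(id=rec.id, bases=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(path: str | Path, records: Iterable[SeqRecord | DuplexSequence]) -> None:
    bio = [_BioRecord(Seq(r.bases), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def subseed(master: int, *key: int) -> int:
    """Derive a per-stage / per-record seed from one master seed.

    Counter-based: the seed depends only on (master, key), never on execution
    order, so per-sequence work is order-independent by construction.
    """
    ss = np.random.SeedSequence([int(master)] + [int(k) for k in key])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def content_hash(*parts) -> str:
    """Stable sha256 over JSON-serialisable parts and/or file paths."""
    h = hashlib.sha256()
    for part in parts:
        if isinstance(part, Path):
            h.update(part.read_bytes())
        else:
            h.update(json.dumps(part, sort_keys=True, default=str).encode())
    return h.hexdigest()


def profile_frame(profiles: Mapping[str, BreathingProfile]) -> pd.DataFrame:
    """Long-format per-position table of flipping probabilities and moments."""
    frames = []
    for sid, prof in profiles.items():
        cols = {"seq_id": sid, "position": np.arange(prof.flip_prob.shape[0])}
        for t, thr in enumerate(prof.threshold_grid):
            cols[f"flip_prob@{thr:g}"] = prof.flip_prob[:, t]
        cols["mean_disp"] = prof.mean_disp
        cols["mean_sq_disp"] = prof.mean_sq_disp
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def write_profiles(path: str | Path, profiles: Mapping[str, BreathingProfile]) -> None:
    profile_frame(profiles).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bubble_tensors(path: str | Path, tensors: Mapping[str, BubbleTensor]) -> None:
    """NPZ container: per-sequence P arrays plus shared axis vectors."""
    first = next(iter(tensors.values()))
    arrays = {f"P:{sid}": t.P for sid, t in tensors.items()}
    np.savez_compressed(
        path,
        length_grid=first.length_grid,
        threshold_grid=first.threshold_grid,
        **arrays,
    )


def read_bubble_tensors(path: str | Path) -> dict[str, BubbleTensor]:
    with np.load(path) as z:
        lengths = z["length_grid"]
        thresholds = z["threshold_grid"]
        return {
            key[2:]: BubbleTensor(
                seq_id=key[2:], P=z[key], length_grid=lengths, threshold_grid=thresholds
            )
            for key in z.files
            if key.startswith("P:")
        }


def write_matches(path: str | Path, matches: Mapping[str, Sequence[MotifMatch]],
                  motif_id: str = "motif") -> None:
    rows = [
        {
            "seq_id": m.seq_id, "start": m.start, "end": m.end, "strand": m.strand,
            "motif": motif_id, "score": m.score, "p_value": m.p_value,
            "strength": m.strength,
        }
        for ms in matches.values()
        for m in ms
    ]
    pd.DataFrame(
        rows, columns=["seq_id", "start", "end", "strand", "motif", "score",
                       "p_value", "strength"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def matches_to_bed(path: str | Path, matches: Mapping[str, Sequence[MotifMatch]],
                   motif_id: str = "motif") -> None:
    """BED6 export; score column is round(1000 * min(1, -log10(p) / 10))."""
    with open(path, "w") as fh:
        for ms in matches.values():
            for m in ms:
                bed_score = int(round(1000 * min(1.0, -np.log10(max(m.p_value, 1e-300)) / 10.0)))
                fh.write(f"{m.seq_id}\t{m.start}\t{m.end}\t{motif_id}\t{bed_score}\t{m.strand}\n")
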