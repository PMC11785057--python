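"""PWM motif scanning with exact dynamic-programming p-values.

Position frequency matrices (JASPAR text format) are turned into log-odds
scoring matrices; sequences are scanned on both strands and every window whose
match p-value clears the weak threshold is reported as a
:class:`MotifMatch`, classified *strong* (p < 1e-4) or *weak*
(1e-4 ≤ p < 1e-3).

P-values are exact under a 0-order background: the distribution of the PWM
score of a random background word is computed by dynamic programming over
motif columns on an integer score lattice.  Column scores are rounded *down*
onto the lattice, and scanned words are scored on the same lattice, so the
reported p-value of a word is exact for the lattice-quantised matrix (within
one lattice bin of the continuous-score p-value) and never understated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import motifs as _bio_motifs

log = logging.getLogger(__name__)

__all__ = [
    "FrequencyMatrix",
    "ScoringMatrix",
    "ScanConfig",
    "MotifMatch",
    "PValueTable",
    "read_jaspar",
    "write_jaspar",
    "build_pwm",
    "score_pvalue_table",
    "scan",
    "strongest_match",
]

_BASES = "ACGT"
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G on row indices

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode bases as integers A=0 C=1 G=2 T=3; anything else becomes -1."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)


@dataclass(frozen=True)
class FrequencyMatrix:
    """Position frequency matrix, rows ordered A, C, G, T."""

    tf_name: str
    matrix_id: str
    counts: np.ndarray  # [4, W]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.float64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(f"motif {self.matrix_id}: counts must be 4 x W with W >= 1")
        if np.any(counts < 0):
            raise ValueError(f"motif {self.matrix_id}: negative counts")
        if np.any(counts.sum(axis=0) == 0):
            raise ValueError(f"motif {self.matrix_id}: all-zero column")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class ScoringMatrix:
    """Log2-odds scoring matrix against a 0-order background."""

    log_odds: np.ndarray    # [4, W], bits
    background: np.ndarray  # [4]
    pseudocount: float

    @property
    def width(self) -> int:
        return self.log_odds.shape[1]

    def reverse_complement(self) -> "ScoringMatrix":
        return ScoringMatrix(
            log_odds=self.log_odds[_COMPLEMENT, ::-1].copy(),
            background=self.background,
            pseudocount=self.pseudocount,
        )


@dataclass(frozen=True)
class ScanConfig:
    strong_p: float = 1e-4
    weak_p_upper: float = 1e-3
    score_discretization: int = 1000  # lattice bins spanning the score range

    def __post_init__(self) -> None:
        if not (0.0 < self.strong_p < self.weak_p_upper < 1.0):
            raise ValueError("require 0 < strong_p < weak_p_upper < 1")
        if self.score_discretization < 10:
            raise ValueError("score lattice too coarse")


@dataclass(frozen=True, order=True)
class MotifMatch:
    """A strand-aware PWM hit; coordinates are forward-strand, 0-based half-open."""

    seq_id: str = field(compare=False)
    start: int = 0
    end: int = 0
    strand: str = "+"
    score: float = 0.0
    p_value: float = 1.0
    strength: str = "weak"


def read_jaspar(path: str | Path) -> list[FrequencyMatrix]:
    """Read JASPAR-format PFMs (rows labeled A/C/G/T with bracketed counts)."""
    path = Path(path)
    with open(path) as handle:
        try:
            records = list(_bio_motifs.parse(handle, "jaspar"))
        except Exception as exc:  # ragged rows, bad counts, ...
            raise ValueError(f"{path}: cannot parse JASPAR file: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no motifs found")
    out = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in _BASES], dtype=np.float64)
        mat_id = rec.matrix_id or rec.name or "motif"
        try:
            out.append(FrequencyMatrix(tf_name=rec.name or mat_id, matrix_id=mat_id, counts=counts))
        except ValueError as exc:
            raise ValueError(f"{path}: invalid motif record {mat_id!r}: {exc}") from exc
    return out


def write_jaspar(path: str | Path, matrices: list[FrequencyMatrix]) -> None:
    with open(path, "w") as fh:
        for fm in matrices:
            fh.write(f">{fm.matrix_id} {fm.tf_name}\n")
            for i, b in enumerate(_BASES):
                vals = " ".join(f"{v:g}" for v in fm.counts[i])
                fh.write(f"{b} [ {vals} ]\n")


def build_pwm(
    fm: FrequencyMatrix,
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
) -> ScoringMatrix:
    """Column probabilities (count + pc*bg) / (total + pc), then log2 odds."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=np.float64)
    if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be 4 positive probabilities summing to 1")
    totals = fm.counts.sum(axis=0)
    probs = (fm.counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    return ScoringMatrix(
        log_odds=np.log2(probs / bg[:, None]),
        background=bg,
        pseudocount=pseudocount,
    )


@dataclass(frozen=True)
class PValueTable:
    """Exact background score distribution on an integer lattice.

    ``int_scores[b, j] = floor(log_odds[b, j] / delta)``; a word's lattice
    score is the sum of its column entries, and ``sf`` maps lattice totals to
    P(lattice score of a random background word >= total).
    """

    int_scores: np.ndarray  # [4, W]
    sf: np.ndarray          # survival function over lattice totals
    min_total: int
    delta: float

    @property
    def width(self) -> int:
        return self.int_scores.shape[1]

    def pvalue_from_lattice(self, totals) -> np.ndarray | float:
        arr = np.asarray(totals)
        idx = np.clip(arr - self.min_total, 0, self.sf.size - 1)
        out = np.where(arr - self.min_total >= self.sf.size, 0.0, self.sf[idx])
        return float(out) if arr.ndim == 0 else out

    def word_lattice_score(self, codes: np.ndarray) -> int:
        return int(self.int_scores[codes, np.arange(self.width)].sum())

    def pvalue_of_word(self, codes: np.ndarray) -> float:
        return float(self.pvalue_from_lattice(self.word_lattice_score(codes)))

    def pvalue(self, score_bits: float) -> float:
        """Conservative p-value for a continuous score not on the lattice."""
        total = int(np.floor(score_bits / self.delta)) - (self.width - 1)
        return float(self.pvalue_from_lattice(total))


def score_pvalue_table(pwm: ScoringMatrix, config: ScanConfig | None = None) -> PValueTable:
    """Exact DP distribution of the PWM score of a random background word."""
    config = config or ScanConfig()
    lo = pwm.log_odds
    score_range = lo.max(axis=0).sum() - lo.min(axis=0).sum()
    if score_range <= 0:  # completely uninformative matrix
        delta = 1.0
    else:
        delta = score_range / config.score_discretization
    ints = np.floor(lo / delta).astype(np.int64)
    col_min = ints.min(axis=0)
    col_max = ints.max(axis=0)
    min_total = int(col_min.sum())
    size = int((col_max - col_min).sum()) + 1
    dist = np.zeros(size)
    dist[0] = 1.0
    used = 1
    for j in range(pwm.width):
        width_j = int(col_max[j] - col_min[j])
        new = np.zeros(used + width_j)
        for b in range(4):
            off = int(ints[b, j] - col_min[j])
            new[off:off + used] += pwm.background[b] * dist[:used]
        used += width_j
        dist = new
    sf = np.cumsum(dist[::-1])[::-1]
    sf = np.minimum(sf, 1.0)
    return PValueTable(int_scores=ints, sf=sf, min_total=min_total, delta=delta)


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every window under ``matrix`` [4, W]; invalid windows masked.

    Returns (scores, valid) with one entry per offset.
    """
    w = matrix.shape[1]
    n_win = codes.size - w + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = ~(windows < 0).any(axis=1)
    safe = np.where(windows < 0, 0, windows)
    scores = matrix[safe, np.arange(w)].sum(axis=1)
    return scores, valid


def scan(
    seq,
    pwm: ScoringMatrix,
    table: PValueTable,
    config: ScanConfig | None = None,
) -> list[MotifMatch]:
    """Scan one sequence on both strands; emit matches with p < weak_p_upper.

    ``seq`` may be a DuplexSequence or any object with ``id`` and ``bases``
    string attributes.  Windows containing non-ACGT symbols are skipped and
    logged.  Coordinates are always on the forward strand, half-open.
    """
    config = config or ScanConfig()
    codes = encode(seq.bases)
    w = pwm.width
    if codes.size < w:
        raise ValueError(f"sequence {seq.id!r} shorter than motif width {w}")
    n_bad = int((codes < 0).sum())
    if n_bad:
        log.warning("sequence %s: windows covering %d non-ACGT symbols skipped", seq.id, n_bad)

    # Lattice scores of the reverse-complement matrix are a reordering of the
    # forward lattice entries, so the same DP distribution serves both strands
    # provided the background is complement-symmetric.
    bg = pwm.background
    if not (abs(bg[0] - bg[3]) < 1e-12 and abs(bg[1] - bg[2]) < 1e-12):
        raise ValueError("scan requires a complement-symmetric background")
    rc = pwm.reverse_complement()
    rc_ints = table.int_scores[_COMPLEMENT, ::-1]

    matches: list[MotifMatch] = []
    for strand, matrix, ints in (("+", pwm.log_odds, table.int_scores),
                                 ("-", rc.log_odds, rc_ints)):
        scores, valid = _window_scores(codes, matrix)
        lattice, _ = _window_scores(codes, ints.astype(np.float64))
        lattice = np.rint(lattice).astype(np.int64)
        pvals = np.asarray(table.pvalue_from_lattice(lattice))
        for off in np.nonzero(valid & (pvals < config.weak_p_upper))[0]:
            p = float(pvals[off])
            matches.append(
                MotifMatch(
                    seq_id=seq.id,
                    start=int(off),
                    end=int(off) + w,
                    strand=strand,
                    score=float(scores[off]),
                    p_value=p,
                    strength="strong" if p < config.strong_p else "weak",
                )
            )
    matches.sort(key=lambda m: (m.start, m.strand))
    return matches


def strongest_match(matches: list[MotifMatch]) -> MotifMatch | None:
    """Lowest p-value; ties broken by higher score, smaller start, then + strand."""
    if not matches:
        return None
    return min(matches, key=lambda m: (m.p_value, -m.score, m.start, m.strand))
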