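"""Synthetic TF-binding datasets with known breathing-binding coupling.

The generator emulates the two study designs the association analyses target:

* *gcPBM-like*: short fixed-length sequences (default 36 bp) with a continuous
  binding affinity in [0, 1];
* *ChIP-like*: longer sequences (default 200 bp) with a binary bound/unbound
  label.

Sequences are i.i.d. with controllable GC content; with probability
``plant_prob`` one motif instance sampled column-wise from a PFM replaces a
random window.  Crucially, the breathing features entering the label models
are computed by the *real* pipeline (simulator -> scanner -> feature
extraction) on the generated sequences, so feature-sequence dependence —
including the GC-breathing confounding the regressions must cope with — is
physical, not parametric.  Labels are then drawn as

    affinity = clamp01(beta0 + beta_motif * score_z + beta_flip * flip_z + eps)
    bound    ~ Bernoulli(logistic(gamma0 + gamma_motif * score_z
                                  + gamma_bubble * bubble_near_10))

with features z-standardised over the dataset (missing motif features are 0
after standardisation) and eps ~ Normal(0, sigma_noise).  The generating
coefficients are recoverable ground truth for the association stage.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import features as feat
from .epbd import (
    FLIP_THRESHOLD,
    BreathingProfile,
    DuplexSequence,
    EPBDParams,
    MCMCConfig,
    simulate,
)
from .io import subseed
from .motifs import (
    FrequencyMatrix,
    MotifMatch,
    ScanConfig,
    build_pwm,
    read_jaspar,
    scan,
)

__all__ = [
    "SynthConfig",
    "SynthDataset",
    "default_motif",
    "gen_sequences",
    "gen_affinity",
    "gen_binding_status",
    "generate_dataset",
]

_STAGE_SEQ, _STAGE_SIM, _STAGE_AFFINITY, _STAGE_BINDING = 1, 2, 3, 4


def default_motif() -> FrequencyMatrix:
    """The bundled synthetic E-box-like PFM (palindromic CACGTG core, 10 bp)."""
    ref = importlib.resources.files("dnabreathing.data") / "ebox_synthetic.jaspar"
    with importlib.resources.as_file(ref) as path:
        return read_jaspar(path)[0]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults describe the gcPBM-like design."""

    n_sequences: int = 1000
    seq_length: int = 36
    gc_content: float = 0.41
    motif: FrequencyMatrix | None = None
    plant_prob: float = 0.8
    # affinity (continuous-label) model
    beta0: float = 0.5
    beta_motif: float = 0.1
    beta_flip: float = 0.15
    sigma_noise: float = 0.15
    # binding-status (binary-label) model
    gamma0: float = 0.5
    gamma_motif: float = 0.5
    gamma_bubble: float = 1.0
    seed: int = 0
    params: EPBDParams = field(default_factory=EPBDParams)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig.reduced)
    scan_config: ScanConfig = field(default_factory=ScanConfig)
    bubble_config: feat.BubbleCallConfig = field(default_factory=feat.BubbleCallConfig)

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_content <= 1.0 and 0.0 <= self.plant_prob <= 1.0):
            raise ValueError("gc_content and plant_prob must be probabilities")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")
        if self.n_sequences < 1 or self.seq_length < 2:
            raise ValueError("need n_sequences >= 1 and seq_length >= 2")

    @classmethod
    def gcpbm_like(cls, **kw) -> "SynthConfig":
        return cls(**kw)

    @classmethod
    def chip_like(cls, **kw) -> "SynthConfig":
        """200-bp sequences at the coarse simulation profile."""
        kw.setdefault("seq_length", 200)
        kw.setdefault("n_sequences", 5000)
        kw.setdefault("plant_prob", 0.7)
        kw.setdefault("mcmc", MCMCConfig.coarse())
        return cls(**kw)

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


@dataclass
class SynthDataset:
    """Generated sequences, labels, pipeline features, and generating truth."""

    sequences: list[DuplexSequence]
    affinity: np.ndarray | None
    bound: np.ndarray | None
    features: pd.DataFrame
    per_position: np.ndarray
    per_position_ids: list[str]
    matches: dict[str, list[MotifMatch]]
    truth: dict


def gen_sequences(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[list[DuplexSequence], list[int | None]]:
    """I.i.d. background sequences with optional planted motif instances.

    Returns the sequences and, per sequence, the 0-based plant start (or None).
    """
    motif = config.motif or default_motif()
    if config.plant_prob > 0 and config.seq_length < motif.width:
        raise ValueError("seq_length shorter than motif width with plant_prob > 0")
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    col_probs = motif.counts / motif.counts.sum(axis=0)
    alphabet = np.array(list("ACGT"))
    seqs: list[DuplexSequence] = []
    plants: list[int | None] = []
    width = motif.width
    for i in range(config.n_sequences):
        codes = rng.choice(4, size=config.seq_length, p=base_p)
        plant: int | None = None
        if rng.random() < config.plant_prob:
            plant = int(rng.integers(0, config.seq_length - width + 1))
            word = np.array([rng.choice(4, p=col_probs[:, j]) for j in range(width)])
            codes[plant:plant + width] = word
        seqs.append(DuplexSequence(f"seq{i:05d}", "".join(alphabet[codes])))
        plants.append(plant)
    return seqs, plants


def _standardise(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Z-score over non-missing entries; missing entries become 0 afterwards."""
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    if not ok.any():
        return np.zeros_like(v), float("nan"), float("nan")
    mu = float(v[ok].mean())
    sd = float(v[ok].std(ddof=0))
    z = np.zeros_like(v)
    if sd > 0:
        z[ok] = (v[ok] - mu) / sd
    return z, mu, sd


def _require_variance(z: np.ndarray, coef: float, name: str) -> None:
    if coef != 0.0 and float(np.std(z)) == 0.0:
        raise ValueError(f"feature {name} has zero variance but a nonzero coefficient")


def gen_affinity(
    features_df: pd.DataFrame, config: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """Continuous affinity in [0, 1] from standardised motif and flip features."""
    score_z, s_mu, s_sd = _standardise(features_df["best_score"].to_numpy())
    flip_z, f_mu, f_sd = _standardise(features_df["avg_flip_motif"].to_numpy())
    _require_variance(score_z, config.beta_motif, "best_score")
    _require_variance(flip_z, config.beta_flip, "avg_flip_motif")
    raw = (
        config.beta0
        + config.beta_motif * score_z
        + config.beta_flip * flip_z
        + rng.normal(0.0, config.sigma_noise, size=len(features_df))
    )
    affinity = np.clip(raw, 0.0, 1.0)
    truth = {
        "score_mean": s_mu, "score_sd": s_sd,
        "flip_mean": f_mu, "flip_sd": f_sd,
        "clamp_rate": float(np.mean((raw < 0) | (raw > 1))),
    }
    return affinity, truth


def gen_binding_status(
    features_df: pd.DataFrame, config: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """Binary bound/unbound labels; bubble proximity enters at the 10 bp cutoff."""
    score_z, s_mu, s_sd = _standardise(features_df["best_score"].to_numpy())
    _require_variance(score_z, config.gamma_motif, "best_score")
    bubble = features_df["bubble_near_10"].to_numpy(dtype=float)
    bubble = np.nan_to_num(bubble, nan=0.0)  # no motif -> no bubble-near-motif
    _require_variance(bubble, config.gamma_bubble, "bubble_near_10")
    eta = config.gamma0 + config.gamma_motif * score_z + config.gamma_bubble * bubble
    p = 1.0 / (1.0 + np.exp(-eta))
    bound = (rng.random(len(features_df)) < p).astype(int)
    truth = {"score_mean": s_mu, "score_sd": s_sd, "bound_fraction": float(bound.mean())}
    return bound, truth


def compute_features(
    sequences: Sequence[DuplexSequence],
    config: SynthConfig,
) -> tuple[pd.DataFrame, dict[str, list[MotifMatch]], np.ndarray, list[str]]:
    """Run the pipeline (simulate, scan, extract) over a set of sequences.

    Per-sequence MCMC seeds are derived from the master seed with a
    counter-based scheme, so results do not depend on iteration order.  Only
    the flip column at the flipping threshold and the sliced bubble
    probabilities are retained per sequence, keeping memory flat in dataset
    size.
    """
    motif = config.motif or default_motif()
    pwm = build_pwm(motif)
    from .motifs import score_pvalue_table  # local to keep import graph tidy

    table = score_pvalue_table(pwm, config.scan_config)
    profiles: dict[str, BreathingProfile] = {}
    sliced: dict[str, np.ndarray] = {}
    matches: dict[str, list[MotifMatch]] = {}
    for i, seq in enumerate(sequences):
        mcmc = config.mcmc.with_seed(subseed(config.seed, _STAGE_SIM, i))
        profile, tensor = simulate(seq, params=config.params, config=mcmc)
        sliced[seq.id] = feat.slice_bubble_prob(tensor, config.bubble_config)
        # compact profile: keep only the flipping-threshold column
        ti = int(np.argmin(np.abs(profile.threshold_grid - FLIP_THRESHOLD)))
        profiles[seq.id] = BreathingProfile(
            seq_id=seq.id,
            flip_prob=profile.flip_prob[:, [ti]],
            mean_disp=profile.mean_disp,
            mean_sq_disp=profile.mean_sq_disp,
            threshold_grid=profile.threshold_grid[[ti]],
            n_samples=profile.n_samples,
        )
        matches[seq.id] = scan(seq, pwm, table, config.scan_config)
    table_df = feat.feature_table(profiles, sliced, matches, config.bubble_config)
    per_pos, ids = feat.per_position_matrix(profiles, matches)
    # restore original sequence order in the table
    table_df = table_df.loc[[s.id for s in sequences]]
    return table_df, matches, per_pos, ids


def generate_dataset(config: SynthConfig, labels: str = "both") -> SynthDataset:
    """Generate sequences, run the feature pipeline, and draw labels.

    ``labels`` selects which label models to evaluate: "affinity", "binding"
    or "both".  Deterministic given ``config`` (including its seed).
    """
    rng_seq = np.random.default_rng(subseed(config.seed, _STAGE_SEQ))
    sequences, plants = gen_sequences(config, rng_seq)
    features_df, matches, per_pos, ids = compute_features(sequences, config)
    affinity = bound = None
    truth: dict = {"plants": plants, "config": config}
    if labels in ("affinity", "both"):
        rng_aff = np.random.default_rng(subseed(config.seed, _STAGE_AFFINITY))
        affinity, t = gen_affinity(features_df, config, rng_aff)
        truth["affinity_model"] = t
    if labels in ("binding", "both"):
        rng_bind = np.random.default_rng(subseed(config.seed, _STAGE_BINDING))
        bound, t = gen_binding_status(features_df, config, rng_bind)
        truth["binding_model"] = t
    return SynthDataset(
        sequences=list(sequences),
        affinity=affinity,
        bound=bound,
        features=features_df,
        per_position=per_pos,
        per_position_ids=ids,
        matches=matches,
        truth=truth,
    )
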