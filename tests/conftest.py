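"""Shared fixtures.

The two large synthetic datasets used by the recovery tests are session-scoped
and generated once: label-model seeds are varied downstream without re-running
the simulator, mirroring how the generator separates sequence/feature
randomness from label randomness.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dnabreathing import synth
from dnabreathing.epbd import EPBDParams, MCMCConfig
from dnabreathing.motifs import FrequencyMatrix, build_pwm, score_pvalue_table

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> EPBDParams:
    return EPBDParams()


@pytest.fixture(scope="session")
def quick_mcmc() -> MCMCConfig:
    """Very short profile for structural (non-statistical) checks."""
    return MCMCConfig(preheat_sweeps=500, production_sweeps=1000)


@pytest.fixture(scope="session")
def ebox() -> FrequencyMatrix:
    return synth.default_motif()


@pytest.fixture(scope="session")
def ebox_pwm(ebox):
    pwm = build_pwm(ebox)
    return pwm, score_pvalue_table(pwm)


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture(scope="session")
def gcpbm_dataset():
    """n = 1000 gcPBM-like dataset at the reduced profile, flip coupling 0.3.

    Generated once; recovery tests redraw only the affinity labels.
    """
    cfg = synth.SynthConfig(n_sequences=1000, seed=20240, beta_flip=0.3)
    return synth.generate_dataset(cfg, labels="affinity"), cfg


@pytest.fixture(scope="session")
def chip_dataset():
    """n = 5000 ChIP-like dataset (200 bp) at the coarse profile, bubble
    coupling 1.0.  Generated once; recovery tests redraw only the labels."""
    cfg = synth.SynthConfig.chip_like(seed=20241, gamma_bubble=1.0)
    return synth.generate_dataset(cfg, labels="binding"), cfg
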