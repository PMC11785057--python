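# dnabreathing

Double-stranded DNA transiently opens through thermal motion ("DNA
breathing"): individual base pairs flip out of the helix and contiguous runs
of open pairs form *bubbles*. Because transcription factors (TFs) read DNA at
and around their sequence motifs, locally melted DNA may help — or hinder —
binding. `dnabreathing` is a toolkit for studying that question
quantitatively. It is aimed at regulatory-genomics researchers who want
sequence-resolved breathing features and a principled statistical harness
connecting them to TF-binding measurements (continuous gcPBM-style affinities
or binary ChIP-seq-style bound/unbound labels).

The package provides, as separately usable layers:

* **`dnabreathing.epbd`** — an equilibrium Metropolis Monte Carlo sampler for
  the extended Peyrard–Bishop–Dauxois (PBD) lattice Hamiltonian

  $$E(y) = \sum_n D_n\,(e^{-a_n y_n}-1)^2 + \sum_n \tfrac{k_n}{2}\,\bigl(1+\rho\,e^{-\beta (y_n+y_{n-1})}\bigr)(y_n-y_{n-1})^2$$

  with sequence-dependent Morse on-site terms (A·T vs G·C) and anharmonic
  stacking. It reports per-position *flipping probabilities*
  P(displacement > t) over an amplitude grid, displacement moments, and the
  three-dimensional *bubble tensor* P[n, l, t] — the probability that all
  base pairs in the window [n, n+l) simultaneously exceed amplitude t.
  A deterministic transfer-sum quadrature oracle evaluates the same model
  exactly for short duplexes and anchors the sampler's correctness.
* **`dnabreathing.motifs`** — JASPAR PFM parsing, log-odds PWM scanning on
  both strands, and *exact* match p-values by dynamic programming over an
  integer score lattice; matches are classed strong (p < 1e-4) or weak
  (1e-4 ≤ p < 1e-3).
* **`dnabreathing.features`** — motif-conditioned feature extraction:
  motif-averaged and per-position flipping probabilities, bubble calls
  (displacement > 3.5 Å sustained over > 10 bp, thresholded at the
  dataset-wide 95th percentile), and bubble-near-motif indicators at 5/10/20
  bp.
* **`dnabreathing.stats`** — the association battery: Pearson and
  point-biserial correlations, Wilcoxon rank-sum, OLS and logistic
  regressions of binding on bubble presence with motif covariates, Bonferroni
  bookkeeping, and the ≥ 3000-peak inclusion filter for binary datasets.
* **`dnabreathing.synth`** — a synthetic-data generator whose labels are
  drawn from *known* couplings to the pipeline's own features, so every
  statistical claim is testable against recoverable ground truth.
* **`breathe`** — a CLI (`simulate`, `scan`, `analyze`, `synth`, `run`) with
  content-addressed stage caching and counter-based per-sequence seeding.

## Worked example

Simulate one 36-bp duplex with an AT-rich head, an E-box (CACGTG core), and a
GC-rich tail, at the reduced desk-scale profile:

```python
import numpy as np
from dnabreathing import epbd

seq = epbd.DuplexSequence("ex", "TTATTTGGCACGTGCCAATTGCGCGGCCGGCCGCGG")
profile, tensor = epbd.simulate(seq, config=epbd.MCMCConfig.reduced(seed=1))
flip = profile.flip_at(epbd.FLIP_THRESHOLD)   # P(separation > 0.5*sqrt(2) A)
print(np.round(flip[:6], 3))   # [0.351 0.342 0.29  0.263 0.234 0.208]
print(np.round(flip[-6:], 3))  # [0.13  0.13  0.119 0.117 0.125 0.142]
```

The AT-rich 5' end breathes two-to-three-fold more than the GC-rich 3' end —
the hydrogen-bonding asymmetry that makes breathing sequence-specific.

A full synthetic study (50 sequences, continuous affinities coupled to motif
score and flipping) runs end to end with:

```bash
breathe run --config tests/golden/config.yaml --out out/demo
```

`out/demo/results.tsv` then contains the association battery, e.g.

```
analysis   tf  effect    p_value    n   significant_corrected
flip_avg   TF  0.584271  0.000357   33  True
```

a strongly positive correlation between motif-averaged flipping probability
and affinity — exactly the coupling the generator planted — together with the
per-position profile and the bubble regressions.

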