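# Methods

## Model

DNA breathing is modelled with a Peyrard–Bishop–Dauxois (PBD) family lattice
Hamiltonian over per-base-pair opening coordinates `y_n` (Å):

```
E(y) = Σ_n D_n (exp(-a_n y_n) - 1)²
     + Σ_n (k_n/2) (1 + ρ exp(-β (y_n + y_{n-1}))) (y_n - y_{n-1})²
```

The Morse on-site term stands for the intra-base-pair hydrogen bonds; its
depth and inverse width are per-base (`D_GC > D_AT`, `a_GC > a_AT`), which is
the whole source of sequence specificity at the single-pair level. The
stacking term penalises displacement differences between neighbours; its
anharmonic prefactor softens when both neighbours are open, which is what
lets bubbles, once nucleated, widen cheaply. Sequence-dependent stacking is
available through a 16-entry dinucleotide multiplier on `k` (default uniform
1.0: the extension hook is present, but no published dinucleotide set is
bundled). Ends are open (no periodic wrap), matching linear oligomers.

Default constants are the Campa–Giansanti parameterization, the canonical
PBD set fitted to DNA melting: `D_AT = 0.05 eV`, `D_GC = 0.075 eV`,
`a_AT = 4.2 /Å`, `a_GC = 6.9 /Å`, `k = 0.025 eV/Å²`, `ρ = 2`, `β = 0.35 /Å`,
T = 310 K, `k_B = 8.617e-5 eV/K`. All are overridable.

### Coordinate convention

The chain samples the standard PBD relative coordinate
`y = (u - v)/√2` of the two strands' displacements. Every *reported*
quantity — thresholds, moments, bubble amplitudes — is on the physical
inter-strand separation scale `√2·y`. Under this convention the
`0.5·√2 Å` flipping threshold is exactly the canonical `y > 0.5 Å`
open-base-pair criterion of the PBD literature, and the bubble amplitude
criterion (> 3.5 Å) corresponds to `y > 2.47 Å`. This is the only reading
under which bubbles of > 10 bp at > 3.5 Å have observable probability at
310 K at any feasible sampling depth, and we treat it as the intended one.

## Sampling

Single-site Metropolis over full lattice sweeps (one Gaussian proposal per
position per sweep, fixed order, width `proposal_sigma = 0.5 Å`).
Displacements are confined to `[-2, 25] Å` by outright rejection at the
walls. The lower wall truncates the steep repulsive Morse branch; the upper
wall is needed because the Morse plateau makes the open state non-normalisable
on an infinite domain. 25 Å is far above every amplitude threshold of
interest (≤ 5 Å); it was chosen over a more distant wall because the open
state is free diffusion on the plateau, so the wall distance directly sets
the mixing time of short oligomers — halving it quarters the equilibration
cost at no cost to bubble statistics.

Runs start from the all-closed state (`y = 0`), discard `preheat_sweeps`,
then accumulate every `thinning`-th of `production_sweeps` sweeps. Only
accumulators are stored, never a trajectory: per position and amplitude
threshold, a histogram of exceedance *run lengths* starting at that position.
Flipping probabilities (run ≥ 1) and the full bubble tensor (run ≥ l) are
suffix sums of this one histogram, so accumulation is O(N·T) per sample.
Positions within `l-1` of the right end have no defined length-`l` bubble and
report 0.

Three named profiles set the sampling depth:

| profile   | preheat | production | thinning | use |
|-----------|---------|------------|----------|-----|
| default   | 50,000  | 80,000     | 1        | full-fidelity runs |
| `reduced` | 2,000   | 8,000      | 1        | desk-scale studies, tests |
| `coarse`  | 500     | 2,000      | 2        | large binary-label screens |

The "steps" of the full profile are interpreted as whole lattice sweeps, so
run length is sequence-length-invariant.

Per-sequence seeds derive from one master seed with a counter-based scheme
(`SeedSequence([master, stage, index])`), so per-sequence results are
independent of execution order and identical (`bit-for-bit`) on re-runs.

## Quadrature oracle

For duplexes of N ≤ 6 bp, `oracle_expectation` evaluates
P(y_n > t) under the Boltzmann density on the same bounded domain by
tensor-product quadrature (trapezoid, spacing ≤ 0.05 Å). The chain structure
of the Hamiltonian factorises the N-dimensional grid sum into
forward/backward matrix passes (O(N·M²)); this is an exact rearrangement of
the same discrete sum, not an approximation on top of it. The threshold cell
is split by linear interpolation of the marginal density, keeping the
estimate O(h²). A convergence mode re-evaluates at half spacing and raises if
the change exceeds 1e-3. An independent adaptive 2-D quadrature
(scipy `dblquad`) cross-checks the N = 2 case in the tests.

Short A/G duplexes at 310 K are largely melted in this bounded model (the
entropy of the plateau dominates two or three Morse wells), so the oracle
battery probes the sampler in a genuinely hard, slowly-mixing regime. The
equivalence tests therefore use an upper 99% confidence bound on the
across-seed standard error (chi-square inflation, 10 seeds) plus a
1/n_samples resolution floor; with 84 simultaneous 3-SE checks this keeps the
family-wise false-alarm probability small while remaining a real constraint —
the observed worst deviation sits near half the tolerance.

## Motif scanning

PWMs are built from JASPAR count matrices with pseudocount 0.1 against a
configurable 0-order background (default uniform):
`p_bj = (n_bj + 0.1·q_b)/(N_j + 0.1)`, scored as `log2(p/q)`. P-values are
exact for the lattice-quantised matrix: column scores are floored onto an
integer lattice of 1000 bins spanning the score range, the full distribution
of a background word's lattice score is obtained by dynamic programming over
columns, and scanned words are scored on the same lattice — so a word's
reported p-value is never understated and agrees with brute-force enumeration
bin-for-bin (verified exhaustively up to width 10 in the tests). Both strands
are scanned; reverse-complement lattice scores are a reordering of the
forward entries, so one distribution serves both strands for
complement-symmetric backgrounds. Matches with p < 1e-3 are reported,
classed strong below 1e-4. Overlapping matches are all retained; windows
containing non-ACGT symbols are skipped and logged.

The bundled motif fixture is a **synthetic** 10-bp E-box-like PFM
(palindromic, CACGTG core at positions 2–7, informative flanks). Width 10
rather than the 6-bp core because under any 0-order background the best
width-6 word has p = 4⁻⁶ ≈ 2.4e-4, i.e. the strong class would be empty by
construction; informative flanks make both strength classes realisable at
the stated thresholds.

## Breathing features

* *Motif-averaged flipping*: mean of P(separation > 0.5·√2 Å) over the
  concatenation of all matched positions; overlapping matches contribute
  with multiplicity. Missing when a sequence has no match.
* *Per-position flipping*: the matched window in motif orientation
  (reversed for minus-strand matches). Breathing itself is a duplex property
  and is never strand-flipped; only the reporting orientation is.
* *Bubble calls*: the tensor is sliced at the smallest grid length strictly
  exceeding 10 bp (l = 11) and the smallest amplitude strictly exceeding
  3.5 Å (t = 4.0 Å on the default grid), giving one probability per
  position; positions above the dataset-wide 95th percentile of the pooled
  values are flagged. The pool is dataset-wide (not per-sequence) so that one
  threshold defines "bubble-positive" for a whole dataset. At desk-scale
  sampling the sliced values are strongly zero-inflated, so the 95th
  percentile is typically 0 and flagging reduces to "any observed event";
  with dense sampling the threshold becomes a genuine quantile.
* *Bubble near motif*: true when any flagged position is inside the match or
  within an edge distance (inclusive) of 5, 10, or 20 bp; monotone in the
  cutoff by construction.

## Association analyses

Continuous-affinity design: Pearson correlation (t-transform p, n−2 df) of
motif-averaged flipping with affinity over sequences with ≥ 1 match;
per-position correlations Bonferroni-corrected within the motif; Wilcoxon
rank-sum (exact for small tie-free samples, tie- and continuity-corrected
normal approximation otherwise) of affinity by bubble presence; OLS of
affinity on bubble presence either adjusting for
(n_strong, n_weak, best_score) or restricted to sequences without strong
matches (adjusting for n_weak). Constant covariate columns (e.g. no strong
match anywhere) are dropped rather than declared rank deficiency; a singular
design involving the bubble term itself is flagged with no estimate.

Binary design: point-biserial correlation of motif-averaged flipping with
bound status, restricted to matched sequences; TFs with fewer than 3000
bound sequences are excluded (inclusive at exactly 3000); Bonferroni across
analysed TFs. Bubble effect: logistic regression (Newton/IRLS, tol 1e-8,
≤ 100 iterations) of bound status on bubble-near-motif at the strongest match
(ties: higher score, then smaller start, then + strand) with the same motif
covariates; complete separation or non-convergence is flagged with no Wald p.

Affinities are used untransformed on their [0, 1] scale.

## Synthetic data

The generator draws i.i.d. sequences at a target GC content (default 0.41,
genome-like), plants at most one motif instance per sequence (sampled
column-wise from the PFM, rate `plant_prob`), and then — crucially — computes
features with the *real* pipeline before drawing labels:

```
affinity = clamp01(β₀ + β_motif·score_z + β_flip·flip_z + N(0, σ))
bound    ~ Bernoulli(logistic(γ₀ + γ_motif·score_z + γ_bubble·bubble_near₁₀))
```

Features are z-standardised over the dataset; missing motif features are 0
after standardisation. Clamping (not a logistic squash) keeps the linear
model exactly recoverable in the interior; default coefficients
(β₀ = 0.5, β_motif = 0.1, β_flip = 0.15, σ = 0.15) keep the clamp rate below
5%. Defaults for the binary design (γ₀ = 0.5, γ_motif = 0.5, γ_bubble = 1.0)
give roughly 60–65% bound sequences so the peak filter passes at n = 5000.
A zero-variance feature attached to a nonzero coefficient is an error — this
is what makes degenerate configurations (e.g. bubble coupling at a sampling
depth with no bubble events) fail loudly instead of silently.

Because breathing features come from the physical simulator, the generator
reproduces the GC-confounding structure that the regressions must cope with
(GC-rich motifs breathe less), not just parametric noise. What it does *not*
emulate: genomic repeat/composition structure, read-level noise, multiple
motifs per TF, or inter-sequence dependence; a passing recovery test shows
the analysis recovers couplings to its own features under realistic
confounding, not that any particular biological dataset behaves this way.

## Study sizes and test scale

The documented desk-scale study sizes are: continuous-affinity studies at
n = 1000 sequences × 36 bp on the `reduced` profile; binary-label studies at
n = 5000 × 200 bp on the `coarse` profile; oracle comparisons at 2,000
preheat / 20,000 production sweeps with 10 seeds. Recovery experiments hold
sequences and features fixed across replicate label draws — the generator
separates sequence randomness from label randomness by design, so replicate
batteries re-enter only the (cheap) label stage.

## Numerical choices and degenerate inputs

* Probabilities are exact ratios of integer counts; profile/tensor
  invariants (bounds, monotonicity in threshold and length, member-exceedance
  domination) hold identically, not approximately.
* Thresholds requested off-grid resolve to the nearest grid point with a
  warning.
* Degenerate pools (all sliced values equal) yield a threshold equal to that
  value and flag nothing, by the strict-inequality convention.
* Wilcoxon on two identical constant samples returns p = 1; Pearson on a
  zero-variance vector raises rather than returning NaN silently.
* The score lattice rounds down, so scanning never promotes a word across a
  significance boundary.

## Known limitations

* Equilibrium statistics only — no kinetics, no autocorrelation times, no
  Langevin dynamics.
* The default uniform dinucleotide table means stacking is sequence-dependent
  only through the hook, not through a fitted parameter set.
* Absolute bubble probabilities depend on the wall position and the
  parameter set; comparative statements (AT vs GC, hot vs cold, motif vs
  flank) are the supported currency.
* Single-motif analyses; TFs with several PWMs must be run per-PWM.
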