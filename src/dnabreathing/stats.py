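"""Association analyses between breathing features and TF binding.

Four analysis families:

* continuous affinity (gcPBM-style): Pearson correlation of motif-averaged
  flipping probability with affinity, per-motif-position correlations with
  Bonferroni correction within the motif, Wilcoxon rank-sum comparison of
  affinity between bubble-positive and bubble-negative sequences, and OLS of
  affinity on bubble presence with motif covariates (or restricted to
  sequences without strong matches);
* binary binding status (ChIP-seq-style): point-biserial correlation of
  motif-averaged flipping with bound/unbound labels (TFs with fewer than
  ``min_peaks`` bound sequences are excluded), and logistic regression of
  binding on bubble-near-motif with motif covariates.

Standard estimators are delegated to scipy/statsmodels; this module owns the
feature plumbing, filtering rules, covariate construction, and the Bonferroni
bookkeeping that mirror the analysis design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

log = logging.getLogger(__name__)

__all__ = [
    "StatsConfig",
    "AssociationResult",
    "pearson_with_p",
    "per_position_correlations",
    "wilcoxon_rank_sum",
    "ols_bubble_regression",
    "logistic_bubble_regression",
    "chip_flip_analysis",
    "chip_flip_analyses",
    "results_frame",
]


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    multiplicity: str = "bonferroni"
    min_peaks: int = 3000

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.multiplicity != "bonferroni":
            raise ValueError("only bonferroni correction is supported")
        if self.min_peaks < 0:
            raise ValueError("min_peaks must be >= 0")


@dataclass
class AssociationResult:
    """One tested feature-binding relationship."""

    analysis: str           # flip_avg | flip_per_position | bubble_wilcoxon | bubble_ols | bubble_logistic
    tf: str
    effect: float           # r, regression coefficient, or log-odds
    se: float
    p_value: float
    n: int
    significant_corrected: bool | None = None
    position: int | None = None
    note: str = ""


def _drop_missing(*arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    arrays = tuple(np.asarray(a, dtype=float) for a in arrays)
    ok = np.ones(arrays[0].shape[0], dtype=bool)
    for a in arrays:
        ok &= np.isfinite(a if a.ndim == 1 else a).all(axis=-1) if a.ndim > 1 else np.isfinite(a)
    return tuple(a[ok] for a in arrays)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-transform p-value (n-2 df).

    Pairs with a missing value in either vector are dropped listwise.
    Raises on zero variance (correlation undefined).
    """
    x, y = _drop_missing(np.asarray(x, float), np.asarray(y, float))
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def per_position_correlations(
    feature_matrix: np.ndarray,
    y: np.ndarray,
    tf: str = "",
    config: StatsConfig | None = None,
) -> list[AssociationResult]:
    """Independent correlation at each motif position, Bonferroni-corrected
    across the positions of this one motif."""
    config = config or StatsConfig()
    fm = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    if fm.ndim != 2 or fm.shape[0] != y.shape[0]:
        raise ValueError("feature matrix must be [n x W] aligned with y")
    width = fm.shape[1]
    out = []
    for j in range(width):
        xj, yj = _drop_missing(fm[:, j], y)
        try:
            r, p = pearson_with_p(xj, yj)
            note = ""
        except ValueError as exc:
            r, p, note = float("nan"), float("nan"), str(exc)
        out.append(
            AssociationResult(
                analysis="flip_per_position",
                tf=tf,
                effect=r,
                se=float("nan"),
                p_value=p,
                n=int(xj.size),
                significant_corrected=bool(p < config.alpha / width) if np.isfinite(p) else None,
                position=j,
                note=note,
            )
        )
    return out


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum test: exact enumeration for small tie-free samples,
    tie-corrected continuity-corrected normal approximation otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    small = min(a.size, b.size) < 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _bubble_design(
    features: pd.DataFrame,
    mode: str,
    indicator_only: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter rows and build the covariate design for the bubble regressions."""
    df = features.copy()
    if mode == "exclude_strong":
        df = df[df["n_strong"] == 0]
        cols = ["bubble", "n_weak"]
    elif mode == "covariate":
        cols = ["bubble", "n_strong", "n_weak", "best_score"]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if indicator_only:
        df = df.assign(has_motif=((df["n_strong"] + df["n_weak"]) > 0).astype(float))
        cols = ["bubble", "has_motif"] if mode == "covariate" else ["bubble"]
    design = df[[c for c in cols if c in df]].astype(float)
    if "best_score" in design:
        design["best_score"] = design["best_score"].fillna(0.0)
    # constant covariates (e.g. no strong match anywhere) carry no information
    # and would only make the design singular; the bubble term is never dropped
    drop = [c for c in design.columns if c != "bubble" and design[c].nunique() <= 1]
    design = design.drop(columns=drop)
    return df, sm.add_constant(design, has_constant="add")


def ols_bubble_regression(
    affinity: np.ndarray,
    bubble_positive: np.ndarray,
    motif_covariates: pd.DataFrame,
    mode: str = "covariate",
    tf: str = "",
    indicator_only: bool = False,
) -> AssociationResult:
    """OLS of affinity on bubble presence, controlling for motifs.

    ``mode='covariate'`` keeps all sequences and adjusts for
    (n_strong, n_weak, best_score); ``mode='exclude_strong'`` drops sequences
    with any strong match and adjusts for n_weak only.  Reports the bubble
    coefficient.
    """
    df = motif_covariates.copy()
    df["bubble"] = np.asarray(bubble_positive, dtype=float)
    df["__y"] = np.asarray(affinity, dtype=float)
    df, design = _bubble_design(df, mode, indicator_only)
    y = df["__y"]
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        return AssociationResult(
            analysis="bubble_ols", tf=tf, effect=float("nan"), se=float("nan"),
            p_value=float("nan"), n=int(len(df)), note="rank-deficient design",
        )
    fit = sm.OLS(y, design).fit()
    return AssociationResult(
        analysis="bubble_ols",
        tf=tf,
        effect=float(fit.params["bubble"]),
        se=float(fit.bse["bubble"]),
        p_value=float(fit.pvalues["bubble"]),
        n=int(fit.nobs),
        note=mode,
    )


def logistic_bubble_regression(
    bound: np.ndarray,
    bubble_near: np.ndarray,
    motif_covariates: pd.DataFrame | None = None,
    tf: str = "",
) -> AssociationResult:
    """Logistic regression of binding status on bubble-near-motif.

    Maximum likelihood via iteratively reweighted least squares (Newton),
    tolerance 1e-8, at most 100 iterations; Wald SE and p for the bubble term.
    Complete separation (or non-convergence) is flagged with no Wald p.
    """
    y = np.asarray(bound, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("bound labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    df = (motif_covariates.copy() if motif_covariates is not None
          else pd.DataFrame(index=pd.RangeIndex(y.size)))
    df = df.reset_index(drop=True)
    df["bubble"] = np.asarray(bubble_near, dtype=float)
    keep = [c for c in ("bubble", "n_strong", "n_weak", "best_score") if c in df]
    design = df[keep].astype(float)
    if "best_score" in design:
        design["best_score"] = design["best_score"].fillna(0.0)
    design = sm.add_constant(design, has_constant="add")
    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            # separation is detected and reported through the result flag
            _warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(method="newton", tol=1e-8, maxiter=100, disp=False)
        converged = bool(fit.mle_retvals.get("converged", True))
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError):
        converged = False
        fit = None
    if fit is not None and (not converged or np.abs(fit.params).max() > 50
                            or not np.isfinite(fit.bse["bubble"])):
        converged = False
    if not converged:
        return AssociationResult(
            analysis="bubble_logistic", tf=tf, effect=float("nan"), se=float("nan"),
            p_value=float("nan"), n=int(y.size), note="separation or non-convergence",
        )
    return AssociationResult(
        analysis="bubble_logistic",
        tf=tf,
        effect=float(fit.params["bubble"]),
        se=float(fit.bse["bubble"]),
        p_value=float(fit.pvalues["bubble"]),
        n=int(fit.nobs),
    )


def chip_flip_analysis(
    features: pd.DataFrame,
    bound: np.ndarray,
    tf: str = "",
    config: StatsConfig | None = None,
) -> AssociationResult | None:
    """Point-biserial correlation of motif-averaged flipping with bound status.

    The analysis is restricted to sequences with at least one motif match; TFs
    with fewer than ``min_peaks`` bound sequences are excluded (returns None
    with a logged reason).  Bonferroni correction across TFs is applied by
    :func:`chip_flip_analyses`.
    """
    config = config or StatsConfig()
    y = np.asarray(bound, dtype=float)
    n_peaks = int((y == 1).sum())
    if n_peaks < config.min_peaks:
        log.info("TF %s excluded: %d bound sequences < min_peaks=%d", tf, n_peaks, config.min_peaks)
        return None
    has_match = (features["n_strong"] + features["n_weak"]) > 0
    x = features.loc[has_match, "avg_flip_motif"].to_numpy(dtype=float)
    yy = y[np.asarray(has_match)]
    try:
        r, p = pearson_with_p(x, yy)
        note = ""
    except ValueError as exc:
        r, p, note = float("nan"), float("nan"), str(exc)
    return AssociationResult(
        analysis="flip_avg", tf=tf, effect=r, se=float("nan"), p_value=p,
        n=int(x[np.isfinite(x)].size), note=note,
    )


def chip_flip_analyses(
    per_tf: Mapping[str, tuple[pd.DataFrame, np.ndarray]],
    config: StatsConfig | None = None,
) -> list[AssociationResult]:
    """Run :func:`chip_flip_analysis` per TF and Bonferroni-correct across the
    TFs that survive the peak-count filter."""
    config = config or StatsConfig()
    results = []
    for tf, (features, bound) in per_tf.items():
        res = chip_flip_analysis(features, bound, tf=tf, config=config)
        if res is not None:
            results.append(res)
    n_tests = sum(1 for r in results if np.isfinite(r.p_value))
    for r in results:
        r.significant_corrected = (
            bool(r.p_value < config.alpha / n_tests) if np.isfinite(r.p_value) and n_tests else None
        )
    return results


def results_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Flatten association results into the canonical TSV-ready table."""
    return pd.DataFrame(
        [
            {
                "analysis": r.analysis,
                "tf": r.tf,
                "position": r.position if r.position is not None else "",
                "effect": r.effect,
                "se": r.se,
                "p_value": r.p_value,
                "n": r.n,
                "significant_corrected": r.significant_corrected,
                "note": r.note,
            }
            for r in results
        ]
    )


def analyze_gcpbm(
    features: pd.DataFrame,
    affinity: np.ndarray,
    per_position: np.ndarray | None = None,
    per_position_ids: Sequence[str] | None = None,
    tf: str = "TF",
    config: StatsConfig | None = None,
) -> list[AssociationResult]:
    """The continuous-affinity analysis battery for one TF.

    Pooled flip-affinity correlation (sequences with >= 1 match), optional
    per-position correlations, Wilcoxon of affinity by bubble presence, and
    the two bubble OLS designs.
    """
    config = config or StatsConfig()
    affinity = np.asarray(affinity, dtype=float)
    results: list[AssociationResult] = []

    has_match = (features["n_strong"] + features["n_weak"]) > 0
    x = features.loc[has_match, "avg_flip_motif"].to_numpy(dtype=float)
    y = affinity[np.asarray(has_match)]
    r, p = pearson_with_p(x, y)
    results.append(
        AssociationResult(
            analysis="flip_avg", tf=tf, effect=r, se=float("nan"), p_value=p,
            n=int(np.isfinite(x).sum()),
            significant_corrected=bool(p < config.alpha),
        )
    )

    if per_position is not None and per_position.size:
        if per_position_ids is None:
            raise ValueError("per_position_ids required with per_position")
        idx = features.index.get_indexer(list(per_position_ids))
        results.extend(
            per_position_correlations(per_position, affinity[idx], tf=tf, config=config)
        )

    bubble = features["bubble_positive"].to_numpy(dtype=bool)
    if 0 < bubble.sum() < bubble.size:
        stat, p = wilcoxon_rank_sum(affinity[bubble], affinity[~bubble])
        results.append(
            AssociationResult(
                analysis="bubble_wilcoxon", tf=tf,
                effect=float(np.median(affinity[bubble]) - np.median(affinity[~bubble])),
                se=float("nan"), p_value=p, n=int(bubble.size),
                significant_corrected=bool(p < config.alpha),
            )
        )
    else:
        results.append(
            AssociationResult(
                analysis="bubble_wilcoxon", tf=tf, effect=float("nan"), se=float("nan"),
                p_value=float("nan"), n=int(bubble.size),
                note="bubble presence constant across sequences",
            )
        )

    cov = features[["n_strong", "n_weak", "best_score"]]
    for mode in ("covariate", "exclude_strong"):
        res = ols_bubble_regression(affinity, bubble, cov, mode=mode, tf=tf)
        res.significant_corrected = (
            bool(res.p_value < config.alpha) if np.isfinite(res.p_value) else None
        )
        results.append(res)
    return results


def analyze_chip(
    features: pd.DataFrame,
    bound: np.ndarray,
    tf: str = "TF",
    near_cutoff: int = 10,
    config: StatsConfig | None = None,
) -> list[AssociationResult]:
    """The binary-label analysis battery for one TF.

    Point-biserial flip correlation subject to the min-peaks filter, and
    logistic regression of binding on bubble-near-motif (strongest match per
    sequence; sequences without a match are dropped from the bubble analysis).
    """
    config = config or StatsConfig()
    bound = np.asarray(bound, dtype=float)
    results: list[AssociationResult] = []
    flip_res = chip_flip_analysis(features, bound, tf=tf, config=config)
    if flip_res is not None:
        flip_res.significant_corrected = (
            bool(flip_res.p_value < config.alpha) if np.isfinite(flip_res.p_value) else None
        )
        results.append(flip_res)
    col = f"bubble_near_{near_cutoff}"
    if col not in features:
        raise ValueError(f"features table lacks {col}")
    has_match = features[col].notna().to_numpy()
    sub = features.loc[has_match]
    y = bound[has_match]
    if y.size and 0.0 < y.mean() < 1.0:
        res = logistic_bubble_regression(
            y, sub[col].to_numpy(dtype=float),
            sub[["n_strong", "n_weak", "best_score"]], tf=tf,
        )
        res.note = (res.note + f" cutoff={near_cutoff}").strip()
        res.significant_corrected = (
            bool(res.p_value < config.alpha) if np.isfinite(res.p_value) else None
        )
        results.append(res)
    return results
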