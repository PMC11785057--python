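"""Pipeline orchestration: synth -> simulate -> scan -> features -> analyze.

A run is driven by one YAML config with sections mirroring the component
configs field-for-field.  Every stage records a content hash of its inputs
(upstream hashes, relevant config section, input files) in ``cache.json``
beside the outputs; a stage re-runs only when that hash changes or an output
file is missing, so repeated runs are idempotent and a downstream config edit
recomputes only downstream stages.  The fully-resolved config is written
beside the outputs of every run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import io as dio
from . import stats as dstats
from . import synth as dsynth
from .epbd import EPBDParams, MCMCConfig, simulate
from .motifs import ScanConfig, build_pwm, read_jaspar, scan, score_pvalue_table

log = logging.getLogger("dnabreathing.pipeline")

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

_SECTION_TYPES = {
    "epbd": EPBDParams,
    "mcmc": MCMCConfig,
    "scan": ScanConfig,
    "bubble": feat.BubbleCallConfig,
    "stats": dstats.StatsConfig,
}

_SYNTH_KEYS = {
    "n_sequences", "seq_length", "gc_content", "plant_prob",
    "beta0", "beta_motif", "beta_flip", "sigma_noise",
    "gamma0", "gamma_motif", "gamma_bubble",
}

_RUN_KEYS = {"seed", "out_dir", "log_level", "mode", "fasta", "labels", "jaspar", "tf"}


@dataclasses.dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    epbd: EPBDParams
    mcmc: MCMCConfig
    scan: ScanConfig
    bubble: feat.BubbleCallConfig
    stats: dstats.StatsConfig
    synth: dict[str, Any]
    seed: int = 0
    out_dir: str = "out"
    log_level: str = "INFO"
    mode: str = "gcpbm"          # gcpbm | chip
    fasta: str | None = None     # if None, the synth stage generates inputs
    labels: str | None = None
    jaspar: str | None = None    # if None, the bundled E-box fixture
    tf: str = "TF"

    def section_dict(self, name: str) -> dict[str, Any]:
        obj = getattr(self, name)
        if isinstance(obj, dict):
            return dict(obj)
        d = dataclasses.asdict(obj)
        d.pop("seed", None)  # run seed is tracked separately
        return d


def _build_section(name: str, cls, data: dict[str, Any]):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"config section {name!r}: unknown keys {sorted(unknown)}")
    if name == "bubble" and "near_cutoffs" in data:
        data["near_cutoffs"] = tuple(data["near_cutoffs"])
    return cls(**data)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML pipeline config; unknown sections or keys are rejected."""
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        for key, val in overrides.items():
            if isinstance(val, dict):
                raw.setdefault(key, {}).update(val)
            else:
                raw.setdefault("run", {})[key] = val
    known = set(_SECTION_TYPES) | {"synth", "run"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections {sorted(unknown)}")
    sections = {
        name: _build_section(name, cls, dict(raw.get(name, {})))
        for name, cls in _SECTION_TYPES.items()
    }
    synth_raw = dict(raw.get("synth", {}))
    bad = set(synth_raw) - _SYNTH_KEYS
    if bad:
        raise ValueError(f"config section 'synth': unknown keys {sorted(bad)}")
    run_raw = dict(raw.get("run", {}))
    bad = set(run_raw) - _RUN_KEYS
    if bad:
        raise ValueError(f"config section 'run': unknown keys {sorted(bad)}")
    return PipelineConfig(synth=synth_raw, **sections, **run_raw)


def _dump_config(cfg: PipelineConfig, path: Path) -> None:
    data = {name: cfg.section_dict(name) for name in _SECTION_TYPES}
    data["synth"] = cfg.synth
    data["run"] = {
        "seed": cfg.seed, "out_dir": str(cfg.out_dir), "log_level": cfg.log_level,
        "mode": cfg.mode, "fasta": cfg.fasta, "labels": cfg.labels,
        "jaspar": cfg.jaspar, "tf": cfg.tf,
    }
    path.write_text(yaml.safe_dump(data, sort_keys=True))


class _Cache:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "cache.json"
        self.state = json.loads(self.path.read_text()) if self.path.exists() else {}

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        return self.state.get(stage) == key and all(p.exists() for p in outputs)

    def record(self, stage: str, key: str) -> None:
        self.state[stage] = key
        self.path.write_text(json.dumps(self.state, indent=2, sort_keys=True))


def _synth_config(cfg: PipelineConfig, motif) -> dsynth.SynthConfig:
    return dsynth.SynthConfig(
        motif=motif, seed=cfg.seed, params=cfg.epbd, mcmc=cfg.mcmc,
        scan_config=cfg.scan, bubble_config=cfg.bubble, **cfg.synth,
    )


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns a result bundle with stage outputs and timings.

    Raises on any stage failure with the stage name in the message.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cache = _Cache(out)
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}
    _dump_config(cfg, out / "config.resolved.yaml")

    motif = (read_jaspar(cfg.jaspar)[0] if cfg.jaspar else dsynth.default_motif())

    # ---- stage: synth (or external inputs) --------------------------------
    t0 = time.perf_counter()
    if cfg.fasta is None:
        fasta_path = out / "sequences.fasta"
        labels_path = out / "labels.tsv"
        truth_path = out / "truth.yaml"
        key = dio.content_hash("synth", cfg.synth, cfg.section_dict("epbd"),
                               cfg.section_dict("mcmc"), cfg.section_dict("scan"),
                               cfg.section_dict("bubble"), cfg.seed, motif.counts.tolist())
        if not cache.fresh("synth", key, [fasta_path, labels_path]):
            log.info("stage synth: generating %s dataset", cfg.mode)
            scfg = _synth_config(cfg, motif)
            ds = dsynth.generate_dataset(scfg)
            dio.write_fasta(fasta_path, ds.sequences)
            labels = pd.DataFrame({"seq_id": [s.id for s in ds.sequences]})
            if ds.affinity is not None:
                labels["affinity"] = ds.affinity
            if ds.bound is not None:
                labels["bound"] = ds.bound
            labels.to_csv(labels_path, sep="\t", index=False, float_format="%.6g")
            truth = {
                "plants": [p if p is not None else -1 for p in ds.truth["plants"]],
                "affinity_model": ds.truth.get("affinity_model", {}),
                "binding_model": ds.truth.get("binding_model", {}),
            }
            truth_path.write_text(yaml.safe_dump(truth, sort_keys=True))
            cache.record("synth", key)
        else:
            log.info("stage synth: cache hit")
    else:
        fasta_path = Path(cfg.fasta)
        labels_path = Path(cfg.labels) if cfg.labels else None
    timings["synth"] = time.perf_counter() - t0

    records = dio.read_fasta(fasta_path)
    counts["sequences"] = len(records)

    # ---- stage: simulate ---------------------------------------------------
    t0 = time.perf_counter()
    profiles_path = out / "profiles.tsv"
    tensors_path = out / "bubble_tensors.npz"
    key = dio.content_hash("simulate", cfg.section_dict("epbd"), cfg.section_dict("mcmc"),
                           cfg.seed, fasta_path)
    if not cache.fresh("simulate", key, [profiles_path, tensors_path]):
        log.info("stage simulate: %d sequences", len(records))
        profiles, tensors = {}, {}
        try:
            for i, rec in enumerate(records):
                mcmc = cfg.mcmc.with_seed(dio.subseed(cfg.seed, dsynth._STAGE_SIM, i))
                prof, tens = simulate(rec.as_duplex(), params=cfg.epbd, config=mcmc)
                profiles[rec.id] = prof
                tensors[rec.id] = tens
        except Exception as exc:
            raise RuntimeError(f"stage simulate failed on record {rec.id!r}: {exc}") from exc
        dio.write_profiles(profiles_path, profiles)
        dio.write_bubble_tensors(tensors_path, tensors)
        cache.record("simulate", key)
    else:
        log.info("stage simulate: cache hit")
    timings["simulate"] = time.perf_counter() - t0

    # ---- stage: scan -------------------------------------------------------
    t0 = time.perf_counter()
    matches_path = out / "matches.tsv"
    bed_path = out / "matches.bed"
    key = dio.content_hash("scan", cfg.section_dict("scan"), motif.counts.tolist(), fasta_path)
    if not cache.fresh("scan", key, [matches_path, bed_path]):
        pwm = build_pwm(motif)
        table = score_pvalue_table(pwm, cfg.scan)
        try:
            matches = {rec.id: scan(rec, pwm, table, cfg.scan) for rec in records}
        except Exception as exc:
            raise RuntimeError(f"stage scan failed: {exc}") from exc
        dio.write_matches(matches_path, matches, motif.matrix_id)
        dio.matches_to_bed(bed_path, matches, motif.matrix_id)
        cache.record("scan", key)
    else:
        log.info("stage scan: cache hit")
    timings["scan"] = time.perf_counter() - t0

    # ---- stage: features ---------------------------------------------------
    t0 = time.perf_counter()
    features_path = out / "features.tsv"
    key = dio.content_hash("features", cache.state.get("simulate"), cache.state.get("scan"),
                           cfg.section_dict("bubble"))
    if not cache.fresh("features", key, [features_path]):
        profiles = _profiles_from_tsv(profiles_path)
        tensors = dio.read_bubble_tensors(tensors_path)
        matches = _matches_from_tsv(matches_path)
        sliced = {sid: feat.slice_bubble_prob(t, cfg.bubble) for sid, t in tensors.items()}
        table_df = feat.feature_table(profiles, sliced, matches, cfg.bubble)
        table_df = table_df.loc[[r.id for r in records]]
        table_df.to_csv(features_path, sep="\t", float_format="%.6g")
        cache.record("features", key)
    else:
        log.info("stage features: cache hit")
    timings["features"] = time.perf_counter() - t0

    # ---- stage: analyze ----------------------------------------------------
    t0 = time.perf_counter()
    results_path = out / "results.tsv"
    results = None
    if labels_path is not None:
        key = dio.content_hash("analyze", cache.state.get("features"),
                               cfg.section_dict("stats"), cfg.mode, labels_path)
        if not cache.fresh("analyze", key, [results_path]):
            features_df = pd.read_csv(features_path, sep="\t", index_col="seq_id")
            labels = pd.read_csv(labels_path, sep="\t", index_col="seq_id")
            labels = labels.loc[features_df.index]
            profiles = _profiles_from_tsv(profiles_path)
            matches = _matches_from_tsv(matches_path)
            per_pos, pp_ids = feat.per_position_matrix(profiles, matches)
            try:
                if cfg.mode == "gcpbm":
                    results = dstats.analyze_gcpbm(
                        features_df, labels["affinity"].to_numpy(), per_pos, pp_ids,
                        tf=cfg.tf, config=cfg.stats,
                    )
                elif cfg.mode == "chip":
                    results = dstats.analyze_chip(
                        features_df, labels["bound"].to_numpy(), tf=cfg.tf, config=cfg.stats,
                    )
                else:
                    raise ValueError(f"unknown mode {cfg.mode!r}")
            except Exception as exc:
                raise RuntimeError(f"stage analyze failed: {exc}") from exc
            dstats.results_frame(results).to_csv(
                results_path, sep="\t", index=False, float_format="%.6g"
            )
            cache.record("analyze", key)
        else:
            log.info("stage analyze: cache hit")
    timings["analyze"] = time.perf_counter() - t0

    log.info("pipeline done: %s", {k: round(v, 2) for k, v in timings.items()})
    return {
        "out_dir": out,
        "timings": timings,
        "counts": counts,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }


def _profiles_from_tsv(path: Path):
    from .epbd import BreathingProfile

    df = pd.read_csv(path, sep="\t")
    flip_cols = [c for c in df.columns if c.startswith("flip_prob@")]
    grid = np.array([float(c.split("@", 1)[1]) for c in flip_cols])
    out = {}
    for sid, grp in df.groupby("seq_id", sort=False):
        grp = grp.sort_values("position")
        out[sid] = BreathingProfile(
            seq_id=str(sid),
            flip_prob=grp[flip_cols].to_numpy(),
            mean_disp=grp["mean_disp"].to_numpy(),
            mean_sq_disp=grp["mean_sq_disp"].to_numpy(),
            threshold_grid=grid,
            n_samples=0,
        )
    return out


def _matches_from_tsv(path: Path):
    from .motifs import MotifMatch

    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[MotifMatch]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.seq_id), []).append(
            MotifMatch(
                seq_id=str(row.seq_id), start=int(row.start), end=int(row.end),
                strand=str(row.strand), score=float(row.score),
                p_value=float(row.p_value), strength=str(row.strength),
            )
        )
    return out
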