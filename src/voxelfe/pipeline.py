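"""End-to-end synthetic precision study.

Generates a cohort of paired scans, segments both scans of every
participant, builds and solves the requested FE model variants, computes
the mechanical outcomes, and aggregates short-term precision (CV%_RMS),
model comparisons and covariate screens into machine- and human-readable
summaries.  Fully deterministic given the study seed.

Identical scan volumes (e.g. the motion-free control arm, where the
follow-up equals the baseline bit-for-bit) are solved once and served
from a content-addressed cache -- the solver is deterministic, so this
changes nothing but runtime.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from .fe_model import (BCSpec, Model, E_CORT_DEFAULT, E_STM_DEFAULT,
                       E_TRAB_DEFAULT, apply_bc, assign_dtm, assign_stm,
                       build_mesh)
from .fe_solver import SolverConfig, solve
from .outcomes import FailureCriterion, ModelOutcomes, compute_outcomes
from .precision import compare_models, precision_table, spearman_screen
from .segmentation import SegmentationConfig, mean_cross_sectional_area, segment
from .volume import DensityVolume

log = logging.getLogger(__name__)

PRIMARY_OUTCOMES = ("stiffness_kN_mm", "apparent_modulus_MPa", "avg_vm_MPa",
                    "failure_load_kN")
COVARIATES = ("interval_days", "motion_amplitude", "common_region_pct")


@dataclass
class StudyConfig:
    n_participants: int = 30
    seed: int = 0
    site: str = "radius"
    grid_shape: tuple[int, int] = (32, 32)
    n_slices: int = 64
    models: tuple[str, ...] = ("STM", "DTM", "EBMD")
    phantom_variability: dict | None = None
    rescan_distribution: dict | None = None
    include_motion_free_control: bool = True
    stm_modulus: float = E_STM_DEFAULT
    dtm_moduli: tuple[float, float] = (E_CORT_DEFAULT, E_TRAB_DEFAULT)
    ebmd_floor: float = 1.0
    applied_strain: float = 0.01
    failure_variant: str = "strain"
    motion_exclusion_cutoff: float = 0.8
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    out_dir: str = "study_out"

    def validate(self) -> None:
        if not self.models:
            raise ValueError("at least one model variant required")
        for m in self.models:
            Model(m)
        self.segmentation.validate()
        self.solver.validate()

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seg = SegmentationConfig(**raw.pop("segmentation", {}))
        sol = SolverConfig(**raw.pop("solver", {}))
        for key in ("grid_shape", "models", "dtm_moduli"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(segmentation=seg, solver=sol, **raw)
        cfg.validate()
        return cfg


def analyze_scan(vol: DensityVolume, cfg: StudyConfig,
                 ) -> dict[str, ModelOutcomes]:
    """Segment one scan and run every requested model variant on it."""
    bone, peri, labels = segment(vol, cfg.segmentation)
    csa = mean_cross_sectional_area(peri, vol.voxel_size)
    bc = BCSpec(applied_strain=cfg.applied_strain)
    results: dict[str, ModelOutcomes] = {}
    for name in cfg.models:
        model = Model(name)
        if model is Model.EBMD:
            mesh = build_mesh(labels, model, vol=vol, periosteal=peri,
                              E_floor=cfg.ebmd_floor)
        else:
            mesh = build_mesh(labels, model, vol=vol)
            if model is Model.STM:
                assign_stm(mesh, cfg.stm_modulus)
            else:
                assign_dtm(mesh, *cfg.dtm_moduli)
        sol = solve(mesh, bc, cfg.solver)
        crit = FailureCriterion.for_model(model, cfg.failure_variant)
        results[name] = compute_outcomes(sol, mesh, bc, csa, crit)
    return results


class _ScanCache:
    """Content-addressed cache of per-scan model outcomes."""

    def __init__(self, cfg: StudyConfig):
        self.cfg = cfg
        self._store: dict[str, dict[str, ModelOutcomes]] = {}
        self.hits = 0

    def outcomes(self, vol: DensityVolume) -> dict[str, ModelOutcomes]:
        key = hashlib.sha256(
            vol.data.tobytes() + np.float64(vol.voxel_size).tobytes()
        ).hexdigest()
        if key in self._store:
            self.hits += 1
        else:
            self._store[key] = analyze_scan(vol, self.cfg)
        return self._store[key]


@dataclass
class StudyResult:
    outcomes: pd.DataFrame        # long format, incl. arm column
    precision: pd.DataFrame
    metadata: pd.DataFrame
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    summary: dict
    excluded: list[str]
    failed: list[str]


def run_study(cfg: StudyConfig, write: bool = True) -> StudyResult:
    cfg.validate()
    t0 = time.time()
    pairs = ph.generate_cohort(
        cfg.n_participants, cfg.phantom_variability, cfg.rescan_distribution,
        seed=cfg.seed, grid_shape=tuple(cfg.grid_shape),
        n_slices=cfg.n_slices, site=cfg.site)
    meta = ph.cohort_metadata(pairs)

    excluded = [p.participant_id for p in pairs
                if p.motion_amplitude > cfg.motion_exclusion_cutoff]
    analysed = [p for p in pairs if p.participant_id not in excluded]
    if len(analysed) < 2:
        raise RuntimeError("study aborted: fewer than two participants left "
                           f"after {len(excluded)} motion exclusions")

    cache = _ScanCache(cfg)
    rows: list[dict] = []
    registrations: list[dict] = []
    failed: list[str] = []
    for pair in analysed:
        t_part = time.time()
        try:
            reg = ph.register_common_region(pair.baseline, pair.followup)
            scans = {("motion", 1): pair.baseline, ("motion", 2): pair.followup}
            if cfg.include_motion_free_control:
                still = ph.rescan(pair.baseline, ph.RescanSpec())
                scans[("control", 1)] = pair.baseline
                scans[("control", 2)] = still
            for (arm, scan_no), vol in scans.items():
                for model, res in cache.outcomes(vol).items():
                    for outcome, value in res.to_dict().items():
                        if outcome == "model":
                            continue
                        rows.append({"participant_id": pair.participant_id,
                                     "arm": arm, "scan": scan_no,
                                     "model": model, "outcome": outcome,
                                     "value": value})
            registrations.append({"participant_id": pair.participant_id,
                                  "slice_shift_est": reg.slice_shift_est,
                                  "common_region_pct": reg.common_region_pct})
        except Exception as exc:  # noqa: BLE001 - stage failures are recorded
            log.warning("participant %s failed: %s", pair.participant_id, exc)
            failed.append(pair.participant_id)
            continue
        log.info("participant %s done in %.1f s", pair.participant_id,
                 time.time() - t_part)
    if analysed and len(failed) > 0.2 * len(analysed):
        raise RuntimeError(
            f"study aborted: {len(failed)}/{len(analysed)} participants failed")

    outcomes = pd.DataFrame(rows)
    reg_df = pd.DataFrame(registrations)
    meta = meta.merge(reg_df, on="participant_id", how="left")

    precision_frames = []
    for arm, group in outcomes.groupby("arm"):
        tab = precision_table(group)
        tab.insert(0, "arm", arm)
        precision_frames.append(tab)
    precision = pd.concat(precision_frames, ignore_index=True)

    comparisons = _model_comparisons(precision[precision.arm == "motion"])
    correlations = _covariate_screens(
        precision[precision.arm == "motion"], meta)

    summary = _build_summary(cfg, meta, precision, comparisons, correlations,
                             excluded, failed, cache.hits, time.time() - t0)
    result = StudyResult(outcomes=outcomes, precision=precision, metadata=meta,
                         comparisons=comparisons, correlations=correlations,
                         summary=summary, excluded=excluded, failed=failed)
    if write:
        _write_outputs(cfg, result)
    return result


def _model_comparisons(precision: pd.DataFrame) -> pd.DataFrame:
    frames = []
    models = sorted(precision.model.unique())
    if len(models) < 2:
        return pd.DataFrame()
    for outcome in PRIMARY_OUTCOMES:
        sub = precision[precision.outcome == outcome]
        tables = {m: sub[sub.model == m].sort_values("participant_id")
                  .cv_pct.to_numpy() for m in models}
        if len({len(v) for v in tables.values()}) != 1:
            continue
        try:
            comp = compare_models(tables)
        except ValueError:
            continue
        comp.insert(0, "outcome", outcome)
        frames.append(comp)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _covariate_screens(precision: pd.DataFrame,
                       meta: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (model, outcome), sub in precision.groupby(["model", "outcome"]):
        if outcome not in PRIMARY_OUTCOMES:
            continue
        merged = sub.merge(meta, on="participant_id")
        for cov in COVARIATES:
            vals = merged[cov].to_numpy(dtype=float)
            if len(vals) < 3 or np.allclose(vals, vals[0]) or \
                    np.allclose(merged.cv_pct, merged.cv_pct.iloc[0]):
                continue
            res = spearman_screen(merged.cv_pct, vals, name=cov)
            rows.append({"model": model, "outcome": outcome, "covariate": cov,
                         "r_s": res.r_s, "p_value": res.p_value, "n": res.n})
    return pd.DataFrame(rows)


def _build_summary(cfg, meta, precision, comparisons, correlations,
                   excluded, failed, cache_hits, elapsed) -> dict:
    cv_rms: dict = {}
    for (arm, model, outcome), sub in precision.groupby(
            ["arm", "model", "outcome"]):
        cv_rms.setdefault(arm, {}).setdefault(model, {})[outcome] = \
            float(sub.cv_rms_pct.iloc[0])
    reg = meta.dropna(subset=["common_region_pct"]) \
        if "common_region_pct" in meta else meta
    summary = {
        "config": {
            "n_participants": cfg.n_participants, "seed": cfg.seed,
            "site": cfg.site, "grid_shape": list(cfg.grid_shape),
            "n_slices": cfg.n_slices, "models": list(cfg.models),
            "failure_variant": cfg.failure_variant,
        },
        "n_excluded_motion": len(excluded),
        "n_failed": len(failed),
        "cache_hits": cache_hits,
        "cv_rms_pct": cv_rms,
        "common_region": {
            "mean_pct": float(reg.common_region_pct.mean()) if len(reg) else None,
            "min_pct": float(reg.common_region_pct.min()) if len(reg) else None,
            "max_pct": float(reg.common_region_pct.max()) if len(reg) else None,
            "mean_slice_shift": float(reg.slice_shift_est.mean())
            if len(reg) else None,
        },
        "comparisons": comparisons.to_dict(orient="records"),
        "correlations": correlations.to_dict(orient="records"),
        "elapsed_s": round(elapsed, 1),
    }
    return summary


def _write_outputs(cfg: StudyConfig, result: StudyResult) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.outcomes.to_csv(out / "outcomes.csv", index=False)
    result.precision.to_csv(out / "precision.csv", index=False)
    result.metadata.to_csv(out / "cohort_metadata.csv", index=False)
    summary = dict(result.summary)
    summary.pop("elapsed_s", None)  # keep the JSON byte-reproducible
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "report.txt", "w") as fh:
        fh.write(_render_report(cfg, result))


def _render_report(cfg: StudyConfig, result: StudyResult) -> str:
    lines = [
        f"Synthetic precision study (seed {cfg.seed})",
        f"site={cfg.site}  n={cfg.n_participants}  "
        f"grid={cfg.grid_shape[0]}x{cfg.grid_shape[1]}x{cfg.n_slices}",
        f"models: {', '.join(cfg.models)}",
        f"excluded for motion: {len(result.excluded)}; "
        f"failed: {len(result.failed)}",
        "",
        "CV%_RMS by arm / model / outcome:",
    ]
    for arm, models in sorted(result.summary["cv_rms_pct"].items()):
        for model, outs in sorted(models.items()):
            for outcome, v in sorted(outs.items()):
                lines.append(f"  {arm:8s} {model:5s} {outcome:24s} {v:8.3f} %")
    cr = result.summary["common_region"]
    if cr["mean_pct"] is not None:
        lines += ["", f"common region: mean {cr['mean_pct']:.1f} % "
                      f"(range {cr['min_pct']:.1f}-{cr['max_pct']:.1f} %), "
                      f"mean slice shift {cr['mean_slice_shift']:+.1f}"]
    if len(result.correlations):
        lines += ["", "Spearman screens (motion arm):"]
        for r in result.correlations.to_dict(orient="records"):
            lines.append(f"  {r['model']:5s} {r['outcome']:24s} "
                         f"{r['covariate']:18s} r_s={r['r_s']:+.3f} "
                         f"p={r['p_value']:.4f}")
    return "\n".join(lines) + "\n"
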