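"""End-to-end pipeline: simulate -> preprocess -> synchrony -> surrogate ->
behavior -> outcomes -> models -> mediate.

Every stage reads and writes plain files (CSV/JSON) under an output directory
so any stage can be inspected or replaced, and a run manifest records the
config hash, seeds, file checksums and per-stage counts.  Subset runs are
allowed when the upstream artifacts already exist; a missing artifact raises
an error naming the stage that produces it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotations as ann
from . import bayes, mediation, outcomes, preprocess, simulate, surrogate, wtc

STAGES = ["simulate", "preprocess", "synchrony", "surrogate", "behavior",
          "outcomes", "models", "mediate"]

DEFAULT_CONFIG = {
    "seed": 0,
    "n_dyads_per_condition": 2,
    "sampling_rate_hz": 7.81,
    "phase_plan": [["manipulation", 600.0, 282.0], ["free_interaction", 600.0, 60.0]],
    "coupling_period_band_s": [8.0, 75.0],
    "coupling_strength": 0.3,
    "motion_rate_per_min": 0.0,
    "structural": {"a_path": 0.0, "b_path": 0.0, "c_prime": 0.0,
                   "sd_mediator_noise": 1.0, "sd_outcome_noise": 1.0},
    "surrogate": {"n_surrogates": 5},
    "models": {"chains": 2, "iterations": 600,
               "synchrony_intercept_prior": [0.3, 0.2]},
    "mediation": {"draws": 600, "chains": 2},
}


def validate_config(config: dict | str | Path) -> list[str]:
    """Schema and cross-field checks; returns a list of warnings, raises on errors."""
    if not isinstance(config, dict):
        config = load_config(config)
    warnings = []
    errors = []
    for key in ("n_dyads_per_condition", "sampling_rate_hz", "phase_plan",
                "coupling_period_band_s"):
        if key not in config:
            errors.append(f"/{key}: required key missing")
    if errors:
        raise ValueError("; ".join(errors))
    if not isinstance(config["n_dyads_per_condition"], int) or config["n_dyads_per_condition"] < 1:
        errors.append("/n_dyads_per_condition: must be a positive integer")
    band = config["coupling_period_band_s"]
    for i, (label, dur, pre) in enumerate(config["phase_plan"]):
        if dur <= 0 or pre < 0:
            errors.append(f"/phase_plan/{i}: durations must be positive")
        elif band[1] > dur / 4.0:
            errors.append(
                f"/phase_plan/{i}: coupling band upper bound {band[1]} s exceeds a "
                f"quarter of the {label} duration ({dur} s)"
            )
    if "seed" not in config:
        config["seed"] = 0
        warnings.append("/seed: missing; auto-seed 0 recorded")
    if errors:
        raise ValueError("; ".join(errors))
    return warnings


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    merged.update(cfg or {})
    return merged


def _sim_config(cfg: dict, seed: int | None = None) -> simulate.SimulationConfig:
    return simulate.SimulationConfig(
        n_dyads_per_condition=cfg["n_dyads_per_condition"],
        sampling_rate_hz=cfg["sampling_rate_hz"],
        phase_plan=tuple((p[0], float(p[1]), float(p[2])) for p in cfg["phase_plan"]),
        coupling_period_band_s=tuple(cfg["coupling_period_band_s"]),
        coupling_strength=cfg["coupling_strength"],
        motion_rate_per_min=cfg.get("motion_rate_per_min", 0.0),
        seed=cfg["seed"] if seed is None else seed,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, producing_stage: str):
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path.name}; run the {producing_stage!r} stage first"
        )
    return path


class PipelineRun:
    """Stateful runner holding the config, output directory and manifest."""

    def __init__(self, config: dict, out_dir: str | Path, seed: int | None = None):
        self.cfg = config
        self.warnings = validate_config(config)
        if seed is not None:
            self.cfg["seed"] = seed
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = {
            "config_hash": hashlib.sha256(
                json.dumps(config, sort_keys=True).encode()).hexdigest(),
            "seed": self.cfg["seed"],
            "stages": {},
            "files": {},
            "warnings": self.warnings,
        }
        self._cohort = None

    # -- helpers -----------------------------------------------------------

    def _record(self, stage: str, files: list[Path], **counts):
        self.manifest["stages"][stage] = counts
        for f in files:
            self.manifest["files"][f.name] = _sha256(f)

    def cohort(self) -> simulate.Cohort:
        if self._cohort is None:
            st = self.cfg["structural"]
            self._cohort = simulate.generate_cohort(
                _sim_config(self.cfg), simulate.StructuralParams(**st))
        return self._cohort

    def _windows(self):
        return [ann.PhaseWindow(label, start, end, pre)
                for label, start, end, pre in
                simulate.phase_windows(_sim_config(self.cfg))]

    # -- stages ------------------------------------------------------------

    def stage_simulate(self):
        cohort = self.cohort()
        files = []
        rec_dir = self.out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for rec in cohort.recordings:
            for phase, data in rec.phases.items():
                for p in (0, 1):
                    f = rec_dir / f"dyad{rec.dyad_id:03d}_p{p}_{phase}.csv"
                    df = pd.DataFrame(data[p].T, columns=[
                        f"ch{c:02d}_{roi}" for c, roi in enumerate(rec.channel_rois)])
                    df.to_csv(f, index=False)
                    files.append(f)
        f_ann = self.out / "annotations.tsv"
        cohort.annotations.to_csv(f_ann, sep="\t", index=False)
        f_out = self.out / "questionnaire.csv"
        cohort.outcomes.to_csv(f_out, index=False)
        f_gt = self.out / "ground_truth.csv"
        cohort.ground_truth.to_csv(f_gt, index=False)
        files += [f_ann, f_out, f_gt]
        self._record("simulate", files, n_dyads=len(cohort.recordings),
                     n_participants=2 * len(cohort.recordings))

    def stage_preprocess(self):
        cohort = self.cohort()
        params = preprocess.PreprocessParams()
        report = {"bad_channels": {}, "excluded_dyads_per_roi_pair": {}}
        pairs = wtc.enumerate_roi_pairs(cohort.config.rois)
        roi_bad = {}
        for rec in cohort.recordings:
            for p in (0, 1):
                raw = simulate.recording_to_intensity(rec, list(rec.phases)[0], p)
                flags = preprocess.channel_quality(raw, params.cv_thresh)
                roi_bad[(rec.dyad_id, p)] = preprocess.roi_quality(flags, rec.channel_rois)
                report["bad_channels"][f"dyad{rec.dyad_id}_p{p}"] = int(flags.sum())
        for pair in pairs:
            excluded = [rec.dyad_id for rec in cohort.recordings
                        if preprocess.dyad_roi_pair_exclusions(
                            roi_bad[(rec.dyad_id, 0)], roi_bad[(rec.dyad_id, 1)], [pair])[pair]]
            report["excluded_dyads_per_roi_pair"][pair] = excluded
        f = self.out / "quality_report.json"
        f.write_text(json.dumps(report, indent=2))
        self._record("preprocess", [f],
                     n_bad_channels=int(sum(report["bad_channels"].values())))

    def stage_synchrony(self):
        cohort = self.cohort()
        tables = [wtc.dyad_synchrony(rec) for rec in cohort.recordings]
        table = pd.concat(tables, ignore_index=True)
        f = self.out / "synchrony.csv"
        table.to_csv(f, index=False)
        self._record("synchrony", [f], n_rows=len(table),
                     n_missing=int(table["wtc_value"].isna().sum()))

    def stage_surrogate(self):
        cohort = self.cohort()
        plan = surrogate.SurrogatePlan(
            n_surrogates=self.cfg["surrogate"]["n_surrogates"], seed=self.cfg["seed"])
        pairs = self.cfg["surrogate"].get("roi_pairs") or \
            wtc.enumerate_roi_pairs(cohort.config.rois)
        phase = cohort.config.phase_plan[0][0]
        table = surrogate.cohort_surrogate_table(cohort.recordings, plan, pairs, phase)
        f = self.out / "surrogate.csv"
        table.to_csv(f, index=False)

        real = pd.read_csv(_require(self.out / "synchrony.csv", "synchrony"))
        report = {}
        mcfg = self.cfg["models"]
        for pair in pairs:
            rv = real.query("roi_pair == @pair and phase == @phase")["wtc_value"].dropna()
            sv = table.query("roi_pair == @pair")["wtc_value"].dropna()
            if len(rv) < 2 or len(sv) < 2:
                continue
            res = surrogate.real_vs_surrogate(
                rv, sv, chains=mcfg["chains"], iterations=mcfg["iterations"],
                seed=self.cfg["seed"])
            s = res.summary().loc["b_is_real"]
            report[pair] = {"difference_mean": s["mean"],
                            "eti": [s["eti_low"], s["eti_high"]],
                            "rhat": None if np.isnan(s["rhat"]) else s["rhat"]}
        f2 = self.out / "surrogate_comparison.json"
        f2.write_text(json.dumps(report, indent=2))
        self._record("surrogate", [f, f2], n_rows=len(table))

    def stage_behavior(self):
        f_ann = _require(self.out / "annotations.tsv", "simulate")
        table = ann.behavior_table(pd.read_csv(f_ann, sep="\t"), self._windows())
        f = self.out / "behavior.csv"
        table.to_csv(f, index=False)
        self._record("behavior", [f], n_dyads=len(table))

    def stage_outcomes(self):
        f_q = _require(self.out / "questionnaire.csv", "simulate")
        f_s = _require(self.out / "synchrony.csv", "synchrony")
        f_b = _require(self.out / "behavior.csv", "behavior")
        dataset = outcomes.build_dyad_dataset(
            pd.read_csv(f_q), pd.read_csv(f_s), pd.read_csv(f_b))
        f = self.out / "dyad_dataset.csv"
        dataset.to_csv(f, index=False)
        self._record("outcomes", [f], n_dyads=len(dataset),
                     n_dropped=len(dataset.attrs.get("dropped", {})))

    def stage_models(self):
        f_d = _require(self.out / "dyad_dataset.csv", "outcomes")
        df = pd.read_csv(f_d)
        mcfg = self.cfg["models"]
        out = {}
        # manipulation check: laughter amount ~ Laughter * Social
        beh = pd.read_csv(_require(self.out / "behavior.csv", "behavior"))
        gt = pd.read_csv(_require(self.out / "ground_truth.csv", "simulate"))
        mc = beh.merge(gt[["dyad_id", "laughter", "social"]], on="dyad_id")
        res = bayes.bayesian_anova(mc, "total_manipulation_s", ["laughter", "social"],
                                   chains=mcfg["chains"], iterations=mcfg["iterations"],
                                   seed=self.cfg["seed"])
        out["manipulation_check"] = json.loads(res.summary().to_json(orient="index"))
        # one synchrony model per ROI pair would be long; fit the first pair as example
        sync_cols = [c for c in df.columns if c.startswith("sync_")]
        ip = mcfg.get("synchrony_intercept_prior", [0.3, 0.2])
        priors = bayes.PriorSpec(intercept_mean=ip[0], intercept_sd=ip[1])
        if sync_cols and {"laughter", "social", "lbmp"} <= set(df.columns):
            col = sync_cols[0]
            fit = bayes.fit_hierarchical(df, f"{col} ~ laughter*social + lbmp",
                                         chains=mcfg["chains"],
                                         iterations=mcfg["iterations"],
                                         seed=self.cfg["seed"], priors=priors)
            out["synchrony_model_example"] = {
                "roi_pair": col,
                "summary": json.loads(fit.summary().to_json(orient="index")),
                "converged": fit.converged,
            }
        f = self.out / "models.json"
        f.write_text(json.dumps(out, indent=2))
        self._record("models", [f], n_models=len(out))

    def stage_mediate(self):
        f_d = _require(self.out / "dyad_dataset.csv", "outcomes")
        df = pd.read_csv(f_d)
        sync_cols = [c for c in df.columns if c.startswith("sync_")]
        mcfg = self.cfg["mediation"]
        grid = mediation.mediation_grid(
            df, treatments=["lbmp"], mediator_columns=sync_cols[:2] or sync_cols,
            outcomes=["liking2_sum"], covariates=[c for c in ("social",) if c in df],
            seed=self.cfg["seed"], draws=mcfg["draws"], chains=mcfg["chains"])
        f = self.out / "mediation.csv"
        grid.to_csv(f, index=False)
        self._record("mediate", [f], n_cells=len(grid))

    # -- driver ------------------------------------------------------------

    def run(self, stages=None) -> dict:
        todo = STAGES if stages is None else [s for s in STAGES if s in set(stages)]
        unknown = set(stages or []) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; choose from {STAGES}")
        for s in todo:
            getattr(self, f"stage_{s}")()
        f = self.out / "manifest.json"
        f.write_text(json.dumps(self.manifest, indent=2, default=str))
        return self.manifest


def run(config_path: str | Path | dict, stages=None, out_dir: str | Path = "dyadsync_out",
        seed: int | None = None) -> dict:
    """Execute the pipeline (or a stage subset) and return the run manifest."""
    cfg = config_path if isinstance(config_path, dict) else load_config(config_path)
    return PipelineRun(cfg, out_dir, seed=seed).run(stages)
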