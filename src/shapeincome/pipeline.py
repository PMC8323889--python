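"""End-to-end orchestration: generate -> embed -> diagnose -> estimate.

One JSON config drives the whole run.  Each stage writes plain CSV/JSON
artifacts into the output directory, a manifest records per-stage config
hashes and seeds, and unchanged upstream stages are reused on rerun (keyed
by their config hash).  Stage seeds are derived deterministically from the
top-level seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import autoencoder as ae
from . import income as inc
from . import reporting as rep
from . import synthetic as syn
from .meshes import flatten_cohort

__all__ = ["RunConfig", "ResultsBundle", "validate_config", "run"]

logger = logging.getLogger("shapeincome")

DEFAULT_CONFIG = {
    "seed": 0,
    "output_dir": "shapeincome_run",
    "stages": {"generate": True, "embed": True,
               "diagnose_errors": True, "estimate": True},
    "cohort": {"n_subjects": 600, "rings": 16, "segments": 12},
    "embedding": {
        "hidden_widths": [64, 32, 16],
        "epochs": 500,
        "batch_size": 100,
        "learning_rate": 3e-3,
        "final_learning_rate": 3e-5,
        "d_candidates": [1, 2, 3, 4],
        "gain_threshold": 0.05,
        "scan": True,
        "fixed_d": {"male": 2, "female": 3},
    },
    "reporting": {"n_boot": 300, "band_level": 0.95, "grid_points": 101},
    "estimation": {"bootstrap_B": 200, "band_level": 0.90,
                   "control_function": True,
                   "classical_terms": ["measured_height", "bmi", "hip_to_waist"]},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults merged in)."""

    raw: dict

    @classmethod
    def from_path(cls, path: str | Path) -> "RunConfig":
        try:
            user = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"config {path} is not valid JSON: {exc}") from exc
        cfg = cls(_merge(DEFAULT_CONFIG, user))
        problems = validate_config_dict(cfg.raw)
        if problems:
            raise ValueError("invalid config:\n" + "\n".join(problems))
        return cfg

    def section(self, name: str) -> dict:
        return self.raw[name]

    def stage_hash(self, stage: str) -> str:
        dep = {
            "generate": ["seed", "cohort"],
            "embed": ["seed", "cohort", "embedding"],
            "diagnose_errors": ["seed", "cohort", "reporting"],
            "estimate": ["seed", "cohort", "embedding", "estimation"],
        }[stage]
        blob = json.dumps({k: self.raw[k] for k in dep}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config_dict(cfg: dict) -> list[str]:
    """Schema and invariant checks; returns a list of '<json.path>: problem'."""
    probs: list[str] = []

    def need(cond, path, msg):
        if not cond:
            probs.append(f"{path}: {msg}")

    need(isinstance(cfg.get("seed"), int), "seed", "must be an integer")
    co = cfg.get("cohort", {})
    need(isinstance(co.get("n_subjects"), int) and co.get("n_subjects", 0) >= 2,
         "cohort.n_subjects", "must be an integer >= 2")
    need(co.get("rings", 16) >= 8, "cohort.rings", "must be >= 8")
    need(co.get("segments", 12) >= 8, "cohort.segments", "must be >= 8")
    for k, v in co.get("noise_scales", {}).items():
        need(v >= 0, f"cohort.noise_scales.{k}", "must be >= 0")
    em = cfg.get("embedding", {})
    need(em.get("epochs", 1) >= 1, "embedding.epochs", "must be >= 1")
    need(em.get("batch_size", 1) >= 1, "embedding.batch_size", "must be >= 1")
    need(0 < em.get("gain_threshold", 0.05) < 1,
         "embedding.gain_threshold", "must be in (0, 1)")
    need(len(em.get("d_candidates", [1, 2])) >= 2,
         "embedding.d_candidates", "need at least two candidates")
    rp = cfg.get("reporting", {})
    need(rp.get("n_boot", 100) >= 100, "reporting.n_boot", "must be >= 100")
    need(0 < rp.get("band_level", 0.95) < 1, "reporting.band_level",
         "must be in (0, 1)")
    need(rp.get("grid_points", 101) >= 2, "reporting.grid_points", "must be >= 2")
    es = cfg.get("estimation", {})
    need(es.get("bootstrap_B", 100) >= 100, "estimation.bootstrap_B",
         "must be >= 100")
    need(0 < es.get("band_level", 0.9) < 1, "estimation.band_level",
         "must be in (0, 1)")
    try:
        syn.CohortConfig(**{k: v for k, v in co.items()})
    except (TypeError, ValueError) as exc:
        probs.append(f"cohort: {exc}")
    return probs


def validate_config(config_path: str | Path) -> list[str]:
    """Validate a config file without running anything."""
    try:
        user = json.loads(Path(config_path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        return [f"<file>: {exc}"]
    return validate_config_dict(_merge(DEFAULT_CONFIG, user))


@dataclass
class ResultsBundle:
    """Where everything landed, plus the manifest for traceability."""

    output_dir: Path
    manifest: dict
    partial: bool = False
    artifacts: dict = field(default_factory=dict)

    def content_hash(self) -> str:
        """Hash of all artifact files (manifest excluded): rerun determinism."""
        h = hashlib.sha256()
        for p in sorted(self.output_dir.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                h.update(p.relative_to(self.output_dir).as_posix().encode())
                h.update(p.read_bytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_generate(cfg: RunConfig, outdir: Path) -> syn.CohortData:
    co = dict(cfg.section("cohort"))
    co["seed"] = cfg.raw["seed"]
    cohort = syn.generate_cohort(syn.CohortConfig(**co))
    syn.write_cohort(cohort, outdir / "cohort", write_meshes=False,
                     write_latents=True)
    return cohort

def _load_generate(outdir: Path, cfg: RunConfig) -> syn.CohortData:
    co = dict(cfg.section("cohort"))
    co["seed"] = cfg.raw["seed"]
    return syn.generate_cohort(syn.CohortConfig(**co))  # regenerate (cheap, exact)


def _stage_embed(cfg: RunConfig, cohort: syn.CohortData, outdir: Path) -> pd.DataFrame:
    em = cfg.section("embedding")
    seed = cfg.raw["seed"] + 1
    edir = outdir / "embed"
    edir.mkdir(parents=True, exist_ok=True)
    table = inc.augment_table(cohort.table)
    pcols: dict[int, dict] = {}
    for gender in ("male", "female"):
        mask = (cohort.table["gender"] == gender).to_numpy()
        meshes = [m for m, keep in zip(cohort.meshes, mask) if keep]
        if not meshes:
            continue
        ids = cohort.table.loc[mask, "id"].tolist()
        ds = flatten_cohort(meshes, center=True, scale=True, subject_ids=ids)
        tc = ae.TrainConfig(
            epochs=em["epochs"], batch_size=em["batch_size"],
            learning_rate=em["learning_rate"],
            final_learning_rate=em["final_learning_rate"], seed=seed)
        if em.get("scan", True):
            scan = ae.scan_intrinsic_dimension(
                ds, em["d_candidates"], em["gain_threshold"],
                tuple(em["hidden_widths"]), tc)
            d = scan.chosen_d
            (edir / f"{gender}_scan.json").write_text(json.dumps({
                "chosen_d": d, "gain_threshold": scan.gain_threshold,
                "validation_mse": {str(k): v for k, v in scan.validation_mse.items()},
                "warnings": scan.warnings}, indent=2) + "\n")
        else:
            d = em["fixed_d"][gender]
        spec = ae.EncoderSpec(ds.n_inputs, d, tuple(em["hidden_widths"]))
        res = ae.GraphicalAutoencoder(ds, spec, tc).fit()
        res.loss_curves.to_csv(edir / f"{gender}_loss_curves.csv", index=False)

        meas_cols = ["measured_height", "measured_weight", "hip_to_waist"][:d]
        meas = table.loc[mask, meas_cols]
        P_aligned, labels = ae.align_to_measurements(res.P, meas)
        r2 = ae.correlate_with_measurements(
            P_aligned, table.loc[mask, ["measured_height", "measured_weight", "bmi"]])
        r2.to_csv(edir / f"{gender}_r2_table.csv", index=False)
        pdf = pd.DataFrame(P_aligned, columns=[f"P{i+1}" for i in range(d)])
        pdf.insert(0, "id", ids)
        pdf.to_csv(edir / f"{gender}_P.csv", index=False)
        for i, sid in enumerate(ids):
            pcols[sid] = {f"P{j+1}": P_aligned[i, j] for j in range(d)}
    for j in range(1, 4):
        col = f"P{j}"
        table[col] = [pcols.get(sid, {}).get(col, np.nan) for sid in table["id"]]
    # 17 significant digits: the cached-reuse path re-reads this file and
    # must reproduce the in-memory doubles bit for bit
    table.to_csv(edir / "subjects_with_P.csv", index=False, float_format="%.17g")
    return table


def _stage_diagnose(cfg: RunConfig, cohort: syn.CohortData, outdir: Path) -> dict:
    rp = cfg.section("reporting")
    seed = cfg.raw["seed"] + 2
    ddir = outdir / "errors"
    ddir.mkdir(parents=True, exist_ok=True)
    crossings: dict = {}
    for gender in ("male", "female"):
        sub = cohort.table[cohort.table["gender"] == gender]
        if len(sub) < 10:
            continue
        for variable, rep_col, meas_col in (
                ("height", "reported_height", "measured_height"),
                ("weight", "reported_weight", "measured_weight")):
            series = rep.compute_reporting_errors(
                sub[rep_col].to_numpy(), sub[meas_col].to_numpy(),
                variable=variable, gender=gender)
            grid = rep.default_grid(series.truth, rp["grid_points"])
            curve = rep.KernelRegression(series).fit_with_bands(
                grid=grid, B=rp["n_boot"], level=rp["band_level"], seed=seed)
            curve.to_frame().to_csv(
                ddir / f"{gender}_{variable}_curve.csv", index=False)
            crossings[f"{gender}_{variable}"] = {
                "zero_crossings": rep.zero_crossing(curve),
                "bandwidth": curve.bandwidth,
            }
    (ddir / "crossings.json").write_text(json.dumps(crossings, indent=2) + "\n")
    return crossings


def _fit_to_frame(fit: inc.IncomeResults, bands: inc.BootstrapBands) -> pd.DataFrame:
    out = pd.DataFrame({
        "coefficient": fit.params, "robust_se": fit.bse,
        "t": fit.tvalues, "p": fit.pvalues,
    })
    out = out.join(bands.bands[["lower", "upper"]])
    return out


def _stage_estimate(cfg: RunConfig, table: pd.DataFrame, outdir: Path) -> dict:
    es = cfg.section("estimation")
    seed = cfg.raw["seed"] + 3
    sdir = outdir / "estimate"
    sdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    for gender in ("male", "female"):
        sub = table[table["gender"] == gender]
        if len(sub) < 50:
            continue
        d = 3 if (gender == "female" and sub["P3"].notna().all()) else 2
        pterms = tuple(f"P{i+1}" for i in range(d))
        entry: dict = {}
        for label, terms in (("deep_learned", pterms),
                             ("classical", tuple(es["classical_terms"]))):
            spec = inc.ModelSpec(body_terms=terms, gender=gender)
            model = inc.IncomeModel(table, spec)
            fit = model.fit()
            bands = inc.bootstrap_fit(model, B=es["bootstrap_B"],
                                      level=es["band_level"], seed=seed)
            frame = _fit_to_frame(fit, bands)
            frame.to_csv(sdir / f"{gender}_{label}_fit.csv")
            entry[label] = {
                term: {"coefficient": float(fit.params[term]),
                       "lower": float(bands.bands.loc[term, "lower"]),
                       "upper": float(bands.bands.loc[term, "upper"])}
                for term in terms
            }
            entry[label]["adj_r_squared"] = float(fit.rsquared_adj)
            entry[label]["n"] = int(fit.nobs)
        if es.get("control_function", True):
            spec = inc.ModelSpec(
                body_terms=pterms, gender=gender, endogenous_term="P1",
                instruments=("shoe_size", "garment_size", "pants_size"))
            cf = inc.ControlFunctionModel(table, spec).fit()
            entry["control_function"] = {
                "stature_coefficient": float(cf.params["P1"]),
                "exogeneity_tstat": cf.exogeneity_tstat,
                "exogeneity_pvalue": cf.exogeneity_pvalue,
                "first_stage_F": cf.first_stage_F,
                "weak_instruments": cf.weak_instruments,
            }
        summary[gender] = entry
    (sdir / "income_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def run(config_path: str | Path, output_dir: str | Path | None = None) -> ResultsBundle:
    """Execute the enabled stages in dependency order.

    Stage outputs land under the config's ``output_dir`` (overridable).  A
    stage whose config hash matches the previous run's manifest is reused
    rather than recomputed.  On stage failure the bundle is marked partial
    and downstream stages are skipped.
    """
    cfg = RunConfig.from_path(config_path)
    outdir = Path(output_dir or cfg.raw["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    previous = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {})
    manifest: dict = {"seed": cfg.raw["seed"], "stages": {},
                      "config": cfg.raw, "started": time.strftime("%Y-%m-%dT%H:%M:%S")}
    stages = cfg.section("stages")
    bundle = ResultsBundle(output_dir=outdir, manifest=manifest)

    cohort = table = None
    order = ["generate", "embed", "diagnose_errors", "estimate"]
    failed = False
    for stage in order:
        if not stages.get(stage, True) or failed:
            continue
        shash = cfg.stage_hash(stage)
        cached = previous.get("stages", {}).get(stage, {}).get("hash") == shash
        t0 = time.time()
        try:
            if stage == "generate":
                cohort = (_load_generate(outdir, cfg) if cached
                          else _stage_generate(cfg, outdir))
            elif stage == "embed":
                if cohort is None:
                    cohort = _load_generate(outdir, cfg)
                path = outdir / "embed" / "subjects_with_P.csv"
                if cached and path.exists():
                    table = pd.read_csv(path, float_precision="round_trip")
                else:
                    table = _stage_embed(cfg, cohort, outdir)
                    cached = False
            elif stage == "diagnose_errors":
                if cohort is None:
                    cohort = _load_generate(outdir, cfg)
                bundle.artifacts["crossings"] = _stage_diagnose(cfg, cohort, outdir)
            elif stage == "estimate":
                if table is None:
                    raise RuntimeError("estimate stage needs the embed stage output")
                bundle.artifacts["income_summary"] = _stage_estimate(cfg, table, outdir)
            manifest["stages"][stage] = {
                "hash": shash, "cached": bool(cached),
                "seconds": round(time.time() - t0, 2), "status": "ok"}
            logger.info(json.dumps({"stage": stage, "status": "ok",
                                    "seconds": round(time.time() - t0, 2)}))
        except Exception as exc:  # stage failure: mark partial, skip downstream
            manifest["stages"][stage] = {"hash": shash, "status": "failed",
                                         "error": str(exc)}
            logger.error(json.dumps({"stage": stage, "status": "failed",
                                     "error": str(exc)}))
            bundle.partial = True
            failed = True
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return bundle
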