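"""End-to-end orchestration: manifest -> preprocess -> thin-limit selection
-> PARAFAC factor sweep -> diagnostics -> report bundle.

Every stage logs its effective parameters and derived seeds so a sweep table
is auditable: each number in the report is recomputable from the archived
preprocessed EEMs and the logged options.  A single master seed fans out to
per-stage seeds by stable hashing.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diagnostics import (concentration_ratio_at_score, discrepancy_maps,
                          per_sample_fit, score_df_curves)
from .eem_core import (EEM, EEMTensor, SampleRecord, read_eem, read_manifest,
                       stack_eems, write_eem)
from .errors import OutOfRangeError, PipelineError
from .inner_filter import THIN_LIMIT_DF, select_thin_limit
from .parafac import FitOptions, core_consistency, fit_parafac, match_factors, model_sweep
from .preprocess import ScatterBandConfig, preprocess_eem, residual_scatter_level

__all__ = ["PipelineConfig", "run_pipeline", "subset_runs", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the master seed."""
    h = np.uint64(1469598103934665603)  # FNV-1a
    for b in f"{master_seed}:{stage}".encode():
        h = np.uint64((int(h) ^ b) * 1099511628211 % (1 << 64))
    return int(h % (1 << 31))


@dataclass
class PipelineConfig:
    manifest: str
    outdir: str
    blank_policy: str = "subtract"          # subtract | none
    scatter: ScatterBandConfig = field(default_factory=ScatterBandConfig)
    thin_limit_threshold: float = THIN_LIMIT_DF
    thin_limit_overrides: list[str] = field(default_factory=list)
    fit: FitOptions = field(default_factory=FitOptions)
    F_range: tuple[int, int] = (1, 7)
    report_factors: int | None = None       # None -> best core consistency F >= 2
    window_fraction: float = 0.10
    score_level: float = 1000.0
    clip_negative: bool = False
    zero_below_rayleigh: bool = True
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scatter = ScatterBandConfig(**raw.pop("scatter", {})) \
            if isinstance(raw.get("scatter"), dict) else ScatterBandConfig()
        raw.pop("scatter", None)
        fit_raw = raw.pop("fit", {})
        if isinstance(fit_raw.get("nonneg"), list):
            fit_raw["nonneg"] = tuple(fit_raw["nonneg"])
        fit = FitOptions(**fit_raw)
        fr = raw.pop("F_range", (1, 7))
        return cls(scatter=scatter, fit=fit, F_range=tuple(fr), **raw)


def _load_inputs(config: PipelineConfig):
    manifest_path = Path(config.manifest)
    if not manifest_path.exists():
        raise PipelineError("load", f"manifest {manifest_path} does not exist")
    pairs = read_manifest(manifest_path)
    if not pairs:
        raise PipelineError("load", "manifest is empty")
    base = manifest_path.parent
    eems, records = [], []
    blanks: dict[str, EEM] = {}
    for rec, rel in pairs:
        p = Path(rel)
        if not p.is_absolute():
            p = base / p
        try:
            eems.append(read_eem(p))
        except Exception as exc:
            raise PipelineError("load", str(exc), rec.sample_id) from exc
        records.append(rec)
        if rec.blank_id and rec.blank_id not in blanks:
            bp = base / f"{rec.blank_id}.csv"
            if bp.exists():
                blanks[rec.blank_id] = read_eem(bp)
    return eems, records, blanks


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; write the report bundle under ``config.outdir``.

    Outputs: preprocessed EEM CSVs, thin-limit exclusion report, factor
    sweep table, loadings and scores CSVs at the reported factor count,
    discrepancy maps, score-DF curves with equal-score concentration
    ratios, and a run log with every effective parameter and seed.
    Failures abort with the stage name and offending sample id; an aborted
    run never leaves a bundle marked complete.
    """
    outdir = Path(config.outdir)
    if outdir.exists():
        shutil.rmtree(outdir)
    outdir.mkdir(parents=True)
    (outdir / "preprocessed").mkdir()

    eems, records, blanks = _load_inputs(config)

    # --- preprocessing -----------------------------------------------------
    processed = []
    residual_levels = {}
    for eem, rec in zip(eems, records):
        try:
            blank = blanks.get(rec.blank_id) if config.blank_policy == "subtract" else None
            clean = preprocess_eem(
                eem, blank=blank, config=config.scatter,
                clip_negative=config.clip_negative,
                zero_below_rayleigh=config.zero_below_rayleigh)
            residual_levels[rec.sample_id] = residual_scatter_level(
                clean, config.scatter)
            write_eem(clean, outdir / "preprocessed" / f"{rec.sample_id}.csv")
            processed.append(clean)
        except Exception as exc:
            raise PipelineError("preprocess", str(exc), rec.sample_id) from exc

    # --- thin-limit selection ---------------------------------------------
    included, report = select_thin_limit(
        records, config.thin_limit_threshold, config.thin_limit_overrides)
    report.to_csv(outdir / "exclusion_report.csv", index=False)
    keep_ids = {r.sample_id for r in included}
    kept = [(e, r) for e, r in zip(processed, records) if r.sample_id in keep_ids]
    if not kept:
        raise PipelineError("select", "no samples left after thin-limit selection")
    tensor = stack_eems([e for e, _ in kept], [r for _, r in kept])

    # --- factor sweep ------------------------------------------------------
    fit_opts = FitOptions(
        nonneg=config.fit.nonneg, tol=config.fit.tol,
        max_iter=config.fit.max_iter, n_starts=config.fit.n_starts,
        init=config.fit.init, seed=stage_seed(config.master_seed, "parafac"))
    lo, hi = config.F_range
    sweep = model_sweep(tensor, range(lo, hi + 1), fit_opts)
    models = sweep.attrs["models"]
    sweep_out = sweep.copy()
    sweep_out.insert(0, "n_dilutions", len(kept))
    sweep_out.insert(0, "n_sources",
                     len({r.source_pool_id or r.sample_id for _, r in kept}))
    sweep_out.to_csv(outdir / "sweep.csv", index=False)

    # --- reported model ----------------------------------------------------
    if config.report_factors is not None:
        F_report = config.report_factors
    else:
        multi = sweep[sweep["F"] >= 2].dropna(subset=["core_consistency"])
        F_report = int(multi.loc[multi["core_consistency"].idxmax(), "F"]) \
            if len(multi) else int(sweep["F"].iloc[0])
    model = models[[int(f) for f in sweep["F"]].index(F_report)]

    pd.DataFrame(
        {"emission_nm": tensor.emission_grid} |
        {f"factor_{f + 1}": model.B[:, f] for f in range(model.F)}
    ).to_csv(outdir / "loadings_emission.csv", index=False)
    pd.DataFrame(
        {"excitation_nm": tensor.excitation_grid} |
        {f"factor_{f + 1}": model.C[:, f] for f in range(model.F)}
    ).to_csv(outdir / "loadings_excitation.csv", index=False)
    scores = pd.DataFrame(
        {"sample_id": tensor.sample_ids(), "DF": tensor.dfs()} |
        {f"factor_{f + 1}": model.A[:, f] for f in range(model.F)})
    scores.to_csv(outdir / "scores.csv", index=False)

    # --- diagnostics -------------------------------------------------------
    modeled = model.reconstruct()
    maps = discrepancy_maps(tensor.values, modeled, config.window_fraction,
                            tensor.emission_grid, tensor.excitation_grid)
    for name, surf in (("bias", maps.bias), ("rmse", maps.rmse), ("sd", maps.sd)):
        write_eem(EEM(tensor.excitation_grid, tensor.emission_grid, surf),
                  outdir / f"discrepancy_{name}.csv")
    per_sample = per_sample_fit(model, tensor)
    per_sample.to_csv(outdir / "per_sample_fit.csv", index=False)
    curves, mono = score_df_curves(model, [r for _, r in kept])
    mono.to_csv(outdir / "score_monotonicity.csv", index=False)
    ratios: dict[int, dict] = {}
    for f in range(1, model.F + 1):
        try:
            ratios[f] = concentration_ratio_at_score(
                curves, config.score_level, factor_id=f)
        except (OutOfRangeError, ValueError):
            ratios[f] = {}

    summary = {
        "rma": maps.rma,
        "F_report": F_report,
        "core_consistency": float(
            sweep.loc[sweep["F"] == F_report, "core_consistency"].iloc[0]),
        "rss": float(sweep.loc[sweep["F"] == F_report, "rss"].iloc[0]),
        "score_level": config.score_level,
        "concentration_ratios": {str(k): v for k, v in ratios.items()},
        "max_residual_scatter_AU": max(residual_levels.values()),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))

    log = {
        "master_seed": config.master_seed,
        "parafac_seed": fit_opts.seed,
        "thin_limit_threshold": config.thin_limit_threshold,
        "thin_limit_overrides": list(config.thin_limit_overrides),
        "scatter_bands": {name: [b.enabled, b.width_above, b.width_below]
                          for name, b in config.scatter.bands().items()},
        "raman_shift": config.scatter.raman_shift,
        "interpolation": config.scatter.interpolation,
        "fit": {"nonneg": list(fit_opts.nonneg), "tol": fit_opts.tol,
                "max_iter": fit_opts.max_iter, "n_starts": fit_opts.n_starts,
                "init": fit_opts.init},
        "F_range": list(config.F_range),
        "window_fraction": config.window_fraction,
        "n_samples_in": len(records),
        "n_samples_fit": len(kept),
        "residual_scatter_AU": residual_levels,
    }
    (outdir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))
    (outdir / "COMPLETE").write_text("ok\n")

    return {"tensor": tensor, "sweep": sweep, "model": model, "models": models,
            "maps": maps, "per_sample": per_sample, "curves": curves,
            "monotonicity": mono, "ratios": ratios, "summary": summary,
            "exclusions": report}


def subset_runs(config: PipelineConfig,
                subsets: dict[str, list[str]]) -> dict[str, dict]:
    """One factor sweep per named sample subset, plus cross-subset matching.

    Enables the incremental analysis (lab-only -> +river sources -> +second
    species).  Subsets must reference existing sample ids and contain at
    least two dilutions; factors of each subset's reported model are matched
    against the first subset's via spectral congruence.
    """
    eems, records, blanks = _load_inputs(config)
    by_id = {r.sample_id: (e, r) for e, r in zip(eems, records)}
    results: dict[str, dict] = {}
    first_model = None
    for name, ids in subsets.items():
        unknown = [s for s in ids if s not in by_id]
        if unknown:
            raise PipelineError("subset", f"unknown sample ids {unknown}")
        if len(ids) < 2:
            raise PipelineError("subset", f"subset {name!r} needs >= 2 samples")
        sub_cfg = PipelineConfig(
            manifest=config.manifest,
            outdir=str(Path(config.outdir) / f"subset_{name}"),
            blank_policy=config.blank_policy, scatter=config.scatter,
            thin_limit_threshold=config.thin_limit_threshold,
            thin_limit_overrides=config.thin_limit_overrides,
            fit=config.fit, F_range=config.F_range,
            report_factors=config.report_factors,
            window_fraction=config.window_fraction,
            score_level=config.score_level, master_seed=config.master_seed)
        res = _run_restricted(sub_cfg, set(ids))
        if first_model is None:
            first_model = res["model"]
            res["factor_match"] = None
        else:
            perm, cong = match_factors(first_model, res["model"])
            res["factor_match"] = {"permutation": perm.tolist(),
                                   "congruence": cong.tolist()}
        results[name] = res
    return results


def _run_restricted(config: PipelineConfig, ids: set[str]) -> dict:
    """run_pipeline limited to a set of sample ids (via a filtered manifest)."""
    import tempfile

    base = Path(config.manifest).parent
    frame = pd.read_csv(config.manifest, dtype=str)
    sub = frame[frame["sample_id"].isin(ids)].copy()
    sub["eem_path"] = [str((base / p) if not Path(p).is_absolute() else p)
                       for p in sub["eem_path"]]
    with tempfile.NamedTemporaryFile("w", suffix=".csv", dir=base,
                                     delete=False) as fh:
        sub.to_csv(fh, index=False)
        tmp = fh.name
    try:
        kwargs = {k: v for k, v in config.__dict__.items()
                  if not k.startswith("_")}
        kwargs["manifest"] = tmp
        return run_pipeline(PipelineConfig(**kwargs))
    finally:
        Path(tmp).unlink(missing_ok=True)
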