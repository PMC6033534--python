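"""CSV/JSON readers and writers and the orchestration pipeline.

Exchange format is plain CSV (comma, UTF-8, "." decimal) with one schema
per data type, plus JSON for the run manifest and ground truth:

* ``water.csv``:    subject_id, time_days, enrichment
* ``labels.csv``:   subject_id, lineage, population, time_days, fraction_labelled
* ``telomere.csv``: subject_id, lineage, theta_bp, sd_bp
* ``yfv.csv``:      subject_id, years_post_vaccination, frequency   (optional)

``run_pipeline`` reproduces the analysis order of the study: fit body
water per subject, test T_SCM homogeneity per subject/lineage (with
pooled p-values), scan the clonal burst size k, fit the explicit
two-subpopulation model (with the vaccine cohort when present), and
simulate clone lifespans — emitting tidy per-stage CSVs and a manifest
recording seed, config hash and input checksums.  Reruns with identical
inputs produce byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fitting import FitConfig, fit_model, homogeneity_test, k_scan, pool_pvalues
from .stochastic import CloneSimConfig, initial_clone_size, simulate_clones
from .synth import StudyDataset, StudyDesign, default_truth, generate_study
from .water import SalivaSeries, fit_water

__all__ = ["SchemaError", "read_study", "write_study", "run_pipeline", "PIPELINE_DEFAULTS"]


logger = logging.getLogger("tscmdyn.pipeline")


class SchemaError(ValueError):
    """A data file violates its schema; names the file, row and column."""

    def __init__(self, path, row, column, message):
        self.path, self.row, self.column = str(path), row, column
        super().__init__(f"{path}: row {row}, column {column!r}: {message}")


_SCHEMAS = {
    "water.csv": ["subject_id", "time_days", "enrichment"],
    "labels.csv": ["subject_id", "lineage", "population", "time_days", "fraction_labelled"],
    "telomere.csv": ["subject_id", "lineage", "theta_bp", "sd_bp"],
    "yfv.csv": ["subject_id", "years_post_vaccination", "frequency"],
}


def _read_csv(path: Path, name: str) -> pd.DataFrame:
    cols = _SCHEMAS[name]
    df = pd.read_csv(path, float_precision="round_trip")
    for col in cols:
        if col not in df.columns:
            raise SchemaError(path, 0, col, "missing required column")
    for col in cols:
        if col in ("subject_id", "lineage", "population"):
            continue
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise SchemaError(path, int(bad[0]) + 2, col, "non-numeric or missing value")
    return df[cols]


def _check_nonneg(df, path, col, strict=False):
    vals = df[col].to_numpy(dtype=float)
    bad = np.nonzero(vals < 0 if not strict else vals <= 0)[0]
    if bad.size:
        raise SchemaError(path, int(df.index[bad[0]]) + 2, col, "value must be positive" if strict else "negative value")


def read_study(directory) -> StudyDataset:
    """Load a study directory; telomere and vaccine files are optional."""
    d = Path(directory)
    water = _read_csv(d / "water.csv", "water.csv")
    labels = _read_csv(d / "labels.csv", "labels.csv")
    _check_nonneg(water, d / "water.csv", "time_days")
    _check_nonneg(labels, d / "labels.csv", "time_days")
    _check_nonneg(labels, d / "labels.csv", "fraction_labelled")
    for sid, grp in water.groupby("subject_id"):
        t = grp["time_days"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            row = int(grp.index[np.nonzero(np.diff(t) <= 0)[0][0] + 1]) + 2
            raise SchemaError(d / "water.csv", row, "time_days", f"non-ascending times for subject {sid}")
    for pop in labels["population"].unique():
        if pop not in ("naive", "tscm"):
            raise SchemaError(d / "labels.csv", 0, "population", f"unknown population {pop!r}")
    telomere = (
        _read_csv(d / "telomere.csv", "telomere.csv")
        if (d / "telomere.csv").exists()
        else pd.DataFrame(columns=_SCHEMAS["telomere.csv"])
    )
    if len(telomere):
        _check_nonneg(telomere, d / "telomere.csv", "sd_bp", strict=True)
    yfv = _read_csv(d / "yfv.csv", "yfv.csv") if (d / "yfv.csv").exists() else None
    if yfv is not None:
        _check_nonneg(yfv, d / "yfv.csv", "years_post_vaccination", strict=True)
        _check_nonneg(yfv, d / "yfv.csv", "frequency")
    truth = None
    if (d / "ground_truth.json").exists():
        truth = json.loads((d / "ground_truth.json").read_text())
    return StudyDataset(water=water, labels=labels, telomere=telomere, yfv=yfv, truth=truth)


def write_study(study: StudyDataset, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    study.water.to_csv(d / "water.csv", index=False)
    study.labels.to_csv(d / "labels.csv", index=False)
    study.telomere.to_csv(d / "telomere.csv", index=False)
    if study.yfv is not None:
        study.yfv.to_csv(d / "yfv.csv", index=False)
    if study.truth is not None:
        (d / "ground_truth.json").write_text(json.dumps(study.truth, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

PIPELINE_DEFAULTS = {
    "k": 5,
    "k_scan": [0, 2, 5, 10, 15, 20],
    "n_starts": 12,
    "weighting": "variance",
    "C_mode": "free",
    "c_fixed": 4.0,  # subject-level enrichment amplification, from calibration
    "explicit_lineage": "CD8",
    "gillespie_runs": 200,
    "gillespie_scale": 1e-3,  # clone-size scale-down for tractable exact SSA
}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _file_checksums(directory: Path) -> dict[str, str]:
    out = {}
    for name in sorted(_SCHEMAS):
        p = directory / name
        if p.exists():
            out[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    return out


def run_pipeline(outdir, data_dir=None, config: dict | None = None, seed: int = 0) -> Path:
    """Run the full analysis and write per-stage CSVs plus a manifest.

    ``data_dir=None`` generates a synthetic study first (seeded).  Stage
    failure halts the run but preserves partial outputs and manifest
    status.
    """
    cfg = dict(PIPELINE_DEFAULTS)
    cfg.update(config or {})
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": seed,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "package_version": __version__,
        "started_utc": datetime.now(timezone.utc).isoformat(),
        "stages": {},
    }

    def save_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    try:
        if data_dir is None:
            study = generate_study(default_truth(), StudyDesign(), seed=seed)
            write_study(study, out / "synthetic_data")
            manifest["input_checksums"] = _file_checksums(out / "synthetic_data")
        else:
            study = read_study(data_dir)
            manifest["input_checksums"] = _file_checksums(Path(data_dir))
        manifest["stages"]["load"] = "ok"
        logger.info("stage load: ok")

        # stage: per-subject body-water fits
        water_rows = []
        water_params = {}
        for sid in sorted(study.water["subject_id"].unique()):
            res = fit_water(study.saliva_series(sid))
            water_params[sid] = res.params
            water_rows.append(
                {
                    "subject_id": sid,
                    "f_r_fraction": res.params.f_r,
                    "delta_w_per_day": res.params.delta_w,
                    "beta_s_fraction": res.params.beta_s,
                    "tau_days": res.params.tau,
                    "ssr": res.ssr,
                    "flags": ";".join(res.flags),
                }
            )
        pd.DataFrame(water_rows).to_csv(out / "water_fits.csv", index=False)
        manifest["stages"]["fit_water"] = "ok"
        logger.info("stage fit_water: ok")

        base = FitConfig(
            variant="implicit",
            datasets=("label", "telomere"),
            weighting=cfg["weighting"],
            k=cfg["k"],
            C_mode=cfg["C_mode"],
            c_fixed=cfg["c_fixed"],
            n_starts=cfg["n_starts"],
            seed=seed,
        )

        # stage: homogeneity tests per subject/lineage
        hom_rows = []
        units = [
            (sid, lin)
            for sid in study.subjects
            for lin in sorted(study.labels["lineage"].unique())
        ]
        for sid, lin in units:
            fd = study.fit_data(sid, lin, water_params=water_params[sid])
            test = homogeneity_test(base, fd)
            hom_rows.append(
                {
                    "subject_id": sid,
                    "lineage": lin,
                    "ssr_homogeneous": test.fit_reduced.ssr,
                    "ssr_implicit": test.fit_full.ssr,
                    "F": test.ftest.statistic,
                    "p_value": test.p_value,
                }
            )
        hom = pd.DataFrame(hom_rows)
        pooled_rows = []
        for lin, grp in hom.groupby("lineage"):
            pp = pool_pvalues(grp["p_value"])
            pooled_rows.append(
                {"lineage": lin, "median_p": pp.median_p, "pooled_p": pp.pooled_p, "n": len(grp)}
            )
        hom.to_csv(out / "homogeneity.csv", index=False)
        pd.DataFrame(pooled_rows).to_csv(out / "homogeneity_pooled.csv", index=False)
        manifest["stages"]["homogeneity"] = "ok"
        logger.info("stage homogeneity: ok")

        # stage: k-scan on the first unit
        sid, lin = units[0]
        fd = study.fit_data(sid, lin, water_params=water_params[sid])
        scan = k_scan(base, fd, ks=cfg["k_scan"])
        scan.to_csv(out / "kscan.csv", index=False)
        manifest["stages"]["k_scan"] = "ok"
        logger.info("stage k_scan: ok")

        # stage: explicit fits (with vaccine cohort when present)
        exp_rows = []
        pred_rows = []
        exp_cfg = replace(
            base,
            variant="explicit",
            datasets=("label", "telomere", "yfv") if study.yfv is not None else ("label", "telomere"),
        )
        for sid in study.subjects:
            fd = study.fit_data(
                sid,
                cfg["explicit_lineage"],
                water_params=water_params[sid],
                include_yfv=study.yfv is not None,
            )
            fit = fit_model(exp_cfg, fd)
            logger.info("explicit fit %s: ssr=%.6g", sid, fit.ssr)
            from .label_models import solve_label_explicit

            curves = solve_label_explicit(fit.model, fd.water, fd.naive_times)
            for pop, vals in (("naive", curves.F_TN), ("tscm", curves.F_TSCM)):
                pred_rows += [
                    {
                        "subject_id": sid,
                        "lineage": cfg["explicit_lineage"],
                        "population": pop,
                        "time_days": t,
                        "fraction_labelled": v,
                        "model": "explicit",
                        "variant": "two_subpopulation",
                    }
                    for t, v in zip(fd.naive_times, vals)
                ]
            exp_rows.append(
                {
                    "subject_id": sid,
                    "half_life_tscm1_years": fit.derived["half_life_1_years"],
                    "half_life_tscm2_years": fit.derived["half_life_2_years"],
                    "relative_size_tscm2_fraction": fit.derived["relative_size_2"],
                    "f_fraction": fit.derived["f"],
                    "fraction_from_naive": fit.derived["fraction_from_naive"],
                    "self_renewal_days": fit.derived["self_renewal_days"],
                    "ssr": fit.ssr,
                }
            )
        exp = pd.DataFrame(exp_rows)
        med = exp.drop(columns="subject_id").median()
        exp_summary = pd.concat([exp, pd.DataFrame([{"subject_id": "MEDIAN", **med}])])
        exp_summary.to_csv(out / "explicit_fits.csv", index=False)
        pd.DataFrame(pred_rows).to_csv(out / "predictions.csv", index=False)
        manifest["stages"]["explicit_fit"] = "ok"

        # stage: stochastic clone lifespans from the median fit
        med_f = float(med["f_fraction"])
        med_hl2 = float(med["half_life_tscm2_years"])
        dnet2 = math.log(2.0) / (med_hl2 * 365.25)
        p2 = 0.002  # representative slow-subpopulation proliferation rate
        n0_full = initial_clone_size(cfg["k"], 1e-5, med_f)
        n0 = max(1, int(round(n0_full * cfg["gillespie_scale"])))
        sim = simulate_clones(
            CloneSimConfig(p=p2, d=p2 + dnet2, n0=n0, n_runs=cfg["gillespie_runs"], seed=seed)
        )
        pd.DataFrame(
            {
                "run": np.arange(cfg["gillespie_runs"]),
                "extinction_days": sim.extinction_times,
                "half_life_days": sim.half_life_times,
                "censored": sim.censored,
            }
        ).to_csv(out / "lifespans.csv", index=False)
        summary = sim.summary()
        summary.update({"n0_simulated": n0, "n0_full_clone": n0_full})
        pd.DataFrame([summary]).to_csv(out / "lifespans_summary.csv", index=False)
        manifest["stages"]["stochastic"] = "ok"
        logger.info("stage stochastic: ok")
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        save_manifest()
        raise
    save_manifest()
    return out
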