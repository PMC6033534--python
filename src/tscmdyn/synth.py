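"""Synthetic-study generator with known ground truth.

Emulates the statistical structure of the four data shapes the analysis
consumes: per-subject saliva enrichment during a 7-week labelling
protocol, per-subject/per-population DNA label-enrichment time courses
over ~300 days, one telomere-length difference Theta per subject and
lineage, and a 37-subject cross-sectional vaccine cohort spanning
0.27-35 years post-vaccination.  Measurement noise is Gaussian: additive
on the label-fraction scale (truncated at zero), additive in base pairs
for Theta, and log-normal (additive on log10) for vaccine frequencies.

The generator's defaults are the study conditions: 5 subjects, label
cessation at day 49, ~12 label sampling times to day ~280, label sd
5e-4 fraction units, Theta sd 150 bp, vaccine log10 sd 0.3.  Ground
truth is stored alongside (never mixed into) the observables, enabling
closed-loop parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fitting import FitConfig, FitData, fit_model
from .label_models import (
    ExplicitModelParams,
    ImplicitModelParams,
    solve_label_explicit,
    solve_label_implicit,
)
from .telomere import TelomereParams, theta_explicit, theta_steady_state
from .water import BodyWaterParams, SalivaSeries, eval_U
from .yfv import link_explicit_to_yfv, yfv_frequency

__all__ = [
    "StudyDesign",
    "StudyTruth",
    "StudyDataset",
    "default_truth",
    "generate_study",
    "simulate_fit_data",
    "recovery_experiment",
]


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design and noise model of the labelling + vaccine study."""

    n_subjects: int = 5
    tau: float = 49.0
    label_times: tuple[float, ...] = (7, 14, 21, 28, 35, 42, 49, 63, 91, 140, 210, 280)
    saliva_times: tuple[float, ...] = (1, 3, 7, 14, 21, 28, 35, 42, 49, 63, 84)
    lineages: tuple[str, ...] = ("CD4", "CD8")
    label_sd: float = 5e-4
    theta_sd: float = 150.0
    saliva_sd: float = 2e-3
    yfv_log10_sd: float = 0.3
    yfv_n: int = 37
    yfv_t_range: tuple[float, float] = (0.27, 35.0)
    water_cv: float = 0.1  # between-subject lognormal CV on f_r and delta_w

    def __post_init__(self) -> None:
        for name in ("label_sd", "theta_sd", "saliva_sd", "yfv_log10_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("label_times", "saliva_times"):
            t = np.asarray(getattr(self, name))
            if np.any(np.diff(t) <= 0) or np.any(t < 0):
                raise ValueError(f"{name} must be non-negative and strictly ascending")


@dataclass(frozen=True)
class StudyTruth:
    """Ground-truth parameter record behind a synthetic study.

    Defaults mirror the headline kinetics of healthy adults: naive
    proliferation 5e-4/day, a fast T_SCM subpopulation (p = 0.015/day,
    half-life 0.41 y), a slow one (p = 0.002/day, half-life 8.74 y),
    burst fraction f = 0.058 entering the slow pool, clonal burst k = 5.
    """

    kinetics: ExplicitModelParams
    water: BodyWaterParams
    telomere: TelomereParams
    yfv_A: float = 5e-4


def default_truth() -> StudyTruth:
    ln2 = np.log(2.0)
    dnet1 = ln2 / (0.41 * 365.25)
    dnet2 = ln2 / (8.74 * 365.25)
    kinetics = ExplicitModelParams(
        p_n=5e-4,
        p_s1=0.015,
        d_s1=0.015 + dnet1,
        p_s2=0.002,
        d_s2=0.002 + dnet2,
        f=0.058,
        Delta=1e-5,
        k=5,
        c=4.0,
    )
    water = BodyWaterParams(f_r=0.02, delta_w=0.06, beta_s=0.001, tau=49.0)
    telo = TelomereParams(delta_bp=50.0, C=2.0)
    return StudyTruth(kinetics=kinetics, water=water, telomere=telo, yfv_A=5e-4)


@dataclass
class StudyDataset:
    """Bundled synthetic (or loaded) observations plus hidden ground truth."""

    water: pd.DataFrame  # subject_id, time_days, enrichment
    labels: pd.DataFrame  # subject_id, lineage, population, time_days, fraction_labelled
    telomere: pd.DataFrame  # subject_id, lineage, theta_bp, sd_bp
    yfv: pd.DataFrame | None  # subject_id, years_post_vaccination, frequency
    truth: dict | None = None
    design: StudyDesign = field(default_factory=StudyDesign)
    water_truth: dict[str, BodyWaterParams] = field(default_factory=dict)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.labels["subject_id"].unique())

    def saliva_series(self, subject: str) -> SalivaSeries:
        sub = self.water[self.water["subject_id"] == subject]
        return SalivaSeries(sub["time_days"].to_numpy(), sub["enrichment"].to_numpy())

    def fit_data(
        self,
        subject: str,
        lineage: str,
        water_params: BodyWaterParams | None = None,
        include_yfv: bool = False,
    ) -> FitData:
        """Assemble one subject/lineage fitting unit.

        ``water_params=None`` uses the stored per-subject truth when
        available, otherwise the caller should fit the saliva series
        first (see :func:`tscmdyn.water.fit_water`).
        """
        if include_yfv and self.yfv is None:
            raise ValueError("dataset has no vaccine cohort")
        if water_params is None:
            if subject not in self.water_truth:
                raise ValueError(
                    f"no water parameters for subject {subject!r}: fit the saliva series first"
                )
            water_params = self.water_truth[subject]
        lab = self.labels[
            (self.labels["subject_id"] == subject) & (self.labels["lineage"] == lineage)
        ]
        naive = lab[lab["population"] == "naive"].sort_values("time_days")
        tscm = lab[lab["population"] == "tscm"].sort_values("time_days")
        tel = self.telomere[
            (self.telomere["subject_id"] == subject) & (self.telomere["lineage"] == lineage)
        ]
        theta = float(tel["theta_bp"].iloc[0]) if len(tel) else None
        theta_sd = float(tel["sd_bp"].iloc[0]) if len(tel) else self.design.theta_sd
        kw: dict = {}
        if include_yfv:
            if self.yfv is None:
                raise ValueError("dataset has no vaccine cohort")
            kw = {
                "yfv_times_years": self.yfv["years_post_vaccination"].to_numpy(),
                "yfv_freq": self.yfv["frequency"].to_numpy(),
            }
        return FitData(
            water=water_params,
            naive_times=naive["time_days"].to_numpy(),
            naive_frac=naive["fraction_labelled"].to_numpy(),
            tscm_times=tscm["time_days"].to_numpy(),
            tscm_frac=tscm["fraction_labelled"].to_numpy(),
            theta=theta,
            theta_sd=theta_sd,
            label_sd=self.design.label_sd,
            yfv_log10_sd=self.design.yfv_log10_sd,
            subject=subject,
            lineage=lineage,
            **kw,
        )


def _jitter_water(water: BodyWaterParams, cv: float, rng: np.random.Generator) -> BodyWaterParams:
    if cv <= 0:
        return water
    sigma = np.sqrt(np.log1p(cv**2))
    f_r = float(np.clip(water.f_r * rng.lognormal(-(sigma**2) / 2, sigma), 1e-4, 0.2))
    dw = float(water.delta_w * rng.lognormal(-(sigma**2) / 2, sigma))
    return BodyWaterParams(f_r=f_r, delta_w=dw, beta_s=min(water.beta_s, f_r), tau=water.tau)


def generate_study(
    truth: StudyTruth | None = None,
    design: StudyDesign | None = None,
    seed: int = 0,
) -> StudyDataset:
    """Generate a full synthetic study with seeded Gaussian noise.

    Noise-free model curves are evaluated at the design times; label
    noise is additive on the fraction scale and truncated at 0, Theta
    noise additive in bp, vaccine noise log-normal (additive on log10).
    The vaccine cohort's sampling times are log-uniform over the cohort
    range, mimicking the cross-sectional spread.
    """
    truth = truth or default_truth()
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)

    water_rows, label_rows, telo_rows = [], [], []
    water_truth: dict[str, BodyWaterParams] = {}
    t_lab = np.asarray(design.label_times, dtype=float)
    t_sal = np.asarray(design.saliva_times, dtype=float)
    theta_true = theta_explicit(truth.kinetics, truth.telomere)
    for i in range(design.n_subjects):
        sid = f"S{i + 1:02d}"
        w = _jitter_water(truth.water, design.water_cv, rng)
        water_truth[sid] = w
        sal = np.clip(eval_U(t_sal, w) + rng.normal(0, design.saliva_sd, t_sal.size), 0.0, 1.0)
        water_rows += [
            {"subject_id": sid, "time_days": t, "enrichment": e} for t, e in zip(t_sal, sal)
        ]
        pred = solve_label_explicit(truth.kinetics, w, t_lab)
        for lineage in design.lineages:
            for pop, curve in (("naive", pred.F_TN), ("tscm", pred.F_TSCM)):
                noisy = np.maximum(curve + rng.normal(0, design.label_sd, t_lab.size), 0.0)
                label_rows += [
                    {
                        "subject_id": sid,
                        "lineage": lineage,
                        "population": pop,
                        "time_days": t,
                        "fraction_labelled": v,
                    }
                    for t, v in zip(t_lab, noisy)
                ]
            telo_rows.append(
                {
                    "subject_id": sid,
                    "lineage": lineage,
                    "theta_bp": float(theta_true + rng.normal(0, design.theta_sd)),
                    "sd_bp": design.theta_sd,
                }
            )

    lo, hi = np.log(design.yfv_t_range[0]), np.log(design.yfv_t_range[1])
    t_yfv = np.sort(np.exp(rng.uniform(lo, hi, design.yfv_n)))
    decay = link_explicit_to_yfv(truth.kinetics, A=truth.yfv_A)
    f_true = yfv_frequency(t_yfv, decay)
    f_obs = 10.0 ** (np.log10(f_true) + rng.normal(0, design.yfv_log10_sd, t_yfv.size))
    yfv = pd.DataFrame(
        {
            "subject_id": [f"V{i + 1:02d}" for i in range(design.yfv_n)],
            "years_post_vaccination": t_yfv,
            "frequency": f_obs,
        }
    )

    truth_record = {
        "kinetics": {
            k: getattr(truth.kinetics, k)
            for k in ("p_n", "p_s1", "d_s1", "p_s2", "d_s2", "f", "Delta", "k", "c")
        },
        "derived": {
            "half_life_1_years": truth.kinetics.half_life_1_years,
            "half_life_2_years": truth.kinetics.half_life_2_years,
            "relative_size_2": truth.kinetics.relative_size_2,
            "theta_bp": theta_true,
        },
        "water": {k: getattr(truth.water, k) for k in ("f_r", "delta_w", "beta_s", "tau")},
        "telomere": {"delta_bp": truth.telomere.delta_bp, "C": truth.telomere.C},
        "yfv_A": truth.yfv_A,
        "seed": seed,
    }
    return StudyDataset(
        water=pd.DataFrame(water_rows),
        labels=pd.DataFrame(label_rows),
        telomere=pd.DataFrame(telo_rows),
        yfv=yfv,
        truth=truth_record,
        design=design,
        water_truth=water_truth,
    )


def simulate_fit_data(
    kinetics: ImplicitModelParams | ExplicitModelParams,
    water: BodyWaterParams,
    telo: TelomereParams,
    design: StudyDesign,
    rng: np.random.Generator,
    include_yfv: bool = False,
    yfv_A: float = 5e-4,
) -> FitData:
    """Lean single-unit generator (no DataFrames) for simulation studies."""
    t_lab = np.asarray(design.label_times, dtype=float)
    explicit = isinstance(kinetics, ExplicitModelParams)
    solver = solve_label_explicit if explicit else solve_label_implicit
    pred = solver(kinetics, water, t_lab)
    naive = np.maximum(pred.F_TN + rng.normal(0, design.label_sd, t_lab.size), 0.0)
    tscm = np.maximum(pred.F_TSCM + rng.normal(0, design.label_sd, t_lab.size), 0.0)
    theta_true = theta_explicit(kinetics, telo) if explicit else theta_steady_state(kinetics, telo)
    theta = float(theta_true + rng.normal(0, design.theta_sd))
    kw: dict = {}
    if include_yfv:
        if not explicit:
            raise ValueError("vaccine data require explicit-model kinetics")
        lo, hi = np.log(design.yfv_t_range[0]), np.log(design.yfv_t_range[1])
        t_yfv = np.sort(np.exp(rng.uniform(lo, hi, design.yfv_n)))
        decay = link_explicit_to_yfv(kinetics, A=yfv_A)
        f_obs = 10.0 ** (
            np.log10(yfv_frequency(t_yfv, decay)) + rng.normal(0, design.yfv_log10_sd, t_yfv.size)
        )
        kw = {"yfv_times_years": t_yfv, "yfv_freq": f_obs}
    return FitData(
        water=water,
        naive_times=t_lab,
        naive_frac=naive,
        tscm_times=t_lab,
        tscm_frac=tscm,
        theta=theta,
        theta_sd=design.theta_sd,
        label_sd=design.label_sd,
        yfv_log10_sd=design.yfv_log10_sd,
        **kw,
    )


def recovery_experiment(
    truth: StudyTruth,
    design: StudyDesign,
    fit_config: FitConfig,
    n_replicates: int = 25,
    seed: int = 0,
    targets: dict[str, float] | None = None,
    n_boot_coverage: int | None = None,
) -> pd.DataFrame:
    """Replicated generate -> fit -> score loop.

    Returns one row per replicate with the fitted parameters and derived
    quantities; ``.attrs["summary"]`` carries bias, RMSE and (when
    ``n_boot_coverage`` is set) bootstrap-CI coverage against the
    supplied (or truth-derived) target values.
    """
    include_yfv = "yfv" in fit_config.datasets
    if targets is None:
        k = truth.kinetics
        targets = {
            "half_life_1_years": k.half_life_1_years,
            "half_life_2_years": k.half_life_2_years,
            "relative_size_2": k.relative_size_2,
            "f": k.f,
            "p_n": k.p_n,
            "c": k.c,
        }
    seqs = np.random.SeedSequence(seed).spawn(n_replicates)
    rows = []
    for i, ss in enumerate(seqs):
        rng = np.random.default_rng(ss)
        data = simulate_fit_data(
            truth.kinetics, truth.water, truth.telomere, design, rng,
            include_yfv=include_yfv, yfv_A=truth.yfv_A,
        )
        cfg = replace(fit_config, seed=int(rng.integers(2**31 - 1)))
        fit = fit_model(cfg, data)
        row = {"replicate": i, "ssr": fit.ssr}
        row.update(fit.params)
        row.update(fit.derived)
        if n_boot_coverage:
            from .fitting import confidence_intervals

            ci = confidence_intervals(
                fit, data, n_boot=n_boot_coverage, seed=int(rng.integers(2**31 - 1))
            )
            for name, target in targets.items():
                if name in ci.intervals:
                    lo, hi = ci.intervals[name]
                    row[f"covered_{name}"] = bool(lo <= target <= hi)
        rows.append(row)
    df = pd.DataFrame(rows)
    summary = {}
    for name, target in targets.items():
        if name in df:
            est = df[name].to_numpy(dtype=float)
            summary[name] = {
                "target": target,
                "median": float(np.median(est)),
                "bias": float(np.mean(est) - target),
                "rmse": float(np.sqrt(np.mean((est - target) ** 2))),
            }
            if f"covered_{name}" in df:
                summary[name]["ci_coverage"] = float(df[f"covered_{name}"].mean())
    df.attrs["summary"] = summary
    return df
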