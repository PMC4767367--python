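"""End-to-end orchestration: simulate/load -> CGM metrics -> association -> report.

A run produces, in the output directory:

* ``cgm_long.csv`` / ``phenotypes.csv`` (simulate mode) -- the raw inputs;
* ``participant_summary.csv`` -- the seven CGM statistics per participant;
* ``characteristics_table.csv`` -- population-characteristics table
  stratified by genotype group with covariate-adjusted p-values;
* ``outcomes_table.csv`` -- per-outcome adjusted (geometric) means, 95% CIs,
  model and permutation p-values;
* ``mediation.csv`` -- the body-composition mediation report;
* ``mean_profile.csv`` + ``mean_profile.png`` -- mean 72-h glucose curve per
  genotype group by clock slot;
* ``manifest.json`` -- seed, config hash, version, per-stage row counts.

Every number in the outcomes table is re-derivable by calling the
association module directly on the summary CSV; the pipeline holds no
hidden state, and a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    fit_adjusted_comparison,
    hwe_test,
    permutation_pvalue,
    run_mediation,
)
from .cgm_metrics import (
    DEFAULT_MIN_COVERAGE,
    CgmSeries,
    read_cgm_csv,
    summarize,
    trim_to_analysis_days,
    write_summary_csv,
)
from .synthetic_cohort import (
    CohortConfig,
    cohort_to_frame,
    simulate_cgm_trace,
    simulate_cohort,
    simulate_cohort_traces,
    traces_to_long_frame,
)

logger = logging.getLogger(__name__)

CGM_OUTCOMES = [
    "mean_24h",
    "mean_nocturnal",
    "mean_diurnal",
    "sd_24h",
    "conga4",
    "modd",
    "range",
]
FASTING_OUTCOMES = ["fasting_glucose", "fasting_insulin"]
CHARACTERISTICS = ["age", "weight", "bmi", "pbf", "whr"]


@dataclass
class PipelineConfig:
    """Run configuration; either input CSV paths or a simulation config."""

    cgm_csv: str | None = None
    phenotype_csv: str | None = None
    simulation: CohortConfig | None = None
    covariates: list[str] = field(default_factory=lambda: ["age", "sex", "offspring"])
    mediators: list[str] = field(default_factory=lambda: ["weight", "pbf"])
    mediation_outcome: str = "mean_nocturnal"
    log_scale_outcomes: list[str] = field(default_factory=lambda: ["fasting_insulin"])
    n_perm: int = 1000
    permutation_unit: str = "cluster"
    min_coverage: float = DEFAULT_MIN_COVERAGE
    expected_interval: int = 5
    seed: int = 0
    out_dir: str = "glycovar_out"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.simulation is None and (
            self.cgm_csv is None or self.phenotype_csv is None
        ):
            self.simulation = CohortConfig(seed=self.seed)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from YAML (or TOML when the suffix is .toml)."""
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            raw = tomllib.loads(path.read_text())
        else:
            import yaml

            raw = yaml.safe_load(path.read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = CohortConfig(**sim)
        return cfg

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, out: Path) -> tuple[Path, Path]:
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    participants = simulate_cohort(sim)
    traces = simulate_cohort_traces(participants, sim)
    pheno = cohort_to_frame(participants)
    long = traces_to_long_frame(traces)
    pheno_path = out / "phenotypes.csv"
    cgm_path = out / "cgm_long.csv"
    pheno.to_csv(pheno_path, index=False, float_format="%.8g")
    long.to_csv(cgm_path, index=False, float_format="%.6f")
    logger.info("simulate: %d participants, %d CGM rows", len(pheno), len(long))
    return cgm_path, pheno_path


def stage_metrics(
    cgm_csv: str | Path,
    out: Path,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    expected_interval: int = 5,
) -> pd.DataFrame:
    series = read_cgm_csv(cgm_csv, expected_interval=expected_interval)
    summaries = []
    trimmed: list[CgmSeries] = []
    for s in series:
        try:
            t = trim_to_analysis_days(s)
        except ValueError as e:
            logger.warning("metrics: skipping %s (%s)", s.participant_id, e)
            continue
        trimmed.append(t)
        summaries.append(summarize(t, min_coverage=min_coverage))
    frame = write_summary_csv(summaries, out / "participant_summary.csv")
    # retain trimmed series for the profile plot
    frame.attrs["trimmed_series"] = trimmed
    logger.info("metrics: %d participants summarised", len(frame))
    return frame


def _merged_table(pheno: pd.DataFrame, summary: pd.DataFrame) -> pd.DataFrame:
    return pheno.merge(summary, on="participant_id", how="inner")


def simulate_analysis_table(
    sim: CohortConfig,
    metrics: tuple[str, ...] | None = None,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Simulate a cohort and return the merged phenotype + CGM-summary table.

    In-memory equivalent of simulate -> metrics -> merge, without the CSV
    round trip; replicate studies (power, calibration, recovery) use it to
    avoid disk traffic. ``metrics`` restricts computation to a subset of the
    summary statistics (default: all seven).
    """
    from .cgm_metrics import (
        WINDOW_24H,
        WINDOW_DIURNAL,
        WINDOW_NOCTURNAL,
        conga,
        glucose_range,
        modd,
        sd_24h,
        window_mean,
    )

    dispatch = {
        "mean_24h": lambda s: window_mean(s, WINDOW_24H, min_coverage),
        "mean_nocturnal": lambda s: window_mean(s, WINDOW_NOCTURNAL, min_coverage),
        "mean_diurnal": lambda s: window_mean(s, WINDOW_DIURNAL, min_coverage),
        "sd_24h": sd_24h,
        "conga4": conga,
        "modd": modd,
        "range": glucose_range,
    }
    metrics = metrics or tuple(dispatch)
    participants = simulate_cohort(sim)
    pheno = cohort_to_frame(participants)
    rows: dict[str, list[float]] = {m: [] for m in metrics}
    for p in participants:
        t = trim_to_analysis_days(simulate_cgm_trace(p, sim))
        for m in metrics:
            rows[m].append(dispatch[m](t))
    for m in metrics:
        pheno[m] = rows[m]
    return pheno


def stage_associate(
    table: pd.DataFrame, config: PipelineConfig, out: Path
) -> pd.DataFrame:
    rows = []
    for outcome in FASTING_OUTCOMES + CGM_OUTCOMES:
        if outcome not in table.columns:
            continue
        log_scale = outcome in config.log_scale_outcomes
        try:
            res = fit_adjusted_comparison(
                table,
                outcome,
                covariates=config.covariates,
                log_scale=log_scale,
            )
            p_perm = permutation_pvalue(
                table,
                outcome,
                covariates=config.covariates,
                n_perm=config.n_perm,
                seed=_outcome_seed(config.seed, outcome),
                log_scale=log_scale,
                unit=config.permutation_unit,
            )
        except ValueError as e:
            logger.warning("associate: %s skipped (%s)", outcome, e)
            continue
        cc, ctt = res.group_means["CC"], res.group_means["CT/TT"]
        rows.append(
            {
                "outcome": outcome,
                "scale": res.scale,
                "n_cc": res.n_cc,
                "n_ctt": res.n_ctt,
                "mean_cc": cc[0],
                "ci_lo_cc": cc[1],
                "ci_hi_cc": cc[2],
                "mean_ctt": ctt[0],
                "ci_lo_ctt": ctt[1],
                "ci_hi_ctt": ctt[2],
                "beta": res.beta,
                "se_robust": res.se_robust,
                "p_model": res.p_model,
                "p_permutation": p_perm,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "outcomes_table.csv", index=False, float_format="%.8g")
    logger.info("associate: %d outcomes", len(frame))
    return frame


def stage_characteristics(
    table: pd.DataFrame, config: PipelineConfig, out: Path
) -> pd.DataFrame:
    """Population-characteristics table stratified by genotype group."""
    rows = []
    g = table["risk_group"].astype(int)
    for char in CHARACTERISTICS:
        if char not in table.columns:
            continue
        covs = [c for c in config.covariates if c != char]
        try:
            res = fit_adjusted_comparison(table, char, covariates=covs)
            p = res.p_model
        except ValueError as e:
            logger.warning("characteristics: %s unadjusted (%s)", char, e)
            p = float("nan")
        v = table[char].astype(float)
        rows.append(
            {
                "characteristic": char,
                "mean_total": v.mean(),
                "sd_total": v.std(ddof=1),
                "mean_cc": v[g == 0].mean(),
                "sem_cc": v[g == 0].std(ddof=1) / np.sqrt((g == 0).sum()),
                "mean_ctt": v[g == 1].mean(),
                "sem_ctt": v[g == 1].std(ddof=1) / np.sqrt((g == 1).sum()),
                "p_adjusted": p,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "characteristics_table.csv", index=False, float_format="%.8g")
    return frame


def stage_mediation(
    table: pd.DataFrame, config: PipelineConfig, out: Path
) -> pd.DataFrame:
    med = run_mediation(
        table,
        config.mediation_outcome,
        mediators=config.mediators,
        covariates=config.covariates,
    )
    frame = pd.DataFrame(
        [
            {
                "outcome": med.outcome_name,
                "mediators": "+".join(config.mediators),
                "beta_unadjusted": med.beta_unadjusted,
                "se_unadjusted": med.se_unadjusted,
                "p_unadjusted": med.p_unadjusted,
                "beta_adjusted": med.beta_adjusted,
                "se_adjusted": med.se_adjusted,
                "p_adjusted": med.p_adjusted,
                "percent_mediated": med.percent_mediated,
                "n_analyzed": med.n_analyzed,
                "interaction_flag": med.interaction_flag,
                **{f"interaction_p_{k}": v for k, v in med.interaction_p.items()},
            }
        ]
    )
    frame.to_csv(out / "mediation.csv", index=False, float_format="%.8g")
    return frame


def _outcome_seed(seed: int, outcome: str) -> int:
    h = hashlib.sha256(f"{seed}:{outcome}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# profile plot


def mean_profile_table(
    trimmed: list[CgmSeries], pheno: pd.DataFrame
) -> pd.DataFrame:
    """Mean glucose per grid slot over the analysis span, per genotype group.

    Slots with no valid sample anywhere in a group stay NaN (rendered as a
    gap, retained in the CSV with a missing marker).
    """
    risk = dict(zip(pheno["participant_id"], pheno["risk_group"].astype(int)))
    groups = {0: "CC", 1: "CT/TT"}
    n_slots = max(s.n_samples for s in trimmed)
    sums = {k: np.zeros(n_slots) for k in groups}
    counts = {k: np.zeros(n_slots) for k in groups}
    present = {k: 0 for k in groups}
    for s in trimmed:
        if s.participant_id not in risk:
            continue
        k = risk[s.participant_id]
        present[k] += 1
        v = s.values
        valid = ~np.isnan(v)
        sums[k][: v.size][valid] += v[valid]
        counts[k][: v.size][valid] += 1
    for k, label in groups.items():
        if present[k] == 0:
            raise ValueError(f"empty genotype group: {label}")
    ref = trimmed[0]
    hours = np.arange(n_slots) * ref.interval / 60.0
    out = pd.DataFrame({"hours_from_analysis_start": hours})
    for k, label in groups.items():
        with np.errstate(invalid="ignore"):
            out[f"mean_{'cc' if k == 0 else 'ctt'}"] = np.where(
                counts[k] > 0, sums[k] / np.maximum(counts[k], 1), np.nan
            )
    return out


def plot_mean_profile(profile: pd.DataFrame, png_path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    h = profile["hours_from_analysis_start"]
    ax.plot(h, profile["mean_cc"], color="black", lw=1.2, label="CC")
    ax.plot(h, profile["mean_ctt"], color="grey", lw=1.2, label="CT/TT")
    # demarcate the nocturnal 3:00-6:00 window on each analysis day
    for day in range(int(np.ceil(h.max() / 24.0))):
        ax.axvspan(day * 24 + 3, day * 24 + 6, color="0.9", zorder=0)
    ax.set_xlabel("hours from start of analysis span")
    ax.set_ylabel("mean glucose (mmol/L)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk).

    Any stage failure aborts with a stage-named error and removes partial
    outputs from the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        if config.cgm_csv is not None and config.phenotype_csv is not None:
            cgm_path, pheno_path = Path(config.cgm_csv), Path(config.phenotype_csv)
        else:
            stage = "simulate"
            cgm_path, pheno_path = stage_simulate(config, out)
            written += [cgm_path, pheno_path]

        stage = "metrics"
        summary = stage_metrics(
            cgm_path, out, config.min_coverage, config.expected_interval
        )
        written.append(out / "participant_summary.csv")
        trimmed = summary.attrs["trimmed_series"]

        stage = "associate"
        pheno = pd.read_csv(pheno_path)
        table = _merged_table(pheno, summary)
        geno = pheno["genotype"].value_counts()
        hwe_p = hwe_test(
            int(geno.get("CC", 0)), int(geno.get("CT", 0)), int(geno.get("TT", 0))
        )
        outcomes = stage_associate(table, config, out)
        written.append(out / "outcomes_table.csv")
        chars = stage_characteristics(table, config, out)
        written.append(out / "characteristics_table.csv")

        stage = "mediation"
        mediation = stage_mediation(table, config, out)
        written.append(out / "mediation.csv")

        stage = "report"
        profile = mean_profile_table(trimmed, pheno)
        profile.to_csv(out / "mean_profile.csv", index=False, float_format="%.8g")
        written.append(out / "mean_profile.csv")
        plot_mean_profile(profile, out / "mean_profile.png")
        written.append(out / "mean_profile.png")

        manifest = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "version": __version__,
            "hwe_p": hwe_p,
            "row_counts": {
                "participants": int(len(pheno)),
                "summaries": int(len(summary)),
                "outcomes": int(len(outcomes)),
                "characteristics": int(len(chars)),
                "mediation": int(len(mediation)),
                "profile_slots": int(len(profile)),
            },
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return manifest
    except Exception as e:
        for f in written:
            f.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e
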