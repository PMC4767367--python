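"""Synthetic cohort generator: genotypes, phenotypes and CGM traces.

Emulates the statistical structure of a family-based candidate-SNP study of
glucose regulation in middle-aged participants without diabetes:

* rs7903146 genotypes (CC/CT/TT) drawn at Hardy-Weinberg proportions from a
  configurable T-allele frequency; a configurable fraction of participants
  are sibling pairs whose genotypes share parental alleles, so genotype is
  family-correlated.
* Body weight and percent body fat act as mediators: risk-group carriers
  (CT/TT) receive configurable mean shifts, and a standardized composite of
  the two mediators feeds back on glucose. A separate direct genotype effect
  raises nocturnal glucose only (raised-cosine weight over 0:00-7:00,
  normalised to average 1 over the 3:00-6:00 analysis window, so the
  configured effects are exactly the ground-truth contrast in the
  nocturnal-mean outcome).
* CGM traces: smooth circadian baseline with a nocturnal nadir, Gaussian
  meal excursions, person- and family-level baseline shifts, first-order
  autoregressive sensor noise, and uniform random missingness.

Everything is bit-reproducible under a fixed seed; each participant's trace
uses an independent stream derived from (seed, participant index).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .cgm_metrics import MINUTES_PER_DAY, CgmSeries, WINDOW_NOCTURNAL

GENOTYPES = ("CC", "CT", "TT")

#: fixed virtual start of every simulated recording (midnight, so a 5-day
#: recording spans exactly 5 calendar days and trimming leaves 72 h)
TRACE_START = pd.Timestamp("2024-01-01 00:00:00")


@dataclass(frozen=True)
class CohortConfig:
    """All generator knobs, with defaults mirroring the study conditions.

    Effects are expressed on the nocturnal-mean glucose scale:
    ``direct_effect`` is the genotype effect not acting through body
    composition, and ``mediator_to_glucose`` (mmol/L per SD of the
    standardized weight/body-fat composite) carries the indirect path. The
    implied mediated fraction is ``indirect_effect / total_effect`` (see
    properties below).
    """

    n_participants: int = 235
    t_allele_freq: float = 0.30
    sibling_fraction: float = 0.6
    # effect structure (mmol/L on the nocturnal-mean scale)
    direct_effect: float = 0.1235
    mediator_effect_weight: float = 2.5  # kg for CT/TT carriers
    mediator_effect_pbf: float = 1.5  # percentage points for CT/TT carriers
    mediator_to_glucose: float = 0.2971  # mmol/L per SD of composite mediator
    # covariate distributions
    age_mean: float = 64.7
    age_sd: float = 5.9
    weight_mean: float = 76.7
    weight_noise_sd: float = 12.0
    pbf_mean: float = 30.3
    pbf_noise_sd: float = 8.2
    mediator_corr: float = 0.5  # correlation of weight and pbf noise
    female_fraction: float = 0.498
    offspring_fraction: float = 0.626
    # trace shape
    nocturnal_nadir: float = 4.455  # mmol/L
    nadir_time: float = 4.0  # clock hours
    circadian_amplitude: float = 0.85  # mmol/L peak-to-nadir of the cosine
    meal_times: tuple[float, ...] = (8.0, 12.5, 18.5)  # clock hours
    meal_amplitude: float = 1.3  # mmol/L
    meal_width: float = 50.0  # minutes (Gaussian SD)
    # noise structure
    person_sd: float = 0.55  # between-participant baseline SD, mmol/L
    family_sd: float = 0.1  # shared family random intercept SD, mmol/L
    noise_ar_coeff: float = 0.7  # AR(1) coefficient of sensor noise
    noise_sd: float = 0.45  # marginal sensor-noise SD, mmol/L
    missing_rate: float = 0.03
    # sampling
    n_days: int = 5
    sample_interval: int = 5  # minutes
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "t_allele_freq",
            "sibling_fraction",
            "female_fraction",
            "offspring_fraction",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if not 0.0 <= self.noise_ar_coeff < 1.0:
            raise ValueError("noise_ar_coeff must be in [0, 1)")
        if self.n_days < 3:
            raise ValueError("n_days must be >= 3 (first/last day are trimmed)")
        if MINUTES_PER_DAY % self.sample_interval != 0:
            raise ValueError("sample_interval must divide 1440")
        if not -1.0 < self.mediator_corr < 1.0:
            raise ValueError("mediator_corr must be in (-1, 1)")
        for name in ("age_sd", "weight_noise_sd", "pbf_noise_sd", "noise_sd",
                     "person_sd", "family_sd", "meal_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    # -- effect decomposition ------------------------------------------------

    @property
    def mediator_composite_shift(self) -> float:
        """Mean shift in the standardized mediator composite for CT/TT vs CC."""
        dz_w = (
            self.mediator_effect_weight / self.weight_noise_sd
            if self.weight_noise_sd > 0
            else 0.0
        )
        dz_p = (
            self.mediator_effect_pbf / self.pbf_noise_sd
            if self.pbf_noise_sd > 0
            else 0.0
        )
        return (dz_w + dz_p) / math.sqrt(2.0 * (1.0 + self.mediator_corr))

    @property
    def indirect_effect(self) -> float:
        """Genotype effect on nocturnal glucose acting through the mediators."""
        return self.mediator_to_glucose * self.mediator_composite_shift

    @property
    def total_effect(self) -> float:
        return self.direct_effect + self.indirect_effect

    @property
    def implied_mediated_fraction(self) -> float:
        total = self.total_effect
        if total == 0:
            return float("nan")
        return self.indirect_effect / total

    def with_effects(
        self, total_effect: float, mediated_fraction: float
    ) -> "CohortConfig":
        """Config with direct/indirect paths rescaled to a target decomposition.

        ``total_effect`` is the ground-truth CT/TT-vs-CC contrast in
        nocturnal-mean glucose (mmol/L) and ``mediated_fraction`` the share
        carried by the body-composition composite.
        """
        shift = self.mediator_composite_shift
        if shift == 0 and mediated_fraction != 0:
            raise ValueError(
                "mediator shift is zero; cannot target a nonzero mediated fraction"
            )
        indirect = total_effect * mediated_fraction
        return replace(
            self,
            direct_effect=total_effect - indirect,
            mediator_to_glucose=(indirect / shift if shift != 0 else 0.0),
        )

    def null(self) -> "CohortConfig":
        """Config with every genotype effect switched off."""
        return replace(
            self,
            direct_effect=0.0,
            mediator_effect_weight=0.0,
            mediator_effect_pbf=0.0,
            mediator_to_glucose=0.0,
        )

    @property
    def samples_per_day(self) -> int:
        return MINUTES_PER_DAY // self.sample_interval

    @property
    def n_samples(self) -> int:
        return self.n_days * self.samples_per_day


@dataclass
class Participant:
    """One study participant; ``family_intercept`` is the latent shared
    family-level glucose shift used by the trace generator."""

    participant_id: str
    family_id: str
    genotype: str
    age: float
    sex: str  # "female" / "male"
    offspring: str  # "offspring" / "partner"
    weight: float
    pbf: float
    bmi: float
    whr: float
    fasting_glucose: float
    fasting_insulin: float
    family_intercept: float = 0.0
    index: int = 0

    @property
    def risk_group(self) -> bool:
        return self.genotype != "CC"


# ---------------------------------------------------------------------------
# cohort simulation


def _genotype_from_alleles(a1: int, a2: int) -> str:
    n_t = a1 + a2
    return GENOTYPES[n_t]


def simulate_cohort(config: CohortConfig) -> list[Participant]:
    """Draw a cohort of participants with family-clustered genotypes.

    Singletons receive two independent alleles at frequency ``t_allele_freq``
    (Hardy-Weinberg proportions); sibling pairs each draw one allele from
    each of two shared simulated parents, so siblings are genotype-correlated
    while marginal frequencies remain at HWE. Risk-group carriers (CT/TT)
    receive the configured mean shifts in weight and percent body fat.
    """
    if config.n_participants < 4:
        raise ValueError("need at least 4 participants to form clusters and groups")
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_participants
    p = config.t_allele_freq

    n_pairs = int(config.sibling_fraction * n) // 2
    genotypes: list[str] = []
    family_ids: list[str] = []
    fam = 0
    for _ in range(n_pairs):
        parent1 = rng.random(2) < p
        parent2 = rng.random(2) < p
        for _sib in range(2):
            a1 = parent1[rng.integers(2)]
            a2 = parent2[rng.integers(2)]
            genotypes.append(_genotype_from_alleles(int(a1), int(a2)))
            family_ids.append(f"F{fam:04d}")
        fam += 1
    for _ in range(n - 2 * n_pairs):
        alleles = rng.random(2) < p
        genotypes.append(_genotype_from_alleles(int(alleles[0]), int(alleles[1])))
        family_ids.append(f"F{fam:04d}")
        fam += 1

    risk = np.array([g != "CC" for g in genotypes])

    # family random intercepts, shared within each family
    unique_fams = sorted(set(family_ids))
    fam_eff = dict(
        zip(unique_fams, rng.normal(0.0, config.family_sd, len(unique_fams)))
    )

    age = rng.normal(config.age_mean, config.age_sd, n)
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    offspring = np.where(
        rng.random(n) < config.offspring_fraction, "offspring", "partner"
    )

    # correlated mediator noise (weight, pbf)
    z = rng.multivariate_normal(
        [0.0, 0.0],
        [[1.0, config.mediator_corr], [config.mediator_corr, 1.0]],
        size=n,
    )
    weight = (
        config.weight_mean
        + config.mediator_effect_weight * risk
        + config.weight_noise_sd * z[:, 0]
    )
    pbf = (
        config.pbf_mean
        + config.mediator_effect_pbf * risk
        + config.pbf_noise_sd * z[:, 1]
    )
    weight = np.clip(weight, 40.0, 140.0)
    pbf = np.clip(pbf, 8.0, 55.0)

    height_m = rng.normal(1.72, 0.087, n)
    bmi = np.clip(weight / height_m**2, 19.0, 33.0)  # eligibility band
    whr = np.clip(rng.normal(0.92, 0.08, n), 0.6, 1.2)
    fasting_glucose = np.clip(
        rng.normal(5.15, 0.45, n) + 0.08 * risk, 3.0, 7.0
    )
    fasting_insulin = np.exp(rng.normal(np.log(2.2), 0.45, n) + 0.05 * risk)

    participants = []
    for i in range(n):
        participants.append(
            Participant(
                participant_id=f"P{i:04d}",
                family_id=family_ids[i],
                genotype=genotypes[i],
                age=float(age[i]),
                sex=str(sex[i]),
                offspring=str(offspring[i]),
                weight=float(weight[i]),
                pbf=float(pbf[i]),
                bmi=float(bmi[i]),
                whr=float(whr[i]),
                fasting_glucose=float(fasting_glucose[i]),
                fasting_insulin=float(fasting_insulin[i]),
                family_intercept=float(fam_eff[family_ids[i]]),
                index=i,
            )
        )
    return participants


def cohort_to_frame(participants: list[Participant]) -> pd.DataFrame:
    """Phenotype table: one row per participant, analysis-ready columns."""
    return pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in participants],
            "family_id": [p.family_id for p in participants],
            "genotype": [p.genotype for p in participants],
            "risk_group": [int(p.risk_group) for p in participants],
            "age": [p.age for p in participants],
            "sex": [p.sex for p in participants],
            "offspring": [p.offspring for p in participants],
            "weight": [p.weight for p in participants],
            "pbf": [p.pbf for p in participants],
            "bmi": [p.bmi for p in participants],
            "whr": [p.whr for p in participants],
            "fasting_glucose": [p.fasting_glucose for p in participants],
            "fasting_insulin": [p.fasting_insulin for p in participants],
        }
    )


# ---------------------------------------------------------------------------
# trace simulation


@functools.lru_cache(maxsize=8)
def _baseline_curves(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """(circadian baseline incl. meals, normalised nocturnal weight) per slot."""
    t_min = np.arange(config.n_samples) * config.sample_interval  # abs minutes
    clock_h = (t_min % MINUTES_PER_DAY) / 60.0

    # 24-h cosine with its minimum (= nocturnal_nadir) at nadir_time
    phase = 2.0 * np.pi * (clock_h - config.nadir_time) / 24.0
    base = config.nocturnal_nadir + config.circadian_amplitude * 0.5 * (
        1.0 - np.cos(phase)
    )

    # Gaussian meal excursions (wrapped on the 24-h circle)
    for mt in config.meal_times:
        d = np.abs(clock_h - mt)
        d = np.minimum(d, 24.0 - d) * 60.0  # minutes on the circle
        base = base + config.meal_amplitude * np.exp(
            -0.5 * (d / config.meal_width) ** 2
        )

    # raised-cosine nocturnal weight over 0:00-7:00, normalised so its mean
    # over the 3:00-6:00 analysis window is exactly 1: the configured direct
    # effect is then the exact ground-truth shift of the nocturnal-mean outcome
    w = np.where(
        clock_h < 7.0, 0.5 * (1.0 - np.cos(2.0 * np.pi * clock_h / 7.0)), 0.0
    )
    clock_min = t_min % MINUTES_PER_DAY
    noct = WINDOW_NOCTURNAL.contains(clock_min)
    w = w / w[noct].mean()

    base.setflags(write=False)
    w.setflags(write=False)
    return base, w


def _mediator_composite(participant: Participant, config: CohortConfig) -> float:
    """Standardized weight/body-fat composite (unit variance under the null)."""
    parts = []
    if config.weight_noise_sd > 0:
        parts.append(
            (participant.weight - config.weight_mean) / config.weight_noise_sd
        )
    if config.pbf_noise_sd > 0:
        parts.append((participant.pbf - config.pbf_mean) / config.pbf_noise_sd)
    if not parts:
        return 0.0
    return float(sum(parts) / math.sqrt(2.0 * (1.0 + config.mediator_corr)))


def simulate_cgm_trace(participant: Participant, config: CohortConfig) -> CgmSeries:
    """One participant's CGM trace on the configured grid.

    trace = circadian baseline + meal excursions
          + direct_effect * risk_group * nocturnal weight
          + mediator_to_glucose * standardized mediator composite
          + person-level and family-level random intercepts
          + AR(1) sensor noise (marginal SD = noise_sd)
    with ``missing_rate`` of samples blanked at random. Deterministic: the
    stream is derived from (config.seed, participant.index).
    """
    base, noct_w = _baseline_curves(config)
    rng = np.random.default_rng([config.seed, 1, participant.index])

    person_shift = rng.normal(0.0, config.person_sd) if config.person_sd > 0 else 0.0
    level = (
        base
        + config.direct_effect * float(participant.risk_group) * noct_w
        + config.mediator_to_glucose * _mediator_composite(participant, config)
        + person_shift
        + participant.family_intercept
    )

    n = config.n_samples
    if config.noise_sd > 0:
        a = config.noise_ar_coeff
        innov_sd = config.noise_sd * math.sqrt(1.0 - a * a)
        eps = rng.standard_normal(n) * innov_sd
        eps[0] = rng.normal(0.0, config.noise_sd)  # stationary start
        noise = lfilter([1.0], [1.0, -a], eps)
    else:
        noise = np.zeros(n)

    values = np.clip(level + noise, 0.5, 39.5)
    if config.missing_rate > 0:
        drop = rng.random(n) < config.missing_rate
        values = values.copy()
        values[drop] = np.nan

    return CgmSeries(
        participant_id=participant.participant_id,
        start=TRACE_START,
        interval=config.sample_interval,
        values=values,
    )


def simulate_cohort_traces(
    participants: list[Participant], config: CohortConfig
) -> list[CgmSeries]:
    """All traces for a cohort (per-participant streams, order-independent)."""
    return [simulate_cgm_trace(p, config) for p in participants]


def traces_to_long_frame(traces: list[CgmSeries]) -> pd.DataFrame:
    """Long CGM table (participant_id, timestamp, glucose); missing rows kept out."""
    frames = []
    for s in traces:
        valid = ~np.isnan(s.values)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "timestamp": s.timestamps[valid].strftime("%Y-%m-%dT%H:%M:%S"),
                    "glucose": np.round(s.values[valid], 6),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
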