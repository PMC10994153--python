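"""Seeded synthetic OGTT cohorts with the structure the analysis assumes.

The study data are restricted, so this generator produces cohorts with the
same statistical skeleton: 5-point glucose trajectories drawn from four
archetypes (monophasic / biphasic / monotonically increasing / flat) at the
published mixture frequencies, insulin curves tied to the glucose excursion
through a per-participant gain, metabolic labs with positive dependence on
latent curve height, and a follow-up dysglycemia outcome whose log-odds are
linear in latent curve height and the latent 120-minute excursion — and,
deliberately, carry no information about fasting glucose, so fasting
glucose alone is a chance-level predictor of the simulated outcome.

Archetype mean curves are monotone piecewise-cubic (PCHIP) bumps through
control points chosen so that, at zero noise, each archetype triggers its
own rule in the shape classifier: the monophasic bump peaks at 45-75 min
and returns toward baseline; the biphasic curve peaks at 30 min, dips by
well over 4.5 mg/dL and re-rises by over 4.5 mg/dL; the monotonic curve
increases through 120 min; the flat curve never rises (the "inconclusive"
path).

A single master seed spawns one named substream per participant, so
enlarging a cohort never perturbs already-generated participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.special import expit, logit

from .cohort import ParticipantRecord, OGTTProfile
from .smoothing import DEFAULT_TIMES

MONOPHASIC = "monophasic"
BIPHASIC = "biphasic"
MONOTONIC = "monotonically_increasing"
FLAT = "flat"

ARCHETYPES = (MONOPHASIC, BIPHASIC, MONOTONIC, FLAT)

#: published cohort shape frequencies (monophasic/biphasic/monotonic/flat)
DEFAULT_MIXTURE = {MONOPHASIC: 0.547, BIPHASIC: 0.420,
                   MONOTONIC: 0.025, FLAT: 0.008}

# reference moments of the latent height / 120-min excursion used to put
# the outcome model on an approximately standardized scale (population
# values of the default generator, estimated once at large n)
H_REF = (33.9, 11.1)
E_REF = (22.4, 11.3)

GLUCOSE_FLOOR = 40.0  # mg/dL
INSULIN_FLOOR = 1.0   # uU/mL


@dataclass(frozen=True)
class ArchetypeSpec:
    """One glucose-response archetype: a positive mean curve and a weight."""

    name: str
    mean_curve: object  # callable t -> mg/dL on [0, 120]
    mixture_weight: float


@dataclass
class GeneratorParams:
    """Everything the cohort generator draws from, with study defaults.

    Demographics and the archetype mixture follow the published cohort
    margins; fasting glucose is N(83, 8) mg/dL; measurement noise is a few
    mg/dL for glucose (assay plus short-term biological variability at
    30-min sampling) and proportional-scale for insulin.  The outcome
    intercept is calibrated so that follow-up dysglycemia prevalence is
    about 7.3% under the default coefficients.
    """

    n: int = 671
    seed: int = 0
    mixture: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    fasting_mean: float = 83.0
    fasting_sd: float = 8.0
    # archetype amplitude scales (mg/dL above fasting), lognormal spread
    amplitude_mean: dict = field(default_factory=lambda: {
        MONOPHASIC: 60.0, BIPHASIC: 40.0, MONOTONIC: 75.0, FLAT: 0.0})
    amplitude_sigma: float = 0.28
    amplitude_floor: dict = field(default_factory=lambda: {
        MONOPHASIC: 25.0, BIPHASIC: 22.0, MONOTONIC: 15.0, FLAT: 0.0})
    amplitude_cap: float = 180.0
    noise_sd_glucose: float = 4.0   # mg/dL
    noise_sd_insulin: float = 4.0   # uU/mL, pre-gain scale
    insulin_gain_log_mean: float = 0.7
    insulin_gain_log_sd: float = 0.30
    followup_fraction: float = 0.288
    outcome_intercept: float = -3.35  # calibrated: prevalence ~= 0.073
    outcome_coef_height: float = 0.9
    outcome_coef_exc120: float = 0.7
    female_fraction: float = 0.539
    race_probs: dict = field(default_factory=lambda: {
        "white": 0.575, "black": 0.316, "other/multiracial": 0.078,
        "unknown": 0.031})
    hispanic_fraction: float = 0.058
    missing_bp: float = 0.031
    missing_waist: float = 0.036
    missing_lipids: float = 0.015

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size n must be positive")
        w = np.array([self.mixture.get(a, 0.0) for a in ARCHETYPES])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("mixture weights must be >= 0 and sum to 1")
        for sd in (self.fasting_sd, self.noise_sd_glucose,
                   self.noise_sd_insulin):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.followup_fraction <= 1:
            raise ValueError("followup_fraction must be in [0, 1]")


def intercept_for_prevalence(p: float) -> float:
    """Outcome intercept giving prevalence ``p`` when all slopes are zero."""
    return float(logit(p))


@dataclass
class Latents:
    """Per-participant latent variables behind both analyte curves."""

    archetype: str
    fasting: float
    amplitude: float
    shape_params: dict
    gain: float
    insulin_basal: float   # pre-gain units
    insulin_scale: float
    insulin_delay: float   # minutes

    @property
    def mean_curve(self):
        if "_curve" not in self.__dict__:
            self.__dict__["_curve"] = archetype_mean_curve(
                self.archetype, self.fasting, self.amplitude,
                self.shape_params)
        return self.__dict__["_curve"]


def archetype_mean_curve(name: str, fasting: float, amplitude: float,
                         shape_params: dict | None = None):
    """Build the noise-free glucose mean curve for one archetype.

    Returns a callable on [0, 120] minutes.  ``shape_params`` hold the
    within-archetype variation: peak shift (monophasic), dip depth /
    re-rise / terminal decline fractions (biphasic), rise fractions
    (monotonic).
    """
    sp = shape_params or {}
    if name == FLAT:
        return lambda t: np.full_like(np.asarray(t, float), fasting)
    if name == MONOPHASIC:
        s = float(sp.get("peak_shift", 0.0))
        knots = np.array([0.0, 30.0, 60.0 + s, 90.0, 120.0])
        frac = np.array([0.0, 0.65, 1.0, 0.55, 0.35])
    elif name == BIPHASIC:
        d = float(sp.get("dip", 0.45))
        r = float(sp.get("rerise", 0.26))
        e = float(sp.get("tail_drop", 0.33))
        knots = np.array([0.0, 30.0, 60.0, 90.0, 120.0])
        frac = np.array([0.0, 1.0, 1.0 - d, 1.0 - d + r, 1.0 - d + r - e])
    elif name == MONOTONIC:
        f = np.asarray(sp.get("rise_fracs", (0.25, 0.5, 0.75)), float)
        knots = np.array([0.0, 30.0, 60.0, 90.0, 120.0])
        frac = np.array([0.0, f[0], f[1], f[2], 1.0])
    else:
        raise ValueError(f"unknown archetype {name!r}")
    interp = PchipInterpolator(knots, fasting + amplitude * frac)
    return lambda t: np.asarray(interp(np.clip(t, 0.0, 120.0)), float)


def _draw_shape_params(name: str, rng: np.random.Generator) -> dict:
    if name == MONOPHASIC:
        return {"peak_shift": rng.uniform(-15.0, 15.0)}
    if name == BIPHASIC:
        return {"dip": rng.uniform(0.40, 0.50),
                "rerise": rng.uniform(0.22, 0.30),
                "tail_drop": rng.uniform(0.25, 0.40)}
    if name == MONOTONIC:
        inc = rng.uniform(0.5, 1.5, size=4)
        f = np.cumsum(inc) / inc.sum()
        return {"rise_fracs": tuple(f[:3])}
    return {}


def generate_profile(latents: Latents, params: GeneratorParams,
                     rng: np.random.Generator) -> OGTTProfile:
    """One OGTT: archetype mean plus noise, insulin as gain x excursion.

    Glucose: mean_curve(t_j) + N(0, noise_sd_glucose), floored at 40 mg/dL.
    Insulin: gain x (basal + scale x excursion(t - delay) + noise), floored
    at 1 uU/mL — so rescaling ``gain`` with an identical noise stream
    rescales pre-floor insulin exactly proportionally.
    """
    times = DEFAULT_TIMES
    curve = latents.mean_curve
    g_noise = rng.normal(0.0, params.noise_sd_glucose, times.size) \
        if params.noise_sd_glucose > 0 else np.zeros(times.size)
    glucose = np.maximum(curve(times) + g_noise, GLUCOSE_FLOOR)
    exc = np.maximum(curve(np.maximum(times - latents.insulin_delay, 0.0))
                     - latents.fasting, 0.0)
    i_noise = rng.normal(0.0, params.noise_sd_insulin, times.size) \
        if params.noise_sd_insulin > 0 else np.zeros(times.size)
    insulin_pre = latents.gain * (
        latents.insulin_basal + latents.insulin_scale * exc + i_noise)
    insulin = np.maximum(insulin_pre, INSULIN_FLOOR)
    return OGTTProfile(glucose=glucose, insulin=insulin)


def latent_height(latents: Latents, step: float = 1.0) -> float:
    """Time-averaged excursion of the mean curve above fasting (mg/dL)."""
    t = np.arange(0.0, 120.0 + step / 2, step)
    return float(np.mean(latents.mean_curve(t) - latents.fasting))


def latent_exc120(latents: Latents) -> float:
    """Noise-free 120-min excursion above fasting (mg/dL)."""
    return float(latents.mean_curve(np.array([120.0]))[0] - latents.fasting)


def event_probability(latents: Latents, params: GeneratorParams) -> float:
    """Follow-up dysglycemia probability for one participant's latents."""
    hz = (latent_height(latents) - H_REF[0]) / H_REF[1]
    ez = (latent_exc120(latents) - E_REF[0]) / E_REF[1]
    lo = (params.outcome_intercept
          + params.outcome_coef_height * hz
          + params.outcome_coef_exc120 * ez)
    return float(expit(lo))


def _draw_bounded(rng, mean, sd, lo, hi, max_tries=100):
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if lo < v <= hi:
            return v
    return float(np.clip(v, lo + 1e-6, hi))


def assign_followup(latents: Latents, params: GeneratorParams,
                    rng: np.random.Generator):
    """Draw the follow-up OGTT and dysglycemia-consistent FPG / 2hrPG.

    The event indicator is Bernoulli with :func:`event_probability`; the
    follow-up fasting and 2-h glucose are then drawn *conditionally* on the
    event so the composite rule (FPG > 100 or 2hrPG > 140) reproduces the
    indicator exactly.  Fasting glucose is drawn from the same bounded
    distribution in both arms, so it carries no outcome information.
    """
    p = event_probability(latents, params)
    event = bool(rng.random() < p)
    fpg = _draw_bounded(rng, 87.0, 5.0, 60.0, 100.0)
    if event:
        pg2h = 140.5 + rng.exponential(12.0)
    else:
        pg2h = _draw_bounded(rng, 103.0, 17.0, 45.0, 140.0)
    fu_latents = Latents(
        archetype=latents.archetype,
        fasting=fpg,
        amplitude=latents.amplitude * float(np.exp(rng.normal(0.0, 0.15))),
        shape_params=latents.shape_params,
        gain=latents.gain * float(np.exp(rng.normal(0.0, 0.10))),
        insulin_basal=latents.insulin_basal,
        insulin_scale=latents.insulin_scale,
        insulin_delay=latents.insulin_delay,
    )
    profile = generate_profile(fu_latents, params, rng)
    glucose = profile.glucose.copy()
    glucose[0], glucose[-1] = fpg, pg2h
    profile = OGTTProfile(glucose=glucose, insulin=profile.insulin)
    interval = 6.0 + float(np.exp(rng.normal(np.log(8.5), 0.45)))
    return profile, interval, event, p


@dataclass
class SyntheticCohort:
    """Generated records plus the ground-truth sidecar table."""

    records: list[ParticipantRecord]
    truth: pd.DataFrame


def _draw_latents(params: GeneratorParams, rng: np.random.Generator,
                  z_bmi: float) -> Latents:
    weights = np.array([params.mixture.get(a, 0.0) for a in ARCHETYPES])
    archetype = ARCHETYPES[int(rng.choice(len(ARCHETYPES),
                                          p=weights / weights.sum()))]
    fasting = rng.normal(params.fasting_mean, params.fasting_sd)
    fasting = float(np.clip(fasting, 55.0, 130.0))
    if archetype == FLAT:
        amplitude = 0.0
    else:
        z_a = 0.45 * z_bmi + np.sqrt(1 - 0.45**2) * rng.normal()
        amplitude = params.amplitude_mean[archetype] * float(
            np.exp(params.amplitude_sigma * z_a))
        amplitude = float(np.clip(amplitude,
                                  params.amplitude_floor[archetype],
                                  params.amplitude_cap))
    z_g = 0.5 * z_bmi + np.sqrt(1 - 0.5**2) * rng.normal()
    gain = float(np.exp(params.insulin_gain_log_mean
                        + params.insulin_gain_log_sd * z_g))
    return Latents(
        archetype=archetype,
        fasting=fasting,
        amplitude=amplitude,
        shape_params=_draw_shape_params(archetype, rng),
        gain=gain,
        insulin_basal=float(rng.uniform(4.0, 8.0)),
        insulin_scale=float(rng.uniform(0.8, 1.2)),
        insulin_delay=float(rng.uniform(5.0, 15.0)),
    )


def generate_participant(pid: str, params: GeneratorParams,
                         rng: np.random.Generator):
    """Generate one participant record plus its ground-truth row."""
    age = float(rng.uniform(8.0, 18.0))
    sex = "female" if rng.random() < params.female_fraction else "male"
    races = list(params.race_probs)
    race = races[int(rng.choice(len(races),
                                p=np.array(list(params.race_probs.values()))))]
    ethnicity = ("hispanic" if rng.random() < params.hispanic_fraction
                 else "non-hispanic")
    bmi = float(np.clip(85.0 + 15.0 * rng.beta(4.0, 1.1), 85.0, 99.9))
    z_bmi = (bmi - 96.8) / 2.5

    latents = _draw_latents(params, rng, z_bmi)
    profile = generate_profile(latents, params, rng)

    h = latent_height(latents)
    hz = (h - H_REF[0]) / H_REF[1]
    zg = (np.log(latents.gain) - params.insulin_gain_log_mean) \
        / params.insulin_gain_log_sd

    hba1c = float(np.clip(5.2 + 0.10 * hz + rng.normal(0, 0.22), 4.0, 9.0))
    trig = float(np.exp(4.45 + 0.12 * hz + 0.10 * zg + rng.normal(0, 0.30)))
    hdl = float(np.exp(3.85 - 0.07 * hz - 0.05 * zg + rng.normal(0, 0.18)))
    ldl = float(np.exp(4.50 + 0.04 * hz + rng.normal(0, 0.22)))
    total_chol = float(ldl + hdl + trig / 5.0 + rng.normal(0, 8.0))
    sbp = float(110.0 + 1.1 * z_bmi + 1.0 * hz + rng.normal(0, 8.0))
    dbp = float(65.0 + 0.7 * z_bmi + 0.6 * hz + rng.normal(0, 6.0))
    waist = float(max(95.0 + 2.2 * z_bmi + 1.2 * hz + rng.normal(0, 9.0),
                      55.0))

    has_fu = rng.random() < params.followup_fraction
    fu_profile = fu_interval = None
    event = None
    p_event = event_probability(latents, params)
    if has_fu:
        fu_profile, fu_interval, event, p_event = assign_followup(
            latents, params, rng)

    # variable-specific missingness, as seen in real lab panels
    miss_bp = rng.random() < params.missing_bp
    miss_waist = rng.random() < params.missing_waist
    miss_lip = rng.random() < params.missing_lipids

    rec = ParticipantRecord(
        id=pid, age=age, sex=sex, race=race, ethnicity=ethnicity,
        bmi_percentile=bmi, hba1c=hba1c,
        baseline_profile=profile,
        waist_cm=None if miss_waist else waist,
        sbp=None if miss_bp else sbp,
        dbp=None if miss_bp else dbp,
        total_chol=None if miss_lip else total_chol,
        ldl=None if miss_lip else ldl,
        hdl=None if miss_lip else hdl,
        triglycerides=None if miss_lip else trig,
        followup_profile=fu_profile,
        followup_interval=fu_interval,
    )
    truth = {
        "id": pid,
        "archetype": latents.archetype,
        "fasting": latents.fasting,
        "amplitude": latents.amplitude,
        "latent_height": h,
        "exc120": latent_exc120(latents),
        "insulin_gain": latents.gain,
        "event_probability": p_event,
        "has_followup": has_fu,
        "event": event,
    }
    return rec, truth


def generate_cohort(params: GeneratorParams | None = None,
                    **overrides) -> SyntheticCohort:
    """Generate a full seeded cohort.

    Keyword overrides are applied on top of ``params`` (or the defaults),
    e.g. ``generate_cohort(n=200, seed=3, followup_fraction=1.0)``.
    """
    if params is None:
        params = GeneratorParams()
    if overrides:
        params = GeneratorParams(**{**params.__dict__, **overrides})
    params.validate()
    master = np.random.SeedSequence(params.seed)
    children = master.spawn(params.n)
    records, truths = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        rec, truth = generate_participant(f"P{i:05d}", params, rng)
        records.append(rec)
        truths.append(truth)
    return SyntheticCohort(records=records, truth=pd.DataFrame(truths))
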