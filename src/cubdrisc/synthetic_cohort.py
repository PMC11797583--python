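"""Seeded synthetic screening cohorts for end-to-end pipeline testing.

The original Jaruco screening dataset is not deposited, so this module
generates cohorts that reproduce its published *marginal* structure — sex
ratio, questionnaire-item prevalences, age/BMI band frequencies and the
five-state glycemic outcome mix — while coupling the outcome to the
questionnaire total through a proportional-odds (ordered-logit) link whose
intercepts are calibrated at run time so the marginal state frequencies hit
their targets on the realised score distribution.

Joint structure beyond the published marginals is deliberately minimal:
items are drawn independently except that waist circumference depends on sex
and BMI, and the glycemic state depends on the FINDRISC total.  The OGTT
glucose pair is drawn from state-conditional truncated normals confined to
each state's diagnostic box, so classifying the generated pair always
recovers the latent state exactly.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .glycemia import (
    DEFAULT_THRESHOLDS,
    GlucoseThresholds,
    GlycemicState,
    STATE_ORDER,
    classify_ogtt_array,
)
from .scales import (
    FamilyHistory,
    ParticipantRecord,
    ScaleName,
    Sex,
    build_scale,
    score_frame,
    write_participants,
)

__all__ = [
    "CohortConfig",
    "LinkCalibration",
    "Cohort",
    "CalibrationError",
    "generate_cohort",
    "eligibility",
    "cohort_flow",
    "write_cohort",
]


class CalibrationError(RuntimeError):
    """The outcome link could not be calibrated to the target marginals."""


# Age bands (inclusive integer years) matching the published frequency table;
# the open top band is truncated at 90 years for sampling.
AGE_BAND_RANGES: tuple[tuple[int, int], ...] = ((20, 44), (45, 54), (55, 64), (65, 90))
# BMI bands: under/normal weight, overweight, obese (kg/m²).
BMI_BAND_RANGES: tuple[tuple[float, float], ...] = ((16.0, 25.0), (25.0, 30.0), (30.0, 45.0))

#: State-conditional glucose distribution parameters:
#: (fpg mean, fpg sd, 2h mean, 2h sd), all mmol/L.  Means sit inside each
#: state's diagnostic box; draws are truncated to the box.
DEFAULT_GLUCOSE_PARAMS: dict[GlycemicState, tuple[float, float, float, float]] = {
    GlycemicState.NORMAL: (4.9, 0.5, 5.8, 1.1),
    GlycemicState.AFG: (6.0, 0.4, 6.3, 0.9),
    GlycemicState.AGT: (5.1, 0.4, 8.8, 0.8),
    GlycemicState.AFG_AGT: (6.1, 0.4, 9.0, 0.8),
    GlycemicState.DM2: (8.5, 1.2, 13.0, 2.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults reproduce the published cohort marginals.

    ``outcome_probs`` orders the five states as (none, AFG, AGT, AFG+AGT,
    DM2).  ``link_slope`` is the log-odds increase in outcome severity per
    questionnaire point; its default was chosen by a calibration experiment
    to give the pipeline a dysglycemia AUC near 0.75, the qualitative regime
    the published evaluation operates in.
    """

    n: int = 3737
    seed: int = 0
    sex_p_woman: float = 0.587
    age_band_probs: tuple[float, ...] = (0.347, 0.199, 0.193, 0.261)
    bmi_band_probs: tuple[float, ...] = (0.465, 0.359, 0.176)
    item_prevalences: Mapping[str, float] = field(
        default_factory=lambda: {
            "activity": 0.533,
            "fruit_veg": 0.174,
            "htn_meds": 0.475,
            "high_glucose_history": 0.355,
            "fh_first_degree": 0.299,
            "fh_second_degree": 0.15,
        }
    )
    outcome_probs: tuple[float, ...] = (0.655, 0.214, 0.035, 0.032, 0.064)
    link_slope: float = 0.22
    # waist model: WC ~ LogNormal(log(base_sex + bmi_coeff * BMI), sigma)
    wc_base: Mapping[str, float] = field(default_factory=lambda: {"M": 62.0, "W": 55.0})
    wc_bmi_coeff: float = 1.15
    wc_sigma: float = 0.07
    bmi_log_mu: float = math.log(26.0)
    bmi_log_sigma: float = 0.16
    glucose_params: Mapping[GlycemicState, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GLUCOSE_PARAMS)
    )
    thresholds: GlucoseThresholds = DEFAULT_THRESHOLDS
    require_risk_factor: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be ≥ 1")
        if self.link_slope < 0:
            raise ValueError("link_slope must be non-negative")
        if not 0 <= self.sex_p_woman <= 1:
            raise ValueError("sex_p_woman must be a probability")
        for name, probs, k in (
            ("age_band_probs", self.age_band_probs, 4),
            ("bmi_band_probs", self.bmi_band_probs, 3),
            ("outcome_probs", self.outcome_probs, 5),
        ):
            if len(probs) != k:
                raise ValueError(f"{name} must have {k} entries")
            if any(p < 0 for p in probs) or abs(sum(probs) - 1) > 1e-9:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        fh = self.item_prevalences["fh_first_degree"] + self.item_prevalences["fh_second_degree"]
        if fh > 1:
            raise ValueError("family-history prevalences exceed 1")

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["glucose_params"] = {
            GlycemicState(k).value: list(v) for k, v in self.glucose_params.items()
        }
        d["thresholds"] = json.loads(self.thresholds.to_json())
        d["item_prevalences"] = dict(self.item_prevalences)
        d["wc_base"] = dict(self.wc_base)
        return d


@dataclass(frozen=True)
class LinkCalibration:
    """Calibrated proportional-odds link: P(state ≤ k | s) = σ(c_k − β·s)."""

    slope: float
    intercepts: tuple[float, ...]  # c_1..c_4, non-decreasing

    def cumulative_probs(self, scores: np.ndarray) -> np.ndarray:
        """(n, 4) array of P(state ≤ k | score) for k = none..AFG_AGT."""
        s = np.asarray(scores, dtype=float)[:, None]
        c = np.asarray(self.intercepts)[None, :]
        return 1 / (1 + np.exp(-(c - self.slope * s)))

    def dysglycemia_prob(self, scores: np.ndarray) -> np.ndarray:
        """P(any non-normal state | score) under the calibrated link."""
        return 1 - self.cumulative_probs(scores)[:, 0]


@dataclass(frozen=True)
class Cohort:
    """A generated cohort: participant table plus generator diagnostics.

    ``frame`` holds the participant CSV columns plus ``latent_state``, the
    glycemic truth from which the glucose pair was drawn.
    """

    frame: pd.DataFrame
    config: CohortConfig
    link: LinkCalibration


def _trunc_normal(
    rng: np.random.Generator, lo: float, hi: float, mean: float, sd: float, size: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_covariates(rng: np.random.Generator, m: int, cfg: CohortConfig) -> pd.DataFrame:
    sex = np.where(rng.random(m) < cfg.sex_p_woman, Sex.WOMAN.value, Sex.MAN.value)

    age_band = rng.choice(len(AGE_BAND_RANGES), size=m, p=cfg.age_band_probs)
    age = np.empty(m, dtype=np.int64)
    for k, (lo, hi) in enumerate(AGE_BAND_RANGES):
        mask = age_band == k
        age[mask] = rng.integers(lo, hi + 1, size=mask.sum())

    bmi_band = rng.choice(len(BMI_BAND_RANGES), size=m, p=cfg.bmi_band_probs)
    bmi = np.empty(m)
    eps = 0.006  # keeps 2-dp rounded values inside the drawn band
    for k, (lo, hi) in enumerate(BMI_BAND_RANGES):
        mask = bmi_band == k
        if not mask.any():
            continue
        # log-normal body-mass distribution truncated to the band; band edges
        # nudged so 25.0 and 30.0 land in the closed middle band only
        band_lo = lo + eps if k == 2 else lo
        band_hi = hi - eps if k == 0 else hi
        bmi[mask] = np.exp(
            _trunc_normal(
                rng,
                math.log(band_lo),
                math.log(band_hi),
                cfg.bmi_log_mu,
                cfg.bmi_log_sigma,
                int(mask.sum()),
            )
        )

    base = np.where(sex == Sex.WOMAN.value, cfg.wc_base["W"], cfg.wc_base["M"])
    wc_mu = np.log(base + cfg.wc_bmi_coeff * bmi)
    waist = np.exp(rng.normal(wc_mu, cfg.wc_sigma))

    prev = cfg.item_prevalences
    u_fh = rng.random(m)
    fh = np.full(m, FamilyHistory.NONE.value, dtype=object)
    fh[u_fh < prev["fh_first_degree"]] = FamilyHistory.FIRST_DEGREE.value
    fh[
        (u_fh >= prev["fh_first_degree"])
        & (u_fh < prev["fh_first_degree"] + prev["fh_second_degree"])
    ] = FamilyHistory.SECOND_DEGREE.value

    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "bmi": np.round(bmi, 2),
            "waist_cm": np.round(waist, 1),
            "physical_activity": rng.random(m) < prev["activity"],
            "daily_fruit_veg": rng.random(m) < prev["fruit_veg"],
            "antihypertensive_meds": rng.random(m) < prev["htn_meds"],
            "history_high_glucose": rng.random(m) < prev["high_glucose_history"],
            "family_history": fh,
        }
    )


def _eligibility_mask(frame: pd.DataFrame) -> np.ndarray:
    """Vectorised core risk-factor screen (see :func:`eligibility`)."""
    wc_cut = np.where(frame["sex"].to_numpy() == Sex.WOMAN.value, 80.0, 90.0)
    return (
        (frame["age"].to_numpy() >= 45)
        | (frame["bmi"].to_numpy() >= 25)
        | (frame["family_history"].to_numpy() != FamilyHistory.NONE.value)
        | (frame["waist_cm"].to_numpy() >= wc_cut)
        | frame["antihypertensive_meds"].to_numpy()
        | ~frame["physical_activity"].to_numpy()
    )


def _calibrate_link(scores: np.ndarray, cfg: CohortConfig) -> LinkCalibration:
    """Solve the ordered-logit intercepts against the realised scores.

    For each cumulative target q_k the intercept c_k solves
    mean_i σ(c_k − β·s_i) = q_k; the mean is strictly increasing in c_k so
    the solution is unique, and solutions are automatically non-decreasing
    in k because the targets are.
    """
    beta = cfg.link_slope
    cum_targets = np.cumsum(cfg.outcome_probs)[:4]
    intercepts = []
    for q in cum_targets:
        if not 0 < q < 1:
            raise CalibrationError(
                f"cumulative outcome target {q} is degenerate; "
                "every state must have positive probability"
            )

        def f(c: float, q=q) -> float:
            return float(np.mean(1 / (1 + np.exp(-(c - beta * scores))))) - q

        lo, hi = -60.0, 60.0 + beta * float(np.max(scores))
        if f(lo) > 0 or f(hi) < 0:
            raise CalibrationError(
                f"cannot reach cumulative target {q} with link_slope={beta}; "
                "reduce the slope or adjust outcome_probs"
            )
        intercepts.append(float(brentq(f, lo, hi, xtol=1e-12)))
    return LinkCalibration(slope=beta, intercepts=tuple(intercepts))


def _draw_states(
    rng: np.random.Generator, scores: np.ndarray, link: LinkCalibration
) -> np.ndarray:
    cum = link.cumulative_probs(scores)
    u = rng.random(len(scores))
    idx = (u[:, None] >= cum).sum(axis=1)  # 0..4 into STATE_ORDER
    return np.array([STATE_ORDER[i].value for i in idx], dtype=object)


def _draw_glucose(
    rng: np.random.Generator, states: np.ndarray, cfg: CohortConfig
) -> tuple[np.ndarray, np.ndarray]:
    t = cfg.thresholds
    # exclusive upper bounds shrink by more than half the 2-dp reporting
    # resolution so rounded values cannot cross a diagnostic threshold
    eps = 0.006
    boxes = {
        GlycemicState.NORMAL: ((2.5, t.fpg_lower - eps), (2.5, t.g2h_lower - eps)),
        GlycemicState.AFG: ((t.fpg_lower, t.fpg_dm - eps), (2.5, t.g2h_lower - eps)),
        GlycemicState.AGT: ((2.5, t.fpg_lower - eps), (t.g2h_lower, t.g2h_dm - eps)),
        GlycemicState.AFG_AGT: (
            (t.fpg_lower, t.fpg_dm - eps),
            (t.g2h_lower, t.g2h_dm - eps),
        ),
        GlycemicState.DM2: ((t.fpg_dm, 18.0), (t.g2h_dm, 28.0)),
    }
    fpg = np.empty(len(states))
    g2h = np.empty(len(states))
    for state, (fpg_box, g2h_box) in boxes.items():
        mask = states == state.value
        if not mask.any():
            continue
        fm, fs, gm, gs = cfg.glucose_params[state]
        k = int(mask.sum())
        fpg[mask] = _trunc_normal(rng, fpg_box[0], fpg_box[1], fm, fs, k)
        g2h[mask] = _trunc_normal(rng, g2h_box[0], g2h_box[1], gm, gs, k)
    return np.round(fpg, 2), np.round(g2h, 2)


def _round_trip_ok(frame: pd.DataFrame, thresholds: GlucoseThresholds) -> np.ndarray:
    observed = classify_ogtt_array(
        frame["fpg_mmol"].to_numpy(), frame["g2h_mmol"].to_numpy(), thresholds
    )
    observed = np.array([s.value for s in observed], dtype=object)
    return observed == frame["latent_state"].to_numpy()


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a seeded cohort; identical config and seed ⇒ identical output.

    With ``require_risk_factor`` the generator rejection-samples until every
    record carries at least one diabetes risk factor, mimicking the study's
    risk-enriched recruitment (at the cost of slightly perturbing the
    configured marginals, since the few rejected records are systematically
    low-risk).
    """
    rng = np.random.default_rng(config.seed)

    chunks: list[pd.DataFrame] = []
    collected = 0
    while collected < config.n:
        m = max(config.n - collected + 64, int((config.n - collected) * 1.1))
        batch = _draw_covariates(rng, m, config)
        if config.require_risk_factor:
            batch = batch[_eligibility_mask(batch)]
        chunks.append(batch)
        collected += len(batch)
    frame = pd.concat(chunks, ignore_index=True).iloc[: config.n].reset_index(drop=True)
    frame.insert(0, "id", [f"S{i:06d}" for i in range(1, config.n + 1)])

    findrisc = score_frame(frame, build_scale(ScaleName.FINDRISC)).to_numpy()
    link = _calibrate_link(findrisc, config)
    states = _draw_states(rng, findrisc, link)
    fpg, g2h = _draw_glucose(rng, states, config)

    frame["fpg_mmol"] = fpg
    frame["g2h_mmol"] = g2h
    frame["latent_state"] = states

    ok = _round_trip_ok(frame, config.thresholds)
    if not ok.all():  # guards against mis-specified custom glucose params
        bad = frame.loc[~ok].iloc[0]
        raise CalibrationError(
            "glucose draw escaped its diagnostic box for latent state "
            f"{bad['latent_state']!r} (fpg={bad['fpg_mmol']}, g2h={bad['g2h_mmol']}); "
            "check glucose_params against the thresholds"
        )
    return Cohort(frame=frame, config=config, link=link)


_CORE_CRITERIA = "age, BMI, family history, waist circumference, hypertension treatment, sedentary lifestyle"


def eligibility(
    record: ParticipantRecord, extended: Mapping[str, object] | None = None
) -> tuple[bool, list[str]]:
    """Risk-factor screen: does this adult qualify for OGTT screening?

    Core criteria: age ≥ 45; BMI ≥ 25 kg/m²; any family history of diabetes;
    waist ≥ 80 cm (women) / ≥ 90 cm (men); antihypertensive treatment;
    sedentary lifestyle (< 150 min of physical activity per week).  Optional
    ``extended`` clinical fields add: triglycerides ≥ 1.7 mmol/L,
    HDL < 1.03 mmol/L, hypertension (≥ 130/85 mmHg), gestational diabetes or
    macrosomic-birth history, atherosclerotic cardiovascular disease, low
    birth weight, polycystic ovary syndrome, acanthosis nigricans.  Absent
    extended fields simply cannot trigger their criteria.
    """
    reasons: list[str] = []
    if record.age >= 45:
        reasons.append("age>=45")
    if record.effective_bmi >= 25:
        reasons.append("bmi>=25")
    if FamilyHistory(record.family_history) is not FamilyHistory.NONE:
        reasons.append("family_history")
    wc_cut = 80.0 if Sex(record.sex) is Sex.WOMAN else 90.0
    if record.waist_cm >= wc_cut:
        reasons.append(f"waist>={wc_cut:g}")
    if record.antihypertensive_meds:
        reasons.append("antihypertensive_treatment")
    if not record.physical_activity:
        reasons.append("sedentary")

    ext = extended or {}
    tg = ext.get("triglycerides_mmol")
    if tg is not None and tg >= 1.7:
        reasons.append("triglycerides>=1.7")
    hdl = ext.get("hdl_mmol")
    if hdl is not None and hdl < 1.03:
        reasons.append("hdl<1.03")
    for flag, reason in (
        ("hypertension", "hypertension"),
        ("gestational_diabetes_history", "gestational_diabetes_history"),
        ("macrosomia_history", "macrosomia_history"),
        ("ascvd", "ascvd"),
        ("low_birth_weight", "low_birth_weight"),
        ("pcos", "pcos"),
        ("acanthosis_nigricans", "acanthosis_nigricans"),
    ):
        if ext.get(flag):
            reasons.append(reason)
    return bool(reasons), reasons


def cohort_flow(
    interviewed: int, no_risk_factor: int, known_diabetes: int, not_examined: int
) -> int:
    """Screening-funnel arithmetic: interviewed minus each exclusion stage.

    Returns the analysable count after removing adults without risk factors,
    those with already-known diabetes, and those not examined.
    """
    counts = (interviewed, no_risk_factor, known_diabetes, not_examined)
    if any(c < 0 for c in counts):
        raise ValueError(f"counts must be non-negative, got {counts}")
    remaining = interviewed
    for stage, removed in (
        ("no_risk_factor", no_risk_factor),
        ("known_diabetes", known_diabetes),
        ("not_examined", not_examined),
    ):
        remaining -= removed
        if remaining < 0:
            raise ValueError(
                f"exclusion stage {stage!r} removes more people than remain"
            )
    return remaining


def write_cohort(cohort: Cohort, csv_path, meta_path=None) -> None:
    """Write the cohort CSV plus a JSON metadata sidecar (seed, config, link)."""
    write_participants(cohort.frame, csv_path)
    if meta_path is None:
        meta_path = str(csv_path) + ".meta.json"
    meta = {
        "seed": cohort.config.seed,
        "n": len(cohort.frame),
        "config": cohort.config.to_json_dict(),
        "link_intercepts": list(cohort.link.intercepts),
        "link_slope": cohort.link.slope,
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
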