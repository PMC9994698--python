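"""Synthetic encounter-history generator.

The generator reproduces the statistical structure the likelihood assumes:
individuals enter at their cohort's release occasion, survive each interval as
a Bernoulli trial with a cohort-by-interval survival (baseline 0.89, with the
2019 cohort's first interval dropped to 0.43 to emulate the mass-mortality
year), are detected with certainty while radio-tracked, with probability
p_year in survey years (0.34 / 0.10 / 0.04 for 2018-2020) when untracked and
alive, and never otherwise.  Defaults mirror the published study conditions:
release schedule 21/36/49/49/48/57 over 2015-2020 and the 23-group telemetry
plan.

All randomness flows through one seeded generator, so output is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .encounters import (
    N_OCCASIONS,
    RELEASE_SCHEDULE,
    SURVEY_YEARS,
    TELEMETRY_PLAN,
    YEARS,
    CohortGroup,
    EncounterHistory,
    StudyDesign,
    ValidationError,
    build_design,
)

N_INTERVALS = N_OCCASIONS - 1


def _default_plan() -> dict[tuple[int, int], int]:
    return dict(TELEMETRY_PLAN)


def _default_schedule() -> dict[int, int]:
    return {y: n for y, n in RELEASE_SCHEDULE.items() if y in YEARS}


def _default_p() -> dict[int, float]:
    return {2018: 0.34, 2019: 0.10, 2020: 0.04}


def _default_first_year() -> dict[int, float]:
    return {2019: 0.43}


@dataclass(frozen=True)
class SimulationScenario:
    """True parameter values and the release/telemetry plan for one run."""

    release_schedule: dict[int, int] = field(default_factory=_default_schedule)
    telemetry_plan: dict[tuple[int, int], int] = field(default_factory=_default_plan)
    phi_baseline: float = 0.89
    #: survival in any cohort's first post-release interval, if acclimation
    #: is simulated for all cohorts (None = same as baseline)
    phi_acclimation: float | None = None
    #: per-year survival overrides, keyed by the interval's starting year
    phi_year: dict[int, float] = field(default_factory=dict)
    #: cohort-specific first-interval survival (the 2019 mortality shock)
    phi_first_year: dict[int, float] = field(default_factory=_default_first_year)
    #: (year, extra hazard): multiplies that year's survival by (1 - hazard)
    mass_mortality: tuple[int, float] | None = None
    p_survey: dict[int, float] = field(default_factory=_default_p)
    #: male:female odds of presumed sex at release
    sex_ratio: tuple[float, float] = (1.0, 1.5)
    seed: int = 0
    scale: int = 1
    #: logit-scale SD of shared survival shocks, one per (group, interval),
    #: applied to all individuals of the group at once.  Correlated fates
    #: that no model sharing survival across groups can absorb are what
    #: inflate multinomial dispersion (c-hat > 1); independent
    #: per-individual heterogeneity would not (sums of unequal Bernoullis
    #: are underdispersed).  Used to inject overdispersion for
    #: goodness-of-fit checks.
    survival_overdispersion_sd: float | None = None

    def validate(self) -> None:
        totals: dict[int, int] = {}
        for (cohort, d), n in self.telemetry_plan.items():
            if cohort not in YEARS:
                raise ValidationError(f"unknown cohort {cohort}")
            if n < 0:
                raise ValidationError("negative group size")
            totals[cohort] = totals.get(cohort, 0) + n
        for cohort, tot in totals.items():
            if tot != self.release_schedule.get(cohort, 0):
                raise ValidationError(
                    f"telemetry plan for {cohort} sums to {tot}, release "
                    f"schedule says {self.release_schedule.get(cohort, 0)}"
                )
        probs = [self.phi_baseline, *self.p_survey.values(),
                 *self.phi_year.values(), *self.phi_first_year.values()]
        if self.phi_acclimation is not None:
            probs.append(self.phi_acclimation)
        if any(not 0 <= v <= 1 for v in probs):
            raise ValidationError("probabilities must lie in [0, 1]")
        if self.scale < 1:
            raise ValidationError("scale must be >= 1")

    def true_phi(self, cohort: int, interval: int) -> float:
        """Resolved survival for a cohort over interval (t, t+1)."""
        r = YEARS.index(cohort)
        v = self.phi_baseline
        if self.phi_acclimation is not None and interval == r:
            v = self.phi_acclimation
        if YEARS[interval] in self.phi_year:
            v = self.phi_year[YEARS[interval]]
        if cohort in self.phi_first_year and interval == r:
            v = self.phi_first_year[cohort]
        if self.mass_mortality and YEARS[interval] == self.mass_mortality[0]:
            v *= 1.0 - self.mass_mortality[1]
        return v

    def true_p(self, year: int) -> float:
        return self.p_survey.get(year, 0.0)

    def truth_record(self) -> dict:
        """The generating values, for parameter-recovery tests."""
        return {
            "phi": {
                f"{cohort},{YEARS[t]}-{YEARS[t + 1]}": self.true_phi(cohort, t)
                for (cohort, _d) in sorted({(c, 0) for (c, _), _n in self.telemetry_plan.items()})
                for t in range(YEARS.index(cohort), N_INTERVALS)
            },
            "phi_baseline": self.phi_baseline,
            "phi_first_year": dict(self.phi_first_year),
            "p_survey": dict(self.p_survey),
            "seed": self.seed,
            "scale": self.scale,
        }


def _simulate_arrays(scenario: SimulationScenario, rng: np.random.Generator):
    """Core forward simulation; returns per-individual arrays."""
    scenario.validate()
    cohorts, telems, ids = [], [], []
    alive_rows, det_rows, capture_rows = [], [], []
    serial = 0
    survey_idx = {YEARS.index(y): y for y in SURVEY_YEARS}
    for (cohort, d), n0 in sorted(scenario.telemetry_plan.items()):
        year_shock = np.zeros(N_INTERVALS)
        if scenario.survival_overdispersion_sd is not None:
            year_shock = rng.normal(
                scale=scenario.survival_overdispersion_sd, size=N_INTERVALS
            )
        n = n0 * scenario.scale
        if n == 0:
            continue
        r = YEARS.index(cohort)
        phi_true = np.array(
            [scenario.true_phi(cohort, t) if t >= r else 0.0 for t in range(N_INTERVALS)]
        )
        alive = np.zeros((n, N_OCCASIONS), dtype=bool)
        alive[:, r] = True
        for t in range(r, N_INTERVALS):
            pv = phi_true[t]
            if scenario.survival_overdispersion_sd is not None:
                logit_pv = np.log(pv / (1.0 - pv)) + year_shock[t]
                pv = 1.0 / (1.0 + np.exp(-logit_pv))
            alive[:, t + 1] = alive[:, t] & (rng.random(n) < pv)
        det = np.zeros((n, N_OCCASIONS), dtype=np.int8)
        cap = np.zeros((n, N_OCCASIONS), dtype=np.int8)
        for t in range(r, N_OCCASIONS):
            tracked = t < r + d
            if t in survey_idx:
                p_t = scenario.true_p(survey_idx[t])
                cap[:, t] = alive[:, t] & (rng.random(n) < p_t)
            if tracked:
                det[:, t] = alive[:, t]
            elif t in survey_idx:
                det[:, t] = cap[:, t]
        cohorts.append(np.full(n, cohort))
        telems.append(np.full(n, d))
        ids.extend(f"s{cohort}d{d}_{serial + i:05d}" for i in range(n))
        serial += n
        alive_rows.append(alive)
        det_rows.append(det)
        capture_rows.append(cap)
    return (
        np.concatenate(cohorts),
        np.concatenate(telems),
        ids,
        np.concatenate(alive_rows),
        np.concatenate(det_rows),
        np.concatenate(capture_rows),
    )


def simulate_histories(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> tuple[list[EncounterHistory], dict]:
    """Simulate one dataset; returns (histories, truth record).

    Every released individual is emitted, including the never-detected ones
    (all-zero histories), so the fixed group superpopulations are exact.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    cohorts, telems, ids, _alive, det, _cap = _simulate_arrays(scenario, rng)
    histories = [
        EncounterHistory(
            individual_id=i,
            cohort=int(c),
            telemetry_occasions=int(d),
            detections=tuple(int(v) for v in row),
        )
        for i, c, d, row in zip(ids, cohorts, telems, det)
    ]
    return histories, scenario.truth_record()


def simulate_capture_records(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> tuple[list[EncounterHistory], pd.DataFrame, dict]:
    """Simulate histories plus per-survey-year capture events with presumed sex.

    Captures are physical trappings: Bernoulli(p_year) for any animal alive in
    a survey year.  For untracked animals a capture and a detection coincide;
    tracked animals are detected regardless but still may be trapped.  Sex is
    assigned at release at the scenario's male:female odds.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    cohorts, telems, ids, _alive, det, cap = _simulate_arrays(scenario, rng)
    a, b = scenario.sex_ratio
    male = rng.random(len(ids)) < a / (a + b)
    rows = []
    for i, ind in enumerate(ids):
        for t in range(N_OCCASIONS):
            if cap[i, t]:
                rows.append(
                    {
                        "individual_id": ind,
                        "year": YEARS[t],
                        "sex": "M" if male[i] else "F",
                    }
                )
    captures = pd.DataFrame(rows, columns=["individual_id", "year", "sex"])
    histories = [
        EncounterHistory(
            individual_id=i,
            cohort=int(c),
            telemetry_occasions=int(d),
            detections=tuple(int(v) for v in row),
        )
        for i, c, d, row in zip(ids, cohorts, telems, det)
    ]
    truth = scenario.truth_record()
    truth["sex_ratio"] = list(scenario.sex_ratio)
    return histories, captures, truth


def scaled_scenario(scenario: SimulationScenario, scale: int) -> SimulationScenario:
    return replace(scenario, scale=scale)


def scenario_design(scenario: SimulationScenario) -> StudyDesign:
    """The study design matching a scenario's telemetry plan and scale."""
    groups = [
        CohortGroup(cohort, d, n * scenario.scale)
        for (cohort, d), n in sorted(scenario.telemetry_plan.items())
        if n > 0
    ]
    return build_design(groups)
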