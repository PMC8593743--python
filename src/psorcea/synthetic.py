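"""Random but structurally valid scenarios for property testing.

There is no patient-level data in this model, so the synthetic generator's
job is to exercise the pipeline: it draws drug economics (costs, dose and
dispense calendars from a menu of realistic patterns), PASI75 efficacies
with coherent CIs, ordered utilities and positive cost blocks, and returns
a scenario that passes full validation.  Degenerate scenarios with
closed-form outcomes (flat utility, zero or perfect efficacy) support exact
engine checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dosing import DispensePlan, DosingSchedule
from .scenario import (BscCosts, DrugProfile, MonitoringCosts, ScenarioConfig,
                       Timeline, UtilitySet)

# (dosing schedule, dispense plan) menu covering the base case's patterns:
# front-loaded, weekly with monthly packs, q4w, q8w and q12w supply.
SCHEDULE_MENU: tuple[tuple[DosingSchedule, DispensePlan], ...] = (
    (DosingSchedule((0, 1), 2), DispensePlan((0, 4, 8), 4)),
    (DosingSchedule((0,), 1), DispensePlan((0, 4, 8), 4)),
    (DosingSchedule((0, 4), 8), DispensePlan((0, 4), 8)),
    (DosingSchedule((0, 2, 4, 6, 8, 10, 12), 4), DispensePlan((0, 2, 4, 6, 8, 10), 12)),
    (DosingSchedule((0, 4), 12), DispensePlan((0, 4), 12)),
    (DosingSchedule((0, 1, 2, 3, 4), 4), DispensePlan((0, 1, 2, 3, 4, 8), 4)),
)


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    n_drugs: int = 4
    cost_range: tuple[float, float] = (500.0, 6000.0)
    efficacy_range: tuple[float, float] = (0.2, 0.95)
    ci_half_width_range: tuple[float, float] = (0.01, 0.08)
    utility_gap_range: tuple[float, float] = (0.05, 0.4)

    def validate(self) -> None:
        if self.n_drugs < 1:
            raise ValueError("n_drugs must be >= 1")
        lo, hi = self.cost_range
        if not 0 < lo <= hi:
            raise ValueError("cost_range must be positive and ordered")
        lo, hi = self.efficacy_range
        if not 0 < lo <= hi < 1:
            raise ValueError("efficacy_range must lie in (0, 1)")
        lo, hi = self.ci_half_width_range
        if not 0 <= lo <= hi:
            raise ValueError("ci_half_width_range must be ordered")
        lo, hi = self.utility_gap_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("utility_gap_range must lie in (0, 1]")


def _draw_prob(rng: np.random.Generator, spec: SyntheticSpec):
    p = rng.uniform(*spec.efficacy_range)
    hw = rng.uniform(*spec.ci_half_width_range)
    lo = max(p - hw, p / 2, 1e-4)
    hi = min(p + hw, (1 + p) / 2, 1 - 1e-4)
    return float(p), (float(lo), float(hi))


def generate_scenario(spec: SyntheticSpec) -> ScenarioConfig:
    """A validated random scenario; identical seeds give identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    drugs = {}
    for i in range(spec.n_drugs):
        name = f"drug{i:02d}"
        sched, plan = SCHEDULE_MENU[int(rng.integers(len(SCHEDULE_MENU)))]
        p_ind, ci_ind = _draw_prob(rng, spec)
        p_mnt, ci_mnt = _draw_prob(rng, spec)
        drugs[name] = DrugProfile(
            name=name,
            cost_per_dispense=float(np.round(rng.uniform(*spec.cost_range), 2)),
            schedule=sched,
            dispense_plan=plan,
            p_induction=p_ind, p_induction_ci=ci_ind,
            p_maintenance=p_mnt, p_maintenance_ci=ci_mnt,
        )
    gap = rng.uniform(*spec.utility_gap_range)
    u_con = float(rng.uniform(gap + 0.01, 1.0))
    u_unc = float(u_con - gap)
    config = ScenarioConfig(
        drugs=drugs,
        monitoring=MonitoringCosts(*(float(np.round(rng.uniform(0, 1000), 2))
                                     for _ in range(4))),
        bsc=BscCosts(*(float(np.round(rng.uniform(50, 8000), 2))
                       for _ in range(4))),
        utilities=UtilitySet(u_unc, float(rng.uniform(0, 0.5)),
                             u_con, float(rng.uniform(0, 0.3))),
        timeline=Timeline(),
        sequencing_rule="base",
        notes=(f"synthetic scenario, seed {spec.seed}",),
    )
    return config.validate()


def degenerate_scenario(kind: str,
                        flat_utility: float = 0.5) -> ScenarioConfig:
    """Closed-form-checkable variants of the bundled base case.

    ``flat_utility``: both health states share one utility, so every arm
    accrues exactly horizon/weeks_per_year × u QALYs.  ``zero_efficacy``:
    nobody ever achieves PASI75, so a 3-line cohort is entirely in BSC from
    week 36.  ``perfect_efficacy``: everyone responds and retains response,
    so the whole cohort stays on its first line.
    """
    from .scenario import builtin_base_case

    base = builtin_base_case()
    if kind == "flat_utility":
        eps = 1e-9  # strict ordering is a scenario invariant
        utils = UtilitySet(flat_utility - eps, 0.0, flat_utility, 0.0)
        return replace(base, utilities=utils).validate()
    if kind in ("zero_efficacy", "perfect_efficacy"):
        p = 1e-12 if kind == "zero_efficacy" else 1 - 1e-12
        drugs = {
            n: replace(d, p_induction=p, p_induction_ci=(p, p),
                       p_maintenance=p, p_maintenance_ci=(p, p))
            for n, d in base.drugs.items()
        }
        return replace(base, drugs=drugs).validate()
    raise ValueError(f"unknown degenerate scenario kind {kind!r}")
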