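"""Cohort state-transition engine for sequenced biologic therapy.

The model follows a closed cohort of severe chronic plaque psoriasis
patients over a 96-week horizon in 12-week cycles.  Each treatment line
opens with a 12-week induction period ending in a PASI75 review; responders
enter 24-week maintenance periods, each ending in a further PASI75 review
with a line-constant retention probability.  Review failures move to the
next biologic line, and failures of the final line enter best supportive
care (BSC), an absorbing state with no chance of regaining PASI75.
Mortality is not modelled (psoriasis is assumed not to affect it) and the
short horizon uses no discounting by default.

Reward accrual follows a within-cycle (half-cycle) correction: state
membership for both utilities and per-cycle costs is averaged over each
cycle's start and end boundary, which is equivalent to assuming transitions
— in particular treatment failures — occur halfway through a cycle.
Transitions falling exactly on the horizon boundary are evaluated, so the
terminal half-cycle reflects the outcome of a review held at week 96.
Alternative membership conventions (`cycle_start_membership`,
`cycle_end_membership`) are provided for sensitivity to this choice; they
accrue plain per-cycle sums.

Two independent evaluation routes are provided: :func:`evaluate_arm`
propagates the cohort cycle by cycle (and yields a trace), while
:func:`enumerate_pathways` exhaustively enumerates every sequence of review
outcomes and accrues rewards per pathway.  Their agreement is a structural
check on both implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, NamedTuple

import numpy as np
import pandas as pd

from .scenario import BSC, ScenarioConfig, Strategy, Timeline

UTILITY_TIMINGS = ("cycle_end_membership", "half_cycle_on_failure",
                   "cycle_start_membership")
FAILURE_DOSINGS = ("full_period", "stop_mid_cycle")


@dataclass(frozen=True)
class RewardConvention:
    """How rewards are attached to cycles.

    utility_timing:
        ``half_cycle_on_failure`` (default, calibrated): trapezoid of the
        start/end state membership for utilities *and* costs — patients are
        assumed to change state halfway through a cycle.
        ``cycle_start_membership`` / ``cycle_end_membership``: each cycle
        earns the utility of the state occupied at its start (resp. end);
        costs accrue as plain per-cycle occupancy sums.
    failure_dosing:
        ``full_period`` (default): review failures receive every dispense
        scheduled up to the review.  ``stop_mid_cycle``: failures forgo
        dispenses scheduled in the final six weeks before the failed review.
    """

    utility_timing: str = "half_cycle_on_failure"
    failure_dosing: str = "full_period"

    def __post_init__(self) -> None:
        if self.utility_timing not in UTILITY_TIMINGS:
            raise ValueError(f"unknown utility_timing {self.utility_timing!r}")
        if self.failure_dosing not in FAILURE_DOSINGS:
            raise ValueError(f"unknown failure_dosing {self.failure_dosing!r}")


@dataclass
class CohortTrace:
    """Tidy per-cycle record of the cohort: state fractions plus the cost
    and QALYs accrued in each cycle."""

    states: pd.DataFrame          # columns: cycle, week_start, state, fraction
    cycle_cost: np.ndarray
    cycle_qaly: np.ndarray

    def to_csv(self, path) -> None:
        df = self.states.copy()
        df["cycle_cost"] = df["cycle"].map(
            dict(enumerate(self.cycle_cost)))
        df["cycle_qaly"] = df["cycle"].map(
            dict(enumerate(self.cycle_qaly)))
        df.to_csv(path, index=False)


@dataclass
class ArmResult:
    strategy: Strategy
    total_cost: float
    total_qaly: float
    trace: CohortTrace | None = None


class Pathway(NamedTuple):
    probability: float
    cost: float
    qaly: float


def review_schedule(line_start_week: int, timeline: Timeline,
                    include_terminal: bool = False) -> list[int]:
    """PASI75 review weeks for a line starting at ``line_start_week``.

    The induction review falls one cycle after the line starts; maintenance
    reviews follow every 24 weeks.  By default only reviews strictly inside
    the horizon are returned; the engine itself also evaluates a review
    falling exactly on the horizon boundary (``include_terminal=True``),
    which affects the terminal half-cycle membership.
    """
    cyc = timeline.cycle_weeks
    lim = timeline.horizon_weeks + (1 if include_terminal else 0)
    out = []
    r = line_start_week + cyc
    if r < lim:
        out.append(r)
        r += timeline.maintenance_review_interval_weeks
        while r < lim:
            out.append(r)
            r += timeline.maintenance_review_interval_weeks
    return out


# ---------------------------------------------------------------------------
# parameter bundle (scalar for the base case; numpy arrays for PSA draws)

def _params_from_config(config: ScenarioConfig,
                        overrides: dict[str, Any] | None = None) -> dict:
    """Flatten scenario values into the engine's parameter dict.

    Override keys: ``("p_induction", drug)``, ``("p_maintenance", drug)``,
    ``"u_controlled"``, ``"u_uncontrolled"``, ``"cyclosporine_induction"``,
    ``"cyclosporine_maintenance"``, ``"foam_induction"``,
    ``"foam_maintenance"``.  Values may be scalars or numpy arrays (all of
    one broadcastable shape) — the engine then evaluates all draws at once.
    """
    ov = overrides or {}
    p = {
        "pi": {d: ov.get(("p_induction", d), prof.p_induction)
               for d, prof in config.drugs.items()},
        "pm": {d: ov.get(("p_maintenance", d), prof.p_maintenance)
               for d, prof in config.drugs.items()},
        "u_con": ov.get("u_controlled", config.utilities.u_controlled),
        "u_unc": ov.get("u_uncontrolled", config.utilities.u_uncontrolled),
    }
    bsc = config.bsc
    cyc_i = ov.get("cyclosporine_induction", bsc.cyclosporine_induction)
    cyc_m = ov.get("cyclosporine_maintenance", bsc.cyclosporine_maintenance)
    foam_i = ov.get("foam_induction", bsc.foam_induction)
    foam_m = ov.get("foam_maintenance", bsc.foam_maintenance)
    p["bsc_entry_cycle"] = cyc_i + foam_i
    # BSC maintenance figures are quoted per 24-week period
    p["bsc_cycle"] = (cyc_m + foam_m) / 2.0
    return p


# ---------------------------------------------------------------------------
# cohort propagation

def _line_cycle_drug_cost(config: ScenarioConfig, drug: str,
                          weeks_on_line: int) -> float:
    prof = config.drugs[drug]
    cyc = config.timeline.cycle_weeks
    n = prof.dispense_plan.dispenses_in_interval(weeks_on_line,
                                                 weeks_on_line + cyc)
    return prof.cost_per_dispense * n


def _propagate(lines: tuple[str, ...], config: ScenarioConfig,
               convention: RewardConvention,
               overrides: dict[str, Any] | None = None,
               want_trace: bool = False):
    """Run the cohort model; returns (cost, qaly, trace-or-None).

    With array-valued overrides, cost and qaly are arrays over draws.
    """
    tl = config.timeline
    cyc = tl.cycle_weeks
    ncyc = tl.n_cycles
    horizon = tl.horizon_weeks
    mon = config.monitoring
    mon_maint_cycle = mon.maintenance_total * cyc / tl.maintenance_review_interval_weeks
    params = _params_from_config(config, overrides)
    pi, pm = params["pi"], params["pm"]
    halfcycle = convention.utility_timing == "half_cycle_on_failure"

    # state keys: ('ind', line_idx, start_week) | ('m', line_idx, start_week,
    # cycle_in_period) | ('bsc', entry_week)
    occ: dict[tuple, Any] = {("ind", 0, 0): 1.0}
    unc_bound = [1.0]                    # uncontrolled fraction at boundaries
    cost_rates = []                      # per-cycle cost rate C_k
    trace_rows: list[dict] = [] if want_trace else None

    def state_cost(st, t):
        kind = st[0]
        if kind == "bsc":
            c = params["bsc_entry_cycle"] if t == st[1] else params["bsc_cycle"]
            return c + mon_maint_cycle
        li, s = st[1], st[2]
        c = _line_cycle_drug_cost(config, lines[li], t - s)
        if kind == "ind":
            # pre-biologic workup (visits + investigations) once, at the
            # start of the first line
            if t == s and li == 0:
                c += mon.induction_total
        else:
            c += mon_maint_cycle
        return c

    def disc(t):
        r = tl.annual_discount_rate
        if r == 0:
            return 1.0
        return (1.0 + r) ** (-(t / tl.weeks_per_year))

    for k in range(ncyc + 1):
        t = k * cyc
        rate = 0.0
        for st, f in occ.items():
            rate = rate + f * state_cost(st, t)
            if want_trace and k < ncyc:
                trace_rows.append({"cycle": k, "week_start": t,
                                   "state": _state_label(st, lines),
                                   "fraction": f})
        cost_rates.append(rate)
        if k == ncyc:
            break
        tb = t + cyc
        new: dict[tuple, Any] = {}
        fail_adjust = 0.0     # dispenses forgone by failures (stop_mid_cycle)

        def add(st, f):
            new[st] = (new[st] + f) if st in new else f

        for st, f in occ.items():
            kind = st[0]
            if kind == "bsc":
                add(st, f)
                continue
            li, s = st[1], st[2]
            d = lines[li]
            prof = config.drugs[d]
            if kind == "ind":
                if tb == s + cyc:        # induction review (week 96 included)
                    p = pi[d]
                    add(("m", li, s, 0), f * p)
                    fail = f * (1 - p)
                    nxt = (("ind", li + 1, tb) if li + 1 < len(lines)
                           else ("bsc", tb))
                    add(nxt, fail)
                    if convention.failure_dosing == "stop_mid_cycle":
                        n = prof.dispense_plan.dispenses_in_interval(
                            tb - s - cyc // 2, tb - s)
                        fail_adjust = fail_adjust + fail * prof.cost_per_dispense * n
                else:
                    add(st, f)
            else:
                kk = st[3]
                per_cycles = tl.maintenance_review_interval_weeks // cyc
                if kk < per_cycles - 1:
                    add(("m", li, s, kk + 1), f)
                else:                     # maintenance review
                    p = pm[d]
                    add(("m", li, s, 0), f * p)
                    fail = f * (1 - p)
                    nxt = (("ind", li + 1, tb) if li + 1 < len(lines)
                           else ("bsc", tb))
                    add(nxt, fail)
                    if convention.failure_dosing == "stop_mid_cycle":
                        n = prof.dispense_plan.dispenses_in_interval(
                            tb - s - cyc // 2, tb - s)
                        fail_adjust = fail_adjust + fail * prof.cost_per_dispense * n
        if convention.failure_dosing == "stop_mid_cycle":
            cost_rates[k] = cost_rates[k] - fail_adjust
        occ = new
        unc = 0.0
        for st, f in occ.items():
            if st[0] in ("ind", "bsc"):
                unc = unc + f
        unc_bound.append(unc)

    # --- utilities -------------------------------------------------------
    u_con, u_unc = params["u_con"], params["u_unc"]
    cycle_qaly = []
    for k in range(ncyc):
        if convention.utility_timing == "cycle_start_membership":
            frac_unc = unc_bound[k]
        elif convention.utility_timing == "cycle_end_membership":
            frac_unc = unc_bound[k + 1]
        else:
            frac_unc = (unc_bound[k] + unc_bound[k + 1]) / 2.0
        u = u_con - frac_unc * (u_con - u_unc)
        cycle_qaly.append(u * cyc / tl.weeks_per_year * disc(k * cyc))
    qaly = sum(cycle_qaly)

    # --- costs -----------------------------------------------------------
    if halfcycle:
        cycle_cost = [(cost_rates[k] + cost_rates[k + 1]) / 2.0 * disc(k * cyc)
                      for k in range(ncyc)]
    else:
        cycle_cost = [cost_rates[k] * disc(k * cyc) for k in range(ncyc)]
    cost = sum(cycle_cost)

    trace = None
    if want_trace:
        trace = CohortTrace(
            states=pd.DataFrame(trace_rows),
            cycle_cost=np.asarray(cycle_cost, dtype=float),
            cycle_qaly=np.asarray(cycle_qaly, dtype=float),
        )
    return cost, qaly, trace


def _state_label(st, lines) -> str:
    if st[0] == "bsc":
        return f"{BSC}(entry={st[1]})"
    phase = "induction" if st[0] == "ind" else f"maintenance.c{st[3]}"
    return f"{lines[st[1]]}:{phase}(start={st[2]})"


def evaluate_arm(strategy: Strategy, config: ScenarioConfig,
                 convention: RewardConvention | None = None,
                 want_trace: bool = True) -> ArmResult:
    """Total discounted cost (AUD) and QALYs for one treatment pathway."""
    convention = convention or RewardConvention()
    for d in strategy.lines:
        if d not in config.drugs:
            raise KeyError(f"strategy {strategy.name}: unknown drug {d!r}")
    cost, qaly, trace = _propagate(strategy.lines, config, convention,
                                   want_trace=want_trace)
    return ArmResult(strategy=strategy, total_cost=float(cost),
                     total_qaly=float(qaly), trace=trace)


def evaluate_arms_vectorized(strategy: Strategy, config: ScenarioConfig,
                             convention: RewardConvention,
                             overrides: dict[str, Any]):
    """Evaluate one strategy under many parameter draws simultaneously.

    Override values are numpy arrays (one entry per draw); returns
    ``(costs, qalys)`` arrays of the broadcast shape.
    """
    cost, qaly, _ = _propagate(strategy.lines, config, convention,
                               overrides=overrides, want_trace=False)
    return np.asarray(cost, dtype=float), np.asarray(qaly, dtype=float)


# ---------------------------------------------------------------------------
# exhaustive pathway enumeration (verification oracle)

def enumerate_pathways(strategy: Strategy, config: ScenarioConfig,
                       convention: RewardConvention | None = None
                       ) -> list[Pathway]:
    """Every root-to-leaf sequence of review outcomes with its probability,
    cost and QALYs, accrued per pathway with the same conventions as
    :func:`evaluate_arm` (undiscounted timelines only).

    The probability-weighted sums equal the cohort totals; this route shares
    no propagation code with the cohort engine.
    """
    convention = convention or RewardConvention()
    tl = config.timeline
    if tl.annual_discount_rate != 0:
        raise NotImplementedError("pathway oracle assumes no discounting")
    cyc = tl.cycle_weeks
    horizon = tl.horizon_weeks
    lines = strategy.lines
    mon = config.monitoring
    mon_maint_cycle = mon.maintenance_total * cyc / tl.maintenance_review_interval_weeks
    params = _params_from_config(config)
    halfcycle = convention.utility_timing == "half_cycle_on_failure"
    half = cyc // 2

    def disp_cost(d: str, a: int, b: int) -> float:
        prof = config.drugs[d]
        return prof.cost_per_dispense * prof.dispense_plan.dispenses_in_interval(a, b)

    out: list[Pathway] = []

    # episode: (drug, s, e, responded, failed)
    def finish(prob, episodes, bsc_entry, terminal):
        # terminal: ('m', drug, s) | ('ind', drug, s) | ('bsc', entry)
        # --- controlled time -------------------------------------------
        controlled = 0.0
        for d, s, e, responded, failed in episodes:
            if not responded:
                continue
            if convention.utility_timing == "half_cycle_on_failure":
                lo, hi = s + half, (e - half if failed else e)
            elif convention.utility_timing == "cycle_end_membership":
                lo, hi = s, (e - cyc if failed else e)
            else:                         # cycle_start_membership
                lo, hi = s + cyc, e
            controlled += max(0, hi - lo)
        u = (params["u_con"] * controlled
             + params["u_unc"] * (horizon - controlled))
        qaly = u / tl.weeks_per_year

        # --- plain occupancy cost --------------------------------------
        cost = mon.induction_total        # first-line workup
        for d, s, e, responded, failed in episodes:
            end = e - s
            if failed and convention.failure_dosing == "stop_mid_cycle":
                cost += disp_cost(d, 0, end) - disp_cost(d, end - half, end)
            else:
                cost += disp_cost(d, 0, end)
            if responded:
                cost += mon_maint_cycle * (e - (s + cyc)) / cyc
        if bsc_entry is not None and bsc_entry < horizon:
            n_bsc = (horizon - bsc_entry) // cyc
            cost += params["bsc_entry_cycle"] + params["bsc_cycle"] * (n_bsc - 1)
            cost += mon_maint_cycle * n_bsc

        if halfcycle:
            c0 = disp_cost(lines[0], 0, cyc) + mon.induction_total
            if (convention.failure_dosing == "stop_mid_cycle" and episodes
                    and episodes[0][4] and episodes[0][2] == cyc):
                # this pathway fails the very first review: the forgone
                # dispenses were netted out of the first cycle's rate, which
                # the trapezoid half-weights
                c0 -= disp_cost(lines[0], cyc - half, cyc)
            kind = terminal[0]
            if kind == "bsc":
                entry = terminal[1]
                c8 = (params["bsc_entry_cycle"] if entry == horizon
                      else params["bsc_cycle"]) + mon_maint_cycle
            elif kind == "m":
                _, d, s = terminal
                c8 = disp_cost(d, horizon - s, horizon - s + cyc) + mon_maint_cycle
            else:                         # induction entered at the horizon
                _, d, s = terminal
                c8 = disp_cost(d, 0, cyc)
            cost = cost - c0 / 2.0 + c8 / 2.0
        out.append(Pathway(float(prob), float(cost), float(qaly)))

    def rec(line_idx, start, prob, episodes):
        if start >= horizon:
            # previous failure happened exactly at the horizon review
            if line_idx < len(lines):
                terminal = ("ind", lines[line_idx], start)
            else:
                terminal = ("bsc", start)
            finish(prob, episodes, None if line_idx < len(lines) else start,
                   terminal)
            return
        if line_idx >= len(lines):
            finish(prob, episodes, start, ("bsc", start))
            return
        d = lines[line_idx]
        pi, pm = params["pi"][d], params["pm"][d]
        reviews = review_schedule(start, tl, include_terminal=True)
        # induction review (always exists for start <= horizon - cycle)
        r0 = reviews[0]
        rec(line_idx + 1, r0, prob * (1 - pi),
            episodes + [(d, start, r0, False, True)])
        # responder: fail at one of the maintenance reviews...
        p_sofar = prob * pi
        for j, r in enumerate(reviews[1:]):
            p_stay_before = 1.0
            for _ in range(j):
                p_stay_before *= pm
            rec(line_idx + 1, r, p_sofar * p_stay_before * (1 - pm),
                episodes + [(d, start, r, True, True)])
        # ... or retain response through every review on the horizon
        p_stay_all = 1.0
        for _ in range(len(reviews) - 1):
            p_stay_all *= pm
        finish(p_sofar * p_stay_all,
               episodes + [(d, start, horizon, True, False)],
               None, ("m", d, start))

    rec(0, 0, 1.0, [])
    return out
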