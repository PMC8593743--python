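"""One-way (tornado) and probabilistic sensitivity analysis.

One-way analysis moves each uncertain input to its bounds — 95% CI bounds
for the PASI75 efficacies, ±20% for utilities (clamped to [0, 1]) and for
the best-supportive-care cost components — re-evaluates every arm, and
records each strategy's ICUR against the reference arm at both ends.

The probabilistic analysis samples all inputs jointly and independently:
Beta distributions for efficacies (method-of-moments from the CI width) and
utilities (from mean/SD), Gamma distributions for BSC cost components
(shape = 1/cv², scale = mean·cv²; cv defaults to 0.2 as no spread is
published).  Per iteration all arms are evaluated; probabilistic ICURs are
ratios of iteration-averaged increments, and the cost-effectiveness
acceptability curve (CEAC) reports, per willingness-to-pay value, the
fraction of iterations in which each arm has the greatest net monetary
benefit NMB = WTP × QALY − cost.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import RewardConvention, evaluate_arm, evaluate_arms_vectorized
from .scenario import ScenarioConfig, Strategy, build_strategies

Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# distribution fitting

@dataclass(frozen=True)
class DistributionSpec:
    family: str                      # "beta" | "gamma" | "point_mass"
    params: dict
    note: str = ""

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "beta":
            return rng.beta(self.params["alpha"], self.params["beta"],
                            size=size)
        if self.family == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"],
                             size=size)
        return np.full(size, self.params["value"])

    @property
    def mean(self) -> float:
        if self.family == "beta":
            a, b = self.params["alpha"], self.params["beta"]
            return a / (a + b)
        if self.family == "gamma":
            return self.params["shape"] * self.params["scale"]
        return self.params["value"]


def _beta_mom(mean: float, var: float, note: str) -> DistributionSpec:
    common = mean * (1 - mean) / var - 1.0
    return DistributionSpec("beta", {"alpha": mean * common,
                                     "beta": (1 - mean) * common}, note)


def beta_from_mean_ci(mean: float, ci_low: float,
                      ci_high: float) -> DistributionSpec:
    """Method-of-moments Beta from a point estimate and its 95% CI.

    The standard error is taken as CI width / (2·1.96).  If the implied
    variance is infeasible for a Beta (se² >= mean(1-mean)) a point mass is
    returned with a warning.
    """
    if not 0 < mean < 1:
        raise ValueError("mean must be in (0, 1)")
    if ci_low > ci_high:
        raise ValueError("ci_low must be <= ci_high")
    se = (ci_high - ci_low) / (2 * Z95)
    if se == 0:
        return DistributionSpec("point_mass", {"value": mean},
                                "degenerate CI")
    if se * se >= mean * (1 - mean):
        warnings.warn("CI too wide for a Beta fit; using point mass")
        return DistributionSpec("point_mass", {"value": mean},
                                "infeasible Beta; point mass fallback")
    return _beta_mom(mean, se * se, f"MoM from CI ({ci_low}, {ci_high})")


def beta_from_mean_sd(mean: float, sd: float) -> DistributionSpec:
    """Method-of-moments Beta from a mean and standard deviation.

    An SD at or above sqrt(mean(1-mean)) cannot arise from a Beta with that
    mean; it is clamped to 0.99 of the bound and the clamping recorded.
    """
    if not 0 < mean < 1:
        raise ValueError("mean must be in (0, 1)")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return DistributionSpec("point_mass", {"value": mean}, "sd = 0")
    bound = math.sqrt(mean * (1 - mean))
    note = f"MoM from mean {mean}, sd {sd}"
    if sd >= bound:
        sd = 0.99 * bound
        note += f"; sd clamped to {sd:.4f} (Beta feasibility)"
        warnings.warn("sd infeasible for a Beta fit; clamped")
    return _beta_mom(mean, sd * sd, note)


def gamma_from_mean_cv(mean: float, cv: float) -> DistributionSpec:
    """Gamma with the given mean and coefficient of variation."""
    if mean <= 0 or cv <= 0:
        raise ValueError("mean and cv must be > 0")
    return DistributionSpec("gamma", {"shape": 1.0 / cv ** 2,
                                      "scale": mean * cv ** 2},
                            f"mean {mean}, cv {cv}")


# ---------------------------------------------------------------------------
# one-way sensitivity analysis

@dataclass(frozen=True)
class OwsaSpec:
    parameter: str
    low: float
    base: float
    high: float
    override_key: object

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.parameter}: require low <= base <= high")


def default_owsa_specs(config: ScenarioConfig,
                       cost_fraction: float = 0.2,
                       clamp_utilities: bool = False) -> list[OwsaSpec]:
    """The published perturbation set: efficacies over their 95% CIs,
    utilities and BSC cost components ±20%.

    By default the +20% controlled-utility bound is *not* truncated at 1.0
    (0.89 × 1.2 = 1.068): the perturbation is a symmetric sensitivity lever
    rather than a realisable health state, and truncating it would shrink
    the reported ICUR range asymmetrically.  Pass ``clamp_utilities=True``
    to restrict utilities to [0, 1].
    """
    specs: list[OwsaSpec] = []
    for name, d in config.drugs.items():
        specs.append(OwsaSpec(f"{name}.p_induction", d.p_induction_ci[0],
                              d.p_induction, d.p_induction_ci[1],
                              ("p_induction", name)))
        specs.append(OwsaSpec(f"{name}.p_maintenance", d.p_maintenance_ci[0],
                              d.p_maintenance, d.p_maintenance_ci[1],
                              ("p_maintenance", name)))
    u = config.utilities
    for label, base, key in (
            ("utility_controlled", u.u_controlled, "u_controlled"),
            ("utility_uncontrolled", u.u_uncontrolled, "u_uncontrolled")):
        lo, hi = base * (1 - cost_fraction), base * (1 + cost_fraction)
        if clamp_utilities:
            lo, hi = max(0.0, lo), min(1.0, hi)
        specs.append(OwsaSpec(label, lo, base, hi, key))
    b = config.bsc
    for attr in ("cyclosporine_induction", "cyclosporine_maintenance",
                 "foam_induction", "foam_maintenance"):
        base = getattr(b, attr)
        specs.append(OwsaSpec(f"bsc.{attr}", base * (1 - cost_fraction),
                              base, base * (1 + cost_fraction), attr))
    return specs


def run_owsa(config: ScenarioConfig,
             convention: RewardConvention | None = None,
             reference: str = "tildrakizumab",
             specs: list[OwsaSpec] | None = None) -> pd.DataFrame:
    """Tornado table: per parameter bound, every strategy's ICUR vs the
    reference strategy (the reference arm is re-evaluated too, since shared
    parameters move both arms)."""
    convention = convention or RewardConvention()
    specs = specs if specs is not None else default_owsa_specs(config)
    strategies = build_strategies(config)
    rows = []
    for spec in specs:
        for bound, value in (("low", spec.low), ("high", spec.high)):
            overrides = {spec.override_key: value}
            res = {
                s.name: evaluate_arms_vectorized(s, config, convention,
                                                 overrides)
                for s in strategies
            }
            c_ref, q_ref = res[reference]
            for s in strategies:
                if s.name == reference:
                    continue
                c, q = res[s.name]
                dq = float(q - q_ref)
                rows.append({
                    "parameter": spec.parameter, "bound": bound,
                    "value": value, "strategy": s.name,
                    "cost": float(c), "qaly": float(q),
                    "reference_cost": float(c_ref),
                    "reference_qaly": float(q_ref),
                    "icur_vs_reference":
                        math.nan if dq == 0 else float(c - c_ref) / dq,
                })
    return pd.DataFrame(rows)


def owsa_ranges(tornado: pd.DataFrame) -> pd.DataFrame:
    """Per-strategy min/max ICUR vs reference across all parameter bounds."""
    g = tornado.groupby("strategy")["icur_vs_reference"]
    out = pd.DataFrame({"icur_min": g.min(), "icur_max": g.max()})
    idx_min = tornado.loc[tornado.groupby("strategy")["icur_vs_reference"]
                          .idxmin(), ["strategy", "parameter"]]
    idx_max = tornado.loc[tornado.groupby("strategy")["icur_vs_reference"]
                          .idxmax(), ["strategy", "parameter"]]
    out["driver_min"] = idx_min.set_index("strategy")["parameter"]
    out["driver_max"] = idx_max.set_index("strategy")["parameter"]
    return out.reset_index()


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

@dataclass
class PsaResult:
    n_iterations: int
    seed: int
    summary: pd.DataFrame          # strategy, mean_cost, mean_qaly, icur
    ceac: pd.DataFrame             # wtp + one winning-fraction column per arm
    reference: str
    costs: pd.DataFrame = field(repr=False, default=None)
    qalys: pd.DataFrame = field(repr=False, default=None)


def psa_distributions(config: ScenarioConfig,
                      bsc_cost_cv: float = 0.2,
                      utility_se_n: int | None = 200) -> dict:
    """The sampled-input set: per-drug Beta efficacies, Beta utilities,
    Gamma BSC cost components.

    The utility inputs are *mean* health-state utilities from a time
    trade-off valuation study, whose quoted SDs describe respondent
    heterogeneity (and are Beta-infeasible for the uncontrolled state).
    What a cohort model should propagate is the sampling uncertainty of the
    mean, so by default the SDs are scaled to standard errors assuming
    ``utility_se_n`` respondents (~200 in the source study).  Pass
    ``utility_se_n=None`` to sample the raw SDs (clamped to Beta
    feasibility).
    """
    dists: dict = {}
    for name, d in config.drugs.items():
        dists[("p_induction", name)] = beta_from_mean_ci(
            d.p_induction, *d.p_induction_ci)
        dists[("p_maintenance", name)] = beta_from_mean_ci(
            d.p_maintenance, *d.p_maintenance_ci)
    u = config.utilities
    scale = 1.0 if utility_se_n is None else 1.0 / math.sqrt(utility_se_n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dists["u_controlled"] = beta_from_mean_sd(
            u.u_controlled, u.u_controlled_sd * scale)
        dists["u_uncontrolled"] = beta_from_mean_sd(
            u.u_uncontrolled, u.u_uncontrolled_sd * scale)
    for attr in ("cyclosporine_induction", "cyclosporine_maintenance",
                 "foam_induction", "foam_maintenance"):
        dists[attr] = gamma_from_mean_cv(getattr(config.bsc, attr),
                                         bsc_cost_cv)
    return dists


def run_psa(config: ScenarioConfig,
            convention: RewardConvention | None = None,
            n_iterations: int = 10_000,
            seed: int = 0,
            reference: str = "tildrakizumab",
            wtp_max: float = 100_000.0,
            wtp_step: float = 1_000.0,
            bsc_cost_cv: float = 0.2,
            utility_se_n: int | None = 200,
            distributions: dict | None = None) -> PsaResult:
    """Monte-Carlo PSA over all strategies of the scenario."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    convention = convention or RewardConvention()
    rng = np.random.default_rng(seed)
    dists = distributions or psa_distributions(config, bsc_cost_cv,
                                               utility_se_n)
    overrides = {key: d.sample(rng, n_iterations) for key, d in dists.items()}

    strategies = build_strategies(config)
    costs = {}
    qalys = {}
    for s in strategies:
        c, q = evaluate_arms_vectorized(s, config, convention, overrides)
        costs[s.name] = np.broadcast_to(c, (n_iterations,)).astype(float)
        qalys[s.name] = np.broadcast_to(q, (n_iterations,)).astype(float)

    names = [s.name for s in strategies]
    mean_cost = {n: float(costs[n].mean()) for n in names}
    mean_qaly = {n: float(qalys[n].mean()) for n in names}
    rows = []
    for n in names:
        dq = mean_qaly[n] - mean_qaly[reference]
        rows.append({
            "strategy": n,
            "mean_cost": mean_cost[n],
            "mean_qaly": mean_qaly[n],
            "icur_vs_reference": (math.nan if n == reference or dq == 0
                                  else (mean_cost[n] - mean_cost[reference]) / dq),
        })
    summary = pd.DataFrame(rows)

    wtps = np.arange(0.0, wtp_max + wtp_step / 2, wtp_step)
    cost_mat = np.vstack([costs[n] for n in names])     # arms x iters
    qaly_mat = np.vstack([qalys[n] for n in names])
    ceac_rows = np.empty((len(wtps), len(names)))
    for i, w in enumerate(wtps):
        nmb = w * qaly_mat - cost_mat
        winners = np.argmax(nmb, axis=0)
        ceac_rows[i] = np.bincount(winners, minlength=len(names)) / n_iterations
    ceac = pd.DataFrame(ceac_rows, columns=names)
    ceac.insert(0, "wtp", wtps)

    return PsaResult(
        n_iterations=n_iterations, seed=seed, summary=summary, ceac=ceac,
        reference=reference,
        costs=pd.DataFrame(costs), qalys=pd.DataFrame(qalys),
    )
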