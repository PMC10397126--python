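"""Model inputs: hazard ratios, utilities, costs, run settings, and the
sampling distributions used for probabilistic analyses.

The model compares statin monotherapy against statin plus one add-on
lipid-lowering drug (icosapent ethyl, evolocumab, alirocumab, ezetimibe, or
fibrate) for primary or secondary cardiovascular prevention.  All inputs for
one drug-vs-statin comparison are collected in a :class:`ParameterSet`,
loaded from a human-editable YAML file and validated on load.

Uncertainty on each input is expressed as a :class:`DistributionSpec` built
from the point estimate and its 95% confidence interval (or a ±25% variation
band for costs), following the distribution family declared for each block
of inputs: normal for hazard ratios, beta for utilities and baseline event
probabilities, gamma for disutility decrements and costs, degenerate
("fixed") for prices, the discount rate, and risk-escalation factors.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

# ---------------------------------------------------------------------------
# Event and state vocabulary

EVENTS: tuple[str, ...] = (
    "nonfatal_mi",
    "nonfatal_stroke",
    "unstable_angina_hosp",
    "coronary_revasc",
    "cvd_death",
    "noncvd_death",
)
#: acute events that carry a one-off cost and a one-cycle utility decrement
NONFATAL_EVENTS: tuple[str, ...] = (
    "nonfatal_mi",
    "nonfatal_stroke",
    "unstable_angina_hosp",
    "coronary_revasc",
)
#: events escalated with the cardiovascular risk-growth factor
CVD_EVENTS: tuple[str, ...] = (
    "nonfatal_mi",
    "nonfatal_stroke",
    "unstable_angina_hosp",
    "coronary_revasc",
    "cvd_death",
)
FATAL_EVENTS: tuple[str, ...] = ("cvd_death", "noncvd_death")
#: events that move a patient from "alive without CVD" to "alive with CVD"
STATE_CHANGING_EVENTS: tuple[str, ...] = ("nonfatal_mi", "nonfatal_stroke")

STATES: tuple[str, ...] = ("alive_without_cvd", "alive_with_cvd", "dead")
ALIVE_STATES: tuple[str, ...] = ("alive_without_cvd", "alive_with_cvd")

SETTINGS: tuple[str, ...] = ("primary", "secondary")

ARM_STATIN = "statin"
ARM_COMBINATION = "combination"
ARMS: tuple[str, ...] = (ARM_STATIN, ARM_COMBINATION)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class ParameterError(ValueError):
    """Invalid or inconsistent model inputs.

    Carries the full list of offending fields so a malformed configuration
    file is reported in one pass.
    """

    def __init__(self, errors: Iterable[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class UnsupportedSettingError(ParameterError):
    """Requested a drug/prevention-setting pair with no trial evidence."""


# ---------------------------------------------------------------------------
# Point estimates with uncertainty bounds


@dataclass(frozen=True)
class Estimate:
    """A point value with its lower/upper variation bounds.

    For hazard ratios and utilities the bounds are the published 95%
    confidence interval; for costs and risk-escalation factors they are the
    ±25% band used in deterministic sensitivity analyses.
    """

    value: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.value <= self.high):
            raise ParameterError(
                [f"estimate bounds must satisfy low <= value <= high, "
                 f"got ({self.low}, {self.value}, {self.high})"]
            )

    @classmethod
    def with_pct_bounds(cls, value: float, pct: float = 0.25) -> "Estimate":
        lo, hi = sorted((value * (1 - pct), value * (1 + pct)))
        return cls(value, lo, hi)

    def to_list(self) -> list[float]:
        return [self.value, self.low, self.high]


# ---------------------------------------------------------------------------
# Sampling distributions

DISTRIBUTION_FAMILIES = ("normal", "lognormal", "beta", "gamma", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """A parametric sampling distribution derived from mean and 95% CI.

    ``params`` holds the family-specific parameters; ``truncate_low`` /
    ``truncate_high`` clip the support (by rejection sampling, so the
    distribution is genuinely truncated rather than censored at the bound).
    """

    family: str
    mean: float
    params: Mapping[str, float]
    truncate_low: float | None = None
    truncate_high: float | None = None

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        n = 1 if size is None else int(size)
        draws = self._draw(rng, n)
        lo = -math.inf if self.truncate_low is None else self.truncate_low
        hi = math.inf if self.truncate_high is None else self.truncate_high
        if self.truncate_low is not None or self.truncate_high is not None:
            for _ in range(1000):
                bad = (draws < lo) | (draws > hi)
                if not bad.any():
                    break
                draws[bad] = self._draw(rng, int(bad.sum()))
            else:  # pragma: no cover - pathological truncation only
                draws = np.clip(draws, lo, hi)
        return float(draws[0]) if size is None else draws

    def _draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.family == "fixed":
            return np.full(n, self.mean)
        if self.family == "normal":
            return rng.normal(p["loc"], p["scale"], size=n)
        if self.family == "lognormal":
            return np.exp(rng.normal(p["mu"], p["sigma"], size=n))
        if self.family == "beta":
            return rng.beta(p["alpha"], p["beta"], size=n)
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], size=n)
        raise ParameterError([f"unknown distribution family {self.family!r}"])


def ci_to_distribution(
    mean: float,
    low: float,
    high: float,
    family: str,
    truncate_low: float | None = None,
    truncate_high: float | None = None,
) -> DistributionSpec:
    """Build a :class:`DistributionSpec` from a mean and 95% interval.

    The interval half-width divided by 1.96 is used as the standard error;
    beta and gamma shapes follow from the method of moments.  A zero-width
    interval (or ``family="fixed"``) yields a degenerate distribution.
    """
    if not (low <= mean <= high):
        raise ParameterError([f"CI must bracket the mean: ({low}, {mean}, {high})"])
    if family not in DISTRIBUTION_FAMILIES:
        raise ParameterError([f"unknown distribution family {family!r}"])
    if family == "fixed" or high == low:
        return DistributionSpec("fixed", mean, {})
    sd = (high - low) / (2.0 * Z_95)
    if family == "normal":
        return DistributionSpec("normal", mean, {"loc": mean, "scale": sd},
                                truncate_low, truncate_high)
    if family == "lognormal":
        if min(mean, low, high) <= 0:
            raise ParameterError(["lognormal requires strictly positive mean and CI"])
        sigma = (math.log(high) - math.log(low)) / (2.0 * Z_95)
        # locate so the median equals the point estimate (field convention
        # for a hazard ratio whose CI is symmetric on the log scale)
        return DistributionSpec("lognormal", mean, {"mu": math.log(mean), "sigma": sigma},
                                truncate_low, truncate_high)
    if family == "beta":
        if not (0.0 < mean < 1.0):
            raise ParameterError([f"beta family requires mean in (0,1), got {mean}"])
        var = sd * sd
        if var >= mean * (1.0 - mean):
            raise ParameterError(
                [f"beta method-of-moments infeasible: variance {var:.4g} too large "
                 f"for mean {mean}"]
            )
        nu = mean * (1.0 - mean) / var - 1.0
        return DistributionSpec("beta", mean, {"alpha": mean * nu, "beta": (1.0 - mean) * nu})
    # gamma
    if mean <= 0:
        raise ParameterError([f"gamma family requires positive mean, got {mean}"])
    var = sd * sd
    return DistributionSpec("gamma", mean, {"shape": mean * mean / var, "scale": var / mean})


#: positive floor applied when hazard ratios are sampled on the natural scale
HR_TRUNCATION_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# Parameter blocks


@dataclass(frozen=True)
class HazardRatioSet:
    """Treatment-effect hazard ratios vs statin for one drug and setting."""

    drug: str
    setting: str
    hazard_ratios: Mapping[str, Estimate]

    def __post_init__(self) -> None:
        errors = []
        if self.setting not in SETTINGS:
            errors.append(f"unknown setting {self.setting!r}")
        for event in EVENTS:
            if event not in self.hazard_ratios:
                errors.append(f"{self.drug}/{self.setting}: missing hazard ratio for {event}")
                continue
            est = self.hazard_ratios[event]
            if est.low <= 0:
                errors.append(f"{self.drug}/{self.setting}/{event}: hazard ratio CI must be > 0")
        if errors:
            raise ParameterError(errors)

    def distribution(self, event: str, scale: str = "natural") -> DistributionSpec:
        est = self.hazard_ratios[event]
        if scale == "natural":
            return ci_to_distribution(est.value, est.low, est.high, "normal",
                                      truncate_low=HR_TRUNCATION_FLOOR)
        if scale == "log":
            return ci_to_distribution(est.value, est.low, est.high, "lognormal")
        raise ParameterError([f"unknown hazard-ratio sampling scale {scale!r}"])


AGE_BANDS = ("age_65_70", "age_70_plus")


@dataclass(frozen=True)
class UtilityParams:
    """Health-state utilities by age band plus acute-event decrements.

    Ages below 70 (including the cohort entry age of 63) use the 65–70 band;
    70 and above use the 70+ band.  Death has utility 0.  Decrements apply
    for the single cycle in which the acute event occurs.
    """

    without_cvd: Mapping[str, Estimate]
    with_cvd: Mapping[str, Estimate]
    decrements: Mapping[str, Estimate]

    def __post_init__(self) -> None:
        errors = []
        for band in AGE_BANDS:
            for name, block in (("without_cvd", self.without_cvd), ("with_cvd", self.with_cvd)):
                if band not in block:
                    errors.append(f"utilities/{name}: missing band {band}")
                    continue
                v = block[band].value
                if not (0.0 <= v <= 1.0):
                    errors.append(f"utilities/{name}/{band}: utility {v} outside [0,1]")
            if band in self.without_cvd and band in self.with_cvd:
                if self.with_cvd[band].value > self.without_cvd[band].value:
                    errors.append(f"utilities/{band}: with-CVD utility exceeds without-CVD")
        for event in NONFATAL_EVENTS:
            if event not in self.decrements:
                errors.append(f"utilities/decrements: missing {event}")
            elif self.decrements[event].value < 0:
                errors.append(f"utilities/decrements/{event}: must be >= 0")
        if errors:
            raise ParameterError(errors)

    def band(self, age: float) -> str:
        return "age_65_70" if age < 70 else "age_70_plus"

    def state_utility(self, state: str, age: float) -> float:
        if state == "dead":
            return 0.0
        block = self.without_cvd if state == "alive_without_cvd" else self.with_cvd
        return block[self.band(age)].value

    def decrement(self, event: str) -> float:
        return self.decrements[event].value


@dataclass(frozen=True)
class CostParams:
    """Annual state costs, one-off event and death costs, and drug prices.

    All costs in 2021 euros from the payer perspective.  Death costs are the
    final hospital/home-weighted values (71% of deaths occur in hospital,
    29% at home); the weighting is an input-preparation step, not a model
    parameter.
    """

    annual_state: Mapping[str, Estimate]       # alive_without_cvd, alive_with_cvd
    event: Mapping[str, Estimate]              # the four non-fatal acute events
    death: Mapping[str, Estimate]              # cvd_death, noncvd_death
    annual_drug_cost: float                    # add-on therapy, €/year
    annual_statin_cost: float                  # background statin, €/year

    def __post_init__(self) -> None:
        errors = []
        for key in ("alive_without_cvd", "alive_with_cvd"):
            if key not in self.annual_state:
                errors.append(f"costs/annual_state: missing {key}")
        for event in NONFATAL_EVENTS:
            if event not in self.event:
                errors.append(f"costs/event: missing {event}")
        for event in FATAL_EVENTS:
            if event not in self.death:
                errors.append(f"costs/death: missing {event}")
        for name, block in (("annual_state", self.annual_state),
                            ("event", self.event), ("death", self.death)):
            for key, est in block.items():
                if est.value < 0 or est.low < 0:
                    errors.append(f"costs/{name}/{key}: costs must be >= 0")
        if self.annual_drug_cost < 0 or self.annual_statin_cost < 0:
            errors.append("costs: drug and statin prices must be >= 0")
        if errors:
            raise ParameterError(errors)


@dataclass(frozen=True)
class ModelSettings:
    """Run-level settings of the cohort simulation.

    discount_first_cycle=True applies weight (1+r)^-(t-1) to cycle t, i.e.
    the first model year is undiscounted; False uses (1+r)^-t.
    """

    time_horizon: int = 20                 # cycles (years)
    cycle_length_years: float = 1.0        # fixed; documented for clarity
    discount_rate: float = 0.03            # shared by costs and utilities
    start_age: float = 63.0
    cvd_risk_growth: float = 1.14          # multiplicative annual rate growth
    noncvd_risk_growth: float = 1.10
    psa_iterations: int = 1000
    seed: int | None = None
    discount_first_cycle: bool = True
    half_cycle_correction: bool = False
    hr_sampling_scale: str = "natural"     # "natural" (per declared family) or "log"
    hr_application: str = "rate"           # "rate" (complement-power) or "probability"
    wtp_max: float = 200_000.0             # CEAC grid upper end, €/QALY
    wtp_step: float = 1_000.0

    def __post_init__(self) -> None:
        errors = []
        if self.time_horizon < 1:
            errors.append("time horizon must be >= 1 cycle")
        if not (0.0 <= self.discount_rate <= 0.10):
            errors.append("discount rate outside the supported 0–0.10 range")
        if self.cvd_risk_growth <= 0 or self.noncvd_risk_growth <= 0:
            errors.append("risk growth factors must be positive")
        if self.hr_application not in ("rate", "probability"):
            errors.append(f"unknown hr_application {self.hr_application!r}")
        if self.hr_sampling_scale not in ("natural", "log"):
            errors.append(f"unknown hr_sampling_scale {self.hr_sampling_scale!r}")
        if errors:
            raise ParameterError(errors)

    def discount_factor(self, cycle: int) -> float:
        exponent = cycle - 1 if self.discount_first_cycle else cycle
        return (1.0 + self.discount_rate) ** (-exponent)

    def wtp_grid(self) -> np.ndarray:
        return np.arange(0.0, self.wtp_max + self.wtp_step / 2, self.wtp_step)


@dataclass(frozen=True)
class BaselineProbabilities:
    """Annual statin-arm event probabilities per health state.

    ``without_cvd`` risks govern the "alive without CVD" state (primary
    prevention); ``with_cvd`` risks govern the "alive with CVD" state.  The
    provenance tag records where the numbers came from: ``supplement``
    (transcribed), ``derived`` (from trial outcomes via the derivation
    pipeline) or ``synthetic``.
    """

    without_cvd: Mapping[str, float]
    with_cvd: Mapping[str, float]
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        errors = []
        for state_name, block in (("without_cvd", self.without_cvd),
                                  ("with_cvd", self.with_cvd)):
            for event in EVENTS:
                if event not in block:
                    errors.append(f"baseline/{state_name}: missing {event}")
                elif not (0.0 <= block[event] < 1.0):
                    errors.append(
                        f"baseline/{state_name}/{event}: probability "
                        f"{block[event]} outside [0, 1)")
        if errors:
            raise ParameterError(errors)

    def for_state(self, state: str) -> Mapping[str, float]:
        return self.without_cvd if state == "alive_without_cvd" else self.with_cvd

    def distribution(self, state: str, event: str) -> DistributionSpec:
        """Beta uncertainty with a ±25% band treated as a 95% interval."""
        p = self.for_state(state)[event]
        if p == 0.0:
            return DistributionSpec("fixed", 0.0, {})
        return ci_to_distribution(p, 0.75 * p, min(1.25 * p, 0.999999), "beta")


@dataclass(frozen=True)
class ParameterSet:
    """Complete validated inputs for one drug-vs-statin comparison."""

    drug: str
    setting: str
    trial: str
    followup_years: float
    hazard_ratios: Mapping[str, HazardRatioSet]  # keyed by setting with evidence
    utilities: UtilityParams
    costs: CostParams
    baseline: BaselineProbabilities
    settings: ModelSettings = field(default_factory=ModelSettings)

    def __post_init__(self) -> None:
        errors = []
        if self.setting not in SETTINGS:
            errors.append(f"unknown prevention setting {self.setting!r}")
        if self.followup_years <= 0:
            errors.append("trial follow-up must be positive")
        if errors:
            raise ParameterError(errors)
        if self.setting not in self.hazard_ratios:
            raise UnsupportedSettingError(
                [f"no trial evidence for {self.drug} in {self.setting} prevention"]
            )

    # -- convenience -------------------------------------------------------
    def hr_for_state(self, state: str) -> HazardRatioSet | None:
        """Hazard ratios governing a health state in this model run.

        Patients in the "alive with CVD" state are always governed by the
        drug's secondary-prevention effect; patients without CVD by the
        primary-prevention effect.  Returns None when the drug has no
        evidence for that state (the state is then unreachable or the
        treatment effect is taken as null there).
        """
        key = "secondary" if state == "alive_with_cvd" else "primary"
        return self.hazard_ratios.get(key)

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def deepcopy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def est(e: Estimate) -> list[float]:
            return e.to_list()

        return {
            "drug": self.drug,
            "setting": self.setting,
            "trial": self.trial,
            "followup_years": self.followup_years,
            "hazard_ratios": {
                s: {ev: est(h.hazard_ratios[ev]) for ev in EVENTS}
                for s, h in self.hazard_ratios.items()
            },
            "utilities": {
                "without_cvd": {b: est(self.utilities.without_cvd[b]) for b in AGE_BANDS},
                "with_cvd": {b: est(self.utilities.with_cvd[b]) for b in AGE_BANDS},
                "decrements": {ev: est(self.utilities.decrements[ev])
                               for ev in NONFATAL_EVENTS},
            },
            "costs": {
                "annual_state": {k: est(v) for k, v in self.costs.annual_state.items()},
                "event": {k: est(v) for k, v in self.costs.event.items()},
                "death": {k: est(v) for k, v in self.costs.death.items()},
                "annual_drug_cost": self.costs.annual_drug_cost,
                "annual_statin_cost": self.costs.annual_statin_cost,
            },
            "baseline": {
                "without_cvd": dict(self.baseline.without_cvd),
                "with_cvd": dict(self.baseline.with_cvd),
                "provenance": self.baseline.provenance,
            },
            "settings": dataclasses.asdict(self.settings),
        }

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        def est(x) -> Estimate:
            return Estimate(*x)

        hrs = {
            s: HazardRatioSet(d["drug"], s, {ev: est(v) for ev, v in block.items()})
            for s, block in d["hazard_ratios"].items()
        }
        util = UtilityParams(
            without_cvd={b: est(v) for b, v in d["utilities"]["without_cvd"].items()},
            with_cvd={b: est(v) for b, v in d["utilities"]["with_cvd"].items()},
            decrements={ev: est(v) for ev, v in d["utilities"]["decrements"].items()},
        )
        costs = CostParams(
            annual_state={k: est(v) for k, v in d["costs"]["annual_state"].items()},
            event={k: est(v) for k, v in d["costs"]["event"].items()},
            death={k: est(v) for k, v in d["costs"]["death"].items()},
            annual_drug_cost=d["costs"]["annual_drug_cost"],
            annual_statin_cost=d["costs"]["annual_statin_cost"],
        )
        baseline = BaselineProbabilities(
            without_cvd=dict(d["baseline"]["without_cvd"]),
            with_cvd=dict(d["baseline"]["with_cvd"]),
            provenance=d["baseline"]["provenance"],
        )
        return cls(
            drug=d["drug"], setting=d["setting"], trial=d["trial"],
            followup_years=d["followup_years"], hazard_ratios=hrs,
            utilities=util, costs=costs, baseline=baseline,
            settings=ModelSettings(**d["settings"]),
        )

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ParameterSet":
        s = str(text_or_path)
        if isinstance(text_or_path, Path) or not s.lstrip().startswith("{"):
            s = Path(s).read_text()
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Loading from the YAML configuration


def default_config_path() -> Path:
    """Path of the parameter file shipped with the package."""
    return Path(__file__).parent / "data" / "table1.yaml"


def _estimate_from_yaml(node, pct_default: float | None = None) -> Estimate:
    if isinstance(node, Mapping):
        value = float(node["value"])
        if "ci" in node:
            lo, hi = (float(x) for x in node["ci"])
            return Estimate(value, lo, hi)
        pct = float(node.get("variation_pct", 25)) / 100.0
        return Estimate.with_pct_bounds(value, pct)
    if isinstance(node, (list, tuple)):
        return Estimate(float(node[0]), float(node[1]), float(node[2]))
    value = float(node)
    if pct_default is not None:
        return Estimate.with_pct_bounds(value, pct_default)
    return Estimate(value, value, value)


def load_parameters(
    path: str | Path | None = None,
    drug: str = "icosapent_ethyl",
    setting: str = "secondary",
    baselines_path: str | Path | None = None,
    settings_overrides: Mapping | None = None,
) -> ParameterSet:
    """Load and validate a complete :class:`ParameterSet` for one comparison.

    ``path`` defaults to the parameter file shipped with the package.  The
    baseline statin-arm probabilities are read from the file referenced by
    the config's ``baseline_probabilities_file`` key (resolved relative to
    the config), unless ``baselines_path`` overrides it.

    Raises :class:`UnsupportedSettingError` for drug/setting pairs without
    trial evidence (ezetimibe, evolocumab, and alirocumab have none in
    primary prevention) and :class:`ParameterError` listing every offending
    field for malformed files.
    """
    cfg_path = Path(path) if path is not None else default_config_path()
    if not cfg_path.exists():
        raise FileNotFoundError(cfg_path)
    cfg = yaml.safe_load(cfg_path.read_text())

    errors: list[str] = []
    for key in ("drugs", "utilities", "costs_eur", "settings"):
        if key not in cfg:
            errors.append(f"config: missing top-level section {key!r}")
    if errors:
        raise ParameterError(errors)

    if drug not in cfg["drugs"]:
        raise ParameterError(
            [f"unknown drug {drug!r}; available: {', '.join(sorted(cfg['drugs']))}"]
        )
    if setting not in SETTINGS:
        raise ParameterError([f"unknown setting {setting!r}; expected one of {SETTINGS}"])
    drug_cfg = cfg["drugs"][drug]
    if setting not in drug_cfg.get("hazard_ratios", {}):
        raise UnsupportedSettingError(
            [f"no clinical trial data for {drug} in {setting} prevention"]
        )

    hrs = {
        s: HazardRatioSet(
            drug, s, {ev: _estimate_from_yaml(v) for ev, v in block.items()}
        )
        for s, block in drug_cfg["hazard_ratios"].items()
    }

    ucfg = cfg["utilities"]
    utilities = UtilityParams(
        without_cvd={b: _estimate_from_yaml(v) for b, v in ucfg["alive_without_cvd"].items()},
        with_cvd={b: _estimate_from_yaml(v) for b, v in ucfg["alive_with_cvd"].items()},
        decrements={ev: _estimate_from_yaml(v) for ev, v in ucfg["event_decrements"].items()},
    )

    ccfg = cfg["costs_eur"]
    costs = CostParams(
        annual_state={k: _estimate_from_yaml(v) for k, v in ccfg["annual_state"].items()},
        event={k: _estimate_from_yaml(v) for k, v in ccfg["one_off_event"].items()},
        death={k: _estimate_from_yaml(v) for k, v in ccfg["one_off_death"].items()},
        annual_drug_cost=float(drug_cfg["annual_cost_eur_per_year"]),
        annual_statin_cost=float(ccfg["annual_statin_cost_eur_per_year"]),
    )

    if baselines_path is None:
        ref = cfg.get("baseline_probabilities_file")
        if ref is None:
            raise ParameterError(["config: missing baseline_probabilities_file"])
        baselines_path = cfg_path.parent / ref
    bcfg = yaml.safe_load(Path(baselines_path).read_text())
    if drug not in bcfg.get("drugs", {}):
        raise ParameterError([f"baseline probabilities: no entry for drug {drug!r}"])
    bdrug = bcfg["drugs"][drug]
    baseline = BaselineProbabilities(
        without_cvd={ev: float(p) for ev, p in bdrug["alive_without_cvd"].items()},
        with_cvd={ev: float(p) for ev, p in bdrug["alive_with_cvd"].items()},
        provenance=str(bcfg.get("provenance", "synthetic")),
    )

    scfg = dict(cfg["settings"])
    known = {f.name for f in dataclasses.fields(ModelSettings)}
    kwargs = {k: v for k, v in scfg.items() if k in known}
    unknown = set(scfg) - known - {"discount_rate_bounds"}
    if unknown:
        raise ParameterError([f"config/settings: unknown keys {sorted(unknown)}"])
    if settings_overrides:
        kwargs.update(settings_overrides)
    settings = ModelSettings(**kwargs)

    return ParameterSet(
        drug=drug,
        setting=setting,
        trial=str(drug_cfg.get("trial", "unknown")),
        followup_years=float(drug_cfg.get("median_followup_years", 1.0)),
        hazard_ratios=hrs,
        utilities=utilities,
        costs=costs,
        baseline=baseline,
        settings=settings,
    )


def available_comparisons(path: str | Path | None = None) -> list[tuple[str, str]]:
    """All (drug, setting) pairs with trial evidence in a config file."""
    cfg_path = Path(path) if path is not None else default_config_path()
    cfg = yaml.safe_load(cfg_path.read_text())
    pairs = []
    for drug, dcfg in cfg["drugs"].items():
        for s in SETTINGS:
            if s in dcfg.get("hazard_ratios", {}):
                pairs.append((drug, s))
    return pairs
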