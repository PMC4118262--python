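"""Seeded synthetic cohorts with the statistical structure the models assume.

The generator emulates residents nested in facilities: a Gaussian facility
random intercept, Bernoulli resident covariates, exponential care-level-
dependent survival censored at the window end, and NB2 event counts whose
mean is person-time x exp(beta0 + beta'x + b_i). Events carry ordered
diagnosis codes constructed so that a configurable fraction match the
bundled PAH code list; the remainder are drawn from a disjoint dummy code
space, so the PAH fraction is exact by construction.

Seeding uses one master ``SeedSequence`` spawning independent streams for
facilities, residents and events (a child stream per facility for the
latter two), so editing the resident count of one facility never perturbs
the draws of another.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, replace

import numpy as np

from .classify import default_code_list
from .cohort import CARE_LEVELS, Facility, FollowUpWindow, HospitalEvent, Resident
from .errors import ConfigError
from .exposure import DAYS_PER_YEAR, person_time

#: Diagnosis prefixes used for non-PAH filler codes. Disjoint from the
#: bundled default code list by construction (the bundled list deliberately
#: has no V/W/X/Y/Z-chapter prefixes).
DUMMY_PREFIXES = ("Z99", "Y99", "X99", "W99")

_FACILITY_TYPES = (
    # (care levels, probability)
    (frozenset({"low"}), 0.40),
    (frozenset({"high"}), 0.20),
    (frozenset({"low", "high"}), 0.25),
    (frozenset({"low", "dementia"}), 0.10),
    (frozenset({"high", "psychogeriatric"}), 0.05),
)

_OWNERSHIP = ("for_profit", "not_for_profit", "public")
_OWNERSHIP_P = (0.6, 0.3, 0.1)


@dataclass(frozen=True)
class SimulationScenario:
    """True parameters of one simulated study.

    ``beta`` maps covariate names to log-rate effects (``"intercept"``
    included) on the all-events scale; covariates present in
    ``covariate_prevalence`` but absent from ``beta`` have a true effect of
    zero (pure-noise candidates for elimination experiments).
    ``residents_per_facility_dispersion=inf`` fixes the count at the mean.
    """

    name: str
    n_facilities: int
    residents_per_facility_mean: float
    residents_per_facility_dispersion: float
    care_level_mix: dict[str, float]
    survival_rates: dict[str, float]  # exponential death rate per year
    covariate_prevalence: dict[str, float]
    beta: dict[str, float]
    sigma_b: float
    dispersion_k: float
    pah_fraction_of_events: float
    window: FollowUpWindow
    seed: int = 0
    n_strata: int = 3
    female_fraction: float = 0.71
    mean_dx_per_event: float = 2.5

    def __post_init__(self) -> None:
        if self.n_facilities < 1:
            raise ConfigError("n_facilities must be >= 1")
        if self.residents_per_facility_mean <= 0:
            raise ConfigError("residents_per_facility_mean must be > 0")
        if abs(sum(self.care_level_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("care_level_mix probabilities must sum to 1")
        bad = set(self.care_level_mix) - set(CARE_LEVELS)
        if bad:
            raise ConfigError(f"unknown care levels {sorted(bad)}")
        for lvl in self.care_level_mix:
            if self.survival_rates.get(lvl, 0) <= 0:
                raise ConfigError(f"survival rate for {lvl!r} must be > 0")
        for name, p in self.covariate_prevalence.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"prevalence of {name!r} outside [0,1]")
        if not 0 <= self.pah_fraction_of_events <= 1:
            raise ConfigError("pah_fraction_of_events must be in [0,1]")
        if self.sigma_b < 0 or self.dispersion_k <= 0:
            raise ConfigError("sigma_b must be >= 0 and dispersion_k > 0")
        if "intercept" not in self.beta:
            raise ConfigError("beta must contain 'intercept'")
        unknown = set(self.beta) - {"intercept"} - set(self.covariate_prevalence)
        if unknown:
            raise ConfigError(f"beta names without prevalence: {sorted(unknown)}")

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(self.covariate_prevalence)

    @property
    def pah_beta(self) -> dict[str, float]:
        """True coefficients on the PAH-count scale.

        Binomial thinning of NB2(mu, k) is NB2(p*mu, k), so the PAH counts
        follow the same model with the intercept shifted by log(p).
        """
        out = {n: self.beta.get(n, 0.0) for n in ("intercept", *self.covariate_names)}
        out["intercept"] += math.log(self.pah_fraction_of_events)
        return out


def calibrated_intercept(
    target_rate: float,
    beta: dict[str, float],
    prevalence: dict[str, float],
    sigma_b: float,
    pah_fraction: float,
) -> float:
    """Intercept giving a marginal PAH rate of ``target_rate`` per
    person-year: solves target = exp(b0) * prod(1 - p_j + p_j e^{b_j})
    * exp(sigma_b^2/2) * pah_fraction."""
    factor = math.exp(sigma_b**2 / 2.0) * pah_fraction
    for name, p in prevalence.items():
        factor *= 1.0 - p + p * math.exp(beta.get(name, 0.0))
    return math.log(target_rate / factor)


_OPAL_WINDOW = FollowUpWindow(dt.date(2008, 7, 1), dt.date(2010, 5, 1))  # 22 months

_OPAL_PREV = {
    "gp_urgent_2wk": 0.08,
    "ed_visit_prior_window": 0.15,
    "prior_diabetes_admission": 0.10,
    "prior_dementia_admission": 0.12,
}
_OPAL_BETA = {
    "gp_urgent_2wk": 0.5,
    "ed_visit_prior_window": 0.4,
    "prior_diabetes_admission": 0.3,
    "prior_dementia_admission": 0.2,
}


def _opal_like(seed: int) -> SimulationScenario:
    sigma_b, k, pah_frac = 0.3, 2.0, 0.8
    beta = dict(_OPAL_BETA)
    beta["intercept"] = calibrated_intercept(0.34, beta, _OPAL_PREV, sigma_b, pah_frac)
    return SimulationScenario(
        name="opal_like",
        n_facilities=149,
        residents_per_facility_mean=6271 / 149,
        residents_per_facility_dispersion=8.0,
        care_level_mix={"low": 0.55, "high": 0.30, "dementia": 0.10,
                        "psychogeriatric": 0.05},
        survival_rates={"low": 0.25, "high": 0.45, "dementia": 0.35,
                        "psychogeriatric": 0.40},
        covariate_prevalence=dict(_OPAL_PREV),
        beta=beta,
        sigma_b=sigma_b,
        dispersion_k=k,
        pah_fraction_of_events=pah_frac,
        window=_OPAL_WINDOW,
        seed=seed,
    )


def _tiny(seed: int) -> SimulationScenario:
    beta = dict(_OPAL_BETA)
    beta["intercept"] = calibrated_intercept(0.34, beta, _OPAL_PREV, 0.3, 1.0)
    return SimulationScenario(
        name="tiny",
        n_facilities=5,
        residents_per_facility_mean=10,
        residents_per_facility_dispersion=math.inf,
        care_level_mix={"low": 0.6, "high": 0.4},
        survival_rates={"low": 0.25, "high": 0.45},
        covariate_prevalence=dict(_OPAL_PREV),
        beta=beta,
        sigma_b=0.3,
        dispersion_k=2.0,
        pah_fraction_of_events=1.0,
        window=_OPAL_WINDOW,
        seed=seed,
    )


_PRESETS = {
    "opal_like": _opal_like,
    "tiny": _tiny,
}


def scenario_presets(seed: int = 0) -> dict[str, SimulationScenario]:
    """All named preset scenarios, instantiated at ``seed``."""
    return {name: make(seed) for name, make in _PRESETS.items()}


def get_preset(name: str, seed: int = 0) -> SimulationScenario:
    """One preset by name; raises listing the presets if unknown."""
    try:
        make = _PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return make(seed)


# ---------------------------------------------------------------------------
# generation

def _draw_code(rng: np.random.Generator, prefixes: tuple[str, ...]) -> str:
    return prefixes[rng.integers(len(prefixes))] + str(rng.integers(10))


def simulate_cohort(
    scenario: SimulationScenario,
    seed: int | None = None,
    return_truth: bool = False,
):
    """Generate (facilities, residents, events) for a scenario.

    ``seed`` overrides ``scenario.seed``. With ``return_truth=True`` a
    fourth element carries the latent ground truth (facility intercepts and
    per-resident expected counts) for calibration tests.
    """
    if seed is not None:
        scenario = replace(scenario, seed=seed)
    master = np.random.SeedSequence(scenario.seed)
    ss_fac, ss_res, ss_ev = master.spawn(3)
    rng_fac = np.random.Generator(np.random.PCG64(ss_fac))
    res_children = ss_res.spawn(scenario.n_facilities)
    ev_children = ss_ev.spawn(scenario.n_facilities)

    code_list = default_code_list()
    pah_prefixes = tuple(p for _, p in code_list.entries)

    win = scenario.window
    levels = tuple(scenario.care_level_mix)
    level_p = np.array([scenario.care_level_mix[l] for l in levels])
    cov_names = scenario.covariate_names
    beta0 = scenario.beta["intercept"]
    betas = np.array([scenario.beta.get(n, 0.0) for n in cov_names])

    type_levels = [t for t, _ in _FACILITY_TYPES]
    type_p = np.array([p for _, p in _FACILITY_TYPES])

    facilities: list[Facility] = []
    residents: list[Resident] = []
    events: list[HospitalEvent] = []
    truth_b: dict[str, float] = {}
    truth_mu: dict[str, float] = {}
    width = len(str(scenario.n_facilities))

    # facility-level draws (one stream, fixed order)
    fac_type_idx = rng_fac.choice(len(type_levels), size=scenario.n_facilities, p=type_p)
    b_i = rng_fac.normal(0.0, scenario.sigma_b, size=scenario.n_facilities)
    own_idx = rng_fac.choice(len(_OWNERSHIP), size=scenario.n_facilities, p=_OWNERSHIP_P)
    chain = rng_fac.random(scenario.n_facilities) < 0.4
    dist = np.round(rng_fac.lognormal(2.0, 0.7, size=scenario.n_facilities), 1)

    ev_counter = 0
    for i in range(scenario.n_facilities):
        fid = f"F{i + 1:0{width}d}"
        truth_b[fid] = float(b_i[i])
        rng_r = np.random.Generator(np.random.PCG64(res_children[i]))
        rng_e = np.random.Generator(np.random.PCG64(ev_children[i]))

        m = scenario.residents_per_facility_mean
        disp = scenario.residents_per_facility_dispersion
        if math.isinf(disp):
            n_res = max(1, round(m))
        else:
            lam = rng_r.gamma(disp, m / disp)
            n_res = max(1, int(rng_r.poisson(lam)))

        fac_levels = type_levels[fac_type_idx[i]]
        facilities.append(
            Facility(
                facility_id=fid,
                care_levels=fac_levels,
                n_beds=int(n_res + rng_r.poisson(3.0)),
                ownership=_OWNERSHIP[own_idx[i]],
                chain_member=bool(chain[i]),
                distance_to_hospital_km=float(dist[i]),
                stratum=f"DHB{(i % scenario.n_strata) + 1}",
            )
        )

        # resident care levels drawn from the mix restricted to this facility
        mask = np.array([l in fac_levels for l in levels], dtype=float)
        p_here = level_p * mask
        if p_here.sum() == 0:  # facility type absent from the mix: uniform
            p_here = mask
        p_here = p_here / p_here.sum()

        for j in range(n_res):
            rid = f"{fid}R{j + 1:03d}"
            level = levels[rng_r.choice(len(levels), p=p_here)]
            age = float(np.clip(rng_r.normal(85.0, 7.0), 65.0, 105.0))
            sex = "F" if rng_r.random() < scenario.female_fraction else "M"
            x = (rng_r.random(len(cov_names))
                 < np.array([scenario.covariate_prevalence[n] for n in cov_names])
                 ).astype(float)

            t_years = rng_r.exponential(1.0 / scenario.survival_rates[level])
            t_days = max(1, int(min(math.floor(t_years * DAYS_PER_YEAR), win.days)))
            death = (win.start_date + dt.timedelta(days=t_days)
                     if t_days < win.days else None)  # censored at window end
            resident = Resident(
                resident_id=rid,
                facility_id=fid,
                care_level=level,
                age_years=round(age, 1),
                sex=sex,
                entry_date=win.start_date,
                death_date=death,
                covariates={n: float(v) for n, v in zip(cov_names, x)},
            )
            residents.append(resident)

            pt = person_time(resident, win)
            mu = pt * math.exp(beta0 + float(betas @ x) + b_i[i])
            truth_mu[rid] = mu
            lam = rng_e.gamma(scenario.dispersion_k, mu / scenario.dispersion_k)
            n_events = int(rng_e.poisson(lam))
            if n_events == 0:
                continue
            expo_days = max(1, int(round(pt * DAYS_PER_YEAR)))
            day_offsets = rng_e.integers(0, expo_days, size=n_events)
            for off in sorted(int(d) for d in day_offsets):
                ev_counter += 1
                n_dx = 1 + int(rng_e.poisson(scenario.mean_dx_per_event - 1))
                codes = [_draw_code(rng_e, DUMMY_PREFIXES) for _ in range(n_dx)]
                if rng_e.random() < scenario.pah_fraction_of_events:
                    pos = int(rng_e.integers(0, min(3, n_dx)))
                    codes[pos] = _draw_code(rng_e, pah_prefixes)
                events.append(
                    HospitalEvent(
                        event_id=f"E{ev_counter:06d}",
                        resident_id=rid,
                        admission_date=win.start_date + dt.timedelta(days=off),
                        acute=True,
                        diagnosis_codes=tuple(codes),
                    )
                )

    if return_truth:
        truth = {"b": truth_b, "mu": truth_mu, "code_list": code_list}
        return facilities, residents, events, truth
    return facilities, residents, events


__all__ = [
    "SimulationScenario", "simulate_cohort", "scenario_presets", "get_preset",
    "calibrated_intercept", "DUMMY_PREFIXES",
]
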