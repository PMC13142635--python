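"""Protocol-faithful behavioral simulator with known ground truth.

The generator emulates the study population and design: a mixed-age
companion-dog cohort (age mean 7 y, SD 4 y, truncated to 1-16 y) tested at
three sites, with retesting at six and twelve months and realistic dropout.
Each dog carries a latent cognitive ability

    a_it = b0 + b1 age_it + b2 age_it^2 + u_i + d_timepoint + e_it,
    u_i ~ N(0, tau^2),  e_it ~ N(0, sigma^2),

with a quadratic (accelerating) age decline, a stable individual component
``u_i`` whose share of variance sets the true repeatability, and
timepoint-specific practice effects ``d``.  Latent ability drives trial
outcomes through logistic links per task; no-choice / no-response events
and fear aborts are injected at configured rates with protocol-correct
motivator repeats, caps and discontinuation rules.  Everything is seeded
and reproducible.

The logistic response model is this module's own construction — it exists
so that scorers and statistics can be exercised end-to-end against known
truth — and its parameters are set so that baseline score distributions
are roughly normal after the Yeo-Johnson step and the composite score's
true repeatability is about 0.6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import data_model as dm
from .errors import ValidationError

#: fixed baited-location order: each location three times, never repeated
#: consecutively, shared by every simulated dog
DS_LOCATION_ORDER = (1, 2, 3, 4, 2, 1, 4, 3, 1, 3, 2, 4)
DS_TYPE_ORDER = ("no_delay",) * 4 + ("d10",) * 2 + ("d10_distract",) * 2 \
    + ("d20_distract",) * 2 + ("d40_distract",) * 2

TIMEPOINT_AGE_OFFSET = {"baseline": 0.0, "m6": 0.5, "m12": 1.0}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Demographics follow the study population (cohort size 239, age 7 +/- 4 y,
    three locations with weights 0.49/0.13/0.33, balanced sexes, ~59% and
    ~49% retention at the six- and twelve-month retests).  The latent-model
    and link parameters are the generator's own, chosen so the simulated
    battery behaves like the real one (see the package methods note).
    """

    n_dogs: int = 239
    age_mean: float = 7.0
    age_sd: float = 4.0
    age_bounds: tuple = (1.0, 16.0)
    location_probs: dict = field(default_factory=lambda: {
        "ACCC": 0.49, "CC": 0.13, "SSP": 0.33})
    p_male: float = 0.5
    p_mixed: float = 0.51
    p_altered: float = 0.92
    weight_mean: float = 22.0
    weight_sd: float = 11.0
    p_hearing_pass: float = 0.95
    retention_m6: float = 0.59
    retention_m12: float = 0.49

    # latent cognition
    beta_age1: float = 0.03
    beta_age2: float = -0.014
    tau: float = 0.866         # between-dog SD (tau^2 ~ 0.75)
    sigma: float = 0.5         # within-dog transient SD
    delta_m6: float = 0.25
    delta_m12: float = 0.0

    # task links
    sr_slope: float = 1.0
    sr_base: float = 1.3
    sr_persev: float = 2.5
    sr_persev_decay: float = 0.7
    ds_slope: float = 1.0
    ds_base: float = 1.5
    ds_penalties: tuple = (0.0, 0.5, 0.9, 1.2, 1.5)
    cyl_slope: float = 0.8
    cyl_base: float = 0.3

    # event rates
    sr_no_choice_rate: float = 0.02
    ds_no_choice_rate: float = 0.015
    cyl_no_response_rate: float = 0.02
    sr_abort_rate: float = 0.012
    ds_abort_rate: float = 0.004
    cyl_abort_rate: float = 0.0

    seed: int = 0

    def validate(self) -> None:
        bad = []
        probs = (["p_male", "p_mixed", "p_altered", "p_hearing_pass",
                  "retention_m6", "retention_m12", "sr_no_choice_rate",
                  "ds_no_choice_rate", "cyl_no_response_rate", "sr_abort_rate",
                  "ds_abort_rate", "cyl_abort_rate", "sr_persev_decay"])
        for name in probs:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad.append(name)
        for name in ("age_sd", "tau", "sigma", "weight_mean", "weight_sd"):
            if getattr(self, name) <= 0:
                bad.append(name)
        if not (0 < self.age_bounds[0] < self.age_bounds[1]):
            bad.append("age_bounds")
        if any(p < 0 for p in self.location_probs.values()):
            bad.append("location_probs")
        if any(b < a for a, b in zip(self.ds_penalties, self.ds_penalties[1:])):
            bad.append("ds_penalties")  # must be nondecreasing with delay
        if bad:
            raise ValidationError("invalid config field(s): " + ", ".join(bad))

    @property
    def latent_sd(self) -> float:
        """Population SD of baseline latent ability (age curve + u + e).

        Practice deltas are specified in these units, so a delta of 0.25
        means a shift of a quarter of the baseline between-dog spread —
        the scale on which standardized scores express practice effects.
        """
        key = (self.age_mean, self.age_sd, self.age_bounds)
        if key not in _TN_CACHE:
            _TN_CACHE[key] = _truncnorm_params(self.age_mean, self.age_sd,
                                               *self.age_bounds)
        mu, s = _TN_CACHE[key]
        lo, hi = self.age_bounds
        d = stats.truncnorm((lo - mu) / s, (hi - mu) / s, loc=mu, scale=s)
        f = lambda a: self.beta_age1 * a + self.beta_age2 * a ** 2
        var_age = d.expect(lambda a: f(a) ** 2) - d.expect(f) ** 2
        return math.sqrt(var_age + self.tau ** 2 + self.sigma ** 2)

    @property
    def beta0(self) -> float:
        """Intercept anchoring mean latent ability to 0 at the age mean."""
        return -(self.beta_age1 * self.age_mean
                 + self.beta_age2 * self.age_mean ** 2)

    @property
    def true_icc(self) -> float:
        return self.tau ** 2 / (self.tau ** 2 + self.sigma ** 2)

    def to_dict(self):
        d = asdict(self)
        d["age_bounds"] = list(self.age_bounds)
        d["ds_penalties"] = list(self.ds_penalties)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "age_bounds" in d:
            d["age_bounds"] = tuple(d["age_bounds"])
        if "ds_penalties" in d:
            d["ds_penalties"] = tuple(d["ds_penalties"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-session latent abilities and the generating parameters."""

    abilities: pd.DataFrame    # dog_id, timepoint, ability
    true_icc: float
    delta_m6: float
    delta_m12: float
    beta_age1: float
    beta_age2: float


def _logistic(x):
    return 1.0 / (1.0 + math.exp(-x))


def _truncnorm_params(mean, sd, lo, hi):
    """Pre-truncation (mu, s) whose truncated moments match (mean, sd)."""

    def moments(p):
        mu, log_s = p
        s = math.exp(log_s)
        a, b = (lo - mu) / s, (hi - mu) / s
        d = stats.truncnorm(a, b, loc=mu, scale=s)
        return [d.mean() - mean, d.std() - sd]

    sol = optimize.root(moments, x0=[mean, math.log(sd)], tol=1e-10)
    if not sol.success:
        raise RuntimeError("truncated-normal moment matching failed")
    return sol.x[0], math.exp(sol.x[1])


_TN_CACHE: dict = {}


def sample_ages(n, config: SimConfig, rng) -> np.ndarray:
    key = (config.age_mean, config.age_sd, config.age_bounds)
    if key not in _TN_CACHE:
        _TN_CACHE[key] = _truncnorm_params(config.age_mean, config.age_sd,
                                           *config.age_bounds)
    mu, s = _TN_CACHE[key]
    lo, hi = config.age_bounds
    a, b = (lo - mu) / s, (hi - mu) / s
    return stats.truncnorm(a, b, loc=mu, scale=s).rvs(n, random_state=rng)


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

def simulate_population(config: SimConfig, seed=None):
    """Draw a cohort: dogs, sessions with dropout, and latent ground truth.

    Returns ``(dogs, sessions, truth)`` where the first two are validated
    data tables and ``truth`` records every session's latent ability.
    """
    config.validate()
    rng = _as_rng(seed if seed is not None else config.seed)
    n = config.n_dogs
    ids = [f"dog{i:04d}" for i in range(n)]
    ages = sample_ages(n, config, rng)
    locs = list(config.location_probs)
    w = np.array([config.location_probs[l] for l in locs], dtype=float)
    location = rng.choice(locs, size=n, p=w / w.sum())
    sex = np.where(rng.random(n) < config.p_male, "male", "female")
    breed = np.where(rng.random(n) < config.p_mixed, "mixed", "purebred")
    neuter = np.where(rng.random(n) < config.p_altered, "altered", "intact")
    lsd2 = math.log(1 + (config.weight_sd / config.weight_mean) ** 2)
    weight = rng.lognormal(math.log(config.weight_mean) - lsd2 / 2,
                           math.sqrt(lsd2), size=n).round(1)
    dogs = pd.DataFrame({"dog_id": ids, "sex": sex, "neuter_status": neuter,
                         "weight_kg": weight, "breed_class": breed},
                        columns=list(dm.DOGS_COLUMNS))

    u = rng.normal(0.0, config.tau, size=n)
    S = config.latent_sd   # deltas are in units of baseline latent SD
    delta = {"baseline": 0.0, "m6": config.delta_m6 * S,
             "m12": config.delta_m12 * S}
    keep_m6 = rng.random(n) < config.retention_m6
    keep_m12 = rng.random(n) < config.retention_m12
    sess_rows, truth_rows = [], []
    for i in range(n):
        for tp in dm.TIMEPOINTS:
            if tp == "m6" and not keep_m6[i]:
                continue
            if tp == "m12" and not keep_m12[i]:
                continue
            age = ages[i] + TIMEPOINT_AGE_OFFSET[tp]
            a = (config.beta0 + config.beta_age1 * age
                 + config.beta_age2 * age ** 2 + u[i] + delta[tp]
                 + rng.normal(0.0, config.sigma))
            sess_rows.append({"dog_id": ids[i], "timepoint": tp,
                              "test_age_years": round(age, 3),
                              "location": location[i], "vision_pass": True,
                              "hearing_pass":
                              bool(rng.random() < config.p_hearing_pass)})
            truth_rows.append({"dog_id": ids[i], "timepoint": tp, "ability": a})
    sessions = pd.DataFrame(sess_rows, columns=list(dm.SESSIONS_COLUMNS))
    truth = GroundTruth(abilities=pd.DataFrame(truth_rows),
                        true_icc=config.true_icc,
                        delta_m6=config.delta_m6, delta_m12=config.delta_m12,
                        beta_age1=config.beta_age1, beta_age2=config.beta_age2)
    return dogs, sessions, truth


# ---------------------------------------------------------------------------
# Trial-level engines
# ---------------------------------------------------------------------------

def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_sr_trials(ability, config: SimConfig, seed,
                       dog_id="dog", timepoint="baseline") -> dm.SRTrialSeq:
    """Run the Spatial Reversal protocol for one dog."""
    rng = _as_rng(seed)
    seq = dm.SRTrialSeq(dog_id=dog_id, timepoint=timepoint)
    abort = rng.random() < config.sr_abort_rate
    abort_at = int(rng.integers(1, 25)) if abort else None

    open_side = "left" if rng.random() < 0.5 else "right"
    index = 0

    def administer(phase, block_index, p_correct):
        """One trial slot incl. motivator repeats; returns scored response."""
        nonlocal index
        original = None
        while True:
            index += 1
            if abort_at is not None and index >= abort_at:
                seq.trials.append(dm.SRTrial(index, phase, block_index,
                                             open_side, dm.ABORT,
                                             repeat_of=original))
                return dm.ABORT
            if rng.random() < config.sr_no_choice_rate:
                seq.trials.append(dm.SRTrial(index, phase, block_index,
                                             open_side, dm.NO_CHOICE,
                                             repeat_of=original))
                if original is None:
                    original = index
                continue
            response = "open" if rng.random() < p_correct else "closed"
            seq.trials.append(dm.SRTrial(index, phase, block_index, open_side,
                                         response, repeat_of=original))
            return response

    def run_block(phase, block_index, p_for_trial, cap):
        """Administer scored trials until criterion or cap; returns
        (criterion_met, scored_trials_used, aborted)."""
        window = []
        scored = 0
        while scored < cap:
            r = administer(phase, block_index, p_for_trial(scored + 1))
            if r == dm.ABORT:
                return False, scored, True
            scored += 1
            window.append(r == "open")
            if len(window) > 4:
                window.pop(0)
            if len(window) >= 4 and sum(window) >= 3:
                return True, scored, False
        return False, scored, False

    # baseline block
    eta = config.sr_slope * ability + config.sr_base
    met, _, aborted = run_block("baseline", 0, lambda t: _logistic(eta), 20)
    if aborted or not met:
        return seq

    # reversal blocks: perseveration decays within each block
    remaining = 20
    for block in (1, 2, 3):
        open_side = "left" if open_side == "right" else "right"
        if remaining == 0:
            break

        def p_reversal(t):
            pull = config.sr_persev * config.sr_persev_decay ** (t - 1)
            return _logistic(eta - pull)

        met, used, aborted = run_block("reversal", block, p_reversal, remaining)
        remaining -= used
        if aborted or not met:
            break
    return seq


def simulate_ds_trials(ability, config: SimConfig, seed,
                       dog_id="dog", timepoint="baseline") -> dm.DSTrialSet:
    """Run the Delayed Search protocol for one dog."""
    rng = _as_rng(seed)
    _check_ds_order(DS_LOCATION_ORDER)
    seq = dm.DSTrialSet(dog_id=dog_id, timepoint=timepoint)
    abort = rng.random() < config.ds_abort_rate
    abort_at = int(rng.integers(1, 14)) if abort else None
    penalties = dict(zip(dm.DS_TRIAL_TYPES, config.ds_penalties))
    index = 0
    n_no_choice = 0
    for loc, ttype in zip(DS_LOCATION_ORDER, DS_TYPE_ORDER):
        original = None
        p = _logistic(config.ds_slope * ability + config.ds_base
                      - penalties[ttype])
        while True:
            index += 1
            if abort_at is not None and index >= abort_at:
                seq.trials.append(dm.DSTrial(index, ttype, loc, dm.ABORT,
                                             repeat_of=original))
                return seq
            if rng.random() < config.ds_no_choice_rate:
                seq.trials.append(dm.DSTrial(index, ttype, loc, dm.NO_CHOICE,
                                             repeat_of=original))
                n_no_choice += 1
                if n_no_choice >= 4:
                    return seq       # task discontinued
                if original is None:
                    original = index
                continue
            if rng.random() < p:
                search = loc
            else:
                search = int(rng.choice([l for l in dm.DS_LOCATIONS
                                         if l != loc]))
            seq.trials.append(dm.DSTrial(index, ttype, loc, search,
                                         repeat_of=original))
            break
    return seq


def _check_ds_order(order):
    counts = {l: 0 for l in dm.DS_LOCATIONS}
    for a, b in zip(order, order[1:]):
        if a == b:
            raise ValidationError("baited-location order repeats consecutively")
    for l in order:
        counts[l] += 1
    if any(v != 3 for v in counts.values()):
        raise ValidationError("baited-location order must use each location "
                              "exactly 3 times")


def simulate_cyl_trials(ability, config: SimConfig, seed,
                        dog_id="dog", timepoint="baseline") -> dm.CylTrialSet:
    """Run the Cylinder inhibitory-control trials for one dog."""
    rng = _as_rng(seed)
    seq = dm.CylTrialSet(dog_id=dog_id, timepoint=timepoint)
    p = _logistic(config.cyl_slope * ability + config.cyl_base)
    index = 0
    n_no_response = 0
    for _ in range(dm.CYL_N_TRIALS):
        original = None
        while True:
            index += 1
            if rng.random() < config.cyl_no_response_rate:
                seq.trials.append(dm.CylTrial(index, False, None,
                                              repeat_of=original))
                n_no_response += 1
                if n_no_response >= 4:
                    return seq       # task discontinued
                if original is None:
                    original = index
                continue
            touched = rng.random() >= p
            seq.trials.append(dm.CylTrial(index, True, bool(touched),
                                          repeat_of=original))
            break
    return seq


# ---------------------------------------------------------------------------
# Whole-cohort convenience
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig, seed=None):
    """Simulate dogs, sessions and all three tasks' trial data.

    Returns a dict with keys ``dogs``, ``sessions``, ``truth`` and the
    per-task session dicts ``sr``, ``ds``, ``cyl`` (keyed by
    ``(dog_id, timepoint)``), ready for the scoring pipeline.
    """
    root = np.random.SeedSequence(seed if seed is not None else config.seed)
    pop_seed, trial_seed = root.spawn(2)
    dogs, sessions, truth = simulate_population(
        config, np.random.default_rng(pop_seed))
    rng = np.random.default_rng(trial_seed)
    ability = {(r.dog_id, r.timepoint): r.ability
               for r in truth.abilities.itertuples()}
    sr, ds, cyl = {}, {}, {}
    for row in sessions.itertuples():
        key = (row.dog_id, row.timepoint)
        a = ability[key]
        sr[key] = simulate_sr_trials(a, config, rng, *key)
        ds[key] = simulate_ds_trials(a, config, rng, *key)
        cyl[key] = simulate_cyl_trials(a, config, rng, *key)
    return {"dogs": dogs, "sessions": sessions, "truth": truth,
            "sr": sr, "ds": ds, "cyl": cyl}


def cohort_measures(cohort) -> pd.DataFrame:
    """Score a simulated cohort and attach session covariates.

    Returns the merged measures table expected by
    :class:`canid.composite.CanidScorer` (one row per dog x timepoint).
    """
    from .task_scoring import score_sessions
    measures = score_sessions(cohort["sr"], cohort["ds"], cohort["cyl"])
    df = measures.merge(cohort["sessions"], on=["dog_id", "timepoint"])
    return df.merge(cohort["dogs"][["dog_id", "sex"]], on="dog_id")
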