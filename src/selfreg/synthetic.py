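"""Synthetic cohort generator.

The real longitudinal cohort — roughly 550 preschoolers observed in a
censored delay-of-gratification task across 21 experimental conditions,
re-surveyed decades later — is confidential.  This module generates
cohorts with the same statistical skeleton so that every downstream
stage (wait-time modelling, index construction, the inference battery)
is testable end to end:

* one wait record per child, log-normal latent wait with condition-level
  random effects, censored at 900 s;
* a single latent self-regulation factor per child that leaks into the
  wait-time error (share ``latent_loading_wait``), into the personality
  item batteries at ages 17/27/37, and into the 11 mid-life
  capital-formation outcomes;
* a survey subsample (default 113 of 543) on which items and outcomes
  are observed, with missing-completely-at-random gaps per variable;
* condition-level "diagnostic" flags covering ~30% of participants.

`calibrate_effect_sizes` tunes the outcome loadings and the wait-time
latent share until the full analysis pipeline recovers target mean
correlations (index-battery and preschool-measure-battery), verified by
replicate simulation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .wait_model import TobitParams, fit_at_params

__all__ = [
    "CCQItemSpec",
    "OutcomeSpec",
    "CohortSpec",
    "SyntheticCohort",
    "CalibrationError",
    "default_spec",
    "generate_cohort",
    "calibrate_effect_sizes",
    "write_cohort",
    "read_cohort",
]

CCQ_AGES = (17, 27, 37)

#: Fixed default allocation of 543 children over 21 conditions
#: (per-condition sizes span 3 to 165, as in the original experiments;
#: the exact allocation is a modelling choice).
DEFAULT_CONDITION_SIZES = (
    3, 4, 5, 6, 8, 10, 12, 14, 16, 18,
    20, 22, 24, 26, 28, 30, 30, 32, 34, 36, 165,
)

# Per-outcome MCAR missingness chosen so survey-sample Ns land in the
# observed 103-113 range.
_DEFAULT_OUTCOMES = [
    # (name, reverse-scaled, missing rate)
    ("net_worth", False, 0.035),
    ("permanent_income", False, 0.009),
    ("wealth_income_ratio", False, 0.035),
    ("high_interest_debt", True, 0.035),
    ("credit_card_misuse", True, 0.0),
    ("delay_choice", False, 0.009),
    ("savings_rate", False, 0.062),
    ("financial_health", False, 0.0),
    ("education_years", False, 0.0),
    ("forward_looking", False, 0.0),
    ("social_status", False, 0.0),
]


class CalibrationError(RuntimeError):
    """Effect-size calibration could not reach the requested targets."""


@dataclass(frozen=True)
class CCQItemSpec:
    """Item battery at one age: every item loads ``loading`` on the
    latent factor (unit total variance); every ``reverse_every``-th item
    is reverse-keyed.  ``wave_missing`` drops whole participants at that
    age; ``item_missing`` blanks individual ratings."""

    age: int
    n_items: int
    loading: float = 0.4
    reverse_every: int = 5
    item_missing: float = 0.02
    wave_missing: float = 0.10

    def item_ids(self) -> list[str]:
        return [f"age{self.age}_item{j:02d}" for j in range(1, self.n_items + 1)]

    def item_signs(self) -> np.ndarray:
        signs = np.ones(self.n_items)
        if self.reverse_every:
            signs[self.reverse_every - 1 :: self.reverse_every] = -1.0
        return signs


@dataclass(frozen=True)
class OutcomeSpec:
    """One capital-formation outcome: correlation-scale loading on the
    latent factor, MCAR missingness, and whether the raw variable is
    recorded in the undesirable direction (reverse-scaled downstream)."""

    name: str
    loading: float
    missing_rate: float = 0.0
    reverse: bool = False


@dataclass(frozen=True)
class CohortSpec:
    """Full generating configuration for one synthetic cohort."""

    n_participants: int = 543
    n_conditions: int = 21
    condition_sizes: tuple[int, ...] | None = None
    tobit_params: TobitParams = TobitParams(2.289, 0.081, -0.673, 0.786, 2.469, 900.0)
    latent_loading_wait: float = 0.011
    item_specs: tuple[CCQItemSpec, ...] = (
        CCQItemSpec(17, 23),
        CCQItemSpec(27, 31),
        CCQItemSpec(37, 31),
    )
    outcome_specs: tuple[OutcomeSpec, ...] = tuple(
        OutcomeSpec(name, 0.21, rate, rev) for name, rev, rate in _DEFAULT_OUTCOMES
    )
    survey_n: int = 113
    n_diagnostic_conditions: int = 6
    diagnostic_share: float = 0.30
    diagnostic_loading_boost: float = 0.0
    age_mean: float = 52.1
    age_sd: float = 5.7
    age_range: tuple[float, float] = (24.0, 72.0)
    p_male: float = 0.48
    seed: int = 0

    def sizes(self) -> np.ndarray:
        if self.condition_sizes is not None:
            return np.asarray(self.condition_sizes, dtype=int)
        if (self.n_participants, self.n_conditions) == (543, 21):
            return np.asarray(DEFAULT_CONDITION_SIZES, dtype=int)
        # even split with remainder spread over the first conditions
        base, rem = divmod(self.n_participants, self.n_conditions)
        out = np.full(self.n_conditions, base, dtype=int)
        out[:rem] += 1
        return out

    def validate(self) -> None:
        sizes = self.sizes()
        if sizes.size != self.n_conditions:
            raise ValueError(
                f"{sizes.size} condition sizes given for {self.n_conditions} conditions"
            )
        if int(sizes.sum()) != self.n_participants:
            raise ValueError(
                f"condition sizes sum to {int(sizes.sum())}, expected {self.n_participants}"
            )
        if (sizes <= 0).any():
            raise ValueError("condition sizes must be positive")
        if not 0.0 <= self.latent_loading_wait <= 1.0:
            raise ValueError("latent_loading_wait must be in [0, 1]")
        for o in self.outcome_specs:
            if not 0.0 <= abs(o.loading) <= 1.0:
                raise ValueError(f"outcome loading out of [0,1]: {o}")
            if not 0.0 <= o.missing_rate < 1.0:
                raise ValueError(f"bad missing rate: {o}")
        for it in self.item_specs:
            if not 0.0 <= it.loading <= 1.0:
                raise ValueError(f"item loading out of [0,1]: {it}")
        if not 0 < self.survey_n <= self.n_participants:
            raise ValueError("survey_n must be in (0, n_participants]")


def default_spec(**overrides) -> CohortSpec:
    """The default study configuration (543 children, 21 conditions,
    published wait-model parameters, 113 surveyed)."""
    return dataclasses.replace(CohortSpec(), **overrides)


@dataclass
class SyntheticCohort:
    """One generated cohort (see module docstring for structure)."""

    spec: CohortSpec
    wait_records: pd.DataFrame        # one row per child
    latent: pd.Series                 # latent self-regulation factor, all children
    ccq_items: dict[int, pd.DataFrame]  # age -> participant x item ratings (survey)
    outcomes: pd.DataFrame            # participant x 11 raw outcomes (survey)
    diagnostic: pd.Series             # bool per participant (condition-level flag)
    survey: pd.Series                 # bool per participant

    @property
    def survey_ids(self) -> pd.Index:
        return self.survey.index[self.survey]


def _pick_diagnostic(sizes: np.ndarray, spec: CohortSpec, rng: np.random.Generator):
    """Random subset of `n_diagnostic_conditions` whose participant share
    is closest to the target (~30%); deterministic given the spec seed."""
    n_cond = sizes.size
    k = min(spec.n_diagnostic_conditions, n_cond)
    best, best_err = None, np.inf
    for _ in range(64):
        subset = rng.choice(n_cond, size=k, replace=False)
        share = sizes[subset].sum() / sizes.sum()
        err = abs(share - spec.diagnostic_share)
        if err < best_err:
            best, best_err = subset, err
    return np.isin(np.arange(n_cond), best)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate one synthetic cohort.  Byte-identical for a fixed spec."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    (rng_demo, rng_lat, rng_wait, rng_ccq, rng_out, rng_miss) = [
        np.random.default_rng(s) for s in ss.spawn(6)
    ]
    sizes = spec.sizes()
    n = spec.n_participants
    participants = pd.Index([f"p{i:04d}" for i in range(1, n + 1)], name="participant")
    condition_ids = [f"c{g:02d}" for g in range(1, spec.n_conditions + 1)]
    cond_of = np.repeat(np.arange(spec.n_conditions), sizes)

    lo, hi = spec.age_range
    a, b = (lo - spec.age_mean) / spec.age_sd, (hi - spec.age_mean) / spec.age_sd
    ages = stats.truncnorm.rvs(a, b, loc=spec.age_mean, scale=spec.age_sd,
                               size=n, random_state=rng_demo)
    male = rng_demo.binomial(1, spec.p_male, size=n)

    latent = rng_lat.standard_normal(n)

    diag_cond = _pick_diagnostic(sizes, spec, rng_demo)
    diagnostic = diag_cond[cond_of]

    # latent wait share, optionally inflated in diagnostic conditions
    # (total individual error variance held at sigma_eps^2)
    w = np.full(n, spec.latent_loading_wait)
    if spec.diagnostic_loading_boost:
        w = np.where(diagnostic,
                     np.clip(w + spec.diagnostic_loading_boost, 0.0, 1.0), w)
    p = spec.tobit_params
    eta = rng_wait.normal(0.0, p.sigma_eta, size=spec.n_conditions)
    eps = p.sigma_eps * (np.sqrt(w) * latent
                         + np.sqrt(1.0 - w) * rng_wait.standard_normal(n))
    y_star = p.fixed_part(ages, male) + eta[cond_of] + eps
    log_c = np.log(p.censor_seconds)
    censored = y_star >= log_c
    wait = np.where(censored, p.censor_seconds, np.clip(np.exp(y_star), 1.0, None))

    wait_records = pd.DataFrame(
        {
            "participant": participants,
            "condition": np.asarray(condition_ids)[cond_of],
            "age_months": np.round(ages, 1),
            "male": male,
            "wait_seconds": np.round(wait, 2),
            "censored": censored,
        }
    )

    survey_idx = np.sort(rng_miss.choice(n, size=spec.survey_n, replace=False))
    survey = pd.Series(np.isin(np.arange(n), survey_idx), index=participants, name="survey")
    sid = participants[survey_idx]
    f_svy = latent[survey_idx]
    m = spec.survey_n

    ccq_items: dict[int, pd.DataFrame] = {}
    for ispec in spec.item_specs:
        lam, signs = ispec.loading, ispec.item_signs()
        noise = rng_ccq.standard_normal((m, ispec.n_items))
        ratings = signs * (lam * f_svy[:, None] + np.sqrt(1 - lam**2) * noise)
        frame = pd.DataFrame(ratings, index=sid, columns=ispec.item_ids())
        gone = rng_miss.uniform(size=m) < ispec.wave_missing
        frame.iloc[gone] = np.nan
        blank = rng_miss.uniform(size=(m, ispec.n_items)) < ispec.item_missing
        frame = frame.mask(blank)
        ccq_items[ispec.age] = frame

    cols = {}
    for ospec in spec.outcome_specs:
        lam = ospec.loading
        raw = lam * f_svy + np.sqrt(1 - lam**2) * rng_out.standard_normal(m)
        if ospec.reverse:
            raw = -raw  # recorded in the undesirable direction
        raw[rng_miss.uniform(size=m) < ospec.missing_rate] = np.nan
        cols[ospec.name] = raw
    outcomes = pd.DataFrame(cols, index=sid)

    return SyntheticCohort(
        spec=spec,
        wait_records=wait_records,
        latent=pd.Series(latent, index=participants, name="latent"),
        ccq_items=ccq_items,
        outcomes=outcomes,
        diagnostic=pd.Series(diagnostic, index=participants, name="diagnostic"),
        survey=survey,
    )


# --------------------------------------------------------------------------
# calibration

def _pipeline_mean_correlations(spec: CohortSpec, n_reps: int, seed: int,
                                n_draws: int = 2_000) -> tuple[float, float]:
    """Replicate-mean battery correlations (index predictor, preschool
    predictor) with the wait model evaluated at the generating truth
    (no refit): the fast surrogate used inside calibration."""
    from . import indices
    from .inference import run_battery
    from .wait_model import compute_rnd

    r_index, r_rnd = [], []
    for rep in range(n_reps):
        rep_spec = dataclasses.replace(spec, seed=seed + rep)
        cohort = generate_cohort(rep_spec)
        fit = fit_at_params(cohort.wait_records, spec.tobit_params)
        rnd = compute_rnd(cohort.wait_records, fit, seed=seed + rep, n_draws=n_draws)
        scores = indices.build_analysis_table(cohort, rnd)
        for pred, acc in (("rnsri", r_index), ("rnd", r_rnd)):
            assocs = run_battery(scores.outcomes, scores.scores[pred],
                                 scores.sex, extra_controls=scores.extra_controls)
            acc.append(np.mean([a.coef for a in assocs]))
    return float(np.mean(r_index)), float(np.mean(r_rnd))


def calibrate_effect_sizes(
    target_mean_r_index: float,
    target_mean_r_rnd: float,
    spec: CohortSpec | None = None,
    n_reps_search: int = 60,
    n_reps_verify: int = 200,
    tol: float = 0.02,
    max_iter: int = 6,
    seed: int = 20_000,
) -> CohortSpec:
    """Tune outcome loadings and the wait-time latent share so the full
    pipeline recovers the target mean correlations.

    Iteratively rescales (i) the common outcome loading toward the
    index-battery target and (ii) the latent share of the wait-time
    error toward the preschool-measure target, measuring each candidate
    by replicate simulation; the final spec is verified on
    ``n_reps_verify`` fresh replicates to within ``tol`` of both targets.

    Raises
    ------
    CalibrationError
        If the targets are infeasible (|target| too close to 1, or the
        verification fails).
    """
    for t in (target_mean_r_index, target_mean_r_rnd):
        if not -1.0 < t < 1.0:
            raise ValueError(f"target correlation {t} outside (-1, 1)")
    spec = spec or CohortSpec()
    if target_mean_r_index == 0.0 and target_mean_r_rnd == 0.0:
        return _with_loadings(spec, 0.0, 0.0)
    if abs(target_mean_r_index) > 0.6 or abs(target_mean_r_rnd) > 0.6:
        # the index-factor and outcome-factor correlations multiply; with
        # unit-variance outcome noise the battery mean cannot reach this
        raise CalibrationError(
            f"targets ({target_mean_r_index}, {target_mean_r_rnd}) infeasible "
            "given the generator's noise structure"
        )

    lam = max(abs(target_mean_r_index), 0.02)
    w = float(np.clip((target_mean_r_rnd / max(lam, 0.05)) ** 2, 0.0, 0.4))
    for it in range(max_iter):
        cand = _with_loadings(spec, lam, w)
        est_idx, est_rnd = _pipeline_mean_correlations(
            cand, n_reps_search, seed=seed + 1000 * it
        )
        ok_idx = abs(est_idx - target_mean_r_index) <= tol / 2
        ok_rnd = abs(est_rnd - target_mean_r_rnd) <= tol / 2
        if ok_idx and ok_rnd:
            break
        if not ok_idx:
            ratio = target_mean_r_index / est_idx if abs(est_idx) > 1e-3 else 2.0
            lam = float(np.clip(lam * np.clip(ratio, 0.3, 3.0), 0.0, 0.9))
        if not ok_rnd:
            if target_mean_r_rnd == 0.0:
                w = 0.0
            elif est_rnd > 1e-3 and w > 0:
                w = float(np.clip(w * np.clip((target_mean_r_rnd / est_rnd) ** 2,
                                              0.1, 10.0), 0.0, 0.6))
            else:
                w = min(w + 0.01, 0.6)
    cand = _with_loadings(spec, lam, w)
    est_idx, est_rnd = _pipeline_mean_correlations(cand, n_reps_verify, seed=seed + 77_000)
    if abs(est_idx - target_mean_r_index) > tol or abs(est_rnd - target_mean_r_rnd) > tol:
        raise CalibrationError(
            f"verification failed: achieved ({est_idx:.3f}, {est_rnd:.3f}) vs "
            f"targets ({target_mean_r_index}, {target_mean_r_rnd}) at tol {tol}"
        )
    return cand


def _with_loadings(spec: CohortSpec, lam: float, w: float) -> CohortSpec:
    outs = tuple(dataclasses.replace(o, loading=lam) for o in spec.outcome_specs)
    return dataclasses.replace(spec, outcome_specs=outs, latent_loading_wait=w)


# --------------------------------------------------------------------------
# on-disk schema (delimited text + JSON metadata)

SCHEMA_VERSION = "1"


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as delimited text: wait records, item ratings in
    long format (participant, age, item, rating), outcomes in wide
    format, and a JSON metadata file echoing the generating spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "wait_records": out / "wait_records.csv",
        "ccq_items": out / "ccq_items.csv",
        "outcomes": out / "outcomes.csv",
        "participants": out / "participants.csv",
        "metadata": out / "cohort_metadata.json",
    }
    cohort.wait_records.to_csv(paths["wait_records"], index=False)
    long = []
    for age, frame in cohort.ccq_items.items():
        stacked = frame.stack().rename("rating").reset_index()
        stacked.columns = ["participant", "item", "rating"]
        stacked.insert(1, "age", age)
        long.append(stacked)
    pd.concat(long, ignore_index=True).to_csv(paths["ccq_items"], index=False)
    cohort.outcomes.to_csv(paths["outcomes"], index_label="participant")
    pd.DataFrame(
        {"diagnostic": cohort.diagnostic, "survey": cohort.survey}
    ).to_csv(paths["participants"], index_label="participant")
    meta = {"schema_version": SCHEMA_VERSION, "spec": _spec_to_dict(cohort.spec)}
    paths["metadata"].write_text(json.dumps(meta, indent=2))
    return paths


def read_cohort(out_dir: str | Path) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    out = Path(out_dir)
    meta = json.loads((out / "cohort_metadata.json").read_text())
    spec = _spec_from_dict(meta["spec"])
    wait = pd.read_csv(out / "wait_records.csv")
    wait["censored"] = wait["censored"].astype(bool)
    part = pd.read_csv(out / "participants.csv", index_col="participant")
    long = pd.read_csv(out / "ccq_items.csv")
    ccq = {
        int(age): grp.pivot(index="participant", columns="item", values="rating")
        for age, grp in long.groupby("age")
    }
    outcomes = pd.read_csv(out / "outcomes.csv", index_col="participant")
    latent = pd.Series(np.nan, index=part.index, name="latent")  # not persisted
    return SyntheticCohort(
        spec=spec, wait_records=wait, latent=latent, ccq_items=ccq,
        outcomes=outcomes, diagnostic=part["diagnostic"].astype(bool),
        survey=part["survey"].astype(bool),
    )


def _spec_to_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    return d


def _spec_from_dict(d: dict) -> CohortSpec:
    d = dict(d)
    d["tobit_params"] = TobitParams(**d["tobit_params"])
    d["item_specs"] = tuple(CCQItemSpec(**x) for x in d["item_specs"])
    d["outcome_specs"] = tuple(OutcomeSpec(**x) for x in d["outcome_specs"])
    for key in ("condition_sizes", "age_range"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    return CohortSpec(**d)
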