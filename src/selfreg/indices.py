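"""Construction of capital-formation outcomes and the self-regulation
indices.

Outcome side: the 11 mid-life capital-formation measures (net worth,
permanent income, wealth-income ratio, high interest-rate debt,
credit-card misuse, delay choice, savings rate, financial health, years
of education, forward-looking behaviors, social status) are each
rank-normalized; the two debt-related measures are reverse-scaled first
so larger always means better.  Multi-component outcomes are
equal-weighted means of rank-normalized components.

Predictor side: the personality item battery (CCQ) at each of ages 17,
27 and 37 is scored into six subscales (delay of gratification, general
cognitive ability, attention, coping, goal pursuit, concern for
others), each the equal-weighted mean of its sign-keyed items, then
rank-normalized; the six subscale scores are averaged and
rank-normalized into an age-level score (RNCCQ).  The composite
self-regulatory index (RNSRI) is the rank-normalized equal-weighted
mean of the preschool delay score (RND) and the three RNCCQ scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transforms import DegenerateInputError, rank_inverse_normal, reverse_scale

__all__ = [
    "SubscaleDef",
    "RNSRIScores",
    "AnalysisTable",
    "default_subscale_defs",
    "high_interest_debt",
    "permanent_income",
    "equal_weight_index",
    "score_ccq",
    "compute_rnsri",
    "build_outcome_scores",
    "capital_formation_index",
    "build_analysis_table",
]

SUBSCALE_NAMES = (
    "delay_of_gratification",
    "general_cognitive_ability",
    "attention",
    "coping",
    "goal_pursuit",
    "concern_for_others",
)


@dataclass(frozen=True)
class SubscaleDef:
    """One CCQ subscale: its items and each item's key direction (+1/-1)."""

    name: str
    items: tuple[str, ...]
    signs: tuple[int, ...]

    def __post_init__(self):
        if len(self.items) != len(self.signs):
            raise ValueError(f"subscale {self.name}: items/signs length mismatch")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError(f"subscale {self.name}: signs must be +/-1")


def default_subscale_defs(age: int, n_items: int, reverse_every: int = 5) -> list[SubscaleDef]:
    """Default partition of an age's items into the six subscales:
    3 items each for delay of gratification and general cognitive
    ability, the remainder split evenly over the four oblique factors.
    Item ids and reverse-keying follow the synthetic generator's
    conventions (every ``reverse_every``-th item negatively keyed)."""
    ids = [f"age{age}_item{j:02d}" for j in range(1, n_items + 1)]
    signs = {iid: 1 for iid in ids}
    if reverse_every:
        for iid in ids[reverse_every - 1 :: reverse_every]:
            signs[iid] = -1
    rest = n_items - 6
    if rest < 4:
        raise ValueError("need at least 10 items for six subscales")
    quarters = [rest // 4 + (1 if k < rest % 4 else 0) for k in range(4)]
    sizes = [3, 3] + quarters
    defs, pos = [], 0
    for name, size in zip(SUBSCALE_NAMES, sizes):
        items = tuple(ids[pos : pos + size])
        defs.append(SubscaleDef(name, items, tuple(signs[i] for i in items)))
        pos += size
    return defs


def high_interest_debt(debt_amounts, rate_bucket_midpoints, threshold: float = 0.06) -> float:
    """Annual interest paid above the threshold rate: for each debt
    category, amount times max(rate − threshold, 0), summed.  Rates are
    category-bucket midpoints expressed as fractions."""
    amounts = np.asarray(debt_amounts, dtype=float)
    rates = np.asarray(rate_bucket_midpoints, dtype=float)
    if amounts.shape != rates.shape:
        raise ValueError("debt amounts and rate midpoints must align")
    if (amounts < 0).any():
        raise ValueError("debt amounts must be non-negative")
    if (rates < 0).any():
        raise ValueError("rate midpoints must be non-negative")
    return float(np.sum(amounts * np.clip(rates - threshold, 0.0, None)))


def permanent_income(income_a, income_b, n_adults, inflation_factor_a=1.0) -> pd.Series:
    """Average of two years of household income (the earlier one already
    inflation-adjusted by the supplied factor) divided by the number of
    adults in the household."""
    inc = (np.asarray(income_a, dtype=float) * inflation_factor_a
           + np.asarray(income_b, dtype=float)) / 2.0
    adults = np.asarray(n_adults, dtype=float)
    if (adults <= 0).any():
        raise ValueError("number of adults must be positive")
    out = inc / adults
    index = income_a.index if isinstance(income_a, pd.Series) else None
    return pd.Series(out, index=index, name="permanent_income")


def equal_weight_index(
    components: list[pd.Series],
    min_present: int = 1,
    rank_components: bool = True,
) -> pd.Series:
    """Equal-weighted mean of (rank-normalized) components, re-rank-
    normalized.

    A participant's index is the mean over their observed components,
    provided at least ``min_present`` are observed; otherwise missing.
    ``rank_components=False`` skips the per-component normalization for
    components already on the rank-normal scale.
    """
    if not components:
        raise ValueError("need at least one component")
    idx = components[0].index
    for c in components[1:]:
        idx = idx.union(c.index)
    mat = pd.DataFrame({i: c.reindex(idx) for i, c in enumerate(components)})
    if mat.notna().sum().sum() == 0:
        raise DegenerateInputError("all components missing for all participants")
    if rank_components:
        mat = mat.apply(rank_inverse_normal)
    mean = mat.mean(axis=1)
    mean[mat.notna().sum(axis=1) < min_present] = np.nan
    return rank_inverse_normal(mean)


def score_ccq(
    ratings: pd.DataFrame,
    defs: list[SubscaleDef],
    min_item_frac: float = 0.5,
    min_subscales: int = 3,
) -> pd.Series:
    """Score one age's item battery into a rank-normalized composite.

    Per subscale: sign-keyed item mean over observed items (requires at
    least ``min_item_frac`` of the subscale's items), rank-normalized.
    Composite: mean of the six subscale scores (requires at least
    ``min_subscales`` observed), rank-normalized.
    """
    known = set(ratings.columns)
    subscales = {}
    for d in defs:
        missing_items = [i for i in d.items if i not in known]
        if missing_items:
            raise KeyError(f"subscale {d.name} references unknown items {missing_items}")
        keyed = ratings[list(d.items)] * np.asarray(d.signs, dtype=float)
        need = math.ceil(min_item_frac * len(d.items))
        mean = keyed.mean(axis=1)
        mean[keyed.notna().sum(axis=1) < need] = np.nan
        subscales[d.name] = rank_inverse_normal(mean)
    sub = pd.DataFrame(subscales)
    composite = sub.mean(axis=1)
    composite[sub.notna().sum(axis=1) < min_subscales] = np.nan
    return rank_inverse_normal(composite).rename("rnccq")


@dataclass
class RNSRIScores:
    """Age-level CCQ scores and the composite self-regulatory index."""

    rnccq_17: pd.Series
    rnccq_27: pd.Series
    rnccq_37: pd.Series
    rnsri: pd.Series


def compute_rnsri(
    rnd: pd.Series,
    rnccq_17: pd.Series,
    rnccq_27: pd.Series,
    rnccq_37: pd.Series,
    min_present: int = 3,
) -> RNSRIScores:
    """Equal-weighted mean of RND and the three age-level CCQ scores,
    rank-normalized.  Defined over participants with CCQ data (the
    survey sample); a participant needs at least ``min_present`` of the
    four components observed."""
    idx = rnccq_17.index.union(rnccq_27.index).union(rnccq_37.index)
    comp = pd.DataFrame(
        {
            "rnd": rnd.reindex(idx),
            "c17": rnccq_17.reindex(idx),
            "c27": rnccq_27.reindex(idx),
            "c37": rnccq_37.reindex(idx),
        }
    )
    mean = comp.mean(axis=1)
    mean[comp.notna().sum(axis=1) < min_present] = np.nan
    rnsri = rank_inverse_normal(mean).rename("rnsri")
    return RNSRIScores(
        rnccq_17=rnccq_17, rnccq_27=rnccq_27, rnccq_37=rnccq_37, rnsri=rnsri
    )


def build_outcome_scores(
    outcomes: pd.DataFrame, reverse_scaled: list[str]
) -> pd.DataFrame:
    """Rank-normalize every outcome column, reverse-scaling the listed
    columns first so larger always means better."""
    out = {}
    for name in outcomes.columns:
        col = outcomes[name]
        if name in reverse_scaled:
            col = reverse_scale(col)
        out[name] = rank_inverse_normal(col)
    return pd.DataFrame(out, index=outcomes.index)


def capital_formation_index(outcome_scores: pd.DataFrame) -> pd.Series:
    """Single capital-formation index: mean of the 11 rank-normalized
    outcomes over participants with no missing outcome, rank-normalized
    (complete-case by construction)."""
    cols = [outcome_scores[c] for c in outcome_scores.columns]
    return equal_weight_index(cols, min_present=len(cols), rank_components=False)


@dataclass
class AnalysisTable:
    """Analysis-ready bundle: rank-normalized outcomes, predictor
    scores, sex, and per-outcome extra controls."""

    outcomes: pd.DataFrame
    scores: dict[str, pd.Series]
    sex: pd.Series
    extra_controls: dict[str, dict[str, pd.Series]] = field(default_factory=dict)


def build_analysis_table(cohort, rnd_scores, subscale_defs=None) -> AnalysisTable:
    """Assemble the analysis table for a synthetic cohort: score each
    age's CCQ battery, build RNSRI, rank-normalize outcomes (reverse-
    scaling the flagged ones), and attach the savings-rate regression's
    permanent-income control."""
    reverse = [o.name for o in cohort.spec.outcome_specs if o.reverse]
    outcome_scores = build_outcome_scores(cohort.outcomes, reverse)
    ccq = {}
    for ispec in cohort.spec.item_specs:
        defs = (subscale_defs or {}).get(ispec.age) if subscale_defs else None
        if defs is None:
            defs = default_subscale_defs(ispec.age, ispec.n_items, ispec.reverse_every)
        ccq[ispec.age] = score_ccq(cohort.ccq_items[ispec.age], defs)
    rnsri = compute_rnsri(rnd_scores.rnd, ccq[17], ccq[27], ccq[37])
    sex = cohort.wait_records.set_index("participant")["male"].astype(float)
    extra = {}
    if {"savings_rate", "permanent_income"} <= set(outcome_scores.columns):
        extra["savings_rate"] = {"permanent_income": outcome_scores["permanent_income"]}
    scores = {
        "rnd": rnd_scores.rnd,
        "rnccq_17": rnsri.rnccq_17,
        "rnccq_27": rnsri.rnccq_27,
        "rnccq_37": rnsri.rnccq_37,
        "rnsri": rnsri.rnsri,
    }
    return AnalysisTable(
        outcomes=outcome_scores, scores=scores, sex=sex, extra_controls=extra
    )
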