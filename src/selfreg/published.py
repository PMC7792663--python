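"""Published Bing-cohort reference estimates.

The original longitudinal cohort (Stanford Bing preschool delay-of-
gratification studies, mid-life follow-up survey) is confidential, but
the study's printed summary tables are public and serve two roles here:

1. as default generating parameters for the synthetic cohort (the wait-
   time model estimates), and
2. as direct inputs to the deterministic parts of the inference battery
   (coefficient averaging, false-discovery-rate reconstruction, Bayesian
   shrinkage), which operate on printed coefficient/SE pairs.

Outcome columns follow the study's fixed ordering of the 11 mid-life
capital-formation measures.
"""

from __future__ import annotations

import pandas as pd

from .wait_model import TobitParams

__all__ = [
    "OUTCOME_NAMES",
    "REVERSE_SCALED",
    "WAIT_MODEL_ESTIMATES",
    "WAIT_MODEL_SE",
    "rnsri_associations",
    "rnd_associations",
    "RNSRI_PRIOR",
    "RND_PRIOR",
]

#: The 11 capital-formation outcomes, in table order.
OUTCOME_NAMES = [
    "net_worth",
    "permanent_income",
    "wealth_income_ratio",
    "high_interest_debt",
    "credit_card_misuse",
    "delay_choice",
    "savings_rate",
    "financial_health",
    "education_years",
    "forward_looking",
    "social_status",
]

#: Outcomes recorded in the undesirable direction and reverse-scaled
#: before rank-normalization.
REVERSE_SCALED = ["high_interest_debt", "credit_card_misuse"]

#: Maximum-likelihood estimates of the random-effects tobit model of log
#: preschool wait time (543 children, 21 experimental conditions,
#: censoring at 900 s).
WAIT_MODEL_ESTIMATES = TobitParams(
    alpha=2.289,
    beta_age=0.081,
    beta_male=-0.673,
    sigma_eta=0.786,
    sigma_eps=2.469,
    censor_seconds=900.0,
)

#: Reported standard errors for the wait-model parameters.
WAIT_MODEL_SE = {
    "alpha": 1.071,
    "beta_age": 0.020,
    "beta_male": 0.227,
    "sigma_eta": 0.218,
    "sigma_eps": 0.101,
}

_RNSRI_COEF = [0.31, 0.32, 0.09, 0.09, 0.18, 0.16, -0.01, 0.24, 0.24, 0.35, 0.14]
_RNSRI_SE = [0.10, 0.09, 0.10, 0.08, 0.08, 0.09, 0.09, 0.09, 0.09, 0.09, 0.09]
_RNSRI_N = [106, 109, 106, 106, 110, 109, 103, 110, 110, 110, 110]

_RND_COEF = [0.09, -0.08, 0.15, -0.01, 0.04, 0.09, -0.06, -0.07, 0.13, 0.09, -0.13]
_RND_SE = [0.10, 0.10, 0.10, 0.08, 0.08, 0.09, 0.09, 0.09, 0.09, 0.09, 0.09]
_RND_N = [109, 112, 109, 109, 113, 112, 106, 113, 113, 113, 113]

#: Pre-registered priors for the per-outcome standardized coefficients.
RNSRI_PRIOR = (0.15, 0.2)
RND_PRIOR = (0.05, 0.2)


def _assoc_frame(coefs, ses, ns) -> pd.DataFrame:
    # Each regression controls for sex; savings-rate additionally controls
    # for permanent income, hence one extra regressor for that outcome.
    k = [4 if name == "savings_rate" else 3 for name in OUTCOME_NAMES]
    return pd.DataFrame(
        {"coef": coefs, "se": ses, "n": ns, "n_regressors": k},
        index=pd.Index(OUTCOME_NAMES, name="outcome"),
    )


def rnsri_associations() -> pd.DataFrame:
    """Published per-outcome OLS coefficients of each rank-normalized
    outcome on the composite self-regulation index (RNSRI), sex-controlled."""
    return _assoc_frame(_RNSRI_COEF, _RNSRI_SE, _RNSRI_N)


def rnd_associations() -> pd.DataFrame:
    """Published per-outcome OLS coefficients on the preschool
    rank-normalized delay measure (RND), sex-controlled."""
    return _assoc_frame(_RND_COEF, _RND_SE, _RND_N)
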