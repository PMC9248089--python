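"""Reference parameter values used as simulator defaults.

The defaults describe a CHARLS-like cohort of Chinese adults aged 60+
observed at three survey waves two years apart (4051 subjects): the
baseline mix over the four living states, per-year transition
intensities of realistic magnitude for this population, one-year
transition probabilities implied by those intensities, and marginal
prevalences of the baseline covariates.  They are the study conditions
every simulation-based test runs under; they are not tuning knobs.
"""

from __future__ import annotations

#: Per-year transition intensities for the 12 allowed transitions.
REFERENCE_INTENSITIES: dict[tuple[int, int], float] = {
    (1, 2): 0.036,  # NS -> CI
    (1, 3): 0.374,  # NS -> PF
    (1, 5): 0.008,  # NS -> Death
    (2, 1): 0.300,  # CI -> NS
    (2, 4): 0.756,  # CI -> CF
    (2, 5): 0.005,  # CI -> Death
    (3, 1): 0.325,  # PF -> NS
    (3, 4): 0.086,  # PF -> CF
    (3, 5): 0.030,  # PF -> Death
    (4, 2): 0.254,  # CF -> CI
    (4, 3): 0.333,  # CF -> PF
    (4, 5): 0.051,  # CF -> Death
}

#: One-year transition probabilities implied by REFERENCE_INTENSITIES
#: (matrix exponential at u=1, rounded to 3 decimals), including the
#: indirect two-step routes through the structural zeros.
REFERENCE_ONE_YEAR_PROBS: dict[tuple[int, int], float] = {
    (1, 1): 0.702, (1, 2): 0.019, (1, 3): 0.251, (1, 4): 0.017, (1, 5): 0.011,
    (2, 1): 0.161, (2, 2): 0.388, (2, 3): 0.095, (2, 4): 0.340, (2, 5): 0.017,
    (3, 1): 0.218, (3, 2): 0.009, (3, 3): 0.692, (3, 4): 0.054, (3, 5): 0.027,
    (4, 1): 0.053, (4, 2): 0.114, (4, 3): 0.208, (4, 4): 0.582, (4, 5): 0.043,
}

#: Baseline counts over the living states for the default cohort of 4051.
REFERENCE_BASELINE_COUNTS: dict[int, int] = {1: 1441, 2: 142, 3: 2001, 4: 467}

#: Marginal prevalences of the binary baseline covariates.
REFERENCE_COVARIATE_PREVALENCE: dict[str, float] = {
    "female": 0.4537,
    "literacy": 0.7137,       # 1 - illiteracy prevalence 28.63%
    "rural": 0.7610,
    "dissatisfied": 0.1321,
    "injury": 0.0985,
    "falls": 0.1804,
    "depression": 0.3930,
    "multimorbidity": 0.4628,
}

#: Marginal distribution of nightly sleep duration categories.
REFERENCE_SLEEP_PROBS: dict[str, float] = {
    "short": 0.0397,
    "intermediate": 0.7660,
    "long": 0.1943,
}

#: Marginal distribution over ten-year age bands at baseline.  Band
#: shares are chosen to match a cohort aged 60+ with mean age ~67 and
#: SD ~6 years.
REFERENCE_AGE_BAND_PROBS: dict[str, float] = {
    "60-69": 0.70,
    "70-79": 0.24,
    "80+": 0.06,
}
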