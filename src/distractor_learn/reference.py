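"""Published group-level parameter estimates used as simulation inputs.

These are the reported hierarchical group estimates for the categorical
suppression model (Model 3) fitted to the constant-probability
additional-singleton experiment: GLM coefficients in seconds, the global
decay rate in natural (per-present-trial) units, and hierarchical spread
taken as the half-width of the reported interval for each estimate. Raw
space: rates live on the log scale, betas are identity.
"""

from __future__ import annotations

import numpy as np

from .simulate import GroupSpec

# natural-space group estimates (interval half-widths in parentheses):
# distractor prediction -0.040 (0.013); global decay beta 0.092 (0.012);
# decay rate 0.015 (interval 0.010-0.020); previous-trial-absent -0.006
# (0.0105); intercept 0.895 (0.062)
MODEL3_GROUP_NATURAL = {
    "b_global": 0.015,
    "beta_intercept": 0.895,
    "beta_global_decay": 0.092,
    "beta_categorical": -0.040,
    "beta_prev_absent": -0.006,
}

# raw order for Model 3: b_global, beta_intercept, beta_global_decay,
# beta_categorical, beta_prev_absent
MODEL3_GROUP_MEAN_RAW = np.array(
    [np.log(0.015), 0.895, 0.092, -0.040, -0.006])
# rate spread on the log scale spans the reported interval (0.010, 0.020)
MODEL3_GROUP_SD_RAW = np.array(
    [(np.log(0.020) - np.log(0.010)) / 2.0, 0.062, 0.012, 0.013, 0.0105])

N_SUBJECTS_EXP1 = 17
LOW_NOISE_SD_MS = 50.0


def exp1_categorical_group_spec(n_subjects: int = N_SUBJECTS_EXP1) -> GroupSpec:
    """Group spec for simulating categorical-model subjects with the
    published constant-probability group estimates."""
    return GroupSpec(model_id=3,
                     group_mean=MODEL3_GROUP_MEAN_RAW.copy(),
                     group_sd=MODEL3_GROUP_SD_RAW.copy(),
                     n_subjects=n_subjects)
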