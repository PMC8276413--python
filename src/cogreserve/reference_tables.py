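"""Published step-1 model statistics for the two source cohorts.

These are the step-1 (age + sex + brain structure) summary statistics —
complete-case n, R-squared to three decimals, and overall model F — reported
for each of the fifteen brain-cognition models in the TILDA and CR/RANN
cohorts. The raw cohort data are access-restricted, so these printed values
serve two purposes here: they document the magnitude of fit the pipeline's
step-1 models are meant to resemble, and they let a consistency check verify
that the reported "f" statistic is the overall model F recomputed from
(R-squared, n, k = 3 predictors) within the rounding interval of the printed
R-squared.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["STEP1_REFERENCE", "step1_reference_frame", "model_f_from_r2"]

# (dataset, brain, cognition, n, r2, f)
STEP1_REFERENCE = [
    ("tilda", "grey_matter_volume", "verbal_fluency", 313, 0.043, 4.597),
    ("tilda", "grey_matter_volume", "processing_speed", 313, 0.129, 15.320),
    ("tilda", "grey_matter_volume", "executive_function", 311, 0.143, 17.070),
    ("tilda", "grey_matter_volume", "episodic_memory", 313, 0.079, 8.780),
    ("tilda", "grey_matter_volume", "global_cognition", 311, 0.159, 19.400),
    ("tilda", "hippocampal_volume", "verbal_fluency", 313, 0.042, 4.475),
    ("tilda", "hippocampal_volume", "processing_speed", 313, 0.129, 15.226),
    ("tilda", "hippocampal_volume", "executive_function", 311, 0.143, 17.010),
    ("tilda", "hippocampal_volume", "episodic_memory", 313, 0.080, 8.902),
    ("tilda", "hippocampal_volume", "global_cognition", 311, 0.158, 19.171),
    ("tilda", "cortical_thickness", "verbal_fluency", 279, 0.051, 4.898),
    ("tilda", "cortical_thickness", "processing_speed", 279, 0.173, 19.217),
    ("tilda", "cortical_thickness", "executive_function", 277, 0.195, 22.040),
    ("tilda", "cortical_thickness", "episodic_memory", 279, 0.091, 9.202),
    ("tilda", "cortical_thickness", "global_cognition", 277, 0.195, 22.105),
    ("crrann", "grey_matter_volume", "verbal_fluency", 234, 0.087, 7.320),
    ("crrann", "grey_matter_volume", "processing_speed", 234, 0.087, 7.344),
    ("crrann", "grey_matter_volume", "executive_function", 234, 0.047, 3.762),
    ("crrann", "grey_matter_volume", "episodic_memory", 234, 0.061, 4.998),
    ("crrann", "grey_matter_volume", "global_cognition", 234, 0.130, 11.498),
    ("crrann", "hippocampal_volume", "verbal_fluency", 234, 0.043, 3.449),
    ("crrann", "hippocampal_volume", "processing_speed", 234, 0.061, 5.014),
    ("crrann", "hippocampal_volume", "executive_function", 234, 0.030, 2.339),
    ("crrann", "hippocampal_volume", "episodic_memory", 234, 0.033, 2.608),
    ("crrann", "hippocampal_volume", "global_cognition", 234, 0.069, 5.671),
    ("crrann", "cortical_thickness", "verbal_fluency", 234, 0.065, 5.303),
    ("crrann", "cortical_thickness", "processing_speed", 234, 0.073, 6.063),
    ("crrann", "cortical_thickness", "executive_function", 234, 0.048, 3.834),
    ("crrann", "cortical_thickness", "episodic_memory", 234, 0.053, 4.281),
    ("crrann", "cortical_thickness", "global_cognition", 234, 0.109, 9.401),
]


def step1_reference_frame() -> pd.DataFrame:
    return pd.DataFrame(
        STEP1_REFERENCE,
        columns=["dataset", "brain", "cognition", "n", "r2", "f"],
    )


def model_f_from_r2(r2: float, n: int, k: int = 3) -> float:
    """Overall model F implied by R-squared with k predictors and n cases."""
    return (r2 / k) / ((1.0 - r2) / (n - k - 1))
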