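"""Synthetic clinical cohorts with the study's covariate structure.

Generates tables of (triglycerides, waist circumference, HDL,
blood-pressure status) records: continuous covariates are Gaussian, the
three-level blood-pressure code is categorical, and the response is a
linear function of the dummy-encoded covariates plus Gaussian noise.
Default effect sizes are of the magnitude a lipid-panel regression
reports, so downstream fits produce clinically plausible numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TRIGLYCERIDE_SPEC, ConfigurationError, ObservationTable

__all__ = ["GeneratorConfig", "generate"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generation parameters.

    ``coefficients`` is (intercept, waist, hdl, border, hyper) on the
    response (mg/dL) scale; ``bp_probs`` the category probabilities of
    (normal, borderline, high) blood pressure; ``noise_sd`` the SD of the
    additive Gaussian noise in mg/dL.
    """

    n: int = 14
    waist_mean: float = 92.0
    waist_sd: float = 10.0
    hdl_mean: float = 50.0
    hdl_sd: float = 12.0
    bp_probs: tuple[float, float, float] = (0.5, 0.25, 0.25)
    coefficients: tuple[float, float, float, float, float] = (
        79.43, 0.3349, 0.5786, 8.557, 19.935,
    )
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        p = np.asarray(self.bp_probs, dtype=float)
        if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError("bp_probs must be 3 non-negative values summing to 1")
        if len(self.coefficients) != 5:
            raise ConfigurationError("coefficients must have 5 entries")


def generate(config: GeneratorConfig) -> ObservationTable:
    """Draw a cohort; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    waist = rng.normal(config.waist_mean, config.waist_sd, size=config.n)
    hdl = rng.normal(config.hdl_mean, config.hdl_sd, size=config.n)
    bp = rng.choice(3, size=config.n, p=np.asarray(config.bp_probs, dtype=float))

    b0, b_waist, b_hdl, b_border, b_hyper = config.coefficients
    mean = b0 + b_waist * waist + b_hdl * hdl + b_border * (bp == 1) + b_hyper * (bp == 2)
    trig = mean + rng.normal(0.0, config.noise_sd, size=config.n) if config.noise_sd > 0 else mean

    df = pd.DataFrame(
        {"Trig": trig, "Waist": waist, "HDL": hdl, "BloodPressure": bp.astype(int)}
    )
    return ObservationTable(specs=TRIGLYCERIDE_SPEC, data=df)
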