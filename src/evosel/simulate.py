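"""Synthetic multi-class expression and survival data generators.

The expression generator emulates the shape of log2-scale multi-class
miRNA-seq data: most features are uninformative Gaussian noise around a
common baseline, while each class owns a block of informative features
that (a) shift upward by ``effect_delta`` noise standard deviations in
that class only and (b) share a latent factor giving exact pairwise
correlation ``block_rho`` inside the block
(x = sqrt(rho) * f + sqrt(1 - rho) * eps). Optional zero inflation mimics
dropout on the count-scale representation by zeroing entries.

The survival generator draws event times from the proportional-hazards
model with an exponential baseline: T ~ Exp(rate = baseline_rate *
exp(x * beta_true)) with independent exponential censoring, so at
beta_true = 0 the expected censored fraction is
censor_rate / (censor_rate + baseline_rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cox import SurvivalRecord
from .expression import ExpressionMatrix, LabelVector, Scale

__all__ = [
    "ExpressionSimDesign",
    "SurvivalSimDesign",
    "simulate_expression",
    "simulate_survival",
]


@dataclass
class ExpressionSimDesign:
    """Desk-scale default: 11 classes x 30 samples, D=60, 3 informative each."""

    n_classes: int = 11
    samples_per_class: int = 30
    n_features: int = 60
    informative_per_class: int = 3
    block_rho: float = 0.6
    effect_delta: float = 2.0
    noise_sd: float = 1.0
    baseline: float = 5.0
    zero_inflation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_classes * self.informative_per_class > self.n_features:
            raise ValueError("informative blocks exceed total features")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must lie in [0, 1)")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def simulate_expression(
    design: ExpressionSimDesign,
) -> tuple[ExpressionMatrix, LabelVector, dict[str, list[str]]]:
    """Generate (expression, labels, truth map class -> informative IDs)."""
    rng = np.random.default_rng(design.seed)
    C, k, D = design.n_classes, design.informative_per_class, design.n_features
    n = C * design.samples_per_class
    class_names = [f"C{c:02d}" for c in range(C)]
    labels = np.repeat(class_names, design.samples_per_class)
    feature_ids = [f"feat{j:04d}" for j in range(D)]
    sample_ids = [f"s{j:04d}" for j in range(n)]

    values = design.baseline + design.noise_sd * rng.standard_normal((D, n))
    truth: dict[str, list[str]] = {}
    rho = design.block_rho
    for c, cname in enumerate(class_names):
        block = list(range(c * k, (c + 1) * k))
        truth[cname] = [feature_ids[j] for j in block]
        factor = rng.standard_normal(n)  # shared latent factor of the block
        eps = rng.standard_normal((k, n))
        noise = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * eps
        shift = np.where(labels == cname, design.effect_delta * design.noise_sd, 0.0)
        values[block] = design.baseline + shift + design.noise_sd * noise
    if design.zero_inflation > 0:
        dropout = rng.random((D, n)) < design.zero_inflation
        values[dropout] = 0.0
    X = ExpressionMatrix(feature_ids, sample_ids, values, Scale.log2)
    y = LabelVector(sample_ids, list(labels))
    return X, y, truth


@dataclass
class SurvivalSimDesign:
    n: int = 300
    beta_true: float = 0.0
    baseline_rate: float = 1.0 / 500.0  # events per day
    censor_rate: float = 1.0 / 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("need at least 10 subjects")
        if self.baseline_rate <= 0 or self.censor_rate <= 0:
            raise ValueError("rates must be positive")


def simulate_survival(design: SurvivalSimDesign) -> tuple[np.ndarray, list[SurvivalRecord]]:
    """Standard-normal covariate with exponential PH event/censoring times."""
    rng = np.random.default_rng(design.seed)
    x = rng.standard_normal(design.n)
    event_times = rng.exponential(1.0 / (design.baseline_rate * np.exp(x * design.beta_true)))
    censor_times = rng.exponential(1.0 / design.censor_rate, size=design.n)
    times = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(int)
    records = [SurvivalRecord(float(t), int(e)) for t, e in zip(times, events)]
    return x, records
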