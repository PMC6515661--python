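"""Digital-PCR copy-number estimation with Poisson partition statistics.

A digital PCR reaction distributes template molecules over many partitions;
a partition is positive when it received at least one molecule. Under
Poisson loading the mean occupancy follows from the positive fraction as
lambda = -ln(1 - positives/total). The integrated copy number of a target
gene (GFP or mCherry, proxies for the two circuit plasmids) is the ratio of
its lambda to that of a single-copy endogenous reference gene (ALG9 in a
haploid host), with a delta-method 95% confidence interval propagated from
the two binomial positive fractions on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "SaturationError",
    "DigitalPCRMeasurement",
    "CopyNumberEstimate",
    "lambda_from_partitions",
    "copies_per_genome",
]

TARGETS = ("GFP", "mCherry", "ALG9")


class SaturationError(ValueError):
    pass


@dataclass(frozen=True)
class DigitalPCRMeasurement:
    """Positive/total partition counts for one target gene."""

    target: str
    positive_partitions: int
    total_partitions: int

    def __post_init__(self):
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}, got {self.target!r}")
        if self.total_partitions < 1:
            raise ValueError("total_partitions must be >= 1")
        if not 0 <= self.positive_partitions <= self.total_partitions:
            raise ValueError(
                f"positive_partitions must lie in [0, {self.total_partitions}], "
                f"got {self.positive_partitions}"
            )

    @property
    def positive_fraction(self) -> float:
        return self.positive_partitions / self.total_partitions


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Copies of a target per genome, with a 95% confidence interval."""

    target: str
    copies_per_genome: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not 0 <= self.ci_low <= self.copies_per_genome <= self.ci_high:
            raise ValueError(
                f"require 0 <= ci_low <= estimate <= ci_high, got "
                f"({self.ci_low}, {self.copies_per_genome}, {self.ci_high})"
            )

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def lambda_from_partitions(m: DigitalPCRMeasurement) -> float:
    """Poisson-corrected mean copies per partition, -ln(1 - positive fraction).

    Saturated measurements (every partition positive) carry no upper
    information and raise; all-negative measurements return 0 with a warning
    since they bound the concentration only from above.
    """
    if m.positive_partitions == m.total_partitions:
        raise SaturationError(
            f"{m.target}: all {m.total_partitions} partitions positive; "
            "concentration is unbounded (dilute and re-run)"
        )
    if m.positive_partitions == 0:
        import warnings

        warnings.warn(
            f"{m.target}: no positive partitions; lambda = 0 carries no "
            "concentration information",
            stacklevel=2,
        )
        return 0.0
    return float(-np.log1p(-m.positive_fraction))


def _lambda_variance(m: DigitalPCRMeasurement) -> float:
    # delta method on the binomial fraction p: var(lambda) = p / ((1-p) N)
    p = m.positive_fraction
    return p / ((1.0 - p) * m.total_partitions)


def copies_per_genome(
    target_m: DigitalPCRMeasurement,
    reference_m: DigitalPCRMeasurement,
    reference_copies: int = 1,
    confidence: float = 0.95,
) -> CopyNumberEstimate:
    """Target copies per genome relative to the endogenous reference.

    Point estimate: (lambda_target / lambda_reference) * reference_copies.
    The CI applies the delta method to log(lambda_target/lambda_reference),
    i.e. a log-normal interval, which keeps the bounds positive and is
    standard for ratio estimators. ``reference_copies`` defaults to 1
    (haploid host, single-copy reference gene).
    """
    if reference_copies < 1:
        raise ValueError("reference_copies must be >= 1")
    lam_t = lambda_from_partitions(target_m)
    lam_r = lambda_from_partitions(reference_m)
    if lam_r == 0:
        raise SaturationError(
            f"reference {reference_m.target}: no positive partitions; ratio undefined"
        )
    ratio = lam_t / lam_r * reference_copies
    if lam_t == 0:
        return CopyNumberEstimate(target_m.target, 0.0, 0.0, 0.0)
    z = norm.ppf(0.5 + confidence / 2.0)
    se_log = np.sqrt(
        _lambda_variance(target_m) / lam_t**2 + _lambda_variance(reference_m) / lam_r**2
    )
    return CopyNumberEstimate(
        target_m.target,
        float(ratio),
        float(ratio * np.exp(-z * se_log)),
        float(ratio * np.exp(z * se_log)),
    )
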