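"""Founder-allele prevalence estimation for a recessive disease.

The estimator uses only three observable quantities: the population
allele frequency ``q`` of the most common (founder) pathogenic variant,
the number ``a`` of founder alleles among affected chromosomes, and the
total number ``A = 2 x cases`` of affected chromosomes. Under random
mating (Hardy-Weinberg) the founder's share of pathogenic chromosomes,
``f = a / A``, scales its population frequency up to the total
pathogenic allele frequency ``Q = q / f``, and disease prevalence is
``Q**2`` with carrier frequency ``2 Q (1 - Q)``.

Uncertainty comes from a parametric bootstrap over the two binomial
counts (founder alleles among patient chromosomes; alt alleles in the
population sample); the paper-style point estimate itself is a plain
ratio and is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FounderInputs",
    "PrevalenceEstimate",
    "estimate",
    "bootstrap_ci",
    "carrier_frequency",
    "round_sig",
]


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (display convention for
    '1 in N' reporting)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class FounderInputs:
    """Inputs of the founder-based prevalence estimate."""

    q_pop: float  # population allele frequency of the founder variant
    a_founder: int  # founder alleles among patient chromosomes
    A_total: int  # total patient chromosomes (2 x cases)
    q_source_counts: tuple[int, int] | None = None  # (alt, total) behind q_pop

    def __post_init__(self) -> None:
        if not 0.0 < self.q_pop <= 1.0:
            raise ValueError(f"q_pop must be in (0, 1], got {self.q_pop}")
        if self.a_founder < 1:
            raise ValueError("a_founder must be >= 1")
        if self.A_total < self.a_founder:
            raise ValueError("a_founder cannot exceed A_total")
        if self.q_source_counts is not None:
            alt, total = self.q_source_counts
            if total < 1 or alt < 0 or alt > total:
                raise ValueError(f"bad q source counts {self.q_source_counts}")
            if abs(self.q_pop - alt / total) > 1e-12:
                raise ValueError(
                    f"q_pop {self.q_pop} does not equal alt/total = {alt / total}"
                )

    @classmethod
    def from_counts(cls, alt: int, total: int, a_founder: int, A_total: int) -> "FounderInputs":
        return cls(alt / total, a_founder, A_total, (alt, total))


@dataclass(frozen=True)
class PrevalenceEstimate:
    f: float  # founder share of pathogenic chromosomes, a / A
    Q: float  # total pathogenic allele frequency, q / f
    prevalence: float  # Q**2
    one_in: float  # 1 / prevalence, full precision
    one_in_display: float  # 1 / prevalence, 3 significant figures
    per_million: float  # 1e6 * prevalence, 2 significant figures
    carrier_freq: float  # 2 Q (1 - Q)
    ci: tuple[float, float] | None = None  # prevalence interval
    ci_level: float | None = None
    n_boot: int | None = None
    seed: int | None = None
    n_rejected: int | None = None


def carrier_frequency(Q: float) -> float:
    """Hardy-Weinberg heterozygous-carrier frequency, ``2 Q (1 - Q)``."""
    if not 0.0 <= Q <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {Q}")
    return 2.0 * Q * (1.0 - Q)


def estimate(inputs: FounderInputs) -> PrevalenceEstimate:
    """Point estimate of disease prevalence from founder-allele data.

    Raises ``ValueError`` when the implied total pathogenic frequency
    ``Q = q / f`` exceeds 1, which signals inconsistent inputs (the
    founder variant cannot be rarer in patients than its own population
    frequency implies).
    """
    f = inputs.a_founder / inputs.A_total
    Q = inputs.q_pop / f
    if Q > 1.0:
        raise ValueError(
            f"inconsistent inputs: total pathogenic allele frequency Q = q/f = {Q:.4g} > 1"
        )
    prevalence = Q * Q
    return PrevalenceEstimate(
        f=f,
        Q=Q,
        prevalence=prevalence,
        one_in=1.0 / prevalence,
        one_in_display=round_sig(1.0 / prevalence, 3),
        per_million=round_sig(1e6 * prevalence, 2),
        carrier_freq=carrier_frequency(Q),
    )


def bootstrap_ci(
    inputs: FounderInputs,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> PrevalenceEstimate:
    """Percentile bootstrap interval for the prevalence.

    Each replicate redraws ``a* ~ Binomial(A, a/A)`` and
    ``alt* ~ Binomial(total, alt/total)`` and recomputes the prevalence;
    replicates with ``a* = 0`` (undefined founder share) are rejected and
    redrawn, with the rejection count reported on the result. Requires
    the source counts behind ``q_pop``; deterministic for a given seed.
    """
    if inputs.q_source_counts is None:
        raise ValueError("bootstrap requires q_source_counts (alt, total)")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alt, total = inputs.q_source_counts
    if alt == total:
        raise ValueError("degenerate q source counts (alt == total implies q = 1)")
    point = estimate(inputs)
    rng = np.random.default_rng(seed)
    p_a = inputs.a_founder / inputs.A_total
    p_q = alt / total
    reps = np.empty(n_boot)
    n_rejected = 0
    filled = 0
    while filled < n_boot:
        need = n_boot - filled
        a_star = rng.binomial(inputs.A_total, p_a, size=need)
        alt_star = rng.binomial(total, p_q, size=need)
        ok = a_star > 0
        n_rejected += int((~ok).sum())
        f_star = a_star[ok] / inputs.A_total
        Q_star = (alt_star[ok] / total) / f_star
        reps[filled : filled + int(ok.sum())] = Q_star**2
        filled += int(ok.sum())
    lo, hi = np.quantile(reps, [(1 - level) / 2, 1 - (1 - level) / 2])
    return PrevalenceEstimate(
        f=point.f,
        Q=point.Q,
        prevalence=point.prevalence,
        one_in=point.one_in,
        one_in_display=point.one_in_display,
        per_million=point.per_million,
        carrier_freq=point.carrier_freq,
        ci=(float(lo), float(hi)),
        ci_level=level,
        n_boot=n_boot,
        seed=seed,
        n_rejected=n_rejected,
    )
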