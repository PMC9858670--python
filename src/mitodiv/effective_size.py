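"""Female effective population size from mitochondrial theta.

For a haploid, maternally inherited locus, theta = 2 N_ef mu per site, so

    N_ef(mu) = (theta_per_sequence / L) / (2 mu).

With a mutation-rate credible interval [mu_low, mu_high], the lower rate
yields the larger size: N_ef is reported at both bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

__all__ = ["NeEstimate", "female_effective_size"]

_SOURCES = ("theta_pi", "theta_S", "theta_K")


@dataclass(frozen=True)
class NeEstimate:
    theta_source: str
    theta_per_sequence: float
    L: float
    mu_low: float
    mu_high: float
    ne_at_mu_low: float   # larger value (slow clock)
    ne_at_mu_high: float  # smaller value (fast clock)

    @property
    def rounded(self) -> tuple[int, int]:
        """(N_ef at mu_low, N_ef at mu_high) rounded for display."""
        return round(self.ne_at_mu_low), round(self.ne_at_mu_high)

    def as_dict(self) -> dict:
        return asdict(self)


def female_effective_size(
    theta_per_sequence: float,
    L: float,
    mu_low: float,
    mu_high: float,
    theta_source: str = "theta_K",
) -> NeEstimate:
    """N_ef at both ends of a per-site per-generation mutation-rate interval.

    ``theta_per_sequence`` is the per-sequence theta estimate (e.g. the Ewens
    MLE); unrounded values should be piped in, since rounding upstream shifts
    the resulting sizes.
    """
    if theta_source not in _SOURCES:
        raise ValueError(f"theta_source must be one of {_SOURCES}")
    if theta_per_sequence < 0:
        raise ValueError("theta must be >= 0")
    if L <= 0:
        raise ValueError("L must be positive")
    if not 0 < mu_low <= mu_high:
        raise ValueError("need 0 < mu_low <= mu_high")
    theta_site = theta_per_sequence / L
    return NeEstimate(
        theta_source=theta_source,
        theta_per_sequence=theta_per_sequence,
        L=L,
        mu_low=mu_low,
        mu_high=mu_high,
        ne_at_mu_low=theta_site / (2.0 * mu_low),
        ne_at_mu_high=theta_site / (2.0 * mu_high),
    )
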