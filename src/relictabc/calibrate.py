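"""Mutation-rate and time-unit calibration.

No nuclear substitution rate is available for the study lineage, so the
nuclear rate is derived from an independently calibrated chloroplast rate
via a fixed cpDNA:nDNA substitution-rate ratio (default 3:16).  All
downstream demographic times are simulated on the coalescent scale (units
of 4*N_ref generations) and converted to calendar units (ka, thousand
years) here, using a configurable generation time (default 15 years).

The ratio is carried as a pair of exact integers so the published point
estimate emerges from rounding only at presentation; full precision is
retained internally.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class RateCalibration:
    """A substitution-rate calibration with uncertainty.

    Attributes
    ----------
    cp_rate, cp_hpd_low, cp_hpd_high:
        Chloroplast substitution rate (substitutions / site / year) with
        its 95% HPD bounds.
    ratio:
        (cp, nuclear) integer pair; nuclear_rate = cp_rate * ratio[1]/ratio[0].
    generation_time:
        Years per generation.
    """

    cp_rate: float
    cp_hpd_low: float
    cp_hpd_high: float
    ratio: tuple[int, int] = (3, 16)
    generation_time: float = 15.0

    def __post_init__(self) -> None:
        if min(self.cp_rate, self.cp_hpd_low, self.cp_hpd_high) <= 0:
            raise ValueError("rates must be positive")
        if self.cp_hpd_low > self.cp_rate or self.cp_rate > self.cp_hpd_high:
            raise ValueError("HPD bounds must bracket the point estimate")
        a, b = self.ratio
        if a <= 0 or b <= 0 or a != int(a) or b != int(b):
            raise ValueError("ratio components must be positive integers")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")

    @property
    def nuclear_rate(self) -> float:
        return self.cp_rate * self.ratio[1] / self.ratio[0]

    @property
    def nuclear_hpd(self) -> tuple[float, float]:
        f = self.ratio[1] / self.ratio[0]
        return (self.cp_hpd_low * f, self.cp_hpd_high * f)


def nuclear_rate_from_cpdna(
    cp_rate: float,
    cp_hpd: tuple[float, float] | None = None,
    ratio: tuple[int, int] = (3, 16),
) -> tuple[float, tuple[float, float] | None]:
    """Scale a cpDNA substitution rate (and optional HPD) to the nuclear rate.

    Each of (point, low, high) is multiplied by ratio[1]/ratio[0]; no
    rounding is applied (presentation formatting is the caller's concern).
    """
    if cp_rate <= 0:
        raise ValueError("cp_rate must be positive")
    f = ratio[1] / ratio[0]
    if cp_hpd is None:
        return cp_rate * f, None
    low, high = cp_hpd
    if low <= 0 or high <= 0:
        raise ValueError("HPD bounds must be positive")
    return cp_rate * f, (low * f, high * f)


def locus_mutation_param(mu: float, k: float, g: float) -> float:
    """Per-locus per-generation mutation parameter u = mu * k * g.

    mu is substitutions per site per year, k the locus length in bp and g
    the generation time in years.
    """
    if mu <= 0 or k <= 0 or g <= 0:
        raise ValueError("mu, k and g must all be positive")
    return mu * k * g


def coalescent_time_to_ka(tau: float, n_ref: float, g: float) -> float:
    """Convert a time in units of 4*N_ref generations to ka."""
    if tau < 0 or n_ref <= 0 or g <= 0:
        raise ValueError("inputs must be positive (tau may be zero)")
    return tau * 4.0 * n_ref * g / 1000.0


def ka_to_coalescent_time(ka: float, n_ref: float, g: float) -> float:
    """Inverse of :func:`coalescent_time_to_ka`; exact round trip."""
    if ka < 0 or n_ref <= 0 or g <= 0:
        raise ValueError("inputs must be positive (ka may be zero)")
    return ka * 1000.0 / (4.0 * n_ref * g)


def format_rate(rate: float, sig: int = 3) -> str:
    """Format a rate to `sig` significant figures (presentation only)."""
    return f"{rate:.{sig - 1}e}"
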