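"""Bulk and compressed powder densities from measuring-cylinder readings.

A bulking agent is characterized by pouring a weighed amount of powder
(9–11 g) into a graduated cylinder (bulk volume ``V_f``), compacting it with
a defined drop procedure (compressed volume ``V_c``), and computing

* bulk density            rho_b = m_f / V_f
* compressed density      rho_c = m_f / V_c
* density increase [%]    (rho_c - rho_b) / rho_c * 100

Replicates are aggregated per agent into a :class:`BulkingAgentProfile`
(mean ± sample SD, n-1 denominator).  The density increase of a profile is
the mean of the per-replicate increases, not the increase of the mean
densities — the convention used when tabulating n = 3 replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "DensityMeasurement",
    "BulkingAgentProfile",
    "bulk_density",
    "compressed_density",
    "density_increase",
    "characterize",
]


@dataclass(frozen=True)
class DensityMeasurement:
    """One measuring-cylinder reading.

    Parameters
    ----------
    powder_mass
        Mass of powder filled into the cylinder, in g.
    bulk_volume
        Volume read after pouring, without vibration, in mL.
    compressed_volume
        Volume read after the compaction procedure, in mL.  Must not
        exceed the bulk volume (powder cannot expand under compression).
    """

    powder_mass: float
    bulk_volume: float
    compressed_volume: float

    def __post_init__(self) -> None:
        if not self.powder_mass > 0:
            raise ValidationError(
                f"powder_mass must be > 0, got {self.powder_mass}"
            )
        if not self.bulk_volume > 0:
            raise ValidationError(
                f"bulk_volume must be > 0, got {self.bulk_volume}"
            )
        if not 0 < self.compressed_volume <= self.bulk_volume:
            raise ValidationError(
                "compressed_volume must satisfy 0 < compressed_volume <= "
                f"bulk_volume, got compressed_volume={self.compressed_volume} "
                f"with bulk_volume={self.bulk_volume}"
            )


@dataclass(frozen=True)
class BulkingAgentProfile:
    """Replicate-aggregated density characterization of one bulking agent.

    All densities in g/mL, the density increase in percent.  SDs are sample
    standard deviations (n-1); with a single replicate they are reported as
    0 and ``sd_estimable`` is False.
    """

    name: str
    bulk_density: float
    bulk_density_sd: float
    compressed_density: float
    compressed_density_sd: float
    density_increase: float
    density_increase_sd: float
    n_replicates: int

    @property
    def sd_estimable(self) -> bool:
        return self.n_replicates >= 2

    def __post_init__(self) -> None:
        if self.compressed_density < self.bulk_density:
            raise ValidationError(
                "compressed_density must be >= bulk_density "
                f"({self.compressed_density} < {self.bulk_density})"
            )
        if not 0 <= self.density_increase < 100:
            raise ValidationError(
                f"density_increase must lie in [0, 100), got "
                f"{self.density_increase}"
            )
        for field in ("bulk_density_sd", "compressed_density_sd",
                      "density_increase_sd"):
            if getattr(self, field) < 0:
                raise ValidationError(f"{field} must be >= 0")


def bulk_density(m: DensityMeasurement) -> float:
    """Bulk density rho_b = m_f / V_f in g/mL."""
    return m.powder_mass / m.bulk_volume


def compressed_density(m: DensityMeasurement) -> float:
    """Compressed density rho_c = m_f / V_c in g/mL."""
    return m.powder_mass / m.compressed_volume


def density_increase(rho_b: float, rho_c: float) -> float:
    """Relative density gain on compression, (rho_c - rho_b)/rho_c * 100 [%]."""
    if rho_b <= 0:
        raise ValidationError(f"rho_b must be > 0, got {rho_b}")
    if rho_b > rho_c:
        raise ValidationError(
            "powder expanded under compression: rho_b "
            f"({rho_b}) > rho_c ({rho_c}); inputs likely swapped"
        )
    return (rho_c - rho_b) / rho_c * 100.0


def characterize(
    replicates: Sequence[DensityMeasurement], name: str
) -> BulkingAgentProfile:
    """Aggregate replicate cylinder readings into an agent profile.

    Per-replicate rho_b, rho_c and density increase are computed first;
    the profile reports the mean ± sample SD of each.  A single replicate
    yields zero SDs (flagged via ``sd_estimable``).
    """
    if len(replicates) == 0:
        raise ValidationError("characterize requires at least one replicate")
    rb = np.array([bulk_density(m) for m in replicates])
    rc = np.array([compressed_density(m) for m in replicates])
    inc = np.array([density_increase(b, c) for b, c in zip(rb, rc)])
    n = len(replicates)

    def sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if n >= 2 else 0.0

    return BulkingAgentProfile(
        name=name,
        bulk_density=float(rb.mean()),
        bulk_density_sd=sd(rb),
        compressed_density=float(rc.mean()),
        compressed_density_sd=sd(rc),
        density_increase=float(inc.mean()),
        density_increase_sd=sd(inc),
        n_replicates=n,
    )
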