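"""API mass balance: capsules + equipment residues + shells + unaccounted.

After a batch is prepared, the weighed-out API either ends up inside the
capsules, adheres to the preparation equipment (swab-recovered), stays in
the capsule shells, or is unaccounted for.  The balance report closes the
conservation identity exactly by defining

    unaccounted = weighed API - in capsules - sum(residues)

Two denominators are used deliberately: equipment residues are expressed
relative to the weighed API (which includes the overage), while shell
retention — the fraction a patient loses when a capsule is opened and
sprinkled onto food — is expressed relative to the nominal dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ValidationError

__all__ = [
    "DEVICES",
    "ResidueSample",
    "BalanceReport",
    "residue_fraction",
    "shell_retention",
    "balance_report",
]

#: Controlled vocabulary of residue locations ("spoon" is accepted as an
#: alias of "spatula").
DEVICES = frozenset(
    {
        "weighing_boat",
        "spatula",
        "pestle",
        "powder_spreader",
        "mixing_bowl",
        "capsule_filling_machine",
        "shells",
    }
)
_ALIASES = {"spoon": "spatula"}


def canonical_device(device: str) -> str:
    d = _ALIASES.get(device, device)
    if d not in DEVICES:
        raise ValidationError(
            f"unknown device {device!r}; expected one of {sorted(DEVICES)}"
        )
    return d


@dataclass(frozen=True)
class ResidueSample:
    """API recovered from one device (swab + rinse assay)."""

    device: str
    recovered_api: float
    extraction_volume: float = 0.0
    n_swabs: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "device", canonical_device(self.device))
        if self.recovered_api < 0:
            raise ValidationError(
                f"{self.device}: recovered_api must be >= 0 mg, "
                f"got {self.recovered_api}"
            )


@dataclass(frozen=True)
class BalanceReport:
    """Closed API ledger for one batch (all masses mg)."""

    weighed_api: float
    in_capsules: float
    per_device: tuple[tuple[str, float, float], ...]  # (device, mg, % weighed)
    total_residue: float
    total_residue_pct: float
    shell_retention_pct: float
    unaccounted: float
    unaccounted_pct: float


def residue_fraction(recovered: float, weighed_api: float) -> float:
    """Recovered residue as percent of the initially weighed API."""
    if not weighed_api > 0:
        raise ValidationError(f"weighed_api must be > 0 mg, got {weighed_api}")
    if recovered < 0:
        raise ValidationError(f"recovered must be >= 0 mg, got {recovered}")
    if recovered > weighed_api:
        warnings.warn(
            f"over-recovery: {recovered} mg recovered exceeds "
            f"{weighed_api} mg weighed (assay noise?)",
            stacklevel=2,
        )
    return 100.0 * recovered / weighed_api


def shell_retention(residual_per_capsule: float, dose: float) -> float:
    """API retained in an emptied shell as percent of the nominal dose."""
    if not dose > 0:
        raise ValidationError(f"dose must be > 0 mg, got {dose}")
    return 100.0 * residual_per_capsule / dose


def balance_report(
    weighed_api: float,
    capsule_contents: Sequence[float],
    residues: Sequence[ResidueSample],
    shell_residues: Sequence[float] = (),
    dose: float | None = None,
) -> BalanceReport:
    """Close the API conservation identity for one batch.

    ``shell_residues`` are per-capsule amounts retained in shells (mg);
    they enter the ledger as a "shells" device.  ``dose`` (mg) is needed
    only to express shell retention relative to the nominal dose.
    """
    if not weighed_api > 0:
        raise ValidationError(f"weighed_api must be > 0 mg, got {weighed_api}")
    in_caps = float(sum(capsule_contents))
    by_device: dict[str, float] = {}
    for r in residues:
        by_device[r.device] = by_device.get(r.device, 0.0) + r.recovered_api
    shell_total = float(sum(shell_residues))
    if shell_total > 0:
        by_device["shells"] = by_device.get("shells", 0.0) + shell_total
    total_res = sum(by_device.values())
    unaccounted = weighed_api - in_caps - total_res
    per_device = tuple(
        sorted(
            ((d, mg, 100.0 * mg / weighed_api) for d, mg in by_device.items()),
            key=lambda t: t[2],
            reverse=True,
        )
    )
    if dose is not None and shell_residues:
        mean_shell = shell_total / len(shell_residues)
        shell_pct = shell_retention(mean_shell, dose)
    else:
        shell_pct = 0.0
    return BalanceReport(
        weighed_api=weighed_api,
        in_capsules=in_caps,
        per_device=per_device,
        total_residue=total_res,
        total_residue_pct=100.0 * total_res / weighed_api,
        shell_retention_pct=shell_pct,
        unaccounted=unaccounted,
        unaccounted_pct=100.0 * unaccounted / weighed_api,
    )
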