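"""Blend formulation for mass-based capsule filling.

The mass-based method doses the bulking agent by weight instead of filling
capsules to a visual volume mark.  The required bulking-agent mass for a
batch is a weighted mean of the bulk and compressed densities:

    m_b = (3 * rho_b + rho_c) / 4 * V_C * n_C        [g]

with ``V_C`` the capsule volume (0.5 mL for size #1) and ``n_C`` the number
of capsules.  The weighting reflects that hand-filled powder ends up mostly
near its poured (bulk) density with only partial compaction from tapping.

The API is weighed with a deliberate overage (10 % by default) to
compensate for powder losses during blending and encapsulation; the label
claim stays at the nominal dose.  The bulking agent itself is a filler
pre-blended with a glidant (0.5 % m/m colloidal silica by default).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "FormulationSpec",
    "BlendComposition",
    "required_bulking_mass",
    "api_batch_mass",
    "blend_composition",
    "target_fill_mass",
]


@dataclass(frozen=True)
class FormulationSpec:
    """A formulation request for one capsule batch.

    Parameters
    ----------
    dose
        Label claim, mg API per capsule.
    n_capsules
        Number of capsules in the batch.
    overage_fraction
        Deliberate API excess (0.10 = 10 %) weighed in on top of
        ``dose * n_capsules``.
    capsule_volume
        Capsule body volume in mL (size #1: 0.5 mL).
    glidant_fraction
        Mass fraction of the bulking agent that is glidant
        (filler + glidant = bulking agent).
    api_name, agent
        Free-text labels carried through to reports.
    """

    dose: float
    n_capsules: int
    overage_fraction: float = 0.10
    capsule_volume: float = 0.5
    glidant_fraction: float = 0.005
    api_name: str = "API"
    agent: str = ""

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValidationError(f"dose must be > 0 mg, got {self.dose}")
        if self.n_capsules < 1:
            raise ValidationError(
                f"n_capsules must be >= 1, got {self.n_capsules}"
            )
        if self.overage_fraction < 0:
            raise ValidationError(
                f"overage_fraction must be >= 0, got {self.overage_fraction}"
            )
        if not self.capsule_volume > 0:
            raise ValidationError(
                f"capsule_volume must be > 0 mL, got {self.capsule_volume}"
            )
        if not 0 <= self.glidant_fraction < 1:
            raise ValidationError(
                f"glidant_fraction must lie in [0, 1), got "
                f"{self.glidant_fraction}"
            )


@dataclass(frozen=True)
class BlendComposition:
    """Masses (mg, unrounded) making up one batch blend.

    Invariants: filler + glidant = bulking agent; API + bulking agent =
    total blend; total blend / n_capsules = target fill mass.
    """

    api_mass: float
    filler_mass: float
    glidant_mass: float
    bulking_agent_mass: float
    total_blend_mass: float
    target_fill_mass: float
    n_capsules: int

    def rounded(self, ndigits: int = 1) -> "BlendComposition":
        """Composition with all masses rounded (default 0.1 mg)."""
        return BlendComposition(
            api_mass=round(self.api_mass, ndigits),
            filler_mass=round(self.filler_mass, ndigits),
            glidant_mass=round(self.glidant_mass, ndigits),
            bulking_agent_mass=round(self.bulking_agent_mass, ndigits),
            total_blend_mass=round(self.total_blend_mass, ndigits),
            target_fill_mass=round(self.target_fill_mass, ndigits),
            n_capsules=self.n_capsules,
        )

    @property
    def api_mass_fraction(self) -> float:
        """API mass fraction of the blend (dimensionless)."""
        return self.api_mass / self.total_blend_mass


def required_bulking_mass(
    rho_b: float,
    rho_c: float,
    capsule_volume: float,
    n_capsules: int,
) -> float:
    """Bulking-agent mass in g for a batch: (3*rho_b + rho_c)/4 * V * n.

    Strictly between the all-bulk and all-compressed extremes
    ``rho_b*V*n`` and ``rho_c*V*n`` unless the densities are equal.
    """
    if rho_b <= 0:
        raise ValidationError(f"rho_b must be > 0, got {rho_b}")
    if rho_b > rho_c:
        raise ValidationError(
            f"density ordering violated: rho_b ({rho_b}) > rho_c ({rho_c})"
        )
    if n_capsules < 1:
        raise ValidationError(f"n_capsules must be >= 1, got {n_capsules}")
    return (3.0 * rho_b + rho_c) / 4.0 * capsule_volume * n_capsules


def api_batch_mass(spec: FormulationSpec) -> float:
    """API to weigh for the batch, mg: dose * n * (1 + overage)."""
    return spec.dose * spec.n_capsules * (1.0 + spec.overage_fraction)


def blend_composition(
    spec: FormulationSpec, bulking_agent_mass: float
) -> BlendComposition:
    """Full blend composition from a spec and the bulking-agent mass in g.

    The glidant fraction splits the bulking agent into filler and glidant;
    returned masses are in mg and unrounded (use ``.rounded()`` for the
    0.1 mg compounding-sheet precision).
    """
    if not bulking_agent_mass > 0:
        raise ValidationError(
            f"bulking_agent_mass must be > 0 g, got {bulking_agent_mass}"
        )
    mb_mg = bulking_agent_mass * 1000.0
    api = api_batch_mass(spec)
    glidant = mb_mg * spec.glidant_fraction
    filler = mb_mg - glidant
    total = api + mb_mg
    return BlendComposition(
        api_mass=api,
        filler_mass=filler,
        glidant_mass=glidant,
        bulking_agent_mass=mb_mg,
        total_blend_mass=total,
        target_fill_mass=total / spec.n_capsules,
        n_capsules=spec.n_capsules,
    )


def target_fill_mass(comp: BlendComposition, n_capsules: int | None = None) -> float:
    """Per-capsule target fill mass in mg (total blend / n)."""
    n = comp.n_capsules if n_capsules is None else n_capsules
    if n < 1:
        raise ValidationError(f"n_capsules must be >= 1, got {n}")
    return comp.total_blend_mass / n
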