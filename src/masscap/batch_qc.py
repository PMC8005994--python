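"""Batch quality evaluation: content uniformity, powder loss, homogeneity.

Content uniformity follows the pharmacopoeial (Ph. Eur. 2.9.40 / USP <905>)
acceptance value for the T <= 101.5 % case:

    AV = |M - X̄| + k * s

where X̄ and s are the mean and sample SD of the individual contents
expressed as percent of the label claim, and the reference value M is

    M = X̄      if 98.5 <= X̄ <= 101.5
    M = 98.5   if X̄ < 98.5
    M = 101.5  if X̄ > 101.5

A batch passes at AV <= 15 (L1).  The acceptability constant k is tied to
the sample size by the compendium: k = 2.4 for n = 10 (first stage),
k = 2.0 for n = 30.  ``default_k`` implements that rule; every entry point
accepts an explicit ``k`` override.

Powder loss compares the blend mass actually ending up inside capsules
against the weighed blend mass m_t:

    loss [%] = (m_t - (m_a - n * m_c)) / m_t * 100

with m_a the summed gross (filled) capsule masses and m_c the mean empty
shell mass.  Mass uniformity is the relative sample SD of the gross
masses; blend homogeneity the relative sample SD of the per-capsule
content / net-mass quotients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "CapsuleObservation",
    "BatchRecord",
    "QCThresholds",
    "QCReport",
    "UniformityResult",
    "default_k",
    "reference_value",
    "acceptance_value",
    "acceptance_value_from_summary",
    "uniformity_test",
    "powder_loss",
    "mass_uniformity",
    "homogeneity",
    "evaluate_batch",
]

#: Pharmacopoeial L1 limit on the acceptance value.
AV_LIMIT = 15.0
#: Guideline limit on powder loss during preparation (DAC/NRF), percent.
LOSS_LIMIT = 3.0
#: Guideline limit on the relative SD of capsule masses (DAC/NRF), percent.
MASS_LIMIT = 5.0
#: Stage-2 limit on individual deviations from M, percent (L2).
L2 = 25.0


@dataclass(frozen=True)
class CapsuleObservation:
    """One filled capsule: machine position, gross mass (mg), assayed content (mg)."""

    index: int
    gross_mass: float
    content: float

    def __post_init__(self) -> None:
        if not self.gross_mass > 0:
            raise ValidationError(
                f"capsule {self.index}: gross_mass must be > 0 mg, "
                f"got {self.gross_mass}"
            )
        if self.content < 0:
            raise ValidationError(
                f"capsule {self.index}: content must be >= 0 mg, "
                f"got {self.content}"
            )


@dataclass(frozen=True)
class BatchRecord:
    """All raw data for one capsule batch.

    ``weighed_blend`` (m_t) is the sum of the initially weighed bulking
    agent and API; ``shell_tare_mean`` (m_c) the mean empty-shell mass.
    Per-capsule tares, when weighed, go in ``shell_tares`` (same order as
    ``capsules``) and take precedence over the mean for net-mass metrics.
    """

    batch_id: str
    label_claim: float
    capsules: tuple[CapsuleObservation, ...]
    weighed_api: float
    weighed_blend: float
    shell_tare_mean: float = 74.0
    shell_tares: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.label_claim > 0:
            raise ValidationError(
                f"batch {self.batch_id}: label_claim must be > 0 mg"
            )
        if not self.weighed_blend > 0:
            raise ValidationError(
                f"batch {self.batch_id}: weighed_blend must be > 0 mg"
            )
        if self.shell_tares is not None and len(self.shell_tares) != len(
            self.capsules
        ):
            raise ValidationError(
                f"batch {self.batch_id}: shell_tares length "
                f"{len(self.shell_tares)} != number of capsules "
                f"{len(self.capsules)}"
            )

    @property
    def n(self) -> int:
        return len(self.capsules)

    def gross_masses(self) -> np.ndarray:
        return np.array([c.gross_mass for c in self.capsules], dtype=float)

    def contents(self) -> np.ndarray:
        return np.array([c.content for c in self.capsules], dtype=float)

    def tares(self) -> np.ndarray:
        if self.shell_tares is not None:
            return np.asarray(self.shell_tares, dtype=float)
        return np.full(self.n, self.shell_tare_mean)

    def net_masses(self) -> np.ndarray:
        return self.gross_masses() - self.tares()

    def contents_pct(self) -> np.ndarray:
        """Individual contents as percent of label claim."""
        return self.contents() / self.label_claim * 100.0


@dataclass(frozen=True)
class QCThresholds:
    """Pass/fail limits: AV (L1), powder loss %, relative mass SD %."""

    av_limit: float = AV_LIMIT
    loss_limit: float = LOSS_LIMIT
    mass_limit: float = MASS_LIMIT

    def __post_init__(self) -> None:
        if min(self.av_limit, self.loss_limit, self.mass_limit) <= 0:
            raise ValidationError("all thresholds must be positive")


def default_k(n: int) -> float:
    """Compendial acceptability constant: 2.4 for n <= 10, else 2.0."""
    return 2.4 if n <= 10 else 2.0


def reference_value(mean_pct: float) -> float:
    """Reference value M of the AV formula (case T <= 101.5)."""
    if mean_pct < 98.5:
        return 98.5
    if mean_pct > 101.5:
        return 101.5
    return mean_pct


def acceptance_value(contents_pct: Sequence[float], k: float | None = None) -> float:
    """AV = |M - X̄| + k*s on individual contents in percent of label.

    ``k`` defaults to the compendial n-based constant.
    """
    x = np.asarray(contents_pct, dtype=float)
    if x.size < 2:
        raise ValidationError(
            f"acceptance_value needs >= 2 contents, got {x.size}"
        )
    if np.any(x < 0):
        raise ValidationError("contents must be >= 0 % of label")
    if k is None:
        k = default_k(x.size)
    if not k > 0:
        raise ValidationError(f"k must be > 0, got {k}")
    mean = float(x.mean())
    s = float(np.std(x, ddof=1))
    return abs(reference_value(mean) - mean) + k * s


def acceptance_value_from_summary(
    mean_content: float,
    sd_rel_content: float,
    label_claim: float,
    k: float = 2.0,
) -> float:
    """AV recomputed from batch summary statistics.

    ``mean_content`` in mg, ``sd_rel_content`` as percent of the mean.
    The SD is rescaled from %-of-mean to %-of-label before applying the
    M-rule, so the result is identical to :func:`acceptance_value` on the
    underlying raw sample (up to the rounding of the summaries).
    """
    if min(mean_content, label_claim, k) <= 0:
        raise ValidationError(
            "mean_content, label_claim and k must all be > 0"
        )
    if sd_rel_content < 0:
        raise ValidationError(f"sd_rel_content must be >= 0, got {sd_rel_content}")
    mean_pct = 100.0 * mean_content / label_claim
    s_pct = sd_rel_content * mean_pct / 100.0
    return abs(reference_value(mean_pct) - mean_pct) + k * s_pct


@dataclass(frozen=True)
class UniformityResult:
    passed: bool
    av: float
    stage: int
    k: float
    n: int
    detail: str = ""


def uniformity_test(
    contents_pct: Sequence[float],
    mode: str = "single",
    k: float | None = None,
) -> UniformityResult:
    """Dosage-unit uniformity test on contents in percent of label.

    mode "single": one-shot AV on all n >= 2 units with the configured k
    (defaulting to the n-based compendial constant); pass iff the AV,
    rounded to 2 dp, is <= 15.

    mode "compendial": the two-stage procedure.  Requires exactly 10
    units (stage 1 only, k = 2.4) or 30 units (stage 1 on the first 10;
    on failure stage 2 on all 30 with k = 2.0 plus the individual-unit
    limit: no unit outside [0.75*M, 1.25*M]).
    """
    x = np.asarray(contents_pct, dtype=float)
    if mode == "single":
        av = acceptance_value(x, k)
        kk = default_k(x.size) if k is None else k
        return UniformityResult(
            passed=round(av, 2) <= AV_LIMIT, av=av, stage=1, k=kk, n=x.size
        )
    if mode != "compendial":
        raise ValidationError(f"unknown uniformity mode: {mode!r}")
    if x.size not in (10, 30):
        raise ValidationError(
            f"compendial mode needs 10 or 30 units, got {x.size}"
        )
    av1 = acceptance_value(x[:10], 2.4)
    if round(av1, 2) <= AV_LIMIT:
        return UniformityResult(True, av1, 1, 2.4, 10, "stage 1 pass")
    if x.size == 10:
        return UniformityResult(
            False, av1, 1, 2.4, 10, "stage 1 fail, no stage-2 units"
        )
    av2 = acceptance_value(x, 2.0)
    m = reference_value(float(x.mean()))
    lo, hi = (1 - L2 / 100.0) * m, (1 + L2 / 100.0) * m
    inside = bool(np.all((x >= lo) & (x <= hi)))
    passed = round(av2, 2) <= AV_LIMIT and inside
    detail = "stage 2" + ("" if inside else "; unit outside [0.75M, 1.25M]")
    return UniformityResult(passed, av2, 2, 2.0, 30, detail)


def powder_loss(batch: BatchRecord) -> float:
    """Percent of the weighed blend mass m_t not inside the capsules.

    Net fill = sum of gross masses - n * mean shell tare.  May be negative
    (weighing noise); callers flag rather than clamp.
    """
    if batch.n == 0:
        raise ValidationError(f"batch {batch.batch_id}: no capsules")
    m_a = float(batch.gross_masses().sum())
    net_fill = m_a - batch.n * batch.shell_tare_mean
    if net_fill < 0:
        raise ValidationError(
            f"batch {batch.batch_id}: total tare exceeds total gross mass "
            f"(net fill {net_fill:.1f} mg)"
        )
    return (batch.weighed_blend - net_fill) / batch.weighed_blend * 100.0


def mass_uniformity(masses: Sequence[float]) -> float:
    """Relative sample SD of capsule masses, percent of the mean."""
    x = np.asarray(masses, dtype=float)
    if x.size < 2:
        raise ValidationError(f"mass_uniformity needs >= 2 masses, got {x.size}")
    return 100.0 * float(np.std(x, ddof=1)) / float(x.mean())


def homogeneity(
    capsules: Sequence[CapsuleObservation],
    shell_tare_mean: float,
    shell_tares: Sequence[float] | None = None,
) -> float:
    """Relative SD (percent) of per-capsule content / net-mass quotients.

    A perfectly homogeneous blend gives a constant quotient (0 %); the
    metric is invariant to the units of content.
    """
    if len(capsules) < 2:
        raise ValidationError("homogeneity needs >= 2 capsules")
    tares = (
        np.asarray(shell_tares, dtype=float)
        if shell_tares is not None
        else np.full(len(capsules), shell_tare_mean)
    )
    net = np.array([c.gross_mass for c in capsules]) - tares
    if np.any(net <= 0):
        bad = int(np.argmax(net <= 0))
        raise ValidationError(
            f"capsule {capsules[bad].index}: non-positive net mass "
            f"({net[bad]:.1f} mg)"
        )
    q = np.array([c.content for c in capsules]) / net
    return 100.0 * float(np.std(q, ddof=1)) / float(q.mean())


@dataclass(frozen=True)
class QCReport:
    """All quality metrics of one batch, plus pass/fail flags.

    Values are unrounded; :meth:`as_row` applies the reporting precision
    (AV 2 dp, percents 2 dp, mean content 0.001 mg).  Flags are evaluated
    on the rounded values, so a batch printing AV 15.00 passes.
    """

    batch_id: str
    acceptance_value: float
    k: float
    mean_content: float
    sd_rel_content: float
    sd_rel_mass: float
    powder_loss: float
    sd_rel_content_mass_ratio: float
    label_claim: float
    n: int
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    @property
    def av_ok(self) -> bool:
        return round(self.acceptance_value, 2) <= self.thresholds.av_limit

    @property
    def loss_ok(self) -> bool:
        return round(self.powder_loss, 2) <= self.thresholds.loss_limit

    @property
    def mass_ok(self) -> bool:
        return round(self.sd_rel_mass, 2) <= self.thresholds.mass_limit

    def as_row(self) -> dict:
        return {
            "batch_id": self.batch_id,
            "av": round(self.acceptance_value, 2),
            "powder_loss_pct": round(self.powder_loss, 2),
            "sd_rel_mass_pct": round(self.sd_rel_mass, 2),
            "sd_rel_content_pct": round(self.sd_rel_content, 2),
            "mean_content_mg": round(self.mean_content, 3),
            "sd_rel_content_mass_pct": round(self.sd_rel_content_mass_ratio, 3),
            "av_ok": self.av_ok,
            "loss_ok": self.loss_ok,
            "mass_ok": self.mass_ok,
        }


def evaluate_batch(
    batch: BatchRecord,
    k: float | None = None,
    thresholds: QCThresholds | None = None,
    use_net_masses: bool = False,
) -> QCReport:
    """Compute every quality metric for a batch.

    ``use_net_masses`` switches mass uniformity from gross filled-capsule
    masses (what a pharmacy weighs) to net fill masses.
    """
    if batch.n < 2:
        raise ValidationError(
            f"batch {batch.batch_id}: >= 2 capsules required for QC"
        )
    thresholds = thresholds or QCThresholds()
    contents = batch.contents()
    pct = batch.contents_pct()
    av = acceptance_value(pct, k)
    masses = batch.net_masses() if use_net_masses else batch.gross_masses()
    return QCReport(
        batch_id=batch.batch_id,
        acceptance_value=av,
        k=default_k(batch.n) if k is None else k,
        mean_content=float(contents.mean()),
        sd_rel_content=100.0 * float(np.std(contents, ddof=1))
        / float(contents.mean()),
        sd_rel_mass=mass_uniformity(masses),
        powder_loss=powder_loss(batch),
        sd_rel_content_mass_ratio=homogeneity(
            batch.capsules, batch.shell_tare_mean, batch.shell_tares
        ),
        label_claim=batch.label_claim,
        n=batch.n,
        thresholds=thresholds,
    )
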