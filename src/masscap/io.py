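"""CSV schemas, configuration, report rendering and published reference data.

All files are plain CSV: comma separator, dot decimal, UTF-8, header row
required.  Column headers carry explicit units (mg, %, g/mL).

Schemas
-------
densities.csv
    agent, replicate, powder_mass_g, bulk_volume_mL, compressed_volume_mL
capsules.csv
    batch_id, label_claim_mg, capsule_index, gross_mass_mg, content_mg
    [, shell_tare_mg]
batch_meta.csv
    batch_id, weighed_api_mg, weighed_blend_mg, shell_tare_mean_mg
residues.csv
    batch_id, device, extraction_volume_mL, n_swabs, recovered_api_mg
summary.csv
    api, label_claim_mg, batch_id, av, powder_loss_pct, sd_rel_mass_pct,
    sd_rel_content_pct, mean_content_mg, sd_rel_content_mass_pct
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .batch_qc import BatchRecord, CapsuleObservation, QCReport, QCThresholds
from .densitometry import DensityMeasurement
from .errors import ValidationError
from .mass_balance import ResidueSample

__all__ = [
    "RunConfig",
    "load_config",
    "read_density_table",
    "read_capsule_table",
    "read_batch_meta",
    "read_residue_table",
    "read_summary_table",
    "write_capsule_table",
    "write_batch_meta",
    "write_residue_table",
    "render_report",
    "reports_to_json",
    "reports_from_json",
    "load_published_summary",
    "load_published_densities",
]

_MODES = ("characterize", "plan", "evaluate", "simulate", "balance", "report")


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: mode, inputs, thresholds, k override, seed."""

    mode: str
    inputs: Mapping[str, str] = field(default_factory=dict)
    k: float | None = None
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    rounding: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValidationError(
                f"mode must be one of {_MODES}, got {self.mode!r}"
            )
        if self.k is not None and self.k <= 0:
            raise ValidationError(f"k override must be > 0, got {self.k}")


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON run configuration."""
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if not isinstance(data, dict):
        raise ValidationError(f"config {path}: expected a mapping")
    thr = data.pop("thresholds", {})
    return RunConfig(
        mode=data.get("mode", "report"),
        inputs=data.get("inputs", {}),
        k=data.get("k"),
        thresholds=QCThresholds(**thr) if thr else QCThresholds(),
        rounding=data.get("rounding", 2),
        seed=data.get("seed", 0),
    )


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    for col in required:
        if col.endswith(("_mg", "_g", "_mL", "_ml", "_pct")) or col in (
            "av", "capsule_index", "replicate", "n_swabs"
        ):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ValidationError(
                    f"{path}: non-numeric value in column {col!r} at row "
                    f"{int(bad[0]) + 2}"  # +2: header + 1-based
                )
            df[col] = coerced
    return df


def read_density_table(path: str | Path) -> dict[str, list[DensityMeasurement]]:
    """densities.csv -> replicate measurements grouped by agent."""
    df = _read_csv(path, ["agent", "replicate", "powder_mass_g",
                          "bulk_volume_mL", "compressed_volume_mL"])
    out: dict[str, list[DensityMeasurement]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["agent"]), []).append(
            DensityMeasurement(
                powder_mass=row["powder_mass_g"],
                bulk_volume=row["bulk_volume_mL"],
                compressed_volume=row["compressed_volume_mL"],
            )
        )
    return out


def read_batch_meta(path: str | Path) -> dict[str, dict]:
    df = _read_csv(path, ["batch_id", "weighed_api_mg", "weighed_blend_mg",
                          "shell_tare_mean_mg"])
    dup = df["batch_id"][df["batch_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate batch_id {dup.iloc[0]!r}")
    return {
        str(r["batch_id"]): {
            "weighed_api": float(r["weighed_api_mg"]),
            "weighed_blend": float(r["weighed_blend_mg"]),
            "shell_tare_mean": float(r["shell_tare_mean_mg"]),
        }
        for _, r in df.iterrows()
    }


def read_capsule_table(
    path: str | Path, meta: Mapping[str, dict] | str | Path | None = None
) -> list[BatchRecord]:
    """capsules.csv (+ optional batch_meta.csv) -> validated BatchRecords.

    Rows are grouped by batch_id; duplicate (batch_id, capsule_index) pairs
    are rejected with the offending row number.  Without metadata the
    weighed masses are reconstructed as the sums over capsules (loss 0).
    """
    df = _read_csv(path, ["batch_id", "label_claim_mg", "capsule_index",
                          "gross_mass_mg", "content_mg"])
    if isinstance(meta, (str, Path)):
        meta = read_batch_meta(meta)
    dup_mask = df.duplicated(subset=["batch_id", "capsule_index"])
    if dup_mask.any():
        row = int(df.index[dup_mask][0]) + 2
        raise ValidationError(
            f"{path}: duplicate (batch_id, capsule_index) at row {row}"
        )
    has_tares = "shell_tare_mg" in df.columns
    records = []
    for batch_id, g in df.groupby("batch_id", sort=False):
        claims = g["label_claim_mg"].unique()
        if len(claims) != 1:
            raise ValidationError(
                f"{path}: batch {batch_id!r} has inconsistent label claims "
                f"{sorted(claims)}"
            )
        capsules = tuple(
            CapsuleObservation(
                index=int(r["capsule_index"]),
                gross_mass=float(r["gross_mass_mg"]),
                content=float(r["content_mg"]),
            )
            for _, r in g.iterrows()
        )
        tares = (
            tuple(float(t) for t in g["shell_tare_mg"]) if has_tares else None
        )
        m = (meta or {}).get(str(batch_id))
        if m is None:
            tare_mean = (
                sum(tares) / len(tares) if tares else 74.0
            )
            net = sum(c.gross_mass for c in capsules) - tare_mean * len(capsules)
            m = {
                "weighed_api": sum(c.content for c in capsules),
                "weighed_blend": max(net, 1e-9),
                "shell_tare_mean": tare_mean,
            }
        records.append(
            BatchRecord(
                batch_id=str(batch_id),
                label_claim=float(claims[0]),
                capsules=capsules,
                shell_tares=tares,
                **m,
            )
        )
    return records


def read_residue_table(path: str | Path) -> dict[str, list[ResidueSample]]:
    df = _read_csv(path, ["batch_id", "device", "extraction_volume_mL",
                          "n_swabs", "recovered_api_mg"])
    out: dict[str, list[ResidueSample]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["batch_id"]), []).append(
            ResidueSample(
                device=str(r["device"]),
                recovered_api=float(r["recovered_api_mg"]),
                extraction_volume=float(r["extraction_volume_mL"]),
                n_swabs=int(r["n_swabs"]),
            )
        )
    return out


_SUMMARY_COLS = [
    "batch_id", "av", "powder_loss_pct", "sd_rel_mass_pct",
    "sd_rel_content_pct", "mean_content_mg", "sd_rel_content_mass_pct",
]


def read_summary_table(path: str | Path) -> pd.DataFrame:
    """Per-batch summary table (the published-table column set)."""
    return _read_csv(path, ["label_claim_mg"] + _SUMMARY_COLS)


def reevaluate_summary(df: pd.DataFrame, k: float = 2.0) -> pd.DataFrame:
    """Recompute the AV from each summary row and classify compliance.

    Adds ``av_recomputed`` (from mean content, relative content SD and
    label claim with the given k) and ``compliant`` (printed AV <= 15 after
    2-dp rounding) columns.
    """
    from .batch_qc import AV_LIMIT, acceptance_value_from_summary

    out = df.copy()
    out["av_recomputed"] = [
        round(
            acceptance_value_from_summary(
                r["mean_content_mg"], r["sd_rel_content_pct"],
                r["label_claim_mg"], k,
            ),
            2,
        )
        for _, r in df.iterrows()
    ]
    out["compliant"] = out["av"].round(2) <= AV_LIMIT
    return out


def write_capsule_table(records: Sequence[BatchRecord], path: str | Path) -> None:
    rows = []
    for b in records:
        tares = b.shell_tares
        for i, c in enumerate(b.capsules):
            row = {
                "batch_id": b.batch_id,
                "label_claim_mg": b.label_claim,
                "capsule_index": c.index,
                "gross_mass_mg": c.gross_mass,
                "content_mg": c.content,
            }
            if tares is not None:
                row["shell_tare_mg"] = tares[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_batch_meta(records: Sequence[BatchRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "batch_id": b.batch_id,
                "weighed_api_mg": b.weighed_api,
                "weighed_blend_mg": b.weighed_blend,
                "shell_tare_mean_mg": b.shell_tare_mean,
            }
            for b in records
        ]
    ).to_csv(path, index=False)


def write_residue_table(
    residues: Mapping[str, Sequence[ResidueSample]], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "batch_id": batch_id,
                "device": r.device,
                "extraction_volume_mL": r.extraction_volume,
                "n_swabs": r.n_swabs,
                "recovered_api_mg": r.recovered_api,
            }
            for batch_id, rs in residues.items()
            for r in rs
        ]
    ).to_csv(path, index=False)


def render_report(reports: Sequence[QCReport]) -> str:
    """Fixed-width text table, one row per batch (published-table layout)."""
    if not reports:
        raise ValidationError("render_report needs >= 1 report")
    header = (
        f"{'Batch':<16}{'AV':>7}{'Loss[%]':>9}{'SDrel Mass[%]':>15}"
        f"{'SDrel Cont[%]':>15}{'Mean Cont[mg]':>15}{'SDrel C/M[%]':>14}"
        f"{'Flags':>18}"
    )
    lines = [header, "-" * len(header)]
    for r in reports:
        row = r.as_row()
        flags = " ".join(
            name for name, ok in
            (("AV", row["av_ok"]), ("loss", row["loss_ok"]),
             ("mass", row["mass_ok"])) if not ok
        )
        lines.append(
            f"{row['batch_id']:<16}{row['av']:>7.2f}"
            f"{row['powder_loss_pct']:>9.2f}{row['sd_rel_mass_pct']:>15.2f}"
            f"{row['sd_rel_content_pct']:>15.2f}"
            f"{row['mean_content_mg']:>15.3f}"
            f"{row['sd_rel_content_mass_pct']:>14.3f}"
            f"{('FAIL: ' + flags) if flags else 'ok':>18}"
        )
    return "\n".join(lines)


def reports_to_json(reports: Sequence[QCReport]) -> str:
    return json.dumps([r.as_row() for r in reports], indent=2)


def reports_from_json(text: str) -> list[dict]:
    return json.loads(text)


def _package_csv(name: str) -> pd.DataFrame:
    with resources.files("masscap.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_published_summary() -> pd.DataFrame:
    """The 54 published batch summaries (6 tables x 9 batches)."""
    return _package_csv("published_batch_summary.csv")


def load_published_densities() -> pd.DataFrame:
    """Published density characterization of the three bulking agents."""
    return _package_csv("published_densities.csv")
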