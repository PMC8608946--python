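"""Session-level pipelines: tables (or images) in, per-model moduli and
per-sample summaries out.

A measurement session is a set of repeated observations on one gel.  The
indentation pipeline resolves each row's depth (directly from the CSV or by
analysing a referenced photograph), evaluates all four indentation models,
and pools repeats into a mean +/- SD of the fully corrected modulus.  The
aspiration pipeline does the analogous job over a pressure sweep.  Rows
that cannot be resolved are reported with a reason and skipped — the
pipeline is fail-soft.

Displayed percentage differences are truncated (not rounded) to integer
percent; numeric columns always keep full precision.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aspiration import (
    AspirationMeasurement,
    AspirationSummary,
    PipetteSpec,
    aggregate_aspiration,
)
from .constitutive import CompressionCurve, compare_fits
from .imaging import analyze_aspiration_image, analyze_indentation_image
from .indentation import (
    GelCylinder,
    IndentationMeasurement,
    IndenterSpec,
    dimitriadis_modulus,
    hertz_estimate,
    nh_fdh_modulus,
    nh_fh_modulus,
)

__all__ = [
    "SessionSummary",
    "ComparisonReport",
    "percent_difference_truncated",
    "run_indentation_pipeline",
    "run_aspiration_pipeline",
    "run_compression_pipeline",
    "build_comparison_report",
    "provenance",
]

RECOMMENDED_REPEATS = 10


@dataclass(frozen=True)
class SessionSummary:
    sample_id: str
    method: str  # "macroindentation" | "aspiration" | "compression"
    n: int
    E_mean_kpa: float
    E_sd_kpa: float
    warnings: tuple[str, ...]


@dataclass(frozen=True)
class ComparisonReport:
    table: pd.DataFrame  # one row per sample, one column per method
    ratios: pd.DataFrame  # max/min ratio and flag per sample
    percent_matrix: dict  # sample -> method-pair -> truncated integer percent


def percent_difference_truncated(a: float, b: float) -> int:
    """100 (a - b)/a truncated toward zero to an integer percent."""
    if a == 0:
        raise ZeroDivisionError("reference value is zero")
    return math.trunc(100.0 * (a - b) / a)


def _load_table(table: pd.DataFrame | str | Path) -> pd.DataFrame:
    if isinstance(table, (str, Path)):
        return pd.read_csv(table)
    return table.copy()


def run_indentation_pipeline(
    table: pd.DataFrame | str | Path,
    image_dir: str | Path | None = None,
) -> tuple[dict[str, SessionSummary], pd.DataFrame, list[dict]]:
    """Per-row moduli under all four models plus per-sample summaries.

    The CSV needs columns sample_id, sphere_label, sphere_mass_mg,
    sphere_radius_mm, delta_mm, h_mm, D_mm; an optional overload_mass_mg
    column and an image_path column (used to fill delta/h/D for rows whose
    delta_mm is missing).  Returns (summaries by sample, per-row records,
    list of skipped rows with reasons).
    """
    df = _load_table(table)
    records: list[dict] = []
    failures: list[dict] = []
    for idx, row in df.iterrows():
        try:
            delta = row.get("delta_mm")
            h = row.get("h_mm")
            D = row.get("D_mm")
            if pd.isna(delta):
                image_path = row.get("image_path")
                if pd.isna(image_path) or image_path is None:
                    raise ValueError("delta_mm missing and no image_path given")
                import imageio.v3 as iio

                path = Path(image_dir or ".") / str(image_path)
                result = analyze_indentation_image(
                    iio.imread(path), float(row["sphere_radius_mm"])
                )
                delta = result.delta_mm
                if pd.isna(h):
                    h = result.h_mm
                if pd.isna(D):
                    D = result.D_mm
            indenter = IndenterSpec(
                label=str(row.get("sphere_label", "")),
                mass_mg=float(row["sphere_mass_mg"]),
                radius_mm=float(row["sphere_radius_mm"]),
                overload_mass_mg=float(row.get("overload_mass_mg", 0.0) or 0.0),
            )
            gel = GelCylinder(height_mm=float(h), diameter_mm=float(D))
            m = IndentationMeasurement(
                indenter, gel, float(delta), sample_id=str(row["sample_id"])
            )
        except Exception as exc:  # fail-soft: keep going on remaining rows
            failures.append({"row": int(idx), "reason": str(exc)})
            continue
        est_h = hertz_estimate(m)
        est_hfh = dimitriadis_modulus(m)
        est_nhfh = nh_fh_modulus(m)
        est_nhfdh = nh_fdh_modulus(m)
        records.append(
            {
                "sample_id": m.sample_id,
                "delta_mm": m.delta_mm,
                "delta_over_h": m.delta_over_h,
                "E_H_kpa": est_h.E_kpa,
                "E_H_fh_kpa": est_hfh.E_kpa,
                "E_NH_fh_kpa": est_nhfh.E_kpa,
                "E_NH_fdh_kpa": est_nhfdh.E_kpa,
                "f_factor": est_nhfdh.f_factor,
                "g_factor": est_nhfdh.g_factor,
                "flags": ";".join(est_nhfdh.validity),
            }
        )
    records_df = pd.DataFrame(records)
    summaries: dict[str, SessionSummary] = {}
    if not records_df.empty:
        for sample_id, group in records_df.groupby("sample_id", sort=False):
            E = group["E_NH_fdh_kpa"].to_numpy()
            warnings = sorted(
                {f for flags in group["flags"] for f in flags.split(";") if f}
            )
            if len(E) < RECOMMENDED_REPEATS:
                warnings.append("small_n")
            summaries[sample_id] = SessionSummary(
                sample_id=sample_id,
                method="macroindentation",
                n=len(E),
                E_mean_kpa=float(E.mean()),
                E_sd_kpa=float(E.std(ddof=1)) if len(E) > 1 else 0.0,
                warnings=tuple(warnings),
            )
    return summaries, records_df, failures


def run_aspiration_pipeline(
    table: pd.DataFrame | str | Path,
    pipette: PipetteSpec | None = None,
    image_dir: str | Path | None = None,
) -> tuple[dict[str, SessionSummary], dict[str, AspirationSummary], list[dict]]:
    """Aggregate a pressure-sweep CSV (sample_id, pressure_kpa, length_mm
    or image_path, optional pipette_a_mm / pipette_A_mm columns)."""
    df = _load_table(table)
    failures: list[dict] = []
    by_sample: dict[str, list[AspirationMeasurement]] = {}
    pipettes: dict[str, PipetteSpec] = {}
    for idx, row in df.iterrows():
        try:
            sid = str(row["sample_id"])
            pip = pipette or PipetteSpec(
                internal_radius_mm=float(row.get("pipette_a_mm", 0.375) or 0.375),
                external_radius_mm=float(row.get("pipette_A_mm", 0.5) or 0.5),
            )
            length = row.get("length_mm")
            if pd.isna(length):
                image_path = row.get("image_path")
                if pd.isna(image_path) or image_path is None:
                    raise ValueError("length_mm missing and no image_path given")
                import imageio.v3 as iio

                path = Path(image_dir or ".") / str(image_path)
                result = analyze_aspiration_image(
                    iio.imread(path), pip.external_radius_mm
                )
                length = result.l_mm
            by_sample.setdefault(sid, []).append(
                AspirationMeasurement(float(row["pressure_kpa"]), float(length), sid)
            )
            pipettes[sid] = pip
        except Exception as exc:
            failures.append({"row": int(idx), "reason": str(exc)})
    summaries: dict[str, SessionSummary] = {}
    details: dict[str, AspirationSummary] = {}
    for sid, series in by_sample.items():
        agg = aggregate_aspiration(series, pipettes[sid], sample_id=sid)
        details[sid] = agg
        warnings = list(agg.warnings)
        if agg.n < RECOMMENDED_REPEATS and "small_n" not in warnings:
            warnings.append("small_n")
        summaries[sid] = SessionSummary(
            sample_id=sid,
            method="aspiration",
            n=agg.n,
            E_mean_kpa=agg.E_mean_kpa,
            E_sd_kpa=agg.E_sd_kpa,
            warnings=tuple(sorted(warnings)),
        )
    return summaries, details, failures


def run_compression_pipeline(
    table: pd.DataFrame | str | Path,
) -> tuple[dict[str, SessionSummary], dict[str, dict], list[dict]]:
    """Fit long-format compression data (sample_id, strain, stress_kpa)."""
    df = _load_table(table)
    failures: list[dict] = []
    summaries: dict[str, SessionSummary] = {}
    comparisons: dict[str, dict] = {}
    for sid, group in df.groupby("sample_id", sort=False):
        try:
            curve = CompressionCurve(
                group["strain"].to_numpy(),
                group["stress_kpa"].to_numpy(),
                sample_id=str(sid),
            )
            comp = compare_fits(curve)
        except Exception as exc:
            failures.append({"row": str(sid), "reason": str(exc)})
            continue
        comparisons[str(sid)] = comp
        best = comp["fits"][comp["preferred"]]
        summaries[str(sid)] = SessionSummary(
            sample_id=str(sid),
            method="compression",
            n=int(curve.strain.size),
            E_mean_kpa=best.E_kpa,
            E_sd_kpa=0.0,
            warnings=(),
        )
    return summaries, comparisons, failures


RATIO_FLAG_THRESHOLD = 3.0


def build_comparison_report(
    summaries: list[SessionSummary],
    external: dict[str, dict[str, float]] | None = None,
) -> ComparisonReport:
    """Cross-method modulus grid with per-sample max/min ratios.

    ``external`` supplies extra per-sample scalars from instruments outside
    this package (e.g. AFM or rheometry), keyed sample -> method -> E kPa.
    Samples whose spread exceeds a 3x ratio are flagged.
    """
    cells: dict[str, dict[str, float]] = {}
    for s in summaries:
        cells.setdefault(s.sample_id, {})[s.method] = s.E_mean_kpa
    for sid, methods in (external or {}).items():
        for method, value in methods.items():
            cells.setdefault(sid, {})[method] = float(value)
    table = pd.DataFrame.from_dict(cells, orient="index").sort_index()
    ratios = []
    percent_matrix: dict[str, dict[str, int]] = {}
    for sid, row in table.iterrows():
        values = row.dropna()
        if len(values) < 2:
            ratio = float("nan")
        else:
            ratio = float(values.max() / values.min())
        ratios.append(
            {
                "sample_id": sid,
                "max_min_ratio": ratio,
                "flag": bool(ratio > RATIO_FLAG_THRESHOLD)
                if not math.isnan(ratio)
                else False,
            }
        )
        pairs = {}
        methods = list(values.index)
        for i, a in enumerate(methods):
            for b in methods[i + 1 :]:
                pairs[f"{a}_vs_{b}"] = percent_difference_truncated(
                    values[a], values[b]
                )
        percent_matrix[sid] = pairs
    return ComparisonReport(
        table=table,
        ratios=pd.DataFrame(ratios).set_index("sample_id"),
        percent_matrix=percent_matrix,
    )


def provenance(
    config: dict | None = None, inputs: list[str | Path] | None = None
) -> dict:
    """Provenance block embedded in every output file: tool version,
    canonical config hash and input checksums."""
    cfg = json.dumps(config or {}, sort_keys=True)
    block = {
        "tool": "gelmech",
        "version": __version__,
        "config_hash": hashlib.sha256(cfg.encode()).hexdigest()[:16],
        "inputs": {},
    }
    for path in inputs or []:
        p = Path(path)
        block["inputs"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    return block
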