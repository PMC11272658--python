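"""Tabular I/O and the cohort → WSS-table driver.

Reads per-animal cohort CSVs and per-group plasma-viscosity tables,
computes tidy per-record WSS results under the selected methods, and
summarizes them per sex × phase × method (mean ± SD), mirroring the usual
hemodynamic-parameters table layout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import defaults
from .core import (
    HemodynamicRecord,
    apparent_viscosity,
    wss_corrected_newtonian,
    wss_fahraeus,
    wss_theoretical_newtonian,
    wss_tn_from_hematocrit,
)
from .errors import FormatError

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort",
    "read_groups",
    "records_from_frame",
    "compute_wss_table",
    "summarize_wss",
    "write_summary_json",
]

COHORT_COLUMNS = (
    "animal_id",
    "sex",
    "phase",
    "diameter_mm",
    "vmax_mm_s",
    "hematocrit",
    "eta_b_cP",
)
GROUP_COLUMNS = ("sex", "eta_p_cP")

CN_VARIANTS = ("plasma", "blood", "apparent")


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a per-animal cohort CSV (one row per animal × phase)."""
    df = pd.read_csv(path)
    _require_columns(df, COHORT_COLUMNS, f"cohort file {path}")
    return df


def read_groups(path: str | Path) -> pd.DataFrame:
    """Read the per-sex group table carrying pooled plasma viscosity."""
    df = pd.read_csv(path)
    _require_columns(df, GROUP_COLUMNS, f"group file {path}")
    return df


def records_from_frame(df: pd.DataFrame) -> list[HemodynamicRecord]:
    _require_columns(df, COHORT_COLUMNS, "cohort frame")
    return [
        HemodynamicRecord(
            animal_id=str(row.animal_id),
            sex=str(row.sex),
            phase=str(row.phase),
            diameter_mm=float(row.diameter_mm),
            vmax_mm_s=float(row.vmax_mm_s),
            hematocrit=float(row.hematocrit),
            heart_rate_bpm=float(row.heart_rate_bpm)
            if "heart_rate_bpm" in df.columns
            else None,
        )
        for row in df.itertuples()
    ]


def compute_wss_table(
    cohort: pd.DataFrame,
    groups: pd.DataFrame,
    methods: Sequence[str] = ("tN", "cN", "F"),
    cn_variants: Sequence[str] = CN_VARIANTS,
    correction_factor: float = defaults.APPARENT_VISCOSITY_FACTOR,
    vmax_vm_ratio: float = defaults.VMAX_VM_RATIO,
    exact_coefficient: bool = False,
    regression_viscosity: bool = False,
) -> pd.DataFrame:
    """Tidy per-record WSS table for the requested methods.

    The cN method is computed once per requested viscosity variant
    (plasma ηp, whole-blood ηb, apparent 1.78·ηp). With
    ``regression_viscosity`` the tN method takes its viscosity from the
    hematocrit regression instead of the measured ηb column.
    """
    unknown = set(methods) - {"tN", "cN", "F"}
    if unknown:
        raise FormatError(f"unknown method(s): {sorted(unknown)}")
    _require_columns(groups, GROUP_COLUMNS, "group frame")
    eta_p_by_sex = dict(zip(groups["sex"], groups["eta_p_cP"]))
    rows = []
    for rec_row, record in zip(cohort.itertuples(), records_from_frame(cohort)):
        eta_b = float(rec_row.eta_b_cP)
        try:
            eta_p = float(eta_p_by_sex[record.sex])
        except KeyError:
            raise FormatError(
                f"group table has no plasma viscosity for sex {record.sex!r}"
            ) from None
        results = []
        if "tN" in methods:
            if regression_viscosity:
                results.append(wss_tn_from_hematocrit(record))
            else:
                results.append(wss_theoretical_newtonian(record, eta_b))
        if "cN" in methods:
            variant_eta = {
                "plasma": eta_p,
                "blood": eta_b,
                "apparent": apparent_viscosity(eta_p, correction_factor),
            }
            for variant in cn_variants:
                results.append(
                    wss_corrected_newtonian(
                        record,
                        variant_eta[variant],
                        vmax_vm_ratio,
                        exact_coefficient=exact_coefficient,
                        viscosity_variant=variant,
                    )
                )
        if "F" in methods:
            results.append(wss_fahraeus(record, eta_p))
        for res in results:
            rows.append(
                {
                    "animal_id": record.animal_id,
                    "sex": record.sex,
                    "phase": record.phase,
                    "method": res.method,
                    "viscosity_variant": res.viscosity_variant,
                    "viscosity_cP": res.viscosity_used_cp,
                    "shear_rate_per_s": res.shear_rate_per_s,
                    "wss_pa": res.wss_pa,
                }
            )
    return pd.DataFrame(rows)


def summarize_wss(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD of WSS per sex × phase × method (× cN viscosity variant)."""
    grouped = table.groupby(
        ["sex", "phase", "method", "viscosity_variant"], dropna=False, sort=True
    )["wss_pa"]
    out = grouped.agg(n="count", mean_pa="mean", sd_pa="std").reset_index()
    out["sd_pa"] = out["sd_pa"].fillna(0.0)
    return out


def write_summary_json(summary: pd.DataFrame, path: str | Path) -> None:
    """Write the sex × phase × method summary as nested JSON."""
    payload: dict = {}
    for row in summary.itertuples():
        method = row.method + (f"({row.viscosity_variant})" if row.viscosity_variant else "")
        payload.setdefault(row.sex, {}).setdefault(row.phase, {})[method] = {
            "n": int(row.n),
            "mean_pa": round(float(row.mean_pa), 4),
            "sd_pa": round(float(row.sd_pa), 4),
        }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
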