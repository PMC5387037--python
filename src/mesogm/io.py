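"""Configuration files and CSV exchange.

Configs are YAML with two nested blocks (`photo`, `resistance`) plus flat
scenario keys.  CSV columns carry their units in the header
(ci_ubar, a_umol, ...) to keep ubar/Pa confusion out of data files;
parsing is header-keyed so column order never matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimation import GasExchangeRecord
from .kinetics import PhotoParams
from .network import OperatingPoint, ResistanceParams

__all__ = [
    "ScenarioConfig",
    "load_config",
    "config_from_dict",
    "write_curve",
    "read_curve",
    "read_records",
    "write_records",
]

log = logging.getLogger("mesogm")

CURVE_COLUMNS = [
    "ci_ubar",
    "cc_ubar",
    "cm_outer_ubar",
    "a_umol",
    "vc_umol",
    "f_umol",
    "limitation",
    "gm_app",
]

_PHOTO_KEYS = {"Vcmax", "J", "Rd", "KmC", "KmO", "Sco", "O", "et_form"}
_RES_KEYS = {"gm_dif", "omega", "sigma", "lam", "k", "rsc"}


@dataclass(frozen=True)
class ScenarioConfig:
    """A full simulation/estimation scenario."""

    photo: PhotoParams
    resistance: ResistanceParams
    ci_start: float = 50.0
    ci_stop: float = 400.0
    ci_step: float = 10.0
    o2_levels: tuple[float, ...] = (20.0, 210.0, 400.0)
    noise_sd: float = 0.2
    seed: int = 0
    output_path: str | None = None

    def __post_init__(self) -> None:
        if self.ci_start <= 0 or self.ci_step <= 0 or self.ci_stop <= self.ci_start:
            raise ValueError(
                f"invalid Ci grid: start={self.ci_start}, stop={self.ci_stop}, "
                f"step={self.ci_step}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if any(o <= 0 for o in self.o2_levels):
            raise ValueError(f"O2 levels must be positive, got {self.o2_levels}")

    @property
    def ci_grid(self) -> np.ndarray:
        return np.arange(self.ci_start, self.ci_stop + 0.5 * self.ci_step, self.ci_step)


def load_config(path: str | Path) -> ScenarioConfig:
    """Read and validate a YAML scenario config.

    All validation failures are collected and reported together; applied
    defaults (ambient O2, stomatal resistance) are logged.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw, source=str(path))


def config_from_dict(raw: dict, source: str = "<dict>") -> ScenarioConfig:
    """Validate a raw config mapping (the path-free core of load_config)."""
    path = source
    errors: list[str] = []

    photo_raw = dict(raw.get("photo") or {})
    res_raw = dict(raw.get("resistance") or {})
    for block, allowed, given in (
        ("photo", _PHOTO_KEYS, photo_raw),
        ("resistance", _RES_KEYS, res_raw),
    ):
        for key in set(given) - allowed:
            errors.append(f"{block}: unknown key '{key}'")
    for key in ("Vcmax", "J", "Rd", "KmC", "KmO", "Sco"):
        if key not in photo_raw:
            errors.append(f"photo: missing required key '{key}'")
    for key in ("gm_dif", "omega"):
        if key not in res_raw:
            errors.append(f"resistance: missing required key '{key}'")
    if "sigma" not in res_raw and "lam" not in res_raw:
        errors.append("resistance: one of 'sigma' or 'lam' is required")

    photo = res = None
    if not errors:
        if "O" not in photo_raw:
            log.info("photo.O not given; defaulting to ambient 210 mbar")
        try:
            photo = PhotoParams(**photo_raw)
        except (ValueError, TypeError) as exc:
            errors.append(f"photo: {exc}")
        if "rsc" not in res_raw:
            log.info("resistance.rsc not given; defaulting to r_m,dif = 1/gm_dif")
        try:
            res = ResistanceParams(**res_raw)
        except (ValueError, TypeError) as exc:
            errors.append(f"resistance: {exc}")

    scenario_raw = {
        k: v for k, v in raw.items() if k not in ("photo", "resistance")
    }
    if "o2_levels" in scenario_raw:
        scenario_raw["o2_levels"] = tuple(scenario_raw["o2_levels"])
    cfg = None
    if not errors:
        try:
            cfg = ScenarioConfig(photo=photo, resistance=res, **scenario_raw)
        except (ValueError, TypeError) as exc:
            errors.append(f"scenario: {exc}")
    if errors:
        raise ValueError(
            f"invalid config {path}:\n  " + "\n  ".join(errors)
        )
    return cfg


def write_curve(points: list[OperatingPoint], path: str | Path) -> None:
    """Write operating points as CSV with the fixed unit-bearing header."""
    rows = [
        {
            "ci_ubar": pt.Ci,
            "cc_ubar": pt.Cc,
            "cm_outer_ubar": pt.Cm_outer,
            "a_umol": pt.A,
            "vc_umol": pt.Vc,
            "f_umol": pt.F,
            "limitation": pt.limitation.value,
            "gm_app": pt.gm_app,
        }
        for pt in points
    ]
    pd.DataFrame(rows, columns=CURVE_COLUMNS).to_csv(path, index=False)


def read_curve(path: str | Path) -> list[OperatingPoint]:
    """Read a curve CSV back into operating points (header-keyed)."""
    df = pd.read_csv(path)
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"curve file {path} lacks columns {sorted(missing)}")
    from .kinetics import Limitation

    return [
        OperatingPoint(
            Ci=row.ci_ubar,
            Cc=row.cc_ubar,
            Cm_outer=row.cm_outer_ubar,
            A=row.a_umol,
            Vc=row.vc_umol,
            F=row.f_umol,
            limitation=Limitation(row.limitation),
            gm_app=row.gm_app,
        )
        for row in df.itertuples()
    ]


def write_records(records: list[GasExchangeRecord], path: str | Path) -> None:
    """Write gas-exchange records as CSV."""
    rows = [
        {
            "ci_ubar": rec.Ci,
            "a_umol": rec.A,
            "j_umol": rec.J,
            "o_mbar": rec.O,
            "rd_umol": rec.Rd,
            "true_cc_ubar": rec.true_Cc,
            "noise_sd": rec.noise_sd,
        }
        for rec in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "ci_ubar",
            "a_umol",
            "j_umol",
            "o_mbar",
            "rd_umol",
            "true_cc_ubar",
            "noise_sd",
        ],
    ).to_csv(path, index=False)


def read_records(
    path: str | Path, default_rd: float = 0.0
) -> list[GasExchangeRecord]:
    """Read gas-exchange records from CSV.

    Requires ci_ubar, a_umol, j_umol, o_mbar; rd_umol falls back to
    `default_rd`.  Column order is irrelevant; a malformed row raises an
    error naming its (1-based data) row number.
    """
    df = pd.read_csv(path)
    required = {"ci_ubar", "a_umol", "j_umol", "o_mbar"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records file {path} lacks columns {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(), start=1):
        try:
            rd = getattr(row, "rd_umol", None)
            rd = default_rd if rd is None or pd.isna(rd) else float(rd)
            cc = getattr(row, "true_cc_ubar", None)
            cc = None if cc is None or pd.isna(cc) else float(cc)
            sd = getattr(row, "noise_sd", 0.0)
            sd = 0.0 if sd is None or pd.isna(sd) else float(sd)
            out.append(
                GasExchangeRecord(
                    Ci=float(row.ci_ubar),
                    A=float(row.a_umol),
                    J=float(row.j_umol),
                    O=float(row.o_mbar),
                    Rd=rd,
                    true_Cc=cc,
                    noise_sd=sd,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"records file {path}, row {i}: {exc}") from exc
    return out
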