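"""Text interchange formats and run configuration.

Curves travel as delimited text (tab default, comma accepted): a block of
``# key: value`` metadata lines, a header row naming the columns with unit
suffixes (``tau_s``, ``value``, optional ``snr``), then the data. Round trips
are lossless to 12 significant digits. Run configuration is a
schema-validated JSON or YAML document whose defaults match the standard
fitting protocol.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .media import CorrelationCurve, LayeredMedium, OpticalLayer

__all__ = [
    "write_curve",
    "read_curve",
    "load_curve",
    "CurveParseError",
    "LayerConfig",
    "MediumConfig",
    "GeometryConfig",
    "FitConfig",
    "SimulateConfig",
    "RunConfig",
]


class CurveParseError(ValueError):
    """Malformed curve file; the message names the offending line."""


_FLOAT_FMT = "{:.12g}"


def write_curve(
    curve: CorrelationCurve,
    path: str | Path,
    metadata: Optional[dict] = None,
    delimiter: str = "\t",
) -> None:
    """Serialize a curve with a ``# key: value`` metadata block."""
    path = Path(path)
    meta = {
        "kind": curve.kind,
        "n_snapshots": curve.n_snapshots,
        "units": "tau in s, value dimensionless, snr dimensionless",
    }
    if metadata:
        meta.update(metadata)
    cols = ["tau_s", "value"] + (["snr"] if curve.snr is not None else [])
    lines = [f"# {key}: {value}" for key, value in meta.items()]
    lines.append(delimiter.join(cols))
    for i in range(len(curve)):
        row = [_FLOAT_FMT.format(curve.tau[i]), _FLOAT_FMT.format(curve.values[i])]
        if curve.snr is not None:
            row.append(_FLOAT_FMT.format(curve.snr[i]))
        lines.append(delimiter.join(row))
    path.write_text("\n".join(lines) + "\n")


def load_curve(path: str | Path) -> tuple[CorrelationCurve, dict]:
    """Parse a curve file; returns (curve, metadata)."""
    path = Path(path)
    meta: dict = {}
    header: Optional[list[str]] = None
    delimiter = "\t"
    tau, values, snr = [], [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        if header is None:
            delimiter = "," if ("," in line and "\t" not in line) else "\t"
            header = [c.strip() for c in line.split(delimiter)]
            if header[:2] != ["tau_s", "value"]:
                raise CurveParseError(
                    f"{path}:{lineno}: header must start with 'tau_s', 'value' "
                    f"(got {header})"
                )
            if len(header) > 2 and header[2] != "snr":
                raise CurveParseError(
                    f"{path}:{lineno}: third column must be 'snr', got {header[2]!r}"
                )
            continue
        fields = [c.strip() for c in line.split(delimiter)]
        if len(fields) != len(header):
            raise CurveParseError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
            )
        try:
            row = [float(f) for f in fields]
        except ValueError as exc:
            raise CurveParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        tau.append(row[0])
        values.append(row[1])
        if len(header) > 2:
            snr.append(row[2])
    if header is None or not tau:
        raise CurveParseError(f"{path}: no data rows found")
    tau_arr = np.asarray(tau)
    if np.any(np.diff(tau_arr) <= 0):
        bad = int(np.argmax(np.diff(tau_arr) <= 0)) + 2
        raise CurveParseError(
            f"{path}: tau not strictly increasing at data row {bad}"
        )
    kind = meta.get("kind", "g1")
    try:
        curve = CorrelationCurve(
            tau_arr,
            np.asarray(values),
            kind=kind,  # type: ignore[arg-type]
            snr=np.asarray(snr) if snr else None,
            n_snapshots=int(meta.get("n_snapshots", 1)),
        )
    except ValueError as exc:
        raise CurveParseError(f"{path}: {exc}") from None
    return curve, meta


def read_curve(path: str | Path) -> CorrelationCurve:
    """Parse a curve file, discarding metadata."""
    return load_curve(path)[0]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


class LayerConfig(BaseModel):
    mu_a_cm1: float = Field(gt=0)
    mu_s_prime_cm1: float = Field(gt=0)
    n_refr: float = Field(default=1.33, ge=1)
    d_b_cm2_s: float = Field(default=0.0, ge=0)
    thickness_mm: Optional[float] = Field(default=None, gt=0)

    def to_layer(self) -> OpticalLayer:
        return OpticalLayer(
            mu_a=self.mu_a_cm1,
            mu_s_prime=self.mu_s_prime_cm1,
            n_refr=self.n_refr,
            d_b=self.d_b_cm2_s,
            thickness=None if self.thickness_mm is None else self.thickness_mm / 10.0,
        )


class MediumConfig(BaseModel):
    layers: list[LayerConfig]
    boundary_length_mode: str = "extrapolated"

    @model_validator(mode="after")
    def _check(self) -> "MediumConfig":
        if len(self.layers) not in (1, 2):
            raise ValueError("medium must have 1 or 2 layers")
        if self.layers[-1].thickness_mm is not None:
            raise ValueError("the last layer must be semi-infinite (no thickness)")
        if self.boundary_length_mode not in ("extrapolated", "mfp"):
            raise ValueError("boundary_length_mode must be 'extrapolated' or 'mfp'")
        return self

    def to_medium(self) -> LayeredMedium:
        return LayeredMedium(
            [lc.to_layer() for lc in self.layers], self.boundary_length_mode
        )


class GeometryConfig(BaseModel):
    sd_mm: list[float] = Field(default=[10.0, 15.0, 20.0, 25.0])
    wavelength_nm: float = Field(default=785.0, gt=0)
    beta: float = Field(default=0.5, gt=0, le=1)

    @field_validator("sd_mm")
    @classmethod
    def _positive(cls, v: list[float]) -> list[float]:
        if not v or any(x <= 0 for x in v):
            raise ValueError("sd_mm must be positive")
        return v


class FitConfig(BaseModel):
    tau_min_s: float = Field(default=1e-6, gt=0)
    tau_max_s: float = Field(default=3e-3, gt=0)
    d1_bounds_mm: tuple[float, float] = (0.0, 20.0)
    db2_bounds_cm2_s: tuple[float, float] = (0.0, 1e-6)
    beta_window_s: tuple[float, float] = (0.5e-6, 0.8e-6)
    conventional_cutoff: float = Field(default=0.7, gt=0, lt=1)
    snr_weighting: bool = True

    @model_validator(mode="after")
    def _ordered(self) -> "FitConfig":
        for lo, hi, name in (
            (self.tau_min_s, self.tau_max_s, "tau range"),
            (*self.d1_bounds_mm, "d1 bounds"),
            (*self.db2_bounds_cm2_s, "db2 bounds"),
            (*self.beta_window_s, "beta window"),
        ):
            if lo >= hi:
                raise ValueError(f"{name} is inverted ({lo} >= {hi})")
        return self


class SimulateConfig(BaseModel):
    duration_s: float = Field(default=100.0, gt=0)
    rate_hz: float = Field(default=2.0, gt=0)
    count_rate: float = Field(default=5e4, gt=0)
    seed: int = 0
    tau_min_s: float = Field(default=1.5e-7, gt=0)
    tau_max_s: float = Field(default=0.1, gt=0)
    n_tau: int = Field(default=128, ge=2)
    attenuation_mm: float = Field(default=5.0, gt=0)


class RunConfig(BaseModel):
    """Full run description: medium, probe geometry, fitting and simulation."""

    medium: MediumConfig
    geometry: GeometryConfig = GeometryConfig()
    fit: FitConfig = FitConfig()
    simulate: SimulateConfig = SimulateConfig()

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return RunConfig.model_validate(data)

    def resolved(self) -> dict:
        """Fully resolved configuration for embedding in result files."""
        return self.model_dump()
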