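"""Delimited-file formats, run configuration and results tables.

Release and mass curves travel as comma- or tab-delimited text with a
header: ``time_s,fraction`` or ``time_s,amount`` (released amount, requiring
an equilibrium amount to normalise) or ``time_s,mass_g`` for swelling
series.  Results tables are written as CSV plus a JSON sidecar carrying
full-precision values and provenance (config hash, seed, package version).

User-facing units match the published tables: thickness in mm, D in cm^2/s.
Thicknesses are converted to cm once, on entry.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffusion import ReleaseCurve
from .errors import ConfigurationError, ParseError
from .swelling import MassSeries

__all__ = ["RunConfig", "read_release_csv", "read_mass_csv",
           "write_results", "read_config"]

logger = logging.getLogger(__name__)

#: Fractions slightly outside [0, 1] (measurement noise) are clipped; beyond
#: this slack the row is rejected.
FRACTION_SLACK = 0.05


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (from YAML or CLI flags)."""

    inputs: list[str] = field(default_factory=list)
    thickness_mm: float | None = None
    water_fraction: float | None = None
    m_inf: float | None = None
    seed: int | None = None
    out_dir: str = "."
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.thickness_mm is not None and not self.thickness_mm > 0:
            raise ConfigurationError("thickness_mm must be > 0")
        if self.water_fraction is not None and not 0 <= self.water_fraction <= 1:
            raise ConfigurationError("water_fraction must lie in [0, 1]")


def read_config(path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    known = {k: raw.pop(k) for k in
             ("inputs", "thickness_mm", "water_fraction", "m_inf", "seed",
              "out_dir", "log_level") if k in raw}
    return RunConfig(**known, extra=raw)


def _read_table(path, required: str, alternatives: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse delimited file: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    df.columns = [c.strip() for c in df.columns]
    if required not in df.columns:
        raise ParseError(f"{path}: missing required column {required!r}")
    value_cols = [c for c in alternatives if c in df.columns]
    if not value_cols:
        raise ParseError(
            f"{path}: need one of the columns {alternatives}"
        )
    for col in (required, *value_cols):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric value in column {col!r}, "
                f"row {int(bad[0]) + 2}"  # +2: header + 1-based
            )
        if coerced.isna().any():
            raise ParseError(
                f"{path}: empty cell in column {col!r}, "
                f"row {int(df.index[coerced.isna()][0]) + 2}"
            )
        df[col] = coerced
    return df


def read_release_csv(path, m_inf: float | None = None) -> ReleaseCurve:
    """Read a release curve from delimited text.

    Columns: ``time_s`` plus ``fraction``, or ``time_s`` plus ``amount``
    (then ``m_inf`` must be supplied or inferable from the plateau).  Rows
    are sorted by time and duplicate times averaged, with a warning logged;
    fractions within ``FRACTION_SLACK`` outside [0, 1] are clipped with a
    warning, farther outside the row is rejected.
    """
    df = _read_table(path, "time_s", ("fraction", "amount"))
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        logger.warning("%s: rows not sorted by time; sorting", path)
    if "fraction" in df.columns:
        f = df["fraction"].to_numpy(dtype=float)
        too_far = (f < -FRACTION_SLACK) | (f > 1 + FRACTION_SLACK)
        if too_far.any():
            row = int(np.flatnonzero(too_far)[0]) + 2
            raise ParseError(
                f"{path}: fraction {f[too_far][0]:g} outside "
                f"[-{FRACTION_SLACK}, {1 + FRACTION_SLACK}] at row {row}"
            )
        clipped = (f < 0) | (f > 1)
        if clipped.any():
            logger.warning("%s: clipped %d fraction(s) to [0, 1] (rows %s)",
                           path, int(clipped.sum()),
                           [int(i) + 2 for i in np.flatnonzero(clipped)])
            f = np.clip(f, 0.0, 1.0)
        if np.unique(t).size < t.size:
            logger.warning("%s: duplicate times averaged", path)
        return ReleaseCurve.from_samples(t, f)
    return ReleaseCurve.from_amounts(t, df["amount"].to_numpy(dtype=float),
                                     m_inf)


def read_mass_csv(path, m0: float | None = None) -> MassSeries:
    """Read a swelling mass series (columns ``time_s``, ``mass_g``).

    The dry mass ``m0`` defaults to the mass at the earliest time point.
    """
    df = _read_table(path, "time_s", ("mass_g",))
    df = df.sort_values("time_s")
    t = df["time_s"].to_numpy(dtype=float)
    m = df["mass_g"].to_numpy(dtype=float)
    if m0 is None:
        m0 = float(m[0])
        logger.info("%s: dry mass taken from the first sample (%g g)", path, m0)
    return MassSeries(times=t, masses=m, m0=m0)


def _config_hash(payload) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(table: pd.DataFrame, path, *, seed: int | None = None,
                  config: dict | None = None) -> Path:
    """Write a results table as CSV plus a JSON provenance sidecar.

    The sidecar (``<path>.meta.json``) holds the rows at full double
    precision, the seed, a hash of the configuration and the package
    version; identical inputs yield byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    sidecar = {
        "package": "filmrelease",
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config or {}),
        "columns": list(table.columns),
        "rows": json.loads(table.to_json(orient="records",
                                         double_precision=15)),
    }
    meta = path.with_name(path.name + ".meta.json")
    meta.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path
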