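"""File formats: trace CSV, table TSV, and instrument-method config.

Traces live in a human-inspectable CSV dialect: '#'-prefixed ``key = value``
metadata lines followed by a header row and two columns, ``time_s`` and
``fluorescence_au``.  Tables (sample sheets, fit results, screen reports)
are TSV, optionally with the same '#' metadata preamble carrying the
package version, seed, and config hash so every output is traceable.
Instrument methods serialize to YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .physics import InstrumentMethod, Taylorgram

__all__ = [
    "read_taylorgram_csv",
    "write_taylorgram_csv",
    "read_method",
    "write_method",
    "read_table",
    "write_table",
    "config_hash",
]

_NUMERIC_META = {"indicator_conc", "analyte_conc", "dilution_factor"}
_INT_META = {"replicate_index"}


def write_taylorgram_csv(trace: Taylorgram, path) -> None:
    path = Path(path)
    lines = []
    for key, val in trace.meta.items():
        lines.append(f"# {key} = {val}")
    lines.append("time_s,fluorescence_au")
    for t, s in zip(trace.time, trace.signal):
        lines.append(f"{float(t)!r},{float(s)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_taylorgram_csv(path, method: InstrumentMethod | None = None) -> Taylorgram:
    """Parse a trace CSV; errors name the first offending line."""
    path = Path(path)
    meta: dict = {}
    time, signal = [], []
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key, val = key.strip(), val.strip()
                    if key in _NUMERIC_META:
                        meta[key] = float(val)
                    elif key in _INT_META:
                        meta[key] = int(val)
                    else:
                        meta[key] = val
                continue
            if not header_seen:
                cols = [c.strip() for c in line.split(",")]
                if cols[:2] != ["time_s", "fluorescence_au"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header 'time_s,"
                        f"fluorescence_au', found {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                time.append(float(parts[0]))
                signal.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value: {exc}") from exc
    if not header_seen:
        raise ValueError(f"{path}: missing 'time_s,fluorescence_au' header")
    t = np.array(time)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # +2: 1-based data row after the offending entry
        raise ValueError(
            f"{path}: time not strictly increasing at data row {bad[0] + 2} "
            f"(t={t[bad[0] + 1]!r} follows t={t[bad[0]]!r})"
        )
    return Taylorgram(time=t, signal=np.array(signal), method=method, **meta)


def write_method(method: InstrumentMethod, path) -> None:
    doc = {
        "capillary_radius_m": method.capillary_radius,
        "total_length_m": method.total_length,
        "detect_length_m": method.detect_length,
        "temperature_K": method.temperature,
        "buffer_viscosity_Pa_s": method.buffer_viscosity,
        "steps": [
            {"label": label, "pressure_mbar": p, "duration_s": d}
            for label, p, d in method.steps
        ],
    }
    header = ("# FIDA instrument method. Lengths in metres, pressures in "
              "mbar, durations in seconds,\n# temperature in kelvin, "
              "viscosity in Pa*s.\n")
    Path(path).write_text(header + yaml.safe_dump(doc, sort_keys=False))


def read_method(path) -> InstrumentMethod:
    doc = yaml.safe_load(Path(path).read_text())
    steps = tuple(
        (s["label"], float(s["pressure_mbar"]), float(s["duration_s"]))
        for s in doc["steps"]
    )
    return InstrumentMethod(
        capillary_radius=float(doc["capillary_radius_m"]),
        total_length=float(doc["total_length_m"]),
        detect_length=float(doc["detect_length_m"]),
        temperature=float(doc["temperature_K"]),
        buffer_viscosity=float(doc["buffer_viscosity_Pa_s"]),
        steps=steps,
    )


def config_hash(config: dict) -> str:
    """Short stable hash of a fully-resolved run configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a TSV with a '#'-prefixed provenance preamble."""
    from . import __version__

    path = Path(path)
    meta = {"fidascreen_version": __version__, **(meta or {})}
    with path.open("w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key} = {val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
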