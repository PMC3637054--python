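"""CSV/JSON readers and writers for traces, panels and reports.

Dialect: comma-separated, ``.`` decimal, UTF-8, mandatory header row.
Trace files carry run metadata in ``#``-prefixed comment lines before the
header.  Numeric output is printed with 6 significant digits so report
diffs stay meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError
from .kinetics import AbsorbanceTrace, AssayCondition
from .panels import ClonePanel

__all__ = [
    "RunConfig",
    "read_trace",
    "write_trace",
    "read_panel",
    "write_panel",
    "write_table",
    "load_run_config",
]

FLOAT_FMT = "%.6g"

PANEL_COLUMNS = ["candidate", "clone_id", "protein_mg_per_mL", "ac_U_per_mL", "sa_U_per_mg"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of a stochastic command."""

    seed: int
    reps: int = 2000
    n_clones: int = 30
    fixture_path: str | None = None
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self):
        if self.reps < 1:
            raise ValidationError("reps must be >= 1")


def load_run_config(path: str | Path) -> dict:
    """Load a JSON config document (flat mapping of option names)."""
    try:
        with open(path, encoding="utf-8") as fh:
            cfg = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a JSON object")
    return cfg


def write_trace(trace: AbsorbanceTrace, path: str | Path) -> None:
    """Write a trace CSV with metadata comment lines and a header row."""
    lines = [f"# wavelength_nm={trace.wavelength_nm:g}", f"# noise_sd={trace.noise_sd:g}"]
    if trace.condition is not None:
        c = trace.condition
        lines += [
            f"# buffer={c.buffer}",
            f"# ph={c.pH:g}",
            f"# path_length_cm={c.path_length_cm:g}",
            f"# reaction_volume_mL={c.reaction_volume_mL:g}",
            f"# enzyme_volume_uL={c.enzyme_volume_uL:g}",
        ]
    lines.append("time_s,absorbance")
    for t, a in zip(trace.times_s, trace.absorbance):
        lines.append(f"{t:.6g},{a:.6g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trace(path: str | Path) -> AbsorbanceTrace:
    """Parse a trace CSV; raises :class:`ParseError` with the line number
    on malformed headers, non-numeric rows, or non-monotone times."""
    text = Path(path).read_text(encoding="utf-8").splitlines()
    meta: dict[str, str] = {}
    header_line = None
    rows: list[tuple[float, float]] = []
    for lineno, raw in enumerate(text, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        if header_line is None:
            if [c.strip() for c in line.split(",")] != ["time_s", "absorbance"]:
                raise ParseError(f"{path}: line {lineno}: expected header 'time_s,absorbance'")
            header_line = lineno
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
        try:
            t, a = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric value") from exc
        if rows and t <= rows[-1][0]:
            raise ParseError(f"{path}: line {lineno}: time {t:g} not after {rows[-1][0]:g}")
        rows.append((t, a))
    if header_line is None:
        raise ParseError(f"{path}: no header row found")
    if not rows:
        raise ParseError(f"{path}: no data rows")

    condition = None
    if "buffer" in meta and "ph" in meta:
        condition = AssayCondition(
            buffer=meta["buffer"],
            pH=float(meta["ph"]),
            wavelength_nm=float(meta.get("wavelength_nm", 293.0)),
            path_length_cm=float(meta.get("path_length_cm", 1.0)),
            reaction_volume_mL=float(meta.get("reaction_volume_mL", 0.80)),
            enzyme_volume_uL=float(meta.get("enzyme_volume_uL", 50.0)),
        )
    arr = np.asarray(rows, dtype=float)
    return AbsorbanceTrace(
        times_s=arr[:, 0],
        absorbance=arr[:, 1],
        wavelength_nm=float(meta.get("wavelength_nm", 293.0)),
        condition=condition,
        noise_sd=float(meta.get("noise_sd", 0.0)),
    )


def write_panel(panel: ClonePanel, path: str | Path) -> None:
    # full precision: the reader re-checks sa = ac/protein at 1e-9
    panel.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_panel(path: str | Path) -> ClonePanel:
    """Read a panel CSV; refuses files where SA != AC/protein (tol 1e-9)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    candidates = df["candidate"].unique()
    if len(candidates) != 1:
        raise ValidationError(f"{path}: expected one candidate per file, got {list(candidates)}")
    protein = df["protein_mg_per_mL"].to_numpy(dtype=float)
    ac = df["ac_U_per_mL"].to_numpy(dtype=float)
    sa = df["sa_U_per_mg"].to_numpy(dtype=float)
    mismatch = np.abs(sa * protein - ac) > 1e-9 * np.maximum(1.0, np.abs(ac))
    if np.any(mismatch):
        row = int(np.argmax(mismatch))
        raise ValidationError(
            f"{path}: row {row + 2}: sa * protein != ac beyond tolerance"
        )
    return ClonePanel(
        candidate=str(candidates[0]),
        n=len(df),
        protein_mg_per_mL=protein,
        ac_U_per_mL=ac,
        sa_U_per_mg=sa,
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any report frame with the package float format."""
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
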