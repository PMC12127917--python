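"""Reading and writing delimited breath tables and processed series.

Metabolic carts export plain delimited text; the reader tolerates comma, semicolon or
tab dialects (decimal comma with the semicolon dialect), configurable column names,
and ``#``-prefixed header lines.  Writers emit the same format with provenance headers
so a processed file documents how it was produced.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import BreathSeries, UniformSeries


class ParseError(ValueError):
    pass


def _sniff(sample_line: str) -> tuple[str, str]:
    """Guess (separator, decimal) from a data line.

    Semicolon and tab take precedence over comma: in the semicolon dialect the comma
    is the decimal mark, so counting commas would mislead.
    """
    for sep in (";", "\t", ","):
        if sep in sample_line:
            decimal = "," if sep == ";" and "," in sample_line else "."
            return sep, decimal
    raise ParseError(f"no delimiter found in line: {sample_line!r}")


def read_breath_table(
    path,
    time_col: str = "time",
    vo2_col: str = "vo2",
    sep: str | None = None,
    decimal: str | None = None,
) -> BreathSeries:
    """Read a breath-by-breath table; ``#`` lines are comments.

    Columns beyond time and VO2 are ignored.  Units are expected as seconds and
    mL·kg⁻¹·min⁻¹.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if len(lines) < 2:
        raise ParseError(f"{path}: no data rows")
    if sep is None or decimal is None:
        s, d = _sniff(lines[1])
        sep = sep or s
        decimal = decimal or d
    df = pd.read_csv(_io.StringIO("\n".join(lines)), sep=sep, decimal=decimal)
    df.columns = [str(c).strip() for c in df.columns]
    for col in (time_col, vo2_col):
        if col not in df.columns:
            raise ParseError(
                f"{path}: column {col!r} not found (have {list(df.columns)})"
            )
    try:
        t = df[time_col].astype(float).to_numpy()
        v = df[vo2_col].astype(float).to_numpy()
    except (TypeError, ValueError) as e:
        raise ParseError(f"{path}: non-numeric value in data columns: {e}") from e
    bad = np.flatnonzero(~np.isfinite(t) | ~np.isfinite(v))
    if len(bad):
        raise ParseError(f"{path}: non-finite value at data row {bad[0] + 1}")
    excluded = None
    if "excluded" in df.columns:
        excluded = df["excluded"].astype(bool).to_numpy()
    return BreathSeries(t, v, excluded)


def write_breath_table(b: BreathSeries, path, header: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for k, v in header.items():
                fh.write(f"# {k}: {json.dumps(v) if not isinstance(v, str) else v}\n")
        fh.write("time,vo2,excluded,reason\n")
        for t, v, ex, rs in zip(b.t, b.vo2, b.excluded, b.reasons):
            fh.write(f"{t:.3f},{v:.6f},{int(ex)},{rs}\n")


def write_uniform_series(u: UniformSeries, path, header: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for step in u.provenance:
            fh.write(f"# provenance: {step}\n")
        if header:
            for k, v in header.items():
                fh.write(f"# {k}: {json.dumps(v) if not isinstance(v, str) else v}\n")
        fh.write("time,vo2\n")
        for t, v in zip(u.t, u.vo2):
            fh.write(f"{t:.3f},{v:.6f}\n")


def read_uniform_series(path) -> UniformSeries:
    path = Path(path)
    provenance = []
    rows = []
    for ln in path.read_text().splitlines():
        if ln.lstrip().startswith("#"):
            stripped = ln.lstrip("# ").strip()
            if stripped.startswith("provenance:"):
                provenance.append(stripped.split("provenance:", 1)[1].strip())
            continue
        if ln.strip():
            rows.append(ln)
    df = pd.read_csv(_io.StringIO("\n".join(rows)))
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ParseError(f"{path}: fewer than two grid points")
    dt = float(t[1] - t[0])
    if not np.allclose(np.diff(t), dt):
        raise ParseError(f"{path}: grid is not uniform")
    return UniformSeries(float(t[0]), dt, df["vo2"].to_numpy(dtype=float), tuple(provenance))


def write_json_report(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def fit_summary_row(report: dict) -> str:
    """One flat delimited line per fit for spreadsheet use."""
    est = report.get("estimates", {})
    cols = [report.get("model", {}).get("form", ""), report.get("model", {}).get("direction", "")]
    cols += [f"{k}={est[k]:.6g}" for k in sorted(est)]
    cols += [f"ser={report.get('ser', float('nan')):.6g}", f"rss={report.get('rss', float('nan')):.6g}"]
    return "\t".join(cols)
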