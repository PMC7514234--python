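"""CSV input/output for series, datasets and feature tables."""

from __future__ import annotations

import csv
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import FeatureMatrix
from .ordinal import permutation_entropy, relative_frequencies

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "read_multiseries_csv",
    "features_from_series",
    "feature_columns",
    "write_features_csv",
    "read_features_csv",
]


def read_series_csv(path) -> np.ndarray:
    """Read a single series: one amplitude per row, optional one-line header."""
    rows = Path(path).read_text().splitlines()
    values = []
    for i, line in enumerate(rows):
        line = line.strip()
        if not line:
            continue
        try:
            values.append(float(line))
        except ValueError:
            if i == 0:
                continue  # header line
            raise ValueError(f"{path}: non-numeric value on line {i + 1}: {line!r}")
    if not values:
        raise ValueError(f"{path}: no amplitude values found")
    return np.asarray(values)


def write_series_csv(path, amplitudes, *, header: str | None = "amplitude") -> None:
    lines = ([header] if header else []) + [repr(float(v)) for v in np.asarray(amplitudes).ravel()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_multiseries_csv(path) -> list[tuple[str, str | None, np.ndarray]]:
    """Read a multi-series CSV: each row is record_id, label, then amplitudes.

    Rows may have different lengths.  A header row is detected by a
    non-numeric third field named anything (it is skipped).
    """
    out = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row or not any(f.strip() for f in row):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}: row {i + 1} has fewer than 3 fields")
            try:
                amps = np.asarray([float(v) for v in row[2:] if v.strip() != ""])
            except ValueError:
                if i == 0:
                    continue
                raise ValueError(f"{path}: non-numeric amplitude in row {i + 1}")
            label = row[1].strip() or None
            out.append((row[0].strip(), label, amps))
    if not out:
        raise ValueError(f"{path}: no series found")
    return out


def feature_columns(m: int) -> list[str]:
    return [f"p_{j + 1}" for j in range(math.factorial(m))]


def features_from_series(series: list, m: int = 3) -> pd.DataFrame:
    """Motif-frequency features (plus PE) for a list of series.

    ``series`` holds ``(record_id, label, amplitudes)`` tuples or
    :class:`~ordpat.hmm.GeneratedSeries` objects.  Output columns are
    ``record_id, label, p_1..p_{m!}, pe`` with frequencies in alphabet order
    and PE in nats.
    """
    rows = []
    for item in series:
        if hasattr(item, "amplitudes"):
            rid, label, amps = item.record_id, item.label, item.amplitudes
        else:
            rid, label, amps = item
        fv = relative_frequencies(amps, m)
        row = {"record_id": rid, "label": label}
        row.update({c: v for c, v in zip(feature_columns(m), fv.p)})
        row["pe"] = permutation_entropy(fv)
        rows.append(row)
    return pd.DataFrame(rows)


def write_features_csv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_features_csv(path, *, feature_mode: str = "vector") -> FeatureMatrix:
    """Load a features CSV as a :class:`FeatureMatrix`.

    ``feature_mode`` selects the frequency-vector columns (``"vector"``) or
    the scalar PE column (``"pe"``).
    """
    df = pd.read_csv(path)
    if feature_mode == "vector":
        cols = [c for c in df.columns if c.startswith("p_")]
        if not cols:
            raise ValueError(f"{path}: no p_* feature columns found")
    elif feature_mode == "pe":
        if "pe" not in df.columns:
            raise ValueError(f"{path}: no 'pe' column found")
        cols = ["pe"]
    else:
        raise ValueError("feature_mode must be 'vector' or 'pe'")
    return FeatureMatrix.from_dataframe(df, cols)
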