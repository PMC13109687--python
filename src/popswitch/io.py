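"""Plain-text readers and writers for the pipeline's tabular formats.

All tables are tab-separated with a header row; every writer's output
round-trips through the matching reader. Parse failures report the file and
line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE
from .profiles import PMFProfile, UmbrellaWindow
from .binding import TitrationSeries

MANIFEST_NAME = "windows_manifest.tsv"


class ParseError(ValueError):
    pass


_STRING_COLUMNS = {"replicate", "window_id", "file", "condition"}


def _read_tsv(path, required_columns):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pandas raises many flavours
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing} "
                         f"(found {list(df.columns)})")
    for col in required_columns:
        if col in _STRING_COLUMNS:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise ParseError(f"{path}: unparseable value in column "
                             f"{col!r} at line {row}")
        df[col] = coerced
    return df


def write_windows(windows: list[UmbrellaWindow], directory) -> Path:
    """One sample file per window plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for w in windows:
        fname = f"{w.window_id}.tsv"
        df = pd.DataFrame({"sample_index": np.arange(w.n_samples),
                           "distance_A": w.samples})
        df.to_csv(directory / fname, sep="\t", index=False,
                  float_format="%.10g")
        rows.append({"window_id": w.window_id, "center_A": w.center,
                     "force_constant": w.force_constant,
                     "n_samples": w.n_samples, "file": fname})
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False,
                              float_format="%.10g")
    return manifest


def read_windows(manifest_path) -> list[UmbrellaWindow]:
    manifest_path = Path(manifest_path)
    mf = _read_tsv(manifest_path,
                   ["window_id", "center_A", "force_constant", "file"])
    windows = []
    for _, row in mf.iterrows():
        sample_file = manifest_path.parent / row["file"]
        df = _read_tsv(sample_file, ["sample_index", "distance_A"])
        windows.append(UmbrellaWindow(
            window_id=str(row["window_id"]), center=float(row["center_A"]),
            force_constant=float(row["force_constant"]),
            samples=df["distance_A"].to_numpy()))
    return windows


def write_pmf(pmf: PMFProfile, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# temperature_K\t{pmf.temperature:.10g}\n")
        fh.write("distance_A\tfree_energy_kcal_per_mol\n")
        for x, w in zip(pmf.grid, pmf.values):
            fh.write(f"{x:.10g}\t{w:.10g}\n")
    return path


def read_pmf(path) -> PMFProfile:
    path = Path(path)
    temperature = DEFAULT_TEMPERATURE
    if path.exists():
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("# temperature_K"):
            temperature = float(first.split("\t")[1])
    df = _read_tsv(path, ["distance_A"])
    if "free_energy_kcal_per_mol" not in df.columns:
        raise ParseError(f"{path}: missing free_energy_kcal_per_mol column")
    return PMFProfile(df["distance_A"].to_numpy(),
                      df["free_energy_kcal_per_mol"].to_numpy(),
                      temperature=temperature)


def write_titration(series: list[TitrationSeries], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = [pd.DataFrame({"replicate": s.replicate_id,
                            "metal_total_nM": s.metal_totals,
                            "signal": s.signals}) for s in series]
    pd.concat(frames).to_csv(path, sep="\t", index=False,
                             float_format="%.10g")
    return path


def read_titration(path) -> list[TitrationSeries]:
    df = _read_tsv(path, ["replicate", "metal_total_nM", "signal"])
    series = []
    for rep, grp in df.groupby("replicate", sort=False):
        series.append(TitrationSeries(
            replicate_id=str(rep),
            metal_totals=grp["metal_total_nM"].to_numpy(),
            signals=grp["signal"].to_numpy()))
    return series


def write_ground_truth(truth: dict, path) -> Path:
    """Key-value sidecar recording a generator's true parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in truth.items():
            fh.write(f"{key}\t{val}\n")
    return path


def read_ground_truth(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: malformed line {lineno}")
            key, val = parts
            try:
                out[key] = float(val)
            except ValueError:
                out[key] = val
    return out


def write_distance_table(frames, values, path, condition=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {"frame": np.asarray(frames), "value_A": np.asarray(values)}
    if condition is not None:
        data["condition"] = condition
    pd.DataFrame(data).to_csv(path, sep="\t", index=False,
                              float_format="%.10g")
    return path


def read_distance_table(path) -> pd.DataFrame:
    return _read_tsv(path, ["frame", "value_A"])


def write_report(report: dict, path=None) -> str:
    """Serialize a run report as JSON (stable key order, 10-sig-fig floats);
    writes to ``path`` if given and returns the JSON text."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"unserializable {type(o)}")

    text = json.dumps(report, indent=2, sort_keys=True, default=default)
    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(text + "\n")
    return text
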