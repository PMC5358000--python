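"""Simulation-versus-experiment statistics: z-scores, RMSE, binned tallies.

Experimental time courses are compared point-by-point: the z-score of a
model value against an experimental point is |model - mean| / SD, with
SEM-reported dispersions converted to SDs as SD = SEM * sqrt(n).  Scores
are binned as Z < 1, 1 <= Z <= 2, Z > 2 (boundary values fall in the
middle bin by convention) and a root-mean-square error is computed per
(protocol, variable) at matched sample times, with linear interpolation of
the model trajectory in time.

No experimental figure data are packaged — published time courses exist
only in figures.  The module instead defines the reference-table CSV
schema (protocol, variable, units, time_min, mean, sd, sem, n; sd or
sem+n required per row) and a synthetic reference generator with chosen
mean/SD structure for testing the harness end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationInputError

REF_COLUMNS = ("protocol", "variable", "units", "time_min", "mean", "sd", "sem", "n")

BIN_LOW, BIN_MID, BIN_HIGH = "Z<1", "1<=Z<=2", "Z>2"


def sem_to_sd(sem: float, n: int) -> float:
    """Convert a standard error of the mean to a standard deviation."""
    if n < 1 or int(n) != n:
        raise ValidationInputError(f"n must be a positive integer, got {n!r}")
    if sem <= 0:
        raise ValidationInputError(f"sem must be positive, got {sem!r}")
    return sem * math.sqrt(n)


def z_score(model_value: float, exp_mean: float, exp_sd: float) -> float:
    """Magnitude of the model-experiment difference in experimental SDs."""
    if exp_sd <= 0:
        raise ValidationInputError(f"exp_sd must be positive, got {exp_sd!r}")
    return abs(model_value - exp_mean) / exp_sd


def z_bin(z: float) -> str:
    if z < 1.0:
        return BIN_LOW
    if z <= 2.0:
        return BIN_MID
    return BIN_HIGH


def rmse(model_series, exp_means) -> float:
    """Root-mean-square error between matched series."""
    m = np.asarray(model_series, dtype=float)
    e = np.asarray(exp_means, dtype=float)
    if m.shape != e.shape or m.size == 0:
        raise ValidationInputError(
            f"series length mismatch or empty: {m.shape} vs {e.shape}")
    return float(np.sqrt(np.mean((m - e) ** 2)))


@dataclass
class ReferenceSeries:
    """One experimental variable in one protocol: times, means, SDs."""

    protocol: str
    variable: str
    units: str
    times: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.means) == len(self.sds)):
            raise ValidationInputError("reference vectors must have equal length")
        if np.any(np.asarray(self.sds) <= 0):
            raise ValidationInputError("reference dispersions must be positive")


@dataclass
class ValidationReport:
    """Per-point z-scores, per-variable RMSE and global bin tallies."""

    points: pd.DataFrame               # protocol, variable, time_min, model, mean, sd, z, bin
    rmse: pd.DataFrame                 # protocol, variable, rmse, n_points
    tallies: dict = field(default_factory=dict)

    @property
    def n_comparisons(self) -> int:
        return int(len(self.points))

    def to_dict(self) -> dict:
        return {
            "tallies": self.tallies,
            "n_comparisons": self.n_comparisons,
            "rmse": self.rmse.to_dict(orient="records"),
            "points": self.points.to_dict(orient="records"),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def to_text_matrix(self) -> str:
        """Plain-text score matrix: bin counts per (protocol, variable)."""
        lines = [f"{'protocol':<10}{'variable':<16}{BIN_LOW:>8}{BIN_MID:>10}{BIN_HIGH:>8}{'rmse':>12}"]
        if self.points.empty:
            lines.append("(no comparisons)")
            return "\n".join(lines)
        for (prot, var), grp in self.points.groupby(["protocol", "variable"], sort=True):
            counts = grp["bin"].value_counts()
            r = self.rmse[(self.rmse.protocol == prot) & (self.rmse.variable == var)]
            rv = float(r["rmse"].iloc[0]) if len(r) else float("nan")
            lines.append(f"{prot:<10}{var:<16}{counts.get(BIN_LOW, 0):>8}"
                         f"{counts.get(BIN_MID, 0):>10}{counts.get(BIN_HIGH, 0):>8}{rv:>12.4g}")
        t = self.tallies
        lines.append(f"{'TOTAL':<10}{'':<16}{t.get(BIN_LOW, 0):>8}"
                     f"{t.get(BIN_MID, 0):>10}{t.get(BIN_HIGH, 0):>8}")
        return "\n".join(lines)


def read_reference_csv(path_or_buf) -> pd.DataFrame:
    """Read a reference table, resolving dispersions to a single sd column."""
    df = pd.read_csv(path_or_buf)
    missing = [c for c in ("protocol", "variable", "time_min", "mean") if c not in df.columns]
    if missing:
        raise ValidationInputError(f"reference CSV missing columns {missing}")
    if "units" not in df.columns:
        df["units"] = ""
    for c in ("sd", "sem", "n"):
        if c not in df.columns:
            df[c] = np.nan
    sd = []
    for row in df.itertuples(index=False):
        if not pd.isna(row.sd):
            if row.sd <= 0:
                raise ValidationInputError(f"non-positive sd in row {row}")
            sd.append(float(row.sd))
        elif not (pd.isna(row.sem) or pd.isna(row.n)):
            sd.append(sem_to_sd(float(row.sem), int(row.n)))
        else:
            raise ValidationInputError(f"row needs sd or (sem, n): {row}")
    out = df.copy()
    out["sd_resolved"] = sd
    return out


def write_reference_csv(df: pd.DataFrame, path_or_buf=None):
    cols = [c for c in REF_COLUMNS if c in df.columns]
    return df[cols].to_csv(path_or_buf, index=False)


def build_report(runs: dict, refs: pd.DataFrame) -> ValidationReport:
    """Compare simulated trajectories with a reference table.

    ``runs`` maps protocol id to a :class:`osmosim.engine.TimeSeries` (or
    any object with ``times`` and ``data``); ``refs`` is a frame as
    returned by :func:`read_reference_csv` (``sd_resolved`` is computed if
    absent).  Every reference point must match a run and a variable; the
    model value is linearly interpolated in time.
    """
    if "sd_resolved" not in refs.columns:
        tmp = refs.to_csv(index=False)
        import io as _io

        refs = read_reference_csv(_io.StringIO(tmp))
    recs = []
    for row in refs.itertuples(index=False):
        if row.protocol not in runs:
            raise ValidationInputError(
                f"reference point for protocol {row.protocol!r} has no matching run")
        run = runs[row.protocol]
        if row.variable not in run.data:
            raise ValidationInputError(
                f"variable {row.variable!r} not present in run {row.protocol!r}")
        t = float(row.time_min)
        if not run.times[0] - 1e-9 <= t <= run.times[-1] + 1e-9:
            raise ValidationInputError(
                f"time {t} outside run {row.protocol!r} span for {row.variable!r}")
        model = float(np.interp(t, run.times, run.data[row.variable]))
        z = z_score(model, float(row.mean), float(row.sd_resolved))
        recs.append({"protocol": row.protocol, "variable": row.variable,
                     "time_min": t, "model": model, "mean": float(row.mean),
                     "sd": float(row.sd_resolved), "z": z, "bin": z_bin(z)})
    points = pd.DataFrame(recs, columns=["protocol", "variable", "time_min",
                                         "model", "mean", "sd", "z", "bin"])
    rmse_rows = []
    if not points.empty:
        for (prot, var), grp in points.groupby(["protocol", "variable"], sort=True):
            rmse_rows.append({"protocol": prot, "variable": var,
                              "rmse": rmse(grp["model"], grp["mean"]),
                              "n_points": int(len(grp))})
    rmse_df = pd.DataFrame(rmse_rows, columns=["protocol", "variable", "rmse", "n_points"])
    tallies = {BIN_LOW: 0, BIN_MID: 0, BIN_HIGH: 0}
    for b in points["bin"]:
        tallies[b] += 1
    return ValidationReport(points=points, rmse=rmse_df, tallies=tallies)


def make_synthetic_refs(runs: dict, variables=("serum_osm", "serum_Na", "avp", "hct"),
                        times=None, offset_sd: float = 1.5, seed: int = 0) -> pd.DataFrame:
    """Generate a synthetic reference table with known z-structure.

    Each reference mean is placed exactly ``offset_sd`` experimental SDs
    below the model value, so every comparison has z = ``offset_sd`` by
    construction — an analytically known tally for testing the harness.
    SD magnitudes (and whether a row reports sd or sem+n) are drawn from a
    seeded generator.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for prot, run in sorted(runs.items()):
        ts = times if times is not None else np.linspace(run.times[0], run.times[-1], 5)
        for var in variables:
            if var not in run.data:
                continue
            for t in ts:
                model = float(np.interp(t, run.times, run.data[var]))
                sd = max(abs(model), 1.0) * rng.uniform(0.03, 0.1)
                mean = model - offset_sd * sd
                row = {"protocol": prot, "variable": var, "units": "",
                       "time_min": float(t), "mean": mean,
                       "sd": np.nan, "sem": np.nan, "n": np.nan}
                if rng.random() < 0.5:
                    n = int(rng.integers(4, 13))
                    row["sem"] = sd / math.sqrt(n)
                    row["n"] = n
                else:
                    row["sd"] = sd
                rows.append(row)
    return pd.DataFrame(rows, columns=list(REF_COLUMNS))
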