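"""Bioassay dataset container, CSV round trip, validation and fit reports.

The on-disk format is a long (tidy) CSV with one row per
(dose, replicate, observation time):

    dose,dose_units,replicate,time,alive,n_initial

``n_initial`` is carried per replicate because droplet-feeding assays
exclude larvae post hoc, so initial counts vary between containers.
Metadata (species, strain, observation window, ...) travels as
``# key = value`` comment lines above the header.  Numbers survive a
write/read round trip at full precision; a Unicode minus sign "−" in the
input is normalised to "-".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import time_effect as te
from .errors import InvalidInputError, ValidationError

__all__ = ["BioassayDataset", "read_bioassay_csv", "write_bioassay_csv", "fit_report"]

REQUIRED_COLUMNS = ("dose", "dose_units", "replicate", "time", "alive", "n_initial")


@dataclass
class BioassayDataset:
    """Long-format multi-dose, multi-replicate count data plus metadata."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        """Check structural invariants; report offending rows by number."""
        bad_rows = []
        if (self.df["alive"] > self.df["n_initial"]).any():
            bad_rows.extend(
                self.df.index[self.df["alive"] > self.df["n_initial"]].tolist()
            )
        for (dose, rep), grp in self.df.groupby(["dose", "replicate"], sort=False):
            grp = grp.sort_values("time")
            increases = np.diff(grp["alive"].to_numpy()) > 1e-9
            if increases.any():
                bad_rows.extend(grp.index.to_numpy()[1:][increases].tolist())
        if bad_rows:
            raise ValidationError(
                f"alive counts increase over time or exceed n_initial at rows {sorted(set(bad_rows))}"
            )

    @property
    def doses(self) -> list[float]:
        return sorted(self.df["dose"].unique().tolist())

    def series_for_dose(self, dose: float, pooled: bool = True):
        """SurvivalSeries for one dose.

        ``pooled=True`` sums alive counts (and initial counts) across
        replicates at each observation time — the population-level curve the
        time–effect model is fitted to.  ``pooled=False`` returns one series
        per replicate, keyed by replicate id (used by the background
        correction).
        """
        sub = self.df[self.df["dose"] == dose]
        if sub.empty:
            raise InvalidInputError(f"no rows for dose {dose}")
        units = str(sub["dose_units"].iloc[0])
        if not pooled:
            out = {}
            for rep, grp in sub.groupby("replicate", sort=False):
                grp = grp.sort_values("time")
                out[rep] = te.SurvivalSeries(
                    times=tuple(grp["time"]),
                    alive=tuple(grp["alive"]),
                    n_initial=float(grp["n_initial"].iloc[0]),
                    dose=float(dose),
                    dose_units=units,
                )
            return out
        n_total = float(
            sub.groupby("replicate", sort=False)["n_initial"].first().sum()
        )
        pooled_alive = sub.groupby("time", sort=True)["alive"].sum()
        counts = sub.groupby("time", sort=True)["alive"].size()
        n_reps = sub["replicate"].nunique()
        if (counts != n_reps).any():
            raise ValidationError(
                f"dose {dose}: replicates observed on different time grids; cannot pool"
            )
        return te.SurvivalSeries(
            times=tuple(pooled_alive.index),
            alive=tuple(pooled_alive.to_numpy(dtype=float)),
            n_initial=n_total,
            dose=float(dose),
            dose_units=units,
        )


def write_bioassay_csv(dataset: BioassayDataset, path) -> None:
    """Write the dataset with metadata comment lines; lossless round trip."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in dataset.metadata.items():
            fh.write(f"# {key} = {val}\n")
        dataset.df.to_csv(fh, index=False, float_format="%.15g")


def read_bioassay_csv(path) -> BioassayDataset:
    """Read and validate a bioassay CSV (schema documented in this module)."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    metadata = {}
    with open(path, encoding="utf-8") as fh:
        text = fh.read().replace("−", "-")
    lines = text.splitlines()
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                metadata[key.strip()] = _coerce(val.strip())
            data_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines[data_start:])))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return BioassayDataset(df, metadata=metadata)


def _coerce(val: str):
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            continue
    return val


REPORT_COLUMNS = [
    "dose",
    "ln_dose",
    "beta1",
    "alpha1",
    "r2",
    "lag_end",
    "lt100",
    "qr",
    "ln_qr",
    "status",
]


def fit_report(dataset: BioassayDataset, min_segment_points: int = 2) -> pd.DataFrame:
    """Per-dose time–effect fit summary.

    One row per dose with (ln(1+D), β1, α1, interior R², fitted lag end
    (α1−1)/β1, LT100 = α1/β1, q_r, ln q_r).  Replicates are pooled before
    fitting.  Per-dose fitting failures are reported in the ``status``
    column, not raised.
    """
    rows = []
    for dose in dataset.doses:
        row = {c: math.nan for c in REPORT_COLUMNS}
        row["dose"] = dose
        row["ln_dose"] = math.log1p(dose)
        try:
            series = dataset.series_for_dose(dose, pooled=True)
            fit = te.fit_time_effect(series, min_segment_points=min_segment_points)
            row.update(
                beta1=fit.beta1,
                alpha1=fit.alpha1,
                r2=fit.r2_segment,
                qr=fit.qr,
                ln_qr=math.log(fit.qr) if fit.qr > 0 else -math.inf,
                status="ok",
            )
            if fit.beta1 > 0:
                row["lag_end"] = te.time_at_q2(fit, 1.0)
                row["lt100"] = te.lt100(fit)
        except Exception as exc:  # per-dose failures must not kill the report
            row["status"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
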