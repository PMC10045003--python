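"""Containers and I/O for right-censored samples and step survival curves.

A :class:`CensoredSample` holds observed times ``t_i = min(T_i, U_i)`` and
event indicators ``delta_i = 1{T_i <= U_i}`` (1 = event/death, 0 =
censored), with optional subject ids and prognostic-index values.

A :class:`StepSurvival` is a right-continuous, non-increasing step function
estimate of a survival function S(t), with S(t) = 1 before the first knot.
Evaluation and integration are exact (piecewise-constant closed forms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CensoredSample",
    "StepSurvival",
    "SurvivalFormatError",
    "read_survival_table",
    "write_curve_table",
]


class SurvivalFormatError(ValueError):
    """Malformed survival table (missing column, bad status code, ...)."""


@dataclass(frozen=True)
class CensoredSample:
    """Right-censored survival sample.

    Parameters
    ----------
    time
        Observed times, strictly positive and finite.
    status
        Event indicators: 1 = event observed, 0 = right-censored.
    id
        Optional subject labels.
    pi
        Optional prognostic-index value per subject.
    """

    time: np.ndarray
    status: np.ndarray
    id: np.ndarray | None = None
    pi: np.ndarray | None = None

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        status = np.asarray(self.status)
        if time.ndim != 1 or time.size == 0:
            raise ValueError("time must be a nonempty 1-d array")
        if not np.all(np.isfinite(time)) or np.any(time <= 0.0):
            raise ValueError("times must be strictly positive and finite")
        if status.shape != time.shape:
            raise ValueError("time and status must have equal length")
        if not np.isin(status, (0, 1)).all():
            raise ValueError("status values must be 0 (censored) or 1 (event)")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "status", status.astype(np.int64))
        for name in ("id", "pi"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != time.shape:
                    raise ValueError(f"{name} must have the same length as time")
                if name == "pi":
                    arr = arr.astype(float)
                object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def n(self) -> int:
        return len(self)

    def sorted_by_time(self) -> "CensoredSample":
        """Stable sort by time, events before censorings at ties.

        The pairing of (time, status, id, pi) is preserved.
        """
        order = np.lexsort((-self.status, self.time))
        return self.subset(order)

    def subset(self, idx) -> "CensoredSample":
        """Sample restricted to (or reordered by) the given indices/mask."""
        idx = np.asarray(idx)
        return CensoredSample(
            time=self.time[idx],
            status=self.status[idx],
            id=None if self.id is None else self.id[idx],
            pi=None if self.pi is None else self.pi[idx],
        )

    def at_risk_count(self, u: float) -> int:
        """Number at risk at time u: #{i : t_i >= u}."""
        if u < 0:
            raise ValueError("time must be >= 0")
        return int(np.count_nonzero(self.time >= u))

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.time, "status": self.status}
        if self.id is not None:
            data = {"id": self.id, **data}
        if self.pi is not None:
            data["pi"] = self.pi
        return pd.DataFrame(data)


@dataclass(frozen=True)
class StepSurvival:
    """Right-continuous non-increasing step survival curve.

    ``knots`` are strictly increasing jump times; ``values[k]`` is the
    curve value at and immediately after ``knots[k]``.  S(t) = 1 for
    t < knots[0]; beyond the last knot the curve is constant.
    """

    knots: np.ndarray = field(default_factory=lambda: np.empty(0))
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if knots.shape != values.shape or knots.ndim != 1:
            raise ValueError("knots and values must be 1-d arrays of equal length")
        if knots.size and np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if np.any(values < -1e-12) or np.any(values > 1.0 + 1e-12):
            raise ValueError("survival values must lie in [0, 1]")
        if values.size and np.any(np.diff(values) > 1e-12):
            raise ValueError("survival values must be non-increasing")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "values", np.clip(values, 0.0, 1.0))

    def __call__(self, t):
        return self.evaluate(t)

    def evaluate(self, t):
        """Right-continuous evaluation S(t); S(t) = 1 before the first knot."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0.0):
            raise ValueError("time must be >= 0")
        if self.knots.size == 0:
            out = np.ones_like(t_arr)
        else:
            idx = np.searchsorted(self.knots, t_arr, side="right")
            padded = np.concatenate(([1.0], self.values))
            out = padded[idx]
        if np.ndim(t) == 0:
            return float(out)
        return out

    def integrate(self, upper: float) -> float:
        """Exact integral of the step function over [0, upper]."""
        upper = float(upper)
        if upper < 0.0:
            raise ValueError("upper limit must be >= 0")
        if upper == 0.0:
            return 0.0
        # segment boundaries clipped to [0, upper]
        edges = np.concatenate(([0.0], np.minimum(self.knots, upper), [upper]))
        heights = np.concatenate(([1.0], self.values))
        widths = np.diff(edges)
        return float(np.sum(widths * heights[: widths.size]))

    def to_frame(self) -> pd.DataFrame:
        """Table with a t=0, S=1 row followed by one row per knot."""
        return pd.DataFrame(
            {
                "time": np.concatenate(([0.0], self.knots)),
                "survival": np.concatenate(([1.0], self.values)),
            }
        )


# ----------------------------------------------------------------------
def read_survival_table(
    path,
    time_col: str = "time",
    status_col: str = "status",
    id_col: str | None = None,
    pi_col: str | None = None,
    censored_code=0,
    event_code=1,
) -> CensoredSample:
    """Read a right-censored sample from a headed CSV file.

    ``censored_code``/``event_code`` remap alternative status encodings
    (e.g. 1/2) onto the internal 0 = censored, 1 = event convention.
    Raises :class:`SurvivalFormatError` naming the offending row/column on
    malformed input.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SurvivalFormatError(f"{path}: empty file") from exc
    if df.empty:
        raise SurvivalFormatError(f"{path}: no data rows")
    for col in filter(None, (time_col, status_col, id_col, pi_col)):
        if col not in df.columns:
            raise SurvivalFormatError(f"{path}: missing required column {col!r}")
    time = pd.to_numeric(df[time_col], errors="coerce").to_numpy(float)
    bad = np.flatnonzero(~np.isfinite(time) | (time <= 0.0))
    if bad.size:
        raise SurvivalFormatError(
            f"{path}: non-positive or non-numeric time in row {bad[0] + 2} "
            f"(column {time_col!r})"
        )
    raw_status = df[status_col].to_numpy()
    status = np.full(raw_status.shape, -1, dtype=np.int64)
    status[raw_status == censored_code] = 0
    status[raw_status == event_code] = 1
    bad = np.flatnonzero(status < 0)
    if bad.size:
        raise SurvivalFormatError(
            f"{path}: status {raw_status[bad[0]]!r} in row {bad[0] + 2} is "
            f"neither {censored_code!r} (censored) nor {event_code!r} (event)"
        )
    pi = None
    if pi_col is not None:
        pi = pd.to_numeric(df[pi_col], errors="coerce").to_numpy(float)
        bad = np.flatnonzero(~np.isfinite(pi))
        if bad.size:
            raise SurvivalFormatError(
                f"{path}: non-numeric value in row {bad[0] + 2} (column {pi_col!r})"
            )
    ids = df[id_col].to_numpy() if id_col is not None else None
    return CensoredSample(time=time, status=status, id=ids, pi=pi)


def write_curve_table(curve: StepSurvival, path) -> None:
    """Write a step curve as CSV (columns time, survival; t=0 row first)."""
    curve.to_frame().to_csv(path, index=False)
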