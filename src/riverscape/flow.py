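"""Flow-regime statistics from daily hydrograph ensembles.

The downstream stages of the assessment chain do not consume daily series
directly; they consume a small set of flow-duration-curve statistics:

* **Q10** — the discharge exceeded on 10% of days, used as a proxy for
  bankfull (channel-forming) discharge in the channel-geometry stage, and
* monthly **Q75 / Q50 / Q25** — low, median and high monthly flows, the
  ecologically meaningful statistics the habitat stage evaluates.

The exceedance convention is hydrological: Qp is the value exceeded p% of
the time, so Q75 ≤ Q50 ≤ Q25. Quantiles are read off the empirical
flow-duration curve using Weibull plotting positions i/(N+1) with linear
interpolation, the standard construction in flow-duration analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Hydrograph", "FlowRegimeSummary", "exceedance_quantile", "monthly_regime"]

MONTHS = range(1, 13)


@dataclass(frozen=True)
class Hydrograph:
    """A daily discharge series.

    Parameters
    ----------
    dates
        Daily timestamps, strictly increasing with no gaps.
    q
        Discharge in m³/s, non-negative, one value per day.
    """

    dates: pd.DatetimeIndex
    q: np.ndarray

    def __post_init__(self):
        dates = pd.DatetimeIndex(self.dates)
        q = np.asarray(self.q, dtype=float)
        if len(dates) != len(q):
            raise ValueError("dates and q must have equal length")
        if len(q) == 0:
            raise ValueError("hydrograph is empty")
        if np.any(q < 0) or np.any(~np.isfinite(q)):
            raise ValueError("discharge must be finite and non-negative")
        deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        if len(deltas) and not np.all(deltas == 1):
            raise ValueError("dates must be consecutive days with no gaps")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "q", q)

    def __len__(self) -> int:
        return len(self.q)

    @property
    def n_years(self) -> float:
        return len(self.q) / 365.25

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Hydrograph":
        return cls(pd.DatetimeIndex(df["date"]), df["q"].to_numpy(dtype=float))


@dataclass(frozen=True)
class FlowRegimeSummary:
    """Ensemble-averaged flow statistics.

    ``monthly`` is a 12×3 DataFrame indexed by month (1–12) with columns
    Q75, Q50, Q25 in m³/s; ``q10`` is the bankfull-proxy discharge.
    """

    q10: float
    monthly: pd.DataFrame
    n_runs: int

    def __post_init__(self):
        m = self.monthly
        if list(m.columns) != ["Q75", "Q50", "Q25"] or len(m) != 12:
            raise ValueError("monthly table must be 12 rows × [Q75, Q50, Q25]")
        if (m.values < 0).any() or self.q10 < 0:
            raise ValueError("flow statistics must be non-negative")
        if not ((m["Q75"] <= m["Q50"] + 1e-12).all() and (m["Q50"] <= m["Q25"] + 1e-12).all()):
            raise ValueError("monthly quantiles must satisfy Q75 <= Q50 <= Q25")

    def to_csv(self, path: str | Path) -> None:
        out = self.monthly.copy()
        out.index.name = "month"
        with open(path, "w") as fh:
            fh.write(f"# q10={self.q10:.6f} n_runs={self.n_runs}\n")
            out.to_csv(fh, float_format="%.6f")


def exceedance_quantile(h: Hydrograph | Sequence[float], p: float) -> float:
    """Discharge exceeded on ``p`` percent of days.

    Sorts the series descending, assigns Weibull plotting positions
    100·i/(N+1), and linearly interpolates; outside the plotting-position
    range the extreme values are returned (clamping).
    """
    if not 0 < p < 100:
        raise ValueError("exceedance percent must lie in (0, 100)")
    q = h.q if isinstance(h, Hydrograph) else np.asarray(h, dtype=float)
    if q.size == 0:
        raise ValueError("empty series")
    desc = np.sort(q)[::-1]
    n = desc.size
    positions = 100.0 * np.arange(1, n + 1) / (n + 1)
    # np.interp clamps outside [positions[0], positions[-1]]
    return float(np.interp(p, positions, desc))


def _single_run_regime(h: Hydrograph, percentiles: Iterable[float]) -> pd.DataFrame:
    months = h.dates.month
    rows = {}
    for m in MONTHS:
        qm = h.q[months == m]
        if qm.size == 0:
            raise ValueError(f"run has no days in month {m}")
        rows[m] = [exceedance_quantile(qm, p) for p in percentiles]
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"Q{int(p)}" for p in percentiles])


def monthly_regime(runs: Sequence[Hydrograph],
                   percentiles: Sequence[float] = (75, 50, 25),
                   pooled_q10: bool = False) -> FlowRegimeSummary:
    """Ensemble flow-regime summary.

    For each run, all days of each calendar month are pooled across years
    and the exceedance quantiles computed; tables are then averaged across
    runs. Q10 is computed per run on the full series and averaged
    (``pooled_q10=True`` instead pools all runs' days first).
    """
    if len(runs) == 0:
        raise ValueError("need at least one run")
    for h in runs:
        if len(h) < 365:
            raise ValueError("each run must cover at least one full year")
    tables = [_single_run_regime(h, percentiles) for h in runs]
    monthly = sum(tables[1:], tables[0].copy()) / len(tables)
    if pooled_q10:
        q10 = exceedance_quantile(np.concatenate([h.q for h in runs]), 10.0)
    else:
        q10 = float(np.mean([exceedance_quantile(h, 10.0) for h in runs]))
    return FlowRegimeSummary(q10=q10, monthly=monthly, n_runs=len(runs))
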