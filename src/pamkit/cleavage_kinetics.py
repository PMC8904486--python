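"""One-phase exponential association fits for in vitro cleavage time courses.

Band intensities from a time-course cleavage assay are converted to a
cleaved fraction, ``cleaved / (cleaved + uncleaved)``, and fitted with

    Y(t) = Ymax * (1 - exp(-k * t))

with no Y-intercept term: the substrate is fully uncleaved at t = 0.
``Ymax`` is the plateau fraction (bounded to [0, 1.05]; the slight > 1
slack absorbs band-quantification noise) and ``k`` is the rate constant
per minute (bounded to (0, 100]).  Replicates are fitted jointly by
pooling their points by default; per-replicate fits are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

YMAX_BOUNDS = (0.0, 1.05)
K_BOUNDS = (1e-9, 100.0)


@dataclass
class CleavageTimeSeries:
    """Cleaved fraction versus incubation time (minutes) for one replicate."""

    times: np.ndarray
    fractions: np.ndarray
    replicate_id: str = "rep1"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.times.shape != self.fractions.shape:
            raise ValueError("times and fractions must have equal lengths")
        if len(self.times) < 3:
            raise ValueError("a time series needs at least 3 points")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.times < 0).any():
            raise ValueError("times must be >= 0")
        if ((self.fractions < 0) | (self.fractions > 1)).any():
            raise ValueError("fractions must be within [0, 1]")


@dataclass
class ExponentialFit:
    """Fitted Y(t) = Ymax (1 - exp(-k t))."""

    y_max: float
    k: float
    rss: float
    converged: bool
    message: str = ""


def cleaved_fraction(cleaved_intensity: float, uncleaved_intensity: float) -> float:
    """Cleaved band fraction, ``cleaved / (cleaved + uncleaved)``."""
    c, u = float(cleaved_intensity), float(uncleaved_intensity)
    if c < 0 or u < 0:
        raise ValueError("band intensities must be >= 0")
    if c + u == 0:
        raise ValueError("cleaved and uncleaved intensities are both zero")
    return c / (c + u)


def association(t, y_max, k):
    return y_max * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))


def _pool(series) -> tuple:
    if isinstance(series, CleavageTimeSeries):
        series = [series]
    t = np.concatenate([s.times for s in series])
    y = np.concatenate([s.fractions for s in series])
    order = np.argsort(t, kind="stable")
    return t[order], y[order]


def fit_association(series, init: tuple | None = None) -> ExponentialFit:
    """Least-squares fit of the one-phase association model.

    *series* is one :class:`CleavageTimeSeries` or a list of replicates
    whose points are pooled.  Default initialization: ``y_max`` from the
    largest observed fraction and ``k`` from inverting the model at the
    earliest nonzero time point.
    """
    t, y = _pool(series)
    if len(t) < 3 or len(np.unique(t[t > 0])) < 2:
        raise ValueError("need >= 3 points with >= 2 distinct nonzero times")

    if not y.any():
        return ExponentialFit(0.0, float("nan"), 0.0, False,
                              "all fractions are zero; no association to fit")

    if init is None:
        y0 = max(float(y.max()), 1e-3)
        nz = (t > 0) & (y > 0)
        if nz.any():
            t1 = t[nz][0]
            f1 = min(y[nz][0] / y0, 0.999)
            k0 = -np.log(1.0 - f1) / t1
        else:
            k0 = 1.0
        k0 = float(np.clip(k0, K_BOUNDS[0] * 10, K_BOUNDS[1] / 2))
        init = (min(y0, YMAX_BOUNDS[1]), k0)

    def jac(tt, y_max, k):
        e = np.exp(-k * tt)
        return np.column_stack([1.0 - e, y_max * tt * e])

    try:
        popt, _ = curve_fit(
            association, t, y, p0=init,
            bounds=([YMAX_BOUNDS[0], K_BOUNDS[0]], [YMAX_BOUNDS[1], K_BOUNDS[1]]),
            jac=jac, maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as exc:
        return ExponentialFit(float("nan"), float("nan"), float("nan"),
                              False, f"optimizer failed: {exc}")
    y_max, k = (float(v) for v in popt)
    rss = float(np.sum((y - association(t, y_max, k)) ** 2))
    return ExponentialFit(y_max, k, rss, True)


def predict(fit: ExponentialFit, t) -> np.ndarray | float:
    """Model prediction Y(t); Y(0) = 0 by construction."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("time must be >= 0")
    out = association(t, fit.y_max, fit.k)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# table IO
# ---------------------------------------------------------------------------

def read_table(path) -> list[CleavageTimeSeries]:
    """Read a TSV of (replicate, time_min, cleaved, uncleaved) or (replicate, time_min, fraction)."""
    df = pd.read_csv(path, sep="\t")
    if {"cleaved", "uncleaved"}.issubset(df.columns):
        df["fraction"] = [
            cleaved_fraction(c, u) for c, u in zip(df["cleaved"], df["uncleaved"])
        ]
    elif "fraction" not in df.columns:
        raise ValueError("table needs either cleaved/uncleaved or fraction columns")
    series = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values("time_min")
        series.append(CleavageTimeSeries(grp["time_min"].to_numpy(),
                                         grp["fraction"].to_numpy(),
                                         replicate_id=str(rep)))
    return series


def fit_table(series: Sequence[CleavageTimeSeries], *, per_replicate: bool = False) -> pd.DataFrame:
    """Fit pooled (default) or per-replicate; returns a tidy fit table."""
    rows = []
    if per_replicate:
        for s in series:
            f = fit_association(s)
            rows.append({"replicate": s.replicate_id, "y_max": f.y_max, "k": f.k,
                         "rss": f.rss, "converged": f.converged})
    else:
        f = fit_association(list(series))
        rows.append({"replicate": "pooled", "y_max": f.y_max, "k": f.k,
                     "rss": f.rss, "converged": f.converged})
    return pd.DataFrame(rows)
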