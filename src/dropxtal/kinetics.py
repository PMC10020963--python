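"""Nucleation kinetics from the clear-droplet fraction.

In an emulsion of N identical, independent droplets of volume V, the
fraction of droplets still clear at time t is the empirical survival
function of the nucleation process.  Under the Poisson nucleation model
the population decays exponentially,

    f_clear(t) = exp(−J·V·t),

so the volumetric nucleation rate J (mm⁻³ s⁻¹) is recovered from the
slope of ln f_clear versus t, fitted only over the decay portion
0.1 < f_clear < 0.75.  The induction time is read off the curve as the
time at which 25% of droplets contain crystals (f_clear = 0.75),
interpolated linearly between frames and measured from the
capillary-sealing epoch t = 0.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from dropxtal.imaging import CLEAR, DropletStateSeries
from dropxtal.synthetic import NEVER

#: Sentinel returned when the curve never reaches the induction threshold.
NOT_REACHED = math.inf

#: Default fit window on f_clear, exclusive on both sides.
DEFAULT_FIT_WINDOW = (0.1, 0.75)

#: Default induction-time threshold on f_clear.
DEFAULT_INDUCTION_THRESHOLD = 0.75


class InsufficientDataError(ValueError):
    """Fewer usable curve points than the fit requires."""


@dataclass
class ClearFractionCurve:
    """f_clear(t) for a droplet population of size ``n_droplets``."""

    timestamps_s: np.ndarray
    f_clear: np.ndarray
    n_droplets: int

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.f_clear = np.asarray(self.f_clear, dtype=float)
        if self.timestamps_s.shape != self.f_clear.shape:
            raise ValueError("timestamps and f_clear must have equal length")
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if np.any(self.f_clear < 0) or np.any(self.f_clear > 1):
            raise ValueError("f_clear must lie in [0, 1]")
        if np.any(np.diff(self.f_clear) > 1e-12):
            raise ValueError("f_clear must be non-increasing")


@dataclass
class KineticsResult:
    """Estimated nucleation rate and induction time with fit diagnostics.

    ``J_estimate`` and ``J_stderr`` are in mm⁻³ s⁻¹; ``fit_window_indices``
    are the (first, last) curve indices that entered the log-linear fit.
    """

    J_estimate: float
    J_stderr: float
    induction_time_s: float
    fit_window_indices: tuple[int, int]
    fit_r_squared: float
    droplet_volume_mm3: float

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["fit_window_indices"] = list(self.fit_window_indices)
        # JSON has no Infinity; serialize the never-reached sentinel as null.
        if math.isinf(d["induction_time_s"]):
            d["induction_time_s"] = None
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


def clear_fraction_curve(series: list[DropletStateSeries]) -> ClearFractionCurve:
    """Fraction of droplets still clear at each frame, N_clear/N."""
    if not series:
        raise ValueError("need at least one droplet state series")
    t0 = series[0].timestamps_s
    for s in series:
        if len(s.timestamps_s) != len(t0) or np.any(s.timestamps_s != t0):
            raise ValueError("all series must share one timestamp grid")
    counts = np.zeros(len(t0))
    for s in series:
        counts += np.array([state == CLEAR for state in s.states], dtype=float)
    return ClearFractionCurve(
        timestamps_s=t0.copy(), f_clear=counts / len(series), n_droplets=len(series)
    )


def clear_fraction_from_times(
    nucleation_times: np.ndarray, timestamps_s: np.ndarray
) -> ClearFractionCurve:
    """Survival curve directly from (possibly censored) nucleation times.

    A droplet is clear at frame time t iff its nucleation time is > t
    (``NEVER`` counts as always clear).  This is the noiseless analogue of
    running the imaging pipeline on rendered frames.
    """
    times = np.asarray(nucleation_times, dtype=float)
    ts = np.asarray(timestamps_s, dtype=float)
    if times.size == 0:
        raise ValueError("need at least one droplet")
    f = (times[None, :] > ts[:, None]).mean(axis=1)
    return ClearFractionCurve(timestamps_s=ts, f_clear=f, n_droplets=times.size)


def induction_time(
    curve: ClearFractionCurve, threshold: float = DEFAULT_INDUCTION_THRESHOLD
) -> float:
    """Time at which f_clear first reaches ``threshold`` (linear interp).

    With the default threshold 0.75 this is the time at which 25% of
    droplets contain crystals, measured from the sealing epoch.  Returns
    ``NOT_REACHED`` (with a warning) if the curve never gets there.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    f = curve.f_clear
    t = curve.timestamps_s
    if f[0] < 1.0:
        warnings.warn(
            f"f_clear starts below 1 ({f[0]:.3f}): crystals present before imaging began",
            stacklevel=2,
        )
    below = np.nonzero(f <= threshold)[0]
    if below.size == 0:
        warnings.warn("f_clear never reaches the induction threshold", stacklevel=2)
        return NOT_REACHED
    k = int(below[0])
    if f[k] == threshold or k == 0:
        return float(t[k])
    # Interpolate between the bracketing frames k-1 (above) and k (below).
    f_hi, f_lo = f[k - 1], f[k]
    return float(t[k - 1] + (f_hi - threshold) / (f_hi - f_lo) * (t[k] - t[k - 1]))


def fit_nucleation_rate(
    curve: ClearFractionCurve,
    droplet_volume_mm3: float,
    window: tuple[float, float] = DEFAULT_FIT_WINDOW,
    weighted: bool = False,
) -> KineticsResult:
    """Estimate J from the exponential decay of f_clear.

    Ordinary least squares of ln f_clear versus t over curve points with
    window_low < f_clear < window_high (strict, so f_clear = 0 never
    enters); J = −slope / V and its standard error is the slope standard
    error scaled the same way.  ``weighted=True`` uses binomial variance
    weights w = N·f/(1−f), appropriate when counting noise dominates.
    """
    if droplet_volume_mm3 <= 0:
        raise ValueError("droplet volume must be positive")
    lo, hi = window
    if not (0 <= lo < hi <= 1):
        raise ValueError("fit window must satisfy 0 <= low < high <= 1")
    in_window = (curve.f_clear > lo) & (curve.f_clear < hi)
    idx = np.nonzero(in_window)[0]
    if idx.size < 3:
        raise InsufficientDataError(
            f"only {idx.size} curve points strictly inside the window {window}; need >= 3"
        )
    t = curve.timestamps_s[idx]
    f = curve.f_clear[idx]
    y = np.log(f)
    if weighted:
        w = curve.n_droplets * f / np.maximum(1.0 - f, 1e-12)
        W = np.sum(w)
        tbar = np.sum(w * t) / W
        ybar = np.sum(w * y) / W
        sxx = np.sum(w * (t - tbar) ** 2)
        slope = np.sum(w * (t - tbar) * (y - ybar)) / sxx
        intercept = ybar - slope * tbar
        resid = y - (intercept + slope * t)
        dof = idx.size - 2
        sigma2 = np.sum(w * resid**2) / dof if dof > 0 else np.nan
        stderr = math.sqrt(sigma2 / sxx)
        ss_tot = np.sum(w * (y - ybar) ** 2)
        r2 = 1.0 - np.sum(w * resid**2) / ss_tot if ss_tot > 0 else 1.0
    else:
        res = stats.linregress(t, y)
        slope, stderr = res.slope, res.stderr
        r2 = res.rvalue**2
    return KineticsResult(
        J_estimate=float(-slope / droplet_volume_mm3),
        J_stderr=float(stderr / droplet_volume_mm3),
        induction_time_s=induction_time(curve),
        fit_window_indices=(int(idx[0]), int(idx[-1])),
        fit_r_squared=float(r2),
        droplet_volume_mm3=float(droplet_volume_mm3),
    )


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean ± sample SD of J and induction time over replicate fits."""

    n: int
    J_mean: float
    J_sd: float
    induction_time_mean_s: float
    induction_time_sd_s: float


def summarize_replicates(results: list[KineticsResult]) -> ReplicateSummary:
    """Arithmetic mean and sample SD (n−1) across replicate experiments."""
    if not results:
        raise ValueError("need at least one replicate")
    J = np.array([r.J_estimate for r in results])
    ti = np.array([r.induction_time_s for r in results])
    if len(results) == 1:
        warnings.warn("single replicate: SD reported as 0", stacklevel=2)
        return ReplicateSummary(1, float(J[0]), 0.0, float(ti[0]), 0.0)
    return ReplicateSummary(
        n=len(results),
        J_mean=float(J.mean()),
        J_sd=float(J.std(ddof=1)),
        induction_time_mean_s=float(ti.mean()),
        induction_time_sd_s=float(ti.std(ddof=1)),
    )


def write_curve_csv(
    curve: ClearFractionCurve,
    path: str | Path,
    window: tuple[float, float] = DEFAULT_FIT_WINDOW,
) -> None:
    """Fitted-curve CSV: t, f_clear, ln f_clear, in_window flag."""
    lo, hi = window
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "f_clear", "ln_f_clear", "in_window"])
        for t, f in zip(curve.timestamps_s, curve.f_clear):
            lnf = "" if f <= 0 else repr(math.log(f))
            w.writerow([repr(float(t)), repr(float(f)), lnf, int(lo < f < hi)])


def read_curve_csv(path: str | Path, n_droplets: int = 1) -> ClearFractionCurve:
    t, f = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            t.append(float(row["time_s"]))
            f.append(float(row["f_clear"]))
    return ClearFractionCurve(np.array(t), np.array(f), n_droplets=n_droplets)


def plot_curve(
    curve: ClearFractionCurve,
    result: KineticsResult | None,
    path: str | Path,
    title: str = "Clear-droplet fraction",
) -> None:
    """Plot f_clear(t) with the fitted exponential overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.timestamps_s / 60.0, curve.f_clear, "o", ms=3, label="observed")
    if result is not None:
        t = np.linspace(curve.timestamps_s[0], curve.timestamps_s[-1], 200)
        jv = result.J_estimate * result.droplet_volume_mm3
        ax.plot(t / 60.0, np.exp(-jv * t), "-", label=f"fit J={result.J_estimate:.2f} mm$^{{-3}}$ s$^{{-1}}$")
        if math.isfinite(result.induction_time_s):
            ax.axvline(result.induction_time_s / 60.0, ls="--", color="gray", label="induction time")
    ax.set_xlabel("time (min)")
    ax.set_ylabel(r"$f_\mathrm{clear}$")
    ax.set_ylim(0, 1.05)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
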