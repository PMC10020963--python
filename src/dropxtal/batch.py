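"""Batch-crystallization probability statistics.

For each condition the nucleation probability is the fraction of drops
containing crystals among drops that did not precipitate (precipitated
drops are excluded from numerator and denominator).  Differences versus a
control condition get 95% percentile-bootstrap confidence intervals:
each arm's non-precipitate outcomes are resampled with replacement, the
difference in probabilities is recomputed, and the 2.5th/97.5th
percentiles of the resampled differences are reported.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from dropxtal.synthetic import BatchCondition


class UndefinedProbabilityError(ValueError):
    """Every drop precipitated: the nucleation probability is undefined."""


@dataclass(frozen=True)
class ProbabilityComparison:
    """Bootstrap comparison of one test condition against the control."""

    condition_name: str
    p_test: float
    p_control: float
    delta: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    seed: int


def _crystal_indicator(condition: BatchCondition) -> np.ndarray:
    """0/1 array over non-precipitate drops (1 = crystal)."""
    kept = [o for o in condition.outcomes if o != "precipitate"]
    if not kept:
        raise UndefinedProbabilityError(
            f"condition {condition.condition_name!r}: all drops precipitated"
        )
    # Sorted so results are exactly invariant to outcome order (resampling
    # is i.i.d. from the empirical distribution; order carries no info).
    return np.sort(np.array([o == "crystal" for o in kept], dtype=float))


def nucleation_probability(condition: BatchCondition) -> float:
    """#crystal / (#crystal + #clear); precipitated drops excluded."""
    if condition.n_total < 1:
        raise ValueError("condition has no drops")
    return float(_crystal_indicator(condition).mean())


def compare_to_control(
    test: BatchCondition,
    control: BatchCondition,
    n_bootstrap: int = 10_000,
    seed: int = 0,
    method: str = "percentile",
) -> ProbabilityComparison:
    """Bootstrap CI for the difference in nucleation probability.

    ``delta`` = p_test − p_control on the observed data.  The default
    percentile bootstrap resamples each arm's non-precipitate outcomes
    independently with replacement ``n_bootstrap`` times; ``method="bca"``
    uses the bias-corrected accelerated interval instead (scipy).
    Deterministic given ``seed``.
    """
    x_test = _crystal_indicator(test)
    x_ctrl = _crystal_indicator(control)
    p_test = float(x_test.mean())
    p_ctrl = float(x_ctrl.mean())
    delta = p_test - p_ctrl
    rng = np.random.default_rng(seed)

    if method == "percentile":
        idx_t = rng.integers(0, x_test.size, size=(n_bootstrap, x_test.size))
        idx_c = rng.integers(0, x_ctrl.size, size=(n_bootstrap, x_ctrl.size))
        deltas = x_test[idx_t].mean(axis=1) - x_ctrl[idx_c].mean(axis=1)
        ci_low, ci_high = np.percentile(deltas, [2.5, 97.5])
    elif method == "bca":
        from scipy import stats

        res = stats.bootstrap(
            (x_test, x_ctrl),
            lambda a, b, axis: np.mean(a, axis=axis) - np.mean(b, axis=axis),
            n_resamples=n_bootstrap,
            method="BCa",
            confidence_level=0.95,
            rng=rng,
        )
        ci_low, ci_high = res.confidence_interval.low, res.confidence_interval.high
    else:
        raise ValueError(f"unknown bootstrap method {method!r}")

    return ProbabilityComparison(
        condition_name=test.condition_name,
        p_test=p_test,
        p_control=p_ctrl,
        delta=delta,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


def write_comparison_csv(comparisons: list[ProbabilityComparison], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["condition", "p", "p_control", "delta", "ci_low", "ci_high"])
        for c in comparisons:
            w.writerow(
                [c.condition_name, c.p_test, c.p_control, c.delta, c.ci_low, c.ci_high]
            )


def plot_comparisons(comparisons: list[ProbabilityComparison], path: str | Path) -> None:
    """Bar chart of probability increases vs control with 95% CI bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [c.condition_name for c in comparisons]
    deltas = [100 * c.delta for c in comparisons]
    err_lo = [100 * (c.delta - c.ci_low) for c in comparisons]
    err_hi = [100 * (c.ci_high - c.delta) for c in comparisons]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(names, deltas, yerr=[err_lo, err_hi], capsize=4, color="#4878a8")
    ax.axhline(0, color="black", lw=0.8)
    ax.set_ylabel("increase in nucleation probability vs control (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
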