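"""Conformer-ensemble descriptor distributions and their summaries.

The workflow this mirrors samples equally spaced frames from the equilibrated
tail of an amorphous-cell trajectory, extracts every molecule from every
frame, computes R3m per conformation, and summarizes the resulting sample
with box-plot statistics and boundary-exceedance fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .descriptors import r_autocorrelation
from .structures import ConformerEnsemble

__all__ = [
    "DistributionSummary",
    "ComparisonReport",
    "select_frames",
    "ensemble_descriptor",
    "summarize_distribution",
    "fraction_above",
    "compare_value_sets",
]


@dataclass(frozen=True)
class DistributionSummary:
    """Box-and-whisker statistics of a descriptor sample.

    Quartiles use linear interpolation between order statistics; whiskers
    extend to the most extreme sample points within 1.5 x IQR beyond the
    quartiles, and points beyond the whiskers are outliers.
    """

    n: int
    median: float
    mean: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    values: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class ComparisonReport:
    """Pairwise comparison of two named descriptor-value sets."""

    n: int
    mean_abs_difference: float
    fraction_within: float
    threshold: float
    slope: float
    intercept: float
    r_squared: float
    differences: dict[str, float]


def select_frames(
    window_start: float, window_end: float, count: int
) -> np.ndarray:
    """``count`` equally spaced frame times, inclusive of both endpoints.

    A single frame returns the window end. Seven frames over a 300-unit
    window gives 50-unit spacing.
    """
    if window_end <= window_start:
        raise ValueError("window_end must exceed window_start")
    if count < 1:
        raise ValueError("count must be a positive integer")
    if count == 1:
        return np.array([float(window_end)])
    return np.linspace(window_start, window_end, count)


def ensemble_descriptor(
    ensemble: ConformerEnsemble, k: int = 3, weight_scheme: str = "mass"
) -> np.ndarray:
    """Descriptor value for every frame, in frame order.

    Equivalent to extracting each frame as a Molecule and calling the
    single-conformation descriptor; errors are re-raised with the frame
    index attached.
    """
    values = np.empty(ensemble.n_frames)
    for i in range(ensemble.n_frames):
        try:
            values[i] = r_autocorrelation(
                ensemble.molecule(i), k=k, weight_scheme=weight_scheme
            ).value
        except Exception as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
    return values


def summarize_distribution(values) -> DistributionSummary:
    """Box-plot summary: type-7 quartiles, 1.5 x IQR whiskers, outliers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    outliers = v[(v < whisker_low) | (v > whisker_high)]
    return DistributionSummary(
        n=int(v.size), median=float(med), mean=float(v.mean()),
        q1=float(q1), q3=float(q3),
        whisker_low=whisker_low, whisker_high=whisker_high,
        outliers=np.sort(outliers), values=np.array(v),
    )


def fraction_above(values, threshold: float) -> float:
    """Fraction of the sample strictly above the threshold."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    return float((v > threshold).sum()) / v.size


def compare_value_sets(
    set_a: dict[str, float], set_b: dict[str, float], threshold: float = 0.05
) -> ComparisonReport:
    """Compare two named value sets matched by name.

    Reports the mean absolute difference, the fraction of matched names with
    |b - a| <= ``threshold``, and the ordinary least-squares regression of b
    on a (slope, intercept, R^2).
    """
    names = sorted(set(set_a) & set(set_b))
    if len(names) < 2:
        raise ValueError("need at least two matched names for the regression")
    a = np.array([set_a[n] for n in names])
    b = np.array([set_b[n] for n in names])
    diffs = b - a
    if np.allclose(a, a[0]):
        raise ValueError("set_a is constant; regression slope undefined")
    fit = _stats.linregress(a, b)
    return ComparisonReport(
        n=len(names),
        mean_abs_difference=float(np.abs(diffs).mean()),
        fraction_within=float((np.abs(diffs) <= threshold).sum()) / len(names),
        threshold=threshold,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        differences={n: float(d) for n, d in zip(names, diffs)},
    )
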