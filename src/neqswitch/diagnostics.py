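"""Quasi-time-series representation of work values and outlier machinery.

Work values from switches launched off restart files inherit a partial
temporal ordering: the 8 blocks are statistically independent, but within a
block the restart files were saved in simulation order.  Plotting the work
values in block-then-save order -- a "quasi time series" -- makes it easy to
spot switches with unusually negative work, which dominate the exponential
average of the one-sided estimator.  A work value is flagged as an outlier
when W < Wbar - k sigma_W (k = 3 by default; one-sided, negative tail only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import FreeEnergyEstimate, jarzynski
from .switching import N_BLOCKS, WorkSet

__all__ = [
    "QuasiTimeSeries",
    "build_quasi_time_series",
    "flag_low_outliers",
    "flag_high_outliers",
    "outlier_impact",
    "OutlierImpact",
]


@dataclass
class QuasiTimeSeries:
    """Work values in block-then-save order with outlier annotations.

    ``works[i]`` corresponds to ``global_indices[i]`` (1-based, continuous
    across blocks, no reset).  ``outlier_indices`` are the global indices
    with W < mean - k*sigma; sigma is the pooled sample SD (n-1 denominator)
    over all blocks.
    """

    works: np.ndarray
    global_indices: np.ndarray
    blocks: np.ndarray
    block_boundaries: np.ndarray     # global index starting each block
    mean: float
    sigma: float
    k: float
    outlier_indices: np.ndarray      # global indices, negative tail
    high_outlier_indices: np.ndarray  # positive tail, reported but never removed


def flag_low_outliers(values, k: float = 3.0) -> np.ndarray:
    """Positions (0-based) of values below mean - k*SD.

    One-sided: only the negative tail is flagged, since only strongly
    negative work values carry outsized Boltzmann weight.  SD uses the n-1
    denominator; with fewer than two values the criterion is undefined.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("outlier criterion requires at least two values")
    threshold = v.mean() - k * v.std(ddof=1)
    return np.flatnonzero(v < threshold)


def flag_high_outliers(values, k: float = 3.0) -> np.ndarray:
    """Positions of values above mean + k*SD (reported only, never removed)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("outlier criterion requires at least two values")
    return np.flatnonzero(v > v.mean() + k * v.std(ddof=1))


def build_quasi_time_series(workset: WorkSet, k: float = 3.0) -> QuasiTimeSeries:
    """Order a work set as a quasi time series and flag outliers.

    Records are sorted by (block, within-block save index); global numbering
    runs continuously, e.g. with a blocksize of 100 the 41st switch of block
    4 is switch 341.  Flags use the pooled mean and SD across all 8 blocks.
    """
    if not workset.records:
        raise ValueError("work set is empty")
    for r in workset.records:
        if not (1 <= r.block <= N_BLOCKS) or r.within_index < 1:
            raise ValueError(
                f"record with invalid block/within indices: "
                f"block={r.block}, within={r.within_index}")
    recs = sorted(workset.records, key=lambda r: (r.block, r.within_index))
    works = np.array([r.work for r in recs])
    gidx = np.array([r.global_index for r in recs])
    blocks = np.array([r.block for r in recs])
    boundaries = np.array([gidx[blocks == b][0] for b in np.unique(blocks)])
    mean = float(works.mean())
    sigma = float(works.std(ddof=1)) if works.size > 1 else 0.0
    if sigma > 0.0:
        low = gidx[np.flatnonzero(works < mean - k * sigma)]
        high = gidx[np.flatnonzero(works > mean + k * sigma)]
    else:
        low = np.array([], dtype=int)   # degenerate spread: criterion vacuous
        high = np.array([], dtype=int)
    return QuasiTimeSeries(works=works, global_indices=gidx, blocks=blocks,
                           block_boundaries=boundaries, mean=mean, sigma=sigma,
                           k=k, outlier_indices=low, high_outlier_indices=high)


@dataclass(frozen=True)
class OutlierImpact:
    """Jarzynski estimates with and without the flagged negative outliers."""

    with_outliers: FreeEnergyEstimate
    without_outliers: FreeEnergyEstimate
    n_outliers: int
    outlier_indices: tuple
    delta_with: "float | None" = None     # deviation from a reference, if given
    delta_without: "float | None" = None


def outlier_impact(workset: WorkSet, temperature: "float | None" = None,
                   k: float = 3.0, reference: "float | None" = None,
                   **jar_kwargs) -> OutlierImpact:
    """Re-estimate Delta A after removing the flagged negative-work outliers.

    Removing works below Wbar - k sigma can only raise the exponential
    average's estimate (those values carry the largest Boltzmann weights),
    so without >= with always holds.  If a ``reference`` free energy is
    given, the deviations delta = Delta A_JAR - reference are reported for
    both variants.
    """
    if not workset.records:
        raise ValueError("work set is empty")
    if temperature is None:
        temperature = workset.temperature
    works = workset.works
    flagged = flag_low_outliers(works, k=k) if works.size >= 2 else np.array([], dtype=int)
    if flagged.size == works.size:
        raise ValueError("all records flagged as outliers; nothing left to estimate")
    with_est = jarzynski(works, temperature, **jar_kwargs)
    without_est = jarzynski(np.delete(works, flagged), temperature, **jar_kwargs)
    gidx = np.array([r.global_index for r in workset.records])
    return OutlierImpact(
        with_outliers=with_est, without_outliers=without_est,
        n_outliers=int(flagged.size), outlier_indices=tuple(int(i) for i in gidx[flagged]),
        delta_with=None if reference is None else with_est.value - reference,
        delta_without=None if reference is None else without_est.value - reference)
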