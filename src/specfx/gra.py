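"""Grey relational analysis (GRA) in Deng's classic formulation.

GRA scores how closely each normalized *subsequence* (a common peak's
area profile across batches) tracks a *parent sequence* (an efficacy
index across the same batches). After mean normalization, the
point-wise absolute differences

    delta_i(k) = |x0(k) - xi(k)|

are turned into relational coefficients with two-level extrema taken
jointly over all subsequences i and points k,

    xi_i(k) = (min_{i,k} delta + rho * max_{i,k} delta)
              / (delta_i(k) + rho * max_{i,k} delta),

with resolution coefficient rho (default 0.5). The unweighted mean of a
subsequence's coefficients is its grey relational degree, in (0, 1];
rank 1 is the highest degree. One GRA run is performed per efficacy
index (parent), so the extrema are computed per parent across all peaks
jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GRAConfig",
    "GRAResult",
    "mean_normalize",
    "relational_coefficients",
    "relational_degree",
    "rank_degrees",
    "grey_relational_analysis",
]


@dataclass(frozen=True)
class GRAConfig:
    """rho is Deng's resolution coefficient in (0, 1]; normalization is
    applied to parent and subsequences alike before differencing."""

    rho: float = 0.5
    normalization: str = "mean"
    normalize_parent: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.rho <= 1.0:
            raise ValueError("rho must lie in (0, 1]")
        if self.normalization not in {"mean", "initial", "minmax"}:
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class GRAResult:
    """Degrees, ranks, and the per-point coefficient matrices per assay."""

    degrees: pd.DataFrame  # peaks x assays
    ranks: pd.DataFrame  # peaks x assays, 1 = highest degree
    coefficients: dict  # assay -> DataFrame (peaks x batches)
    config: GRAConfig = field(default_factory=GRAConfig)


def _normalize(series: np.ndarray, how: str, label: str = "series") -> np.ndarray:
    if how == "mean":
        m = series.mean()
        if m == 0:
            raise ValueError(f"{label}: mean normalization undefined for zero mean")
        return series / m
    if how == "initial":
        if series[0] == 0:
            raise ValueError(f"{label}: initial-value normalization undefined, first value is 0")
        return series / series[0]
    if how == "minmax":
        rng = series.max() - series.min()
        if rng == 0:
            raise ValueError(f"{label}: min-max normalization undefined for constant series")
        return (series - series.min()) / rng
    raise ValueError(f"unknown normalization {how!r}")


def mean_normalize(series) -> np.ndarray:
    """Divide a series by its mean; the output mean is exactly 1."""
    s = np.asarray(series, dtype=float)
    return _normalize(s, "mean")


def relational_coefficients(parent, children, rho: float = 0.5, config: GRAConfig | None = None) -> np.ndarray:
    """Deng grey relational coefficients for each (child, point).

    Extrema are two-level: taken jointly over all children and all
    points of one parent-sequence run. Returns an (n_children, n_points)
    array of values in (0, 1].
    """
    cfg = config or GRAConfig(rho=rho)
    x0 = np.asarray(parent, dtype=float)
    xs = np.asarray(children, dtype=float)
    if xs.ndim == 1:
        xs = xs[None, :]
    if x0.ndim != 1 or xs.shape[1] != x0.size or x0.size < 2:
        raise ValueError("parent and children must share a length >= 2")
    if cfg.normalize_parent:
        x0 = _normalize(x0, cfg.normalization, "parent")
    xn = np.vstack(
        [_normalize(xs[i], cfg.normalization, f"child {i}") for i in range(xs.shape[0])]
    )
    delta = np.abs(xn - x0[None, :])
    m, M = delta.min(), delta.max()
    if M == 0:
        logger.warning("all subsequences identical to parent after normalization")
        return np.ones_like(delta)
    return (m + cfg.rho * M) / (delta + cfg.rho * M)


def relational_degree(coefficients_row) -> float:
    """Unweighted mean of one subsequence's relational coefficients."""
    row = np.asarray(coefficients_row, dtype=float)
    if row.size == 0:
        raise ValueError("empty coefficient row")
    return float(row.mean())


def rank_degrees(degrees) -> np.ndarray:
    """Rank degrees descending: 1 = largest; ties broken by index, logged."""
    d = np.asarray(degrees, dtype=float)
    if d.size == 0:
        raise ValueError("no degrees to rank")
    if np.unique(d).size < d.size:
        logger.warning("tied relational degrees; ties broken by peak index")
    order = np.lexsort((np.arange(d.size), -d))
    ranks = np.empty(d.size, dtype=int)
    ranks[order] = np.arange(1, d.size + 1)
    return ranks


def grey_relational_analysis(
    areas: pd.DataFrame,
    activity: pd.DataFrame,
    config: GRAConfig | None = None,
) -> GRAResult:
    """Run one GRA per efficacy index against every common peak.

    ``areas`` is batches x peaks (relative or raw areas); ``activity``
    is batches x assays. Batch sets must coincide; rows are aligned by
    batch id.
    """
    cfg = config or GRAConfig()
    if set(areas.index) != set(activity.index):
        raise ValueError("areas and activity tables cover different batch sets")
    act = activity.loc[areas.index]
    peaks = [str(p) for p in areas.columns]
    degrees = {}
    ranks = {}
    coeffs = {}
    children = areas.to_numpy(dtype=float).T  # peaks x batches
    for assay in act.columns:
        xi = relational_coefficients(act[assay].to_numpy(dtype=float), children, config=cfg)
        deg = xi.mean(axis=1)
        degrees[assay] = deg
        ranks[assay] = rank_degrees(deg)
        coeffs[assay] = pd.DataFrame(xi, index=peaks, columns=areas.index)
    return GRAResult(
        degrees=pd.DataFrame(degrees, index=peaks),
        ranks=pd.DataFrame(ranks, index=peaks),
        coefficients=coeffs,
        config=cfg,
    )
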