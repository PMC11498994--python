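"""In-vitro antioxidant assay computation.

Converts microplate absorbances into the two efficacy indices used
downstream: the DPPH radical scavenging rate (517 nm) and the total
antioxidant capacity, T-AOC (593 nm, linear calibration against a
standard series). Out-of-range values are flagged, never clamped, so
the multivariate stages see the raw numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "dpph_scavenging_rate",
    "t_aoc",
    "summarize_replicates",
    "activity_table",
]

#: Dilution implied by the default T-AOC plate layout:
#: 180 uL reaction mixture + 18 uL water + 6 uL sample => 204/6 = 34.
DEFAULT_TAOC_DILUTION = 34.0


@dataclass(frozen=True)
class StandardCurve:
    """Ordinary least-squares calibration line absorbance = slope*conc + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a standard curve needs at least 2 points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


def fit_standard_curve(concentrations, absorbances) -> StandardCurve:
    """Fit the calibration line by ordinary least squares."""
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size != a.size or c.size < 2:
        raise ValueError("need equal-length arrays with at least 2 points")
    if np.unique(c).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    res = stats.linregress(c, a)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(c.size),
    )


def dpph_scavenging_rate(a_sample: float, a_control: float, a_standard: float) -> float:
    """DPPH radical scavenging rate in percent.

    rate = [1 - (A_sample - A_control)/A_standard] * 100, where A_sample
    is sample + radical, A_control is sample + solvent (sample-colour
    blank), and A_standard is solvent + radical. The result may fall
    outside [0, 100]; such values are flagged by the caller, not clamped.
    """
    if a_standard <= 0:
        raise ValueError("a_standard must be > 0")
    rate = 100.0 * (1.0 - (a_sample - a_control) / a_standard)
    if not 0.0 <= rate <= 100.0:
        logger.warning("DPPH scavenging rate %.2f%% outside [0, 100]", rate)
    return float(rate)


def t_aoc(
    a_sample: float,
    a_blank: float,
    calibration: StandardCurve,
    dilution_factor: float = DEFAULT_TAOC_DILUTION,
) -> float:
    """Total antioxidant capacity from the 593-nm colourimetric reading.

    Inverts the linear calibration on the blank-corrected absorbance and
    scales by the in-well dilution factor. Negative capacities are
    flagged, not clamped.
    """
    if calibration.slope == 0:
        raise ValueError("calibration slope must be nonzero")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be > 0")
    value = ((a_sample - a_blank) - calibration.intercept) / calibration.slope
    value *= dilution_factor
    if value < 0:
        logger.warning("negative T-AOC %.4f flagged", value)
    return float(value)


def summarize_replicates(values):
    """Mean and sample SD of replicate measurements; SD is None for n = 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    if v.size == 1:
        return float(v[0]), None
    return float(v.mean()), float(v.std(ddof=1))


def activity_table(batch_results: dict) -> pd.DataFrame:
    """Assemble per-batch replicate results into an activity table.

    ``batch_results`` maps batch_id -> dict with keys ``dpph`` and/or
    ``taoc``, each a sequence of replicate values. Returns a DataFrame
    with columns dpph_pct, t_aoc, sd_dpph, sd_taoc indexed by batch_id.
    """
    rows = {}
    for batch, res in batch_results.items():
        row = {}
        if "dpph" in res:
            row["dpph_pct"], row["sd_dpph"] = summarize_replicates(res["dpph"])
        if "taoc" in res:
            row["t_aoc"], row["sd_taoc"] = summarize_replicates(res["taoc"])
        rows[str(batch)] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "batch_id"
    return df
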