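"""Synthetic multi-batch fingerprint and activity generator with known truth.

Emulates the statistical structure the spectrum-effect analysis assumes:
peak areas vary log-normally across batches with small retention-time
jitter, and each activity index is a linear combination of a designated
*active* peak subset (on the standardized-area scale, so effect sizes
are scale-free) plus structured and unstructured noise.

Two nuisance latents are generated, both controlled by
``orthogonal_confounder_strength``:

* a batch latent that loads on the *inactive* peaks' log-areas only —
  structured X-variation orthogonal to the activity signal, which is
  exactly what the OPLS orthogonal component exists to remove;
* a structured noise term in the activity itself, residualized against
  the active standardized areas so it cannot alias the true signal.

Everything is reproducible from the single seed; the ground-truth dict
records the active set, effects, latents, and the affine map used to
place the DPPH-style index inside (0, 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .fingerprint import Chromatogram, PeakTable

__all__ = ["SyntheticSpec", "generate", "generate_chromatograms", "DEFAULT_RT_CENTERS"]

#: Nominal retention-time centers (min): the 15 common-peak relative
#: retention times of a 10-batch herbal fingerprint scaled to a
#: 15-minute reference peak.
DEFAULT_RT_CENTERS = tuple(
    round(r * 15.0, 3)
    for r in (0.103, 0.164, 0.346, 0.517, 0.579, 0.709, 0.837, 0.865,
              1.000, 1.036, 1.084, 1.307, 1.441, 1.484, 1.577)
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters for one synthetic dataset.

    Defaults mirror the reference dataset: 10 batches, 15 common peaks,
    log-normal area variation comparable to relative-area RSDs of
    roughly 40-70%, retention-time jitter well inside the 0.1-min
    matching window, and three active peaks of unit standardized effect.
    ``noise_sd = None`` derives the activity noise so the active signal
    explains ``target_r2`` of the activity variance.
    """

    n_batches: int = 10
    n_peaks: int = 15
    active_set: tuple = (10, 11, 14)  # 1-based peak indices
    effect_sizes: tuple = (1.0, 1.0, 1.0)
    rt_centers: tuple = DEFAULT_RT_CENTERS
    rt_jitter_sd: float = 0.02
    area_lognormal_sd: float = 0.45
    noise_sd: float | None = None
    target_r2: float = 0.8
    orthogonal_confounder_strength: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches < 2 or self.n_peaks < 1:
            raise ValueError("need n_batches >= 2 and n_peaks >= 1")
        if len(self.rt_centers) < self.n_peaks:
            raise ValueError("rt_centers must cover n_peaks")
        centers = self.rt_centers[: self.n_peaks]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("rt_centers must be strictly increasing")
        if not set(self.active_set) <= set(range(1, self.n_peaks + 1)):
            raise ValueError("active_set must be 1-based peak indices within n_peaks")
        if len(self.effect_sizes) != len(self.active_set):
            raise ValueError("one effect size per active peak")
        if min(self.rt_jitter_sd, self.area_lognormal_sd,
               self.orthogonal_confounder_strength) < 0:
            raise ValueError("spread parameters must be >= 0")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.target_r2 < 1:
            raise ValueError("target_r2 must lie in (0, 1)")


def _standardize(A: np.ndarray) -> np.ndarray:
    sd = A.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (A - A.mean(axis=0)) / sd


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residual of v after OLS projection onto the columns of Z, unit SD."""
    if Z.size:
        coef, *_ = np.linalg.lstsq(Z, v, rcond=None)
        v = v - Z @ coef
    sd = v.std(ddof=1)
    return v / sd if sd > 0 else v


def generate(spec: SyntheticSpec):
    """Generate (peak tables, activity table, ground truth) from a spec."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_batches, spec.n_peaks
    centers = np.asarray(spec.rt_centers[:p])
    active = np.asarray(spec.active_set, dtype=int) - 1
    inactive = np.setdiff1d(np.arange(p), active)
    beta = np.asarray(spec.effect_sizes, dtype=float)

    # log-normal areas around per-peak typical levels
    mu = rng.normal(0.0, 0.7, size=p)
    log_areas = mu + spec.area_lognormal_sd * rng.standard_normal((n, p))

    # batch latent loading on inactive peaks only: X-variation orthogonal
    # to the activity signal (what the OPLS orthogonal component removes)
    gamma = spec.orthogonal_confounder_strength
    x_latent = rng.standard_normal(n)
    loadings = np.zeros(p)
    if inactive.size and gamma > 0:
        raw = rng.standard_normal(inactive.size)
        loadings[inactive] = raw / np.linalg.norm(raw)
        log_areas += gamma * np.outer(x_latent, loadings)

    areas = np.exp(log_areas)
    rts = centers + spec.rt_jitter_sd * rng.standard_normal((n, p))
    rts = np.clip(rts, 1e-3, None)

    Z = _standardize(areas)
    signal = Z[:, active] @ beta

    noise_sd = spec.noise_sd
    if noise_sd is None:
        var_signal = float(signal.var(ddof=1))
        resid = var_signal * (1.0 - spec.target_r2) / spec.target_r2 - gamma**2
        noise_sd = float(np.sqrt(max(resid, 0.0)))

    batch_ids = [f"S{i + 1}" for i in range(n)]
    activity = {}
    latents = {}
    squash = {}
    for assay, (loc, scale) in (("dpph_pct", (70.0, 8.0)), ("t_aoc", (1.3, 0.3))):
        c = _residualize(rng.standard_normal(n), Z[:, active])
        y = signal + gamma * c + noise_sd * rng.standard_normal(n)
        y_sd = y.std(ddof=1)
        a = scale / y_sd if y_sd > 0 else 1.0
        b = loc - a * y.mean()
        activity[assay] = a * y + b
        latents[assay] = c
        squash[assay] = {"slope": float(a), "intercept": float(b)}

    tables = [
        PeakTable(
            batch_ids[i],
            tuple((str(j + 1), float(rts[i, j]), float(areas[i, j])) for j in range(p)),
        )
        for i in range(n)
    ]
    activity_df = pd.DataFrame(activity, index=pd.Index(batch_ids, name="batch_id"))
    truth = {
        "active_set": [int(a + 1) for a in active],
        "effect_sizes": beta.tolist(),
        "noise_sd": float(noise_sd),
        "confounder_strength": gamma,
        "x_latent": x_latent.tolist(),
        "x_latent_loadings": loadings.tolist(),
        "activity_latents": {k: v.tolist() for k, v in latents.items()},
        "squash": squash,
        "rt_centers": centers.tolist(),
        "seed": spec.seed,
    }
    return tables, activity_df, truth


def generate_chromatograms(
    tables,
    peak_width_sd: float = 0.05,
    baseline_drift: float = 0.0,
    step: float = 0.01,
    pad: float = 1.0,
):
    """Render peak tables as Gaussian-peak chromatograms on a fixed grid.

    Each peak contributes an area-preserving Gaussian of SD
    ``peak_width_sd`` minutes; a linear baseline rises by
    ``baseline_drift`` intensity units over the run.
    """
    if peak_width_sd <= 0:
        raise ValueError("peak_width_sd must be > 0")
    tables = list(tables)
    lo = min(t.rts.min() for t in tables) - pad
    hi = max(t.rts.max() for t in tables) + pad
    grid = np.arange(max(lo, 0.0), hi + step / 2, step)
    span = grid[-1] - grid[0] if grid.size > 1 else 1.0
    out = []
    for t in tables:
        y = baseline_drift * (grid - grid[0]) / span
        for _, rt, area in t.peaks:
            y = y + area * _stats.norm.pdf(grid, loc=rt, scale=peak_width_sd)
        out.append(Chromatogram(t.batch_id, grid, y))
    return out
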