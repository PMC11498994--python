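"""Joint active-component screening across assays.

A peak is a candidate for one assay when its VIP exceeds the threshold
(default 1.0) *and* its scaled regression coefficient is positive —
important for the response and positively associated with it. The core
set is the intersection of the per-assay candidate sets. Peaks whose
VIP falls just below the threshold (within ``near_miss_slack``) with a
positive coefficient in at least one assay are surfaced as near-misses
rather than discarded, so the expert-judgement step stays transparent.
Grey relational degrees and ranks are reported alongside; they are not
thresholded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gra import GRAResult

logger = logging.getLogger(__name__)

__all__ = ["AssayStats", "ScreeningReport", "screen", "report"]


@dataclass(frozen=True)
class AssayStats:
    """Per-assay screening inputs: VIP and scaled coefficient per peak."""

    peak_ids: tuple
    vip: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "peak_ids", tuple(str(p) for p in self.peak_ids))
        object.__setattr__(self, "vip", np.asarray(self.vip, dtype=float))
        object.__setattr__(self, "coefficients", np.asarray(self.coefficients, dtype=float))
        if not (len(self.peak_ids) == self.vip.size == self.coefficients.size):
            raise ValueError("peak_ids, vip and coefficients must align")

    @classmethod
    def from_model(cls, model) -> "AssayStats":
        ids = model.peak_ids or [str(j + 1) for j in range(model.vip.size)]
        return cls(tuple(ids), model.vip, model.coefficients_scaled)


@dataclass
class ScreeningReport:
    per_peak: pd.DataFrame  # multiindexed columns (assay, {vip, coefficient, passes})
    core_set: list
    flagged_set: list  # near-misses
    per_assay_sets: dict  # assay -> sorted candidate peak list
    gra_degrees: pd.DataFrame | None = None
    gra_ranks: pd.DataFrame | None = None
    vip_threshold: float = 1.0
    near_miss_slack: float = 0.1

    def to_dict(self) -> dict:
        out = {
            "vip_threshold": self.vip_threshold,
            "near_miss_slack": self.near_miss_slack,
            "core_set": list(self.core_set),
            "flagged_set": list(self.flagged_set),
            "per_assay_sets": {a: list(s) for a, s in self.per_assay_sets.items()},
            "per_peak": {
                "_".join(col): self.per_peak[col].tolist() for col in self.per_peak.columns
            },
            "peaks": list(self.per_peak.index),
        }
        if self.gra_degrees is not None:
            out["gra_degrees"] = {
                a: self.gra_degrees[a].tolist() for a in self.gra_degrees.columns
            }
            out["gra_ranks"] = {
                a: [int(r) for r in self.gra_ranks[a]] for a in self.gra_ranks.columns
            }
        return out


def screen(
    models: dict,
    gra: GRAResult | None = None,
    vip_threshold: float = 1.0,
    near_miss_slack: float = 0.1,
) -> ScreeningReport:
    """Apply the joint VIP-and-sign rule over all assays.

    ``models`` maps assay name -> fitted OPLS model or :class:`AssayStats`.
    Candidate per assay: VIP > threshold and coefficient > 0; core set:
    candidate in every assay; near-miss: VIP in
    [threshold - slack, threshold] with positive coefficient in at least
    one assay, excluding core-set members. Within each set peaks are
    sorted by their minimum-across-assays VIP, descending.
    """
    stats = {
        a: (m if isinstance(m, AssayStats) else AssayStats.from_model(m))
        for a, m in models.items()
    }
    if not stats:
        raise ValueError("no assays supplied")
    peak_sets = {a: s.peak_ids for a, s in stats.items()}
    first = next(iter(peak_sets.values()))
    if any(p != first for p in peak_sets.values()):
        raise ValueError("assays were fitted over different peak sets")
    if gra is not None and set(gra.degrees.index) != set(first):
        raise ValueError("GRA result covers a different peak set")
    peaks = list(first)

    cols = {}
    per_assay_sets = {}
    near_any = np.zeros(len(peaks), dtype=bool)
    for a, s in stats.items():
        passes = (s.vip > vip_threshold) & (s.coefficients > 0)
        near = (
            (s.vip >= vip_threshold - near_miss_slack)
            & (s.vip <= vip_threshold)
            & (s.coefficients > 0)
        )
        near_any |= near
        cols[(a, "vip")] = s.vip
        cols[(a, "coefficient")] = s.coefficients
        cols[(a, "passes")] = passes
        per_assay_sets[a] = [p for p, ok in zip(peaks, passes) if ok]

    per_peak = pd.DataFrame(cols, index=peaks)
    per_peak.columns = pd.MultiIndex.from_tuples(per_peak.columns)

    min_vip = np.min(np.vstack([s.vip for s in stats.values()]), axis=0)
    order = {p: v for p, v in zip(peaks, min_vip)}

    core = set(peaks)
    for s in per_assay_sets.values():
        core &= set(s)
    core_sorted = sorted(core, key=lambda p: -order[p])
    flagged = [p for p, nm in zip(peaks, near_any) if nm and p not in core]
    flagged_sorted = sorted(flagged, key=lambda p: -order[p])

    return ScreeningReport(
        per_peak=per_peak,
        core_set=core_sorted,
        flagged_set=flagged_sorted,
        per_assay_sets=per_assay_sets,
        gra_degrees=gra.degrees.loc[peaks] if gra is not None else None,
        gra_ranks=gra.ranks.loc[peaks] if gra is not None else None,
        vip_threshold=vip_threshold,
        near_miss_slack=near_miss_slack,
    )


def report(screening: ScreeningReport, identities: dict | None = None) -> dict:
    """Render a screening report as JSON-ready dict plus markdown text.

    ``identities`` optionally maps peak id -> compound name; unknown
    peaks in the map trigger a warning, not an error.
    """
    identities = {str(k): v for k, v in (identities or {}).items()}
    peaks = set(screening.per_peak.index)
    for p in identities:
        if p not in peaks:
            logger.warning("identity map names unknown peak %s", p)

    def label(p: str) -> str:
        return f"{p} ({identities[p]})" if p in identities else str(p)

    lines = ["# Spectrum-effect screening report", ""]
    if screening.core_set:
        lines.append(
            "Core candidates (VIP > "
            f"{screening.vip_threshold:g} and positive coefficient in every assay): "
            + ", ".join(label(p) for p in screening.core_set)
        )
    else:
        lines.append("No peaks pass the joint rule in every assay; no candidates.")
    if screening.flagged_set:
        lines.append(
            "Near-misses (VIP within "
            f"{screening.near_miss_slack:g} of the threshold): "
            + ", ".join(label(p) for p in screening.flagged_set)
        )
    for a, s in screening.per_assay_sets.items():
        lines.append(f"- {a}: candidates {', '.join(map(label, s)) if s else 'none'}")
    doc = screening.to_dict()
    doc["identities"] = identities
    doc["markdown"] = "\n".join(lines)
    return doc
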