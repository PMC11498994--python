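"""Chromatographic fingerprint construction and quality control.

Builds the common-peak matrix from per-batch peak tables, expresses
retention times and areas relative to a reference peak, computes RSD
repeatability summaries, and scores batch-to-batch fingerprint
similarity against a median consensus fingerprint.

A *common peak* is one matched (by retention time, within a fixed time
window) across all batches of a preparation; the common-peak area matrix
is the independent-variable block for the downstream spectrum-effect
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Chromatogram",
    "PeakTable",
    "CommonPeakMatrix",
    "FingerprintSummary",
    "match_common_peaks",
    "relative_to_reference",
    "rsd",
    "reference_fingerprint",
    "cosine_similarity",
    "similarity_matrix",
    "multipoint_rt_correction",
    "resample_chromatograms",
]


@dataclass(frozen=True)
class Chromatogram:
    """A single batch's detector trace at one wavelength.

    Times are minutes, strictly increasing; intensities are in arbitrary
    detector units and must be finite.
    """

    batch_id: str
    times: np.ndarray
    intensities: np.ndarray
    wavelength_nm: float = 330.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size or t.size < 2:
            raise ValueError("times and intensities must be 1-d, equal length >= 2")
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"times must be strictly increasing (batch {self.batch_id})")
        if not np.all(np.isfinite(y)):
            raise ValueError(f"non-finite intensities (batch {self.batch_id})")


@dataclass(frozen=True)
class PeakTable:
    """Detected peaks of one batch: (peak id, retention time in min, area)."""

    batch_id: str
    peaks: tuple  # of (local_peak_id: str, rt_min: float, area: float)

    def __post_init__(self) -> None:
        peaks = tuple((str(pid), float(rt), float(a)) for pid, rt, a in self.peaks)
        object.__setattr__(self, "peaks", peaks)
        if not peaks:
            raise ValueError(f"batch {self.batch_id}: at least one peak required")
        ids = [p[0] for p in peaks]
        if len(set(ids)) != len(ids):
            raise ValueError(f"batch {self.batch_id}: duplicate local peak ids")
        if any(p[1] <= 0 for p in peaks):
            raise ValueError(f"batch {self.batch_id}: retention times must be > 0")
        if any(p[2] < 0 for p in peaks):
            raise ValueError(f"batch {self.batch_id}: areas must be >= 0")

    @property
    def rts(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])

    @property
    def areas(self) -> np.ndarray:
        return np.array([p[2] for p in self.peaks])


@dataclass
class CommonPeakMatrix:
    """Batches x common peaks of areas and retention times after matching."""

    batch_ids: list
    peak_ids: list
    areas: np.ndarray  # (n_batches, n_peaks)
    rts: np.ndarray  # (n_batches, n_peaks)
    reference_peak_id: str | None = None
    occupancy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.rts = np.asarray(self.rts, dtype=float)
        if self.areas.shape != self.rts.shape:
            raise ValueError("areas and rts must have identical shape")
        if self.areas.shape != (len(self.batch_ids), len(self.peak_ids)):
            raise ValueError("matrix shape does not match batch/peak labels")
        self.peak_ids = [str(p) for p in self.peak_ids]
        self.batch_ids = [str(b) for b in self.batch_ids]

    @property
    def n_batches(self) -> int:
        return len(self.batch_ids)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_ids)

    def areas_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.areas, index=self.batch_ids, columns=self.peak_ids)

    def rts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rts, index=self.batch_ids, columns=self.peak_ids)


@dataclass
class FingerprintSummary:
    """QC report: per-peak RSDs, pairwise similarity, consensus fingerprint."""

    relative_rt_rsd: pd.Series
    relative_area_rsd: pd.Series
    similarity: pd.DataFrame
    reference_fingerprint: np.ndarray
    reference_peak_id: str | None = None


def rsd(values) -> float:
    """Relative standard deviation in percent: 100 * sample SD / mean.

    Uses the n-1 (sample) standard deviation throughout, matching the
    convention of chromatographic method-validation reports.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("rsd requires at least 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("rsd undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)


def _min_window_segments(rts, window: float) -> list:
    """Partition sorted rts into the fewest contiguous segments whose
    members all lie within ``window`` of the segment median.

    Returns index ranges per segment. A valid segment spans at most
    2*window, so the dynamic program only scans bounded history.
    """
    eps = 1e-9 * max(1.0, window)
    rts = list(rts)
    n = len(rts)

    def valid(j: int, i: int) -> bool:  # segment rts[j:i]
        seg = rts[j:i]
        mid = len(seg) // 2
        med = seg[mid] if len(seg) % 2 else 0.5 * (seg[mid - 1] + seg[mid])
        return (rts[i - 1] - med) <= window + eps and (med - rts[j]) <= window + eps

    INF = n + 1
    best = [0] + [INF] * n
    back = [0] * (n + 1)
    for i in range(1, n + 1):
        j = i - 1
        while j >= 0 and rts[i - 1] - rts[j] <= 2 * window + eps:
            if best[j] + 1 < best[i] and valid(j, i):
                best[i] = best[j] + 1
                back[i] = j
            j -= 1
    segments = []
    i = n
    while i > 0:
        segments.append(range(back[i], i))
        i = back[i]
    return segments[::-1]


def match_common_peaks(
    tables,
    time_window: float = 0.1,
    min_occupancy: float = 1.0,
) -> CommonPeakMatrix:
    """Cluster peaks across batches by retention time into common peaks.

    The pooled, rt-sorted peak list is partitioned into the fewest
    contiguous segments such that every member of a segment lies within
    ``time_window`` of the segment's median rt (minimal-segmentation
    dynamic program; ties resolved toward a shorter last segment). Each
    batch contributes at most one peak per cluster; when two peaks of
    one batch are equally near the cluster median the earlier rt wins
    (logged). Clusters present in at least ``min_occupancy`` of batches
    become common peaks, ordered by median rt and labelled "1", "2", ...

    Anchoring the window to the cluster median (rather than
    nearest-neighbour chaining) makes the result depend only on the
    pooled rt multiset, hence invariant to batch order and within-batch
    peak order.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("need at least 2 peak tables to match common peaks")
    if time_window <= 0:
        raise ValueError("time_window must be > 0")

    # pooled peaks sorted by rt, ties broken deterministically by batch id
    pooled = sorted(
        (
            (rt, str(t.batch_id), pid, area)
            for t in tables
            for pid, rt, area in t.peaks
        ),
        key=lambda x: (x[0], x[1], x[2]),
    )

    refined = [
        [pooled[k] for k in seg]
        for seg in _min_window_segments([r[0] for r in pooled], time_window)
    ]

    batch_ids = [str(t.batch_id) for t in tables]
    n_batches = len(batch_ids)
    common = []
    for cl in refined:
        med = float(np.median([r[0] for r in cl]))
        # one peak per batch: nearest to median, tie -> earlier rt
        per_batch: dict[str, tuple] = {}
        for r in sorted(cl, key=lambda r: (abs(r[0] - med), r[0])):
            if r[1] not in per_batch:
                per_batch[r[1]] = r
            else:
                logger.debug(
                    "batch %s: extra peak %s at rt %.3f dropped from cluster at %.3f",
                    r[1], r[2], r[0], med,
                )
        occ = len(per_batch) / n_batches
        if occ >= min_occupancy:
            common.append((med, occ, per_batch))

    common.sort(key=lambda c: c[0])
    peak_ids = [str(i + 1) for i in range(len(common))]
    areas = np.full((n_batches, len(common)), np.nan)
    rts = np.full((n_batches, len(common)), np.nan)
    for j, (_, _, per_batch) in enumerate(common):
        for i, b in enumerate(batch_ids):
            if b in per_batch:
                rec = per_batch[b]
                rts[i, j] = rec[0]
                areas[i, j] = rec[3]
    occupancy = np.array([c[1] for c in common])
    return CommonPeakMatrix(batch_ids, peak_ids, areas, rts, occupancy=occupancy)


def relative_to_reference(matrix: CommonPeakMatrix, reference_peak_id):
    """Express rts and areas relative to the reference peak, per batch.

    Returns ``(relative_rts, relative_areas)`` as DataFrames; the
    reference peak's columns are exactly 1.0 in every batch.
    """
    ref = str(reference_peak_id)
    if ref not in matrix.peak_ids:
        raise ValueError(f"reference peak {ref!r} not among common peaks")
    j = matrix.peak_ids.index(ref)
    ref_rt = matrix.rts[:, j]
    ref_area = matrix.areas[:, j]
    for name, col in (("retention time", ref_rt), ("area", ref_area)):
        bad = np.where(~(col > 0))[0]
        if bad.size:
            raise ValueError(
                f"reference peak {ref} has non-positive {name} in batch "
                f"{matrix.batch_ids[bad[0]]}"
            )
    rel_rts = matrix.rts / ref_rt[:, None]
    rel_areas = matrix.areas / ref_area[:, None]
    rel_rts[:, j] = 1.0
    rel_areas[:, j] = 1.0
    idx, cols = matrix.batch_ids, matrix.peak_ids
    return (
        pd.DataFrame(rel_rts, index=idx, columns=cols),
        pd.DataFrame(rel_areas, index=idx, columns=cols),
    )


def reference_fingerprint(vectors, method: str = "median") -> np.ndarray:
    """Consensus fingerprint across batches: component-wise median (or mean).

    ``vectors`` is a (n_batches, n_features) array-like of conformable
    batch vectors (common-peak areas, or chromatograms already resampled
    to a shared grid).
    """
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need a 2-d (batches x features) array with >= 1 batch")
    if method == "median":
        return np.median(arr, axis=0)
    if method == "mean":
        return arr.mean(axis=0)
    raise ValueError(f"unknown consensus method {method!r}")


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two fingerprint vectors.

    In [0, 1] for nonnegative chromatographic data; invariant to uniform
    scaling of either vector.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("vectors must be 1-d and of equal length >= 1")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(a @ b / (na * nb))


def _correlation_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return cosine_similarity(a - a.mean(), b - b.mean())


def similarity_matrix(
    vectors,
    batch_ids=None,
    include_reference: bool = True,
    method: str = "cosine",
) -> pd.DataFrame:
    """All pairwise batch similarities, optionally plus the median consensus.

    ``method`` is ``"cosine"`` (default, the usual fingerprint-similarity
    score) or ``"correlation"`` (cosine of mean-centred vectors).
    """
    if isinstance(vectors, CommonPeakMatrix):
        batch_ids = vectors.batch_ids
        arr = vectors.areas
    else:
        arr = np.asarray(vectors, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 batches")
    if batch_ids is None:
        batch_ids = [f"S{i + 1}" for i in range(arr.shape[0])]
    labels = list(batch_ids)
    rows = [arr[i] for i in range(arr.shape[0])]
    if include_reference:
        rows.append(reference_fingerprint(arr))
        labels = labels + ["Control"]
    score = cosine_similarity if method == "cosine" else _correlation_similarity
    n = len(rows)
    sim = np.eye(n)
    for i in range(n):
        for k in range(i + 1, n):
            sim[i, k] = sim[k, i] = score(rows[i], rows[k])
    return pd.DataFrame(sim, index=labels, columns=labels)


def multipoint_rt_correction(table: PeakTable, anchors) -> PeakTable:
    """Remap retention times through a piecewise-linear anchor function.

    ``anchors`` is a sequence of (observed_rt, reference_rt) pairs,
    strictly increasing in both coordinates; times beyond the outermost
    anchors are extrapolated linearly. Areas are unchanged.
    """
    anchors = sorted((float(o), float(r)) for o, r in anchors)
    if len(anchors) < 2:
        raise ValueError("need at least 2 anchors")
    obs = np.array([a[0] for a in anchors])
    ref = np.array([a[1] for a in anchors])
    if not (np.all(np.diff(obs) > 0) and np.all(np.diff(ref) > 0)):
        raise ValueError("anchors must be strictly increasing in both coordinates")

    def remap(t: float) -> float:
        if t <= obs[0]:
            i = 0
        elif t >= obs[-1]:
            i = len(obs) - 2
        else:
            i = int(np.searchsorted(obs, t, side="right")) - 1
        slope = (ref[i + 1] - ref[i]) / (obs[i + 1] - obs[i])
        return ref[i] + slope * (t - obs[i])

    new_peaks = tuple((pid, remap(rt), area) for pid, rt, area in table.peaks)
    return PeakTable(table.batch_id, new_peaks)


def resample_chromatograms(chromatograms) -> tuple[np.ndarray, np.ndarray]:
    """Linear-interpolate chromatograms onto the union time grid.

    The grid spans the intersection of the time ranges at the finest
    input step; returns (grid, intensities matrix of shape
    (n_batches, len(grid))).
    """
    chroms = list(chromatograms)
    if not chroms:
        raise ValueError("no chromatograms")
    start = max(c.times[0] for c in chroms)
    stop = min(c.times[-1] for c in chroms)
    if stop <= start:
        raise ValueError("chromatogram time ranges do not overlap")
    step = min(np.min(np.diff(c.times)) for c in chroms)
    grid = np.arange(start, stop + step / 2, step)
    mat = np.vstack([np.interp(grid, c.times, c.intensities) for c in chroms])
    return grid, mat


def fingerprint_summary(
    matrix: CommonPeakMatrix,
    reference_peak_id,
    similarity_method: str = "cosine",
) -> FingerprintSummary:
    """Full QC summary: relative-RT/area RSDs and the similarity matrix."""
    rel_rts, rel_areas = relative_to_reference(matrix, reference_peak_id)
    rt_rsd = pd.Series(
        {p: (0.0 if p == str(reference_peak_id) else rsd(rel_rts[p])) for p in matrix.peak_ids}
    )
    area_rsd = pd.Series(
        {p: (0.0 if p == str(reference_peak_id) else rsd(rel_areas[p])) for p in matrix.peak_ids}
    )
    sim = similarity_matrix(matrix, method=similarity_method)
    return FingerprintSummary(
        relative_rt_rsd=rt_rsd,
        relative_area_rsd=area_rsd,
        similarity=sim,
        reference_fingerprint=reference_fingerprint(matrix.areas),
        reference_peak_id=str(reference_peak_id),
    )
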