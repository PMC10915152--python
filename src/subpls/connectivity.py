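"""Region-of-interest time series to vectorized functional-connectivity profiles.

Functional connectivity (FC) between two brain regions is the Pearson
correlation of their BOLD time series, mapped through the Fisher r-to-z
transform ``z = atanh(r)`` so that edge values are approximately normal and
unbounded.  For a ``d``-region parcellation the full ``d x d`` correlation
matrix is symmetric with a meaningless diagonal, so a subject's FC profile is
the row-major upper triangle (``i < j``), a vector of length ``d(d-1)/2``
(1431 edges for the 54-subregion subcortical parcellation used throughout
this package).

Optional motion "scrubbing" censors frames whose framewise displacement (FD)
exceeds a threshold before correlations are computed; correlations are then
computed on the surviving frames only, with no interpolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "ConnectivityProfile",
    "ScrubbingWarning",
    "scrub",
    "compute_fc",
    "vectorize",
    "devectorize",
    "make_pair_labels",
    "n_edges",
]


class ScrubbingWarning(UserWarning):
    """Raised as a warning when motion censoring removes an unusual share of frames."""


def n_edges(n_regions: int) -> int:
    """Number of unique off-diagonal region pairs, d(d-1)/2."""
    return n_regions * (n_regions - 1) // 2


@dataclass
class RoiTimeSeries:
    """One subject's extracted ROI signals.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    data : ndarray, shape (timepoints, regions)
        Mean BOLD signal per frame and region.
    region_labels : list of str
        Parcel names, one per column of ``data``.
    fd : ndarray, shape (timepoints,), optional
        Framewise displacement in mm, used for scrubbing.
    meta : dict
        Free-form provenance (e.g. scrubbing bookkeeping).
    """

    subject_id: str
    data: np.ndarray
    region_labels: list[str]
    fd: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (timepoints x regions)")
        self.region_labels = list(self.region_labels)
        t, d = self.data.shape
        if len(self.region_labels) != d:
            raise ValueError(
                f"{len(self.region_labels)} region labels for {d} data columns"
            )
        if self.fd is not None:
            self.fd = np.asarray(self.fd, dtype=float)
            if self.fd.shape != (t,):
                raise ValueError("fd trace length must equal the number of frames")
        if t < 2 * d:
            warnings.warn(
                f"subject {self.subject_id}: only {t} frames for {d} regions; "
                "correlation estimates may be unstable",
                UserWarning,
                stacklevel=2,
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityProfile:
    """One subject's Fisher-z FC values on the unique region pairs (i < j)."""

    subject_id: str
    values: np.ndarray
    pair_labels: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("FC profile must be a 1-D vector")
        if len(self.pair_labels) != self.values.size:
            raise ValueError("pair label count must match value count")
        _n_regions_from_length(self.values.size)  # validates triangular length
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FC profile contains non-finite values")

    @property
    def n_regions(self) -> int:
        return _n_regions_from_length(self.values.size)


def _n_regions_from_length(length: int) -> int:
    """Invert length = d(d-1)/2; raise if length is not triangular."""
    d = (1 + math.isqrt(1 + 8 * length)) // 2
    if d * (d - 1) // 2 != length or length < 1:
        raise ValueError(f"length {length} is not of the form d(d-1)/2")
    return d


def make_pair_labels(region_labels: list[str]) -> list[tuple[str, str]]:
    """Ordered (region_i, region_j) pairs, i < j, row-major upper triangle."""
    labels = list(region_labels)
    return [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]


def scrub(
    ts: RoiTimeSeries,
    fd_threshold: float = 0.5,
    augment_neighbors: bool = False,
) -> RoiTimeSeries:
    """Censor high-motion frames by framewise displacement.

    Frames with ``fd > fd_threshold`` are removed.  With
    ``augment_neighbors=True`` the censoring mask is widened to 1 frame back
    and 2 frames forward of every offending frame, the common augmentation
    for motion artifact spillover.

    Returns a new :class:`RoiTimeSeries` on the surviving frames; the number
    of censored frames is recorded in ``meta``.  A :class:`ScrubbingWarning`
    is issued (and ``meta['low_retention']`` set) when fewer than half of the
    frames survive.

    Raises
    ------
    ValueError
        If the series carries no FD trace, the threshold is not positive, or
        censoring removes every frame.
    """
    if ts.fd is None:
        raise ValueError(f"subject {ts.subject_id}: no framewise-displacement trace")
    if fd_threshold <= 0:
        raise ValueError("fd_threshold must be positive")

    bad = ts.fd > fd_threshold
    if augment_neighbors:
        widened = bad.copy()
        for i in np.flatnonzero(bad):
            widened[max(i - 1, 0) : i + 3] = True
        bad = widened

    keep = ~bad
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise ValueError(
            f"subject {ts.subject_id}: scrubbing at FD > {fd_threshold} mm "
            "removed every frame"
        )
    low = n_keep < 0.5 * ts.n_frames
    if low:
        warnings.warn(
            f"subject {ts.subject_id}: only {n_keep}/{ts.n_frames} frames "
            f"survive scrubbing at FD > {fd_threshold} mm",
            ScrubbingWarning,
            stacklevel=2,
        )
    meta = dict(ts.meta)
    meta.update(
        scrub_fd_threshold=fd_threshold,
        scrub_augmented=augment_neighbors,
        n_input_frames=ts.n_frames,
        n_censored=ts.n_frames - n_keep,
        low_retention=low,
    )
    with warnings.catch_warnings():
        # the post-scrub series may legitimately be short; warned above instead
        warnings.simplefilter("ignore", UserWarning)
        out = RoiTimeSeries(
            subject_id=ts.subject_id,
            data=ts.data[keep],
            region_labels=ts.region_labels,
            fd=ts.fd[keep],
            meta=meta,
        )
    return out


def compute_fc(ts: RoiTimeSeries) -> ConnectivityProfile:
    """Pairwise Pearson correlations between region signals, Fisher z-transformed.

    The diagonal is excluded (atanh(1) diverges) and each symmetric pair is
    stored once, in row-major upper-triangle order.

    Raises
    ------
    ValueError
        If fewer than 3 frames remain, a region has zero variance (named in
        the message), or two distinct regions are perfectly correlated
        (infinite Fisher z).
    """
    t, d = ts.data.shape
    if t < 3:
        raise ValueError(f"subject {ts.subject_id}: need >= 3 timepoints, got {t}")
    sd = ts.data.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = ", ".join(ts.region_labels[i] for i in flat)
        raise ValueError(
            f"subject {ts.subject_id}: zero-variance region(s): {names}"
        )
    r = np.corrcoef(ts.data, rowvar=False)
    iu = np.triu_indices(d, k=1)
    r_vec = r[iu]
    sat = np.abs(r_vec) >= 1.0 - 1e-12
    if np.any(sat):
        i, j = iu[0][sat][0], iu[1][sat][0]
        raise ValueError(
            f"subject {ts.subject_id}: |r| = 1 between distinct regions "
            f"{ts.region_labels[i]} and {ts.region_labels[j]} (infinite Fisher z)"
        )
    return ConnectivityProfile(
        subject_id=ts.subject_id,
        values=np.arctanh(r_vec),
        pair_labels=make_pair_labels(ts.region_labels),
    )


def vectorize(matrix: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Row-major upper-triangle (i < j) vector of a symmetric matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(m, m.T, atol=atol, rtol=0):
        raise ValueError("matrix is not symmetric")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def devectorize(vector: np.ndarray) -> np.ndarray:
    """Rebuild the symmetric matrix (zero diagonal) from an upper-triangle vector."""
    v = np.asarray(vector, dtype=float).ravel()
    d = _n_regions_from_length(v.size)
    m = np.zeros((d, d))
    iu = np.triu_indices(d, k=1)
    m[iu] = v
    m += m.T
    return m
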