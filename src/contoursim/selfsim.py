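"""Self-similarity statistic Gamma of a cyclic entropy profile.

The profile (length ``L``, required to be a multiple of the window size
``W``) is tiled by ``K = L / W`` non-overlapping windows; an ordinary
least-squares slope is fitted in each window.  Two windows are *similar*
when their slopes agree in sign and the ratio of the smaller to the larger
slope magnitude reaches the threshold ``c``.  The window tiling is then
cyclically shifted by multiples of the lag ``phi`` — offsets ``j*phi`` for
``j = 0 .. theta`` with ``theta = LCM(W, phi)/phi - 1`` — and for each
offset the fraction of similar window pairs, ``gamma_j`` (in percent), is
recorded.  Gamma is the maximum of the ``gamma_j``.

Gamma is defined only for profiles of closed contours (the shifted windows
wrap around the profile end).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .entropy import EntropyProfile
from .errors import ContourError, OpenContourError, ProfileLengthError

__all__ = [
    "GammaParams",
    "SlopeRow",
    "CountMatrix",
    "GammaResult",
    "window_slope",
    "is_similar",
    "row_offsets",
    "slopes_for_row",
    "count_matrix",
    "gamma_from_row",
    "self_similarity",
]


@dataclass(frozen=True)
class GammaParams:
    """Window size ``W``, lag ``phi`` and similarity threshold ``c``.

    ``flat_tolerance`` relaxes the strict sign test: slopes whose magnitude
    does not exceed it are treated as flat, and two flat windows count as
    similar.  The default 0.0 keeps the strict rule (a zero slope is similar
    to nothing).
    """

    window_size: int = 20
    lag: int = 20
    c: float = 0.8
    flat_tolerance: float = 0.0

    def __post_init__(self) -> None:
        if int(self.window_size) != self.window_size or self.window_size < 2:
            raise ContourError(f"window_size must be an integer >= 2, got {self.window_size}")
        if int(self.lag) != self.lag or not 1 <= self.lag <= self.window_size:
            raise ContourError(
                f"lag must be an integer in [1, window_size], got {self.lag}"
            )
        if not 0.0 < self.c <= 1.0:
            raise ContourError(f"c must be in (0, 1], got {self.c}")
        if self.flat_tolerance < 0:
            raise ContourError("flat_tolerance must be non-negative")

    @property
    def theta(self) -> int:
        """Number of extra cyclically shifted rows: LCM(W, phi)/phi - 1."""
        return math.lcm(self.window_size, self.lag) // self.lag - 1


@dataclass(frozen=True)
class SlopeRow:
    offset: int
    slopes: np.ndarray


@dataclass(frozen=True)
class CountMatrix:
    """(theta+1) x K matrix of similar-window counts, self-comparison included."""

    rows: np.ndarray
    theta: int

    @property
    def n_windows(self) -> int:
        return self.rows.shape[1]


@dataclass(frozen=True)
class GammaResult:
    gamma_by_offset: np.ndarray  # percent, one per row offset
    gamma: float                 # max of gamma_by_offset, percent
    params: GammaParams
    counts: CountMatrix

    @property
    def n_windows(self) -> int:
        return self.counts.n_windows


def window_slope(values) -> float:
    """Ordinary least-squares slope of ``values`` against abscissae 0..W-1."""
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ContourError("window_slope needs at least 2 values")
    x = np.arange(y.size, dtype=float)
    xc = x - x.mean()
    return float((xc * (y - y.mean())).sum() / (xc * xc).sum())


def is_similar(w1: float, w2: float, c: float = 0.8, flat_tolerance: float = 0.0) -> bool:
    """Slope-similarity criterion.

    True when the slopes agree in sign and min(|w1|, |w2|) / max(|w1|, |w2|)
    >= c.  With a positive ``flat_tolerance`` two near-flat slopes (both
    magnitudes <= tolerance) are also similar.
    """
    a1, a2 = abs(w1), abs(w2)
    if flat_tolerance > 0 and a1 <= flat_tolerance and a2 <= flat_tolerance:
        return True
    if w1 * w2 <= 0:
        return False
    lo, hi = (a1, a2) if a1 <= a2 else (a2, a1)
    return lo / hi >= c


def row_offsets(params: GammaParams) -> np.ndarray:
    """Cyclic offsets j*phi for j = 0..theta."""
    return params.lag * np.arange(params.theta + 1)


def _as_cyclic_values(profile, params: GammaParams) -> np.ndarray:
    if isinstance(profile, EntropyProfile):
        if not profile.closed:
            raise OpenContourError(
                "Gamma requires a profile from a closed contour (cyclic shifts wrap)"
            )
        values = profile.normalized
    else:
        values = np.asarray(profile, dtype=float)
    if values.ndim != 1:
        raise ContourError("profile must be one-dimensional")
    L, W = values.size, params.window_size
    if L < W or L % W != 0:
        raise ProfileLengthError(
            f"profile length {L} is not a positive multiple of window size {W}; "
            "resample the contour (e.g. to 1000 nodes) before computing Gamma"
        )
    return values


def _row_slopes(values: np.ndarray, params: GammaParams, offset: int) -> np.ndarray:
    L, W = values.size, params.window_size
    K = L // W
    idx = (offset + np.arange(L)) % L
    windows = values[idx].reshape(K, W)
    x = np.arange(W, dtype=float)
    xc = x - x.mean()
    yc = windows - windows.mean(axis=1, keepdims=True)
    return (yc @ xc) / (xc @ xc)


def slopes_for_row(profile, params: GammaParams, j: int) -> SlopeRow:
    """Window slopes for row ``j``: window ``k`` covers indices
    ``j*phi + k*W .. j*phi + k*W + W - 1`` modulo ``L``."""
    values = _as_cyclic_values(profile, params)
    if not 0 <= j <= params.theta:
        raise ContourError(f"row index {j} out of range 0..{params.theta}")
    offset = j * params.lag
    return SlopeRow(offset=offset, slopes=_row_slopes(values, params, offset))


def _similar_matrix(slopes: np.ndarray, params: GammaParams) -> np.ndarray:
    """Boolean K x K matrix of pairwise slope similarity (diagonal False)."""
    w = slopes
    a = np.abs(w)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.minimum.outer(a, a) / np.maximum.outer(a, a)
    ratio = np.nan_to_num(ratio, nan=0.0)
    sim = (np.multiply.outer(w, w) > 0) & (ratio >= params.c)
    if params.flat_tolerance > 0:
        flat = a <= params.flat_tolerance
        sim |= np.logical_and.outer(flat, flat)
    np.fill_diagonal(sim, False)
    return sim


def count_matrix(profile, params: GammaParams = GammaParams()) -> CountMatrix:
    """Similar-window counts M[j, k] per row offset; self-comparison included,
    so every entry is at least 1."""
    values = _as_cyclic_values(profile, params)
    rows = []
    for offset in row_offsets(params):
        slopes = _row_slopes(values, params, offset)
        sim = _similar_matrix(slopes, params)
        rows.append(1 + sim.sum(axis=1))
    return CountMatrix(rows=np.array(rows, dtype=int), theta=params.theta)


def gamma_from_row(row, K: int | None = None) -> float:
    """Percentage of similar unordered window pairs in one count-matrix row.

    gamma = 2 h / (K (K - 1)) * 100 with h = sum_k (M_k - 1) / 2.
    """
    counts = np.asarray(row, dtype=float)
    if K is None:
        K = counts.size
    if K < 2:
        raise ContourError("gamma needs at least 2 windows")
    h = ((counts - 1.0) / 2.0).sum()
    return float(2.0 * h / (K * (K - 1.0)) * 100.0)


def self_similarity(profile, params: GammaParams = GammaParams()) -> GammaResult:
    """Gamma = max over row offsets of gamma_j, with the full count matrix
    and per-offset values retained for inspection."""
    counts = count_matrix(profile, params)
    K = counts.n_windows
    gammas = np.array([gamma_from_row(r, K) for r in counts.rows])
    return GammaResult(
        gamma_by_offset=gammas,
        gamma=float(gammas.max()),
        params=params,
        counts=counts,
    )
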