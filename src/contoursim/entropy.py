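"""Branch-length-similarity (BLS) entropy and per-node contour profiles.

For a star network with branches of lengths ``L_1..L_n`` the entropy is

    S = -sum_j p_j log(p_j) / log(n),   p_j = L_j / sum_k L_k

so ``S`` is 1 exactly when all branches are equal and decreases as the
lengths spread out.  The entropy *profile* of a contour makes every node in
turn the hub of a star network reaching all other nodes and records ``S``
per node, in node order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import ContourError, ParseError, ZeroBranchError
from .shapes import Contour

__all__ = [
    "branch_probabilities",
    "bls_entropy",
    "star_distances",
    "entropy_profile",
    "EntropyProfile",
    "write_profile_csv",
    "read_profile_csv",
]


def _validate_lengths(lengths) -> np.ndarray:
    arr = np.asarray(lengths, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < 2:
        raise ZeroBranchError(f"a star network needs at least 2 branches, got {arr.size}")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ZeroBranchError("all branch lengths must be positive and finite")
    return arr


def branch_probabilities(lengths) -> np.ndarray:
    """Branch-length proportions p_j = L_j / sum(L); non-negative, sums to 1."""
    arr = _validate_lengths(lengths)
    return arr / arr.sum()


def bls_entropy(lengths) -> float:
    """Normalized Shannon entropy of branch-length proportions, in (0, 1].

    The value is independent of the logarithm base (the ratio cancels) and
    invariant to permutation and uniform scaling of the lengths.
    """
    p = branch_probabilities(lengths)
    return float(-(p * np.log(p)).sum() / np.log(p.size))


def star_distances(contour: Contour, i: int) -> np.ndarray:
    """Euclidean distances from node ``i`` to every other node, in node order."""
    pts = contour.points
    n = len(pts)
    if n < 3:
        raise ContourError("star distances need a contour of at least 3 nodes")
    if not -n <= i < n:
        raise IndexError(f"node index {i} out of range for {n} nodes")
    others = np.delete(np.arange(n), i % n)
    d = np.linalg.norm(pts[others] - pts[i], axis=1)
    if np.any(d == 0.0):
        j = int(others[d == 0.0][0])
        raise ZeroBranchError(
            f"node {i % n} coincides with node {j} (zero branch length)"
        )
    return d


@dataclass(frozen=True)
class EntropyProfile:
    """Per-node BLS entropy sequence of a contour.

    ``raw`` holds the entropy values in node order; ``normalized`` is the
    min-max rescaling of ``raw`` to [0, 1].  A constant raw profile cannot be
    min-max scaled: ``normalized`` is then all zeros and ``is_constant`` set.
    """

    raw: np.ndarray
    normalized: np.ndarray
    closed: bool
    is_constant: bool = False

    def __len__(self) -> int:
        return len(self.raw)


def entropy_profile(contour: Contour) -> EntropyProfile:
    """BLS entropy of the star network rooted at each contour node.

    Raises :class:`ZeroBranchError`, naming the offending node, if any two
    contour nodes coincide.
    """
    pts = contour.points
    n = len(pts)
    if n < 3:
        raise ContourError("an entropy profile needs at least 3 nodes")
    dist = squareform(pdist(pts))
    off_diag = ~np.eye(n, dtype=bool)
    zero = (dist == 0.0) & off_diag
    if zero.any():
        i = int(np.argwhere(zero)[0, 0])
        raise ZeroBranchError(f"node {i} coincides with another contour node")
    sums = dist.sum(axis=1)
    p = dist / sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(off_diag, p * np.log(p), 0.0)
    raw = -plogp.sum(axis=1) / np.log(n - 1)
    lo, hi = raw.min(), raw.max()
    # a spread at round-off level (e.g. a perfect circle) is treated as
    # constant rather than min-max amplified into noise
    if hi - lo > 1e-12 * max(1.0, abs(hi)):
        normalized = (raw - lo) / (hi - lo)
        constant = False
    else:
        normalized = np.zeros_like(raw)
        constant = True
    return EntropyProfile(raw=raw, normalized=normalized, closed=contour.closed,
                          is_constant=constant)


def write_profile_csv(profile: EntropyProfile, path: str | Path) -> None:
    """Write columns (index, raw_entropy, normalized_entropy) at 17 significant
    digits so the round-trip is lossless for doubles."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "raw_entropy", "normalized_entropy"])
        for i, (r, z) in enumerate(zip(profile.raw, profile.normalized)):
            writer.writerow([i, format(r, ".17g"), format(z, ".17g")])


def read_profile_csv(path: str | Path, closed: bool = True) -> EntropyProfile:
    path = Path(path)
    raw, norm = [], []
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if lineno == 1 and not row[0].strip().lstrip("-").replace(".", "", 1).isdigit():
                continue  # header
            if len(row) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            try:
                raw.append(float(row[1]))
                norm.append(float(row[2]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value in {row!r}") from exc
    if not raw:
        raise ParseError(f"{path}: empty profile")
    raw_arr = np.array(raw)
    return EntropyProfile(
        raw=raw_arr,
        normalized=np.array(norm),
        closed=closed,
        is_constant=bool(raw_arr.max() == raw_arr.min()),
    )
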