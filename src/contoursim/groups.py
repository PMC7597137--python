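"""Group statistics over entropy profiles: cyclic-shift correlation Q, the
group statistic Z, the (Gamma, Z) feature table and a nearest-centroid
classifier.

``Q`` between two equal-length cyclic profiles is the maximum Pearson
correlation over all cyclic shifts of one of them.  Within a group, each
shape's mean Q against the other members is treated as a branch length of a
star network; ``Z`` is one tenth of the BLS entropy of those branch
lengths, so ``Z`` is 0.1 exactly when the group correlates homogeneously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .entropy import EntropyProfile, bls_entropy
from .errors import ConstantProfileError, ContourError
from .selfsim import GammaParams, self_similarity

__all__ = [
    "ProfileGroup",
    "GroupFeatures",
    "max_shift_correlation",
    "group_mean_Q",
    "group_z",
    "group_features",
    "TrainedCentroids",
    "Prediction",
    "fit_centroids",
    "nearest_centroid_classify",
    "leave_one_out",
]

# the printed definition of Z divides by 10 (the paper's group size);
# pass prefactor="1/G" to scale by the actual group size instead
DEFAULT_Z_PREFACTOR = 0.1


def _as_profile_array(profile) -> np.ndarray:
    if isinstance(profile, EntropyProfile):
        return np.asarray(profile.normalized, dtype=float)
    return np.asarray(profile, dtype=float)


@dataclass(frozen=True)
class ProfileGroup:
    """A labelled group of equal-length normalized entropy profiles."""

    group_id: int | str
    profiles: np.ndarray  # (G, L)

    def __post_init__(self) -> None:
        arr = np.asarray(
            [_as_profile_array(p) for p in self.profiles], dtype=float
        )
        if arr.ndim != 2:
            raise ContourError("profiles in a group must all have the same length")
        if arr.shape[0] < 2:
            raise ContourError("a profile group needs at least 2 members")
        object.__setattr__(self, "profiles", arr)

    @property
    def size(self) -> int:
        return self.profiles.shape[0]

    @property
    def length(self) -> int:
        return self.profiles.shape[1]


@dataclass(frozen=True)
class GroupFeatures:
    group_id: int | str
    gamma_mean: float
    gamma_std: float
    z: float


def _center_std(p: np.ndarray) -> tuple[np.ndarray, float]:
    c = p - p.mean()
    s = float(np.sqrt((c * c).mean()))
    return c, s


def max_shift_correlation(p1, p2) -> float:
    """Maximum Pearson correlation between ``p1`` cyclically shifted and
    ``p2``, over all shifts.  Symmetric in its arguments; in [-1, 1].

    The scan over shifts uses the FFT circular cross-correlation; the value
    at the best shift is then recomputed directly so that exact alignments
    give exactly 1.0.
    """
    a = _as_profile_array(p1)
    b = _as_profile_array(p2)
    if a.shape != b.shape or a.ndim != 1:
        raise ContourError("profiles must be one-dimensional and of equal length")
    L = a.size
    if L < 3:
        raise ContourError("profiles must have length >= 3")
    ac, sa = _center_std(a)
    bc, sb = _center_std(b)
    if sa == 0.0 or sb == 0.0:
        raise ConstantProfileError("correlation undefined for a constant profile")
    cross = np.fft.irfft(np.fft.rfft(ac) * np.conj(np.fft.rfft(bc)), n=L)
    best = int(np.argmax(cross))
    # polish at the winning shift to remove FFT round-off
    shifted = np.roll(a, -best)
    q = float(np.corrcoef(shifted, b)[0, 1])
    return min(1.0, max(-1.0, q))


def _pairwise_Q(profiles: np.ndarray) -> np.ndarray:
    """Symmetric matrix of max-shift correlations (diagonal 1)."""
    n = profiles.shape[0]
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = max_shift_correlation(profiles[i], profiles[j])
    return out


def group_mean_Q(group: ProfileGroup) -> np.ndarray:
    """Per-shape mean of Q against every *other* member of the same group."""
    q = _pairwise_Q(group.profiles)
    g = group.size
    return (q.sum(axis=1) - np.diag(q)) / (g - 1)


def _z_from_means(means: np.ndarray, group_id, prefactor: float | str) -> float:
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        raise ContourError(
            f"group {group_id!r}: shape {int(bad[0])} has non-positive mean Q "
            f"({means[bad[0]]:.6g}); Z is undefined for non-positive branch lengths"
        )
    factor = 1.0 / means.size if prefactor == "1/G" else float(prefactor)
    return factor * bls_entropy(means)


def group_z(group: ProfileGroup, prefactor: float | str = DEFAULT_Z_PREFACTOR) -> float:
    """Z = prefactor * BLS entropy of the per-shape mean-Q values.

    With the default prefactor 0.1, Z lies in (0, 0.1] and equals 0.1
    exactly when all mean-Q values are equal.
    """
    return _z_from_means(group_mean_Q(group), group.group_id, prefactor)


def group_features(
    groups: Sequence[ProfileGroup],
    params: GammaParams = GammaParams(),
    prefactor: float | str = DEFAULT_Z_PREFACTOR,
) -> pd.DataFrame:
    """Per-group mean/std of Gamma over member shapes, plus Z."""
    rows = []
    for group in groups:
        gammas = np.array(
            [self_similarity(p, params).gamma for p in group.profiles]
        )
        rows.append(
            {
                "group_id": group.group_id,
                "gamma_mean": float(gammas.mean()),
                "gamma_std": float(gammas.std()),
                "z": group_z(group, prefactor),
            }
        )
    return pd.DataFrame(rows).set_index("group_id")


# ---------------------------------------------------------------------------
# nearest-centroid classification in (Gamma, Z) space

@dataclass(frozen=True)
class TrainedCentroids:
    """Fitted per-group centroids plus the member profiles needed to score a
    query's group-conditional Z."""

    features: pd.DataFrame  # index group_id, columns gamma_mean, gamma_std, z
    groups: tuple[ProfileGroup, ...]
    params: GammaParams
    prefactor: float | str = DEFAULT_Z_PREFACTOR


@dataclass(frozen=True)
class Prediction:
    group_id: int | str
    tie: bool
    distances: pd.Series


def fit_centroids(
    groups: Sequence[ProfileGroup],
    params: GammaParams = GammaParams(),
    prefactor: float | str = DEFAULT_Z_PREFACTOR,
) -> TrainedCentroids:
    feats = group_features(groups, params, prefactor)
    return TrainedCentroids(
        features=feats, groups=tuple(groups), params=params, prefactor=prefactor
    )


def _augmented_z(
    group: ProfileGroup, query: np.ndarray, prefactor: float | str
) -> float:
    """Z of the candidate group with the query profile appended.

    Close to the group's own Z when the query correlates with the members
    like they do with each other; depressed otherwise.
    """
    stacked = np.vstack([group.profiles, query[None, :]])
    aug = ProfileGroup(group_id=group.group_id, profiles=stacked)
    return group_z(aug, prefactor)


def nearest_centroid_classify(train: TrainedCentroids, profile) -> Prediction:
    """Assign the group whose (Gamma-mean, Z) centroid is nearest to the
    query in standardized Euclidean distance.

    The query's Gamma coordinate is its own self-similarity; its Z
    coordinate is evaluated per candidate group as the group's Z with the
    query appended.  A candidate whose augmented Z is undefined (non-positive
    mean Q) is assigned infinite distance.  Exact ties resolve to the
    smallest group_id and set the ``tie`` flag.
    """
    query = _as_profile_array(profile)
    feats = train.features
    gamma_q = self_similarity(query, train.params).gamma
    s_gamma = max(float(feats["gamma_mean"].std(ddof=0)), 1e-15)
    s_z = max(float(feats["z"].std(ddof=0)), 1e-15)
    dists = {}
    for group in train.groups:
        row = feats.loc[group.group_id]
        try:
            z_q = _augmented_z(group, query, train.prefactor)
        except ContourError:
            dists[group.group_id] = np.inf
            continue
        d = np.hypot(
            (gamma_q - row["gamma_mean"]) / s_gamma, (z_q - row["z"]) / s_z
        )
        dists[group.group_id] = float(d)
    series = pd.Series(dists)
    order = sorted(series.index)
    best = min(order, key=lambda g: (series[g], order.index(g)))
    tie = int((series == series[best]).sum()) > 1
    return Prediction(group_id=best, tie=tie, distances=series)


def leave_one_out(
    groups: Sequence[ProfileGroup],
    params: GammaParams = GammaParams(),
    prefactor: float | str = DEFAULT_Z_PREFACTOR,
) -> pd.DataFrame:
    """Leave-one-out evaluation of the nearest-centroid classifier.

    Returns one row per held-out shape with its true and predicted group.
    Overall accuracy is ``(df.true == df.predicted).mean()``.
    """
    records = []
    for gi, group in enumerate(groups):
        for j in range(group.size):
            rest = np.delete(group.profiles, j, axis=0)
            fold_groups = list(groups)
            fold_groups[gi] = ProfileGroup(group.group_id, rest)
            train = fit_centroids(fold_groups, params, prefactor)
            pred = nearest_centroid_classify(train, group.profiles[j])
            records.append(
                {
                    "true": group.group_id,
                    "member": j,
                    "predicted": pred.group_id,
                    "tie": pred.tie,
                }
            )
    return pd.DataFrame(records)
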