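"""Synthetic contour generators, boundary tracing and contour I/O.

A :class:`Contour` is an ordered sequence of planar nodes.  Closed contours
wrap implicitly: the first node is *not* repeated at the end.  Generators are
deterministic — the same arguments (and seed, where applicable) always yield
bit-identical node sequences.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    AmbiguousMaskError,
    ContourError,
    InvalidSpecError,
    MaskError,
    NoShapeError,
    ParseError,
    TooSmallError,
)

__all__ = [
    "Contour",
    "ShapeSpec",
    "make_segmented_line",
    "make_triangle",
    "make_regular_polygon",
    "make_random_polygon",
    "perturb_contour",
    "make_template_groups",
    "rasterize_contour",
    "trace_boundary",
    "resample_contour",
    "read_contour_csv",
    "write_contour_csv",
]


@dataclass(frozen=True)
class Contour:
    """Ordered planar nodes of a shape boundary.

    Parameters
    ----------
    points
        ``(N, 2)`` float array of ``(x, y)`` coordinates.
    closed
        Whether the node sequence wraps around.  For a closed contour the
        first and last nodes must be distinct (the wrap is implicit).
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourError(f"points must be (N, 2), got shape {pts.shape}")
        if len(pts) < 2:
            raise ContourError("a contour needs at least 2 points")
        seg = np.diff(pts, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise ContourError("consecutive contour points must be distinct")
        if self.closed and np.all(pts[0] == pts[-1]):
            raise ContourError(
                "closed contour must not repeat its first point; the wrap is implicit"
            )
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    def segment_lengths(self) -> np.ndarray:
        """Lengths of the edges between consecutive nodes (wrap included if closed)."""
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return np.linalg.norm(np.diff(pts, axis=0), axis=1)

    def arc_length(self) -> float:
        return float(self.segment_lengths().sum())

    def signed_area(self) -> float:
        """Shoelace signed area; positive means counterclockwise node order."""
        x, y = self.points[:, 0], self.points[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.points + np.array([dx, dy]), self.closed)

    def rotated(self, angle: float) -> "Contour":
        c, s = math.cos(angle), math.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        return Contour(self.points @ rot.T, self.closed)

    def scaled(self, factor: float) -> "Contour":
        if factor <= 0:
            raise ContourError("scale factor must be positive")
        return Contour(self.points * factor, self.closed)


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of a synthetic shape, dispatchable via :meth:`build`."""

    kind: str
    node_counts: tuple = ()
    n_vertices: int = 0
    seed: int = 0
    nodes_total: int = 1000
    segment_length: float = 1.0

    _KINDS = ("segmented_line", "triangle", "regular_polygon", "random_polygon", "square")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise InvalidSpecError(
                f"unknown shape kind {self.kind!r}; expected one of {self._KINDS}"
            )

    def build(self) -> Contour:
        if self.kind == "segmented_line":
            n1, n2 = self.node_counts
            return make_segmented_line(n1, n2, self.segment_length)
        if self.kind == "triangle":
            n_ab, n_bc, n_ca = self.node_counts
            return make_triangle(n_ab, n_bc, n_ca)
        if self.kind == "square":
            (nodes_per_side,) = self.node_counts or (250,)
            return make_regular_polygon(4, nodes_per_side)
        if self.kind == "regular_polygon":
            n_sides, nodes_per_side = self.node_counts
            return make_regular_polygon(n_sides, nodes_per_side)
        # random_polygon
        return make_random_polygon(self.n_vertices, self.seed, self.nodes_total)


def _check_count(n: int, minimum: int, what: str) -> None:
    if int(n) != n or n < minimum:
        raise InvalidSpecError(f"{what} must be an integer >= {minimum}, got {n!r}")


def make_segmented_line(n1: int, n2: int, segment_length: float = 1.0) -> Contour:
    """Open collinear contour of two equal-length segments with node counts
    ``n1`` and ``n2``; the junction node is shared (counted once)."""
    _check_count(n1, 2, "n1")
    _check_count(n2, 2, "n2")
    if segment_length <= 0:
        raise InvalidSpecError("segment_length must be positive")
    x1 = np.linspace(0.0, segment_length, n1)
    x2 = np.linspace(segment_length, 2.0 * segment_length, n2)[1:]
    x = np.concatenate([x1, x2])
    return Contour(np.column_stack([x, np.zeros_like(x)]), closed=False)


def make_triangle(n_ab: int, n_bc: int, n_ca: int) -> Contour:
    """Equilateral triangle, counterclockwise from vertex ``a``, with the
    given node counts on sides a-b, b-c and c-a.  Shared vertices are
    counted once, so the total is ``n_ab + n_bc + n_ca - 3``."""
    for n, name in ((n_ab, "n_ab"), (n_bc, "n_bc"), (n_ca, "n_ca")):
        _check_count(n, 2, name)
    a = np.array([0.0, 0.0])
    b = np.array([1.0, 0.0])
    c = np.array([0.5, math.sqrt(3.0) / 2.0])
    sides = [
        np.linspace(a, b, n_ab)[:-1],
        np.linspace(b, c, n_bc)[:-1],
        np.linspace(c, a, n_ca)[:-1],
    ]
    return Contour(np.vstack(sides), closed=True)


def make_regular_polygon(n_sides: int, nodes_per_side: int) -> Contour:
    """Unit-circumradius regular polygon, counterclockwise, uniform node
    spacing per side, vertices counted once."""
    _check_count(n_sides, 3, "n_sides")
    _check_count(nodes_per_side, 2, "nodes_per_side")
    angles = 2.0 * np.pi * np.arange(n_sides) / n_sides
    verts = np.column_stack([np.cos(angles), np.sin(angles)])
    sides = []
    for k in range(n_sides):
        v0, v1 = verts[k], verts[(k + 1) % n_sides]
        sides.append(np.linspace(v0, v1, nodes_per_side)[:-1])
    return Contour(np.vstack(sides), closed=True)


def make_random_polygon(n_vertices: int, seed: int, nodes_total: int = 1000) -> Contour:
    """Simple random polygon by angular sort: random radii at sorted random
    angles about the origin (star-shaped, hence non-self-intersecting),
    resampled to ``nodes_total`` nodes uniform in arc length."""
    _check_count(n_vertices, 3, "n_vertices")
    _check_count(nodes_total, 3, "nodes_total")
    rng = np.random.default_rng(seed)
    while True:
        angles = np.sort(rng.uniform(0.0, 2.0 * np.pi, n_vertices))
        # distinct angles guarantee a simple star-shaped polygon
        if np.all(np.diff(angles) > 1e-9):
            break
    radii = rng.uniform(0.4, 1.0, n_vertices)
    verts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    return resample_contour(Contour(verts, closed=True), nodes_total)


def perturb_contour(contour: Contour, amplitude: float, seed: int) -> Contour:
    """Add deterministic i.i.d. Gaussian displacement of standard deviation
    ``amplitude`` (absolute units) to every node."""
    if amplitude < 0:
        raise InvalidSpecError("amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, amplitude, contour.points.shape)
    return Contour(contour.points + noise, contour.closed)


def make_template_groups(
    n_groups: int = 10,
    group_size: int = 10,
    nodes_total: int = 1000,
    noise_fraction: float = 0.01,
    seed: int = 0,
    n_vertices_range: tuple[int, int] = (10, 17),
) -> list[tuple[int, list[Contour]]]:
    """Template-plus-noise shape groups: one random-polygon template per
    group, members are the template with boundary noise whose amplitude is
    ``noise_fraction`` of the template's spatial scale.

    Returns a list of ``(group_id, [Contour, ...])`` with group ids 1..n.
    """
    rng = np.random.default_rng(seed)
    groups: list[tuple[int, list[Contour]]] = []
    for gid in range(1, n_groups + 1):
        n_vertices = int(rng.integers(n_vertices_range[0], n_vertices_range[1] + 1))
        template = make_random_polygon(n_vertices, int(rng.integers(0, 2**31)), nodes_total)
        extent = template.points.max(axis=0) - template.points.min(axis=0)
        amp = noise_fraction * float(extent.max())
        members = [
            perturb_contour(template, amp, int(rng.integers(0, 2**31)))
            for _ in range(group_size)
        ]
        groups.append((gid, members))
    return groups


# ---------------------------------------------------------------------------
# boundary tracing

# Moore neighborhood in clockwise order starting from west, as (drow, dcol)
_MOORE = np.array(
    [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
)
_MOORE_INDEX = {tuple(d): i for i, d in enumerate(map(tuple, _MOORE))}


def trace_boundary(mask: np.ndarray) -> Contour:
    """Ordered boundary pixels of the single 4-connected foreground
    component of a binary mask.

    Moore-neighbor tracing with Jacob's stopping criterion; the start pixel
    is the topmost-then-leftmost foreground pixel and the output orientation
    is normalized to counterclockwise (positive signed area in (x, y) =
    (column, row) coordinates).
    """
    from scipy import ndimage

    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise MaskError(f"mask must be 2D, got {arr.ndim} dimensions")
    fg = arr.astype(bool)
    if not fg.any():
        raise NoShapeError("mask contains no foreground pixels")
    labels, n_comp = ndimage.label(fg, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n_comp > 1:
        raise AmbiguousMaskError(f"mask contains {n_comp} foreground components, expected 1")

    padded = np.zeros((fg.shape[0] + 2, fg.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = fg
    rows, cols = np.nonzero(padded)
    start = (int(rows[0]), int(cols[np.argmin(cols[rows == rows[0]])]))

    # Walk the Moore boundary tracking the (pixel, backtrack) state.  The
    # walk is deterministic over finitely many states, so it must enter a
    # cycle; that cycle is one full loop of the boundary (Jacob's stopping
    # criterion occasionally misses the closure on spurred blobs, cycle
    # detection never does).
    state = (start, (start[0], start[1] - 1))  # west of start is background
    path: list[tuple[int, int]] = []
    seen: dict = {}
    while state not in seen:
        seen[state] = len(path)
        p, b = state
        path.append(p)
        start_dir = _MOORE_INDEX[(b[0] - p[0], b[1] - p[1])]
        nxt = None
        for k in range(1, 9):
            d = _MOORE[(start_dir + k) % 8]
            q = (p[0] + int(d[0]), p[1] + int(d[1]))
            if padded[q]:
                nxt = q
                break
            b = q
        if nxt is None:  # isolated pixel: no neighbors at all
            break
        state = (nxt, b)
    boundary = path[seen[state]:] if nxt is not None else path

    if len(boundary) < 3:
        raise TooSmallError(
            f"foreground component has only {len(boundary)} boundary pixel(s), need >= 3"
        )
    # start-node convention: topmost-then-leftmost boundary pixel
    anchor = boundary.index(min(boundary))
    boundary = boundary[anchor:] + boundary[:anchor]
    pts = np.array([(c - 1, r - 1) for r, c in boundary], dtype=float)  # (x, y)
    contour = Contour(pts, closed=True)
    if contour.signed_area() < 0:
        pts = np.vstack([pts[:1], pts[1:][::-1]])
        contour = Contour(pts, closed=True)
    return contour


def resample_contour(contour: Contour, n: int) -> Contour:
    """Resample to ``n`` nodes uniformly spaced in cumulative arc length.

    The first output node coincides with the input's first node.  Closed
    contours wrap; open contours keep both endpoints.
    """
    _check_count(n, 3, "n")
    pts = contour.points
    if contour.closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0:
        raise ContourError("cannot resample a zero-length contour")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if contour.closed:
        targets = np.linspace(0.0, total, n, endpoint=False)
    else:
        targets = np.linspace(0.0, total, n)
    x = np.interp(targets, s, pts[:, 0])
    y = np.interp(targets, s, pts[:, 1])
    out = np.column_stack([x, y])
    out[0] = contour.points[0]
    return Contour(out, contour.closed)


def rasterize_contour(contour: Contour, image_size: int = 256, margin: int = 8) -> np.ndarray:
    """Filled binary mask of a closed contour, scaled to fit ``image_size``."""
    from skimage.draw import polygon

    if not contour.closed:
        raise ContourError("only closed contours can be rasterized to a mask")
    pts = contour.points
    lo = pts.min(axis=0)
    span = float((pts.max(axis=0) - lo).max())
    if span <= 0:
        raise ContourError("degenerate contour cannot be rasterized")
    scale = (image_size - 1 - 2 * margin) / span
    scaled = (pts - lo) * scale + margin
    mask = np.zeros((image_size, image_size), dtype=np.uint8)
    rr, cc = polygon(scaled[:, 1], scaled[:, 0], shape=mask.shape)
    mask[rr, cc] = 1
    return mask


# ---------------------------------------------------------------------------
# contour file I/O

def write_contour_csv(contour: Contour, path: str | Path) -> None:
    """Write a contour as CSV with columns x,y at full double precision."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y"])
        for x, y in contour.points:
            writer.writerow([format(x, ".17g"), format(y, ".17g")])


def read_contour_csv(path: str | Path, closed: bool = True) -> Contour:
    """Read a two-column (x, y) CSV, with or without a header row."""
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not cell.strip() for cell in row):
                continue
            if lineno == 1 and not _is_numeric_row(row):
                continue  # header
            if len(row) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {len(row)}")
            try:
                rows.append((float(row[0]), float(row[1])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value in {row!r}") from exc
    if len(rows) < 3:
        raise TooSmallError(f"{path}: contour needs at least 3 points, got {len(rows)}")
    return Contour(np.array(rows, dtype=float), closed=closed)


def _is_numeric_row(row: Sequence[str]) -> bool:
    try:
        [float(cell) for cell in row[:2]]
        return True
    except ValueError:
        return False
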