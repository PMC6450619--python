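"""Reference and per-iteration distribution functions.

Bond, angle and torsion histograms are normalised probability densities over
uniform grids (sum(values) * bin_width == 1); non-bonded pair distributions
are full radial distribution functions g(r) normalised by shell volume,
frame count and ideal-pair density so g -> 1 for an uncorrelated fluid.

For the inverse-Monte-Carlo cross-correlation matrix, raw per-frame bin
counts are retained: the matrix A_ag = (<S_a><S_g> - <S_a S_g>) / kB T is
the (negative) covariance of fluctuating counts over frames, estimated over
the concatenated bins of all interactions.  The same counts convention is
used on the reference and iteration sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import KB_KCAL

__all__ = [
    "Distribution",
    "DistributionSet",
    "CorrelationMatrix",
    "DistributionError",
    "bond_lengths",
    "angle_values",
    "torsion_values",
    "histogram_bonded",
    "compute_rdf",
    "estimate_correlation_matrix",
]


class DistributionError(ValueError):
    pass


@dataclass
class Distribution:
    """A histogrammed distribution function on a uniform grid.

    ``values`` is the probability density (bond/angle/torsion) or g(r)
    (rdf kind).  ``counts_mean`` is the mean raw per-frame bin count — the
    <S> used by the IMC machinery.  ``frames`` optionally stores the raw
    per-frame count matrix (n_frames, n_bins).
    """

    kind: str  # bond | angle | torsion | rdf
    name: str
    edges: np.ndarray
    values: np.ndarray
    counts_mean: np.ndarray | None = None
    n_samples: int = 0
    n_frames: int = 0
    frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        widths = np.diff(self.edges)
        if not np.allclose(widths, widths[0], rtol=1e-8):
            raise DistributionError("grid must be uniform")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise DistributionError("distribution values must be finite and >= 0")

    @property
    def key(self) -> str:
        """Unique identifier: a bond type and a pair type may share a name."""
        return f"{self.kind}:{self.name}"

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1


@dataclass
class DistributionSet:
    """Ordered collection of distributions with unique interaction names."""

    members: list[Distribution] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [d.key for d in self.members]
        if len(keys) != len(set(keys)):
            raise DistributionError("interaction (kind, name) keys must be unique")

    @property
    def n_interactions(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, key: str) -> Distribution:
        """Look up by full ``kind:name`` key, or by name when unambiguous."""
        hits = [d for d in self.members if d.key == key or d.name == key]
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            raise KeyError(f"{key!r} is ambiguous; use the kind:name form")
        raise KeyError(key)

    def keys(self) -> list[str]:
        return [d.key for d in self.members]

    def names(self) -> list[str]:
        return [d.name for d in self.members]


def _minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    return disp - np.round(disp / box) * box


def bond_lengths(pos: np.ndarray, box: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    d = _minimum_image(pos[pairs[:, 1]] - pos[pairs[:, 0]], box)
    return np.linalg.norm(d, axis=1)


def angle_values(pos: np.ndarray, box: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Angles in degrees in [0, 180] for i-j-k triples (j the apex)."""
    u = _minimum_image(pos[triples[:, 0]] - pos[triples[:, 1]], box)
    v = _minimum_image(pos[triples[:, 2]] - pos[triples[:, 1]], box)
    cosang = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def torsion_values(pos: np.ndarray, box: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Signed dihedrals in degrees in (-180, 180], standard convention.

    The sign is preserved, so chirally asymmetric torsion distributions
    (e.g. around a glycerol centre) are representable.
    """
    b1 = _minimum_image(pos[quads[:, 1]] - pos[quads[:, 0]], box)
    b2 = _minimum_image(pos[quads[:, 2]] - pos[quads[:, 1]], box)
    b3 = _minimum_image(pos[quads[:, 3]] - pos[quads[:, 2]], box)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2n)
    phi = np.degrees(np.arctan2(y, x))
    # fold -180 onto +180 so the support is (-180, 180]
    phi[phi <= -180.0] = 180.0
    return phi


_VALUE_FUNCS = {"bond": bond_lengths, "angle": angle_values, "torsion": torsion_values}


def default_grid(kind: str, r_max: float = 2.0) -> np.ndarray:
    """Default uniform grids: 0.01 nm (bond/rdf), 2 deg (angle), 4 deg (torsion)."""
    if kind in ("bond", "rdf"):
        return np.arange(0.0, r_max + 1e-9, 0.01)
    if kind == "angle":
        return np.arange(0.0, 180.0 + 1e-9, 2.0)
    if kind == "torsion":
        return np.arange(-180.0, 180.0 + 1e-9, 4.0)
    raise DistributionError(f"unknown kind {kind!r}")


def histogram_bonded(
    frames: np.ndarray,
    boxes: np.ndarray,
    term_indices: dict[str, np.ndarray],
    kind: str,
    edges: np.ndarray,
    keep_frames: bool = False,
) -> DistributionSet:
    """Histogram one bonded kind over a CG trajectory, per interaction type.

    Parameters
    ----------
    frames : (F, N, 3) positions in nm
    boxes : (F, 3) or (3,) box lengths in nm
    term_indices : type name -> (n_terms, arity) index array
    kind : 'bond' | 'angle' | 'torsion'
    edges : uniform bin edges (nm or degrees)
    keep_frames : retain per-frame raw count matrices (for IMC)
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise DistributionError("empty trajectory")
    boxes = np.broadcast_to(np.asarray(boxes, dtype=float), (frames.shape[0], 3))
    func = _VALUE_FUNCS[kind]
    edges = np.asarray(edges, dtype=float)
    width = edges[1] - edges[0]

    out = []
    for name, idx in term_indices.items():
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise DistributionError(f"no terms for type {name!r}")
        per_frame = np.empty((frames.shape[0], len(edges) - 1))
        for f in range(frames.shape[0]):
            vals = func(frames[f], boxes[f], idx)
            if kind == "bond" and (vals.min() < edges[0] or vals.max() > edges[-1]):
                raise DistributionError(
                    f"bond length outside grid range for type {name!r}: "
                    f"[{vals.min():.4f}, {vals.max():.4f}] vs "
                    f"[{edges[0]:.4f}, {edges[-1]:.4f}]"
                )
            per_frame[f], _ = np.histogram(vals, bins=edges)
        total = per_frame.sum()
        density = per_frame.sum(axis=0) / (total * width)
        out.append(
            Distribution(
                kind=kind,
                name=name,
                edges=edges,
                values=density,
                counts_mean=per_frame.mean(axis=0),
                n_samples=int(total),
                n_frames=frames.shape[0],
                frames=per_frame if keep_frames else None,
            )
        )
    return DistributionSet(out)


def _pair_indices(
    types: list[str], pair: tuple[str, str], exclusions: set[tuple[int, int]]
) -> np.ndarray:
    ta, tb = pair
    ia = [i for i, t in enumerate(types) if t == ta]
    ib = [i for i, t in enumerate(types) if t == tb]
    if not ia or not ib:
        raise DistributionError(f"unknown or absent type label in pair {pair}")
    pairs = set()
    for i in ia:
        for j in ib:
            if i == j:
                continue
            p = (min(i, j), max(i, j))
            if p not in exclusions:
                pairs.add(p)
    return np.array(sorted(pairs), dtype=int).reshape(-1, 2)


def compute_rdf(
    frames: np.ndarray,
    boxes: np.ndarray,
    bead_types: list[str],
    pair: tuple[str, str],
    exclusions: set[tuple[int, int]],
    edges: np.ndarray,
    keep_frames: bool = False,
    name: str | None = None,
) -> Distribution:
    """Type-type radial distribution function over non-excluded pairs.

    Normalised by shell volume 4 pi r^2 l, frame count, and the ideal-pair
    density of the counted pair list, so an uncorrelated fluid gives
    g(r) = 1.  Requires an orthorhombic box; the grid may not exceed half
    the smallest box length.
    """
    frames = np.asarray(frames, dtype=float)
    boxes = np.broadcast_to(np.asarray(boxes, dtype=float), (frames.shape[0], 3))
    edges = np.asarray(edges, dtype=float)
    if edges[-1] > boxes.min() / 2 + 1e-9:
        raise DistributionError(
            f"grid max {edges[-1]:.3f} nm exceeds half the minimum box length "
            f"{boxes.min() / 2:.3f} nm"
        )
    pairs = _pair_indices(bead_types, pair, exclusions)
    width = edges[1] - edges[0]
    nb = len(edges) - 1
    per_frame = np.zeros((frames.shape[0], nb))
    for f in range(frames.shape[0]):
        if pairs.size:
            d = bond_lengths(frames[f], boxes[f], pairs)
            per_frame[f], _ = np.histogram(d, bins=edges)
    volume = float(np.prod(boxes[0]))
    shell = 4.0 * np.pi * (0.5 * (edges[:-1] + edges[1:])) ** 2 * width
    n_pairs = max(len(pairs), 1)
    ideal = n_pairs * shell / volume  # expected count per frame, uncorrelated
    g = per_frame.mean(axis=0) / ideal
    from .mapping import canonical_type_name

    return Distribution(
        kind="rdf",
        name=name or canonical_type_name(pair),
        edges=edges,
        values=g,
        counts_mean=per_frame.mean(axis=0),
        n_samples=int(per_frame.sum()),
        n_frames=frames.shape[0],
        frames=per_frame if keep_frames else None,
    )


@dataclass
class CorrelationMatrix:
    """The IMC fluctuation matrix over concatenated bins of all interactions."""

    matrix: np.ndarray
    labels: list[tuple[str, int]]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise DistributionError("correlation matrix shape/label mismatch")
        scale = max(np.abs(m).max(), 1e-300)
        if np.abs(m - m.T).max() > 1e-10 * scale:
            raise DistributionError("correlation matrix must be symmetric")
        self.matrix = 0.5 * (m + m.T)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


def estimate_correlation_matrix(
    dist_set: DistributionSet, temperature: float, kB: float = KB_KCAL
) -> CorrelationMatrix:
    """A_ag = (<S_a><S_g> - <S_a S_g>) / kB T from per-frame count vectors.

    Averages run over trajectory frames; requires every member to carry its
    per-frame count matrix and at least two frames.
    """
    blocks, labels = [], []
    for d in dist_set:
        if d.frames is None:
            raise DistributionError(f"distribution {d.name!r} lacks per-frame counts")
        blocks.append(np.asarray(d.frames, dtype=float))
        labels.extend((d.name, b) for b in range(d.n_bins))
    S = np.concatenate(blocks, axis=1)
    if S.shape[0] < 2:
        raise DistributionError("correlation matrix needs at least 2 frames")
    mean = S.mean(axis=0)
    second = S.T @ S / S.shape[0]
    A = (np.outer(mean, mean) - second) / (kB * temperature)
    return CorrelationMatrix(0.5 * (A + A.T), labels)
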