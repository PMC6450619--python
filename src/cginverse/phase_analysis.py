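"""Structural observables for validating CG lipid models.

Covers the standard lamellar/hexagonal diagnostics: number-density profiles
along the bilayer normal (centred on the lipid centre of mass), bilayer
thickness as the head-group peak-to-peak distance, 2D cross-section
histograms with the modal cylinder spacing of an inverted-hexagonal
lattice, the two cone-angle order parameters that discriminate lamellar
from non-lamellar lipid shapes, and the area per lipid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mapping import CGTopology

__all__ = [
    "DensityProfile",
    "OrderParameterDistribution",
    "AnalysisError",
    "z_density_profile",
    "bilayer_thickness",
    "cross_section_histogram_2d",
    "cone_angle_order_parameters",
    "area_per_lipid",
]

_AXES = {"x": 0, "y": 1, "z": 2}


class AnalysisError(ValueError):
    pass


@dataclass
class DensityProfile:
    """Per-selection number densities (nm^-3) along one box axis.

    Bin centres are relative to the per-frame centre of mass of all
    selected beads, so the profile is centred on the structure.
    """

    axis: str
    centers: np.ndarray
    densities: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, d in self.densities.items():
            if np.any(np.asarray(d) < 0):
                raise AnalysisError(f"negative density in selection {name!r}")


def z_density_profile(
    frames: np.ndarray,
    box: np.ndarray,
    selections: dict[str, np.ndarray],
    axis: str = "z",
    bin_width: float = 0.1,
) -> DensityProfile:
    """Number-density profile of bead selections across the structure.

    ``selections`` maps a label to a bead index array.  Each frame is
    centred on the centre of mass (unweighted centroid) of the union of
    all selections before histogramming, so bilayer drift cancels.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    ax = _AXES[axis]
    box = np.asarray(box, dtype=float)
    L = float(box[ax])
    edges = np.arange(-L / 2, L / 2 + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    all_idx = np.unique(np.concatenate([np.asarray(v, int) for v in selections.values()]))
    if all_idx.size == 0:
        raise AnalysisError("empty selection")
    lateral = np.prod([box[d] for d in range(3) if d != ax])
    vol_bin = lateral * bin_width
    out = {name: np.zeros(len(centers)) for name in selections}
    nf = frames.shape[0]
    for f in range(nf):
        z = frames[f, :, ax]
        zc = z[all_idx]
        # circular mean handles structures straddling the periodic boundary
        ang = zc / L * 2 * np.pi
        center = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi) * L
        for name, idx in selections.items():
            idx = np.asarray(idx, int)
            if idx.size == 0:
                raise AnalysisError(f"empty selection {name!r}")
            rel = z[idx] - center
            rel -= np.round(rel / L) * L
            h, _ = np.histogram(rel, bins=edges)
            out[name] += h
    for name in out:
        out[name] /= nf * vol_bin
    return DensityProfile(axis, centers, out)


def _refine_peak(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Parabolic refinement of a local maximum at index i."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom >= 0:
        return float(x[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(x[i] + shift * (x[1] - x[0]))


def bilayer_thickness(profile: DensityProfile, selection: str = "head") -> float:
    """Peak-to-peak head-group distance (nm) with parabolic refinement.

    Raises if the head-group profile does not resolve two separated maxima
    (no bilayer present).
    """
    y = profile.densities[selection]
    x = profile.centers
    interior = (y > np.roll(y, 1)) & (y >= np.roll(y, -1))
    interior[0] = interior[-1] = False
    peaks = np.nonzero(interior & (y > 0.2 * y.max()))[0]
    neg = [p for p in peaks if x[p] < 0]
    pos = [p for p in peaks if x[p] >= 0]
    if not neg or not pos:
        raise AnalysisError("no bilayer: head-group profile lacks two resolvable peaks")
    lo = max(neg, key=lambda p: y[p])
    hi = max(pos, key=lambda p: y[p])
    return _refine_peak(x, y, hi) - _refine_peak(x, y, lo)


def cross_section_histogram_2d(
    frames: np.ndarray,
    box: np.ndarray,
    projection_axis: str = "x",
    bin_width: float = 0.2,
    threshold_quantile: float = 0.80,
    smooth_sigma: float = 0.8,
    min_separation: float = 2.0,
) -> tuple[np.ndarray, float | None]:
    """2D bead-count histogram perpendicular to the cylinder axis.

    Returns the raw histogram and the modal nearest-neighbour distance
    (nm) between detected density maxima — the hexagonal cylinder spacing.
    Because an implicit-solvent cylinder projects as a hollow ring, the
    histogram is Gaussian-blurred (``smooth_sigma``, nm) before peak
    detection so each cylinder collapses to a single blob; maxima are
    local peaks above the given quantile of nonzero smoothed bins, at
    least ``min_separation`` nm apart.  With fewer than two maxima the
    spacing is undefined and None is returned.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    ax = _AXES[projection_axis]
    d1, d2 = [d for d in range(3) if d != ax]
    box = np.asarray(box, dtype=float)
    e1 = np.arange(0, box[d1] + bin_width / 2, bin_width)
    e2 = np.arange(0, box[d2] + bin_width / 2, bin_width)
    H = np.zeros((len(e1) - 1, len(e2) - 1))
    for f in range(frames.shape[0]):
        h, _, _ = np.histogram2d(frames[f, :, d1] % box[d1],
                                 frames[f, :, d2] % box[d2], bins=(e1, e2))
        H += h
    Hs = ndimage.gaussian_filter(H, sigma=smooth_sigma / bin_width, mode="wrap")
    nz = Hs[Hs > 0]
    if nz.size == 0:
        return H, None
    thr = np.quantile(nz, threshold_quantile)
    win = max(3, int(round(min_separation / bin_width)) | 1)
    local_max = Hs == ndimage.maximum_filter(Hs, size=win, mode="wrap")
    peaks = np.argwhere(local_max & (Hs >= thr) & (Hs > 0))
    if len(peaks) < 2:
        return H, None

    def refine(idx, axis_len, axis):
        # periodic 1D parabolic refinement around the smoothed maximum
        sl = [peaks[idx][0], peaks[idx][1]]
        i = sl[axis]
        lo = Hs[(sl[0] - (axis == 0)) % Hs.shape[0], (sl[1] - (axis == 1)) % Hs.shape[1]]
        hi = Hs[(sl[0] + (axis == 0)) % Hs.shape[0], (sl[1] + (axis == 1)) % Hs.shape[1]]
        mid = Hs[sl[0], sl[1]]
        denom = lo - 2 * mid + hi
        shift = 0.5 * (lo - hi) / denom if denom < 0 else 0.0
        return (i + 0.5 + shift) * bin_width

    pts = np.array([[refine(k, Hs.shape[0], 0), refine(k, Hs.shape[1], 1)]
                    for k in range(len(peaks))])
    span = np.array([box[d1], box[d2]])
    diff = pts[:, None, :] - pts[None, :, :]
    diff -= np.round(diff / span) * span
    dist = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(dist, np.inf)
    nn = dist.min(axis=1)
    # modal NN distance, at half-bin resolution after peak refinement
    res = 0.5 * bin_width
    vals, counts = np.unique(np.round(nn / res).astype(int), return_counts=True)
    return H, float(vals[np.argmax(counts)] * res)


@dataclass
class OrderParameterDistribution:
    """Histograms of the two cone angles of each lipid (degrees).

    ``mid_tail``: angle between the vectors from the P bead to the two
    mid-tail (CdB) beads.  ``tail_end``: same with the two terminal (C4)
    beads.  Wide angles indicate the splayed, cone-like shape of
    inverted-hexagonal packing; narrow angles the cylindrical shape of a
    bilayer lipid.
    """

    edges: np.ndarray
    mid_tail: np.ndarray
    tail_end: np.ndarray
    mean_mid_tail: float = np.nan
    mean_tail_end: float = np.nan


def _vector_angle(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    c = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def cone_angle_order_parameters(
    frames: np.ndarray,
    box: np.ndarray,
    topology: CGTopology,
    bin_width: float = 2.0,
) -> OrderParameterDistribution:
    """Per-lipid cone-angle order parameters over a trajectory.

    Requires each molecule to expose one P bead, two CdB beads and two
    terminal C4 beads.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    box = np.asarray(box, dtype=float)
    types = np.array(topology.bead_types)
    mols = np.unique(topology.molecule_ids)
    p_idx, cdb_idx, c4_idx = [], [], []
    for m in mols:
        sel = np.nonzero(topology.molecule_ids == m)[0]
        p = sel[types[sel] == "P"]
        cdb = sel[types[sel] == "CdB"]
        c4 = sel[types[sel] == "C4"]
        if len(p) != 1 or len(cdb) != 2 or len(c4) != 2:
            raise AnalysisError(
                f"molecule {m}: need 1 P, 2 CdB, 2 C4 beads, found "
                f"{len(p)}/{len(cdb)}/{len(c4)}"
            )
        p_idx.append(p[0])
        cdb_idx.append(cdb)
        c4_idx.append(c4)
    p_idx = np.array(p_idx)
    cdb_idx = np.array(cdb_idx)
    c4_idx = np.array(c4_idx)

    edges = np.arange(0.0, 180.0 + bin_width / 2, bin_width)
    h_mid = np.zeros(len(edges) - 1)
    h_end = np.zeros(len(edges) - 1)
    all_mid, all_end = [], []
    for f in range(frames.shape[0]):
        pos = frames[f]

        def vec(to_idx):
            d = pos[to_idx] - pos[p_idx]
            return d - np.round(d / box) * box

        a_mid = _vector_angle(vec(cdb_idx[:, 0]), vec(cdb_idx[:, 1]))
        a_end = _vector_angle(vec(c4_idx[:, 0]), vec(c4_idx[:, 1]))
        h_mid += np.histogram(a_mid, bins=edges)[0]
        h_end += np.histogram(a_end, bins=edges)[0]
        all_mid.append(a_mid)
        all_end.append(a_end)
    norm_mid = h_mid.sum() * bin_width
    norm_end = h_end.sum() * bin_width
    return OrderParameterDistribution(
        edges=edges,
        mid_tail=h_mid / norm_mid if norm_mid else h_mid,
        tail_end=h_end / norm_end if norm_end else h_end,
        mean_mid_tail=float(np.mean(np.concatenate(all_mid))),
        mean_tail_end=float(np.mean(np.concatenate(all_end))),
    )


def area_per_lipid(box: np.ndarray, n_lipids: int, normal_axis: str = "z") -> float:
    """A_L = 2 * (lateral box area) / n_lipids for a two-leaflet bilayer."""
    if n_lipids <= 0:
        raise AnalysisError("n_lipids must be positive")
    box = np.asarray(box, dtype=float)
    ax = _AXES[normal_axis]
    lateral = np.prod([box[d] for d in range(3) if d != ax])
    return float(2.0 * lateral / n_lipids)
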