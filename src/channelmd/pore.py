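"""HOLE-style pore-radius profiling and fourfold-symmetry metrics.

At each position z along the conduction axis the pore radius is the
radius of the largest sphere, centered in the plane perpendicular to the
axis at z, that overlaps no atom's van der Waals sphere:

    R(z) = max_c  min_i ( |c - x_i| - r_i ),   c in the plane at z.

The maximization is solved by seeded multi-start Nelder-Mead in the
plane; a brute-force in-plane grid oracle is provided for validation.
Radii are classified into the bands used for K+ conduction analysis:
below the K+ ionic radius (1.33 A), between ionic and hydrodynamic
radius (3.6 A), and bulk-like above it.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .errors import FitError, OutOfRangeError, SelectionError
from .io import Selection, Structure, Trajectory, resolve_selection

BAND_SUB_IONIC = "sub_ionic"
BAND_INTERMEDIATE = "intermediate"
BAND_BULK = "bulk"

#: K+ ionic radius (A); pore slices narrower than this require full
#: ion desolvation.
K_IONIC_RADIUS = 1.33
#: K+ hydrodynamic radius (A); slices wider than this are bulk-like.
K_HYDRODYNAMIC_RADIUS = 3.6


@dataclass(frozen=True)
class PoreAxis:
    """Channel axis: origin plus unit direction (intra- to extracellular)."""

    origin: tuple[float, float, float]
    direction: tuple[float, float, float]

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("axis direction must be a unit vector")

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(e1, e2, d): an orthonormal in-plane basis plus the direction."""
        d = np.asarray(self.direction, dtype=float)
        seed = np.array([1.0, 0.0, 0.0])
        if abs(d @ seed) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        e1 = seed - (seed @ d) * d
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        return e1, e2, d


@dataclass
class SphereResult:
    radius: float
    center: np.ndarray
    bulk: bool = False  # radius ran into the search-disc boundary


@dataclass
class PoreProfile:
    z_grid: np.ndarray  # (n_z,)
    radius: np.ndarray  # (n_sampled_frames, n_z)
    mean_radius: np.ndarray  # (n_z,)
    band: list[str]  # per z, classified on the mean profile
    frame_indices: np.ndarray

    def to_frame_table(self) -> pd.DataFrame:
        rows = []
        for fi, frame in zip(self.frame_indices, self.radius):
            for z, r in zip(self.z_grid, frame):
                rows.append(
                    dict(frame=int(fi), z=z, radius=r, band=classify_radius(r))
                )
        return pd.DataFrame(rows)

    def to_mean_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(z=self.z_grid, radius=self.mean_radius, band=self.band)
        )


@dataclass
class OpposingDistances:
    """Per-frame distances between diagonally opposed subunits."""

    pair_labels: tuple[tuple[str, str], tuple[str, str]]
    pair_a: np.ndarray  # e.g. A-C, per frame
    pair_b: np.ndarray  # e.g. B-D, per frame
    symmetry_index: np.ndarray  # |d1 - d2| / mean(d1, d2), per frame


def fit_pore_axis(
    structure: Structure,
    sel: Selection,
    orient_reference: tuple[Selection, Selection] | None = None,
) -> PoreAxis:
    """Fit the channel axis as the principal axis of a selection.

    Origin is the selection centroid; direction is the dominant
    eigenvector of the coordinate covariance, oriented either toward the
    second selection of ``orient_reference`` (intracellular, extracellular)
    or, by default, with a positive z component.
    """
    idx = resolve_selection(structure, sel)
    if len(idx) < 4:
        raise FitError(f"axis fit needs >= 4 atoms, selection gave {len(idx)}")
    chains = {structure.atoms[i].chain_id for i in idx}
    if len(chains) < 2:
        raise FitError("axis fit selection must span >= 2 subunits")
    x = structure.coords()[idx]
    centroid = x.mean(axis=0)
    cov = np.cov((x - centroid).T)
    w, v = np.linalg.eigh(cov)
    if (w[-1] - w[-2]) <= 1e-9 * max(w[-1], 1.0):
        raise FitError("degenerate selection: principal axis is not unique")
    d = v[:, -1]
    if orient_reference is not None:
        lo, hi = orient_reference
        p_lo = structure.coords()[resolve_selection(structure, lo)].mean(axis=0)
        p_hi = structure.coords()[resolve_selection(structure, hi)].mean(axis=0)
        if (p_hi - p_lo) @ d < 0:
            d = -d
    elif d[2] < 0:
        d = -d
    d = d / np.linalg.norm(d)
    return PoreAxis(tuple(centroid), tuple(d))


def _clearance(centers: np.ndarray, coords: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """min_i(|c - x_i| - r_i) for each center (vectorized)."""
    d = cdist(np.atleast_2d(centers), coords)
    return (d - radii[None, :]).min(axis=1)


def _check_plane(coords: np.ndarray, radii: np.ndarray, axis: PoreAxis, z: float):
    d = np.asarray(axis.direction)
    proj = (coords - np.asarray(axis.origin)) @ d
    margin = radii.max()
    if z < proj.min() - margin or z > proj.max() + margin:
        raise OutOfRangeError(
            f"plane z={z} lies outside the structure's axial extent "
            f"[{proj.min():.2f}, {proj.max():.2f}] (+/- {margin:.2f})"
        )


def max_sphere_radius(
    structure: Structure,
    axis: PoreAxis,
    z: float,
    search_disc: float = 15.0,
    n_starts: int = 32,
    seed: int = 0,
) -> SphereResult:
    """Largest sphere centered in the plane at z clearing all vdW spheres.

    Solved by ``n_starts`` seeded random starts in a disc of radius
    ``search_disc`` around the axis, each refined by Nelder-Mead; centers
    are constrained exactly to the plane (2-D search).  A radius running
    into the disc boundary is flagged as bulk.
    """
    coords = structure.coords()
    radii = structure.vdw_radii()
    _check_plane(coords, radii, axis, z)
    e1, e2, d = axis.basis()
    p0 = np.asarray(axis.origin) + z * d

    def neg_clearance(uv):
        c = p0 + uv[0] * e1 + uv[1] * e2
        return -float(_clearance(c[None, :], coords, radii)[0])

    rng = np.random.default_rng(seed)
    r_st = search_disc * np.sqrt(rng.uniform(0, 1, n_starts - 1))
    th_st = rng.uniform(0, 2 * np.pi, n_starts - 1)
    starts = np.vstack(
        [[0.0, 0.0], np.column_stack([r_st * np.cos(th_st), r_st * np.sin(th_st)])]
    )
    best_val, best_uv = -np.inf, starts[0]
    for uv0 in starts:
        res = minimize(
            neg_clearance,
            uv0,
            method="Nelder-Mead",
            options=dict(xatol=1e-5, fatol=1e-7, maxiter=400),
        )
        in_disc = np.hypot(*res.x) <= search_disc
        if in_disc and -res.fun > best_val:
            best_val, best_uv = -res.fun, res.x
    center = p0 + best_uv[0] * e1 + best_uv[1] * e2
    return SphereResult(
        radius=max(best_val, 0.0), center=center, bulk=best_val > search_disc
    )


def grid_radius(
    structure: Structure,
    axis: PoreAxis,
    z: float,
    search_disc: float = 6.0,
    grid_step: float = 0.01,
    chunk: int = 200_000,
) -> float:
    """Brute-force in-plane grid oracle for :func:`max_sphere_radius`.

    Evaluates the clearance on a regular ``grid_step`` grid over the
    search disc and returns the maximum; deliberately independent of the
    optimizer path so it can serve as its validation oracle.
    """
    coords = structure.coords()
    radii = structure.vdw_radii()
    _check_plane(coords, radii, axis, z)
    e1, e2, d = axis.basis()
    p0 = np.asarray(axis.origin) + z * d
    ax = np.arange(-search_disc, search_disc + grid_step / 2, grid_step)
    uu, vv = np.meshgrid(ax, ax)
    mask = uu**2 + vv**2 <= search_disc**2
    uv = np.column_stack([uu[mask], vv[mask]])
    centers = p0 + uv[:, :1] * e1 + uv[:, 1:2] * e2
    best = -np.inf
    for i in range(0, centers.shape[0], chunk):
        val = _clearance(centers[i : i + chunk], coords, radii).max()
        best = max(best, val)
    return float(max(best, 0.0))


def pore_profile(
    traj: Trajectory,
    axis: PoreAxis,
    z_min: float,
    z_max: float,
    z_step: float = 0.125,
    frame_stride: int = 1,
    search_disc: float = 15.0,
    n_starts: int = 32,
    seed: int = 0,
    ionic: float = K_IONIC_RADIUS,
    hydrodynamic: float = K_HYDRODYNAMIC_RADIUS,
) -> PoreProfile:
    """Per-frame radius profile on a fixed-step z grid plus its mean.

    Frames are sampled every ``frame_stride`` frames starting at frame 0;
    the default grid step of 0.125 A matches standard HOLE-style
    profiling practice.  The band classification is applied to the
    across-frame mean profile.
    """
    if z_min >= z_max:
        raise ValueError("z_min must be < z_max")
    if frame_stride < 1:
        raise ValueError("frame_stride must be >= 1")
    z_grid = np.arange(z_min, z_max + z_step / 2, z_step)
    frame_indices = np.arange(0, traj.n_frames, frame_stride)
    out = np.empty((frame_indices.size, z_grid.size))
    for k, fi in enumerate(frame_indices):
        frame = traj.frame_structure(fi)
        for j, z in enumerate(z_grid):
            out[k, j] = max_sphere_radius(
                frame, axis, z, search_disc=search_disc, n_starts=n_starts, seed=seed
            ).radius
    mean = out.mean(axis=0)
    band = [classify_radius(r, ionic, hydrodynamic) for r in mean]
    return PoreProfile(z_grid, out, mean, band, frame_indices)


def classify_radius(
    r: float,
    ionic: float = K_IONIC_RADIUS,
    hydrodynamic: float = K_HYDRODYNAMIC_RADIUS,
) -> str:
    """Band classification of a pore radius; boundaries are inclusive to
    the intermediate band (sub_ionic strictly below the ionic radius,
    bulk strictly above the hydrodynamic radius)."""
    if r < 0:
        raise ValueError("radius must be non-negative")
    if r < ionic:
        return BAND_SUB_IONIC
    if r <= hydrodynamic:
        return BAND_INTERMEDIATE
    return BAND_BULK


def opposing_distances(
    traj: Trajectory,
    residue_id: int,
    atom_name: str,
    subunit_pairs: Sequence[tuple[str, str]] = (("A", "C"), ("B", "D")),
) -> OpposingDistances:
    """Per-frame distances between one named atom in diagonally opposed
    subunits, plus the dimensionless asymmetry of the two diagonals."""

    def atom_index(subunit: str) -> int:
        chains = {
            c for c, s in traj.roster.subunit_map.items() if s == subunit
        } or {subunit}
        for i, a in enumerate(traj.roster.atoms):
            if (
                a.chain_id in chains
                and a.residue_id == residue_id
                and a.atom_name == atom_name
            ):
                return i
        raise SelectionError(
            f"atom {atom_name} of residue {residue_id} missing in subunit "
            f"{subunit}"
        )

    (s1, s2), (s3, s4) = subunit_pairs
    i1, i2, i3, i4 = (atom_index(s) for s in (s1, s2, s3, s4))
    d_a = np.linalg.norm(traj.frames[:, i1] - traj.frames[:, i2], axis=1)
    d_b = np.linalg.norm(traj.frames[:, i3] - traj.frames[:, i4], axis=1)
    sym = np.abs(d_a - d_b) / ((d_a + d_b) / 2.0)
    return OpposingDistances(
        pair_labels=((s1, s2), (s3, s4)),
        pair_a=d_a,
        pair_b=d_b,
        symmetry_index=sym,
    )


SF_CONDUCTIVE = "conductive"
SF_INACTIVE = "inactive"
SF_INTERMEDIATE = "intermediate"
SF_UNDEFINED = "undefined"


def classify_sf_state(mean_opposing_ca_distance: float) -> str:
    """Selectivity-filter state from the mean opposing-Calpha distance.

    ~8 A between opposing G626 Calpha atoms characterizes the symmetric
    conductive filter, 5-7 A the asymmetric stable inactive states; the
    7-7.5 A gap is reported as intermediate rather than forced into
    either state, and distances below 5 A are flagged undefined.
    """
    d = mean_opposing_ca_distance
    if d <= 0:
        raise ValueError("distance must be positive")
    if d >= 7.5:
        return SF_CONDUCTIVE
    if 5.0 <= d <= 7.0:
        return SF_INACTIVE
    if 7.0 < d < 7.5:
        return SF_INTERMEDIATE
    return SF_UNDEFINED
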