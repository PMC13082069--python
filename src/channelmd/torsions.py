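"""Backbone dihedrals, Ramachandran summaries, carbonyl orientation and
the S4-S5 interhelical torsion.

Torsions follow the IUPAC sign convention: looking along the central
bond p2 -> p3, a clockwise rotation of p4 relative to p1 is positive.
Angles are reported in degrees on (-180, 180].
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import circmean, circstd

from .errors import EmptyInputError, FitError, GeometryError, SelectionError
from .io import Selection, Structure, Trajectory, resolve_selection
from .pore import PoreAxis


@dataclass
class TorsionTrace:
    """Per-frame torsion series for one residue (or a custom angle)."""

    residue_id: int
    chain_id: str
    angle_name: str  # phi, psi, omega, or a custom label
    values: np.ndarray  # degrees in (-180, 180]
    frame_dt: float = 1.0


def _wrap(deg):
    """Map angles to (-180, 180]."""
    out = np.asarray(deg, dtype=float)
    out = -((-out + 180.0) % 360.0 - 180.0)
    return out


def dihedral_frames(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> np.ndarray:
    """Signed dihedral (degrees) for stacked points of shape (..., 3)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2, axis=-1, keepdims=True)
    if np.any(nb2 < 1e-10):
        raise GeometryError("coincident central points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-10) or np.any(
        np.linalg.norm(n2, axis=-1) < 1e-10
    ):
        raise GeometryError("collinear points in dihedral")
    m1 = np.cross(n1, b2 / nb2)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    # sign such that rotating p4 by +t (right-hand rule about p2->p3)
    # increases the dihedral by +t
    return _wrap(-np.degrees(np.arctan2(y, x)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle of four points, degrees in (-180, 180]."""
    return float(dihedral_frames(*(np.asarray(p) for p in (p1, p2, p3, p4))))


# ---------------------------------------------------------------------------
# phi/psi traces
# ---------------------------------------------------------------------------

def _atom_index_map(structure: Structure) -> dict[tuple[str, int, str], int]:
    return {
        (a.chain_id, a.residue_id, a.atom_name): i
        for i, a in enumerate(structure.atoms)
    }


def phi_psi_traces(
    traj: Trajectory,
    residues: Selection,
    frame_stride: int = 1,
) -> list[TorsionTrace]:
    """Phi/psi series for every selected residue.

    phi = C(i-1)-N-CA-C and psi = N-CA-C-N(i+1), with neighbors defined
    by consecutive author residue numbering within a chain.  At chain
    termini the undefined angle is simply absent from the result; a
    missing backbone atom on a residue that has a sequence neighbor is a
    structural error naming the residue.
    """
    amap = _atom_index_map(traj.roster)
    residues_present = sorted(
        {
            (a.chain_id, a.residue_id)
            for a in traj.roster.atoms
            if residues.matches(a)
        }
    )
    resid_set = {
        (a.chain_id, a.residue_id) for a in traj.roster.atoms
    }
    frames = traj.frames[::frame_stride]
    dt = traj.frame_dt * frame_stride
    traces: list[TorsionTrace] = []
    for chain, rid in residues_present:
        def need(c, r, name):
            key = (c, r, name)
            if key not in amap:
                raise SelectionError(
                    f"residue {r} chain {c} lacks backbone atom {name}"
                )
            return amap[key]

        i_n = need(chain, rid, "N")
        i_ca = need(chain, rid, "CA")
        i_c = need(chain, rid, "C")
        if (chain, rid - 1) in resid_set:
            i_cprev = need(chain, rid - 1, "C")
            phi = dihedral_frames(
                frames[:, i_cprev], frames[:, i_n], frames[:, i_ca], frames[:, i_c]
            )
            traces.append(TorsionTrace(rid, chain, "phi", phi, dt))
        if (chain, rid + 1) in resid_set:
            i_nnext = need(chain, rid + 1, "N")
            psi = dihedral_frames(
                frames[:, i_n], frames[:, i_ca], frames[:, i_c], frames[:, i_nnext]
            )
            traces.append(TorsionTrace(rid, chain, "psi", psi, dt))
    return traces


def torsion_table(traces: list[TorsionTrace]) -> pd.DataFrame:
    rows = []
    for t in traces:
        for f, v in enumerate(t.values):
            rows.append(
                dict(
                    frame=f,
                    chain=t.chain_id,
                    residue=t.residue_id,
                    angle_name=t.angle_name,
                    value=v,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ramachandran summaries
# ---------------------------------------------------------------------------

@dataclass
class RamachandranSummary:
    """2-D phi/psi occupancy plus circular spread statistics."""

    residue_id: int
    chain_id: str
    bin_edges: np.ndarray  # shared for both axes, covers (-180, 180]
    occupancy: np.ndarray  # (n_bins, n_bins), sums to 1, phi rows psi cols
    phi_mean: float
    psi_mean: float
    phi_sd: float  # circular sd, degrees
    psi_sd: float
    phi_resultant: float  # mean resultant length, in [0, 1]
    psi_resultant: float
    #: circular mean is unstable when the resultant length is small
    phi_mean_reliable: bool = True
    psi_mean_reliable: bool = True


def _circ_stats(deg: np.ndarray) -> tuple[float, float, float]:
    rad = np.radians(deg)
    mean = float(np.degrees(circmean(rad, high=np.pi, low=-np.pi)))
    sd = float(np.degrees(circstd(rad, high=np.pi, low=-np.pi)))
    resultant = float(np.abs(np.exp(1j * rad).mean()))
    return _wrap(mean).item(), sd, resultant


def ramachandran_summary(
    phi: TorsionTrace,
    psi: TorsionTrace,
    bin_width: float = 10.0,
    resultant_floor: float = 0.1,
) -> RamachandranSummary:
    """Normalized 2-D histogram over (-180, 180]^2 with circular stats.

    The circular mean is flagged unreliable when the mean resultant
    length drops below ``resultant_floor`` (near-uniform angles).
    """
    if len(phi.values) == 0 or len(psi.values) == 0:
        raise EmptyInputError("empty torsion traces")
    if len(phi.values) != len(psi.values):
        raise ValueError("phi and psi traces must have equal length")
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    pv, sv = _wrap(phi.values), _wrap(psi.values)
    # values exactly at -180 belong to the (170, 180] wrap-around bin
    h, _, _ = np.histogram2d(pv, sv, bins=[edges, edges])
    occupancy = h / h.sum()
    pm, psd, pr = _circ_stats(pv)
    sm, ssd, sr = _circ_stats(sv)
    return RamachandranSummary(
        residue_id=phi.residue_id,
        chain_id=phi.chain_id,
        bin_edges=edges,
        occupancy=occupancy,
        phi_mean=pm,
        psi_mean=sm,
        phi_sd=psd,
        psi_sd=ssd,
        phi_resultant=pr,
        psi_resultant=sr,
        phi_mean_reliable=pr >= resultant_floor,
        psi_mean_reliable=sr >= resultant_floor,
    )


def ramachandran_shift(
    variant: RamachandranSummary, reference: RamachandranSummary
) -> dict[str, float]:
    """Circular mean difference (variant - reference) per angle, degrees."""
    return {
        "delta_phi": float(_wrap(variant.phi_mean - reference.phi_mean)),
        "delta_psi": float(_wrap(variant.psi_mean - reference.psi_mean)),
    }


# ---------------------------------------------------------------------------
# Carbonyl orientation
# ---------------------------------------------------------------------------

@dataclass
class CarbonylOrientationTrace:
    residue_id: int
    chain_id: str
    state: list[str]  # 'in' or 'out' per frame
    radial_projection: np.ndarray  # in [-1, 1] per frame


def carbonyl_orientation(
    traj: Trajectory,
    residue_id: int,
    chain_id: str,
    axis: PoreAxis,
) -> CarbonylOrientationTrace:
    """Classify the backbone C=O of one residue as pointing toward the
    pore axis ('in', radial projection < 0) or away ('out', >= 0).

    The radial projection is the cosine between the C->O bond and the
    outward radial direction from the axis to the carbonyl carbon;
    a projection of exactly zero is 'out' by convention.
    """
    amap = _atom_index_map(traj.roster)
    try:
        i_c = amap[(chain_id, residue_id, "C")]
        i_o = amap[(chain_id, residue_id, "O")]
    except KeyError as exc:
        raise SelectionError(
            f"residue {residue_id} chain {chain_id} lacks backbone C/O"
        ) from exc
    d = np.asarray(axis.direction)
    origin = np.asarray(axis.origin)
    c = traj.frames[:, i_c]
    o = traj.frames[:, i_o]
    co = o - c
    nco = np.linalg.norm(co, axis=1)
    if np.any(nco < 1e-10):
        raise GeometryError("coincident C and O atoms")
    radial = (c - origin) - np.outer((c - origin) @ d, d)
    nr = np.linalg.norm(radial, axis=1)
    if np.any(nr < 1e-10):
        raise GeometryError("carbonyl carbon lies on the pore axis")
    proj = np.sum((co / nco[:, None]) * (radial / nr[:, None]), axis=1)
    state = ["in" if p < 0 else "out" for p in proj]
    return CarbonylOrientationTrace(residue_id, chain_id, state, proj)


# ---------------------------------------------------------------------------
# Helix axes and the S4-S5 interhelical torsion
# ---------------------------------------------------------------------------

def helix_axis(
    structure: Structure,
    residue_range: tuple[int, int],
    chain: str,
) -> PoreAxis:
    """Principal axis of a helix's CA atoms, oriented N -> C terminus."""
    lo, hi = residue_range
    sel = Selection.of(chains=chain, residues=range(lo, hi + 1), atoms="CA")
    idx = resolve_selection(structure, sel)
    if len(idx) < 4:
        raise FitError(f"helix axis fit needs >= 4 CA atoms, got {len(idx)}")
    x = structure.coords()[idx]
    centroid = x.mean(axis=0)
    cov = np.cov((x - centroid).T)
    w, v = np.linalg.eigh(cov)
    d = v[:, -1]
    if (x[-1] - x[0]) @ d < 0:
        d = -d
    return PoreAxis(tuple(centroid), tuple(d / np.linalg.norm(d)))


def _half_centroids(
    traj: Trajectory, chain: str, residue_range: tuple[int, int], proximal_high: bool
) -> tuple[np.ndarray, np.ndarray]:
    """(distal, proximal) per-frame CA centroids of the two helix halves.

    The half adjacent to the linker (``proximal``) is the high-numbered
    half when the helix precedes the linker in sequence; with an odd
    residue count the middle residue joins the high-numbered half.
    """
    lo, hi = residue_range
    rids = [
        r
        for r in range(lo, hi + 1)
        if any(
            a.chain_id == chain and a.residue_id == r and a.atom_name == "CA"
            for a in traj.roster.atoms
        )
    ]
    if len(rids) < 2:
        raise GeometryError(f"helix range {residue_range} has < 2 CA atoms")
    amap = _atom_index_map(traj.roster)
    split = len(rids) // 2
    low_idx = [amap[(chain, r, "CA")] for r in rids[:split]]
    high_idx = [amap[(chain, r, "CA")] for r in rids[split:]]
    low_c = traj.frames[:, low_idx].mean(axis=1)
    high_c = traj.frames[:, high_idx].mean(axis=1)
    return (low_c, high_c) if proximal_high else (high_c, low_c)


def interhelix_torsion(
    traj: Trajectory,
    s4_range: tuple[int, int],
    linker_range: tuple[int, int],
    s5_range: tuple[int, int],
    chain: str,
    frame_stride: int = 1,
) -> TorsionTrace:
    """Torsion of the S5 helix about the S4-S5 linker axis, per frame.

    Defined as the dihedral of four centroids: S4 distal half, S4
    proximal half, S5 proximal half, S5 distal half (proximal = adjacent
    to the linker); the middle two centroids span the linker axis.
    """
    linker_mid = (linker_range[0] + linker_range[1]) / 2.0
    s4_distal, s4_prox = _half_centroids(
        traj, chain, s4_range, proximal_high=(sum(s4_range) / 2.0) < linker_mid
    )
    s5_distal, s5_prox = _half_centroids(
        traj, chain, s5_range, proximal_high=(sum(s5_range) / 2.0) < linker_mid
    )
    sl = slice(None, None, frame_stride)
    values = dihedral_frames(s4_distal[sl], s4_prox[sl], s5_prox[sl], s5_distal[sl])
    return TorsionTrace(
        residue_id=-1,
        chain_id=chain,
        angle_name="s4_s5_torsion",
        values=np.atleast_1d(values),
        frame_dt=traj.frame_dt * frame_stride,
    )
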