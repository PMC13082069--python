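"""Kabsch superposition and Calpha RMSD/RMSF with region summaries."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, FitError
from .io import Selection, Structure, Trajectory, resolve_selection

#: Default region map (1-based author numbering, inclusive bounds) for a
#: Kv11.1-like subunit: cytoplasmic PAS domain, transmembrane region,
#: C-linker and cyclic-nucleotide-binding domain.
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "PAS": (1, 131),
    "TM": (398, 687),
    "C_LINKER": (688, 741),
    "CNBD": (742, 863),
}


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper orthogonal
    translation: np.ndarray  # applied after rotation
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class MobilityProfile:
    rmsd: np.ndarray  # per frame, vs the mean structure, A
    rmsf: pd.DataFrame  # chain, residue, value
    region_means: dict[str, float] = field(default_factory=dict)


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition (SVD, reflections
    excluded by determinant correction)."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[0] < 3:
        raise FitError("superposition needs matching point sets of >= 3 points")
    if weights is None:
        w = np.ones(mobile.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    a = mobile - mc
    b = reference - rc
    h = (w[:, None] * a).T @ b
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise FitError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = a @ rot.T
    rmsd = float(np.sqrt((w * ((moved - b) ** 2).sum(axis=1)).sum()))
    translation = rc - mc @ rot.T
    return SuperpositionResult(rotation=rot, translation=translation, rmsd=rmsd)


def rmsd_trace(
    traj: Trajectory,
    reference: Structure,
    sel: Selection | None = None,
) -> np.ndarray:
    """Per-frame RMSD after superposing each frame onto the reference
    over the selection (default: CA atoms)."""
    sel = sel or Selection.of(atoms="CA")
    idx = resolve_selection(traj.roster, sel)
    if len(idx) < 3:
        raise FitError("selection resolves to fewer than 3 atoms")
    ref = reference.coords()[idx]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        out[i] = kabsch_superpose(traj.frames[i, idx], ref).rmsd
    return out


def rmsf_profile(
    traj: Trajectory,
    sel: Selection | None = None,
    regions: dict[str, tuple[int, int]] | None = None,
) -> MobilityProfile:
    """Per-residue RMSF about the iterated mean structure.

    Two-pass estimator: frames are first superposed onto frame 0, the
    mean structure is computed, and all frames are re-superposed onto
    that mean; RMSF_i = sqrt(<|x_i - <x_i>|^2>).  Region means are taken
    over inclusive residue ranges (default: the four Kv11.1-like
    domains of :data:`DEFAULT_REGIONS`, restricted to residues present).
    """
    if traj.n_frames < 2:
        raise DegenerateDataError("RMSF needs at least 2 frames")
    sel = sel or Selection.of(atoms="CA")
    idx = resolve_selection(traj.roster, sel)
    if len(idx) < 3:
        raise FitError("selection resolves to fewer than 3 atoms")
    x = traj.frames[:, idx, :]

    def superpose_all(target: np.ndarray, pts: np.ndarray) -> np.ndarray:
        out = np.empty_like(pts)
        for i in range(pts.shape[0]):
            out[i] = kabsch_superpose(pts[i], target).apply(pts[i])
        return out

    aligned = superpose_all(x[0], x)
    # iterate superposition onto the running mean until the mean is a
    # fixed point, so the result does not depend on the seeding frame
    for _ in range(50):
        mean = aligned.mean(axis=0)
        new_aligned = superpose_all(mean, x)
        delta = np.abs(new_aligned - aligned).max()
        aligned = new_aligned
        if delta < 1e-10:
            break
    mean = aligned.mean(axis=0)
    dev = aligned - mean
    rmsf = np.sqrt((dev**2).sum(axis=2).mean(axis=0))
    rmsd = np.sqrt((dev**2).sum(axis=2).mean(axis=1))
    atoms = [traj.roster.atoms[i] for i in idx]
    table = pd.DataFrame(
        dict(
            chain=[a.chain_id for a in atoms],
            residue=[a.residue_id for a in atoms],
            value=rmsf,
        )
    )
    regions = DEFAULT_REGIONS if regions is None else regions
    region_means = {}
    for label, (lo, hi) in regions.items():
        sub = table[(table.residue >= lo) & (table.residue <= hi)]
        if len(sub):
            region_means[label] = float(sub.value.mean())
    return MobilityProfile(rmsd=rmsd, rmsf=table, region_means=region_means)
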