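"""Synthetic structures, trajectories and scalar traces with known truth.

Every analysis stage of the toolkit is validated against data produced
here: a fourfold-symmetric toy channel whose exact on-axis pore radius is
known analytically, stationary correlated traces with a prescribed
Pearson structure, two-valued occupancy traces whose below-threshold
fraction is exact by construction, and ideal-geometry helices whose
phi/psi torsions are the generator inputs.  All generators are seeded
and byte-deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .contacts import ScalarTrace
from .errors import LookupError_, SpecError
from .io import AtomRecord, Structure, Trajectory

#: Ideal backbone internal coordinates used by :func:`make_helix`.
#: Only the torsions matter to downstream tests; these remaining internals
#: are frozen constants.
IDEAL_BACKBONE = {
    "bond_N_CA": 1.458,  # A
    "bond_CA_C": 1.525,
    "bond_C_N": 1.329,
    "bond_C_O": 1.231,
    "angle_N_CA_C": 111.2,  # deg
    "angle_CA_C_N": 116.6,
    "angle_C_N_CA": 121.9,
    "angle_CA_C_O": 120.5,
}

_SUBUNIT_LETTERS = "ABCDEFGHIJKLMNOP"


@dataclass(frozen=True)
class RingSpec:
    """One ring of pore-lining atoms: z position, distance of atom centers
    from the axis, atom vdW radius, and number of atoms on the ring."""

    z: float
    axial_distance: float
    atom_radius: float
    atoms_per_ring: int = 4


@dataclass
class ToyChannelSpec:
    rings: list[RingSpec]
    n_subunits: int = 4
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.rings = [
            r
            if isinstance(r, RingSpec)
            else (RingSpec(**r) if isinstance(r, dict) else RingSpec(*r))
            for r in self.rings
        ]
        if self.n_subunits < 2:
            raise SpecError("n_subunits must be >= 2")
        if self.n_subunits > len(_SUBUNIT_LETTERS):
            raise SpecError("too many subunits")
        for r in self.rings:
            if r.axial_distance <= r.atom_radius:
                raise SpecError(
                    f"ring at z={r.z}: axial_distance {r.axial_distance} <= "
                    f"atom_radius {r.atom_radius} closes the pore"
                )
            if r.atoms_per_ring % self.n_subunits != 0:
                raise SpecError(
                    "atoms_per_ring must be divisible by n_subunits"
                )


@dataclass
class ToyChannel:
    """A generated toy channel plus its analytic ground-truth profile."""

    structure: Structure
    #: on-axis maximal-sphere radius at each ring z (exact for jitter_sd=0)
    true_profile: dict[float, float]


def make_toy_channel(spec: ToyChannelSpec) -> ToyChannel:
    """Build an n-fold symmetric ring channel about the z axis.

    For each ring the exact on-axis maximal-sphere radius is
    ``axial_distance - atom_radius`` when jitter_sd is zero; the analytic
    profile is recorded alongside the structure as the oracle for the
    pore profiler.
    """
    rng = np.random.default_rng(spec.seed)
    atoms: list[AtomRecord] = []
    serial = 1
    per_chain_counts: dict[tuple[str, int], int] = {}
    for ring_idx, ring in enumerate(spec.rings):
        per_chain = ring.atoms_per_ring // spec.n_subunits
        for j in range(ring.atoms_per_ring):
            theta = 2 * np.pi * j / ring.atoms_per_ring
            pos = np.array(
                [
                    ring.axial_distance * np.cos(theta),
                    ring.axial_distance * np.sin(theta),
                    ring.z,
                ]
            )
            if spec.jitter_sd > 0:
                pos = pos + rng.normal(0.0, spec.jitter_sd, size=3)
            chain = _SUBUNIT_LETTERS[j // per_chain]
            key = (chain, ring_idx + 1)
            m = per_chain_counts.get(key, 0) + 1
            per_chain_counts[key] = m
            atoms.append(
                AtomRecord(
                    serial=serial,
                    atom_name=f"C{m}",
                    residue_name="RNG",
                    residue_id=ring_idx + 1,
                    chain_id=chain,
                    position=tuple(pos),
                    element="C",
                    vdw_radius=ring.atom_radius,
                )
            )
            serial += 1
    subunit_map = {
        _SUBUNIT_LETTERS[i]: _SUBUNIT_LETTERS[i] for i in range(spec.n_subunits)
    }
    profile = {r.z: r.axial_distance - r.atom_radius for r in spec.rings}
    return ToyChannel(Structure(atoms, subunit_map), profile)


def perturb_subunit(
    structure: Structure, subunit: str, displacement: Sequence[float]
) -> Structure:
    """Rigidly translate all atoms of one subunit; others untouched."""
    chains = {c for c, s in structure.subunit_map.items() if s == subunit}
    if not chains:
        raise LookupError_(f"subunit '{subunit}' not in subunit map")
    d = np.asarray(displacement, dtype=float)
    atoms = [
        replace(a, position=tuple(np.asarray(a.position) + d))
        if a.chain_id in chains
        else a
        for a in structure.atoms
    ]
    return Structure(atoms, dict(structure.subunit_map))


def jittered_trajectory(
    structure: Structure,
    n_frames: int,
    sd: float,
    seed: int = 0,
    frame_dt: float = 1.0,
) -> Trajectory:
    """Frames = reference coordinates plus iid isotropic Gaussian jitter."""
    rng = np.random.default_rng(seed)
    base = structure.coords()
    frames = base[None, :, :] + rng.normal(0.0, sd, size=(n_frames, len(structure), 3))
    return Trajectory(roster=structure, frames=frames, frame_dt=frame_dt)


# ---------------------------------------------------------------------------
# Correlated scalar traces (stationary VAR(1) / discrete Ornstein-Uhlenbeck)
# ---------------------------------------------------------------------------

@dataclass
class TraceSpec:
    n_frames: int
    means: np.ndarray
    sds: np.ndarray
    target_correlation: np.ndarray
    frame_dt: float = 1.0
    relaxation_frames: float = 1.0
    seed: int = 0
    names: list[str] | None = None

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float).ravel()
        self.sds = np.asarray(self.sds, dtype=float).ravel()
        self.target_correlation = np.asarray(self.target_correlation, dtype=float)
        m = self.means.size
        if self.sds.size != m or self.target_correlation.shape != (m, m):
            raise SpecError("means, sds and target_correlation sizes disagree")
        if np.any(self.sds <= 0):
            raise SpecError("sds must be positive")
        if not np.allclose(self.target_correlation, self.target_correlation.T):
            raise SpecError("target_correlation must be symmetric")
        if not np.allclose(np.diag(self.target_correlation), 1.0):
            raise SpecError("target_correlation must have unit diagonal")
        if self.relaxation_frames <= 0:
            raise SpecError("relaxation_frames must be positive")
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")
        if self.names is not None and len(self.names) != m:
            raise SpecError("names length disagrees with means")


def _psd_factor(c: np.ndarray) -> np.ndarray:
    """Square-root factor of a PSD matrix; SpecError if not PSD."""
    w, v = np.linalg.eigh(c)
    if w.min() < -1e-8:
        raise SpecError(
            f"target_correlation is not positive semi-definite "
            f"(min eigenvalue {w.min():.3g})"
        )
    return v * np.sqrt(np.clip(w, 0.0, None))


def make_correlated_traces(spec: TraceSpec) -> list[ScalarTrace]:
    """Stationary first-order vector autoregression with the prescribed
    Pearson structure.

    x_t = phi x_{t-1} + e_t with scalar coefficient
    phi = exp(-1/relaxation_frames) and innovation covariance
    (1 - phi^2) C, so the stationary covariance is exactly the target
    correlation C.  The chain is started from a stationary draw; the
    sample correlation converges to C at rate ~ 1/sqrt(n_frames).
    """
    m = spec.means.size
    phi = float(np.exp(-1.0 / spec.relaxation_frames))
    c = spec.target_correlation
    l_stat = _psd_factor(c)
    l_innov = _psd_factor((1.0 - phi**2) * c)
    rng = np.random.default_rng(spec.seed)
    x = np.empty((spec.n_frames, m))
    x[0] = l_stat @ rng.standard_normal(m)
    for t in range(1, spec.n_frames):
        x[t] = phi * x[t - 1] + l_innov @ rng.standard_normal(m)
    y = spec.means + spec.sds * x
    names = spec.names or [f"trace_{i}" for i in range(m)]
    return [
        ScalarTrace(name=names[i], values=y[:, i], frame_dt=spec.frame_dt)
        for i in range(m)
    ]


def make_occupancy_trace(
    n_frames: int,
    p_below: float,
    threshold: float,
    low_value: float,
    high_value: float,
    seed: int = 0,
    frame_dt: float = 1.0,
    name: str = "occupancy",
) -> ScalarTrace:
    """Two-valued trace with an exact below-threshold fraction.

    Exactly ``round(p_below * n_frames)`` frames take ``low_value``, the
    rest ``high_value``, in a seeded shuffled order; the planted fraction
    is exact by construction, isolating the interaction-probability
    statistic from any density estimation.
    """
    if not (low_value < threshold < high_value):
        raise SpecError("need low_value < threshold < high_value")
    if not (0.0 <= p_below <= 1.0):
        raise SpecError("p_below must lie in [0, 1]")
    k = int(round(p_below * n_frames))
    values = np.full(n_frames, high_value, dtype=float)
    values[:k] = low_value
    rng = np.random.default_rng(seed)
    rng.shuffle(values)
    return ScalarTrace(name=name, values=values, frame_dt=frame_dt)


# ---------------------------------------------------------------------------
# Ideal-geometry helix builder (NeRF internal-coordinate placement)
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom d with |cd| = bond, angle(b,c,d) = angle and signed
    dihedral(a,b,c,d) = torsion (IUPAC sign convention)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_helix(
    n_residues: int,
    phi: float,
    psi: float,
    omega: float = 180.0,
    chain_id: str = "A",
    first_residue_id: int = 1,
) -> Structure:
    """Poly-alanine backbone (N, CA, C, O) with uniform phi/psi/omega.

    Built by sequential internal-coordinate placement with the fixed
    ideal bond lengths and angles of :data:`IDEAL_BACKBONE`; recomputing
    phi/psi on the product returns the inputs to well below 1e-6 deg.
    """
    if n_residues < 3:
        raise SpecError("need at least 3 residues")
    g = IDEAL_BACKBONE
    coords: dict[tuple[int, str], np.ndarray] = {}
    n0 = np.zeros(3)
    ca0 = np.array([g["bond_N_CA"], 0.0, 0.0])
    th = np.radians(g["angle_N_CA_C"])
    c0 = ca0 + g["bond_CA_C"] * np.array([-np.cos(th), np.sin(th), 0.0])
    coords[(0, "N")], coords[(0, "CA")], coords[(0, "C")] = n0, ca0, c0
    for i in range(n_residues - 1):
        n_i, ca_i, c_i = coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")]
        n_next = _place_atom(
            n_i, ca_i, c_i, g["bond_C_N"], g["angle_CA_C_N"], psi
        )
        ca_next = _place_atom(
            ca_i, c_i, n_next, g["bond_N_CA"], g["angle_C_N_CA"], omega
        )
        c_next = _place_atom(
            c_i, n_next, ca_next, g["bond_CA_C"], g["angle_N_CA_C"], phi
        )
        coords[(i + 1, "N")] = n_next
        coords[(i + 1, "CA")] = ca_next
        coords[(i + 1, "C")] = c_next
    for i in range(n_residues):
        coords[(i, "O")] = _place_atom(
            coords[(i, "N")],
            coords[(i, "CA")],
            coords[(i, "C")],
            g["bond_C_O"],
            g["angle_CA_C_O"],
            psi + 180.0,
        )
    atoms: list[AtomRecord] = []
    serial = 1
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    for i in range(n_residues):
        for name in ("N", "CA", "C", "O"):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    atom_name=name,
                    residue_name="ALA",
                    residue_id=first_residue_id + i,
                    chain_id=chain_id,
                    position=tuple(coords[(i, name)]),
                    element=elements[name],
                )
            )
            serial += 1
    return Structure(atoms, {chain_id: chain_id})
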