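"""Config-driven orchestration and the packaged synthetic validation run.

`run_pipeline` executes any subset of analysis stages on a structure +
trajectory pair from a validated YAML-able configuration and records a
run manifest; `run_validation_scenario` exercises the whole toolkit on
synthetic inputs with known ground truth and reports pass/fail per
invariant.
"""
from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import contacts as contacts_mod
from . import io as io_mod
from . import mobility as mobility_mod
from . import network as network_mod
from . import pore as pore_mod
from . import synth as synth_mod
from . import torsions as torsions_mod
from .errors import ConfigError, StageError
from .io import Selection

log = logging.getLogger("channelmd")

try:
    PACKAGE_VERSION = _pkg_version("channelmd")
except PackageNotFoundError:  # pragma: no cover - editable corner case
    PACKAGE_VERSION = "unknown"


def stage_seed(global_seed: int, stage: str) -> int:
    """Fan one global seed out to stable per-stage seeds.

    Hash-based so that adding or removing a stage never perturbs the
    randomness of the others; result is < 2**31.
    """
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SelectionSpec(_Strict):
    chains: list[str] | None = None
    residues: list[int] | None = None
    atoms: list[str] | None = None

    def to_selection(self) -> Selection:
        return Selection.of(self.chains, self.residues, self.atoms)


class AxisSpec(_Strict):
    selection: SelectionSpec = Field(default_factory=SelectionSpec)


class PoreSpec(_Strict):
    z_min: float = -10.0
    z_max: float = 10.0
    z_step: float = 0.125
    sample_every_ns: float | None = 20.0  # HOLE-profile sampling cadence
    search_disc: float = 15.0
    n_starts: int = 32
    ionic_radius: float = pore_mod.K_IONIC_RADIUS
    hydrodynamic_radius: float = pore_mod.K_HYDRODYNAMIC_RADIUS
    opposing_residue: int | None = None
    opposing_atom: str = "CA"


class TorsionSpec(_Strict):
    residues: SelectionSpec = Field(default_factory=SelectionSpec)
    sample_every_ns: float | None = 2.0


class ContactSpec(_Strict):
    pair_name: str
    donor: SelectionSpec
    acceptor: SelectionSpec
    contact_class: Literal["hbond", "salt_bridge", "cation_pi", "hydrophobic"]
    threshold: float | None = None
    per_subunit: bool = True


class MobilitySpec(_Strict):
    regions: dict[str, tuple[int, int]] | None = None
    selection: SelectionSpec = Field(
        default_factory=lambda: SelectionSpec(atoms=["CA"])
    )


class CouplingSpec(_Strict):
    alpha: float = 0.05
    autocorrelation_correction: bool = True
    alignment: Literal["intersect_stride", "resample"] = "resample"


class AnalysisConfig(_Strict):
    """Validated pipeline configuration (YAML-serializable)."""

    structure: str
    trajectory: str | None = None
    frame_dt: float = 1.0  # ns
    stages: list[Literal["pore", "torsions", "contacts", "mobility", "coupling"]] = (
        Field(default_factory=lambda: ["pore", "torsions", "contacts", "mobility"])
    )
    output_dir: str = "channelmd_out"
    seed: int = 0
    vdw_table: dict[str, float] | None = None
    vdw_default: float | None = None
    subunits: dict[str, str] | None = None
    axis: AxisSpec = Field(default_factory=AxisSpec)
    pore: PoreSpec = Field(default_factory=PoreSpec)
    torsions: TorsionSpec = Field(default_factory=TorsionSpec)
    contacts: list[ContactSpec] = Field(default_factory=list)
    mobility: MobilitySpec = Field(default_factory=MobilitySpec)
    coupling: CouplingSpec = Field(default_factory=CouplingSpec)


def _known_fields(model: type[BaseModel]) -> list[str]:
    return list(model.model_fields)


def load_config(data: dict | str | Path) -> AnalysisConfig:
    """Build an AnalysisConfig from a dict or YAML path; on validation
    failure every problem is reported at once and unknown keys come with
    a closest-match suggestion."""
    if not isinstance(data, dict):
        with open(data) as fh:
            data = yaml.safe_load(fh)
    try:
        return AnalysisConfig.model_validate(data)
    except ValidationError as exc:
        problems = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            msg = f"{loc}: {err['msg']}"
            if err["type"] == "extra_forbidden":
                bad = str(err["loc"][-1])
                guess = difflib.get_close_matches(
                    bad, _known_fields(AnalysisConfig) + _known_fields(PoreSpec)
                    + _known_fields(TorsionSpec) + _known_fields(CouplingSpec)
                    + _known_fields(ContactSpec) + _known_fields(SelectionSpec),
                    n=1,
                )
                if guess:
                    msg += f" (did you mean '{guess[0]}'?)"
            problems.append(msg)
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems)) from exc


def default_config_yaml() -> str:
    return yaml.safe_dump(
        AnalysisConfig(structure="structure.pdb").model_dump(), sort_keys=False
    )


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass
class StageRecord:
    stage: str
    parameters: dict
    outputs: list[str] = field(default_factory=list)
    status: str = "ok"
    error: str | None = None


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    stages: list[StageRecord] = field(default_factory=list)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _config_hash(config: AnalysisConfig) -> str:
    canon = yaml.safe_dump(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stride(frame_dt: float, sample_every_ns: float | None) -> int:
    if sample_every_ns is None:
        return 1
    return max(1, int(round(sample_every_ns / frame_dt)))


def run_pipeline(config: AnalysisConfig | dict) -> RunManifest:
    """Execute the requested stages in dependency order.

    Stage order is io -> axis -> {pore, torsions, contacts, mobility} ->
    coupling; a failing stage is isolated (recorded in the manifest with
    its error) and the remaining stages still run.  All tabular results
    are written as CSV under ``output_dir`` alongside ``manifest.json``.
    """
    if isinstance(config, dict):
        config = load_config(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(_config_hash(config), PACKAGE_VERSION, config.seed)
    manifest.write(out / "manifest.json")

    structure = io_mod.read_structure(config.structure)
    structure = io_mod.assign_vdw_radii(
        structure, config.vdw_table, default=config.vdw_default or 1.5
    )
    if config.subunits:
        structure.subunit_map.update(config.subunits)
    elif not structure.subunit_map:
        structure.subunit_map.update({c: c for c in structure.chain_ids()})
    if config.trajectory:
        traj = io_mod.read_trajectory(config.trajectory, structure, config.frame_dt)
    else:
        traj = io_mod.Trajectory(structure, structure.coords()[None], config.frame_dt)

    axis = None
    collected_traces: list[contacts_mod.ScalarTrace] = []

    def run_stage(name: str, params: dict, fn):
        record = StageRecord(stage=name, parameters=params)
        try:
            record.outputs = fn()
            log.info("stage %s ok: %s", name, record.outputs)
        except Exception as exc:  # noqa: BLE001 - isolate failing stage
            record.status = "failed"
            record.error = f"{type(exc).__name__}: {exc}"
            log.warning("stage %s failed: %s", name, record.error)
        manifest.stages.append(record)

    needs_axis = "pore" in config.stages or "torsions" in config.stages

    if needs_axis:
        def do_axis():
            nonlocal axis
            axis = pore_mod.fit_pore_axis(structure, config.axis.selection.to_selection())
            return []

        run_stage("axis", config.axis.model_dump(), do_axis)

    if "pore" in config.stages:
        p = config.pore

        def do_pore():
            if axis is None:
                raise StageError("pore", RuntimeError("axis fit failed"))
            profile = pore_mod.pore_profile(
                traj,
                axis,
                p.z_min,
                p.z_max,
                z_step=p.z_step,
                frame_stride=_stride(traj.frame_dt, p.sample_every_ns),
                search_disc=p.search_disc,
                n_starts=p.n_starts,
                seed=stage_seed(config.seed, "pore"),
                ionic=p.ionic_radius,
                hydrodynamic=p.hydrodynamic_radius,
            )
            files = [out / "pore_profile_frames.csv", out / "pore_profile_mean.csv"]
            io_mod.write_table(profile.to_frame_table(), files[0])
            io_mod.write_table(profile.to_mean_table(), files[1])
            if p.opposing_residue is not None:
                od = pore_mod.opposing_distances(traj, p.opposing_residue, p.opposing_atom)
                df = pd.DataFrame(
                    dict(
                        frame=np.arange(traj.n_frames),
                        pair_a=od.pair_a,
                        pair_b=od.pair_b,
                        symmetry_index=od.symmetry_index,
                    )
                )
                files.append(out / "opposing_distances.csv")
                io_mod.write_table(df, files[-1])
            return [str(f) for f in files]

        run_stage("pore", p.model_dump(), do_pore)

    if "torsions" in config.stages:
        t = config.torsions

        def do_torsions():
            traces = torsions_mod.phi_psi_traces(
                traj,
                t.residues.to_selection(),
                frame_stride=_stride(traj.frame_dt, t.sample_every_ns),
            )
            f = out / "torsions.csv"
            io_mod.write_table(torsions_mod.torsion_table(traces), f)
            return [str(f)]

        run_stage("torsions", t.model_dump(), do_torsions)

    if "contacts" in config.stages:
        defs = [
            contacts_mod.ContactDefinition(
                pair_name=c.pair_name,
                donor_atoms=c.donor.to_selection(),
                acceptor_atoms=c.acceptor.to_selection(),
                contact_class=c.contact_class,
                threshold=c.threshold,
            )
            for c in config.contacts
        ]

        def do_contacts():
            table = contacts_mod.contact_table(traj, defs, per_subunit=True)
            f = out / "interaction_probabilities.csv"
            io_mod.write_table(table.rows, f)
            for d in defs:  # collect traces for the coupling stage
                try:
                    tr = contacts_mod.distance_trace(
                        traj, d.donor_atoms, d.acceptor_atoms, d.mode, d.pair_name
                    )
                    collected_traces.append(tr)
                except Exception:  # noqa: BLE001
                    pass
            if table.errors:
                log.warning("unresolvable contacts: %s", table.errors)
            return [str(f)]

        run_stage("contacts", {"n_contacts": len(defs)}, do_contacts)

    if "mobility" in config.stages:
        def do_mobility():
            files = []
            msel = config.mobility.selection.to_selection()
            rms = mobility_mod.rmsd_trace(traj, structure, msel)
            files.append(out / "rmsd.csv")
            io_mod.write_table(
                pd.DataFrame(dict(frame=np.arange(traj.n_frames), value=rms)),
                files[-1],
            )
            if traj.n_frames >= 2:
                prof = mobility_mod.rmsf_profile(
                    traj, sel=msel, regions=config.mobility.regions
                )
                files.append(out / "rmsf.csv")
                io_mod.write_table(prof.rmsf, files[-1])
                files.append(out / "rmsf_regions.csv")
                io_mod.write_table(
                    pd.DataFrame(
                        [
                            dict(region=k, mean=v)
                            for k, v in prof.region_means.items()
                        ]
                    ),
                    files[-1],
                )
            return [str(f) for f in files]

        run_stage("mobility", config.mobility.model_dump(), do_mobility)

    if "coupling" in config.stages:
        cc = config.coupling

        def do_coupling():
            if len(collected_traces) < 2:
                raise StageError(
                    "coupling",
                    RuntimeError("needs >= 2 contact traces; configure contacts"),
                )
            obs = network_mod.build_observable_matrix(
                collected_traces, alignment=cc.alignment
            )
            report = network_mod.pearson_report(
                obs,
                alpha=cc.alpha,
                autocorrelation_correction=cc.autocorrelation_correction,
            )
            files = []
            for key, df in report.to_tables().items():
                files.append(out / f"correlation_{key}.csv")
                df.to_csv(files[-1])
            return [str(f) for f in files]

        run_stage("coupling", cc.model_dump(), do_coupling)

    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Synthetic validation scenario
# ---------------------------------------------------------------------------

#: Observables of the synthetic coupling scenario.  The "wild-type-like"
#: condition couples the two VSD salt-bridge distances; the
#: "variant-like" condition removes that coupling and instead couples
#: the SF carbonyl distance to the C-linker salt bridge.
SCENARIO_OBSERVABLES = [
    "sf_carbonyl",
    "clinker_saltbridge",
    "vsd_K525_D509",
    "vsd_R531_D460",
    "pore_hydrophobic",
    "s4s5_torsion",
]
SCENARIO_RHO = 0.7
_GAINED = ("sf_carbonyl", "clinker_saltbridge")
_LOST = ("vsd_K525_D509", "vsd_R531_D460")


def _scenario_corr(coupled: tuple[str, str]) -> np.ndarray:
    m = len(SCENARIO_OBSERVABLES)
    c = np.eye(m)
    i, j = (SCENARIO_OBSERVABLES.index(x) for x in coupled)
    c[i, j] = c[j, i] = SCENARIO_RHO
    return c


def run_validation_scenario(
    seed: int,
    out_dir: str | Path | None = None,
    n_frames: int = 4000,
) -> dict:
    """Full synthetic validation: toy-channel pore oracle, torsion
    round-trip, occupancy exactness, rigid-motion mobility, and the
    end-to-end coupling contrast with injected gained/lost pairs.

    Returns a report dict with one pass/fail entry per invariant; CSV
    and JSON artifacts are written to ``out_dir`` when given.
    """
    report: dict = {"seed": seed, "checks": {}}

    def check(name: str, passed: bool, **info):
        report["checks"][name] = dict(passed=bool(passed), **info)

    # --- pore stage: analytic single ring + optimizer-vs-grid oracle
    single = synth_mod.make_toy_channel(
        synth_mod.ToyChannelSpec(rings=[synth_mod.RingSpec(0.0, 5.0, 1.7, 8)])
    )
    axis0 = pore_mod.PoreAxis((0.0, 0.0, 0.0), (0.0, 0.0, 1.0))
    r_single = pore_mod.max_sphere_radius(
        single.structure, axis0, 0.0, seed=stage_seed(seed, "pore")
    ).radius
    check(
        "pore_single_ring_analytic",
        abs(r_single - 3.3) <= 1e-3,
        radius=r_single,
        expected=3.3,
    )

    toy = synth_mod.make_toy_channel(
        synth_mod.ToyChannelSpec(
            rings=[
                synth_mod.RingSpec(0.0, 5.0, 1.7, 8),
                synth_mod.RingSpec(6.0, 3.5, 1.52, 8),
                synth_mod.RingSpec(12.0, 6.0, 1.7, 8),
            ],
            jitter_sd=0.1,
            seed=stage_seed(seed, "toy"),
        )
    )
    axis = pore_mod.fit_pore_axis(toy.structure, Selection())
    # slice positions expressed in fitted-axis coordinates
    coords = toy.structure.coords()
    proj = (coords - np.asarray(axis.origin)) @ np.asarray(axis.direction)
    z_slices = np.linspace(proj.min() + 1.0, proj.max() - 1.0, 5)
    errs = []
    for z in z_slices:
        r_opt = pore_mod.max_sphere_radius(
            toy.structure, axis, float(z), search_disc=6.0,
            seed=stage_seed(seed, "pore"),
        ).radius
        r_grid = pore_mod.grid_radius(toy.structure, axis, float(z), search_disc=6.0)
        errs.append(abs(r_opt - r_grid))
    check(
        "pore_grid_oracle",
        max(errs) <= 0.05,
        max_abs_error=float(max(errs)),
        n_slices=len(z_slices),
    )

    # --- torsion round-trip
    max_tors_err = 0.0
    for phi, psi in [(-57.0, -47.0), (-120.0, 130.0)]:
        helix = synth_mod.make_helix(10, phi, psi)
        traj1 = io_mod.Trajectory(helix, helix.coords()[None], 1.0)
        for tr in torsions_mod.phi_psi_traces(traj1, Selection()):
            target = phi if tr.angle_name == "phi" else psi
            max_tors_err = max(max_tors_err, float(np.abs(tr.values - target).max()))
    check("torsion_round_trip", max_tors_err <= 1e-6, max_abs_error_deg=max_tors_err)

    # --- occupancy exactness
    occ = synth_mod.make_occupancy_trace(
        1000, 0.37, 3.5, 2.8, 4.5, seed=stage_seed(seed, "occupancy")
    )
    p_emp = contacts_mod.interaction_probability(occ, 3.5)
    check("occupancy_exact", p_emp == 0.37, probability=p_emp, planted=0.37)

    # --- mobility: rigid motions leave RMSD at zero
    rng = np.random.default_rng(stage_seed(seed, "mobility"))
    base = toy.structure.coords()
    frames = []
    from scipy.spatial.transform import Rotation as _R

    for _ in range(5):
        rot = _R.random(rng=rng).as_matrix()
        frames.append(base @ rot.T + rng.normal(size=3))
    rigid = io_mod.Trajectory(toy.structure, np.stack(frames), 1.0)
    rms = mobility_mod.rmsd_trace(rigid, toy.structure, Selection())
    check("mobility_rigid_rmsd", float(rms.max()) < 1e-9, max_rmsd=float(rms.max()))

    # --- end-to-end coupling contrast
    def make_report(coupled: tuple[str, str], tag: str):
        spec = synth_mod.TraceSpec(
            n_frames=n_frames,
            means=np.full(len(SCENARIO_OBSERVABLES), 4.0),
            sds=np.full(len(SCENARIO_OBSERVABLES), 0.4),
            target_correlation=_scenario_corr(coupled),
            relaxation_frames=2.0,
            seed=stage_seed(seed, f"traces:{tag}"),
            names=SCENARIO_OBSERVABLES,
        )
        traces = synth_mod.make_correlated_traces(spec)
        obs = network_mod.build_observable_matrix(traces)
        return network_mod.pearson_report(obs, alpha=0.05)

    ref_report = make_report(_LOST, "wt")
    var_report = make_report(_GAINED, "variant")
    contrast = network_mod.contrast_reports(ref_report, var_report, r_change_min=0.3)
    gained = set(map(tuple, contrast.pairs_with_status("gained")))
    lost = set(map(tuple, contrast.pairs_with_status("lost")))
    flipped = contrast.pairs_with_status("sign_flipped")
    ok = (
        gained == {tuple(sorted(_GAINED, key=SCENARIO_OBSERVABLES.index))}
        and lost == {tuple(sorted(_LOST, key=SCENARIO_OBSERVABLES.index))}
        and not flipped
    )
    check(
        "coupling_contrast_recovery",
        ok,
        gained=sorted(gained),
        lost=sorted(lost),
        sign_flipped=sorted(map(tuple, flipped)),
        injected_gained=_GAINED,
        injected_lost=_LOST,
        n_frames=n_frames,
    )

    report["passed"] = all(c["passed"] for c in report["checks"].values())
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        contrast.rows.to_csv(out / "coupling_contrast.csv", index=False)
        for key, df in ref_report.to_tables().items():
            df.to_csv(out / f"wt_correlation_{key}.csv")
        for key, df in var_report.to_tables().items():
            df.to_csv(out / f"variant_correlation_{key}.csv")
        with open(out / "validation_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
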