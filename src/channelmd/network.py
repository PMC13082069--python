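"""Significance-masked Pearson correlation networks over scalar traces.

Heterogeneously sampled traces (distances per frame, torsions every few
ns) are aligned onto one frame grid, correlated pairwise, and each
coefficient is reported together with a two-sided p-value from the
t statistic r*sqrt((n-2)/(1-r^2)).  Because MD frames are serially
correlated, the sample count can optionally be replaced per pair by the
lag-1 effective sample size n*(1 - rho1*rho2)/(1 + rho1*rho2); reports
from replicate trajectories can be pooled, and two reports contrasted
to flag gained, lost, sign-flipped and preserved couplings.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .contacts import ScalarTrace
from .errors import (
    AlignmentError,
    ContrastError,
    DegenerateDataError,
    PoolingError,
)
from .torsions import _wrap


@dataclass
class ObservableMatrix:
    """Aligned samples: frames x observables, with per-trace provenance."""

    observables: list[str]
    samples: np.ndarray  # (n_frames, n_observables)
    frame_dt: float
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.observables):
            raise ValueError("samples shape disagrees with observable names")
        if len(self.observables) < 2 or self.samples.shape[0] < 3:
            raise ValueError("need >= 2 observables and >= 3 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("observable matrix contains non-finite values")


@dataclass
class CorrelationReport:
    observables: list[str]
    r: np.ndarray  # symmetric, unit diagonal
    p: np.ndarray  # symmetric, zero diagonal
    mask: np.ndarray  # p < alpha
    n_effective: np.ndarray  # per-pair sample count used for p
    alpha: float = 0.05
    autocorrelation_correction: bool = True

    def pair(self, a: str, b: str) -> tuple[float, float, bool]:
        i, j = self.observables.index(a), self.observables.index(b)
        return float(self.r[i, j]), float(self.p[i, j]), bool(self.mask[i, j])

    def to_tables(self) -> dict[str, pd.DataFrame]:
        names = self.observables
        return {
            "r": pd.DataFrame(self.r, index=names, columns=names),
            "p": pd.DataFrame(self.p, index=names, columns=names),
            "mask": pd.DataFrame(self.mask, index=names, columns=names),
        }


@dataclass
class CouplingContrast:
    """Pairwise status changes between a reference and a variant report."""

    rows: pd.DataFrame  # pair_a, pair_b, status, r_ref, r_var, p_ref, p_var
    r_change_min: float

    def pairs_with_status(self, status: str) -> list[tuple[str, str]]:
        sub = self.rows[self.rows.status == status]
        return list(zip(sub.pair_a, sub.pair_b))


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

_TIME_DECIMALS = 9  # round times to 1e-9 ns when intersecting grids


def build_observable_matrix(
    traces: Sequence[ScalarTrace],
    alignment: Literal["intersect_stride", "resample"] = "intersect_stride",
    angular_sd_flag: float = 60.0,
) -> ObservableMatrix:
    """Stack heterogeneous traces onto one common frame grid.

    ``intersect_stride`` keeps only time points present in every trace's
    sampling grid; ``resample`` linearly interpolates finer traces onto
    the coarsest grid.  Angular traces are unwrapped about their
    starting branch before interpolation and entered in (unwrapped)
    degrees; an angular trace whose circular spread exceeds
    ``angular_sd_flag`` degrees is flagged in the provenance as
    unreliable under linearization.
    """
    if len(traces) < 2:
        raise AlignmentError("need at least two traces")
    names = []
    for tr in traces:
        label = f"{tr.name}/{tr.subunit}" if tr.subunit else tr.name
        if label in names:
            raise AlignmentError(f"duplicate trace name '{label}'")
        names.append(label)
    dts = np.array([tr.frame_dt for tr in traces])
    coarsest = dts.max()
    times = [np.round(np.arange(len(tr)) * tr.frame_dt, _TIME_DECIMALS) for tr in traces]

    def prepared_values(tr: ScalarTrace) -> np.ndarray:
        if tr.angular:
            return np.degrees(np.unwrap(np.radians(tr.values)))
        return tr.values

    provenance: dict[str, dict] = {}
    for name, tr in zip(names, traces):
        info = dict(frame_dt=tr.frame_dt, angular=tr.angular, subunit=tr.subunit)
        if tr.angular:
            rad = np.radians(tr.values)
            resultant = np.abs(np.exp(1j * rad).mean())
            circ_sd = np.degrees(np.sqrt(-2 * np.log(max(resultant, 1e-12))))
            info["circular_sd"] = float(circ_sd)
            info["linearization_reliable"] = bool(circ_sd <= angular_sd_flag)
        provenance[name] = info

    if alignment == "intersect_stride":
        common = times[0]
        for tt in times[1:]:
            common = np.intersect1d(common, tt)
        if common.size < 3:
            raise AlignmentError(
                "trace sampling grids share fewer than 3 time points; "
                "use alignment='resample'"
            )
        cols = []
        for tr, tt in zip(traces, times):
            pos = np.searchsorted(tt, common)
            cols.append(prepared_values(tr)[pos])
        samples = np.column_stack(cols)
        frame_dt = float(common[1] - common[0]) if common.size > 1 else coarsest
    elif alignment == "resample":
        t_end = min(tt[-1] for tt in times)
        grid = np.arange(0.0, t_end + coarsest / 2, coarsest)
        cols = [
            np.interp(grid, tt, prepared_values(tr))
            for tr, tt in zip(traces, times)
        ]
        samples = np.column_stack(cols)
        frame_dt = coarsest
    else:
        raise ValueError(f"unknown alignment '{alignment}'")
    return ObservableMatrix(names, samples, frame_dt, provenance)


# ---------------------------------------------------------------------------
# Pearson report
# ---------------------------------------------------------------------------

def _lag1_autocorr(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return 0.0
    return float(x[:-1] @ x[1:] / denom)


def pearson_report(
    obs: ObservableMatrix,
    alpha: float = 0.05,
    autocorrelation_correction: bool = True,
) -> CorrelationReport:
    """Pairwise Pearson r with two-sided p-values and a significance mask.

    With the autocorrelation correction the sample count entering the t
    test is replaced per pair by n*(1 - rho1*rho2)/(1 + rho1*rho2) using
    the lag-1 autocorrelations of the two columns (floored at 3), which
    counters the significance inflation caused by serially correlated
    trajectory frames.
    """
    x = obs.samples
    n, m = x.shape
    sds = x.std(axis=0)
    if np.any(sds == 0):
        bad = [obs.observables[i] for i in np.flatnonzero(sds == 0)]
        raise DegenerateDataError(f"zero-variance observables: {bad}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    if autocorrelation_correction:
        rho = np.array([_lag1_autocorr(x[:, j]) for j in range(m)])
        prod = np.clip(np.outer(rho, rho), -0.999, 0.999)
        n_eff = np.maximum(n * (1.0 - prod) / (1.0 + prod), 3.0)
    else:
        n_eff = np.full((m, m), float(n))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = r * np.sqrt((n_eff - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * t_dist.sf(np.abs(t_stat), np.maximum(n_eff - 2, 1.0))
    np.fill_diagonal(p, 0.0)
    mask = p < alpha
    return CorrelationReport(
        observables=list(obs.observables),
        r=r,
        p=p,
        mask=mask,
        n_effective=n_eff,
        alpha=alpha,
        autocorrelation_correction=autocorrelation_correction,
    )


def benjamini_hochberg_mask(report: CorrelationReport, alpha: float = 0.05) -> np.ndarray:
    """Optional FDR-controlled mask over the upper-triangle p-values."""
    m = len(report.observables)
    iu = np.triu_indices(m, k=1)
    pvals = report.p[iu]
    order = np.argsort(pvals)
    ranked = pvals[order]
    k = np.arange(1, ranked.size + 1)
    passed = ranked <= alpha * k / ranked.size
    cutoff = ranked[passed].max() if passed.any() else -1.0
    mask = np.zeros((m, m), dtype=bool)
    sel = pvals <= cutoff
    mask[iu] = sel
    mask = mask | mask.T
    np.fill_diagonal(mask, True)
    return mask


# ---------------------------------------------------------------------------
# Replicate pooling
# ---------------------------------------------------------------------------

def pool_replicates(
    replicates: Sequence[ObservableMatrix] | Sequence[CorrelationReport],
    method: Literal["concat", "fisher_z"] = "concat",
    alpha: float = 0.05,
    autocorrelation_correction: bool = True,
) -> CorrelationReport:
    """Merge replicate trajectories into one correlation report.

    ``concat`` standardizes each observable within each replicate
    (removing between-replicate mean shifts that would otherwise
    manufacture correlation) and concatenates the samples; it takes
    :class:`ObservableMatrix` inputs.  ``fisher_z`` averages atanh(r)
    across :class:`CorrelationReport` inputs and back-transforms, with
    the combined sample count.
    """
    if not replicates:
        raise PoolingError("no replicates supplied")
    rosters = [list(r.observables) for r in replicates]
    for other in rosters[1:]:
        if other != rosters[0]:
            diff = sorted(set(other) ^ set(rosters[0]))
            raise PoolingError(f"replicate observable rosters differ: {diff}")
    if method == "concat":
        mats = []
        for rep in replicates:
            if not isinstance(rep, ObservableMatrix):
                raise PoolingError("concat pooling takes ObservableMatrix inputs")
            x = rep.samples
            sd = x.std(axis=0)
            if np.any(sd == 0):
                bad = [rep.observables[i] for i in np.flatnonzero(sd == 0)]
                raise DegenerateDataError(f"zero-variance observables: {bad}")
            mats.append((x - x.mean(axis=0)) / sd)
        pooled = ObservableMatrix(
            rosters[0], np.vstack(mats), replicates[0].frame_dt
        )
        return pearson_report(
            pooled,
            alpha=alpha,
            autocorrelation_correction=autocorrelation_correction,
        )
    if method == "fisher_z":
        reports = list(replicates)
        if not all(isinstance(r, CorrelationReport) for r in reports):
            raise PoolingError("fisher_z pooling takes CorrelationReport inputs")
        zs = [np.arctanh(np.clip(r.r, -0.999999, 0.999999)) for r in reports]
        r_pooled = np.tanh(np.mean(zs, axis=0))
        np.fill_diagonal(r_pooled, 1.0)
        n_eff = np.sum([r.n_effective for r in reports], axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = r_pooled * np.sqrt(
                (n_eff - 2) / np.maximum(1.0 - r_pooled**2, 1e-300)
            )
        p = 2.0 * t_dist.sf(np.abs(t_stat), np.maximum(n_eff - 2, 1.0))
        np.fill_diagonal(p, 0.0)
        return CorrelationReport(
            observables=rosters[0],
            r=r_pooled,
            p=p,
            mask=p < alpha,
            n_effective=np.asarray(n_eff, dtype=float),
            alpha=alpha,
            autocorrelation_correction=reports[0].autocorrelation_correction,
        )
    raise ValueError(f"unknown pooling method '{method}'")


# ---------------------------------------------------------------------------
# Variant contrast
# ---------------------------------------------------------------------------

def contrast_reports(
    reference: CorrelationReport,
    variant: CorrelationReport,
    r_change_min: float = 0.3,
) -> CouplingContrast:
    """Flag couplings lost, gained, sign-flipped or preserved between a
    reference and a variant report.

    lost: significant in the reference only, with |r_ref - r_var| >=
    r_change_min; gained: the converse; sign_flipped: significant in
    both with opposite signs; preserved: significant in both, same sign.
    """
    if list(reference.observables) != list(variant.observables):
        raise ContrastError("reports have different observable rosters")
    rows = []
    names = reference.observables
    for i, j in combinations(range(len(names)), 2):
        sig_ref, sig_var = bool(reference.mask[i, j]), bool(variant.mask[i, j])
        r_ref, r_var = float(reference.r[i, j]), float(variant.r[i, j])
        dr = abs(r_ref - r_var)
        status = None
        if sig_ref and not sig_var and dr >= r_change_min:
            status = "lost"
        elif sig_var and not sig_ref and dr >= r_change_min:
            status = "gained"
        elif sig_ref and sig_var:
            status = "sign_flipped" if r_ref * r_var < 0 else "preserved"
        if status is not None:
            rows.append(
                dict(
                    pair_a=names[i],
                    pair_b=names[j],
                    status=status,
                    r_ref=r_ref,
                    r_var=r_var,
                    p_ref=float(reference.p[i, j]),
                    p_var=float(variant.p[i, j]),
                )
            )
    columns = ["pair_a", "pair_b", "status", "r_ref", "r_var", "p_ref", "p_var"]
    return CouplingContrast(
        rows=pd.DataFrame(rows, columns=columns), r_change_min=r_change_min
    )
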