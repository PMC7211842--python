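"""Work and free-energy computations for pulling transitions.

Experimental (AFM) side: the unfolding work of a rip between two
WLC-fitted branches is

    W_unfold = W_rip - dG_s,

where W_rip is the quasi-static work across the transition -- the trapezoid
area (f1(x1) + f2(x2)) (x2 - x1) / 2 under the segment connecting the two
branches -- and dG_s is the change in stretching free energy of the whole
chain between the two branches,

    dG_s = int_0^{x2} f2_WLC - int_0^{x1} f1_WLC,

both integrals in closed form from the WLC antiderivative.

Simulation (SMD) side: the unfolding work profile is the force integral
along the end-to-end extension minus the stretching work of the unravelled
chain, modelled by an extensible-FJC baseline fitted to the last part of
the trace:

    W_unfold(x) = int_0^x F dx' - int_0^x f_FJC dx'.

Free energies are then estimated from the work distribution with the mean
work estimator (sample mean; upward-biased by dissipation) and Jarzynski's
equality, -kBT ln < exp(-W/kBT) >, which by Jensen's inequality never
exceeds the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kbt, pn_nm_to_kcal_mol, PN_NM_PER_KCAL_MOL
from .polymer import FJCParams, fit_fjc, fjc_force, wlc_force, wlc_stretch_energy
from .segmentation import AnalysisError, BranchSegment, SegmentedTrace, downsample, _drop_runs
from .trace_io import Trace

__all__ = [
    "TransitionWork",
    "FreeEnergyProfile",
    "WorkDistributionSummary",
    "rip_work",
    "transition_unfolding_work",
    "trace_transition_works",
    "cumulative_transition_profile",
    "smd_work_profile",
    "fit_smd_tail",
    "mean_work_estimate",
    "jarzynski_estimate",
    "work_distribution_summary",
    "ensemble_profile",
]


@dataclass(frozen=True)
class TransitionWork:
    """Unfolding work bookkeeping for one rip.

    All energies in pN·nm; ``w_unfold_kcal_mol`` converts on read.  The
    identity ``w_unfold == w_rip - dg_s`` holds exactly by construction.
    """

    index: int
    label: str
    x1: float
    x2: float
    w_rip: float
    dg_s: float
    w_unfold: float

    @property
    def w_unfold_kcal_mol(self) -> float:
        return pn_nm_to_kcal_mol(self.w_unfold)


@dataclass
class FreeEnergyProfile:
    """Cumulative unfolding work versus extension, in kcal/mol.

    ``sd`` is populated for ensemble profiles (instantaneous standard
    deviation across traces at each grid point).
    """

    extension: np.ndarray          # nm, monotone increasing
    work: np.ndarray               # kcal/mol
    sd: np.ndarray | None = None   # kcal/mol
    n_traces: int = 1

    def __post_init__(self) -> None:
        self.extension = np.asarray(self.extension, float)
        self.work = np.asarray(self.work, float)
        if len(self.extension) != len(self.work):
            raise ValueError("extension and work grids must have equal length")
        if np.any(np.diff(self.extension) <= 0):
            raise ValueError("extension grid must be strictly increasing")

    @property
    def final_work(self) -> float:
        return float(self.work[-1])


@dataclass(frozen=True)
class WorkDistributionSummary:
    """Moments and free-energy estimators of a work sample (kcal/mol)."""

    n: int
    mean: float
    sd: float
    se: float
    mean_work_estimate: float
    jarzynski_estimate: float
    temperature: float


def rip_work(f1: float, f2: float, x1: float, x2: float) -> float:
    """Quasi-static work (pN·nm) across a transition: trapezoid area
    (f1 + f2)(x2 - x1)/2 of the segment connecting the two branches."""
    if x2 <= x1:
        raise ValueError(f"transition requires x2 > x1, got x1={x1}, x2={x2}")
    return 0.5 * (f1 + f2) * (x2 - x1)


def transition_unfolding_work(
    branch1: BranchSegment,
    branch2: BranchSegment,
    x1: float,
    x2: float,
    index: int = 0,
    label: str = "unlabeled",
) -> TransitionWork:
    """Unfolding work of one rip from the two fitted branch models.

    dG_s uses the closed-form WLC stretch energies at the endpoints; W_rip
    the fitted-model forces there.  Raises if either fit is missing or
    unconverged (such traces never reach the energetics stage when the
    acceptance filters are on).
    """
    for br in (branch1, branch2):
        if br.fit is None or not br.fit.converged:
            raise AnalysisError("unfolding work requires converged WLC fits on both branches")
    p1, p2 = branch1.fit.params, branch2.fit.params
    if x2 > x1:
        f1 = wlc_force(x1, p1)
        f2 = wlc_force(x2, p2)
        w_rip = rip_work(f1, f2, x1, x2)
    elif x2 == x1 and p1 == p2:
        w_rip = 0.0  # degenerate no-transition case
    else:
        raise ValueError(f"transition requires x2 > x1, got x1={x1}, x2={x2}")
    dg_s = wlc_stretch_energy(x2, p2) - wlc_stretch_energy(x1, p1)
    return TransitionWork(
        index=index, label=label, x1=x1, x2=x2,
        w_rip=w_rip, dg_s=dg_s, w_unfold=w_rip - dg_s,
    )


def trace_transition_works(seg: SegmentedTrace) -> list[TransitionWork]:
    """All unfolding-transition works of a segmented trace (detachment excluded)."""
    works = []
    for k, tr in enumerate(seg.transitions[:-1]):
        works.append(
            transition_unfolding_work(
                seg.branches[k], seg.branches[k + 1], tr.x1, tr.x2,
                index=k, label=tr.label,
            )
        )
    return works


def cumulative_transition_profile(works: list[TransitionWork]) -> FreeEnergyProfile:
    """Cumulative unfolding work of a trace's transitions, in extension order.

    Grid points sit at each transition's landing extension x2, preceded by a
    zero anchor at the origin.  This is the experimental analogue of the
    continuous SMD work profile.
    """
    if not works:
        raise ValueError("no transition works to accumulate")
    ordered = sorted(works, key=lambda w: w.x2)
    x = np.array([0.0] + [w.x2 for w in ordered])
    w = np.concatenate(([0.0], np.cumsum([pn_nm_to_kcal_mol(wk.w_unfold) for wk in ordered])))
    return FreeEnergyProfile(extension=x, work=w)


def smd_work_profile(
    trace: Trace,
    fjc: FJCParams,
    grid_step: float = 0.1,
) -> FreeEnergyProfile:
    """Unfolding work profile of an SMD trace with the FJC baseline removed.

    The pulling work is accumulated by trapezoid over successive (x, F)
    samples *in time order* -- the extension fluctuates thermally, and signed
    increments let the fluctuations cancel instead of biasing the integral
    upward.  The baseline integral of the fitted FJC force is evaluated by
    cumulative trapezoid on the output grid.  The profile is reported on a
    uniform extension grid over [0, max extension], in kcal/mol.
    """
    x = trace.extension
    f = trace.force
    x_max = float(np.max(x))
    if x_max <= grid_step:
        raise ValueError("trace extension never exceeds the grid start")

    cum = np.concatenate(([0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(x))))
    # monotone envelope: the profile value at extension g is the accumulated
    # work when the trace first definitively passes g (running-max envelope)
    run_max = np.maximum.accumulate(x)
    keep = np.concatenate(([True], np.diff(run_max) > 0))
    x_env, cum_env = run_max[keep], cum[keep]

    grid = np.arange(0.0, x_max + grid_step / 2, grid_step)
    grid = grid[grid <= x_env[-1]]
    w_pull = np.interp(grid, x_env, cum_env, left=0.0)

    f_base = np.asarray(fjc_force(grid, fjc))
    w_base = np.concatenate(([0.0], np.cumsum(0.5 * (f_base[1:] + f_base[:-1]) * np.diff(grid))))

    return FreeEnergyProfile(extension=grid, work=pn_nm_to_kcal_mol(1.0) * (w_pull - w_base))


def fit_smd_tail(
    trace: Trace,
    drop_threshold: float = 200.0,
    downsample_width: float = 0.5,
    margin: float = 2.0,
    min_points: int = 50,
) -> FJCParams:
    """Fit the extensible-FJC baseline to the post-unfolding part of an SMD trace.

    The last force drop steeper than ``drop_threshold`` (pN per
    ``downsample_width``-nm bin) marks the end of unfolding; all raw samples
    beyond it plus a ``margin`` (nm) feed the FJC fit.
    """
    ds = downsample(trace, downsample_width)
    runs = _drop_runs(ds.force, drop_threshold)
    if not runs:
        raise AnalysisError("no force drop detected; cannot locate the stretch tail")
    last_drop_x = float(ds.extension[runs[-1][1]])
    sel = trace.extension >= last_drop_x + margin
    if int(np.sum(sel)) < min_points:
        raise AnalysisError(
            f"stretch tail too short: {int(np.sum(sel))} points beyond "
            f"{last_drop_x + margin:.1f} nm (need {min_points})"
        )
    pts = np.column_stack((trace.extension[sel], np.maximum(trace.force[sel], 0.0)))
    fit = fit_fjc(pts, temperature=trace.metadata.get("temperature_K", DEFAULT_TEMPERATURE))
    if not fit.converged:
        raise AnalysisError("FJC tail fit did not converge")
    return fit.params


def mean_work_estimate(works) -> tuple[float, float, float]:
    """Sample mean, SD (n-1 denominator) and standard error of work values."""
    w = np.asarray(works, float)
    if w.size == 0:
        raise ValueError("empty work sample")
    mean = float(np.mean(w))
    sd = float(np.std(w, ddof=1)) if w.size > 1 else 0.0
    return mean, sd, sd / np.sqrt(w.size)


def jarzynski_estimate(works, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Jarzynski free-energy estimate -kBT ln <exp(-W/kBT)> in kcal/mol.

    ``works`` are in kcal/mol; the exponential average is stabilized by
    shifting with the sample minimum (log-sum-exp).
    """
    w = np.asarray(works, float)
    if w.size == 0:
        raise ValueError("empty work sample")
    kbt_kcal = kbt(temperature) / PN_NM_PER_KCAL_MOL
    w_min = float(np.min(w))
    return w_min - kbt_kcal * float(
        np.log(np.mean(np.exp(-(w - w_min) / kbt_kcal)))
    )


def work_distribution_summary(works, temperature: float = DEFAULT_TEMPERATURE) -> WorkDistributionSummary:
    """Summary of a work sample (kcal/mol): moments plus both estimators."""
    mean, sd, se = mean_work_estimate(works)
    return WorkDistributionSummary(
        n=len(np.atleast_1d(works)),
        mean=mean,
        sd=sd,
        se=se,
        mean_work_estimate=mean,
        jarzynski_estimate=jarzynski_estimate(works, temperature),
        temperature=temperature,
    )


def ensemble_profile(profiles: list[FreeEnergyProfile], n_grid: int = 400) -> FreeEnergyProfile:
    """Pointwise mean and SD of several work profiles on a common grid.

    Profiles are linearly interpolated onto a uniform grid spanning the
    intersection of their extension ranges; requires at least two profiles
    with overlapping ranges.
    """
    if len(profiles) < 2:
        raise ValueError("ensemble profile requires at least 2 profiles")
    lo = max(float(p.extension[0]) for p in profiles)
    hi = min(float(p.extension[-1]) for p in profiles)
    if hi <= lo:
        raise ValueError("profiles have disjoint extension ranges")
    grid = np.linspace(lo, hi, n_grid)
    stack = np.vstack([np.interp(grid, p.extension, p.work) for p in profiles])
    return FreeEnergyProfile(
        extension=grid,
        work=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=1),
        n_traces=len(profiles),
    )
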