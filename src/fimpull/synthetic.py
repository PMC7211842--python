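"""Synthetic pulling traces with exactly known ground truth.

The AFM generator emulates the experimental construct: a polyprotein of
four I91 titin markers flanking one FimG pilus subunit, pulled at constant
stage speed through a Hookean cantilever.  Unfolding events are placed by
force threshold -- each branch follows its worm-like chain until the force
reaches that domain's sampled unfolding strength, then the contour length
grows by the domain's sampled increment -- so every branch model, peak
force, increment and quasi-static transition work is known exactly.  The
default distributions are the measured ones for this construct
(I91: force N(219, 33) pN, increment N(34, 3) nm; FimG: N(422, 69) pN,
N(48, 11) nm), with a 15 pN/nm cantilever retracted at 400 nm/s and sampled
every 0.2 ms.

Traces include a pushed contact region before the origin, a detachment
peak taller than all unfolding peaks, a flat zero-force tail, the
cantilever convolution (recorded extension = stage position - F/k), and
additive Gaussian force noise.  A defect catalogue produces traces that
each violate exactly one acceptance criterion, for filter testing.

The SMD generator rides an extensible freely-jointed-chain backbone with
localized rip excursions of prescribed area (the injected rip works) and
Ornstein-Uhlenbeck force noise.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import optimize

from .constants import DEFAULT_TEMPERATURE
from .polymer import FJCParams, WLCParams, fjc_extension, wlc_force, wlc_stretch_energy
from .trace_io import DatasetManifest, ManifestEntry, Trace, write_manifest, write_trace

__all__ = [
    "SyntheticSpec",
    "SMDSpec",
    "TrueEvent",
    "GroundTruth",
    "SMDGroundTruth",
    "DEFECT_KINDS",
    "DEFECT_EXPECTED_REASON",
    "generate_afm_trace",
    "generate_smd_trace",
    "generate_afm_dataset",
    "generate_smd_dataset",
    "generate_dataset",
]

#: defect kind -> acceptance criterion it is constructed to violate
DEFECT_EXPECTED_REASON = {
    "short_tail": "tail_length",
    "sloped_tail": "tail_slope",
    "too_few_markers": "i91_count",
    "too_many_markers": "i91_count",
    "no_fimg_peak": "fimg_count",
    "weak_detachment": "detachment_tallest",
    "noisy_branch": "rmse",
    "bad_persistence": "persistence_length",
    "bad_increment": "i91_increment",
}

DEFECT_KINDS = ("none",) + tuple(DEFECT_EXPECTED_REASON)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of the AFM trace generator."""

    # instrument
    spring_constant: float = 15.0        # pN/nm
    pulling_speed: float = 400.0         # nm/s
    sampling_interval: float = 2e-4      # s (0.2 ms)
    # construct
    n_i91: int = 4
    n_fimg: int = 1
    i91_force_mean: float = 219.0        # pN
    i91_force_sd: float = 33.0
    fimg_force_mean: float = 422.0
    fimg_force_sd: float = 69.0
    i91_increment_mean: float = 34.0     # nm
    i91_increment_sd: float = 3.0
    fimg_increment_mean: float = 48.0
    fimg_increment_sd: float = 11.0
    persistence_length: float = 0.4      # nm
    folded_contour: float = 60.0         # nm, first-branch contour length
    temperature: float = DEFAULT_TEMPERATURE
    # trace dressing
    noise_sd: float = 8.0                # pN, raw force noise
    contact_offset: float = 30.0         # nm, absolute extension of the origin
    contact_depth: float = 200.0         # pN, push force at contact start
    contact_length: float = 5.0          # nm
    detachment_factor: float = 1.3       # x tallest unfolding peak
    tail_length: float = 150.0           # nm of flat tail past detachment
    # testing hooks
    defect: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.defect not in DEFECT_KINDS:
            raise ValueError(f"unknown defect kind {self.defect!r}; valid: {DEFECT_KINDS}")
        for name in ("i91_force_sd", "fimg_force_sd", "i91_increment_sd",
                     "fimg_increment_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_i91 < 0 or self.n_fimg < 0:
            raise ValueError("domain counts must be non-negative")


@dataclass(frozen=True)
class TrueEvent:
    """Ground truth for one unfolding transition."""

    label: str
    force: float            # pN, true unfolding (peak) force
    x1: float               # nm, extension at the rip
    x2: float               # nm, landing extension on the next branch
    increment: float        # nm, contour-length gain
    w_rip: float            # pN·nm, quasi-static trapezoid work
    dg_s: float             # pN·nm, stretch free-energy change
    w_unfold: float         # pN·nm, w_rip - dg_s


@dataclass
class GroundTruth:
    """Everything the AFM generator knows about the trace it produced."""

    events: list[TrueEvent]
    branch_params: list[WLCParams]      # one per branch, in order
    detachment_force: float             # pN
    detachment_extension: float         # nm
    origin_offset: float                # nm, absolute extension of the origin


@dataclass
class SMDGroundTruth:
    fjc_params: FJCParams
    rip_centers: list[float]        # nm
    rip_widths: list[float]         # nm
    rip_works: list[float]          # pN·nm, injected areas within the trace range
    total_work: float               # pN·nm


def _wlc_inverse(force: float, p: WLCParams) -> float:
    """Extension at which the WLC reaches the given force (brentq)."""
    hi = p.contour_length * (1.0 - 1e-9)
    if wlc_force(hi, p) < force:
        raise ValueError(f"force {force} pN unreachable below 0.99 L for {p}")
    return optimize.brentq(
        lambda x: wlc_force(x, p) - force, 0.0, hi, xtol=1e-12, rtol=1e-14
    )


def _balance_extension(z: float, p: WLCParams, k: float) -> float:
    """Chain extension satisfying the cantilever force balance at stage z:
    wlc(x) + k x = k z (recorded extension = stage - F/k)."""
    hi = min(z, p.contour_length * (1.0 - 1e-9))
    return optimize.brentq(
        lambda x: wlc_force(x, p) + k * x - k * z, 0.0, hi, xtol=1e-12, rtol=1e-14
    )


def _sample_events(spec: SyntheticSpec, rng: np.random.Generator):
    """Draw per-domain unfolding forces and increments, applying the defect."""
    n_i91, n_fimg = spec.n_i91, spec.n_fimg
    i91_force_cap = None
    fimg_force = None

    defect = spec.defect
    fimg_force_floor = None
    if defect == "too_few_markers":
        # marker-count probes pin the FimG draw clear of the barrier so the
        # trace violates only the criterion it is built for
        n_i91, i91_force_cap, fimg_force_floor = 2, 290.0, 330.0
    elif defect == "too_many_markers":
        n_i91, i91_force_cap, fimg_force_floor = 6, 290.0, 330.0
    elif defect in ("noisy_branch", "bad_increment", "weak_detachment", "sloped_tail",
                    "short_tail", "bad_persistence"):
        i91_force_cap, fimg_force_floor = 290.0, 330.0
    elif defect == "no_fimg_peak":
        # FimG strength drawn below the classification barrier: the
        # misattribution failure mode
        fimg_force, i91_force_cap = 280.0, 290.0

    i91_f = rng.normal(spec.i91_force_mean, spec.i91_force_sd, n_i91)
    i91_f = np.maximum(i91_f, 30.0)
    if i91_force_cap is not None:
        i91_f = np.minimum(i91_f, i91_force_cap)
    if defect == "bad_increment":
        i91_s = rng.normal(50.0, 0.5, n_i91)
    else:
        i91_s = np.maximum(rng.normal(spec.i91_increment_mean, spec.i91_increment_sd, n_i91), 1.0)

    fimg_f = rng.normal(spec.fimg_force_mean, spec.fimg_force_sd, n_fimg)
    fimg_f = np.maximum(fimg_f, 30.0)
    if fimg_force_floor is not None:
        fimg_f = np.maximum(fimg_f, fimg_force_floor)
    if fimg_force is not None:
        fimg_f = np.full(n_fimg, fimg_force)
    fimg_s = np.maximum(rng.normal(spec.fimg_increment_mean, spec.fimg_increment_sd, n_fimg), 1.0)

    events = [("I91", f, s) for f, s in zip(i91_f, i91_s)]
    events += [("FimG", f, s) for f, s in zip(fimg_f, fimg_s)]
    # threshold placement: the weakest remaining domain unfolds first
    events.sort(key=lambda e: e[1])
    return events


def generate_afm_trace(spec: SyntheticSpec) -> tuple[Trace, GroundTruth]:
    """Generate one AFM-like sawtooth trace and its ground truth.

    Deterministic given ``spec.seed``.  The stage coordinate advances in
    steps of pulling_speed x sampling_interval; for each branch the force
    balance F = wlc(x), x = z - F/k is solved on a dense grid and sampled
    onto the stage grid by interpolation.
    """
    rng = np.random.default_rng(spec.seed)
    events = _sample_events(spec, rng)
    P = 1.5 if spec.defect == "bad_persistence" else spec.persistence_length
    k = spec.spring_constant
    tail_length = 10.0 if spec.defect == "short_tail" else spec.tail_length
    det_factor = 0.95 if spec.defect == "weak_detachment" else spec.detachment_factor

    # branch contour lengths
    contours = [spec.folded_contour]
    for _, _, s in events:
        contours.append(contours[-1] + s)
    params = [WLCParams(P, L, spec.temperature) for L in contours]

    # event geometry and ground-truth works
    true_events: list[TrueEvent] = []
    z_rips: list[float] = []
    x_land = 0.0
    for i, (label, f_unfold, s) in enumerate(events):
        p1, p2 = params[i], params[i + 1]
        x1 = _wlc_inverse(min(f_unfold, wlc_force(p1.contour_length * 0.99, p1)), p1)
        z_rip = x1 + wlc_force(x1, p1) / k
        x2 = _balance_extension(z_rip, p2, k)
        f1 = wlc_force(x1, p1)
        f2 = wlc_force(x2, p2)
        w_rip = 0.5 * (f1 + f2) * (x2 - x1)
        dg_s = wlc_stretch_energy(x2, p2) - wlc_stretch_energy(x1, p1)
        true_events.append(TrueEvent(label, f1, x1, x2, s, w_rip, dg_s, w_rip - dg_s))
        z_rips.append(z_rip)
        x_land = x2

    peak_forces = [e.force for e in true_events]
    f_det = det_factor * (max(peak_forces) if peak_forces else 300.0)
    p_last = params[-1]
    x_det = _wlc_inverse(min(f_det, wlc_force(p_last.contour_length * 0.99, p_last)), p_last)
    z_det = x_det + wlc_force(x_det, p_last) / k

    # assemble samples on the uniform stage grid
    dz = spec.pulling_speed * spec.sampling_interval
    z0 = -spec.contact_length
    z_end = z_det + tail_length
    z = np.arange(z0, z_end, dz)
    ext = np.empty_like(z)
    force = np.empty_like(z)

    contact = z < 0
    ext[contact] = spec.contact_offset + z[contact]
    force[contact] = (spec.contact_depth / spec.contact_length) * z[contact]

    branch_starts = [0.0] + z_rips
    branch_ends = z_rips + [z_det]
    # the spike goes on the first branch: it is the longest, and its peak
    # force sits far below the I91/FimG barrier, so the contaminated fit
    # cannot change the peak grouping
    noisy_idx = 0 if spec.defect == "noisy_branch" else None

    for i, (za, zb) in enumerate(zip(branch_starts, branch_ends)):
        sel = (z >= za) & (z < zb)
        if not np.any(sel):
            continue
        p = params[i]
        x_lo = _balance_extension(max(za, 1e-9), p, k) if za > 0 else 0.0
        x_hi = _balance_extension(zb, p, k)
        x_grid = np.linspace(x_lo, x_hi, 2500)
        f_grid = np.asarray(wlc_force(np.minimum(x_grid, p.contour_length * (1 - 1e-12)), p))
        z_grid = x_grid + f_grid / k
        x_sel = np.interp(z[sel], z_grid, x_grid)
        ext[sel] = spec.contact_offset + x_sel
        force[sel] = np.interp(z[sel], z_grid, f_grid)
        if i == noisy_idx:
            # a sawtooth spike the monotone WLC cannot follow (fit rms well
            # above the quality bound).  The rise is instantaneous (upward
            # steps never register as transitions) and the decay, 40 pN/nm,
            # stays below the transition threshold, so only the fit-quality
            # criterion is violated
            span = x_hi - x_lo
            decay_rate = 40.0
            # amplitude sized so the residual rms, amp^(3/2)/sqrt(3*decay*span),
            # lands near 160 pN -- well above the fit-quality bound
            amp = min((160.0**2 * 3.0 * decay_rate * span) ** (1.0 / 3.0),
                      decay_rate * 0.6 * span)
            d = x_sel - (x_lo + 0.15 * span)
            force[sel] += np.where((d >= 0) & (d <= amp / decay_rate),
                                   amp - decay_rate * d, 0.0)

    tail = z >= z_det
    ext[tail] = spec.contact_offset + z[tail]
    force[tail] = 0.0
    if spec.defect == "sloped_tail":
        force[tail] = 0.05 * (z[tail] - z_det)

    if spec.noise_sd > 0:
        force = force + rng.normal(0.0, spec.noise_sd, len(force))

    time = np.arange(len(z)) * spec.sampling_interval
    trace = Trace(
        kind="afm",
        time=time,
        extension=ext,
        force=force,
        metadata={
            "spring_constant_pN_per_nm": k,
            "pulling_speed_nm_per_s": spec.pulling_speed,
            "sampling_interval_s": spec.sampling_interval,
            "temperature_K": spec.temperature,
            "source_id": f"afm_seed{spec.seed}_{spec.defect}",
            "defect": spec.defect,
        },
    )
    truth = GroundTruth(
        events=true_events,
        branch_params=params,
        detachment_force=wlc_force(x_det, p_last),
        detachment_extension=x_det,
        origin_offset=spec.contact_offset,
    )
    return trace, truth


@dataclass(frozen=True)
class SMDSpec:
    """Parameterization of the steered-MD-like trace generator.

    The backbone is the extensible FJC of the fully unravelled chain held by
    its disulfide loop; rips are Gaussian force excursions in extension with
    prescribed areas (the injected unfolding works).  The default three rips
    emulate the observed sequence -- a double peak from the two
    linker-strand rips followed by the intra-sheet rip -- with areas chosen
    so the cumulative profile plateaus near 540 kcal/mol after the double
    peak and ends near 1060 kcal/mol.
    """

    pulling_speed: float = 1.0          # nm/ns
    sampling_interval: float = 0.01     # ns
    duration: float = 45.0              # ns
    kuhn_length: float = 0.8            # nm
    contour_length: float = 40.0        # nm
    stretch_modulus: float = 15000.0    # pN
    temperature: float = DEFAULT_TEMPERATURE
    rip_centers: tuple[float, ...] = (5.5, 9.0, 22.0)     # nm
    rip_widths: tuple[float, ...] = (0.8, 0.8, 1.2)       # nm (Gaussian sigma)
    rip_works: tuple[float, ...] = (2000.0, 1730.0, 3600.0)  # pN·nm
    rip_work_rel_sd: float = 0.09       # per-trace multiplicative spread
    force_noise_sd: float = 30.0        # pN (OU stationary SD)
    force_noise_tau: float = 0.1        # ns (OU correlation time)
    extension_jitter_sd: float = 0.03   # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.rip_centers) == len(self.rip_widths) == len(self.rip_works)):
            raise ValueError("rip_centers, rip_widths and rip_works must have equal lengths")
        order = np.argsort(self.rip_centers)
        c = np.asarray(self.rip_centers)[order]
        w = np.asarray(self.rip_widths)[order]
        if np.any(c[1:] - c[:-1] < 2.0 * (w[1:] + w[:-1])):
            raise ValueError("rip windows overlap")


def _ou_noise(rng: np.random.Generator, n: int, sd: float, tau: float, dt: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck noise sampled at interval dt."""
    if sd == 0:
        return np.zeros(n)
    a = math.exp(-dt / tau)
    innov_sd = sd * math.sqrt(1.0 - a * a)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, innov_sd, n - 1)
    for i in range(1, n):
        out[i] = a * out[i - 1] + shocks[i - 1]
    return out


def generate_smd_trace(spec: SMDSpec) -> tuple[Trace, SMDGroundTruth]:
    """Generate one SMD-like pull trace and its ground truth.

    The force field is conservative in extension (FJC baseline + Gaussian
    rip bumps), so the injected work of each rip equals its bump area over
    the trace's extension range exactly, regardless of extension jitter.
    """
    rng = np.random.default_rng(spec.seed)
    fjc = FJCParams(spec.kuhn_length, spec.contour_length, spec.stretch_modulus,
                    spec.temperature)
    n = int(round(spec.duration / spec.sampling_interval)) + 1
    t = np.arange(n) * spec.sampling_interval
    x = spec.pulling_speed * t
    if spec.extension_jitter_sd > 0:
        jitter = _ou_noise(rng, n, spec.extension_jitter_sd, spec.force_noise_tau,
                           spec.sampling_interval)
        jitter[0] = 0.0
        x = np.maximum(x + jitter, 0.0)
    x_max = float(x.max())

    # baseline by inverse interpolation of the closed-form x(F)
    f_grid = np.linspace(0.0, 5000.0, 4000)
    x_of_f = np.asarray(fjc_extension(f_grid, fjc))
    baseline = np.interp(x, x_of_f, f_grid)

    areas = np.asarray(spec.rip_works, float)
    if spec.rip_work_rel_sd > 0 and len(areas):
        areas = areas * (1.0 + rng.normal(0.0, spec.rip_work_rel_sd, len(areas)))
    force = baseline.copy()
    realized: list[float] = []
    for c, w, a in zip(spec.rip_centers, spec.rip_widths, areas):
        force += a / (w * math.sqrt(2 * math.pi)) * np.exp(-((x - c) ** 2) / (2 * w * w))
        # injected work actually inside [0, x_max]
        lo = 0.5 * (1 + math.erf((0.0 - c) / (w * math.sqrt(2))))
        hi = 0.5 * (1 + math.erf((x_max - c) / (w * math.sqrt(2))))
        realized.append(float(a) * (hi - lo))
    force += _ou_noise(rng, n, spec.force_noise_sd, spec.force_noise_tau,
                       spec.sampling_interval)

    trace = Trace(
        kind="smd",
        time=t,
        extension=x,
        force=force,
        metadata={
            "pulling_speed_nm_per_ns": spec.pulling_speed,
            "sampling_interval_ns": spec.sampling_interval,
            "temperature_K": spec.temperature,
            "source_id": f"smd_seed{spec.seed}",
        },
    )
    truth = SMDGroundTruth(
        fjc_params=fjc,
        rip_centers=list(spec.rip_centers),
        rip_widths=list(spec.rip_widths),
        rip_works=realized,
        total_work=float(sum(realized)),
    )
    return trace, truth


def _child_seed(master_seed: int, i: int) -> int:
    return (master_seed * 1000003 + 7919 * i + 1) % (2**31 - 1)


def generate_afm_dataset(
    spec: SyntheticSpec,
    n_good: int,
    defect_counts: dict[str, int] | None = None,
    master_seed: int = 0,
) -> list[tuple[Trace, GroundTruth]]:
    """Generate an in-memory AFM dataset: good traces plus defective ones.

    Per-trace seeds are derived from the master seed by fixed arithmetic, so
    the dataset is reproducible trace by trace.
    """
    if n_good < 0:
        raise ValueError("n_good must be non-negative")
    out = []
    i = 0
    for _ in range(n_good):
        out.append(generate_afm_trace(replace(spec, defect="none",
                                              seed=_child_seed(master_seed, i))))
        i += 1
    for kind, count in (defect_counts or {}).items():
        for _ in range(count):
            out.append(generate_afm_trace(replace(spec, defect=kind,
                                                  seed=_child_seed(master_seed, i))))
            i += 1
    return out


def generate_smd_dataset(
    spec: SMDSpec, n_traces: int, master_seed: int = 0
) -> list[tuple[Trace, SMDGroundTruth]]:
    return [
        generate_smd_trace(replace(spec, seed=_child_seed(master_seed, i)))
        for i in range(n_traces)
    ]


def generate_dataset(
    outdir,
    spec: SyntheticSpec | None = None,
    n_good: int = 10,
    defect_counts: dict[str, int] | None = None,
    master_seed: int = 0,
) -> DatasetManifest:
    """Write an AFM dataset to disk: trace TSVs, manifest, ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or SyntheticSpec()
    pairs = generate_afm_dataset(spec, n_good, defect_counts, master_seed)

    entries: list[ManifestEntry] = []
    sidecar_rows: list[str] = []
    for i, (trace, truth) in enumerate(pairs):
        name = f"trace_{i:04d}.tsv"
        trace.metadata["source_id"] = f"trace_{i:04d}"
        write_trace(trace, outdir / name)
        entries.append(ManifestEntry(path=name, kind="afm"))
        for j, ev in enumerate(truth.events):
            sidecar_rows.append(
                f"trace_{i:04d}\t{j}\t{ev.label}\t{ev.force:.6g}\t"
                f"{ev.increment:.6g}\t{ev.w_unfold:.8g}"
            )
    manifest = DatasetManifest(entries=entries, notes=f"synthetic AFM dataset, master_seed={master_seed}")
    write_manifest(manifest, outdir / "manifest.json")
    header = "trace_id\tevent\tlabel\ttrue_force\ttrue_increment\ttrue_work"
    (outdir / "ground_truth.tsv").write_text("\n".join([header] + sidecar_rows) + "\n")
    return manifest
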