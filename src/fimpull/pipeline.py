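"""End-to-end orchestration: datasets in, tables and reports out.

These functions are the programmatic surface the command-line tool, the
analysis drivers and the tests all share.  Each stage is deterministic:
manifest + config + seed fully determine every output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .energetics import (
    FreeEnergyProfile,
    WorkDistributionSummary,
    ensemble_profile,
    fit_smd_tail,
    smd_work_profile,
    trace_transition_works,
    work_distribution_summary,
)
from .segmentation import AnalysisError, AnalyzerConfig, SegmentedTrace, segment_trace
from .trace_io import DatasetManifest, Trace, read_manifest, read_trace

__all__ = [
    "AFMRunReport",
    "SMDRunReport",
    "analyze_afm_traces",
    "analyze_smd_traces",
    "load_manifest_traces",
    "run_analyze_afm",
    "run_analyze_smd",
    "normal_fit",
    "summarize_results",
]


@dataclass
class AFMRunReport:
    """Bookkeeping of one AFM analysis run.

    ``trace_rows`` has one row per input trace (accepted flag + primary
    rejection reason); ``transitions`` one row per unfolding transition of
    every accepted trace; ``label_stats`` the per-label peak-force and
    increment statistics.  ``rejected_by_reason`` counts primary reasons.
    """

    config: AnalyzerConfig
    n_total: int = 0
    n_accepted: int = 0
    rejected_by_reason: dict = field(default_factory=dict)
    trace_rows: pd.DataFrame | None = None
    transitions: pd.DataFrame | None = None
    label_stats: pd.DataFrame | None = None
    fimg_work: WorkDistributionSummary | None = None
    segmented: list[SegmentedTrace] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return self.n_total - self.n_accepted


def analyze_afm_traces(traces, cfg: AnalyzerConfig | None = None) -> AFMRunReport:
    """Run the full analyzer on an iterable of AFM traces.

    Traces that cannot be segmented at all (no contact region, no
    transitions) are rejected with that reason; segmentable traces carry the
    first failing acceptance criterion.  Unfolding works are computed for
    accepted traces only.
    """
    cfg = cfg or AnalyzerConfig()
    rows = []
    transition_rows = []
    report = AFMRunReport(config=cfg)
    for trace in traces:
        trace_id = str(trace.metadata.get("source_id", f"trace_{report.n_total}"))
        report.n_total += 1
        try:
            seg = segment_trace(trace, cfg)
        except AnalysisError as err:
            reason = "no_contact_region" if "contact" in str(err) else "no_transitions"
            rows.append({"trace_id": trace_id, "accepted": False, "reason": reason})
            report.rejected_by_reason[reason] = report.rejected_by_reason.get(reason, 0) + 1
            continue
        if not seg.report.accepted:
            reason = seg.report.rejection_reason
            rows.append({"trace_id": trace_id, "accepted": False, "reason": reason})
            report.rejected_by_reason[reason] = report.rejected_by_reason.get(reason, 0) + 1
            continue
        report.n_accepted += 1
        report.segmented.append(seg)
        rows.append({"trace_id": trace_id, "accepted": True, "reason": ""})
        for tw in trace_transition_works(seg):
            transition_rows.append({
                "trace_id": trace_id,
                "label": tw.label,
                "x1_nm": tw.x1,
                "x2_nm": tw.x2,
                "peak_force_pN": seg.transitions[tw.index].peak_force,
                "increment_nm": seg.transitions[tw.index].contour_increment,
                "w_rip_pN_nm": tw.w_rip,
                "dg_s_pN_nm": tw.dg_s,
                "w_unfold_pN_nm": tw.w_unfold,
                "w_unfold_kcal_mol": tw.w_unfold_kcal_mol,
            })

    report.trace_rows = pd.DataFrame(rows, columns=["trace_id", "accepted", "reason"])
    report.transitions = pd.DataFrame(
        transition_rows,
        columns=["trace_id", "label", "x1_nm", "x2_nm", "peak_force_pN",
                 "increment_nm", "w_rip_pN_nm", "dg_s_pN_nm", "w_unfold_pN_nm",
                 "w_unfold_kcal_mol"],
    )

    stats = []
    for label in ("I91", "FimG"):
        sub = report.transitions[report.transitions["label"] == label]
        if len(sub) == 0:
            continue
        stats.append({
            "label": label,
            "n": len(sub),
            "peak_force_mean_pN": sub["peak_force_pN"].mean(),
            "peak_force_sd_pN": sub["peak_force_pN"].std(ddof=1),
            "increment_mean_nm": sub["increment_nm"].mean(),
            "increment_sd_nm": sub["increment_nm"].std(ddof=1),
            "w_unfold_mean_kcal_mol": sub["w_unfold_kcal_mol"].mean(),
            "w_unfold_sd_kcal_mol": sub["w_unfold_kcal_mol"].std(ddof=1),
        })
    report.label_stats = pd.DataFrame(stats)

    fimg_w = report.transitions.loc[report.transitions["label"] == "FimG",
                                    "w_unfold_kcal_mol"].to_numpy()
    if len(fimg_w):
        report.fimg_work = work_distribution_summary(fimg_w, cfg.temperature)
    return report


@dataclass
class SMDRunReport:
    n_total: int = 0
    n_ok: int = 0
    works: pd.DataFrame | None = None          # per-trace final W_unfold
    profiles: list[FreeEnergyProfile] = field(default_factory=list)
    ensemble: FreeEnergyProfile | None = None
    summary: WorkDistributionSummary | None = None
    failures: list[tuple[str, str]] = field(default_factory=list)


def analyze_smd_traces(
    traces,
    grid_step: float = 0.1,
    temperature: float = 300.0,
    tail_kwargs: dict | None = None,
) -> SMDRunReport:
    """Per-trace FJC tail fit and work profile, plus the ensemble summary.

    A trace whose stretch tail cannot be fitted is flagged and excluded; the
    run continues with the rest.
    """
    report = SMDRunReport()
    rows = []
    for trace in traces:
        trace_id = str(trace.metadata.get("source_id", f"smd_{report.n_total}"))
        report.n_total += 1
        try:
            fjc = fit_smd_tail(trace, **(tail_kwargs or {}))
            profile = smd_work_profile(trace, fjc, grid_step=grid_step)
        except (AnalysisError, ValueError) as err:
            report.failures.append((trace_id, str(err)))
            continue
        report.n_ok += 1
        report.profiles.append(profile)
        rows.append({
            "trace_id": trace_id,
            "w_unfold_final_kcal_mol": profile.final_work,
            "fjc_kuhn_nm": fjc.kuhn_length,
            "fjc_contour_nm": fjc.contour_length,
            "fjc_modulus_pN": fjc.stretch_modulus,
        })
    report.works = pd.DataFrame(
        rows, columns=["trace_id", "w_unfold_final_kcal_mol", "fjc_kuhn_nm",
                       "fjc_contour_nm", "fjc_modulus_pN"],
    )
    if report.n_ok >= 2:
        report.ensemble = ensemble_profile(report.profiles)
    elif report.n_ok == 1:
        report.ensemble = report.profiles[0]
    if report.n_ok >= 1:
        report.summary = work_distribution_summary(
            report.works["w_unfold_final_kcal_mol"].to_numpy(), temperature
        )
    return report


def load_manifest_traces(manifest_path) -> list[Trace]:
    """Read every trace listed in a dataset manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    manifest: DatasetManifest = read_manifest(manifest_path)
    return [
        read_trace(manifest_path.parent / e.path, kind=e.kind,
                   metadata_overrides=e.metadata_overrides)
        for e in manifest.entries
    ]


def _write_rejection_log(report: AFMRunReport, path: Path) -> None:
    lines = []
    for _, row in report.trace_rows.iterrows():
        if not row["accepted"]:
            lines.append(f"{row['trace_id']}\tREJECT\t{row['reason']}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def run_analyze_afm(manifest_path, outdir, cfg: AnalyzerConfig | None = None) -> AFMRunReport:
    """Analyze an on-disk AFM dataset and write all result tables.

    Writes: per-trace acceptance table, transitions table, per-label
    statistics, rejection log, run summary JSON and the full effective
    config snapshot.
    """
    cfg = cfg or AnalyzerConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = analyze_afm_traces(load_manifest_traces(manifest_path), cfg)

    report.trace_rows.to_csv(outdir / "traces.tsv", sep="\t", index=False)
    report.transitions.to_csv(outdir / "transitions.tsv", sep="\t", index=False)
    report.label_stats.to_csv(outdir / "label_stats.tsv", sep="\t", index=False)
    _write_rejection_log(report, outdir / "rejections.log")
    cfg.to_yaml(outdir / "analyzer_config.yaml")
    summary = {
        "n_total": report.n_total,
        "n_accepted": report.n_accepted,
        "rejected_by_reason": report.rejected_by_reason,
    }
    if report.fimg_work is not None:
        summary["fimg_work_kcal_mol"] = {
            "n": report.fimg_work.n,
            "mean": report.fimg_work.mean,
            "sd": report.fimg_work.sd,
            "se": report.fimg_work.se,
            "jarzynski": report.fimg_work.jarzynski_estimate,
        }
    (outdir / "run_report.json").write_text(json.dumps(summary, indent=2) + "\n")
    return report


def run_analyze_smd(manifest_path, outdir, grid_step: float = 0.1,
                    tail_kwargs: dict | None = None) -> SMDRunReport:
    """Analyze an on-disk SMD dataset and write works, profiles and summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = analyze_smd_traces(load_manifest_traces(manifest_path),
                                grid_step=grid_step, tail_kwargs=tail_kwargs)
    report.works.to_csv(outdir / "smd_works.tsv", sep="\t", index=False)
    if report.ensemble is not None:
        prof = pd.DataFrame({
            "extension_nm": report.ensemble.extension,
            "w_unfold_mean_kcal_mol": report.ensemble.work,
        })
        if report.ensemble.sd is not None:
            prof["w_unfold_sd_kcal_mol"] = report.ensemble.sd
        prof.to_csv(outdir / "smd_profile.tsv", sep="\t", index=False)
    summary = {
        "n_total": report.n_total,
        "n_ok": report.n_ok,
        "failures": report.failures,
    }
    if report.summary is not None:
        summary["work_kcal_mol"] = {
            "n": report.summary.n,
            "mean": report.summary.mean,
            "sd": report.summary.sd,
            "se": report.summary.se,
            "jarzynski": report.summary.jarzynski_estimate,
        }
    (outdir / "smd_report.json").write_text(json.dumps(summary, indent=2) + "\n")
    return report


def normal_fit(values) -> tuple[float, float]:
    """Maximum-likelihood normal fit (mean, SD with n denominator)."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("cannot fit a normal distribution to an empty sample")
    return float(np.mean(v)), float(np.std(v, ddof=0))


def summarize_results(results_dir, bin_width_force: float = 25.0,
                      bin_width_work: float = 50.0) -> pd.DataFrame:
    """Distribution summaries of a prior AFM run: histograms + normal fits.

    Reads ``transitions.tsv`` from a results directory and returns (and
    writes back) per-label normal fits of peak force and unfolding work;
    histogram tables are written alongside.  Rows are order-invariant.
    """
    results_dir = Path(results_dir)
    tr = pd.read_csv(results_dir / "transitions.tsv", sep="\t")
    rows = []
    hist_rows = []
    for label, sub in sorted(tr.groupby("label"), key=lambda kv: kv[0]):
        for quantity, col, width in (
            ("peak_force_pN", "peak_force_pN", bin_width_force),
            ("w_unfold_kcal_mol", "w_unfold_kcal_mol", bin_width_work),
        ):
            vals = np.sort(sub[col].to_numpy())
            mu, sigma = normal_fit(vals)
            rows.append({
                "label": label, "quantity": quantity, "n": len(vals),
                "mean": mu, "sd": sigma, "degenerate": bool(len(vals) < 2 or sigma == 0.0),
            })
            lo = np.floor(vals.min() / width) * width
            edges = np.arange(lo, vals.max() + width, width)
            if len(edges) < 2:
                edges = np.array([lo, lo + width])
            counts, edges = np.histogram(vals, bins=edges)
            for c, e0, e1 in zip(counts, edges[:-1], edges[1:]):
                hist_rows.append({"label": label, "quantity": quantity,
                                  "bin_lo": e0, "bin_hi": e1, "count": int(c)})
    fits = pd.DataFrame(rows)
    fits.to_csv(results_dir / "distribution_fits.tsv", sep="\t", index=False)
    pd.DataFrame(hist_rows).to_csv(results_dir / "histograms.tsv", sep="\t", index=False)
    return fits
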