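"""End-to-end pipeline: simulate -> (render/detect) -> metrics -> bursts ->
coupling -> compare -> report.

A run is driven by a single configuration mapping and a master seed, echoed
verbatim into ``manifest.json``; rerunning from the manifest reproduces every
TSV/JSON output byte for byte.  All stage boundaries emit one structured log
line with input/output counts so the pipeline's filters are auditable.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .bursts import network_burst_rate, session_bursts, detect_network_bursts
from .coupling import session_coupling_distribution
from .detection import bandpass_filter, detect_spikes
from .io import (
    read_json,
    read_session,
    write_ground_truth,
    write_json,
    write_raw,
    write_session,
)
from .metrics import drug_response_ratio, electrode_metrics, session_mfr
from .stats import (
    comparisons_to_frame,
    condition_genotype_comparison,
    kruskal_wallis,
    paired_t,
)
from .synthetic import default_spike_template, make_cohort, render_raw_traces
from .types import (
    BurstParams,
    CCGParams,
    DetectionParams,
    SessionRecord,
    SimulationConfig,
)

log = logging.getLogger("meanet")

_TSV_KW = dict(sep="\t", index=False, float_format="%.6g")


def _session_tag(session: SessionRecord) -> str:
    return f"{session.assembloid_id}_{session.condition}"


def build_configs(config: Mapping) -> dict:
    """Materialize parameter bundles from a raw configuration mapping."""
    sim_by_genotype = {
        genotype: SimulationConfig(**kwargs)
        for genotype, kwargs in config.get("genotypes", {}).items()
    }
    return {
        "sim_by_genotype": sim_by_genotype,
        "n_assembloids": int(config.get("n_assembloids", 4)),
        "conditions": list(config.get("conditions", ["BL", "GABA", "PTX"])),
        "render_raw": bool(config.get("render_raw", False)),
        "detection": DetectionParams(**config.get("detection", {})),
        "bursts": BurstParams(**config.get("bursts", {})),
        "ccg": CCGParams(**config.get("ccg", {})),
        "min_rate_hz": float(config.get("metrics", {}).get("min_rate_hz", 0.1)),
        "mfr_scope": str(config.get("metrics", {}).get("mfr_scope", "all")),
        "log_offset": float(config.get("metrics", {}).get("log_offset", 0.0)),
        "pooling": str(config.get("comparison", {}).get("pooling", "pooled_pairs")),
        "noise_sd": float(config.get("render", {}).get("noise_sd", 1.0)),
        "template_amplitude": float(config.get("render", {}).get("template_amplitude", 8.0)),
        "seed": int(config.get("seed", 0)),
    }


def stage_simulate(cfg: dict, run_dir: Path) -> list[SessionRecord]:
    """Simulate the cohort; optionally render raw traces and re-detect spikes."""
    sessions_dir = run_dir / "sessions"
    truth_dir = run_dir / "truth"
    sessions_dir.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)
    sessions, truths = make_cohort(
        cfg["sim_by_genotype"], cfg["n_assembloids"], cfg["conditions"], seed=cfg["seed"]
    )
    out_sessions = []
    for session in sessions:
        tag = _session_tag(session)
        truth = truths[(session.assembloid_id, session.condition)]
        write_ground_truth(truth, truth_dir / f"{tag}.truth.tsv",
                           truth_dir / f"{tag}.truth.json")
        if cfg["render_raw"]:
            raw_dir = run_dir / "raw"
            raw_dir.mkdir(exist_ok=True)
            sim = cfg["sim_by_genotype"][session.genotype]
            template = default_spike_template(
                sim.sampling_rate_hz, cfg["template_amplitude"] * cfg["noise_sd"]
            )
            raw = render_raw_traces(session, template, cfg["noise_sd"],
                                    sim.sampling_rate_hz, seed=cfg["seed"])
            write_raw(raw, raw_dir / f"{tag}.h5")
            filtered = bandpass_filter(raw, cfg["detection"])
            trains = detect_spikes(filtered, cfg["detection"])
            session = SessionRecord(
                assembloid_id=session.assembloid_id, genotype=session.genotype,
                condition=session.condition, duration_s=session.duration_s,
                trains=tuple(trains),
            )
        write_session(session, sessions_dir / f"{tag}.spikes.tsv",
                      sessions_dir / f"{tag}.meta.json")
        out_sessions.append(session)
    write_json(
        [{"assembloid_id": s.assembloid_id, "genotype": s.genotype,
          "condition": s.condition, "tag": _session_tag(s)} for s in out_sessions],
        run_dir / "sessions" / "index.json",
    )
    log.info("simulate: %d sessions, %d spikes total", len(out_sessions),
             sum(tr.n_spikes for s in out_sessions for tr in s.trains))
    return out_sessions


def load_sessions(run_dir: Path) -> list[SessionRecord]:
    index = read_json(run_dir / "sessions" / "index.json")
    return [
        read_session(run_dir / "sessions" / f"{e['tag']}.spikes.tsv",
                     run_dir / "sessions" / f"{e['tag']}.meta.json")
        for e in index
    ]


def stage_metrics(cfg: dict, run_dir: Path, sessions: list[SessionRecord]) -> pd.DataFrame:
    """Per-electrode tables plus the per-session summary (active electrodes,
    MFR, log MFR) and per-assembloid drug-response ratios."""
    mdir = run_dir / "metrics"
    mdir.mkdir(exist_ok=True)
    rows = []
    for session in sessions:
        ms = electrode_metrics(session, cfg["min_rate_hz"])
        pd.DataFrame(
            {
                "electrode_id": [m.electrode_id for m in ms],
                "spike_count": [m.spike_count for m in ms],
                "mfr_hz": [m.mfr_hz for m in ms],
                "active": [m.active for m in ms],
                "min_rate_hz": cfg["min_rate_hz"],
            }
        ).to_csv(mdir / f"{_session_tag(session)}.electrodes.tsv", **_TSV_KW)
        mfr = session_mfr(session, cfg["mfr_scope"], cfg["min_rate_hz"])
        v = mfr + cfg["log_offset"]
        rows.append(
            {
                "assembloid": session.assembloid_id,
                "genotype": session.genotype,
                "condition": session.condition,
                "n_active": sum(m.active for m in ms),
                "mfr_hz": mfr,
                "log10_mfr": math.log10(v) if v > 0 else math.nan,
                "mfr_scope": cfg["mfr_scope"],
                "log_offset": cfg["log_offset"],
            }
        )
    summary = pd.DataFrame(rows)
    by_key = {(s.assembloid_id, s.condition): s for s in sessions}
    ratio_rows = []
    for (aid, cond), session in sorted(by_key.items()):
        if cond == "BL" or (aid, "BL") not in by_key:
            continue
        ratio_rows.append(
            {
                "assembloid": aid,
                "genotype": session.genotype,
                "condition": cond,
                "response_ratio": drug_response_ratio(
                    session, by_key[(aid, "BL")], cfg["mfr_scope"], cfg["min_rate_hz"]
                ),
            }
        )
    ratios = pd.DataFrame(
        ratio_rows, columns=["assembloid", "genotype", "condition", "response_ratio"]
    )
    summary.to_csv(run_dir / "session_summary.tsv", **_TSV_KW)
    ratios.to_csv(run_dir / "drug_response.tsv", **_TSV_KW)
    log.info("metrics: %d sessions, %d drug ratios", len(summary), len(ratios))
    return summary


def stage_bursts(cfg: dict, run_dir: Path, sessions: list[SessionRecord]) -> pd.DataFrame:
    bdir = run_dir / "bursts"
    bdir.mkdir(exist_ok=True)
    rows = []
    for session in sessions:
        tag = _session_tag(session)
        by_el = session_bursts(session, cfg["bursts"])
        flat = [b for bl in by_el.values() for b in bl]
        pd.DataFrame(
            {
                "electrode_id": [b.electrode_id for b in flat],
                "start_s": [b.start_s for b in flat],
                "end_s": [b.end_s for b in flat],
                "n_spikes": [b.n_spikes for b in flat],
            }
        ).to_csv(bdir / f"{tag}.bursts.tsv", **_TSV_KW)
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            nbs = detect_network_bursts(session, by_el, cfg["bursts"], cfg["min_rate_hz"])
        pd.DataFrame(
            {
                "start_s": [nb.start_s for nb in nbs],
                "end_s": [nb.end_s for nb in nbs],
                "n_participants": [nb.n_participants for nb in nbs],
            }
        ).to_csv(bdir / f"{tag}.network_bursts.tsv", **_TSV_KW)
        rows.append(
            {
                "assembloid": session.assembloid_id,
                "genotype": session.genotype,
                "condition": session.condition,
                "n_bursts": len(flat),
                "n_network_bursts": len(nbs),
                "nb_rate_per_min": network_burst_rate(nbs, session.duration_s),
            }
        )
    nb_summary = pd.DataFrame(rows)
    nb_summary.to_csv(run_dir / "burst_summary.tsv", **_TSV_KW)
    log.info("bursts: %d sessions, %d network bursts",
             len(nb_summary), int(nb_summary["n_network_bursts"].sum()))
    return nb_summary


def stage_coupling(cfg: dict, run_dir: Path, sessions: list[SessionRecord]) -> pd.DataFrame:
    cdir = run_dir / "coupling"
    cdir.mkdir(exist_ok=True)
    rows = []
    for session in sessions:
        tag = _session_tag(session)
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            dist, results = session_coupling_distribution(
                session, cfg["ccg"], electrode_scope="active",
                min_rate_hz=cfg["min_rate_hz"], return_results=True,
            )
        tested = [r for r in results if r.testable]
        pd.DataFrame(
            {
                "electrode_i": [r.pair[0] for r in tested],
                "electrode_j": [r.pair[1] for r in tested],
                "peak_lag_s": [r.peak_lag_s for r in tested],
                "coupling_strength": [r.coupling_strength for r in tested],
                "z_peak": [r.z_peak for r in tested],
                "p_value": [r.p_value for r in tested],
                "significant": [r.significant for r in tested],
                "null_threshold": [r.null_threshold for r in tested],
            }
        ).to_csv(cdir / f"{tag}.pairs.tsv", **_TSV_KW)
        write_json(
            {
                "assembloid_id": dist.assembloid_id,
                "condition": dist.condition,
                "n_pairs_tested": dist.n_pairs_tested,
                "n_significant": dist.n_significant,
                "strengths": dist.strengths,
                "normalization": "counts / sqrt(N_i * N_j)",
                "electrode_scope": "active",
            },
            cdir / f"{tag}.distribution.json",
        )
        rows.append(
            {
                "assembloid": session.assembloid_id,
                "genotype": session.genotype,
                "condition": session.condition,
                "n_pairs_tested": dist.n_pairs_tested,
                "n_significant": dist.n_significant,
                "mean_sig_strength": float(np.mean(dist.strengths)) if dist.n_significant else math.nan,
            }
        )
    csum = pd.DataFrame(rows)
    csum.to_csv(run_dir / "coupling_summary.tsv", **_TSV_KW)
    log.info("coupling: %d sessions, %d significant pairs",
             len(csum), int(csum["n_significant"].sum()))
    return csum


def stage_compare(cfg: dict, run_dir: Path) -> pd.DataFrame:
    """Cohort comparisons: Kruskal-Wallis between genotypes on coupling
    strengths per condition, paired t for drug effects, and the two-factor
    genotype x condition decomposition of log MFR."""
    summary = pd.read_csv(run_dir / "session_summary.tsv", sep="\t")
    index = read_json(run_dir / "sessions" / "index.json")
    results = []

    genotypes = sorted(summary["genotype"].unique())
    conditions = sorted(summary["condition"].unique())

    # coupling distributions per condition: KW between genotypes
    for cond in conditions:
        groups = []
        for genotype in genotypes:
            strengths: list[float] = []
            for e in index:
                if e["genotype"] != genotype or e["condition"] != cond:
                    continue
                d = read_json(run_dir / "coupling" / f"{e['tag']}.distribution.json")
                if cfg["pooling"] == "pooled_pairs":
                    strengths.extend(d["strengths"])
                else:  # per-assembloid summary: one mean strength per assembloid
                    if d["strengths"]:
                        strengths.append(float(np.mean(d["strengths"])))
            groups.append(strengths)
        if all(len(g) > 0 for g in groups) and sum(len(g) for g in groups) >= 3:
            results.append(
                kruskal_wallis(groups, label=f"coupling_strength:{cond}:{cfg['pooling']}")
            )

    # drug effect on MFR within genotype (paired by assembloid)
    for genotype in genotypes:
        sub = summary[summary["genotype"] == genotype]
        piv = sub.pivot(index="assembloid", columns="condition", values="mfr_hz")
        for drug in ("GABA", "PTX"):
            if "BL" in piv.columns and drug in piv.columns and len(piv) >= 2:
                results.append(
                    paired_t(piv["BL"], piv[drug], label=f"mfr:{genotype}:BL-vs-{drug}")
                )

    # genotype x condition factorial on log MFR
    if len(genotypes) >= 2 and len(conditions) >= 2:
        table = summary.rename(columns={"log10_mfr": "value"})[
            ["assembloid", "genotype", "condition", "value"]
        ]
        n_excluded = int(table["value"].isna().sum())
        if n_excluded:
            log.info("compare: excluded %d sessions with undefined log MFR", n_excluded)
        try:
            results.extend(condition_genotype_comparison(table.dropna(), "value"))
        except ValueError as exc:
            log.warning("compare: factorial comparison skipped (%s)", exc)

    frame = comparisons_to_frame(results)
    frame.to_csv(run_dir / "comparisons.tsv", **_TSV_KW)
    log.info("compare: %d comparisons", len(frame))
    return frame


def stage_report(cfg: dict, run_dir: Path, figures: bool = False) -> dict:
    summary = pd.read_csv(run_dir / "session_summary.tsv", sep="\t")
    bursts = pd.read_csv(run_dir / "burst_summary.tsv", sep="\t")
    coup = pd.read_csv(run_dir / "coupling_summary.tsv", sep="\t")
    ratios = pd.read_csv(run_dir / "drug_response.tsv", sep="\t")
    by_gc = (
        summary.groupby(["genotype", "condition"], observed=True)
        .agg(mean_mfr_hz=("mfr_hz", "mean"), mean_active=("n_active", "mean"))
        .reset_index()
    )
    report = {
        "n_sessions": int(len(summary)),
        "per_genotype_condition": by_gc.to_dict(orient="records"),
        "drug_response": ratios.groupby(["genotype", "condition"], observed=True)["response_ratio"]
        .mean().reset_index().to_dict(orient="records"),
        "network_bursts": bursts.groupby(["genotype", "condition"], observed=True)["n_network_bursts"]
        .sum().reset_index().to_dict(orient="records"),
        "significant_pairs": coup.groupby(["genotype", "condition"], observed=True)["n_significant"]
        .sum().reset_index().to_dict(orient="records"),
    }
    write_json(report, run_dir / "summary.json")
    if figures:
        from . import plots

        sessions = load_sessions(run_dir)
        fig_dir = run_dir / "figures"
        fig_dir.mkdir(exist_ok=True)
        first = sessions[0]
        plots.raster_plot(first, path=fig_dir / f"{_session_tag(first)}_raster.png")
        for e in read_json(run_dir / "sessions" / "index.json")[:1]:
            d = read_json(run_dir / "coupling" / f"{e['tag']}.distribution.json")
            plots.coupling_histogram(
                np.asarray(d["strengths"]), path=fig_dir / f"{e['tag']}_coupling.png"
            )
    log.info("report: summary.json written")
    return report


def run_pipeline(config: Mapping, out_dir: str | Path, figures: bool = False) -> Path:
    """Execute all stages; returns the run directory.

    The manifest (configuration echo, package version, master seed) is
    written first so a failed run still documents what was attempted; a
    FAILED marker is left behind if any stage raises.
    """
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    write_json({"config": dict(config), "version": __version__}, run_dir / "manifest.json")
    cfg = build_configs(config)
    try:
        sessions = stage_simulate(cfg, run_dir)
        stage_metrics(cfg, run_dir, sessions)
        stage_bursts(cfg, run_dir, sessions)
        stage_coupling(cfg, run_dir, sessions)
        stage_compare(cfg, run_dir)
        stage_report(cfg, run_dir, figures=figures)
    except Exception:
        (run_dir / "FAILED").write_text("pipeline stage raised; partial outputs retained\n")
        raise
    return run_dir


def rerun_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> Path:
    """Reproduce a run from its manifest alone."""
    manifest = read_json(manifest_path)
    return run_pipeline(manifest["config"], out_dir)
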