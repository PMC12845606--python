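"""End-to-end orchestration: simulate -> preprocess -> extract -> match ->
features -> stats, as plain files in a run directory.

Every stage reads and writes ordinary files so stages are independently
re-runnable from intermediates, and a run manifest records the config
snapshot, seeds, per-stage wall time, every output file, and a per-subject
log (cycles found/used, selected k, matched synergies, quarantines).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import emg_io, group_stats, preprocess, synergy, synergy_matching
from .emg_io import GROUPS, PHASES, SESSIONS, PipelineConfig
from .synthetic_emg import (
    SYNERGY_NAMES,
    CohortSpec,
    default_ground_truth,
    synthesize_cohort,
)

log = logging.getLogger("synkick")

__all__ = ["run_all", "simulate_stage", "report"]


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    emg_io.write_json_document(manifest, out_dir / "manifest.json")


def simulate_stage(spec: CohortSpec, out_dir: str | Path) -> dict:
    """Write a synthetic cohort (signals, metadata, events, ground truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    gt = default_ground_truth()
    for member in synthesize_cohort(spec, gt):
        stem = f"{member.subject}_{member.session}"
        emg_io.write_recording(
            member.recording, out_dir / f"{stem}.csv", out_dir / f"{stem}.json"
        )
        emg_io.write_events(member.events, out_dir / f"{stem}_events.csv")
        files += [f"{stem}.csv", f"{stem}.json", f"{stem}_events.csv"]
    emg_io.write_json_document(
        {
            "weights": gt.weights,
            "weights_normalized": gt.weights_normalized,
            "timing": [dataclasses.asdict(b) for b in gt.timing],
            "phase_fractions": list(gt.phase_fractions),
            "muscles": list(gt.muscle_labels),
            "spec": dataclasses.asdict(spec),
        },
        out_dir / "ground_truth.json",
    )
    files.append("ground_truth.json")
    return {"n_recordings": len(files) // 3, "files": files}


def _discover_recordings(in_dir: Path) -> list[tuple[Path, Path, Path]]:
    out = []
    for meta_path in sorted(in_dir.glob("*.json")):
        if meta_path.name in ("ground_truth.json", "manifest.json"):
            continue
        stem = meta_path.stem
        sig = in_dir / f"{stem}.csv"
        ev = in_dir / f"{stem}_events.csv"
        if sig.exists() and ev.exists():
            out.append((sig, meta_path, ev))
    return out


def run_all(
    config: PipelineConfig,
    in_dir: str | Path,
    out_dir: str | Path,
    spec: CohortSpec | None = None,
    stats_measures: list[str] | None = None,
) -> dict:
    """Run every stage; failures quarantine the subject and the run goes on.

    If ``spec`` is given the simulate stage writes the cohort into
    ``in_dir`` first; otherwise ``in_dir`` must already hold recordings.
    Returns the manifest (also written to ``out_dir/manifest.json``).
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "subjects": {},
        "quarantined": [],
        "outputs": ["manifest.json"],
    }

    if spec is not None:
        t0 = time.perf_counter()
        sim = simulate_stage(spec, in_dir)
        manifest["stages"]["simulate"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "n_recordings": sim["n_recordings"],
        }
        manifest["seed"] = spec.seed

    # --- preprocess + extract -------------------------------------------
    t0 = time.perf_counter()
    sets_by_cell: dict[tuple[str, str], list[synergy.SynergySet]] = {
        (g, s): [] for g in GROUPS for s in SESSIONS
    }
    td_rows = []
    recordings = _discover_recordings(in_dir)
    if not recordings:
        raise ValueError(f"no recordings found in {in_dir}")
    for sig_path, meta_path, ev_path in recordings:
        stem = sig_path.stem
        try:
            rec = emg_io.read_recording(sig_path, meta_path)
            events = emg_io.read_events(ev_path)
            env = preprocess.extract_envelope_matrix(rec, events, config)
            td = preprocess.time_domain_features(rec, events, config)
            sset = synergy.select_order(
                env,
                k_min=config.k_min,
                k_max=config.k_max,
                vaf_threshold=config.vaf_threshold,
                seed=config.nmf_seed,
                restarts=config.nmf_restarts,
                tol=config.nmf_tol,
                max_iter=config.nmf_max_iter,
                centered_sst=config.vaf_centered_sst,
            )
            sset = synergy.normalize_weights(sset)
            sset.meta.update(
                subject=rec.meta.subject,
                group=rec.meta.group,
                session=rec.meta.session,
            )
            # stash envelope for independent VAF recomputation downstream
            sset.meta["envelope"] = env
            sets_by_cell[(rec.meta.group, rec.meta.session)].append(sset)
            td_rows.append(td)
            used = preprocess.select_cycles(events.n_cycles, config.cycle_select)
            manifest["subjects"][stem] = {
                "cycles_found": events.n_cycles,
                "cycles_used": len(used),
                "selected_k": sset.k,
                "vaf": sset.vaf,
                "vaf_threshold_met": sset.threshold_met,
            }
            if not sset.threshold_met:
                log.warning("%s: no k reached VAF threshold; using k=%d", stem, sset.k)
        except Exception as exc:  # quarantine, keep going
            log.warning("quarantining %s: %s", stem, exc)
            manifest["quarantined"].append({"subject": stem, "error": str(exc)})
    if not any(sets_by_cell.values()):
        raise ValueError("every recording failed preprocessing/extraction")
    td_table = pd.concat(td_rows, ignore_index=True)
    td_table.to_csv(out_dir / "time_domain_features.csv", index=False)
    manifest["outputs"].append("time_domain_features.csv")
    manifest["stages"]["extract"] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "n_synergy_sets": int(sum(len(v) for v in sets_by_cell.values())),
    }

    # --- reference building + matching ----------------------------------
    t0 = time.perf_counter()
    refs: dict[tuple[str, str], synergy_matching.ReferenceSynergySet] = {}
    for cell, sets in sets_by_cell.items():
        if not sets:
            continue
        refs[cell] = synergy_matching.build_reference(
            sets,
            s_min=config.cluster_s_min,
            s_max=config.cluster_s_max,
            drop_tol=config.cluster_drop_tol,
            seed=config.cluster_seed,
            restarts=config.cluster_restarts,
            group=cell[0],
            session=cell[1],
        )
    if ("control", "pre") in refs:
        refs = synergy_matching.align_references(refs, anchor=("control", "pre"))

    match_rows, weight_rows, timing_rows = [], [], []
    for cell, sets in sets_by_cell.items():
        if cell not in refs:
            continue
        ref = refs[cell]
        for sset in sets:
            matches = synergy_matching.match_to_reference(
                sset, ref, config.match_r_threshold, config.match_method
            )
            manifest["subjects"].setdefault(
                f"{sset.meta['subject']}_{sset.meta['session']}", {}
            )["matched_synergies"] = len(matches)
            for mm in matches:
                syn_name = ref.names[mm.cluster]
                match_rows.append(
                    {
                        "subject": mm.subject,
                        "group": cell[0],
                        "session": cell[1],
                        "synergy": syn_name,
                        "column": mm.column,
                        "r": mm.r,
                    }
                )
                for mi, muscle in enumerate(sset.muscle_labels):
                    weight_rows.append(
                        {
                            "subject": mm.subject,
                            "group": cell[0],
                            "session": cell[1],
                            "measure": f"weight:{syn_name}:{muscle}",
                            "value": float(sset.W[mi, mm.column]),
                        }
                    )
                if sset.cycle_fraction_map is not None:
                    feats = synergy_matching.activation_features(
                        sset.H[mm.column],
                        sset.cycle_fraction_map,
                        config.activation_threshold,
                    )
                    for name, val in (
                        ("T", feats.T),
                        ("Tmax", feats.t_max),
                        ("Tstart", feats.t_start),
                    ):
                        timing_rows.append(
                            {
                                "subject": mm.subject,
                                "group": cell[0],
                                "session": cell[1],
                                "measure": f"timing:{syn_name}:{name}",
                                "value": val,
                            }
                        )
    pd.DataFrame(match_rows).to_csv(out_dir / "assignments.csv", index=False)
    emg_io.write_json_document(
        {
            f"{g},{s}": {
                "s": ref.s,
                "centroids": ref.centroids,
                "muscles": ref.muscle_labels,
                "sse_curve": {str(k): v for k, v in ref.sse_curve.items()},
            }
            for (g, s), ref in refs.items()
        },
        out_dir / "reference_synergies.json",
    )
    features = pd.DataFrame(weight_rows + timing_rows)
    features.to_csv(out_dir / "synergy_features.csv", index=False)
    manifest["outputs"] += [
        "assignments.csv",
        "reference_synergies.json",
        "synergy_features.csv",
    ]
    manifest["stages"]["match"] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "n_reference_sets": len(refs),
        "n_matches": len(match_rows),
        "s_per_cell": {f"{g},{s}": ref.s for (g, s), ref in refs.items()},
    }

    # --- statistics ------------------------------------------------------
    if stats_measures:
        t0 = time.perf_counter()
        stat_rows = []
        for measure in stats_measures:
            sub = features[features["measure"] == measure][
                ["subject", "group", "session", "value"]
            ].copy()
            # keep only subjects observed in both sessions for this measure
            complete = (
                sub.groupby("subject")["session"].nunique().pipe(lambda s: s[s == 2])
            ).index
            sub = sub[sub["subject"].isin(complete)]
            try:
                res = group_stats.analyze_measure(
                    sub,
                    measure=measure,
                    alpha=config.alpha,
                    outlier_mode=config.outlier_mode,
                )
            except ValueError as exc:
                log.warning("stats skipped for %s: %s", measure, exc)
                continue
            stat_rows += [dataclasses.asdict(r) for r in res]
        pd.DataFrame(stat_rows).to_csv(out_dir / "stats.csv", index=False)
        manifest["outputs"].append("stats.csv")
        manifest["stages"]["stats"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "n_measures": len(stats_measures),
        }

    # drop non-serializable envelope stash before writing
    _write_manifest(out_dir, manifest)
    return manifest


def report(out_dir: str | Path) -> str:
    """Human-readable run summary from stage outputs; idempotent."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {out_dir}; run the pipeline first")
    manifest = emg_io.read_json_document(manifest_path)
    lines = ["# synkick run report", ""]

    subjects = manifest.get("subjects", {})
    ks = [v["selected_k"] for v in subjects.values() if "selected_k" in v]
    if ks:
        vals, counts = np.unique(ks, return_counts=True)
        lines.append("## Model order")
        lines.append(
            "selected k distribution: "
            + ", ".join(f"k={int(v)}: {int(c)}" for v, c in zip(vals, counts))
        )
        vafs = [v["vaf"] for v in subjects.values() if "vaf" in v]
        lines.append(
            f"VAF at selected k: min {min(vafs):.3f}, "
            f"median {float(np.median(vafs)):.3f}, max {max(vafs):.3f}"
        )
        lines.append("")

    ref_path = out_dir / "reference_synergies.json"
    if ref_path.exists():
        refs = emg_io.read_json_document(ref_path)
        lines.append("## Reference synergies (per group x session cell)")
        for cell, ref in refs.items():
            lines.append(f"- {cell}: s = {ref['s']}")
        lines.append("")
        lines.append("## Centroid weights")
        for cell, ref in refs.items():
            lines.append(f"### {cell}")
            muscles = ref["muscles"]
            cents = np.asarray(ref["centroids"])
            header = "muscle," + ",".join(f"SYN{j + 1}" for j in range(len(cents)))
            lines.append(header)
            for i, muscle in enumerate(muscles):
                lines.append(
                    muscle + "," + ",".join(f"{cents[j][i]:.2f}" for j in range(len(cents)))
                )
            lines.append("")

    feat_path = out_dir / "synergy_features.csv"
    if feat_path.exists():
        try:
            feats = pd.read_csv(feat_path)
        except pd.errors.EmptyDataError:
            feats = pd.DataFrame(columns=["measure"])
        timing = feats[feats["measure"].str.startswith("timing:")]
        if not timing.empty:
            lines.append("## Activation timing (mean ± SD per cell)")
            summary = (
                timing.groupby(["measure", "group", "session"])["value"]
                .agg(["mean", "std"])
                .reset_index()
            )
            for _, row in summary.iterrows():
                lines.append(
                    f"- {row['measure']} [{row['group']}, {row['session']}]: "
                    f"{row['mean']:.2f} ± {row['std']:.2f}"
                )
            lines.append("")

    stats_path = out_dir / "stats.csv"
    lines.append("## Statistics")
    if stats_path.exists():
        try:
            stats = pd.read_csv(stats_path)
        except pd.errors.EmptyDataError:
            stats = pd.DataFrame()
        if stats.empty:
            lines.append("stats stage produced no results (see run log)")
        for _, row in stats.iterrows():
            lines.append(
                f"- {row['measure']} / {row['effect']} ({row['family']}): "
                f"stat={row['statistic']:.3g}, p={row['p']:.3g}, "
                f"adj p={row['adjusted_p']:.3g}"
            )
    else:
        lines.append("stats stage was not run; no stats.csv present")
    lines.append("")

    if manifest.get("quarantined"):
        lines.append("## Quarantined subjects")
        for q in manifest["quarantined"]:
            lines.append(f"- {q['subject']}: {q['error']}")
        lines.append("")

    text = "\n".join(lines)
    (out_dir / "report.md").write_text(text)
    return text
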