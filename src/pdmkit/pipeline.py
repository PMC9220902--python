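"""End-to-end orchestration of the PDM analysis stages.

Chains, in assay order: blank filter -> median-centering/log2 -> HCL
clustering -> pathway summaries -> cytotoxicity fold changes, tests and
sensitivity grades -> responder/non-responder split -> 20% signature filter
-> pathway Mann-Whitney tests -> per-protein grade correlations ->
(optional) treated/vehicle TR time-course analysis -> (optional) co-culture
killing analysis.  Every threshold applied is recorded in the run log, and
every number in the JSON summary is taken from one stage's output.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import cytotox, io, killing as killing_mod, rppa, signatures, synthdata, timecourse


def simulate_cohort(cfg: synthdata.SimConfig, out_dir) -> dict:
    """Generate all four synthetic inputs and write them as CSV + truth JSON.

    Returns the paths of the written files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth_rppa = synthdata.simulate_rppa(cfg)
    plate, truth_plate = synthdata.simulate_plate(cfg)
    treated, vehicle, truth_tr = synthdata.simulate_tr_pair(cfg)
    records, truth_kill = synthdata.simulate_killing(cfg)

    paths = {
        "nfi_csv": str(out / "nfi_matrix.csv"),
        "plate_csv": str(out / "plate_table.csv"),
        "tr_treated_csv": str(out / "tr_treated.csv"),
        "tr_vehicle_csv": str(out / "tr_vehicle.csv"),
        "killing_csv": str(out / "killing_table.csv"),
        "truth_json": str(out / "truth.json"),
    }
    io.write_nfi_csv(matrix, paths["nfi_csv"])
    io.write_plate_csv(plate, paths["plate_csv"])
    io.write_nfi_csv(treated, paths["tr_treated_csv"])
    io.write_nfi_csv(vehicle, paths["tr_vehicle_csv"])
    io.write_killing_csv(records, paths["killing_csv"])
    io.write_json(
        {
            "rppa": truth_rppa.to_dict(),
            "plate": truth_plate.to_dict(),
            "tr": truth_tr.to_dict(),
            "killing": truth_kill.to_dict(),
        },
        paths["truth_json"],
    )
    return paths


def _write_figures(centered: rppa.NFIMatrix, cluster: rppa.ClusterResult, out: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    ordered = centered.values[cluster.order]
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_xticks(range(len(cluster.order)))
    ax.set_xticklabels(cluster.order, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel("proteins")
    ax.set_title("Centered log2 NFI (HCL sample order)")
    fig.colorbar(im, ax=ax, label="log2 relative NFI")
    fig.tight_layout()
    fig.savefig(out / "heatmap.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    hierarchy.dendrogram(cluster.linkage, labels=cluster.sample_ids, ax=ax)
    ax.set_ylabel("1 - Pearson r (average linkage)")
    fig.tight_layout()
    fig.savefig(out / "dendrogram.png", dpi=120)
    plt.close(fig)


def run_pipeline(cfg: io.RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the JSON-serializable summary dict (also written to
    ``<out_dir>/summary.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    note(f"config: {dataclasses.asdict(cfg)}")
    summary: dict = {"drug": cfg.drug, "seed": cfg.seed}

    if cfg.nfi_csv is None or cfg.plate_csv is None:
        raise ValueError("run_pipeline requires nfi_csv and plate_csv inputs")

    # --- RPPA processing -------------------------------------------------
    raw = io.read_nfi_csv(cfg.nfi_csv)
    filtered, excluded = rppa.apply_blank_filter(raw, blank=cfg.blank_nfi)
    note(f"blank filter at {cfg.blank_nfi} NFI excluded {len(excluded)} proteins: "
         f"{excluded}")
    centered = rppa.center_log2(filtered)
    cluster = rppa.hcl_cluster(
        centered, k=min(cfg.hcl_k, centered.n_samples),
        metric=cfg.hcl_metric, method=cfg.hcl_linkage,
    )
    note(f"HCL: metric={cfg.hcl_metric}, linkage={cfg.hcl_linkage}, k={cluster.k}")
    pw_medians, _ = rppa.pathway_summarize(centered)
    pw_medians.to_csv(out / "pathway_medians.csv")
    summary["rppa"] = {
        "n_proteins_raw": raw.n_proteins,
        "n_proteins_retained": centered.n_proteins,
        "blank_excluded": excluded,
        "hcl_order": cluster.order,
        "hcl_partition": {str(k): v for k, v in cluster.partition().items()},
    }
    if cfg.write_figures:
        _write_figures(centered, cluster, out)

    # --- cytotoxicity grading --------------------------------------------
    plate = io.read_plate_csv(cfg.plate_csv)
    grades, fct = cytotox.grade_all(
        plate, cfg.drug, z_cutoff=cfg.outlier_z,
        final_time=cfg.final_time_h, p_cuts=cfg.grade_p_cuts,
    )
    fct.strata.to_csv(out / "fold_changes.csv", index=False)
    fct.outliers.to_csv(out / "plate_outliers.csv", index=False)
    grade_df = pd.DataFrame(
        [(g.model, g.drug, g.grade, g.responder, g.p_min) for g in grades],
        columns=["model", "drug", "grade", "responder", "p_min"],
    )
    grade_df.to_csv(out / "sensitivity_grades.csv", index=False)
    note(f"outlier removal: modified Z cutoff {cfg.outlier_z}; "
         f"{len(fct.outliers)} records removed")
    note(f"grading: min Holm-adjusted p across doses at {cfg.final_time_h} h, "
         f"cuts {cfg.grade_p_cuts}")
    summary["cytotox"] = {
        "n_outliers_removed": int(len(fct.outliers)),
        "grades": {g.model: g.grade for g in grades},
        "responders": sorted(g.model for g in grades if g.responder),
    }

    # --- responder signatures --------------------------------------------
    summary["signatures"] = None
    graded_models = {g.model for g in grades}
    if graded_models >= set(centered.sample_ids):
        try:
            split = signatures.split_groups(grades, centered)
        except signatures.AnalysisError as exc:
            note(f"signature stage skipped: {exc}")
        else:
            sig = signatures.filter_20pct(
                centered, split, min_ratio=cfg.signature_min_ratio
            )
            sig.to_csv(out / "signature_table.csv")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pw_tests = signatures.test_pathways(sig, centered, split)
            pw_df = pd.DataFrame(
                [(r.pathway, r.n_proteins, r.u_stat, r.p_value) for r in pw_tests],
                columns=["pathway", "n_proteins", "u_stat", "p_value"],
            )
            pw_df.to_csv(out / "pathway_tests.csv", index=False)
            corr_rows = []
            for protein in sig.index[sig["passes"]]:
                c = signatures.correlate_with_grade(centered, grades, protein)
                corr_rows.append((protein, c.r, c.p_value, c.method))
            corr_df = pd.DataFrame(
                corr_rows, columns=["protein", "spearman_r", "p_value", "method"]
            )
            corr_df.to_csv(out / "grade_correlations.csv", index=False)
            note(f"signature filter: linear ratio >= {cfg.signature_min_ratio} "
                 f"({int(sig['passes'].sum())}/{len(sig)} proteins pass); "
                 "pathway p-values downstream of the filter are descriptive "
                 "(selection + pooled pseudo-replication)")
            summary["signatures"] = {
                "responders": list(split.responders),
                "non_responders": list(split.non_responders),
                "n_passing": int(sig["passes"].sum()),
                "pathway_p": {r.pathway: r.p_value for r in pw_tests},
            }

    # --- TR time course ----------------------------------------------------
    summary["timecourse"] = None
    if cfg.tr_treated_csv and cfg.tr_vehicle_csv:
        treated = io.read_nfi_csv(cfg.tr_treated_csv)
        vehicle = io.read_nfi_csv(cfg.tr_vehicle_csv)
        profile = timecourse.compute_tr(
            treated, vehicle, drug=cfg.drug,
            threshold_fraction=cfg.tr_threshold_fraction,
        )
        kept, report = timecourse.threshold_tr(profile)
        report.to_csv(out / "tr_threshold_report.csv")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tc_tests = timecourse.test_timecourse(kept)
        note(f"TR threshold: |linear ratio - 1| >= {cfg.tr_threshold_fraction} "
             f"({kept.values.shape[0]}/{profile.values.shape[0]} proteins retained)")
        summary["timecourse"] = {
            "n_retained": int(kept.values.shape[0]),
            "pathway_pairwise_p": {
                r.pathway: {
                    f"{row.time_a}v{row.time_b}": row.p_value
                    for row in r.pairwise.itertuples()
                }
                for r in tc_tests
            },
            "pathway_vs_control_p": {
                r.pathway: {str(row.time): row.p_value for row in r.vs_control.itertuples()}
                for r in tc_tests
            },
        }

    # --- co-culture killing -------------------------------------------------
    summary["killing"] = None
    if cfg.killing_csv:
        records = io.read_killing_csv(cfg.killing_csv)
        result = killing_mod.summarize_arms(records)
        result.per_arm.to_csv(out / "killing_per_arm.csv", index=False)
        result.comparisons.to_csv(out / "killing_comparisons.csv", index=False)
        summary["killing"] = {
            "per_arm_mean_percent": {
                row.arm: row.mean_percent for row in result.per_arm.itertuples()
            },
            "comparisons": {
                f"{row.arm_a} vs {row.arm_b}": row.p_value
                for row in result.comparisons.itertuples()
            },
        }
        note("killing: Eq.-style dead:viable ratio per imaged PDM, "
             "two-sided Mann-Whitney U between arms")

    io.write_json(summary, out / "summary.json")
    (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    return summary


def run_demo(seed: int, out_dir) -> dict:
    """Generate a synthetic cohort and run the full pipeline on it."""
    out = Path(out_dir)
    sim_cfg = synthdata.SimConfig(seed=seed)
    paths = simulate_cohort(sim_cfg, out / "inputs")
    run_cfg = io.RunConfig(
        out_dir=str(out),
        seed=seed,
        nfi_csv=paths["nfi_csv"],
        plate_csv=paths["plate_csv"],
        tr_treated_csv=paths["tr_treated_csv"],
        tr_vehicle_csv=paths["tr_vehicle_csv"],
        killing_csv=paths["killing_csv"],
    )
    run_cfg.to_json(out / "run_config.json")
    return run_pipeline(run_cfg)
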