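"""Pipeline orchestration: configuration, stage execution and reporting.

Stages communicate through files under the output directory so any stage can
be rerun in isolation, and every threshold and seed actually used is logged
into the run manifest — the audit trail is sufficient to reproduce a run.

Stage order: qc -> select-refs -> discover -> validate -> perf -> survival
(-> tissue, when paired-tissue data are supplied), followed by a
human-readable ``report.md``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomarker_performance as perf
from . import cohort_validation as cv
from . import discovery_screen as ds
from . import reference_selection as rs
from . import survival_analysis as sa
from .errors import ConfigError, ExomirError, PipelineError
from .qpcr_io import (
    GROUP_METASTASIS,
    GROUP_NON_METASTASIS,
    interplate_calibrate,
    read_ct_matrix,
    read_sample_table,
    spikein_qc,
    write_ct_matrix,
)

log = logging.getLogger("exomir")

__all__ = ["RunConfig", "load_config", "dump_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a run needs; serializes losslessly to YAML/JSON."""

    profiling_ct: str | None = None
    profiling_layout: str | None = None
    validation_ct: str | None = None
    validation_layout: str | None = None
    samples: str | None = None
    pairs: str | None = None
    tissue: str | None = None
    outdir: str = "results"
    seed: int = 0
    undetermined_token: str = "Undetermined"
    ct_max: float = 40.0
    impute_ct: float = 40.0
    qc_max_dev: float = 2.0
    reference_candidates: list[str] = field(
        default_factory=lambda: [
            "hsa-miR-16-5p",
            "hsa-miR-93-5p",
            "hsa-miR-486-3p",
            "SNORD38B",
        ]
    )
    k_references: int = 2
    max_mean_ct: float = 35.0
    up_threshold: float = 1.5
    down_threshold: float = 1.0 / 1.5
    validation_assays: list[str] = field(
        default_factory=lambda: [
            "hsa-let-7c-5p",
            "hsa-miR-144-5p",
            "hsa-miR-379-5p",
            "hsa-miR-410-3p",
            "hsa-miR-98-5p",
            "hsa-miR-505-5p",
            "hsa-miR-934",
        ]
    )
    biomarkers: list[str] = field(
        default_factory=lambda: ["hsa-miR-379-5p", "hsa-miR-410-3p"]
    )
    cutoff_criterion: str = "youden"
    make_plots: bool = True


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run config; omitted fields take the documented
    defaults, unknown keys are rejected by name."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = sorted(set(doc) - _FIELDS)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {unknown}")
    try:
        return RunConfig(**doc)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(f"{path}: {exc}") from exc


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# stages


def stage_qc(cfg: RunConfig, which: str = "profiling") -> Path:
    """Spike-in QC and inter-plate calibration for one input matrix; writes
    the advisory QC report and the calibrated matrix."""
    if which == "profiling":
        src, layout = cfg.profiling_ct, cfg.profiling_layout
    else:
        src, layout = cfg.validation_ct, cfg.validation_layout
    if src is None:
        raise PipelineError("qc", f"no {which} Ct matrix configured")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = read_ct_matrix(src, cfg.undetermined_token, cfg.ct_max, layout=layout)
    report = spikein_qc(m, cfg.qc_max_dev)
    report.to_frame().to_csv(outdir / f"qc_report_{which}.tsv", sep="\t", index=False)
    cal = interplate_calibrate(m)
    out = outdir / f"calibrated_{which}.csv"
    write_ct_matrix(cal, out, cfg.undetermined_token)
    log.info(
        "qc[%s]: %d samples, %d flags, plates %s",
        which,
        len(m.sample_ids),
        len(report.flags),
        sorted(report.ipc_plate_means),
    )
    return out


def stage_references(cfg: RunConfig) -> list[str]:
    """Evaluate the candidate internal controls on the calibrated validation
    cohort and select the k most stable; writes references.tsv."""
    outdir = Path(cfg.outdir)
    m = read_ct_matrix(
        outdir / "calibrated_validation.csv", cfg.undetermined_token, cfg.ct_max
    )
    cands = rs.evaluate_candidates(m, cfg.reference_candidates)
    selected = rs.select_references(cands, cfg.k_references, cfg.max_mean_ct)
    rows = pd.DataFrame(
        [
            {
                "assay_id": c.assay_id,
                "n": c.n_samples,
                "detect_fraction": c.detect_fraction,
                "mean_ct": c.mean_ct,
                "sd_ct": c.sd_ct,
                "cv_percent": c.cv_percent,
                "selected": c.assay_id in selected,
            }
            for c in cands
        ]
    )
    rows.to_csv(outdir / "references.tsv", sep="\t", index=False)
    log.info("references: selected %s (k=%d)", selected, cfg.k_references)
    return selected


def stage_discovery(cfg: RunConfig, references: list[str]) -> dict:
    """Paired screen on the calibrated profiling matrix; writes the per-pair
    fold changes and the consensus table."""
    outdir = Path(cfg.outdir)
    m = read_ct_matrix(
        outdir / "calibrated_profiling.csv", cfg.undetermined_token, cfg.ct_max
    )
    pairs = ds.read_pairs(cfg.pairs)
    res = ds.run_discovery(
        m,
        pairs,
        references,
        cfg.up_threshold,
        cfg.down_threshold,
        cfg.impute_ct,
    )
    ds.records_to_frame(res["records"]).to_csv(
        outdir / "discovery_foldchanges.tsv", sep="\t", index=False
    )
    cons = res["consensus"]
    ref1, ref2 = references[0], references[1] if len(references) > 1 else references[0]
    rows = [
        {
            "assay_id": a,
            "direction": d,
            f"fc_{ref1}": res["averages"][ref1][a].fold_change,
            f"fc_{ref2}": res["averages"][ref2][a].fold_change,
        }
        for d, assays in (("up", cons.consensus_up), ("down", cons.consensus_down))
        for a in assays
    ]
    pd.DataFrame(
        rows, columns=["assay_id", "direction", f"fc_{ref1}", f"fc_{ref2}"]
    ).to_csv(outdir / "consensus.tsv", sep="\t", index=False)
    log.info(
        "discovery: detected per pair %s, common %d, consensus %d up / %d down "
        "(thresholds %.3g/%.3g)",
        {k: len(v) for k, v in res["detected_per_pair"].items()},
        len(res["common"]),
        len(cons.consensus_up),
        len(cons.consensus_down),
        cfg.up_threshold,
        cfg.down_threshold,
    )
    return res


def stage_validation(cfg: RunConfig, references: list[str]) -> pd.DataFrame:
    """Mann-Whitney comparison of relative expression between groups for each
    shortlisted assay under each reference; writes validation_stats.tsv and
    the clinical contingency statistics."""
    outdir = Path(cfg.outdir)
    m = read_ct_matrix(
        outdir / "calibrated_validation.csv", cfg.undetermined_token, cfg.ct_max
    )
    table = read_sample_table(cfg.samples)
    groups = table.set_index("sample_id")["group"]
    rows = []
    for assay in cfg.validation_assays:
        if assay not in m.ct.index:
            continue
        for ref in references:
            ev = cv.cohort_expression(m, assay, ref)
            ev.groups = groups.reindex(ev.values.index)
            x, y = ev.split(GROUP_METASTASIS, GROUP_NON_METASTASIS)
            comp = cv.mann_whitney(x, y, mode="normal")
            rows.append(
                {
                    "assay_id": assay,
                    "reference_id": ref,
                    "n_met": comp.n1,
                    "n_nonmet": comp.n2,
                    "n_censored": ev.n_censored,
                    "median_met": comp.summary1,
                    "median_nonmet": comp.summary2,
                    "U": comp.statistic,
                    "p_value": comp.p_value,
                }
            )
    stats_df = pd.DataFrame(rows)
    stats_df.to_csv(outdir / "validation_stats.tsv", sep="\t", index=False)

    # clinical characteristics: stage x group (3x2) and gender x group (2x2)
    stage_tab = pd.crosstab(table["stage"], table["group"])
    chi2, df_, p = cv.chi_square(stage_tab.to_numpy())
    gender_tab = pd.crosstab(table["gender"], table["group"])
    g_chi2, g_df, g_p = cv.chi_square(gender_tab.to_numpy())
    pd.DataFrame(
        [
            {"characteristic": "stage", "statistic": chi2, "df": df_, "p_value": p},
            {"characteristic": "gender", "statistic": g_chi2, "df": g_df, "p_value": g_p},
        ]
    ).to_csv(outdir / "clinical_tables.tsv", sep="\t", index=False)
    log.info("validation: %d assay x reference comparisons", len(stats_df))
    return stats_df


def stage_performance(cfg: RunConfig, references: list[str]) -> pd.DataFrame:
    """ROC / optimal cut-off / dichotomization per biomarker and reference;
    writes performance.tsv, sites.tsv and positivity labels."""
    outdir = Path(cfg.outdir)
    m = read_ct_matrix(
        outdir / "calibrated_validation.csv", cfg.undetermined_token, cfg.ct_max
    )
    table = read_sample_table(cfg.samples)
    groups = table.set_index("sample_id")["group"]
    sites = dict(zip(table["sample_id"], table["met_sites"]))
    rows, site_frames, labels_frames = [], [], []
    for assay in cfg.biomarkers:
        if assay not in m.ct.index:
            continue
        for ref in references:
            ev = cv.cohort_expression(m, assay, ref)
            ev.groups = groups.reindex(ev.values.index)
            pos, neg = ev.split(GROUP_METASTASIS, GROUP_NON_METASTASIS)
            roc = perf.roc_curve(pos, neg)
            cut = perf.optimal_cutoff(roc, cfg.cutoff_criterion)
            rows.append(
                {
                    "assay_id": assay,
                    "reference_id": ref,
                    "cutoff": cut.cutoff,
                    "sensitivity": cut.sensitivity,
                    "specificity": cut.specificity,
                    "youden_j": cut.youden_j,
                    "auc": roc.auc,
                    "n_pos": cut.tp + cut.fp,
                    "n_neg": cut.fn + cut.tn,
                }
            )
            labels = perf.dichotomize(ev.values.to_numpy(), cut.cutoff)
            labels_frames.append(
                pd.DataFrame(
                    {
                        "sample_id": ev.values.index,
                        "assay_id": assay,
                        "reference_id": ref,
                        "positive": labels,
                    }
                )
            )
            met_mask = ev.groups == GROUP_METASTASIS
            met_labels = pd.Series(
                labels[met_mask.to_numpy()], index=ev.values.index[met_mask]
            )
            tab = perf.site_association(met_labels, sites).reset_index()
            tab.insert(0, "reference_id", ref)
            tab.insert(0, "assay_id", assay)
            site_frames.append(tab)
    out = pd.DataFrame(rows)
    out.to_csv(outdir / "performance.tsv", sep="\t", index=False)
    pd.concat(site_frames, ignore_index=True).to_csv(
        outdir / "sites.tsv", sep="\t", index=False
    )
    pd.concat(labels_frames, ignore_index=True).to_csv(
        outdir / "positivity.tsv", sep="\t", index=False
    )
    log.info("performance: %d biomarker x reference ROC analyses", len(out))
    return out


def stage_survival(cfg: RunConfig) -> pd.DataFrame:
    """Kaplan-Meier PFS stratified by each biomarker positivity label plus the
    log-rank test; writes survival.tsv and optional KM plots."""
    outdir = Path(cfg.outdir)
    table = read_sample_table(cfg.samples)
    labels_df = pd.read_csv(outdir / "positivity.tsv", sep="\t")
    rows = []
    for (assay, ref), sub in labels_df.groupby(["assay_id", "reference_id"]):
        labels = pd.Series(sub["positive"].to_numpy(), index=sub["sample_id"])
        km_pos, km_neg, lr = sa.pfs_by_biomarker(table, labels)
        rows.append(
            {
                "assay_id": assay,
                "reference_id": ref,
                "n_positive": km_pos.n,
                "n_negative": km_neg.n,
                "events_positive": int(lr.observed[0]),
                "events_negative": int(lr.observed[1]),
                "median_pfs_positive": km_pos.median,
                "median_pfs_negative": km_neg.median,
                "logrank_chi2": lr.statistic,
                "logrank_p": lr.p_value,
            }
        )
        if cfg.make_plots:
            _km_plot(km_pos, km_neg, outdir / f"km_{assay}_{ref}.png")
    out = pd.DataFrame(rows)
    out.to_csv(outdir / "survival.tsv", sep="\t", index=False)
    log.info("survival: %d stratified analyses", len(out))
    return out


def _km_plot(km_pos, km_neg, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for km, label, color in ((km_pos, "positive", "C3"), (km_neg, "negative", "C0")):
        t = np.concatenate([[0.0], km.times])
        s = np.concatenate([[1.0], km.survival])
        ax.step(t, s, where="post", label=f"{label} (n={km.n})", color=color)
    ax.set_xlabel("months")
    ax.set_ylabel("progression-free survival")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def stage_tissue(cfg: RunConfig) -> pd.DataFrame:
    """Paired tumour/adjacent comparison: down-regulation counts and the
    Wilcoxon signed-rank test on log2 expression; writes tissue_stats.tsv."""
    outdir = Path(cfg.outdir)
    df = pd.read_csv(cfg.tissue)
    rows = []
    for assay, sub in df.groupby("assay_id"):
        pairs = sub[["tumour", "adjacent"]].to_numpy()
        n_down, n_total = cv.paired_direction_count(pairs)
        comp = cv.wilcoxon_signed_rank(np.log2(pairs), mode="auto")
        rows.append(
            {
                "assay_id": assay,
                "n_pairs": n_total,
                "n_down": n_down,
                "down_percent": 100.0 * n_down / n_total,
                "W": comp.statistic,
                "p_value": comp.p_value,
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(outdir / "tissue_stats.tsv", sep="\t", index=False)
    return out


# ---------------------------------------------------------------------------
# full run


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every configured stage in order and write ``report.md``.

    On a stage failure, partial outputs are retained and MANIFEST.json notes
    the incomplete stage before the error is re-raised.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(cfg), "completed": []}
    results: dict = {}
    plan: list[tuple[str, object]] = [
        ("qc_profiling", lambda: stage_qc(cfg, "profiling")),
        ("qc_validation", lambda: stage_qc(cfg, "validation")),
        ("select_refs", lambda: stage_references(cfg)),
        ("discover", lambda: stage_discovery(cfg, results["select_refs"])),
        ("validate", lambda: stage_validation(cfg, results["select_refs"])),
        ("perf", lambda: stage_performance(cfg, results["select_refs"])),
        ("survival", lambda: stage_survival(cfg)),
    ]
    if cfg.tissue:
        plan.append(("tissue", lambda: stage_tissue(cfg)))
    try:
        for name, fn in plan:
            log.info("stage %s ...", name)
            results[name] = fn()
            manifest["completed"].append(name)
    except ExomirError as exc:
        manifest["failed_stage"] = name
        manifest["error"] = str(exc)
        with open(outdir / "MANIFEST.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(name, str(exc)) from exc

    write_report(cfg, results, outdir / "report.md")
    manifest["completed"].append("report")
    with open(outdir / "MANIFEST.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return results


def write_report(cfg: RunConfig, results: dict, path: Path) -> None:
    disc = results.get("discover")
    lines = ["# Exosomal-miRNA biomarker pipeline report", ""]
    lines += [
        "## Configuration",
        f"- seed: {cfg.seed}",
        f"- censoring threshold Ct > {cfg.ct_max}; imputation at Ct {cfg.impute_ct}",
        f"- fold-change thresholds: up >= {cfg.up_threshold:.4g}, "
        f"down <= {cfg.down_threshold:.4g}",
        f"- references selected: {results.get('select_refs')}",
        "",
    ]
    if disc:
        cons = disc["consensus"]
        lines += ["## Discovery screen"]
        for pid, assays in disc["detected_per_pair"].items():
            lines.append(f"- {pid}: {len(assays)} assays detected")
        lines.append(f"- common to all pairs: {len(disc['common'])}")
        for ref, (up, down) in disc["calls"].items():
            lines.append(f"- vs {ref}: {len(up)} up, {len(down)} down")
        if cons.consensus_up or cons.consensus_down:
            lines.append(
                f"- consensus: {len(cons.consensus_up)} up "
                f"({', '.join(cons.consensus_up)}); "
                f"{len(cons.consensus_down)} down "
                f"({', '.join(cons.consensus_down)})"
            )
        else:
            lines.append("- no consensus biomarkers at the configured thresholds")
        lines.append("")
    for key, title in (
        ("validate", "## Validation cohort (Mann-Whitney)"),
        ("perf", "## Biomarker performance (ROC)"),
        ("survival", "## Progression-free survival (log-rank)"),
        ("tissue", "## Paired tissue (Wilcoxon signed-rank)"),
    ):
        df = results.get(key)
        if df is not None and len(df):
            lines += [title, "```", df.to_string(index=False), "```", ""]
    path.write_text("\n".join(lines), encoding="utf-8")
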