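"""Cohort aggregation: per-tumor metrics, group comparisons, plots.

``process_tumor`` runs every analysis stage whose inputs exist in a tumor
directory (layout per :func:`pdxmet.synthetic.make_cohort`);
``build_report`` aggregates the records, runs the group comparisons and
renders summary tables and figures. Missing stages are logged and their
columns left empty — the report is still produced for available metrics.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .adc import compute_adc_map, summarize_adc
from .hp import lp_map_and_mean, select_voxels
from .isotopomer import MultipletSet, fit_isotopomer, select_model
from .nmr import add_fractional_enrichment, quantify_1d
from .stats import compare_groups, growth_rate, two_way_anova
from .t2w import analyze_t2w

logger = logging.getLogger("pdxmet.report")

__all__ = ["process_tumor", "build_report", "run_all"]

#: imaging metrics compared by one-way ANOVA + Tukey, reported mean +- SD
IMAGING_METRICS = ("pct_hyper", "pct_hypo", "mean_adc", "lp_auc_ratio",
                   "growth_rate")


def process_tumor(tumor_dir: str | Path, isotopomer_seed: int = 0) -> dict:
    """Compute every available metric for one tumor directory."""
    tumor_dir = Path(tumor_dir)
    rec: dict = {"tumor_id": tumor_dir.name}
    missing: list[str] = []

    t0 = time.perf_counter()
    if (tumor_dir / "t2w.nii").exists():
        vol = _io.load_volume(tumor_dir / "t2w.nii")
        rois = _io.load_rois(tumor_dir / "tumor_mask.nii",
                             tumor_dir / "kidney_mask.nii")
        summary = analyze_t2w(vol, rois)
        rec.update(pct_hyper=summary.pct_hyper, pct_hypo=summary.pct_hypo,
                   n_hyper=summary.n_hyper, n_hypo=summary.n_hypo,
                   n_tumor_voxels=summary.n_total,
                   t2w_ref_mean=summary.ref_mean, t2w_ref_sd=summary.ref_sd)
        rec["_t2w_values"] = summary.values  # for the histogram overlay
    else:
        missing.append("t2w")
    logger.info("%s t2w stage: %.2fs", tumor_dir.name, time.perf_counter() - t0)

    t0 = time.perf_counter()
    if (tumor_dir / "dwi.nii").exists():
        series = _io.load_dwi(tumor_dir / "dwi.nii")
        mask = _io.load_mask(tumor_dir / "dwi_mask.nii")
        adc_map = compute_adc_map(series, mask)
        s = summarize_adc(adc_map)
        rec.update(mean_adc=s.mean_adc, adc_n_pass=s.n_pass,
                   adc_n_fail=s.n_fail)
    else:
        missing.append("adc")
    logger.info("%s adc stage: %.2fs", tumor_dir.name, time.perf_counter() - t0)

    t0 = time.perf_counter()
    if (tumor_dir / "hp_dynamics.nii").exists():
        grid = _io.load_dynamic_grid(tumor_dir / "hp_dynamics.nii")
        hp_mask = None
        if (tumor_dir / "hp_mask.nii").exists():
            hp_mask = _io.load_mask(tumor_dir / "hp_mask.nii")
        selection = select_voxels(grid)
        result = lp_map_and_mean(grid, selection, hp_mask)
        rec.update(lp_auc_ratio=result.mean_ratio,
                   lp_n_voxels=result.n_voxels)
    else:
        missing.append("hp")
    logger.info("%s hp stage: %.2fs", tumor_dir.name, time.perf_counter() - t0)

    t0 = time.perf_counter()
    if (tumor_dir / "nmr_peaks1d.csv").exists():
        peaks = pd.read_csv(tumor_dir / "nmr_peaks1d.csv")
        ref = _io.read_json(tumor_dir / "nmr_reference.json")
        table = quantify_1d(peaks, ref["tsp_amount_nmol"],
                            ref["tissue_mass_mg"],
                            tsp_protons=int(ref.get("tsp_protons", 9)))
        if (tumor_dir / "nmr_hsqc.csv").exists():
            hsqc = pd.read_csv(tumor_dir / "nmr_hsqc.csv")
            table = add_fractional_enrichment(table, hsqc)
        table.to_csv(tumor_dir / "metabolite_table.csv", index=False)
        rec["_metabolites"] = table
        for met in ("lactate", "glutamate"):
            row = table[table["metabolite"] == met]
            if len(row):
                rec[f"{met}_nmol_mg"] = float(row["absolute_nmol_mg"].iloc[0])
                if "fe" in row:
                    rec[f"{met}_fe"] = float(row["fe"].iloc[0])
        if (tumor_dir / "nmr_multiplets.csv").exists():
            mult = MultipletSet.from_frame(
                pd.read_csv(tumor_dir / "nmr_multiplets.csv"))
            fits = fit_isotopomer(mult, seed=isotopomer_seed)
            best, diag = select_model(fits)
            diag.to_csv(tumor_dir / "isotopomer_fits.csv", index=False)
            rec.update(isotopomer_model=best.model,
                       f_pdh=best.params["f_pdh"], y_pc=best.params["y_pc"],
                       y_s=best.params["y_s"], isotopomer_aicc=best.aicc,
                       isotopomer_adp=best.adp,
                       isotopomer_overfit=best.overfit_flag)
    else:
        missing.append("nmr")
    logger.info("%s nmr stage: %.2fs", tumor_dir.name, time.perf_counter() - t0)

    if (tumor_dir / "volumes.csv").exists():
        gv = pd.read_csv(tumor_dir / "volumes.csv")
        rec["growth_rate"] = growth_rate(gv["volume_cc"], gv["day"])
    else:
        missing.append("growth")

    if missing:
        logger.warning("%s: missing stages %s", tumor_dir.name, missing)
    rec["missing_stages"] = ";".join(missing)
    return rec


def _comparison_rows(records: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for metric in IMAGING_METRICS + ("lactate_fe", "glutamate_fe"):
        if metric not in records.columns:
            continue
        try:
            res = compare_groups(records, metric, "group", test="anova_tukey")
        except ValueError as err:
            rows.append({"metric": metric, "test": "anova_tukey",
                         "statistic": np.nan, "pvalue": np.nan,
                         "significant": False, "note": str(err)})
            continue
        rows.append({"metric": metric, "test": res.test,
                     "statistic": res.statistic, "pvalue": res.pvalue,
                     "significant": res.significant, "note": ""})
    return pd.DataFrame(rows)


def _plots(records: pd.DataFrame, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    from .t2w import pdf_histogram

    # normalized T2w histogram overlay, one averaged curve per group
    if "_t2w_values" in records.columns:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for g, sub in records.groupby("group"):
            pooled = np.concatenate([v for v in sub["_t2w_values"] if v is not None])
            edges, dens = pdf_histogram(pooled, 100)
            ax.plot(0.5 * (edges[:-1] + edges[1:]), dens, label=str(g))
        ax.set_xlabel("normalized T2w intensity")
        ax.set_ylabel("probability density")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / "t2w_histograms.png", dpi=120)
        plt.close(fig)

    metrics = [m for m in IMAGING_METRICS if m in records.columns]
    if metrics:
        fig, axes = plt.subplots(1, len(metrics), figsize=(3 * len(metrics), 3))
        axes = np.atleast_1d(axes)
        for ax, metric in zip(axes, metrics):
            stats = records.groupby("group")[metric].agg(["mean", "std"])
            ax.bar(stats.index.astype(str), stats["mean"],
                   yerr=stats["std"].fillna(0.0), capsize=4)
            ax.set_title(metric)
            ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        fig.savefig(out_dir / "group_metrics.png", dpi=120)
        plt.close(fig)


def build_report(cohort_dir: str | Path, out_dir: str | Path,
                 seed: int = 0, plots: bool = True) -> pd.DataFrame:
    """Run all stages over a cohort directory and write the report bundle.

    Writes ``records.csv`` (one row per tumor), ``comparisons.csv``,
    ``metabolite_anova.csv`` (two-way metabolite x group, when available),
    ``summary.json`` and PNG figures into ``out_dir``. Returns the records
    table.
    """
    cohort_dir, out_dir = Path(cohort_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = None
    if (cohort_dir / "manifest.csv").exists():
        manifest = pd.read_csv(cohort_dir / "manifest.csv")

    tumor_dirs = sorted(p for p in cohort_dir.iterdir() if p.is_dir())
    if not tumor_dirs:
        raise ValueError(f"no tumor directories under {cohort_dir}")
    records = []
    for td in tumor_dirs:
        t0 = time.perf_counter()
        rec = process_tumor(td, isotopomer_seed=seed)
        logger.info("%s: total %.2fs", td.name, time.perf_counter() - t0)
        records.append(rec)
    records = pd.DataFrame(records)

    if manifest is not None:
        records = records.merge(manifest[["tumor_id", "group"]],
                                on="tumor_id", how="left")
    if "group" not in records.columns or records["group"].isna().all():
        records["group"] = "all"

    public = records.drop(columns=[c for c in records.columns
                                   if c.startswith("_")])
    public.to_csv(out_dir / "records.csv", index=False)

    comparisons = _comparison_rows(records)
    comparisons.to_csv(out_dir / "comparisons.csv", index=False)

    # metabolite x group two-way ANOVA on absolute concentrations
    if "_metabolites" in records.columns:
        long = []
        for _, row in records.iterrows():
            tab = row["_metabolites"]
            if tab is None:
                continue
            for _, m in tab.iterrows():
                long.append({"tumor_id": row["tumor_id"], "group": row["group"],
                             "metabolite": m["metabolite"],
                             "absolute_nmol_mg": m["absolute_nmol_mg"]})
        long = pd.DataFrame(long)
        if len(long) and long["group"].nunique() >= 2:
            try:
                table = two_way_anova(long, "absolute_nmol_mg",
                                      "metabolite", "group")
                table.to_csv(out_dir / "metabolite_anova.csv")
            except ValueError as err:
                logger.warning("metabolite two-way ANOVA skipped: %s", err)
        long.to_csv(out_dir / "metabolites_long.csv", index=False)

    summary = {
        "n_tumors": int(len(records)),
        "groups": sorted(records["group"].astype(str).unique().tolist()),
        "group_means": {
            metric: {str(g): float(v) for g, v in
                     records.groupby("group")[metric].mean().items()}
            for metric in IMAGING_METRICS if metric in records.columns
        },
    }
    _io.write_json(out_dir / "summary.json", summary)

    if plots:
        _plots(records, out_dir)
    return public


def run_all(out_dir: str | Path, seed: int = 0,
            groups=None, plots: bool = True) -> pd.DataFrame:
    """End-to-end chain: simulate a cohort, run every stage, build the report.

    The cohort is written to ``out_dir/cohort`` and the report bundle to
    ``out_dir/report``. Identical seeds give byte-identical outputs.
    """
    from .synthetic import make_cohort

    out_dir = Path(out_dir)
    cohort_dir = out_dir / "cohort"
    report_dir = out_dir / "report"
    t0 = time.perf_counter()
    make_cohort(groups, cohort_dir, seed=seed)
    logger.info("simulate stage: %.2fs", time.perf_counter() - t0)
    return build_report(cohort_dir, report_dir, seed=seed, plots=plots)
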