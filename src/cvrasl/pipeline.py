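"""End-to-end orchestration: phantom -> preprocessing -> CVR/lag -> ASL fit
-> comparative statistics, with on-disk outputs and a JSON report.

The per-subject stage order is fixed: tNSR masking, bulk trace alignment,
nuisance regression, wavelet denoising, spatial smoothing, x4 temporal
interpolation, CVR regression, steal segmentation (on the bulk-aligned
CVR), lag mapping, kinetic-model inversion of the ASL series.  The cohort
analysis then builds tissue-ROI summaries (Kruskal-Wallis + FDR,
Spearman), 5%-bin ROIs feeding repeated-measures correlations, and
voxelwise Pearson correlations with a group-level Wilcoxon test.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .asl_quant import (compute_perfusion_weighted, fit_kinetic_model,
                        reconstruct_t1w_from_m0)
from .config import RunConfig
from .core import (AslAcquisitionParams, AslSeries, BoldSeries, BreathingTrace,
                   LabelMap, Tissue, ANALYZED_TISSUES)
from .cvr_lag import StealMasks, fit_cvr_map, map_hemodynamic_lag, segment_steal
from .preprocess import (bulk_align_trace, compute_tnsr_mask,
                         interpolate_temporal, regress_nuisance, smooth_spatial,
                         wavelet_denoise)
from .stats import (benjamini_hochberg, bin_rois, cohort_summary,
                    exclude_nonanalyzed, kruskal_wallis, rmcorr, spearman,
                    tissue_roi_summary, voxelwise_correlation,
                    wilcoxon_signed_rank)
from .synthdata import (BreathingProtocol, GeometrySpec, generate_asl_phantom,
                        generate_bold_phantom, generate_label_map,
                        generate_petco2_trace, make_coupled_truth)

logger = logging.getLogger("cvrasl")

__all__ = ["SubjectMaps", "PipelineError", "process_subject",
           "analyze_cohort", "simulate_subject", "run_pipeline"]

#: the four metric names used across tables and the report
METRICS = ("CBF", "AAT", "CVR", "lag")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class SubjectMaps:
    """Per-subject outputs entering the comparative statistics."""

    subject: str
    cvr: np.ndarray          # bulk-aligned CVR (enters steal segmentation/stats)
    lag: np.ndarray
    cbf: np.ndarray
    aat: np.ndarray
    labels: LabelMap
    analyzed_mask: np.ndarray
    steal: StealMasks
    bulk_shift: float
    cvr_at_lag: np.ndarray | None = None  # lag-optimized CVR, for comparison


def simulate_subject(cfg: RunConfig, subject_seed: int, subject: str):
    """Generate one subject's phantom inputs (trace, BOLD, ASL, labels)."""
    labels = generate_label_map(cfg.shape, GeometrySpec(), seed=subject_seed)
    truth = make_coupled_truth(labels, seed=subject_seed,
                               noise_sd=cfg.bold_noise_sd)
    protocol = BreathingProtocol()
    trace = generate_petco2_trace(protocol, dt=cfg.trace_dt,
                                  noise_sd=cfg.trace_noise_sd,
                                  seed=subject_seed + 1)
    bold = generate_bold_phantom(truth, trace, tr=cfg.tr,
                                 baseline_petco2=protocol.baseline_petco2)
    asl = generate_asl_phantom(truth, AslAcquisitionParams(),
                               noise_sd=2.0, seed=subject_seed + 2)
    return truth, trace, bold, asl


def process_subject(bold: BoldSeries,
                    trace: BreathingTrace,
                    asl: AslSeries | None,
                    labels: LabelMap,
                    cfg: RunConfig,
                    subject: str = "s01",
                    baseline_end_s: float = 300.0) -> SubjectMaps:
    """Run the full per-subject processing chain."""
    try:
        tnsr = compute_tnsr_mask(bold, percentile=cfg.tnsr_percentile)
    except ValueError as exc:
        raise PipelineError("tnsr", str(exc)) from exc
    masked = BoldSeries(bold.data, bold.tr, bold.voxel_size, tnsr.retained)

    gm_mask = labels.mask(Tissue.GM) & tnsr.retained
    if not gm_mask.any():
        raise PipelineError("align", "no grey-matter voxels after masking")
    gm_ts = masked.data[gm_mask].mean(axis=0)
    try:
        aligned, shift = bulk_align_trace(trace, gm_ts, bold.tr,
                                          max_shift=cfg.max_shift)
    except ValueError as exc:
        raise PipelineError("align", str(exc)) from exc

    conditioned = regress_nuisance(masked, None, gm_ts,
                                   corr_threshold=cfg.corr_threshold)
    conditioned = wavelet_denoise(conditioned)
    conditioned = smooth_spatial(conditioned, fwhm_mm=cfg.fwhm_mm)

    bold_i = interpolate_temporal(conditioned, factor=cfg.interp_factor)
    reg_i = interpolate_temporal(aligned.petco2, factor=cfg.interp_factor)

    # frames fully inside the pre-stimulus baseline window
    n_base = int(baseline_end_s / bold_i.tr)
    baseline_idx = np.arange(max(min(n_base, bold_i.n_volumes // 2), 2))

    try:
        cvr_map = fit_cvr_map(bold_i, reg_i, baseline_index=baseline_idx)
        lag_map, _cvr_at_lag = map_hemodynamic_lag(
            bold_i, reg_i, lag_range=cfg.lag_range,
            baseline_index=baseline_idx)
    except ValueError as exc:
        raise PipelineError("cvr_lag", str(exc)) from exc

    try:
        analyzed = exclude_nonanalyzed(labels, tnsr.retained)
    except ValueError as exc:
        raise PipelineError("exclude", str(exc)) from exc
    steal = segment_steal(cvr_map, analyzed)

    if asl is not None:
        try:
            recon = reconstruct_t1w_from_m0(asl.m0, asl.params)
            dm, _kept = compute_perfusion_weighted(asl)
            m0_eq = np.where(recon.valid, recon.equilibrium, 0.0)
            perf = fit_kinetic_model(dm, m0_eq, asl.params,
                                     mask=labels.brain_mask)
        except ValueError as exc:
            raise PipelineError("asl", str(exc)) from exc
        cbf, aat = perf.cbf, np.nan_to_num(perf.aat, nan=0.0)
    else:
        cbf = np.zeros(labels.data.shape)
        aat = np.zeros(labels.data.shape)

    return SubjectMaps(subject=subject, cvr=cvr_map.cvr, lag=lag_map.lag,
                       cbf=cbf, aat=aat, labels=labels,
                       analyzed_mask=analyzed, steal=steal, bulk_shift=shift,
                       cvr_at_lag=_cvr_at_lag.cvr)


def _metric_maps(sm: SubjectMaps) -> dict[str, np.ndarray]:
    return {"CBF": sm.cbf, "AAT": sm.aat, "CVR": sm.cvr, "lag": sm.lag}


def analyze_cohort(subjects: list[SubjectMaps],
                   n_bins: int = 20,
                   fdr_q: float = 0.05) -> dict:
    """The three comparative analyses over a list of processed subjects.

    Returns a JSON-serializable report with blocks ``tissue_roi``,
    ``binned_rmcorr`` and ``voxelwise``, plus the tidy tables under
    ``tables`` (pandas DataFrames; stripped before JSON dumping).
    """
    # -- analysis A: tissue ROI statistics ---------------------------------
    roi_rows = [tissue_roi_summary(_metric_maps(sm), sm.labels, sm.steal,
                                   subject=sm.subject,
                                   analyzed_mask=sm.analyzed_mask)
                for sm in subjects]
    roi = pd.concat(roi_rows, ignore_index=True)

    kw_tests = []
    for metric in METRICS:
        for status in ("steal", "non_steal"):
            sub = roi[(roi.metric == metric) & (roi.steal_status == status)]
            groups, names = [], []
            for tissue in ANALYZED_TISSUES:
                vals = sub[sub.tissue == tissue.name]["mean"].to_numpy()
                if len(vals) > 0:
                    groups.append(vals)
                    names.append(tissue.name)
            if len(groups) < 2:
                continue
            res = kruskal_wallis(groups, labels=tuple(names))
            kw_tests.append({"metric": metric, "steal_status": status,
                             "H": res.statistic, "p": res.p})
    if kw_tests:
        reject, p_adj = benjamini_hochberg([t["p"] for t in kw_tests], q=fdr_q)
        for t, rej, pa in zip(kw_tests, reject, p_adj):
            t["p_adjusted"] = float(pa)
            t["reject"] = bool(rej)

    spearman_tests = []
    pairs = (("CBF", "CVR"), ("AAT", "CVR"), ("CBF", "lag"), ("AAT", "lag"))
    for status in ("steal", "non_steal"):
        for tissue in ANALYZED_TISSUES:
            cell = roi[(roi.steal_status == status) & (roi.tissue == tissue.name)]
            wide = cell.pivot(index="subject", columns="metric", values="mean")
            for a, b in pairs:
                if a in wide and b in wide and wide[[a, b]].dropna().shape[0] >= 3:
                    sub = wide[[a, b]].dropna()
                    res = spearman(sub[a], sub[b])
                    spearman_tests.append({
                        "tissue": tissue.name, "steal_status": status,
                        "pair": f"{a}-{b}", "rho": res.statistic, "p": res.p})

    # -- analysis B: 5%-bin ROIs + repeated-measures correlation -----------
    bin_tables = []
    for sm in subjects:
        for status, mask in (("non_steal", sm.steal.non_steal),
                             ("steal", sm.steal.steal)):
            for sort_name in ("AAT", "CBF"):
                if mask.sum() < n_bins:
                    warnings.warn(
                        f"{sm.subject}/{status}: fewer voxels than bins")
                    continue
                maps = _metric_maps(sm)
                sort_map = maps.pop(sort_name)
                try:
                    tb = bin_rois(sort_map, maps, mask, n_bins=n_bins,
                                  sort_name=sort_name, subject=sm.subject)
                except ValueError as exc:
                    warnings.warn(f"{sm.subject}/{status}/{sort_name}: {exc}")
                    continue
                tb["steal_status"] = status
                tb["bin_variable"] = sort_name
                bin_tables.append(tb)
    binned = (pd.concat(bin_tables, ignore_index=True)
              if bin_tables else pd.DataFrame())

    rm_results = []
    rm_pairs = ((("AAT",), "mean_AAT", "mean_lag", "lag-AAT"),
                (("AAT",), "mean_AAT", "mean_CVR", "CVR-AAT"),
                (("CBF",), "mean_CBF", "mean_lag", "lag-CBF"),
                (("CBF",), "mean_CBF", "mean_CVR", "CVR-CBF"))
    for status in ("non_steal", "steal"):
        for (bin_var,), xcol, ycol, name in rm_pairs:
            sub = binned[(binned.get("steal_status") == status)
                         & (binned.get("bin_variable") == bin_var)] \
                if len(binned) else pd.DataFrame()
            if len(sub) == 0 or sub["subject"].nunique() < 2:
                continue
            try:
                res = rmcorr(sub.rename(columns={xcol: "x", ycol: "y"}),
                             x="x", y="y")
            except ValueError as exc:
                warnings.warn(f"rmcorr {name}/{status}: {exc}")
                continue
            rm_results.append({"pair": name, "steal_status": status,
                               "r_rm": res.r_rm, "slope": res.common_slope,
                               "df": res.df, "p": res.p})

    # -- analysis C: voxelwise correlation + group Wilcoxon ----------------
    vox_pairs = (("CBF", "CVR"), ("AAT", "lag"), ("CBF", "lag"), ("AAT", "CVR"))
    vox_rows = []
    for sm in subjects:
        maps = _metric_maps(sm)
        masks = {}
        if sm.steal.non_steal.sum() >= 3:
            masks["non_steal"] = sm.steal.non_steal
        if sm.steal.steal.sum() >= 3:
            masks["steal"] = sm.steal.steal
        for a, b in vox_pairs:
            try:
                rs = voxelwise_correlation(maps[a], maps[b], masks)
            except ValueError:
                continue
            for status, r in rs.items():
                vox_rows.append({"subject": sm.subject, "pair": f"{a}-{b}",
                                 "steal_status": status, "r": r})
    vox = pd.DataFrame(vox_rows)
    vox_tests = []
    if len(vox):
        for (pair, status), grp in vox.groupby(["pair", "steal_status"]):
            res = wilcoxon_signed_rank(grp["r"].to_numpy())
            vox_tests.append({"pair": pair, "steal_status": status,
                              "median_r": float(grp["r"].median()),
                              "W": res.statistic, "p": res.p,
                              "flagged": res.flagged})

    return {
        "tissue_roi": {"kruskal_wallis": kw_tests, "spearman": spearman_tests},
        "binned_rmcorr": rm_results,
        "voxelwise": vox_tests,
        "tables": {"roi": roi, "binned": binned, "voxelwise_r": vox},
    }


def run_pipeline(cfg: RunConfig, write_outputs: bool = True) -> dict:
    """Execute the configured workflow and write maps, tables and a report."""
    from .io import read_asl_params, read_nifti, read_trace, write_nifti

    cfg.validate()
    outdir = Path(cfg.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    subjects: list[SubjectMaps] = []
    rng = np.random.SeedSequence(cfg.seed)
    if cfg.simulate:
        seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                 rng.spawn(cfg.n_subjects)]
        for i, s_seed in enumerate(seeds):
            sid = f"sub{i + 1:02d}"
            _truth, trace, bold, asl = simulate_subject(cfg, s_seed, sid)
            sm = process_subject(bold, trace,
                                 asl if cfg.run_asl else None,
                                 _truth.labels, cfg, subject=sid)
            subjects.append(sm)
            logger.info("processed %s (seed %d, bulk shift %.3f s)",
                        sid, s_seed, sm.bulk_shift)
    else:
        data, voxel_size, tr = read_nifti(cfg.bold_path)
        lab_data, _, _ = read_nifti(cfg.labels_path)
        labels = LabelMap(np.rint(lab_data).astype(np.int16))
        bold = BoldSeries(data, tr or cfg.tr, voxel_size, labels.brain_mask)
        trace = read_trace(cfg.trace_path)
        asl = None
        if cfg.run_asl:
            params = read_asl_params(cfg.asl_params_path)
            asl_data, _, _ = read_nifti(cfg.asl_path)
            # 5D layout: (x, y, z, n_plds, 2*n_pairs + 1) with the last axis
            # alternating control/label pairs and the M0 pair first
            if asl_data.ndim != 5 or asl_data.shape[4] < 3:
                raise PipelineError(
                    "asl", "ASL input must be 5D (x, y, z, plds, 2*pairs+1) "
                           "with the M0 volume first on the last axis")
            m0 = np.moveaxis(asl_data[..., 0], 3, 0)
            rest = asl_data[..., 1:]
            control = np.moveaxis(rest[..., 0::2], (3, 4), (1, 0))
            label = np.moveaxis(rest[..., 1::2], (3, 4), (1, 0))
            asl = AslSeries(label=label, control=control, m0=m0, params=params)
        subjects.append(process_subject(bold, trace, asl, labels, cfg))

    report = analyze_cohort(subjects, n_bins=cfg.n_bins, fdr_q=cfg.fdr_q)
    tables = report.pop("tables")
    report["cohort_table1"] = cohort_summary()
    report["config"] = {"seed": cfg.seed, "n_subjects": len(subjects),
                        "version": __version__}
    report["subjects"] = [{"subject": sm.subject,
                           "bulk_shift_s": sm.bulk_shift,
                           "steal_voxels": int(sm.steal.steal.sum()),
                           "analyzed_voxels": int(sm.analyzed_mask.sum())}
                          for sm in subjects]

    if write_outputs:
        for sm in subjects:
            sdir = outdir / sm.subject
            sdir.mkdir(parents=True, exist_ok=True)
            for name, arr in _metric_maps(sm).items():
                write_nifti(arr, sdir / f"{name.lower()}.nii.gz")
            write_nifti(sm.labels.data.astype(np.int16),
                        sdir / "labels.nii.gz")
        for name, tb in tables.items():
            tb.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
    report["tables"] = tables
    return report
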