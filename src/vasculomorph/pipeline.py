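"""End-to-end orchestration of the vascular-microscopy workflow.

``run_pipeline`` drives the whole chain on a synthetic phantom — tree
generation, rasterization, multi-echo simulation, relaxometry, vessel
segmentation, skeleton morphometry, zonal analysis, DTI, and the
cross-modality fractional-volume validation — writing every stage's maps
and tables into a run directory together with a JSON manifest (config hash,
per-stage wall time, key summary numbers).  ``make_report`` renders the
summaries into a text report and figures.

A single global seed fans out to per-stage seeds through a fixed counter
scheme (``stage_seed = (seed * 1009 + stage_index) mod 2^31``) so that a
stage rerun in isolation reproduces its in-pipeline output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dti import GradientScheme, fa_from_eigenvalues, fact_track, fit_tensor, scalar_maps, streamlines_table
from .io_formats import write_table, write_volume
from .morphometry import branch_table, coarse_grid_fv, distance_map, fractional_volume, skeletonize
from .phantom import (PhantomSpec, SignalParams, ZoneParams, generate_vessel_tree,
                      ground_truth_morphometry, rasterize_tree, simulate_dwi, simulate_mge)
from .registration import compare_invivo_exvivo, fv_correlation, resample
from .relaxometry import EchoSeries, delta_r2star, fit_monoexponential
from .segmentation import (MUCT_MIN_VOXELS, MUCT_SIGMAS, MUMRI_MIN_VOXELS,
                           MUMRI_SIGMAS, segment_vessels)
from .volume import Volume3D
from .zones import compare_zones, make_zones, spherical_element, zonal_morphometry

STAGES = ("phantom", "mge", "relaxometry", "segmentation",
          "morphometry", "zones", "dti", "validation")


@dataclass
class RunConfig:
    """Flat parameter set for one pipeline run; serializes to flat TOML."""

    seed: int = 0
    # phantom geometry; the ultra-high-resolution grid so the ~100 µm
    # zonal structuring element stays well-resolved
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_um: tuple[float, float, float] = (33.0, 31.0, 30.0)
    tumor_radius_frac: float = 0.25     # tumor radius / min domain half-size
    transition_width_um: float = 200.0
    snr: float = 20.0
    noise: str = "rician"
    # segmentation
    preset: str = "mumri"               # "mumri" | "muct"
    sigmas: tuple[float, ...] = MUMRI_SIGMAS
    min_voxels: int = MUMRI_MIN_VOXELS
    # zones
    element_um: float = 100.0
    # validation
    grid_dims: tuple[int, int, int] = (4, 4, 4)
    # dti
    fa_threshold: float = 0.2
    angle_threshold_deg: float = 40.0
    run_dti: bool = True
    run_zones: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.preset == "muct":
            self.sigmas = MUCT_SIGMAS
            self.min_voxels = MUCT_MIN_VOXELS

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1009 + STAGES.index(stage)) % (2**31)

    # -- flat TOML round-trip ------------------------------------------

    def to_toml(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            elif isinstance(v, bool):
                lines.append(f"{f.name} = {'true' if v else 'false'}")
            elif isinstance(v, tuple):
                lines.append(f"{f.name} = [{', '.join(repr(x) for x in v)}]")
            else:
                lines.append(f"{f.name} = {v!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, text: str) -> "RunConfig":
        raw = tomllib.loads(text)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_toml().encode()).hexdigest()[:16]


def _phantom_spec(cfg: RunConfig) -> PhantomSpec:
    shape = np.asarray(cfg.shape)
    sp = np.asarray(cfg.spacing_um)
    dom = shape * sp
    r_t = cfg.tumor_radius_frac * dom.min() / 2.0 + cfg.transition_width_um / 2.0
    return PhantomSpec(
        domain_size_um=tuple(dom),
        spacing_um=tuple(sp),
        tumor_center_um=tuple(dom / 2.0),
        tumor_radius_um=float(r_t),
        transition_width_um=cfg.transition_width_um,
        noise=cfg.noise,  # type: ignore[arg-type]
        snr=cfg.snr,
        seed=cfg.stage_seed("phantom"),
    )


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run the full workflow into ``out_dir``; returns the manifest dict.

    Any stage failure aborts with the stage name while retaining the
    partial outputs already written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.toml").write_text(cfg.to_toml())
    manifest: dict = {"config_hash": cfg.config_hash(), "version": __version__,
                      "stages": {}, "summary": {}}
    t_all = time.perf_counter()
    stage = "phantom"
    try:
        # ---- phantom -------------------------------------------------
        t0 = time.perf_counter()
        spec = _phantom_spec(cfg)
        tree = generate_vessel_tree(spec)
        vessels_gt, labels, radius_map = rasterize_tree(tree, cfg.shape, cfg.spacing_um)
        gt_table, gt_fv = ground_truth_morphometry(tree, spec)
        write_volume(vessels_gt, out / "vessels_gt.nii.gz")
        write_volume(radius_map, out / "radius_gt.nii.gz")
        write_table(gt_table, out / "segments_gt.csv")
        manifest["summary"]["gt_fv"] = gt_fv
        manifest["summary"]["n_gt_segments"] = len(tree)
        manifest["stages"]["phantom"] = {"seconds": time.perf_counter() - t0,
                                         "n_segments": len(tree)}

        # ---- MGE simulation -----------------------------------------
        stage = "mge"
        t0 = time.perf_counter()
        params = SignalParams()
        dom = np.asarray(spec.domain_size_um)
        grid_um = vessels_gt.voxel_to_physical(np.argwhere(np.ones(cfg.shape, dtype=bool)))
        tumor_dist = np.linalg.norm(grid_um - dom / 2.0, axis=1).reshape(cfg.shape)
        tumor_sphere = tumor_dist <= spec.tumor_radius_um
        r2_pre = np.full(cfg.shape, params.r2star_tissue)
        # contrast agent: R2* boost proportional to local blood volume,
        # strongest in the tumor sphere
        r2_post = r2_pre + 0.04 * tumor_sphere + 0.01
        echoes_pre = simulate_mge(vessels_gt, params, noise=cfg.noise, snr=cfg.snr,
                                  seed=cfg.stage_seed("mge"), r2star_map=r2_pre)
        echoes_post = simulate_mge(vessels_gt, params, noise=cfg.noise, snr=cfg.snr,
                                   seed=cfg.stage_seed("mge") + 1, r2star_map=r2_post)
        write_volume(echoes_pre[0], out / "mge_echo1.nii.gz")
        manifest["stages"]["mge"] = {"seconds": time.perf_counter() - t0,
                                     "echo_times_ms": list(params.echo_times_ms)}

        # ---- relaxometry --------------------------------------------
        stage = "relaxometry"
        t0 = time.perf_counter()
        series_pre = EchoSeries(params.echo_times_ms, echoes_pre)
        series_post = EchoSeries(params.echo_times_ms, echoes_post)
        fit_pre = fit_monoexponential(series_pre)
        fit_post = fit_monoexponential(series_post)
        dcbv = delta_r2star(fit_pre, fit_post)
        write_volume(fit_pre.r2star, out / "r2star_pre.nii.gz")
        write_volume(fit_post.r2star, out / "r2star_post.nii.gz")
        write_volume(dcbv, out / "delta_r2star.nii.gz")
        manifest["stages"]["relaxometry"] = {"seconds": time.perf_counter() - t0}

        # ---- segmentation -------------------------------------------
        stage = "segmentation"
        t0 = time.perf_counter()
        vessels = segment_vessels(echoes_pre[0], sigmas=cfg.sigmas,
                                  polarity="dark_tubes", min_voxels=cfg.min_voxels)
        write_volume(vessels, out / "vessels_segmented.nii.gz")
        inter = (np.asarray(vessels.data) > 0) & (np.asarray(vessels_gt.data) > 0)
        dice = 2.0 * inter.sum() / max(1, (np.asarray(vessels.data) > 0).sum()
                                       + (np.asarray(vessels_gt.data) > 0).sum())
        manifest["summary"]["dice_vs_gt"] = float(dice)
        manifest["stages"]["segmentation"] = {
            "seconds": time.perf_counter() - t0,
            "sigmas": list(cfg.sigmas), "min_voxels": cfg.min_voxels,
            "preset": cfg.preset, "dice": float(dice)}

        # ---- morphometry --------------------------------------------
        stage = "morphometry"
        t0 = time.perf_counter()
        skel = skeletonize(vessels)
        edm = distance_map(vessels)
        segs = branch_table(skel, edm)
        write_table(segs, out / "segments.csv")
        roi_all = vessels.with_data(np.ones(cfg.shape, dtype=np.uint8), kind="binary")
        fv_total = fractional_volume(vessels, roi_all)
        fv_grid, fv_cells = coarse_grid_fv(vessels, cfg.grid_dims)
        write_table(fv_cells, out / "fv_grid.csv")
        manifest["summary"]["fv_segmented"] = fv_total
        manifest["stages"]["morphometry"] = {"seconds": time.perf_counter() - t0,
                                             "n_branches": len(segs)}

        # ---- zones ---------------------------------------------------
        if cfg.run_zones:
            stage = "zones"
            t0 = time.perf_counter()
            roi = vessels.with_data(tumor_sphere.astype(np.uint8), kind="binary")
            brain = roi_all
            element = spherical_element(cfg.element_um, vessels.spacing)
            zones = make_zones(roi, brain, element)
            seg_z, summary = zonal_morphometry(segs, skel, zones)
            write_table(seg_z, out / "segments_zoned.csv")
            write_table(summary, out / "zones_summary.csv")
            per_zone = {z: seg_z.loc[seg_z["zone"] == z, "length_um"].to_numpy()
                        for z in ("tumor", "transition", "normal")}
            tests = compare_zones(per_zone)
            write_table(tests, out / "zones_tests.csv")
            manifest["stages"]["zones"] = {"seconds": time.perf_counter() - t0,
                                           "element_um": cfg.element_um}

        # ---- DTI -----------------------------------------------------
        if cfg.run_dti:
            stage = "dti"
            t0 = time.perf_counter()
            scheme = GradientScheme()
            dshape = tuple(max(8, s // 2) for s in cfg.shape)
            tens = np.zeros(dshape + (3, 3))
            # white-matter-like anisotropy along x outside the tumor,
            # near-isotropic diffusion inside it
            iso = np.eye(3) * 7e-4
            aniso = np.diag([1.5e-3, 3e-4, 3e-4])
            ci = np.array(dshape) / 2.0
            ii, jj, kk = np.meshgrid(*[np.arange(s) for s in dshape], indexing="ij")
            dist = np.sqrt(((ii - ci[0]) ** 2 + (jj - ci[1]) ** 2 + (kk - ci[2]) ** 2))
            in_tumor = dist <= min(dshape) / 4.0
            tens[...] = aniso
            tens[in_tumor] = iso
            b0, dwis = simulate_dwi(tens, SignalParams(b_value=scheme.b_value,
                                                       directions=scheme.directions),
                                    noise=cfg.noise, snr=cfg.snr,
                                    seed=cfg.stage_seed("dti"),
                                    spacing=(94.0, 97.0, 600.0))
            field_fit = fit_tensor(b0, dwis, scheme)
            adc, fa = scalar_maps(field_fit)
            write_volume(adc, out / "adc.nii.gz")
            write_volume(fa, out / "fa.nii.gz")
            seeds = [(i, dshape[1] // 2, dshape[2] // 2) for i in range(0, dshape[0], 4)]
            lines = fact_track(field_fit, seeds, cfg.fa_threshold, cfg.angle_threshold_deg)
            write_table(streamlines_table(lines), out / "streamlines.csv")
            manifest["summary"]["median_fa_outside_tumor"] = float(
                np.median(np.asarray(fa.data)[~in_tumor]))
            manifest["stages"]["dti"] = {
                "seconds": time.perf_counter() - t0,
                "fa_threshold": cfg.fa_threshold,
                "angle_threshold_deg": cfg.angle_threshold_deg,
                "n_streamlines": int(sum(len(l) > 0 for l in lines))}

        # ---- validation ---------------------------------------------
        stage = "validation"
        t0 = time.perf_counter()
        fva, _ = coarse_grid_fv(vessels, cfg.grid_dims)
        fvb, _ = coarse_grid_fv(vessels_gt, cfg.grid_dims)
        rep = fv_correlation(fva, fvb)
        write_table(rep.pairs.assign(r=rep.r, slope=rep.slope,
                                     intercept=rep.intercept),
                    out / "fv_correlation.csv")
        roi_t = vessels.with_data(tumor_sphere.astype(np.uint8), kind="binary")
        roi_c = vessels.with_data((~tumor_sphere).astype(np.uint8), kind="binary")
        fv_map = vessels.with_data(np.asarray(vessels.data, dtype=float), kind="parametric")
        comp = compare_invivo_exvivo(dcbv, fv_map, roi_t, roi_c)
        manifest["summary"]["fv_corr_r"] = rep.r
        manifest["summary"]["fv_corr_slope"] = rep.slope
        manifest["summary"]["median_dcbv_tumor"] = comp["rois"]["tumor"]["median_dcbv"]
        manifest["summary"]["median_dcbv_contra"] = comp["rois"]["contralateral"]["median_dcbv"]
        manifest["stages"]["validation"] = {"seconds": time.perf_counter() - t0,
                                            "grid_dims": list(cfg.grid_dims)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["total_seconds"] = time.perf_counter() - t_all
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def make_report(run_dir: str | Path) -> Path:
    """Summarize a completed run: text report plus figures.

    Missing stage outputs are listed in the report rather than raising, so
    a partial run still yields a usable summary.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    manifest = json.loads((run / "manifest.json").read_text())
    lines = [f"vasculomorph run report — config {manifest['config_hash']}", ""]
    missing = []

    zoned = run / "segments_zoned.csv"
    if zoned.exists():
        df = pd.read_csv(zoned)
        fig, ax = plt.subplots(figsize=(5, 4))
        zones_present = [z for z in ("normal", "transition", "tumor")
                         if (df["zone"] == z).any()]
        data = [df.loc[df["zone"] == z, "length_um"] for z in zones_present]
        ax.boxplot(data, tick_labels=zones_present)
        ax.set_ylabel("branch length (µm)")
        fig.savefig(run / "report_zonal_lengths.png", dpi=100)
        plt.close(fig)
        lines.append("Zonal branch-length summary:")
        for z in zones_present:
            sub = df.loc[df["zone"] == z, "length_um"]
            lines.append(f"  {z:>10}: n={len(sub)} median={sub.median():.1f} µm")
        lines.append("")
    else:
        missing.append(zoned.name)

    corr = run / "fv_correlation.csv"
    if corr.exists():
        df = pd.read_csv(corr)
        r = df["r"].iloc[0]
        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.scatter(df["fv_a"], df["fv_b"], s=12)
        ax.set_xlabel("FV (segmented)")
        ax.set_ylabel("FV (ground truth)")
        ax.set_title(f"r = {r:.3f}")
        fig.savefig(run / "report_fv_correlation.png", dpi=100)
        plt.close(fig)
        lines.append(f"FV cross-grid correlation: r = {r:.3f}")
        lines.append("")
    else:
        missing.append(corr.name)

    fa_file = run / "fa.nii.gz"
    if fa_file.exists():
        lines.append(f"FA map present; median FA outside tumor = "
                     f"{manifest['summary'].get('median_fa_outside_tumor', float('nan')):.3f}")
        lines.append("")

    if missing:
        lines.append("Missing stage outputs: " + ", ".join(missing))
    for k, v in sorted(manifest["summary"].items()):
        lines.append(f"{k}: {v}")
    report = run / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    return report
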