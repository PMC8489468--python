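"""End-to-end orchestration: simulate -> average -> train -> denoise ->
quantify -> evaluate, with a checksum manifest for reproducibility.

Every stochastic stage derives its seed from the global seed via fixed
offsets (see :func:`quickdwi.interface.config.stage_seed`), so a config +
seed pair pins the whole run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..acquisition import (
    AcquisitionProtocol,
    ClinicalImage,
    DWIStack,
    TraceStack,
    acquire,
    average_acquisitions,
    denormalize,
    normalize,
    trace_weighted,
)
from ..dnif import DnifModel, build_model, denoise, train
from ..evaluate import image_metrics, wilcoxon_bh
from ..phantom import GroundTruth, generate_phantom, random_phantom_spec
from ..quantify import fit_adc, mavd, rdm, roi_stats
from .config import PipelineConfig, stage_seed
from .io import write_clinical, write_nifti, write_stack

__all__ = ["PhantomRun", "run_pipeline", "simulate_phantom", "training_pairs", "denoised_b_images"]

log = logging.getLogger("quickdwi")


@dataclass
class PhantomRun:
    """All simulated artifacts of one phantom."""

    index: int
    gt: GroundTruth
    stack: DWIStack
    traces: TraceStack
    clinical: ClinicalImage


def simulate_phantom(cfg: PipelineConfig, index: int) -> PhantomRun:
    """Generate phantom #index and push it through the averaging chain."""
    ph = cfg.phantoms
    spec = random_phantom_spec(
        seed=stage_seed(cfg.global_seed, "phantom", index),
        grid_shape=ph.grid_shape,
        lesion_adc=ph.lesion_adc,
        lesion_radius=ph.lesion_radius,
        lesion_s0_range=tuple(ph.lesion_s0_range),
        background_s0=ph.background_s0,
    )
    gt = generate_phantom(spec)
    protocol = AcquisitionProtocol(
        b_values=cfg.protocol.b_values,
        n_directions=cfg.protocol.n_directions,
        n_acquisitions=cfg.protocol.n_acquisitions,
        noise_sigma=cfg.protocol.noise_sigma,
        intensity_ceiling=cfg.protocol.intensity_ceiling,
        seed=stage_seed(cfg.global_seed, "acquire", index),
    )
    stack = acquire(gt, protocol)
    traces = trace_weighted(stack)
    clinical = average_acquisitions(traces)
    return PhantomRun(index=index, gt=gt, stack=stack, traces=traces, clinical=clinical)


def training_pairs(run: PhantomRun, n_acquisitions: int | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    """(normalized single-acquisition image, normalized clinical target) pairs.

    Pools every b-value and direction; optionally restricts to the first
    ``n_acquisitions`` repeats to bound training cost.
    """
    p = run.stack.protocol
    ceiling = p.intensity_ceiling
    na = p.n_acquisitions if n_acquisitions is None else min(n_acquisitions, p.n_acquisitions)
    pairs = []
    for ib in range(len(p.b_values)):
        target = normalize(run.clinical.data[ib], ceiling)
        for j in range(p.n_directions):
            for a in range(na):
                pairs.append((normalize(run.stack.data[ib, j, a], ceiling), target))
    return pairs


def denoised_b_images(model: DnifModel, run: PhantomRun) -> np.ndarray:
    """Denoise the (direction 0, acquisition 0) single-shot image per b-value.

    Returns raw-intensity images (denormalized, clipped to >= 0).
    """
    p = run.stack.protocol
    out = np.empty_like(run.clinical.data)
    for ib in range(len(p.b_values)):
        noisy = normalize(run.stack.data[ib, 0, 0], p.intensity_ceiling)
        out[ib] = np.clip(denormalize(denoise(model, noisy), p.intensity_ceiling), 0.0, None)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full pipeline; returns (and writes) the artifact manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "files": {}, "training_files": {}}
    stage = "simulate"
    try:
        # ---- simulate + average -------------------------------------
        log.info("simulate: %d train + %d val phantoms (seed %d)",
                 cfg.phantoms.n_train, cfg.phantoms.n_val, cfg.global_seed)
        train_runs = [simulate_phantom(cfg, i) for i in range(cfg.phantoms.n_train)]
        val_runs = [
            simulate_phantom(cfg, cfg.phantoms.n_train + i)
            for i in range(cfg.phantoms.n_val)
        ]
        files: list[Path] = []
        for run in val_runs:
            d = out / f"val{run.index:03d}"
            files += write_stack(run.stack, d, "noa1")
            files += write_clinical(run.clinical, d, "clinical")
            files.append(write_nifti(run.gt.adc_map, d / "gt_adc.nii"))
            for label, mask in run.gt.roi_masks.items():
                files.append(write_nifti(mask.astype(np.float32), d / f"roi_{label}.nii"))
        manifest["stages"].append("simulate")
        manifest["stages"].append("average")

        # ---- train ---------------------------------------------------
        stage = "train"
        pairs = []
        for run in train_runs:
            pairs += training_pairs(run, n_acquisitions=cfg.train_acquisition_subset)
        log.info("train: %d pairs, loss=%s, seed %d", len(pairs), cfg.train.loss,
                 stage_seed(cfg.global_seed, "train"))
        model_cfg = cfg.model
        model = build_model(model_cfg)
        train_cfg = cfg.train
        if train_cfg.seed == 0:
            from dataclasses import replace

            train_cfg = replace(train_cfg, seed=stage_seed(cfg.global_seed, "train"))
        model = train(model, pairs, train_cfg)
        ckpt = out / "model.ckpt.npz"
        model.save(str(ckpt))
        loss_csv = out / "loss_history.csv"
        loss_csv.write_text(
            "epoch,loss\n"
            + "\n".join(f"{i},{v:.10g}" for i, v in enumerate(model.training_history))
        )
        train_files = [ckpt, loss_csv]

        # ---- denoise + quantify + evaluate ---------------------------
        stage = "denoise"
        rows = ["phantom,image,mse,ssim,psnr"]
        metric_pairs: dict[str, list[tuple[float, float]]] = {
            "mse": [], "ssim": [], "psnr": []
        }
        quant_report: dict[str, dict] = {}
        for run in val_runs:
            d = out / f"val{run.index:03d}"
            p = run.stack.protocol
            ceiling = p.intensity_ceiling
            dnif_imgs = denoised_b_images(model, run)
            for ib, b in enumerate(p.b_values):
                files.append(write_nifti(dnif_imgs[ib], d / f"dnif_b{int(round(b)):04d}.nii"))

            stage = "evaluate"
            for ib, b in enumerate(p.b_values):
                ref = normalize(run.clinical.data[ib], ceiling)
                noisy = normalize(run.stack.data[ib, 0, 0], ceiling)
                pred = normalize(dnif_imgs[ib], ceiling)
                mn = image_metrics(noisy, ref)
                md = image_metrics(pred, ref)
                rows.append(f"{run.index},noa1_b{int(b)},{mn.mse:.8g},{mn.ssim:.8g},{mn.psnr:.8g}")
                rows.append(f"{run.index},dnif_b{int(b)},{md.mse:.8g},{md.ssim:.8g},{md.psnr:.8g}")
                metric_pairs["mse"].append((mn.mse, md.mse))
                metric_pairs["ssim"].append((mn.ssim, md.ssim))
                metric_pairs["psnr"].append((mn.psnr, md.psnr))

            stage = "quantify"
            b_vals = p.b_values
            adc_noa1 = fit_adc(run.stack.data[:, 0, 0], b_vals, source="noa1")
            adc_clin = fit_adc(run.clinical.data, b_vals, source="noa_n")
            adc_dnif = fit_adc(dnif_imgs, b_vals, source="dnif")
            files.append(write_nifti(adc_noa1.data, d / "adc_noa1.nii"))
            files.append(write_nifti(adc_clin.data, d / "adc_noa_n.nii"))
            files.append(write_nifti(adc_dnif.data, d / "adc_dnif.nii"))
            entry: dict = {}
            for label, mask in run.gt.roi_masks.items():
                s_clin = roi_stats(adc_clin, mask)
                entry[label] = {
                    "noa": run.clinical.noa,
                    "mean_adc_noa_n": s_clin.mean_adc,
                    "cov_noa_n": s_clin.cov,
                    "stats": {},
                }
                for tag, amap in (("noa1", adc_noa1), ("dnif", adc_dnif)):
                    s = roi_stats(amap, mask)
                    entry[label]["stats"][tag] = {
                        "mean_adc": s.mean_adc,
                        "cov": s.cov,
                        "rdm_vs_noa_n_percent": rdm(amap, adc_clin, mask),
                        "mavd_vs_noa_n": mavd(amap, adc_clin, mask),
                    }
            quant_report[f"val{run.index:03d}"] = entry

        stage = "evaluate"
        comparisons = wilcoxon_bh(
            {
                name: (
                    np.array([a for a, _ in vals]),
                    np.array([b for _, b in vals]),
                )
                for name, vals in metric_pairs.items()
            }
        )
        metrics_csv = out / "quality_metrics.csv"
        metrics_csv.write_text("\n".join(rows) + "\n")
        files.append(metrics_csv)
        quant_json = out / "roi_stats.json"
        quant_json.write_text(json.dumps(quant_report, indent=2))
        files.append(quant_json)
        comp_json = out / "comparisons.json"
        comp_json.write_text(
            json.dumps(
                [
                    dict(
                        metric=r.metric_name,
                        raw_p=None if r.undefined else r.raw_p,
                        adjusted_p=None if r.undefined else r.adjusted_p,
                        significant=r.significant,
                        undefined=r.undefined,
                    )
                    for r in comparisons
                ],
                indent=2,
            )
        )
        files.append(comp_json)
        manifest["stages"] += ["train", "denoise", "quantify", "evaluate"]

        manifest["files"] = {str(f.relative_to(out)): _sha256(f) for f in files}
        manifest["training_files"] = {str(f.relative_to(out)): _sha256(f) for f in train_files}
        manifest["global_seed"] = cfg.global_seed
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
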