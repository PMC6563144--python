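"""End-to-end orchestration with run manifests and stage caching.

A run executes simulate -> detect/crop -> train VAE -> embed -> classify
-> report, writing every intermediate artifact to disk and recording one
JSON manifest (config snapshot, derived per-stage seeds, artifact paths,
wall times, loss/accuracy summaries).  A stage is skipped when its
outputs already exist and no upstream stage re-ran, so deleting one
intermediate regenerates only the stages downstream of it.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import LatentMatrix, fewshot_svm, kmeans_classify
from .config import RunConfig, dump_config
from .detect import detect_and_crop
from .imgio import write_image
from .synth import generate_flow_sequence
from .train import TrainedModel, derive_seed
from .vae import VaeConfig, encode, standardize_crops, train_vae

STAGES = ("simulate", "detect", "vae_train", "embed", "classify", "report")


@dataclass
class RunManifest:
    seed: int
    config_yaml: str
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, name: str, seconds: float, outputs: list[str],
               summary: dict | None = None, skipped: bool = False) -> None:
        self.stages[name] = {"wall_time_s": round(seconds, 3),
                             "outputs": outputs,
                             "seed": derive_seed(self.seed, name),
                             "summary": summary or {},
                             "skipped": skipped}

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"seed": self.seed, "version": self.version,
             "config": self.config_yaml, "stages": self.stages}, indent=2))


def _outputs_exist(paths) -> bool:
    return all(Path(p).exists() for p in paths)


def end_to_end(cfg: RunConfig, out_dir, force: bool = False) -> RunManifest:
    """Run the full pipeline into ``out_dir``; returns the saved manifest.

    Deterministic given ``cfg.seed``: every stage derives its own sub-seed
    from the run seed, recorded in the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg.seed, dump_config(cfg))
    upstream_ran = force

    # ---- simulate ----
    frames_npz = out / "frames.npz"
    truth_csv = out / "ground_truth.csv"
    t0 = time.perf_counter()
    if upstream_ran or not _outputs_exist([frames_npz, truth_csv]):
        import dataclasses
        flow = dataclasses.replace(cfg.flow,
                                   seed=derive_seed(cfg.seed, "simulate"))
        frames, truth = generate_flow_sequence(flow, cfg.optics)
        np.savez_compressed(frames_npz,
                            pixels=np.stack([f.pixels for f in frames]),
                            px_size=cfg.optics.px_size)
        truth.to_csv(truth_csv, index=False)
        upstream_ran = True
        skipped = False
    else:
        skipped = True
    manifest.record("simulate", time.perf_counter() - t0,
                    [str(frames_npz), str(truth_csv)], skipped=skipped)

    # ---- detect / crop ----
    crops_npz = out / "crops.npz"
    index_csv = out / "crop_index.csv"
    t0 = time.perf_counter()
    if upstream_ran or not _outputs_exist([crops_npz, index_csv]):
        data = np.load(frames_npz)
        frames_arr = data["pixels"]
        truth = pd.read_csv(truth_csv, keep_default_na=False)
        crops = detect_and_crop(list(frames_arr), cfg.detector, truth)
        pixels = np.stack([c.pixels for c in crops]) if crops else \
            np.zeros((0, cfg.detector.crop_size, cfg.detector.crop_size))
        index = pd.DataFrame(
            {"crop_id": np.arange(len(crops)),
             "source_frame": [c.source_frame for c in crops],
             "center_row": [c.center[0] for c in crops],
             "center_col": [c.center[1] for c in crops],
             "species": [(c.ground_truth or {}).get("species", "") for c in crops],
             "z_um": [(c.ground_truth or {}).get("z", np.nan) for c in crops]})
        np.savez_compressed(crops_npz, pixels=pixels)
        index.to_csv(index_csv, index=False)
        upstream_ran = True
        skipped = False
        summary = {"n_frames": int(len(frames_arr)), "n_crops": int(len(crops))}
    else:
        skipped = True
        summary = {}
    manifest.record("detect", time.perf_counter() - t0,
                    [str(crops_npz), str(index_csv)], summary, skipped)

    # ---- VAE training ----
    model_path = out / "vae_model.npz"
    t0 = time.perf_counter()
    if upstream_ran or not _outputs_exist([model_path]):
        pixels = np.load(crops_npz)["pixels"]
        xs, mean, std = standardize_crops(pixels)
        import dataclasses
        vae_cfg = dataclasses.replace(cfg.vae,
                                      seed=derive_seed(cfg.seed, "vae_train"))
        model = train_vae(xs, vae_cfg)
        model.config["crop_mean"] = mean
        model.config["crop_std"] = std
        model.save(model_path)
        upstream_ran = True
        skipped = False
        summary = {"epochs": len(model.log),
                   "final": model.log[-1] if model.log else {}}
    else:
        skipped = True
        summary = {}
    manifest.record("vae_train", time.perf_counter() - t0,
                    [str(model_path)], summary, skipped)

    # ---- embed ----
    latents_csv = out / "latents.csv"
    t0 = time.perf_counter()
    if upstream_ran or not _outputs_exist([latents_csv]):
        model = TrainedModel.load(model_path)
        pixels = np.load(crops_npz)["pixels"]
        xs = (pixels - model.config["crop_mean"]) / model.config["crop_std"]
        code = encode(model, xs.astype(np.float32),
                      rng=np.random.default_rng(derive_seed(cfg.seed, "embed")))
        d = code.mu.shape[1]
        df = pd.DataFrame({"crop_id": np.arange(len(code.mu))})
        for j in range(d):
            df[f"mu_{j}"] = code.mu[:, j]
        for j in range(d):
            df[f"logvar_{j}"] = code.log_var[:, j]
        for j in range(d):
            df[f"z_{j}"] = code.z[:, j]
        df.to_csv(latents_csv, index=False)
        upstream_ran = True
        skipped = False
    else:
        skipped = True
    manifest.record("embed", time.perf_counter() - t0, [str(latents_csv)],
                    skipped=skipped)

    # ---- classify + report ----
    report_json = out / "report.json"
    t0 = time.perf_counter()
    if upstream_ran or not _outputs_exist([report_json]):
        lat = pd.read_csv(latents_csv)
        index = pd.read_csv(index_csv, keep_default_na=False)
        mu_cols = [c for c in lat.columns if c.startswith("mu_")]
        labels = index["species"].to_numpy()
        mask = labels != ""
        latmat = LatentMatrix(lat.loc[mask, mu_cols].to_numpy(),
                              ids=index.loc[mask, "crop_id"].to_numpy(),
                              labels=labels[mask])
        seed_cls = derive_seed(cfg.seed, "classify")
        km = kmeans_classify(latmat, k=cfg.analysis.kmeans_k, seed=seed_cls,
                             n_init=cfg.analysis.kmeans_restarts)
        fs, _ = fewshot_svm(latmat, n_per_class=cfg.analysis.fewshot_per_class,
                            seed=seed_cls, kernel=cfg.analysis.svm_kernel,
                            C=cfg.analysis.svm_c)
        report = {"kmeans": km.to_dict(), "fewshot_svm": fs.to_dict()}
        report_json.write_text(json.dumps(report, indent=2))
        skipped = False
        summary = {"kmeans_accuracy": km.accuracy,
                   "fewshot_accuracy": fs.accuracy}
    else:
        skipped = True
        summary = {}
    manifest.record("classify", time.perf_counter() - t0, [str(report_json)],
                    summary, skipped)

    manifest.save(out / "manifest.json")
    return manifest
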