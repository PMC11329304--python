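"""Experiment harness: phantom dataset -> trained cascade -> evaluation.

One call trains the patch presegmenter on mass-centered patches, generates
saliency maps for every image, trains the PSA-guided cascade and (for
comparison) an identical Attention U-net without PSA guidance, evaluates
both on held-out images in original-image space, and writes per-image CSVs
plus a JSON summary.  Every random draw descends deterministically from the
single master seed, so repeated runs produce byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .cascade import CascadeBundle, presegmenter_saliency
from .metrics import compute_metrics, summarize, write_reports_csv
from .networks import NetConfig, build_presegmenter, CascadeAttentionUNet
from .patching import extract_mass_centered_patches
from .phantom import PhantomConfig, generate_dataset
from .preprocess import binarize, preprocess_to_nspace, resize_image, \
    resize_mask, restore_to_original
from .training import TrainConfig, kfold_split, train_model

log = logging.getLogger("mammoseg.experiment")

__all__ = ["DEFAULT_CONFIG", "load_config", "run_experiment"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "threshold": 0.5,
    "phantom": {
        "n": 120,
        "image_size": 128,
        "n_masses_range": [1, 2],
        "mass_radius_range": [8.0, 16.0],
        "mass_contrast_range": [0.25, 0.45],
        "texture_noise_sd": 0.04,
        "boundary_irregularity": 0.3,
    },
    "geometry": {
        "patch_size": 128,
        "stride": 64,
        "preseg_input": 64,
        "cascade_input": 128,
    },
    "presegmenter_net": {"levels": 3, "filters": [4, 8, 16]},
    "cascade_net": {"levels": 3, "filters": [4, 8, 16]},
    "train": {"epochs": 30, "learning_rate": 1e-3, "batch_size": 2,
              "augment": False},
    "split": {"k": 1, "test_fraction": 0.2},
    "compare_standalone": True,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(source: str | Path | dict | None) -> dict:
    """Merge a YAML file / dict over the desk-scale defaults."""
    if source is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    if isinstance(source, dict):
        user = source
    else:
        user = yaml.safe_load(Path(source).read_text())
        if not isinstance(user, dict):
            raise ValueError(f"malformed config file {source}")
    return _merge(DEFAULT_CONFIG, user)


def _sub_seed(master: int, tag: str) -> int:
    return (int(master) * 2654435761 + zlib.crc32(tag.encode())) % (2 ** 31)


@dataclass
class _Sample:
    image_id: str
    image: np.ndarray          # raw phantom, original space
    mask: np.ndarray           # ground truth, original space
    mass_class: str
    three_n: np.ndarray        # padded-N-space three-channel
    mask_n: np.ndarray
    record: object
    img_model: np.ndarray      # cascade-input-space image
    mask_model: np.ndarray
    saliency_model: np.ndarray | None = None


def _prepare_samples(cfg: dict) -> list[_Sample]:
    ph = cfg["phantom"]
    geo = cfg["geometry"]
    pconf = PhantomConfig(
        image_size=ph["image_size"],
        n_masses=1,
        n_masses_range=tuple(ph.get("n_masses_range", [1, 1])),
        mass_radius_range=tuple(ph["mass_radius_range"]),
        mass_contrast_range=tuple(ph["mass_contrast_range"]),
        texture_noise_sd=ph["texture_noise_sd"],
        boundary_irregularity=ph["boundary_irregularity"],
        seed=_sub_seed(cfg["seed"], "phantom"),
    )
    raw = generate_dataset(ph["n"], pconf)
    cs = geo["cascade_input"]
    samples = []
    for i, s in enumerate(raw):
        three_n, mask_n, record = preprocess_to_nspace(s.image, s.mask,
                                                       model_size=cs)
        img_model = np.clip(resize_image(three_n, (cs, cs)), 0, 1)
        mask_model = resize_mask(mask_n, (cs, cs))
        mass_class = s.mass_records[0][3] if s.mass_records else "unknown"
        samples.append(_Sample(
            image_id=f"phantom_{i:04d}", image=s.image, mask=s.mask,
            mass_class=mass_class, three_n=three_n, mask_n=mask_n,
            record=record, img_model=img_model, mask_model=mask_model))
    return samples


def _patch_training_set(samples: list[_Sample], geo: dict) -> list[tuple]:
    """Mass-centered (image patch, mask patch) pairs resized to the
    presegmenter input size."""
    ps, inp = geo["patch_size"], geo["preseg_input"]
    out = []
    for s in samples:
        if not (s.mask_n > 0).any():
            continue
        for img_p, msk_p in extract_mass_centered_patches(s.three_n, s.mask_n, ps):
            out.append((np.clip(resize_image(img_p, (inp, inp)), 0, 1),
                        resize_mask(msk_p, (inp, inp))))
    return out


def _evaluate(samples: list[_Sample], predict_fn, threshold: float):
    reports = []
    for s in samples:
        prob = predict_fn(s)
        pred_model = binarize(prob, threshold).astype(np.float64)
        pred = binarize(restore_to_original(pred_model, s.record))
        reports.append(compute_metrics(pred, s.mask, image_id=s.image_id,
                                       mass_class=s.mass_class))
    return reports


def run_experiment(config: str | Path | dict | None = None,
                   out_dir: str | Path | None = None) -> dict:
    """Run the full desk-scale cascade experiment; returns the summary dict.

    When ``out_dir`` is given, per-image metric CSVs, the summary JSON,
    model weights and fold assignments are written there.
    """
    cfg = load_config(config)
    seed = int(cfg["seed"])
    geo = cfg["geometry"]
    threshold = float(cfg["threshold"])
    log.info("preparing %d phantoms (seed %d)", cfg["phantom"]["n"], seed)
    samples = _prepare_samples(cfg)
    ids = [s.image_id for s in samples]
    by_id = {s.image_id: s for s in samples}

    k = int(cfg["split"].get("k", 1))
    if k > 1:
        split = kfold_split(ids, k, seed=_sub_seed(seed, "folds"))
        folds = [(split.train_ids(f), split.fold_ids(f)) for f in range(k)]
        assignments = split.assignments
    else:
        rng = np.random.default_rng(_sub_seed(seed, "holdout"))
        order = list(rng.permutation(len(ids)))
        n_test = max(1, int(round(len(ids) * cfg["split"].get("test_fraction", 0.2))))
        test_ids = [ids[i] for i in order[:n_test]]
        train_ids = [ids[i] for i in order[n_test:]]
        folds = [(train_ids, test_ids)]
        assignments = {i: (0 if i in set(test_ids) else -1) for i in ids}

    tr = cfg["train"]

    def _train_cfg(tag: str, fold: int) -> TrainConfig:
        return TrainConfig(learning_rate=float(tr["learning_rate"]),
                           batch_size=int(tr["batch_size"]),
                           epochs=int(tr["epochs"]),
                           augment=bool(tr.get("augment", False)),
                           threshold=threshold,
                           seed=_sub_seed(seed, f"{tag}-train-f{fold}"))

    all_reports = {"cascade": [], "standalone": [], "presegmenter": []}
    histories = {"presegmenter": [], "cascade": [], "standalone": []}
    trained_nets: dict[str, object] = {}

    for fold, (train_ids, test_ids) in enumerate(folds):
        train_s = [by_id[i] for i in train_ids]
        test_s = [by_id[i] for i in test_ids]

        # ---- stage 1: patch presegmenter ----
        pn = cfg["presegmenter_net"]
        preseg = build_presegmenter(NetConfig(
            levels=int(pn["levels"]), filters_per_level=tuple(pn["filters"]),
            input_size=geo["preseg_input"], with_psa=False,
            seed=_sub_seed(seed, f"preseg-init-f{fold}")))
        patches = _patch_training_set(train_s, geo)
        log.info("fold %d: training presegmenter on %d mass patches",
                 fold, len(patches))
        _, hist = train_model(preseg, patches, _train_cfg("preseg", fold))
        histories["presegmenter"].append(hist)
        trained_nets[f"presegmenter_fold{fold}"] = preseg

        bundle = CascadeBundle(
            presegmenter_mode="patch", presegmenter=preseg, cascade=None,
            patch_size=geo["patch_size"], stride=geo["stride"],
            preseg_input_size=geo["preseg_input"],
            cascade_input_size=geo["cascade_input"], threshold=threshold)

        # ---- saliency maps for every image ----
        cs = geo["cascade_input"]
        for s in samples:
            sal = presegmenter_saliency(s.three_n, bundle)
            s.saliency_model = np.clip(resize_image(sal.grid, (cs, cs)), 0, 1)

        # presegmenter-only evaluation (thresholded saliency, image level)
        all_reports["presegmenter"].extend(_evaluate(
            test_s, lambda s: s.saliency_model, threshold))

        # ---- stage 2: PSA cascade vs standalone ----
        cn = cfg["cascade_net"]

        def _second_stage(with_psa: bool, tag: str):
            net = CascadeAttentionUNet(NetConfig(
                levels=int(cn["levels"]), filters_per_level=tuple(cn["filters"]),
                input_size=cs, with_psa=with_psa,
                seed=_sub_seed(seed, f"{tag}-init-f{fold}")))
            if with_psa:
                data = [(s.img_model, s.saliency_model, s.mask_model)
                        for s in train_s]
            else:
                data = [(s.img_model, s.mask_model) for s in train_s]
            _, hist = train_model(net, data, _train_cfg(tag, fold))
            histories[tag].append(hist)
            trained_nets[f"{tag}_fold{fold}"] = net
            return net

        log.info("fold %d: training cascade segmenter", fold)
        cascade_net = _second_stage(True, "cascade")
        all_reports["cascade"].extend(_evaluate(
            test_s, lambda s: cascade_net.predict(s.img_model, s.saliency_model),
            threshold))

        if cfg.get("compare_standalone", True):
            log.info("fold %d: training standalone segmenter", fold)
            standalone = _second_stage(False, "standalone")
            all_reports["standalone"].extend(_evaluate(
                test_s, lambda s: standalone.predict(s.img_model), threshold))

    summary = {
        "seed": seed,
        "n_images": len(samples),
        "n_test_images": sum(len(t) for _, t in folds),
        "threshold": threshold,
        "presegmenter": summarize(all_reports["presegmenter"],
                                  stratify_by_class=True),
        "cascade": summarize(all_reports["cascade"], stratify_by_class=True),
        "final_train_loss": {k: [h[-1] for h in v if h]
                             for k, v in histories.items()},
    }
    if all_reports["standalone"]:
        summary["standalone"] = summarize(all_reports["standalone"],
                                          stratify_by_class=True)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, reports in all_reports.items():
            if reports:
                write_reports_csv(reports, out / f"metrics_{name}.csv")
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
        (out / "folds.json").write_text(json.dumps(assignments, indent=2,
                                                   sort_keys=True))
        (out / "config.json").write_text(json.dumps(cfg, indent=2,
                                                    sort_keys=True))
        weights_dir = out / "weights"
        weights_dir.mkdir(exist_ok=True)
        for name, net in trained_nets.items():
            path = weights_dir / f"{name}.npz"
            net.save(path)
            digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
            net.config.validate()
            (weights_dir / f"{name}.yaml").write_text(net.config.to_yaml())
            log.info("checkpoint %s sha256:%s", path.name, digest)
    return summary
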