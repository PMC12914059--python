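"""End-to-end orchestration: simulate -> segment -> features -> dynamics ->
classify -> report, plus dataset builders shared by the tests, the
acceptance script and the CLI.

The default run sizes are chosen so that a full demo completes in minutes
on one CPU while exercising every stage on a few hundred synthetic cells.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, dynamics, features, io, segment, synth

log = logging.getLogger("deepuv")

STATIC_MIX = {"activated": 0.4, "quiescent": 0.4, "dead": 0.2}
SUBTYPE_MIX = {"cd4": 0.5, "cd8": 0.5}


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    scene: synth.SceneConfig = field(default_factory=synth.SceneConfig)
    train: classify.TrainConfig = field(default_factory=classify.TrainConfig)
    f_min: float = dynamics.DEFAULT_F_MIN
    crop_side: int = segment.DEFAULT_CROP_SIDE
    n_static_scenes: int = 8
    n_dynamic_scenes: int = 4
    run_segmentation: bool = True
    run_features: bool = True
    run_dynamics: bool = True
    run_classification: bool = True
    run_embedding: bool = False  # UMAP is the slowest optional stage

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "scene" in d and isinstance(d["scene"], dict):
            d["scene"] = synth.SceneConfig(**d["scene"])
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = classify.TrainConfig(**d["train"])
        return cls(**d)


def nucleus_in_frame(frame: np.ndarray, cell_mask: np.ndarray) -> np.ndarray:
    """Full-frame nucleus mask for one cell via Otsu binarization."""
    rows, cols = np.nonzero(cell_mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    sub = np.where(cell_mask, frame, 0.0)[r0:r1, c0:c1]
    seg = segment.segment_nucleus(sub)
    out = np.zeros_like(cell_mask, dtype=bool)
    out[r0:r1, c0:c1] = seg.nucleus
    return out


def collect_cells(frame, truth, crop_side=segment.DEFAULT_CROP_SIDE,
                  min_iou=0.5, use_segmentation=True):
    """Segment a scene and pair each detected cell with its ground truth.

    Returns a list of dicts with the predicted cell mask, the zero-padded
    crop of the background-corrected frame, and the matched ground-truth
    label.  Detections without a >= ``min_iou`` ground-truth partner are
    dropped (and vice versa), mirroring curation of an annotated dataset.
    """
    corrected = segment.background_correct(frame)
    if use_segmentation:
        pred = segment.segment_cells(corrected)
    else:
        pred = truth.label_mask
    matches = segment.match_labels(pred, truth.label_mask)
    spec = truth.cells.set_index("cell_id")
    cells = []
    for t_label, (p_label, iou) in sorted(matches.items()):
        if p_label == 0 or iou < min_iou:
            continue
        mask = pred == p_label
        try:
            crop = segment.crop_and_pad(corrected, pred, p_label, side=crop_side)
        except ValueError:
            continue
        cells.append(dict(
            cell_mask=mask, crop=crop, label=spec.loc[t_label, "label"],
            truth_id=t_label, pred_id=p_label, iou=iou,
        ))
    return cells


def generate_static_dataset(n_scenes=8, cells_per_scene=12, class_mix=None,
                            seed=0, scene_shape=(256, 256), pixel_size=0.3,
                            crop_side=segment.DEFAULT_CROP_SIDE,
                            use_segmentation=True):
    """Static 3-class dataset: crops, labels and a feature table."""
    class_mix = dict(class_mix or STATIC_MIX)
    crops, labels = [], []
    for k in range(n_scenes):
        cfg = synth.SceneConfig(
            image_height=scene_shape[0], image_width=scene_shape[1],
            pixel_size=pixel_size, n_cells=cells_per_scene,
            class_mix=class_mix, seed=int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31)),
        )
        frame, truth = synth.make_scene(cfg)
        for cell in collect_cells(frame, truth, crop_side=crop_side,
                                  use_segmentation=use_segmentation):
            crops.append(cell["crop"])
            labels.append(cell["label"])
    table = features.feature_table(crops, pixel_size=pixel_size)
    return crops, np.array(labels), table


def dynamic_cell_features(stack, frame, truth, frame_rate=8.0,
                          f_min=dynamics.DEFAULT_F_MIN,
                          crop_side=segment.DEFAULT_CROP_SIDE,
                          use_segmentation=True, truth_nuclei=False,
                          with_crops=False):
    """Per-cell dynamic (and static) features for one scene's stack.

    Segments the first frame, computes the pixelwise dynamic maps over the
    detected cells, partitions each into nucleus/cytoplasm, and aggregates
    phasor and power-law statistics per compartment.  Optionally also
    returns 4-channel crops [attenuation, g, s, beta] for the conv-net.
    """
    corrected = segment.background_correct(frame)
    cells = collect_cells(frame, truth, crop_side=crop_side,
                          use_segmentation=use_segmentation)
    if not cells:
        return pd.DataFrame(), [], []
    union = np.zeros(frame.shape, dtype=bool)
    for c in cells:
        union |= c["cell_mask"]
    maps = dynamics.dynamic_maps(stack, union, frame_rate, f_min=f_min)

    rows, labels, four_channel = [], [], []
    for c in cells:
        if truth_nuclei:
            nucleus = (truth.nucleus_mask == c["truth_id"]) & c["cell_mask"]
        else:
            nucleus = nucleus_in_frame(corrected, c["cell_mask"])
        agg = dynamics.aggregate_cell_dynamics(maps, c["cell_mask"], nucleus)
        static = features.static_features(c["crop"])
        rows.append({**agg, **static.to_dict()})
        labels.append(c["label"])
        if with_crops:
            pred_mask = np.where(c["cell_mask"], 1, 0)
            chans = [c["crop"].image]
            for plane in (maps.g, maps.s, maps.beta):
                chan = segment.crop_and_pad(np.nan_to_num(plane, nan=0.0),
                                            pred_mask, 1, side=crop_side)
                chans.append(chan.image)
            four_channel.append(np.stack(chans))  # [attenuation, g, s, beta]
    return pd.DataFrame(rows), np.array(labels), four_channel


def generate_subtype_dataset(n_scenes=10, cells_per_scene=12, seed=0,
                             scene_shape=(256, 256), n_frames=500,
                             frame_rate=8.0, f_min=dynamics.DEFAULT_F_MIN,
                             use_segmentation=True, truth_nuclei=False,
                             with_crops=False,
                             noise_sd=synth.DETECTOR_NOISE_SD):
    """CD4-like / CD8-like dynamic dataset across several scenes.

    Returns ``(table, labels, crops4)`` where ``table`` holds per-cell
    dynamic + static features and ``crops4`` the 4-channel crops (empty
    unless ``with_crops``).
    """
    tables, all_labels, all_crops = [], [], []
    for k in range(n_scenes):
        cfg = synth.SceneConfig(
            image_height=scene_shape[0], image_width=scene_shape[1],
            n_cells=cells_per_scene, class_mix=dict(SUBTYPE_MIX),
            seed=int(np.random.SeedSequence([seed, 7000 + k]).generate_state(1)[0] % (2**31)),
            n_frames=n_frames, frame_rate=frame_rate,
        )
        frame, truth = synth.make_scene(cfg)
        stack = synth.render_stack(cfg, frame, truth, noise_sd=noise_sd)
        tab, labels, crops4 = dynamic_cell_features(
            stack, frame, truth, frame_rate=frame_rate, f_min=f_min,
            use_segmentation=use_segmentation, truth_nuclei=truth_nuclei,
            with_crops=with_crops)
        if len(tab):
            tables.append(tab)
            all_labels.append(labels)
            all_crops.extend(crops4)
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    labels = np.concatenate(all_labels) if all_labels else np.array([])
    return table, labels, all_crops


DYNAMIC_FEATURE_COLUMNS = [
    "cell_mean_g", "cell_mean_s", "cell_mean_beta", "cell_mean_gs",
    "nucleus_mean_g", "nucleus_mean_s", "nucleus_mean_beta", "nucleus_mean_gs",
    "cyto_mean_g", "cyto_mean_s", "cyto_mean_beta", "cyto_mean_gs",
    "beta_skew", "beta_entropy", "g_skew", "g_entropy", "g_fractal",
    "s_skew", "s_entropy", "s_fractal",
]


def subtype_feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Dynamic + static feature columns used for subtype classification."""
    cols = [c for c in DYNAMIC_FEATURE_COLUMNS + features.STATIC_COLUMNS if c in table.columns]
    return table[cols]


def composition_experiment(n_train_scenes=12, n_samples=20, sample_cells=24,
                           seed=0, scene_shape=(320, 320), pixel_size=0.3):
    """Composition-estimation study on samples of known class mix.

    Trains the linear baseline on static features of a 3-class training
    set, then for each of ``n_samples`` simulated samples with a random
    known composition predicts per-cell classes and derives viability and
    activation percentages.  Returns a DataFrame of true vs predicted
    percentages plus the agreement fits.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    crops, labels, table = generate_static_dataset(
        n_scenes=n_train_scenes, cells_per_scene=12, seed=seed,
        pixel_size=pixel_size)
    model = classify.LinearBaselineClassifier().fit(
        features_matrix(table), labels)

    rows = []
    for k in range(n_samples):
        # random but bounded mixes keep every sample plausibly T-cell-like
        frac_dead = rng.uniform(0.05, 0.6)
        frac_act = rng.uniform(0.1, 0.9) * (1 - frac_dead)
        mix = {"dead": frac_dead, "activated": frac_act,
               "quiescent": 1 - frac_dead - frac_act}
        cfg = synth.SceneConfig(
            image_height=scene_shape[0], image_width=scene_shape[1],
            pixel_size=pixel_size, n_cells=sample_cells, class_mix=mix,
            seed=int(rng.integers(0, 2**31)),
        )
        frame, truth = synth.make_scene(cfg)
        cells = collect_cells(frame, truth)
        if not cells:
            continue
        tab = features.feature_table([c["crop"] for c in cells],
                                     pixel_size=pixel_size)
        viability, activation = classify.predict_composition(
            model, features_matrix(tab))
        counts = truth.cells["label"].value_counts()
        n_total = len(truth.cells)
        n_dead = int(counts.get("dead", 0))
        n_act = int(counts.get("activated", 0))
        n_quiet = int(counts.get("quiescent", 0))
        rows.append(dict(
            sample=k,
            true_viability=100.0 * (1 - n_dead / n_total),
            true_activation=100.0 * n_act / max(n_act + n_quiet, 1),
            pred_viability=viability, pred_activation=activation,
        ))
    result = pd.DataFrame(rows)
    via_fit = classify.agreement_fit(result["pred_viability"], result["true_viability"])
    act_fit = classify.agreement_fit(result["pred_activation"], result["true_activation"])
    return result, via_fit, act_fit


def features_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric static feature columns (drops validity flag and labels)."""
    return table[[c for c in features.STATIC_COLUMNS if c in table.columns]]


def frame_sweep(frame_counts, n_scenes=6, cells_per_scene=10, seed=0,
                n_frames=500, frame_rate=8.0) -> pd.DataFrame:
    """Subtype classification accuracy as a function of stack length.

    Generates full-length CD4-like/CD8-like stacks once, truncates each to
    every requested count, recomputes the dynamic features, and reports
    5-fold cross-validated baseline accuracy per count.
    """
    scenes = []
    for k in range(n_scenes):
        cfg = synth.SceneConfig(
            n_cells=cells_per_scene, class_mix=dict(SUBTYPE_MIX),
            seed=int(np.random.SeedSequence([seed, 8800 + k]).generate_state(1)[0] % (2**31)),
            n_frames=n_frames, frame_rate=frame_rate,
        )
        frame, truth = synth.make_scene(cfg)
        stack = synth.render_stack(cfg, frame, truth)
        scenes.append((stack, frame, truth))

    rows = []
    for count in frame_counts:
        tables, labels = [], []
        for stack, frame, truth in scenes:
            short = dynamics.truncate_stack(stack, count)
            tab, lab, _ = dynamic_cell_features(short, frame, truth,
                                                frame_rate=frame_rate)
            if len(tab):
                tables.append(tab)
                labels.append(lab)
        table = pd.concat(tables, ignore_index=True)
        y = np.concatenate(labels)
        pooled, _ = classify.cross_validate(
            classify.LinearBaselineClassifier(),
            subtype_feature_matrix(table), y, folds=5, seed=seed)
        rows.append(dict(n_frames=count, accuracy=pooled.accuracy,
                         n_cells=len(y)))
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the configured stages, writing artifacts into ``outdir``.

    Writes stacks/masks (TIFF), feature tables and embeddings (CSV),
    dynamic maps (float TIFF), pseudocolor panels (PNG), a metrics JSON
    and a structured log.  Re-running with the same config reproduces all
    numeric outputs.  Any stage failure raises with the stage name; the
    artifacts written so far are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    metrics: dict = {"config": config.to_dict()}
    t0 = time.time()
    stage = "simulate"
    try:
        io.save_json(outdir / "config.json", config.to_dict())
        log.info("simulating static scenes")
        demo_cfg = dataclasses.replace(config.scene, seed=config.seed)
        frame, truth = synth.make_scene(demo_cfg)
        io.save_mask(outdir / "truth_mask.tif", truth.label_mask)
        truth.cells.to_csv(outdir / "truth_cells.csv", index=False)

        crops, labels, table = generate_static_dataset(
            n_scenes=config.n_static_scenes, seed=config.seed,
            crop_side=config.crop_side,
            use_segmentation=config.run_segmentation)
        metrics["n_static_cells"] = int(len(labels))

        if config.run_features:
            stage = "features"
            table_out = table.copy()
            table_out["label"] = labels
            table_out.to_csv(outdir / "static_features.csv", index=False)
            ranking = features.rank_features_chi2(features_matrix(table), labels)
            ranking.to_csv(outdir / "feature_ranking.csv", index=False)
            metrics["top_features_3class"] = ranking["feature"].head(12).tolist()
            if config.run_embedding and len(labels) >= 16:
                coords = features.embed_2d(features_matrix(table), seed=config.seed)
                pd.DataFrame({"umap_1": coords[:, 0], "umap_2": coords[:, 1],
                              "label": labels}).to_csv(outdir / "embedding.csv", index=False)

        if config.run_dynamics:
            stage = "dynamics"
            log.info("simulating dynamic subtype scenes")
            dyn_table, dyn_labels, _ = generate_subtype_dataset(
                n_scenes=config.n_dynamic_scenes, seed=config.seed,
                n_frames=config.scene.n_frames, frame_rate=config.scene.frame_rate,
                f_min=config.f_min)
            out = dyn_table.copy()
            out["label"] = dyn_labels
            out.to_csv(outdir / "dynamic_features.csv", index=False)
            metrics["n_dynamic_cells"] = int(len(dyn_labels))

            # one illustrative scene's maps + pseudocolor panel
            cfg = dataclasses.replace(
                config.scene, n_cells=6, class_mix=dict(SUBTYPE_MIX), seed=config.seed)
            sframe, struth = synth.make_scene(cfg)
            stack = synth.render_stack(cfg, sframe, struth)
            io.save_stack(outdir / "demo_stack.tif", stack[:50])  # preview pages
            maps = dynamics.dynamic_maps(stack, struth.label_mask, cfg.frame_rate,
                                         f_min=config.f_min)
            io.save_map(outdir / "beta_map.tif", maps.beta)
            io.save_map(outdir / "phasor_g_map.tif", maps.g)
            io.save_map(outdir / "phasor_s_map.tif", maps.s)
            io.save_png(outdir / "beta_pseudocolor.png",
                        dynamics.pseudocolor(maps.beta, (1.0, 2.0), struth.label_mask))
            gs = maps.gs
            finite = gs[np.isfinite(gs)]
            if finite.size:
                io.save_png(outdir / "phasor_gs_pseudocolor.png",
                            dynamics.pseudocolor(gs, (finite.min(), finite.max() + 1e-9),
                                                 struth.label_mask))
            for comp in ("nucleus", "cyto"):
                col = f"{comp}_mean_beta"
                a = dyn_table.loc[dyn_labels == "cd4", col].dropna()
                b = dyn_table.loc[dyn_labels == "cd8", col].dropna()
                if len(a) >= 3 and len(b) >= 3:
                    t, p = dynamics.compare_groups(a, b)
                    metrics[f"{comp}_beta_ttest"] = {"t": t, "p": p,
                                                     "mean_cd4": float(a.mean()),
                                                     "mean_cd8": float(b.mean())}

        if config.run_classification:
            stage = "classification"
            log.info("training baseline classifiers")
            pooled3, _ = classify.cross_validate(
                classify.LinearBaselineClassifier(), features_matrix(table),
                labels, folds=config.train.folds, seed=config.seed)
            metrics["static_3class_cv_accuracy"] = pooled3.accuracy
            metrics["static_3class_confusion"] = pooled3.confusion.tolist()
            if config.run_dynamics and len(dyn_labels):
                pooled2, _ = classify.cross_validate(
                    classify.LinearBaselineClassifier(),
                    subtype_feature_matrix(dyn_table), dyn_labels,
                    folds=config.train.folds, seed=config.seed)
                metrics["subtype_cv_accuracy"] = pooled2.accuracy
                metrics["subtype_sensitivity"] = pooled2.sensitivity
                metrics["subtype_specificity"] = pooled2.specificity
                metrics["subtype_confusion"] = pooled2.confusion.tolist()
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    metrics["elapsed_s"] = time.time() - t0
    io.save_json(outdir / "metrics.json", metrics)
    return metrics
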