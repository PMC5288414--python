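"""Configuration-driven orchestration: simulate -> preprocess -> featurize ->
evaluate.

A run is described by one YAML/JSON config and executed into a run directory
containing every stage's outputs plus a manifest (config copy, fanned-out
seeds, content hashes), so the same config reproduces byte-identical results.
One global seed is fanned out to per-stage seeds by fixed offsets, keeping
stages reproducible independently of which subset runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import io as aio
from .evaluation import DEFAULT_C_GRID, nested_cv
from .image import (RedactionRegion, binarize, blank_region, deskew,
                    estimate_skew, locate_marker_line, sobel_edges,
                    MarkerNotFoundError)
from .imbalance import InterpolationUpsampler  # noqa: F401  (config surface)
from .lda import GibbsLDA, topic_feature_matrix
from .embeddings import Doc2Vec, embedding_feature_matrix
from .synthetic import (CorpusSpec, FormImageSpec, generate_corpus,
                        generate_form_image)
from .text import (BagOfWordsVectorizer, TfidfVectorizer, bow_matrix,
                   combine_features, tf_idf_matrix)

__all__ = ["load_config", "run_pipeline", "STAGE_SEED_OFFSETS"]

STAGE_SEED_OFFSETS = {"simulate": 11, "preprocess": 23, "featurize": 37,
                      "evaluate": 53}


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_seed(config: dict, stage: str) -> int:
    return (int(config.get("seed", 0)) + STAGE_SEED_OFFSETS[stage]) % (2 ** 31)


def stage_simulate(config: dict, run_dir: Path) -> None:
    seed = _stage_seed(config, "simulate")
    sim = config.get("simulate", {})
    out = run_dir / "simulated"
    out.mkdir(parents=True, exist_ok=True)

    img_cfg = dict(sim.get("images", {}))
    n_images = int(img_cfg.pop("n_images", 3))
    truths = {}
    for i in range(n_images):
        spec = FormImageSpec(seed=seed + i, **img_cfg)
        image, truth = generate_form_image(spec)
        name = f"form{i:03d}.tiff"
        aio.save_image(out / name, image)
        truths[name] = truth
    (out / "image_ground_truth.json").write_text(json.dumps(truths, indent=1))

    corpus_cfg = dict(sim.get("corpus", {}))
    spec = CorpusSpec(seed=seed + 1000, **corpus_cfg)
    corpus, truth = generate_corpus(spec)
    aio.save_corpus(out / "corpus", corpus)
    (out / "corpus_ground_truth.json").write_text(json.dumps(
        {"class_word": {str(c): list(map(float, v))
                        for c, v in truth["class_word"].items()},
         "vocabulary": truth["vocabulary"]}, indent=1))


def stage_preprocess(config: dict, run_dir: Path) -> None:
    pre = config.get("preprocess", {})
    in_dir = Path(pre.get("input", run_dir / "simulated"))
    out = run_dir / "preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    masks = pre.get("masks", {})
    report = {}
    for path in sorted(in_dir.glob("*.tif*")) + sorted(in_dir.glob("*.png")):
        image = binarize(aio.load_image(path), pre.get("threshold"))
        est = estimate_skew(image, range_deg=pre.get("range_deg", 20.0),
                            step_deg=pre.get("step_deg", 1.0))
        fixed = deskew(image, est.angle_deg)
        entry = {"angle_deg": est.angle_deg, "entropy": est.entropy}
        if path.name in masks:
            region = RedactionRegion(**masks[path.name])
            entry["marker_row"] = None
        else:
            try:
                row = locate_marker_line(sobel_edges(fixed),
                                         pre.get("search_fraction", 0.5))
                region = RedactionRegion(0, max(1, row), 0, fixed.shape[1])
                entry["marker_row"] = row
            except MarkerNotFoundError:
                region = None
                entry["marker_row"] = None
        if region is not None:
            fixed = blank_region(fixed, region)
            entry["redaction"] = region.__dict__
        aio.save_image(out / path.name, fixed)
        report[path.name] = entry
    (out / "preprocess_report.json").write_text(json.dumps(report, indent=1))


def _featurize(config: dict, run_dir: Path, corpus):
    feat = config.get("featurize", {})
    method = feat.get("method", "bow")
    seed = _stage_seed(config, "featurize")
    if method == "bow":
        return bow_matrix(corpus)
    if method == "ngram":
        return bow_matrix(corpus, ngram_sizes=(2, 3))
    if method == "tfidf":
        return tf_idf_matrix(corpus)
    if method == "lexical":  # all three families combined
        return combine_features([
            bow_matrix(corpus),
            tf_idf_matrix(corpus),
            bow_matrix(corpus, ngram_sizes=(2, 3)),
        ])
    if method == "lda":
        model = GibbsLDA(n_topics=feat.get("dim", 50),
                         n_iterations=feat.get("iterations", 200),
                         seed=seed).fit(corpus)
        return topic_feature_matrix(model, corpus)
    if method == "doc2vec":
        model = Doc2Vec(dim=feat.get("dim", 150),
                        window=feat.get("window", 5),
                        n_epochs=feat.get("epochs", 50),
                        seed=seed).fit(corpus)
        return embedding_feature_matrix(model.training_vectors())
    raise ValueError(f"unknown featurize method: {method}")


def stage_featurize(config: dict, run_dir: Path) -> None:
    feat = config.get("featurize", {})
    corpus_dir = Path(feat.get("input", run_dir / "simulated" / "corpus"))
    corpus = aio.load_corpus(corpus_dir, stopwords=set())
    out = run_dir / "features"
    out.mkdir(parents=True, exist_ok=True)
    dims = feat.get("dims")
    if dims:  # dimension sweep, one matrix per size
        for dim in dims:
            fm = _featurize({**config, "featurize": {**feat, "dim": dim}},
                            run_dir, corpus)
            aio.save_feature_matrix(out / f"{feat['method']}_{dim}.mtx", fm)
    else:
        fm = _featurize(config, run_dir, corpus)
        aio.save_feature_matrix(out / f"{feat.get('method', 'bow')}.mtx", fm)
    corpus_labels = corpus.labels
    np.savetxt(out / "labels.csv", corpus_labels, fmt="%d", header="label",
               comments="")


def stage_evaluate(config: dict, run_dir: Path) -> None:
    ev = config.get("evaluate", {})
    feat_dir = Path(ev.get("input", run_dir / "features"))
    matrices = sorted(feat_dir.glob("*.mtx"))
    labels = np.loadtxt(feat_dir / "labels.csv", skiprows=1, dtype=int)
    out = run_dir / "evaluation"
    out.mkdir(parents=True, exist_ok=True)
    upsample_cfg = ev.get("upsample")
    for path in matrices:
        fm = aio.load_feature_matrix(path)
        report = nested_cv(fm, labels,
                           outer_k=ev.get("outer_k", 7),
                           inner_k=ev.get("inner_k", 5),
                           C_grid=ev.get("C_grid", DEFAULT_C_GRID),
                           upsample_cfg=upsample_cfg,
                           seed=_stage_seed(config, "evaluate"))
        (out / f"{path.stem}_report.json").write_text(
            json.dumps(report.to_dict(), indent=1))


_STAGES = {"simulate": stage_simulate, "preprocess": stage_preprocess,
           "featurize": stage_featurize, "evaluate": stage_evaluate}


def run_pipeline(config: dict, run_dir: str | Path) -> Path:
    """Execute the enabled stages in order and write a manifest.

    ``config["stages"]`` lists the stages to run (default: all four in
    order).  Each stage reads its predecessor's outputs from the run
    directory unless the config points elsewhere; a missing upstream artifact
    raises an error naming the stage.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(_STAGES))
    unknown = set(stages) - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage in stages:
        try:
            _STAGES[stage](config, run_dir)
        except FileNotFoundError as exc:
            raise FileNotFoundError(
                f"stage '{stage}' is missing an upstream artifact: {exc}"
            ) from exc
    manifest = {
        "config": config,
        "seed": config.get("seed", 0),
        "stage_seeds": {s: _stage_seed(config, s) for s in stages},
        "outputs": {str(p.relative_to(run_dir)): _hash_file(p)
                    for p in sorted(run_dir.rglob("*"))
                    if p.is_file() and p.name != "manifest.json"},
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return run_dir
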