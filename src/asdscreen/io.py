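"""File-format plumbing: images, corpora, labels, feature matrices.

Images travel as TIFF or PNG (grayscale, intensities rescaled to [0, 1]);
corpora as one UTF-8 text file per document plus a ``labels.csv``
(``doc_id,label``); feature matrices as MatrixMarket ``.mtx`` with a sidecar
JSON carrying feature names and the penalty hint.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import tifffile
from PIL import Image

from .text import Corpus, Document, FeatureMatrix, tokenize

__all__ = [
    "save_image", "load_image",
    "save_corpus", "load_corpus",
    "save_feature_matrix", "load_feature_matrix",
]


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale TIFF or PNG."""
    path = Path(path)
    arr = (np.clip(np.asarray(image, dtype=float), 0, 1) * 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="L").save(path)


def load_image(path: str | Path) -> np.ndarray:
    """Read TIFF/PNG as a float image in [0, 1] (RGB collapses to luminance)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("L"))
    arr = arr.astype(float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


def save_corpus(directory: str | Path, corpus: Corpus) -> None:
    """One ``<doc_id>.txt`` per document plus ``labels.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for doc in corpus:
        (directory / f"{doc.doc_id}.txt").write_text(
            " ".join(doc.tokens), encoding="utf-8")
        rows.append({"doc_id": doc.doc_id, "label": doc.label})
    pd.DataFrame(rows).to_csv(directory / "labels.csv", index=False)


def load_corpus(directory: str | Path,
                stopwords: set[str] | None = None) -> Corpus:
    """Rebuild a corpus from per-document text files and ``labels.csv``.

    Text is re-tokenized, so externally transcribed documents go through the
    same normalization as synthetic ones.  An explicit empty ``stopwords``
    set disables stop-word removal (synthetic tokens are never stop words, so
    round-trips are exact either way).
    """
    directory = Path(directory)
    labels = pd.read_csv(directory / "labels.csv")
    docs = []
    for row in labels.itertuples():
        text = (directory / f"{row.doc_id}.txt").read_text(encoding="utf-8")
        label = None if pd.isna(row.label) else int(row.label)
        docs.append(Document(doc_id=str(row.doc_id),
                             tokens=tokenize(text, stopwords),
                             label=label))
    return Corpus(docs)


def save_feature_matrix(path: str | Path, fm: FeatureMatrix) -> None:
    """MatrixMarket file plus ``<stem>.json`` sidecar of names and hint."""
    from scipy.io import mmwrite
    path = Path(path)
    mmwrite(str(path), sp.coo_matrix(fm.values))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "feature_names": fm.feature_names,
        "penalty_hint": fm.penalty_hint,
    }))


def load_feature_matrix(path: str | Path) -> FeatureMatrix:
    from scipy.io import mmread
    path = Path(path)
    values = sp.csr_matrix(mmread(str(path)))
    meta = json.loads(path.with_suffix(".json").read_text())
    return FeatureMatrix(values, meta["feature_names"], meta["penalty_hint"])
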