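"""asdscreen: screening scanned medical forms for autism spectrum disorder.

De-skews and de-identifies scanned form images, turns transcribed text into
lexical, topic and paragraph-vector representations, rebalances the positive
class by nearest-neighbour interpolation, and evaluates squared-hinge linear
SVMs under nested cross-validation with the recall-weighted F2 score.
"""

from .evaluation import EvalReport, compute_metrics, f2_score, nested_cv
from .image import (MarkerNotFoundError, RedactionRegion, SkewEstimate,
                    binarize, blank_region, deskew, estimate_skew,
                    locate_marker_line, row_profile, skew_entropy, sobel_edges)
from .imbalance import InterpolationUpsampler, upsample
from .lda import GibbsLDA, topic_feature_matrix
from .embeddings import (Doc2Vec, embedding_feature_matrix, softmax_prob,
                         train_cbow, train_doc2vec)
from .svm import SquaredHingeSVM, objective, top_features
from .synthetic import (CorpusSpec, FormImageSpec, generate_corpus,
                        generate_form_image)
from .text import (BagOfWordsVectorizer, Corpus, Document, FeatureMatrix,
                   TfidfVectorizer, bow_matrix, combine_features,
                   extract_ngrams, tf_idf_matrix, tokenize)

__version__ = "0.1.0"

__all__ = [
    "EvalReport", "compute_metrics", "f2_score", "nested_cv",
    "MarkerNotFoundError", "RedactionRegion", "SkewEstimate", "binarize",
    "blank_region", "deskew", "estimate_skew", "locate_marker_line",
    "row_profile", "skew_entropy", "sobel_edges",
    "InterpolationUpsampler", "upsample",
    "GibbsLDA", "topic_feature_matrix",
    "Doc2Vec", "embedding_feature_matrix", "softmax_prob",
    "train_cbow", "train_doc2vec",
    "SquaredHingeSVM", "objective", "top_features",
    "CorpusSpec", "FormImageSpec", "generate_corpus", "generate_form_image",
    "BagOfWordsVectorizer", "Corpus", "Document", "FeatureMatrix",
    "TfidfVectorizer", "bow_matrix", "combine_features", "extract_ngrams",
    "tf_idf_matrix", "tokenize",
]
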