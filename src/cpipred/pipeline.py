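"""End-to-end orchestration: curate -> featurize -> train -> evaluate.

Convenience functions composing the stage modules, used by the CLI and by
benchmark evaluations. Feature models (fingerprint PCA, protein CBOW) are
fitted on the training split only and frozen for test/external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import curation, features, metrics
from .model import MLPInteractionClassifier

__all__ = ["FeatureModels", "fit_feature_models", "featurize_pairs",
           "train_eval_split", "evaluate_predictions"]


@dataclass
class FeatureModels:
    """Frozen featurization state: PCA projection + CBOW word model."""

    compound_pca: features.CompoundFingerprintPCA
    protein_embedder: features.ProteinCBOWEmbedder
    compound_vectors: dict[str, np.ndarray] = field(default_factory=dict)
    protein_vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def compound_vector(self, cid: str, fingerprints) -> np.ndarray:
        if cid not in self.compound_vectors:
            self.compound_vectors[cid] = self.compound_pca.transform(
                np.asarray(fingerprints[cid], dtype=float)[None, :]
            )[0]
        return self.compound_vectors[cid]

    def protein_vector(self, pid: str, sequences) -> np.ndarray:
        if pid not in self.protein_vectors:
            self.protein_vectors[pid] = self.protein_embedder.transform(
                [sequences[pid]]
            )[0]
        return self.protein_vectors[pid]


def fit_feature_models(
    train_pairs: list[curation.CPIPair],
    fingerprints: dict[str, np.ndarray],
    sequences: dict[str, str],
    n_compound: int = 200,
    n_protein: int = 100,
    cbow_epochs: int = 20,
    seed: int = 0,
) -> FeatureModels:
    """Fit the fingerprint PCA and protein CBOW on the training split only."""
    train_cids = sorted({p.compound_id for p in train_pairs})
    train_pids = sorted({p.protein_id for p in train_pairs})
    pca = features.CompoundFingerprintPCA(n_components=n_compound).fit(
        np.stack([fingerprints[c] for c in train_cids]).astype(float)
    )
    embedder = features.ProteinCBOWEmbedder(
        vector_size=n_protein, epochs=cbow_epochs, seed=seed,
    ).fit([sequences[p] for p in train_pids])
    return FeatureModels(compound_pca=pca, protein_embedder=embedder)


def featurize_pairs(
    pairs: list[curation.CPIPair],
    models: FeatureModels,
    fingerprints: dict[str, np.ndarray],
    sequences: dict[str, str],
) -> tuple[np.ndarray, np.ndarray]:
    """Pair feature matrix (compound block first) and label vector."""
    X = np.empty((len(pairs), models.compound_pca.n_components
                  + models.protein_embedder.vector_size))
    y = np.empty(len(pairs), dtype=int)
    for i, p in enumerate(pairs):
        X[i] = features.build_pair_vector(
            models.compound_vector(p.compound_id, fingerprints),
            models.protein_vector(p.protein_id, sequences),
            n_compound=models.compound_pca.n_components,
            n_protein=models.protein_embedder.vector_size,
        )
        y[i] = p.label
    return X, y


def train_eval_split(
    pairs, fingerprints, sequences, cfg: curation.CurationConfig,
    model_params: dict | None = None, cbow_epochs: int = 20,
):
    """Split, featurize, train and evaluate; returns (clf, models, results).

    ``results`` holds the held-out scalar metrics plus AUROC/AUPR and the
    split feature matrices for further analysis.
    """
    train, test = curation.split_dataset(pairs, cfg)
    models = fit_feature_models(
        train, fingerprints, sequences, cbow_epochs=cbow_epochs, seed=cfg.seed
    )
    X_tr, y_tr = featurize_pairs(train, models, fingerprints, sequences)
    X_te, y_te = featurize_pairs(test, models, fingerprints, sequences)
    params = dict(hidden1=256, hidden2=128, dropout=0.0, learning_rate=0.001,
                  epochs=150, input_scaling="global", seed=cfg.seed)
    params.update(model_params or {})
    clf = MLPInteractionClassifier(**params).fit(X_tr, y_tr)
    scores = clf.predict_proba(X_te)[:, 1]
    results = evaluate_predictions(y_te, scores, cutoff=clf.cutoff)
    results.update(
        train_pairs=train, test_pairs=test, X_train=X_tr, y_train=y_tr,
        X_test=X_te, y_test=y_te, scores=scores,
    )
    return clf, models, results


def evaluate_predictions(y_true, scores, cutoff: float = 0.5) -> dict:
    """Scalar + ranking metrics of probability scores against labels."""
    pred = (np.asarray(scores) >= cutoff).astype(int)
    out = metrics.scalar_metrics(metrics.confusion(y_true, pred))
    out["AUROC"] = metrics.auroc(y_true, scores)
    out["AUPR"] = metrics.aupr(y_true, scores)
    return out
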