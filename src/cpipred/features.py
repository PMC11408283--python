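"""Pair featurization: fingerprint PCA for compounds, 3-mer CBOW for proteins.

A compound-protein pair is represented by a 300-dimensional vector: the
first 200 components are principal-component scores of the compound's
2048-bit radius-2 Morgan fingerprint, the last 100 are the mean of CBOW
embeddings of the protein's non-overlapping 3-mer words.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .word2vec import CBOWWordModel

__all__ = [
    "morgan_fingerprint",
    "CompoundFingerprintPCA",
    "tokenize_protein",
    "ProteinCBOWEmbedder",
    "build_pair_vector",
    "build_pair_matrix",
]

_RDKIT_GEN = {}


def _fingerprint_generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _RDKIT_GEN:
        from rdkit.Chem import rdFingerprintGenerator

        _RDKIT_GEN[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _RDKIT_GEN[key]


def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """Circular (Morgan) fingerprint of a molecule as a 0/1 uint8 vector.

    Deterministic for a given structure: two SMILES spellings of the same
    molecule yield identical bits. Raises ``ValueError`` naming the input
    when the SMILES does not parse.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    fp = _fingerprint_generator(radius, n_bits).GetFingerprintAsNumPy(mol)
    return fp.astype(np.uint8)


class CompoundFingerprintPCA(BaseEstimator, TransformerMixin):
    """PCA reduction of fingerprint bit vectors to compound feature vectors.

    Fit on training-set fingerprints only; external compounds are
    transformed with the frozen projection (no leakage). When the requested
    component count exceeds the data rank the projection is truncated with
    a warning and transforms are zero-padded back to ``n_components`` so
    downstream dimensionality is stable.

    Parameters
    ----------
    n_components : number of principal components to retain (default 200).
    """

    def __init__(self, n_components: int = 200):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-d fingerprint matrix")
        k = min(self.n_components, min(X.shape))
        if k < self.n_components:
            warnings.warn(
                f"requested {self.n_components} components but data supports "
                f"only {k}; truncating"
            )
        self._pca = PCA(n_components=k, svd_solver="auto", random_state=0)
        self._pca.fit(X)
        self.components_ = self._pca.components_
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        self.mean_ = self._pca.mean_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = self._pca.transform(X)
        if scores.shape[1] < self.n_components:
            pad = np.zeros((scores.shape[0], self.n_components - scores.shape[1]))
            scores = np.hstack([scores, pad])
        return scores


def tokenize_protein(sequence: str) -> list[str]:
    """Split a protein sequence into non-overlapping 3-mer words.

    Single reading frame from the first residue; the trailing 1-2 residues
    of sequences whose length is not a multiple of three are dropped.
    """
    if len(sequence) < 3:
        raise ValueError(f"sequence too short to tokenize: {len(sequence)} < 3")
    return [sequence[i:i + 3] for i in range(0, len(sequence) - 2, 3)]


class ProteinCBOWEmbedder(BaseEstimator, TransformerMixin):
    """Protein embeddings: mean of CBOW vectors of the sequence's 3-mers.

    ``fit`` treats each training sequence as a document of non-overlapping
    3-mer words and trains a CBOW word model (dim 100, window 5, 5 negative
    samples by default); ``transform`` averages the fixed word vectors over
    each protein's words. Out-of-vocabulary words are skipped; a protein
    with no in-vocabulary word is outside the feature space and raises.

    ``workers=1`` with a fixed seed gives reproducible training; higher
    worker counts are accepted for configuration compatibility.
    """

    def __init__(self, vector_size=100, window=5, negative=5, epochs=20,
                 min_count=1, seed=0, workers=1):
        self.vector_size = vector_size
        self.window = window
        self.negative = negative
        self.epochs = epochs
        self.min_count = min_count
        self.seed = seed
        self.workers = workers

    def fit(self, sequences, y=None):
        corpus = [tokenize_protein(s) for s in sequences]
        self.word_model_ = CBOWWordModel(
            vector_size=self.vector_size, window=self.window,
            negative=self.negative, epochs=self.epochs,
            min_count=self.min_count, seed=self.seed, workers=self.workers,
        ).fit(corpus)
        self.vocabulary_ = self.word_model_.vocab_
        return self

    def transform(self, sequences) -> np.ndarray:
        check_is_fitted(self, "word_model_")
        out = np.empty((len(sequences), self.vector_size))
        for i, s in enumerate(sequences):
            out[i] = self.word_model_.mean_vector(tokenize_protein(s))
        return out


def build_pair_vector(
    compound_vec: np.ndarray, protein_vec: np.ndarray,
    n_compound: int = 200, n_protein: int = 100,
) -> np.ndarray:
    """Concatenate compound and protein features, compound block first."""
    cv = np.asarray(compound_vec, dtype=float).ravel()
    pv = np.asarray(protein_vec, dtype=float).ravel()
    if cv.size != n_compound:
        raise ValueError(f"compound vector length {cv.size} != {n_compound}")
    if pv.size != n_protein:
        raise ValueError(f"protein vector length {pv.size} != {n_protein}")
    return np.concatenate([cv, pv])


def build_pair_matrix(compound_vecs, protein_vecs) -> np.ndarray:
    """Row-wise concatenation of aligned compound and protein feature matrices."""
    C = np.atleast_2d(np.asarray(compound_vecs, dtype=float))
    P = np.atleast_2d(np.asarray(protein_vecs, dtype=float))
    if C.shape[0] != P.shape[0]:
        raise ValueError("compound and protein matrices differ in row count")
    return np.hstack([C, P])
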