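"""Applicability-domain analysis by protein embedding distance.

A trained CPI model is only reliable for proteins resembling its training
set. Similarity between a tested protein and the training proteins is
measured by Euclidean distance or cosine similarity between their CBOW
embeddings, or by global sequence identity. These metrics are validated
against the shared-active-compound principle (proteins with similar active
compound sets are functionally similar), then the Euclidean distance to
the nearest training protein is binned and model performance per bin is
reported. A nearest-training distance of at most 0.4 marks a prediction as
within the applicability domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import auroc, confusion, scalar_metrics

__all__ = [
    "protein_distance",
    "sequence_identity",
    "shared_active_count",
    "similarity_vs_shared_report",
    "nearest_training_distance",
    "embedding_scale",
    "ApplicabilityVerdict",
    "within_domain",
    "binned_performance",
    "DEFAULT_BIN_EDGES",
    "DOMAIN_THRESHOLD",
]

#: critical nearest-training Euclidean distance for reliable predictions
DOMAIN_THRESHOLD = 0.4

#: default distance bin edges covering all reported intervals
DEFAULT_BIN_EDGES = (0.0, 0.4, 0.67, 1.0, 2.0, 3.0, 4.0, 10.0)


def protein_distance(a, b, metric: str = "euclidean") -> float:
    """Distance/similarity between two protein embeddings.

    ``euclidean`` returns a distance >= 0; ``cosine`` returns the cosine
    similarity in [-1, 1] (zero vectors are an error).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("embedding dimensions differ")
    if metric == "euclidean":
        return float(np.linalg.norm(a - b))
    if metric == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            raise ValueError("cosine similarity undefined for zero vectors")
        return float(np.clip(a @ b / (na * nb), -1.0, 1.0))
    raise ValueError(f"unknown metric {metric!r}")


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from a global alignment.

    Alignment scoring: match +1, mismatch 0, gap -1; identity is the number
    of identical aligned residue pairs divided by the alignment length
    (columns, gaps included), times 100. Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(seq_a, seq_b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    return 100.0 * matches / len(s1)


def shared_active_count(prot_a: str, prot_b: str, positives) -> int:
    """Number of active compounds shared by two proteins.

    ``positives`` is an iterable of (compound_id, protein_id) positive
    pairs. An unknown protein contributes an empty active set.
    """
    actives: dict[str, set] = {}
    for c, p in positives:
        actives.setdefault(p, set()).add(c)
    if prot_a not in actives or prot_b not in actives:
        import warnings

        warnings.warn(f"protein without actives: {prot_a if prot_a not in actives else prot_b}")
    return len(actives.get(prot_a, set()) & actives.get(prot_b, set()))


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bins [lo, hi); the last bin is closed at its upper edge."""
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[np.asarray(values) == edges[-1]] = len(edges) - 2
    return idx


def similarity_vs_shared_report(
    embeddings: dict[str, np.ndarray],
    positives,
    metric: str = "euclidean",
    bin_edges=DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Shared-active-compound distribution per protein-similarity bin.

    All unordered protein pairs are binned by the chosen similarity metric;
    each bin row reports the pair count and median/quartiles of the number
    of shared active compounds. Empty bins appear with n = 0.
    """
    ids = sorted(embeddings)
    if len(ids) < 2:
        raise ValueError("need >= 2 proteins")
    actives: dict[str, set] = {}
    for c, p in positives:
        actives.setdefault(p, set()).add(c)
    sims, shared = [], []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            sims.append(protein_distance(embeddings[a], embeddings[b], metric))
            shared.append(len(actives.get(a, set()) & actives.get(b, set())))
    sims = np.array(sims)
    shared = np.array(shared)
    edges = np.asarray(bin_edges, dtype=float)
    idx = _bin_index(sims, edges)
    rows = []
    for k in range(len(edges) - 1):
        mask = idx == k
        n = int(mask.sum())
        vals = shared[mask]
        rows.append({
            "bin_lo": edges[k], "bin_hi": edges[k + 1], "n_pairs": n,
            "shared_median": float(np.median(vals)) if n else np.nan,
            "shared_q1": float(np.percentile(vals, 25)) if n else np.nan,
            "shared_q3": float(np.percentile(vals, 75)) if n else np.nan,
            "shared_max": int(vals.max()) if n else 0,
        })
    return pd.DataFrame(rows)


def nearest_training_distance(
    test_embedding, train_embeddings: np.ndarray, train_ids=None,
) -> tuple[float, object]:
    """Euclidean distance to the closest training protein (and its id)."""
    E = np.atleast_2d(np.asarray(train_embeddings, dtype=float))
    if E.shape[0] == 0:
        raise ValueError("empty training set")
    d = np.linalg.norm(E - np.asarray(test_embedding, dtype=float), axis=1)
    i = int(np.argmin(d))
    ident = train_ids[i] if train_ids is not None else i
    return float(d[i]), ident


def embedding_scale(embeddings: np.ndarray) -> float:
    """Mean pairwise Euclidean distance: the natural length scale of an
    embedding cloud, used to express thresholds on synthetic data whose
    embedding spread is not calibrated to the trained full-scale model."""
    E = np.atleast_2d(np.asarray(embeddings, dtype=float))
    n = E.shape[0]
    if n < 2:
        raise ValueError("need >= 2 embeddings")
    sq = np.sum(E ** 2, axis=1)
    d2 = np.clip(sq[:, None] + sq[None, :] - 2 * E @ E.T, 0, None)
    iu = np.triu_indices(n, 1)
    return float(np.mean(np.sqrt(d2[iu])))


@dataclass(frozen=True)
class ApplicabilityVerdict:
    protein_id: str
    nearest_distance: float
    within_domain: bool
    threshold: float = DOMAIN_THRESHOLD


def within_domain(
    distance: float, threshold: float = DOMAIN_THRESHOLD, protein_id: str = "",
) -> ApplicabilityVerdict:
    """Domain verdict: reliable iff nearest distance <= threshold (inclusive)."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return ApplicabilityVerdict(
        protein_id=protein_id,
        nearest_distance=float(distance),
        within_domain=distance <= threshold,
        threshold=threshold,
    )


def binned_performance(
    labels, scores, distances, bin_edges=DEFAULT_BIN_EDGES, cutoff: float = 0.5,
) -> pd.DataFrame:
    """Model performance per nearest-training-distance bin.

    Each row reports the pair count, accuracy, true/false prediction
    proportions and (when both classes are present) AUROC for one
    half-open distance interval [lo, hi); the last bin is closed. Bins
    partition the data exactly; empty bins carry n = 0 and NaN metrics.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    d = np.asarray(distances, dtype=float)
    if not (y.shape == s.shape == d.shape):
        raise ValueError("labels, scores and distances must be aligned")
    edges = np.asarray(bin_edges, dtype=float)
    idx = _bin_index(d, edges)
    rows = []
    for k in range(len(edges) - 1):
        mask = idx == k
        n = int(mask.sum())
        row = {"bin_lo": edges[k], "bin_hi": edges[k + 1], "n": n,
               "ACC": np.nan, "AUROC": np.nan,
               "true_fraction": np.nan, "false_fraction": np.nan}
        if n:
            yb, sb = y[mask], s[mask]
            pred = (sb >= cutoff).astype(int)
            m = scalar_metrics(confusion(yb, pred))
            row["ACC"] = m["ACC"]
            row["true_fraction"] = m["ACC"]
            row["false_fraction"] = 1.0 - m["ACC"]
            if 0 < yb.sum() < n:
                row["AUROC"] = auroc(yb, sb)
        rows.append(row)
    return pd.DataFrame(rows)
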