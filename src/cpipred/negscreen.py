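"""Canonical-correlation negative screening (compound-target correlation space).

Candidate negatives produced by curation may still contain true binders.
The screen builds a compound-target correlation space from *known positive*
pairs: compound and protein descriptor blocks are standardized and
projected by canonical correlation analysis (ridge-regularized for
stability) so that paired compound/protein coordinates are maximally
correlated. For each compound with at least two known targets, those
targets form a "target space" in the protein-side canonical coordinates; a
distance threshold is set at the upper limit of the 95% confidence
interval of the mean pairwise distance among the targets. A candidate
negative (compound, protein) is *confirmed* as a non-interaction only when
the protein's projected coordinates lie farther than the threshold from
every target of the compound; otherwise it is rejected as a possible
binder. Compounds without a usable target space pass through unscreened.

Descriptor tables are plain DataFrames (entity id index, numeric columns),
so externally computed descriptor sets plug in directly; built-in
descriptors (fingerprint block counts and physchem proxies for compounds,
amino-acid/homodipeptide composition and length for proteins) keep the
screen runnable without third-party descriptor software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh, svd
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "compound_descriptors",
    "protein_descriptors",
    "reduce_descriptors",
    "TargetSpace",
    "target_space_threshold",
    "CCANegativeScreen",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


def compound_descriptors(
    ids, smiles: dict[str, str] | None = None,
    fingerprints: dict[str, np.ndarray] | None = None,
    n_blocks: int = 32,
) -> pd.DataFrame:
    """Built-in numeric compound descriptors.

    From SMILES (when available): molecular weight, ring count, heteroatom
    fraction, plus folded fingerprint block counts. From raw fingerprints:
    block counts and total on-bit count only.
    """
    if smiles is None and fingerprints is None:
        raise ValueError("need smiles and/or fingerprints")
    rows = {}
    for cid in ids:
        feats = {}
        if fingerprints is not None and cid in fingerprints:
            fp = np.asarray(fingerprints[cid]).astype(float)
            blocks = fp.reshape(n_blocks, -1).sum(axis=1)
            feats.update({f"fp_block_{i}": blocks[i] for i in range(n_blocks)})
            feats["fp_total"] = float(fp.sum())
        if smiles is not None and cid in smiles:
            from rdkit import Chem
            from rdkit.Chem import Descriptors, rdMolDescriptors

            mol = Chem.MolFromSmiles(smiles[cid])
            if mol is None:
                raise ValueError(f"unparseable SMILES for {cid}")
            n_atoms = mol.GetNumAtoms()
            n_hetero = sum(1 for a in mol.GetAtoms() if a.GetSymbol() not in ("C", "H"))
            feats["mol_weight"] = Descriptors.MolWt(mol)
            feats["ring_count"] = float(rdMolDescriptors.CalcNumRings(mol))
            feats["heteroatom_fraction"] = n_hetero / max(n_atoms, 1)
        rows[cid] = feats
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)


def protein_descriptors(sequences: dict[str, str]) -> pd.DataFrame:
    """Built-in protein descriptors: amino-acid composition (20), a
    homodipeptide-composition subset (20) and log sequence length."""
    rows = {}
    for pid, seq in sequences.items():
        n = len(seq)
        feats = {f"aa_{a}": seq.count(a) / n for a in _AA}
        for a in _AA:
            feats[f"dipep_{a}{a}"] = seq.count(a + a) / max(n - 1, 1)
        feats["log_length"] = np.log(n)
        rows[pid] = feats
    return pd.DataFrame.from_dict(rows, orient="index")


def reduce_descriptors(table: pd.DataFrame, retain) -> pd.DataFrame:
    """PCA reduction of a descriptor table.

    ``retain`` is either a component count or a variance fraction in (0,1).
    Requests beyond the data rank are truncated with a warning.
    """
    X = table.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 entities and >= 2 descriptors")
    rank = min(X.shape[0] - 1, X.shape[1])
    if isinstance(retain, float) and 0 < retain < 1:
        pca = PCA(n_components=retain, svd_solver="full")
        pca.fit(X)
    else:
        k = int(retain)
        if k > rank:
            warnings.warn(f"requested {k} components exceeds rank {rank}; truncated")
            k = rank
        pca = PCA(n_components=k).fit(X)
    scores = pca.transform(X)
    cols = [f"pc{i + 1}" for i in range(scores.shape[1])]
    out = pd.DataFrame(scores, index=table.index, columns=cols)
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_
    return out


@dataclass
class TargetSpace:
    """Known-target coordinates of one compound plus its distance threshold."""

    compound_id: str
    coordinates: np.ndarray  # (n_targets, n_components)
    target_ids: list[str]
    distance_threshold: float


def target_space_threshold(coords: np.ndarray, ci: float = 0.95) -> float:
    """Distance threshold of a target space.

    Mean pairwise Euclidean distance among the targets plus the upper
    t-based confidence limit ``t(1-(1-ci)/2, m-1) * sd / sqrt(m)`` over the
    m pairwise distances. With a single pair (two targets) the dispersion
    is undefined and the threshold degenerates to that distance itself.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    k = coords.shape[0]
    if k < 2:
        raise ValueError("need >= 2 targets for a finite threshold")
    d = [
        float(np.linalg.norm(coords[i] - coords[j]))
        for i in range(k) for j in range(i + 1, k)
    ]
    m = len(d)
    mean = float(np.mean(d))
    if m == 1:
        return mean
    sd = float(np.std(d, ddof=1))
    q = t_dist.ppf(0.5 + ci / 2.0, df=m - 1)
    return mean + q * sd / np.sqrt(m)


class CCANegativeScreen(BaseEstimator):
    """CTCS-style negative screen in a canonical-correlation space.

    Parameters
    ----------
    n_components : cap on canonical components (actual: min(cap, ranks)).
    ridge : ridge added to the covariance blocks for numerical stability.
    standardize : z-score descriptor columns before fitting.
    ci : confidence level of the target-space threshold.
    distance_mode : "min" (distance to the nearest target; conservative
        against discarding true binders) or "centroid".

    Fitted attributes
    -----------------
    x_weights_, y_weights_ : compound / protein projection weights.
    correlations_ : per-component canonical correlations, non-increasing.
    target_spaces_ : compound_id -> :class:`TargetSpace` for compounds with
        at least two known positive targets.
    """

    def __init__(self, n_components=5, ridge=1e-6, standardize=True,
                 ci=0.95, distance_mode="min"):
        self.n_components = n_components
        self.ridge = ridge
        self.standardize = standardize
        self.ci = ci
        self.distance_mode = distance_mode

    # -- internals --------------------------------------------------------
    def _prep(self, df: pd.DataFrame, mean, std):
        X = df.to_numpy(dtype=float)
        return (X - mean) / std if self.standardize else X - mean

    @staticmethod
    def _inv_sqrt(S):
        w, V = eigh(S)
        w = np.clip(w, 1e-12, None)
        return V @ np.diag(w ** -0.5) @ V.T

    def fit(self, positive_pairs, compound_desc: pd.DataFrame,
            protein_desc: pd.DataFrame):
        """Fit the correlation space on known positive pairs.

        ``positive_pairs`` is an iterable of (compound_id, protein_id);
        each id must index a row of the corresponding descriptor table.
        """
        pairs = [(c, p) for c, p in positive_pairs
                 if c in compound_desc.index and p in protein_desc.index]
        if len(pairs) < 3:
            raise ValueError("need >= 3 positive pairs with descriptors")
        self.pairs_ = pairs

        self._c_mean = compound_desc.to_numpy(dtype=float).mean(axis=0)
        c_sd = compound_desc.to_numpy(dtype=float).std(axis=0)
        self._c_std = np.where(c_sd > 0, c_sd, 1.0)
        self._p_mean = protein_desc.to_numpy(dtype=float).mean(axis=0)
        p_sd = protein_desc.to_numpy(dtype=float).std(axis=0)
        self._p_std = np.where(p_sd > 0, p_sd, 1.0)
        self._c_cols = list(compound_desc.columns)
        self._p_cols = list(protein_desc.columns)

        Xall = self._prep(compound_desc, self._c_mean, self._c_std)
        Yall = self._prep(protein_desc, self._p_mean, self._p_std)
        c_idx = {c: i for i, c in enumerate(compound_desc.index)}
        p_idx = {p: i for i, p in enumerate(protein_desc.index)}
        X = np.stack([Xall[c_idx[c]] for c, _ in pairs])
        Y = np.stack([Yall[p_idx[p]] for _, p in pairs])
        n = X.shape[0]

        Sxx = X.T @ X / n + self.ridge * np.eye(X.shape[1])
        Syy = Y.T @ Y / n + self.ridge * np.eye(Y.shape[1])
        Sxy = X.T @ Y / n
        cond = min(np.linalg.cond(Sxx), np.linalg.cond(Syy))
        if cond > 1e10:
            warnings.warn("degenerate descriptor covariance; ridge-regularized fit")
        Rx = self._inv_sqrt(Sxx)
        Ry = self._inv_sqrt(Syy)
        U, s, Vt = svd(Rx @ Sxy @ Ry, full_matrices=False)
        k = min(self.n_components, s.size)
        self.x_weights_ = Rx @ U[:, :k]
        self.y_weights_ = Ry @ Vt[:k].T
        self.correlations_ = np.clip(s[:k], 0.0, 1.0)

        # target spaces: protein-side coordinates of each compound's targets
        proj = Yall @ self.y_weights_
        targets_of: dict[str, list[str]] = {}
        for c, p in pairs:
            targets_of.setdefault(c, []).append(p)
        self.target_spaces_ = {}
        self.single_target_compounds_ = set()
        for c, plist in targets_of.items():
            uniq = sorted(set(plist))
            if len(uniq) < 2:
                self.single_target_compounds_.add(c)
                continue
            coords = np.stack([proj[p_idx[p]] for p in uniq])
            self.target_spaces_[c] = TargetSpace(
                compound_id=c,
                coordinates=coords,
                target_ids=uniq,
                distance_threshold=target_space_threshold(coords, self.ci),
            )
        return self

    def project_proteins(self, protein_desc: pd.DataFrame) -> pd.DataFrame:
        """Protein-side canonical coordinates for a descriptor table."""
        check_is_fitted(self, "y_weights_")
        if list(protein_desc.columns) != self._p_cols:
            raise ValueError("protein descriptor columns differ from the fit")
        Y = self._prep(protein_desc, self._p_mean, self._p_std)
        return pd.DataFrame(Y @ self.y_weights_, index=protein_desc.index)

    def project_compounds(self, compound_desc: pd.DataFrame) -> pd.DataFrame:
        """Compound-side canonical coordinates for a descriptor table."""
        check_is_fitted(self, "x_weights_")
        if list(compound_desc.columns) != self._c_cols:
            raise ValueError("compound descriptor columns differ from the fit")
        X = self._prep(compound_desc, self._c_mean, self._c_std)
        return pd.DataFrame(X @ self.x_weights_, index=compound_desc.index)

    def _distance(self, point: np.ndarray, tspace: TargetSpace) -> float:
        if self.distance_mode == "centroid":
            return float(np.linalg.norm(point - tspace.coordinates.mean(axis=0)))
        return float(np.min(np.linalg.norm(tspace.coordinates - point, axis=1)))

    def confirm_negative(self, compound_id: str, protein_coords: np.ndarray) -> bool:
        """True iff the protein lies beyond the compound's distance threshold."""
        check_is_fitted(self, "target_spaces_")
        tspace = self.target_spaces_.get(compound_id)
        if tspace is None:
            raise KeyError(f"no target space for compound {compound_id}")
        return bool(self._distance(np.asarray(protein_coords, dtype=float),
                                   tspace) > tspace.distance_threshold)

    def screen(self, candidate_pairs, protein_desc: pd.DataFrame):
        """Partition candidate negatives into (retained, rejected, unscreened).

        retained: confirmed non-interactions (beyond the threshold);
        rejected: within the threshold — possible binders, dropped from the
        negative set; unscreened: compounds without a target space (kept as
        negatives, flagged). Also returns a per-pair report DataFrame.
        """
        check_is_fitted(self, "target_spaces_")
        proj = self.project_proteins(protein_desc)
        retained, rejected, unscreened, rows = [], [], [], []
        for c, p in candidate_pairs:
            tspace = self.target_spaces_.get(c)
            if tspace is None or p not in proj.index:
                unscreened.append((c, p))
                rows.append((c, p, np.nan, np.nan, "unscreened"))
                continue
            d = self._distance(proj.loc[p].to_numpy(), tspace)
            if d > tspace.distance_threshold:
                retained.append((c, p))
                verdict = "retained"
            else:
                rejected.append((c, p))
                verdict = "rejected"
            rows.append((c, p, d, tspace.distance_threshold, verdict))
        report = pd.DataFrame(
            rows, columns=["compound_id", "protein_id", "min_distance",
                           "threshold", "verdict"],
        )
        return retained, rejected, unscreened, report
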