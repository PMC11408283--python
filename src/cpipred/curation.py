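"""Curation of multi-source bioactivity records into a labeled CPI dataset.

The pipeline turns raw potency / binary-activity measurements into unique,
labeled compound-protein pairs:

1. label resolution — a pair is positive if *any* source calls it active
   (potency <= 10 uM, an explicit "active" flag, or membership in a
   known-interaction catalogue) and negative only if every source calls it
   inactive; the smallest potency is kept as the representative value;
2. molecular-weight window — compounds outside [100, 1000] Da are dropped
   (small-molecule focus);
3. ligand-bias removal — within each protein, groups of mutually similar
   compounds (Morgan-fingerprint Tanimoto > 0.8) are collapsed to the
   single compound with the most interactions, so a model cannot score by
   recognising near-duplicate ligands;
4. negative capping — at most 1,000 negatives per protein, ranked by
   interaction count, mutually dissimilar (Tanimoto < 0.8);
5. a reproducible 80/20 random split.

Cross-source overlap statistics (pair counts and percentage overlap
relative to the smaller source) are reported as a matrix.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssayType",
    "BioactivityRecord",
    "Compound",
    "Protein",
    "CPIPair",
    "CurationConfig",
    "normalize_potency_uM",
    "resolve_activity",
    "filter_by_weight",
    "tanimoto",
    "deduplicate_ligand_bias",
    "cap_negatives_per_protein",
    "dataset_overlap_stats",
    "overlap_percentage",
    "split_dataset",
    "curate",
]

#: unit tag -> factor converting to micromolar
_UNIT_TO_UM = {"nm": 1e-3, "um": 1.0, "µm": 1.0, "μm": 1.0, "mm": 1e3, "m": 1e6}


class AssayType(str, Enum):
    IC50 = "IC50"
    KI = "Ki"
    EC50 = "EC50"
    BINARY = "BINARY"


@dataclass(frozen=True)
class BioactivityRecord:
    """One potency or binary-activity measurement from one source."""

    compound_id: str
    protein_id: str
    assay_type: AssayType
    value_uM: float | None = None
    binary_label: str | None = None  # "active" / "inactive"
    source: str = ""

    def __post_init__(self):
        if (self.value_uM is None) == (self.binary_label is None):
            raise ValueError(
                f"{self.compound_id}/{self.protein_id}: exactly one of "
                "value_uM and binary_label must be present"
            )
        if self.value_uM is not None and self.value_uM < 0:
            raise ValueError("potency must be non-negative")
        if self.binary_label is not None and self.binary_label not in ("active", "inactive"):
            raise ValueError(f"binary_label must be active/inactive, got {self.binary_label!r}")
        if (self.assay_type == AssayType.BINARY) != (self.binary_label is not None):
            raise ValueError("binary_label present iff assay_type is BINARY")


@dataclass(frozen=True)
class Compound:
    compound_id: str
    smiles: str = ""
    mol_weight_Da: float | None = None


@dataclass(frozen=True)
class Protein:
    protein_id: str
    sequence: str


@dataclass
class CPIPair:
    """A curated, labeled compound-protein pair."""

    compound_id: str
    protein_id: str
    label: int  # 1 positive, 0 negative
    representative_value_uM: float | None = None
    provenance: frozenset = field(default_factory=frozenset)

    @property
    def key(self) -> tuple[str, str]:
        return (self.compound_id, self.protein_id)


@dataclass
class CurationConfig:
    activity_threshold_uM: float = 10.0
    mw_min_Da: float = 100.0
    mw_max_Da: float = 1000.0
    tanimoto_cutoff: float = 0.8
    negatives_cap_per_protein: int = 1000
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.tanimoto_cutoff < 1:
            raise ValueError("tanimoto_cutoff must be in (0, 1)")
        if not self.mw_min_Da < self.mw_max_Da:
            raise ValueError("mw_min_Da must be < mw_max_Da")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def normalize_potency_uM(value: float, unit: str) -> float:
    """Convert a potency value to micromolar; unknown units raise."""
    factor = _UNIT_TO_UM.get(unit.strip().lower())
    if factor is None:
        raise ValueError(f"unknown potency unit {unit!r}")
    return value * factor


def resolve_activity(
    records: list[BioactivityRecord], cfg: CurationConfig
) -> CPIPair | None:
    """Collapse all records for one compound-protein pair into a labeled pair.

    Any-active rule: the pair is positive if at least one record is active
    (potency <= threshold or an explicit active flag); it is negative only
    when every record says inactive. The representative potency is the
    minimum over all reported values. Returns ``None`` when no record is
    interpretable.
    """
    if not records:
        return None
    keys = {(r.compound_id, r.protein_id) for r in records}
    if len(keys) != 1:
        raise ValueError(f"records span multiple pairs: {sorted(keys)}")
    compound_id, protein_id = keys.pop()

    any_active = False
    all_negative_votes = []
    values = []
    sources = set()
    binary_votes_by_source: dict[str, set[str]] = defaultdict(set)
    for r in records:
        sources.add(r.source)
        if r.value_uM is not None:
            values.append(r.value_uM)
            vote = r.value_uM <= cfg.activity_threshold_uM
        else:
            vote = r.binary_label == "active"
            binary_votes_by_source[r.source].add(r.binary_label)
        any_active = any_active or vote
        all_negative_votes.append(not vote)

    for src, votes in binary_votes_by_source.items():
        if len(votes) > 1:
            logger.warning(
                "conflicting binary labels for %s/%s from source %r; "
                "resolved by the any-active rule",
                compound_id, protein_id, src,
            )

    if not all_negative_votes:  # no interpretable record
        return None
    label = 1 if any_active else 0
    rep = min(values) if values else None
    return CPIPair(
        compound_id=compound_id,
        protein_id=protein_id,
        label=label,
        representative_value_uM=rep,
        provenance=frozenset(sources),
    )


def filter_by_weight(
    compounds: dict[str, Compound], cfg: CurationConfig
) -> dict[str, Compound]:
    """Keep compounds with mw_min <= MW <= mw_max (boundaries inclusive)."""
    kept = {}
    for cid, c in compounds.items():
        if c.mol_weight_Da is None:
            warnings.warn(f"compound {cid} lacks a molecular weight; rejected")
            continue
        if cfg.mw_min_Da <= c.mol_weight_Da <= cfg.mw_max_Da:
            kept[cid] = c
    return kept


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto similarity |A&B| / |A|B| between two equal-length bit vectors.

    Defined as 0 when both vectors are empty.
    """
    a = np.asarray(fp_a).astype(bool)
    b = np.asarray(fp_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def _ranked(compounds_with_counts):
    # descending interaction count; lexicographic compound_id breaks ties
    return sorted(compounds_with_counts, key=lambda t: (-t[1], t[0].compound_id))


def deduplicate_ligand_bias(
    protein_id: str,
    compounds_with_counts: list[tuple[Compound, int]],
    fingerprints: dict[str, np.ndarray],
    cfg: CurationConfig,
) -> list[Compound]:
    """Collapse near-duplicate ligands of one protein to single survivors.

    Greedy leader clustering: compounds are visited in decreasing
    interaction-count order; each joins the first leader with Tanimoto
    similarity > cutoff, otherwise it becomes a leader. Leaders (the
    most-connected member of each similarity group) survive.
    """
    leaders: list[Compound] = []
    for comp, _count in _ranked(compounds_with_counts):
        fp = fingerprints[comp.compound_id]
        absorbed = any(
            tanimoto(fp, fingerprints[ld.compound_id]) > cfg.tanimoto_cutoff
            for ld in leaders
        )
        if not absorbed:
            leaders.append(comp)
    return leaders


def cap_negatives_per_protein(
    protein_id: str,
    negatives: list[tuple[Compound, int]],
    fingerprints: dict[str, np.ndarray],
    cfg: CurationConfig,
) -> list[Compound]:
    """Keep at most the top-N negatives per protein, mutually dissimilar.

    Candidates are ranked by interaction count (descending); a candidate is
    accepted only if its Tanimoto similarity to every previously accepted
    survivor is < cutoff, until the cap is reached.
    """
    accepted: list[Compound] = []
    for comp, _count in _ranked(negatives):
        if len(accepted) >= cfg.negatives_cap_per_protein:
            break
        fp = fingerprints[comp.compound_id]
        if all(
            tanimoto(fp, fingerprints[a.compound_id]) < cfg.tanimoto_cutoff
            for a in accepted
        ):
            accepted.append(comp)
    return accepted


def overlap_percentage(n_a: int, n_b: int, n_overlap: int) -> float | None:
    """Overlap count as a percentage of the smaller of the two sets.

    Rounded to 2 decimals; ``None`` when either set is empty.
    """
    smaller = min(n_a, n_b)
    if smaller == 0:
        return None
    return round(100.0 * n_overlap / smaller, 2)


def dataset_overlap_stats(datasets: dict[str, set]) -> pd.DataFrame:
    """Cross-source overlap matrix.

    Diagonal: dataset sizes. Above the diagonal: pairwise overlap counts.
    Below: percentage of the overlap relative to the smaller dataset
    (2 decimals; NaN for empty datasets).
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    names = list(datasets)
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        mat.loc[a, a] = len(datasets[a])
        for b in names[i + 1:]:
            ov = len(datasets[a] & datasets[b])
            mat.loc[a, b] = ov
            pct = overlap_percentage(len(datasets[a]), len(datasets[b]), ov)
            mat.loc[b, a] = np.nan if pct is None else pct
    return mat


def split_dataset(
    pairs: list[CPIPair], cfg: CurationConfig
) -> tuple[list[CPIPair], list[CPIPair]]:
    """Random, seed-reproducible train/test split.

    The train side takes round-half-up(train_fraction * n) pairs.
    """
    n = len(pairs)
    if n < 5:
        raise ValueError(f"need at least 5 pairs to split, got {n}")
    n_train = int(np.floor(cfg.train_fraction * n + 0.5))
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(n)
    train = [pairs[i] for i in sorted(order[:n_train])]
    test = [pairs[i] for i in sorted(order[n_train:])]
    return train, test


def curate(
    records: list[BioactivityRecord],
    compounds: dict[str, Compound],
    fingerprints: dict[str, np.ndarray],
    cfg: CurationConfig | None = None,
) -> tuple[list[CPIPair], dict]:
    """Run the full curation pipeline and return (pairs, report).

    Stages: label resolution per pair, molecular-weight window, per-protein
    ligand deduplication (positives and negatives separately), per-protein
    negative capping. The report counts records/pairs removed at each stage.
    """
    cfg = cfg or CurationConfig()

    by_pair: dict[tuple[str, str], list[BioactivityRecord]] = defaultdict(list)
    for r in records:
        by_pair[(r.compound_id, r.protein_id)].append(r)

    resolved: list[CPIPair] = []
    uninterpretable = 0
    for recs in by_pair.values():
        pair = resolve_activity(recs, cfg)
        if pair is None:
            uninterpretable += 1
        else:
            resolved.append(pair)

    kept_compounds = filter_by_weight(
        {cid: c for cid, c in compounds.items()}, cfg
    )
    after_mw = [p for p in resolved if p.compound_id in kept_compounds]

    counts = Counter(p.compound_id for p in after_mw)

    survivors: list[CPIPair] = []
    n_dedup_removed = 0
    n_cap_removed = 0
    by_protein: dict[str, list[CPIPair]] = defaultdict(list)
    for p in after_mw:
        by_protein[p.protein_id].append(p)
    for protein_id, plist in by_protein.items():
        for label in (1, 0):
            group = [p for p in plist if p.label == label]
            if not group:
                continue
            cwc = [(kept_compounds[p.compound_id], counts[p.compound_id]) for p in group]
            kept = deduplicate_ligand_bias(protein_id, cwc, fingerprints, cfg)
            n_dedup_removed += len(group) - len(kept)
            if label == 0:
                capped = cap_negatives_per_protein(
                    protein_id, [(c, counts[c.compound_id]) for c in kept],
                    fingerprints, cfg,
                )
                n_cap_removed += len(kept) - len(capped)
                kept = capped
            kept_ids = {c.compound_id for c in kept}
            survivors.extend(p for p in group if p.compound_id in kept_ids)

    report = {
        "n_records": len(records),
        "n_unique_pairs": len(by_pair),
        "n_uninterpretable": uninterpretable,
        "n_resolved": len(resolved),
        "n_removed_mw": len(resolved) - len(after_mw),
        "n_removed_dedup": n_dedup_removed,
        "n_removed_cap": n_cap_removed,
        "n_final": len(survivors),
        "n_positive": sum(p.label for p in survivors),
        "n_negative": sum(1 - p.label for p in survivors),
    }
    return survivors, report
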