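"""Seeded synthetic benchmarks with the structure the pipeline assumes.

The generator plants a latent interaction signal expressed on both sides:
every compound carries a latent vector ``u`` that modulates the activation
probabilities of its 2048-bit fingerprint (so PCA can recover it), and
every protein carries a latent vector ``v`` encoded in the sampling
frequencies of 3-mer sequence motifs (so CBOW embeddings can recover it).
A pair interacts with probability ``logistic(u.v / temperature)``;
potencies are drawn log-normally around 1 uM for interacting and 100 uM
for non-interacting pairs, so the 10-uM activity rule recovers the planted
labels up to the configured noise. Multi-source duplicate records with
value jitter, binary catalogue records and near-duplicate ligand twins
(Tanimoto > 0.8) exercise the any-active, min-value and deduplication
rules of curation.

External proteins for applicability analysis come in two kinds: "near"
proteins are resampled sequences from a training protein's own motif
distribution (in-domain, signal preserved) and "far" proteins draw their
motif composition from a sharpened latent unrelated to their interaction
latent (out-of-domain embeddings whose features carry no interaction
signal) — the situation the applicability domain is meant to flag.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .curation import AssayType, BioactivityRecord, Compound

__all__ = [
    "GeneratorConfig",
    "SyntheticBenchmark",
    "generate_compounds",
    "generate_proteins",
    "generate_external_proteins",
    "generate_interactions",
    "make_benchmark",
    "make_benchmark_fixture",
    "golden_curation_fixture",
    "random_smiles",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class GeneratorConfig:
    """Benchmark generator settings.

    Defaults define the standard desk-scale benchmark: 2,000 compounds by
    50 proteins, a 4-d latent interaction signal at temperature 0.15 (label
    probabilities mostly saturated, Bayes error a few percent), 2% label
    noise, 5% near-duplicate ligand twins, 20% multi-source duplicate
    records, and 20% of the compound-protein grid sampled as records.
    """

    n_compounds: int = 2000
    n_proteins: int = 50
    latent_dim: int = 4
    interaction_temperature: float = 0.15
    label_noise_rate: float = 0.02
    near_duplicate_rate: float = 0.05
    multi_source_rate: float = 0.2
    protein_length_range: tuple[int, int] = (240, 600)
    pair_density: float = 0.2
    n_bits: int = 2048
    n_motifs: int = 64
    bit_base_logit: float = -3.0
    bit_signal_scale: float = 6.0
    motif_temperature: float = 1.0
    catalog_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for r in (self.label_noise_rate, self.near_duplicate_rate,
                  self.multi_source_rate, self.pair_density):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.protein_length_range[0] < 9:
            raise ValueError("proteins must be at least 9 residues")


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


@dataclass
class SyntheticBenchmark:
    """A generated benchmark: inputs plus ground truth."""

    config: GeneratorConfig
    compound_ids: list[str]
    compound_latents: dict[str, np.ndarray]
    fingerprints: dict[str, np.ndarray]
    compounds: dict[str, Compound]
    twin_pairs: list[tuple[str, str]]
    protein_ids: list[str]
    protein_latents: dict[str, np.ndarray]
    sequences: dict[str, str]
    records: list[BioactivityRecord]
    truth: dict[tuple[str, str], int]
    smiles: dict[str, str] = field(default_factory=dict)


# -- compounds -------------------------------------------------------------

_FRAGMENTS = ("C", "CC", "CCO", "CN", "c1ccccc1", "C(=O)O", "CO",
              "C1CCCCC1", "N", "O", "CC(C)", "c1ccncc1")


def random_smiles(rng: np.random.Generator, n_frag_range=(3, 7)) -> str:
    """A simple valid SMILES assembled from a small fragment grammar."""
    k = int(rng.integers(*n_frag_range))
    return "".join(rng.choice(_FRAGMENTS, size=k))


def generate_compounds(cfg: GeneratorConfig, rng: np.random.Generator | None = None):
    """Compounds with planted latent vectors and fingerprint bit patterns.

    Bit j of compound i activates with probability
    ``sigmoid(base_logit + signal_scale * (W u_i)_j / sqrt(d))`` for a fixed
    random projection W, so the latent coordinates are recoverable from the
    bit matrix by PCA. A ``near_duplicate_rate`` fraction of compounds gets
    a twin with a few random bit flips (Tanimoto > 0.8) sharing the same
    latent, to exercise ligand deduplication.

    Returns (ids, latents, fingerprints, compounds, twin_pairs).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n, d = cfg.n_compounds, cfg.latent_dim
    U = rng.standard_normal((n, d))
    W = rng.standard_normal((cfg.n_bits, d))
    logits = cfg.bit_base_logit + cfg.bit_signal_scale * (U @ W.T) / np.sqrt(d)
    bits = (rng.random((n, cfg.n_bits)) < _sigmoid(logits)).astype(np.uint8)

    ids = [f"C{i:05d}" for i in range(n)]
    latents = {cid: U[i] for i, cid in enumerate(ids)}
    fingerprints = {cid: bits[i] for i, cid in enumerate(ids)}
    mw = rng.uniform(150.0, 950.0, size=n)
    compounds = {
        cid: Compound(compound_id=cid, mol_weight_Da=float(mw[i]))
        for i, cid in enumerate(ids)
    }

    twin_pairs: list[tuple[str, str]] = []
    n_dup = int(round(cfg.near_duplicate_rate * n))
    if n_dup:
        for base_i in rng.choice(n, size=n_dup, replace=False):
            base = ids[base_i]
            twin = base + "d"
            fp = fingerprints[base].copy()
            flips = rng.random(cfg.n_bits) < 0.004  # ~8 flips of 2048 bits
            fp[flips] ^= 1
            fingerprints[twin] = fp
            latents[twin] = latents[base]
            compounds[twin] = Compound(
                compound_id=twin, mol_weight_Da=compounds[base].mol_weight_Da
            )
            ids.append(twin)
            twin_pairs.append((base, twin))
    return ids, latents, fingerprints, compounds, twin_pairs


# -- proteins --------------------------------------------------------------

def _motif_vocabulary(cfg: GeneratorConfig, rng: np.random.Generator):
    all_motifs = rng.choice(
        ["".join(t) for t in itertools.product(_AA20, repeat=3)],
        size=cfg.n_motifs, replace=False,
    )
    directions = rng.standard_normal((cfg.n_motifs, cfg.latent_dim))
    return list(all_motifs), directions


def _sample_sequence(v, motifs, directions, cfg, rng):
    logits = directions @ v / cfg.motif_temperature
    p = np.exp(logits - logits.max())
    p /= p.sum()
    lo, hi = cfg.protein_length_range
    n_words = int(rng.integers(lo, hi + 1)) // 3
    return "".join(rng.choice(motifs, size=n_words, p=p))


def generate_proteins(cfg: GeneratorConfig, rng: np.random.Generator | None = None):
    """Proteins with planted latent vectors encoded in 3-mer composition.

    Each protein samples its non-overlapping 3-mer words from a softmax
    distribution over a fixed motif vocabulary whose logits are linear in
    the protein's latent vector, so CBOW mean embeddings correlate with
    the latent coordinates.

    Returns (ids, latents, sequences, (motifs, directions)).
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    motifs, directions = _motif_vocabulary(cfg, rng)
    ids = [f"P{i:04d}" for i in range(cfg.n_proteins)]
    V = rng.standard_normal((cfg.n_proteins, cfg.latent_dim))
    latents = {pid: V[i] for i, pid in enumerate(ids)}
    sequences = {
        pid: _sample_sequence(V[i], motifs, directions, cfg, rng)
        for i, pid in enumerate(ids)
    }
    return ids, latents, sequences, (motifs, directions)


def _softmax(z):
    e = np.exp(z - z.max())
    return e / e.sum()


def generate_external_proteins(
    cfg: GeneratorConfig,
    latents: dict[str, np.ndarray],
    vocabulary,
    n_external: int = 40,
    near_fraction: float = 0.5,
    far_scale: float = 5.0,
    n_candidates: int = 30,
    rng: np.random.Generator | None = None,
):
    """External proteins for applicability analysis.

    "Near" proteins resample a fresh sequence from a training protein's own
    motif distribution: their embedding lands close to the training protein
    and still encodes the interaction latent. "Far" proteins keep a fresh
    interaction latent but draw their composition from an *unrelated*
    sharpened latent (norm ``far_scale * sqrt(d)``), chosen among
    ``n_candidates`` random draws as the one whose motif distribution is
    least (cosine-)similar to every training protein's: their embeddings
    sit away from the training cloud and carry no interaction signal.

    Returns (ids, latents, sequences, kinds) with kind in {"near", "far"}.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    motifs, directions = vocabulary
    train_ids = sorted(latents)
    train_comp = np.stack([
        _softmax(directions @ latents[p] / cfg.motif_temperature)
        for p in train_ids
    ])
    train_comp /= np.linalg.norm(train_comp, axis=1, keepdims=True)

    def far_latent():
        best, best_cos = None, np.inf
        for _ in range(n_candidates):
            w = rng.standard_normal(cfg.latent_dim)
            w *= far_scale * np.sqrt(cfg.latent_dim) / max(np.linalg.norm(w), 1e-9)
            p = _softmax(directions @ w / cfg.motif_temperature)
            c = float((train_comp @ (p / np.linalg.norm(p))).max())
            if c < best_cos:
                best_cos, best = c, w
        return best

    n_near = int(round(near_fraction * n_external))
    ids, ext_latents, sequences, kinds = [], {}, {}, {}
    for i in range(n_external):
        pid = f"X{i:04d}"
        if i < n_near:
            src = train_ids[int(rng.integers(len(train_ids)))]
            v = latents[src]
            seq = _sample_sequence(v, motifs, directions, cfg, rng)
            kinds[pid] = "near"
        else:
            v = rng.standard_normal(cfg.latent_dim)
            seq = _sample_sequence(far_latent(), motifs, directions, cfg, rng)
            kinds[pid] = "far"
        ids.append(pid)
        ext_latents[pid] = v
        sequences[pid] = seq
    return ids, ext_latents, sequences, kinds


# -- interactions ----------------------------------------------------------

_ASSAYS = (AssayType.IC50, AssayType.KI, AssayType.EC50)


def generate_interactions(
    compound_latents: dict[str, np.ndarray],
    protein_latents: dict[str, np.ndarray],
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
    twin_pairs: list[tuple[str, str]] | None = None,
):
    """Bioactivity records plus the ground-truth interaction map.

    For each sampled (compound, protein) pair the true interaction is
    Bernoulli(logistic(u.v / temperature)); the observed activity flips
    with ``label_noise_rate``. Potencies are log-normal (median 1 uM for
    active, 100 uM for inactive, sigma 1 in log units) so the 10-uM rule
    recovers the observed activity ~99% of the time. ``multi_source_rate``
    of pairs receive a second jittered record from another source, and
    ``catalog_rate`` of active pairs an extra binary "known interaction"
    record. Twins inherit a subset of their base compound's proteins so
    deduplication has real work to do.
    """
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    protein_ids = sorted(protein_latents)
    twin_of = dict(tp[::-1] for tp in (twin_pairs or []))  # twin -> base
    n_per = max(1, int(round(cfg.pair_density * len(protein_ids))))

    chosen: dict[str, np.ndarray] = {}
    for cid in sorted(compound_latents):
        if cid in twin_of:
            continue
        chosen[cid] = rng.choice(protein_ids, size=n_per, replace=False)
    for twin, base in sorted(twin_of.items()):
        k = max(1, n_per // 2)
        chosen[twin] = rng.choice(chosen[base], size=k, replace=False)

    records: list[BioactivityRecord] = []
    truth: dict[tuple[str, str], int] = {}
    for cid in sorted(chosen):
        u = compound_latents[cid]
        for pid in chosen[cid]:
            v = protein_latents[pid]
            p = _sigmoid(float(u @ v) / cfg.interaction_temperature)
            interact = int(rng.random() < p)
            truth[(cid, pid)] = interact
            observed = interact ^ int(rng.random() < cfg.label_noise_rate)
            median = 1.0 if observed else 100.0
            value = float(median * np.exp(rng.normal(0.0, 1.0)))
            assay = _ASSAYS[int(rng.integers(3))]
            records.append(BioactivityRecord(
                compound_id=cid, protein_id=str(pid), assay_type=assay,
                value_uM=value, source="synthdb_A",
            ))
            if rng.random() < cfg.multi_source_rate:
                jitter = float(np.exp(rng.normal(0.0, 0.2)))
                records.append(BioactivityRecord(
                    compound_id=cid, protein_id=str(pid), assay_type=assay,
                    value_uM=value * jitter, source="synthdb_B",
                ))
            if observed and rng.random() < cfg.catalog_rate:
                records.append(BioactivityRecord(
                    compound_id=cid, protein_id=str(pid),
                    assay_type=AssayType.BINARY, binary_label="active",
                    source="synthdb_catalog",
                ))
    return records, truth


def make_benchmark(cfg: GeneratorConfig | None = None) -> SyntheticBenchmark:
    """Generate a full benchmark (compounds, proteins, records, truth)."""
    cfg = cfg or GeneratorConfig()
    c_ids, c_lat, fps, compounds, twins = generate_compounds(cfg)
    p_ids, p_lat, seqs, vocab = generate_proteins(cfg)
    records, truth = generate_interactions(c_lat, p_lat, cfg, twin_pairs=twins)
    bench = SyntheticBenchmark(
        config=cfg, compound_ids=c_ids, compound_latents=c_lat,
        fingerprints=fps, compounds=compounds, twin_pairs=twins,
        protein_ids=p_ids, protein_latents=p_lat, sequences=seqs,
        records=records, truth=truth,
    )
    bench.vocabulary = vocab
    return bench


# -- file round-trip -------------------------------------------------------

def make_benchmark_fixture(cfg: GeneratorConfig, outdir) -> SyntheticBenchmark:
    """Generate a benchmark and write it in the pipeline's input formats.

    Emits records.tsv, proteins.fasta, fingerprints.tsv (hex-packed bits),
    compounds.tsv (id, molecular weight) and truth.json.
    """
    from . import io as _io

    bench = make_benchmark(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_records_tsv(bench.records, outdir / "records.tsv")
    _io.write_fasta(bench.sequences, outdir / "proteins.fasta")
    _io.write_fingerprints_tsv(bench.fingerprints, outdir / "fingerprints.tsv")
    _io.write_compounds_tsv(bench.compounds, outdir / "compounds.tsv")
    truth = {f"{c}\t{p}": int(l) for (c, p), l in bench.truth.items()}
    with open(outdir / "truth.json", "w") as fh:
        json.dump({"config": asdict(cfg), "truth": truth}, fh)
    return bench


# -- tiny hand-checkable curation fixture ----------------------------------

def golden_curation_fixture():
    """A 12-record fixture exercising every curation rule, with documented
    expected survivors.

    Compounds (real structures; C05 is a 75-carbon alkane above the
    1,000-Da window, C06/C08 are decane/undecane whose Morgan fingerprints
    have Tanimoto > 0.8):

    ========  ======================================  =========
    id        structure                               MW window
    ========  ======================================  =========
    C01       aspirin                                 in
    C02       caffeine                                in
    C03       ibuprofen                               in
    C04       paracetamol                             in
    C05       C75 alkane (~1052 Da)                   out
    C06       decane                                  in
    C07       benzoic acid                            in
    C08       undecane (near-duplicate of C06)        in
    ========  ======================================  =========

    The 12 records resolve to 8 pairs; after the weight filter and ligand
    deduplication 7 survive — 5 positive, 2 negative:

    * C01/P1 positive, representative 5 uM (min of {5, 8});
    * C02/P1 positive (10 uM boundary is inclusive);
    * C03/P1 negative, representative 15 uM (min of {15, 20});
    * C04/P1 positive by the any-active rule (20 uM but binary active);
    * C06/P1 positive (4 uM) — gives C06 two interactions;
    * C05/P2 dropped: molecular weight above 1,000 Da;
    * C06/P2 positive (3 uM);
    * C07/P2 negative (50 uM);
    * C08/P2 dropped: Tanimoto(C06, C08) > 0.8 on P2 and C06 has more
      interactions (2 vs 1).

    Returns (records, compounds, fingerprints, expected) where ``expected``
    maps (compound_id, protein_id) -> (label, representative_value_uM).
    """
    from .features import morgan_fingerprint

    smiles = {
        "C01": "CC(=O)Oc1ccccc1C(=O)O",
        "C02": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
        "C03": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
        "C04": "CC(=O)Nc1ccc(O)cc1",
        "C05": "C" * 75,
        "C06": "CCCCCCCCCC",
        "C07": "OC(=O)c1ccccc1",
        "C08": "CCCCCCCCCCC",
    }
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    compounds = {}
    fingerprints = {}
    for cid, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        compounds[cid] = Compound(
            compound_id=cid, smiles=smi, mol_weight_Da=Descriptors.MolWt(mol)
        )
        fingerprints[cid] = morgan_fingerprint(smi)

    R = BioactivityRecord
    A = AssayType
    records = [
        R("C01", "P1", A.IC50, value_uM=5.0, source="dbA"),
        R("C01", "P1", A.IC50, value_uM=8.0, source="dbB"),
        R("C02", "P1", A.IC50, value_uM=10.0, source="dbA"),
        R("C03", "P1", A.KI, value_uM=15.0, source="dbA"),
        R("C03", "P1", A.KI, value_uM=20.0, source="dbB"),
        R("C04", "P1", A.IC50, value_uM=20.0, source="dbA"),
        R("C04", "P1", A.BINARY, binary_label="active", source="dbC"),
        R("C05", "P2", A.IC50, value_uM=2.0, source="dbA"),
        R("C06", "P2", A.IC50, value_uM=3.0, source="dbA"),
        R("C07", "P2", A.IC50, value_uM=50.0, source="dbA"),
        R("C08", "P2", A.BINARY, binary_label="active", source="dbC"),
        R("C06", "P1", A.IC50, value_uM=4.0, source="dbB"),
    ]
    expected = {
        ("C01", "P1"): (1, 5.0),
        ("C02", "P1"): (1, 10.0),
        ("C03", "P1"): (0, 15.0),
        ("C04", "P1"): (1, 20.0),
        ("C06", "P1"): (1, 4.0),
        ("C06", "P2"): (1, 3.0),
        ("C07", "P2"): (0, 50.0),
    }
    return records, compounds, fingerprints, expected
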