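"""File ingest and export for the pipeline's tabular and sequence formats.

Formats: bioactivity records TSV (compound_id, protein_id, assay_type,
value, unit, label, source), SMILES files (id<TAB>smiles), FASTA protein
sequences, hex-packed fingerprint TSV, curated-pair TSV and JSON reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import AssayType, BioactivityRecord, Compound, CPIPair, normalize_potency_uM

RECORD_COLUMNS = ["compound_id", "protein_id", "assay_type", "value", "unit",
                  "label", "source"]


def read_records_tsv(path) -> list[BioactivityRecord]:
    """Read bioactivity records; potencies are normalized to uM on ingest.

    Rows with unknown units are rejected with a warning.
    """
    import warnings

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file lacks columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        assay = AssayType(row.assay_type)
        if assay == AssayType.BINARY:
            records.append(BioactivityRecord(
                compound_id=row.compound_id, protein_id=row.protein_id,
                assay_type=assay, binary_label=row.label, source=row.source,
            ))
        else:
            try:
                value = normalize_potency_uM(float(row.value), row.unit)
            except ValueError as e:
                warnings.warn(f"record rejected: {e}")
                continue
            records.append(BioactivityRecord(
                compound_id=row.compound_id, protein_id=row.protein_id,
                assay_type=assay, value_uM=value, source=row.source,
            ))
    return records


def write_records_tsv(records: list[BioactivityRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "compound_id": r.compound_id, "protein_id": r.protein_id,
            "assay_type": r.assay_type.value,
            "value": "" if r.value_uM is None else repr(r.value_uM),
            "unit": "" if r.value_uM is None else "uM",
            "label": r.binary_label or "",
            "source": r.source,
        })
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, sep="\t", index=False)


def read_smiles(path) -> dict[str, str]:
    """Read an id<TAB>smiles file."""
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        cid, smi = line.split("\t")[:2]
        out[cid] = smi
    return out


def write_smiles(smiles: dict[str, str], path) -> None:
    Path(path).write_text(
        "".join(f"{cid}\t{smi}\n" for cid, smi in smiles.items())
    )


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_fingerprints_tsv(fingerprints: dict[str, np.ndarray], path) -> None:
    """Write bit vectors as hex strings (4 bits per character)."""
    with open(path, "w") as fh:
        fh.write("compound_id\tn_bits\thex\n")
        for cid, fp in fingerprints.items():
            bits = np.asarray(fp).astype(np.uint8)
            packed = np.packbits(bits)
            fh.write(f"{cid}\t{bits.size}\t{packed.tobytes().hex()}\n")


def read_fingerprints_tsv(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        n = int(row.n_bits)
        arr = np.unpackbits(np.frombuffer(bytes.fromhex(row.hex), dtype=np.uint8))
        out[row.compound_id] = arr[:n].astype(np.uint8)
    return out


def write_compounds_tsv(compounds: dict[str, Compound], path) -> None:
    rows = [
        {"compound_id": c.compound_id, "smiles": c.smiles,
         "mol_weight_Da": c.mol_weight_Da}
        for c in compounds.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_compounds_tsv(path) -> dict[str, Compound]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = {}
    for row in df.itertuples(index=False):
        mw = row.mol_weight_Da
        out[row.compound_id] = Compound(
            compound_id=row.compound_id, smiles=row.smiles or "",
            mol_weight_Da=None if mw == "" else float(mw),
        )
    return out


def write_pairs_tsv(pairs: list[CPIPair], path) -> None:
    rows = [
        {"compound_id": p.compound_id, "protein_id": p.protein_id,
         "label": "positive" if p.label else "negative",
         "representative_value_uM": "" if p.representative_value_uM is None
         else repr(p.representative_value_uM),
         "provenance": ",".join(sorted(p.provenance))}
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> list[CPIPair]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(CPIPair(
            compound_id=row.compound_id, protein_id=row.protein_id,
            label=1 if row.label == "positive" else 0,
            representative_value_uM=(
                None if row.representative_value_uM == ""
                else float(row.representative_value_uM)
            ),
            provenance=frozenset(row.provenance.split(",")) if row.provenance
            else frozenset(),
        ))
    return out


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
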