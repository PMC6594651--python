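"""Dataset I/O and assembly.

File dialects are deliberately rigid for bit-exact interchange: FASTA per NCBI
conventions for proteins, UTF-8 TSV with a header row and no quoting for drug
tables, interaction pair tables and binding-site annotations. Residue
coordinates are 1-based inclusive everywhere, matching the PDB convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r} has an empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DrugRecord:
    """A drug identified by id, carrying a SMILES string and/or a precomputed
    binary fingerprint (the latter lets synthetic datasets bypass chemistry)."""

    drug_id: str
    smiles: str | None = None
    fingerprint: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.smiles is None and self.fingerprint is None:
            raise ValueError(f"drug {self.drug_id!r} needs a SMILES or a fingerprint")
        if self.fingerprint is not None:
            fp = np.asarray(self.fingerprint)
            if not np.isin(fp, (0, 1)).all():
                raise ValueError(f"drug {self.drug_id!r}: fingerprint must be 0/1")
            object.__setattr__(self, "fingerprint", fp.astype(np.int8))


@dataclass
class InteractionDataset:
    """Binary drug-protein interaction pairs plus entity lookup tables."""

    pairs: list[tuple[str, str, int]]
    drugs: dict[str, DrugRecord]
    proteins: dict[str, ProteinRecord]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for d, p, y in self.pairs:
            if y not in (0, 1):
                raise ValueError(f"non-binary label {y!r} for pair ({d}, {p})")
            if d not in self.drugs:
                raise ValueError(f"pair ({d}, {p}) references unknown drug {d!r}")
            if p not in self.proteins:
                raise ValueError(f"pair ({d}, {p}) references unknown protein {p!r}")
            if (d, p) in seen:
                raise ValueError(f"duplicate pair ({d}, {p})")
            seen.add((d, p))

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([y for _, _, y in self.pairs], dtype=np.int64)

    def subset(self, indices: Iterable[int]) -> "InteractionDataset":
        return InteractionDataset(
            [self.pairs[i] for i in indices], self.drugs, self.proteins
        )

    def positive_pairs(self) -> set[tuple[str, str]]:
        return {(d, p) for d, p, y in self.pairs if y == 1}


@dataclass(frozen=True)
class BindingSiteAnnotation:
    """A set of 1-based residue indices annotated as a ligand-binding site,
    keyed by a structure entry id and the protein it belongs to."""

    entry_id: str
    protein_id: str
    residues: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"entry {self.entry_id!r}: empty residue set")
        if min(self.residues) < 1:
            raise ValueError(f"entry {self.entry_id!r}: residue indices are 1-based")

    @property
    def sorted_residues(self) -> tuple[int, ...]:
        return tuple(sorted(self.residues))


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file, uppercasing sequences.

    Duplicate identifiers are an error, reported with both entry positions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    positions: dict[str, int] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq).strip().upper()
        if not seq:
            raise ValueError(f"{path}: entry {rec.id!r} (#{i}) has an empty sequence")
        if rec.id in positions:
            raise ValueError(
                f"{path}: duplicate identifier {rec.id!r} at entries "
                f"#{positions[rec.id]} and #{i}"
            )
        positions[rec.id] = i
        records.append(ProteinRecord(rec.id, seq))
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def _read_tsv(path: str | Path, required: Sequence[str]) -> list[dict[str, str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        if reader.fieldnames is None or any(c not in reader.fieldnames for c in required):
            raise ValueError(f"{path}: expected TSV header with columns {list(required)}")
        return list(reader)


def read_drug_table(path: str | Path) -> list[DrugRecord]:
    """Read a TSV of (drug_id, smiles)."""
    rows = _read_tsv(path, ("drug_id", "smiles"))
    return [DrugRecord(r["drug_id"], smiles=r["smiles"]) for r in rows]


def read_interactions(
    path: str | Path,
    drugs: Mapping[str, DrugRecord],
    proteins: Mapping[str, ProteinRecord],
) -> InteractionDataset:
    """Read a TSV of (drug_id, protein_id, label) into an InteractionDataset.

    Rows referencing unknown ids, carrying non-binary labels, or duplicating a
    pair are rejected with their row numbers (header = row 1).
    """
    rows = _read_tsv(path, ("drug_id", "protein_id", "label"))
    pairs: list[tuple[str, str, int]] = []
    first_row: dict[tuple[str, str], int] = {}
    for i, r in enumerate(rows, start=2):
        d, p, label = r["drug_id"], r["protein_id"], r["label"]
        if d not in drugs:
            raise ValueError(f"{path}: row {i} references unknown drug {d!r}")
        if p not in proteins:
            raise ValueError(f"{path}: row {i} references unknown protein {p!r}")
        if label not in ("0", "1"):
            raise ValueError(f"{path}: row {i} has non-binary label {label!r}")
        if (d, p) in first_row:
            raise ValueError(
                f"{path}: duplicate pair ({d}, {p}) at rows {first_row[(d, p)]} and {i}"
            )
        first_row[(d, p)] = i
        pairs.append((d, p, int(label)))
    return InteractionDataset(pairs, dict(drugs), dict(proteins))


def write_interactions(dataset: InteractionDataset, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["drug_id", "protein_id", "label"])
        for d, p, y in dataset.pairs:
            w.writerow([d, p, y])


def read_binding_sites(path: str | Path) -> list[BindingSiteAnnotation]:
    """Read a TSV of (entry_id, protein_id, residues) binding-site annotations.

    ``residues`` is a comma-separated list of 1-based indices; duplicates are
    collapsed and the set is stored sorted.
    """
    rows = _read_tsv(path, ("entry_id", "protein_id", "residues"))
    annotations = []
    for i, r in enumerate(rows, start=2):
        raw = [tok for tok in r["residues"].split(",") if tok.strip()]
        if not raw:
            raise ValueError(f"{path}: row {i} has an empty residue list")
        residues = frozenset(int(tok) for tok in raw)
        if min(residues) < 1:
            raise ValueError(f"{path}: row {i} has a residue index <= 0 (1-based)")
        annotations.append(BindingSiteAnnotation(r["entry_id"], r["protein_id"], residues))
    return annotations


def write_binding_sites(annotations: Sequence[BindingSiteAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["entry_id", "protein_id", "residues"])
        for a in annotations:
            w.writerow([a.entry_id, a.protein_id, ",".join(map(str, a.sorted_residues))])


def write_drug_table(drugs: Sequence[DrugRecord], path: str | Path) -> None:
    """Write drugs as TSV; direct fingerprints are serialised as the indices
    of their set bits (column ``fingerprint_bits``)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["drug_id", "smiles", "n_bits", "fingerprint_bits"])
        for d in drugs:
            if d.fingerprint is not None:
                bits = ",".join(map(str, np.flatnonzero(d.fingerprint)))
                w.writerow([d.drug_id, d.smiles or "", d.fingerprint.size, bits])
            else:
                w.writerow([d.drug_id, d.smiles, "", ""])


def read_drug_table_with_bits(path: str | Path) -> list[DrugRecord]:
    rows = _read_tsv(path, ("drug_id", "smiles"))
    out = []
    for r in rows:
        if r.get("n_bits"):
            fp = np.zeros(int(r["n_bits"]), dtype=np.int8)
            if r.get("fingerprint_bits"):
                fp[[int(b) for b in r["fingerprint_bits"].split(",")]] = 1
            out.append(DrugRecord(r["drug_id"], smiles=r["smiles"] or None, fingerprint=fp))
        else:
            out.append(DrugRecord(r["drug_id"], smiles=r["smiles"]))
    return out


# ---------------------------------------------------------------------------
# dataset assembly


def sample_negative_sets(
    dataset: InteractionDataset,
    n_sets: int = 10,
    ratio: float = 1.0,
    seed: int = 0,
    *,
    disjoint: bool = False,
) -> list[InteractionDataset]:
    """Augment a positive-only dataset with randomly sampled negative pairs.

    Negatives are drawn uniformly without replacement from the non-positive
    cells of the drug x protein grid spanned by the positives, ``ratio``
    negatives per positive. Each of the ``n_sets`` returned datasets shares
    the positives; by default the negative sets are only exclusive of the
    positives, with ``disjoint=True`` additionally pairwise-disjoint.
    """
    if any(y != 1 for _, _, y in dataset.pairs):
        raise ValueError("negative sampling expects a positive-only dataset")
    n_neg = round(len(dataset.pairs) * ratio)
    drug_ids = sorted(dataset.drugs)
    protein_ids = sorted(dataset.proteins)
    positives = {(d, p) for d, p, _ in dataset.pairs}
    complement = [
        (d, p) for d in drug_ids for p in protein_ids if (d, p) not in positives
    ]
    needed = n_sets * n_neg if disjoint else n_neg
    if needed > len(complement):
        raise ValueError(
            f"cannot draw {needed} negatives from a complement of {len(complement)} "
            f"non-positive pairs"
        )
    rng = np.random.default_rng(seed)
    out = []
    pool = list(complement)
    for _ in range(n_sets):
        idx = rng.choice(len(pool), size=n_neg, replace=False)
        sampled = [pool[i] for i in idx]
        if disjoint:
            chosen = set(sampled)
            pool = [c for c in pool if c not in chosen]
        out.append(
            InteractionDataset(
                list(dataset.pairs) + [(d, p, 0) for d, p in sampled],
                dataset.drugs,
                dataset.proteins,
            )
        )
    return out


def split_by_novelty(
    train: InteractionDataset, test: InteractionDataset
) -> dict[str, InteractionDataset]:
    """Partition test pairs by whether their compound/protein occur in train.

    Returns the four overlapping subsets ``all``, ``unseen_compound``,
    ``unseen_protein`` and ``unseen_both``; unseen_both is contained in each
    single-novelty subset, and every subset in ``all``.
    """
    train_drugs = set(train.drugs) & {d for d, _, _ in train.pairs}
    train_proteins = set(train.proteins) & {p for _, p, _ in train.pairs}
    idx_all = range(len(test.pairs))
    idx_uc = [i for i in idx_all if test.pairs[i][0] not in train_drugs]
    idx_up = [i for i in idx_all if test.pairs[i][1] not in train_proteins]
    idx_ub = [i for i in idx_all if i in set(idx_uc) and i in set(idx_up)]
    return {
        "all": test.subset(idx_all),
        "unseen_compound": test.subset(idx_uc),
        "unseen_protein": test.subset(idx_up),
        "unseen_both": test.subset(idx_ub),
    }


def write_predictions(
    rows: Sequence[tuple[str, str, float, int]], path: str | Path
) -> None:
    """Write (drug_id, protein_id, score, call) prediction rows as TSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["drug_id", "protein_id", "score", "call"])
        for d, p, s, c in rows:
            w.writerow([d, p, f"{s:.6f}", c])
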