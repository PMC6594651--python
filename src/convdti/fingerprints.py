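"""Morgan/circular fingerprint featurisation of drugs.

Drugs are represented as fixed-length binary vectors whose set bits mark the
presence of hashed circular substructures up to a bond radius (ECFP-style);
the defaults — radius 2, 2048 bits, no chirality — give the common ECFP4-like
encoding. SMILES parsing and hashing are delegated to RDKit; drug records may
instead carry a precomputed fingerprint, which is passed through verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import RDLogger

from .io_data import DrugRecord

RDLogger.DisableLog("rdApp.error")

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048


@dataclass(frozen=True)
class Fingerprint:
    bits: np.ndarray
    radius: int = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.int8)
        if bits.ndim != 1 or not np.isin(bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be a 1-D 0/1 vector")
        object.__setattr__(self, "bits", bits)

    @property
    def n_bits(self) -> int:
        return self.bits.size


def morgan_fingerprint(
    smiles: str, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS
) -> Fingerprint:
    """Hashed binary Morgan fingerprint of a molecule given as SMILES.

    Deterministic: identical molecules (even written as different SMILES)
    yield identical bit vectors. Unparseable or empty SMILES raise ValueError.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=np.int8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(bits, radius)


def featurize_table(
    drugs: Sequence[DrugRecord],
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> np.ndarray:
    """Stack drug fingerprints into an (n_drugs, n_bits) binary matrix.

    Row order matches the input order. Records with a precomputed fingerprint
    are passed through unchanged (the dimension must match ``n_bits``); the
    rest are featurised from their SMILES.
    """
    rows = []
    for rec in drugs:
        if rec.fingerprint is not None:
            if rec.fingerprint.size != n_bits:
                raise ValueError(
                    f"drug {rec.drug_id!r}: precomputed fingerprint has "
                    f"{rec.fingerprint.size} bits, expected {n_bits}"
                )
            rows.append(np.asarray(rec.fingerprint, dtype=np.int8))
        else:
            rows.append(morgan_fingerprint(rec.smiles, radius, n_bits).bits)
    return np.stack(rows)
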