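"""Protein sequence encoding.

Amino-acid sequences of arbitrary length are mapped to fixed-length integer
label vectors: each residue becomes an index into a small vocabulary (the 20
canonical amino acids plus a pad token ``$`` and an unknown token ``X?``), and
the tail up to the maximum protein length (MPL) is filled with the pad index.
The embedding lookup downstream turns these labels into trainable vectors;
convolution windows that extend into the padded margin are masked out before
global max-pooling so that padding never wins the max.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
PAD_TOKEN = "$"
UNKNOWN_TOKEN = "?"

DEFAULT_MPL = 2500


@dataclass(frozen=True)
class Vocabulary:
    """Bijective residue-token → integer index mapping.

    Index 0 is reserved for the pad token so that zero-initialised label
    arrays are valid "all padding" encodings.
    """

    tokens: tuple[str, ...] = (PAD_TOKEN,) + tuple(CANONICAL_RESIDUES) + (UNKNOWN_TOKEN,)

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")
        if PAD_TOKEN not in self.tokens or UNKNOWN_TOKEN not in self.tokens:
            raise ValueError("vocabulary must contain pad and unknown tokens")

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def pad_index(self) -> int:
        return self.tokens.index(PAD_TOKEN)

    @property
    def unknown_index(self) -> int:
        return self.tokens.index(UNKNOWN_TOKEN)

    def index(self, token: str) -> int:
        try:
            return self.tokens.index(token)
        except ValueError:
            return self.unknown_index

    def decode(self, labels: np.ndarray, true_length: int) -> str:
        return "".join(self.tokens[i] for i in labels[:true_length])


DEFAULT_VOCABULARY = Vocabulary()


@dataclass
class EncodedProtein:
    """Padded integer label vector with its true (un-padded) length."""

    labels: np.ndarray
    true_length: int
    protein_id: str = ""
    vocabulary: Vocabulary = field(default_factory=lambda: DEFAULT_VOCABULARY)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D integer vector")
        if not (0 < self.true_length <= self.labels.shape[0]):
            raise ValueError("true_length must be in 1..len(labels)")

    @property
    def mpl(self) -> int:
        return self.labels.shape[0]

    def window_mask(self, window_size: int) -> set[int]:
        """Valid 1-based start positions for windows of ``window_size``."""
        return valid_window_positions(self.true_length, window_size)


def valid_window_positions(true_length: int, window_size: int) -> set[int]:
    """1-based start positions of windows lying entirely within the sequence.

    Exactly ``{1 .. true_length - window_size + 1}``; empty when the window is
    longer than the sequence.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    return set(range(1, true_length - window_size + 2))


def encode_sequence(
    sequence: str,
    vocabulary: Vocabulary = DEFAULT_VOCABULARY,
    mpl: int = DEFAULT_MPL,
    *,
    protein_id: str = "",
    on_overflow: str = "truncate",
) -> EncodedProtein:
    """Encode an amino-acid string as a padded integer label vector.

    Residues outside the 20 canonical letters (B, Z, X, U, O, ...) map to the
    unknown token. Sequences longer than ``mpl`` are truncated to their first
    ``mpl`` residues with a warning (``on_overflow="error"`` rejects instead).
    """
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    if mpl < 1:
        raise ValueError("mpl must be >= 1")
    sequence = sequence.upper()
    if len(sequence) > mpl:
        if on_overflow == "error":
            raise ValueError(
                f"sequence {protein_id or '<anonymous>'} has length "
                f"{len(sequence)} > mpl={mpl}"
            )
        msg = (
            f"sequence {protein_id or '<anonymous>'} of length {len(sequence)} "
            f"truncated to the first {mpl} residues"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        sequence = sequence[:mpl]
    labels = np.full(mpl, vocabulary.pad_index, dtype=np.int64)
    for i, ch in enumerate(sequence):
        labels[i] = vocabulary.index(ch)
    return EncodedProtein(labels, len(sequence), protein_id, vocabulary)


def decode_sequence(encoded: EncodedProtein) -> str:
    return encoded.vocabulary.decode(encoded.labels, encoded.true_length)


def init_embedding(
    vocabulary: Vocabulary,
    embedding_size: int,
    seed: int,
    *,
    zero_pad_row: bool = False,
) -> np.ndarray:
    """Xavier/Glorot-normal embedding table of shape ``(|V|, ES)``.

    Rows are drawn i.i.d. N(0, 2 / (fan_in + fan_out)) with fan_in = |V| and
    fan_out = ES, reproducibly from ``seed``. With ``zero_pad_row`` the pad
    row is fixed at zero (useful with masking disabled).
    """
    if embedding_size < 1:
        raise ValueError("embedding_size must be >= 1")
    rng = np.random.default_rng(seed)
    std = np.sqrt(2.0 / (vocabulary.size + embedding_size))
    table = rng.normal(0.0, std, size=(vocabulary.size, embedding_size))
    if zero_pad_row:
        table[vocabulary.pad_index] = 0.0
    return table
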