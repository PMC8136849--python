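"""Sequence representation, one-hot encoding, batch padding and k-mer counting.

All sequences live in RNA space over the alphabet ``{A, C, G, U}`` (``T`` is
accepted on input and mapped to ``U``; ``N`` is tolerated and encodes as an
all-zero one-hot row).  The 3' end of a 5'UTR sequence abuts the canonical
start codon, so reading-frame arithmetic is anchored at the 3' end: a codon
starting at 0-based position ``i`` of a length-``L`` sequence is in frame with
the canonical CDS iff ``(L - i) % 3 == 0``.

Coordinates in this module are sequence-local and 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ALPHABET",
    "NucSequence",
    "PaddedOneHotBatch",
    "KmerFeatures",
    "one_hot_encode",
    "pad_batch",
    "encode_batch",
    "frame_index",
    "kmer_counts",
    "kmer_feature_matrix",
    "read_sequence_table",
    "write_sequence_table",
    "read_fasta_sequences",
]

ALPHABET = "ACGU"
_CHANNEL = {b: i for i, b in enumerate(ALPHABET)}

# Minimum length the models accept: one position per reading frame.
MIN_MODEL_LENGTH = 3


class NucSequence:
    """A validated RNA sequence (uppercase, T mapped to U, N allowed).

    Behaves like a thin immutable wrapper around ``str``; most functions in
    this package accept either a plain string or a ``NucSequence`` and coerce
    via :func:`as_sequence`.
    """

    __slots__ = ("bases",)

    def __init__(self, bases: str):
        if not isinstance(bases, str):
            raise TypeError(f"expected str, got {type(bases).__name__}")
        cleaned = bases.upper().replace("T", "U")
        if len(cleaned) == 0:
            raise ValueError("empty sequence")
        for pos, ch in enumerate(cleaned):
            if ch not in "ACGUN":
                raise ValueError(
                    f"invalid character {ch!r} at position {pos} (alphabet ACGU/T, N)"
                )
        object.__setattr__(self, "bases", cleaned)

    def __setattr__(self, *a):  # immutability
        raise AttributeError("NucSequence is immutable")

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def __repr__(self) -> str:
        return f"NucSequence({self.bases!r})"

    def __eq__(self, other) -> bool:
        if isinstance(other, NucSequence):
            return self.bases == other.bases
        if isinstance(other, str):
            return self.bases == NucSequence(other).bases
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.bases)

    def __getitem__(self, item) -> str:
        return self.bases[item]


def as_sequence(seq: "NucSequence | str") -> NucSequence:
    """Coerce a string to :class:`NucSequence` (no-op if already one)."""
    return seq if isinstance(seq, NucSequence) else NucSequence(seq)


def one_hot_encode(seq: "NucSequence | str", dtype=np.float32) -> np.ndarray:
    """One-hot encode a sequence as an ``L x 4`` matrix, channels (A, C, G, U).

    ``N`` encodes as an all-zero row, matching the zero-padding convention.
    """
    seq = as_sequence(seq)
    mat = np.zeros((len(seq), 4), dtype=dtype)
    for i, ch in enumerate(seq.bases):
        if ch != "N":
            mat[i, _CHANNEL[ch]] = 1.0
    return mat


@dataclass(frozen=True)
class PaddedOneHotBatch:
    """A batch of one-hot sequences, zero-padded on the 5' end.

    Sequences are right-aligned: all 3' ends coincide at index ``Lmax - 1``,
    so reading-frame classes are consistent across the batch.  ``mask`` marks
    real (valid) positions; padded positions are all-zero and invalid.
    """

    values: np.ndarray  # (B, Lmax, 4)
    mask: np.ndarray  # (B, Lmax) bool
    lengths: np.ndarray  # (B,) int

    def __post_init__(self):
        if self.values.ndim != 3 or self.values.shape[2] != 4:
            raise ValueError(f"values must be (B, L, 4), got {self.values.shape}")
        if self.mask.shape != self.values.shape[:2]:
            raise ValueError("mask shape mismatch")
        if self.lengths.shape != (self.values.shape[0],):
            raise ValueError("lengths shape mismatch")

    @property
    def batch_size(self) -> int:
        return self.values.shape[0]

    @property
    def max_length(self) -> int:
        return self.values.shape[1]

    def unpad(self) -> list[np.ndarray]:
        """Strip the 5' padding, recovering the original one-hot matrices."""
        Lmax = self.max_length
        return [self.values[b, Lmax - n :] for b, n in enumerate(self.lengths)]

    def with_3prime_padding(self, k: int) -> "PaddedOneHotBatch":
        """Append ``k`` masked all-zero positions at the 3' end of every
        sequence, shifting the reading frame of every real position by ``k``.

        This is the simulated-frameshift device used in variant scoring; the
        appended positions are padding, not real bases, and stay masked.
        """
        if k < 0:
            raise ValueError("k must be >= 0")
        if k == 0:
            return self
        B = self.batch_size
        tail_vals = np.zeros((B, k, 4), dtype=self.values.dtype)
        tail_mask = np.zeros((B, k), dtype=bool)
        return PaddedOneHotBatch(
            values=np.concatenate([self.values, tail_vals], axis=1),
            mask=np.concatenate([self.mask, tail_mask], axis=1),
            lengths=self.lengths.copy(),
        )


def pad_batch(mats: Sequence[np.ndarray]) -> PaddedOneHotBatch:
    """Assemble one-hot matrices into a 5'-zero-padded, masked batch.

    All sequences are padded on the 5' end (low indices) to the longest in
    the batch so that their 3' ends coincide; order is preserved.
    """
    if len(mats) == 0:
        raise ValueError("empty batch")
    lengths = np.array([m.shape[0] for m in mats], dtype=np.int64)
    Lmax = int(lengths.max())
    B = len(mats)
    values = np.zeros((B, Lmax, 4), dtype=mats[0].dtype)
    mask = np.zeros((B, Lmax), dtype=bool)
    for b, m in enumerate(mats):
        n = m.shape[0]
        values[b, Lmax - n :] = m
        mask[b, Lmax - n :] = True
    return PaddedOneHotBatch(values=values, mask=mask, lengths=lengths)


def encode_batch(
    seqs: Iterable["NucSequence | str"], dtype=np.float32
) -> PaddedOneHotBatch:
    """One-hot encode and pad a collection of sequences in one step."""
    return pad_batch([one_hot_encode(s, dtype=dtype) for s in seqs])


def frame_index(i: int, L: int) -> int:
    """Reading frame of position ``i`` in a length-``L`` 5'UTR.

    Returns ``(L - i) % 3``; a codon starting at ``i`` is in frame with the
    canonical start codon (which sits immediately 3' of the sequence) iff the
    result is 0.
    """
    if not 0 <= i < L:
        raise ValueError(f"position {i} out of range for length {L}")
    return (L - i) % 3


@dataclass(frozen=True)
class KmerFeatures:
    """k-mer count features, optionally separated by reading frame.

    Unframed counts have length ``4**k``; framed counts have length
    ``3 * 4**k`` laid out as [frame 0 | frame 1 | frame 2], where each
    occurrence is assigned the frame of its first base.
    """

    k: int
    framed: bool
    counts: np.ndarray

    def __post_init__(self):
        expect = (3 if self.framed else 1) * 4**self.k
        if self.counts.shape != (expect,):
            raise ValueError(f"expected {expect} counts, got {self.counts.shape}")


def _kmer_code(window: str) -> int | None:
    code = 0
    for ch in window:
        idx = _CHANNEL.get(ch)
        if idx is None:  # window contains N: not countable
            return None
        code = code * 4 + idx
    return code


def kmer_counts(seq: "NucSequence | str", k: int, framed: bool = False) -> KmerFeatures:
    """Count k-mer occurrences over all ``L - k + 1`` windows.

    In framed mode each occurrence lands in the block of
    ``frame_index(start, L)``.  Windows containing ``N`` are not counted.
    A sequence shorter than ``k`` yields the zero vector.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = as_sequence(seq)
    L = len(seq)
    n_kmers = 4**k
    counts = np.zeros((3 if framed else 1) * n_kmers, dtype=np.int64)
    for start in range(L - k + 1):
        code = _kmer_code(seq.bases[start : start + k])
        if code is None:
            continue
        if framed:
            counts[frame_index(start, L) * n_kmers + code] += 1
        else:
            counts[code] += 1
    return KmerFeatures(k=k, framed=framed, counts=counts)


def kmer_feature_matrix(
    seqs: Iterable["NucSequence | str"], k: int, framed: bool = False
) -> np.ndarray:
    """Stack per-sequence k-mer count vectors into an ``n x d`` float matrix."""
    return np.stack(
        [kmer_counts(s, k, framed).counts.astype(np.float64) for s in seqs]
    )


# ---------------------------------------------------------------------------
# Sequence tables and FASTA input
# ---------------------------------------------------------------------------

def read_sequence_table(path, sep=None):
    """Read a CSV/TSV with columns ``utr`` (required), ``mrl``, ``library``.

    The separator is inferred from the extension when not given (.tsv -> tab).
    """
    import pandas as pd

    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if "utr" not in df.columns:
        raise ValueError(f"{path}: missing required column 'utr'")
    return df


def write_sequence_table(df, path, sep=None) -> None:
    import pandas as pd  # noqa: F401

    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False)


def read_fasta_sequences(path) -> dict[str, NucSequence]:
    """Read sequences from a FASTA file as ``{record id: NucSequence}``."""
    from Bio import SeqIO

    return {rec.id: NucSequence(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}
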