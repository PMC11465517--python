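"""Protein multiple sequence alignments.

Sequences are stored as a (n_sequences, n_columns) uint8 matrix over the 20
amino-acid codes (PAML/PhyML residue order ``ARNDCQEGHILKMFPSTWYV``), plus
code 20 for the gap symbol ``-`` and code 21 for missing data ``X``.  In the
likelihood both gap and missing are treated as fully undetermined states.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["AA_LETTERS", "GAP_CODE", "MISSING_CODE", "ProteinAlignment"]

AA_LETTERS = "ARNDCQEGHILKMFPSTWYV"
GAP_CODE = 20
MISSING_CODE = 21
_ALPHABET = AA_LETTERS + "-X"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(_ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_DECODE = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _ENCODE[raw]
    if np.any(codes == 255):
        bad = sorted({chr(b) for b in raw[codes == 255]})
        raise ValueError(
            f"invalid residue symbol(s) {bad}; allowed: 20 amino acids, '-' and 'X'"
        )
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


class ProteinAlignment:
    """Equal-length amino-acid sequences keyed by species label."""

    def __init__(self, labels: Sequence[str], data: np.ndarray):
        self.labels = list(labels)
        self.data = np.asarray(data, dtype=np.uint8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError("data must be (n_sequences, n_columns)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")
        if self.data.size and self.data.max() > MISSING_CODE:
            raise ValueError("invalid residue codes in data")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_dict(cls, seqs: Mapping[str, str]) -> "ProteinAlignment":
        labels = list(seqs)
        if not labels:
            raise ValueError("empty alignment")
        rows = [encode_sequence(seqs[lab]) for lab in labels]
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        return cls(labels, np.vstack(rows) if rows[0].size else
                   np.empty((len(rows), 0), dtype=np.uint8))

    @classmethod
    def read_fasta(cls, path) -> "ProteinAlignment":
        seqs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate FASTA record {rec.id!r}")
            seqs[rec.id] = str(rec.seq)
        return cls.from_dict(seqs)

    # ------------------------------------------------------------------ basic
    @property
    def n_sequences(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def sequence(self, label: str) -> str:
        return decode_sequence(self.data[self._index[label]])

    def to_dict(self) -> dict[str, str]:
        return {lab: self.sequence(lab) for lab in self.labels}

    def subset(self, labels: Sequence[str]) -> "ProteinAlignment":
        rows = [self._index[lab] for lab in labels]
        return ProteinAlignment(list(labels), self.data[rows])

    def take_columns(self, cols: Sequence[int]) -> "ProteinAlignment":
        return ProteinAlignment(self.labels, self.data[:, np.asarray(cols, int)])

    def residue_frequencies(self, pseudocount: float = 0.0) -> np.ndarray:
        """Observed frequencies of the 20 amino acids (gap/missing ignored)."""
        counts = np.bincount(self.data.ravel(), minlength=22)[:20].astype(float)
        counts += pseudocount
        total = counts.sum()
        if total == 0:
            raise ValueError("alignment contains no determined residues")
        return counts / total

    def write_fasta(self, path) -> None:
        recs = [
            SeqRecord(Seq(self.sequence(lab)), id=lab, description="")
            for lab in self.labels
        ]
        SeqIO.write(recs, str(path), "fasta")

    def __repr__(self):  # pragma: no cover
        return f"<ProteinAlignment {self.n_sequences} seqs x {self.n_sites} cols>"
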