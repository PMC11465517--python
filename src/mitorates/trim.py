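"""Conserved-block alignment trimming.

A simplified conserved-block filter in the spirit of classic block-trimming
tools: a column is *conserved* when its most frequent amino acid reaches a
conservation threshold among the non-missing rows, and only maximal runs of
conserved columns at least ``min_block_len`` long are kept.  Defaults
(minimum block of 6 columns, 50% conservation, gaps allowed) mirror the
"amino-acid alignment, blocks >= 6, gaps allowed" trimming regime used for
deep-divergence protein supermatrices.  This is deliberately not a
bit-compatible clone of any particular trimmer: the analysis depends on
conservative block filtering, not on one program's exact heuristics.
"""

from __future__ import annotations

import numpy as np

from .alignment import GAP_CODE, MISSING_CODE, ProteinAlignment

__all__ = ["trim_blocks"]


def trim_blocks(
    msa: ProteinAlignment,
    min_block_len: int = 6,
    conservation_threshold: float = 0.5,
    allow_gaps: bool = True,
) -> tuple[ProteinAlignment, np.ndarray]:
    """Keep conserved blocks; return the trimmed alignment and column map.

    A column counts as conserved iff the count of its modal residue (gaps and
    missing never count as residues) is at least ``conservation_threshold``
    times the number of non-missing rows; with ``allow_gaps=False`` any gap
    disqualifies the column outright.  The column map lists the retained
    0-based input column indices, strictly increasing.
    """
    if msa.n_sites == 0 or msa.n_sequences == 0:
        raise ValueError("cannot trim an empty alignment")
    if min_block_len < 1:
        raise ValueError("min_block_len must be >= 1")
    if not (0 < conservation_threshold <= 1):
        raise ValueError("conservation_threshold must be in (0, 1]")
    data = msa.data
    counts = np.stack(
        [(data == a).sum(axis=0) for a in range(20)]
    )  # (20, n_cols)
    modal = counts.max(axis=0)
    n_missing = (data == MISSING_CODE).sum(axis=0)
    denom = np.maximum(data.shape[0] - n_missing, 1)
    conserved = modal >= conservation_threshold * denom
    conserved &= modal > 0
    if not allow_gaps:
        conserved &= ~(data == GAP_CODE).any(axis=0)

    keep = np.zeros(msa.n_sites, dtype=bool)
    i = 0
    n = msa.n_sites
    while i < n:
        if conserved[i]:
            j = i
            while j < n and conserved[j]:
                j += 1
            if j - i >= min_block_len:
                keep[i:j] = True
            i = j
        else:
            i += 1
    cols = np.flatnonzero(keep)
    return msa.take_columns(cols), cols
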