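"""Ortholog-group bookkeeping: gene categories, presence filters, paralog
resolution and per-category concatenation.

Six gene categories mirror the study design: mitochondrion-encoded OXPHOS
subunits (mtOXPHOS), nuclear-encoded OXPHOS subunits (nucOXPHOS, with a
complex-2 flag — complex 2 is the only entirely nuclear-encoded complex),
nuclear-encoded mitochondrial ribosomal proteins (nucMTRP), and three
mitochondrion-unrelated controls: cytosolic ribosomal proteins (nucCRP),
strictly single-copy genes (nucControlSingle) and a broad background set
(nucControl).  Category membership is defined by marker gene-id lists.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import ProteinAlignment

__all__ = [
    "GeneRecord",
    "OrthologGroup",
    "CategoryMap",
    "assign_categories",
    "select_single_copy",
    "select_background",
    "resolve_paralogs",
    "concatenate",
]

STANDARD_CATEGORIES = (
    "mtOXPHOS",
    "nucOXPHOS",
    "nucMTRP",
    "nucCRP",
    "nucControlSingle",
    "nucControl",
)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    sequence: str  # aligned: residues, '-' gap, 'X' missing


def _is_vacuous(seq: str) -> bool:
    return all(c in "-X" for c in seq)


class OrthologGroup:
    """One ortholog group: 0..n aligned gene copies per species.

    Records that consist entirely of gap/missing symbols count as absent for
    presence and copy-number purposes (a species with only an all-gap entry
    contributes no data).
    """

    def __init__(self, group_id: str, genes: Mapping[str, Sequence[GeneRecord]]):
        self.group_id = group_id
        self.genes = {sp: list(recs) for sp, recs in genes.items() if recs}
        lengths = {
            len(r.sequence) for recs in self.genes.values() for r in recs
        }
        if len(lengths) > 1:
            raise ValueError(
                f"group {group_id}: sequences of unequal length {sorted(lengths)}"
            )
        self.length = lengths.pop() if lengths else 0
        ids = [r.gene_id for recs in self.genes.values() for r in recs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"group {group_id}: duplicate gene ids")

    @property
    def gene_ids(self) -> set[str]:
        return {r.gene_id for recs in self.genes.values() for r in recs}

    def copy_number(self, species: str) -> int:
        return sum(
            1 for r in self.genes.get(species, []) if not _is_vacuous(r.sequence)
        )

    @property
    def species_present(self) -> set[str]:
        return {sp for sp in self.genes if self.copy_number(sp) > 0}

    # ------------------------------------------------------------------- I/O
    @classmethod
    def from_fasta(cls, path, group_id: str | None = None) -> "OrthologGroup":
        """Read a per-group FASTA with headers ``species|gene_id``."""
        import os

        if group_id is None:
            group_id = os.path.splitext(os.path.basename(str(path)))[0]
        genes: dict[str, list[GeneRecord]] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if "|" not in rec.id:
                raise ValueError(
                    f"{path}: FASTA header {rec.id!r} is not 'species|gene_id'"
                )
            sp, gid = rec.id.split("|", 1)
            genes.setdefault(sp, []).append(GeneRecord(gid, str(rec.seq)))
        return cls(group_id, genes)

    def to_fasta(self, path) -> None:
        recs = [
            SeqRecord(Seq(r.sequence), id=f"{sp}|{r.gene_id}", description="")
            for sp in sorted(self.genes)
            for r in self.genes[sp]
        ]
        SeqIO.write(recs, str(path), "fasta")

    def __repr__(self):  # pragma: no cover
        return (
            f"<OrthologGroup {self.group_id}: {len(self.genes)} species, "
            f"L={self.length}>"
        )


@dataclass
class CategoryMap:
    """category name -> set of group ids, plus complex-2 flags on nucOXPHOS."""

    categories: dict[str, set[str]]
    complex2: set[str] = field(default_factory=set)
    overlaps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["group_id", "categories"])
    )

    def __post_init__(self):
        if self.complex2 and "nucOXPHOS" in self.categories:
            stray = self.complex2 - self.categories["nucOXPHOS"]
            if stray:
                raise ValueError(
                    f"complex-2 flag on groups outside nucOXPHOS: {sorted(stray)}"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": cat, "group_id": gid,
             "complex2": gid in self.complex2 and cat == "nucOXPHOS"}
            for cat, gids in self.categories.items()
            for gid in sorted(gids)
        ]
        return pd.DataFrame(rows, columns=["category", "group_id", "complex2"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "CategoryMap":
        df = pd.read_csv(path, sep="\t")
        cats: dict[str, set[str]] = {}
        for _, row in df.iterrows():
            cats.setdefault(row["category"], set()).add(row["group_id"])
        c2 = set(df.loc[df.get("complex2", False) == True, "group_id"])  # noqa: E712
        return cls(cats, c2)


def assign_categories(
    groups: Iterable[OrthologGroup],
    marker_lists: Mapping[str, Iterable[str]],
    complex2_markers: Iterable[str] | None = None,
) -> CategoryMap:
    """Assign groups to categories by marker gene-id membership.

    A group belongs to a category iff it contains at least one gene id from
    that category's marker list; a group may match several categories (these
    are reported in the ``overlaps`` table and via a warning).
    """
    groups = list(groups)
    ids = [g.group_id for g in groups]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate ortholog group ids")
    marker_sets = {cat: set(m) for cat, m in marker_lists.items()}
    for cat, mset in marker_sets.items():
        if not mset:
            warnings.warn(f"category {cat!r} has an empty marker list")
    categories: dict[str, set[str]] = {cat: set() for cat in marker_sets}
    membership: dict[str, list[str]] = {}
    for g in groups:
        gids = g.gene_ids
        for cat, mset in marker_sets.items():
            if gids & mset:
                categories[cat].add(g.group_id)
                membership.setdefault(g.group_id, []).append(cat)
    multi = [
        {"group_id": gid, "categories": ",".join(cats)}
        for gid, cats in sorted(membership.items())
        if len(cats) > 1
    ]
    overlaps = pd.DataFrame(multi, columns=["group_id", "categories"])
    if multi:
        warnings.warn(
            f"{len(multi)} group(s) match several category marker lists; "
            "see CategoryMap.overlaps"
        )
    complex2: set[str] = set()
    if complex2_markers is not None:
        c2set = set(complex2_markers)
        for g in groups:
            if g.gene_ids & c2set:
                complex2.add(g.group_id)
        if "nucOXPHOS" in categories:
            complex2 &= categories["nucOXPHOS"]
    return CategoryMap(categories, complex2, overlaps)


def select_single_copy(
    groups: Iterable[OrthologGroup], species_list: Sequence[str]
) -> set[str]:
    """Groups with exactly one (non-vacuous) copy in every listed species."""
    if not species_list:
        raise ValueError("species_list must be non-empty")
    return {
        g.group_id
        for g in groups
        if all(g.copy_number(sp) == 1 for sp in species_list)
    }


def select_background(
    groups: Iterable[OrthologGroup],
    species_list: Sequence[str],
    min_fraction: float = 0.8,
) -> set[str]:
    """Groups present (>=1 copy) in at least ``ceil(min_fraction * n)`` species.

    With 76 species and an 80% cutoff the threshold is 61 species.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    n = len(species_list)
    if n == 0:
        raise ValueError("species_list must be non-empty")
    threshold = math.ceil(min_fraction * n - 1e-9)
    keep = set(species_list)
    return {
        g.group_id
        for g in groups
        if len(g.species_present & keep) >= threshold
    }


def resolve_paralogs(group: OrthologGroup, seed: int) -> dict[str, GeneRecord]:
    """Pick one copy per species uniformly at random (seeded).

    Species with no (non-vacuous) copy are absent from the result.  The
    species are visited in sorted order so a fixed seed gives a fixed choice.
    """
    if not group.genes:
        raise ValueError(f"group {group.group_id} is empty")
    rng = np.random.default_rng(seed)
    out: dict[str, GeneRecord] = {}
    for sp in sorted(group.genes):
        recs = [r for r in group.genes[sp] if not _is_vacuous(r.sequence)]
        if not recs:
            continue
        out[sp] = recs[int(rng.integers(len(recs)))] if len(recs) > 1 else recs[0]
    return out


def concatenate(
    blocks: Sequence[tuple[str, Mapping[str, str]]],
    species_list: Sequence[str],
) -> tuple[ProteinAlignment, pd.DataFrame]:
    """Concatenate per-group alignments into a category supermatrix.

    ``blocks`` is an ordered list of ``(group_id, {species: sequence})``;
    species missing from a block are filled with the missing symbol ``X``
    (undetermined in the likelihood, which is also how the estimator treats
    gaps).  Returns the supermatrix plus a BED-like table of 0-based
    half-open column coordinates per gene block.
    """
    if not blocks:
        raise ValueError("cannot concatenate an empty list of groups")
    if len(set(species_list)) != len(species_list):
        raise ValueError("duplicate species in species_list")
    parts: dict[str, list[str]] = {sp: [] for sp in species_list}
    coords = []
    start = 0
    for group_id, seqs in blocks:
        if len(seqs) == 0:
            raise ValueError(f"group {group_id}: empty block")
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError(
                f"group {group_id}: unequal sequence lengths {sorted(lengths)}"
            )
        L = lengths.pop()
        for sp in species_list:
            parts[sp].append(seqs.get(sp, "X" * L))
        coords.append({"group_id": group_id, "start": start, "end": start + L})
        start += L
    msa = ProteinAlignment.from_dict(
        {sp: "".join(parts[sp]) for sp in species_list}
    )
    return msa, pd.DataFrame(coords, columns=["group_id", "start", "end"])
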