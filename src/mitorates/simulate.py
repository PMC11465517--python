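"""Synthetic study generator.

Produces everything the analysis consumes, with known truth: an ultrametric
chronogram carrying several independently placed haplodiploid clades, gene
categories whose protein sequences evolve with category-by-lineage rate
multipliers (mitochondrion-related categories accelerated inside the
haplodiploid clades, controls not), species metadata, and gene copy numbers
evolving by a linear birth-death process with optional group-biased families.

The chronogram is a Yule (pure-birth) backbone rescaled to a fixed root age.
Haplodiploid clades are grafted onto backbone branches with stems attaching
close to the root (2-10% of the root age by default), emulating deep
independent origins of haplodiploidy spread over the tree's full time span;
rate shifts therefore act over (nearly) the whole root-to-tip path of the
affected species, so clade rate multipliers are recoverable from root-to-tip
rates.  One clade is designated "hymenoptera" and split at its crown into
bees/ants and sawflies/wasps subgroups.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .alignment import AA_LETTERS, ProteinAlignment
from .catalog import GeneRecord, OrthologGroup
from .likelihood import discretize_gamma
from .models import SubstitutionModel, poisson_model
from .trees import TimeTree

__all__ = [
    "SpeciesMeta",
    "CategorySpec",
    "BiasSpec",
    "SimulationConfig",
    "StudyBundle",
    "simulate_time_tree",
    "simulate_alignment",
    "simulate_copy_numbers",
    "simulate_study",
    "default_config",
]

GROUPS = ("hymenoptera", "other_haplodiploid", "diploid")
SUBGROUPS = ("bees_ants", "sawflies_wasps", "none")
HD_TYPES = ("arrhenotoky", "PGE", "none")


@dataclass
class SpeciesMeta:
    """Species -> group / subgroup / haplodiploidy type / clade labels."""

    group: dict[str, str]
    subgroup: dict[str, str]
    haplodiploidy_type: dict[str, str]
    clade: dict[str, str] = field(default_factory=dict)  # clade name or "none"

    def __post_init__(self):
        for sp, g in self.group.items():
            if g not in GROUPS:
                raise ValueError(f"{sp}: unknown group {g!r}")
            sub = self.subgroup.get(sp, "none")
            if sub not in SUBGROUPS:
                raise ValueError(f"{sp}: unknown subgroup {sub!r}")
            if sub != "none" and g != "hymenoptera":
                raise ValueError(f"{sp}: subgroup set but group is {g!r}")
            hd = self.haplodiploidy_type.get(sp, "none")
            if hd not in HD_TYPES:
                raise ValueError(f"{sp}: unknown haplodiploidy type {hd!r}")
            if (hd == "none") != (g == "diploid"):
                raise ValueError(
                    f"{sp}: haplodiploidy_type must be 'none' iff group is diploid"
                )

    @property
    def species(self) -> list[str]:
        return list(self.group)

    def in_group(self, group: str) -> list[str]:
        return [sp for sp, g in self.group.items() if g == group]

    def in_subgroup(self, subgroup: str) -> list[str]:
        return [sp for sp, s in self.subgroup.items() if s == subgroup]

    def members(self, label: str) -> list[str]:
        """Species in a group, subgroup, or 'haplodiploid' super-group."""
        if label in GROUPS:
            return self.in_group(label)
        if label in ("bees_ants", "sawflies_wasps"):
            return self.in_subgroup(label)
        if label == "haplodiploid":
            return [sp for sp, g in self.group.items() if g != "diploid"]
        raise KeyError(f"unknown species-group label {label!r}")

    @property
    def clades(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sp, c in self.clade.items():
            if c != "none":
                out.setdefault(c, []).append(sp)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "group": [self.group[s] for s in self.species],
                "subgroup": [self.subgroup.get(s, "none") for s in self.species],
                "haplodiploidy_type": [
                    self.haplodiploidy_type.get(s, "none") for s in self.species
                ],
                "clade": [self.clade.get(s, "none") for s in self.species],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "SpeciesMeta":
        df = pd.read_csv(path, sep="\t").fillna("none")
        return cls(
            dict(zip(df["species"], df["group"])),
            dict(zip(df["species"], df["subgroup"])),
            dict(zip(df["species"], df["haplodiploidy_type"])),
            dict(zip(df["species"], df.get("clade", "none"))),
        )


# --------------------------------------------------------------------------
# chronogram
# --------------------------------------------------------------------------


class _TreeBuilder:
    """Mutable node store keyed by depth from the root (MY)."""

    def __init__(self):
        self.parent: list[int] = []
        self.depth: list[float] = []
        self.label: list[str | None] = []

    def add(self, parent: int, depth: float, label: str | None = None) -> int:
        self.parent.append(parent)
        self.depth.append(depth)
        self.label.append(label)
        return len(self.parent) - 1

    def to_tree(self) -> TimeTree:
        lengths = [
            0.0 if p < 0 else self.depth[i] - self.depth[p]
            for i, p in enumerate(self.parent)
        ]
        return TimeTree(self.parent, lengths, self.label)


def _yule_depths(n: int, height: float, rng: np.random.Generator):
    """Split depths and topology of a Yule tree with n tips, root depth 0."""
    b = _TreeBuilder()
    root = b.add(-1, 0.0)
    if n == 1:
        b.add(root, height, "tip")  # degenerate; callers avoid this
        return b
    t = 0.0
    events = []
    for k in range(2, n):
        t += rng.exponential(1.0 / k)
        events.append(t)
    t += rng.exponential(1.0 / n)
    scale = height / t
    active = [root, root]
    for ev in events:
        j = int(rng.integers(len(active)))
        v = b.add(active[j], ev * scale)
        active[j] = v
        active.append(v)
    for p in active:
        b.add(p, height, "tip")
    return b


def _graft(b: _TreeBuilder, backbone_edges: list[int], depth: float,
           rng: np.random.Generator) -> tuple[int, list[int]]:
    """Split a backbone edge crossing ``depth``; return the new attach node."""
    cands = [
        v for v in backbone_edges
        if b.depth[b.parent[v]] < depth <= b.depth[v]
    ]
    if not cands:
        raise ValueError(
            f"no backbone branch crosses depth {depth:.3g}; cannot place a "
            "haplodiploid clade stem there (too many clades for this backbone)"
        )
    v = cands[int(rng.integers(len(cands)))]
    w = b.add(b.parent[v], depth)
    b.parent[v] = w
    backbone_edges.append(w)
    return w, backbone_edges


def simulate_time_tree(
    n_species: int,
    n_haplodiploid_clades: int = 5,
    root_age: float = 500.0,
    seed: int = 0,
    hymenoptera_frac: float = 0.3,
    stem_depth_range: tuple[float, float] = (0.02, 0.10),
    crown_frac_range: tuple[float, float] = (0.4, 0.6),
) -> tuple[TimeTree, SpeciesMeta]:
    """Ultrametric chronogram with marked haplodiploid clades.

    The requested number of mutually non-nested clades is marked haplodiploid:
    one multi-species clade labelled "hymenoptera" (about
    ``hymenoptera_frac`` of the species, at least 4, split internally into
    bees/ants and sawflies/wasps) and singleton lineages for the rest,
    mirroring a study system of one densely sampled haplodiploid order plus
    isolated haplodiploid species.  All clade stems attach within
    ``stem_depth_range`` (fractions of root age) below the root.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if n_haplodiploid_clades < 0:
        raise ValueError("n_haplodiploid_clades must be >= 0")
    rng = np.random.default_rng(seed)
    if n_haplodiploid_clades == 0:
        b = _yule_depths(n_species, root_age, rng)
        tips = [i for i, lab in enumerate(b.label) if lab == "tip"]
        for j, v in enumerate(tips):
            b.label[v] = f"dip{j + 1:03d}"
        tree = b.to_tree()
        meta = SpeciesMeta(
            {s: "diploid" for s in tree.tip_labels},
            {s: "none" for s in tree.tip_labels},
            {s: "none" for s in tree.tip_labels},
            {s: "none" for s in tree.tip_labels},
        )
        return tree, meta

    hym_size = max(4, round(hymenoptera_frac * n_species))
    n_singletons = n_haplodiploid_clades - 1
    n_backbone = n_species - hym_size - n_singletons
    if n_backbone < 2:
        raise ValueError(
            f"cannot place {n_haplodiploid_clades} non-nested haplodiploid "
            f"clades (hymenoptera size {hym_size} + {n_singletons} singletons) "
            f"in a tree of {n_species} species: the diploid backbone would "
            f"have {n_backbone} < 2 species"
        )
    b = _yule_depths(n_backbone, root_age, rng)
    backbone_edges = [i for i in range(1, len(b.parent))]
    tips = [i for i, lab in enumerate(b.label) if lab == "tip"]
    for j, v in enumerate(tips):
        b.label[v] = f"dip{j + 1:03d}"

    group: dict[str, str] = {b.label[v]: "diploid" for v in tips}
    subgroup: dict[str, str] = {b.label[v]: "none" for v in tips}
    hd_type: dict[str, str] = {b.label[v]: "none" for v in tips}
    clade: dict[str, str] = {b.label[v]: "none" for v in tips}

    stem_depths = np.sort(
        root_age * rng.uniform(*stem_depth_range, size=n_haplodiploid_clades)
    )
    # hymenoptera clade
    attach, backbone_edges = _graft(b, backbone_edges, float(stem_depths[0]), rng)
    crown_depth = root_age - float(
        rng.uniform(*crown_frac_range) * (root_age - stem_depths[0])
    )
    sub = _yule_depths(hym_size, root_age - crown_depth, rng)
    offset = len(b.parent)
    crown = None
    hym_tips: list[int] = []
    for i in range(len(sub.parent)):
        p = sub.parent[i]
        gp = attach if p < 0 else offset + p
        v = b.add(gp, crown_depth + sub.depth[i], None)
        if p < 0:
            crown = v
        if sub.label[i] == "tip":
            hym_tips.append(v)
    for j, v in enumerate(hym_tips):
        b.label[v] = f"hym{j + 1:03d}"
        sp = b.label[v]
        group[sp] = "hymenoptera"
        hd_type[sp] = "arrhenotoky"
        clade[sp] = "hymenoptera"
    # bees/ants vs sawflies/wasps: split at the hymenoptera crown; the larger
    # side is the bees/ants radiation
    kids = [i for i, p in enumerate(b.parent) if p == crown]
    sides = []
    for c in kids:
        stack, side = [c], []
        while stack:
            v = stack.pop()
            ch = [i for i, p in enumerate(b.parent) if p == v]
            if not ch:
                side.append(v)
            stack.extend(ch)
        sides.append(side)
    sides.sort(key=len, reverse=True)
    for v in sides[0]:
        subgroup[b.label[v]] = "bees_ants"
    for side in sides[1:]:
        for v in side:
            subgroup[b.label[v]] = "sawflies_wasps"

    # singleton haplodiploid lineages; PGE and arrhenotoky alternate
    for i in range(n_singletons):
        attach, backbone_edges = _graft(
            b, backbone_edges, float(stem_depths[i + 1]), rng
        )
        name = f"hap{i + 2:02d}"
        v = b.add(attach, root_age, name)
        group[name] = "other_haplodiploid"
        subgroup[name] = "none"
        hd_type[name] = "PGE" if i % 2 == 0 else "arrhenotoky"
        clade[name] = f"haplo{i + 2}"

    tree = b.to_tree()
    meta = SpeciesMeta(
        {s: group[s] for s in tree.tip_labels},
        {s: subgroup[s] for s in tree.tip_labels},
        {s: hd_type[s] for s in tree.tip_labels},
        {s: clade[s] for s in tree.tip_labels},
    )
    return tree, meta


# --------------------------------------------------------------------------
# sequence evolution
# --------------------------------------------------------------------------


def _branch_multipliers(
    tree: TimeTree,
    clade_multipliers: Mapping[str, float] | None,
    clades: Mapping[str, Sequence[str]] | None,
) -> np.ndarray:
    mult = np.ones(tree.n_nodes)
    if not clade_multipliers:
        return mult
    if clades is None:
        raise ValueError("clade_multipliers given but no clade definitions")
    for name, factor in clade_multipliers.items():
        if not factor > 0:
            raise ValueError(f"clade multiplier for {name!r} must be > 0")
        members = set(clades[name])
        for v in range(tree.n_nodes):
            tips = {tree.labels[t] for t in tree.clade_tips(v)}
            if tips and tips <= members:
                mult[v] *= factor  # clade branches incl. the stem
    return mult


def simulate_alignment(
    tree: TimeTree,
    model: SubstitutionModel,
    site_rate: float,
    clade_multipliers: Mapping[str, float] | None,
    n_sites: int,
    seed: int,
    clades: Mapping[str, Sequence[str]] | None = None,
    branch_rate_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ProteinAlignment:
    """Evolve ``n_sites`` residues from the root to the tips.

    The expected number of substitutions on a branch is
    ``duration * site_rate * product(applicable clade multipliers)``, further
    scaled per site by a discrete-gamma rate drawn from the same categories
    the estimator uses.  A branch belongs to a clade iff all tips below it
    are clade members (which includes the clade's stem branch).

    ``branch_rate_sd`` adds lineage rate variation: every branch's rate is
    additionally multiplied by an independent mean-1 lognormal factor with
    the given log-scale standard deviation (a simple uncorrelated relaxed
    clock).  Real lineages vary in rate for reasons unrelated to the factor
    under study; without this, the only across-species rate variation in an
    unshifted category would be estimation noise.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if site_rate < 0:
        raise ValueError("site_rate must be >= 0")
    if branch_rate_sd < 0:
        raise ValueError("branch_rate_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    rates = discretize_gamma(model.alpha, model.n_categories)
    k = model.n_categories
    mult = _branch_multipliers(tree, clade_multipliers, clades)
    if branch_rate_sd > 0:
        s = branch_rate_sd
        jitter = np.exp(rng.normal(-0.5 * s * s, s, tree.n_nodes))
        jitter[tree.root] = 1.0
        mult = mult * jitter
    site_cat = rng.integers(k, size=n_sites)
    pi = model.frequencies
    states: dict[int, np.ndarray] = {}
    states[tree.root] = rng.choice(20, size=n_sites, p=pi)
    for v in tree.preorder():
        if v == tree.root:
            continue
        t = tree.lengths[v] * site_rate * mult[v]
        parent_states = states[int(tree.parent[v])]
        if t == 0:
            states[v] = parent_states.copy()
        else:
            P = np.stack([model.transition_matrix(t * r) for r in rates])
            if not np.allclose(P.sum(axis=2), 1.0, atol=1e-8):
                raise ValueError("non-stochastic transition matrix")
            cum = np.cumsum(P, axis=2)
            rows = cum[site_cat, parent_states]  # (n_sites, 20)
            u = rng.random(n_sites)
            states[v] = np.minimum((rows < u[:, None]).sum(axis=1), 19)
    data = np.vstack([states[t] for t in tree.tip_ids]).astype(np.uint8)
    return ProteinAlignment([tree.labels[t] for t in tree.tip_ids], data)


# --------------------------------------------------------------------------
# copy numbers
# --------------------------------------------------------------------------


@dataclass
class BiasSpec:
    """Group-conditional copy-number override for a set of biased families.

    ``group_counts`` maps a group/subgroup label (or 'haplodiploid') to the
    copy number imposed on its species; each species keeps its birth-death
    count with probability ``flip_prob`` (lineage-specific exceptions, so a
    contrast like "two copies in sawflies/wasps, one in bees/ants" holds in
    most but not all species, as for the mitochondrial elongation-factor
    duplicate lost in most bees and ants).
    """

    group_counts: dict[str, int]
    n_families: int = 5
    flip_prob: float = 0.05
    name: str = "bias"


def _bd_branch(n0: int, duration: float, birth: float, death: float,
               rng: np.random.Generator) -> int:
    n, t = n0, 0.0
    total = birth + death
    if total == 0:
        return n0
    while n > 0:
        t += rng.exponential(1.0 / (n * total))
        if t > duration:
            break
        if rng.random() < birth / total:
            n += 1
        else:
            n -= 1
    return n


def simulate_copy_numbers(
    tree: TimeTree,
    birth_rate: float,
    death_rate: float,
    root_count: int,
    n_families: int,
    biased_spec: Sequence[BiasSpec] | None = None,
    seed: int = 0,
    meta: SpeciesMeta | None = None,
) -> pd.DataFrame:
    """Gene copy numbers per family x species.

    Counts evolve along each branch by a linear birth-death process
    (per-copy rates per MY); zero copies is absorbing.  Families listed in
    ``biased_spec`` additionally receive group-conditional copy numbers
    (see :class:`BiasSpec`).  Biased family ids are recorded in
    ``df.attrs['biased_families']``.
    """
    if birth_rate < 0 or death_rate < 0:
        raise ValueError("birth and death rates must be >= 0")
    if root_count < 0:
        raise ValueError("root_count must be >= 0")
    rng = np.random.default_rng(seed)
    specs = list(biased_spec) if biased_spec else []
    if specs and meta is None:
        raise ValueError("biased_spec requires species metadata")
    fam_ids = [f"fam{i + 1:05d}" for i in range(n_families)]
    bias_of: dict[str, BiasSpec] = {}
    for j, spec in enumerate(specs):
        for i in range(spec.n_families):
            fid = f"{spec.name}{j + 1}_{i + 1:03d}"
            fam_ids.append(fid)
            bias_of[fid] = spec
    tips = tree.tip_ids
    rows = []
    for fid in fam_ids:
        counts: dict[int, int] = {tree.root: root_count}
        for v in tree.preorder():
            if v == tree.root:
                continue
            counts[v] = _bd_branch(
                counts[int(tree.parent[v])], float(tree.lengths[v]),
                birth_rate, death_rate, rng,
            )
        row = {tree.labels[t]: counts[t] for t in tips}
        spec = bias_of.get(fid)
        if spec is not None:
            for label, value in spec.group_counts.items():
                for sp in meta.members(label):
                    if rng.random() >= spec.flip_prob:
                        row[sp] = value
        rows.append(row)
    tip_labels = [tree.labels[t] for t in tips]
    df = pd.DataFrame(rows, index=pd.Index(fam_ids, name="family"),
                      columns=tip_labels)
    df = df[tip_labels]
    df.attrs["biased_families"] = list(bias_of)
    return df


# --------------------------------------------------------------------------
# full study
# --------------------------------------------------------------------------


@dataclass
class CategorySpec:
    """One gene category: size, base rate and lineage rate shifts."""

    name: str
    n_genes: int
    base_rate: float  # AA/site/MY on diploid-background branches
    clade_multipliers: dict[str, float] = field(default_factory=dict)
    mean_gene_length: int = 350
    lineage_sd: float = 0.2         # per-branch lognormal rate jitter
    dropout_prob: float = 0.0       # per species x gene: all-gap sequence
    duplication_prob: float = 0.0   # per species x gene: extra paralog copy
    n_complex2: int = 0             # leading genes flagged complex-2

    def __post_init__(self):
        if self.base_rate <= 0:
            raise ValueError(f"{self.name}: base_rate must be > 0")
        if any(m <= 0 for m in self.clade_multipliers.values()):
            raise ValueError(f"{self.name}: multipliers must be > 0")


@dataclass
class SimulationConfig:
    n_species: int = 76
    n_haplodiploid_clades: int = 5
    root_age: float = 500.0
    alpha: float = 0.7
    n_gamma_categories: int = 4
    categories: list[CategorySpec] = field(default_factory=list)
    # slow turnover: most families keep their ancestral copy number over the
    # tree's full depth, with occasional gains/losses
    birth_rate: float = 1e-4
    death_rate: float = 1e-4
    copy_root_count: int = 1
    n_copy_families: int = 100
    biased_families: list[BiasSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0 or self.n_gamma_categories < 1:
            raise ValueError("invalid gamma settings")

    def to_yaml(self, path) -> None:
        from dataclasses import asdict

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


_MITO_MULT = {"hymenoptera": 2.5, "haplo2": 2.5, "haplo3": 2.5, "haplo4": 2.5,
              "haplo5": 2.5}


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-scale defaults: 76 species, 5 haplodiploid clades, 500 MY root,
    per-category gene counts of the study design, base rates near the
    observed all-species medians (AA/site/MY), mitochondrion-related
    categories accelerated 2.5x in every haplodiploid clade."""
    cats = [
        CategorySpec("mtOXPHOS", 13, 0.0018, dict(_MITO_MULT)),
        CategorySpec("nucOXPHOS", 65, 0.0012, dict(_MITO_MULT), n_complex2=4),
        CategorySpec("nucMTRP", 74, 0.0015, dict(_MITO_MULT)),
        CategorySpec("nucCRP", 77, 0.00084, {}),
        CategorySpec("nucControlSingle", 150, 0.00118, {}),
        CategorySpec("nucControl", 5746, 0.00136, {}, dropout_prob=0.05,
                     duplication_prob=0.05),
    ]
    biased = [
        BiasSpec({"sawflies_wasps": 2, "bees_ants": 1}, n_families=5,
                 name="biasEFTu"),
        BiasSpec({"haplodiploid": 2, "diploid": 1}, n_families=5,
                 name="biasHD"),
    ]
    return SimulationConfig(categories=cats, biased_families=biased, seed=seed)


@dataclass
class StudyBundle:
    """Everything one synthetic study produced, plus truth tables."""

    tree: TimeTree
    meta: SpeciesMeta
    config: SimulationConfig
    orthogroups: dict[str, list[OrthologGroup]]
    marker_lists: dict[str, set[str]]
    complex2_markers: set[str]
    category_alignments: dict[str, ProteinAlignment]
    copy_numbers: pd.DataFrame
    truth: dict[str, pd.DataFrame]

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.tree.write_newick(out / "chronogram.nwk")
        self.meta.write_tsv(out / "species_meta.tsv")
        self.config.to_yaml(out / "config.yaml")
        markers = [
            {"category": cat, "gene_id": gid}
            for cat, gids in self.marker_lists.items()
            for gid in sorted(gids)
        ]
        pd.DataFrame(markers).to_csv(out / "markers.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"gene_id": sorted(self.complex2_markers)}
        ).to_csv(out / "complex2_markers.tsv", sep="\t", index=False)
        gdir = out / "orthogroups"
        gdir.mkdir(exist_ok=True)
        manifest = []
        for cat, groups in self.orthogroups.items():
            for g in groups:
                g.to_fasta(gdir / f"{g.group_id}.fasta")
                manifest.append({"group_id": g.group_id, "category_truth": cat})
        pd.DataFrame(manifest).to_csv(out / "manifest.tsv", sep="\t", index=False)
        adir = out / "alignments"
        adir.mkdir(exist_ok=True)
        for cat, msa in self.category_alignments.items():
            msa.write_fasta(adir / f"{cat}.fasta")
        self.copy_numbers.to_csv(out / "copy_numbers.tsv", sep="\t")
        for name, df in self.truth.items():
            df.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)


def simulate_study(config: SimulationConfig,
                   outdir=None) -> StudyBundle:
    """Generate a full synthetic study (see module docstring).

    Writes Newick + FASTA + TSV files to ``outdir`` when given; always
    returns the in-memory bundle with truth tables for parameter-recovery
    checks.
    """
    root_seed = np.random.SeedSequence(config.seed)
    seeds = root_seed.spawn(4 + len(config.categories))
    tree, meta = simulate_time_tree(
        config.n_species, config.n_haplodiploid_clades, config.root_age,
        seed=seeds[0],
    )
    clades = meta.clades
    model = poisson_model(alpha=config.alpha,
                          n_categories=config.n_gamma_categories)
    orthogroups: dict[str, list[OrthologGroup]] = {}
    markers: dict[str, set[str]] = {}
    complex2_markers: set[str] = set()
    category_alignments: dict[str, ProteinAlignment] = {}
    truth_mult_rows = []
    truth_gene_rows = []
    tip_labels = [tree.labels[t] for t in tree.tip_ids]
    for ci, spec in enumerate(config.categories):
        rng = np.random.default_rng(seeds[4 + ci])
        # gene lengths vary around the category mean but depend only on the
        # category name, so different master seeds give identical shapes
        len_rng = np.random.default_rng(zlib.crc32(spec.name.encode()))
        gene_lengths = np.maximum(
            50, len_rng.poisson(spec.mean_gene_length, size=spec.n_genes)
        )
        n_sites = int(gene_lengths.sum())
        msa = simulate_alignment(
            tree, model, spec.base_rate, spec.clade_multipliers, n_sites,
            seed=0, clades=clades, branch_rate_sd=spec.lineage_sd, rng=rng,
        )
        category_alignments[spec.name] = msa
        groups: list[OrthologGroup] = []
        markers[spec.name] = set()
        start = 0
        for gi, L in enumerate(gene_lengths):
            gid = f"{spec.name}_g{gi + 1:04d}"
            block = msa.take_columns(range(start, start + int(L)))
            start += int(L)
            genes: dict[str, list[GeneRecord]] = {}
            for sp in tip_labels:
                seq = block.sequence(sp)
                if spec.dropout_prob and rng.random() < spec.dropout_prob:
                    genes[sp] = [GeneRecord(f"{gid}_{sp}_c1", "-" * int(L))]
                    continue
                recs = [GeneRecord(f"{gid}_{sp}_c1", seq)]
                if spec.duplication_prob and rng.random() < spec.duplication_prob:
                    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                    nmut = max(1, int(0.02 * L))
                    pos = rng.choice(int(L), size=nmut, replace=False)
                    sub = rng.choice(20, size=nmut, p=model.frequencies)
                    arr[pos] = np.frombuffer(
                        AA_LETTERS.encode(), dtype=np.uint8
                    )[sub]
                    recs.append(
                        GeneRecord(f"{gid}_{sp}_c2", arr.tobytes().decode())
                    )
                genes[sp] = recs
            groups.append(OrthologGroup(gid, genes))
            # markers reference one known member gene per group
            markers[spec.name].add(f"{gid}_{tip_labels[0]}_c1")
            if gi < spec.n_complex2:
                complex2_markers.add(f"{gid}_{tip_labels[0]}_c1")
            truth_gene_rows.append(
                {"category": spec.name, "group_id": gid, "length": int(L),
                 "base_rate": spec.base_rate,
                 "complex2": gi < spec.n_complex2}
            )
        orthogroups[spec.name] = groups
        for clade_name, m in spec.clade_multipliers.items():
            truth_mult_rows.append(
                {"category": spec.name, "clade": clade_name, "multiplier": m}
            )
        for clade_name in clades:
            if clade_name not in spec.clade_multipliers:
                truth_mult_rows.append(
                    {"category": spec.name, "clade": clade_name,
                     "multiplier": 1.0}
                )
    copy_numbers = simulate_copy_numbers(
        tree, config.birth_rate, config.death_rate, config.copy_root_count,
        config.n_copy_families, config.biased_families, seed=seeds[1],
        meta=meta,
    )
    truth = {
        "multipliers": pd.DataFrame(
            truth_mult_rows, columns=["category", "clade", "multiplier"]
        ),
        "genes": pd.DataFrame(truth_gene_rows),
        "biased_families": pd.DataFrame(
            {"family": copy_numbers.attrs["biased_families"]}
        ),
    }
    bundle = StudyBundle(
        tree, meta, config, orthogroups, markers, complex2_markers,
        category_alignments, copy_numbers, truth,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle
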