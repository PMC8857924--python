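"""Self-contained fixture generator: tree, reference VCF, marker table,
and damaged low-coverage query pileups with known truth.

The generator emulates the study conditions of ancient-DNA lineage
placement: an infinite-sites reference panel over a random rooted tree
(each variant arose exactly once, on a branch drawn proportionally to
branch length, so its carriers form exactly one clade), and a query
sample attached at a point along a known branch, observed only through
sparse, error-prone, deamination-damaged reads.

Attachment is mid-branch: the query carries the derived allele at all
SNPs on strict ancestors of its attachment branch and at the proximal
fraction of that branch's own SNPs (the ones that arose above the
attachment point), and the ancestral allele elsewhere.  Deamination is
applied per read — any C read as T, any G read as A, with probability
``deamination`` — which reproduces both the transition-site confusion
the filters target and the off-allele mismatches seen at transversion
sites.

Everything is deterministic given the seed; identical configs produce
byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .treemodel import ReferenceTree, read_newick

__all__ = [
    "SimConfig",
    "SimTruth",
    "ReferenceSim",
    "QuerySim",
    "sim_reference",
    "sim_query",
    "sim_markers",
    "write_reference_vcf",
    "write_query_bam",
]

_BASES = ("A", "C", "G", "T")


@dataclass
class SimConfig:
    """Study conditions for one simulated data set.

    Defaults mirror a realistic ancient-DNA placement scenario at desk
    scale: a dense marker panel (~30 sites per branch, matching the
    order of sites-per-branch in large published Y panels), coverage 3
    reads/site, and clean data unless error/damage rates are raised.
    """

    seed: int
    n_leaves: int = 16
    n_sites: int | None = None  # default: 30 per branch
    attachment: int | str = "random"
    attach_fraction: float = 0.5
    # when set, exactly this many of the attachment branch's own sites
    # (the distal ones) stay ancestral, overriding attach_fraction
    attach_ancestral_own: int | None = None
    coverage: float = 3.0
    base_error: float = 0.0
    deamination: float = 0.0
    missing_fraction: float = 0.0
    chrom: str = "chrS"
    genome_length: int | None = None

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        for rate in (
            self.base_error,
            self.deamination,
            self.missing_fraction,
            self.attach_fraction,
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")

    def resolved_n_sites(self, n_branches: int) -> int:
        return self.n_sites if self.n_sites is not None else 30 * n_branches


@dataclass
class SimTruth:
    """Ground truth backing one simulated reference (+ optional query)."""

    newick: str
    site_branch: dict[int, int]  # pos -> true branch id
    site_swapped: dict[int, bool]  # pos -> REF/ALT polarity swapped in VCF
    site_anc: dict[int, str]
    site_der: dict[int, str]
    attachment_branch: int | None = None
    attach_fraction: float | None = None
    query_genotype: dict[int, str] = field(default_factory=dict)  # pos->state

    def to_json(self, path: str) -> None:
        payload = {
            "newick": self.newick,
            "site_branch": {str(k): v for k, v in self.site_branch.items()},
            "site_swapped": {str(k): v for k, v in self.site_swapped.items()},
            "site_anc": {str(k): v for k, v in self.site_anc.items()},
            "site_der": {str(k): v for k, v in self.site_der.items()},
            "attachment_branch": self.attachment_branch,
            "attach_fraction": self.attach_fraction,
            "query_genotype": {
                str(k): v for k, v in self.query_genotype.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            newick=d["newick"],
            site_branch={int(k): v for k, v in d["site_branch"].items()},
            site_swapped={int(k): v for k, v in d["site_swapped"].items()},
            site_anc={int(k): v for k, v in d["site_anc"].items()},
            site_der={int(k): v for k, v in d["site_der"].items()},
            attachment_branch=d["attachment_branch"],
            attach_fraction=d["attach_fraction"],
            query_genotype={
                int(k): v for k, v in d["query_genotype"].items()
            },
        )


@dataclass
class ReferenceSim:
    tree: ReferenceTree
    newick: str
    sites: pd.DataFrame  # pos, ref, alt, branch, swapped, anc, der
    genotypes: np.ndarray  # sites x leaves, 0/1/-1, VCF (ref/alt) coding
    truth: SimTruth
    config: SimConfig


@dataclass
class QuerySim:
    pileup: pd.DataFrame  # chrom pos ref alt A C G T
    reads: list[tuple[int, str]]  # (pos, base) per retained read
    truth: SimTruth


def _random_tree(rng: np.random.Generator, n_leaves: int) -> str:
    """Yule-style growth: repeatedly split a uniformly chosen leaf."""
    # nodes: list of (children or leaf-id)
    children: dict[int, list[int]] = {0: [1, 2]}
    leaves = [1, 2]
    nxt = 3
    while len(leaves) < n_leaves:
        i = int(rng.integers(len(leaves)))
        v = leaves.pop(i)
        children[v] = [nxt, nxt + 1]
        leaves.extend([nxt, nxt + 1])
        nxt += 2
    lengths = {v: float(rng.uniform(0.5, 1.5)) for v in range(1, nxt)}
    names: dict[int, str] = {}
    for v in sorted(leaves):
        names[v] = f"S{len(names):03d}"

    def render(v: int) -> str:
        if v in children:
            inner = ",".join(render(c) for c in children[v])
            s = f"({inner})"
        else:
            s = names[v]
        if v != 0:
            s += f":{lengths[v]:.6f}"
        return s

    return render(0) + ";"


def sim_reference(config: SimConfig) -> ReferenceSim:
    """Simulate the reference panel: tree, polarized sites, genotypes.

    Each site is placed on one branch sampled proportionally to branch
    length (infinite sites: unique positions); leaves in the branch's
    clade carry the derived allele.  VCF polarity (which of REF/ALT is
    the derived allele) is swapped per site with probability 0.5 and
    recorded, to exercise polarity inference downstream.
    """
    rng = np.random.default_rng(config.seed)
    newick = _random_tree(rng, config.n_leaves)
    tree = read_newick(newick)
    n_sites = config.resolved_n_sites(tree.n_branches)
    genome_length = config.genome_length or max(10 * n_sites, 100)
    if n_sites > genome_length:
        raise ValueError("n_sites exceeds available genome positions")
    positions = np.sort(
        rng.choice(np.arange(1, genome_length + 1), size=n_sites, replace=False)
    )
    lengths = np.array(
        [tree.lengths[b] or 1.0 for b in tree.branches], dtype=float
    )
    probs = lengths / lengths.sum()
    branch_idx = rng.choice(len(tree.branches), size=n_sites, p=probs)
    base_idx = rng.integers(0, 4, size=n_sites)
    offset = rng.integers(1, 4, size=n_sites)
    swapped = rng.random(n_sites) < 0.5
    rows = []
    L = tree.n_leaves
    G = np.zeros((n_sites, L), dtype=np.int8)
    site_branch: dict[int, int] = {}
    site_swapped: dict[int, bool] = {}
    site_anc: dict[int, str] = {}
    site_der: dict[int, str] = {}
    for s in range(n_sites):
        b = tree.branches[int(branch_idx[s])]
        anc = _BASES[int(base_idx[s])]
        der = _BASES[(int(base_idx[s]) + int(offset[s])) % 4]
        pos = int(positions[s])
        bits = tree.clade_bits[b]
        carriers = np.zeros(L, dtype=bool)
        for li in range(L):
            if bits >> li & 1:
                carriers[li] = True
        sw = bool(swapped[s])
        if sw:
            ref, alt = der, anc
            G[s] = np.where(carriers, 0, 1)
        else:
            ref, alt = anc, der
            G[s] = np.where(carriers, 1, 0)
        rows.append(
            {
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "branch": b,
                "swapped": sw,
                "anc": anc,
                "der": der,
            }
        )
        site_branch[pos] = b
        site_swapped[pos] = sw
        site_anc[pos] = anc
        site_der[pos] = der
    if config.missing_fraction > 0:
        mask = rng.random(G.shape) < config.missing_fraction
        G[mask] = -1
    truth = SimTruth(
        newick=newick,
        site_branch=site_branch,
        site_swapped=site_swapped,
        site_anc=site_anc,
        site_der=site_der,
    )
    return ReferenceSim(
        tree=tree,
        newick=newick,
        sites=pd.DataFrame(rows),
        genotypes=G,
        truth=truth,
        config=config,
    )


def pick_attachment(
    ref: ReferenceSim, rng: np.random.Generator, min_own_sites: int = 0
) -> int:
    """Draw an attachment branch, optionally requiring a minimum number
    of sites on the branch itself (needed for the placement to be
    identifiable among its immediate neighbours)."""
    counts = ref.sites["branch"].value_counts()
    eligible = [
        b for b in ref.tree.branches if counts.get(b, 0) >= min_own_sites
    ]
    if not eligible:
        raise ValueError("no branch satisfies the site-count requirement")
    return int(eligible[int(rng.integers(len(eligible)))])


def sim_query(
    config: SimConfig,
    ref: ReferenceSim,
) -> QuerySim:
    """Simulate one query sample's pileups at the reference sites.

    The query attaches ``attach_fraction`` of the way down the
    attachment branch: derived at strict-ancestor SNPs and at the first
    ``ceil(fraction * k)`` (by position) of the branch's own ``k`` SNPs,
    ancestral elsewhere.  Reads per site are Poisson(coverage); each
    read is hit by uniform base error, then C->T / G->A deamination.
    """
    rng = np.random.default_rng((config.seed, 1))
    if config.attachment == "random":
        b_star = pick_attachment(ref, rng)
    else:
        b_star = int(config.attachment)
        ref.tree._check_branch(b_star)
    anc_branches = set(ref.tree.strict_ancestors(b_star))
    own = sorted(
        int(p)
        for p, b in ref.truth.site_branch.items()
        if b == b_star
    )
    if config.attach_ancestral_own is not None:
        n_derived_own = max(0, len(own) - config.attach_ancestral_own)
    else:
        n_derived_own = math.ceil(config.attach_fraction * len(own))
    derived_own = set(own[:n_derived_own])
    truth = ref.truth
    truth.attachment_branch = b_star
    truth.attach_fraction = config.attach_fraction
    rows = []
    reads: list[tuple[int, str]] = []
    for _, site in ref.sites.iterrows():
        pos = int(site["pos"])
        b = int(site["branch"])
        if b in anc_branches or pos in derived_own:
            state = "derived"
            true_base = site["der"]
        else:
            state = "ancestral"
            true_base = site["anc"]
        truth.query_genotype[pos] = state
        n_reads = int(rng.poisson(config.coverage))
        counts = {b_: 0 for b_ in _BASES}
        for _ in range(n_reads):
            base = true_base
            if config.base_error > 0 and rng.random() < config.base_error:
                others = [x for x in _BASES if x != base]
                base = others[int(rng.integers(3))]
            if config.deamination > 0:
                if base == "C" and rng.random() < config.deamination:
                    base = "T"
                elif base == "G" and rng.random() < config.deamination:
                    base = "A"
            counts[base] += 1
            reads.append((pos, base))
        rows.append(
            {
                "chrom": config.chrom,
                "pos": pos,
                "ref": site["ref"],
                "alt": site["alt"],
                **counts,
            }
        )
    return QuerySim(pileup=pd.DataFrame(rows), reads=reads, truth=truth)


def sim_markers(
    ref: ReferenceSim,
    chrom: str | None = None,
    root_label: str = "H",
) -> pd.DataFrame:
    """Curated marker table consistent with the tree.

    Labels follow long-form nesting along the tree: each branch gets the
    parent's label plus one character (digits and letters alternating),
    and every site on the branch becomes a marker for that label.
    """
    tree = ref.tree
    chrom = chrom or ref.config.chrom
    labels: dict[int, str] = {}
    for b in tree.branches:
        p = tree.parent[b]
        parent_label = (
            root_label if p == tree.root or p is None else labels[p]
        )
        sibs = tree.children[p]
        i = sibs.index(b)
        token = str(i + 1) if len(parent_label) % 2 else "abcdefghij"[i]
        labels[b] = parent_label + token
    rows = []
    for _, site in ref.sites.iterrows():
        b = int(site["branch"])
        rows.append(
            {
                "name": f"M{int(site['pos'])}",
                "haplogroup": labels[b],
                "chrom": chrom,
                "pos": int(site["pos"]),
                "ancestral": site["anc"],
                "derived": site["der"],
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["branch_labels"] = labels
    return df


# ----------------------------------------------------------------------
# file output


def write_reference_vcf(ref: ReferenceSim, path: str) -> None:
    """Write the simulated panel as a haploid single-contig VCF."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##source=treeplace-simulate")
    genome_length = ref.config.genome_length or max(
        10 * len(ref.sites), 100
    )
    header.add_line(
        f"##contig=<ID={ref.config.chrom},length={genome_length}>"
    )
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    for name in ref.tree.leaf_names:
        header.add_sample(name)
    with pysam.VariantFile(path, "w", header=header) as out:
        for s, (_, site) in enumerate(ref.sites.iterrows()):
            rec = out.new_record(
                contig=ref.config.chrom,
                start=int(site["pos"]) - 1,
                stop=int(site["pos"]),
                alleles=(str(site["ref"]), str(site["alt"])),
            )
            for li, name in enumerate(ref.tree.leaf_names):
                g = int(ref.genotypes[s, li])
                rec.samples[name]["GT"] = (None,) if g < 0 else (g,)
            out.write(rec)


def write_query_bam(
    query: QuerySim,
    path: str,
    chrom: str,
    genome_length: int,
    base_quality: int = 37,
    mapping_quality: int = 60,
) -> None:
    """Write the query's reads as a minimal sorted+indexed BAM.

    One single-base alignment per simulated read; used to exercise the
    BAM pileup path in integration tests (pileup tables are the primary
    simulated format).
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": int(genome_length)}],
    }
    reads = sorted(query.reads)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for i, (pos, base) in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i:06d}"
            a.query_sequence = base
            a.reference_id = 0
            a.reference_start = pos - 1
            a.mapping_quality = mapping_quality
            a.cigarstring = "1M"
            a.query_qualities = pysam.qualitystring_to_array(
                chr(base_quality + 33)
            )
            bam.write(a)
    pysam.index(path)


def write_fixture(
    config: SimConfig,
    outdir: str,
    with_query: bool = True,
    with_markers: bool = True,
) -> dict[str, str]:
    """Write a complete simulated fixture directory; returns file paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    ref = sim_reference(config)
    paths = {
        "tree": os.path.join(outdir, "reference.nwk"),
        "vcf": os.path.join(outdir, "reference.vcf"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    with open(paths["tree"], "w") as fh:
        fh.write(ref.newick + "\n")
    write_reference_vcf(ref, paths["vcf"])
    if with_markers:
        paths["markers"] = os.path.join(outdir, "markers.tsv")
        sim_markers(ref).drop(columns=[], errors="ignore").to_csv(
            paths["markers"], sep="\t", index=False
        )
    if with_query:
        query = sim_query(config, ref)
        paths["pileup"] = os.path.join(outdir, "query.pileup.tsv")
        query.pileup.to_csv(paths["pileup"], sep="\t", index=False)
    ref.truth.to_json(paths["truth"])
    return paths
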