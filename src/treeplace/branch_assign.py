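"""Assign biallelic SNPs from a reference panel to branches of the tree.

Under an infinite-sites view, a variant that arose once on branch ``b``
is carried in the derived state by exactly the leaves of the clade below
``b`` and in the ancestral state by everyone else.  Each site is scored
against every (branch, polarity) hypothesis with a symmetric
genotype-error flip model: an observed genotype matches its expected
state with probability ``1 - epsilon`` and mismatches with probability
``epsilon``; missing genotypes are marginalized out (contribute 0 to the
log-likelihood).  Because ``epsilon < 0.5``, the maximum-likelihood
hypothesis is exactly the minimum-mismatch hypothesis, which is what the
brute-force oracle in the test-suite checks.

Sites where the best hypothesis still implies too many mismatching
genotypes (repeated mutation, repeated genotype error) are excluded from
downstream use, as are multiallelic records and monomorphic sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .treemodel import ReferenceTree, check_sample_overlap

__all__ = [
    "BranchAssignedSNP",
    "AssignmentReport",
    "score_snp_on_branch",
    "assign_snp",
    "assign_matrix",
    "assign_all",
    "write_branch_sites",
    "read_branch_sites",
    "write_bed",
    "default_loglik_margin",
]

STATUS_ASSIGNED = "assigned"
STATUS_MULTIALLELIC = "excluded_multiallelic"
STATUS_LOW_LIK = "excluded_low_likelihood"
STATUS_MONOMORPHIC = "excluded_monomorphic"

MISSING = -1


@dataclass
class BranchAssignedSNP:
    """A biallelic site mapped to one branch with inferred polarity."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    status: str
    derived_allele: str | None = None  # equals ref_allele or alt_allele
    branch: int | None = None
    loglik: float | None = None
    n_mismatch: int | None = None
    haplogroup: str | None = None

    def __post_init__(self) -> None:
        if self.status == STATUS_ASSIGNED:
            if self.branch is None or self.loglik is None:
                raise ValueError("assigned SNP must carry branch and loglik")
            if self.derived_allele not in (self.ref_allele, self.alt_allele):
                raise ValueError("derived allele must be ref or alt")

    @property
    def ancestral_allele(self) -> str | None:
        if self.derived_allele is None:
            return None
        return (
            self.alt_allele
            if self.derived_allele == self.ref_allele
            else self.ref_allele
        )


@dataclass
class AssignmentReport:
    """Counts per status over one reference VCF pass."""

    counts: dict[str, int] = field(default_factory=dict)
    total: int = 0
    n_het_as_missing: int = 0
    leaves_without_genotypes: list[str] = field(default_factory=list)
    samples_not_in_tree: list[str] = field(default_factory=list)

    @property
    def fraction_assigned(self) -> float:
        if self.total == 0:
            return 0.0
        return self.counts.get(STATUS_ASSIGNED, 0) / self.total

    def add(self, status: str) -> None:
        self.counts[status] = self.counts.get(status, 0) + 1
        self.total += 1

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"status": s, "count": c} for s, c in sorted(self.counts.items())
        ]
        rows.append({"status": "total", "count": self.total})
        return pd.DataFrame(rows)


def default_loglik_margin(epsilon: float, max_mismatches: int = 3) -> float:
    """Margin (nats) below the perfect-fit log-likelihood tolerated before
    exclusion; equals the cost of ``max_mismatches`` flipped genotypes."""
    return max_mismatches * (math.log1p(-epsilon) - math.log(epsilon))


def _genotype_bits(
    genotypes: Mapping[str, int], tree: ReferenceTree
) -> tuple[int, int]:
    """(alt_bits, nonmissing_bits) over tree leaf indices.

    Genotypes are 0 (ref), 1 (alt) or -1/None (missing).
    """
    index = {name: i for i, name in enumerate(tree.leaf_names)}
    alt = 0
    nonmiss = 0
    for leaf, g in genotypes.items():
        try:
            i = index[leaf]
        except KeyError:
            raise ValueError(f"genotype for unknown leaf: {leaf!r}") from None
        if g is None or g == MISSING:
            continue
        nonmiss |= 1 << i
        if g == 1:
            alt |= 1 << i
    return alt, nonmiss


def _mismatches(clade: int, alt: int, nonmiss: int, derived_is_alt: bool) -> int:
    cm = (clade & nonmiss).bit_count()
    ca = (clade & alt).bit_count()
    n_alt = alt.bit_count()
    n_obs = nonmiss.bit_count()
    if derived_is_alt:
        return cm + n_alt - 2 * ca
    return n_obs - cm - n_alt + 2 * ca


def score_snp_on_branch(
    genotypes: Mapping[str, int],
    tree: ReferenceTree,
    branch: int,
    derived_is_alt: bool,
    epsilon: float = 0.001,
) -> float:
    """Log-likelihood (nats) of the site arising on ``branch``.

    Leaves inside the branch's clade are expected derived, leaves outside
    ancestral; each non-missing genotype contributes ``log(1-epsilon)``
    on a match and ``log(epsilon)`` on a mismatch.
    """
    if not (0.0 < epsilon < 0.5):
        raise ValueError("epsilon must be in (0, 0.5)")
    tree._check_branch(branch)
    alt, nonmiss = _genotype_bits(genotypes, tree)
    k = _mismatches(tree.clade_bits[branch], alt, nonmiss, derived_is_alt)
    n = nonmiss.bit_count()
    return (n - k) * math.log1p(-epsilon) + k * math.log(epsilon)


def assign_snp(
    genotypes: Mapping[str, int],
    tree: ReferenceTree,
    chrom: str = "chr",
    pos: int = 0,
    ref_allele: str = "A",
    alt_allele: str = "G",
    epsilon: float = 0.001,
    loglik_margin: float | None = None,
    derived_hint: str | None = None,
) -> BranchAssignedSNP:
    """Exhaustive argmax over all (branch, polarity) hypotheses.

    ``derived_hint`` ("ref"/"alt"), e.g. from an ancestral-allele INFO
    annotation, pins the polarity instead of inferring it.  Ties are
    broken deterministically by (mismatches, branch id, alt-polarity
    first).
    """
    if not (0.0 < epsilon < 0.5):
        raise ValueError("epsilon must be in (0, 0.5)")
    alt, nonmiss = _genotype_bits(genotypes, tree)
    n_obs = nonmiss.bit_count()
    n_alt = alt.bit_count()
    if n_obs == 0 or n_alt == 0 or n_alt == n_obs:
        return BranchAssignedSNP(
            chrom, pos, ref_allele, alt_allele, STATUS_MONOMORPHIC
        )
    if loglik_margin is None:
        loglik_margin = default_loglik_margin(epsilon)
    polarities = (True, False)
    if derived_hint == "alt":
        polarities = (True,)
    elif derived_hint == "ref":
        polarities = (False,)
    best: tuple[int, int, int] | None = None  # (k, branch, pol_rank)
    for b in tree.branches:
        clade = tree.clade_bits[b]
        for pol in polarities:
            k = _mismatches(clade, alt, nonmiss, pol)
            key = (k, b, 0 if pol else 1)
            if best is None or key < best:
                best = key
    assert best is not None
    k, branch, pol_rank = best
    derived_is_alt = pol_rank == 0
    step = math.log1p(-epsilon) - math.log(epsilon)
    loglik = n_obs * math.log1p(-epsilon) - k * step
    if k * step > loglik_margin:
        return BranchAssignedSNP(
            chrom,
            pos,
            ref_allele,
            alt_allele,
            STATUS_LOW_LIK,
            n_mismatch=k,
        )
    return BranchAssignedSNP(
        chrom,
        pos,
        ref_allele,
        alt_allele,
        STATUS_ASSIGNED,
        derived_allele=alt_allele if derived_is_alt else ref_allele,
        branch=branch,
        loglik=loglik,
        n_mismatch=k,
    )


def assign_matrix(
    genotype_matrix: np.ndarray,
    tree: ReferenceTree,
    chrom: str,
    positions: np.ndarray,
    ref_alleles: list[str],
    alt_alleles: list[str],
    epsilon: float = 0.001,
    loglik_margin: float | None = None,
) -> tuple[list[BranchAssignedSNP], AssignmentReport]:
    """Vectorized assignment of a sites x leaves genotype matrix.

    ``genotype_matrix`` holds 0/1/-1 (missing) with columns in tree leaf
    order.  This is the fast path used by the simulator-driven tests and
    by :func:`assign_all` after VCF decoding.
    """
    if loglik_margin is None:
        loglik_margin = default_loglik_margin(epsilon)
    G = np.asarray(genotype_matrix)
    S, L = G.shape
    if L != tree.n_leaves:
        raise ValueError("genotype matrix columns must match tree leaves")
    B = tree.n_branches
    clade = np.zeros((B, L), dtype=bool)
    for i, b in enumerate(tree.branches):
        bits = tree.clade_bits[b]
        for li in range(L):
            if bits >> li & 1:
                clade[i, li] = True
    Cmat = clade.astype(np.int32)
    A = (G == 1).astype(np.int32)  # S x L
    M = (G >= 0).astype(np.int32)
    CM = M @ Cmat.T  # S x B : non-missing inside clade
    CA = A @ Cmat.T  # S x B : alt carriers inside clade
    n_alt = A.sum(axis=1)  # S
    n_obs = M.sum(axis=1)
    k_alt = CM + n_alt[:, None] - 2 * CA  # derived = alt
    k_ref = (n_obs - n_alt)[:, None] - CM + 2 * CA  # derived = ref
    # lexicographic tie-break (k, branch order, alt first) via scaled key
    rank = np.arange(B, dtype=np.int64)[None, :]
    key_alt = k_alt.astype(np.int64) * (2 * B) + 2 * rank
    key_ref = k_ref.astype(np.int64) * (2 * B) + 2 * rank + 1
    keys = np.concatenate([key_alt, key_ref], axis=1)
    flat = np.argmin(keys, axis=1)
    step = math.log1p(-epsilon) - math.log(epsilon)
    report = AssignmentReport()
    out: list[BranchAssignedSNP] = []
    branch_ids = tree.branches
    for s in range(S):
        pos = int(positions[s])
        ref, altb = ref_alleles[s], alt_alleles[s]
        if n_obs[s] == 0 or n_alt[s] == 0 or n_alt[s] == n_obs[s]:
            rec = BranchAssignedSNP(chrom, pos, ref, altb, STATUS_MONOMORPHIC)
        else:
            idx = int(flat[s])
            derived_is_alt = idx < B
            bidx = idx if derived_is_alt else idx - B
            k = int(k_alt[s, bidx] if derived_is_alt else k_ref[s, bidx])
            if k * step > loglik_margin:
                rec = BranchAssignedSNP(
                    chrom, pos, ref, altb, STATUS_LOW_LIK, n_mismatch=k
                )
            else:
                rec = BranchAssignedSNP(
                    chrom,
                    pos,
                    ref,
                    altb,
                    STATUS_ASSIGNED,
                    derived_allele=altb if derived_is_alt else ref,
                    branch=branch_ids[bidx],
                    loglik=float(n_obs[s]) * math.log1p(-epsilon) - k * step,
                    n_mismatch=k,
                )
        report.add(rec.status)
        out.append(rec)
    return out, report


_BASES = {"A", "C", "G", "T"}


def assign_all(
    vcf_path: str,
    tree: ReferenceTree,
    epsilon: float = 0.001,
    loglik_margin: float | None = None,
    use_aa_info: bool = True,
) -> tuple[list[BranchAssignedSNP], AssignmentReport]:
    """Assign every site of a reference VCF to a branch.

    Multiallelic, symbolic and indel records are excluded without
    scoring.  Diploid-coded genotypes are accepted when homozygous;
    heterozygous calls are treated as missing and counted in the report.
    An ``AA`` INFO ancestral-allele annotation, when present and matching
    ref or alt, pins the polarity.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    missing_leaves, extra = check_sample_overlap(tree, samples)
    if len(samples) - len(extra) == 0:
        raise ValueError(
            "no overlap between VCF samples and tree leaves; "
            f"first VCF samples: {samples[:5]}, first leaves: {tree.leaf_names[:5]}"
        )
    leaf_index = {name: i for i, name in enumerate(tree.leaf_names)}
    col_of_sample = [leaf_index.get(s) for s in samples]
    report = AssignmentReport(
        leaves_without_genotypes=missing_leaves, samples_not_in_tree=extra
    )
    rows: list[np.ndarray] = []
    meta: list[tuple[str, int, str, str, str | None]] = []
    excluded: list[BranchAssignedSNP] = []
    order: list[tuple[str, int]] = []  # to restore input order
    for v in vcf:
        chrom, pos = v.CHROM, v.POS
        ref, alts = v.REF, v.ALT
        if (
            len(alts) != 1
            or ref.upper() not in _BASES
            or alts[0].upper() not in _BASES
        ):
            alt = alts[0] if alts else "."
            excluded.append(
                BranchAssignedSNP(chrom, pos, ref, alt, STATUS_MULTIALLELIC)
            )
            report.add(STATUS_MULTIALLELIC)
            order.append((chrom, pos))
            continue
        alt = alts[0]
        row = np.full(tree.n_leaves, MISSING, dtype=np.int8)
        for si, gt in enumerate(v.genotypes):
            col = col_of_sample[si]
            if col is None:
                continue
            alleles = [a for a in gt[:-1] if a is not None and a >= 0]
            if not alleles:
                continue
            if len(set(alleles)) > 1:  # heterozygous diploid call
                report.n_het_as_missing += 1
                continue
            row[col] = 1 if alleles[0] == 1 else 0
        hint = None
        if use_aa_info:
            aa = v.INFO.get("AA")
            if isinstance(aa, str):
                aa = aa.upper()
                if aa == ref.upper():
                    hint = "alt"
                elif aa == alt.upper():
                    hint = "ref"
        rows.append(row)
        meta.append((chrom, pos, ref, alt, hint))
        order.append((chrom, pos))
    assigned: dict[tuple[str, int], BranchAssignedSNP] = {}
    for row, (chrom, pos, ref, alt, hint) in zip(rows, meta):
        genotypes = {
            tree.leaf_names[i]: int(row[i])
            for i in range(tree.n_leaves)
            if row[i] != MISSING
        }
        rec = assign_snp(
            genotypes,
            tree,
            chrom=chrom,
            pos=pos,
            ref_allele=ref,
            alt_allele=alt,
            epsilon=epsilon,
            loglik_margin=loglik_margin,
            derived_hint=hint,
        )
        report.add(rec.status)
        assigned[(chrom, pos)] = rec
    for rec in excluded:
        assigned[(rec.chrom, rec.pos)] = rec
    return [assigned[key] for key in order], report


# ----------------------------------------------------------------------
# serialization

_SITES_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "derived",
    "branch",
    "loglik",
    "n_mismatch",
    "status",
    "haplogroup",
]


def write_branch_sites(
    assignments: Iterable[BranchAssignedSNP],
    sites_path: str,
    bed_path: str | None = None,
) -> pd.DataFrame:
    """Write the sites TSV (all records) and the BED of assigned sites.

    BED intervals are 0-based half-open of width 1; only assigned sites
    are emitted there (they are the pileup targets).
    """
    assignments = list(assignments)
    rows = []
    for a in assignments:
        rows.append(
            {
                "chrom": a.chrom,
                "pos": a.pos,
                "ref": a.ref_allele,
                "alt": a.alt_allele,
                "derived": a.derived_allele if a.derived_allele else ".",
                "branch": a.branch if a.branch is not None else ".",
                "loglik": repr(a.loglik) if a.loglik is not None else ".",
                "n_mismatch": a.n_mismatch if a.n_mismatch is not None else ".",
                "status": a.status,
                "haplogroup": a.haplogroup if a.haplogroup else ".",
            }
        )
    df = pd.DataFrame(rows, columns=_SITES_COLUMNS)
    df.to_csv(sites_path, sep="\t", index=False)
    if bed_path is not None:
        write_bed(assignments, bed_path)
    return df


def write_bed(assignments: Iterable[BranchAssignedSNP], bed_path: str) -> None:
    with open(bed_path, "w") as fh:
        for a in assignments:
            if a.status == STATUS_ASSIGNED:
                fh.write(f"{a.chrom}\t{a.pos - 1}\t{a.pos}\n")


def read_branch_sites(sites_path: str) -> list[BranchAssignedSNP]:
    """Inverse of :func:`write_branch_sites` (lossless round-trip)."""
    df = pd.read_csv(sites_path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        status = r["status"]
        out.append(
            BranchAssignedSNP(
                chrom=r["chrom"],
                pos=int(r["pos"]),
                ref_allele=r["ref"],
                alt_allele=r["alt"],
                status=status,
                derived_allele=None if r["derived"] == "." else r["derived"],
                branch=None if r["branch"] == "." else int(r["branch"]),
                loglik=None if r["loglik"] == "." else float(r["loglik"]),
                n_mismatch=(
                    None if r["n_mismatch"] == "." else int(r["n_mismatch"])
                ),
                haplogroup=None if r["haplogroup"] == "." else r["haplogroup"],
            )
        )
    return out
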