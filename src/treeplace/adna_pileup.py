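"""Base-call collection and ancient-DNA-aware filtering at informative sites.

Post-mortem deamination makes cytosines read as thymines (and, on the
complementary strand, guanines as adenines), so transition sites (C/T,
G/A) are exactly the ones a damaged read can silently flip.  The filters
here implement three modes:

``no-filter``
    keep every base matching REF or ALT;
``default``
    additionally drop a *singleton* T at a C/T site and a singleton A at
    a G/A site (a lone transition call is indistinguishable from damage);
``transversions``
    exclude C/T and G/A sites altogether.

After filtering, the genotype is the most frequent remaining base
provided it reaches the consensus fraction (default 70%) of retained
calls, otherwise missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .branch_assign import BranchAssignedSNP, STATUS_ASSIGNED

__all__ = [
    "SitePileup",
    "SiteCall",
    "FILTER_MODES",
    "pileup_at_sites",
    "filter_calls",
    "filter_all",
    "calls_from_vcf",
    "read_pileup_table",
    "write_calls",
]

FILTER_MODES = ("no-filter", "default", "transversions")
_BASES = ("A", "C", "G", "T")
_TRANSITION_PAIRS = ({"C", "T"}, {"G", "A"})


@dataclass
class SitePileup:
    """Filtered base counts at one informative site."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    base_counts: dict[str, int] = field(default_factory=dict)
    raw_depth: int = 0
    derived_allele: str | None = None

    def __post_init__(self) -> None:
        for b, c in self.base_counts.items():
            if b not in _BASES or c < 0:
                raise ValueError(f"bad base count {b}:{c}")


@dataclass
class SiteCall:
    """A query sample's state at one site after filtering."""

    chrom: str
    pos: int
    state: str  # "ancestral" | "derived" | "missing"
    base: str | None = None
    fraction: float | None = None
    filter_mode: str = "default"
    n_used: int = 0
    n_dropped: int = 0


def pileup_at_sites(
    bam_path: str,
    sites: Iterable[BranchAssignedSNP],
    min_bq: int = 20,
    min_mq: int = 25,
) -> list[SitePileup]:
    """Count A/C/G/T per site from reads passing both quality gates.

    Sites with zero passing reads are returned with empty counts.  The
    BAM must be indexed and use the same contig naming as the sites.
    """
    import pysam

    sites = list(sites)
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        contigs = set(bam.references)
        wanted = {s.chrom for s in sites}
        if wanted and not wanted & contigs:
            raise ValueError(
                f"no site contig found in BAM header; sites use "
                f"{sorted(wanted)}, BAM has {sorted(contigs)[:5]}"
            )
        out = []
        for s in sites:
            counts: dict[str, int] = {}
            raw = 0
            if s.chrom in contigs:
                for col in bam.pileup(
                    s.chrom,
                    s.pos - 1,
                    s.pos,
                    truncate=True,
                    min_base_quality=min_bq,
                    min_mapping_quality=min_mq,
                    ignore_overlaps=False,
                ):
                    raw = col.nsegments
                    for read in col.pileups:
                        if read.is_del or read.is_refskip:
                            continue
                        base = read.alignment.query_sequence[
                            read.query_position
                        ].upper()
                        if base in _BASES:
                            counts[base] = counts.get(base, 0) + 1
            out.append(
                SitePileup(
                    chrom=s.chrom,
                    pos=s.pos,
                    ref_allele=s.ref_allele,
                    alt_allele=s.alt_allele,
                    base_counts=counts,
                    raw_depth=raw,
                    derived_allele=s.derived_allele,
                )
            )
    return out


def filter_calls(
    pileup: SitePileup,
    mode: str = "default",
    consensus_fraction: float = 0.7,
) -> SiteCall:
    """Convert one pileup into an ancestral/derived/missing call.

    Step 1 drops bases matching neither REF nor ALT.  Step 2 applies the
    mode-specific deamination rule (see module docstring); the singleton
    rule is evaluated on post-step-1 counts.  Step 3 calls the most
    frequent remaining base iff its fraction of retained calls reaches
    ``consensus_fraction`` (ties at the threshold pass).
    """
    if mode not in FILTER_MODES:
        raise ValueError(f"unknown filter mode: {mode!r}")
    if not (0.5 < consensus_fraction <= 1.0):
        raise ValueError("consensus_fraction must be in (0.5, 1]")
    alleles = {pileup.ref_allele.upper(), pileup.alt_allele.upper()}
    total_in = sum(pileup.base_counts.values())
    counts = {
        b: c for b, c in pileup.base_counts.items() if b in alleles and c > 0
    }
    is_transition = alleles in _TRANSITION_PAIRS
    if mode == "transversions" and is_transition:
        return SiteCall(
            pileup.chrom,
            pileup.pos,
            "missing",
            filter_mode=mode,
            n_used=0,
            n_dropped=total_in,
        )
    if mode == "default":
        if alleles == {"C", "T"} and counts.get("T") == 1:
            del counts["T"]
        if alleles == {"G", "A"} and counts.get("A") == 1:
            del counts["A"]
    remaining = sum(counts.values())
    if remaining == 0:
        return SiteCall(
            pileup.chrom,
            pileup.pos,
            "missing",
            filter_mode=mode,
            n_used=0,
            n_dropped=total_in,
        )
    # deterministic top base: count desc, then alphabetic
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    frac = top[1] / remaining
    if frac < consensus_fraction:
        state = "missing"
        base = None
    else:
        base = top[0]
        if pileup.derived_allele is not None:
            state = (
                "derived"
                if base == pileup.derived_allele.upper()
                else "ancestral"
            )
        else:
            state = "derived" if base == pileup.alt_allele.upper() else "ancestral"
    return SiteCall(
        pileup.chrom,
        pileup.pos,
        state,
        base=base,
        fraction=frac if base is not None else None,
        filter_mode=mode,
        n_used=remaining,
        n_dropped=total_in - remaining,
    )


def filter_all(
    pileups: Iterable[SitePileup],
    mode: str = "default",
    consensus_fraction: float = 0.7,
) -> list[SiteCall]:
    return [filter_calls(p, mode, consensus_fraction) for p in pileups]


def calls_from_vcf(
    query_vcf: str,
    sites: Iterable[BranchAssignedSNP],
    sample: str | None = None,
) -> tuple[list[SiteCall], int]:
    """Map pre-called query genotypes to site calls.

    Sites absent from the VCF are missing; rows whose alleles cannot be
    matched to the site's ref/alt (even after a ref/alt swap) are
    dropped and counted in the returned warning count.
    """
    from cyvcf2 import VCF

    vcf = VCF(query_vcf)
    if sample is None:
        if len(vcf.samples) != 1:
            raise ValueError(
                "query VCF has multiple samples; select one with sample="
            )
        si = 0
    else:
        if sample not in vcf.samples:
            raise ValueError(f"sample {sample!r} not in query VCF")
        si = vcf.samples.index(sample)
    observed: dict[tuple[str, int], str] = {}
    n_warn = 0
    table = {(s.chrom, s.pos): s for s in sites}
    for v in vcf:
        key = (v.CHROM, v.POS)
        site = table.get(key)
        if site is None:
            continue
        if len(v.ALT) > 1:
            n_warn += 1
            continue
        gt = v.genotypes[si]
        alleles = [a for a in gt[:-1] if a is not None and a >= 0]
        if not alleles or len(set(alleles)) > 1:
            continue
        vcf_alleles = [v.REF.upper()] + [a.upper() for a in v.ALT]
        try:
            base = vcf_alleles[alleles[0]]
        except IndexError:
            n_warn += 1
            continue
        if base not in (site.ref_allele.upper(), site.alt_allele.upper()):
            n_warn += 1
            continue
        observed[key] = base
    calls = []
    for key, site in table.items():
        base = observed.get(key)
        if base is None:
            calls.append(SiteCall(site.chrom, site.pos, "missing"))
            continue
        derived = site.derived_allele or site.alt_allele
        state = "derived" if base == derived.upper() else "ancestral"
        calls.append(
            SiteCall(
                site.chrom,
                site.pos,
                state,
                base=base,
                fraction=1.0,
                filter_mode="vcf",
                n_used=1,
            )
        )
    return calls, n_warn


# ----------------------------------------------------------------------
# plain-text pileup tables (the simulator's native query format)


def read_pileup_table(
    path: str, sites: Iterable[BranchAssignedSNP] | None = None
) -> list[SitePileup]:
    """Read a TSV of per-site base counts (chrom pos ref alt A C G T).

    When ``sites`` is given, derived alleles are attached by (chrom,
    pos) so downstream calls carry ancestral/derived states.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    derived = {}
    if sites is not None:
        derived = {(s.chrom, s.pos): s.derived_allele for s in sites}
    out = []
    for _, r in df.iterrows():
        counts = {b: int(r[b]) for b in _BASES if b in r and int(r[b]) > 0}
        out.append(
            SitePileup(
                chrom=str(r["chrom"]),
                pos=int(r["pos"]),
                ref_allele=str(r["ref"]),
                alt_allele=str(r["alt"]),
                base_counts=counts,
                raw_depth=sum(counts.values()),
                derived_allele=derived.get((str(r["chrom"]), int(r["pos"]))),
            )
        )
    return out


def pileups_from_frame(df: pd.DataFrame) -> list[SitePileup]:
    """Convert a per-site base-count DataFrame (chrom pos ref alt A C G T)
    into :class:`SitePileup` objects (the simulator's in-memory path)."""
    out = []
    for _, r in df.iterrows():
        counts = {b: int(r[b]) for b in _BASES if int(r[b]) > 0}
        out.append(
            SitePileup(
                chrom=str(r["chrom"]),
                pos=int(r["pos"]),
                ref_allele=str(r["ref"]),
                alt_allele=str(r["alt"]),
                base_counts=counts,
                raw_depth=sum(counts.values()),
            )
        )
    return out


def attach_derived(
    pileups: Iterable[SitePileup],
    sites: Iterable[BranchAssignedSNP],
    assigned_only: bool = True,
) -> list[SitePileup]:
    """Attach derived alleles from a sites table onto pileups in place."""
    table = {
        (s.chrom, s.pos): s.derived_allele
        for s in sites
        if not assigned_only or s.status == STATUS_ASSIGNED
    }
    out = []
    for p in pileups:
        p.derived_allele = table.get((p.chrom, p.pos), p.derived_allele)
        out.append(p)
    return out


def write_calls(calls: Iterable[SiteCall], path: str) -> pd.DataFrame:
    rows = [
        {
            "chrom": c.chrom,
            "pos": c.pos,
            "state": c.state,
            "base": c.base or ".",
            "fraction": f"{c.fraction:.4f}" if c.fraction is not None else ".",
            "filter_mode": c.filter_mode,
            "n_used": c.n_used,
            "n_dropped": c.n_dropped,
        }
        for c in calls
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
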