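"""Reconcile tree placements with a curated haplogroup marker table.

Non-recombining phylogenies (Y chromosome, mtDNA) carry a community
nomenclature in which long-form labels encode the hierarchy by string
nesting: A1b1b2a is a sublineage of A1b1b2.  A curated marker table
(ISOGG-style: marker name, position, ancestral/derived alleles, label)
lets us (a) attach labels to tree branches wherever a curated marker
coincides with a branch-assigned SNP, and (b) refine a placed query
below its assignment branch by testing curated markers for sublineages
that the reference panel itself does not capture.

Markers with provisional/uncertain status (tilde or parenthesis
suffixes in their names) are retained but flagged; they can support a
terminal label only when no unflagged marker contradicts them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .adna_pileup import SiteCall
from .branch_assign import BranchAssignedSNP, STATUS_ASSIGNED
from .treemodel import ReferenceTree

__all__ = [
    "CuratedMarker",
    "HaplogroupCall",
    "load_markers",
    "label_branches",
    "refine_below",
    "annotate_assignments",
]

_BASES = {"A", "C", "G", "T"}


@dataclass
class CuratedMarker:
    names: list[str]  # all marker names at this (pos, derived)
    haplogroup: str
    chrom: str
    pos: int  # 1-based
    ancestral_allele: str
    derived_allele: str
    provisional: bool = False

    @property
    def name(self) -> str:
        return "/".join(self.names)


@dataclass
class HaplogroupCall:
    terminal: str | None
    anchor_branch: int | None
    anchor_label: str | None
    supporting: list[str] = field(default_factory=list)  # marker names
    conflicting: list[str] = field(default_factory=list)
    alternates: dict[str, int] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)


def _is_provisional(name: str, label: str) -> bool:
    return "~" in name or "(" in name or "~" in label


def load_markers(
    path_or_frame: str | pd.DataFrame,
    synonyms: Mapping[str, str] | None = None,
) -> list[CuratedMarker]:
    """Load and validate a curated marker TSV.

    Expected columns: ``name``, ``haplogroup``, ``pos``, ``ancestral``,
    ``derived`` (plus optional ``chrom``, default ``chrY``).  Non-SNP
    rows (multi-base or identical alleles) are skipped with a counted
    warning; duplicates by (chrom, pos, derived) are collapsed keeping
    all names.  ``synonyms`` maps short names (e.g. ``E-M293``) to the
    long-form labels used for the hierarchy.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        df = pd.read_csv(path_or_frame, sep="\t", dtype=str, comment="#")
    required = {"name", "haplogroup", "pos", "ancestral", "derived"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"marker table lacks columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("empty marker table")
    synonyms = dict(synonyms or {})
    markers: dict[tuple[str, int, str], CuratedMarker] = {}
    n_skipped = 0
    for _, r in df.iterrows():
        try:
            pos = int(r["pos"])
            anc = str(r["ancestral"]).upper()
            der = str(r["derived"]).upper()
            label = str(r["haplogroup"]).strip()
            name = str(r["name"]).strip()
        except (TypeError, ValueError):
            n_skipped += 1
            continue
        label = synonyms.get(label, label)
        if (
            anc not in _BASES
            or der not in _BASES
            or anc == der
            or not label
            or label == "nan"
        ):
            n_skipped += 1
            continue
        chrom = str(r["chrom"]) if "chrom" in df.columns else "chrY"
        key = (chrom, pos, der)
        if key in markers:
            markers[key].names.append(name)
        else:
            markers[key] = CuratedMarker(
                names=[name],
                haplogroup=label.rstrip("~").strip(),
                chrom=chrom,
                pos=pos,
                ancestral_allele=anc,
                derived_allele=der,
                provisional=_is_provisional(name, label),
            )
    out = list(markers.values())
    if not out:
        raise ValueError("no valid biallelic SNP markers in table")
    out.sort(key=lambda m: (m.chrom, m.pos))
    load_markers.n_skipped = n_skipped  # type: ignore[attr-defined]
    return out


def label_branches(
    tree: ReferenceTree,
    assignments: Iterable[BranchAssignedSNP],
    markers: Iterable[CuratedMarker],
) -> dict[int, set[str]]:
    """Branch -> label set wherever a curated marker coincides with an
    assigned SNP by (chrom, pos) and matching derived allele.

    Labels are for reporting only; they never alter placement.
    """
    by_site: dict[tuple[str, int], list[CuratedMarker]] = {}
    for m in markers:
        by_site.setdefault((m.chrom, m.pos), []).append(m)
    root_children = tree.children[tree.root]
    labels: dict[int, set[str]] = {}
    for a in assignments:
        if a.status != STATUS_ASSIGNED or a.branch is None:
            continue
        for m in by_site.get((a.chrom, a.pos), []):
            if m.derived_allele == (a.derived_allele or "").upper():
                labels.setdefault(a.branch, set()).add(m.haplogroup)
            elif (
                m.derived_allele == (a.ancestral_allele or "").upper()
                and a.branch in root_children
                and len(root_children) == 2
            ):
                # a SNP on one root-child branch is the same unrooted
                # split as the sibling branch with flipped polarity; a
                # marker derived for the coded-ancestral allele therefore
                # labels the complementary root clade
                sibling = next(b for b in root_children if b != a.branch)
                labels.setdefault(sibling, set()).add(m.haplogroup)
    return labels


def _is_sublabel(child: str, parent: str) -> bool:
    """Hierarchy by long-form name nesting: child is below-or-equal parent."""
    return child.startswith(parent)


def _anchor_label(
    tree: ReferenceTree, branch: int, branch_labels: Mapping[int, set[str]]
) -> str | None:
    """Most specific label on the nearest labeled ancestor-or-self branch."""
    for b in [branch] + list(tree.strict_ancestors(branch)):
        labels = branch_labels.get(b)
        if labels:
            return max(labels, key=lambda s: (len(s), s))
    return None


def refine_below(
    anchor_branch: int | None,
    calls: Iterable[SiteCall],
    markers: Iterable[CuratedMarker],
    branch_labels: Mapping[int, set[str]],
    tree: ReferenceTree,
) -> HaplogroupCall:
    """Most specific supported label at or below the anchor's label.

    Candidate labels are restricted to hierarchical descendants-or-self
    of the anchor label; a label is supported when at least one of its
    markers is observed in the derived state.  Conflicting support for
    labels on diverging sub-lineages falls back to their deepest common
    ancestor label, reporting the contenders as alternates.
    """
    markers = list(markers)
    anchor_label = (
        _anchor_label(tree, anchor_branch, branch_labels)
        if anchor_branch is not None
        else None
    )
    if anchor_label is None:
        return HaplogroupCall(
            terminal=None,
            anchor_branch=anchor_branch,
            anchor_label=None,
            flags={"tree-only-placement"},
        )
    observed: dict[tuple[str, int], str] = {}
    for c in calls:
        if c.state != "missing" and c.base:
            observed[(c.chrom, c.pos)] = c.base.upper()
    derived_by_label: dict[str, list[CuratedMarker]] = {}
    ancestral_by_label: dict[str, list[CuratedMarker]] = {}
    for m in markers:
        if not _is_sublabel(m.haplogroup, anchor_label):
            continue
        base = observed.get((m.chrom, m.pos))
        if base is None:
            continue
        if base == m.derived_allele:
            derived_by_label.setdefault(m.haplogroup, []).append(m)
        elif base == m.ancestral_allele:
            ancestral_by_label.setdefault(m.haplogroup, []).append(m)
    # provisional markers support a label only without unflagged contradiction
    supported: dict[str, list[CuratedMarker]] = {}
    for label, ms in derived_by_label.items():
        firm = [m for m in ms if not m.provisional]
        contradicted = any(
            not m.provisional for m in ancestral_by_label.get(label, [])
        )
        if firm or not contradicted:
            supported[label] = ms
    if not supported:
        return HaplogroupCall(
            terminal=anchor_label,
            anchor_branch=anchor_branch,
            anchor_label=anchor_label,
            flags={"no-sublineage-data"},
        )
    # maximal supported labels (not a prefix of a longer supported one)
    labels = sorted(supported, key=len, reverse=True)
    maximal: list[str] = []
    for lab in labels:
        if not any(_is_sublabel(longer, lab) for longer in maximal):
            maximal.append(lab)
    if len(maximal) == 1:
        terminal = maximal[0]
        flags: set[str] = set()
    else:
        # diverging sub-lineages: deepest common ancestor label
        common = maximal[0]
        for lab in maximal[1:]:
            n = 0
            for x, y in zip(common, lab):
                if x != y:
                    break
                n += 1
            common = common[:n]
        terminal = common if len(common) >= len(anchor_label) else anchor_label
        flags = {"conflicting-sublineages"}
    support_markers = [
        m
        for lab, ms in supported.items()
        if _is_sublabel(terminal, lab) or _is_sublabel(lab, terminal)
        for m in ms
    ]
    supporting = [m.name for m in support_markers]
    if support_markers and all(m.provisional for m in support_markers):
        flags.add("provisional-support")
    conflicting = [
        m.name
        for lab, ms in ancestral_by_label.items()
        if _is_sublabel(terminal, lab)
        for m in ms
    ]
    alternates = {
        lab: len(supported[lab])
        for lab in maximal
        if lab != terminal
    }
    return HaplogroupCall(
        terminal=terminal,
        anchor_branch=anchor_branch,
        anchor_label=anchor_label,
        supporting=sorted(set(supporting)),
        conflicting=sorted(set(conflicting)),
        alternates=alternates,
        flags=flags,
    )


def annotate_assignments(
    assignments: Iterable[BranchAssignedSNP],
    markers: Iterable[CuratedMarker],
) -> None:
    """Attach curated labels to assigned SNP records in place (for the
    sites table's ``haplogroup`` column)."""
    by_site = {}
    for m in markers:
        by_site.setdefault((m.chrom, m.pos), []).append(m)
    for a in assignments:
        if a.status != STATUS_ASSIGNED:
            continue
        for m in by_site.get((a.chrom, a.pos), []):
            if m.derived_allele == (a.derived_allele or "").upper():
                a.haplogroup = m.haplogroup


def write_haplogroup_call(call: HaplogroupCall, path: str) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "terminal": call.terminal or ".",
                "anchor_branch": (
                    call.anchor_branch if call.anchor_branch is not None else "."
                ),
                "anchor_label": call.anchor_label or ".",
                "n_support": len(call.supporting),
                "support": ",".join(call.supporting) or ".",
                "conflicts": ",".join(call.conflicting) or ".",
                "alternates": (
                    ",".join(
                        f"{k}:{v}" for k, v in sorted(call.alternates.items())
                    )
                    or "."
                ),
                "flags": ",".join(sorted(call.flags)) or ".",
            }
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
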