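"""Place a query sample onto the reference tree from its site calls.

Two estimators are provided.

**Best path** walks every root-to-tip path, pruning a path at the first
branch carrying more conflicting (ancestral-state) markers than
``max_conflict``; every admissible path prefix is a candidate placement
scored by its cumulative support (derived-state markers), and the argmax
wins.  The result carries the marker bookkeeping string
``[support_above-conflict_above; support_on-conflict_on]`` that is
appended to the query's leaf label on output.

**Likelihood** scores every edge ``e`` of the tree: a query attached on
``e`` is expected derived at SNPs on strict ancestors of ``e`` and
ancestral elsewhere, while SNPs on ``e`` itself are ignored — a
conservative simplification, since markers on the attachment branch may
fall on either side of the divergence point.  Each marker matches its
expectation with probability ``1 - epsilon``.  Log-likelihoods are
normalized to posteriors with a uniform prior over edges; branches above
the reporting threshold (default 0.01) are reported, and the deepest
branch whose inclusive clade holds more than ``1 - P`` of the posterior
mass (default P = 0.01) gives a conservative 99% placement clade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .adna_pileup import SiteCall
from .branch_assign import BranchAssignedSNP, STATUS_ASSIGNED
from .treemodel import ReferenceTree

__all__ = [
    "BranchTally",
    "BestPathResult",
    "PlacementPosterior",
    "tally",
    "best_path",
    "likelihood_place",
    "annotate_and_insert",
    "PlacementModel",
    "PlacementResults",
]


@dataclass
class BranchTally:
    """Per-branch support (derived) / conflict (ancestral) marker counts."""

    support: dict[int, int] = field(default_factory=dict)
    conflict: dict[int, int] = field(default_factory=dict)
    n_ignored: int = 0  # calls at sites without an assigned branch

    @property
    def total(self) -> int:
        return sum(self.support.values()) + sum(self.conflict.values())

    def sup(self, b: int) -> int:
        return self.support.get(b, 0)

    def con(self, b: int) -> int:
        return self.conflict.get(b, 0)


@dataclass
class BestPathResult:
    branch: int | None  # None: unplaced (empty tally -> root)
    support_above: int = 0
    conflict_above: int = 0
    support_on: int = 0
    conflict_on: int = 0
    insertion_fraction: float = 0.5
    tie: bool = False
    n_pruned_paths: int = 0

    @property
    def annotation(self) -> str:
        return (
            f"[{self.support_above}-{self.conflict_above}; "
            f"{self.support_on}-{self.conflict_on}]"
        )

    @property
    def total_support(self) -> int:
        return self.support_above + self.support_on


@dataclass
class PlacementPosterior:
    branch_ids: list[int]
    posteriors: np.ndarray  # aligned with branch_ids, sums to 1
    max_branch: int
    reported: dict[int, float]  # posterior > threshold (plus the argmax)
    clade_branch: int | None  # 99% placement clade; None = root ambiguity
    loglik: np.ndarray | None = None

    def posterior_of(self, branch: int) -> float:
        return float(self.posteriors[self.branch_ids.index(branch)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"branch": self.branch_ids, "posterior": self.posteriors}
        )


def tally(
    calls: Iterable[SiteCall],
    assignments: Iterable[BranchAssignedSNP],
) -> BranchTally:
    """Bin a query's non-missing calls into per-branch support/conflict."""
    table = {
        (a.chrom, a.pos): a for a in assignments if a.status == STATUS_ASSIGNED
    }
    t = BranchTally()
    for c in calls:
        if c.state == "missing":
            continue
        a = table.get((c.chrom, c.pos))
        if a is None:
            t.n_ignored += 1
            continue
        b = a.branch
        assert b is not None
        if c.state == "derived":
            t.support[b] = t.support.get(b, 0) + 1
        else:
            t.conflict[b] = t.conflict.get(b, 0) + 1
    return t


def _chain(tree: ReferenceTree, branches: list[int]) -> bool:
    """True iff the branches all lie on one root-to-tip chain."""
    ordered = sorted(branches, key=lambda b: tree.depth[b])
    return all(
        tree.is_ancestor_or_self(a, b) for a, b in zip(ordered, ordered[1:])
    )


def best_path(
    tree: ReferenceTree,
    t: BranchTally,
    max_conflict: int = 3,
) -> BestPathResult:
    """Maximum-support path placement with conflict pruning.

    A branch with conflict > ``max_conflict`` stops its path: the branch
    itself and everything below it become ineligible, while the prefix
    above remains a candidate.  Candidates are scored by cumulative
    support along the path from the root; ties are broken by fewer
    cumulative conflicts, then shallower branch, then smaller branch id.
    The tie flag is set only when candidates that survive the conflict
    tie-break are not nested on a single root-to-tip chain.
    """
    if t.total == 0:
        return BestPathResult(branch=None, tie=True, insertion_fraction=0.5)
    best_key: tuple[int, int, int, int] | None = None
    best_branch: int | None = None
    tied: list[int] = []
    n_pruned = 0
    # iterative DFS carrying cumulative (support, conflict)
    stack: list[tuple[int, int, int]] = [
        (c, 0, 0) for c in reversed(tree.children[tree.root])
    ]
    while stack:
        b, sup_above, con_above = stack.pop()
        if t.con(b) > max_conflict:
            # every root-to-tip path through b stops here
            n_pruned += max(1, tree.clade_bits[b].bit_count())
            continue
        sup = sup_above + t.sup(b)
        con = con_above + t.con(b)
        key = (-sup, con, tree.depth[b], b)
        if best_key is None or key < best_key:
            best_key = key
            best_branch = b
            tied = [b]
        elif key[:2] == best_key[:2]:
            tied.append(b)
        for c in reversed(tree.children[b]):
            stack.append((c, sup, con))
    if best_branch is None:
        # every root-adjacent branch overflowed with conflicts
        return BestPathResult(
            branch=None, tie=True, n_pruned_paths=n_pruned
        )
    sup_on = t.sup(best_branch)
    con_on = t.con(best_branch)
    assert best_key is not None
    sup_above = -best_key[0] - sup_on
    con_above = best_key[1] - con_on
    denom = sup_on + con_on
    frac = sup_on / denom if denom else 0.5
    return BestPathResult(
        branch=best_branch,
        support_above=sup_above,
        conflict_above=con_above,
        support_on=sup_on,
        conflict_on=con_on,
        insertion_fraction=frac,
        tie=len(tied) > 1 and not _chain(tree, tied),
        n_pruned_paths=n_pruned,
    )


def likelihood_place(
    tree: ReferenceTree,
    t: BranchTally,
    epsilon: float = 0.01,
    posterior_threshold: float = 0.01,
    clade_p: float = 0.01,
) -> PlacementPosterior:
    """Per-edge likelihood placement with Bayesian posteriors.

    See the module docstring for the model.  Complexity is O(branches)
    given the tally: ancestor-cumulative counts are propagated in one
    preorder pass.
    """
    if not (0.0 < epsilon < 0.5):
        raise ValueError("epsilon must be in (0, 0.5)")
    l1 = math.log1p(-epsilon)
    le = math.log(epsilon)
    branches = tree.branches
    idx = {b: i for i, b in enumerate(branches)}
    tot_s = sum(t.support.values())
    tot_c = sum(t.conflict.values())
    anc_s = {b: 0 for b in branches}
    anc_c = {b: 0 for b in branches}
    for b in branches:  # preorder guarantees parent before child
        p = tree.parent[b]
        if p is not None and p != tree.root:
            anc_s[b] = anc_s[p] + t.sup(p)
            anc_c[b] = anc_c[p] + t.con(p)
    ll = np.empty(len(branches))
    for i, b in enumerate(branches):
        s_above, c_above = anc_s[b], anc_c[b]
        s_below = tot_s - s_above - t.sup(b)
        c_below = tot_c - c_above - t.con(b)
        ll[i] = (s_above + c_below) * l1 + (c_above + s_below) * le
    post = np.exp(ll - logsumexp(ll))
    post /= post.sum()
    max_i = int(np.argmax(post))
    max_branch = branches[max_i]
    reported = {
        b: float(post[i])
        for i, b in enumerate(branches)
        if post[i] > posterior_threshold
    }
    reported.setdefault(max_branch, float(post[max_i]))
    # conservative placement clade: deepest branch on the root->argmax
    # chain whose inclusive clade carries > 1-P of the posterior mass
    sums = tree.subtree_sums({b: float(post[idx[b]]) for b in branches})
    clade_branch: int | None = None
    for b in tree.path_to_root(max_branch):
        if sums[b] > 1.0 - clade_p:
            clade_branch = b  # keep walking: deeper is more specific
        else:
            break
    return PlacementPosterior(
        branch_ids=list(branches),
        posteriors=post,
        max_branch=max_branch,
        reported=reported,
        clade_branch=clade_branch,
        loglik=ll,
    )


def annotate_and_insert(
    tree: ReferenceTree,
    result: BestPathResult,
    name: str,
    posterior: PlacementPosterior | None = None,
    separator: str = " ",
) -> tuple[ReferenceTree, bool]:
    """Insert the placed query as an annotated leaf.

    The leaf label is ``name + separator + annotation``.  On a tie the
    insertion falls back to the conservative placement clade branch when
    a posterior is available.  Returns ``(tree, placed)``; an empty
    result leaves the tree unchanged.
    """
    if result.branch is None:
        return tree, False
    branch = result.branch
    fraction = result.insertion_fraction
    if result.tie and posterior is not None and posterior.clade_branch is not None:
        branch = posterior.clade_branch
        fraction = 0.5
    label = f"{name}{separator}{result.annotation}"
    return tree.insert_query(branch, fraction, label), True


# ----------------------------------------------------------------------
# model / results facade


class PlacementModel:
    """Placement of one query sample, statsmodels-style.

    Bundles the fixed reference (tree + branch-assigned SNPs) with one
    query's site calls; :meth:`fit` runs the chosen estimator(s) and
    returns a :class:`PlacementResults`.
    """

    def __init__(
        self,
        tree: ReferenceTree,
        assignments: Iterable[BranchAssignedSNP],
        calls: Iterable[SiteCall],
        name: str = "query",
    ) -> None:
        self.tree = tree
        self.assignments = list(assignments)
        self.calls = list(calls)
        self.name = name
        self.tally = tally(self.calls, self.assignments)

    @classmethod
    def from_files(
        cls,
        tree_path: str,
        sites_path: str,
        calls: Iterable[SiteCall],
        name: str = "query",
    ) -> "PlacementModel":
        from .branch_assign import read_branch_sites
        from .treemodel import read_newick_file

        return cls(
            read_newick_file(tree_path),
            read_branch_sites(sites_path),
            calls,
            name=name,
        )

    def fit(
        self,
        method: str = "both",
        max_conflict: int = 3,
        epsilon: float = 0.01,
        posterior_threshold: float = 0.01,
        clade_p: float = 0.01,
    ) -> "PlacementResults":
        if method not in ("best-path", "likelihood", "both"):
            raise ValueError(f"unknown method: {method!r}")
        bp = (
            best_path(self.tree, self.tally, max_conflict=max_conflict)
            if method in ("best-path", "both")
            else None
        )
        post = (
            likelihood_place(
                self.tree,
                self.tally,
                epsilon=epsilon,
                posterior_threshold=posterior_threshold,
                clade_p=clade_p,
            )
            if method in ("likelihood", "both")
            else None
        )
        return PlacementResults(self, method, bp, post)


class PlacementResults:
    """Estimates, uncertainties and diagnostics for one placement."""

    def __init__(
        self,
        model: PlacementModel,
        method: str,
        best_path_result: BestPathResult | None,
        posterior: PlacementPosterior | None,
    ) -> None:
        self.model = model
        self.method = method
        self.best_path = best_path_result
        self.posterior = posterior

    @property
    def branch(self) -> int | None:
        """Point estimate: best-path branch if fitted, else max-posterior."""
        if self.best_path is not None and self.best_path.branch is not None:
            return self.best_path.branch
        if self.posterior is not None:
            return self.posterior.max_branch
        return None

    @property
    def placed(self) -> bool:
        return self.model.tally.total > 0 and self.branch is not None

    def insert_into_tree(self, separator: str = " ") -> tuple[ReferenceTree, bool]:
        bp = self.best_path
        if bp is None:
            if self.posterior is None or self.model.tally.total == 0:
                return self.model.tree, False
            b = self.posterior.max_branch
            bp = BestPathResult(branch=b)
        return annotate_and_insert(
            self.model.tree, bp, self.model.name, self.posterior, separator
        )

    def summary(self) -> str:
        m = self.model
        lines = [
            "Placement results",
            "=" * 60,
            f"query:           {m.name}",
            f"tree:            {m.tree.n_leaves} leaves, {m.tree.n_branches} branches",
            f"informative calls: {m.tally.total} "
            f"(+{m.tally.n_ignored} at unassigned sites)",
        ]
        if self.best_path is not None:
            bp = self.best_path
            lines += [
                "-" * 60,
                "best path",
                f"  branch:        {bp.branch if bp.branch is not None else 'unplaced (root)'}",
                f"  markers:       {bp.annotation}"
                + ("  (tie)" if bp.tie else ""),
                f"  insertion:     {bp.insertion_fraction:.3f} from parent end",
                f"  pruned paths:  {bp.n_pruned_paths}",
            ]
        if self.posterior is not None:
            po = self.posterior
            lines += ["-" * 60, "likelihood placement"]
            lines.append(
                f"  max posterior: branch {po.max_branch} "
                f"(p = {po.posterior_of(po.max_branch):.4f})"
            )
            top = sorted(po.reported.items(), key=lambda kv: -kv[1])[:8]
            for b, p in top:
                lines.append(f"    branch {b:>5}  posterior {p:.4f}")
            clade = (
                f"branch {po.clade_branch}"
                if po.clade_branch is not None
                else "root (ambiguous)"
            )
            lines.append(f"  99% placement clade: {clade}")
        return "\n".join(lines)
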