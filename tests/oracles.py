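"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's bitset/cumulative-count
machinery: mismatches are counted leaf by leaf over explicit clade sets,
and best-path candidates are enumerated path by path.
"""

from __future__ import annotations

from treeplace.placement import BranchTally
from treeplace.treemodel import ReferenceTree


def brute_force_min_mismatch(
    genotypes: dict[str, int], tree: ReferenceTree
) -> tuple[int, set[tuple[int, bool]]]:
    """Minimum mismatch count over all (branch, derived_is_alt)
    hypotheses, with the full argmin set."""
    best_k: int | None = None
    argmin: set[tuple[int, bool]] = set()
    for b in tree.branches:
        clade = tree.clade_leaves(b)
        for derived_is_alt in (True, False):
            k = 0
            for leaf, g in genotypes.items():
                if g is None or g < 0:
                    continue
                if leaf in clade:
                    expected = 1 if derived_is_alt else 0
                else:
                    expected = 0 if derived_is_alt else 1
                if g != expected:
                    k += 1
            if best_k is None or k < best_k:
                best_k = k
                argmin = {(b, derived_is_alt)}
            elif k == best_k:
                argmin.add((b, derived_is_alt))
    assert best_k is not None
    return best_k, argmin


def brute_force_best_path(
    tree: ReferenceTree, t: BranchTally, max_conflict: int = 3
) -> tuple[int, int, int] | None:
    """Exhaustive enumeration of all root-to-tip path prefixes with the
    conflict-pruning rule.

    Returns (branch, cumulative_support, cumulative_conflict) of the
    winner under the tie-break order (max support, min conflict,
    shallowest, smallest id), or None when no branch is admissible.
    """
    tips = [b for b in tree.branches if tree.is_leaf(b)]
    candidates: dict[int, tuple[int, int]] = {}
    for tip in tips:
        sup = con = 0
        for b in tree.path_to_root(tip):
            if t.con(b) > max_conflict:
                break  # path stops; the offending branch is ineligible
            sup += t.sup(b)
            con += t.con(b)
            candidates[b] = (sup, con)
    if not candidates:
        return None
    ranked = sorted(
        candidates.items(),
        key=lambda kv: (-kv[1][0], kv[1][1], tree.depth[kv[0]], kv[0]),
    )
    b, (sup, con) = ranked[0]
    return b, sup, con
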