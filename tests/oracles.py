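"""Independent reference implementations used only to cross-check the package.

These deliberately use different mechanisms from the production code: the
classifier iterates the assessment rules to a fixpoint instead of a single
ordered pass, the subset-enumeration oracle tests connectivity of every
subset exhaustively, and the parent oracle computes the minimal-superset
relation by direct O(n^2) subset comparison.
"""

from itertools import combinations

from fragnet.network import Assessment, FeatureNetwork


def fixpoint_classify(net: FeatureNetwork) -> dict:
    """Evaluate the assessment rules declaratively until nothing changes."""
    types: dict[int, Assessment] = {}
    # inactive nodes depend only on raw child predictions
    for n in net.nodes:
        if not n.prediction.is_active:
            has_active_child = any(
                net.node(c).prediction.is_active for c in n.child_indices
            )
            types[n.index] = (
                Assessment.DEACTIVATING if has_active_child else Assessment.IGNORE
            )
    changed = True
    while changed:
        changed = False
        for n in net.nodes:
            if not n.prediction.is_active:
                continue
            if any(not net.node(p).prediction.is_active for p in n.parent_indices):
                new = Assessment.DEACTIVATED
            elif any(
                types.get(d) is Assessment.ACTIVATING for d in n.descendant_indices
            ):
                new = Assessment.ACTIVITY_IDENTIFIED
            elif any(
                not net.node(a).prediction.is_active for a in n.ascendant_indices
            ):
                new = Assessment.NEGATED
            else:
                new = Assessment.ACTIVATING
            if types.get(n.index) is not new:
                types[n.index] = new
                changed = True
    return types


def connected_subsets_brute_force(n_units: int, edges: set) -> set:
    """Every connected subset of a unit graph, by exhaustive enumeration."""
    adjacency = {u: set() for u in range(n_units)}
    for e in edges:
        a, b = tuple(e)
        adjacency[a].add(b)
        adjacency[b].add(a)

    def connected(subset):
        subset = set(subset)
        seen = set()
        stack = [next(iter(subset))]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend((adjacency[u] & subset) - seen)
        return seen == subset

    out = set()
    for k in range(1, n_units + 1):
        for subset in combinations(range(n_units), k):
            if connected(subset):
                out.add(frozenset(subset))
    return out


def minimal_superset_parents(sets_by_index: dict) -> dict:
    """Parent relation by direct pairwise subset comparison."""
    parents = {}
    for i, s in sets_by_index.items():
        supers = [j for j, t in sets_by_index.items() if j != i and s < t]
        parents[i] = sorted(
            p
            for p in supers
            if not any(q != p and sets_by_index[q] < sets_by_index[p] for q in supers)
        )
    return parents
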