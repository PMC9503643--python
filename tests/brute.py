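"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (windowed scans, exhaustive clade
enumeration on nested-tuple trees) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N"}


def rc(motif: str) -> str:
    return "".join(_COMP[c] for c in reversed(motif))


def window_matches(seq: str, motif: str) -> list[int]:
    """0-based start positions where the IUPAC motif matches, by letter sets."""
    out = []
    k = len(motif)
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in IUPAC_SETS[motif[j]] for j in range(k)):
            out.append(i)
    return out


def brute_cut_positions(seq: str, recognition: str, cut_offset: int) -> list[int]:
    """All 1-based cut coordinates on both strands, naive double scan."""
    cuts = set()
    for i in window_matches(seq, recognition):
        cuts.add(i + cut_offset + 1)
    if recognition != rc(recognition):
        for i in window_matches(seq, rc(recognition)):
            cuts.add(i + len(recognition) - cut_offset + 1)
    return sorted(c for c in cuts if 2 <= c <= len(seq))


def brute_coverage(alignments, G: int) -> np.ndarray:
    """Per-base coverage by walking every read base one at a time."""
    cov = np.zeros(G, dtype=int)
    for start, strand, length in alignments:
        step = 1 if strand == "+" else -1
        for k in range(length):
            cov[(start - 1 + step * k) % G] += 1
    return cov


# --- nested-tuple trees -----------------------------------------------------
# leaf: a tip-name string.  internal node: (children_tuple, support_or_None).


def random_tree(rng: np.random.Generator, n_tips: int):
    """Random rooted multifurcating tree; returns (tuple_tree, newick)."""
    names = [f"t{i}" for i in rng.permutation(n_tips)]

    def build(tips):
        if len(tips) == 1:
            return tips[0]
        k = int(rng.integers(2, min(3, len(tips)) + 1))
        cuts = sorted(rng.choice(np.arange(1, len(tips)), size=k - 1, replace=False))
        parts, prev = [], 0
        for c in list(cuts) + [len(tips)]:
            parts.append(tips[prev:c])
            prev = c
        support = None if rng.random() < 0.15 else int(rng.integers(0, 101))
        return (tuple(build(p) for p in parts), support)

    tree = build(names)
    if isinstance(tree, str):
        tree = ((tree,), None)
    return tree, to_newick(tree) + ";"


def to_newick(node) -> str:
    if isinstance(node, str):
        return node
    children, support = node
    inner = ",".join(to_newick(c) for c in children)
    return f"({inner})" + ("" if support is None else str(support))


def leaf_set(node) -> frozenset:
    if isinstance(node, str):
        return frozenset([node])
    return frozenset().union(*(leaf_set(c) for c in node[0]))


def all_clades(node, acc=None):
    """(tip_set, support, is_leaf) for every node of the tree."""
    if acc is None:
        acc = []
    if isinstance(node, str):
        acc.append((frozenset([node]), None, True))
        return acc
    acc.append((leaf_set(node), node[1], False))
    for c in node[0]:
        all_clades(c, acc)
    return acc


def brute_mrca_tips(tree, tip_subset) -> frozenset:
    """Tip set of the smallest clade containing the subset (exhaustive)."""
    want = frozenset(tip_subset)
    candidates = [c for c in all_clades(tree) if want <= c[0]]
    return min(candidates, key=lambda c: len(c[0]))[0]


def brute_propagate(tree, labels: dict, threshold: float):
    """Exhaustive clade-rule: returns (assigned, impure_strategies, unassigned)."""
    assigned: dict[str, str] = {}
    impure: set[str] = set()
    clades = all_clades(tree)
    for strat in sorted(set(labels.values())):
        tips = {t for t, s in labels.items() if s == strat}
        mrca_tips, support, is_leaf = min(
            (c for c in clades if tips <= c[0]), key=lambda c: len(c[0])
        )
        if any(labels.get(t, strat) != strat for t in mrca_tips):
            impure.add(strat)
            continue
        sup = 100.0 if is_leaf else (support if support is not None else 0.0)
        if is_leaf:
            continue  # a lone verified tip lends its strategy to nobody
        if sup >= threshold:
            for t in mrca_tips - set(labels):
                assigned[t] = strat
    unassigned = leaf_set(tree) - set(labels) - set(assigned)
    return assigned, impure, unassigned
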