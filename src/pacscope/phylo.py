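"""Packaging-strategy label propagation on terminase (TerL) phylogenies.

The large terminase subunit is the packaging motor's ATPase/nuclease, and
its sequence phylogeny tracks packaging strategy well enough that a clade
anchored by experimentally verified phages can lend its strategy to
unverified members.  The rule implemented here is deliberately
conservative: for each strategy, take the MRCA of its verified tips; if
that clade contains a tip verified as a *different* strategy the group is
paraphyletic ("strategy break") and propagates to nobody; otherwise, if the
MRCA branch is well supported (ultrafast-bootstrap >= threshold, default
95), every unlabeled tip in the clade inherits the strategy.  Everything
else stays unassigned.

Trees are consumed, not inferred; rooting is taken as given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import dendropy
import pandas as pd

__all__ = [
    "LabeledTree",
    "StrategyClade",
    "PropagationResult",
    "read_tree",
    "read_label_table",
    "mrca",
    "propagate_labels",
    "clade_report",
]


@dataclass
class LabeledTree:
    """A rooted tree with branch supports plus a partial tip -> strategy map."""

    tree: dendropy.Tree
    labels: dict[str, str]  # tip name -> strategy

    @property
    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def support(self, node: dendropy.Node) -> float:
        """Branch support of an internal node; unlabeled nodes count as 0."""
        if node.is_leaf():
            return 100.0
        label = node.label
        if label is None:
            return 0.0
        try:
            return float(label)
        except ValueError:
            return 0.0


def read_tree(newick_text: str, label_table: Mapping[str, str]) -> LabeledTree:
    """Parse a newick tree (internal-node labels = supports) and join labels.

    Every label must reference an existing tip; unknown tips are an error so
    that silently dropped verification data cannot skew propagation.
    """
    tree = dendropy.Tree.get(
        data=newick_text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    tree.is_rooted = True  # rooting happens upstream; consume the tree as given
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if len(tips) != sum(1 for _ in tree.leaf_node_iter()):
        raise ValueError("tip names must be unique")
    missing = sorted(set(label_table) - tips)
    if missing:
        raise ValueError(f"labels reference tips absent from the tree: {missing}")
    return LabeledTree(tree=tree, labels=dict(label_table))


def read_label_table(path) -> dict[str, str]:
    """Two-column TSV (tip_name, strategy), no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["tip", "strategy"], dtype=str)
    dupes = df["tip"][df["tip"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate tips in label table: {dupes}")
    return dict(zip(df["tip"], df["strategy"]))


def _leaf_names(node: dendropy.Node) -> set[str]:
    return {leaf.taxon.label for leaf in node.leaf_iter()}


def mrca(tree: dendropy.Tree, tip_set) -> dendropy.Node:
    """Most recent common ancestor of a set of tips on the rooted tree."""
    tips = list(tip_set)
    if not tips:
        raise ValueError("tip_set must be non-empty")
    known = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = sorted(set(tips) - known)
    if unknown:
        raise ValueError(f"unknown tips: {unknown}")
    if len(tips) == 1:
        return tree.find_node_with_taxon_label(tips[0])
    node = tree.mrca(taxa=[tree.taxon_namespace.get_taxon(t) for t in tips])
    return node


@dataclass
class StrategyClade:
    """Outcome of the clade rule for one strategy."""

    strategy: str
    mrca_is_tip: bool
    support: float
    clade_tips: set[str]
    labeled_tips: set[str]
    is_pure: bool
    supported: bool
    propagated_tips: set[str] = field(default_factory=set)


@dataclass
class PropagationResult:
    clades: dict[str, StrategyClade]
    conflicts: list[tuple[str, str, str]]  # (strategy, intruding tip, its label)
    assigned: dict[str, str]  # tip -> propagated strategy (input labels excluded)
    unassigned_tips: set[str]

    def as_dict(self) -> dict:
        return {
            "clades": {
                s: {
                    "support": c.support,
                    "mrca_is_tip": c.mrca_is_tip,
                    "clade_size": len(c.clade_tips),
                    "is_pure": c.is_pure,
                    "supported": c.supported,
                    "propagated_tips": sorted(c.propagated_tips),
                }
                for s, c in self.clades.items()
            },
            "conflicts": [list(c) for c in self.conflicts],
            "assigned": dict(sorted(self.assigned.items())),
            "unassigned_tips": sorted(self.unassigned_tips),
        }


def propagate_labels(labeled: LabeledTree, support_threshold: float = 95.0) -> PropagationResult:
    """Apply the MRCA/clade rule to every strategy present in the labels.

    A strategy with a single labeled tip has that tip as its MRCA and never
    propagates beyond itself.  Input labels are never overwritten; because
    clades on one tree are laminar, a propagated tip can belong to at most
    one pure supported clade, which is asserted.
    """
    if not labeled.labels:
        raise ValueError("no labeled tips; nothing to propagate")
    tree = labeled.tree
    labels = labeled.labels
    strategies = sorted(set(labels.values()))
    clades: dict[str, StrategyClade] = {}
    conflicts: list[tuple[str, str, str]] = []
    assigned: dict[str, str] = {}

    for strat in strategies:
        strat_tips = {t for t, s in labels.items() if s == strat}
        node = mrca(tree, strat_tips)
        clade_tips = _leaf_names(node)
        intruders = {
            t: labels[t] for t in clade_tips if t in labels and labels[t] != strat
        }
        support = labeled.support(node)
        is_pure = not intruders
        supported = node.is_leaf() or support >= support_threshold
        clade = StrategyClade(
            strategy=strat,
            mrca_is_tip=node.is_leaf(),
            support=support,
            clade_tips=clade_tips,
            labeled_tips=strat_tips,
            is_pure=is_pure,
            supported=supported,
        )
        if not is_pure:
            for tip, lab in sorted(intruders.items()):
                conflicts.append((strat, tip, lab))
        elif supported and not node.is_leaf():
            clade.propagated_tips = clade_tips - set(labels)
            for tip in clade.propagated_tips:
                assert tip not in assigned, "laminar clades cannot double-assign"
                assigned[tip] = strat
        clades[strat] = clade

    all_tips = set(labeled.tip_names)
    unassigned = all_tips - set(labels) - set(assigned)
    return PropagationResult(
        clades=clades, conflicts=conflicts, assigned=assigned, unassigned_tips=unassigned
    )


def clade_report(result: PropagationResult, labeled: LabeledTree) -> pd.DataFrame:
    """Per-strategy summary table plus the count of unassigned tips.

    Columns: strategy, monophyletic, mrca_support, clade_size, n_labeled,
    n_propagated, intruders.  The unassigned count is stored in
    ``df.attrs['n_unassigned']``.
    """
    rows = []
    for strat, clade in sorted(result.clades.items()):
        intruders = sorted(t for s, t, _ in result.conflicts if s == strat)
        rows.append(
            {
                "strategy": strat,
                "monophyletic": clade.is_pure,
                "mrca_support": clade.support,
                "clade_size": len(clade.clade_tips),
                "n_labeled": len(clade.labeled_tips),
                "n_propagated": len(clade.propagated_tips),
                "intruders": ",".join(intruders),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_unassigned"] = len(result.unassigned_tips)
    return df
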