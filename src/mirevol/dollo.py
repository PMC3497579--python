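"""Dollo-parsimony reconstruction of family gains and losses.

Under Dollo parsimony a family is gained exactly once and may be lost any
number of times afterwards. On a rooted tree this makes the reconstruction
closed-form: the gain node is the MRCA of the presence leaves, and the
minimal losses are the maximal subtrees below the gain node that contain
no presence leaf. Node statistics (age as root distance, gains per node,
cumulative gains, context fractions among gained families) feed the
summary figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ProfileMatrix, SpeciesTree

__all__ = [
    "GainLossReconstruction",
    "dollo_reconstruct",
    "node_statistics",
    "annotate_tree_figure",
]


@dataclass
class GainLossReconstruction:
    """Per-family gain node and maximal loss edges (edge = its child node)."""

    tree: SpeciesTree
    gain_node: dict[str, int] = field(default_factory=dict)
    loss_edges: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def loss_count(self, family: str) -> int:
        return len(self.loss_edges[family])

    @property
    def families(self) -> list[str]:
        return sorted(self.gain_node)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam in self.families:
            rows.append(
                {
                    "family": fam,
                    "gain_node": self.gain_node[fam],
                    "loss_edges": ",".join(map(str, self.loss_edges[fam])),
                    "n_losses": self.loss_count(fam),
                }
            )
        return pd.DataFrame(rows).set_index("family")


def dollo_reconstruct(
    presence: ProfileMatrix, tree: SpeciesTree
) -> GainLossReconstruction:
    """Reconstruct gains and minimal losses for every family.

    The gain node is the MRCA of all presence leaves; loss edges are the
    maximal subtrees below it with zero presence leaves. This loss set is
    provably minimal among single-gain scenarios. Families with no presence
    leaf are rejected.
    """
    presence = presence.to_presence()
    presence.check_against_tree(tree)
    rec = GainLossReconstruction(tree=tree)
    # per-node presence-leaf counts per family, vectorised over families
    data = presence.data
    for fam in data.index:
        present = [sp for sp in data.columns if data.loc[fam, sp] == 1]
        if not present:
            raise ValueError(f"family {fam} is absent from every species")
        gain = tree.mrca(present)
        present_ids = {tree.leaf_id(sp) for sp in present}
        _, losses = _maximal_empty_subtrees(tree, gain, present_ids)
        rec.gain_node[fam] = gain
        rec.loss_edges[fam] = tuple(sorted(losses))
    return rec


def _maximal_empty_subtrees(
    tree: SpeciesTree, nid: int, present_ids: set[int]
) -> tuple[bool, list[int]]:
    """Post-order walk: (subtree has a presence leaf, maximal empty subtrees).

    A child subtree with no presence leaf is recorded as one loss edge and
    not descended into further, so the returned edges are maximal."""
    node = tree.nodes[nid]
    if node.is_leaf:
        return nid in present_ids, []
    results = [_maximal_empty_subtrees(tree, c, present_ids)
               for c in node.children]
    has = any(r[0] for r in results)
    if not has:
        return False, []
    losses: list[int] = []
    for (child_has, child_losses), c in zip(results, node.children):
        if not child_has:
            losses.append(c)
        else:
            losses.extend(child_losses)
    return True, losses


@dataclass
class NodeStats:
    """Per-node summary: age, gains, cumulative gains, context fractions."""

    table: pd.DataFrame  # indexed by node id

    def row(self, node_id: int) -> pd.Series:
        return self.table.loc[node_id]


def node_statistics(
    rec: GainLossReconstruction,
    tree: SpeciesTree,
    family_intronic: dict[str, bool] | None = None,
    family_clustered: dict[str, bool] | None = None,
) -> NodeStats:
    """Summarise the reconstruction per tree node.

    ``family_intronic`` / ``family_clustered`` flag each family by the
    majority context of its present-day loci (see
    :func:`mirevol.profiles.family_context_flags`); when omitted the
    percentage columns are NaN. Age is the branch-length distance from the
    root; cumulative gains at a node count families gained at the node or
    any ancestor.
    """
    gains_at: dict[int, list[str]] = {n.id: [] for n in tree.nodes}
    for fam, g in rec.gain_node.items():
        gains_at[g].append(fam)
    losses_at: dict[int, int] = {n.id: 0 for n in tree.nodes}
    for fam, edges in rec.loss_edges.items():
        for e in edges:
            losses_at[e] += 1
    rows = []
    for node in tree.preorder():
        nid = node.id
        fams = gains_at[nid]
        cumulative = sum(
            len(gains_at[a]) for a in tree.path_to_root(nid)
        )
        pct_intronic = np.nan
        pct_clustered = np.nan
        if family_intronic is not None and fams:
            pct_intronic = 100.0 * np.mean(
                [bool(family_intronic.get(f, False)) for f in fams]
            )
        if family_clustered is not None and fams:
            pct_clustered = 100.0 * np.mean(
                [bool(family_clustered.get(f, False)) for f in fams]
            )
        rows.append(
            {
                "node": nid,
                "label": node.label or "",
                "is_leaf": node.is_leaf,
                "age": tree.node_age(nid),
                "n_gains": len(fams),
                "cumulative_gains": cumulative,
                "n_losses": losses_at[nid],
                "net_balance": len(fams) - losses_at[nid],
                "pct_intronic": pct_intronic,
                "pct_clustered": pct_clustered,
            }
        )
    table = pd.DataFrame(rows).set_index("node")
    return NodeStats(table)


def annotate_tree_figure(
    stats: NodeStats,
    tree: SpeciesTree,
    rec: GainLossReconstruction,
    svg_path=None,
    balance_decile: float = 0.10,
) -> pd.DataFrame:
    """Render the gain/loss tree and return the per-branch annotation table.

    Branch width is proportional to the number of families present among
    the leaves of the branch; branches in the top/bottom ``balance_decile``
    of net gain-loss balance are coloured red (gain) / blue (loss) — a
    presentation threshold, not an inference. The numeric annotations are
    returned (and written alongside the SVG) so the figure is checkable.
    """
    presence_per_branch = {}
    for node in tree.nodes:
        leaves = tree.leaf_labels_under(node.id)
        n_fam = 0
        for fam, g in rec.gain_node.items():
            gained_leaves = tree.leaf_labels_under(g)
            lost = set()
            for e in rec.loss_edges[fam]:
                lost |= tree.leaf_labels_under(e)
            if (gained_leaves - lost) & leaves:
                n_fam += 1
        presence_per_branch[node.id] = n_fam
    tab = stats.table.copy()
    tab["families_among_leaves"] = [
        presence_per_branch[nid] for nid in tab.index
    ]
    balances = tab["net_balance"].to_numpy(dtype=float)
    lo = np.quantile(balances, balance_decile)
    hi = np.quantile(balances, 1.0 - balance_decile)
    tab["color"] = [
        "red" if b >= hi and b > 0 else ("blue" if b <= lo and b < 0 else "black")
        for b in balances
    ]
    if svg_path is not None:
        _render_tree_svg(tree, tab, svg_path)
    return tab


def _render_tree_svg(tree: SpeciesTree, tab: pd.DataFrame, svg_path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    with plt.rc_context({"svg.hashsalt": "mirevol"}):
        fig, ax = plt.subplots(figsize=(8, 0.4 * len(tree.leaves) + 1))
        ycoord: dict[int, float] = {}
        leaves = sorted(tree.leaves, key=lambda n: n.label)
        for i, leaf in enumerate(leaves):
            ycoord[leaf.id] = float(i)
        for node in tree.postorder():
            if not node.is_leaf:
                ycoord[node.id] = np.mean([ycoord[c] for c in node.children])
        maxfam = max(tab["families_among_leaves"].max(), 1)
        for node in tree.nodes:
            x1 = tree.node_age(node.id)
            x0 = x1 - node.length
            width = 0.5 + 3.0 * tab.loc[node.id, "families_among_leaves"] / maxfam
            color = tab.loc[node.id, "color"]
            ax.plot([x0, x1], [ycoord[node.id]] * 2, lw=width, color=color,
                    solid_capstyle="butt")
            if not node.is_leaf:
                ys = [ycoord[c] for c in node.children]
                ax.plot([x1, x1], [min(ys), max(ys)], lw=0.8, color="grey")
            else:
                ax.text(x1, ycoord[node.id], " " + node.label, va="center",
                        fontsize=8)
        ax.set_xlabel("distance from root (subst./site)")
        ax.set_yticks([])
        fig.tight_layout()
        fig.savefig(svg_path, format="svg", metadata={"Date": None})
        plt.close(fig)
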