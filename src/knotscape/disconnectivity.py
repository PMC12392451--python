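"""Disconnectivity graphs: superbasin trees and SVG rendering.

Branches terminate at the potential energies of local minima and merge
at the lowest discretised energy level at which the minima can
interconvert through transition states below that level.  Leaves can be
coloured by any per-minimum scalar (occupation-gradient sign sets,
MFPT, winding number, writhe) for landscape annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["DisconnectivityTree", "build_tree", "color_tree", "render"]


@dataclass
class TreeNode:
    level: int              # 0 = top level (E_max)
    energy: float           # level energy at creation
    members: frozenset      # minima in this superbasin
    parent: int | None
    children: list = field(default_factory=list)
    split_energy: float | None = None  # lowest level at which the basin
    #                                    is still one component (the
    #                                    merge energy of its children)


@dataclass
class DisconnectivityTree:
    nodes: list            # TreeNode, index = node id; 0 is the root
    delta_e: float
    e_max: float
    minima_energy: dict    # minimum id -> V
    leaf_colors: dict = field(default_factory=dict)

    def leaf_ids(self):
        return sorted(self.minima_energy)

    def n_leaves(self) -> int:
        return len(self.minima_energy)


def build_tree(ktn, delta_e=None, e_max=None, n_lowest: int = 3000) -> DisconnectivityTree:
    """Union-find sweep over descending energy levels.

    Only the ``n_lowest`` lowest minima connected to the global minimum
    are included.  ``delta_e`` defaults to (E_max - V_global)/100.
    """
    g = ktn.graph()
    global_min = min(ktn.minima, key=lambda i: ktn.minima[i].energy)
    comp = nx.node_connected_component(g, global_min)
    included = sorted(comp, key=lambda i: ktn.minima[i].energy)[:n_lowest]
    inc = set(included)
    edges = [
        (ts.min_a, ts.min_b, ts.energy)
        for ts in ktn.transition_states.values()
        if ts.min_a in inc and ts.min_b in inc and ts.min_a != ts.min_b
    ]
    energies = {i: ktn.minima[i].energy for i in included}
    v_global = energies[global_min]
    if e_max is None:
        top = max((e for _, _, e in edges), default=v_global)
        e_max = top + 0.05 * max(top - v_global, 1.0)
    if delta_e is None:
        delta_e = (e_max - v_global) / 100.0
    if delta_e <= 0:
        raise ValueError("delta_e must be positive")

    nodes: list[TreeNode] = [
        TreeNode(level=0, energy=e_max, members=frozenset(included), parent=None)
    ]
    # a minimum with V above the current level can have no TS edge at or
    # below it (TS energy >= V), so it splits off as a singleton
    # automatically; singleton superbasins stop descending and their
    # branch is drawn down to V at render time.
    frontier = {0: nodes[0]} if len(included) > 1 else {}
    level = 0
    while frontier:
        level += 1
        e_level = e_max - level * delta_e
        new_frontier = {}
        for nid, node in frontier.items():
            sub = nx.Graph()
            sub.add_nodes_from(node.members)
            sub.add_edges_from(
                (a, b) for a, b, e in edges
                if e <= e_level and a in node.members and b in node.members
            )
            comps = list(nx.connected_components(sub))
            if len(comps) == 1:
                node.split_energy = e_level  # still one basin here
                continue  # unchanged superbasin: keep the same node
            if node.split_energy is None:
                node.split_energy = node.energy  # split right away
            for cc in comps:
                child = TreeNode(
                    level=level, energy=e_level, members=frozenset(cc), parent=nid
                )
                nodes.append(child)
                cid = len(nodes) - 1
                node.children.append(cid)
                if len(cc) > 1:
                    new_frontier[cid] = child
        for nid, node in frontier.items():
            if not node.children:
                new_frontier[nid] = node  # still descending as a block
        frontier = {
            nid: nd for nid, nd in new_frontier.items() if len(nd.members) > 1
        }
        if level > 100000:
            raise RuntimeError("level sweep failed to terminate")
    return DisconnectivityTree(
        nodes=nodes, delta_e=delta_e, e_max=e_max, minima_energy=energies
    )


def color_tree(tree: DisconnectivityTree, values: dict, palette=None) -> DisconnectivityTree:
    """Attach leaf colours from per-minimum scalars (linear red->blue
    map) or from sign labels ('+'/'-' -> blue/red).

    Missing leaves raise with the offending ids listed."""
    missing = [i for i in tree.leaf_ids() if i not in values]
    if missing:
        raise KeyError(f"values missing for leaves: {missing}")
    vals = {i: values[i] for i in tree.leaf_ids()}
    if all(isinstance(v, str) for v in vals.values()):
        colors = {
            i: ("#d62728" if v == "-" else "#1f77b4") for i, v in vals.items()
        }
    else:
        arr = np.array([float(v) for v in vals.values()])
        finite = arr[np.isfinite(arr)]
        lo = finite.min() if len(finite) else 0.0
        hi = finite.max() if len(finite) else 1.0
        span = hi - lo if hi > lo else 1.0
        colors = {}
        for i, v in vals.items():
            x = (min(max(float(v), lo), hi) - lo) / span
            r = int(round(255 * (1 - x)))
            b = int(round(255 * x))
            colors[i] = f"#{r:02x}40{b:02x}"
    tree.leaf_colors = colors
    return tree


def _layout(tree: DisconnectivityTree) -> dict:
    """Deterministic x positions: recursive slot allocation by subtree
    leaf count, with the lowest-energy child centred in each funnel."""
    xpos: dict[int, float] = {}

    def min_energy(node_id):
        return min(tree.minima_energy[m] for m in tree.nodes[node_id].members)

    def place(node_id, x0, x1):
        node = tree.nodes[node_id]
        xpos[node_id] = 0.5 * (x0 + x1)
        kids = list(node.children)
        if not kids:
            return
        # lowest-energy child in the middle, others alternating outwards
        kids.sort(key=min_energy)
        ordered = [None] * len(kids)
        mid = len(kids) // 2
        order_slots = sorted(range(len(kids)), key=lambda s: abs(s - mid))
        for child, slot in zip(kids, order_slots):
            ordered[slot] = child
        widths = np.array([len(tree.nodes[c].members) for c in ordered], dtype=float)
        widths /= widths.sum()
        edges_x = x0 + (x1 - x0) * np.concatenate([[0.0], np.cumsum(widths)])
        for k, child in enumerate(ordered):
            place(child, edges_x[k], edges_x[k + 1])

    place(0, 0.0, 1.0)
    return xpos


def render(tree: DisconnectivityTree, path) -> None:
    """Write the tree as a deterministic standalone SVG."""
    xpos = _layout(tree)
    width, height = 800.0, 600.0
    margin = 40.0
    e_lo = min(tree.minima_energy.values())
    e_hi = tree.e_max
    span = max(e_hi - e_lo, 1e-12)

    def sx(x):
        return margin + x * (width - 2 * margin)

    def sy(e):
        return margin + (e_hi - e) / span * (height - 2 * margin)

    def node_bottom(node):
        # forks happen at the split energy; leaves run down to V_gamma
        if node.children:
            return node.split_energy
        if len(node.members) == 1:
            (m,) = node.members
            return tree.minima_energy[m]
        return node.split_energy if node.split_energy is not None else node.energy

    lines = []
    for nid, node in enumerate(tree.nodes):
        color = "#000000"
        if len(node.members) == 1 and not node.children:
            (m,) = node.members
            color = tree.leaf_colors.get(m, "#000000")
        top = (
            tree.nodes[node.parent].split_energy
            if node.parent is not None
            else tree.e_max
        )
        x_top = sx(xpos[node.parent]) if node.parent is not None else sx(xpos[nid])
        lines.append(
            f'<line x1="{x_top:.2f}" y1="{sy(top):.2f}" '
            f'x2="{sx(xpos[nid]):.2f}" y2="{sy(node_bottom(node)):.2f}" '
            f'stroke="{color}" stroke-width="1.2"/>'
        )
    svg = (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" viewBox="0 0 {width:.0f} {height:.0f}">\n'
        + "\n".join(lines)
        + "\n</svg>\n"
    )
    with open(path, "w") as fh:
        fh.write(svg)
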