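"""Disconnectivity graphs of potential- and free-energy landscapes.

At each of a descending ladder of energy thresholds (spacing delta_e),
the minima still mutually accessible through transition states below the
threshold form a superbasin; stacking the superbasins level by level
yields a tree whose leaves are individual minima (or free-energy groups)
hanging at their own energies.  Leaves can be coloured by any scalar
order parameter and the tree rendered to a deterministic SVG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DisconnectivityTree", "TreeNode", "build_tree", "color_tree",
           "render"]


@dataclass
class TreeNode:
    id: int
    level: int                 # index into tree.thresholds
    threshold: float
    members: frozenset
    parent: int | None = None


@dataclass
class DisconnectivityTree:
    """Superbasin hierarchy over descending thresholds."""

    thresholds: list[float]              # descending, spacing delta_e
    delta_e: float
    nodes: dict[int, TreeNode]
    leaf_values: dict[int, float]        # leaf id -> energy / free energy
    leaf_colors: dict[int, float] | None = None
    mode: str = "pe"

    @property
    def leaf_count(self) -> int:
        return len(self.leaf_values)

    def roots(self) -> list[TreeNode]:
        return [n for n in self.nodes.values() if n.parent is None]

    def children(self, node_id: int) -> list[TreeNode]:
        ch = [n for n in self.nodes.values() if n.parent == node_id]
        ch.sort(key=lambda n: (min(self.leaf_values[m] for m in n.members),
                               min(n.members)))
        return ch

    def merge_level(self, leaf_a, leaf_b) -> float:
        """Lowest threshold at which two leaves share a superbasin."""
        best = None
        for n in self.nodes.values():
            if leaf_a in n.members and leaf_b in n.members:
                if best is None or n.threshold < best:
                    best = n.threshold
        if best is None:
            raise ValueError(f"leaves {leaf_a}, {leaf_b} never merge")
        return best


def _components(leaves: list, edges: list[tuple], threshold: float):
    """Connected components of the sub-network below ``threshold``."""
    present = [l for l in leaves if True]
    parent = {l: l for l in present}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, e in edges:
        if e < threshold and a in parent and b in parent:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    comps: dict = {}
    for l in present:
        comps.setdefault(find(l), set()).add(l)
    return [frozenset(c) for c in comps.values()]


def _as_leaf_edge_lists(source):
    """Adapter: KTN or GroupedNetwork -> (leaves, edges, mode)."""
    if hasattr(source, "transition_states"):   # KTN
        leaves = {mid: m.energy for mid, m in source.minima.items()}
        edges = [(ts.minus_min_id, ts.plus_min_id, ts.energy)
                 for ts in source.transition_states.values()
                 if ts.minus_min_id != ts.plus_min_id]
        return leaves, edges, "pe"
    if hasattr(source, "groups"):              # GroupedNetwork
        leaves = {gi: g.free_energy for gi, g in enumerate(source.groups)}
        edges = sorted((min(p), max(p), f)
                       for p, f in source.edge_free_energies.items())
        return leaves, edges, "fe"
    raise TypeError(f"cannot build a disconnectivity tree from {type(source)!r}")


def build_tree(source, delta_e: float | None = None,
               top: float | None = None) -> DisconnectivityTree:
    """Build the superbasin tree of a network.

    ``delta_e`` defaults to (span of barrier + minimum energies) / 40;
    ``top`` defaults to one spacing above the highest barrier.
    """
    leaves, edges, mode = _as_leaf_edge_lists(source)
    if not leaves:
        raise ValueError("empty network")
    e_min = min(leaves.values())
    e_high = max([e for (_, _, e) in edges], default=max(leaves.values()))
    e_high = max(e_high, max(leaves.values()))
    if delta_e is None:
        span = e_high - e_min
        delta_e = span / 40.0 if span > 0 else 1.0
    if delta_e <= 0:
        raise ValueError("delta_e must be positive")
    if top is None:
        top = e_high + delta_e
    n_levels = max(1, int(np.ceil((top - e_min) / delta_e)))
    thresholds = [top - k * delta_e for k in range(n_levels)]
    if thresholds[-1] <= e_min:  # keep every leaf below the lowest level
        thresholds = thresholds[:-1] or [top]
    leaf_ids = sorted(leaves)
    nodes: dict[int, TreeNode] = {}
    next_id = 0
    prev_level: dict[frozenset, int] = {}
    for li, L in enumerate(thresholds):
        comps = _components(leaf_ids, edges, L)
        comps.sort(key=lambda c: (min(leaves[m] for m in c), min(c)))
        cur: dict[frozenset, int] = {}
        for comp in comps:
            parent = None
            for pmembers, pid in prev_level.items():
                if comp <= pmembers:
                    parent = pid
                    break
            node = TreeNode(id=next_id, level=li, threshold=L,
                            members=comp, parent=parent)
            nodes[next_id] = node
            cur[comp] = next_id
            next_id += 1
        prev_level = cur
    return DisconnectivityTree(thresholds=thresholds, delta_e=float(delta_e),
                               nodes=nodes, leaf_values=dict(leaves),
                               mode=mode)


def color_tree(tree: DisconnectivityTree, values: dict,
               scale: tuple[float, float]) -> DisconnectivityTree:
    """Attach normalised leaf colours (linear on ``scale``, clipped)."""
    missing = [l for l in tree.leaf_values if l not in values]
    if missing:
        raise ValueError(f"missing colour values for leaves {sorted(missing)}")
    lo, hi = scale
    if hi == lo:
        tree.leaf_colors = {l: 0.5 for l in tree.leaf_values}
        return tree
    tree.leaf_colors = {
        l: float(np.clip((values[l] - lo) / (hi - lo), 0.0, 1.0))
        for l in tree.leaf_values}
    return tree


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _colormap_rgb(t: float) -> str:
    """red (0) -> green (0.5) -> blue (1)."""
    t = float(np.clip(t, 0.0, 1.0))
    if t <= 0.5:
        u = t / 0.5
        r, g, b = 1.0 - u, u, 0.0
    else:
        u = (t - 0.5) / 0.5
        r, g, b = 0.0, 1.0 - u, u
    return f"#{int(round(255 * r)):02x}{int(round(255 * g)):02x}" \
           f"{int(round(255 * b)):02x}"


@dataclass
class _Branch:
    """Compressed chain of lattice nodes with identical membership."""

    members: frozenset
    top: float                  # threshold where this branch hangs
    children: list = field(default_factory=list)
    leaf: int | None = None
    x: float = 0.0


def _compress(tree: DisconnectivityTree) -> list[_Branch]:
    def descend(node: TreeNode, top_threshold: float) -> _Branch:
        cur = node
        while True:
            kids = tree.children(cur.id)
            if len(kids) == 1 and kids[0].members == cur.members:
                cur = kids[0]
                continue
            break
        br = _Branch(members=cur.members, top=top_threshold)
        kids = tree.children(cur.id)
        if not kids:
            if len(cur.members) == 1:
                br.leaf = next(iter(cur.members))
            return br
        for k in kids:
            br.children.append(descend(k, cur.threshold - tree.delta_e))
        covered = frozenset().union(*[k.members for k in kids]) if kids \
            else frozenset()
        for m in sorted(cur.members - covered):
            lb = _Branch(members=frozenset([m]),
                         top=cur.threshold - tree.delta_e, leaf=m)
            br.children.append(lb)
        return br

    roots = sorted(tree.roots(),
                   key=lambda n: (min(tree.leaf_values[m] for m in n.members),
                                  min(n.members)))
    return [descend(r, r.threshold) for r in roots]


def _center_out(items: list) -> list:
    """Place the first (lowest-energy) item centrally, rest alternating."""
    return items[::2][::-1] + items[1::2]


def _layout(branches: list[_Branch], x0: float, x1: float,
            leaf_values: dict) -> None:
    for br in branches:
        if br.leaf is not None and not br.children:
            br.x = 0.5 * (x0 + x1)
            continue
        kids = sorted(br.children,
                      key=lambda c: (min(leaf_values[m] for m in c.members),
                                     min(c.members)))
        kids = _center_out(kids)
        total = sum(len(c.members) for c in kids)
        xs = x0
        for c in kids:
            w = (x1 - x0) * len(c.members) / total
            _layout([c], xs, xs + w, leaf_values)
            xs += w
        br.x = float(np.mean([c.x for c in br.children]))


def render(tree: DisconnectivityTree, out_path, style: dict | None = None
           ) -> str:
    """Write a deterministic SVG of the tree; returns the SVG text.

    Vertical axis is energy (or free energy); each leaf ends in a
    terminal stem at its own energy; branches join at the quantized merge
    thresholds.  The energy-to-pixel affine transform is declared in the
    <desc> element so positions can be mapped back to energies.
    """
    style = dict(style or {})
    width = style.get("width", 640.0)
    height = style.get("height", 480.0)
    margin = style.get("margin", 50.0)
    stroke = style.get("stroke_width", 1.5)
    label = style.get("label",
                      "free energy" if tree.mode == "fe" else "energy")
    unit = style.get("unit", "kcal/mol")
    e_top = tree.thresholds[0]
    e_bot = min(tree.leaf_values.values())
    if e_top == e_bot:
        e_top = e_bot + 1.0
    y_top, y_bot = margin, height - margin

    def y_of(e: float) -> float:
        return y_bot + (e - e_bot) * (y_top - y_bot) / (e_top - e_bot)

    branches = _compress(tree)
    _layout(branches, margin, width - margin, tree.leaf_values)

    lines: list[str] = []

    def emit(br: _Branch) -> None:
        if br.leaf is not None and not br.children:
            color = "#000000"
            if tree.leaf_colors is not None:
                color = _colormap_rgb(tree.leaf_colors[br.leaf])
            lines.append(
                f'<line class="stem" data-leaf="{br.leaf}" '
                f'x1="{br.x:.3f}" y1="{y_of(br.top):.3f}" '
                f'x2="{br.x:.3f}" y2="{y_of(tree.leaf_values[br.leaf]):.3f}" '
                f'stroke="{color}" stroke-width="{stroke:.3f}"/>')
            return
        join_y = y_of(br.top - tree.delta_e)
        xs = sorted(c.x for c in br.children)
        lines.append(
            f'<line class="join" x1="{xs[0]:.3f}" y1="{join_y:.3f}" '
            f'x2="{xs[-1]:.3f}" y2="{join_y:.3f}" '
            f'stroke="#000000" stroke-width="{stroke:.3f}"/>')
        lines.append(
            f'<line class="branch" x1="{br.x:.3f}" y1="{y_of(br.top):.3f}" '
            f'x2="{br.x:.3f}" y2="{join_y:.3f}" '
            f'stroke="#000000" stroke-width="{stroke:.3f}"/>')
        for c in sorted(br.children, key=lambda c: (c.x, min(c.members))):
            if not (c.leaf is not None and not c.children):
                lines.append(
                    f'<line class="drop" x1="{c.x:.3f}" y1="{join_y:.3f}" '
                    f'x2="{c.x:.3f}" y2="{y_of(c.top):.3f}" '
                    f'stroke="#000000" stroke-width="{stroke:.3f}"/>')
            emit(c)

    for br in branches:
        emit(br)

    # simple energy axis with ~8 ticks
    ticks = np.linspace(e_bot, e_top, 9)
    axis = [f'<line x1="{margin * 0.6:.3f}" y1="{y_of(e_bot):.3f}" '
            f'x2="{margin * 0.6:.3f}" y2="{y_of(e_top):.3f}" '
            f'stroke="#000000" stroke-width="1.000"/>']
    for t in ticks:
        axis.append(
            f'<line x1="{margin * 0.45:.3f}" y1="{y_of(t):.3f}" '
            f'x2="{margin * 0.6:.3f}" y2="{y_of(t):.3f}" '
            f'stroke="#000000" stroke-width="1.000"/>')
        axis.append(
            f'<text x="{margin * 0.4:.3f}" y="{y_of(t) + 3.0:.3f}" '
            f'font-size="9" text-anchor="end">{t:.2f}</text>')
    axis.append(
        f'<text x="{margin * 0.25:.3f}" y="{margin * 0.6:.3f}" '
        f'font-size="11">{label} ({unit})</text>')

    desc = (f"axis-transform: e_bot={e_bot!r} e_top={e_top!r} "
            f"y_bot={y_bot!r} y_top={y_top!r}")
    svg = "\n".join(
        [f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:g}" '
         f'height="{height:g}" viewBox="0 0 {width:g} {height:g}">',
         f"<desc>{desc}</desc>"] + axis + lines + ["</svg>", ""])
    if out_path is not None:
        with open(str(out_path), "w") as fh:
            fh.write(svg)
    return svg
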