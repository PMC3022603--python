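"""Graph exports (GraphML, DOT) and SVG renderings of haplowebs.

Drawing conventions follow the published figures: observed haplotypes are
circles with diameter proportional to the number of individuals harbouring
them, median vectors are small unlabelled points, co-occurrence links are
curves with stroke width proportional to the number of heterozygotes, allele
pools are enclosed in dashed convex hulls, and reconciliation drawings give
each bipartition a stroke width proportional to the number of supporting
datasets.  Diameter (not area) is linear in the count by default; an area
mode is available for perceptually linear scaling.

All renderings are pure functions of their inputs and the layout seed:
identical calls produce byte-identical SVG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from xml.etree import ElementTree as ET

import networkx as nx
import numpy as np
from scipy.spatial import ConvexHull

from .congruence import SupportTable, partition_meet
from .errors import ConfigError
from .webffr import Haploweb, Partition

SVG_NS = "http://www.w3.org/2000/svg"


@dataclass
class StyleSpec:
    """Scale factors for the proportional drawing conventions."""

    diameter_per_count: float = 6.0
    min_node_diameter: float = 8.0
    max_node_diameter: float = 72.0
    curve_width_per_heterozygote: float = 1.5
    bipartition_line_width_per_dataset: float = 2.0
    pool_dash: str = "6,4"
    layout_seed: int = 0
    area_mode: bool = False  # scale area, not diameter, linearly in count

    def __post_init__(self):
        for name in (
            "diameter_per_count",
            "min_node_diameter",
            "max_node_diameter",
            "curve_width_per_heterozygote",
            "bipartition_line_width_per_dataset",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"style scale factor {name} must be > 0")

    def node_diameter(self, count: int) -> float:
        d = self.diameter_per_count * (math.sqrt(count) if self.area_mode else count)
        return min(max(d, self.min_node_diameter), self.max_node_diameter)


def _web_multigraph(web: Haploweb) -> nx.MultiGraph:
    g = nx.MultiGraph()
    pool_of = web.pool_of
    for nid, node in web.network.nodes.items():
        g.add_node(
            nid,
            hap_id=node.hap_id or "",
            count=int(node.count),
            pool=int(pool_of.get(node.hap_id, -1)) if node.hap_id else -1,
            observed=node.observed,
            sequence=node.sequence,
        )
    for e in web.network.edges:
        g.add_edge(
            e.u,
            e.v,
            kind="network",
            length=int(e.length),
            positions=",".join(map(str, e.positions)),
        )
    for link in web.links:
        g.add_edge(link.hap_u, link.hap_v, kind="cooccurrence", weight=int(link.weight))
    return g


def export_graphml(web: Haploweb, path: str | Path) -> None:
    nx.write_graphml(_web_multigraph(web), str(path))


def export_dot(web: Haploweb, path: str | Path) -> None:
    """Minimal hand-written DOT: solid network edges, dashed link edges."""
    lines = [f'graph "{web.network.marker}" {{']
    for nid, data in sorted(_web_multigraph(web).nodes(data=True)):
        shape = "circle" if data["observed"] else "point"
        lines.append(
            f'  "{nid}" [shape={shape}, label="{data["hap_id"]}", '
            f'count={data["count"]}, pool={data["pool"]}];'
        )
    for e in web.network.edges:
        lines.append(f'  "{e.u}" -- "{e.v}" [label="{e.length}"];')
    for link in web.links:
        lines.append(
            f'  "{link.hap_u}" -- "{link.hap_v}" '
            f"[style=dashed, penwidth={link.weight}];"
        )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def _layout(g: nx.Graph, seed: int, scale: float = 240.0) -> dict[str, tuple[float, float]]:
    pos = nx.spring_layout(g, seed=seed, scale=scale)
    return {n: (float(x) + 300.0, float(y) + 300.0) for n, (x, y) in pos.items()}


def _svg_root(width: int = 600, height: int = 600) -> ET.Element:
    return ET.Element(
        "svg",
        {
            "xmlns": SVG_NS,
            "width": str(width),
            "height": str(height),
            "viewBox": f"0 0 {width} {height}",
        },
    )


def _serialize(root: ET.Element) -> str:
    return '<?xml version="1.0" encoding="utf-8"?>\n' + ET.tostring(
        root, encoding="unicode"
    )


def render_haploweb_svg(web: Haploweb, style: StyleSpec | None = None) -> str:
    """Haploweb drawing: network underlay, co-occurrence curves, pool hulls."""
    style = style or StyleSpec()
    net = web.network
    g = nx.Graph()
    g.add_nodes_from(sorted(net.nodes))
    g.add_edges_from((e.u, e.v) for e in net.edges)
    pos = _layout(g, style.layout_seed)
    hap_pos = {net.nodes[n].hap_id: pos[n] for n in net.nodes if net.nodes[n].hap_id}
    radius = {
        n: (style.node_diameter(net.nodes[n].count) / 2 if net.nodes[n].observed else 3.0)
        for n in net.nodes
    }

    root = _svg_root()

    hulls = ET.SubElement(root, "g", {"class": "pools"})
    for i, pool in enumerate(web.pools):
        pts = []
        for h in sorted(pool):
            x, y = hap_pos[h]
            r = radius[h] + 6.0  # observed node ids coincide with hap ids
            for k in range(8):
                a = 2 * math.pi * k / 8
                pts.append((x + r * math.cos(a), y + r * math.sin(a)))
        arr = np.array(pts)
        hull = ConvexHull(arr)
        d = "M " + " L ".join(
            f"{_fmt(arr[v][0])} {_fmt(arr[v][1])}" for v in hull.vertices
        ) + " Z"
        ET.SubElement(
            hulls,
            "path",
            {
                "class": "pool",
                "data-pool": str(i),
                "d": d,
                "fill": "none",
                "stroke": "green",
                "stroke-dasharray": style.pool_dash,
            },
        )

    edges = ET.SubElement(root, "g", {"class": "network-edges"})
    for e in sorted(net.edges, key=lambda e: (e.u, e.v)):
        (x1, y1), (x2, y2) = pos[e.u], pos[e.v]
        line = ET.SubElement(
            edges,
            "line",
            {
                "class": "net-edge",
                "x1": _fmt(x1),
                "y1": _fmt(y1),
                "x2": _fmt(x2),
                "y2": _fmt(y2),
                "stroke": "black",
            },
        )
        line.set("data-length", str(e.length))
        label = ET.SubElement(
            edges,
            "text",
            {
                "x": _fmt((x1 + x2) / 2),
                "y": _fmt((y1 + y2) / 2),
                "fill": "red",
                "font-size": "8",
            },
        )
        label.text = ",".join(map(str, e.positions))

    curves = ET.SubElement(root, "g", {"class": "cooccurrence"})
    for link in sorted(web.links, key=lambda l: (l.hap_u, l.hap_v)):
        (x1, y1), (x2, y2) = hap_pos[link.hap_u], hap_pos[link.hap_v]
        mx, my = (x1 + x2) / 2, (y1 + y2) / 2
        dx, dy = x2 - x1, y2 - y1
        norm = math.hypot(dx, dy) or 1.0
        cx, cy = mx - dy / norm * 20.0, my + dx / norm * 20.0
        ET.SubElement(
            curves,
            "path",
            {
                "class": "link",
                "d": f"M {_fmt(x1)} {_fmt(y1)} Q {_fmt(cx)} {_fmt(cy)} "
                f"{_fmt(x2)} {_fmt(y2)}",
                "fill": "none",
                "stroke": "steelblue",
                "stroke-width": _fmt(style.curve_width_per_heterozygote * link.weight),
            },
        )

    nodes_g = ET.SubElement(root, "g", {"class": "nodes"})
    for nid in sorted(net.nodes):
        node = net.nodes[nid]
        x, y = pos[nid]
        circ = ET.SubElement(
            nodes_g,
            "circle",
            {
                "class": "observed" if node.observed else "median",
                "cx": _fmt(x),
                "cy": _fmt(y),
                "r": _fmt(radius[nid]),
                "fill": "white" if node.observed else "black",
                "stroke": "black",
            },
        )
        circ.set("data-count", str(node.count))
        if node.observed:
            t = ET.SubElement(
                nodes_g,
                "text",
                {"x": _fmt(x), "y": _fmt(y), "font-size": "9",
                 "text-anchor": "middle"},
            )
            t.text = node.hap_id
    return _serialize(root)


def render_reconciliation_svg(
    table: SupportTable,
    partitions: list[Partition],
    style: StyleSpec | None = None,
    threshold: float | None = None,
) -> str:
    """Bipartitions drawn as closed curves around groups of individuals.

    Individuals are laid out grouped by the meet of the input partitions;
    each support row becomes a rounded rectangle around its smaller side,
    stroke width proportional to the number of supporting datasets.  With
    ``threshold`` set, rows at or below it are omitted (the published
    50%-filtered variant of the figure).
    """
    style = style or StyleSpec()
    meet = partition_meet(partitions, label="meet") if partitions else None
    blocks = list(meet.blocks) if meet else [frozenset(table.universe)]

    rows = [
        r for r in table.rows
        if threshold is None or float(r.support) > threshold
    ]
    row_numbers = {id(r): i + 1 for i, r in enumerate(table.rows)}

    # order blocks by their membership signature across rows so that each
    # bipartition side covers a contiguous run of blocks where possible
    def signature(block: frozenset[str]) -> tuple:
        probe = min(block)
        return tuple(probe in r.bipartition.side for r in table.rows)

    blocks.sort(key=lambda b: (signature(b), -len(b), min(b)))

    col_w, dot_gap, top = 90.0, 14.0, 80.0
    positions: dict[str, tuple[float, float]] = {}
    for ci, block in enumerate(blocks):
        for ri, ind in enumerate(sorted(block)):
            positions[ind] = (60.0 + ci * col_w, top + ri * dot_gap)

    height = int(top + dot_gap * max(len(b) for b in blocks) + 120)
    width = int(120 + col_w * len(blocks))
    root = _svg_root(width, height)

    curves = ET.SubElement(root, "g", {"class": "bipartitions"})
    for r in rows:
        side = min(
            (r.bipartition.side, r.bipartition.complement),
            key=lambda s: (len(s), sorted(s)),
        )
        xs = [positions[i][0] for i in side]
        ys = [positions[i][1] for i in side]
        pad = 8.0 + 3.0 * len(r.supported_by)
        rect = ET.SubElement(
            curves,
            "rect",
            {
                "class": "bipartition",
                "x": _fmt(min(xs) - pad),
                "y": _fmt(min(ys) - pad),
                "width": _fmt(max(xs) - min(xs) + 2 * pad),
                "height": _fmt(max(ys) - min(ys) + 2 * pad),
                "rx": "12",
                "fill": "none",
                "stroke": "black",
                "stroke-width": _fmt(
                    style.bipartition_line_width_per_dataset * len(r.supported_by)
                ),
            },
        )
        rect.set("data-row", str(row_numbers[id(r)]))
        rect.set("data-support", str(r.percent))
        label = ET.SubElement(
            curves,
            "text",
            {
                "x": _fmt(min(xs) - pad),
                "y": _fmt(min(ys) - pad - 2),
                "font-size": "10",
            },
        )
        label.text = str(row_numbers[id(r)])

    dots = ET.SubElement(root, "g", {"class": "individuals"})
    for ind in sorted(positions):
        x, y = positions[ind]
        ET.SubElement(
            dots,
            "circle",
            {"class": "individual", "cx": _fmt(x), "cy": _fmt(y), "r": "3",
             "fill": "black"},
        )
    return _serialize(root)


def write_svg(svg: str, path: str | Path) -> None:
    Path(path).write_text(svg)
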