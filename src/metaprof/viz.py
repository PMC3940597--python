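"""Standalone SVG/HTML exports of taxonomic and functional profiles.

``layout_sample_view`` converts any hierarchical profile (taxonomic,
4-level SEED or GO-slim) into a multi-ring pie layout: wedge angles are
proportional to counts, sibling sweeps sum exactly to their parent sweep,
and the root ring covers 360 degrees.  Mass resolved at a parent but not
at any child is rendered as a gray "Unclassified" wedge, so every ring
conserves angle.  One layout engine serves both taxonomic and functional
views.

``export_html`` bundles one or more layouts into a single self-contained
HTML file (inline SVG + a small script for sample switching and
click-to-zoom; no network fetches).  ``export_global_view`` draws the
comparison table as a hierarchical tree with per-sample abundance bars at
each node.  All exports are byte-deterministic given identical inputs.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from math import cos, pi, sin
from pathlib import Path
from typing import Sequence

from .io_formats import RANKS, UNCLASSIFIED, stable_hash
from .compare import ComparisonTable

__all__ = ["Wedge", "WedgeLayout", "layout_sample_view", "export_html",
           "export_global_view"]

_GRAY = "#999999"


@dataclass(frozen=True)
class Wedge:
    path: tuple[str, ...]
    label: str
    depth: int            # ring index, 1-based
    start: float          # degrees
    sweep: float          # degrees
    color: str
    value: float          # tooltip count


@dataclass
class WedgeLayout:
    label: str
    wedges: list[Wedge] = field(default_factory=list)

    def at_depth(self, depth: int) -> list[Wedge]:
        return [w for w in self.wedges if w.depth == depth]

    def children_of(self, path: tuple[str, ...]) -> list[Wedge]:
        return [w for w in self.wedges
                if w.depth == len(path) + 1 and w.path[:len(path)] == path]


def _wedge_color(path: tuple[str, ...]) -> str:
    if path and path[-1] == UNCLASSIFIED:
        return _GRAY
    h = stable_hash(";".join(path))
    hue = h % 360
    sat = 45 + (h // 360) % 30
    lig = 45 + (h // (360 * 30)) % 20
    return f"hsl({hue},{sat}%,{lig}%)"


def _profile_hierarchy(profile) -> tuple[dict[tuple[str, ...], float], float]:
    """Extract {path: count} plus the root total from any profile object."""
    paths: dict[tuple[str, ...], float] = {}
    for _, path, count, _ in profile.rows():
        paths[tuple(path)] = paths.get(tuple(path), 0.0) + count
    # profiles that only report leaf paths (e.g. 4-level SEED) need their
    # parent prefixes synthesized by aggregation
    max_depth = max((len(p) for p in paths), default=0)
    for depth in range(max_depth, 1, -1):
        filled: dict[tuple[str, ...], float] = {}
        for p, c in paths.items():
            if len(p) == depth and p[:-1] not in paths:
                filled[p[:-1]] = filled.get(p[:-1], 0.0) + c
        paths.update(filled)
    total = getattr(profile, "total_assigned", None)
    if not total:
        total = sum(c for p, c in paths.items() if len(p) == 1)
    return paths, float(total)


def layout_sample_view(profile, label: str | None = None) -> WedgeLayout:
    """Multi-layer pie layout of a hierarchical profile.

    Angles are proportional to counts within each parent; the residual
    mass of a parent (count not covered by any child) becomes a gray
    Unclassified wedge, so sibling sweeps always sum to the parent sweep.
    An empty profile yields a single "no data" wedge.
    """
    label = label if label is not None else getattr(profile, "database",
                                                    getattr(profile, "engine", "sample"))
    layout = WedgeLayout(label=str(label))
    paths, total = _profile_hierarchy(profile)
    if not paths or total <= 0:
        layout.wedges.append(Wedge(path=("no data",), label="no data", depth=1,
                                   start=0.0, sweep=360.0, color=_GRAY, value=0.0))
        return layout
    max_depth = max(len(p) for p in paths)

    def place(parent: tuple[str, ...], parent_count: float,
              start: float, sweep: float, depth: int) -> None:
        if depth > max_depth:
            return
        children = sorted(
            ((p, c) for p, c in paths.items()
             if len(p) == depth and p[:depth - 1] == parent),
            key=lambda pc: (-pc[1], pc[0]),
        )
        covered = sum(c for _, c in children)
        residual = parent_count - covered
        entries = list(children)
        if residual > 1e-9 and parent:  # unresolved-below-parent mass
            entries.append((parent + (UNCLASSIFIED,), residual))
        elif residual > 1e-9 and not parent:
            entries.append(((UNCLASSIFIED,), residual))
        angle = start
        for p, c in entries:
            frac = c / parent_count if parent_count else 0.0
            w_sweep = sweep * frac
            layout.wedges.append(Wedge(
                path=p, label=p[-1], depth=depth, start=angle, sweep=w_sweep,
                color=_wedge_color(p), value=c,
            ))
            if p[-1] != UNCLASSIFIED:
                place(p, c, angle, w_sweep, depth + 1)
            angle += w_sweep

    place((), total, 0.0, 360.0, 1)
    return layout


# ---------------------------------------------------------------------------
# SVG rendering
# ---------------------------------------------------------------------------

_CX = _CY = 320.0
_R0 = 40.0
_RING = 42.0


def _annulus_path(start_deg: float, sweep_deg: float, r_in: float, r_out: float) -> str:
    if sweep_deg >= 360.0 - 1e-9:
        # full ring: two half-arcs to keep a valid path
        return (f"M {_CX + r_out:.4f} {_CY:.4f} "
                f"A {r_out:.4f} {r_out:.4f} 0 1 1 {_CX - r_out:.4f} {_CY:.4f} "
                f"A {r_out:.4f} {r_out:.4f} 0 1 1 {_CX + r_out:.4f} {_CY:.4f} Z "
                f"M {_CX + r_in:.4f} {_CY:.4f} "
                f"A {r_in:.4f} {r_in:.4f} 0 1 0 {_CX - r_in:.4f} {_CY:.4f} "
                f"A {r_in:.4f} {r_in:.4f} 0 1 0 {_CX + r_in:.4f} {_CY:.4f} Z")
    a0 = (start_deg - 90.0) * pi / 180.0
    a1 = (start_deg + sweep_deg - 90.0) * pi / 180.0
    large = 1 if sweep_deg > 180.0 else 0
    x0o, y0o = _CX + r_out * cos(a0), _CY + r_out * sin(a0)
    x1o, y1o = _CX + r_out * cos(a1), _CY + r_out * sin(a1)
    x0i, y0i = _CX + r_in * cos(a0), _CY + r_in * sin(a0)
    x1i, y1i = _CX + r_in * cos(a1), _CY + r_in * sin(a1)
    return (f"M {x0o:.4f} {y0o:.4f} "
            f"A {r_out:.4f} {r_out:.4f} 0 {large} 1 {x1o:.4f} {y1o:.4f} "
            f"L {x1i:.4f} {y1i:.4f} "
            f"A {r_in:.4f} {r_in:.4f} 0 {large} 0 {x0i:.4f} {y0i:.4f} Z")


def _render_layout_svg(layout: WedgeLayout, visible: bool) -> str:
    parts = [f'<g class="sample" id="sample-{html.escape(layout.label, quote=True)}" '
             f'style="display:{"inline" if visible else "none"}">']
    for w in sorted(layout.wedges, key=lambda w: (w.depth, w.start, w.path)):
        r_in = _R0 + (w.depth - 1) * _RING
        r_out = r_in + _RING
        d = _annulus_path(w.start, w.sweep, r_in, r_out)
        tip = f"{';'.join(w.path)} ({w.value:g})"
        parts.append(
            f'<path class="wedge" d="{d}" fill="{w.color}" stroke="#ffffff" '
            f'stroke-width="0.5"><title>{html.escape(tip)}</title></path>'
        )
    parts.append("</g>")
    return "\n".join(parts)


_HTML_SCRIPT = """//<![CDATA[
function showSample(label) {
  var groups = document.getElementsByClassName('sample');
  for (var i = 0; i < groups.length; i++) {
    groups[i].style.display = 'none';
  }
  var g = document.getElementById('sample-' + label);
  if (g) { g.style.display = 'inline'; }
}
function zoomTo(evt) {
  var svg = document.getElementById('ringview');
  var box = evt.target.getBBox();
  var pad = 10;
  svg.setAttribute('viewBox',
    (box.x - pad) + ' ' + (box.y - pad) + ' ' +
    (box.width + 2 * pad) + ' ' + (box.height + 2 * pad));
}
function resetZoom() {
  var svg = document.getElementById('ringview');
  svg.setAttribute('viewBox', '0 0 640 640');
}
window.addEventListener('load', function () {
  var wedges = document.getElementsByClassName('wedge');
  for (var i = 0; i < wedges.length; i++) {
    wedges[i].addEventListener('click', zoomTo);
  }
  document.getElementById('reset').addEventListener('click', resetZoom);
});
//]]>"""


def export_html(layouts: Sequence[WedgeLayout], metadata: dict,
                path: str | Path) -> None:
    """Write a standalone multi-sample ring-view HTML file.

    One SVG group per sample; buttons switch samples, clicking a wedge
    zooms to it.  The file is self-contained and byte-deterministic.
    """
    if not layouts:
        raise ValueError("export_html requires at least one layout")
    path = Path(path)
    meta_rows = "".join(
        f"<tr><td>{html.escape(str(k))}</td><td>{html.escape(str(metadata[k]))}</td></tr>"
        for k in sorted(metadata)
    )
    buttons = "".join(
        f'<button onclick="showSample(\'{html.escape(l.label, quote=True)}\')">'
        f"{html.escape(l.label)}</button>"
        for l in layouts
    )
    groups = "\n".join(_render_layout_svg(l, i == 0) for i, l in enumerate(layouts))
    doc = f"""<html xmlns="http://www.w3.org/1999/xhtml">
<head>
<meta charset="utf-8"/>
<title>metaprof sample view</title>
<style>
body {{ font-family: sans-serif; margin: 1em; }}
button {{ margin-right: 0.4em; }}
</style>
<script type="text/javascript">
{_HTML_SCRIPT}
</script>
</head>
<body>
<h1>Sample view</h1>
<div>{buttons}<button id="reset">reset zoom</button></div>
<svg id="ringview" xmlns="http://www.w3.org/2000/svg" width="640" height="640" viewBox="0 0 640 640">
{groups}
</svg>
<table>{meta_rows}</table>
</body>
</html>
"""
    path.write_text(doc, encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# global view
# ---------------------------------------------------------------------------

_SAMPLE_COLORS = ("#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
                  "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf")


def export_global_view(comparison: ComparisonTable, tree=None,
                       path: str | Path = "global_view.svg") -> None:
    """Tree-with-bars SVG of a multi-sample comparison table.

    Every distinct lineage prefix of the table becomes a tree node drawn
    with one bar per sample, bar length proportional to the sample's
    relative abundance summed over the node's subtree.  The optional
    *tree* argument is ignored when None (the hierarchy is derived from
    the lineage paths themselves).
    """
    path = Path(path)
    n_samples = len(comparison.sample_labels)
    # accumulate per-prefix abundance sums
    prefixes: dict[tuple[str, ...], list[float]] = {}
    for row_path, values in comparison.rows:
        for d in range(1, len(row_path) + 1):
            pref = row_path[:d]
            acc = prefixes.setdefault(pref, [0.0] * n_samples)
            for i, v in enumerate(values):
                acc[i] += v
    ordered = sorted(prefixes)
    leaves = [p for p in ordered
              if not any(q != p and q[:len(p)] == p for q in ordered)]
    y_of: dict[tuple[str, ...], float] = {}
    for i, leaf in enumerate(leaves):
        y_of[leaf] = 40.0 + i * 34.0
    for p in sorted(ordered, key=len, reverse=True):
        if p in y_of:
            continue
        child_ys = [y_of[q] for q in ordered if len(q) == len(p) + 1 and q[:len(p)] == p]
        y_of[p] = sum(child_ys) / len(child_ys)
    max_depth = max(len(p) for p in ordered) if ordered else 1
    x_step = 150.0
    bar_max = 60.0
    width = 80 + max_depth * x_step + bar_max + 220
    height = 80 + len(leaves) * 34.0

    elems: list[str] = []
    for p in ordered:
        x = 40.0 + (len(p) - 1) * x_step
        y = y_of[p]
        # connector to parent
        if len(p) > 1:
            px = 40.0 + (len(p) - 2) * x_step
            py = y_of[p[:-1]]
            elems.append(f'<path d="M {px:.2f} {py:.2f} L {px:.2f} {y:.2f} '
                         f'L {x:.2f} {y:.2f}" fill="none" stroke="#777777"/>')
    for p in ordered:
        x = 40.0 + (len(p) - 1) * x_step
        y = y_of[p]
        bars = []
        for i, v in enumerate(prefixes[p]):
            bw = bar_max * v
            by = y - 10 + i * (16.0 / max(1, n_samples))
            bh = 14.0 / max(1, n_samples)
            color = _SAMPLE_COLORS[i % len(_SAMPLE_COLORS)]
            bars.append(f'<rect x="{x + 6:.2f}" y="{by:.2f}" width="{bw:.4f}" '
                        f'height="{bh:.2f}" fill="{color}">'
                        f"<title>{html.escape(comparison.sample_labels[i])}: {v:.6f}</title></rect>")
        elems.append(
            f'<g class="node" data-path="{html.escape(";".join(p), quote=True)}">'
            f'<circle cx="{x:.2f}" cy="{y:.2f}" r="3" fill="#333333"/>'
            f'<text x="{x:.2f}" y="{y - 6:.2f}" font-size="10">{html.escape(p[-1])}</text>'
            + "".join(bars) + "</g>")
    legend = "".join(
        f'<g><rect x="{width - 200:.0f}" y="{20 + i * 16}" width="12" height="10" '
        f'fill="{_SAMPLE_COLORS[i % len(_SAMPLE_COLORS)]}"/>'
        f'<text x="{width - 182:.0f}" y="{29 + i * 16}" font-size="10">'
        f"{html.escape(lbl)}</text></g>"
        for i, lbl in enumerate(comparison.sample_labels)
    )
    doc = (f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
           f'height="{height:.0f}">\n'
           f'<text x="10" y="18" font-size="13">Global view (rank: '
           f"{html.escape(comparison.rank)})</text>\n"
           + legend + "\n" + "\n".join(elems) + "\n</svg>\n")
    path.write_text(doc, encoding="utf-8", newline="\n")
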