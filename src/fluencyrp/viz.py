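"""Rendering: individual pair plots, group heatmaps, and a self-contained
interactive HTML export.

Pair-plot semantics: the chronologically first list runs along the x axis
(position 1 at the left), the second along the y axis (position 1 at the
bottom), so identical lists fill the rising diagonal. Matches are dark-blue
points; items present in one list but missing from the other are orange
points on the axis of the list that contains them; repeats are linked to
their first occurrence by a green arrow with green tick labels; intrusions
get a red "x" and an asterisk on the tick label. Axes are drawn to equal
scale, so the plot's aspect ratio encodes the length change between the
two lists (square = no change).
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import matplotlib.pyplot as plt
import numpy as np

from .group_aggregate import DifferenceMap, GroupHeatmap
from .recurrence import AnnotatedPair

#: Marker colors; `colorblind=True` switches to an Okabe–Ito-based palette.
PALETTE = {"match": "#00008B", "missing": "#FF8C00", "repeat": "#1A7A1A", "intrusion": "#CC0000"}
PALETTE_CB = {"match": "#0072B2", "missing": "#E69F00", "repeat": "#009E73", "intrusion": "#D55E00"}


@dataclass
class PlotSpec:
    """Rendering options shared by the static and interactive exporters."""

    marker_size: float = 60.0
    cell_inches: float = 0.32          # figure inches per sequence position
    colorblind: bool = False
    dpi: int = 150

    @property
    def palette(self) -> dict[str, str]:
        return PALETTE_CB if self.colorblind else PALETTE


def _pair_geometry(pair: AnnotatedPair) -> dict:
    """Everything both renderers need, as plain coordinates.

    Returns match points (raw-mode 1-cells), missing-item axis points,
    repetition links, intrusion positions and styled tick labels. Exposed
    so tests can check the drawn points against the recurrence matrix.
    """
    matches = [(int(i), int(j)) for i, j in pair.matrix("raw").match_indices()]
    missing_b = set(pair.missing_from_b)
    missing_a = set(pair.missing_from_a)
    miss_x = [i for i, t in enumerate(pair.tokens_a) if t in missing_b]
    miss_y = [j for j, t in enumerate(pair.tokens_b) if t in missing_a]

    def _rep_links(reps, other_tokens, axis):
        links = []
        for r in reps:
            hits = [k for k, t in enumerate(other_tokens) if t == r.token]
            anchor = hits[0] if hits else None
            links.append({"from": r.position, "to": r.first_position,
                          "token": r.token, "axis": axis, "anchor": anchor})
        return links

    return {
        "matches": matches,
        "missing_x": miss_x,
        "missing_y": miss_y,
        "repeat_links_x": _rep_links(pair.repetitions_a, pair.tokens_b, "x"),
        "repeat_links_y": _rep_links(pair.repetitions_b, pair.tokens_a, "y"),
        "intrusions_x": list(pair.intrusions_a),
        "intrusions_y": list(pair.intrusions_b),
    }


def _tick_labels(tokens, repeats, intrusions):
    labels = []
    for k, t in enumerate(tokens):
        lab = t + ("*" if k in intrusions else "")
        labels.append(lab)
    return labels


def render_pair_plot(
    pair: AnnotatedPair, path: str | Path | None = None, spec: PlotSpec | None = None
):
    """Draw the annotated recurrence plot of one pair of lists.

    Returns ``(fig, ax)``; saves to ``path`` (PNG or SVG by extension) when
    given. Raises if both lists are empty.
    """
    spec = spec or PlotSpec()
    nx, ny = len(pair.tokens_a), len(pair.tokens_b)
    if nx == 0 and ny == 0:
        raise ValueError("cannot plot a pair of two empty lists")
    geo = _pair_geometry(pair)
    pal = spec.palette

    fig, ax = plt.subplots(
        figsize=(max(2.5, nx * spec.cell_inches) + 1.6,
                 max(2.5, ny * spec.cell_inches) + 1.2)
    )
    if geo["matches"]:
        xs, ys = zip(*geo["matches"])
        ax.scatter(xs, ys, s=spec.marker_size, color=pal["match"], zorder=3,
                   gid="matches", label="match")
    if geo["missing_x"]:
        ax.scatter(geo["missing_x"], [-0.8] * len(geo["missing_x"]),
                   s=spec.marker_size * 0.8, color=pal["missing"], clip_on=False,
                   zorder=3, gid="missing_x")
    if geo["missing_y"]:
        ax.scatter([-0.8] * len(geo["missing_y"]), geo["missing_y"],
                   s=spec.marker_size * 0.8, color=pal["missing"], clip_on=False,
                   zorder=3, gid="missing_y")

    for link in geo["repeat_links_x"]:
        y0 = link["anchor"] if link["anchor"] is not None else -0.8
        ax.annotate(
            "", xy=(link["to"], y0), xytext=(link["from"], y0),
            arrowprops=dict(arrowstyle="->", color=pal["repeat"], lw=1.6,
                            connectionstyle="arc3,rad=0.25"),
            annotation_clip=False,
        )
    for link in geo["repeat_links_y"]:
        x0 = link["anchor"] if link["anchor"] is not None else -0.8
        ax.annotate(
            "", xy=(x0, link["to"]), xytext=(x0, link["from"]),
            arrowprops=dict(arrowstyle="->", color=pal["repeat"], lw=1.6,
                            connectionstyle="arc3,rad=-0.25"),
            annotation_clip=False,
        )

    for i in geo["intrusions_x"]:
        rows = [j for (ii, j) in geo["matches"] if ii == i]
        pts = [(i, j) for j in rows] or [(i, -0.8)]
        for (x, y) in pts:
            ax.scatter([x], [y], marker="x", s=spec.marker_size * 1.4,
                       color=pal["intrusion"], zorder=4, clip_on=False, gid="intrusion")
    for j in geo["intrusions_y"]:
        cols = [i for (i, jj) in geo["matches"] if jj == j]
        pts = [(i, j) for i in cols] or [(-0.8, j)]
        for (x, y) in pts:
            ax.scatter([x], [y], marker="x", s=spec.marker_size * 1.4,
                       color=pal["intrusion"], zorder=4, clip_on=False, gid="intrusion")

    ax.set_xticks(range(nx))
    ax.set_xticklabels(
        _tick_labels(pair.tokens_a, pair.repetitions_a, set(geo["intrusions_x"])),
        rotation=90, fontsize=8,
    )
    ax.set_yticks(range(ny))
    ax.set_yticklabels(
        _tick_labels(pair.tokens_b, pair.repetitions_b, set(geo["intrusions_y"])),
        fontsize=8,
    )
    rep_x = {r.position for r in pair.repetitions_a} | {r.first_position for r in pair.repetitions_a}
    rep_y = {r.position for r in pair.repetitions_b} | {r.first_position for r in pair.repetitions_b}
    for k, lab in enumerate(ax.get_xticklabels()):
        if k in geo["intrusions_x"]:
            lab.set_color(pal["intrusion"])
        elif k in rep_x:
            lab.set_color(pal["repeat"])
    for k, lab in enumerate(ax.get_yticklabels()):
        if k in geo["intrusions_y"]:
            lab.set_color(pal["intrusion"])
        elif k in rep_y:
            lab.set_color(pal["repeat"])

    ax.set_xlim(-0.5, max(nx - 0.5, 0.5))
    ax.set_ylim(-0.5, max(ny - 0.5, 0.5))
    ax.set_aspect("equal")
    ax.set_xlabel(f"{pair.list_a.participant_id} — visit {pair.list_a.visit_index}")
    ax.set_ylabel(f"{pair.list_b.participant_id} — visit {pair.list_b.visit_index}")
    ax.grid(True, lw=0.3, alpha=0.4)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=spec.dpi)
    return fig, ax


def render_heatmap(
    hm: GroupHeatmap | DifferenceMap, path: str | Path | None = None,
    spec: PlotSpec | None = None,
):
    """Render a cumulative group heatmap (sequential scale on [0, max]) or a
    difference map (diverging scale centered at 0, group labels at the
    scale ends). Returns ``(fig, ax)``."""
    spec = spec or PlotSpec()
    grid = hm.grid
    if grid.size == 0:
        raise ValueError("empty heatmap grid")
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    if isinstance(hm, DifferenceMap):
        vmax = max(float(np.abs(grid).max()), 1e-12)
        im = ax.imshow(grid.T, origin="lower", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                       interpolation="nearest")
        cbar = fig.colorbar(im, ax=ax)
        cbar.ax.text(0.5, 1.02, hm.label_a, transform=cbar.ax.transAxes,
                     ha="center", va="bottom")
        cbar.ax.text(0.5, -0.02, hm.label_b, transform=cbar.ax.transAxes,
                     ha="center", va="top")
        ax.set_title(f"{hm.label_a} − {hm.label_b} ({hm.mode} mode)")
    else:
        vmax = max(float(grid.max()), 1e-12)
        im = ax.imshow(grid.T, origin="lower", cmap="Blues", vmin=0.0, vmax=vmax,
                       interpolation="nearest")
        cbar = fig.colorbar(im, ax=ax)
        cbar.set_label("proportion of pairs matching")
        ax.set_title(f"{hm.group}: {hm.n_pairs} pairs ({hm.mode} mode)")
    ax.set_xlabel("position in first list")
    ax.set_ylabel("position in second list")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=spec.dpi)
    return fig, ax


# ------------------------------------------------------- interactive HTML

_HTML_HEAD = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
 body {{ font-family: sans-serif; }}
 circle:hover, path:hover {{ stroke: black; stroke-width: 2; }}
</style></head><body>
<h3>{title}</h3>
<p>Hover over a point to see the items it links and any special attributes
(repeated, invalid/intrusion, missing).</p>
"""


def render_interactive(
    pair: AnnotatedPair, path: str | Path, spec: PlotSpec | None = None
) -> Path:
    """Write a self-contained interactive HTML view of a pair plot.

    The document embeds an inline SVG whose markers carry native ``<title>``
    tooltips — it opens offline, fetches nothing, and mirrors the static
    plot's marker semantics (match/missing/repeat/intrusion).
    """
    spec = spec or PlotSpec()
    pal = spec.palette
    geo = _pair_geometry(pair)
    nx, ny = len(pair.tokens_a), len(pair.tokens_b)
    if nx == 0 and ny == 0:
        raise ValueError("cannot plot a pair of two empty lists")
    cell = 26
    pad = 110
    w, h = pad + (nx + 1) * cell, pad + (ny + 1) * cell

    def X(i: float) -> float:
        return pad + (i + 0.5) * cell

    def Y(j: float) -> float:
        return h - pad - (j + 0.5) * cell  # position 1 at the bottom

    rep_x = {r.position for r in pair.repetitions_a}
    rep_y = {r.position for r in pair.repetitions_b}
    intr_x, intr_y = set(geo["intrusions_x"]), set(geo["intrusions_y"])

    def attrs(i: int | None, j: int | None) -> str:
        notes = []
        if i is not None:
            if i in rep_x:
                notes.append("repeated in first list")
            if i in intr_x:
                notes.append("invalid item (intrusion) in first list")
        if j is not None:
            if j in rep_y:
                notes.append("repeated in second list")
            if j in intr_y:
                notes.append("invalid item (intrusion) in second list")
        return "; ".join(notes)

    parts = [_HTML_HEAD.format(title=_html.escape(
        f"{pair.list_a.participant_id}: visit {pair.list_a.visit_index} vs "
        f"visit {pair.list_b.visit_index}"))]
    parts.append(f'<svg width="{w}" height="{h}" '
                 f'viewBox="0 0 {w} {h}" role="img">')
    parts.append(f'<rect x="{pad}" y="{cell}" width="{nx * cell}" '
                 f'height="{ny * cell}" fill="#f8f8f8" stroke="#999"/>')

    for i, j in geo["matches"]:
        tip = (f"x: {pair.tokens_a[i]} (position {i + 1}) | "
               f"y: {pair.tokens_b[j]} (position {j + 1})")
        extra = attrs(i, j)
        if extra:
            tip += " | " + extra
        color = pal["intrusion"] if (i in intr_x or j in intr_y) else pal["match"]
        parts.append(
            f'<circle cx="{X(i)}" cy="{Y(j)}" r="7" fill="{color}">'
            f"<title>{_html.escape(tip)}</title></circle>"
        )
    for i in geo["missing_x"]:
        tip = (f"x: {pair.tokens_a[i]} (position {i + 1}) — present in first "
               f"list, missing from second")
        extra = attrs(i, None)
        if extra:
            tip += " | " + extra
        parts.append(
            f'<circle cx="{X(i)}" cy="{Y(-1)}" r="6" fill="{pal["missing"]}">'
            f"<title>{_html.escape(tip)}</title></circle>"
        )
    for j in geo["missing_y"]:
        tip = (f"y: {pair.tokens_b[j]} (position {j + 1}) — present in second "
               f"list, missing from first")
        extra = attrs(None, j)
        if extra:
            tip += " | " + extra
        parts.append(
            f'<circle cx="{X(-1)}" cy="{Y(j)}" r="6" fill="{pal["missing"]}">'
            f"<title>{_html.escape(tip)}</title></circle>"
        )
    for axis, links in (("x", geo["repeat_links_x"]), ("y", geo["repeat_links_y"])):
        for link in links:
            anchor = link["anchor"] if link["anchor"] is not None else -1
            if axis == "x":
                x1, y1, x2, y2 = X(link["from"]), Y(anchor), X(link["to"]), Y(anchor)
            else:
                x1, y1, x2, y2 = X(anchor), Y(link["from"]), X(anchor), Y(link["to"])
            tip = f"repeated item: {link['token']}"
            parts.append(
                f'<path d="M {x1} {y1} L {x2} {y2}" stroke="{pal["repeat"]}" '
                f'stroke-width="2.5" fill="none" marker-end="url(#arrow)">'
                f"<title>{_html.escape(tip)}</title></path>"
            )
    # unmatched intrusions as red crosses on the margin
    matched_x = {i for i, _ in geo["matches"]}
    matched_y = {j for _, j in geo["matches"]}
    for i in intr_x - matched_x:
        tip = f"x: {pair.tokens_a[i]} (position {i + 1}) — invalid item (intrusion)"
        parts.append(
            f'<text x="{X(i)}" y="{Y(-1)}" fill="{pal["intrusion"]}" '
            f'text-anchor="middle" font-size="14">✕'
            f"<title>{_html.escape(tip)}</title></text>"
        )
    for j in intr_y - matched_y:
        tip = f"y: {pair.tokens_b[j]} (position {j + 1}) — invalid item (intrusion)"
        parts.append(
            f'<text x="{X(-1)}" y="{Y(j)}" fill="{pal["intrusion"]}" '
            f'text-anchor="middle" font-size="14">✕'
            f"<title>{_html.escape(tip)}</title></text>"
        )
    parts.append(
        '<defs><marker id="arrow" markerWidth="8" markerHeight="8" refX="6" '
        'refY="3" orient="auto"><path d="M0,0 L6,3 L0,6 z" '
        f'fill="{pal["repeat"]}"/></marker></defs>'
    )
    for i, t in enumerate(pair.tokens_a):
        lab = t + ("*" if i in intr_x else "")
        color = pal["intrusion"] if i in intr_x else (pal["repeat"] if i in rep_x else "#222")
        parts.append(
            f'<text x="{X(i)}" y="{h - pad + 14}" fill="{color}" font-size="10" '
            f'text-anchor="end" transform="rotate(-60 {X(i)} {h - pad + 14})">'
            f"{_html.escape(lab)}</text>"
        )
    for j, t in enumerate(pair.tokens_b):
        lab = t + ("*" if j in intr_y else "")
        color = pal["intrusion"] if j in intr_y else (pal["repeat"] if j in rep_y else "#222")
        parts.append(
            f'<text x="{pad - 6}" y="{Y(j) + 4}" fill="{color}" font-size="10" '
            f'text-anchor="end">{_html.escape(lab)}</text>'
        )
    parts.append("</svg></body></html>")
    out = Path(path)
    out.write_text("\n".join(parts), encoding="utf-8")
    return out
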