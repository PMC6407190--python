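"""Deterministic rendering of dotplots and dual-scheme karyograms.

SVG is the primary output: it is written by a small local emitter with fixed
number formatting and stable element ordering, so identical inputs produce
byte-identical files (a contract the tests hold).  A ``.png`` output path
routes the same geometry through matplotlib instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import load_data_json
from .painting import Karyogram

__all__ = ["ColorScheme", "render_dotplot", "render_karyogram"]

_CANVAS = 800.0
_MARGIN = 60.0
_FALLBACK_PALETTE = [
    "#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00", "#a65628",
    "#f781bf", "#999999", "#66c2a5", "#fc8d62", "#8da0cb", "#e78ac3",
]


@dataclass
class ColorScheme:
    """Label and hit-rank colors; total over the alphabet in use."""

    labels: dict[str, str] = field(default_factory=dict)
    ranks: dict[str, str] = field(default_factory=lambda: {
        "best": "#d62728", "second": "#1f77b4", "other": "#bbbbbb"})
    classes: dict[str, str] = field(default_factory=lambda: {
        "primary": "#d62728", "secondary": "#1f77b4", "other": "#bbbbbb"})

    @classmethod
    def default(cls) -> "ColorScheme":
        d = load_data_json("color_scheme.json")
        return cls(labels=dict(d["labels"]), ranks=dict(d["ranks"]),
                   classes=dict(d["classes"]))

    def label_color(self, label: str) -> str:
        if label in self.labels:
            return self.labels[label]
        # deterministic fallback for alphabets beyond the shipped palette
        return _FALLBACK_PALETTE[hash_label(label) % len(_FALLBACK_PALETTE)]

    def require(self, labels: Iterable[str]) -> None:
        missing = sorted(set(labels) - set(self.labels))
        if missing:
            raise KeyError(f"color scheme lacks labels: {missing}")


def hash_label(label: str) -> int:
    h = 0
    for ch in label:
        h = (h * 131 + ord(ch)) % 1_000_003
    return h


# ---------------------------------------------------------------------------
# svg primitives
# ---------------------------------------------------------------------------

def _f(x: float) -> str:
    return f"{x:.2f}"


class _Svg:
    def __init__(self, width: float, height: float):
        self.parts = [
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{_f(width)}" '
            f'height="{_f(height)}" viewBox="0 0 {_f(width)} {_f(height)}">\n'
        ]

    def rect(self, x, y, w, h, fill="none", stroke="none", stroke_width=1.0):
        self.parts.append(
            f'<rect x="{_f(x)}" y="{_f(y)}" width="{_f(w)}" height="{_f(h)}" '
            f'fill="{fill}" stroke="{stroke}" stroke-width="{_f(stroke_width)}"/>\n'
        )

    def line(self, x1, y1, x2, y2, stroke="#000000", stroke_width=0.5):
        self.parts.append(
            f'<line x1="{_f(x1)}" y1="{_f(y1)}" x2="{_f(x2)}" y2="{_f(y2)}" '
            f'stroke="{stroke}" stroke-width="{_f(stroke_width)}"/>\n'
        )

    def circle(self, cx, cy, r, fill):
        self.parts.append(
            f'<circle cx="{_f(cx)}" cy="{_f(cy)}" r="{_f(r)}" fill="{fill}"/>\n'
        )

    def text(self, x, y, s, size=10.0, anchor="middle"):
        self.parts.append(
            f'<text x="{_f(x)}" y="{_f(y)}" font-size="{_f(size)}" '
            f'font-family="sans-serif" text-anchor="{anchor}">{s}</text>\n'
        )

    def tostring(self) -> str:
        return "".join(self.parts) + "</svg>\n"


def _layout_offsets(layout: Sequence[tuple[str, int]], span: float
                    ) -> tuple[dict[str, float], dict[str, float], float]:
    total = sum(max(length, 1) for _, length in layout)
    scale = span / total if total else 1.0
    offsets: dict[str, float] = {}
    sizes: dict[str, float] = {}
    pos = 0.0
    for chrom, length in layout:
        offsets[chrom] = pos
        sizes[chrom] = max(length, 1) * scale
        pos += sizes[chrom]
    return offsets, sizes, scale


# ---------------------------------------------------------------------------
# dotplot
# ---------------------------------------------------------------------------

def render_dotplot(
    points: Sequence[tuple[str, int, str, int, str]],
    layout_a: Sequence[tuple[str, int]],
    layout_b: Sequence[tuple[str, int]],
    scheme: ColorScheme | None = None,
    out_path: str | None = None,
    *,
    color_by: str = "ranks",
    title: str = "",
) -> str:
    """Homologous-gene dotplot.

    ``points`` are (chrom_a, bp_a, chrom_b, bp_b, category) with category a
    key of the scheme's rank palette ("best", "second", "other") or class
    palette ("primary", "secondary"); ``layout_*`` give each genome's
    chromosomes in display order with their bp lengths (a horizontal,
    b vertical).  A point on a chromosome absent from the layout raises.
    Output is deterministic; returns the SVG text (also written to
    ``out_path`` when given; a ``.png`` suffix rasterizes via matplotlib).
    """
    scheme = scheme or ColorScheme.default()
    palette = scheme.ranks if color_by == "ranks" else scheme.classes
    span = _CANVAS - 2 * _MARGIN
    offs_a, sizes_a, _ = _layout_offsets(layout_a, span)
    offs_b, sizes_b, _ = _layout_offsets(layout_b, span)
    len_a = {c: max(l, 1) for c, l in layout_a}
    len_b = {c: max(l, 1) for c, l in layout_b}

    def xy(chrom_a: str, bp_a: int, chrom_b: str, bp_b: int) -> tuple[float, float]:
        if chrom_a not in offs_a:
            raise KeyError(f"point on {chrom_a!r} but chromosome not in layout")
        if chrom_b not in offs_b:
            raise KeyError(f"point on {chrom_b!r} but chromosome not in layout")
        x = _MARGIN + offs_a[chrom_a] + bp_a / len_a[chrom_a] * sizes_a[chrom_a]
        y = _MARGIN + offs_b[chrom_b] + bp_b / len_b[chrom_b] * sizes_b[chrom_b]
        return x, y

    svg = _Svg(_CANVAS, _CANVAS)
    svg.rect(_MARGIN, _MARGIN, span, span, fill="#ffffff", stroke="#000000")
    for chrom, _ in layout_a:
        x = _MARGIN + offs_a[chrom]
        svg.line(x, _MARGIN, x, _CANVAS - _MARGIN, stroke="#888888")
        svg.text(x + sizes_a[chrom] / 2, _MARGIN - 8, chrom, size=9)
    for chrom, _ in layout_b:
        y = _MARGIN + offs_b[chrom]
        svg.line(_MARGIN, y, _CANVAS - _MARGIN, y, stroke="#888888")
        svg.text(_MARGIN - 8, y + sizes_b[chrom] / 2, chrom, size=9, anchor="end")
    if title:
        svg.text(_CANVAS / 2, 20, title, size=14)

    for chrom_a, bp_a, chrom_b, bp_b, cat in sorted(points):
        x, y = xy(chrom_a, bp_a, chrom_b, bp_b)
        svg.circle(x, y, 1.5, palette.get(cat, palette.get("other", "#bbbbbb")))

    text = svg.tostring()
    if out_path is not None:
        if str(out_path).endswith(".png"):
            _dotplot_png(points, layout_a, layout_b, palette, out_path, title)
        else:
            with open(out_path, "w") as fh:
                fh.write(text)
    return text


def _dotplot_png(points, layout_a, layout_b, palette, out_path, title):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    offs_a, _, _ = _layout_offsets(layout_a, 1.0)
    offs_b, _, _ = _layout_offsets(layout_b, 1.0)
    sizes_a = dict(_layout_offsets(layout_a, 1.0)[1])
    sizes_b = dict(_layout_offsets(layout_b, 1.0)[1])
    len_a = {c: max(l, 1) for c, l in layout_a}
    len_b = {c: max(l, 1) for c, l in layout_b}
    fig, ax = plt.subplots(figsize=(8, 8))
    xs, ys, cs = [], [], []
    for chrom_a, bp_a, chrom_b, bp_b, cat in sorted(points):
        xs.append(offs_a[chrom_a] + bp_a / len_a[chrom_a] * sizes_a[chrom_a])
        ys.append(offs_b[chrom_b] + bp_b / len_b[chrom_b] * sizes_b[chrom_b])
        cs.append(palette.get(cat, "#bbbbbb"))
    ax.scatter(xs, ys, s=2, c=cs)
    for chrom, _ in layout_a:
        ax.axvline(offs_a[chrom], color="#888888", lw=0.5)
    for chrom, _ in layout_b:
        ax.axhline(offs_b[chrom], color="#888888", lw=0.5)
    ax.set_xlim(0, 1)
    ax.set_ylim(1, 0)
    ax.set_title(title)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# karyogram
# ---------------------------------------------------------------------------

def render_karyogram(
    karyo_ancestral: Karyogram,
    karyo_reference: Karyogram,
    scheme: ColorScheme | None = None,
    out_path: str | None = None,
    *,
    title: str = "",
) -> str:
    """Dual-scheme karyogram: each chromosome is a vertical bar, left half
    painted by ancestral (proto) labels, right half by reference labels.
    Both karyograms must cover the same chromosomes."""
    scheme = scheme or ColorScheme.default()
    chroms = sorted(karyo_ancestral.paints)
    if sorted(karyo_reference.paints) != chroms:
        raise ValueError("the two karyograms cover different chromosomes")
    for karyo in (karyo_ancestral, karyo_reference):
        scheme.require(
            s.ref_label for segs in karyo.paints.values() for s in segs
        )

    max_bp = max(
        (seg.end_bp for segs in karyo_reference.paints.values() for seg in segs),
        default=1,
    )
    n = max(len(chroms), 1)
    bar_w = min(40.0, (_CANVAS - 2 * _MARGIN) / (2.0 * n))
    gap = (_CANVAS - 2 * _MARGIN - n * bar_w) / max(n, 1)
    vspan = _CANVAS - 2 * _MARGIN

    svg = _Svg(_CANVAS, _CANVAS)
    if title:
        svg.text(_CANVAS / 2, 20, title, size=14)
    for i, chrom in enumerate(chroms):
        x = _MARGIN + i * (bar_w + gap)
        svg.text(x + bar_w / 2, _MARGIN - 6, chrom, size=9)
        for karyo, x0 in ((karyo_ancestral, x), (karyo_reference, x + bar_w / 2)):
            for seg in karyo.paints[chrom]:
                y0 = _MARGIN + (seg.start_bp - 1) / max_bp * vspan
                y1 = _MARGIN + seg.end_bp / max_bp * vspan
                svg.rect(x0, y0, bar_w / 2, max(y1 - y0, 0.5),
                         fill=scheme.label_color(seg.ref_label),
                         stroke="#000000", stroke_width=0.3)

    text = svg.tostring()
    if out_path is not None:
        if str(out_path).endswith(".png"):
            _karyogram_png(karyo_ancestral, karyo_reference, scheme, out_path,
                           chroms, max_bp, title)
        else:
            with open(out_path, "w") as fh:
                fh.write(text)
    return text


def _karyogram_png(karyo_ancestral, karyo_reference, scheme, out_path,
                   chroms, max_bp, title):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(figsize=(8, 8))
    for i, chrom in enumerate(chroms):
        for karyo, dx in ((karyo_ancestral, 0.0), (karyo_reference, 0.2)):
            for seg in karyo.paints[chrom]:
                ax.add_patch(Rectangle(
                    (i + dx, (seg.start_bp - 1) / max_bp), 0.2,
                    (seg.end_bp - seg.start_bp + 1) / max_bp,
                    facecolor=scheme.label_color(seg.ref_label),
                    edgecolor="black", linewidth=0.3,
                ))
    ax.set_xlim(-0.5, len(chroms))
    ax.set_ylim(1.05, -0.05)
    ax.set_xticks([i + 0.2 for i in range(len(chroms))])
    ax.set_xticklabels(chroms)
    ax.set_title(title)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
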