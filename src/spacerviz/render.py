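"""Lay out and write the SVG figure.

One row per sample, one column per locus number, with CRISPR 1 as the
rightmost data column and higher locus numbers extending leftward.  Within a
column every locus is right-aligned: because new spacers enter arrays at the
5' end while the 3' end is conserved, right-aligning the 5'->3' rows puts
shared (old) spacers of different strains in the same vertical position.
Each spacer is a colored square with a diamond inscribed at its center
(vertices at the edge midpoints); the sample name sits to the right of the
rightmost column.

The SVG is deliberately plain — rects, polygons and text only, integer
coordinates, stable element order — so output is byte-identical across runs
and easy to post-edit in Inkscape or Illustrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from xml.sax.saxutils import escape

from .colors import DisplayColor
from .order import StrainOrdering
from .records import Dataset


@dataclass
class RenderOptions:
    cell_px: int = 20
    gap_px: int = 2
    column_gap_px: int = 30
    margin_px: int = 10
    show_length_labels: bool = False
    label_all: bool = False  # extend length labels beyond grayed cells
    locus1_rightmost: bool = True
    font_family: str = "Helvetica"
    font_size: int = 12

    def __post_init__(self) -> None:
        if self.cell_px <= 0:
            raise ValueError("cell_px must be positive")


@dataclass(frozen=True)
class Cell:
    x: int
    y: int
    square_hex: str
    diamond_hex: str
    label: str | None


@dataclass(frozen=True)
class Label:
    x: int
    y: int
    text: str
    anchor: str = "start"


@dataclass
class SvgScene:
    width: int
    height: int
    cells: list[Cell] = field(default_factory=list)
    labels: list[Label] = field(default_factory=list)
    options: RenderOptions = field(default_factory=RenderOptions)


def layout(
    ds: Dataset,
    ordering: StrainOrdering,
    display: list[DisplayColor],
    opts: RenderOptions | None = None,
) -> SvgScene:
    """Place every spacer cell and every sample label on the canvas."""
    opts = opts or RenderOptions()
    colors = {d.spacer_id: d for d in display}
    for sp in ds.spacers():
        if sp.spacer_id not in colors:
            raise KeyError(f"no display color for spacer {sp.spacer_id}")
    missing = [sid for sid in ordering.ordered_samples if sid not in ds.samples]
    if missing:
        raise KeyError(f"ordering names unknown samples: {missing}")

    if not ds.samples:
        return SvgScene(width=2 * opts.margin_px, height=2 * opts.margin_px, options=opts)

    loci_by_sample = {
        sid: {loc.locus_num: loc for loc in ds.samples[sid]} for sid in ds.samples
    }
    locus_nums = sorted({loc.locus_num for loc in ds.loci()})
    # left-to-right column order: highest locus number first by default
    column_order = sorted(locus_nums, reverse=opts.locus1_rightmost)

    pitch = opts.cell_px + opts.gap_px
    col_cells = {
        ln: max(
            (len(loci[ln].spacers) for loci in loci_by_sample.values() if ln in loci),
            default=0,
        )
        for ln in locus_nums
    }
    # x of each column's left edge and fixed right edge
    col_left: dict[int, int] = {}
    x = opts.margin_px
    for ln in column_order:
        col_left[ln] = x
        x += col_cells[ln] * pitch - opts.gap_px + opts.column_gap_px
    label_x = x  # right of the rightmost column
    row_pitch = opts.cell_px + opts.gap_px

    scene = SvgScene(width=0, height=0, options=opts)
    for row, sid in enumerate(ordering.ordered_samples):
        y = opts.margin_px + row * row_pitch
        for ln in column_order:
            locus = loci_by_sample[sid].get(ln)
            if locus is None:
                continue  # this sample lacks the locus; column stays empty
            right_edge = col_left[ln] + col_cells[ln] * pitch - opts.gap_px
            n_sp = len(locus.spacers)
            for k, sp in enumerate(locus.spacers):
                # right-align: the 3'-terminal spacer touches the column edge
                cx = right_edge - (n_sp - k) * pitch + opts.gap_px
                d = colors[sp.spacer_id]
                want_label = opts.show_length_labels and (d.grayed or opts.label_all)
                scene.cells.append(
                    Cell(
                        x=cx,
                        y=y,
                        square_hex=d.square_hex,
                        diamond_hex=d.diamond_hex,
                        label=str(d.label if d.label is not None else sp.length)
                        if want_label
                        else None,
                    )
                )
        scene.labels.append(
            Label(
                x=label_x,
                y=y + round(0.75 * opts.cell_px),
                text=sid,
            )
        )
    longest_name = max((len(l.text) for l in scene.labels), default=0)
    scene.width = label_x + longest_name * opts.font_size + opts.margin_px
    scene.height = (
        opts.margin_px * 2 + len(ordering.ordered_samples) * row_pitch - opts.gap_px
    )
    return scene


def svg_text(scene: SvgScene) -> str:
    """Serialize a scene to SVG 1.1 with a stable byte-for-byte layout."""
    o = scene.options
    c = o.cell_px
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{scene.width}" height="{scene.height}" '
        f'viewBox="0 0 {scene.width} {scene.height}">',
    ]
    half = c // 2
    for cell in scene.cells:
        x, y = cell.x, cell.y
        out.append(
            f'<rect x="{x}" y="{y}" width="{c}" height="{c}" '
            f'fill="{cell.square_hex}" stroke="#000" stroke-width="1"/>'
        )
        pts = (
            f"{x + half},{y} {x + c},{y + half} {x + half},{y + c} {x},{y + half}"
        )
        out.append(f'<polygon points="{pts}" fill="{cell.diamond_hex}"/>')
        if cell.label is not None:
            out.append(
                f'<text x="{x + half}" y="{y + half + 3}" text-anchor="middle" '
                f'font-family="{o.font_family}" font-size="{max(6, o.font_size - 4)}" '
                f'fill="#333">{escape(cell.label)}</text>'
            )
    for lab in scene.labels:
        out.append(
            f'<text x="{lab.x}" y="{lab.y}" text-anchor="{lab.anchor}" '
            f'font-family="{o.font_family}" font-size="{o.font_size}" '
            f'fill="#000">{escape(lab.text)}</text>'
        )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def write_svg(scene: SvgScene, path: str | PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(svg_text(scene))
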