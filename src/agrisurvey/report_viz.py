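"""Pseudo-color rendering, histogram plots, and PDF report assembly.

Index maps are rendered as 8-bit RGBA images (nodata transparent) with a
linear value-to-color mapping over [vmin, vmax], histograms as bar plots
optionally colored by classification rule, and a mission report is a PDF
with a metadata page followed by one page per index (pseudo-color +
histogram + class counts). All rendering is deterministic: identical inputs
and configuration produce byte-identical files (PDF/PNG timestamp metadata
is suppressed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless; must precede pyplot import

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.backends.backend_pdf import PdfPages
from PIL import Image

from .errors import InvalidInputError, InvalidSpecError
from .indices import IndexMap, classify, histogram, lookup
from .errors import UnknownIndexError

__all__ = [
    "ReportSpec",
    "render_pseudocolor",
    "render_histogram",
    "build_report",
    "load_index_map",
    "DEFAULT_COLORMAP",
]

#: Default palette: green = vigorous vegetation, red = stressed/bare.
DEFAULT_COLORMAP = "RdYlGn"

_PNG_NO_STAMP = {"Software": None}  # strip the renderer tag for byte-stable output


@dataclass
class ReportSpec:
    """What goes into a mission report PDF."""

    maps: list  # IndexMap objects or paths to saved map TIFFs
    output: str | Path
    mission_metadata: dict = field(default_factory=dict)
    colormaps: dict = field(default_factory=dict)  # index name -> colormap name
    bins: int = 20


def _color_limits(imap: IndexMap, vmin, vmax) -> tuple[float, float]:
    if vmin is None or vmax is None:
        hint = imap.range_hint
        vals = imap.valid_values
        if vals.size == 0:
            raise InvalidInputError("cannot render an all-nodata index map")
        if hint is not None:
            lo, hi = hint
        else:
            lo, hi = float(vals.min()), float(vals.max())
        vmin = lo if vmin is None else vmin
        vmax = hi if vmax is None else vmax
    if not vmax > vmin:
        raise InvalidInputError(f"need vmax > vmin, got [{vmin}, {vmax}]")
    return float(vmin), float(vmax)


def render_pseudocolor(
    imap: IndexMap,
    path: str | Path,
    colormap: str = DEFAULT_COLORMAP,
    vmin: float | None = None,
    vmax: float | None = None,
    max_px: int = 2048,
) -> Path:
    """Save an 8-bit RGBA PNG of the map; nodata pixels are transparent.

    Colors are linear in value over [vmin, vmax] (defaulting to the index's
    expected range, e.g. [-1, 1] for NDVI); out-of-range values saturate at
    the colormap endpoints. Maps larger than ``max_px`` on a side are
    decimated by integer striding before rendering.
    """
    if not imap.valid_mask.any():
        raise InvalidInputError("cannot render an all-nodata index map")
    vmin, vmax = _color_limits(imap, vmin, vmax)
    values = imap.values
    stride = max(1, int(np.ceil(max(values.shape) / max_px)))
    values = values[::stride, ::stride]
    cmap = plt.get_cmap(colormap)
    norm = np.clip((values - vmin) / (vmax - vmin), 0.0, 1.0)
    rgba = (cmap(np.nan_to_num(norm)) * 255).round().astype(np.uint8)
    rgba[..., 3] = np.where(np.isfinite(values), 255, 0)
    path = Path(path)
    Image.fromarray(rgba, mode="RGBA").save(path, format="PNG")
    return path


def _classified_bar_colors(edges: np.ndarray, rules) -> list[str]:
    """One color per bar: green for bars wholly above the first threshold."""
    palette = ["#c0504d", "#4f9153", "#4472c4", "#8064a2", "#f79646"]
    colors = []
    centers = (edges[:-1] + edges[1:]) / 2.0
    for c in centers:
        k = next(
            (i for i, (_, lo, hi) in enumerate(rules) if lo < c <= hi),
            len(palette) - 1,
        )
        colors.append(palette[k % len(palette)])
    return colors


def render_histogram(
    imap: IndexMap,
    path: str | Path,
    bins: int | np.ndarray = 20,
    classification=None,
) -> Path:
    """Save a histogram PNG; with ``classification`` rules (or True for the
    index's defaults) bars are colored per class interval."""
    edges, counts = histogram(imap, bins)
    rules = None
    if classification is True:
        rules = lookup(imap.index_name).classification
        if rules is None:
            raise InvalidInputError(
                f"index {imap.index_name} has no default classification rules"
            )
    elif classification:
        rules = list(classification)

    fig, ax = plt.subplots(figsize=(6, 4), dpi=100)
    colors = _classified_bar_colors(edges, rules) if rules else "#4472c4"
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", color=colors, edgecolor="none")
    ax.set_xlabel(imap.index_name)
    ax.set_ylabel("pixel count")
    title = f"{imap.index_name} histogram"
    if rules:
        title += " (categorized)"
    ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, format="png", metadata=_PNG_NO_STAMP)
    plt.close(fig)
    return path


def load_index_map(path: str | Path) -> IndexMap:
    """Load an index map saved by :func:`agrisurvey.indices.save_index_map`."""
    import tifffile

    path = Path(path)
    if not path.exists():
        raise InvalidSpecError(f"missing index-map artifact: {path}")
    sidecar = path.with_suffix(".json")
    name, provenance = path.stem.upper(), {}
    if sidecar.exists():
        doc = json.loads(sidecar.read_text())
        name = doc.get("index", name)
        provenance = doc.get("provenance", {})
    return IndexMap(tifffile.imread(path), name, provenance=provenance)


def build_report(spec: ReportSpec) -> Path:
    """Assemble the PDF: a mission-metadata page, then one page per index
    (pseudo-color rendering, histogram, class counts). Page count is
    1 + number of index maps. Regeneration with identical inputs yields
    byte-identical files (creation timestamps suppressed)."""
    if not spec.maps:
        raise InvalidSpecError("report needs at least one index map")
    maps = [m if isinstance(m, IndexMap) else load_index_map(m) for m in spec.maps]

    out = Path(spec.output)
    meta = {"CreationDate": None, "ModDate": None, "Producer": "agrisurvey"}
    with PdfPages(out, metadata=meta) as pdf:
        fig = plt.figure(figsize=(8.27, 11.69))
        fig.text(0.5, 0.85, "Survey index report", ha="center", size=22, weight="bold")
        rows = list(spec.mission_metadata.items()) or [("maps", len(maps))]
        y = 0.75
        for key, val in rows:
            fig.text(0.2, y, str(key), size=11, weight="bold")
            fig.text(0.45, y, str(val), size=11)
            y -= 0.035
        fig.text(0.2, y - 0.02, "indices", size=11, weight="bold")
        fig.text(0.45, y - 0.02, ", ".join(m.index_name for m in maps), size=11)
        pdf.savefig(fig)
        plt.close(fig)

        for imap in maps:
            fig = plt.figure(figsize=(8.27, 11.69))
            fig.suptitle(imap.index_name, size=18, weight="bold")

            ax_img = fig.add_axes([0.12, 0.5, 0.76, 0.38])
            vmin, vmax = _color_limits(imap, None, None)
            cmap = spec.colormaps.get(imap.index_name, DEFAULT_COLORMAP)
            im = ax_img.imshow(imap.values, cmap=cmap, vmin=vmin, vmax=vmax)
            ax_img.set_xticks([])
            ax_img.set_yticks([])
            fig.colorbar(im, ax=ax_img, fraction=0.04)

            ax_h = fig.add_axes([0.12, 0.18, 0.76, 0.24])
            edges, counts = histogram(imap, spec.bins)
            ax_h.bar(
                edges[:-1], counts, width=np.diff(edges), align="edge", color="#4472c4"
            )
            ax_h.set_xlabel(imap.index_name)
            ax_h.set_ylabel("pixel count")

            try:
                rules = lookup(imap.index_name).classification
            except UnknownIndexError:
                rules = None
            if rules is not None:
                _, class_counts = classify(imap, rules)
                total = sum(class_counts.values())
                txt = "   ".join(
                    f"{k}: {v} ({100.0 * v / total:.1f}%)" for k, v in class_counts.items()
                )
                fig.text(0.12, 0.10, txt, size=10)
            pdf.savefig(fig)
            plt.close(fig)
    return out
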