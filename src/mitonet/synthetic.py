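"""Synthetic micrographs with known network topology.

Real mitochondrial micrographs for the reference conditions are not
redistributable, so this module provides the test bed for the whole
pipeline: parametric toy multigraphs (paths, cycles, 3-armed stars,
theta graphs, isolated edges) and a renderer that draws any graph built
from those component shapes onto a dark canvas as thin bright strokes,
optionally with Gaussian blur, additive noise, a legend box, or a
non-mitochondrial color channel.

The renderer is engineered so that extraction is *exactly* invertible on
clean output: each toy edge is drawn as a stroke of ``px_per_edge``
pixels, and shapes are corner-compensated for the deterministic one
pixel that topology-preserving thinning shaves off every 90-degree turn.
Pixel-scale loop sizes and branch lengths therefore map back to toy
edges by integer rounding (:func:`sizes_to_edge_units`), and component
count and cycle rank are preserved identically.

Components are placed on a collision-free shelf layout with seeded
jitter, so rendering is deterministic given ``layout_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
from scipy.ndimage import gaussian_filter

from .graphs import collapse_chains, write_graphml

__all__ = [
    "ComponentSpec",
    "ToyGraphSpec",
    "RenderParams",
    "RenderedImage",
    "LayoutError",
    "make_toy_graph",
    "render_graph_to_image",
    "add_artifacts",
    "sizes_to_edge_units",
    "write_synthetic_dataset",
]

KINDS = ("path", "cycle", "star", "theta", "isolated-edge")


class LayoutError(ValueError):
    """A component cannot be placed or drawn at the requested scale."""


@dataclass(frozen=True)
class ComponentSpec:
    """One toy component: a shape kind and its size in edges."""

    kind: str
    size: int

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown component kind {self.kind!r}")
        if self.size < 1:
            raise ValueError("component size must be >= 1 edge")
        if self.kind in ("star", "theta") and self.size < 3:
            raise ValueError(f"{self.kind} needs >= 3 edges")
        if self.kind == "isolated-edge" and self.size != 1:
            raise ValueError("isolated-edge has exactly 1 edge")


@dataclass(frozen=True)
class ToyGraphSpec:
    components: tuple
    layout_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(
            c if isinstance(c, ComponentSpec) else ComponentSpec(*c)
            for c in self.components))

    @property
    def n_edges(self) -> int:
        return sum(c.size for c in self.components)


def _split3(size: int) -> list:
    """Balanced 3-way partition, descending."""
    base, rem = divmod(size, 3)
    return sorted(([base + 1] * rem + [base] * 3)[:3], reverse=True)


def make_toy_graph(spec: ToyGraphSpec) -> nx.MultiGraph:
    """Build the multigraph described by ``spec``.

    Nodes are ``(component_index, i)`` tuples; per-component topology
    matches the descriptor exactly (a cycle of 1 is a self-loop, a cycle
    of 2 a pair of parallel edges).
    """
    g = nx.MultiGraph()
    for ci, comp in enumerate(spec.components):
        n = lambda i: (ci, i)  # noqa: E731
        s = comp.size
        if comp.kind in ("path", "isolated-edge"):
            nx.add_path(g, [n(i) for i in range(s + 1)])
        elif comp.kind == "cycle":
            if s == 1:
                g.add_edge(n(0), n(0))
            else:
                nx.add_cycle(g, [n(i) for i in range(s)])
        elif comp.kind == "star":
            hub, nid = n(0), 1
            for arm in _split3(s):
                prev = hub
                for _ in range(arm):
                    g.add_edge(prev, n(nid))
                    prev = n(nid)
                    nid += 1
        elif comp.kind == "theta":
            u, v, nid = n(0), n(1), 2
            for chain in _split3(s):
                prev = u
                for j in range(chain - 1):
                    g.add_edge(prev, n(nid))
                    prev = n(nid)
                    nid += 1
                g.add_edge(prev, v)
    return g


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderParams:
    """How to rasterize a graph.

    ``px_per_edge`` pixels of stroke per unit edge (divisible by 4 so
    rings close exactly); ``stroke_width`` in pixels (1-3 are exactly
    invertible); intensities in [0, 1] with foreground > background.
    ``image_shape=None`` sizes the canvas to fit.
    """

    image_shape: tuple = None
    stroke_width: int = 1
    foreground: float = 1.0
    background: float = 0.0
    noise_sd: float = 0.0
    blur_sigma: float = 0.0
    px_per_edge: int = 8
    margin: int = 6
    legend: dict = None

    def __post_init__(self):
        if self.stroke_width < 1:
            raise ValueError("stroke_width must be >= 1 pixel")
        if not self.foreground > self.background:
            raise ValueError("foreground level must exceed background level")
        if self.px_per_edge % 4 or self.px_per_edge < 4:
            raise ValueError("px_per_edge must be a positive multiple of 4")


@dataclass
class RenderedImage:
    """Renderer output: the micrograph plus ground truth for round-trips."""

    image: np.ndarray
    stroke_mask: np.ndarray
    px_per_edge: int
    layout_seed: int
    placements: list = field(default_factory=list)


def _hline(px, r, c0, c1):
    for c in range(min(c0, c1), max(c0, c1) + 1):
        px.add((r, c))


def _vline(px, c, r0, r1):
    for r in range(min(r0, r1), max(r0, r1) + 1):
        px.add((r, c))


def _ring(px, side, r0=0, c0=0):
    _hline(px, r0, c0, c0 + side - 1)
    _hline(px, r0 + side - 1, c0, c0 + side - 1)
    _vline(px, c0, r0, r0 + side - 1)
    _vline(px, c0 + side - 1, r0, r0 + side - 1)


def _ring_side(loop_edges: int, p: int, stroke: int) -> int:
    # skeleton keeps 4*side - 8 pixels of a square ring (one lost per corner)
    if (loop_edges * p) % 4:
        raise LayoutError(f"cannot close a ring of {loop_edges} edges at "
                          f"{p} px/edge")
    side = loop_edges * p // 4 + 2
    # the hole must survive dilation with margin, or thinning distorts it
    min_hole = 1 if stroke == 1 else stroke + 1
    if side - 2 < min_hole:
        raise LayoutError(f"ring of {loop_edges} edges too small for "
                          f"stroke width {stroke}")
    return side


def _component_pixels(pattern: tuple, p: int, stroke: int) -> set:
    """Centerline pixels of one component, local coordinates >= 0."""
    kind, sizes = pattern
    px = set()
    if kind == "dot":
        px.add((0, 0))
    elif kind == "path":
        _hline(px, 0, 0, sizes[0] * p)
    elif kind == "cycle":
        _ring(px, _ring_side(sizes[0], p, stroke))
    elif kind == "star":
        w, e, n = sizes  # arm lengths west, east, north (edges)
        r0 = n * p
        _hline(px, r0, 0, (w + e) * p)
        _vline(px, w * p, 0, r0)
    elif kind == "theta":
        c1, c2, c3 = sizes  # c1, c2 strictly longer than the chord c3
        if c1 <= c3 or c2 <= c3:
            raise LayoutError(
                "theta needs a strictly shortest chain to render (chain "
                f"sizes {sizes}); pick sizes with a unique minimum")
        span = c3 * p
        h1 = (p * (c1 - c3) + 2) // 2  # corner-compensated bow heights
        h2 = (p * (c2 - c3) + 2) // 2
        if min(h1, h2) - 2 * (stroke // 2) < 2:
            raise LayoutError(f"theta chains too close for stroke {stroke}")
        r = h1
        _hline(px, r, 0, span)
        _hline(px, r - h1, 0, span)
        _vline(px, 0, r - h1, r)
        _vline(px, span, r - h1, r)
        _hline(px, r + h2, 0, span)
        _vline(px, 0, r, r + h2)
        _vline(px, span, r, r + h2)
    elif kind == "tadpole":
        loop, tail = sizes
        side = _ring_side(loop, p, stroke)
        if side < 5:
            raise LayoutError("tadpole loop too small to attach a tail")
        _ring(px, side)
        rm = side // 2
        _hline(px, rm, side - 1, side - 1 + tail * p)
    else:
        raise LayoutError(f"unsupported component pattern {kind!r}")
    return px


def _classify_component(sub: nx.MultiGraph) -> tuple:
    """Map a graph component to a renderable pattern ``(kind, sizes)``."""
    if sub.number_of_edges() == 0:
        return ("dot", ())
    col = collapse_chains(sub)
    edges = sorted((d["weight"] for _, _, d in col.edges(data=True)), reverse=True)
    junctions = [n for n, d in sub.degree() if d != 2]
    self_loops = [w for u, v, w in col.edges(data="weight") if u == v]
    if not junctions and len(edges) == 1:
        return ("cycle", (edges[0],))
    if len(junctions) == 2 and len(edges) == 1:
        return ("path", (edges[0],))
    degs = sorted(dict(sub.degree(junctions)).values())
    if len(junctions) == 4 and degs == [1, 1, 1, 3] and len(edges) == 3:
        w, e, n = edges
        return ("star", (w, e, n))
    if len(junctions) == 2 and degs == [1, 3] and len(self_loops) == 1 and len(edges) == 2:
        tail = [w for u, v, w in col.edges(data="weight") if u != v][0]
        return ("tadpole", (self_loops[0], tail))
    if len(junctions) == 2 and degs == [3, 3] and len(edges) == 3 and not self_loops:
        return ("theta", tuple(edges))
    raise LayoutError(
        f"component with {sub.number_of_edges()} edges and junction degrees "
        f"{degs} does not match any renderable pattern")


def _dilate(mask: np.ndarray, stroke: int) -> np.ndarray:
    if stroke <= 1:
        return mask
    from skimage.morphology import dilation, disk, footprint_rectangle

    fp = footprint_rectangle((2, 2)) if stroke == 2 else disk(stroke // 2)
    return dilation(mask, fp)


def render_graph_to_image(graph: nx.MultiGraph, params: RenderParams = None,
                          layout_seed: int = 0) -> RenderedImage:
    """Rasterize a graph into a synthetic micrograph.

    Components are classified structurally (path / cycle / 3-armed star /
    theta / tadpole / isolated dot), drawn as corner-compensated strokes
    of ``px_per_edge`` pixels per edge, dilated to ``stroke_width``, and
    packed on a jittered shelf layout.  Raises :class:`LayoutError`,
    naming the offending component, if a component has no renderable
    pattern or the requested canvas cannot hold the layout.
    """
    params = params or RenderParams()
    p, stroke = params.px_per_edge, params.stroke_width
    rng = np.random.default_rng(layout_seed)

    comp_pixels = []
    for idx, comp in enumerate(nx.connected_components(graph)):
        sub = graph.subgraph(comp)
        try:
            pattern = _classify_component(sub)
            pixels = _component_pixels(pattern, p, stroke)
        except LayoutError as err:
            raise LayoutError(f"component {idx}: {err}") from None
        rows = [r for r, _ in pixels]
        cols = [c for _, c in pixels]
        h = max(rows) - min(rows) + 1
        w = max(cols) - min(cols) + 1
        shifted = {(r - min(rows), c - min(cols)) for r, c in pixels}
        comp_pixels.append((idx, h, w, shifted))

    pad = stroke + 3 + params.margin // 2
    jitter = 2
    placements, shelf = [], []
    r_cursor = pad
    c_cursor = pad
    shelf_h = 0
    max_w = (params.image_shape[1] - pad if params.image_shape
             else int(np.ceil(np.sqrt(sum(h * w for _, h, w, _ in comp_pixels)) * 2))
             + max((w for _, _, w, _ in comp_pixels), default=0) + 2 * pad)
    for idx, h, w, pixels in comp_pixels:
        if c_cursor + w + pad > max_w and shelf:
            r_cursor += shelf_h + pad + jitter
            c_cursor = pad
            shelf_h = 0
        jr, jc = (int(rng.integers(0, jitter + 1)), int(rng.integers(0, jitter + 1)))
        placements.append((idx, r_cursor + jr, c_cursor + jc, pixels))
        shelf.append(idx)
        c_cursor += w + pad + jitter
        shelf_h = max(shelf_h, h + jitter)

    height = max((r + max(pr for pr, _ in px) for _, r, _, px in placements),
                 default=0) + pad + 1
    width = max((c + max(pc for _, pc in px) for _, _, c, px in placements),
                default=0) + pad + 1
    if params.image_shape is not None:
        if height > params.image_shape[0] or width > params.image_shape[1]:
            over = next((i for i, r, c, px in placements
                         if r + max(pr for pr, _ in px) >= params.image_shape[0]),
                        placements[-1][0] if placements else 0)
            raise LayoutError(
                f"image shape {params.image_shape} too small for the layout "
                f"(component {over} does not fit)")
        height, width = params.image_shape

    mask = np.zeros((height, width), dtype=bool)
    for _, r, c, pixels in placements:
        for pr, pc in pixels:
            mask[r + pr, c + pc] = True
    mask = _dilate(mask, stroke)

    image = np.full(mask.shape, params.background, dtype=float)
    image[mask] = params.foreground
    if params.blur_sigma > 0:
        image = gaussian_filter(image, params.blur_sigma)
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, image.shape)
    image = np.clip(image, 0.0, 1.0)
    if params.legend is not None:
        image = add_artifacts(image, legend_spec=params.legend)
    return RenderedImage(image=image, stroke_mask=mask, px_per_edge=p,
                         layout_seed=layout_seed,
                         placements=[(i, r, c) for i, r, c, _ in placements])


def add_artifacts(image: np.ndarray, legend_spec: dict = None,
                  extra_channel_spec: dict = None) -> np.ndarray:
    """Overlay non-mitochondrial artifacts on a rendered micrograph.

    ``legend_spec``: ``{"row", "col", "height", "width", "intensity"}``
    paints a bright box (a figure legend).  ``extra_channel_spec``:
    ``{"channel", "center", "radius", "intensity"}`` adds a filled disk
    in a different color channel (e.g. a red nuclear stain); a grayscale
    input is promoted to RGB with the mitochondrial signal in the green
    channel.  Pixels outside the artifacts are untouched.
    """
    out = np.array(image, dtype=float, copy=True)
    if legend_spec is not None:
        r, c = legend_spec["row"], legend_spec["col"]
        h, w = legend_spec["height"], legend_spec["width"]
        if r < 0 or c < 0 or r + h > out.shape[0] or c + w > out.shape[1]:
            raise ValueError("legend box outside image bounds")
        out[r:r + h, c:c + w] = legend_spec.get("intensity", 1.0)
    if extra_channel_spec is not None:
        if out.ndim == 2:
            rgb = np.zeros(out.shape + (3,), dtype=float)
            rgb[:, :, 1] = out
            out = rgb
        ch = {"red": 0, "green": 1, "blue": 2}.get(
            extra_channel_spec.get("channel", "red"),
            extra_channel_spec.get("channel", 0))
        cr, cc = extra_channel_spec["center"]
        rad = extra_channel_spec["radius"]
        rr, cchan = np.ogrid[:out.shape[0], :out.shape[1]]
        disk_mask = (rr - cr) ** 2 + (cchan - cc) ** 2 <= rad ** 2
        out[disk_mask, ch] = np.maximum(out[disk_mask, ch],
                                        extra_channel_spec.get("intensity", 1.0))
    return out


def sizes_to_edge_units(sizes, px_per_edge: int) -> list:
    """Map pixel-scale loop/branch sizes back to toy-edge units.

    Thinning and junction geometry perturb pixel counts by at most a few
    pixels, well under half of ``px_per_edge``, so integer rounding
    recovers the drawn sizes exactly on clean renderings.
    """
    return sorted(int(round(s / px_per_edge)) for s in sizes)


def write_synthetic_dataset(outdir, spec: ToyGraphSpec,
                            params: RenderParams = None) -> dict:
    """Render a toy spec and write image + ground truth side by side.

    Writes ``image.png`` (8-bit), ``image.tif`` (16-bit),
    ``truth.graphml`` and ``meta.json`` into ``outdir``; returns the
    metadata dict.
    """
    import imageio.v3 as iio
    import tifffile
    from pathlib import Path

    params = params or RenderParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph = make_toy_graph(spec)
    rendered = render_graph_to_image(graph, params, spec.layout_seed)
    img = np.clip(rendered.image, 0, 1)
    if img.ndim == 2:
        tifffile.imwrite(outdir / "image.tif", (img * 65535).astype(np.uint16))
    iio.imwrite(outdir / "image.png", (img * 255).astype(np.uint8))
    write_graphml(graph, outdir / "truth.graphml")
    meta = {
        "components": [asdict(c) for c in spec.components],
        "layout_seed": spec.layout_seed,
        "n_edges": spec.n_edges,
        "px_per_edge": params.px_per_edge,
        "stroke_width": params.stroke_width,
        "noise_sd": params.noise_sd,
        "blur_sigma": params.blur_sigma,
    }
    with open(outdir / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return meta
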