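"""Single-cell and population quantification from label-mask time-lapses.

Works on pairs of (integer label mask, fluorescence) frames: removes
border-touching segmentation artifacts, measures per-cell mean fluorescence
(I_cell), links cells across frames into a lineage forest with a greedy
overlap tracker, assigns generation numbers (founders are generation zero,
both daughters gain one generation at each recorded division), and reduces
frames to population series — cell count N_population, mean intensity
I_population — from which growth rates μ, intensity slopes ΔI/Δt and
fold-changes are fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import regionprops

__all__ = [
    "LabelMaskFrame",
    "CellRecord",
    "LineageForest",
    "PopulationSeries",
    "border_filter",
    "cell_intensities",
    "track_cells",
    "assign_generations",
    "population_series",
    "growth_rate",
    "intensity_slope",
    "fold_change",
    "intensity_vs_generation",
]

DEFAULT_PIXEL_SIZE_UM = 0.065


@dataclass(frozen=True)
class LabelMaskFrame:
    """One time point's integer label mask (0 = background, k > 0 = cell k)."""

    labels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_index: int = 0
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("labels must be a 2-D image")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "labels", labels)

    def cell_labels(self) -> np.ndarray:
        lab = np.unique(self.labels)
        return lab[lab > 0]


@dataclass(frozen=True)
class CellRecord:
    """Per-cell measurement at one frame."""

    frame_index: int
    cell_id: int
    centroid: tuple[float, float]
    area_um2: float
    mean_intensity: float
    timestamp_s: float = 0.0
    border_filtered: bool = False


class LineageForest:
    """Parent→child links between consecutive frames, with generations.

    Nodes are ``(frame_index, cell_id)``; each node has at most one parent
    and at most two children at the next frame.  Thin wrapper over a
    :class:`networkx.DiGraph`.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    def add_node(self, frame_index: int, cell_id: int, **attrs) -> None:
        self.graph.add_node((frame_index, cell_id), **attrs)

    def add_edge(self, parent: tuple[int, int], child: tuple[int, int]) -> None:
        if self.graph.in_degree(child) >= 1:
            raise ValueError(f"node {child} already has a parent")
        if self.graph.out_degree(parent) >= 2:
            raise ValueError(f"node {parent} already has two children")
        self.graph.add_edge(parent, child)

    @property
    def roots(self) -> list[tuple[int, int]]:
        return [n for n in self.graph.nodes if self.graph.in_degree(n) == 0]

    def n_divisions(self) -> int:
        return sum(1 for n in self.graph.nodes if self.graph.out_degree(n) == 2)

    def generation(self, node: tuple[int, int]) -> int:
        return self.graph.nodes[node]["generation"]

    def generations_at_frame(self, frame_index: int) -> dict[int, int]:
        """cell_id → generation for every cell present at the given frame."""
        return {
            n[1]: self.graph.nodes[n]["generation"]
            for n in self.graph.nodes
            if n[0] == frame_index and "generation" in self.graph.nodes[n]
        }

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parent_frame": p[0], "parent_id": p[1],
                "child_frame": c[0], "child_id": c[1],
            }
            for p, c in self.graph.edges
        ]
        return pd.DataFrame(
            rows, columns=["parent_frame", "parent_id", "child_frame", "child_id"]
        )


@dataclass(frozen=True)
class PopulationSeries:
    """Per-frame population size and mean cell intensity."""

    timestamps_s: np.ndarray
    n_population: np.ndarray
    i_population: np.ndarray  # NaN where n = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.timestamps_s,
                "n_population": self.n_population,
                "i_population": self.i_population,
            }
        )


def border_filter(
    frame: LabelMaskFrame, margin_um: float = 0.5
) -> tuple[LabelMaskFrame, list[int]]:
    """Remove cells with any pixel center within ``margin_um`` of an edge.

    Cells cut by the field of view produce truncated contours and biased
    intensities; the default 0.5 μm margin removes them.  Returns the
    filtered frame and the list of removed labels.
    """
    if margin_um < 0:
        raise ValueError("margin_um must be non-negative")
    labels = frame.labels
    margin_px = margin_um / frame.pixel_size_um
    # pixel i's center sits (i + 0.5) pixels from the image edge
    k = max(int(np.ceil(margin_px - 0.5)), 0)
    h, w = labels.shape
    if 2 * k >= min(h, w):
        warnings.warn("margin spans the whole image; all cells removed")
    border = np.zeros_like(labels, dtype=bool)
    if k > 0:
        border[:k, :] = True
        border[h - k:, :] = True
        border[:, :k] = True
        border[:, w - k:] = True
    removed = sorted(int(v) for v in np.unique(labels[border]) if v > 0)
    out = labels.copy()
    out[np.isin(out, removed)] = 0
    return (
        LabelMaskFrame(
            labels=out,
            pixel_size_um=frame.pixel_size_um,
            frame_index=frame.frame_index,
            timestamp_s=frame.timestamp_s,
        ),
        removed,
    )


def cell_intensities(
    frame: LabelMaskFrame, fluor: np.ndarray
) -> list[CellRecord]:
    """Mean fluorescence inside every labelled cell contour.

    Returns one record per retained label with centroid (pixel coordinates,
    row/col) and area in μm².
    """
    fluor = np.asarray(fluor, dtype=float)
    if fluor.shape != frame.labels.shape:
        raise ValueError(
            f"fluorescence shape {fluor.shape} does not match mask shape "
            f"{frame.labels.shape}"
        )
    px_area = frame.pixel_size_um ** 2
    records = []
    for prop in regionprops(frame.labels, intensity_image=fluor):
        records.append(
            CellRecord(
                frame_index=frame.frame_index,
                cell_id=int(prop.label),
                centroid=tuple(float(c) for c in prop.centroid),
                area_um2=float(prop.area * px_area),
                mean_intensity=float(prop.intensity_mean),
                timestamp_s=frame.timestamp_s,
            )
        )
    return records


def _pairwise_overlaps(
    prev: np.ndarray, curr: np.ndarray
) -> list[tuple[float, int, int]]:
    """(IoU, prev_label, curr_label) for every overlapping label pair."""
    a = prev.ravel().astype(np.int64)
    b = curr.ravel().astype(np.int64)
    area_a = np.bincount(a)
    area_b = np.bincount(b)
    both = (a > 0) & (b > 0)
    if not np.any(both):
        return []
    key = a[both] * (int(b.max()) + 1) + b[both]
    pairs, inter = np.unique(key, return_counts=True)
    out = []
    for k, n in zip(pairs, inter):
        la = int(k // (int(b.max()) + 1))
        lb = int(k % (int(b.max()) + 1))
        union = area_a[la] + area_b[lb] - n
        out.append((float(n / union), la, lb))
    return out


def track_cells(
    frames: list[LabelMaskFrame], min_iou: float = 0.2
) -> LineageForest:
    """Greedy overlap tracker: frame-to-frame assignment by descending
    intersection-over-union.

    Each source cell may claim up to two targets (two matches above
    ``min_iou`` ⇒ a division); unmatched targets become new lineage roots.
    Ties break deterministically by (IoU descending, target label
    ascending).  Generations are assigned on the resulting forest.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to track")
    shape = frames[0].labels.shape
    if any(f.labels.shape != shape for f in frames):
        raise ValueError("all frames must share the same geometry")

    forest = LineageForest()
    for f in frames:
        for lab in f.cell_labels():
            forest.add_node(f.frame_index, int(lab))

    for prev, curr in zip(frames[:-1], frames[1:]):
        candidates = [
            (iou, a, b)
            for iou, a, b in _pairwise_overlaps(prev.labels, curr.labels)
            if iou >= min_iou
        ]
        # IoU descending, then source label, then target label ascending
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        taken_targets: set[int] = set()
        n_matches: dict[int, int] = {}
        for iou, a, b in candidates:
            if b in taken_targets or n_matches.get(a, 0) >= 2:
                continue
            forest.add_edge(
                (prev.frame_index, a), (curr.frame_index, b)
            )
            taken_targets.add(b)
            n_matches[a] = n_matches.get(a, 0) + 1
    assign_generations(forest)
    return forest


def assign_generations(forest: LineageForest) -> LineageForest:
    """Propagate generation numbers breadth-first.

    Roots get generation 0; a child inherits its parent's generation, plus
    one if that parent divided (had two children) at the transition.
    """
    g = forest.graph
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("lineage forest contains a cycle; corrupt input")
    for node in nx.topological_sort(g):
        preds = list(g.predecessors(node))
        if not preds:
            g.nodes[node]["generation"] = 0
        else:
            parent = preds[0]
            bump = 1 if g.out_degree(parent) == 2 else 0
            g.nodes[node]["generation"] = g.nodes[parent]["generation"] + bump
    return forest


def population_series(
    records_per_frame: list[list[CellRecord]],
    timestamps_s: np.ndarray | None = None,
) -> PopulationSeries:
    """Reduce per-frame cell records to N_population and I_population.

    I_population is the *unweighted* mean of I_cell over retained cells and
    is undefined (NaN) on empty frames.  ``timestamps_s`` overrides the
    record timestamps (required when frames can be empty).
    """
    times, counts, means = [], [], []
    for i, records in enumerate(records_per_frame):
        if timestamps_s is not None:
            times.append(float(timestamps_s[i]))
        elif records:
            times.append(records[0].timestamp_s)
        else:
            times.append(times[-1] + 1.0 if times else 0.0)
        if records:
            counts.append(len(records))
            means.append(float(np.mean([r.mean_intensity for r in records])))
        else:
            counts.append(0)
            means.append(np.nan)
    return PopulationSeries(
        timestamps_s=np.asarray(times, dtype=float),
        n_population=np.asarray(counts, dtype=int),
        i_population=np.asarray(means, dtype=float),
    )


def _window_mask(t_h: np.ndarray, window) -> np.ndarray:
    if window is None:
        return np.ones_like(t_h, dtype=bool)
    lo, hi = window
    return (t_h >= lo) & (t_h <= hi)


def growth_rate(
    series: PopulationSeries, window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Population growth rate μ (h⁻¹) by OLS of ln(N) against time.

    Parameters
    ----------
    window
        (start_h, end_h) fit window in hours since experiment start;
        ``None`` fits the whole series.  Frames with N = 0 are skipped with
        a warning.

    Returns
    -------
    (mu, stderr)
        Slope of ln N vs t in h⁻¹ and its OLS standard error.
    """
    t_h = series.timestamps_s / 3600.0
    mask = _window_mask(t_h, window) & (series.n_population > 0)
    n_zero = int(np.sum(_window_mask(t_h, window) & (series.n_population == 0)))
    if n_zero:
        warnings.warn(f"skipped {n_zero} frames with zero cells")
    if mask.sum() < 3:
        raise ValueError("need at least 3 frames with cells in the window")
    fit = stats.linregress(t_h[mask], np.log(series.n_population[mask]))
    return float(fit.slope), float(fit.stderr)


def intensity_slope(
    series: PopulationSeries, window: tuple[float, float] | None = None
) -> tuple[float, float, float]:
    """ΔI_population/Δt (a.u. h⁻¹) by OLS over the window.

    Returns (slope, stderr, r_squared); frames with undefined I are skipped.
    """
    t_h = series.timestamps_s / 3600.0
    mask = _window_mask(t_h, window) & np.isfinite(series.i_population)
    if mask.sum() < 3:
        raise ValueError("need at least 3 frames with intensities in the window")
    fit = stats.linregress(t_h[mask], series.i_population[mask])
    return float(fit.slope), float(fit.stderr), float(fit.rvalue ** 2)


def fold_change(slope_post: float, slope_pre: float) -> tuple[float, int]:
    """Ratio of two intensity slopes and its nearest-integer fold.

    The sign is preserved in the ratio; the fold is the rounded ratio.
    """
    if slope_pre == 0:
        raise ValueError("reference slope is zero; fold-change undefined")
    ratio = slope_post / slope_pre
    return ratio, int(np.floor(ratio + 0.5))


def intensity_vs_generation(
    records: list[CellRecord], forest: LineageForest, frame_index: int | None = None
) -> pd.DataFrame:
    """Per-cell (generation, I_cell) table at one frame.

    Use :func:`generation_summary` / :func:`generation_correlation` on the
    result for per-generation statistics and the rank correlation between
    generation number and intensity.
    """
    if frame_index is None:
        frames = {r.frame_index for r in records}
        if len(frames) != 1:
            raise ValueError("records span multiple frames; pass frame_index")
        frame_index = frames.pop()
    gen = forest.generations_at_frame(frame_index)
    rows = []
    for r in records:
        if r.frame_index != frame_index:
            continue
        if r.cell_id not in gen:
            continue
        rows.append(
            {
                "cell_id": r.cell_id,
                "generation": gen[r.cell_id],
                "i_cell": r.mean_intensity,
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "generation", "i_cell"])


def generation_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Count, mean and SD of I_cell per generation."""
    return (
        table.groupby("generation")["i_cell"]
        .agg(["count", "mean", "std"])
        .reset_index()
    )


def generation_correlation(table: pd.DataFrame) -> float:
    """Spearman rank correlation between generation and I_cell."""
    if len(table) < 2:
        raise ValueError("need at least 2 cells")
    rho = stats.spearmanr(table["generation"], table["i_cell"]).statistic
    return float(rho)
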