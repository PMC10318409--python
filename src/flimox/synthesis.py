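"""Synthetic data generator for the oxygen-control FLIM pipeline.

Emulates, with exact ground truth, everything the analysis consumes:

* **Chip oxygen dynamics** — the PDMS chip equilibrates with the supplied gas
  by diffusion, so the chamber concentration relaxes toward each programmed
  setpoint as a lumped first-order system, ``c(t) = s + (c0 − s)·exp(−t/T)``.
  The default time constant T = 37 min follows the diffusion scaling
  t ≈ d²/D for a millimetre-scale PDMS slab (D_O2 ≈ 1e−9 m²/s) and puts
  t90 = T·ln 10 ≈ 85 min in the experimentally observed 80–90 min band.

* **FLIM stacks** — the RTDP sensor lifetime follows the forward
  Stern–Volmer model τ = τ0/(1 + Kq·[O2]); each frame is rendered as a
  K-phase-step modulated intensity stack with optional Gaussian or Poisson
  pixel noise.

* **Monolayer micro-colonies** — rod-shaped cells grow exponentially in a
  50×30 μm chamber of 1 μm height (one cell layer).  Interdivision times are
  lognormal; their mean is set by the Euler–Lotka renewal condition so the
  expected population growth rate equals the requested μ.  Each cell carries
  an immature (dark) and a mature (fluorescent) GFP pool: expression fills
  the immature pool, maturation converts it at a first-order rate *only when
  oxygen is available*, and division partitions both pools between the
  daughters in proportion to their lengths — so fluorescence dilutes in
  fast-dividing lineages.  Cells pushed past the open chamber ends exit into
  the supply channels and are removed (but stay in the GFP ledger).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .cellquant import CellRecord, LineageForest, PopulationSeries, population_series
from .fdflim import DEFAULT_FREQUENCY_HZ, ModulatedFrameStack
from .oxygen import (
    O2Trace,
    SternVolmerCalibration,
    StepSchedule,
    fit_stern_volmer,
    lifetime_from_o2,
)

__all__ = [
    "O2ResponseModel",
    "ChamberGeometry",
    "GFPKinetics",
    "SyntheticDataset",
    "Experiment",
    "simulate_o2_response",
    "simulate_flim_series",
    "simulate_colony",
    "render_frames",
    "make_experiment",
    "DEFAULT_CALIBRATION_30C",
]

#: Two-point RTDP calibration measured at 30°C (τ0 = 526 ns, τ100% = 144 ns).
DEFAULT_CALIBRATION_30C = fit_stern_volmer(526.0, 144.0, 1.0, 30.0)


@dataclass(frozen=True)
class O2ResponseModel:
    """Lumped first-order model of the chip's gas-exchange dynamics.

    ``response_time_constant_min`` is a free parameter, not a PDMS physics
    claim; the classmethod derives an order-of-magnitude value from the
    diffusion scaling t ≈ d²/D.
    """

    response_time_constant_min: float = 37.0

    def __post_init__(self) -> None:
        if self.response_time_constant_min <= 0:
            raise ValueError("time constant must be positive")

    @classmethod
    def from_diffusion(
        cls, thickness_m: float, diffusion_m2_s: float = 1e-9
    ) -> "O2ResponseModel":
        """T ≈ d²/D, converted to minutes."""
        return cls(response_time_constant_min=thickness_m**2 / diffusion_m2_s / 60.0)


@dataclass(frozen=True)
class ChamberGeometry:
    """Monolayer cultivation chamber; the 1 μm height confines cells to a
    single focal plane (one E. coli diameter)."""

    width_um: float = 50.0
    depth_um: float = 30.0
    height_um: float = 1.0

    @property
    def volume_pl(self) -> float:
        """Chamber volume in pL (1 μm³ = 1 fL)."""
        return self.width_um * self.depth_um * self.height_um * 1e-3

    @property
    def area_um2(self) -> float:
        return self.width_um * self.depth_um


@dataclass(frozen=True)
class GFPKinetics:
    """Expression → O2-gated maturation → dilution-by-division kinetics.

    ``expression_rate`` is the fully induced immature-GFP production per
    cell (a.u. h⁻¹); induction builds up linearly over
    ``induction_ramp_h`` after the inducer is introduced at t = 0, which
    reproduces the near-linear population fluorescence rise seen in
    continuously induced aerobic cultures.  Maturation is first-order at
    ``maturation_rate_per_h`` and halts completely below ``o2_min`` (the
    chromophore's final folding step requires oxygen; the literature bound
    is ~0.1 ppm, effectively zero on the 0–100% scale used here).
    """

    expression_rate: float = 850.0
    maturation_rate_per_h: float = 0.5
    o2_min: float = 1e-4
    bleaching_rate_per_h: float = 0.0
    induction_ramp_h: float = 9.0

    def __post_init__(self) -> None:
        if min(self.expression_rate, self.maturation_rate_per_h,
               self.bleaching_rate_per_h) < 0:
            raise ValueError("rates must be non-negative")

    def expression_at(self, t_h: float) -> float:
        if self.induction_ramp_h <= 0:
            return self.expression_rate
        return self.expression_rate * min(t_h / self.induction_ramp_h, 1.0)


def simulate_o2_response(
    schedule: StepSchedule,
    model: O2ResponseModel = O2ResponseModel(),
    sample_interval_min: float | None = None,
) -> O2Trace:
    """Ground-truth chamber O2 over a programmed step schedule.

    Within each step the concentration relaxes first-order from its entry
    value toward the setpoint, continuously across step boundaries.
    """
    if sample_interval_min is None:
        sample_interval_min = schedule.sample_interval_min
    total_s = schedule.total_duration_h * 3600.0
    times = np.arange(0.0, total_s + 1e-9, sample_interval_min * 60.0)
    tau_s = model.response_time_constant_min * 60.0
    o2 = np.empty_like(times)
    c = schedule.levels_percent[0] / 100.0  # start equilibrated at level 0
    bounds = schedule.step_bounds_s()
    levels = [v / 100.0 for v in schedule.levels_percent]
    for (start, end), s in zip(bounds, levels):
        mask = (times >= start) & (times <= end) if end == bounds[-1][1] \
            else (times >= start) & (times < end)
        o2[mask] = s + (c - s) * np.exp(-(times[mask] - start) / tau_s)
        c = s + (c - s) * math.exp(-(end - start) / tau_s)
    return O2Trace(times_s=times, o2_fraction=o2, source_roi="simulated")


def simulate_flim_series(
    o2_trace: O2Trace,
    calib: SternVolmerCalibration = DEFAULT_CALIBRATION_30C,
    image_shape: tuple[int, int] = (32, 32),
    noise_sd: float = 0.0,
    photon_noise: bool = False,
    dc_level: float = 1000.0,
    f_hz: float = DEFAULT_FREQUENCY_HZ,
    k_phases: int = 8,
    seed: int | None = None,
) -> list[ModulatedFrameStack]:
    """Render an O2 trace as phase-stepped modulated FLIM stacks.

    Per frame, the sensor lifetime is τ(t) = τ0/(1 + Kq·[O2](t)); every
    pixel's K-step series has phase arctan(ωτ) and modulation depth
    1/sqrt(1+(ωτ)²) around ``dc_level``, with optional additive Gaussian
    (``noise_sd``, counts) or Poisson (``photon_noise``) pixel noise.
    """
    rng = np.random.default_rng(seed)
    omega = 2 * np.pi * f_hz
    angles = 2 * np.pi * np.arange(k_phases) / k_phases
    stacks = []
    for t_s, o2 in zip(o2_trace.times_s, o2_trace.o2_fraction):
        tau_s = lifetime_from_o2(max(float(o2), 0.0), calib) * 1e-9
        phi = math.atan(omega * tau_s)
        m = 1.0 / math.sqrt(1.0 + (omega * tau_s) ** 2)
        series = dc_level * (1.0 + m * np.cos(angles - phi))
        pixels = np.broadcast_to(
            series[:, None, None], (k_phases, *image_shape)
        ).copy()
        if photon_noise:
            pixels = rng.poisson(pixels).astype(float)
        elif noise_sd > 0:
            pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)
            pixels = np.clip(pixels, 0.0, None)
        stacks.append(
            ModulatedFrameStack(
                pixels=pixels,
                modulation_frequency_hz=f_hz,
                timestamp_s=float(t_s),
            )
        )
    return stacks


# --------------------------------------------------------------------------
# monolayer colony simulation
# --------------------------------------------------------------------------

def euler_lotka_mean_interdivision_h(
    target_mu_per_h: float, division_cv: float
) -> float:
    """Mean of the lognormal interdivision time giving population growth μ.

    For symmetric binary fission with i.i.d. interdivision times T the
    population growth rate μ satisfies the renewal condition
    ``2·E[exp(−μT)] = 1``.  With T deterministic this reduces to
    T = ln2/μ; dispersion (CV > 0) shifts the required mean upward.
    """
    if target_mu_per_h <= 0:
        raise ValueError("target growth rate must be positive")
    if division_cv < 0:
        raise ValueError("division_cv must be non-negative")
    if division_cv == 0:
        return math.log(2.0) / target_mu_per_h
    sigma2 = math.log(1.0 + division_cv**2)
    sigma = math.sqrt(sigma2)
    nodes, weights = np.polynomial.hermite.hermgauss(60)

    def condition(mean_h: float) -> float:
        mu_ln = math.log(mean_h) - sigma2 / 2.0
        t = np.exp(mu_ln + sigma * math.sqrt(2.0) * nodes)
        e = np.sum(weights * np.exp(-target_mu_per_h * t)) / math.sqrt(math.pi)
        return 2.0 * e - 1.0

    t0 = math.log(2.0) / target_mu_per_h
    return brentq(condition, 0.3 * t0, 3.0 * t0, xtol=1e-10)


@dataclass
class _Cell:
    uid: int
    parent_uid: int | None
    generation: int
    birth_time_h: float
    interdivision_h: float
    x: float
    y: float
    angle: float
    length_um: float
    width_um: float
    immature: float
    mature: float

    @property
    def division_time_h(self) -> float:
        return self.birth_time_h + self.interdivision_h

    @property
    def growth_rate_per_h(self) -> float:
        # doubles its length over one interdivision interval
        return math.log(2.0) / self.interdivision_h

    @property
    def area_um2(self) -> float:
        return self.length_um * self.width_um


@dataclass
class SyntheticDataset:
    """One simulated chamber: per-frame cell tables plus full ground truth."""

    frame_times_s: np.ndarray
    cells: list[pd.DataFrame]           # one table per frame
    forest: LineageForest               # ground-truth lineage, generations set
    o2: O2Trace                         # oxygen seen by the cells
    geometry: ChamberGeometry
    gfp: GFPKinetics
    target_mu_per_h: float
    seed: int
    cumulative_expression: float
    cumulative_bleached: float
    gfp_in_exited: float
    n_exited: int
    crowding_stop: bool
    fluorescence: np.ndarray | None = None   # (T, H, W) if rendered
    masks: np.ndarray | None = None          # (T, H, W) if rendered
    pixel_size_um: float | None = None

    def truth_records(self, frame_index: int) -> list[CellRecord]:
        """Cell records built from ground truth (I_cell = mature GFP per
        μm² of cell area), usable by every cellquant operation."""
        table = self.cells[frame_index]
        t_s = float(self.frame_times_s[frame_index])
        return [
            CellRecord(
                frame_index=frame_index,
                cell_id=int(row.label),
                centroid=(float(row.y), float(row.x)),
                area_um2=float(row.length_um * row.width_um),
                mean_intensity=float(row.mature / (row.length_um * row.width_um)),
                timestamp_s=t_s,
            )
            for row in table.itertuples()
        ]

    def population(self) -> PopulationSeries:
        """Ground-truth N_population and I_population per frame."""
        return population_series(
            [self.truth_records(i) for i in range(len(self.cells))],
            timestamps_s=self.frame_times_s,
        )

    def total_mature_per_frame(self) -> np.ndarray:
        return np.array([float(t["mature"].sum()) for t in self.cells])

    def gfp_ledger_total(self) -> float:
        """Immature + mature over living and exited cells (conservation)."""
        live = float(self.cells[-1][["immature", "mature"]].to_numpy().sum())
        return live + self.gfp_in_exited


def _o2_interpolator(o2_trace: O2Trace | float):
    if isinstance(o2_trace, (int, float)):
        level = float(o2_trace)
        return lambda t_h: level
    t = o2_trace.times_s / 3600.0
    v = o2_trace.o2_fraction
    return lambda t_h: float(np.interp(t_h, t, v))


def _relax_overlaps(cells: list[_Cell], geometry: ChamberGeometry,
                    n_iter: int = 3) -> None:
    """Pairwise push-apart along the centroid axis; walls confine in y,
    the x ends are open (supply channels)."""
    n = len(cells)
    if n < 2:
        return
    for _ in range(n_iter):
        xy = np.array([[c.x, c.y] for c in cells])
        half = np.array([max((c.length_um - c.width_um) / 2.0, 0.0) for c in cells])
        ang = np.array([c.angle for c in cells])
        width = np.array([c.width_um for c in cells])
        axis = np.stack([np.cos(ang), np.sin(ang)], axis=1)
        p0 = xy - axis * half[:, None]
        p1 = xy + axis * half[:, None]
        max_reach = half + width / 2.0
        tree = cKDTree(xy)
        pairs = tree.query_pairs(2.0 * float(max_reach.max()) + 1e-6,
                                 output_type="ndarray")
        if len(pairs) == 0:
            break
        i, j = pairs[:, 0], pairs[:, 1]
        d = _segment_distance(p0[i], p1[i], p0[j], p1[j])
        touch = (width[i] + width[j]) / 2.0
        overlap = touch - d
        hit = overlap > 1e-9
        if not np.any(hit):
            break
        i, j, overlap = i[hit], j[hit], overlap[hit]
        delta = xy[j] - xy[i]
        norm = np.linalg.norm(delta, axis=1)
        # coincident centroids: push along x deterministically
        unit = np.where(norm[:, None] > 1e-9, delta / np.maximum(norm, 1e-9)[:, None],
                        np.array([1.0, 0.0]))
        shift = 0.5 * overlap[:, None] * unit
        moves = np.zeros((n, 2))
        np.add.at(moves, i, -shift)
        np.add.at(moves, j, shift)
        for k, c in enumerate(cells):
            c.x += moves[k, 0]
            c.y += moves[k, 1]
            ext_y = abs(math.sin(c.angle)) * max((c.length_um - c.width_um) / 2, 0) \
                + c.width_um / 2
            c.y = min(max(c.y, ext_y), geometry.depth_um - ext_y)


def _segment_distance(a0, a1, b0, b1):
    """Vectorized minimum distance between segment pairs (a0,a1)-(b0,b1)."""
    d1 = a1 - a0
    d2 = b1 - b0
    r = a0 - b0
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = a * e - b * b
    s = np.where(denom > 1e-12, (b * f - c * e) / np.where(denom > 1e-12, denom, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    t = np.where(e > 1e-12, (b * s + f) / np.where(e > 1e-12, e, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    s = np.where(a > 1e-12, np.clip((b * t - c) / np.where(a > 1e-12, a, 1.0), 0.0, 1.0), 0.0)
    pa = a0 + s[:, None] * d1
    pb = b0 + t[:, None] * d2
    return np.linalg.norm(pa - pb, axis=1)


def simulate_colony(
    geometry: ChamberGeometry = ChamberGeometry(),
    target_mu_per_h: float = 0.55,
    division_cv: float = 0.2,
    gfp: GFPKinetics = GFPKinetics(),
    o2_trace: O2Trace | float = 0.21,
    frame_interval_min: float = 5.0,
    duration_h: float = 9.0,
    n_seed_cells: int = 2,
    seed: int = 0,
    dt_min: float = 1.0,
    birth_length_um: float = 2.5,
    cell_width_um: float = 1.0,
    max_packing: float = 0.9,
) -> SyntheticDataset:
    """Agent-based monolayer micro-colony with O2-gated GFP maturation.

    Rod cells elongate exponentially (each doubles its birth length over its
    drawn interdivision time) and divide symmetrically; GFP pools split in
    proportion to daughter lengths.  Oxygen (``o2_trace``: a constant
    fraction or an :class:`~flimox.oxygen.O2Trace`) gates maturation.  Cells
    whose centroid leaves the open chamber ends are removed and logged.
    The simulation stops early with a flag if the packing fraction exceeds
    ``max_packing``.
    """
    rng = np.random.default_rng(seed)
    mean_interdiv = euler_lotka_mean_interdivision_h(target_mu_per_h, division_cv)
    sigma2 = math.log(1.0 + division_cv**2) if division_cv > 0 else 0.0
    sigma = math.sqrt(sigma2)

    def draw_interdivision() -> float:
        if sigma == 0:
            return mean_interdiv
        return float(rng.lognormal(math.log(mean_interdiv) - sigma2 / 2, sigma))

    o2_at = _o2_interpolator(o2_trace)
    next_uid = 0
    cells: list[_Cell] = []
    for i in range(n_seed_cells):
        interdiv = draw_interdivision()
        age_frac = float(rng.uniform(0.0, 1.0))
        cells.append(
            _Cell(
                uid=next_uid, parent_uid=None, generation=0,
                birth_time_h=-age_frac * interdiv, interdivision_h=interdiv,
                x=geometry.width_um * (i + 1) / (n_seed_cells + 1),
                y=geometry.depth_um / 2.0 + float(rng.normal(0, 1.0)),
                angle=float(rng.normal(0.0, 0.2)),
                length_um=birth_length_um * 2.0 ** age_frac,
                width_um=cell_width_um,
                immature=0.0, mature=0.0,
            )
        )
        next_uid += 1

    dt_h = dt_min / 60.0
    n_steps = int(round(duration_h * 60.0 / dt_min))
    frame_every = max(int(round(frame_interval_min / dt_min)), 1)
    cumulative_expression = 0.0
    cumulative_bleached = 0.0
    gfp_in_exited = 0.0
    n_exited = 0
    crowding_stop = False

    frame_times: list[float] = []
    frames: list[pd.DataFrame] = []
    uid_history: list[dict[int, int]] = []  # per frame: uid -> label
    parent_of: dict[int, int | None] = {c.uid: None for c in cells}
    generation_of: dict[int, int] = {c.uid: 0 for c in cells}

    def snapshot(t_h: float) -> None:
        order = sorted(cells, key=lambda c: c.uid)
        frames.append(
            pd.DataFrame(
                {
                    "label": np.arange(1, len(order) + 1, dtype=int),
                    "uid": [c.uid for c in order],
                    "parent_uid": [
                        -1 if c.parent_uid is None else c.parent_uid for c in order
                    ],
                    "generation": [c.generation for c in order],
                    "x": [c.x for c in order],
                    "y": [c.y for c in order],
                    "angle": [c.angle for c in order],
                    "length_um": [c.length_um for c in order],
                    "width_um": [c.width_um for c in order],
                    "immature": [c.immature for c in order],
                    "mature": [c.mature for c in order],
                }
            )
        )
        frame_times.append(t_h * 3600.0)
        uid_history.append({c.uid: lbl for lbl, c in enumerate(order, start=1)})

    snapshot(0.0)
    for step in range(1, n_steps + 1):
        t_h = step * dt_h
        # growth
        for c in cells:
            c.length_um *= math.exp(c.growth_rate_per_h * dt_h)
        # expression (rate evaluated mid-step for 2nd-order accuracy)
        rate = gfp.expression_at(t_h - dt_h / 2.0)
        for c in cells:
            c.immature += rate * dt_h
        cumulative_expression += rate * dt_h * len(cells)
        # O2-gated maturation and bleaching
        if o2_at(t_h) >= gfp.o2_min and gfp.maturation_rate_per_h > 0:
            frac = 1.0 - math.exp(-gfp.maturation_rate_per_h * dt_h)
            for c in cells:
                dm = c.immature * frac
                c.immature -= dm
                c.mature += dm
        if gfp.bleaching_rate_per_h > 0:
            keep = math.exp(-gfp.bleaching_rate_per_h * dt_h)
            for c in cells:
                cumulative_bleached += c.mature * (1.0 - keep)
                c.mature *= keep
        # divisions (deterministic order by uid)
        newborns: list[_Cell] = []
        survivors: list[_Cell] = []
        for c in sorted(cells, key=lambda cc: cc.uid):
            if t_h < c.division_time_h:
                survivors.append(c)
                continue
            half_len = c.length_um / 2.0
            offset = c.length_um / 4.0
            dx, dy = math.cos(c.angle), math.sin(c.angle)
            for sign in (-1.0, 1.0):
                interdiv = draw_interdivision()
                child = _Cell(
                    uid=next_uid, parent_uid=c.uid,
                    generation=c.generation + 1,
                    birth_time_h=c.division_time_h,
                    interdivision_h=interdiv,
                    x=c.x + sign * offset * dx,
                    y=c.y + sign * offset * dy,
                    angle=c.angle + float(rng.normal(0.0, 0.1)),
                    length_um=half_len, width_um=c.width_um,
                    immature=c.immature / 2.0, mature=c.mature / 2.0,
                )
                parent_of[child.uid] = c.uid
                generation_of[child.uid] = child.generation
                newborns.append(child)
                next_uid += 1
        cells = survivors + newborns
        # mechanics + exits
        _relax_overlaps(cells, geometry)
        kept = []
        for c in cells:
            if 0.0 <= c.x <= geometry.width_um:
                kept.append(c)
            else:
                gfp_in_exited += c.immature + c.mature
                n_exited += 1
        cells = kept
        if sum(c.area_um2 for c in cells) / geometry.area_um2 > max_packing:
            crowding_stop = True
            snapshot(t_h)
            break
        if step % frame_every == 0:
            snapshot(t_h)

    forest = _truth_forest(frames, parent_of)
    if isinstance(o2_trace, (int, float)):
        times = np.asarray(frame_times)
        o2 = O2Trace(
            times_s=times,
            o2_fraction=np.full(len(times), float(o2_trace)),
            source_roi="constant",
        )
    else:
        o2 = o2_trace
    return SyntheticDataset(
        frame_times_s=np.asarray(frame_times),
        cells=frames,
        forest=forest,
        o2=o2,
        geometry=geometry,
        gfp=gfp,
        target_mu_per_h=target_mu_per_h,
        seed=seed,
        cumulative_expression=cumulative_expression,
        cumulative_bleached=cumulative_bleached,
        gfp_in_exited=gfp_in_exited,
        n_exited=n_exited,
        crowding_stop=crowding_stop,
    )


def _truth_forest(
    frames: list[pd.DataFrame], parent_of: dict[int, int | None]
) -> LineageForest:
    """Ground-truth lineage forest over the recorded frames.

    A cell present in consecutive frames is linked to itself; a newborn is
    linked to its most recent ancestor present in the previous frame.
    Generations come from the simulator, not from re-derivation.
    """
    forest = LineageForest()
    for fi, table in enumerate(frames):
        for row in table.itertuples():
            forest.add_node(fi, int(row.label), generation=int(row.generation),
                            uid=int(row.uid))
    for fi in range(1, len(frames)):
        prev_label = {int(r.uid): int(r.label) for r in frames[fi - 1].itertuples()}
        for row in frames[fi].itertuples():
            uid = int(row.uid)
            anc = uid
            while anc is not None and anc not in prev_label:
                anc = parent_of.get(anc)
            if anc is None:
                continue
            forest.add_edge((fi - 1, prev_label[anc]), (fi, int(row.label)))
    return forest


def render_frames(
    dataset: SyntheticDataset,
    pixel_size_um: float = 0.1,
    psf_sigma_um: float = 0.0,
    background: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    pad_um: float = 2.0,
) -> SyntheticDataset:
    """Rasterize a colony as paired fluorescence and label-mask frames.

    Masks paint each rod (capsule footprint) with its frame-local label;
    fluorescence paints the cell's mature-GFP concentration (a.u. per μm²)
    over the same footprint, optionally blurred with a Gaussian PSF and
    degraded with background plus Gaussian noise.  The field of view extends
    ``pad_um`` beyond the chamber on every side, as in cropped chamber
    images where the walls sit inside the frame.  Returns a copy of the
    dataset with ``fluorescence``, ``masks`` and ``pixel_size_um`` set.
    """
    import warnings as _warnings

    from scipy.ndimage import gaussian_filter

    if pixel_size_um > 0.5:
        _warnings.warn(
            f"pixel size {pixel_size_um} μm is too coarse to separate "
            "1-μm-wide cells"
        )
    rng = np.random.default_rng(seed)
    geom = dataset.geometry
    h = int(round((geom.depth_um + 2 * pad_um) / pixel_size_um))
    w = int(round((geom.width_um + 2 * pad_um) / pixel_size_um))
    n_frames = len(dataset.cells)
    fluor = np.zeros((n_frames, h, w), dtype=np.float32)
    masks = np.zeros((n_frames, h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    px_x = (xx + 0.5) * pixel_size_um - pad_um
    px_y = (yy + 0.5) * pixel_size_um - pad_um
    for fi, table in enumerate(dataset.cells):
        for row in table.itertuples():
            half = max((row.length_um - row.width_um) / 2.0, 0.0)
            dx, dy = math.cos(row.angle), math.sin(row.angle)
            # restrict to a bounding box around the cell
            reach = half + row.width_um / 2.0 + pixel_size_um
            x0 = max(int((row.x + pad_um - reach) / pixel_size_um), 0)
            x1 = min(int((row.x + pad_um + reach) / pixel_size_um) + 2, w)
            y0 = max(int((row.y + pad_um - reach) / pixel_size_um), 0)
            y1 = min(int((row.y + pad_um + reach) / pixel_size_um) + 2, h)
            if x0 >= x1 or y0 >= y1:
                continue
            bx = px_x[y0:y1, x0:x1] - row.x
            by = px_y[y0:y1, x0:x1] - row.y
            proj = np.clip(bx * dx + by * dy, -half, half)
            dist2 = (bx - proj * dx) ** 2 + (by - proj * dy) ** 2
            inside = dist2 <= (row.width_um / 2.0) ** 2
            conc = row.mature / (row.length_um * row.width_um)
            sub_m = masks[fi, y0:y1, x0:x1]
            sub_f = fluor[fi, y0:y1, x0:x1]
            sub_m[inside] = int(row.label)
            sub_f[inside] = conc
        if psf_sigma_um > 0:
            fluor[fi] = gaussian_filter(
                fluor[fi], sigma=psf_sigma_um / pixel_size_um, mode="constant"
            )
        if background:
            fluor[fi] += background
        if noise_sd > 0:
            fluor[fi] += rng.normal(0.0, noise_sd, size=(h, w)).astype(np.float32)
    return replace(
        dataset, fluorescence=fluor, masks=masks, pixel_size_um=pixel_size_um
    )


@dataclass(frozen=True)
class Experiment:
    """A preset study: replicate chambers plus the oxygen programme."""

    preset: str
    datasets: list[SyntheticDataset]
    o2: O2Trace
    schedule: StepSchedule | None
    switch_time_h: float | None = None


#: Growth regimes observed for E. coli MG1655 on this chip (h⁻¹).
AEROBIC_MU_PER_H = 0.55
ANAEROBIC_MU_PER_H = 0.52

PRESETS = ("aerobic", "anaerobic_switch", "step_test")


def make_experiment(
    preset: str,
    seed: int = 0,
    n_chambers: int = 5,
    response: O2ResponseModel = O2ResponseModel(),
    gfp: GFPKinetics = GFPKinetics(),
    division_cv: float = 0.2,
) -> Experiment:
    """Build one of the three canonical study designs.

    * ``aerobic`` — constant 21% O2, 9 h, μ target 0.55 h⁻¹.
    * ``anaerobic_switch`` — 0% O2 for 8 h, then a switch to 21% filtered by
      the chip's first-order response; 9 h total, μ target 0.52 h⁻¹.
    * ``step_test`` — the default 9-level step schedule through the chip
      response model (no colonies; sensor characterization).

    Chamber seeds derive deterministically from ``seed``.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    if preset == "step_test":
        schedule = StepSchedule()
        trace = simulate_o2_response(schedule, response)
        return Experiment(preset=preset, datasets=[], o2=trace, schedule=schedule)

    duration_h = 9.0
    times = np.arange(0.0, duration_h * 3600.0 + 1e-9, 300.0)
    if preset == "aerobic":
        o2 = O2Trace(times_s=times, o2_fraction=np.full(len(times), 0.21),
                     source_roi="aerobic")
        mu, switch = AEROBIC_MU_PER_H, None
    else:
        switch = 8.0
        tau_s = response.response_time_constant_min * 60.0
        o2_vals = np.where(
            times < switch * 3600.0,
            0.0,
            0.21 * (1.0 - np.exp(-(times - switch * 3600.0) / tau_s)),
        )
        o2 = O2Trace(times_s=times, o2_fraction=o2_vals, source_roi="switch")
        mu = ANAEROBIC_MU_PER_H
    datasets = [
        simulate_colony(
            target_mu_per_h=mu,
            division_cv=division_cv,
            gfp=gfp,
            o2_trace=o2,
            duration_h=duration_h,
            n_seed_cells=2,
            seed=seed * 1000 + i + 1,
        )
        for i in range(n_chambers)
    ]
    return Experiment(
        preset=preset, datasets=datasets, o2=o2, schedule=None,
        switch_time_h=switch,
    )
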