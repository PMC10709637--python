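"""Seeded synthetic-data generators for every input class of the pipeline.

These produce fluorescence traces, reconstitution series, decarboxylation
time courses and coarse-grained trajectory frames with the statistical
structure the analysis stages assume: exponential bleaching/extraction
phases, Poisson vesicle occupancy, the 4-state linear import kinetics, and
bilayers with planted transbilayer flip events, a hydrated defect disc and
a thinned patch. Noise is multiplicative Gaussian on the normalized signal
(sigma default 0.02); all generators are deterministic for a fixed seed.

The generators emulate the *kinetic structure* of the assays only — no
photophysics (bleaching drift, inner-filter effects) and no real
force-field dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assay import FluorescenceTrace, compute_F_min_bsa
from .kinetics import DecarbTimeCourse, KineticParameters, closed_form
from .reconstitution import ReconstitutionPoint
from .trajectory import TrajectoryFrame

__all__ = [
    "TraceSpec",
    "DecarbSpec",
    "TrajectorySpec",
    "DiscRegion",
    "generate_trace",
    "generate_occupancy_series",
    "generate_decarb_timecourse",
    "generate_trajectory",
    "PLC_UNTREATED_CPM",
    "PLC_TRITON_MAX_CPM",
]

#: Scintillation-count scale used for synthetic phospholipase series.
PLC_UNTREATED_CPM = 200.0
PLC_TRITON_MAX_CPM = 20200.0

#: Default noise level (relative Gaussian) on normalized signals.
DEFAULT_NOISE_SD = 0.02


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of one synthetic assay trace.

    half_times holds per-phase half-times in seconds (fast, slow); for the
    slow-scrambling assay the single half-time is in the unit of the time
    axis (hours). f_refractory is the non-bleachable vesicle fraction folded
    into the floor (F_dith_min_floor = f_refractory / 2).
    """

    assay_kind: str = "dithionite"
    f_pore: float = 0.0
    f_scr: float = 0.0
    phi: float = 0.4
    outer_fraction: float = 0.5
    half_times: tuple[float, ...] = (7.0, 50.0)
    baseline_duration: float = 30.0
    total_duration: float = 400.0
    sampling_interval: float = 1.0
    noise_sd: float = DEFAULT_NOISE_SD
    f_refractory: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("f_pore", "f_scr", "outer_fraction", "f_refractory"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must lie in (0, 1)")
        if any(h <= 0 for h in self.half_times):
            raise ValueError("half_times must be > 0")
        if self.sampling_interval <= 0 or self.total_duration <= 0:
            raise ValueError("durations and sampling interval must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: Default TLC aliquot schedule (s): minute-scale early samples resolve the
#: scrambling step (expected half-times tens to hundreds of seconds), the
#: tail tracks the decarboxylation-limited approach to completion.
DECARB_SCHEDULE_S = (0.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0, 300.0, 450.0, 600.0, 1200.0, 1800.0)


@dataclass(frozen=True)
class DecarbSpec:
    """Parameters of synthetic PS->PE decarboxylation time courses."""

    params: KineticParameters
    time_points: tuple[float, ...] = DECARB_SCHEDULE_S
    noise_sd: float = DEFAULT_NOISE_SD
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.time_points, dtype=float)
        if np.any(tp < 0) or np.any(np.diff(tp) <= 0):
            raise ValueError("time_points must be non-negative and strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class DiscRegion:
    """An xy disc (center, radius in nm) used for planted defects/thinning."""

    cx: float
    cy: float
    radius: float
    waters_per_frame: int = 0  # defect discs: hydration beads added per frame
    phosphate_offset_nm: float | None = None  # thinned discs: reduced offset

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.radius**2


@dataclass(frozen=True)
class TrajectorySpec:
    """Layout of a synthetic coarse-grained bilayer trajectory.

    Lipids are one phosphate bead each, placed on an xy grid in two leaflets
    at +/- phosphate_z_offset around the box midplane with Gaussian z jitter
    (clipped so leaflet identity stays unambiguous). planted_flips maps lipid
    resid -> frame index at which its phosphate moves to the opposite leaflet
    and stays there.
    """

    n_lipids: int = 100
    n_waters: int = 200
    box: tuple[float, float, float] = (10.0, 10.0, 10.0)
    phosphate_z_offset: float = 2.0
    z_jitter_sd: float = 0.3
    n_frames: int = 10
    frame_interval_ps: float = 10000.0
    planted_flips: tuple[tuple[int, int], ...] = ()
    defect_region: DiscRegion | None = None
    thinned_region: DiscRegion | None = None
    n_protein_beads: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lipids < 2 or self.n_lipids % 2:
            raise ValueError("n_lipids must be an even number >= 2")
        if any(b <= 0 for b in self.box):
            raise ValueError("box dimensions must be > 0")
        if self.phosphate_z_offset <= 0:
            raise ValueError("phosphate_z_offset must be > 0")
        min_offset = self.phosphate_z_offset
        if self.thinned_region is not None and self.thinned_region.phosphate_offset_nm:
            min_offset = min(min_offset, self.thinned_region.phosphate_offset_nm)
        if self.z_jitter_sd >= min_offset:
            raise ValueError(
                "z jitter >= leaflet offset: leaflet assignment would be ambiguous"
            )
        for lid, fidx in self.planted_flips:
            if not (1 <= lid <= self.n_lipids):
                raise ValueError(f"planted flip for unknown lipid {lid}")
            if not (0 <= fidx < self.n_frames):
                raise ValueError(f"flip frame {fidx} outside trajectory")
        for region in (self.defect_region, self.thinned_region):
            if region is None:
                continue
            if not (
                0 <= region.cx <= self.box[0]
                and 0 <= region.cy <= self.box[1]
                and region.radius > 0
            ):
                raise ValueError("region must lie inside the box")


# ---------------------------------------------------------------------------
# traces


def _trace_phases(spec: TraceSpec) -> tuple[float, list[tuple[float, float]]]:
    """Plateau and [(amplitude, half_time)] for a decay-type assay trace."""
    floor = spec.f_refractory / 2.0  # refractory vesicles keep both leaflets dark
    if spec.assay_kind == "dithionite":
        # fast phase: outer-leaflet bleaching in every vesicle;
        # slow phase: channel-mediated bleaching of the protected pool.
        protected = 1.0 - spec.outer_fraction - floor
        plateau = 1.0 - spec.outer_fraction - spec.f_pore * protected
        phases = [
            (spec.outer_fraction, spec.half_times[0]),
            (spec.f_pore * protected, spec.half_times[min(1, len(spec.half_times) - 1)]),
        ]
    elif spec.assay_kind == "bsa":
        f_l = 1.0 - spec.outer_fraction * (1.0 - spec.phi)
        f_min = compute_F_min_bsa(floor, spec.phi)
        plateau = f_l - spec.f_scr * (f_l - f_min)
        phases = [
            (1.0 - f_l, spec.half_times[0]),
            (spec.f_scr * (f_l - f_min), spec.half_times[min(1, len(spec.half_times) - 1)]),
        ]
    else:
        raise ValueError(f"no decay-phase model for assay kind {spec.assay_kind!r}")
    return plateau, [(a, h) for a, h in phases if a > 0]


def generate_trace(spec: TraceSpec) -> FluorescenceTrace:
    """Generate one synthetic assay trace.

    dithionite / bsa: normalized fluorescence, baseline at 1.0 followed by a
    one- or two-phase decay to the plateau implied by (f_pore or f_scr, phi,
    outer_fraction, refractory floor).

    plc: scintillation counts rising from the untreated offset toward the
    hydrolysis plateau (outer_fraction + f_scr * inner fraction of the
    Triton-disrupted maximum).

    slow_scrambling: outer-leaflet probe fraction decaying from 1 toward the
    equilibrium outer fraction with the given half-time; the time axis is in
    hours.
    """
    rng = np.random.default_rng(spec.seed)

    if spec.assay_kind in ("dithionite", "bsa"):
        plateau, phases = _trace_phases(spec)
        if not 0.0 <= plateau <= 1.0:
            raise ValueError(f"implied plateau {plateau:.3f} outside [0, 1]")
        time = np.arange(0.0, spec.baseline_duration + spec.total_duration, spec.sampling_interval)
        t_post = time - spec.baseline_duration
        signal = np.full_like(time, 1.0)
        post = t_post >= 0
        decay = np.full(post.sum(), plateau)
        for amp, ht in phases:
            decay += amp * np.exp(-math.log(2) / ht * t_post[post])
        signal[post] = decay
        if spec.noise_sd > 0:
            signal = signal * (1.0 + rng.normal(0.0, spec.noise_sd, signal.size))
        return FluorescenceTrace(
            time=time, intensity=np.clip(signal, 0.0, None),
            addition_time=spec.baseline_duration, assay_kind=spec.assay_kind,
            label=f"synthetic-{spec.assay_kind}",
        )

    if spec.assay_kind == "plc":
        hyd_max = spec.outer_fraction + spec.f_scr * (1.0 - spec.outer_fraction)
        if not 0.0 <= hyd_max <= 1.0:
            raise ValueError(f"implied hydrolysis plateau {hyd_max:.3f} outside [0, 1]")
        time = np.arange(0.0, spec.baseline_duration + spec.total_duration, spec.sampling_interval)
        t_post = time - spec.baseline_duration
        frac = np.where(
            t_post >= 0, hyd_max * (1.0 - np.exp(-math.log(2) / spec.half_times[0] * t_post)), 0.0
        )
        cpm = PLC_UNTREATED_CPM + frac * (PLC_TRITON_MAX_CPM - PLC_UNTREATED_CPM)
        if spec.noise_sd > 0:
            cpm = cpm * (1.0 + rng.normal(0.0, spec.noise_sd, cpm.size))
        return FluorescenceTrace(
            time=time, intensity=np.clip(cpm, 0.0, None),
            addition_time=spec.baseline_duration, assay_kind="plc",
            label="synthetic-plc",
        )

    if spec.assay_kind == "slow_scrambling":
        # hours time base; equilibrium = outer-leaflet lipid fraction
        eq = spec.outer_fraction
        time = np.arange(0.0, spec.total_duration, spec.sampling_interval)
        frac = eq + (1.0 - eq) * np.exp(-math.log(2) / spec.half_times[0] * time)
        if spec.noise_sd > 0:
            frac = frac * (1.0 + rng.normal(0.0, spec.noise_sd, frac.size))
        return FluorescenceTrace(
            time=time, intensity=np.clip(frac, 0.0, None),
            addition_time=-1.0, assay_kind="slow_scrambling",
            label="synthetic-slow-scrambling", normalized=True,
        )

    raise ValueError(f"unknown assay kind {spec.assay_kind!r}")


# ---------------------------------------------------------------------------
# occupancy


def generate_occupancy_series(
    tau: float,
    ppr_values,
    n_vesicles: int = 10_000,
    seed: int = 0,
    F_dith_min: float = 0.0,
) -> list[ReconstitutionPoint]:
    """Simulate a protein-dependence series under Poisson occupancy.

    For each PPR, every vesicle receives a Poisson number of functional
    units with mean PPR*/tau; the reported f_pore is the occupied fraction.
    Sampling error shrinks as 1/sqrt(n_vesicles).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if n_vesicles < 1:
        raise ValueError("n_vesicles must be >= 1")
    rng = np.random.default_rng(seed)
    r = 2.0 * F_dith_min
    if r >= 1:
        raise ValueError("refractory fraction >= 1")
    points = []
    for ppr in ppr_values:
        if ppr < 0:
            raise ValueError("PPR values must be >= 0")
        lam = (ppr / (1.0 - r)) / tau
        occupied = rng.poisson(lam, n_vesicles) > 0
        points.append(
            ReconstitutionPoint(ppr=float(ppr), f_pore=float(occupied.mean()), F_dith_min=F_dith_min)
        )
    return points


# ---------------------------------------------------------------------------
# decarboxylation


def generate_decarb_timecourse(spec: DecarbSpec) -> list[DecarbTimeCourse]:
    """Synthetic PE-fraction time courses from the 4-state import model.

    The noiseless curve is the exact P3(t) of the linear system with
    S(0) = 1; replicates add independent multiplicative Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.time_points, dtype=float)
    p3 = closed_form(spec.params, times)[:, 3]
    out = []
    for rep in range(spec.replicates):
        y = p3.copy()
        if spec.noise_sd > 0:
            y = y * (1.0 + rng.normal(0.0, spec.noise_sd, y.size))
        out.append(
            DecarbTimeCourse(
                times=times, pe_fraction=np.clip(y, 0.0, 1.0), replicate=rep,
            )
        )
    return out


# ---------------------------------------------------------------------------
# trajectories


def generate_trajectory(spec: TrajectorySpec) -> list[TrajectoryFrame]:
    """Build a synthetic coarse-grained bilayer trajectory.

    Lipids (one PO4 bead each) sit on an xy grid in two leaflets at
    +/- phosphate_z_offset about the box midplane, with clipped Gaussian z
    jitter. Planted flips relocate a lipid's phosphate to the opposite
    leaflet from its flip frame onward. Water beads fill the solvent slabs
    (> 1 nm away from the leaflet shells); a defect disc adds hydration
    beads within 1 nm of the membrane center; a thinned disc pulls its
    lipids to a reduced offset. Optional protein beads sit at the box
    center.
    """
    rng = np.random.default_rng(spec.seed)
    bx, by, bz = spec.box
    zmid = bz / 2.0
    n_half = spec.n_lipids // 2

    # xy grid per leaflet
    ncol = int(math.ceil(math.sqrt(n_half)))
    xs = (np.arange(n_half) % ncol + 0.5) * (bx / ncol)
    ys = (np.arange(n_half) // ncol + 0.5) * (by / max(1, math.ceil(n_half / ncol)))
    lipid_xy = np.concatenate([np.column_stack([xs, ys])] * 2)
    leaflet_sign = np.concatenate([np.ones(n_half), -np.ones(n_half)])
    resids = np.arange(1, spec.n_lipids + 1)

    flips = dict(spec.planted_flips)
    offsets = np.full(spec.n_lipids, spec.phosphate_z_offset)
    if spec.thinned_region is not None and spec.thinned_region.phosphate_offset_nm:
        inside = spec.thinned_region.contains(lipid_xy[:, 0], lipid_xy[:, 1])
        offsets[inside] = spec.thinned_region.phosphate_offset_nm

    clip = 0.9 * offsets.min()
    frames = []
    for fi in range(spec.n_frames):
        sign = leaflet_sign.copy()
        for lid, fidx in flips.items():
            if fi >= fidx:
                sign[lid - 1] *= -1
        jitter = np.clip(rng.normal(0.0, spec.z_jitter_sd, spec.n_lipids), -clip, clip)
        lipid_z = zmid + sign * offsets + jitter

        names = ["PO4"] * spec.n_lipids
        resn = ["POPC"] * spec.n_lipids
        rid = list(resids)
        pos = [np.column_stack([lipid_xy, lipid_z])]

        # solvent slabs, clear of the membrane shell
        shell = spec.phosphate_z_offset + 1.0
        if spec.n_waters:
            wx = rng.uniform(0, bx, spec.n_waters)
            wy = rng.uniform(0, by, spec.n_waters)
            slab = max(zmid - shell, 0.1)
            wz_low = rng.uniform(0, slab, spec.n_waters)
            upper = rng.random(spec.n_waters) < 0.5
            wz = np.where(upper, bz - wz_low, wz_low)
            pos.append(np.column_stack([wx, wy, wz]))
            names += ["W"] * spec.n_waters
            resn += ["W"] * spec.n_waters
            rid += list(range(spec.n_lipids + 1, spec.n_lipids + spec.n_waters + 1))

        if spec.defect_region is not None and spec.defect_region.waters_per_frame:
            nd = spec.defect_region.waters_per_frame
            rr = spec.defect_region.radius * np.sqrt(rng.random(nd))
            th = rng.uniform(0, 2 * math.pi, nd)
            dx = spec.defect_region.cx + rr * np.cos(th)
            dy = spec.defect_region.cy + rr * np.sin(th)
            dz = zmid + rng.uniform(-0.9, 0.9, nd)
            pos.append(np.column_stack([dx, dy, dz]))
            names += ["W"] * nd
            resn += ["W"] * nd
            base = max(rid) if rid else 0
            rid += list(range(base + 1, base + nd + 1))

        if spec.n_protein_beads:
            pxy = np.column_stack(
                [
                    bx / 2 + 0.2 * np.cos(np.linspace(0, 2 * math.pi, spec.n_protein_beads, endpoint=False)),
                    by / 2 + 0.2 * np.sin(np.linspace(0, 2 * math.pi, spec.n_protein_beads, endpoint=False)),
                ]
            )
            pz = np.full(spec.n_protein_beads, zmid)
            pos.append(np.column_stack([pxy, pz]))
            names += ["BB"] * spec.n_protein_beads
            resn += ["PROT"] * spec.n_protein_beads
            base = max(rid) if rid else 0
            rid += [base + 1] * spec.n_protein_beads

        frames.append(
            TrajectoryFrame(
                resids=np.array(rid),
                resnames=np.array(resn, dtype=object),
                atomnames=np.array(names, dtype=object),
                positions=np.vstack(pos),
                box=np.array([bx, by, bz]),
                time_ps=fi * spec.frame_interval_ps,
                title="synthetic bilayer",
            )
        )
    return frames
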