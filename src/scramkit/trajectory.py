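"""Coarse-grained trajectory analysis: leaflet bookkeeping, scrambling, maps.

Works on Martini-style coarse-grained frames stored as GRO-format text
(single frames, per-frame files, or concatenated multi-frame streams). A
lipid is represented by its phosphate bead (name ``PO4`` by default); it is
assigned to the upper or lower leaflet by the phosphate z-position relative
to the membrane center (mean phosphate z of the frame) and counts as
"scrambled" once it occupies a different leaflet than in the reference
(first) frame.

Membrane-disruption observables are accumulated on an xy mesh with 0.1-nm
bins: the water defect (average number of water beads within 1 nm of the
membrane center along z, sampled every 100 ps) and the membrane thickness
(mean upper- minus mean lower-leaflet phosphate z). Bins with fewer than
100 samples are masked.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TrajectoryFrame",
    "LeafletAssignment",
    "ScramblingSeries",
    "GridMap",
    "BeadClassifier",
    "read_gro",
    "write_gro",
    "assign_leaflets",
    "scrambled_series",
    "water_defect_map",
    "thickness_map",
    "center_on_protein",
]

#: Default bead-name / residue-name classification (Martini conventions).
DEFAULT_KINDS = {
    "W": "water",
    "WN": "water",
    "ION": "ion",
    "NA": "ion",
    "CL": "ion",
    "K": "ion",
    "POPC": "lipid",
    "POPE": "lipid",
    "POPG": "lipid",
    "POPS": "lipid",
    "DPPC": "lipid",
    "LIP": "lipid",
    "PROT": "protein",
    "BB": "protein",
}

PHOSPHATE_BEAD = "PO4"


@dataclass
class BeadClassifier:
    """Maps residue names (and bead names as fallback) to bead kinds.

    Kinds are 'lipid', 'water', 'protein', 'ion'. Unknown names default to
    'protein', matching the convention that anything that is not solvent,
    ion, or a recognized lipid belongs to the embedded protein.
    """

    by_resname: dict = field(default_factory=lambda: dict(DEFAULT_KINDS))

    def kind(self, resname: str, atomname: str) -> str:
        if resname in self.by_resname:
            return self.by_resname[resname]
        if atomname in self.by_resname:
            return self.by_resname[atomname]
        return "protein"


@dataclass
class TrajectoryFrame:
    """One coarse-grained frame: bead identities, coordinates (nm), box (nm)."""

    resids: np.ndarray
    resnames: np.ndarray
    atomnames: np.ndarray
    positions: np.ndarray
    box: np.ndarray
    time_ps: float = 0.0
    title: str = "frame"

    def __post_init__(self) -> None:
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.atomnames = np.asarray(self.atomnames, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        n = self.resids.size
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n_beads, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box dimensions must be positive")

    @property
    def n_beads(self) -> int:
        return self.resids.size

    def phosphates(self, bead_name: str = PHOSPHATE_BEAD) -> tuple[np.ndarray, np.ndarray]:
        """(lipid resids, phosphate positions) for every phosphate bead."""
        mask = self.atomnames == bead_name
        return self.resids[mask], self.positions[mask]

    def kind_mask(self, kind: str, classifier: BeadClassifier | None = None) -> np.ndarray:
        cl = classifier or BeadClassifier()
        return np.array(
            [cl.kind(r, a) == kind for r, a in zip(self.resnames, self.atomnames)]
        )

    def wrapped(self) -> "TrajectoryFrame":
        """Coordinates wrapped into the primary box (periodic boundaries)."""
        pos = np.mod(self.positions, self.box)
        return TrajectoryFrame(
            self.resids, self.resnames, self.atomnames, pos, self.box,
            self.time_ps, self.title,
        )


@dataclass
class LeafletAssignment:
    """Per-lipid leaflet labels ('upper'/'lower') at a reference frame."""

    labels: dict
    center_z: float


@dataclass
class ScramblingSeries:
    """Scrambled-lipid percentage sampled at fixed cadence.

    times_ns / percent are the raw sampled series; running_average smooths
    over a fixed window; rate is the least-squares slope of the raw series
    in percent per microsecond.
    """

    times_ns: np.ndarray
    percent: np.ndarray
    running_average: np.ndarray
    rate_percent_per_us: float
    window_ns: float = 200.0


@dataclass
class GridMap:
    """An xy-binned field (water-defect count or thickness in nm).

    values is NaN in masked bins; counts holds per-bin sample counts and
    mask is True where the <min_samples exclusion applies.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    mask: np.ndarray
    bin_nm: float = 0.1


# ---------------------------------------------------------------------------
# GRO text format (fixed columns: resid 5, resname 5, atom 5, atomid 5, xyz 8.3)

_TIME_RE = re.compile(r"t\s*=\s*([0-9.eE+-]+)")


def write_gro(frames, path) -> None:
    """Write one or more frames as (concatenated) GRO-format text."""
    if isinstance(frames, TrajectoryFrame):
        frames = [frames]
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{fr.title} t= {fr.time_ps:.3f}\n")
            fh.write(f"{fr.n_beads:5d}\n")
            for i in range(fr.n_beads):
                x, y, z = fr.positions[i]
                fh.write(
                    f"{fr.resids[i] % 100000:5d}{str(fr.resnames[i]):<5.5s}"
                    f"{str(fr.atomnames[i]):>5.5s}{(i + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            fh.write(f"{fr.box[0]:10.5f}{fr.box[1]:10.5f}{fr.box[2]:10.5f}\n")


def read_gro(source) -> list[TrajectoryFrame]:
    """Read GRO-format frames from a file path, list of paths, or text.

    Accepts a single frame, a concatenated multi-frame stream, or a list of
    per-frame files. Frame times are taken from a ``t= <ps>`` tag on the
    title line when present, else numbered by frame index.
    """
    if isinstance(source, (list, tuple)):
        frames: list[TrajectoryFrame] = []
        for p in source:
            frames.extend(read_gro(p))
        return frames
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    lines = text.splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        try:
            n = int(lines[i + 1])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"malformed GRO stream near line {i + 1}") from exc
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ValueError("truncated GRO frame")
        resids = np.empty(n, dtype=int)
        resnames = np.empty(n, dtype=object)
        atomnames = np.empty(n, dtype=object)
        pos = np.empty((n, 3))
        for j, ln in enumerate(body):
            resids[j] = int(ln[0:5])
            resnames[j] = ln[5:10].strip()
            atomnames[j] = ln[10:15].strip()
            pos[j] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
        box = np.array([float(v) for v in lines[i + 2 + n].split()[:3]])
        m = _TIME_RE.search(title)
        t = float(m.group(1)) if m else float(len(frames))
        frames.append(
            TrajectoryFrame(resids, resnames, atomnames, pos, box, time_ps=t, title=title.split(" t=")[0])
        )
        i += n + 3
    return frames


# ---------------------------------------------------------------------------
# analyzers


def _membrane_center(frame: TrajectoryFrame, bead_name: str = PHOSPHATE_BEAD) -> float:
    _, pos = frame.phosphates(bead_name)
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 phosphate beads to define a membrane")
    return float(pos[:, 2].mean())


def assign_leaflets(
    frame: TrajectoryFrame,
    bead_name: str = PHOSPHATE_BEAD,
    previous: LeafletAssignment | None = None,
) -> LeafletAssignment:
    """Label each lipid upper/lower by phosphate z relative to the center.

    A phosphate exactly at the center keeps its previous-frame label
    (hysteresis); without a previous assignment this is an error.
    """
    resids, pos = frame.phosphates(bead_name)
    if resids.size < 2:
        raise ValueError("need at least 2 lipids")
    center = float(pos[:, 2].mean())
    labels: dict = {}
    for rid, z in zip(resids, pos[:, 2]):
        if z > center:
            labels[int(rid)] = "upper"
        elif z < center:
            labels[int(rid)] = "lower"
        else:
            if previous is not None and int(rid) in previous.labels:
                labels[int(rid)] = previous.labels[int(rid)]
            else:
                raise ValueError(
                    f"lipid {rid}: phosphate exactly at membrane center and no prior label"
                )
    return LeafletAssignment(labels=labels, center_z=center)


def scrambled_series(
    frames: list[TrajectoryFrame],
    reference: LeafletAssignment | None = None,
    sample_every_ns: float = 10.0,
    window_ns: float = 200.0,
    bead_name: str = PHOSPHATE_BEAD,
) -> ScramblingSeries:
    """Percentage of scrambled lipids over time, with running average and rate.

    A lipid is scrambled when its current leaflet differs from its leaflet in
    the reference (by default the first) frame. Frames are sampled on a fixed
    cadence (default every 10 ns); the running average uses a centered window
    (default 200 ns) and the rate is the least-squares slope of the raw
    series, in % per microsecond.
    """
    if not frames:
        raise ValueError("empty trajectory")
    ref = reference or assign_leaflets(frames[0], bead_name)
    n_lipids = len(ref.labels)

    times, pct = [], []
    next_sample = frames[0].time_ps
    prev = ref
    step_ps = sample_every_ns * 1000.0
    for fr in frames:
        if fr.time_ps + 1e-9 < next_sample:
            continue
        cur = assign_leaflets(fr, bead_name, previous=prev)
        missing = set(ref.labels) - set(cur.labels)
        if missing:
            raise ValueError(f"lipid(s) {sorted(missing)} missing phosphate bead")
        n_scr = sum(1 for rid, lab in ref.labels.items() if cur.labels[rid] != lab)
        times.append(fr.time_ps / 1000.0)
        pct.append(100.0 * n_scr / n_lipids)
        prev = cur
        next_sample += step_ps

    times = np.asarray(times)
    pct = np.asarray(pct)
    half_w = window_ns / 2.0
    run = np.array(
        [pct[(times >= t - half_w) & (times <= t + half_w)].mean() for t in times]
    )
    if times.size >= 2 and float(np.ptp(times)) > 0:
        slope = float(np.polyfit(times / 1000.0, pct, 1)[0])  # % per us
    else:
        slope = math.nan
    return ScramblingSeries(
        times_ns=times, percent=pct, running_average=run,
        rate_percent_per_us=slope, window_ns=window_ns,
    )


def _grid_edges(box_xy: np.ndarray, bin_nm: float) -> tuple[np.ndarray, np.ndarray]:
    nx = max(1, int(round(box_xy[0] / bin_nm)))
    ny = max(1, int(round(box_xy[1] / bin_nm)))
    return np.arange(nx + 1) * bin_nm, np.arange(ny + 1) * bin_nm


def _sampled(frames, sample_every_ps: float):
    next_sample = frames[0].time_ps
    for fr in frames:
        if fr.time_ps + 1e-9 < next_sample:
            continue
        yield fr
        next_sample += sample_every_ps


def water_defect_map(
    frames: list[TrajectoryFrame],
    z_threshold_nm: float = 1.0,
    bin_nm: float = 0.1,
    sample_every_ps: float = 100.0,
    min_samples: int = 100,
    classifier: BeadClassifier | None = None,
) -> GridMap:
    """Average number of water beads near the membrane core, per xy bin.

    A water bead counts toward the defect when |z - membrane center| is below
    the threshold (default 1 nm). Each sampled frame (default every 100 ps)
    contributes one sample to every bin; bins with fewer than ``min_samples``
    samples are masked.
    """
    if not frames:
        raise ValueError("empty trajectory")
    x_edges, y_edges = _grid_edges(frames[0].box[:2], bin_nm)
    total = np.zeros((x_edges.size - 1, y_edges.size - 1))
    n_sampled = 0
    any_water = False
    for fr in _sampled(frames, sample_every_ps):
        fr = fr.wrapped()
        center = _membrane_center(fr)
        wmask = fr.kind_mask("water", classifier)
        n_sampled += 1
        if not wmask.any():
            continue
        any_water = True
        pos = fr.positions[wmask]
        near = np.abs(pos[:, 2] - center) < z_threshold_nm
        if near.any():
            h, _, _ = np.histogram2d(
                pos[near, 0], pos[near, 1], bins=(x_edges, y_edges)
            )
            total += h
    if not any_water:
        warnings.warn("no water beads found: water-defect map is all zero")
    counts = np.full(total.shape, n_sampled)
    mask = counts < min_samples
    values = np.where(mask, np.nan, total / max(n_sampled, 1))
    return GridMap(x_edges, y_edges, values, counts, mask, bin_nm)


def thickness_map(
    frames: list[TrajectoryFrame],
    bin_nm: float = 0.1,
    sample_every_ps: float = 100.0,
    min_samples: int = 100,
    bead_name: str = PHOSPHATE_BEAD,
) -> GridMap:
    """Membrane thickness per xy bin: mean upper minus mean lower phosphate z.

    Bins with fewer than ``min_samples`` phosphate observations, or with only
    one leaflet sampled, are masked.
    """
    if not frames:
        raise ValueError("empty trajectory")
    x_edges, y_edges = _grid_edges(frames[0].box[:2], bin_nm)
    shape = (x_edges.size - 1, y_edges.size - 1)
    sum_up = np.zeros(shape)
    n_up = np.zeros(shape, dtype=int)
    sum_lo = np.zeros(shape)
    n_lo = np.zeros(shape, dtype=int)
    prev = None
    for fr in _sampled(frames, sample_every_ps):
        fr = fr.wrapped()
        assignment = assign_leaflets(fr, bead_name, previous=prev)
        prev = assignment
        resids, pos = fr.phosphates(bead_name)
        ix = np.minimum((pos[:, 0] / bin_nm).astype(int), shape[0] - 1)
        iy = np.minimum((pos[:, 1] / bin_nm).astype(int), shape[1] - 1)
        for rid, i, j, z in zip(resids, ix, iy, pos[:, 2]):
            if assignment.labels[int(rid)] == "upper":
                sum_up[i, j] += z
                n_up[i, j] += 1
            else:
                sum_lo[i, j] += z
                n_lo[i, j] += 1
    counts = n_up + n_lo
    mask = (counts < min_samples) | (n_up == 0) | (n_lo == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(mask, np.nan, sum_up / np.maximum(n_up, 1) - sum_lo / np.maximum(n_lo, 1))
    return GridMap(x_edges, y_edges, values, counts, mask, bin_nm)


def center_on_protein(
    frames: list[TrajectoryFrame],
    classifier: BeadClassifier | None = None,
) -> list[TrajectoryFrame]:
    """Translate each frame so the protein centroid sits at the xy box center.

    Coordinates are re-wrapped into the primary box. Frames without protein
    beads pass through unchanged (with a warning).
    """
    out = []
    warned = False
    for fr in frames:
        pmask = fr.kind_mask("protein", classifier)
        if not pmask.any():
            if not warned:
                warnings.warn("no protein beads: centering is the identity")
                warned = True
            out.append(fr)
            continue
        centroid = fr.positions[pmask, :2].mean(axis=0)
        shift = fr.box[:2] / 2.0 - centroid
        pos = fr.positions.copy()
        pos[:, :2] += shift
        out.append(
            TrajectoryFrame(
                fr.resids, fr.resnames, fr.atomnames, pos, fr.box, fr.time_ps, fr.title
            ).wrapped()
        )
    return out
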