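"""Analyses on top of the dynamic simulation: gait events, per-component
kinematics, regional von Mises stress summaries, and the internal-stiffness
sweep experiments with linear fits.

Gait-event convention within one half gait cycle: t2 and t4 are the
instants of the highest and lowest vertical displacement of the driven
(clavicle) point; t1 and t3 — foot-off and foot-strike in the original
gait definition — cannot be detected from a clavicle trace alone and are
defined here as the mid-phase crossings of the vertical waveform (its
analogues on synthetic data).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .constitutive import neo_hookean
from .fesolve import (BoundaryConditions, ConvergenceError, FEModel,
                      SimulationResult, solve_dynamic, solve_static)
from .mesh import LabelledTetMesh
from .trajectory import Trajectory

GLAND_E_GRID = (5.0, 7.5, 10.0, 12.5, 15.0)       # kPa
LIGAMENT_E_GRID = (80.0, 100.0, 120.0, 140.0, 160.0)  # kPa
EVENT_NAMES = ("t1", "t2", "t3", "t4")


@dataclass
class GaitEvents:
    """Event times (s) within one analysed half gait cycle."""

    t1: float
    t2: float
    t3: float
    t4: float

    def __post_init__(self):
        if not self.t1 < self.t2 < self.t3 < self.t4:
            raise ValueError(
                f"gait events must be ordered t1 < t2 < t3 < t4, got "
                f"{self.t1}, {self.t2}, {self.t3}, {self.t4}")

    def as_dict(self) -> dict:
        return {"t1": self.t1, "t2": self.t2, "t3": self.t3, "t4": self.t4}

    def frames(self, times: np.ndarray) -> dict:
        """Nearest frame index per event on a given time grid."""
        times = np.asarray(times)
        return {k: int(np.argmin(np.abs(times - v)))
                for k, v in self.as_dict().items()}


def detect_events(driven: Trajectory, half_cycle: float | None = None,
                  index: int = 0) -> GaitEvents:
    """Locate t1..t4 in the vertical component of the driven trajectory.

    ``half_cycle`` is the duration of one half gait cycle (estimated from
    the dominant spectral peak when omitted); ``index`` selects which
    half-cycle to analyse.  Raises on a flat signal.
    """
    y = driven.axis("y")
    t = driven.times
    if np.ptp(y) < 1e-9:
        raise ValueError("flat vertical signal: no gait events")
    if half_cycle is None:
        spec = np.abs(np.fft.rfft(y - y.mean()))
        freqs = np.fft.rfftfreq(y.size, 1.0 / driven.sample_rate)
        half_cycle = 1.0 / freqs[1:][np.argmax(spec[1:])]
    t_start = t[0] + index * half_cycle
    win = (t >= t_start - 1e-9) & (t <= t_start + half_cycle + 1e-9)
    if win.sum() < 4:
        raise ValueError("requested half-cycle not covered by the signal")
    iw = np.flatnonzero(win)
    i2 = iw[np.argmax(y[iw])]
    after = iw[iw >= i2]
    i4 = after[np.argmin(y[after])]
    if i4 <= i2:
        raise ValueError("could not order vertical extrema within the window")
    mid = 0.5 * (y[i2] + y[i4])

    def crossing(lo, hi):
        seg = np.arange(lo, hi)
        s = y[seg] - mid
        sign = np.signbit(s)
        flips = np.flatnonzero(sign[1:] != sign[:-1])
        if flips.size == 0:
            return None
        j = seg[flips[-1] if lo < i2 else flips[0]]
        # linear interpolation of the crossing instant
        f = s[j - lo] / (s[j - lo] - s[j + 1 - lo])
        return t[j] + f * (t[j + 1] - t[j])

    t3 = crossing(i2, i4 + 1)
    t1 = crossing(iw[0], i2 + 1)
    if t1 is None:
        t1 = float(t[iw[0]])
    if t3 is None:
        t3 = 0.5 * (t[i2] + t[i4])
    return GaitEvents(t1=float(t1), t2=float(t[i2]), t3=float(t3),
                      t4=float(t[i4]))


# -- kinematics ------------------------------------------------------------

def representative_nodes(mesh: LabelledTetMesh) -> dict:
    """One material point per breast component: the nipple and driven
    clavicle nodes from the mesh node sets, and the node nearest each
    remaining component's centroid."""
    out = {"nipple": int(mesh.node_sets["nipple"][0]),
           "clavicle": int(mesh.node_sets["clavicle"][0])}
    cen = mesh.nodes[mesh.tets].mean(axis=1)
    driven = np.zeros(mesh.n_nodes, dtype=bool)
    driven[mesh.node_sets["torso_base"]] = True

    def pick(idx, comp):
        if idx.size == 0:
            raise KeyError(f"mesh has no {comp} elements")
        target = cen[idx].mean(axis=0)
        nodes = np.unique(mesh.tets[idx])
        nodes = nodes[~driven[nodes]] if (~driven[nodes]).any() else nodes
        return int(nodes[np.argmin(
            np.linalg.norm(mesh.nodes[nodes] - target, axis=1))])

    # tracked points mirror where each tissue is observed: the ligament at
    # its anterior sheet just behind the nipple, the gland at its lobules
    # (mid-depth), the pectoralis at the slab centre
    lig = np.flatnonzero(mesh.element_region == "lig_anterior")
    if lig.size == 0:
        lig = mesh.component_elements("ligament")
    lig_nodes = np.unique(mesh.tets[lig])
    lig_nodes = lig_nodes[~driven[lig_nodes]] if (~driven[lig_nodes]).any() \
        else lig_nodes
    nip_pos = mesh.nodes[out["nipple"]]
    out["ligament"] = int(lig_nodes[np.argmin(
        np.linalg.norm(mesh.nodes[lig_nodes] - nip_pos, axis=1))])
    lobes = np.flatnonzero(np.char.startswith(
        mesh.element_region.astype(str), "lobe_"))
    if lobes.size == 0:
        lobes = mesh.component_elements("gland")
    out["gland"] = pick(lobes, "gland")
    out["pectoralis"] = pick(mesh.component_elements("pectoralis"), "pectoralis")
    return out


def extract_component_kinematics(result: SimulationResult,
                                 mesh: LabelledTetMesh) -> dict:
    """Total displacement and acceleration magnitude histories for the
    representative point of each component.

    The total displacement is the Euclidean norm of the three direction
    components, measured from the first (standing, gravity-loaded) frame.
    Returns ``{component: {node, displacement, acceleration,
    peak_displacement, peak_acceleration}}``.
    """
    reps = representative_nodes(mesh)
    out = {}
    for comp, node in reps.items():
        u = result.nodal_displacement[:, node, :]
        disp = np.linalg.norm(u - u[0], axis=1)
        acc = np.linalg.norm(result.nodal_acceleration[:, node, :], axis=1)
        out[comp] = {"node": node, "displacement": disp, "acceleration": acc,
                     "peak_displacement": float(disp.max()),
                     "peak_acceleration": float(acc.max())}
    return out


# -- regional stress -------------------------------------------------------

def default_regions(mesh: LabelledTetMesh) -> dict:
    """Named element sets for the regional stress summaries.

    Ligaments: the 8 radial septa L1..L8 plus the anterior sheet (facing
    the adipose tissue / skin) and posterior sheet (attached to the
    pectoralis).  Pectoralis: anterior / posterior halves.  Gland:
    rear / bottom / top / front quadrants around the gland centroid.
    Adipose: the shell of elements adjacent to the gland.
    """
    regions = {}
    for k in range(1, 9):
        idx = np.flatnonzero(mesh.element_region == f"septum_L{k}")
        if idx.size:
            regions[f"L{k}"] = idx
    for tag, name in (("lig_anterior", "lig_anterior"),
                      ("lig_posterior", "lig_posterior")):
        idx = np.flatnonzero(mesh.element_region == tag)
        if idx.size:
            regions[name] = idx

    cen = mesh.nodes[mesh.tets].mean(axis=1)
    pec = mesh.component_elements("pectoralis")
    if pec.size:
        zmed = np.median(cen[pec, 2])
        regions["pec_anterior"] = pec[cen[pec, 2] >= zmed]
        regions["pec_posterior"] = pec[cen[pec, 2] < zmed]

    gland = mesh.component_elements("gland")
    if gland.size:
        gc = cen[gland].mean(axis=0)
        d = cen[gland] - gc
        ang = np.degrees(np.arctan2(d[:, 1], d[:, 2]))  # y vs z
        quadrants = {"gland_front": np.abs(ang) <= 45.0,
                     "gland_top": (ang > 45.0) & (ang <= 135.0),
                     "gland_rear": np.abs(ang) > 135.0,
                     "gland_bottom": (ang < -45.0) & (ang >= -135.0)}
        for name, mask in quadrants.items():
            if mask.any():
                regions[name] = gland[mask]
        adip = mesh.component_elements("adipose")
        if adip.size:
            from scipy.spatial import cKDTree
            shell = np.mean(mesh.tet_volumes()) ** (1.0 / 3.0) * 1.8
            dist, _ = cKDTree(cen[gland]).query(cen[adip])
            near = adip[dist <= shell]
            if near.size:
                regions["adipose_near_gland"] = near
    return regions


def regional_stress_summary(result: SimulationResult, mesh: LabelledTetMesh,
                            regions: dict | None = None,
                            frame_range: tuple | None = None) -> dict:
    """Volume-weighted mean von Mises history and peak per region.

    ``frame_range=(i0, i1)`` restricts the peak search to a frame window
    (e.g. one analysed half-cycle); the history always covers the full
    run.  Returns ``{region: {mean_history, peak_value, peak_time,
    peak_frame, peak_element}}``; raises on an empty region.
    """
    if regions is None:
        regions = default_regions(mesh)
    vols = mesh.tet_volumes()
    i0, i1 = (0, result.n_frames) if frame_range is None else frame_range
    out = {}
    for name, idx in regions.items():
        idx = np.asarray(idx, int)
        if idx.size == 0:
            raise ValueError(f"region {name!r} is empty")
        w = vols[idx] / vols[idx].sum()
        hist = result.element_von_mises[:, idx] @ w
        pk = i0 + int(np.argmax(hist[i0:i1]))
        el_peak = idx[int(np.argmax(result.element_von_mises[pk, idx]))]
        out[name] = {"mean_history": hist, "peak_value": float(hist[pk]),
                     "peak_time": float(result.times[pk]), "peak_frame": pk,
                     "peak_element": int(el_peak)}
    return out


# -- stiffness sweeps ------------------------------------------------------

@dataclass
class SweepConfig:
    """Shared configuration of one sweep: geometry, base materials,
    driving trajectory and time discretization."""

    mesh: LabelledTetMesh
    materials: dict
    trajectory: Trajectory
    dt: float = 0.005
    n_steps: int = 76           # one ~0.38 s half cycle at dt = 0.005
    half_cycle: float = 0.38
    event_index: int = 0        # which half-cycle to analyse
    event_window: float | None = None   # s; peak window per event (None:
    bcs: BoundaryConditions | None = None  # instantaneous sample)

    def __post_init__(self):
        if self.bcs is None:
            self.bcs = BoundaryConditions.from_mesh(self.mesh)


@dataclass
class SweepResult:
    """Peak nipple displacement vs Young's modulus with per-event OLS fits."""

    component: str
    E_values: np.ndarray                 # kPa
    events: GaitEvents
    displacement: np.ndarray             # (n_E, 4) mm at t1..t4, NaN on failure
    slope: dict = field(default_factory=dict)         # event -> mm/kPa
    correlation: dict = field(default_factory=dict)   # event -> Pearson r
    failed: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, E in enumerate(self.E_values):
            for j, ev in enumerate(EVENT_NAMES):
                rows.append({"E_kPa": E, "event": ev,
                             "peak_disp_mm": self.displacement[i, j]})
        return pd.DataFrame(rows)

    def fit_summary(self) -> dict:
        return {"component": self.component,
                "E_kPa": list(map(float, self.E_values)),
                "slope_mm_per_kPa": {k: float(v) for k, v in self.slope.items()},
                "pearson_r": {k: float(v) for k, v in self.correlation.items()}}


def nipple_displacement_at_events(result: SimulationResult,
                                  mesh: LabelledTetMesh,
                                  events: GaitEvents,
                                  window: float | None = None) -> np.ndarray:
    """Nipple total displacement (from the first frame) per gait event.

    With *window* (s), the peak of the displacement magnitude within
    t_event +/- window/2 is reported instead of the instantaneous sample —
    the robust choice for an undamped simulation, whose small residual
    free oscillation jitters the phase of the response peak relative to
    the driving extrema.  ``window=None`` gives the instantaneous value.
    """
    nip = int(mesh.node_sets["nipple"][0])
    u = result.nodal_displacement[:, nip, :]
    disp = np.linalg.norm(u - u[0], axis=1)
    out = []
    for e in EVENT_NAMES:
        t_e = events.as_dict()[e]
        if window is None:
            out.append(disp[int(np.argmin(np.abs(result.times - t_e)))])
        else:
            sel = np.abs(result.times - t_e) <= window / 2.0
            out.append(disp[sel].max())
    return np.array(out)


def stiffness_sweep(config: SweepConfig, component: str,
                    E_values=None, verbose: bool = False) -> SweepResult:
    """Re-run the dynamic simulation over a grid of Young's moduli for one
    internal component (``gland`` or ``ligament``), holding every other
    material fixed, and linearly fit nipple displacement vs E per event.

    A non-convergent run is recorded as NaN with a failure flag rather
    than aborting the sweep.
    """
    if E_values is None:
        if component == "gland":
            E_values = GLAND_E_GRID
        elif component == "ligament":
            E_values = LIGAMENT_E_GRID
        else:
            raise ValueError("component must be 'gland' or 'ligament'")
    E_values = np.asarray(E_values, float)
    if np.any(E_values <= 0):
        raise ValueError("Young's moduli must be positive")
    base = config.materials[component]
    events = detect_events(config.trajectory, half_cycle=config.half_cycle,
                           index=config.event_index)

    disp = np.full((E_values.size, 4), np.nan)
    failed = np.zeros(E_values.size, dtype=bool)
    for i, E in enumerate(E_values):
        mats = dict(config.materials)
        mats[component] = replace(base, E=float(E))
        model = FEModel(config.mesh, mats)
        try:
            stat = solve_static(config.mesh, mats, config.bcs, model=model)
            dyn = solve_dynamic(config.mesh, mats, config.bcs,
                                config.trajectory, dt=config.dt,
                                n_steps=config.n_steps, static_prestate=stat,
                                model=model)
        except ConvergenceError:
            failed[i] = True
            continue
        disp[i] = nipple_displacement_at_events(dyn, config.mesh, events,
                                                window=config.event_window)
        if verbose:
            print(f"  {component} E = {E:g} kPa -> nipple displacement at "
                  f"t1..t4: {np.round(disp[i], 2)} mm")

    result = SweepResult(component=component, E_values=E_values, events=events,
                         displacement=disp, failed=failed)
    ok = ~failed
    for j, ev in enumerate(EVENT_NAMES):
        if ok.sum() >= 2:
            fit = stats.linregress(E_values[ok], disp[ok, j])
            result.slope[ev] = fit.slope
            result.correlation[ev] = fit.rvalue
    return result
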