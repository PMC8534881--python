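"""S1-S2 stimulation protocols and the unidirectional-block interval search.

S1 emulates sinus-rhythm pacing applied along one sheet edge (the desk-scale
stand-in for the sinus node); S2 is an ectopic train of 5 beats at a 110 ms
cycle length, rectangular pulses of 2 ms and 28 pA/pF, whose first beat is
placed at a coupling interval that produces unidirectional block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_tissue import TissueGrid

S2_CYCLE_LENGTH = 110.0     # ms
S2_N_BEATS = 5
PULSE_DURATION = 2.0        # ms
PULSE_AMPLITUDE = 28.0      # pA/pF, depolarizing

#: activation criterion used when classifying post-S2 propagation
ACTIVATION_DVDT = 10.0      # mV/ms
ACTIVATION_WINDOW = 50.0    # ms after the pulse

#: an "edge" stimulus site is this many node lines deep, so the 2 ms /
#: 28 pA/pF pulse reliably excites the sheet against its diffusive load
EDGE_STIM_DEPTH = 3


def resolve_site(site, grid: TissueGrid) -> np.ndarray:
    """Resolve a site spec to flat node indices on the grid.

    Specs: ``("edge", "left"|"right"|"top"|"bottom")`` (a boundary strip
    EDGE_STIM_DEPTH nodes deep), ``("rect", (j0, j1, i0, i1))`` (half-open
    row/col ranges), or ``("nodes", indices)``.
    """
    tag, arg = site
    ny, nx = grid.ny, grid.nx
    idx = np.arange(ny * nx).reshape(ny, nx)
    if tag == "edge":
        d = EDGE_STIM_DEPTH
        sel = {"left": idx[:, :d], "right": idx[:, -d:],
               "bottom": idx[:d, :], "top": idx[-d:, :]}[arg]
        return sel.ravel()
    if tag == "rect":
        j0, j1, i0, i1 = arg
        return idx[j0:j1, i0:i1].ravel()
    if tag == "nodes":
        return np.asarray(arg, dtype=np.int64).ravel()
    raise ValueError(f"unknown site spec: {tag!r}")


@dataclass
class StimulusProtocol:
    """Pulse schedule: S1 beats plus an optional 5-beat S2 ectopic train."""

    s1_site: tuple
    s1_times: tuple = (0.0,)
    s2_site: tuple | None = None
    s2_coupling_interval: float | None = None
    s2_n_beats: int = S2_N_BEATS
    s2_cycle_length: float = S2_CYCLE_LENGTH
    pulse_duration: float = PULSE_DURATION
    pulse_amplitude: float = PULSE_AMPLITUDE

    def __post_init__(self):
        if any(t < 0 for t in self.s1_times):
            raise ValueError("stimulus times must be non-negative")
        if self.s2_site is not None:
            if self.s2_coupling_interval is None or self.s2_coupling_interval <= 0:
                raise ValueError("S2 coupling interval must be positive")
            if self.s2_n_beats < 1:
                raise ValueError("S2 must deliver at least one beat")
        if self.pulse_duration <= 0 or self.pulse_amplitude <= 0:
            raise ValueError("pulse duration and amplitude must be positive")

    def s2_onsets(self):
        if self.s2_site is None:
            return []
        ci = self.s2_coupling_interval
        return [ci + k * self.s2_cycle_length for k in range(self.s2_n_beats)]

    def events(self):
        """[(t_on, t_off, amplitude pA/pF, site_id)] with site 0=S1, 1=S2."""
        ev = [(t, t + self.pulse_duration, self.pulse_amplitude, 0)
              for t in self.s1_times]
        ev += [(t, t + self.pulse_duration, self.pulse_amplitude, 1)
               for t in self.s2_onsets()]
        return sorted(ev)

    def site_node_indices(self, grid: TissueGrid):
        sites = [resolve_site(self.s1_site, grid)]
        if self.s2_site is not None:
            sites.append(resolve_site(self.s2_site, grid))
        return sites

    def to_dict(self) -> dict:
        return {
            "s1_site": list(map(str, self.s1_site)),
            "s1_times": list(self.s1_times),
            "s2_site": None if self.s2_site is None else list(map(str, self.s2_site)),
            "s2_coupling_interval": self.s2_coupling_interval,
            "s2_n_beats": self.s2_n_beats,
            "s2_cycle_length": self.s2_cycle_length,
            "pulse_duration": self.pulse_duration,
            "pulse_amplitude": self.pulse_amplitude,
        }


def build_s1s2(grid: TissueGrid, s1_site, s2_site,
               coupling_interval: float, n_beats: int = S2_N_BEATS,
               cycle_length: float = S2_CYCLE_LENGTH) -> StimulusProtocol:
    """S1 at t = 0 plus the S2 train at coupling_interval + k * cycle_length.

    The S1 and S2 node sets must be disjoint on the grid.
    """
    a = set(resolve_site(s1_site, grid).tolist())
    b = set(resolve_site(s2_site, grid).tolist())
    if a & b:
        raise ValueError("S1 and S2 sites must be disjoint")
    return StimulusProtocol(s1_site=s1_site, s1_times=(0.0,), s2_site=s2_site,
                            s2_coupling_interval=coupling_interval,
                            s2_n_beats=n_beats, s2_cycle_length=cycle_length)


def pacing_train(site, cycle_length: float, n_beats: int,
                 start: float = 0.0) -> StimulusProtocol:
    """Plain S1 pacing train (used for the rapid-pacing EGM experiments)."""
    times = tuple(start + k * cycle_length for k in range(n_beats))
    return StimulusProtocol(s1_site=site, s1_times=times)


# ---------------------------------------------------------------------------
# Unidirectional-block search
# ---------------------------------------------------------------------------

def _activated_after(times, vm, t0: float, window: float = ACTIVATION_WINDOW,
                     threshold: float = ACTIVATION_DVDT) -> bool:
    sel = (times >= t0) & (times <= t0 + window)
    if sel.sum() < 2:
        return False
    dv = np.diff(vm[sel]) / np.diff(times[sel])
    return bool(np.max(dv) >= threshold)


def classify_s2_response(grid: TissueGrid, s1_site, s2_site,
                         coupling_interval: float, config=None,
                         profiles=None, myo_init=None,
                         sentinel_offset: int = 6) -> str:
    """Classify post-S2 propagation: bidirectional / unidirectional / block.

    A single S1 beat at t = 0 is followed by one S2 pulse at the coupling
    interval; sentinel nodes flanking the S2 site along the propagation axis
    report activation (dV/dt crossing 10 mV/ms within 50 ms of the pulse).
    """
    from .monodomain import SolverConfig, simulate

    s2_nodes = resolve_site(s2_site, grid)
    rows = s2_nodes // grid.nx
    cols = s2_nodes % grid.nx
    j = int(round(rows.mean()))
    left = (j, max(int(cols.min()) - sentinel_offset, 0))
    right = (j, min(int(cols.max()) + sentinel_offset, grid.nx - 1))

    base = config or SolverConfig()
    cfg = SolverConfig(dt=base.dt, surface_to_volume=base.surface_to_volume,
                       specific_capacitance=base.specific_capacitance,
                       snapshot_interval=0, probes=[left, right])
    protocol = StimulusProtocol(
        s1_site=s1_site, s1_times=(0.0,), s2_site=s2_site,
        s2_coupling_interval=coupling_interval, s2_n_beats=1)
    duration = coupling_interval + ACTIVATION_WINDOW + 10.0
    res = simulate(grid, protocol, duration, cfg, profiles, myo_init=myo_init)
    t = res.probe_times
    hit_left = _activated_after(t, res.probe_vm[:, 0], coupling_interval)
    hit_right = _activated_after(t, res.probe_vm[:, 1], coupling_interval)
    if hit_left and hit_right:
        return "bidirectional"
    if hit_left or hit_right:
        return "unidirectional"
    return "block"


def find_unidirectional_block_interval(grid: TissueGrid, s1_site, s2_site,
                                       search_range, step: float = 5.0,
                                       refine_step: float = 1.0,
                                       config=None, profiles=None,
                                       myo_init=None,
                                       sentinel_offset: int = 6):
    """Longest S2 coupling interval that yields unidirectional block, or None.

    Coupling intervals are scanned descending over ``search_range`` at the
    coarse ``step``; around the first unidirectional hit the search is
    refined at ``refine_step``.  Absence of a unidirectional window is a
    valid outcome (returns None).
    """
    lo, hi = search_range
    if step <= 0 or lo <= 0 or hi <= lo:
        raise ValueError("invalid search range or step")

    def classify(ci):
        return classify_s2_response(grid, s1_site, s2_site, ci, config,
                                    profiles, myo_init, sentinel_offset)

    coarse = np.arange(hi, lo - 1e-9, -step)
    hit = None
    for ci in coarse:
        if classify(float(ci)) == "unidirectional":
            hit = float(ci)
            break
    if hit is None:
        return None
    if refine_step and refine_step < step:
        for ci in np.arange(min(hit + step - refine_step, hi), hit, -refine_step):
            if classify(float(ci)) == "unidirectional":
                return float(ci)
    return hit
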