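"""Action-potential biomarkers from probe traces.

Activation time is the time of maximum upstroke velocity of the first action
potential whose peak exceeds -20 mV; APD90 runs from activation to the
crossing of 90% repolarization (Vrest + 0.1 * (Vpeak - Vrest), with the
diastolic value immediately before the upstroke as Vrest); conduction
velocity is the two-probe straight-line estimate used in the tissue
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

AP_PEAK_THRESHOLD = -20.0    # mV; a deflection must exceed this to count as an AP


def _as_arrays(trace):
    """Accept (t, v) tuples or objects with .probe_trace-style pairs."""
    t, v = trace
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("trace must be two equal-length 1D arrays (t, v)")
    return t, v


def _upstroke_run(t, v):
    """(i0, i1, ipk): maximal-slope segment run and peak of the first AP."""
    above = np.flatnonzero(v > AP_PEAK_THRESHOLD)
    if above.size == 0:
        return None
    # end of the first AP's upstroke: first local maximum above threshold
    k = above[0]
    while k + 1 < len(v) and v[k + 1] >= v[k]:
        k += 1
    slopes = np.diff(v[:k + 1]) / np.diff(t[:k + 1])
    if slopes.size == 0:
        return None
    smax = slopes.max()
    if smax <= 0:
        return None
    is_max = np.isclose(slopes, smax, rtol=1e-9, atol=0.0)
    i1 = int(np.flatnonzero(is_max)[-1])
    i0 = i1
    while i0 > 0 and is_max[i0 - 1]:
        i0 -= 1
    return i0, i1, k


def activation_time(trace):
    """Time of maximum upstroke velocity of the first AP, or None.

    The maximum of dV/dt is located on the sampled segments; for a run of
    equally steep segments (piecewise-linear upstroke) the run midpoint is
    returned, which linearly interpolates between samples.
    """
    t, v = _as_arrays(trace)
    run = _upstroke_run(t, v)
    if run is None:
        return None
    i0, i1, _ = run
    return 0.5 * (t[i0] + t[i1 + 1])


def apd90(trace):
    """Action potential duration at 90% repolarization, in ms.

    Raises ``ValueError`` when no AP is detected and flags (returns None)
    when the AP never repolarizes to the 90% level before the next upstroke
    or the end of the trace.
    """
    t, v = _as_arrays(trace)
    run = _upstroke_run(t, v)
    if run is None:
        raise ValueError("no action potential detected in trace")
    i0, _, ipk = run
    act = activation_time((t, v))
    # diastolic value immediately before the upstroke: walk back from the
    # steepest segment to the local minimum where depolarization began
    k0 = i0
    while k0 > 0 and v[k0 - 1] < v[k0]:
        k0 -= 1
    v_rest = v[k0]
    v_peak = v[ipk]
    threshold = v_rest + 0.1 * (v_peak - v_rest)

    below = np.flatnonzero(v[ipk:] <= threshold)
    if below.size == 0:
        return None
    k = ipk + below[0]
    if k == ipk:
        return None
    # flagged if the next AP starts before the 90% level is reached
    seg = v[ipk:k]
    dropped = np.flatnonzero(seg <= AP_PEAK_THRESHOLD)
    if dropped.size and np.any(seg[dropped[0]:] > AP_PEAK_THRESHOLD):
        return None
    # linear interpolation on the crossing segment
    t_cross = t[k - 1] + (threshold - v[k - 1]) / (v[k] - v[k - 1]) \
        * (t[k] - t[k - 1])
    return t_cross - act


def conduction_velocity(trace_a, trace_b, distance: float) -> float:
    """Straight-line conduction velocity (cm/s) between two probes.

    ``distance`` is in cm; probe B must activate after probe A (probes
    mis-ordered or conduction block are rejected).
    """
    if distance <= 0:
        raise ValueError("probe distance must be positive")
    ta = activation_time(trace_a)
    tb = activation_time(trace_b)
    if ta is None or tb is None:
        raise ValueError("activation not detected at both probes")
    dt_ms = tb - ta
    if dt_ms <= 0:
        raise ValueError("non-positive activation delay: probes mis-ordered "
                         "or conduction block")
    return distance / dt_ms * 1000.0


def percent_reduction(reference: float, value: float) -> float:
    """100 * (ref - value) / ref."""
    return 100.0 * (reference - value) / reference


@dataclass
class BiomarkerReport:
    """Per-scenario electrophysiological measurements."""

    configuration: str
    density: float | None
    apd90: float | None = None
    cv: float | None = None
    resting_vm: float | None = None
    activation_times: dict | None = None
    seed: int | None = None

    def complete(self) -> bool:
        return self.apd90 is not None and self.cv is not None


def reduction_table(reports, reference: BiomarkerReport) -> pd.DataFrame:
    """Table of APD90 / CV values and percent reductions vs the control.

    Incomplete rows (missing APD or CV) are kept and flagged rather than
    dropped.
    """
    rows = []
    for rep in reports:
        row = {
            "configuration": rep.configuration,
            "density": rep.density,
            "apd90_ms": rep.apd90,
            "cv_cm_s": rep.cv,
            "apd90_reduction_pct": (
                percent_reduction(reference.apd90, rep.apd90)
                if rep.apd90 is not None and reference.apd90 else None),
            "cv_reduction_pct": (
                percent_reduction(reference.cv, rep.cv)
                if rep.cv is not None and reference.cv else None),
            "incomplete": not rep.complete(),
        }
        rows.append(row)
    return pd.DataFrame(rows)
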