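"""Unipolar electrogram forward model and dominant-frequency analysis.

The extracellular potential at a virtual electrode is the volume integral of
the transmembrane-potential gradient against the dipole kernel,

    Phi_e(r) = -(sigma_i / (4 pi sigma_e)) * sum_elements
               grad' Vm . grad'(1 / |r' - r|) dv,

discretized element-wise on the tissue sheet and sampled at 1 ms.  Spectral
analysis band-passes the EGM at 40-250 Hz, rectifies, low-passes at 20 Hz
(all zero-phase Butterworth), and takes the dominant frequency as the
highest peak of the Fourier power spectrum of the resulting envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthetic_tissue import REGION_NAME, ElectrodeArray, TissueGrid

SIGMA_RATIO = 1.0          # sigma_i / sigma_e; pure amplitude factor
EGM_DT_MS = 1.0            # EGM sampling interval
BANDPASS_HZ = (40.0, 250.0)
LOWPASS_HZ = 20.0
FILTER_ORDER = 4
DF_BAND_HZ = (2.0, 20.0)
DF_GRID_HZ = 0.1           # zero-padded frequency resolution


@dataclass
class EgmTrace:
    """Electrode signal at fixed sampling (arbitrary units x sigma_i/sigma_e)."""

    electrode_id: int
    samples: np.ndarray
    dt: float = EGM_DT_MS       # ms
    region: str = "left_atrium"

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.dt

    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt


@dataclass
class SpectrumResult:
    frequencies: np.ndarray
    power: np.ndarray
    df: float | None
    morphology: str | None = None
    flag: str | None = None


def element_gradients(vm_frames: np.ndarray, grid: TissueGrid):
    """Element-center in-plane gradients of Vm, (n_frames, n_elem, 2) in mV/cm."""
    if vm_frames.ndim == 2:
        vm_frames = vm_frames[None, ...]
    v = vm_frames.astype(float)
    dx = grid.spacing
    gx = ((v[:, :-1, 1:] + v[:, 1:, 1:]) - (v[:, :-1, :-1] + v[:, 1:, :-1])) \
        / (2.0 * dx)
    gy = ((v[:, 1:, :-1] + v[:, 1:, 1:]) - (v[:, :-1, :-1] + v[:, :-1, 1:])) \
        / (2.0 * dx)
    nf = v.shape[0]
    return np.stack([gx.reshape(nf, -1), gy.reshape(nf, -1)], axis=-1)


def element_centers(grid: TissueGrid, z: float = 0.0) -> np.ndarray:
    """(n_elem, 3) element centers in cm (sheet plane at height ``z``)."""
    x = (np.arange(grid.nx - 1) + 0.5) * grid.spacing
    y = (np.arange(grid.ny - 1) + 0.5) * grid.spacing
    xx, yy = np.meshgrid(x, y)
    return np.stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)], axis=-1)


def dipole_kernel(grid: TissueGrid, electrode_pos: np.ndarray,
                  z: float = 0.0) -> np.ndarray:
    """grad'(1/|r' - r|) at every element center, (n_elem, 3).

    The gradient is taken with respect to the source point r'; an electrode
    coinciding with a source point makes the kernel singular and is rejected.
    """
    centers = element_centers(grid, z)
    d = centers - np.asarray(electrode_pos, dtype=float)[None, :]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-9):
        raise ValueError("electrode coincides with a source point "
                         "(singular kernel)")
    return -d / r[:, None] ** 3


def _layer_stack(vm_history, tissue):
    """Normalize snapshot history to (n_frames, n_layers, ny, nx) + layers."""
    layers = list(tissue.layers) if hasattr(tissue, "layers") else [tissue]
    v = np.asarray(vm_history)
    if v.ndim == 2:
        v = v[None, None, ...]
    elif v.ndim == 3:
        v = v[:, None, ...]
    if v.shape[1] != len(layers):
        raise ValueError("snapshot history does not match the tissue layers")
    return v, layers


def compute_egm(vm_history: np.ndarray, tissue, electrode_pos,
                electrode_id: int = 0, region: str = "left_atrium",
                sigma_ratio: float = SIGMA_RATIO,
                dt: float = EGM_DT_MS) -> EgmTrace:
    """Forward unipolar EGM at one electrode from the Vm snapshot history.

    ``vm_history`` is (n_frames, ny, nx) for a sheet, or
    (n_frames, n_layers, ny, nx) for a slab (in-plane gradients of every
    layer contribute with the layer's height); sampled at ``dt`` ms.
    """
    v, layers = _layer_stack(vm_history, tissue)
    dv = layers[0].spacing ** 3                          # one-element slab
    phi = 0.0
    for l, g in enumerate(layers):
        grads = element_gradients(v[:, l], g)            # (nf, ne, 2)
        kern = dipole_kernel(g, electrode_pos, z=l * g.spacing)[:, :2]
        phi = phi - (sigma_ratio / (4.0 * np.pi)) * dv * np.einsum(
            "fez,ez->f", grads, kern)
    return EgmTrace(electrode_id=electrode_id, samples=phi, dt=dt,
                    region=region)


def compute_egm_array(vm_history: np.ndarray, tissue,
                      electrodes: ElectrodeArray,
                      sigma_ratio: float = SIGMA_RATIO,
                      dt: float = EGM_DT_MS) -> list:
    """Forward EGMs for a whole electrode array (shared gradient pass)."""
    v, layers = _layer_stack(vm_history, tissue)
    dv = layers[0].spacing ** 3
    grads = [element_gradients(v[:, l], g) for l, g in enumerate(layers)]
    out = []
    for k, pos in enumerate(electrodes.positions):
        phi = 0.0
        for l, g in enumerate(layers):
            kern = dipole_kernel(g, pos, z=l * g.spacing)[:, :2]
            phi = phi - (sigma_ratio / (4.0 * np.pi)) * dv * np.einsum(
                "fez,ez->f", grads[l], kern)
        out.append(EgmTrace(electrode_id=k, samples=phi, dt=dt,
                            region=REGION_NAME[int(electrodes.region[k])]))
    return out


# ---------------------------------------------------------------------------
# Spectral pipeline
# ---------------------------------------------------------------------------

def preprocess(egm: EgmTrace) -> np.ndarray:
    """Band-pass 40-250 Hz, rectify, low-pass 20 Hz (all zero-phase).

    Requires at least 1 s of signal (filter warm-up).
    """
    x = np.asarray(egm.samples, dtype=float)
    fs = egm.fs
    if len(x) * egm.dt < 1000.0:
        raise ValueError("signal shorter than 1 s: too short for filtering")
    lo, hi = BANDPASS_HZ
    hi = min(hi, 0.49 * fs)
    sos_bp = signal.butter(FILTER_ORDER, [lo, hi], btype="bandpass",
                           fs=fs, output="sos")
    sos_lp = signal.butter(FILTER_ORDER, LOWPASS_HZ, btype="lowpass",
                           fs=fs, output="sos")
    y = signal.sosfiltfilt(sos_bp, x)
    y = np.abs(y)
    return signal.sosfiltfilt(sos_lp, y)


def dominant_frequency(envelope: np.ndarray, fs: float = 1000.0,
                       band=DF_BAND_HZ, min_duration_s: float = 4.0,
                       enforce_min_duration: bool = True) -> SpectrumResult:
    """Highest-peak frequency of the envelope power spectrum within the band.

    Hann-tapered periodogram, zero-padded to a 0.1 Hz grid; ties break
    toward the lower frequency.  A flat (DC-only) envelope yields an
    absent-value result with a flag.
    """
    x = np.asarray(envelope, dtype=float)
    if enforce_min_duration and len(x) / fs < min_duration_s:
        raise ValueError(
            f"envelope shorter than {min_duration_s} s: frequency resolution "
            "would be too coarse")
    x = x - x.mean()
    nfft = max(int(round(fs / DF_GRID_HZ)), len(x))
    freqs, power = signal.periodogram(x, fs=fs, window="hann", nfft=nfft,
                                      detrend=False)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    fsel, psel = freqs[sel], power[sel]
    total = psel.sum()
    if total <= 0 or not np.isfinite(total) or psel.max() < 1e-12 * max(
            power.max(), 1e-300):
        return SpectrumResult(frequencies=fsel, power=psel, df=None,
                              flag="flat_spectrum")
    return SpectrumResult(frequencies=fsel, power=psel,
                          df=float(fsel[int(np.argmax(psel))]))


def egm_dominant_frequency(egm: EgmTrace, discard_ms: float = 500.0,
                           **kwargs) -> SpectrumResult:
    """Full pipeline for one EGM: preprocess, drop the transient, take DF."""
    env = preprocess(egm)
    n_skip = int(round(discard_ms / egm.dt))
    return dominant_frequency(env[n_skip:], fs=egm.fs, **kwargs)


def df_gradient(la_dfs, ra_dfs) -> float:
    """Left-to-right DF gradient: mean RA DF minus mean LA DF (Hz).

    Positive when the left atrium is slower, matching the sign convention of
    the per-configuration DF tables.
    """
    la = [f for f in np.atleast_1d(la_dfs) if f is not None and np.isfinite(f)]
    ra = [f for f in np.atleast_1d(ra_dfs) if f is not None and np.isfinite(f)]
    if not la or not ra:
        raise ValueError("both DF sets must be nonempty")
    return float(np.mean(ra) - np.mean(la))


# ---------------------------------------------------------------------------
# Morphology classification
# ---------------------------------------------------------------------------

def classify_morphology(egm: EgmTrace, amp_fraction: float = 0.2,
                        cv_threshold: float = 0.2,
                        min_gap_ms: float = 60.0) -> str:
    """Tag an EGM as single / double / fragmented.

    Deflections are upward excursions of the detrended signal above
    ``amp_fraction`` of its robust (98th-percentile) amplitude; excursions
    separated by more than ``min_gap_ms`` start a new activation window.
    One deflection per window is a single potential, two a double potential;
    three or more with cycle-length variation above ``cv_threshold`` mark a
    fragmented electrogram.
    """
    x = np.asarray(egm.samples, dtype=float)
    if len(x) * egm.dt < 1000.0:
        raise ValueError("signal shorter than 1 s")
    x = x - np.median(x)
    robust_amp = np.percentile(np.abs(x), 98)
    if robust_amp <= 0:
        return "single"
    thr = amp_fraction * robust_amp
    above = x > thr
    # rising edges of the threshold crossings
    edges = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if edges.size == 0:
        return "single"
    t_edges = edges * egm.dt
    gaps = np.diff(t_edges)
    window_starts = [t_edges[0]]
    counts = [1]
    for g, te in zip(gaps, t_edges[1:]):
        if g > min_gap_ms:
            window_starts.append(te)
            counts.append(1)
        else:
            counts[-1] += 1
    mean_defl = float(np.mean(counts))
    if len(window_starts) >= 3:
        cls = np.diff(window_starts)
        cl_cv = float(np.std(cls) / np.mean(cls))
    else:
        cl_cv = 0.0
    if mean_defl < 1.5:
        return "single"
    if mean_defl < 2.5 or cl_cv <= cv_threshold:
        return "double"
    return "fragmented"


def egms_to_csv(egms: list, path) -> None:
    """EGM bundle as CSV: time ms plus one column per electrode."""
    n = len(egms[0].samples)
    t = egms[0].times()
    cols = np.column_stack([t] + [e.samples for e in egms])
    header = "time_ms," + ",".join(f"egm_{e.electrode_id}" for e in egms)
    np.savetxt(path, cols, delimiter=",", header=header, comments="")
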