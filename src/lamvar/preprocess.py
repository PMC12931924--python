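"""Preprocessing: multi-unit event detection, unit gating (responsiveness and
size tuning), current-source-density (CSD) analysis and laminar assignment.

The CSD is computed as the second spatial derivative of the band-passed,
trial-averaged laminar LFP; the granular layer is bounded above by the
earliest significant current sink and below by the first sink-to-source
reversal beneath it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from scipy.interpolate import CubicSpline

__all__ = [
    "CSDMap",
    "LayerBoundaries",
    "estimate_noise_sd",
    "detect_mu_events",
    "is_visually_responsive",
    "is_size_tuned",
    "compute_csd",
    "assign_layers",
]

#: median(|N(0,1)|) — scales the median absolute signal to a Gaussian SD
MAD_SCALE = 0.6745
CSD_DEPTH_STEP_UM = 10.0
CSD_BAND_HZ = (1.0, 100.0)
CSD_BASELINE_MS = 200.0


def estimate_noise_sd(trace) -> float:
    """Robust noise SD: median(|x|) / 0.6745.

    The median of the absolute signal divided by 0.6745 estimates the SD of
    the Gaussian background while ignoring sparse large spikes (which a raw
    SD would inflate).
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 1000:
        raise ValueError("need >= 1000 samples for a stable noise estimate")
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("all-NaN trace")
    return float(np.median(np.abs(x)) / MAD_SCALE)


def detect_mu_events(trace, fs: float, band_hz: tuple[float, float] = (300.0, 5000.0),
                     k: float = 4.0, polarity: int = -1,
                     refractory_ms: float = 1.0) -> np.ndarray:
    """Threshold-crossing event times (seconds) on the band-passed trace.

    The trace is band-pass filtered, thresholded at ``k`` times the robust
    noise SD of the filtered trace (negative excursions by default, the
    extracellular convention), and one event is emitted per contiguous
    supra-threshold excursion at the time of its absolute peak, with a
    refractory period enforced.
    """
    x = np.asarray(trace, dtype=float)
    if fs < 10_000:
        raise ValueError("sampling rate must be >= 10 kHz")
    lo, hi = band_hz
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"invalid band {band_hz} for fs={fs}")
    sos = signal.butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    if x.size < 3 * 3 * 2 * 3:  # a few filter lengths
        raise ValueError("trace shorter than the filter transient")
    y = signal.sosfiltfilt(sos, x)
    sd = estimate_noise_sd(y)
    if sd == 0:
        return np.empty(0)
    excursion = (polarity * y) > (k * sd)
    if not np.any(excursion):
        return np.empty(0)
    # contiguous runs of supra-threshold samples
    d = np.diff(excursion.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if excursion[0]:
        starts = np.r_[0, starts]
    if excursion[-1]:
        ends = np.r_[ends, excursion.size]
    peaks = np.array([s + np.argmax(np.abs(y[s:e])) for s, e in zip(starts, ends)])
    times = peaks / fs
    refr = refractory_ms / 1000.0
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refr:
            kept.append(t)
    return np.asarray(kept)


def is_visually_responsive(stim_counts, base_counts,
                           stim_window_ms: float = 300.0,
                           base_window_ms: float = 400.0,
                           min_evoked: float = 3.0) -> bool:
    """True iff, at the best diameter, the mean stimulus count exceeds the
    duration-matched mean baseline count by at least ``min_evoked`` spikes.

    ``stim_counts`` and ``base_counts`` are (diameters, trials) arrays; the
    baseline mean is rescaled by the window-length ratio before comparison.
    """
    s = np.asarray(stim_counts, dtype=float)
    b = np.asarray(base_counts, dtype=float)
    if s.ndim != 2 or b.ndim != 2 or s.shape != b.shape or s.shape[1] < 2:
        raise ValueError("stim and baseline counts must be matching (diameters, trials>=2)")
    evoked = s.mean(axis=1) - b.mean(axis=1) * (stim_window_ms / base_window_ms)
    return bool(np.max(evoked) >= min_evoked)


def is_size_tuned(counts_by_diameter, alpha: float = 0.05) -> bool:
    """One-way fixed-effects ANOVA of stimulus-window counts across diameter
    groups; True iff p < ``alpha``."""
    groups = [np.asarray(g, dtype=float) for g in counts_by_diameter]
    if len(groups) < 2:
        raise ValueError("need >= 2 diameter groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("every diameter group needs >= 2 trials")
    if all(np.ptp(g) == 0 for g in groups) and len({g.mean() for g in groups}) == 1:
        return False  # identical constant groups: no tuning, ANOVA degenerate
    _, p = stats.f_oneway(*groups)
    return bool(p < alpha)


@dataclass
class CSDMap:
    """Z-scored CSD on a 10 um depth grid.

    Z-scoring uses only the pre-stimulus baseline samples of each depth.
    """

    depths_um: np.ndarray
    times_ms: np.ndarray
    z: np.ndarray  # (depths, times), Z-scored
    raw: np.ndarray | None = None  # unnormalized second spatial derivative

    def __post_init__(self) -> None:
        step = np.diff(self.depths_um)
        if not np.allclose(step, CSD_DEPTH_STEP_UM):
            raise ValueError("depth grid spacing must be exactly 10 um")


@dataclass
class LayerBoundaries:
    """Laminar compartments from the CSD sink/reversal geometry."""

    sink_depth_um: float       # depth of the earliest sink's extremum
    sg_g_boundary_um: float    # top of the significant sink region
    g_ig_boundary_um: float    # sink-to-source reversal below the sink

    def layer_of(self, depth_um: float) -> str:
        if depth_um < self.sg_g_boundary_um:
            return "SG"
        if depth_um <= self.g_ig_boundary_um:
            return "G"
        return "IG"


class UnassignableLaminarProfile(ValueError):
    """No significant current sink: layers cannot be assigned."""


def compute_csd(lfp, times_ms, depths_um, fs: float,
                band_hz: tuple[float, float] = CSD_BAND_HZ,
                baseline_ms: float = CSD_BASELINE_MS) -> CSDMap:
    """CSD of a laminar LFP: band-pass, trial-average, second spatial
    difference, cubic interpolation to a 10 um grid, per-depth Z-scoring
    against the pre-stimulus baseline.

    ``lfp`` has shape (channels, times, trials) on a uniformly spaced depth
    axis; ``times_ms`` is stimulus-locked (onset at 0).
    """
    lfp = np.asarray(lfp, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    depths_um = np.asarray(depths_um, dtype=float)
    if lfp.ndim != 3 or lfp.shape[0] < 5:
        raise ValueError("need (channels>=5, times, trials) LFP")
    spacing = np.diff(depths_um)
    if not np.allclose(spacing, spacing[0]):
        raise ValueError("non-uniform channel spacing")
    h_um = float(spacing[0])

    lo, hi = band_hz
    nyq = fs / 2.0
    duration_s = (times_ms[-1] - times_ms[0]) / 1000.0
    if duration_s >= 2.0 / lo:
        sos = signal.butter(3, [lo, min(hi, 0.95 * nyq)], btype="bandpass",
                            fs=fs, output="sos")
    else:
        # the high-pass corner is unsupported on a trace this short: the
        # zero-phase filter would smear the evoked transient across the
        # pre-stimulus baseline, corrupting the Z-scoring reference
        sos = signal.butter(3, min(hi, 0.95 * nyq), btype="lowpass",
                            fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, lfp, axis=1)
    avg = filt.mean(axis=2)  # (channels, times)

    # second spatial difference (interior channels), per mm^2 scale unit-free
    d2 = (avg[:-2] - 2 * avg[1:-1] + avg[2:]) / (h_um ** 2)
    mid_depths = depths_um[1:-1]

    grid = np.arange(mid_depths[0], mid_depths[-1] + CSD_DEPTH_STEP_UM / 2,
                     CSD_DEPTH_STEP_UM)
    csd = CubicSpline(mid_depths, d2, axis=0)(grid)

    base = (times_ms >= -baseline_ms) & (times_ms < 0)
    if not np.any(base):
        raise ValueError("no pre-stimulus baseline samples to Z-score against")
    mu = csd[:, base].mean(axis=1, keepdims=True)
    sd = csd[:, base].std(axis=1, ddof=1, keepdims=True)
    # a baseline SD at numerical-noise level (quiet channel) must not blow
    # up the Z-score; floor it relative to the profile's overall scale
    floor = max(1e-9 * float(np.abs(csd).max()), 1e-300)
    sd = np.maximum(sd, floor)
    return CSDMap(depths_um=grid, times_ms=times_ms, z=(csd - mu) / sd, raw=csd)


def assign_layers(csd: CSDMap, z_threshold: float = 2.0,
                  peak_window_ms: float = 40.0) -> LayerBoundaries:
    """Locate the earliest significant current sink and the sink-to-source
    reversal below it; depths above the sink are SG, between sink top and
    reversal G, below the reversal IG.

    Raises :class:`UnassignableLaminarProfile` when no post-stimulus sink
    reaches ``-z_threshold``.
    """
    post = csd.times_ms >= 0
    z = csd.z[:, post]
    t_post = csd.times_ms[post]
    # deepest (most negative) post-stimulus deflection anchors the sink;
    # single-sample threshold crossings are baseline-level noise
    di, ti = np.unravel_index(int(np.argmin(z)), z.shape)
    if z[di, ti] > -z_threshold:
        raise UnassignableLaminarProfile(
            f"no CSD sink below -{z_threshold} found after stimulus onset")
    win = np.abs(t_post - t_post[ti]) <= peak_window_ms / 2.0
    prof = z[:, win].mean(axis=1)

    sig = prof <= -z_threshold
    if not np.any(sig):
        # an isolated sub-threshold extremum with no sustained sink in the
        # averaged profile is noise, not an evoked sink
        raise UnassignableLaminarProfile(
            f"no sustained CSD sink below -{z_threshold} in the averaged profile")
    sink_idx = int(np.argmin(prof))
    # contiguous significant sink region containing the extremum
    top = sink_idx
    while top > 0 and sig[top - 1]:
        top -= 1
    bottom = sink_idx
    while bottom < prof.size - 1 and prof[bottom + 1] < 0:
        bottom += 1
    # first zero crossing (sink -> source) below the sink region
    below = prof[bottom:]
    cross = np.flatnonzero(below >= 0)
    if cross.size:
        rev_idx = bottom + int(cross[0])
    else:
        rev_idx = prof.size - 1
    return LayerBoundaries(
        sink_depth_um=float(csd.depths_um[sink_idx]),
        sg_g_boundary_um=float(csd.depths_um[top]),
        g_ig_boundary_um=float(csd.depths_um[rev_idx]),
    )


def layer_table(boundaries: LayerBoundaries, channel_depths_um) -> list[str]:
    """Layer label per channel depth (SG/G/IG)."""
    return [boundaries.layer_of(d) for d in np.asarray(channel_depths_um, dtype=float)]
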