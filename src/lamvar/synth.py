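"""Synthetic laminar sessions with known ground truth.

The generative model for spike counts is a doubly stochastic (gain-modulated)
Poisson process.  On trial ``t`` of diameter ``s``, unit ``u`` fires

    N_{u,t} ~ Poisson( mu_u(s) * T * g_{u,t} * h_{u,t} )

with a *private* log-normal gain  g = exp(sigma_u(s) * eps_{u,t} - sigma^2/2)
(eps i.i.d. standard normal) and a *shared* gain
h = exp(lambda_u(s) * z_t - lambda^2/2) coupling all units of a penetration
through one latent z_t ~ N(0,1).  Both gains have mean one, so mu is the true
mean rate, and the spike-count moments have closed forms:

    E[N]   = m,                        m = mu * T
    Var[N] = m + m^2 (e^{sigma^2 + lambda^2} - 1)
    Cov[N_u, N_v] = m_u m_v (e^{lambda_u lambda_v} - 1)        (u != v)

hence the Fano-factor is FF = 1 + (e^{sigma^2+lambda^2} - 1) * m and, for small
loadings, the single-factor shared variance per unit is (m_u lambda_u)^2.
These moments are the recovery oracles for every downstream stage.

Mean rates follow per-unit ratio-of-Gaussians size tuning; the default
configuration gives the three laminar compartments distinct variability
size tuning (SG: far-surround increase; G: flat beyond the RF; IG:
near-surround decrease) so end-to-end sign-recovery tests are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.interpolate import PchipInterpolator

from .datamodel import LAYER_VOCAB, TrialSpikeData, UnitRecord
from .tuning import RoGParams, rf_diameter, rog, suppression_index

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "default_config",
    "simulate_session",
    "simulate_voltage",
    "simulate_laminar_lfp",
    "default_diameters",
]

#: FF and shared-variance size-tuning profiles per layer, as multipliers of the
#: value at the RF, pinned at {s_min, RF, 2RF (near surround), 26 deg (far)}.
LAYER_FF_PROFILE = {
    "SG": (1.55, 1.0, 1.0, 1.45),
    "G": (1.55, 1.0, 1.0, 1.0),
    "IG": (1.50, 1.0, 0.65, 0.72),
    "unassigned": (1.0, 1.0, 1.0, 1.0),
}
#: fraction of the excess (super-Poisson) log-variance carried by the shared
#: latent, pinned at {s_min, RF, 2RF, 26 deg}; the rest is private gain.
#: Because the Fano-factor excess itself is size-tuned, these fractions give
#: shared variance the same laminar sign pattern as the Fano-factor, with
#: the SG far-surround rise reinforced.
LAYER_SHARED_FRACTION = {
    "SG": (0.5, 0.5, 0.5, 0.95),
    "G": (0.6, 0.6, 0.6, 0.6),
    "IG": (0.6, 0.6, 0.35, 0.35),
    "unassigned": (0.6, 0.6, 0.6, 0.6),
}
#: expected sign of the per-layer median % change (near = 2RF vs RF,
#: far = 26 deg vs RF); 0 means "flat" (|median| small).  G-layer flatness
#: is a Fano-factor property; its shared variance inherits the rate decline.
LAYER_SIGN_PATTERN = {
    "SG": {"ff_far": 1, "sv_far": 1},
    "G": {"ff_far": 0},
    "IG": {"ff_near": -1, "sv_near": -1},
}

LAMBDA_CAP = 0.9


def default_diameters(n: int = 12, s_min: float = 0.1, s_max: float = 26.0) -> np.ndarray:
    """Log-spaced grating diameters, 0.1-26 deg."""
    return np.geomspace(s_min, s_max, n)


def default_layer_map(n_channels: int = 24) -> list[str]:
    """Laminar label per channel, superficial to deep (SG above G above IG)."""
    if n_channels < 6:
        raise ValueError("need at least 6 channels for a laminar map")
    n_edge = 1 if n_channels < 16 else 2
    body = n_channels - 2 * n_edge
    n_sg = round(body * 0.35)
    n_g = max(round(body * 0.2), 1)
    n_ig = body - n_sg - n_g
    return (["unassigned"] * n_edge + ["SG"] * n_sg + ["G"] * n_g
            + ["IG"] * n_ig + ["unassigned"] * n_edge)


@dataclass
class SynthConfig:
    """Full specification of a synthetic laminar session.

    ``private_gain_sd`` and ``shared_loading`` are arrays of shape
    (n_units, n_diameters) giving sigma_u(s) and lambda_u(s) at the stimulus
    diameters; ``rate_params`` is one RoG parameter set per unit.
    """

    n_penetrations: int
    channels_per_penetration: int
    layer_assignment: list[str]
    diameters: np.ndarray
    trials_per_diameter: int
    rate_params: list[RoGParams]
    private_gain_sd: np.ndarray
    shared_loading: np.ndarray
    baseline_rate: np.ndarray
    baseline_gain_sd: np.ndarray
    baseline_loading: np.ndarray
    stim_ms: float = 500.0
    baseline_ms: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        if np.any(np.diff(self.diameters) <= 0) or np.any(self.diameters <= 0):
            raise ValueError("diameters must be strictly increasing and positive")
        if self.trials_per_diameter < 2:
            raise ValueError("need at least 2 trials per diameter")
        if self.stim_ms <= 0 or self.baseline_ms <= 0:
            raise ValueError("durations must be positive")
        if len(self.layer_assignment) != self.channels_per_penetration:
            raise ValueError("layer_assignment must have one label per channel")
        if set(self.layer_assignment) - set(LAYER_VOCAB):
            raise ValueError("unknown layer label in assignment")
        n_units = self.n_penetrations * self.channels_per_penetration
        self.private_gain_sd = np.asarray(self.private_gain_sd, dtype=float)
        self.shared_loading = np.asarray(self.shared_loading, dtype=float)
        shape = (n_units, self.diameters.size)
        if self.private_gain_sd.shape != shape or self.shared_loading.shape != shape:
            raise ValueError(f"gain arrays must have shape {shape}")
        if np.any(self.private_gain_sd < 0):
            raise ValueError("sigma_G(s) must be >= 0")
        if len(self.rate_params) != n_units:
            raise ValueError("need one RoGParams per unit")
        self.baseline_rate = np.asarray(self.baseline_rate, dtype=float)
        if np.any(self.baseline_rate < 0) or not np.all(np.isfinite(self.baseline_rate)):
            raise ValueError("baseline rates must be finite and >= 0")

    @property
    def n_units(self) -> int:
        return self.n_penetrations * self.channels_per_penetration

    def unit_layer(self, unit_index: int) -> str:
        return self.layer_assignment[unit_index % self.channels_per_penetration]


@dataclass
class GroundTruth:
    """Generator parameters in the units downstream analyses measure.

    ``excess_var_rate[u, d]`` is (e^{sigma^2+lambda^2} - 1) * mu(s) in 1/s, so
    the true Fano-factor in a count window of length ``T`` seconds is
    ``1 + excess_var_rate * T``.  ``shared_sd_rate[u, d]`` is
    ``sqrt(e^{lambda^2} - 1) * mu``, so the single-factor shared variance in a
    window ``T`` is ``(shared_sd_rate * T)^2`` (exact for loadings equal
    across units; the rank-one scale for small heterogeneous loadings).
    """

    diameters: np.ndarray
    unit_ids: list[str]
    layers: list[str]
    rf_deg: np.ndarray
    si: np.ndarray
    mean_rate_hz: np.ndarray           # (units, diameters)
    excess_var_rate: np.ndarray        # (units, diameters), 1/s
    shared_sd_rate: np.ndarray         # (units, diameters), 1/s
    baseline_rate_hz: np.ndarray
    baseline_excess_var_rate: np.ndarray
    baseline_shared_sd_rate: np.ndarray
    sign_pattern: dict = field(default_factory=lambda: dict(LAYER_SIGN_PATTERN))

    def ff_curve(self, window_s: float = 0.4) -> np.ndarray:
        """True Fano-factor per unit x diameter for a window of ``window_s``."""
        ff = 1.0 + self.excess_var_rate * window_s
        return ff

    def baseline_ff(self, window_s: float = 0.4) -> np.ndarray:
        return 1.0 + self.baseline_excess_var_rate * window_s

    def shared_variance_curve(self, window_s: float = 0.3) -> np.ndarray:
        """True per-unit shared variance (count^2) for a window of ``window_s``."""
        return (self.shared_sd_rate * window_s) ** 2

    def to_dict(self) -> dict:
        return {
            "diameters": self.diameters.tolist(),
            "unit_ids": list(self.unit_ids),
            "layers": list(self.layers),
            "rf_deg": self.rf_deg.tolist(),
            "si": self.si.tolist(),
            "mean_rate_hz": self.mean_rate_hz.tolist(),
            "excess_var_rate": self.excess_var_rate.tolist(),
            "shared_sd_rate": self.shared_sd_rate.tolist(),
            "baseline_rate_hz": self.baseline_rate_hz.tolist(),
            "baseline_excess_var_rate": self.baseline_excess_var_rate.tolist(),
            "baseline_shared_sd_rate": self.baseline_shared_sd_rate.tolist(),
            "sign_pattern": self.sign_pattern,
        }

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _profile_interpolant(s_min: float, rf: float, values4, s_max: float = 26.0):
    """Monotone-in-between curve through multipliers pinned at
    {s_min, RF, 2RF, 26 deg} (log-diameter PCHIP)."""
    knots_s = np.array([s_min, rf, min(2 * rf, 0.9 * s_max), s_max])
    vals = np.asarray(values4, dtype=float)
    order = np.argsort(knots_s)
    ks, vs = knots_s[order], vals[order]
    # degenerate spacing can only happen for absurd RFs; nudge apart
    ks = np.maximum.accumulate(ks + np.arange(4) * 1e-6)
    return PchipInterpolator(np.log(ks), vs, extrapolate=True)


def _draw_rate_params(rng: np.random.Generator, baseline_hz: float) -> RoGParams:
    """One unit's rate size-tuning: RF around ~1 deg, SI around 0.35-0.65."""
    w_c = float(rng.lognormal(np.log(0.8), 0.25))
    w_s = w_c * float(rng.uniform(3.0, 6.0))
    k_s = float(rng.uniform(0.8, 2.5))
    peak_target = float(rng.uniform(20.0, 40.0))
    k_c = (peak_target - baseline_hz) * (1.0 + k_s)
    return RoGParams(k_c=max(k_c, 1.0), w_c=w_c, k_s=k_s, w_s=w_s, r0=baseline_hz)


def default_config(
    seed: int = 0,
    n_penetrations: int = 5,
    channels_per_penetration: int = 24,
    n_diameters: int = 12,
    trials_per_diameter: int = 30,
    amplifier_fraction: float = 0.65,
    ff_at_rf: float = 2.2,
    baseline_ff: float = 3.0,
) -> SynthConfig:
    """Study-condition defaults: 5 penetrations x 24 channels, log-spaced
    diameters 0.1-26 deg, 500 ms stimulus / 400 ms baseline per trial,
    size-tuned rates, private gains and one shared latent per penetration
    with layer-dependent loadings.

    ``amplifier_fraction`` of units get a small-stimulus Fano-factor above
    their pre-stimulus baseline (variability amplifiers); the rest sit below
    it everywhere (quenchers).
    """
    rng = np.random.default_rng(seed)
    diameters = default_diameters(n_diameters)
    layer_map = default_layer_map(channels_per_penetration)
    n_units = n_penetrations * channels_per_penetration
    s_min, s_max = diameters[0], diameters[-1]

    rate_params: list[RoGParams] = []
    sigma = np.zeros((n_units, n_diameters))
    lam = np.zeros((n_units, n_diameters))
    base_rate = np.zeros(n_units)
    base_sigma = np.zeros(n_units)
    base_lam = np.full(n_units, 0.3)
    T_ref = 0.4  # reference count window (s) at which FF targets are pinned

    for u in range(n_units):
        layer = layer_map[u % channels_per_penetration]
        base_rate[u] = rng.uniform(3.5, 6.5)
        p = _draw_rate_params(rng, base_rate[u])
        rate_params.append(p)
        rf = rf_diameter(p) or 1.0
        mu = rog(diameters, p)
        m = mu * T_ref

        is_amp = rng.random() < amplifier_fraction
        ffp = LAYER_FF_PROFILE[layer]
        # amplifiers exceed their baseline FF for the smallest stimuli
        small_mult = (baseline_ff - 1.0) / (ff_at_rf - 1.0) * (1.35 if is_amp else 0.75)
        far_knot = ffp[3]
        if layer == "SG":
            # far-surround variability amplification grows with surround
            # suppression (the FF-change-vs-SI correlation seen in SG)
            si_u = 0.5 if rf is None else float(
                np.clip(suppression_index(p, rf=rf), 0.0, 1.0))
            far_knot = 1.4 + 1.0 * si_u
        ff_knots = (small_mult * ffp[1], ffp[1], ffp[2], far_knot)
        ff_interp = _profile_interpolant(s_min, rf, ff_knots, s_max)
        ff_target = 1.0 + (ff_at_rf - 1.0) * np.clip(ff_interp(np.log(diameters)), 0.05, None)

        # total super-Poisson log-variance needed to hit the FF target, then
        # split between shared latent and private gain per layer profile
        total_logvar = np.log1p((ff_target - 1.0) / np.maximum(m, 1e-9))
        phi = np.clip(
            _profile_interpolant(s_min, rf, LAYER_SHARED_FRACTION[layer], s_max)(
                np.log(diameters)), 0.0, 0.95)
        lam[u] = np.minimum(np.sqrt(phi * total_logvar), LAMBDA_CAP)
        sigma[u] = np.sqrt(np.maximum(total_logvar - lam[u] ** 2, 0.0))

        m_b = base_rate[u] * T_ref
        base_logvar = np.log1p((baseline_ff - 1.0) / m_b)
        base_lam[u] = min(np.sqrt(0.3 * base_logvar), LAMBDA_CAP)
        base_sigma[u] = np.sqrt(max(base_logvar - base_lam[u] ** 2, 0.0))

    return SynthConfig(
        n_penetrations=n_penetrations,
        channels_per_penetration=channels_per_penetration,
        layer_assignment=layer_map,
        diameters=diameters,
        trials_per_diameter=trials_per_diameter,
        rate_params=rate_params,
        private_gain_sd=sigma,
        shared_loading=lam,
        baseline_rate=base_rate,
        baseline_gain_sd=base_sigma,
        baseline_loading=base_lam,
        seed=seed,
    )


def simulate_session(config: SynthConfig) -> tuple[TrialSpikeData, GroundTruth]:
    """Draw one session from the generative model; deterministic given
    ``config.seed``.  Spike times are placed uniformly within their segment
    (only counts matter downstream) and rounded to 0.1 ms.
    """
    rng = np.random.default_rng(config.seed)
    n_ch = config.channels_per_penetration
    n_diam = config.diameters.size
    n_tr = config.trials_per_diameter
    stim_s = config.stim_ms / 1000.0
    base_s = config.baseline_ms / 1000.0

    units: list[UnitRecord] = []
    spikes: list[list[list[np.ndarray]]] = []
    mean_rate = np.zeros((config.n_units, n_diam))
    rf_arr = np.zeros(config.n_units)
    si_arr = np.zeros(config.n_units)

    for pen in range(config.n_penetrations):
        u_slice = range(pen * n_ch, (pen + 1) * n_ch)
        # one shared latent per trial (stimulus) and per trial (baseline)
        z_stim = rng.standard_normal((n_diam, n_tr))
        z_base = rng.standard_normal((n_diam, n_tr))
        for ch, u in enumerate(u_slice):
            layer = config.layer_assignment[ch]
            rec = UnitRecord(unit_id=f"p{pen}c{ch:02d}", penetration=pen, channel=ch,
                             depth_um=ch * 100.0, layer=layer)
            units.append(rec)
            p = config.rate_params[u]
            mu = rog(config.diameters, p)
            if not np.all(np.isfinite(mu)):
                raise ValueError(f"non-finite rate for unit {rec.unit_id}")
            mean_rate[u] = mu
            rf = rf_diameter(p)
            rf_arr[u] = np.nan if rf is None else rf
            si_arr[u] = np.nan if rf is None else suppression_index(p, rf=rf)

            per_unit: list[list[np.ndarray]] = []
            sig_u = config.private_gain_sd[u]
            lam_u = config.shared_loading[u]
            for di in range(n_diam):
                s2 = sig_u[di] ** 2
                l2 = lam_u[di] ** 2
                eps = rng.standard_normal(n_tr)
                gain = np.exp(sig_u[di] * eps - s2 / 2.0) * np.exp(
                    lam_u[di] * z_stim[di] - l2 / 2.0)
                n_stim = rng.poisson(mu[di] * stim_s * gain)

                bs2 = config.baseline_gain_sd[u] ** 2
                bl2 = config.baseline_loading[u] ** 2
                eps_b = rng.standard_normal(n_tr)
                gain_b = np.exp(config.baseline_gain_sd[u] * eps_b - bs2 / 2.0) * np.exp(
                    config.baseline_loading[u] * z_base[di] - bl2 / 2.0)
                n_base = rng.poisson(config.baseline_rate[u] * base_s * gain_b)

                trials = []
                for ti in range(n_tr):
                    t_stim = rng.uniform(0.0, config.stim_ms, size=n_stim[ti])
                    t_base = rng.uniform(-config.baseline_ms, 0.0, size=n_base[ti])
                    t = np.sort(np.concatenate([t_base, t_stim]))
                    trials.append(np.round(t, 1))
                per_unit.append(trials)
            spikes.append(per_unit)

    layers = [config.layer_assignment[i % n_ch] for i in range(config.n_units)]
    total_logvar = config.private_gain_sd ** 2 + config.shared_loading ** 2
    excess = np.expm1(total_logvar) * mean_rate
    base_total = config.baseline_gain_sd ** 2 + config.baseline_loading ** 2
    truth = GroundTruth(
        diameters=config.diameters.copy(),
        unit_ids=[u.unit_id for u in units],
        layers=layers,
        rf_deg=rf_arr,
        si=si_arr,
        mean_rate_hz=mean_rate,
        excess_var_rate=excess,
        shared_sd_rate=np.sqrt(np.expm1(config.shared_loading ** 2)) * mean_rate,
        baseline_rate_hz=config.baseline_rate.copy(),
        baseline_excess_var_rate=np.expm1(base_total) * config.baseline_rate,
        baseline_shared_sd_rate=np.sqrt(np.expm1(config.baseline_loading ** 2))
        * config.baseline_rate,
    )
    data = TrialSpikeData(units=units, diameters=config.diameters.copy(), spikes=spikes,
                          t_start_ms=-config.baseline_ms, t_stop_ms=config.stim_ms)
    return data, truth


# ---------------------------------------------------------------------------
# raw-signal fixtures


def simulate_voltage(duration_s: float, fs: float, noise_sd: float,
                     spike_times_s, waveform, seed: int = 0) -> np.ndarray:
    """Gaussian noise with a spike waveform inserted at each spike time.

    Fixture for the event detector: the ground truth is exactly
    ``spike_times_s``.  Requires fs >= 10 kHz and spikes inside the trace.
    """
    if fs < 10_000:
        raise ValueError("sampling rate must be >= 10 kHz")
    spike_times_s = np.asarray(spike_times_s, dtype=float)
    waveform = np.asarray(waveform, dtype=float)
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    trace = rng.standard_normal(n) * noise_sd if noise_sd > 0 else np.zeros(n)
    for t in spike_times_s:
        i0 = int(round(t * fs))
        if i0 < 0 or i0 + waveform.size > n:
            raise ValueError(f"spike at {t} s extends beyond the trace")
        trace[i0:i0 + waveform.size] += waveform
    return trace


def default_waveform(fs: float, amp: float = 1.0, width_ms: float = 0.4) -> np.ndarray:
    """Biphasic (negative-leading) extracellular-style spike waveform."""
    n = max(int(round(2.0 * width_ms * 1e-3 * fs)), 8)
    t = np.arange(n) / fs * 1e3  # ms
    w = -np.exp(-((t - 0.3 * width_ms) ** 2) / (2 * (0.18 * width_ms) ** 2))
    w += 0.35 * np.exp(-((t - 1.1 * width_ms) ** 2) / (2 * (0.35 * width_ms) ** 2))
    return amp * w / np.abs(w.min())  # negative peak at -amp


def simulate_laminar_lfp(
    n_channels: int = 24,
    depth_spacing_um: float = 100.0,
    sink_channel: int = 12,
    source_channel: int = 16,
    fs: float = 1000.0,
    pre_ms: float = 300.0,
    post_ms: float = 500.0,
    n_trials: int = 20,
    noise_sd: float = 0.02,
    dipole_width_um: float = 150.0,
    depth_offset_um: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Laminar LFP with a known sink/source dipole for CSD tests.

    The potential is a positive Gaussian bump in depth at the sink channel and
    a negative one at the source channel (so its second spatial derivative has
    a negative extremum at the sink and a positive one at the source), scaled
    by a post-stimulus alpha-function time course, plus white noise.

    Returns ``(lfp[channel, time, trial], times_ms, depths_um)``.
    """
    if n_channels < 5:
        raise ValueError("need at least 5 channels")
    if sink_channel == source_channel:
        raise ValueError("sink and source must differ")
    for c in (sink_channel, source_channel):
        if not 0 <= c < n_channels:
            raise ValueError("sink/source channel outside range")
    rng = np.random.default_rng(seed)
    depths = np.arange(n_channels) * depth_spacing_um + depth_offset_um
    times = np.arange(-pre_ms, post_ms, 1000.0 / fs)
    z_sink = depths[sink_channel]
    z_source = depths[source_channel]
    prof = (np.exp(-((depths - z_sink) ** 2) / (2 * dipole_width_um ** 2))
            - np.exp(-((depths - z_source) ** 2) / (2 * dipole_width_um ** 2)))
    tau = 40.0
    tt = np.clip(times - 30.0, 0.0, None)
    alpha = (tt / tau) * np.exp(1.0 - tt / tau)
    clean = prof[:, None] * alpha[None, :]
    lfp = clean[:, :, None] + rng.standard_normal((n_channels, times.size, n_trials)) * noise_sd
    return lfp, times, depths
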