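"""Ground-truth synthetic sessions: behavior, voltage traces, movies, protocols.

The generator emulates the phenomenology of 1 kHz voltage imaging of
hippocampal CA1 pyramidal cells during virtual-track navigation, so that
every downstream stage of the pipeline has a recoverable target:

* a 180 cm unidirectional virtual track run in discrete trials with 1-3 s
  inter-trial intervals and 20% reward omission;
* fluorescence traces built from Gaussian baseline noise plus spike
  templates at a controlled spike-height/noise ratio (SNR, default 8.8),
  6-10 Hz theta with in-field amplitude modulation, an in-field subthreshold
  ramp, plateau-driven complex spikes (~46 ms, ~59% of spike height) carrying
  riding spike bursts, and multiplicative exponential photobleaching;
* protocol sessions: closed-loop place-field induction (Pre/Stim/Post
  epochs with a 300 ms stimulus at a fixed track location and an injected
  backward-shifted place field), stepped 500 ms excitability (F-I) stimuli,
  and 1 Hz presynaptic test pulses evoking EPSPs/IPSPs and spikes.

All amplitudes of subthreshold events are specified as fractions of spike
height; the rendered fluorescence is ``bleach(t) * F0 * (1 + spike_df * u(t))``
where ``u`` is the trace in spike-height units, making every downstream
statistic invariant to the absolute fluorescence scale.

Determinism: every public generator draws from ``numpy.random.default_rng``
seeded by ``config.rng_seed`` (or an explicit ``rng``); identical seed and
config give byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .core import BehaviorTrack, Trace
from .errors import InvalidConfigError

SESSION_MODES = ("plasticity", "fi", "synaptic")


@dataclass
class SynthConfig:
    """Generation parameters; defaults are the emulated study conditions."""

    sample_rate: float = 1000.0          # Hz
    track_length: float = 180.0          # cm
    n_trials: int = 10
    snr: float = 8.8                     # spike height / baseline noise sigma
    theta_band: tuple = (6.0, 10.0)      # Hz
    theta_amp_in: float = 0.091          # fraction of spike height, in-field
    theta_amp_out: float = 0.065         # fraction of spike height, out-of-field
    ramp_amp: float = 0.094              # in-field subthreshold ramp amplitude
    plateau_duration_ms: float = 46.0
    plateau_amp: float = 0.589           # fraction of spike height
    plateau_rate_hz: float = 0.7         # in-field complex-spike event rate
    bleach_tau_s: float = 300.0
    reward_omission_prob: float = 0.2
    iti_range: tuple = (1.0, 3.0)        # s
    rng_seed: int = 0
    # place field and firing rates
    field_center_cm: float = 90.0
    field_width_cm: float = 60.0         # ~ +/- 2 sigma extent of the Gaussian field
    rate_peak_hz: float = 12.0           # peak in-field rate (in-field mean ~9-10 Hz)
    rate_baseline_hz: float = 1.8        # out-of-field rate
    refractory_ms: float = 3.0
    # running profile
    mean_speed_cms: float = 20.0
    speed_sd_cms: float = 4.0
    # fluorescence rendering
    baseline_f: float = 1.0              # camera units
    spike_df: float = 0.05               # fractional dF per spike height

    def validate(self) -> None:
        if self.snr <= 0:
            raise InvalidConfigError("snr must be > 0")
        if not (0.0 <= self.reward_omission_prob <= 1.0):
            raise InvalidConfigError("reward_omission_prob must be in [0, 1]")
        if self.track_length <= 0:
            raise InvalidConfigError("track_length must be > 0")
        if self.n_trials < 1:
            raise InvalidConfigError("n_trials must be >= 1")
        if self.iti_range[0] > self.iti_range[1]:
            raise InvalidConfigError("iti_range must be sorted")
        if self.sample_rate <= 0:
            raise InvalidConfigError("sample_rate must be > 0")

    @property
    def field_sigma_cm(self) -> float:
        return self.field_width_cm / 4.0


@dataclass
class PSPEvent:
    onset_sample: int       # sample of the postsynaptic potential onset
    polarity: int           # +1 EPSP, -1 IPSP
    amplitude: float        # peak, fraction of spike height (signed)
    latency_ms: float       # onset latency from the presynaptic stimulus


@dataclass
class StimEvent:
    onset_sample: int
    duration_ms: float
    intensity: float        # mW/mm^2


@dataclass
class GroundTruth:
    """The generator's record of everything it injected."""

    true_spike_times: np.ndarray                  # sample indices
    true_plateau_intervals: np.ndarray            # (n, 2) sample-index pairs
    field_center: float | None = None             # cm
    field_width: float | None = None              # cm
    psp_events: list = field(default_factory=list)
    bleach_tau: float = np.inf
    epoch_labels: list | None = None              # per-trial Pre/Stim/Post tags
    extra: dict = field(default_factory=dict)


@dataclass
class SessionBundle:
    mode: str
    traces: list
    behavior: BehaviorTrack | None
    stim_events: list
    ground_truth: GroundTruth
    epoch_of_trial: list | None = None
    stim_location_cm: float | None = None


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

def draw_trial_structure(config: SynthConfig, rng=None) -> dict:
    """Draw per-trial ITI durations and reward outcomes (no 1 kHz rendering)."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    iti = rng.uniform(config.iti_range[0], config.iti_range[1], config.n_trials)
    rewarded = rng.random(config.n_trials) >= config.reward_omission_prob
    return {"iti_s": iti, "rewarded": rewarded}


def _run_speed_profile(config: SynthConfig, rng) -> np.ndarray:
    """Smoothed positive random-walk speed for one traversal (cm/s)."""
    fs, dt = config.sample_rate, 1.0 / config.sample_rate
    # generous cap: 4x the nominal traversal time
    n_max = int(4 * config.track_length / max(config.mean_speed_cms, 1.0) * fs) + int(fs)
    tau_v = 0.5  # s, speed autocorrelation time
    a = np.exp(-dt / tau_v)
    noise = rng.normal(0.0, config.speed_sd_cms * np.sqrt(1 - a**2), n_max)
    v = np.empty(n_max)
    v[0] = config.mean_speed_cms
    for i in range(1, n_max):
        v[i] = config.mean_speed_cms + a * (v[i - 1] - config.mean_speed_cms) + noise[i]
    v = gaussian_filter1d(v, 0.05 * fs)
    return np.clip(v, 1.0, None)


def simulate_behavior(config: SynthConfig, rng=None) -> BehaviorTrack:
    """Render trial-structured running on the virtual track at the sample rate.

    Each trial is an inter-trial interval (position pinned at 0) followed by a
    monotone 0 -> track_length traversal at a stochastic speed; reward is
    delivered at the track end on ~(1 - reward_omission_prob) of trials.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    struct = draw_trial_structure(config, rng)
    fs, dt = config.sample_rate, 1.0 / config.sample_rate

    pos_parts, vel_parts, trial_parts = [], [], []
    reward_parts, lick_parts = [], []
    reward_samples = max(int(0.05 * fs), 1)
    lick_samples = max(int(0.2 * fs), 1)
    for k in range(config.n_trials):
        n_iti = max(int(round(struct["iti_s"][k] * fs)), 1)
        v = _run_speed_profile(config, rng)
        pos = np.cumsum(v) * dt
        stop = int(np.searchsorted(pos, config.track_length))
        stop = min(stop + 1, len(pos))
        pos, v = pos[:stop], v[:stop]
        pos = np.minimum(pos, config.track_length)

        n_run = len(pos)
        trial_parts.append(np.full(n_iti + n_run, k, dtype=np.int64))
        pos_parts.append(np.concatenate([np.zeros(n_iti), pos]))
        vel_parts.append(np.concatenate([np.zeros(n_iti), v]))
        rew = np.zeros(n_iti + n_run, dtype=bool)
        lick = np.zeros(n_iti + n_run, dtype=bool)
        if struct["rewarded"][k]:
            rew[-reward_samples:] = True
            lick[-min(lick_samples, n_run):] = True
        reward_parts.append(rew)
        lick_parts.append(lick)

    position = np.concatenate(pos_parts)
    n = len(position)
    return BehaviorTrack(
        time=np.arange(n) * dt,
        position=position,
        velocity=np.concatenate(vel_parts),
        trial_index=np.concatenate(trial_parts),
        reward_flag=np.concatenate(reward_parts),
        lick_flag=np.concatenate(lick_parts),
        stim_gate=np.zeros(n, dtype=bool),
        track_length=config.track_length,
        sample_rate=fs,
        rewarded_trials=struct["rewarded"],
    )


# --------------------------------------------------------------------------
# trace rendering
# --------------------------------------------------------------------------

def _theta_process(n: int, config: SynthConfig, rng) -> np.ndarray:
    """Quasi-periodic theta: 6-10 Hz narrowband noise with unit mean envelope.

    Band-passed Gaussian noise drifts in phase like physiological theta (a
    pure tone would phase-lock to any periodic stimulus schedule).  The
    process is normalized so its Hilbert-envelope mean is 1; multiplying by
    the theta amplitude profile yields the requested envelope in
    spike-height units.
    """
    from scipy.signal import filtfilt, hilbert

    from .filters import theta_bandpass_taps

    taps = theta_bandpass_taps(config.sample_rate, config.theta_band)
    pad = 3 * (len(taps) - 1)
    w = rng.normal(0.0, 1.0, n + 2 * pad)
    z = filtfilt(taps, [1.0], w)[pad:pad + n]
    env_mean = np.abs(hilbert(z)).mean()
    return z / env_mean if env_mean > 0 else z


def spike_template(sample_rate: float = 1000.0) -> np.ndarray:
    """Peak-normalized biexponential action-potential kernel (0.5 ms rise, 1.5 ms decay)."""
    t = np.arange(0.0, 0.006, 1.0 / sample_rate)
    k = (1.0 - np.exp(-t / 0.0005)) * np.exp(-t / 0.0015)
    return k / k.max()


def _plateau_template(duration_ms: float, amp: float, sample_rate: float,
                      edge_ms: float = 8.0) -> np.ndarray:
    """Flat-top depolarization with raised-cosine edges.

    The half-amplitude points are separated by exactly ``duration_ms``; the
    soft (8 ms) edges keep the event out of the spike-detection band.
    """
    fs = sample_rate
    n_edge = max(int(round(edge_ms * fs / 1000.0)), 1)
    n_flat = max(int(round(duration_ms * fs / 1000.0)) - n_edge, 1)
    rise = 0.5 * (1 - np.cos(np.pi * np.arange(n_edge) / n_edge))
    return amp * np.concatenate([rise, np.ones(n_flat), rise[::-1]])


def _add_kernel(signal_out: np.ndarray, kernel: np.ndarray, start: int, peak_offset: int = 0):
    """Add kernel so its index ``peak_offset`` lands on ``start``; clipped at edges."""
    a = start - peak_offset
    b = a + len(kernel)
    ka, kb = max(0, -a), len(kernel) - max(0, b - len(signal_out))
    a, b = max(a, 0), min(b, len(signal_out))
    if kb > ka:
        signal_out[a:b] += kernel[ka:kb]


def _thin_refractory(samples: np.ndarray, refractory_samples: int) -> np.ndarray:
    """Greedy absolute-refractory thinning of sorted spike samples."""
    kept = []
    last = -np.inf
    for s in np.sort(samples):
        if s - last >= refractory_samples:
            kept.append(s)
            last = s
    return np.asarray(kept, dtype=np.int64)


def _render_trace(
    config: SynthConfig,
    n: int,
    rate_hz: np.ndarray,
    theta_amp: np.ndarray,
    ramp: np.ndarray,
    plateau_rate_hz: np.ndarray,
    rng,
    deterministic_wave: np.ndarray | None = None,
    forced_spikes: np.ndarray | None = None,
    cell_id: str = "cell0",
) -> tuple[Trace, GroundTruth]:
    """Assemble one trace in spike-height units and render to fluorescence."""
    fs, dt = config.sample_rate, 1.0 / config.sample_rate
    t = np.arange(n) * dt
    refr = max(int(round(config.refractory_ms * fs / 1000.0)), 1)

    sub = ramp.astype(float).copy()
    sub += theta_amp * _theta_process(n, config, rng)
    if deterministic_wave is not None:
        sub += deterministic_wave

    # plateau events: Poisson onsets, non-overlapping, each carrying >=2 riding spikes
    plat_kernel = _plateau_template(config.plateau_duration_ms, config.plateau_amp, fs)
    n_plat = len(plat_kernel)
    onset_draws = np.flatnonzero(rng.random(n) < plateau_rate_hz * dt)
    plateau_intervals = []
    riding = []
    last_end = -n_plat
    for s in onset_draws:
        if s < last_end + int(0.05 * fs) or s + n_plat >= n:
            continue
        _add_kernel(sub, plat_kernel, s)
        plateau_intervals.append((s, s + n_plat))
        last_end = s + n_plat
        # riding burst: ~80 Hz within the flat top, at least two spikes
        lo, hi = s + int(0.010 * fs), s + n_plat - int(0.012 * fs)
        burst = lo + np.flatnonzero(rng.random(max(hi - lo, 0)) < 80.0 * dt)
        burst = _thin_refractory(burst, refr)
        if len(burst) < 2 and hi > lo:
            burst = np.array([lo, (lo + hi) // 2], dtype=np.int64)
        riding.append(burst)

    # place/background spiking: inhomogeneous Poisson thinned by the refractory
    # period; the draw rate is dead-time compensated so the realized rate after
    # thinning matches the requested rate
    r = np.clip(rate_hz, 0.0, None)
    t_ref = config.refractory_ms / 1000.0
    r_draw = r / np.clip(1.0 - r * t_ref, 0.2, 1.0)
    spikes = np.flatnonzero(rng.random(n) < r_draw * dt)
    all_spikes = [spikes] + riding
    if forced_spikes is not None:
        all_spikes.append(np.asarray(forced_spikes, dtype=np.int64))
    spike_samples = _thin_refractory(np.concatenate(all_spikes), refr)
    spike_samples = spike_samples[(spike_samples >= 0) & (spike_samples < n)]

    ap = spike_template(fs)
    peak_offset = int(np.argmax(ap))
    spike_sig = np.zeros(n)
    for s in spike_samples:
        _add_kernel(spike_sig, ap, s, peak_offset)

    u = sub + spike_sig + rng.normal(0.0, 1.0 / config.snr, n)
    bleach = np.exp(-t / config.bleach_tau_s) if np.isfinite(config.bleach_tau_s) else 1.0
    f = config.baseline_f * bleach * (1.0 + config.spike_df * u)

    gt = GroundTruth(
        true_spike_times=spike_samples,
        true_plateau_intervals=np.asarray(plateau_intervals, dtype=np.int64).reshape(-1, 2),
        bleach_tau=config.bleach_tau_s,
    )
    return Trace(f, sample_rate=fs, normalization="raw", cell_id=cell_id), gt


def _field_modulation(position: np.ndarray, config: SynthConfig,
                      center: float | None = None) -> np.ndarray:
    c = config.field_center_cm if center is None else center
    sig = config.field_sigma_cm
    return np.exp(-0.5 * ((position - c) / sig) ** 2)


def simulate_voltage_trace(config: SynthConfig, behavior: BehaviorTrack,
                           rng=None) -> tuple[Trace, GroundTruth]:
    """One place cell's fluorescence trace aligned to a behavior record."""
    config.validate()
    if behavior.sample_rate != config.sample_rate:
        raise InvalidConfigError("behavior and config sample rates differ")
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    n = len(behavior)
    m = _field_modulation(behavior.position, config)
    rate = config.rate_baseline_hz + (config.rate_peak_hz - config.rate_baseline_hz) * m
    theta_amp = config.theta_amp_out + (config.theta_amp_in - config.theta_amp_out) * m
    trace, gt = _render_trace(
        config, n, rate, theta_amp, config.ramp_amp * m, config.plateau_rate_hz * m, rng
    )
    gt.field_center = config.field_center_cm
    gt.field_width = config.field_width_cm
    return trace, gt


# --------------------------------------------------------------------------
# movies
# --------------------------------------------------------------------------

def gaussian_footprint(frame_shape, x: float, y: float, sigma: float,
                       amplitude: float = 1.0) -> np.ndarray:
    h, w = frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    return amplitude * np.exp(-0.5 * (((xx - x) ** 2 + (yy - y) ** 2) / sigma**2))


def simulate_movie(
    traces: list,
    footprints: list,
    frame_shape=(32, 32),
    bg_amp: float = 0.1,
    shot_noise: float = 0.01,
    overlap_limit: float = 0.2,
    rng=None,
    seed: int = 0,
):
    """Render traces into a movie: sum of footprints x traces + smooth background + noise.

    ``footprints`` is a list of dicts with keys x, y, sigma (pixels) and
    optional amplitude.  Returns ``(movie, footprint_images, background)``;
    the footprint images are the per-pixel ground-truth membership.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    h, w = frame_shape
    if traces:
        n_frames = len(traces[0])
        for tr in traces:
            if len(tr) != n_frames:
                raise InvalidConfigError("all traces must share length")
    else:
        n_frames = 1000

    fps = []
    for spec in footprints:
        if not (0 <= spec["x"] < w and 0 <= spec["y"] < h):
            raise InvalidConfigError("footprint center outside frame bounds")
        fps.append(gaussian_footprint(frame_shape, spec["x"], spec["y"],
                                      spec["sigma"], spec.get("amplitude", 1.0)))
    # warn (not error) on heavy overlap
    supports = [fp > 0.05 * fp.max() for fp in fps]
    for i in range(len(supports)):
        for j in range(i + 1, len(supports)):
            inter = np.logical_and(supports[i], supports[j]).sum()
            union = np.logical_or(supports[i], supports[j]).sum()
            if union and inter / union > overlap_limit:
                warnings.warn(f"footprints {i} and {j} overlap by {inter / union:.0%}")

    bg_profile = gaussian_filter(rng.normal(1.0, 0.2, frame_shape), sigma=4.0)
    bg_t = 1.0 + bg_amp * gaussian_filter1d(
        np.cumsum(rng.normal(0, 1.0 / np.sqrt(n_frames), n_frames)), 50, mode="nearest"
    )
    movie = bg_t[:, None, None] * bg_profile[None, :, :]
    for fp, tr in zip(fps, traces):
        movie = movie + fp[None, :, :] * tr.data[:, None, None]
    background = movie.copy() if not fps else bg_t[:, None, None] * bg_profile[None, :, :]
    movie = movie + rng.normal(0.0, shot_noise, movie.shape)
    return movie, fps, background


# --------------------------------------------------------------------------
# protocol sessions
# --------------------------------------------------------------------------

def simulate_session(mode: str, config: SynthConfig, rng=None, **kwargs) -> SessionBundle:
    """Full protocol session with ground truth.

    modes: ``plasticity`` (Pre/Stim/Post closed-loop place-field induction),
    ``fi`` (stepped 500 ms excitability stimuli), ``synaptic`` (1 Hz, 20 ms
    presynaptic test pulses evoking EPSPs/IPSPs and spikes).
    """
    config.validate()
    if mode not in SESSION_MODES:
        raise InvalidConfigError(f"unknown session mode {mode!r}")
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    return {"plasticity": _session_plasticity, "fi": _session_fi,
            "synaptic": _session_synaptic}[mode](config, rng, **kwargs)


def _session_plasticity(
    config: SynthConfig,
    rng,
    n_pre: int = 30,
    n_stim: int = 20,
    n_post: int = 100,
    stim_location_cm: float = 90.0,
    induced_shift_cm: float = -12.0,
    induced_field_width_cm: float = 30.0,
    stim_duration_ms: float = 300.0,
    stim_intensity: float = 25.0,
    stim_rate_hz: float = 50.0,
    stim_depol: float = 0.5,
) -> SessionBundle:
    fs = config.sample_rate
    cfg = replace(config, n_trials=n_pre + n_stim + n_post)
    behavior = simulate_behavior(cfg, rng)
    n = len(behavior)
    epochs = ["Pre"] * n_pre + ["Stim"] * n_stim + ["Post"] * n_post

    # the induced field is a narrow bump at the (backward-shifted) location,
    # expressed only in the Post epoch
    field_center = stim_location_cm + induced_shift_cm
    field_cfg = replace(config, field_width_cm=induced_field_width_cm)
    post_mask = behavior.trial_mask(range(n_pre + n_stim, cfg.n_trials))
    m = _field_modulation(behavior.position, field_cfg, center=field_center) * post_mask

    rate = config.rate_baseline_hz + (config.rate_peak_hz - config.rate_baseline_hz) * m
    theta_amp = config.theta_amp_out + (config.theta_amp_in - config.theta_amp_out) * m
    ramp = config.ramp_amp * m
    plateau_rate = config.plateau_rate_hz * m

    # closed-loop stimulus: 300 ms upon crossing the stimulation location
    stim_samples = int(round(stim_duration_ms * fs / 1000.0))
    depol = _plateau_template(stim_duration_ms, stim_depol, fs)
    det_wave = np.zeros(n)
    stim_events = []
    for k in range(n_pre, n_pre + n_stim):
        in_trial = np.flatnonzero(
            (behavior.trial_index == k) & (behavior.position >= stim_location_cm)
            & (behavior.velocity > 0)
        )
        if len(in_trial) == 0:
            continue
        s = int(in_trial[0])
        _add_kernel(det_wave, depol, s)
        rate[s:s + stim_samples] += stim_rate_hz
        behavior.stim_gate[s:s + stim_samples] = True
        stim_events.append(StimEvent(s, stim_duration_ms, stim_intensity))

    trace, gt = _render_trace(config, n, rate, theta_amp, ramp, plateau_rate, rng,
                              deterministic_wave=det_wave)
    gt.field_center = field_center
    gt.field_width = induced_field_width_cm
    gt.epoch_labels = epochs
    gt.extra = {"stim_location_cm": stim_location_cm, "induced_shift_cm": induced_shift_cm}
    return SessionBundle("plasticity", [trace], behavior, stim_events, gt,
                         epoch_of_trial=epochs, stim_location_cm=stim_location_cm)


def _session_fi(
    config: SynthConfig,
    rng,
    intensities=None,
    n_repeats: int = 20,
    gain_hz_per_intensity: float = 2.0,
    spont_rate_hz: float = 1.2,
    stim_duration_ms: float = 500.0,
    period_s: float = 1.0,
    artifact_step: float = 0.05,
) -> SessionBundle:
    """Stepped excitability session: F = spont + gain * I inside stimulus windows."""
    fs = config.sample_rate
    if intensities is None:
        intensities = np.linspace(4.8, 20.0, 8)  # mW/mm^2, eight steps
    intensities = np.asarray(intensities, float)
    n_cycles = n_repeats * len(intensities)
    lead = int(fs)  # 1 s spontaneous head/tail for the I=0 estimate
    n = 2 * lead + int(n_cycles * period_s * fs)
    stim_samples = int(round(stim_duration_ms * fs / 1000.0))

    rate = np.full(n, spont_rate_hz)
    det_wave = np.zeros(n)
    stim_events = []
    schedule = []
    k = 0
    for _ in range(n_repeats):
        for inten in intensities:
            s = lead + int(k * period_s * fs) + int(0.25 * fs)
            rate[s:s + stim_samples] += gain_hz_per_intensity * inten
            det_wave[s:s + stim_samples] += artifact_step  # step-like optogenetic artifact
            stim_events.append(StimEvent(s, stim_duration_ms, float(inten)))
            schedule.append((s, float(inten)))
            k += 1

    trace, gt = _render_trace(config, n, rate, np.full(n, config.theta_amp_out),
                              np.zeros(n), np.zeros(n), rng, deterministic_wave=det_wave)
    gt.extra = {
        "gain_hz_per_intensity": gain_hz_per_intensity,
        "spont_rate_hz": spont_rate_hz,
        "schedule": schedule,
        "intensities": intensities,
        "stim_duration_ms": stim_duration_ms,
    }
    return SessionBundle("fi", [trace], None, stim_events, gt)


def _psp_kernel(rise_ms: float, decay_ms: float, amp: float, sample_rate: float) -> np.ndarray:
    t = np.arange(0.0, 6 * decay_ms / 1000.0, 1.0 / sample_rate)
    k = np.exp(-t / (decay_ms / 1000.0)) - np.exp(-t / (rise_ms / 1000.0))
    return amp * k / np.abs(k).max()


def _session_synaptic(
    config: SynthConfig,
    rng,
    n_pulses: int = 12,
    cell_type: str = "excitatory",
    pulse_period_s: float = 1.0,
    pulse_duration_ms: float = 20.0,
    pulse_intensity: float = 5.0,
    epsp_amp: float = 0.124,
    ipsp_amp: float = -0.155,
    epsp_onset_ms: float = 12.0,
    ipsp_onset_ms: float = 16.0,
    evoke_prob: float = 0.3,
    evoked_latency_mean_ms: float = 17.0,
    evoked_latency_sd_ms: float = 6.0,
    spont_rate_hz: float = 2.4,
    suppression_factor: float = 0.2,
    suppression_window_ms=(16.0, 100.0),
) -> SessionBundle:
    """Presynaptic test-pulse session: 1 Hz trains of 20 ms pulses.

    ``excitatory`` cells receive an EPSP on every pulse and an evoked spike
    with probability ``evoke_prob`` at a truncated-normal latency;
    ``inhibitory`` cells receive an IPSP and a suppressed spontaneous rate in
    the 25-85 ms post-pulse window.
    """
    if cell_type not in ("excitatory", "inhibitory"):
        raise InvalidConfigError(f"unknown cell_type {cell_type!r}")
    fs = config.sample_rate
    lead = int(fs)
    n = 2 * lead + int(n_pulses * pulse_period_s * fs)
    onsets = lead + (np.arange(n_pulses) * pulse_period_s * fs).astype(int)

    rate = np.full(n, spont_rate_hz)
    det_wave = np.zeros(n)
    psp_events = []
    forced = []
    if cell_type == "excitatory":
        kern = _psp_kernel(4.0, 40.0, epsp_amp, fs)
        onset_ms, amp, pol = epsp_onset_ms, epsp_amp, 1
    else:
        kern = _psp_kernel(8.0, 60.0, ipsp_amp, fs)
        onset_ms, amp, pol = ipsp_onset_ms, ipsp_amp, -1
    for s in onsets:
        psp_start = s + int(onset_ms * fs / 1000.0)
        _add_kernel(det_wave, kern, psp_start)
        psp_events.append(PSPEvent(int(psp_start), pol, amp, onset_ms))
        if cell_type == "excitatory":
            if rng.random() < evoke_prob:
                lat = np.clip(rng.normal(evoked_latency_mean_ms, evoked_latency_sd_ms), 2.0, 25.0)
                forced.append(s + int(round(lat * fs / 1000.0)))
        else:
            # hyperpolarization suppresses firing from the IPSP onset onward
            lo = s + int(suppression_window_ms[0] * fs / 1000.0)
            hi = s + int(suppression_window_ms[1] * fs / 1000.0)
            rate[lo:hi] *= suppression_factor

    trace, gt = _render_trace(
        config, n, rate, np.full(n, config.theta_amp_out), np.zeros(n), np.zeros(n),
        rng, deterministic_wave=det_wave,
        forced_spikes=np.asarray(forced, dtype=np.int64) if forced else None,
    )
    gt.psp_events = psp_events
    gt.extra = {
        "cell_type": cell_type,
        "evoked_spike_samples": np.asarray(forced, dtype=np.int64),
        "spont_rate_hz": spont_rate_hz,
    }
    stim_events = [StimEvent(int(s), pulse_duration_ms, pulse_intensity) for s in onsets]
    return SessionBundle("synaptic", [trace], None, stim_events, gt)
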