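"""Synthetic auditory-chirp EEG cohorts.

Generates every input the analysis pipeline needs without any recording:

* the chirp stimulus — a pink-noise carrier amplitude-modulated by a
  sinusoid whose frequency rises linearly from 0 to 100 Hz over 2 s;
* the stimulation paradigm — 200 repetitions with interstimulus gaps drawn
  uniformly from 1500–2000 ms (offset-to-onset convention);
* per-subject source-space node epochs built from additive components:
  an onset-evoked low-frequency transient, a chirp-following oscillation
  whose trial-to-trial phase spread follows a von Mises law, asynchronous
  band-limited gamma noise, alpha oscillations and a 1/f background;
* cohorts with designed standardized group x sex x region effects on the
  component parameters, and clinical scores with designed Spearman
  correlations to EEG features (calibrated to the study population's
  score means and SDs).

Every stochastic output is reproducible bit-for-bit under a fixed seed;
per-component random streams are derived independently so that epochs
synthesized one component at a time sum exactly to the all-component epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import hilbert
from scipy.special import i0, i1

from ._atlas import DK_NODE_INDEX, DK_NODES, REDUCED_NODE_SET, load_region_map

ALL_COMPONENTS = ("evoked", "chirp", "gamma", "alpha", "pink")

# stable stream indices so toggling one component never perturbs another
_COMPONENT_STREAM = {name: i for i, name in enumerate(ALL_COMPONENTS)}


# ----------------------------------------------------------------------
# stimulus and paradigm
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSpec:
    """Chirp stimulus parameters (times in ms, frequencies in Hz)."""

    sample_rate: float = 1000.0
    duration: float = 2000.0
    f_start: float = 0.0
    f_end: float = 100.0
    carrier: str = "pink_noise"          # or "unit_carrier"
    modulation_depth: float = 1.0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if not (self.f_end > self.f_start >= 0):
            raise ValueError("need f_end > f_start >= 0")
        if not (0 < self.modulation_depth <= 1):
            raise ValueError("modulation_depth must lie in (0, 1]")
        if self.carrier not in ("pink_noise", "unit_carrier"):
            raise ValueError(f"unknown carrier {self.carrier!r}")

    def phase(self, t_s: np.ndarray) -> np.ndarray:
        """Modulator phase Phi(t) = 2*pi*(f0*t + (f1-f0)*t^2/(2*D)), t in s."""
        d_s = self.duration / 1000.0
        return 2.0 * np.pi * (
            self.f_start * t_s + (self.f_end - self.f_start) * t_s ** 2 / (2 * d_s)
        )

    def instantaneous_freq(self, t_s: np.ndarray) -> np.ndarray:
        """Linear chirp law f(t) = f0 + (f1 - f0) * t / D, t in seconds."""
        d_s = self.duration / 1000.0
        return self.f_start + (self.f_end - self.f_start) * np.asarray(t_s) / d_s


@dataclass(frozen=True)
class ParadigmSpec:
    n_repetitions: int = 200
    isi_min: float = 1500.0  # ms, stimulus offset to next onset
    isi_max: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.isi_min > self.isi_max:
            raise ValueError("need isi_min <= isi_max")


def pink_noise(
    n_samples: int,
    sample_rate: float,
    rng: np.random.Generator,
    f_lo: float = 1.0,
    f_hi: float | None = None,
) -> np.ndarray:
    """Unit-RMS noise with power spectral density ~ 1/f over [f_lo, f_hi].

    Spectral shaping of white Gaussian noise: rFFT amplitudes are scaled by
    f^(-1/2) inside the band and zeroed outside.  ``f_hi`` defaults to
    0.4 * sample_rate.
    """
    if f_hi is None:
        f_hi = 0.4 * sample_rate
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    gain = np.zeros_like(freqs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    gain[band] = freqs[band] ** -0.5
    shaped = np.fft.irfft(spec * gain, n_samples)
    rms = np.sqrt(np.mean(shaped ** 2))
    return shaped / rms if rms > 0 else shaped


def generate_chirp_stimulus(
    spec: StimulusSpec = StimulusSpec(), seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize the stimulus; returns ``(waveform, modulator)``.

    ``modulator`` is the bare AM envelope
    ``1 - depth/2 + (depth/2) * sin(Phi(t))``; ``waveform`` is the carrier
    times the modulator.  Deterministic under a fixed seed.
    """
    n = int(round(spec.duration * spec.sample_rate / 1000.0))
    t_s = np.arange(n) / spec.sample_rate
    depth = spec.modulation_depth
    modulator = 1.0 - depth / 2.0 + (depth / 2.0) * np.sin(spec.phase(t_s))
    if spec.carrier == "pink_noise":
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
        carrier = pink_noise(n, spec.sample_rate, rng)
    else:
        carrier = np.ones(n)
    return carrier * modulator, modulator


def instantaneous_frequency(x: np.ndarray, sample_rate: float) -> np.ndarray:
    """Analytic-signal instantaneous frequency, Hz, per sample.

    Mean-subtracts, takes the Hilbert analytic signal and differentiates the
    unwrapped phase (central differences; one-sided at the edges).
    """
    analytic = hilbert(np.asarray(x, dtype=float) - np.mean(x))
    phase = np.unwrap(np.angle(analytic))
    return np.gradient(phase) * sample_rate / (2.0 * np.pi)


def edge_instantaneous_frequency(
    x: np.ndarray,
    sample_rate: float,
    edge: str = "end",
    fit_samples: int = 128,
) -> float:
    """Instantaneous frequency at a series boundary, Hz.

    The per-sample analytic-phase derivative rings near the edges of a
    finite series (the discrete Hilbert transform assumes periodicity), so
    the boundary value is estimated by fitting a quadratic to the unwrapped
    phase over the trailing (or leading) ``fit_samples`` — exact for a
    linear chirp — and evaluating its derivative at the boundary sample.
    """
    x = np.asarray(x, dtype=float)
    if fit_samples < 3 or fit_samples > x.size:
        raise ValueError("fit_samples must lie in [3, len(x)]")
    phase = np.unwrap(np.angle(hilbert(x - x.mean())))
    if edge == "end":
        t = (np.arange(fit_samples) - (fit_samples - 1)) / sample_rate
        seg = phase[-fit_samples:]
    elif edge == "start":
        t = np.arange(fit_samples) / sample_rate
        seg = phase[:fit_samples]
    else:
        raise ValueError("edge must be 'start' or 'end'")
    coeffs = np.polyfit(t, seg, 2)
    return float(coeffs[1] / (2.0 * np.pi))


def generate_paradigm(spec: ParadigmSpec = ParadigmSpec(),
                      stimulus_duration: float = 2000.0) -> np.ndarray:
    """Stimulus onset times in ms.

    Gaps from each stimulus offset to the next onset are drawn uniformly
    from ``[isi_min, isi_max]``; the first onset is at 0 ms.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    gaps = rng.uniform(spec.isi_min, spec.isi_max, size=spec.n_repetitions - 1)
    onsets = np.concatenate([[0.0], np.cumsum(stimulus_duration + gaps)])
    return onsets


# ----------------------------------------------------------------------
# subject-level epoch synthesis
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectProfile:
    """Component parameters for one synthetic subject.

    ``kappa_*`` are von Mises concentrations of per-trial phase offsets
    (0 = uniform phase, large = near-perfect locking); amplitudes are in
    source-current arbitrary units (declared microvolt-equivalent in the
    container metadata).
    """

    subject_id: str
    group: str = "TDC"                 # FXS | TDC
    sex: str = "M"                     # M | F
    kappa_chirp: float = 2.0
    kappa_onset: float = 5.0
    chirp_amp: float = 0.8
    onset_gain: float = 2.0
    gamma_bg_power: float = 1.0
    alpha_power: float = 2.0
    noise_1f_scale: float = 4.0

    def __post_init__(self) -> None:
        if self.group not in ("FXS", "TDC"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex {self.sex!r}")
        for name in ("kappa_chirp", "kappa_onset", "chirp_amp", "onset_gain",
                     "gamma_bg_power", "alpha_power", "noise_1f_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class NodeEpochs:
    """Trials x samples source time series for one node of one subject."""

    subject_id: str
    node: str
    data: np.ndarray                       # (n_trials, n_samples)
    epoch_window: tuple[float, float] = (-500.0, 2750.0)
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        span = self.epoch_window[1] - self.epoch_window[0]
        expected = int(round(span * self.sample_rate / 1000.0))
        if self.data.shape[1] != expected:
            raise ValueError(
                f"{self.data.shape[1]} samples inconsistent with window "
                f"{self.epoch_window} at {self.sample_rate} Hz ({expected})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epochs contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def _bandlimited_noise(rng, n_trials, n_samples, sample_rate, f_lo, f_hi):
    """Per-trial unit-RMS Gaussian noise band-limited to [f_lo, f_hi]."""
    white = rng.standard_normal((n_trials, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    spec[:, (freqs < f_lo) | (freqs > f_hi)] = 0.0
    out = np.fft.irfft(spec, n_samples, axis=-1)
    rms = np.sqrt(np.mean(out ** 2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return out / rms


def _pink_noise_trials(rng, n_trials, n_samples, sample_rate, f_lo, f_hi):
    """Per-trial unit-RMS 1/f noise (vectorised spectral shaping)."""
    white = rng.standard_normal((n_trials, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    gain = np.zeros_like(freqs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    gain[band] = freqs[band] ** -0.5
    out = np.fft.irfft(spec * gain, n_samples, axis=-1)
    rms = np.sqrt(np.mean(out ** 2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return out / rms


def _gabor(t_s, centre_s, freq, sigma_s, phases):
    """Damped oscillatory burst, one row per trial phase offset."""
    env = np.exp(-((t_s - centre_s) ** 2) / (2.0 * sigma_s ** 2))
    arg = 2.0 * np.pi * freq * (t_s - centre_s)
    return env[None, :] * np.cos(arg[None, :] + phases[:, None])


def synthesize_subject_epochs(
    profile: SubjectProfile,
    nodes=REDUCED_NODE_SET,
    n_trials: int = 60,
    seed: int = 0,
    stimulus: StimulusSpec = StimulusSpec(),
    epoch_window: tuple[float, float] = (-500.0, 2750.0),
    components=ALL_COMPONENTS,
    node_overrides: dict[str, dict[str, float]] | None = None,
) -> dict[str, NodeEpochs]:
    """Synthesize epoched node time series for one subject.

    Per trial and node, the epoch is the sum of the enabled ``components``:

    ``evoked``
        a 6-Hz Gabor burst peaking 100 ms after onset (per-trial phase
        ~ von Mises(0, ``kappa_onset``)) plus a half-amplitude offset burst
        peaking 100 ms after stimulus end;
    ``chirp``
        the chirp-following oscillation at the modulation frequency
        (instantaneous frequency 50*t Hz during 0–2000 ms), constant
        amplitude, per-trial phase ~ von Mises(0, ``kappa_chirp``);
    ``gamma``
        asynchronous 30–100 Hz noise scaled by ``gamma_bg_power``;
    ``alpha``
        8–12 Hz narrowband noise scaled by ``alpha_power``;
    ``pink``
        1/f background scaled by ``noise_1f_scale``.

    Component random streams are derived independently from
    ``(seed, node, component)``, so disabling a component never changes the
    others and component-wise epochs sum exactly to the full epoch.
    ``node_overrides`` maps node -> {parameter: value} for regional effects.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    unknown = [c for c in components if c not in ALL_COMPONENTS]
    if unknown:
        raise ValueError(f"unknown components: {unknown}")
    fs = stimulus.sample_rate
    n_samples = int(round((epoch_window[1] - epoch_window[0]) * fs / 1000.0))
    t_s = (epoch_window[0] + np.arange(n_samples) * 1000.0 / fs) / 1000.0
    d_s = stimulus.duration / 1000.0
    node_overrides = node_overrides or {}

    out: dict[str, NodeEpochs] = {}
    for node in nodes:
        if node not in DK_NODE_INDEX:
            raise KeyError(f"unknown node label: {node}")
        params = {**profile.__dict__, **node_overrides.get(node, {})}
        node_idx = DK_NODE_INDEX[node]

        def comp_rng(name: str) -> np.random.Generator:
            return np.random.default_rng(np.random.SeedSequence(
                [int(seed), node_idx, _COMPONENT_STREAM[name]]))

        epochs = np.zeros((n_trials, n_samples))

        if "evoked" in components:
            rng = comp_rng("evoked")
            ph_on = rng.vonmises(0.0, params["kappa_onset"], size=n_trials)
            ph_off = rng.vonmises(0.0, params["kappa_onset"], size=n_trials)
            epochs += params["onset_gain"] * _gabor(t_s, 0.100, 6.0, 0.050, ph_on)
            epochs += 0.5 * params["onset_gain"] * _gabor(
                t_s, d_s + 0.100, 6.0, 0.050, ph_off)

        if "chirp" in components:
            rng = comp_rng("chirp")
            phases = rng.vonmises(0.0, params["kappa_chirp"], size=n_trials)
            in_stim = (t_s >= 0.0) & (t_s <= d_s)
            phi = stimulus.phase(np.clip(t_s, 0.0, d_s))
            ramp = np.clip(t_s / 0.05, 0.0, 1.0) * np.clip((d_s - t_s) / 0.05, 0.0, 1.0)
            ramp = np.where(in_stim, np.clip(ramp, 0.0, 1.0), 0.0)
            epochs += params["chirp_amp"] * ramp[None, :] * np.cos(
                phi[None, :] + phases[:, None])

        if "gamma" in components:
            rng = comp_rng("gamma")
            epochs += params["gamma_bg_power"] * _bandlimited_noise(
                rng, n_trials, n_samples, fs, 30.0, 100.0)

        if "alpha" in components:
            rng = comp_rng("alpha")
            epochs += params["alpha_power"] * _bandlimited_noise(
                rng, n_trials, n_samples, fs, 8.0, 12.0)

        if "pink" in components:
            rng = comp_rng("pink")
            epochs += params["noise_1f_scale"] * _pink_noise_trials(
                rng, n_trials, n_samples, fs, f_lo=1.0, f_hi=150.0)

        out[node] = NodeEpochs(
            subject_id=profile.subject_id, node=node, data=epochs,
            epoch_window=epoch_window, sample_rate=fs,
        )
    return out


# ----------------------------------------------------------------------
# cohorts with designed effects
# ----------------------------------------------------------------------

def mean_resultant_length(kappa: float) -> float:
    """Expected phase-locking (I1/I0) of a von Mises sample, large n."""
    if kappa <= 0:
        return 0.0
    # use the exponentially-scaled ratio for numerical stability
    return float(i1(kappa) / i0(kappa)) if kappa < 700 else 1.0 - 1.0 / (2 * kappa)


def kappa_for_locking(r_target: float) -> float:
    """Von Mises concentration whose expected resultant length is r_target."""
    if not 0.0 <= r_target < 1.0:
        raise ValueError("r_target must lie in [0, 1)")
    if r_target == 0.0:
        return 0.0
    return float(brentq(lambda k: mean_resultant_length(k) - r_target,
                        1e-9, 1e4, xtol=1e-9))


@dataclass(frozen=True)
class EffectSpec:
    """A standardized effect on one generator trait.

    ``trait`` is one of ``chirp_locking`` (phase-locking target on the ITPC
    scale), ``gamma_bg``, ``alpha`` or ``onset`` (log-amplitude scale);
    ``d`` is the shift in between-subject SD units applied to subjects in
    ``group`` (and ``sex``, if given) at nodes in ``regions`` (all if None).
    """

    trait: str
    d: float
    group: str = "FXS"
    sex: str | None = None
    regions: tuple[str, ...] | None = None


#: per-trait baselines: (base value, between-subject SD on the trait scale)
TRAIT_SCALES = {
    "chirp_locking": (0.45, 0.08),   # target raw phase-locking of the chirp
    "gamma_bg": (0.0, 1.5),          # dB around the profile's base amplitude
    "alpha": (0.0, 1.5),
    "onset": (0.0, 1.5),
}


def default_effect_map() -> tuple[EffectSpec, ...]:
    """Group effects emulating the study's headline pattern.

    Males of the affected group show reduced temporal gamma phase locking
    and elevated asynchronous background gamma; both sexes show an enhanced
    frontal/cingulate onset response.
    """
    temporal = ("left_temporal", "right_temporal")
    frontal = ("left_frontal", "right_frontal",
               "left_cingulate", "right_cingulate")
    return (
        EffectSpec("chirp_locking", d=-0.75, group="FXS", sex="M", regions=temporal),
        EffectSpec("gamma_bg", d=+0.75, group="FXS", sex="M", regions=temporal),
        EffectSpec("gamma_bg", d=+0.40, group="FXS", sex="F", regions=temporal),
        EffectSpec("onset", d=+0.60, group="FXS", sex=None, regions=frontal),
    )


#: baseline regional offsets on the background-gamma dB scale: auditory
#: (temporal) cortex shows elevated stimulus-driven gamma relative to the
#: rest of the parcellation during auditory stimulation
REGIONAL_GAMMA_DB: dict[str, float] = {
    "left_temporal": 2.5,
    "right_temporal": 2.5,
}


@dataclass
class SyntheticCohortConfig:
    n_per_cell: int = 10
    n_trials: int = 60
    node_set: tuple[str, ...] = REDUCED_NODE_SET
    effect_map: tuple[EffectSpec, ...] = ()
    clinical_rho_map: dict | None = None
    seed: int = 0
    groups: tuple[str, ...] = ("FXS", "TDC")
    sexes: tuple[str, ...] = ("M", "F")
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    epoch_window: tuple[float, float] = (-500.0, 2750.0)
    regional_gamma_db: dict | None = None   # None -> REGIONAL_GAMMA_DB

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1 (empty cell)")
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        for node in self.node_set:
            if node not in DK_NODE_INDEX:
                raise ValueError(f"unknown node label: {node}")
        for eff in self.effect_map:
            if eff.trait not in TRAIT_SCALES:
                raise ValueError(f"unknown trait {eff.trait!r}")
        for entry in (self.clinical_rho_map or {}).values():
            if abs(entry["rho"]) >= 1:
                raise ValueError("designed |rho| must be < 1")


@dataclass
class Cohort:
    """Lazy cohort: metadata plus deterministic per-subject synthesis."""

    config: SyntheticCohortConfig
    metadata: pd.DataFrame                       # subject_id, group, sex
    profiles: dict[str, SubjectProfile]
    node_overrides: dict[str, dict[str, dict[str, float]]]
    _subject_seeds: dict[str, int]

    def epochs(self, subject_id: str) -> dict[str, NodeEpochs]:
        cfg = self.config
        return synthesize_subject_epochs(
            self.profiles[subject_id],
            nodes=cfg.node_set,
            n_trials=cfg.n_trials,
            seed=self._subject_seeds[subject_id],
            stimulus=cfg.stimulus,
            epoch_window=cfg.epoch_window,
            node_overrides=self.node_overrides.get(subject_id),
        )

    def iter_epochs(self):
        for sid in self.metadata["subject_id"]:
            yield sid, self.epochs(sid)


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """Draw per-cell subject profiles realizing the designed effects.

    Each subject carries one latent N(0, 1) trait per component; a designed
    effect shifts the trait mean of its group/sex cell by ``d`` at nodes of
    the targeted regions, so standardized feature differences match the
    design in expectation.  Trait values map to generator parameters
    monotonically: phase-locking targets through the inverse von Mises
    resultant length, amplitudes on a dB scale.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 10]))
    region_map = load_region_map()
    rows, profiles, overrides, subject_seeds = [], {}, {}, {}
    counter = 0
    for group in config.groups:
        for sex in config.sexes:
            for _ in range(config.n_per_cell):
                sid = f"S{counter:03d}"
                counter += 1
                rows.append({"subject_id": sid, "group": group, "sex": sex})
                traits = {t: rng.standard_normal() for t in TRAIT_SCALES}
                base = SubjectProfile(subject_id=sid, group=group, sex=sex)

                def trait_value(trait, extra_shift=0.0):
                    base_v, sd = TRAIT_SCALES[trait]
                    return base_v + sd * (traits[trait] + extra_shift)

                def applies(eff, region=None):
                    if eff.group != group:
                        return False
                    if eff.sex is not None and eff.sex != sex:
                        return False
                    return eff.regions is None or region in eff.regions

                regional_db = (config.regional_gamma_db
                               if config.regional_gamma_db is not None
                               else REGIONAL_GAMMA_DB)

                # subject-level (region-free) parameter values
                def params_for(region):
                    shifts = {t: 0.0 for t in TRAIT_SCALES}
                    for eff in config.effect_map:
                        if applies(eff, region):
                            shifts[eff.trait] += eff.d
                    lock = np.clip(trait_value("chirp_locking",
                                               shifts["chirp_locking"]), 0.02, 0.95)
                    gamma_db = (trait_value("gamma_bg", shifts["gamma_bg"])
                                + regional_db.get(region, 0.0))
                    return {
                        "kappa_chirp": kappa_for_locking(float(lock)),
                        "gamma_bg_power": base.gamma_bg_power
                        * 10 ** (gamma_db / 20),
                        "alpha_power": base.alpha_power
                        * 10 ** (trait_value("alpha", shifts["alpha"]) / 20),
                        "onset_gain": base.onset_gain
                        * 10 ** (trait_value("onset", shifts["onset"]) / 20),
                    }

                global_params = params_for(None)
                profiles[sid] = replace(base, **global_params)
                node_over = {}
                for node in config.node_set:
                    p = params_for(region_map[node])
                    if p != global_params:
                        node_over[node] = p
                overrides[sid] = node_over
                subject_seeds[sid] = int(
                    np.random.SeedSequence([int(config.seed), 20, counter])
                    .generate_state(1)[0] % (2 ** 31)
                )
    metadata = pd.DataFrame(rows)
    return Cohort(config=config, metadata=metadata, profiles=profiles,
                  node_overrides=overrides, _subject_seeds=subject_seeds)


# ----------------------------------------------------------------------
# clinical scores
# ----------------------------------------------------------------------

#: score calibration (mean, SD) per group, from the study population
CLINICAL_CALIBRATION: dict[str, dict[str, tuple[float, float]]] = {
    "WJ3": {"FXS": (65.2, 17.9), "TDC": (91.9, 11.7)},
    "DeviationIQ": {"FXS": (42.4, 29.1), "TDC": (102.9, 8.3)},
    "NVIQ": {"FXS": (31.9, 36.1), "TDC": (103.6, 11.2)},
    "VIQ": {"FXS": (54.9, 28.3), "TDC": (102.3, 1.8)},
    "ADAMS_Anxiety": {"FXS": (7.7, 4.8), "TDC": (2.4, 2.6)},
    "ADAMS_OCD": {"FXS": (2.4, 2.3), "TDC": (0.5, 1.3)},
    "SCQ": {"FXS": (14.0, 7.9), "TDC": (2.2, 2.4)},
    "ABC_Irritability": {"FXS": (11.2, 11.4), "TDC": (0.6, 2.4)},
    "ABC_Lethargy": {"FXS": (5.5, 4.4), "TDC": (0.6, 1.5)},
    "ABC_Stereotypy": {"FXS": (4.0, 4.5), "TDC": (0.1, 0.4)},
    "ABC_Hyperactivity": {"FXS": (7.7, 5.9), "TDC": (0.9, 2.1)},
    "ABC_InappropriateSpeech": {"FXS": (4.4, 3.5), "TDC": (0.2, 0.6)},
}


def generate_clinical_scores(
    metadata: pd.DataFrame,
    features: pd.DataFrame | None,
    clinical_rho_map: dict | None,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical scores with designed within-group Spearman correlations.

    ``clinical_rho_map`` maps score name -> ``{"feature": column, "rho": r}``
    where ``column`` names a per-subject column of ``features`` (indexed by
    subject_id).  Scores are built through a Gaussian copula on the feature
    ranks within each group (Pearson latent correlation ``2*sin(pi*rho/6)``)
    and calibrated to the group's catalogued mean and SD; unmapped scores are
    independent noise with the same calibration.
    """
    clinical_rho_map = clinical_rho_map or {}
    for entry in clinical_rho_map.values():
        if abs(entry["rho"]) >= 1:
            raise ValueError("designed |rho| must be < 1")
        if features is None or entry["feature"] not in features.columns:
            raise ValueError(f"feature {entry['feature']!r} not supplied")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 30]))
    from scipy.stats import norm, rankdata

    out = metadata[["subject_id", "group", "sex"]].copy().set_index("subject_id")
    for score, cal in CLINICAL_CALIBRATION.items():
        vals = np.full(len(out), np.nan)
        for g in out["group"].unique():
            mask = (out["group"] == g).to_numpy()
            n = int(mask.sum())
            mu, sd = cal.get(g, (0.0, 1.0))
            eps = rng.standard_normal(n)
            if score in clinical_rho_map and n >= 2:
                entry = clinical_rho_map[score]
                fvals = features.loc[out.index[mask], entry["feature"]].to_numpy()
                ranks = rankdata(fvals)
                z_f = norm.ppf((ranks - 0.5) / n)
                z_f /= max(z_f.std(), 1e-12)
                rho_g = 2.0 * np.sin(np.pi * entry["rho"] / 6.0)
                z_s = rho_g * z_f + np.sqrt(1.0 - rho_g ** 2) * eps
            else:
                z_s = eps
            vals[mask] = mu + sd * z_s
        out[score] = vals
    return out.reset_index()
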