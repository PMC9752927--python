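"""Seeded synthetic multichannel EEG cohorts with controlled phase coupling.

The generator is a parametric stand-in for resting eyes-closed scalp
recordings: each channel is a sum of narrow-band Gaussian components
(band-passed white noise, so phase jitter is realistic) plus 1/f
background noise.  Phase coupling between electrode sets is produced by
a shared band-limited oscillator injected into the coupled channels
with per-node constant phase lags (imposed by time-shifting the shared
component) and a controlled fraction of channel variance.

The cohort generator emulates a temporal-lobe-epilepsy study design:
"patients" carry a frontotemporal theta-band oscillator whose strength
follows a severity score through a configurable link, laterality is
assigned left/right/bilateral, and "controls" carry posterior alpha
coupling instead.  All draws flow from one root seed, so cohorts are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .montage import (
    BANDS,
    LEFT_FRONTOTEMPORAL,
    MONTAGE_25,
    RIGHT_FRONTOTEMPORAL,
    check_labels,
)
from .preprocess import EEGRecording, _filter_delay_compensated, fir_taps
from .stats import SubjectRecord

_ASM_NAMES = ("VPA", "CBZ", "TPM", "LEV", "OXC", "PB", "LTG", "PHT")


@dataclass(frozen=True)
class SimChannelModel:
    """Background activity: narrow-band components plus 1/f noise.

    ``band_components`` lists (center_freq Hz, bandwidth Hz, amplitude)
    triples; each contributes ``amplitude**2`` to the channel variance.
    """

    band_components: tuple[tuple[float, float, float], ...] = (
        (2.5, 3.0, 8.0),    # delta
        (5.5, 3.0, 7.0),    # theta
        (10.5, 5.0, 12.0),  # alpha, dominant eyes-closed
        (22.0, 16.0, 4.0),  # beta
        (37.5, 15.0, 2.0),  # gamma
    )
    noise_exponent: float = 1.0
    noise_amplitude: float = 6.0

    def __post_init__(self) -> None:
        for cf, bw, amp in self.band_components:
            if not 0 < cf <= 45:
                raise ValueError(f"component center {cf} Hz outside (0, 45]")
            if bw <= 0:
                raise ValueError("component bandwidth must be positive")
            if amp < 0:
                raise ValueError("component amplitude must be non-negative")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude must be non-negative")

    @property
    def variance(self) -> float:
        return sum(a**2 for _, _, a in self.band_components) + self.noise_amplitude**2


@dataclass(frozen=True)
class SimCouplingSpec:
    """A shared oscillator linking two electrode sets at a constant lag.

    Channels in ``node_set_a`` receive the oscillator at lag 0 and those
    in ``node_set_b`` at ``phase_lag`` radians (``stagger`` adds
    ``k * stagger`` to the k-th member of set b, giving a traveling-wave
    chain).  ``strength`` is the fraction of channel variance carried by
    the oscillator.  A zero lag yields PLI 0 by the sign convention, so
    couplings meant to register on PLI must use a nonzero lag.
    """

    node_set_a: tuple[str, ...]
    node_set_b: tuple[str, ...]
    band: str = "theta"
    phase_lag: float = math.pi / 4
    strength: float = 0.5
    stagger: float = 0.0

    def __post_init__(self) -> None:
        check_labels(self.node_set_a)
        check_labels(self.node_set_b)
        if not 0 <= self.strength <= 1:
            raise ValueError("coupling strength must lie in [0, 1]")
        if not -math.pi < self.phase_lag <= math.pi:
            raise ValueError("phase lag must lie in (-pi, pi]")
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")

    def compile(self) -> "OscillatorSpec":
        lags = {lab: 0.0 for lab in self.node_set_a}
        for k, lab in enumerate(self.node_set_b):
            lags[lab] = self.phase_lag + k * self.stagger
        return OscillatorSpec(band=self.band, strength=self.strength, node_lags=lags)


@dataclass(frozen=True)
class OscillatorSpec:
    """Generalized shared oscillator: per-node lags and variance gains.

    ``node_lags`` maps electrode label -> phase lag (radians at the band
    center frequency); ``node_gains`` scales the variance fraction per
    node (default 1), letting hub nodes carry more of the oscillator.
    """

    band: str
    strength: float
    node_lags: dict[str, float]
    node_gains: dict[str, float] | None = None

    def compile(self) -> "OscillatorSpec":
        return self

    def gain(self, label: str) -> float:
        return 1.0 if self.node_gains is None else self.node_gains.get(label, 1.0)


@dataclass(frozen=True)
class SeverityLink:
    """Severity score -> coupling strength.

    ``strength = clip(intercept + slope * t(severity) + N(0, noise_sd))``
    with ``t`` the identity or the natural log.  The default log link
    spreads the heavy-tailed severity scores over strengths in (0, 1).
    """

    intercept: float = 0.01
    slope: float = 0.045
    noise_sd: float = 0.025
    transform: str = "log"  # "log" | "identity"
    clip: tuple[float, float] = (0.01, 0.30)

    def __call__(self, severity: float, rng: np.random.Generator) -> float:
        t = math.log(severity) if self.transform == "log" else severity
        raw = self.intercept + self.slope * t + rng.normal(0.0, self.noise_sd)
        return float(np.clip(raw, *self.clip))


@dataclass(frozen=True)
class SimCohortSpec:
    """Generative parameters of one synthetic cohort."""

    n_patients: int = 60
    n_controls: int = 20
    duration_s: float = 90.0
    fs: float = 500.0
    seed: int = 0
    severity_model: SeverityLink = field(default_factory=SeverityLink)
    base_channel_model: SimChannelModel = field(default_factory=SimChannelModel)
    patient_coupling: tuple | None = None  # SimCouplingSpec/OscillatorSpec templates
    control_coupling: tuple | None = None
    #: L-TLE / R-TLE / B-TLE mixing proportions.
    laterality_proportions: tuple[float, float, float] = (56, 55, 40)
    #: log-normal severity parameters: median 40 exactly; sigma trades
    #: off the printed dispersion summaries (SD ~ 356 vs 379 reported).
    severity_mu: float = math.log(40.0)
    severity_sigma: float = 1.5
    #: between-subject log-SD of background component amplitudes; real
    #: resting EEG varies severalfold in band power across individuals,
    #: which decorrelates broadband network features from the coupled band.
    amplitude_sd_log: float = 0.2
    #: (mean, SD) of the severity-independent resting-alpha network
    #: strength; relatively dominant in controls.
    alpha_strength_patients: tuple[float, float] = (0.30, 0.12)
    alpha_strength_controls: tuple[float, float] = (0.45, 0.12)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.fs <= 2 * 45:
            raise ValueError("sampling rate must exceed twice the highest band edge (45 Hz)")


def _unit_narrowband(rng: np.random.Generator, n: int, f_lo: float, f_hi: float,
                     fs: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    x = rng.standard_normal(n)
    taps = fir_taps(f_lo, f_hi, fs)
    y = _filter_delay_compensated(x[np.newaxis, :], taps)[0]
    sd = y.std()
    return y / sd if sd > 0 else y


def _unit_one_over_f(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    y = np.fft.irfft(spec * scale, n)
    sd = y.std()
    return y / sd if sd > 0 else y


def _band_center(band: str) -> tuple[float, float]:
    lo, hi = BANDS[band]
    return (lo + hi) / 2.0, hi - lo


def simulate_recording(
    channel_model: SimChannelModel,
    couplings: list | None = None,
    duration_s: float = 90.0,
    fs: float = 500.0,
    seed: int | np.random.Generator = 0,
    labels: tuple[str, ...] = MONTAGE_25,
    subject_id: str = "sim",
) -> EEGRecording:
    """Simulate one multichannel recording (labels x duration*fs, µV).

    Each channel is independent background (components + 1/f) unless a
    coupling injects the shared oscillator; couplings replace the
    specified variance fraction so the per-channel variance budget is
    preserved.
    """
    if fs <= 2 * 45:
        raise ValueError("sampling rate must exceed twice the highest band edge (45 Hz)")
    check_labels(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))

    compiled = [c.compile() for c in (couplings or [])]
    for osc in compiled:
        check_labels(osc.node_lags.keys())
        unknown = [l for l in osc.node_lags if l not in labels]
        if unknown:
            raise ValueError(f"coupling references labels not being simulated: {unknown!r}")

    # per-oscillator variance fraction on each channel; injected additively
    # on top of the background so each band's signal-to-background ratio
    # depends only on its own coupling (fraction f maps to an
    # oscillator/background variance ratio f/(1-f))
    fractions = np.zeros((len(compiled), len(labels)))
    for q, osc in enumerate(compiled):
        for lab in osc.node_lags:
            f = osc.strength * osc.gain(lab)
            if f > 0.97:
                f = 0.97  # keep a sliver of background; PLI is unaffected
            fractions[q, labels.index(lab)] = f

    # shared oscillators, generated with padding so lags can be applied as shifts
    osc_signals: list[dict[int, np.ndarray]] = []
    for osc in compiled:
        center, bw = _band_center(osc.band)
        shifts = {
            labels.index(lab): int(round(lag / (2 * math.pi * center) * fs))
            for lab, lag in osc.node_lags.items()
        }
        pad = max(abs(s) for s in shifts.values()) if shifts else 0
        base = _unit_narrowband(rng, n + 2 * pad, center - bw / 2, center + bw / 2, fs)
        per_channel = {}
        for ch, shift in shifts.items():
            seg = base[pad - shift: pad - shift + n]
            sd = seg.std()
            per_channel[ch] = seg / sd if sd > 0 else seg
        osc_signals.append(per_channel)

    sigma = math.sqrt(channel_model.variance)
    data = np.empty((len(labels), n))
    for ch in range(len(labels)):
        bg = np.zeros(n)
        for cf, bw, amp in channel_model.band_components:
            if amp > 0:
                bg += amp * _unit_narrowband(rng, n, cf - bw / 2, cf + bw / 2, fs)
        if channel_model.noise_amplitude > 0:
            bg += channel_model.noise_amplitude * _unit_one_over_f(
                rng, n, channel_model.noise_exponent
            )
        x = bg
        for q, per_channel in enumerate(osc_signals):
            f = fractions[q, ch]
            if ch in per_channel and f > 0:
                x = x + math.sqrt(f / (1.0 - f)) * sigma * per_channel[ch]
        data[ch] = x
    return EEGRecording(data=data, fs=fs, labels=labels, subject_id=subject_id)


#: Hub-weighted gains along the frontotemporal chain: the temporal-chain
#: electrodes carry most of the oscillator, emulating a temporal focus
#: radiating into frontal and posterior neighbors.
_CHAIN_GAINS = (1.0, 0.95, 0.80, 0.75, 0.70, 0.65, 0.55, 0.50)
#: Weak contralateral spread: as the oscillator strengthens, even the
#: contralateral frontotemporal electrodes couple through the focus,
#: pulling the network backbone into a hub topology.
_CONTRA_GAIN = 0.30


def _wrap_lag(lag: float) -> float:
    return float(np.angle(np.exp(1j * lag)))


def frontotemporal_oscillator(side: str, strength: float) -> OscillatorSpec:
    """Theta oscillator over the frontotemporal set, focused on one side.

    Lags are staggered in steps of pi/8 along the chain so every pair of
    coupled electrodes has a nonzero phase difference (and hence a
    nonzero PLI).  Gains fall off with distance from the ipsilateral
    temporal focus; the contralateral chain receives a weak spill-over.
    """
    ipsi = LEFT_FRONTOTEMPORAL if side == "L" else RIGHT_FRONTOTEMPORAL
    contra = RIGHT_FRONTOTEMPORAL if side == "L" else LEFT_FRONTOTEMPORAL
    chain = tuple(ipsi) + tuple(contra)
    lags = {lab: _wrap_lag(k * math.pi / 8) for k, lab in enumerate(chain)}
    gains = {lab: g for lab, g in zip(ipsi, _CHAIN_GAINS)}
    gains.update({lab: _CONTRA_GAIN for lab in contra})
    return OscillatorSpec(band="theta", strength=strength, node_lags=lags,
                          node_gains=gains)


#: Posterior-dominant gains of the resting alpha network, ordered
#: posterior -> anterior; every healthy resting EEG carries this
#: oscillation with large inter-individual strength differences.
_ALPHA_GAINS = {
    "O1": 1.0, "O2": 1.0,
    "P3": 0.7, "P4": 0.7, "P7": 0.7, "P8": 0.7, "P9": 0.7, "P10": 0.7, "Pz": 0.7,
    "C3": 0.45, "C4": 0.45, "Cz": 0.45, "T7": 0.45, "T8": 0.45, "T9": 0.45, "T10": 0.45,
    "Fp1": 0.3, "Fp2": 0.3, "F3": 0.3, "F4": 0.3, "F7": 0.3, "F8": 0.3,
    "F9": 0.3, "F10": 0.3, "Fz": 0.3,
}


def resting_alpha_oscillator(strength: float) -> OscillatorSpec:
    """Widespread posterior-dominant alpha coupling (strongest bilaterally
    occipital), the severity-independent background network every subject
    carries; its per-subject strength varies strongly across individuals.

    Lags step through 2*pi/29 per electrode (29 prime > 25), so no pair
    of coupled electrodes ends up at exactly zero wrapped lag.
    """
    labels = list(_ALPHA_GAINS)
    lags = {lab: _wrap_lag(k * 2 * math.pi / 29) for k, lab in enumerate(labels)}
    return OscillatorSpec(band="alpha", strength=strength, node_lags=lags,
                          node_gains=dict(_ALPHA_GAINS))


def broadband_sync_oscillator(strength: float) -> OscillatorSpec:
    """Global broadband (1-45 Hz) synchrony shared by all electrodes.

    Individuals differ in overall functional-connectivity level
    independently of any disease process; this oscillator carries that
    variance, loading on broadband connectivity far more than on any
    narrow band (its per-band spectral content is only a few percent).
    """
    labels = list(MONTAGE_25)
    lags = {lab: _wrap_lag(k * 2 * math.pi / 31) for k, lab in enumerate(labels)}
    gains = {lab: 0.4 for lab in labels}
    return OscillatorSpec(band="full", strength=strength, node_lags=lags,
                          node_gains=gains)


def _theta_patch(rng: np.random.Generator, existing_fraction: np.ndarray,
                 labels: tuple[str, ...] = MONTAGE_25,
                 budget: float = 0.92) -> OscillatorSpec | None:
    """A small random theta-synchrony patch (3 electrodes, random lags).

    Emulates idiosyncratic resting theta synchrony unrelated to disease
    severity; its strength is capped so no channel's total coupled
    variance fraction exceeds *budget*.
    """
    picks = rng.choice(len(labels), size=3, replace=False)
    headroom = budget - max(existing_fraction[p] for p in picks)
    strength = min(abs(rng.normal(0.06, 0.04)), 0.15, headroom)
    if strength <= 0.0:
        return None
    lags = {labels[p]: float(rng.uniform(math.pi / 8, 7 * math.pi / 8)
                             * rng.choice([-1.0, 1.0]))
            for p in picks}
    return OscillatorSpec(band="theta", strength=float(strength), node_lags=lags)


def _coupling_fractions(couplings, labels: tuple[str, ...] = MONTAGE_25) -> np.ndarray:
    frac = np.zeros(len(labels))
    for osc in couplings:
        for lab in osc.node_lags:
            frac[labels.index(lab)] += osc.strength * osc.gain(lab)
    return frac


def default_control_coupling() -> SimCouplingSpec:
    """Bilateral posterior alpha coupling, the control-group signature."""
    return SimCouplingSpec(
        node_set_a=("O1", "P3"), node_set_b=("O2", "P4"),
        band="alpha", phase_lag=math.pi / 4, stagger=math.pi / 8, strength=0.5,
    )


def _jitter_channel_model(model: SimChannelModel, rng: np.random.Generator,
                          sd_log: float) -> SimChannelModel:
    """Per-subject background variability: log-normal amplitude scaling."""
    if sd_log <= 0:
        return model
    comps = tuple((cf, bw, amp * rng.lognormal(0.0, sd_log))
                  for cf, bw, amp in model.band_components)
    return replace(model, band_components=comps,
                   noise_amplitude=model.noise_amplitude * rng.lognormal(0.0, sd_log))


def _patient_record(rng: np.random.Generator, subject_id: str, group: str,
                    severity: float) -> SubjectRecord:
    age = float(np.clip(rng.normal(41.5, 18.3), 14, 80))
    duration = float(min(np.clip(rng.lognormal(math.log(4.0), 1.1), 0.1, 40.0), age - 14 + 0.1))
    ln_sev = math.log(severity)
    freq_class = int(np.digitize(ln_sev, [math.log(10), math.log(40), math.log(200)])) + 1
    dre = bool(rng.random() < 1 / (1 + math.exp(-(ln_sev - math.log(150.0)))))
    n_asm = int(rng.choice([0, 1, 2, 3], p=np.array([46, 65, 25, 15]) / 151))
    asm = tuple(rng.choice(_ASM_NAMES, size=n_asm, replace=False)) if n_asm else ()
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        age=age,
        sex="M" if rng.random() < 88 / 151 else "F",
        age_of_onset=max(age - duration, 0.0),
        duration=duration,
        seizure_freq_class=freq_class,
        dre=dre,
        va2=severity,
        asm_list=asm,
        febrile_history=bool(rng.random() < 0.106),
        family_history=bool(rng.random() < 0.026),
        status_epilepticus=bool(rng.random() < 0.05),
        aura=bool(rng.random() < 0.5),
        generalized=bool(rng.random() < 125 / 151),
        postictal_confusion=bool(rng.random() < 0.5),
        seizure_duration_min=float(rng.lognormal(math.log(2.0), 0.6)),
    )


def simulate_cohort(spec: SimCohortSpec) -> list[tuple[EEGRecording, SubjectRecord]]:
    """Generate the full synthetic cohort.

    Patients draw a log-normal severity score; the severity link maps it
    to the strength of an ipsilateral frontotemporal theta oscillator
    (both sides for the bilateral subgroup).  Controls carry posterior
    alpha coupling and no severity score.
    """
    if spec.n_patients < 0 or spec.n_controls < 0 or spec.n_patients + spec.n_controls == 0:
        raise ValueError("cohort sizes must be non-negative and not both zero")
    root = np.random.SeedSequence(spec.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    subject_seeds = root.spawn(spec.n_patients + spec.n_controls)

    props = np.asarray(spec.laterality_proportions, dtype=float)
    props = props / props.sum()
    out: list[tuple[EEGRecording, SubjectRecord]] = []

    for p in range(spec.n_patients):
        rng = np.random.default_rng(subject_seeds[p])
        sid = f"pat{p:03d}"
        side = assign_rng.choice(["L", "R", "B"], p=props)
        severity = float(rng.lognormal(spec.severity_mu, spec.severity_sigma))
        strength = spec.severity_model(severity, rng)
        if spec.patient_coupling is not None:
            couplings = [replace(c.compile(), strength=strength)
                         for c in spec.patient_coupling]
        else:
            sides = ["L", "R"] if side == "B" else [side]
            couplings = [frontotemporal_oscillator(s, strength) for s in sides]
            mu, sd = spec.alpha_strength_patients
            couplings.append(resting_alpha_oscillator(
                float(np.clip(rng.normal(mu, sd), 0.05, 0.60))))
            couplings.append(broadband_sync_oscillator(
                float(np.clip(rng.normal(0.12, 0.06), 0.02, 0.30))))
            patch = _theta_patch(rng, _coupling_fractions(couplings))
            if patch is not None:
                couplings.append(patch)
        model = _jitter_channel_model(spec.base_channel_model, rng, spec.amplitude_sd_log)
        rec = simulate_recording(
            model, couplings, spec.duration_s, spec.fs, seed=rng, subject_id=sid,
        )
        record = _patient_record(rng, sid, f"{side}-TLE", severity)
        out.append((rec, record))

    for c in range(spec.n_controls):
        rng = np.random.default_rng(subject_seeds[spec.n_patients + c])
        sid = f"ctl{c:03d}"
        if spec.control_coupling is not None:
            control_coupling = list(spec.control_coupling)
        else:
            mu, sd = spec.alpha_strength_controls
            control_coupling = [resting_alpha_oscillator(
                float(np.clip(rng.normal(mu, sd), 0.05, 0.70)))]
            control_coupling.append(broadband_sync_oscillator(
                float(np.clip(rng.normal(0.12, 0.06), 0.02, 0.30))))
            patch = _theta_patch(rng, _coupling_fractions(control_coupling))
            if patch is not None:
                control_coupling.append(patch)
        model = _jitter_channel_model(spec.base_channel_model, rng, spec.amplitude_sd_log)
        rec = simulate_recording(
            model, control_coupling, spec.duration_s,
            spec.fs, seed=rng, subject_id=sid,
        )
        record = SubjectRecord(
            subject_id=sid, group="control",
            age=float(np.clip(rng.normal(38.4, 17.5), 14, 80)),
            sex="M" if rng.random() < 17 / 36 else "F",
        )
        out.append((rec, record))
    return out
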