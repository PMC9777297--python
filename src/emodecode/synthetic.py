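"""Seeded synthetic EEG cohorts with the study's block/trial structure.

The generator emulates the experiment the features and classifier are built
for: multi-channel 10-10 recordings at 250 Hz, organised into emotional
blocks of 12-s pleasure or grief trials separated by 12-s neutral segments
(one block = 4 emotion + 3 neutral segments = 84 s), with

* a 1/f ("pink") Gaussian background per channel,
* band-limited oscillations realised as band-pass-filtered white noise
  (so they carry realistic fluctuating amplitude envelopes),
* a condition-dependent frontal alpha asymmetry: during pleasure trials the
  left-frontal alpha amplitude is scaled down and the right scaled up so
  that the between-condition difference in frontal alpha asymmetry
  (ln right-power - ln left-power) equals the configured contrast ``delta``;
  grief reverses the tilt,
* eye-blink artifacts: 0.5-s half-cosine transients with a fixed spatial
  profile decaying from frontal to occipital rows (a separable rank-one
  component, which is what ICA-based cleaning exploits).

Everything is a deterministic function of the master seed; per-participant
streams are derived with ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import fft as sfft

from .bands import BandSpec
from .montage import Montage, default_montage

CONDITIONS = ("pleasure", "grief", "neutral")
MODALITIES = ("text", "audio", "video", "picture")


@dataclass(frozen=True)
class OscillationSpec:
    """A band-limited oscillatory component with a target RMS amplitude (uV)."""

    band: BandSpec
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("oscillation amplitude must be >= 0")


# Default oscillatory content: a prominent alpha rhythm (the carrier of the
# emotion contrast) over weaker theta and beta activity.  Amplitudes are RMS
# in uV, sized against the ~8 uV broadband 1/f background so that alpha-band
# power on any channel is dominated by the alpha oscillation.
DEFAULT_OSCILLATIONS: tuple[OscillationSpec, ...] = (
    OscillationSpec(BandSpec("theta", 4.0, 7.0), 2.0),
    OscillationSpec(BandSpec("alpha", 8.0, 15.0), 9.0),
    OscillationSpec(BandSpec("beta", 16.0, 31.0), 1.5),
)


@dataclass(frozen=True)
class Annotation:
    """One experimental segment: [onset, onset + duration) seconds."""

    onset: float
    duration: float
    condition: str
    modality: str
    trial_id: int


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated study.

    ``faa_effect`` (delta) is the between-condition contrast in frontal alpha
    asymmetry, in ln-power units: mean FAA(pleasure) - mean FAA(grief) on
    frontal homologous pairs equals delta (0 = no class signal).
    """

    n_participants: int = 14
    sampling_rate: float = 250.0
    montage: Montage = field(default_factory=default_montage)
    blocks_per_condition: int = 4
    segment_duration: float = 12.0
    oscillations: tuple[OscillationSpec, ...] = DEFAULT_OSCILLATIONS
    faa_effect: float = 1.0
    background_rms: float = 8.0
    noise_exponent: float = 1.0
    artifact_rate: float = 2.0
    blink_amplitude: float = 120.0
    modality: str = "video"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.sampling_rate <= 0 or self.segment_duration <= 0:
            raise ValueError("sampling_rate and segment_duration must be > 0")
        if self.faa_effect < 0:
            raise ValueError("faa_effect must be >= 0")
        if self.artifact_rate < 0 or self.background_rms < 0:
            raise ValueError("rates/amplitudes must be >= 0")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        top = max((o.band.f_hi for o in self.oscillations), default=0.0)
        if self.sampling_rate <= 2 * top:
            raise ValueError("sampling_rate must exceed twice the highest band edge")
        n = self.segment_duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("segment_duration x sampling_rate must be integral")

    @property
    def segment_samples(self) -> int:
        return round(self.segment_duration * self.sampling_rate)


@dataclass(frozen=True)
class Recording:
    """One participant's continuous EEG (channels x samples, uV)."""

    data: np.ndarray
    sampling_rate: float
    montage: Montage
    annotations: tuple[Annotation, ...]
    participant_id: int

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != self.montage.n_channels:
            raise ValueError("data must be (n_channels, n_samples)")
        total = self.data.shape[1] / self.sampling_rate
        ids = [a.trial_id for a in self.annotations]
        if len(set(ids)) != len(ids):
            raise ValueError("trial ids must be unique")
        prev_end = 0.0
        for a in sorted(self.annotations, key=lambda a: a.onset):
            if a.onset < prev_end - 1e-9:
                raise ValueError("annotations overlap")
            if a.onset + a.duration > total + 1e-9:
                raise ValueError("annotation extends beyond recording")
            prev_end = a.onset + a.duration

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def build_block_schedule(config: SimConfig) -> tuple[Annotation, ...]:
    """Lay out the session: alternating pleasure/grief blocks, contiguous.

    One emotional block is four emotion segments of ``segment_duration``
    interleaved with three neutral segments of the same length (7 segments;
    84 s at the default 12 s).  Blocks alternate pleasure/grief until each
    condition has ``blocks_per_condition`` blocks.
    """
    seg = config.segment_duration
    annotations: list[Annotation] = []
    t = 0.0
    trial = 0
    for b in range(2 * config.blocks_per_condition):
        condition = "pleasure" if b % 2 == 0 else "grief"
        for s in range(7):
            cond = condition if s % 2 == 0 else "neutral"
            annotations.append(Annotation(t, seg, cond, config.modality, trial))
            trial += 1
            t += seg
    return tuple(annotations)


def block_duration(config: SimConfig) -> float:
    """Duration of one emotional block in seconds (7 x segment_duration)."""
    return 7 * config.segment_duration


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, exponent: float, rms: float) -> np.ndarray:
    """1/f^exponent Gaussian noise, per channel, scaled to target RMS."""
    freqs = sfft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size)))
    x = sfft.irfft(spec * shape, n=n_samples, axis=1)
    x *= rms / np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x


def _band_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, band: BandSpec) -> np.ndarray:
    """Unit-RMS narrowband noise: white noise masked to the band in frequency."""
    freqs = sfft.rfftfreq(n_samples, 1.0 / fs)
    mask = ((freqs >= band.f_lo) & (freqs <= band.f_hi)).astype(float)
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size)))
    x = sfft.irfft(spec * mask, n=n_samples, axis=1)
    x /= np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x


_BLINK_REGION_GAIN = {
    "frontal": 1.0, "temporal": 0.25, "central_parietal": 0.12,
    "occipital": 0.05, "midline": 0.35,
}


def _alpha_gain(config: SimConfig, annotations: tuple[Annotation, ...],
                hemisphere: str) -> np.ndarray:
    """Per-sample amplitude gain implementing the FAA contrast delta.

    Amplitude scaling by exp(-/+ delta/8) shifts ln band power by -/+ delta/4
    per side, so FAA = ln P_R - ln P_L moves by +delta/2 under pleasure and
    -delta/2 under grief: a between-condition FAA difference of delta.
    """
    fs = config.sampling_rate
    sign = -1.0 if hemisphere == "left" else 1.0
    n_total = sum(round(a.duration * fs) for a in annotations)
    gain = np.ones(n_total)
    for a in annotations:
        i0 = round(a.onset * fs)
        i1 = i0 + round(a.duration * fs)
        if a.condition == "pleasure":
            gain[i0:i1] = np.exp(sign * config.faa_effect / 8.0)
        elif a.condition == "grief":
            gain[i0:i1] = np.exp(-sign * config.faa_effect / 8.0)
    return gain


def generate_recording(config: SimConfig, participant_id: int,
                       seed_seq: np.random.SeedSequence | None = None) -> Recording:
    """Simulate one participant's session; deterministic in (seed, id)."""
    if seed_seq is None:
        seed_seq = np.random.SeedSequence([config.seed, int(participant_id)])
    rng = np.random.default_rng(seed_seq)
    montage = config.montage
    annotations = build_block_schedule(config)
    fs = config.sampling_rate
    n_samples = sum(round(a.duration * fs) for a in annotations)
    n_ch = montage.n_channels

    data = _pink_noise(rng, n_ch, n_samples, fs,
                       config.noise_exponent, config.background_rms)

    is_alpha = [o.band.f_lo >= 8.0 and o.band.f_hi <= 15.0
                for o in config.oscillations]
    frontal_left = [montage.index(c) for c in montage.channels_in("frontal", "left")]
    frontal_right = [montage.index(c) for c in montage.channels_in("frontal", "right")]
    for osc, alpha_like in zip(config.oscillations, is_alpha):
        if osc.amplitude == 0:
            continue
        comp = osc.amplitude * _band_noise(rng, n_ch, n_samples, fs, osc.band)
        if alpha_like and config.faa_effect > 0:
            comp[frontal_left] *= _alpha_gain(config, annotations, "left")
            comp[frontal_right] *= _alpha_gain(config, annotations, "right")
        data += comp

    if config.artifact_rate > 0:
        n_blinks = rng.poisson(config.artifact_rate * n_samples / fs / 60.0)
        width = round(0.5 * fs)
        shape = np.sin(np.pi * np.arange(width) / width)  # half-cosine hump
        spatial = np.array([_BLINK_REGION_GAIN[montage.region[c]]
                            for c in montage.channel_names])
        spatial = spatial * (0.85 + 0.3 * rng.random(n_ch))
        onsets = rng.integers(0, max(1, n_samples - width), size=n_blinks)
        blink_tc = np.zeros(n_samples)
        for o in onsets:
            blink_tc[o:o + width] += config.blink_amplitude * shape
        data += spatial[:, None] * blink_tc[None, :]

    return Recording(data=data, sampling_rate=fs, montage=montage,
                     annotations=annotations, participant_id=int(participant_id))


def generate_cohort(config: SimConfig) -> list[Recording]:
    """One recording per participant, each from its own derived seed stream."""
    return [generate_recording(config, pid)
            for pid in range(config.n_participants)]


# ---------------------------------------------------------------------------
# Persistence: raw float32 binary + JSON sidecar.

def save_recording(recording: Recording, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"sub-{recording.participant_id:02d}"
    recording.data.astype("<f4").tofile(out / f"{stem}_eeg.dat")
    sidecar = {
        "participant_id": recording.participant_id,
        "sampling_rate": recording.sampling_rate,
        "shape": list(recording.data.shape),
        "dtype": "<f4",
        "montage": json.loads(recording.montage.to_json()),
        "annotations": [
            [a.onset, a.duration, a.condition, a.modality, a.trial_id]
            for a in recording.annotations
        ],
    }
    (out / f"{stem}_eeg.json").write_text(json.dumps(sidecar, indent=2))
    return out / f"{stem}_eeg.json"


def load_recording(sidecar_path: str | Path) -> Recording:
    sidecar = json.loads(Path(sidecar_path).read_text())
    data_path = Path(sidecar_path).with_suffix("").name.replace("_eeg", "")
    raw = np.fromfile(Path(sidecar_path).parent / f"{data_path}_eeg.dat",
                      dtype=sidecar["dtype"]).reshape(sidecar["shape"])
    montage = Montage.from_json(json.dumps(sidecar["montage"]))
    annotations = tuple(Annotation(*a) for a in sidecar["annotations"])
    return Recording(data=raw.astype(np.float64), sampling_rate=sidecar["sampling_rate"],
                     montage=montage, annotations=annotations,
                     participant_id=sidecar["participant_id"])
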