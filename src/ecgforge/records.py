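"""12-lead ECG records and synthetic signal generators.

The central container is :class:`ECGRecord`: a 12 x N matrix of trace values
in millivolts with a sampling rate and the canonical clinical lead ordering
(I, II, III, aVR, aVL, aVF, V1..V6).  Generators produce the two fixture
families every downstream stage is tested against: sine-wave validation
records (a known-amplitude, known-frequency sine in exactly one lead, all
other leads flat at 0 mV) and plausible PQRST waveforms built from per-lead
sums of Gaussians with seeded beat-to-beat jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical clinical lead order; row k of every signal matrix is this lead.
CANONICAL_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: Accepted spellings for each canonical lead name (case-insensitive keys).
_LEAD_ALIASES = {lead.upper(): lead for lead in CANONICAL_LEADS}
_LEAD_ALIASES.update({"AVR": "aVR", "AVL": "aVL", "AVF": "aVF"})


class RecordError(ValueError):
    """Invalid or unsupported ECG record."""


def canonical_lead_name(name: str) -> str:
    """Map a lead label (any common spelling) to its canonical form."""
    key = name.strip().upper()
    if key not in _LEAD_ALIASES:
        raise RecordError(f"unmapped lead name: {name!r}")
    return _LEAD_ALIASES[key]


@dataclass
class ECGRecord:
    """A 12-lead ECG signal in millivolts.

    Attributes
    ----------
    signals : ndarray, shape (12, N)
        Trace values in mV, one row per lead in :data:`CANONICAL_LEADS` order.
    fs : float
        Sampling rate in Hz.
    record_id : str
        Identifier carried through rendering and degradation manifests.
    labels : list of str
        Optional diagnostic statements (carried verbatim, never interpreted).
    """

    signals: np.ndarray
    fs: float
    record_id: str = "record"
    labels: list[str] = field(default_factory=list)
    leads: tuple[str, ...] = CANONICAL_LEADS

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2 or self.signals.shape[0] != 12:
            raise RecordError(
                f"expected 12 traces, got shape {self.signals.shape}"
            )
        if self.fs <= 0:
            raise RecordError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.signals)):
            raise RecordError("signal values must be finite")
        if tuple(self.leads) != CANONICAL_LEADS:
            raise RecordError("leads must be in canonical order")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead_index(self, lead: str) -> int:
        return CANONICAL_LEADS.index(canonical_lead_name(lead))

    def lead(self, lead: str) -> np.ndarray:
        return self.signals[self.lead_index(lead)]

    def truncated(self, duration_s: float = 10.0) -> "ECGRecord":
        """First ``duration_s`` seconds; rejects shorter records."""
        n = int(round(duration_s * self.fs))
        if self.n_samples < n:
            raise RecordError(
                f"record {self.record_id!r} is {self.duration_s:.2f} s, "
                f"need at least {duration_s} s"
            )
        return replace(self, signals=self.signals[:, :n].copy())


def make_sine_validation_record(
    sine_lead: int,
    amplitude: float = 0.5,
    frequency: float = 1.25,
    duration: float = 10.0,
    fs: float = 500.0,
    record_id: str | None = None,
) -> ECGRecord:
    """A validation record: ``a * sin(2*pi*f*t)`` in one lead, 0 mV elsewhere.

    Parameters mirror the calibration targets of standard ECG paper: at the
    default 0.5 mV / 1.25 Hz the rendered trace should deflect 5 mm and
    repeat every 20 mm.
    """
    if not 0 <= sine_lead < 12:
        raise RecordError(f"sine_lead must be 0..11, got {sine_lead}")
    if amplitude < 0:
        raise RecordError("amplitude must be non-negative")
    if frequency <= 0:
        raise RecordError("frequency must be positive")
    if duration < 10.0:
        raise RecordError("duration must be at least 10 s for the standard layout")
    if frequency >= fs / 2:
        raise RecordError(
            f"frequency {frequency} Hz aliases at fs={fs} Hz (Nyquist {fs / 2})"
        )
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    signals = np.zeros((12, n))
    signals[sine_lead] = amplitude * np.sin(2 * np.pi * frequency * t)
    if record_id is None:
        record_id = f"sine_{CANONICAL_LEADS[sine_lead]}_{amplitude:g}mV_{frequency:g}Hz"
    return ECGRecord(signals=signals, fs=fs, record_id=record_id)


def make_validation_suite(
    amplitude: float = 0.5, frequency: float = 1.25,
    duration: float = 10.0, fs: float = 500.0,
) -> list[ECGRecord]:
    """The 12-record validation suite: record k carries the sine in lead k."""
    return [
        make_sine_validation_record(k, amplitude, frequency, duration, fs)
        for k in range(12)
    ]


# Per-lead projection of the five waves (P, Q, R, S, T) onto the 12 leads.
# Rough frontal/precordial weights: aVR inverted, R-wave progression V1->V6.
_LEAD_WEIGHTS = np.array([
    #  P      Q      R      S      T
    [0.08, -0.06,  0.70, -0.15,  0.25],   # I
    [0.12, -0.08,  1.00, -0.20,  0.35],   # II
    [0.05, -0.04,  0.45, -0.10,  0.12],   # III
    [-0.10, 0.05, -0.75,  0.15, -0.28],   # aVR
    [0.03, -0.03,  0.25, -0.06,  0.08],   # aVL
    [0.08, -0.06,  0.70, -0.15,  0.25],   # aVF
    [0.04,  0.02,  0.25, -0.80,  0.10],   # V1
    [0.05,  0.02,  0.45, -0.70,  0.30],   # V2
    [0.06, -0.02,  0.65, -0.50,  0.35],   # V3
    [0.08, -0.05,  0.95, -0.30,  0.35],   # V4
    [0.08, -0.06,  0.90, -0.20,  0.30],   # V5
    [0.08, -0.06,  0.75, -0.15,  0.25],   # V6
])

# Wave centers (s relative to the R peak) and Gaussian widths (s).
_WAVE_CENTERS = np.array([-0.17, -0.028, 0.0, 0.030, 0.26])
_WAVE_WIDTHS = np.array([0.030, 0.010, 0.012, 0.011, 0.055])


def make_synthetic_pqrst_record(
    heart_rate: float = 60.0,
    seed: int = 0,
    duration: float = 10.0,
    fs: float = 500.0,
    record_id: str | None = None,
) -> ECGRecord:
    """Deterministic plausible 12-lead PQRST waveform.

    Each beat is a per-lead sum of five Gaussians (P, Q, R, S, T) placed on a
    regular beat schedule at ``heart_rate`` with small seeded RR and amplitude
    jitter plus slow baseline wander.  Intended as a rendering fixture, not a
    physiological simulator.
    """
    if not 30 <= heart_rate <= 250:
        raise RecordError(f"heart_rate must be 30..250 bpm, got {heart_rate}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rr = 60.0 / heart_rate
    # Beat schedule: first R peak 0.3 s in, +-2% RR jitter per interval.
    r_times = [0.3]
    while r_times[-1] + rr * 0.8 < duration:
        r_times.append(r_times[-1] + rr * (1.0 + 0.02 * rng.standard_normal()))
    r_times = np.array([rt for rt in r_times if rt < duration - 0.05])

    signals = np.zeros((12, n))
    for rt in r_times:
        beat_gain = 1.0 + 0.05 * rng.standard_normal()
        for w in range(5):
            profile = np.exp(-0.5 * ((t - rt - _WAVE_CENTERS[w]) / _WAVE_WIDTHS[w]) ** 2)
            signals += beat_gain * np.outer(_LEAD_WEIGHTS[:, w], profile)
    # Respiratory-style baseline wander, small enough not to leave the panel.
    wander_phase = rng.uniform(0, 2 * np.pi, size=12)
    signals += 0.04 * np.sin(2 * np.pi * 0.25 * t[None, :] + wander_phase[:, None])
    np.clip(signals, -3.0, 3.0, out=signals)
    if record_id is None:
        record_id = f"pqrst_hr{heart_rate:g}_seed{seed}"
    return ECGRecord(signals=signals, fs=fs, record_id=record_id)
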