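"""Round-trip validation: measure amplitude/frequency of rendered sines.

Automates the manual step of the technical validation: an observer reading
the deflection and cycle length of a known sine wave off the printed grid.
The extractor suppresses the red calibration grid by thresholding the red
channel (grid ink is bright in red, trace ink is dark), takes the per-column
ink centroid as the trace centre, and converts pixels to (s, mV) through the
render manifest.  ``validation_report`` then checks lead placement and
computes Spearman correlations between measured and true values over a
harness grid of amplitudes/frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .render import PanelGeometry, RenderManifest


class ExtractionError(RuntimeError):
    """Trace could not be recovered from the image."""


@dataclass
class SineMeasurement:
    """Measured vs true parameters of one rendered validation sine."""

    record_id: str
    lead: str
    measured_amplitude: float          # mV, half peak-to-trough
    measured_frequency: float | None   # Hz; None for flat traces
    true_amplitude: float | None = None
    true_frequency: float | None = None


@dataclass
class ValidationReport:
    measurements: list[SineMeasurement] = field(default_factory=list)
    lead_placement_ok: bool = True
    placement_failures: list[str] = field(default_factory=list)
    amplitude_rho: float | None = None
    amplitude_p: float | None = None
    frequency_rho: float | None = None
    frequency_p: float | None = None

    def as_dict(self) -> dict:
        return {
            "lead_placement_ok": self.lead_placement_ok,
            "placement_failures": self.placement_failures,
            "amplitude_rho": self.amplitude_rho,
            "amplitude_p": self.amplitude_p,
            "frequency_rho": self.frequency_rho,
            "frequency_p": self.frequency_p,
            "n_measurements": len(self.measurements),
            "measurements": [
                {
                    "record_id": m.record_id, "lead": m.lead,
                    "measured_amplitude": m.measured_amplitude,
                    "measured_frequency": m.measured_frequency,
                    "true_amplitude": m.true_amplitude,
                    "true_frequency": m.true_frequency,
                }
                for m in self.measurements
            ],
        }


def extract_trace(
    image: np.ndarray, manifest: RenderManifest, panel: PanelGeometry | str,
    max_gap_fraction: float = 0.20,
) -> tuple[np.ndarray, np.ndarray]:
    """Recover the (t, v) series of one panel from a clean render.

    For every pixel column of the panel (inset 2 px from the panel edges so
    neighbouring panels' ink cannot bleed in) the darkness-weighted centroid
    of trace ink gives the y-centre, converted to mV via the manifest's
    baseline and px/mV.  Columns under lead labels or markers are masked and
    interpolated; more than ``max_gap_fraction`` gaps raises.
    """
    if isinstance(panel, str):
        panel = manifest.panel(panel)
    x0, y0, x1, y1 = panel.bbox
    x0, x1 = x0 + 2, x1 - 2
    red = image[y0:y1, x0:x1, 0].astype(np.float32)
    darkness = np.clip((160.0 - red) / 160.0, 0.0, 1.0)

    for mx0, my0, mx1, my1 in manifest.ink_masks:
        cx0, cx1 = max(mx0, x0), min(mx1, x1)
        cy0, cy1 = max(my0, y0), min(my1, y1)
        if cx0 < cx1 and cy0 < cy1:
            darkness[cy0 - y0:cy1 - y0, cx0 - x0:cx1 - x0] = 0.0

    weight = darkness.sum(axis=0)
    rows = np.arange(y0, y1, dtype=np.float32)
    with np.errstate(invalid="ignore"):
        centroid = (darkness * rows[:, None]).sum(axis=0) / weight
    valid = weight > 0.2
    if valid.mean() < 1.0 - max_gap_fraction:
        raise ExtractionError(
            f"panel {panel.name}: {(~valid).sum()} of {valid.size} columns empty"
        )
    cols = np.arange(x0, x1, dtype=np.float32)
    y_trace = np.interp(cols, cols[valid], centroid[valid])
    t = panel.t_start + (cols - panel.x_origin) / panel.px_per_s
    v = (panel.baseline_y - y_trace) / panel.px_per_mV
    return t, v


def measure_sine(
    image: np.ndarray, manifest: RenderManifest, lead: str,
    true_amplitude: float | None = None, true_frequency: float | None = None,
) -> SineMeasurement:
    """Amplitude (half peak-to-trough) and frequency (1 / median peak gap)."""
    t, v = extract_trace(image, manifest, lead)
    amplitude = float(v.max() - v.min()) / 2.0
    frequency: float | None = None
    if amplitude > 0.05:  # a flat trace has no measurable cycle length
        prominence = 0.6 * amplitude
        peaks, _ = sps.find_peaks(v, prominence=prominence)
        if len(peaks) >= 2:
            frequency = float(1.0 / np.median(np.diff(t[peaks])))
    return SineMeasurement(
        record_id=manifest.record_id, lead=lead,
        measured_amplitude=amplitude, measured_frequency=frequency,
        true_amplitude=true_amplitude, true_frequency=true_frequency,
    )


def check_lead_placement(
    image: np.ndarray, manifest: RenderManifest, expected_lead: str,
    flat_tolerance_mV: float = 0.05,
) -> list[str]:
    """Confirm the sine sits in ``expected_lead`` and every other lead is flat.

    Returns a list of failure descriptions (empty when placement is correct).
    """
    failures = []
    for p in manifest.panels:
        if p.col is None:
            continue
        t, v = extract_trace(image, manifest, p)
        swing = float(v.max() - v.min()) / 2.0
        if p.lead == expected_lead:
            if swing <= flat_tolerance_mV:
                failures.append(f"{manifest.record_id}: lead {p.lead} unexpectedly flat")
        elif swing > flat_tolerance_mV:
            failures.append(
                f"{manifest.record_id}: lead {p.lead} not flat (swing {swing:.3f} mV)"
            )
    return failures


def _grid_readout(m: SineMeasurement, mm_per_mV: float, mm_per_s: float) -> tuple[float, float | None]:
    """Quantize a measurement the way an observer reads the printed grid.

    Amplitude is read in mm of deflection at half-millimetre precision
    (0.05 mV at standard gain); cycle length is read in whole millimetres of
    paper.  This read-out model is what makes rank correlations over a
    harness grid well defined: repeats of the same true value produce
    identical read-outs (ties), exactly as in a manual measurement.
    """
    amp_mm = m.measured_amplitude * mm_per_mV
    amp = round(amp_mm * 2) / 2 / mm_per_mV
    freq = None
    if m.measured_frequency:
        cycle_mm = round(mm_per_s / m.measured_frequency)
        freq = mm_per_s / cycle_mm if cycle_mm > 0 else None
    return amp, freq


def validation_report(
    suite: list[tuple[np.ndarray, RenderManifest, str, float, float]],
) -> ValidationReport:
    """Full validation over rendered sine records.

    ``suite`` rows are (image, manifest, sine_lead, true_amplitude,
    true_frequency).  Requires at least two distinct true values per
    correlated quantity; otherwise Spearman's rho is undefined and the
    harness grid must be widened.
    """
    report = ValidationReport()
    amp_true, amp_meas, freq_true, freq_meas = [], [], [], []
    for image, manifest, lead, a_true, f_true in suite:
        m = measure_sine(image, manifest, lead, a_true, f_true)
        report.measurements.append(m)
        report.placement_failures.extend(check_lead_placement(image, manifest, lead))
        mm_per_mV = manifest.render_spec.get("mm_per_mV", 10.0)
        mm_per_s = manifest.render_spec.get("mm_per_s", 25.0)
        amp_q, freq_q = _grid_readout(m, mm_per_mV, mm_per_s)
        amp_true.append(a_true)
        amp_meas.append(amp_q)
        if freq_q is not None:
            freq_true.append(f_true)
            freq_meas.append(freq_q)
    report.lead_placement_ok = not report.placement_failures

    for truths, meas, which in (
        (amp_true, amp_meas, "amplitude"),
        (freq_true, freq_meas, "frequency"),
    ):
        if len(set(truths)) < 2:
            raise ValueError(
                f"{which}: all true values identical; Spearman's rho is "
                "undefined — widen the harness grid"
            )
        rho, p = stats.spearmanr(truths, meas)
        setattr(report, f"{which}_rho", float(rho))
        setattr(report, f"{which}_p", float(p))
    return report
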