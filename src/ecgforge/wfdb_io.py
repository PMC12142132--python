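"""Minimal WFDB (.hea/.dat) reader and writer for 12-lead records.

Supports single-segment records in signal format 16 (16-bit little-endian
two's complement, sample-interleaved), the format PTB-XL and the validation
fixtures use.  ADC counts are converted to millivolts via each channel's
stored gain and baseline, and leads are reordered to the canonical clinical
sequence on read.
"""

from __future__ import annotations

import os
import re

import numpy as np

from .records import CANONICAL_LEADS, ECGRecord, RecordError, canonical_lead_name


class WFDBFormatError(RecordError):
    """Header or signal file not parseable as a supported WFDB record."""


# gain may carry "(baseline)" and "/units", e.g. "1000.0(0)/mV"
_GAIN_RE = re.compile(
    r"^(?P<gain>-?\d+(?:\.\d+)?)(?:\((?P<baseline>-?\d+)\))?(?:/(?P<units>\S+))?$"
)


def _parse_header(hea_path: str) -> tuple[str, int, float, int, list[dict]]:
    try:
        with open(hea_path, "r", encoding="ascii") as fh:
            lines = [
                ln.strip() for ln in fh
                if ln.strip() and not ln.startswith("#")
            ]
    except OSError as exc:
        raise WFDBFormatError(f"cannot read header {hea_path}: {exc}") from exc
    if not lines:
        raise WFDBFormatError(f"empty header: {hea_path}")
    head = lines[0].split()
    if len(head) < 4:
        raise WFDBFormatError(f"malformed record line: {lines[0]!r}")
    record_name = head[0].split("/")[0]
    try:
        n_sig = int(head[1])
        fs = float(head[2].split("/")[0])
        n_samples = int(head[3])
    except ValueError as exc:
        raise WFDBFormatError(f"malformed record line: {lines[0]!r}") from exc

    channels = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        if len(parts) < 2:
            raise WFDBFormatError(f"malformed signal line: {ln!r}")
        fmt = parts[1].split("x")[0].split(":")[0].split("+")[0]
        if fmt != "16":
            raise WFDBFormatError(f"unsupported signal format {parts[1]!r} (only 16)")
        gain, baseline = 200.0, 0  # WFDB defaults
        if len(parts) >= 3:
            m = _GAIN_RE.match(parts[2])
            if not m:
                raise WFDBFormatError(f"malformed gain field: {parts[2]!r}")
            gain = float(m.group("gain")) or 200.0
            if m.group("baseline") is not None:
                baseline = int(m.group("baseline"))
            elif len(parts) >= 5:
                baseline = int(parts[4])  # adczero stands in when no "(baseline)"
        description = " ".join(parts[8:]) if len(parts) > 8 else f"ch{len(channels)}"
        channels.append(
            {"file": parts[0], "gain": gain, "baseline": baseline,
             "name": description}
        )
    if len(channels) != n_sig:
        raise WFDBFormatError(
            f"header declares {n_sig} signals but lists {len(channels)}"
        )
    return record_name, n_sig, fs, n_samples, channels


def read_wfdb_record(path: str) -> ECGRecord:
    """Read a 12-channel WFDB record (``path`` with or without ``.hea``).

    Converts ADC counts to mV with each channel's gain/baseline and permutes
    rows into canonical lead order (I, II, III, aVR, aVL, aVF, V1..V6).
    """
    base = path[:-4] if path.endswith(".hea") else path
    record_name, n_sig, fs, n_samples, channels = _parse_header(base + ".hea")
    if n_sig != 12:
        raise WFDBFormatError(f"expected 12 channels, header declares {n_sig}")

    dat_names = {ch["file"] for ch in channels}
    if len(dat_names) != 1:
        raise WFDBFormatError("multi-file signal groups are not supported")
    dat_path = os.path.join(os.path.dirname(base), dat_names.pop())
    raw = np.fromfile(dat_path, dtype="<i2")
    if raw.size < n_samples * 12:
        raise WFDBFormatError(
            f"{dat_path}: expected {n_samples * 12} samples, found {raw.size}"
        )
    adc = raw[: n_samples * 12].reshape(n_samples, 12).T.astype(float)

    signals = np.empty_like(adc)
    order = {}
    for i, ch in enumerate(channels):
        signals[i] = (adc[i] - ch["baseline"]) / ch["gain"]
        order[canonical_lead_name(ch["name"])] = i
    missing = set(CANONICAL_LEADS) - set(order)
    if missing:
        raise WFDBFormatError(f"record lacks leads: {sorted(missing)}")
    perm = [order[lead] for lead in CANONICAL_LEADS]
    return ECGRecord(signals=signals[perm], fs=fs, record_id=record_name)


def write_wfdb_record(record: ECGRecord, directory: str, gain: float = 1000.0) -> str:
    """Write ``record`` as a format-16 .hea/.dat pair; returns the base path.

    The default gain of 1000 ADC units/mV gives 1 uV per least-significant
    bit, the PTB-XL convention; quantization error is therefore at most half
    an ADC quantum (0.0005 mV).
    """
    os.makedirs(directory, exist_ok=True)
    base = os.path.join(directory, record.record_id)
    adc = np.rint(record.signals * gain).astype(np.int64)
    if np.any(np.abs(adc) > 32767):
        raise WFDBFormatError(
            f"signal exceeds int16 range at gain {gain} ADC units/mV"
        )
    adc16 = adc.astype("<i2")
    interleaved = adc16.T.reshape(-1)
    dat_name = record.record_id + ".dat"
    interleaved.tofile(os.path.join(directory, dat_name))

    lines = [f"{record.record_id} 12 {record.fs:g} {record.n_samples}"]
    for i, lead in enumerate(CANONICAL_LEADS):
        checksum = int(np.sum(adc16[i], dtype=np.int16))
        first = int(adc16[i, 0])
        lines.append(
            f"{dat_name} 16 {gain:g}(0)/mV 16 0 {first} {checksum} 0 {lead}"
        )
    with open(base + ".hea", "w", encoding="ascii") as fh:
        fh.write("\n".join(lines) + "\n")
    return base
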