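"""Paper-format ECG layout: the standard 3x4 panel grid plus rhythm strip.

The layout follows the AHA/ACCF/HRS simultaneous-lead format: a continuous
10 s recording split into four 2.5 s columns of three leads each
(I,II,III / aVR,aVL,aVF / V1,V2,V3 / V4,V5,V6) with a full 10 s lead II
rhythm strip underneath.  ``RenderSpec`` holds the physical calibration of
standard ECG paper (25 mm/s, 10 mm/mV) and the raster scale (5 px/mm) that
yields the default 1397 x 1029 px canvas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import CANONICAL_LEADS, ECGRecord, RecordError

#: (row, column) -> lead name for the 3x4 grid.
DEFAULT_PANEL_MAP: dict[tuple[int, int], str] = {
    (0, 0): "I",   (0, 1): "aVR", (0, 2): "V1", (0, 3): "V4",
    (1, 0): "II",  (1, 1): "aVL", (1, 2): "V2", (1, 3): "V5",
    (2, 0): "III", (2, 1): "aVF", (2, 2): "V3", (2, 3): "V6",
}


@dataclass(frozen=True)
class LayoutSpec:
    """Panel-to-lead assignment and timing of the paper layout."""

    panel_map: dict[tuple[int, int], str] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_MAP)
    )
    epoch_s: float = 2.5
    rhythm_lead: str = "II"
    rhythm_duration_s: float = 10.0
    calibration_mV: float = 1.0
    calibration_ms: float = 200.0

    def __post_init__(self) -> None:
        leads = sorted(self.panel_map.values())
        if leads != sorted(CANONICAL_LEADS):
            raise ValueError("panel_map must cover all 12 leads exactly once")


@dataclass(frozen=True)
class RenderSpec:
    """Physical and raster calibration of the rendered image.

    ``px_per_mm * mm_per_s`` gives the horizontal scale (125 px/s at
    defaults) and ``px_per_mm * mm_per_mV`` the vertical scale (50 px/mV).
    Margins are chosen so the default canvas is exactly 1397 x 1029 px:
    1250 px of signal plus 97 px left / 50 px right, and four 240 px rows
    plus 40 px top / 29 px bottom.
    """

    mm_per_s: float = 25.0
    mm_per_mV: float = 10.0
    px_per_mm: float = 5.0
    left_margin_px: int = 97
    right_margin_px: int = 50
    top_margin_px: int = 40
    bottom_margin_px: int = 29
    row_height_px: int = 240
    background: tuple[int, int, int] = (255, 255, 255)
    grid_minor: tuple[int, int, int] = (255, 204, 204)
    grid_major: tuple[int, int, int] = (255, 153, 153)
    trace_color: tuple[int, int, int] = (16, 16, 16)
    trace_width_px: float = 1.0
    min_points_per_s: int = 150

    @property
    def px_per_s(self) -> float:
        return self.px_per_mm * self.mm_per_s

    @property
    def px_per_mV(self) -> float:
        return self.px_per_mm * self.mm_per_mV

    @property
    def canvas_px(self) -> tuple[int, int]:
        """(width, height) of the output raster in pixels."""
        width = int(round(
            self.left_margin_px + 10.0 * self.px_per_s + self.right_margin_px
        ))
        height = self.top_margin_px + 4 * self.row_height_px + self.bottom_margin_px
        return width, height


@dataclass
class PanelSegment:
    """One lead's slice of the recording destined for one panel."""

    lead: str
    row: int
    col: int | None          # None for the rhythm strip
    t_start: float
    t_end: float
    samples: np.ndarray
    fs: float

    @property
    def is_rhythm(self) -> bool:
        return self.col is None


def compose_layout(record: ECGRecord, layout: LayoutSpec | None = None) -> list[PanelSegment]:
    """Slice a record into the 13 panel segments of the paper layout.

    The four columns partition [0, 10) s into consecutive ``epoch_s`` epochs;
    the rhythm segment carries the rhythm lead over the full 10 s.  Records
    longer than 10 s are truncated; shorter ones are rejected.
    """
    layout = layout or LayoutSpec()
    total_s = 4 * layout.epoch_s
    if record.duration_s < total_s - 1e-9:
        raise RecordError(
            f"record {record.record_id!r} is {record.duration_s:.2f} s; "
            f"the layout needs {total_s:g} s"
        )
    record = record.truncated(total_s)
    segments: list[PanelSegment] = []
    for (row, col), lead in sorted(layout.panel_map.items()):
        t0, t1 = col * layout.epoch_s, (col + 1) * layout.epoch_s
        i0, i1 = int(round(t0 * record.fs)), int(round(t1 * record.fs))
        segments.append(PanelSegment(
            lead=lead, row=row, col=col, t_start=t0, t_end=t1,
            samples=record.lead(lead)[i0:i1], fs=record.fs,
        ))
    segments.append(PanelSegment(
        lead=layout.rhythm_lead, row=3, col=None,
        t_start=0.0, t_end=layout.rhythm_duration_s,
        samples=record.lead(layout.rhythm_lead), fs=record.fs,
    ))
    return segments
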