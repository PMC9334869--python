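"""Sliding-window augmentation of ROI time series.

A full resting-state series of M timepoints is cut into K overlapping windows
of fixed length W advanced by a stride of s timepoints,

    K = floor((M - W) / s) + 1,

and every window later becomes an independent graph sample carrying the
subject's label. Trailing timepoints that do not fill a whole window are
dropped so all windows share one shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SubjectRecord


@dataclass
class WindowSeries:
    subject_id: str
    window_index: int  # 1-based, matching the l of reports
    series: np.ndarray  # shape (W, R)
    label: int

    @property
    def n_rois(self) -> int:
        return self.series.shape[1]


def compute_window_count(m: int, w: int, s: int) -> int:
    """Number of length-``w`` windows at stride ``s`` in a series of ``m`` points."""
    if s < 1:
        raise ValueError(f"stride must be >= 1, got {s}")
    if w < s:
        raise ValueError(f"window length {w} smaller than stride {s}")
    if w > m:
        raise ValueError(f"window length {w} exceeds series length {m}")
    return (m - w) // s + 1


def slide_windows(subject: SubjectRecord, w: int, s: int) -> list[WindowSeries]:
    """Cut one subject's series into overlapping windows.

    Window l (1-based) covers rows [(l-1)*s, (l-1)*s + w); each window is a
    contiguous view-copy of the parent matrix and inherits the subject label.
    """
    k = compute_window_count(subject.n_timepoints, w, s)
    out = []
    for l in range(k):
        start = l * s
        out.append(
            WindowSeries(
                subject_id=subject.subject_id,
                window_index=l + 1,
                series=np.array(subject.series[start : start + w]),
                label=subject.label,
            )
        )
    return out
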