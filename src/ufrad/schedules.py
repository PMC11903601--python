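"""Acquisition time axes for the two dynamic series.

The ultrafast series is a precontrast frame followed by 14 post-contrast
frames at 4.2 s temporal resolution (first minute after injection); the
standard series is a precontrast frame followed by 4 post-contrast frames
at 58.8, 138.8, 218.8 and 298.8 s after injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ULTRAFAST_INTERVAL_S = 4.2
N_ULTRAFAST_FRAMES = 15  # 1 precontrast + 14 post-contrast
STANDARD_POST_TIMES_S = (58.8, 138.8, 218.8, 298.8)


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Time axis of one dynamic series.

    Parameters
    ----------
    modality : {"ultrafast", "standard"}
    times : array of float
        Seconds since contrast injection; the first entry is the
        precontrast frame (<= 0), times strictly increasing.
    frame_interval_s : float or None
        Post-contrast frame spacing; defined for the ultrafast series.
    """

    modality: str
    times: np.ndarray
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.modality not in ("ultrafast", "standard"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if t.ndim != 1 or t.size < 2:
            raise ValueError("schedule needs at least 2 frames")
        if t[0] > 0:
            raise ValueError("first frame must be precontrast (time <= 0)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.modality == "ultrafast":
            if t.size != N_ULTRAFAST_FRAMES:
                raise ValueError(
                    f"ultrafast schedule has {N_ULTRAFAST_FRAMES} frames, got {t.size}"
                )
            post = np.diff(t[1:])
            if not np.allclose(post, ULTRAFAST_INTERVAL_S):
                raise ValueError("ultrafast post-contrast spacing must be 4.2 s")
        else:
            if t.size != 5:
                raise ValueError(f"standard schedule has 5 frames, got {t.size}")
            if not np.allclose(t[1:], STANDARD_POST_TIMES_S):
                raise ValueError(
                    "standard post-contrast times must be 58.8/138.8/218.8/298.8 s"
                )

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def n_precontrast(self) -> int:
        return int(np.sum(self.times <= 0))


def ultrafast_schedule() -> AcquisitionSchedule:
    """Precontrast at t=0 plus 14 frames at 4.2 s spacing."""
    times = np.concatenate(
        [[0.0], ULTRAFAST_INTERVAL_S * np.arange(1, N_ULTRAFAST_FRAMES)]
    )
    return AcquisitionSchedule("ultrafast", times, ULTRAFAST_INTERVAL_S)


def standard_schedule() -> AcquisitionSchedule:
    """Precontrast at t=0 plus the four standard post-contrast frames."""
    times = np.concatenate([[0.0], STANDARD_POST_TIMES_S])
    return AcquisitionSchedule("standard", times, None)
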