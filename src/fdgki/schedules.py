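"""Site-realistic frame schedule templates.

Two acquisition protocols are emulated, both harmonized to end at 67 min
post-injection:

* ``aarhus_schedule`` — aorta sampling from a dynamic whole-body protocol on
  a conventional-FOV PET/CT with continuous bed motion: 0.1-min frames for
  the first minute, 0.5-min frames to 6 min, 2-min frames to 22 min, then
  5-min frames to 67 min. The last three frames cover 52-67 min.
* ``bern_schedule`` — list-mode binning on a long-axial-FOV scanner:
  2x10 s, 30x2 s, 4x10 s, 8x30 s, 4x60 s, 5x120 s and 10x300 s frames, with
  the final 300-s frame linearly truncated at 67 min.
"""

from __future__ import annotations

import numpy as np

from .tac import TRUNCATION_MIN, FrameSchedule


def _from_durations(durations_min) -> FrameSchedule:
    edges = np.concatenate([[0.0], np.cumsum(np.asarray(durations_min, dtype=float))])
    start, end = edges[:-1], edges[1:]
    keep = start < TRUNCATION_MIN
    start, end = start[keep], end[keep].clip(max=TRUNCATION_MIN)
    return FrameSchedule(start, end)


def aarhus_schedule() -> FrameSchedule:
    durations = [0.1] * 10 + [0.5] * 10 + [2.0] * 8 + [5.0] * 9
    return _from_durations(durations)


def bern_schedule() -> FrameSchedule:
    sec = [10] * 2 + [2] * 30 + [10] * 4 + [30] * 8 + [60] * 4 + [120] * 5 + [300] * 10
    return _from_durations(np.asarray(sec) / 60.0)


SITE_SCHEDULES = {"Aarhus": aarhus_schedule, "Bern": bern_schedule}
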