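"""Switch-time-peak (STP) calling.

Filtered switch events are binned into fixed-width time bins (3 h by
default, matching the sampling interval) and a bin is called a switch
time peak when it is a strict local maximum of the count histogram and
its count exceeds mean + alpha * sd of all bin counts. The study this
package implements reads peaks off the histogram by eye; the quantitative
rule here is a reconstruction with a single sensitivity knob (``alpha``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .switch_detection import SwitchEvent

__all__ = ["SwitchHistogram", "StpCall", "bin_switch_times", "detect_stps",
           "assign_events_to_stp"]


@dataclass
class SwitchHistogram:
    """Counts of switch events per half-open time bin [edge_k, edge_{k+1})."""

    bin_edges: np.ndarray
    counts: np.ndarray
    members: list[list[SwitchEvent]]
    overflow: list[SwitchEvent]

    @property
    def n_bins(self) -> int:
        return self.counts.size

    def bin_interval(self, k: int) -> tuple[float, float]:
        return float(self.bin_edges[k]), float(self.bin_edges[k + 1])


@dataclass
class StpCall:
    rank: int  # STP1, STP2, ... in ascending time order
    bin_start: float
    bin_end: float
    count: int
    members: list[SwitchEvent]

    @property
    def name(self) -> str:
        return f"STP{self.rank}"


def bin_switch_times(
    events: Sequence[SwitchEvent],
    bin_width: float = 3.0,
    origin: float = 0.0,
    t_max: float | None = None,
) -> SwitchHistogram:
    """Bin switch times into half-open bins of ``bin_width`` hours.

    Bins run from ``origin`` to the smallest grid point covering the
    latest event (or ``t_max``). Events before the origin or at/after the
    last edge land in the overflow bucket and are reported, not dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if t_max is None:
        latest = max((e.switch_time for e in events), default=origin)
        t_max = origin + bin_width * max(1, int(np.ceil((latest - origin) / bin_width)))
        if latest >= t_max:  # event exactly on the last edge
            t_max += bin_width
    edges = np.arange(origin, t_max + 0.5 * bin_width, bin_width)
    counts = np.zeros(edges.size - 1, dtype=int)
    members: list[list[SwitchEvent]] = [[] for _ in range(counts.size)]
    overflow: list[SwitchEvent] = []
    for ev in events:
        k = int(np.floor((ev.switch_time - origin) / bin_width))
        if 0 <= k < counts.size:
            counts[k] += 1
            members[k].append(ev)
        else:
            overflow.append(ev)
    return SwitchHistogram(bin_edges=edges, counts=counts, members=members,
                           overflow=overflow)


def detect_stps(hist: SwitchHistogram, alpha: float = 1.0) -> list[StpCall]:
    """Call switch time peaks on a binned switch-time histogram.

    A bin is an STP iff (a) its count strictly exceeds both neighbours
    (boundary bins compare to their single neighbour), and (b) its count
    is at least mean(counts) + alpha * sd(counts). Adjacent equal maxima
    resolve to the earlier bin. Calls are ranked STP1, STP2, ... by time.
    """
    c = hist.counts.astype(float)
    if c.size < 3:
        raise ValueError("need at least 3 bins to call peaks")
    threshold = c.mean() + alpha * c.std(ddof=0)
    calls: list[StpCall] = []
    for k in range(c.size):
        left_ok = k == 0 or c[k] > c[k - 1]
        right_ok = k == c.size - 1 or c[k] > c[k + 1]
        if left_ok and right_ok and c[k] >= threshold and c[k] > 0:
            lo, hi = hist.bin_interval(k)
            calls.append(StpCall(rank=0, bin_start=lo, bin_end=hi,
                                 count=int(hist.counts[k]),
                                 members=list(hist.members[k])))
    for rank, call in enumerate(sorted(calls, key=lambda s: s.bin_start), start=1):
        call.rank = rank
    return sorted(calls, key=lambda s: s.rank)


def assign_events_to_stp(
    events: Iterable[SwitchEvent], stps: Sequence[StpCall]
) -> dict[SwitchEvent, StpCall | None]:
    """Map each event to the STP whose half-open bin contains its switch
    time, or to None."""
    out: dict[SwitchEvent, StpCall | None] = {}
    for ev in events:
        hit = None
        for stp in stps:
            if stp.bin_start <= ev.switch_time < stp.bin_end:
                hit = stp
                break
        out[ev] = hit
    return out
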