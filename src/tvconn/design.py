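"""Block-design timing: the experiment's temporal skeleton.

A :class:`TaskDesign` records when task blocks occur on the scanner's volume
grid, how many volumes were acquired and how many initial volumes are thrown
away before analysis (dummy scans / T1-equilibration).  Everything downstream
(epoching, sub-period windows, task regressors) derives its sample indices
from this object, so the onset-to-sample conventions live here in one place.

Conventions
-----------
* Absolute time 0 s = start of the scan; volume ``i`` is sampled at ``i * tr``.
* The retained (post-discard) series starts at ``t0 = n_discard * tr``.
* An onset maps to the *nearest* retained sample; relative time 0 of an epoch
  is that onset sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TaskDesign", "checkerboard_design"]


@dataclass(frozen=True)
class TaskDesign:
    """Timing of a block-designed run on a uniform TR grid.

    Parameters
    ----------
    onsets
        Block onset times in seconds from scan start, strictly increasing.
    block_duration
        Duration of each task block in seconds.
    tr
        Repetition time (sampling interval) in seconds.
    n_volumes
        Number of volumes acquired.
    n_discard
        Number of initial volumes removed before analysis.
    """

    onsets: tuple = field(default_factory=tuple)
    block_duration: float = 20.0
    tr: float = 0.645
    n_volumes: int = 240
    n_discard: int = 0

    def __post_init__(self):
        onsets = tuple(float(o) for o in self.onsets)
        object.__setattr__(self, "onsets", onsets)
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.block_duration <= 0:
            raise ValueError("block_duration must be positive")
        if len(onsets) == 0:
            raise ValueError("at least one block onset is required")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("onsets must be strictly increasing")
        total = self.n_volumes * self.tr
        if any(o + self.block_duration > total + 1e-9 for o in onsets):
            raise ValueError("a block extends past the end of the scan")
        if not 0 <= self.n_discard < self.n_volumes:
            raise ValueError("n_discard must lie in [0, n_volumes)")
        if self.n_discard * self.tr >= onsets[0]:
            raise ValueError(
                "discarded volumes overlap the first onset; no pre-task "
                "baseline would survive"
            )

    # -- derived geometry -------------------------------------------------

    @property
    def n_retained(self) -> int:
        """Number of volumes kept for analysis."""
        return self.n_volumes - self.n_discard

    @property
    def t0(self) -> float:
        """Time (s from scan start) of the first retained sample."""
        return self.n_discard * self.tr

    def times_full(self) -> np.ndarray:
        """Sample times of the full acquisition grid, in seconds."""
        return np.arange(self.n_volumes) * self.tr

    def times_retained(self) -> np.ndarray:
        """Sample times of the retained grid, in seconds from scan start."""
        return (np.arange(self.n_retained) + self.n_discard) * self.tr

    def boxcar(self) -> np.ndarray:
        """Unit boxcar on the *full* volume grid (1 during task, else 0)."""
        t = self.times_full()
        box = np.zeros(self.n_volumes)
        for onset in self.onsets:
            box[(t >= onset) & (t < onset + self.block_duration)] = 1.0
        return box

    def onset_indices(self) -> np.ndarray:
        """Index of the sample nearest each onset, on the retained grid."""
        idx = np.rint(np.asarray(self.onsets) / self.tr).astype(int) - self.n_discard
        return idx


def checkerboard_design() -> TaskDesign:
    """Timing of the NKI/Rockland flickering-checkerboard run.

    20 s rest followed by a 20 s checkerboard block, repeated three times,
    with a 35 s terminal rest: 3 x (20 + 20) + 35 = 155 s, matching the 240
    volumes at TR = 0.645 s (154.8 s).  The first 14 volumes (~9 s) are
    discarded before analysis.
    """
    return TaskDesign(
        onsets=(20.0, 60.0, 100.0),
        block_duration=20.0,
        tr=0.645,
        n_volumes=240,
        n_discard=14,
    )
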