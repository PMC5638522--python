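"""Frame/trajectory classification of fibril topology states.

The three filament interfaces of a C3 fibril carry a characteristic
number of atom-pair contacts per layer.  A retained triple fibril keeps
all three interfaces populated at comparable levels; in the rearranged
2+1 state one interface is strongly reinforced while the other two decay
to a small residue; on dissociation the interfaces empty out.  The
classifier turns the three per-layer contact counts of a frame into one
of the labels TRIPLE, TWO_PLUS_ONE, DISSOCIATED or OTHER.

The state boundaries are free parameters (the underlying taxonomy is
qualitative); defaults separate the typical magnitudes — interfaces of an
intact fibril at tens of contacts per layer, a reinforced pair well above
a hundred, broken interfaces near zero — and every report echoes the
thresholds actually applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError
from .contact_analysis import ContactSeries

__all__ = ["TopologyLabel", "ClassifierConfig", "classify_frame",
           "classify_trajectory", "TRIPLE", "TWO_PLUS_ONE", "DISSOCIATED",
           "OTHER"]

TRIPLE = "TRIPLE"
TWO_PLUS_ONE = "TWO_PLUS_ONE"
DISSOCIATED = "DISSOCIATED"
OTHER = "OTHER"


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds (contacts per layer) and smoothing for classification.

    ``t_low``: below this an interface counts as broken.
    ``t_high``: above this an interface counts as a reinforced pair.
    ``window``: moving-average window (frames) applied before labelling.
    ``balance_ratio``: max/min ratio tolerated for a symmetric triple.
    """

    t_low: float = 10.0
    t_high: float = 40.0
    window: int = 10
    balance_ratio: float = 3.0

    def __post_init__(self):
        if not 0 <= self.t_low < self.t_high:
            raise ArgumentError("thresholds must satisfy 0 <= t_low < t_high")
        if self.window < 1:
            raise ArgumentError("smoothing window must be >= 1")


@dataclass(frozen=True)
class TopologyLabel:
    """Label of one frame plus the evidence used to assign it."""

    label: str
    counts: tuple
    config: ClassifierConfig


def classify_frame(per_pair_contacts_per_layer,
                   cfg: ClassifierConfig = ClassifierConfig()) -> TopologyLabel:
    """Classify one frame from its three per-layer interface contact counts.

    Rules, applied in order (the first match wins):

    1. TWO_PLUS_ONE — exactly one interface >= t_high and the other two
       below 2*t_low (one reinforced pair, third filament loose).
    2. DISSOCIATED — at least two interfaces below t_low.
    3. TRIPLE — all interfaces >= t_low and max/min < balance_ratio.
    4. OTHER — anything else.

    The 2+1 test precedes the dissociation test because a reinforced pair
    with two broken interfaces satisfies both.
    """
    counts = np.asarray(per_pair_contacts_per_layer, dtype=float)
    if counts.shape != (3,):
        raise ArgumentError("exactly three interface counts expected")
    if np.any(counts < 0):
        raise ArgumentError("contact counts must be non-negative")

    n_high = int(np.sum(counts >= cfg.t_high))
    n_low = int(np.sum(counts < cfg.t_low))
    others_loose = np.sum(counts < 2 * cfg.t_low) == 2

    if n_high == 1 and others_loose and counts.max() >= cfg.t_high:
        label = TWO_PLUS_ONE
    elif n_low >= 2:
        label = DISSOCIATED
    elif (counts.min() >= cfg.t_low
          and counts.max() / counts.min() < cfg.balance_ratio):
        label = TRIPLE
    else:
        label = OTHER
    return TopologyLabel(label, tuple(counts), cfg)


def classify_trajectory(series: ContactSeries,
                        cfg: ClassifierConfig = ClassifierConfig()):
    """Label every frame of a contact series; report the end state.

    Counts are smoothed with a centered moving average (window ``cfg.window``,
    shrinking at the edges) before frame-wise classification.  The end
    state is the modal label over the final ``cfg.window`` frames, ties
    broken in favour of the most recent label.

    Returns ``(labels, end_state)`` with ``labels`` a list of
    :class:`TopologyLabel`.
    """
    counts = np.asarray(series.counts, dtype=float)
    n = counts.shape[0]
    if n == 0:
        raise ArgumentError("empty contact series")
    if cfg.window > n:
        raise ArgumentError(
            f"smoothing window {cfg.window} exceeds series length {n}")
    smoothed = _moving_average(counts, cfg.window)
    labels = [classify_frame(row, cfg) for row in smoothed]
    tail = [lab.label for lab in labels[-cfg.window:]]
    end_state = _mode_latest(tail)
    return labels, end_state


def _moving_average(counts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average per column, window shrinking at the edges."""
    n = counts.shape[0]
    out = np.empty_like(counts)
    half = window // 2
    for t in range(n):
        lo = max(0, t - half)
        hi = min(n, t + window - half)
        out[t] = counts[lo:hi].mean(axis=0)
    return out


def _mode_latest(labels: list[str]) -> str:
    best, best_count, best_pos = None, -1, -1
    for pos, lab in enumerate(labels):
        c = labels.count(lab)
        if c > best_count or (c == best_count and pos > best_pos):
            best, best_count, best_pos = lab, c, pos
    return best
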