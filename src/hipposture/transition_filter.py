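"""Probability-to-label decoding and the two-pass transition filter.

The classifier emits, per 5-s window, a probability for each of the five
posture classes.  Decoding assigns each window its most probable class, then
two filtering passes remove implausible transition predictions:

* pass one removes adjacent pairs of transition-labeled windows — the member
  with the lower probability for its own transition label is reassigned to
  its most probable non-transition class — repeated until no adjacent pair
  remains (a run of three or more transitions can expose a new pair after a
  removal);
* pass two removes transitions without valid context: a sit-to-stand is
  valid only if preceded by SIT and followed by STAND or STEP; a
  stand-to-sit only if preceded by STAND or STEP and followed by SIT.
  Boundary windows have no neighbour and are invalid.  Invalid transitions
  are reassigned to their most probable non-transition class in a single
  left-to-right pass.

Filtering never changes a non-transition label, never increases the number
of transition windows, and the full filter is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PostureClass

__all__ = [
    "PostureSequence",
    "argmax_labels",
    "filter_pass_one",
    "filter_pass_two",
    "apply_time_filter",
]

_S2S = int(PostureClass.SIT_TO_STAND)
_ST2S = int(PostureClass.STAND_TO_SIT)
_SIT = int(PostureClass.SIT)
_STAND = int(PostureClass.STAND)
_STEP = int(PostureClass.STEP)


@dataclass
class PostureSequence:
    """Per-window labels with parallel access to the class probabilities."""

    labels: np.ndarray  # (n,) int, PostureClass values
    probs: np.ndarray  # (n, 5) float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape != (self.labels.size, 5):
            raise ValueError("probs must have shape (n_windows, 5)")

    def __len__(self) -> int:
        return len(self.labels)

    def copy(self) -> "PostureSequence":
        return PostureSequence(self.labels.copy(), self.probs)


def _validate_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 5:
        raise ValueError("probs must have shape (n_windows, 5)")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("window probabilities must sum to 1")
    return probs


def argmax_labels(probs: np.ndarray) -> PostureSequence:
    """Assign each window its maximal-probability class.

    Ties break by the fixed class order SIT < STAND < STEP < SIT_TO_STAND <
    STAND_TO_SIT (argmax returns the first maximum).
    """
    probs = _validate_probs(probs)
    return PostureSequence(np.argmax(probs, axis=1), probs)


def _best_nontransition(probs_row: np.ndarray) -> int:
    # ties break by class order SIT < STAND < STEP (first maximum)
    return int(np.argmax(probs_row[:3]))


def filter_pass_one(seq: PostureSequence) -> PostureSequence:
    """Remove adjacent transition pairs, iterating to convergence."""
    out = seq.copy()
    labels, probs = out.labels, out.probs
    trans = labels >= 3
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(labels) - 1:
            if trans[i] and trans[i + 1]:
                p_left = probs[i, labels[i]]
                p_right = probs[i + 1, labels[i + 1]]
                victim = i if p_left < p_right else i + 1
                labels[victim] = _best_nontransition(probs[victim])
                trans[victim] = False
                changed = True
            i += 1
    return out


def filter_pass_two(seq: PostureSequence) -> PostureSequence:
    """Remove transitions without valid neighbouring activities (one pass)."""
    out = seq.copy()
    labels, probs = out.labels, out.probs
    n = len(labels)
    for i in range(n):
        lab = labels[i]
        if lab == _S2S:
            valid = (
                i > 0
                and i < n - 1
                and labels[i - 1] == _SIT
                and labels[i + 1] in (_STAND, _STEP)
            )
        elif lab == _ST2S:
            valid = (
                i > 0
                and i < n - 1
                and labels[i - 1] in (_STAND, _STEP)
                and labels[i + 1] == _SIT
            )
        else:
            continue
        if not valid:
            labels[i] = _best_nontransition(probs[i])
    return out


def apply_time_filter(probs: np.ndarray) -> PostureSequence:
    """Full decoding: argmax, then pass one, then pass two."""
    return filter_pass_two(filter_pass_one(argmax_labels(probs)))
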