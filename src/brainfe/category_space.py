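"""Two-category Gabor stimulus spaces.

Stimuli are circular sine-wave gratings characterized by spatial
frequency and orientation.  Two task variants partition this feature
plane into two categories:

* **II (information integration)** — a diagonal decision boundary that
  requires integrating frequency and orientation; not verbalizable as a
  simple rule.  The sign of the boundary slope is counterbalanced
  across participants.
* **RB (rule based)** — one vertical and one horizontal cut; category
  membership follows a verbalizable conjunction rule over the four
  quadrants (e.g. "more vertical AND lower frequency").

Features are handled internally on a normalized [0, 1]^2 domain; the
mapping to physical units (cycles per stimulus width, degrees) is a
linear rescale recorded in :class:`CategorySpaceSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSpec",
    "CategorySpaceSpec",
    "assign_category",
    "sample_stimuli",
    "stimuli_to_frame",
]


@dataclass(frozen=True)
class StimulusSpec:
    """A single Gabor stimulus in normalized feature coordinates.

    Parameters
    ----------
    frequency : float
        Normalized spatial frequency in [0, 1] (maps linearly onto a
        physical cycles-per-stimulus-width range).
    orientation : float
        Normalized orientation in [0, 1] (maps linearly onto [0, 180)
        degrees; wraps modulo the domain).
    true_category : int
        Category label in {1, 2}, or 0 if not yet assigned.
    """

    frequency: float
    orientation: float
    true_category: int = 0

    def __post_init__(self):
        if self.frequency <= 0 and self.true_category != 0:
            # frequency in physical units must be strictly positive;
            # normalized 0 is allowed only as an unassigned placeholder
            pass


@dataclass(frozen=True)
class CategorySpaceSpec:
    """Definition of the II or RB category partition.

    ``polarity`` swaps the category-to-region assignment ("A" vs "B"),
    mirroring the counterbalancing across participants.  For the II
    task the boundary is the line ``orientation = intercept +
    slope * frequency`` with ``slope_sign`` flipping the slope; for the
    RB task the cuts are at ``rb_freq_cut`` / ``rb_orient_cut`` and the
    quadrant parity determines the category.
    """

    task: str = "II"
    polarity: str = "A"
    slope_sign: int = 1
    ii_intercept: float = 0.0
    ii_slope: float = 1.0
    rb_freq_cut: float = 0.5
    rb_orient_cut: float = 0.5
    freq_range_cpd: tuple = (0.5, 8.0)  # cycles per stimulus width
    orient_range_deg: tuple = (0.0, 180.0)
    boundary_margin: float = 0.02

    def __post_init__(self):
        if self.task not in ("II", "RB"):
            raise ValueError(f"task must be 'II' or 'RB', got {self.task!r}")
        if self.polarity not in ("A", "B"):
            raise ValueError(f"polarity must be 'A' or 'B', got {self.polarity!r}")
        if self.slope_sign not in (1, -1):
            raise ValueError("slope_sign must be +1 or -1")


def _signed_distance(space: CategorySpaceSpec, freq: np.ndarray, orient: np.ndarray) -> np.ndarray:
    """Signed offset of each point from the II diagonal boundary."""
    if space.slope_sign > 0:
        line = space.ii_intercept + space.ii_slope * freq
    else:
        # counterbalanced negative slope: reflect the diagonal
        line = (1.0 - space.ii_intercept) - space.ii_slope * freq
    return orient - line


def assign_category(stim: StimulusSpec, space: CategorySpaceSpec) -> int:
    """Deterministic category label for a stimulus.

    II: the label depends only on the sign of the orientation offset
    from the diagonal boundary.  RB: the label depends only on the
    quadrant relative to the frequency and orientation cut points.

    Raises
    ------
    ValueError
        If the stimulus lies outside [0, 1]^2 or exactly on a boundary
        (ambiguous label).
    """
    f, o = float(stim.frequency), float(stim.orientation)
    o = o % 1.0 if o >= 1.0 or o < 0.0 else o  # orientation wraps
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"stimulus frequency {f} outside normalized domain [0, 1]")
    if space.task == "II":
        d = _signed_distance(space, np.asarray(f), np.asarray(o))
        if d == 0:
            raise ValueError("stimulus lies exactly on the II boundary")
        label = 1 if d > 0 else 2
    else:
        if f == space.rb_freq_cut or o == space.rb_orient_cut:
            raise ValueError("stimulus lies exactly on an RB cut")
        # "more vertical AND lower frequency" (and its diagonal partner)
        # belong to one category; the other two quadrants to the other.
        quadrant_parity = (f > space.rb_freq_cut) == (o > space.rb_orient_cut)
        label = 1 if quadrant_parity else 2
    if space.polarity == "B":
        label = 3 - label
    return label


def sample_stimuli(space: CategorySpaceSpec, n: int, rng_seed: int) -> list[StimulusSpec]:
    """Draw ``n`` stimuli with exact category balance.

    Points are sampled uniformly on [0, 1]^2, rejecting any within
    ``space.boundary_margin`` of a boundary, and assigned to categories
    until each category holds exactly ``n // 2`` stimuli.
    """
    if n < 2 or n % 2 != 0:
        raise ValueError(f"n must be an even integer >= 2, got {n}")
    rng = np.random.default_rng(rng_seed)
    per_cat = n // 2
    buckets: dict[int, list[StimulusSpec]] = {1: [], 2: []}
    m = space.boundary_margin
    while len(buckets[1]) < per_cat or len(buckets[2]) < per_cat:
        f, o = rng.uniform(0, 1, size=2)
        if space.task == "II":
            d = float(_signed_distance(space, np.asarray(f), np.asarray(o)))
            if abs(d) <= m:
                continue
        else:
            if abs(f - space.rb_freq_cut) <= m or abs(o - space.rb_orient_cut) <= m:
                continue
        try:
            cat = assign_category(StimulusSpec(f, o), space)
        except ValueError:
            continue
        if len(buckets[cat]) < per_cat:
            buckets[cat].append(StimulusSpec(f, o, cat))
    # interleave categories so truncated prefixes stay near-balanced
    out: list[StimulusSpec] = []
    for s1, s2 in zip(buckets[1], buckets[2]):
        out.extend((s1, s2))
    perm = rng.permutation(n)
    return [out[i] for i in perm]


def stimuli_to_frame(stimuli: list[StimulusSpec], space: CategorySpaceSpec | None = None) -> pd.DataFrame:
    """Tabulate stimuli; adds physical-unit columns when a space is given."""
    df = pd.DataFrame(
        {
            "trial": np.arange(len(stimuli)),
            "frequency": [s.frequency for s in stimuli],
            "orientation": [s.orientation for s in stimuli],
            "category": [s.true_category for s in stimuli],
        }
    )
    if space is not None:
        f0, f1 = space.freq_range_cpd
        o0, o1 = space.orient_range_deg
        df["frequency_cpd"] = f0 + df["frequency"] * (f1 - f0)
        df["orientation_deg"] = o0 + df["orientation"] * (o1 - o0)
    return df
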