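"""In-line probing reactivity model and protection calls.

In-line probing reads out backbone flexibility: each phosphodiester
linkage cleaves slowly when it can sample the in-line attack geometry,
so band intensity at a position reports local flexibility.  An
unstructured RNA cleaves uniformly; once the protein-stabilized
stem-loop forms, stem (paired) and protein-footprinted positions are
protected while the terminal loop becomes more reactive.  Occlusion of
the Shine-Dalgarno interval inside the stem is the OFF-switch readout.

Reactivities here are arbitrary band-intensity units used for
simulation and comparison; the protection/enhancement thresholds are
conventional two-fold changes and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StateModel",
    "ReactivityLevels",
    "ReactivityProfile",
    "ProtectionCallSet",
    "predict_reactivity",
    "call_protection",
    "sd_occlusion_score",
    "read_profile_csv",
]


@dataclass
class StateModel:
    """Structural state of the UTR: pairing, protein footprint, loop."""

    sequence: str
    paired: Sequence[bool]
    footprints: list[tuple[int, int]] = field(default_factory=list)
    loop: tuple[int, int] | None = None
    protein_bound: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.paired) != len(self.sequence):
            raise ValueError("paired mask length must equal sequence length")
        n = len(self.sequence)
        for lo, hi in self.footprints:
            if not (0 <= lo <= hi <= n):
                raise ValueError(f"footprint {(lo, hi)} outside sequence bounds")
        if self.loop is not None:
            lo, hi = self.loop
            if not (0 <= lo <= hi <= n):
                raise ValueError(f"loop {self.loop} outside sequence bounds")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReactivityLevels:
    """Simulation levels (arbitrary units); protected < baseline < enhanced."""

    baseline: float = 1.0
    protected: float = 0.2
    enhanced: float = 2.5

    def __post_init__(self) -> None:
        if not (self.protected < self.baseline < self.enhanced):
            raise ValueError("levels must satisfy protected < baseline < enhanced")


@dataclass
class ReactivityProfile:
    """Per-position in-line probing reactivities for one condition."""

    reactivities: np.ndarray
    condition: str = ""
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = np.asarray(self.reactivities, dtype=float)
        if np.any(arr < 0):
            raise ValueError("reactivities must be non-negative")
        self.reactivities = arr

    def __len__(self) -> int:
        return len(self.reactivities)


@dataclass
class ProtectionCallSet:
    """Per-position protected/enhanced/unchanged calls between conditions."""

    calls: list[str]
    fold_changes: np.ndarray
    down_fc: float
    up_fc: float
    flagged_zero_apo: list[int] = field(default_factory=list)

    def positions(self, call: str) -> list[int]:
        return [i for i, c in enumerate(self.calls) if c == call]


def predict_reactivity(state: StateModel,
                       levels: ReactivityLevels = ReactivityLevels()
                       ) -> ReactivityProfile:
    """Deterministic reactivity prediction from a structural state.

    Unpaired, unfootprinted positions sit at baseline; paired or
    footprinted positions are protected; terminal-loop positions of a
    protein-bound state are enhanced.  A position claimed by both
    protection and enhancement (e.g. a footprinted loop nucleotide)
    resolves to the lower level, with a note.
    """
    n = len(state)
    levels_arr = np.full(n, levels.baseline)
    notes: list[str] = []
    in_footprint = np.zeros(n, dtype=bool)
    for lo, hi in state.footprints:
        in_footprint[lo:hi] = True
    for i in range(n):
        protected = state.paired[i] or in_footprint[i]
        enhanced = (state.protein_bound and state.loop is not None
                    and state.loop[0] <= i < state.loop[1])
        if protected and enhanced:
            levels_arr[i] = min(levels.protected, levels.enhanced)
            notes.append(f"position {i}: contradictory protected/enhanced "
                         f"assignment resolved to min level")
        elif protected:
            levels_arr[i] = levels.protected
        elif enhanced:
            levels_arr[i] = levels.enhanced
    label = state.name or ("bound" if state.protein_bound else "apo")
    return ReactivityProfile(levels_arr, condition=label, notes=notes)


def call_protection(apo: ReactivityProfile, bound: ReactivityProfile,
                    down_fc: float = 0.5, up_fc: float = 2.0
                    ) -> ProtectionCallSet:
    """Call protected/enhanced/unchanged per position from two profiles.

    bound/apo <= ``down_fc`` -> protected; >= ``up_fc`` -> enhanced;
    otherwise unchanged.  Positions with zero apo reactivity have an
    undefined fold change and are called unchanged with a flag.
    """
    if len(apo) != len(bound):
        raise ValueError("profiles differ in length")
    if not (0 < down_fc < 1 < up_fc):
        raise ValueError("thresholds must satisfy 0 < down_fc < 1 < up_fc")
    a = apo.reactivities
    b = bound.reactivities
    fc = np.full(len(a), np.nan)
    calls: list[str] = []
    zero_apo: list[int] = []
    for i in range(len(a)):
        if a[i] == 0:
            zero_apo.append(i)
            calls.append("unchanged")
            continue
        fc[i] = b[i] / a[i]
        if fc[i] <= down_fc:
            calls.append("protected")
        elif fc[i] >= up_fc:
            calls.append("enhanced")
        else:
            calls.append("unchanged")
    return ProtectionCallSet(calls=calls, fold_changes=fc,
                             down_fc=down_fc, up_fc=up_fc,
                             flagged_zero_apo=zero_apo)


def sd_occlusion_score(calls: ProtectionCallSet,
                       sd_interval: tuple[int, int]) -> float:
    """Fraction of Shine-Dalgarno positions called protected, in [0, 1]."""
    lo, hi = sd_interval
    if not (0 <= lo < hi <= len(calls.calls)):
        raise IndexError(f"SD interval {sd_interval} outside profile bounds")
    window = calls.calls[lo:hi]
    return sum(c == "protected" for c in window) / len(window)


def read_profile_csv(path, condition: str = "") -> ReactivityProfile:
    """Read a 'position, reactivity' CSV (positions must be 0..n-1)."""
    import pandas as pd

    df = pd.read_csv(path)
    df = df.sort_values(df.columns[0])
    return ReactivityProfile(df[df.columns[1]].to_numpy(), condition=condition)
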