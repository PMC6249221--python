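"""Core containers: ECG records, analysis segments, and CNN channel stacks.

Amplitudes are in millivolts throughout; sampling rates in Hz; time in seconds.
Labels follow AED convention: 1 = shockable (SH: VF/VT/ventricular flutter),
0 = non-shockable (NSH).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Rhythm annotation codes mapped to the shockable class.
SH_RHYTHMS = frozenset({"VF", "VT", "VFL"})

#: Annotation codes that trigger segment exclusion regardless of class.
EXCLUSION_RHYTHMS = frozenset({"NOISE", "ARTIFACT", "ASYS", "TRANS"})

SH = 1
NSH = 0


@dataclass
class RhythmAnnotation:
    """One rhythm change-point: the rhythm `label` holds from sample `onset` on."""

    onset: int
    label: str


@dataclass
class EcgRecord:
    """A single patient's single-channel ECG with rhythm annotations.

    Each record corresponds to one patient; cross-validation folds are
    assigned at the record level so no patient ever spans train and test.
    """

    record_id: str
    samples: np.ndarray
    fs: float
    annotations: list[RhythmAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("EcgRecord holds a single channel (1-D samples)")
        onsets = [a.onset for a in self.annotations]
        if onsets != sorted(onsets):
            raise ValueError("annotations must be sorted by onset")
        if onsets and (onsets[0] < 0 or onsets[-1] >= len(self.samples)):
            raise ValueError("annotation onsets must lie within the signal")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class Segment:
    """One fixed-length analysis window cut from a record.

    `label` is the SH/NSH ground truth derived from the dominant annotated
    rhythm; `rhythm` keeps the dominant annotation code itself so the
    exclusion rules (slow VT, low-amplitude VF, noise...) can be applied.
    """

    record_id: str
    start: int
    samples: np.ndarray
    label: int
    rhythm: str = "N"
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.label not in (SH, NSH):
            raise ValueError(f"label must be 0 (NSH) or 1 (SH), got {self.label}")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class ChannelStack:
    """The three aligned CNN input channels for one segment.

    pecg        -- the preprocessed ECG segment
    sh_signal   -- sum of the 5 modes pinned at {2, 3.5, 5, 6.5, 8} Hz
                   (power concentrated below 10 Hz, shockability-oriented)
    nsh_signal  -- sum of the free modes whose centers settle above 10 Hz
    """

    pecg: np.ndarray
    sh_signal: np.ndarray
    nsh_signal: np.ndarray
    label: int
    record_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.pecg)
        if len(self.sh_signal) != n or len(self.nsh_signal) != n:
            raise ValueError("channel lengths must match")

    def as_array(self) -> np.ndarray:
        """Stack as a (3, n_samples) array in CNN channel order."""
        return np.stack([self.pecg, self.sh_signal, self.nsh_signal])

    def __len__(self) -> int:
        return len(self.pecg)
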