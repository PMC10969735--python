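"""The six m-CTSIB balance conditions.

The modified Clinical Test of Sensory Interaction on Balance crosses
support surface (stable floor vs. foam) with visual state (eyes open,
eyes closed, or eyes open with visual interference), giving conditions
C1..C6. The mapping is fixed by the protocol:

=========  ========  =============
condition  surface   vision
=========  ========  =============
C1         stable    open
C2         stable    closed
C3         stable    interference
C4         foam      open
C5         foam      closed
C6         foam      interference
=========  ========  =============
"""

from __future__ import annotations

import enum


class Surface(str, enum.Enum):
    STABLE = "stable"
    FOAM = "foam"


class Vision(str, enum.Enum):
    OPEN = "open"
    CLOSED = "closed"
    INTERFERENCE = "interference"


class Condition(str, enum.Enum):
    """m-CTSIB condition code."""

    C1 = "C1"
    C2 = "C2"
    C3 = "C3"
    C4 = "C4"
    C5 = "C5"
    C6 = "C6"

    @property
    def surface(self) -> Surface:
        return Surface.FOAM if self in (Condition.C4, Condition.C5, Condition.C6) else Surface.STABLE

    @property
    def vision(self) -> Vision:
        return _VISION[self]


_VISION = {
    Condition.C1: Vision.OPEN,
    Condition.C2: Vision.CLOSED,
    Condition.C3: Vision.INTERFERENCE,
    Condition.C4: Vision.OPEN,
    Condition.C5: Vision.CLOSED,
    Condition.C6: Vision.INTERFERENCE,
}

ALL_CONDITIONS: tuple[Condition, ...] = tuple(Condition)


class Marker(str, enum.Enum):
    """Anatomical landmark tracked in the sagittal-plane video."""

    LATERAL_MALLEOLUS = "lateral_malleolus"
    MASTOID_PROCESS = "mastoid_process"


ALL_MARKERS: tuple[Marker, ...] = tuple(Marker)
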