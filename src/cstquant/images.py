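"""Core image container shared by the generator and the quantification stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageSet:
    """Registered donor / acceptor / FRET channel images of one field.

    All three channels are float arrays in detector counts with identical
    shape. ``metadata`` carries acquisition context (bit depth, background
    level, pixel size) used by QC and I/O.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    fret: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d, a, f = (np.asarray(x, dtype=float) for x in (self.donor, self.acceptor, self.fret))
        if not (d.shape == a.shape == f.shape):
            raise ValueError(
                f"channel shapes differ: donor {d.shape}, acceptor {a.shape}, fret {f.shape}"
            )
        self.donor, self.acceptor, self.fret = d, a, f

    @property
    def shape(self) -> tuple[int, ...]:
        return self.donor.shape

    def channels(self) -> dict[str, np.ndarray]:
        return {"donor": self.donor, "acceptor": self.acceptor, "fret": self.fret}
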