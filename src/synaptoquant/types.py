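"""Shared lightweight containers used across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FieldImageSet:
    """The four channel images of one imaged site plus its identity.

    ``images`` maps a canonical channel name (``MAP2``, ``Psd95``, ``Gphn``,
    ``Syn1``) to a 2-D float array. All four images share one shape.
    """

    plate: str
    well: str
    site: int
    images: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.images.values()))
        return first.shape

    def validate(self) -> None:
        shapes = {ch: im.shape for ch, im in self.images.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel images differ in shape: {shapes}")
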