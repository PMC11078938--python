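"""In-memory container for multi-cycle, multi-channel image stacks.

A cyclic immunofluorescence experiment produces, per staining cycle, one
nuclear-stain reference image (used for registration and segmentation) and,
per marker channel, a *stained* image (acquired after antibody staining) and
an *erased* image (acquired after fluorophore cleavage, serving as the
per-cycle background).  All intensities are stored as floats on a [0, 1]
scale so that thresholds have a single meaning throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MarkerChannel:
    """One marker channel of one cycle: a stained/erased image pair."""

    name: str
    stained: np.ndarray
    erased: np.ndarray | None = None


@dataclass
class Cycle:
    """One staining cycle: a reference (nuclear stain) plus marker channels."""

    index: int
    reference: np.ndarray
    channels: list[MarkerChannel] = field(default_factory=list)


@dataclass
class CycleStack:
    """Ordered cycles of an experiment.  Cycle 0 is the registration reference."""

    cycles: list[Cycle]

    def __post_init__(self) -> None:
        if not self.cycles:
            raise ValueError("a CycleStack needs at least one cycle")
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.cycles[0].reference.shape)  # type: ignore[return-value]

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def marker_names(self) -> list[str]:
        return [ch.name for cyc in self.cycles for ch in cyc.channels]

    def validate(self) -> None:
        """Check that every image in the stack shares one shape."""
        shape = self.cycles[0].reference.shape
        for cyc in self.cycles:
            images = [cyc.reference] + [
                img
                for ch in cyc.channels
                for img in (ch.stained, ch.erased)
                if img is not None
            ]
            for img in images:
                if img.shape != shape:
                    raise ValueError(
                        f"cycle {cyc.index}: image shape {img.shape} != {shape}"
                    )
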