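"""Core image containers for paired MAR_off / MAR_on CBCT stacks.

The unit of analysis is an :class:`ImageStack`: the ordered axial slices of
one acquisition, on the 8-bit grayscale scale (0-255).  A :class:`StackPair`
binds the MAR-off and MAR-on acquisitions of the same object so that slices
can be compared index-by-index.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "MarState",
    "StackLabel",
    "ImageSlice",
    "ImageStack",
    "StackPair",
    "InconsistentStackError",
    "PairingError",
    "LabelMismatchError",
    "EmptyStackError",
]

MIN_DIM = 8

PROSTHESIS_TYPES = ("amalgam", "gold", "pfm", "zirconia", "synthetic")


class InconsistentStackError(ValueError):
    """Slices in one stack disagree in shape."""


class PairingError(ValueError):
    """MAR_off and MAR_on stacks cannot be paired slice-by-slice."""


class LabelMismatchError(ValueError):
    """Paired stacks differ in acquisition labels other than mar_state."""


class EmptyStackError(ValueError):
    """A stack ended up with no slices (empty input or all-blank trim)."""


@dataclass(frozen=True)
class StackLabel:
    """Acquisition descriptor: MAR state plus the grouping factors.

    ``prosthesis`` is one of amalgam/gold/pfm/zirconia for scanned phantoms,
    or "synthetic" for simulated stacks.  ``voxel_mm`` and ``kvp`` carry the
    scan protocol (isotropic voxel edge in mm, peak tube voltage).
    """

    mar_state: str  # "on" | "off"
    prosthesis: str = "synthetic"
    voxel_mm: Optional[float] = None
    kvp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mar_state not in ("on", "off"):
            raise ValueError(f"mar_state must be 'on' or 'off', got {self.mar_state!r}")
        if self.prosthesis not in PROSTHESIS_TYPES:
            raise ValueError(
                f"prosthesis must be one of {PROSTHESIS_TYPES}, got {self.prosthesis!r}"
            )

    def matches_except_mar(self, other: "StackLabel") -> bool:
        return (
            self.prosthesis == other.prosthesis
            and self.voxel_mm == other.voxel_mm
            and self.kvp == other.kvp
        )


# Alias kept for readers coming from the acquisition side.
MarState = str


@dataclass(frozen=True)
class ImageSlice:
    """One axial grayscale slice on the 8-bit scale.

    ``pixels`` is a 2-D uint8 array (row-major, origin top-left); ``index``
    is the 0-based position in its stack; ``pixel_spacing`` is the physical
    pixel size in mm when known.
    """

    pixels: np.ndarray
    index: int = 0
    pixel_spacing: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"slice pixels must be 2-D, got shape {px.shape}")
        if min(px.shape) < MIN_DIM:
            raise ValueError(f"slice dimensions must be >= {MIN_DIM}, got {px.shape}")
        if px.dtype != np.uint8:
            arr = np.asarray(px, dtype=np.float64)
            if arr.size and (arr.min() < 0 or arr.max() > 255):
                raise ValueError("slice intensities must lie in [0, 255]")
            px = arr.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ImageStack:
    """Ordered axial slices of one acquisition, all the same shape."""

    slices: tuple[ImageSlice, ...]
    label: StackLabel

    def __post_init__(self) -> None:
        slices = tuple(self.slices)
        if not slices:
            raise EmptyStackError("an ImageStack needs at least one slice")
        shape0 = slices[0].shape
        for s in slices:
            if s.shape != shape0:
                raise InconsistentStackError(
                    f"mixed slice dimensions: {shape0} vs {s.shape}"
                )
        # Re-base indices so they are always contiguous from 0.
        slices = tuple(replace(s, index=i) for i, s in enumerate(slices))
        object.__setattr__(self, "slices", slices)

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self) -> Iterator[ImageSlice]:
        return iter(self.slices)

    def __getitem__(self, i: int) -> ImageSlice:
        return self.slices[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape

    def as_array(self) -> np.ndarray:
        """Stack pixels into a (n_slices, rows, cols) uint8 array."""
        return np.stack([s.pixels for s in self.slices])

    @classmethod
    def from_array(
        cls,
        volume: np.ndarray | Sequence[np.ndarray],
        label: StackLabel,
        pixel_spacing: Optional[float] = None,
    ) -> "ImageStack":
        vol = [np.asarray(a) for a in volume]
        return cls(
            slices=tuple(
                ImageSlice(pixels=a, index=i, pixel_spacing=pixel_spacing)
                for i, a in enumerate(vol)
            ),
            label=label,
        )


@dataclass(frozen=True)
class StackPair:
    """Matched MAR_off / MAR_on acquisitions of the same object.

    Slices are paired by equal post-trim index; the invariants (equal slice
    counts, equal shapes, identical labels apart from mar_state) are checked
    at construction.
    """

    off_stack: ImageStack
    on_stack: ImageStack

    def __post_init__(self) -> None:
        off, on = self.off_stack, self.on_stack
        if off.label.mar_state != "off" or on.label.mar_state != "on":
            raise LabelMismatchError(
                "off_stack must be labelled mar_state='off' and on_stack 'on' "
                f"(got {off.label.mar_state!r}/{on.label.mar_state!r})"
            )
        if len(off) != len(on):
            raise PairingError(
                f"cannot pair stacks of {len(off)} (off) vs {len(on)} (on) slices"
            )
        if off.shape != on.shape:
            raise PairingError(
                f"cannot pair stacks with slice shapes {off.shape} vs {on.shape}"
            )
        if not off.label.matches_except_mar(on.label):
            raise LabelMismatchError(
                f"labels differ beyond mar_state: {off.label} vs {on.label}"
            )

    def __len__(self) -> int:
        return len(self.off_stack)
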