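"""Synthetic arch-phantom generator with controllable streak artifacts.

Emulates the axial appearance of a dental arch phantom scanned by CBCT: a
horseshoe-shaped resin arch, one dense prosthesis-like insert, and radial
bright/dark streak bands emanating from the insert (the beam-hardening /
photon-starvation signature of a dense object).  Metal-artifact reduction
is modelled combinatorially: the MAR_on stack contains a subset of the
MAR_off streaks with identical geometry, so the pair carries exact
ground-truth streak counts and a known true reduction ratio — something a
physical reconstruction can never provide.

Geometry is chosen so every drawn structure produces one isolated closed
Canny contour: the insert sits in the open interior of the horseshoe and
streak bands are finite radial ribbons that start outside the insert and
end before the arch.  All region boundaries get a fixed one-pixel linear
anti-aliasing ramp so a band edge stays a single line instead of a
staircase of fragments.

Streak bands clip to [0, 255] against the background, so the background
level bounds the contrast a dark (subtractive) band can reach; the default
background of 60 leaves dark bands with contrast comparable to the other
structures, keeping every ground-truth streak detectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .types import ImageStack, StackLabel, StackPair

__all__ = [
    "PhantomSpec",
    "StreakSpec",
    "SimulatedPair",
    "render_phantom",
    "add_streaks",
    "add_streak_bands",
    "add_noise",
    "make_pair",
    "sample_streak_angles",
    "save_pair",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of the arch phantom geometry.

    Intensities are on the 8-bit scale and must be ordered
    ``insert > arch > background``.  The arch is an annulus sector centred
    at ``arch_center`` with the opening (the "anterior gap") pointing
    towards the top of the image; ``arch_gap_half_deg`` is the half-angle
    of that opening.
    """

    slice_dims: tuple[int, int] = (256, 256)
    n_slices: int = 10
    background_intensity: float = 60.0
    arch_intensity: float = 120.0
    insert_intensity: float = 250.0
    insert_center: tuple[float, float] = (140.0, 128.0)
    insert_radius: float = 8.0
    arch_center: tuple[float, float] = (140.0, 128.0)
    arch_inner_radius: float = 78.0
    arch_outer_radius: float = 104.0
    arch_gap_half_deg: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.slice_dims
        if rows < 8 or cols < 8:
            raise ValueError("slice dimensions must be at least 8x8")
        if self.n_slices < 1:
            raise ValueError("need at least one slice")
        if not (self.insert_intensity > self.arch_intensity > self.background_intensity):
            raise ValueError("intensities must satisfy insert > arch > background")
        if not 0 <= self.background_intensity <= 255 or self.insert_intensity > 255:
            raise ValueError("intensities must lie in [0, 255]")
        r0, c0 = self.insert_center
        r = self.insert_radius
        if r < 0:
            raise ValueError("insert_radius must be >= 0")
        if r0 - r < 0 or r0 + r > rows - 1 or c0 - r < 0 or c0 + r > cols - 1:
            raise ValueError("insert disk must lie fully inside the image")
        if not 0 < self.arch_inner_radius < self.arch_outer_radius:
            raise ValueError("arch radii must satisfy 0 < inner < outer")


@dataclass(frozen=True)
class StreakSpec:
    """Radial streak-band parameters.

    Bands are ribbons of the given ``width`` running radially outward from
    the streak origin, starting at ``start_radius`` and extending
    ``length`` pixels.  Amplitudes are added to (bright) or subtracted from
    (dark) the underlying image, alternating bright/dark in draw order, and
    the result clips to [0, 255].  ``min_angular_separation`` keeps band
    contours disjoint.
    """

    n_streaks: int = 10
    width: float = 6.0
    length: float = 40.0
    start_radius: float = 24.0
    bright_amplitude: float = 100.0
    dark_amplitude: float = 60.0
    min_angular_separation: float = 0.5

    def __post_init__(self) -> None:
        if self.n_streaks < 0:
            raise ValueError("n_streaks must be >= 0")
        if self.width < 1:
            raise ValueError("streak width must be >= 1 pixel")
        if self.length <= 0 or self.start_radius < 0:
            raise ValueError("length must be > 0 and start_radius >= 0")
        if self.min_angular_separation < 0:
            raise ValueError("min_angular_separation must be >= 0")
        if self.n_streaks * self.min_angular_separation >= 2 * np.pi:
            raise ValueError(
                "infeasible streak spec: n_streaks * min_angular_separation "
                "must be < 2*pi"
            )


@dataclass(frozen=True)
class SimulatedPair:
    """A matched MAR_off/MAR_on simulation with exact ground truth."""

    pair: StackPair
    k_off: int
    k_on: int
    true_ratio_pct: float
    seed: int
    angles: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.k_on > self.k_off:
            raise ValueError("k_on must be <= k_off")


def _coverage(signed_distance: np.ndarray) -> np.ndarray:
    """One-pixel linear anti-aliasing ramp: 1 inside, 0 outside."""
    return np.clip(0.5 - signed_distance, 0.0, 1.0)


def _render_slice(spec: PhantomSpec) -> np.ndarray:
    rows, cols = spec.slice_dims
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)

    img = np.full((rows, cols), spec.background_intensity, dtype=np.float64)

    # Horseshoe arch: annulus sector with the gap opening upward (-row).
    ar, ac = spec.arch_center
    dy, dx = rr - ar, cc - ac
    radius = np.hypot(dy, dx)
    # angular distance from the "up" direction
    ang = np.arctan2(dx, -dy)  # 0 along -row, in (-pi, pi]
    gap_half = np.radians(spec.arch_gap_half_deg)
    d_ang = (gap_half - np.abs(ang)) * radius  # >0 inside the gap
    d_arch = np.maximum.reduce(
        [spec.arch_inner_radius - radius, radius - spec.arch_outer_radius, d_ang]
    )
    cov = _coverage(d_arch)
    img = img + cov * (spec.arch_intensity - img)

    # Dense insert disk.
    if spec.insert_radius > 0:
        ir, ic = spec.insert_center
        d_ins = np.hypot(rr - ir, cc - ic) - spec.insert_radius
        cov = _coverage(d_ins)
        img = img + cov * (spec.insert_intensity - img)

    return img


def render_phantom(spec: PhantomSpec) -> ImageStack:
    """Render the noise-free, streak-free phantom stack (identical slices)."""
    base = np.clip(np.rint(_render_slice(spec)), 0, 255).astype(np.uint8)
    vol = np.repeat(base[None, :, :], spec.n_slices, axis=0)
    return ImageStack.from_array(vol, label=StackLabel(mar_state="off"))


def sample_streak_angles(
    streaks: StreakSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` angles with pairwise circular separation >= the minimum.

    Uses the spacing construction (minimum gaps plus a uniformly split
    surplus plus a random rotation), which is always feasible when
    ``n * min_angular_separation < 2*pi`` and needs no rejection loop.  The
    returned angles are in draw order (randomly permuted), so truncating to
    the first ``k`` preserves a uniform subset.
    """
    if n == 0:
        return np.zeros(0)
    if n == 1:
        return np.array([rng.uniform(0.0, 2 * np.pi)])
    sep = streaks.min_angular_separation
    if n * sep >= 2 * np.pi:
        raise ValueError("cannot place streaks with the requested separation")
    surplus = 2 * np.pi - n * sep
    gaps = sep + surplus * rng.dirichlet(np.ones(n))
    angles = (rng.uniform(0.0, 2 * np.pi) + np.cumsum(gaps)) % (2 * np.pi)
    return rng.permutation(angles)


def add_streak_bands(
    stack: ImageStack,
    streaks: StreakSpec,
    origin: tuple[float, float],
    angles: Sequence[float],
) -> ImageStack:
    """Draw radial bands at explicit angles (bright/dark alternating in order)."""
    rows, cols = stack.shape
    orow, ocol = origin
    if not (0 <= orow < rows and 0 <= ocol < cols):
        raise ValueError("streak origin must lie inside the image")
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)
    dy, dx = rr - orow, cc - ocol

    delta = np.zeros((rows, cols), dtype=np.float64)
    for i, ang in enumerate(angles):
        vy, vx = np.cos(ang), np.sin(ang)
        along = dy * vy + dx * vx
        perp = np.abs(dy * vx - dx * vy)
        d_band = np.maximum.reduce(
            [
                perp - streaks.width / 2.0,
                streaks.start_radius - along,
                along - (streaks.start_radius + streaks.length),
            ]
        )
        amp = streaks.bright_amplitude if i % 2 == 0 else -streaks.dark_amplitude
        delta += amp * _coverage(d_band)

    base = stack.as_array().astype(np.float64)
    out = np.clip(np.rint(base + delta[None, :, :]), 0, 255).astype(np.uint8)
    return ImageStack.from_array(out, label=stack.label)


def add_streaks(
    stack: ImageStack,
    streaks: StreakSpec,
    origin: tuple[float, float],
    seed: int,
) -> ImageStack:
    """Draw ``n_streaks`` bands at seeded-random angles from ``origin``."""
    rng = np.random.default_rng(seed)
    angles = sample_streak_angles(streaks, streaks.n_streaks, rng)
    return add_streak_bands(stack, streaks, origin, angles)


def add_noise(stack: ImageStack, sigma: float, seed: int) -> ImageStack:
    """Additive seeded Gaussian noise, clipped to [0, 255]; sigma 0 is identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return stack
    rng = np.random.default_rng(seed)
    base = stack.as_array().astype(np.float64)
    noisy = base + rng.normal(0.0, sigma, size=base.shape)
    return ImageStack.from_array(
        np.clip(np.rint(noisy), 0, 255).astype(np.uint8), label=stack.label
    )


def make_pair(
    spec: PhantomSpec = PhantomSpec(),
    streaks: StreakSpec = StreakSpec(),
    k_off: int = 10,
    k_on: int = 4,
    noise_sigma: float = 0.0,
    seed: int = 0,
    voxel_mm: Optional[float] = None,
    kvp: Optional[float] = None,
) -> SimulatedPair:
    """Simulate a matched MAR_off/MAR_on pair with known streak counts.

    The same phantom is rendered twice; the off stack gets ``k_off`` streak
    bands and the on stack the *same first* ``k_on`` of them (MAR removes
    streaks, geometry unchanged).  Noise, when requested, is drawn
    independently per stack.  The whole pair is a pure function of its
    arguments, so one seed reproduces it bit-exactly.
    """
    if k_off < 1:
        raise ValueError("k_off must be >= 1")
    if k_on > k_off or k_on < 0:
        raise ValueError("k_on must satisfy 0 <= k_on <= k_off")

    ss = np.random.SeedSequence(seed)
    seed_angles, seed_noise_off, seed_noise_on = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    rng = np.random.default_rng(seed_angles)
    angles = sample_streak_angles(streaks, k_off, rng)

    base = render_phantom(spec)
    off_label = StackLabel(mar_state="off", prosthesis="synthetic", voxel_mm=voxel_mm, kvp=kvp)
    on_label = StackLabel(mar_state="on", prosthesis="synthetic", voxel_mm=voxel_mm, kvp=kvp)

    off = ImageStack.from_array(base.as_array(), label=off_label)
    on = ImageStack.from_array(base.as_array(), label=on_label)
    off = add_streak_bands(off, streaks, spec.insert_center, angles)
    on = add_streak_bands(on, streaks, spec.insert_center, angles[:k_on])
    if noise_sigma > 0:
        off = add_noise(off, noise_sigma, seed_noise_off)
        on = add_noise(on, noise_sigma, seed_noise_on)

    return SimulatedPair(
        pair=StackPair(off_stack=off, on_stack=on),
        k_off=k_off,
        k_on=k_on,
        true_ratio_pct=100.0 * (k_off - k_on) / k_off,
        seed=seed,
        angles=tuple(float(a) for a in angles),
    )


def save_pair(sim: SimulatedPair, out_dir: str | Path) -> None:
    """Write both stacks as PNG slice directories plus a ground-truth sidecar."""
    from . import io as _io  # local import to avoid a cycle at import time

    out = Path(out_dir)
    _io.write_stack(sim.pair.off_stack, out / "mar_off")
    _io.write_stack(sim.pair.on_stack, out / "mar_on")
    sidecar = {
        "k_off": sim.k_off,
        "k_on": sim.k_on,
        "true_ratio_pct": sim.true_ratio_pct,
        "seed": sim.seed,
        "angles": list(sim.angles),
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=2) + "\n")
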