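"""Translation registration of serial sections.

Physical serial sections land on the coverslip with small random offsets, so
consecutive images of a ribbon are mutually translated.  We estimate the
integer-pixel translation between adjacent sections on one reference channel
by maximising the zero-fill cross-correlation over all integer shifts within
a search radius, compose the adjacent shifts cumulatively back to section 0,
and apply the same correction to every channel of a section (all channels
are imaged on the same physical section, so they share its displacement).

Rotation and subpixel motion are deliberately out of scope: section jitter
on a ribbon is translational to good approximation, and integer translation
keeps the whole pipeline exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import RegistrationError
from .stack_io import ROLE_PRESYNAPSE, SectionSeries, VolumeStack
from .synthetic_data import translate_image

DEFAULT_SEARCH_RADIUS = 10


@dataclass
class AlignmentTransform:
    """Per-section displacement (dx_px, dy_px) relative to section 0.

    Stored as the displacement of each section's content; alignment applies
    the negated displacement.  Section 0 is always (0, 0).
    """

    shifts: list[tuple[int, int]]
    reference_channel: str

    def __post_init__(self):
        if self.shifts and self.shifts[0] != (0, 0):
            raise ValueError("section 0 must carry the identity transform")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, s[0], s[1]) for k, s in enumerate(self.shifts)],
            columns=["section", "dx_px", "dy_px"],
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _overlap_score(a: np.ndarray, b: np.ndarray, dx: int, dy: int) -> float:
    """Mean-subtracted cross-correlation of a with b displaced by (dx, dy).

    The score is the per-pixel cross-covariance over the overlap region
    (zero-fill outside the frame).  Mean subtraction removes the
    background-offset bias; dividing by the overlap size removes the bias
    a stationary background would otherwise give to small shifts; and the
    absence of variance normalization means a candidate shift must match
    the true shift's shared signal energy — a small-overlap fluke alignment
    of unrelated bright objects cannot outscore the genuine alignment the
    way it can under per-overlap variance normalization.
    """
    h, w = a.shape
    ys0, ys1 = max(0, dy), min(h, h + dy)
    xs0, xs1 = max(0, dx), min(w, w + dx)
    if ys0 >= ys1 or xs0 >= xs1:
        return -np.inf
    # b[r, c] sits over a[r - dy, c - dx]
    av = a[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
    bv = b[ys0:ys1, xs0:xs1]
    n = av.size
    return (float(np.dot(av.ravel(), bv.ravel())) - av.sum() * bv.sum() / n) / n


def estimate_shift(
    image_a: np.ndarray, image_b: np.ndarray, search_radius: int = DEFAULT_SEARCH_RADIUS
) -> tuple[int, int]:
    """Displacement of ``image_b``'s content relative to ``image_a``.

    Exhaustive search over all integer shifts within ``search_radius``; the
    returned ``(dx, dy)`` is the shift such that translating ``image_a`` by
    it reproduces ``image_b`` (so applying the negated shift to ``image_b``
    aligns it onto ``image_a``).  Ties are broken toward the smallest
    displacement, then lexicographically, so the result is deterministic.
    """
    if image_a.shape != image_b.shape:
        raise RegistrationError(f"shape mismatch: {image_a.shape} vs {image_b.shape}")
    a = image_a.astype(np.float64)
    b = image_b.astype(np.float64)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise RegistrationError("no registration signal: constant image")
    candidates = sorted(
        (
            (dx, dy)
            for dx in range(-search_radius, search_radius + 1)
            for dy in range(-search_radius, search_radius + 1)
        ),
        key=lambda s: (abs(s[0]) + abs(s[1]), s[0], s[1]),
    )
    best, best_score = (0, 0), -np.inf
    for dx, dy in candidates:
        score = _overlap_score(a, b, dx, dy)
        if score > best_score:
            best, best_score = (dx, dy), score
    return best


def align_series(
    series: SectionSeries,
    reference_channel: str = ROLE_PRESYNAPSE,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
) -> tuple[dict[str, VolumeStack], AlignmentTransform]:
    """Align all channels of a series into volume stacks.

    Adjacent-pair shifts are estimated on the reference channel only and
    composed cumulatively to section 0; the same per-section correction is
    applied to every channel.  Out-of-frame voxels are zero-filled.
    """
    if reference_channel not in series.channels:
        raise RegistrationError(
            f"reference channel {reference_channel!r} not in series "
            f"(have {sorted(series.channels)})"
        )
    ref = series.channels[reference_channel]
    shifts: list[tuple[int, int]] = [(0, 0)]
    for k in range(1, series.n_sections):
        try:
            adj = estimate_shift(ref[k - 1], ref[k], search_radius)
        except RegistrationError as exc:
            raise RegistrationError(f"section {k}: {exc}") from exc
        prev = shifts[-1]
        shifts.append((prev[0] + adj[0], prev[1] + adj[1]))

    stacks: dict[str, VolumeStack] = {}
    for role, imgs in series.channels.items():
        aligned = [
            translate_image(img, -sdx, -sdy) for img, (sdx, sdy) in zip(imgs, shifts)
        ]
        stacks[role] = VolumeStack(
            role=role,
            data=np.stack(aligned, axis=0),
            pixel_size_um=series.pixel_size_um,
            section_thickness_um=series.section_thickness_um,
        )
    return stacks, AlignmentTransform(shifts=shifts, reference_channel=reference_channel)
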