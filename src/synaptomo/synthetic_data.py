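"""Ground-truthed synthetic array-tomography scenes.

Real input to this analysis is a ribbon of 70 nm serial sections of mouse
dentate gyrus, immunostained for presynapses (synaptophysin), tau-expressing
presynapses (GFP), postsynapses (PSD95) and human tau (Tau13).  This module
emulates the statistical structure such stacks present to the measurement
pipeline so that every downstream quantity has a known planted value:

* puncta are intensity ellipsoids spanning 2–5 consecutive sections, with a
  dim and a bright amplitude class (so combined thresholding is exercised);
* a configurable fraction of postsynapses contains tau, rendered congruently
  in the tau channel; GFP is rendered inside the flagged presynapses, and
  tau inside a configurable fraction of the GFP-positive presynapses (tau
  travels in the axons of the GFP-labelled, tau-expressing neurons);
* each GFP-positive presynapse is given a paired postsynapse placed at a
  small random 3D offset (mean ``pair_offset_um``), the planted synaptic
  pairs;
* per-section random integer translations model ribbon misalignment, applied
  identically to all channels of a section;
* Gaussian background noise and single-section "speckle" artifacts model
  the noise classes the single-section filter is designed to remove.

Randomness flows from one seed, expanded into independent substreams per
purpose, so adding a channel or noise source never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, SceneTooCrowdedError
from .stack_io import (
    ROLE_GFP,
    ROLE_POSTSYNAPSE,
    ROLE_PRESYNAPSE,
    ROLE_TAU,
    SectionSeries,
)

# Substream keys: fixed per purpose so streams are independent and stable.
_STREAM_KEYS = {
    ROLE_PRESYNAPSE: 1,
    ROLE_POSTSYNAPSE: 2,
    "jitter": 3,
    "speckle": 4,
    "noise": 5,
    "texture": 6,
}


def _substream(seed: int, purpose: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAM_KEYS[purpose],))
    )


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic imaging volume.

    Defaults describe a 10 μm × 10 μm field of 30 × 70 nm sections at
    0.1 μm/px — the crop geometry of the original analysis — populated at a
    neuropil-realistic synapse density.
    """

    footprint_um: tuple[float, float] = (10.0, 10.0)
    n_sections: int = 30
    section_thickness_um: float = 0.07
    pixel_size_um: float = 0.1
    density_per_channel: dict[str, float] = field(
        default_factory=lambda: {ROLE_PRESYNAPSE: 0.6, ROLE_POSTSYNAPSE: 0.6}
    )
    punctum_radius_um: tuple[float, float] = (0.25, 0.05)  # (mean, sd) in-plane
    punctum_span_sections: tuple[int, int] = (2, 5)
    frac_post_tau_positive: float = 0.10
    frac_pre_gfp_positive: float = 0.30
    frac_pre_tau_positive: float = 0.50  # among GFP-positive presynapses
    pair_offset_um: float = 0.25
    pair_offset_sd_um: float = 0.05
    jitter_px: int = 3
    speckle_count: int = 3  # per section, per rendered channel
    background_noise_sd: float = 2.0
    # correlation length (px) of the background field; fluorescence background
    # is spatially smooth (out-of-focus light seen through the PSF), so
    # suprathreshold background forms in-plane patches confined to one
    # section, the noise class the single-section filter removes.  0 → iid.
    background_corr_px: float = 2.5
    amplitude_dim: tuple[float, float] = (25.0, 40.0)
    amplitude_bright: tuple[float, float] = (150.0, 220.0)
    frac_dim: float = 0.3
    # static tissue texture: stationary out-of-focus neuropil fluorescence,
    # identical on every section of a channel (the tissue hardly changes
    # over 70 nm).  It is what registration locks onto in real ribbons.
    # Default 0 keeps the background model purely per-section independent.
    texture_sd: float = 0.0
    texture_corr_px: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.footprint_um) <= 0 or self.n_sections <= 0:
            raise ConfigError("footprint and section count must be positive")
        if self.section_thickness_um <= 0 or self.pixel_size_um <= 0:
            raise ConfigError("calibration must be strictly positive")
        for frac in (
            self.frac_post_tau_positive,
            self.frac_pre_gfp_positive,
            self.frac_pre_tau_positive,
            self.frac_dim,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"fractions must be in [0, 1], got {frac}")
        if any(d < 0 for d in self.density_per_channel.values()):
            raise ConfigError("densities must be nonnegative")
        smin, smax = self.punctum_span_sections
        if smin < 2 or smax < smin:
            raise ConfigError("punctum span must satisfy 2 <= min <= max")
        if smax > self.n_sections:
            raise ConfigError("punctum span exceeds section count")
        if self.punctum_radius_um[0] <= 0 or self.punctum_radius_um[1] < 0:
            raise ConfigError("punctum radius mean must be positive, sd nonnegative")
        if self.pair_offset_um < 0 or self.pair_offset_sd_um < 0:
            raise ConfigError("pair offset parameters must be nonnegative")
        if self.jitter_px < 0 or self.speckle_count < 0 or self.background_noise_sd < 0:
            raise ConfigError("noise parameters must be nonnegative")
        if self.background_corr_px < 0:
            raise ConfigError("background correlation length must be nonnegative")
        if self.texture_sd < 0 or self.texture_corr_px < 0:
            raise ConfigError("texture parameters must be nonnegative")

    @property
    def volume_um3(self) -> float:
        fx, fy = self.footprint_um
        return fx * fy * self.n_sections * self.section_thickness_um

    def planted_count(self, role: str) -> int:
        return int(round(self.density_per_channel.get(role, 0.0) * self.volume_um3))


@dataclass
class PlantedPunctum:
    id: int
    channel: str
    cx_um: float
    cy_um: float
    cz_um: float
    r_xy_um: float
    z_first: int  # first section touched (inclusive)
    z_last: int   # last section touched (inclusive)
    amplitude: float
    tau_positive: bool = False
    gfp_positive: bool = False
    pair_partner_id: int = -1  # -1: unpaired

    @property
    def section_span(self) -> int:
        return self.z_last - self.z_first + 1


@dataclass
class Speckle:
    channel: str
    section: int
    cx_um: float
    cy_um: float
    r_um: float
    amplitude: float


@dataclass
class GroundTruth:
    """Planted objects and nuisance parameters of one synthetic scene."""

    puncta: list[PlantedPunctum]
    speckles: list[Speckle]
    section_shifts_px: list[tuple[int, int]]  # (dx, dy) applied to each section
    config: SceneConfig | None = None

    def by_channel(self, role: str) -> list[PlantedPunctum]:
        return [p for p in self.puncta if p.channel == role]

    def pairs(self) -> list[tuple[PlantedPunctum, PlantedPunctum]]:
        """Planted (presynapse, postsynapse) pairs."""
        by_id = {p.id: p for p in self.puncta}
        return [
            (p, by_id[p.pair_partner_id])
            for p in self.puncta
            if p.channel == ROLE_PRESYNAPSE and p.pair_partner_id >= 0
        ]


# --------------------------------------------------------------------------
# geometry helpers

# radial intensity profile floor: pixels at the disc rim render at 70% of
# the peak amplitude.  Fluorescent puncta are bright-centred, not flat; the
# falloff also gives registration a strict correlation optimum instead of a
# plateau when one section's disc is contained in the next section's.
_PROFILE_FLOOR = 0.7


def _render_disc(img: np.ndarray, cx: float, cy: float, r: float, amp: float, dx: float):
    """Paint a radially-shaded disc (pixel centres within r of (cx, cy) μm)."""
    ny, nx = img.shape
    c0 = max(int((cx - r) / dx - 1), 0)
    c1 = min(int((cx + r) / dx + 2), nx)
    r0 = max(int((cy - r) / dx - 1), 0)
    r1 = min(int((cy + r) / dx + 2), ny)
    if c0 >= c1 or r0 >= r1:
        return
    cols = (np.arange(c0, c1) + 0.5) * dx
    rows = (np.arange(r0, r1) + 0.5) * dx
    rho2 = (cols[None, :] - cx) ** 2 + (rows[:, None] - cy) ** 2
    inside = rho2 <= r * r
    shade = np.zeros_like(rho2)
    shade[inside] = amp * (
        _PROFILE_FLOOR
        + (1 - _PROFILE_FLOOR) * np.sqrt(1.0 - rho2[inside] / (r * r))
    )
    region = img[r0:r1, c0:c1]
    np.maximum(region, shade, out=region)


def section_radius(p: PlantedPunctum, section: int, dz: float) -> float:
    """In-plane radius of the punctum's ellipsoid on a given section.

    The punctum is an ellipsoid with semi-axes (r_xy, r_xy, r_z) where
    r_z = span·dz/2, centred at the middle of its section span; each section
    is evaluated at its physical centre.  End sections always retain a
    positive radius because the section centre lies strictly inside r_z.
    """
    r_z = p.section_span * dz / 2.0
    z_k = (section + 0.5) * dz
    frac = 1.0 - ((z_k - p.cz_um) / r_z) ** 2
    if frac <= 0:
        return 0.0
    return p.r_xy_um * math.sqrt(frac)


def render_punctum(volume: np.ndarray, p: PlantedPunctum, dx: float, dz: float):
    for k in range(p.z_first, p.z_last + 1):
        r_k = section_radius(p, k, dz)
        if r_k > 0:
            _render_disc(volume[k], p.cx_um, p.cy_um, r_k, p.amplitude, dx)


def _background_field(
    rng: np.random.Generator, shape: tuple[int, int], sd: float, corr_px: float
) -> np.ndarray:
    """Zero-mean Gaussian background with in-plane correlation length corr_px.

    A white Gaussian field smoothed with a Gaussian kernel and rescaled back
    to the requested standard deviation; sections are independent.
    """
    from scipy import ndimage as _ndi

    white = rng.normal(0.0, 1.0, shape)
    if corr_px <= 0:
        return sd * white
    smooth = _ndi.gaussian_filter(white, sigma=corr_px, mode="reflect")
    scale = smooth.std()
    if scale == 0:
        return np.zeros(shape)
    return sd * smooth / scale


def translate_image(img: np.ndarray, dx_px: int, dy_px: int) -> np.ndarray:
    """Shift image content by (dx, dy) pixels with zero fill."""
    out = np.zeros_like(img)
    h, w = img.shape
    xs0, xs1 = max(0, dx_px), min(w, w + dx_px)
    ys0, ys1 = max(0, dy_px), min(h, h + dy_px)
    if xs0 >= xs1 or ys0 >= ys1:
        return out
    out[ys0:ys1, xs0:xs1] = img[ys0 - dy_px : ys1 - dy_px, xs0 - dx_px : xs1 - dx_px]
    return out


# --------------------------------------------------------------------------
# placement

_RETRY_CAP = 200
# clearance so distinct planted objects cannot fuse into one 26-connected
# component through the threshold skirt or residual 1-px misalignment
_PLACEMENT_GAP_UM = 0.3
_PLACEMENT_GAP_Z = 1  # sections


def _overlaps(p: PlantedPunctum, others: list[PlantedPunctum]) -> bool:
    """True when p could touch an existing same-channel object after dilation."""
    for q in others:
        if (
            p.z_first > q.z_last + _PLACEMENT_GAP_Z
            or p.z_last < q.z_first - _PLACEMENT_GAP_Z
        ):
            continue
        d2 = (p.cx_um - q.cx_um) ** 2 + (p.cy_um - q.cy_um) ** 2
        if d2 < (p.r_xy_um + q.r_xy_um + _PLACEMENT_GAP_UM) ** 2:
            return True
    return False


def _draw_geometry(cfg: SceneConfig, rng: np.random.Generator):
    r = max(float(rng.normal(*cfg.punctum_radius_um)), 0.08)
    span = int(rng.integers(cfg.punctum_span_sections[0], cfg.punctum_span_sections[1] + 1))
    amp_range = cfg.amplitude_dim if rng.random() < cfg.frac_dim else cfg.amplitude_bright
    amp = float(rng.uniform(*amp_range))
    return r, span, amp


def _margin_um(cfg: SceneConfig) -> float:
    # keep whole objects (and their pair partners, under jitter) inside the frame
    r_max = cfg.punctum_radius_um[0] + 3 * cfg.punctum_radius_um[1]
    pair_reach = cfg.pair_offset_um + 3 * cfg.pair_offset_sd_um
    return r_max + cfg.jitter_px * cfg.pixel_size_um + pair_reach + cfg.pixel_size_um


def _place_channel(
    cfg: SceneConfig,
    role: str,
    count: int,
    rng: np.random.Generator,
    start_id: int,
) -> list[PlantedPunctum]:
    fx, fy = cfg.footprint_um
    m = _margin_um(cfg)
    if count > 0 and (fx - 2 * m <= 0 or fy - 2 * m <= 0):
        raise SceneTooCrowdedError(role, 0, count)
    placed: list[PlantedPunctum] = []
    for i in range(count):
        for _ in range(_RETRY_CAP):
            r, span, amp = _draw_geometry(cfg, rng)
            z_first = int(rng.integers(0, cfg.n_sections - span + 1))
            p = PlantedPunctum(
                id=start_id + i,
                channel=role,
                cx_um=float(rng.uniform(m, fx - m)),
                cy_um=float(rng.uniform(m, fy - m)),
                cz_um=(z_first + span / 2.0) * cfg.section_thickness_um,
                r_xy_um=r,
                z_first=z_first,
                z_last=z_first + span - 1,
                amplitude=amp,
            )
            if not _overlaps(p, placed):
                placed.append(p)
                break
        else:
            raise SceneTooCrowdedError(role, len(placed), count)
    return placed


# cap on the mutual volume overlap of a planted pair's ellipsoids: pre
# terminal and postsynaptic density are adjacent but mutually exclusive
# compartments, so neither may cover enough of the other to trip the 50%
# colocalization rule through mere apposition
_PAIR_OVERLAP_CAP = 0.25


def _lens_area(r1: float, r2: float, d: float) -> float:
    """Intersection area of two discs with radii r1, r2 at centre distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r * r
    a1 = r1 * r1 * math.acos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * math.acos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    tri = 0.5 * math.sqrt(
        max((-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2), 0.0)
    )
    return a1 + a2 - tri


def _mutual_overlap(
    a: PlantedPunctum, b: PlantedPunctum, dz: float
) -> tuple[float, float]:
    """Fractions of a's and b's ellipsoid areas covered by the other."""
    d_xy = math.hypot(a.cx_um - b.cx_um, a.cy_um - b.cy_um)
    inter = 0.0
    for k in range(max(a.z_first, b.z_first), min(a.z_last, b.z_last) + 1):
        inter += _lens_area(section_radius(a, k, dz), section_radius(b, k, dz), d_xy)
    area_a = sum(
        math.pi * section_radius(a, k, dz) ** 2 for k in range(a.z_first, a.z_last + 1)
    )
    area_b = sum(
        math.pi * section_radius(b, k, dz) ** 2 for k in range(b.z_first, b.z_last + 1)
    )
    return inter / area_a if area_a else 0.0, inter / area_b if area_b else 0.0


def _place_partner(
    cfg: SceneConfig,
    pre: PlantedPunctum,
    rng: np.random.Generator,
    placed: list[PlantedPunctum],
    new_id: int,
) -> PlantedPunctum | None:
    """Place a postsynapse at an isotropic random offset from a presynapse."""
    bound = cfg.pair_offset_um + 3 * cfg.pair_offset_sd_um
    dz = cfg.section_thickness_um
    # the volume-exclusion cap makes single draws fail often for large-radius
    # presynapses, so the partner sampler gets a deeper retry budget
    for _ in range(_RETRY_CAP * 25):
        mag = abs(float(rng.normal(cfg.pair_offset_um, cfg.pair_offset_sd_um)))
        if mag > bound:
            continue
        vec = rng.normal(size=3)
        norm = np.linalg.norm(vec)
        if norm == 0:
            continue
        off = vec / norm * mag
        r, span, amp = _draw_geometry(cfg, rng)
        cz_target = pre.cz_um + off[2]
        z_first = int(np.clip(round(cz_target / dz - span / 2.0), 0, cfg.n_sections - span))
        p = PlantedPunctum(
            id=new_id,
            channel=ROLE_POSTSYNAPSE,
            cx_um=pre.cx_um + float(off[0]),
            cy_um=pre.cy_um + float(off[1]),
            cz_um=(z_first + span / 2.0) * dz,
            r_xy_um=r,
            z_first=z_first,
            z_last=z_first + span - 1,
            amplitude=amp,
            pair_partner_id=pre.id,
        )
        d = math.sqrt(
            (p.cx_um - pre.cx_um) ** 2
            + (p.cy_um - pre.cy_um) ** 2
            + (p.cz_um - pre.cz_um) ** 2
        )
        # section-grid quantisation of cz can stretch the offset past the bound
        if d > bound or _overlaps(p, placed):
            continue
        frac_pre, frac_post = _mutual_overlap(pre, p, dz)
        if frac_pre > _PAIR_OVERLAP_CAP or frac_post > _PAIR_OVERLAP_CAP:
            continue
        return p
    # neighbourhood fully occupied: this presynapse goes unpaired (None)
    return None


# --------------------------------------------------------------------------
# public API

def generate_scene(cfg: SceneConfig) -> tuple[GroundTruth, SectionSeries]:
    """Generate one synthetic multi-channel serial-section series.

    Returns the ground truth (planted puncta with flags and pairings, the
    speckles, the applied per-section shifts) and the raw, jittered, noisy
    :class:`SectionSeries` exactly as the measurement pipeline would receive
    it.  Same config (including seed) → bit-identical output.
    """
    cfg.validate()
    fx, fy = cfg.footprint_um
    dx, dz = cfg.pixel_size_um, cfg.section_thickness_um
    nx, ny, nz = int(round(fx / dx)), int(round(fy / dx)), cfg.n_sections

    # --- plant presynapses, flags drawn from the presynapse stream
    rng_pre = _substream(cfg.seed, ROLE_PRESYNAPSE)
    pres = _place_channel(cfg, ROLE_PRESYNAPSE, cfg.planted_count(ROLE_PRESYNAPSE), rng_pre, 0)
    for p in pres:
        p.gfp_positive = bool(rng_pre.random() < cfg.frac_pre_gfp_positive)
    for p in pres:
        if p.gfp_positive:
            p.tau_positive = bool(rng_pre.random() < cfg.frac_pre_tau_positive)

    # --- plant postsynapses: pair partners for GFP+ presynapses first
    rng_post = _substream(cfg.seed, ROLE_POSTSYNAPSE)
    n_post = cfg.planted_count(ROLE_POSTSYNAPSE)
    posts: list[PlantedPunctum] = []
    next_id = len(pres)
    gfp_pres = [p for p in pres if p.gfp_positive]
    for pre in gfp_pres:
        if len(posts) >= n_post:
            break
        partner = _place_partner(cfg, pre, rng_post, posts, next_id)
        if partner is None:
            continue
        pre.pair_partner_id = partner.id
        posts.append(partner)
        next_id += 1
    free = _place_channel(cfg, ROLE_POSTSYNAPSE, n_post - len(posts), rng_post, next_id)
    # free posts must not collide with the already-placed partners either
    kept_free: list[PlantedPunctum] = []
    for p in free:
        if _overlaps(p, posts):
            for _ in range(_RETRY_CAP):
                r, span, amp = _draw_geometry(cfg, rng_post)
                m = _margin_um(cfg)
                z_first = int(rng_post.integers(0, nz - span + 1))
                q = replace(
                    p,
                    cx_um=float(rng_post.uniform(m, fx - m)),
                    cy_um=float(rng_post.uniform(m, fy - m)),
                    cz_um=(z_first + span / 2.0) * dz,
                    r_xy_um=r,
                    z_first=z_first,
                    z_last=z_first + span - 1,
                    amplitude=amp,
                )
                if not _overlaps(q, posts + kept_free):
                    p = q
                    break
            else:
                raise SceneTooCrowdedError(ROLE_POSTSYNAPSE, len(posts) + len(kept_free), n_post)
        kept_free.append(p)
    posts.extend(kept_free)
    for p in posts:
        p.tau_positive = bool(rng_post.random() < cfg.frac_post_tau_positive)

    puncta = pres + posts

    # --- render the four channels in the true (unjittered) frame
    volumes = {role: np.zeros((nz, ny, nx), dtype=np.float64) for role in
               (ROLE_PRESYNAPSE, ROLE_GFP, ROLE_POSTSYNAPSE, ROLE_TAU)}
    for p in pres:
        render_punctum(volumes[ROLE_PRESYNAPSE], p, dx, dz)
        if p.gfp_positive:
            render_punctum(volumes[ROLE_GFP], p, dx, dz)
        if p.tau_positive:
            render_punctum(volumes[ROLE_TAU], p, dx, dz)
    for p in posts:
        render_punctum(volumes[ROLE_POSTSYNAPSE], p, dx, dz)
        if p.tau_positive:
            render_punctum(volumes[ROLE_TAU], p, dx, dz)

    # --- single-section speckle artifacts, per channel
    rng_speckle = _substream(cfg.seed, "speckle")
    speckles: list[Speckle] = []
    for role in volumes:
        for k in range(nz):
            for _ in range(cfg.speckle_count):
                s = Speckle(
                    channel=role,
                    section=k,
                    cx_um=float(rng_speckle.uniform(0.3, fx - 0.3)),
                    cy_um=float(rng_speckle.uniform(0.3, fy - 0.3)),
                    r_um=float(rng_speckle.uniform(0.10, 0.20)),
                    amplitude=float(rng_speckle.uniform(60, 220)),
                )
                _render_disc(volumes[role][k], s.cx_um, s.cy_um, s.r_um, s.amplitude, dx)
                speckles.append(s)

    # --- section jitter (identical across channels) and background noise
    rng_jitter = _substream(cfg.seed, "jitter")
    shifts = [(0, 0)]
    for _ in range(1, nz):
        shifts.append(
            (
                int(rng_jitter.integers(-cfg.jitter_px, cfg.jitter_px + 1)),
                int(rng_jitter.integers(-cfg.jitter_px, cfg.jitter_px + 1)),
            )
        )

    rng_noise = _substream(cfg.seed, "noise")
    rng_texture = _substream(cfg.seed, "texture")
    channels: dict[str, list[np.ndarray]] = {}
    for role, vol in volumes.items():
        if cfg.texture_sd > 0:
            # stationary tissue fluorescence, shared by all sections
            texture = np.abs(
                _background_field(rng_texture, (ny, nx), cfg.texture_sd,
                                  cfg.texture_corr_px)
            )
            vol = vol + texture[None, :, :]
        imgs = []
        for k in range(nz):
            img = translate_image(vol[k], *shifts[k])
            if cfg.background_noise_sd > 0:
                img = img + _background_field(
                    rng_noise, img.shape, cfg.background_noise_sd, cfg.background_corr_px
                )
            imgs.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))
        channels[role] = imgs

    gt = GroundTruth(puncta=puncta, speckles=speckles, section_shifts_px=shifts, config=cfg)
    series = SectionSeries(channels, pixel_size_um=dx, section_thickness_um=dz)
    return gt, series


def match_to_ground_truth(
    detected_centroids_um: list[tuple[float, float, float]],
    planted: list[PlantedPunctum],
    tol_um: float = 0.3,
) -> tuple[int, int, int]:
    """Greedy one-to-one match of detected centroids to planted puncta.

    Returns ``(n_matched, n_detected, n_planted)`` for precision/recall
    bookkeeping; a detection matches a planted punctum when their centroids
    lie within ``tol_um`` (Euclidean, μm).
    """
    cands = []
    for i, (dx_, dy_, dz_) in enumerate(detected_centroids_um):
        for j, p in enumerate(planted):
            d = math.sqrt(
                (dx_ - p.cx_um) ** 2 + (dy_ - p.cy_um) ** 2 + (dz_ - p.cz_um) ** 2
            )
            if d <= tol_um:
                cands.append((d, i, j))
    cands.sort()
    used_d: set[int] = set()
    used_p: set[int] = set()
    for _, i, j in cands:
        if i in used_d or j in used_p:
            continue
        used_d.add(i)
        used_p.add(j)
    return len(used_d), len(detected_centroids_um), len(planted)


def detection_f1(
    detected_centroids_um: list[tuple[float, float, float]],
    planted: list[PlantedPunctum],
    tol_um: float = 0.3,
) -> float:
    """Object-level F1 of a detection result against the planted truth."""
    matched, n_det, n_planted = match_to_ground_truth(
        detected_centroids_um, planted, tol_um
    )
    if n_det == 0 or n_planted == 0:
        return 0.0
    precision = matched / n_det
    recall = matched / n_planted
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


_PUNCTUM_COLS = [
    "kind", "id", "channel", "cx_um", "cy_um", "cz_um", "r_um",
    "z_first", "z_last", "amplitude", "tau_positive", "gfp_positive",
    "pair_partner_id", "section", "dx_px", "dy_px",
]


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Write all planted records (puncta, speckles, section shifts) to one CSV."""
    rows = []
    for p in gt.puncta:
        rows.append(dict(
            kind="punctum", id=p.id, channel=p.channel, cx_um=p.cx_um, cy_um=p.cy_um,
            cz_um=p.cz_um, r_um=p.r_xy_um, z_first=p.z_first, z_last=p.z_last,
            amplitude=p.amplitude, tau_positive=int(p.tau_positive),
            gfp_positive=int(p.gfp_positive), pair_partner_id=p.pair_partner_id,
        ))
    for s in gt.speckles:
        rows.append(dict(
            kind="speckle", channel=s.channel, cx_um=s.cx_um, cy_um=s.cy_um,
            r_um=s.r_um, amplitude=s.amplitude, section=s.section,
        ))
    for k, (sdx, sdy) in enumerate(gt.section_shifts_px):
        rows.append(dict(kind="shift", section=k, dx_px=sdx, dy_px=sdy))
    df = pd.DataFrame(rows, columns=_PUNCTUM_COLS)
    # %.17g preserves float64 exactly, so the round-trip is lossless
    df.to_csv(path, index=False, float_format="%.17g")


def read_ground_truth(path) -> GroundTruth:
    """Inverse of :func:`write_ground_truth` (the config is not round-tripped)."""
    df = pd.read_csv(path, float_precision="round_trip")
    puncta, speckles, shifts = [], [], {}
    for _, row in df.iterrows():
        if row["kind"] == "punctum":
            puncta.append(PlantedPunctum(
                id=int(row["id"]), channel=row["channel"],
                cx_um=float(row["cx_um"]), cy_um=float(row["cy_um"]),
                cz_um=float(row["cz_um"]), r_xy_um=float(row["r_um"]),
                z_first=int(row["z_first"]), z_last=int(row["z_last"]),
                amplitude=float(row["amplitude"]),
                tau_positive=bool(int(row["tau_positive"])),
                gfp_positive=bool(int(row["gfp_positive"])),
                pair_partner_id=int(row["pair_partner_id"]),
            ))
        elif row["kind"] == "speckle":
            speckles.append(Speckle(
                channel=row["channel"], section=int(row["section"]),
                cx_um=float(row["cx_um"]), cy_um=float(row["cy_um"]),
                r_um=float(row["r_um"]), amplitude=float(row["amplitude"]),
            ))
        elif row["kind"] == "shift":
            shifts[int(row["section"])] = (int(row["dx_px"]), int(row["dy_px"]))
    shift_list = [shifts[k] for k in sorted(shifts)]
    return GroundTruth(puncta=puncta, speckles=speckles, section_shifts_px=shift_list)
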