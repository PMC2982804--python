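"""Ground-truthed synthetic micrographs and plus-end comet tracks.

Generates the inputs the measurement procedures expect from real data:
raster images of a cell confined to an adhesive line of known width (cell
mask, line-pattern mask, nucleus mask, filament fluorescence channel) and
plus-end comet trajectories whose fate on hitting the lateral cortex is
governed by the contact-angle rule (shallow contact bends the microtubule
along the axis, steep contact triggers catastrophe).

Conventions: rasters are row-major with the origin at the top-left; the
adhesive line runs vertically (image rows = line axis).  Filament and track
angles are measured from the line axis, signed, in degrees within [-90, 90].
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from skimage.draw import disk, line_aa
from skimage.filters import gaussian

__all__ = [
    "FateRule",
    "FilamentSegment",
    "GroundTruth",
    "SyntheticCellImage",
    "CometTrack",
    "CometTrackSet",
    "render_patterned_cell",
    "simulate_comet_tracks",
    "save_image",
    "load_image",
]

#: Calibration fluorescence of a single filament: total grey-level per pixel
#: of filament length (one "single-filament intensity unit").
DEFAULT_FILAMENT_UNIT = 100.0


# ---------------------------------------------------------------------------
# Fate rule (contact-angle dependent plus-end behaviour at the cortex)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FateRule:
    """Angle-dependent fate of a plus end contacting the lateral cortex.

    Contact angles are measured between the growth direction and the cortex
    plane (which is parallel to the line axis).  |angle| <= ``bend_max``
    bends the microtubule to grow along the axis; |angle| >= ``cat_min``
    triggers catastrophe; in between, fate is Bernoulli with bend
    probability ``mixed_bend_prob``.
    """

    bend_max: float = 25.0
    cat_min: float = 32.0
    mixed_bend_prob: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.bend_max <= self.cat_min <= 90:
            raise ValueError("need 0 < bend_max <= cat_min <= 90 "
                             f"(got {self.bend_max}, {self.cat_min})")
        if not 0 <= self.mixed_bend_prob <= 1:
            raise ValueError("mixed_bend_prob must be in [0, 1]")

    def fate(self, angle_deg: float, rng: np.random.Generator) -> str:
        """Return ``"bend"`` or ``"catastrophe"`` for a contact angle."""
        a = abs(angle_deg)
        if a > 90:
            raise ValueError("contact angle must lie in [-90, 90]")
        if a <= self.bend_max:
            return "bend"
        if a >= self.cat_min:
            return "catastrophe"
        return "bend" if rng.random() < self.mixed_bend_prob else "catastrophe"


# ---------------------------------------------------------------------------
# Patterned-cell image generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilamentSegment:
    """One rendered filament: endpoints in pixel coordinates (row, col),
    signed angle to the line axis (degrees), intensity in single-filament
    units, and length in µm."""

    r0: float
    c0: float
    r1: float
    c1: float
    angle_deg: float
    intensity_units: int
    length_um: float


@dataclass
class GroundTruth:
    cell_length_um: float
    pattern_width_um: float
    pixel_size: float
    single_filament_unit: float
    nucleus_count: int
    segments: list[FilamentSegment] = field(default_factory=list)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([s.angle_deg for s in self.segments])

    def mean_segment_length_px(self) -> float:
        if not self.segments:
            return 0.0
        return float(np.mean([s.length_um / self.pixel_size
                              for s in self.segments]))


@dataclass
class SyntheticCellImage:
    """A synthetic micrograph of one cell on an adhesive line."""

    filament: np.ndarray      # grayscale fluorescence channel
    cell_mask: np.ndarray     # binary
    line_mask: np.ndarray     # binary
    nucleus_mask: np.ndarray  # binary
    pixel_size: float         # µm / pixel
    ground_truth: GroundTruth

    def __post_init__(self) -> None:
        shapes = {self.filament.shape, self.cell_mask.shape,
                  self.line_mask.shape, self.nucleus_mask.shape}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")


def _sample_angles(n: int, angle_model, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` signed filament angles (degrees in [-90, 90]).

    ``angle_model`` is ``("point", a)``, ``("uniform",)`` /
    ``("uniform", lo, hi)``, or ``("vonmises", kappa)`` — a von Mises
    distribution centred on the line axis, folded into [-90, 90] (axial
    symmetry: an angle and its 180°-rotation are the same filament).
    """
    name, *args = angle_model
    if name == "point":
        (a,) = args
        if not -90 <= a <= 90:
            raise ValueError("point-mass angle must lie in [-90, 90]")
        return np.full(n, float(a))
    if name == "uniform":
        lo, hi = args if args else (-90.0, 90.0)
        return rng.uniform(lo, hi, n)
    if name == "vonmises":
        (kappa,) = args
        theta = np.degrees(rng.vonmises(0.0, kappa, n))
        # fold the full circle onto the axial range [-90, 90]
        theta = np.where(theta > 90, theta - 180, theta)
        theta = np.where(theta < -90, theta + 180, theta)
        return theta
    raise ValueError(f"unknown angle model {name!r}")


def render_patterned_cell(length: float, width: float, pixel_size: float = 1.0,
                          n_filaments: int = 0,
                          angle_model=("point", 0.0),
                          noise_sd: float = 0.0,
                          seed: int = 0, *,
                          filament_length: float | tuple[float, float] = 10.0,
                          intensity_units: int = 1,
                          single_filament_unit: float = DEFAULT_FILAMENT_UNIT,
                          nucleus_count: int = 1,
                          margin: int = 10,
                          placement_box=None,
                          max_retries: int = 200) -> SyntheticCellImage:
    """Render a rectangular cell on a vertical adhesive line.

    The cell is a ``length x width`` (µm) axis-aligned rectangle centred on
    the line; the line-pattern mask is a full-height vertical stripe of the
    same width; the nucleus is one (or ``nucleus_count``) small discs at the
    cell centre.  ``n_filaments`` straight filaments are placed uniformly
    inside the cell with angles drawn from ``angle_model`` and rendered as
    anti-aliased 1-px strokes, flux-normalised so each filament deposits
    exactly ``intensity_units * single_filament_unit`` grey-levels per pixel
    of its length, then blurred (Gaussian, sigma 1 px) with additive Gaussian
    noise of standard deviation ``noise_sd``.

    ``filament_length`` is a fixed length in µm or a ``(lo, hi)`` uniform
    range; ``placement_box`` optionally restricts filament midpoints to a
    ``(row_lo, row_hi, col_lo, col_hi)`` pixel box (e.g. an edge band).
    Deterministic for a fixed ``seed``; the ground truth records the exact
    generated geometry.
    """
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be > 0")
    rng = np.random.default_rng(seed)

    len_px = int(round(length / pixel_size))
    wid_px = int(round(width / pixel_size))
    H = len_px + 2 * margin
    W = wid_px + 2 * margin
    r0, c0 = margin, margin           # top-left corner of cell/stripe

    line_mask = np.zeros((H, W), dtype=bool)
    line_mask[:, c0:c0 + wid_px] = True
    cell_mask = np.zeros((H, W), dtype=bool)
    cell_mask[r0:r0 + len_px, c0:c0 + wid_px] = True

    nucleus_mask = np.zeros((H, W), dtype=bool)
    centre = (r0 + len_px / 2.0, c0 + wid_px / 2.0)
    nuc_radius = max(2.0, min(len_px, wid_px) * 0.2)
    offsets = np.linspace(-(nucleus_count - 1), nucleus_count - 1,
                          nucleus_count) * (nuc_radius + 2)
    for off in offsets:
        rr, cc = disk((centre[0] + off, centre[1]), nuc_radius, shape=(H, W))
        nucleus_mask[rr, cc] = True

    angles = _sample_angles(n_filaments, angle_model, rng)
    canvas = np.zeros((H, W), dtype=float)
    segments: list[FilamentSegment] = []
    for angle in angles:
        if isinstance(filament_length, tuple):
            flen_um = rng.uniform(*filament_length)
        else:
            flen_um = float(filament_length)
        flen_px = flen_um / pixel_size
        dr = -np.cos(np.radians(angle)) * flen_px / 2.0
        dc = np.sin(np.radians(angle)) * flen_px / 2.0
        for attempt in range(max_retries + 1):
            if placement_box is None:
                mr = rng.uniform(r0, r0 + len_px)
                mc = rng.uniform(c0, c0 + wid_px)
            else:
                blo, bhi, clo, chi = placement_box
                mr = rng.uniform(blo, bhi)
                mc = rng.uniform(clo, chi)
            p0 = (mr - dr, mc - dc)
            p1 = (mr + dr, mc + dc)
            inside = all(r0 <= p[0] <= r0 + len_px - 1 and
                         c0 <= p[1] <= c0 + wid_px - 1 for p in (p0, p1))
            if inside:
                break
        else:
            raise ValueError(
                f"could not place a {flen_um} µm filament at {angle:.1f}° "
                f"inside the cell after {max_retries} retries")
        rr, cc, val = line_aa(int(round(p0[0])), int(round(p0[1])),
                              int(round(p1[0])), int(round(p1[1])))
        # flux normalisation: total deposited grey-level is exactly
        # intensity_units * unit * length_px, whatever the AA weights sum to
        target_flux = intensity_units * single_filament_unit * max(flen_px, 1.0)
        canvas[rr, cc] += val * (target_flux / val.sum())
        segments.append(FilamentSegment(
            r0=p0[0], c0=p0[1], r1=p1[0], c1=p1[1],
            angle_deg=float(angle), intensity_units=int(intensity_units),
            length_um=float(flen_um)))

    channel = gaussian(canvas, sigma=1.0, preserve_range=True)
    if noise_sd > 0:
        channel = channel + rng.normal(0.0, noise_sd, channel.shape)

    gt = GroundTruth(cell_length_um=len_px * pixel_size,
                     pattern_width_um=wid_px * pixel_size,
                     pixel_size=pixel_size,
                     single_filament_unit=single_filament_unit,
                     nucleus_count=nucleus_count, segments=segments)
    return SyntheticCellImage(filament=channel, cell_mask=cell_mask,
                              line_mask=line_mask, nucleus_mask=nucleus_mask,
                              pixel_size=pixel_size, ground_truth=gt)


# ---------------------------------------------------------------------------
# Plus-end comet tracks with cortical-contact fates
# ---------------------------------------------------------------------------

@dataclass
class CometTrack:
    """Time-stamped tip positions (µm): x lateral, y along the line axis."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    contact_angle_deg: float | None   # ground-truth angle at lateral contact
    fate: str | None                  # "bend" | "catastrophe" | None


@dataclass
class CometTrackSet:
    tracks: list[CometTrack]
    cell_length: float
    cell_width: float
    fate_rule: FateRule

    @property
    def contact_events(self) -> list[tuple[float, str]]:
        """(ground-truth contact angle, fate) per track that hit the cortex."""
        return [(tr.contact_angle_deg, tr.fate) for tr in self.tracks
                if tr.fate is not None]

    def catastrophe_fraction(self) -> float:
        events = self.contact_events
        if not events:
            return 0.0
        return sum(1 for _, f in events if f == "catastrophe") / len(events)


def simulate_comet_tracks(cell_length: float, cell_width: float,
                          fate_rule: FateRule, n_tracks: int,
                          angle_sampler=("uniform", 0.0, 90.0),
                          seed: int = 0, *,
                          speed: float = 15.0,
                          post_bend_run: float = 5.0,
                          time_step: float = 0.05) -> CometTrackSet:
    """Simulate plus-end comets growing from the cell centre.

    Each comet starts at the centre with a signed angle to the line axis
    drawn from ``angle_sampler`` (same grammar as the image angle models)
    and advances in a straight line at ``speed`` µm/min.  On reaching the
    lateral cortex (|x| = width/2) its fate follows ``fate_rule``:
    catastrophe ends the track at the contact point; a bend redirects it
    along the axis (within ``bend_max`` of the boundary direction) for a
    further ``post_bend_run`` µm.  The cell is treated as long compared
    with a comet's run, so every off-axis comet meets the lateral cortex;
    comets growing exactly along the axis (angle 0) reach the cell end
    without a cortical contact event.
    """
    if n_tracks <= 0:
        raise ValueError("n_tracks must be > 0")
    if cell_length <= 0 or cell_width <= 0:
        raise ValueError("cell geometry must be positive")
    rng = np.random.default_rng(seed)
    angles = _sample_angles(n_tracks, angle_sampler, rng)
    half_w, half_l = cell_width / 2.0, cell_length / 2.0

    tracks: list[CometTrack] = []
    for angle in angles:
        a = np.radians(angle)
        dx, dy = np.sin(a), np.cos(a)
        if dx != 0:                   # lateral cortex contact
            d_side = half_w / abs(dx)
            xs = [0.0, dx * d_side]
            ys = [0.0, dy * d_side]
            fate = fate_rule.fate(angle, rng)
            if fate == "bend":
                # bent comets grow along the boundary, hugging the cortex
                # (direction parallel to the axis, i.e. 0° from the boundary)
                xs.append(xs[-1])
                ys.append(ys[-1] + post_bend_run)
            contact_angle = float(angle)
        else:                          # axial comet: reaches the end cap
            xs = [0.0, 0.0]
            ys = [0.0, half_l]
            fate = None
            contact_angle = None
        xs, ys = np.array(xs), np.array(ys)
        dists = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(xs),
                                                          np.diff(ys)))])
        t = dists / speed
        tracks.append(CometTrack(t=t, x=xs, y=ys,
                                 contact_angle_deg=contact_angle, fate=fate))
    return CometTrackSet(tracks=tracks, cell_length=cell_length,
                         cell_width=cell_width, fate_rule=fate_rule)


# ---------------------------------------------------------------------------
# IO: multi-channel TIFF + JSON ground-truth sidecar
# ---------------------------------------------------------------------------

def save_image(img: SyntheticCellImage, path) -> None:
    """Write the four channels as a TIFF stack and the ground truth as JSON
    (``<path>.json``).  Channel order: filament, cell, line, nucleus."""
    import tifffile

    stack = np.stack([img.filament.astype(np.float32),
                      img.cell_mask.astype(np.float32),
                      img.line_mask.astype(np.float32),
                      img.nucleus_mask.astype(np.float32)])
    tifffile.imwrite(path, stack, photometric="minisblack")
    gt = asdict(img.ground_truth)
    with open(str(path) + ".json", "w") as fh:
        json.dump(gt, fh, indent=2)


def load_image(path) -> SyntheticCellImage:
    import tifffile

    stack = tifffile.imread(path)
    with open(str(path) + ".json") as fh:
        gt = json.load(fh)
    segments = [FilamentSegment(**s) for s in gt.pop("segments")]
    pixel_size = gt["pixel_size"]
    truth = GroundTruth(segments=segments, **gt)
    return SyntheticCellImage(
        filament=stack[0].astype(float), cell_mask=stack[1] > 0.5,
        line_mask=stack[2] > 0.5, nucleus_mask=stack[3] > 0.5,
        pixel_size=pixel_size, ground_truth=truth)
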