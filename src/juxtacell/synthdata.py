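"""Synthetic inputs with known ground truth: luminescence traces and GUV images.

Every measurement the pipeline quantifies can be generated here from first
principles, so each quantifier has a matched generator whose parameters are
the ground truth it must recover:

* decay traces from the kinetics model, with optional multiplicative
  log-normal noise (plate-reader style);
* single-vesicle fluorescence-style images — dim lumen disk, bright
  membrane ring, Gaussian point-spread blur, Poisson shot noise plus
  Gaussian read noise, quantized to 16-bit;
* deflated vesicle pairs sharing a flattened contact interface whose
  painted intensity encodes a known interface:lumen ratio, with the five
  measurement lines the interface quantifier expects.

Pixel convention: 0-based (row, col) coordinates with pixel centers at
integers; every truth sidecar states this.  All randomness flows through a
single integer seed, and identical spec + seed produce byte-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import tifffile
from scipy import ndimage

from .kinetics import KineticParams, LuminescenceTrace, model_flux

__all__ = [
    "VesicleSpec",
    "InterfaceSpec",
    "ImageSpec",
    "GUVImage",
    "make_trace_set",
    "make_assay_panel",
    "render_image",
    "make_pair_image",
    "make_vesicle_cohort",
    "write_image",
    "read_image",
]

PIXEL_CONVENTION = "0-based (row, col); pixel centers at integer coordinates"


@dataclass(frozen=True)
class VesicleSpec:
    """One vesicle: lumen disk of ``radius - ring_width/2`` plus membrane ring.

    The ring is the annulus ``|d - radius| <= ring_width/2`` centered on the
    annotated radius, so periphery sampling at that radius hits the ring
    centerline.  ``truth_ratio`` is the generating membrane:lumen contrast
    ``(membrane_level - background) / (lumen_level - background)``.
    """

    center: tuple[float, float]  # (row, col) px
    radius: float  # px
    lumen_level: float  # counts
    membrane_level: float  # counts
    ring_width: float = 6.0  # px

    def truth_ratio(self, background: float) -> float:
        return (self.membrane_level - background) / (self.lumen_level - background)


@dataclass(frozen=True)
class InterfaceSpec:
    """Flattened contact chord between a vesicle pair."""

    p0: tuple[float, float]  # (row, col) px, chord endpoint
    p1: tuple[float, float]
    level: float  # painted counts
    thickness: float = 6.0  # px


@dataclass
class ImageSpec:
    """Full recipe for one synthetic image (also its ground-truth record)."""

    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.2  # um/px
    vesicles: list[VesicleSpec] = field(default_factory=list)
    interface: Optional[InterfaceSpec] = None
    background_level: float = 100.0
    psf_sigma: float = 1.5  # px
    poisson: bool = True
    read_sigma: float = 2.0  # counts
    seed: int = 0
    lines: list[tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=list
    )
    lumen_fraction: float = 0.5
    background_region: Optional[tuple[int, int, int, int]] = None  # r0,c0,r1,c1

    def __post_init__(self) -> None:
        if self.background_level < 0 or self.read_sigma < 0:
            raise ValueError("levels and noise must be >= 0")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        h, w = self.shape
        for v in self.vesicles:
            if v.radius <= v.ring_width:
                raise ValueError("vesicle radius must exceed ring_width")
            if min(v.lumen_level, v.membrane_level) < 0:
                raise ValueError("intensity levels must be >= 0")
            r_out = v.radius + v.ring_width / 2
            cr, cc = v.center
            if cr - r_out < 0 or cc - r_out < 0 or cr + r_out > h - 1 or cc + r_out > w - 1:
                raise ValueError(f"vesicle at {v.center} extends outside the frame")
        if self.background_region is None:
            self.background_region = (2, 2, 22, 22)

    # -- truth sidecar -----------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "pixel_convention": PIXEL_CONVENTION,
            "shape": list(self.shape),
            "pixel_size_um": self.pixel_size,
            "background_level": self.background_level,
            "psf_sigma": self.psf_sigma,
            "noise": {"poisson": self.poisson, "read_sigma": self.read_sigma},
            "seed": self.seed,
            "lumen_fraction": self.lumen_fraction,
            "background_region": list(self.background_region),
            "vesicles": [
                {
                    "center": list(v.center),
                    "radius": v.radius,
                    "lumen_level": v.lumen_level,
                    "membrane_level": v.membrane_level,
                    "ring_width": v.ring_width,
                    "truth_ratio": v.truth_ratio(self.background_level),
                }
                for v in self.vesicles
            ],
            "interface": None
            if self.interface is None
            else {
                "p0": list(self.interface.p0),
                "p1": list(self.interface.p1),
                "level": self.interface.level,
                "thickness": self.interface.thickness,
            },
            "lines": [[list(p0), list(p1)] for p0, p1 in self.lines],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ImageSpec":
        iface = d.get("interface")
        return cls(
            shape=tuple(d["shape"]),
            pixel_size=d.get("pixel_size_um", 1.0),
            vesicles=[
                VesicleSpec(
                    center=tuple(v["center"]),
                    radius=v["radius"],
                    lumen_level=v["lumen_level"],
                    membrane_level=v["membrane_level"],
                    ring_width=v["ring_width"],
                )
                for v in d["vesicles"]
            ],
            interface=None
            if iface is None
            else InterfaceSpec(
                p0=tuple(iface["p0"]),
                p1=tuple(iface["p1"]),
                level=iface["level"],
                thickness=iface["thickness"],
            ),
            background_level=d["background_level"],
            psf_sigma=d["psf_sigma"],
            poisson=d["noise"]["poisson"],
            read_sigma=d["noise"]["read_sigma"],
            seed=d["seed"],
            lines=[(tuple(p0), tuple(p1)) for p0, p1 in d.get("lines", [])],
            lumen_fraction=d.get("lumen_fraction", 0.5),
            background_region=tuple(d["background_region"]),
        )


@dataclass
class GUVImage:
    """Rendered pixels plus the generating spec (the ground truth)."""

    pixels: np.ndarray  # uint16, (H, W)
    truth: ImageSpec


# ---------------------------------------------------------------------------
# Luminescence trace generators

def make_trace_set(
    K: float,
    E_list: Sequence[float],
    S0: float = 20e-6,
    alpha: float = 1e15,
    noise_cv: float = 0.0,
    seed: int = 0,
    t_grid: Optional[Sequence[float]] = None,
) -> list[LuminescenceTrace]:
    """One model trace per enzyme concentration, optional log-normal noise.

    ``noise_cv`` is the coefficient of variation of the multiplicative noise
    factor; 0 yields the noiseless model exactly.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if t_grid is None:
        t_grid = np.arange(0.0, 1801.0, 60.0)  # 30 min sampled every minute
    rng = np.random.default_rng(seed)
    traces = []
    for E in E_list:
        tr = model_flux(KineticParams(K=K, E=E, S0=S0, alpha=alpha), t_grid)
        flux = tr.flux
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv**2))
            factors = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=flux.shape)
            flux = flux * factors
        traces.append(
            LuminescenceTrace(
                times=np.asarray(t_grid, float),
                flux=flux,
                enzyme_concentration=float(E),
                label=f"E={E:.3g}M",
            )
        )
    return traces


def make_assay_panel(
    seed: int = 0,
    K: float = 10644.0,
    E: float = 500e-9,
    S0: float = 20e-6,
    alpha: float = 1e13,
    baseline: float = 50.0,
) -> list[LuminescenceTrace]:
    """Four-reaction complementation panel.

    Only the tagged-fragment mixture reconstitutes an active luciferase; the
    three controls emit baseline detector noise.  Labels follow the assay:
    ``ST-SmBiT``, ``SC-LgBiT``, ``ST-SmBiT+SC-LgBiT`` (the signal), and
    ``SC-LgBiT+SmBiT`` (untagged-peptide control).
    """
    rng = np.random.default_rng(seed)
    t_grid = np.arange(0.0, 1801.0, 60.0)
    panel = []
    for label in ("ST-SmBiT", "SC-LgBiT", "SC-LgBiT+SmBiT"):
        flux = np.abs(rng.normal(loc=baseline, scale=baseline / 5, size=t_grid.shape))
        panel.append(
            LuminescenceTrace(times=t_grid, flux=flux, enzyme_concentration=0.0, label=label)
        )
    tr = model_flux(KineticParams(K=K, E=E, S0=S0, alpha=alpha), t_grid)
    mix = LuminescenceTrace(
        times=t_grid,
        flux=tr.flux,
        enzyme_concentration=E,
        label="ST-SmBiT+SC-LgBiT",
    )
    panel.insert(2, mix)
    return panel


# ---------------------------------------------------------------------------
# Image rendering

def _paint_ideal(spec: ImageSpec) -> np.ndarray:
    h, w = spec.shape
    img = np.full((h, w), float(spec.background_level))
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    for v in spec.vesicles:
        d = np.hypot(rr - v.center[0], cc - v.center[1])
        img[d < v.radius - v.ring_width / 2] = v.lumen_level
        img[np.abs(d - v.radius) <= v.ring_width / 2] = v.membrane_level
    if spec.interface is not None:
        p0 = np.array(spec.interface.p0)
        p1 = np.array(spec.interface.p1)
        seg = p1 - p0
        L2 = float(seg @ seg)
        # distance from each pixel to the chord segment
        t = ((rr - p0[0]) * seg[0] + (cc - p0[1]) * seg[1]) / L2
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(rr - (p0[0] + t * seg[0]), cc - (p0[1] + t * seg[1]))
        img[dist <= spec.interface.thickness / 2] = spec.interface.level
    return img


def render_image(spec: ImageSpec) -> GUVImage:
    """Render: paint levels, PSF blur, Poisson + read noise, 16-bit quantize."""
    img = _paint_ideal(spec)
    if spec.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.psf_sigma, mode="nearest")
    rng = np.random.default_rng(spec.seed)
    if spec.poisson:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if spec.read_sigma > 0:
        img = img + rng.normal(0.0, spec.read_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return GUVImage(pixels=img, truth=spec)


def make_pair_image(
    ratio_interface: float,
    seed: int = 0,
    shape: tuple[int, int] = (224, 320),
    radius: float = 45.0,
    center_distance: float = 80.0,
    lumen_level: float = 400.0,
    background_level: float = 100.0,
    sender_membrane_level: Optional[float] = None,
    psf_sigma: float = 1.5,
    poisson: bool = True,
    read_sigma: float = 2.0,
    n_lines: int = 5,
) -> GUVImage:
    """Two deflated vesicles sharing a flattened, painted contact chord.

    Geometry: two equal circles whose centers are ``center_distance`` apart
    (< 2*radius, so they overlap); the shared chord lies on the radical
    line and each disk is truncated there — a simple proxy for osmotic
    deflation.  The receiver (right) vesicle carries the fluorescent lumen;
    the chord is painted at ``background + ratio_interface * (lumen -
    background)``, so ``ratio_interface`` is the ground truth the interface
    quantifier must recover.  ``n_lines`` measurement segments perpendicular
    to the chord (sender side -> receiver lumen) are stored in the truth
    record.
    """
    if ratio_interface < 0:
        raise ValueError("ratio_interface must be >= 0")
    if center_distance >= 2 * radius:
        raise ValueError("circles must overlap to form a contact chord")
    h, w = shape
    # integer frame center so the chord lies on a pixel column and the
    # 1 px-spaced measurement samples land on pixel centers
    cy = float(h // 2)
    cx = float(w // 2)
    sender_c = (cy, cx - center_distance / 2.0)
    receiver_c = (cy, cx + center_distance / 2.0)
    # radical line: midway for equal radii; half-chord length
    half_chord = float(np.sqrt(radius**2 - (center_distance / 2.0) ** 2))
    chord_col = cx
    p0 = (cy - half_chord, chord_col)
    p1 = (cy + half_chord, chord_col)

    d_lum = lumen_level - background_level
    interface_level = background_level + ratio_interface * d_lum
    if sender_membrane_level is None:
        sender_membrane_level = background_level + 0.4 * d_lum
    ring_w = 6.0
    iface_w = 3.0  # a membrane-membrane contact is optically thin

    # measurement lines: perpendicular to the chord, outside->in (left->right),
    # crossing it at evenly spaced interior points
    inset = 0.25 * half_chord
    ys = np.linspace(cy - half_chord + inset, cy + half_chord - inset, n_lines)
    lines = [((float(y), chord_col - 8.0), (float(y), chord_col + 28.0)) for y in ys]

    spec = ImageSpec(
        shape=shape,
        vesicles=[
            VesicleSpec(
                center=sender_c,
                radius=radius,
                lumen_level=background_level + 0.05 * d_lum,  # dim in this channel
                membrane_level=sender_membrane_level,
                ring_width=ring_w,
            ),
            VesicleSpec(
                center=receiver_c,
                radius=radius,
                lumen_level=lumen_level,
                membrane_level=lumen_level,  # unenhanced membrane baseline
                ring_width=ring_w,
            ),
        ],
        interface=InterfaceSpec(p0=p0, p1=p1, level=interface_level, thickness=iface_w),
        background_level=background_level,
        psf_sigma=psf_sigma,
        poisson=poisson,
        read_sigma=read_sigma,
        seed=seed,
        lines=lines,
    )
    return render_image(spec)


def make_vesicle_cohort(
    truth_ratio: float,
    n: int = 15,
    seed: int = 0,
    shape: tuple[int, int] = (192, 192),
    radius_range: tuple[float, float] = (30.0, 50.0),
    lumen_level: float = 400.0,
    background_level: float = 100.0,
    ring_width: float = 6.0,
    psf_sigma: float = 1.5,
    poisson: bool = True,
    read_sigma: float = 2.0,
) -> list[GUVImage]:
    """A cohort of single-vesicle images sharing one true membrane:lumen ratio.

    Radii are drawn uniformly from ``radius_range`` (a documented stand-in
    for the unreported vesicle size distribution); centers jitter a few
    pixels.  Each image gets an independent sub-seed derived from ``seed``.
    """
    rng = np.random.default_rng(seed)
    membrane_level = background_level + truth_ratio * (lumen_level - background_level)
    images = []
    h, w = shape
    for i in range(n):
        r = float(rng.uniform(*radius_range))
        jitter = rng.uniform(-4, 4, size=2)
        center = (float((h - 1) / 2 + jitter[0]), float((w - 1) / 2 + jitter[1]))
        spec = ImageSpec(
            shape=shape,
            vesicles=[
                VesicleSpec(
                    center=center,
                    radius=r,
                    lumen_level=lumen_level,
                    membrane_level=membrane_level,
                    ring_width=ring_width,
                )
            ],
            background_level=background_level,
            psf_sigma=psf_sigma,
            poisson=poisson,
            read_sigma=read_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        images.append(render_image(spec))
    return images


# ---------------------------------------------------------------------------
# File I/O: 16-bit TIFF + JSON truth sidecar

def write_image(guv: GUVImage, path) -> None:
    """Write a 16-bit grayscale TIFF and its ``<image>.truth.json`` sidecar."""
    path = str(path)
    tifffile.imwrite(path, guv.pixels)
    with open(path + ".truth.json", "w") as fh:
        json.dump(guv.truth.to_json_dict(), fh, indent=1)


def read_image(path) -> GUVImage:
    """Read a TIFF written by :func:`write_image` together with its truth."""
    path = str(path)
    pixels = tifffile.imread(path)
    with open(path + ".truth.json") as fh:
        spec = ImageSpec.from_json_dict(json.load(fh))
    return GUVImage(pixels=pixels, truth=spec)
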