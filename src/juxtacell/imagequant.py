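"""Membrane-recruitment quantification of annotated vesicle images.

Three procedures, matching how GUV fluorescence images are scored by hand
in ImageJ-style workflows:

* **periphery ratio** — sample the image at 30 points equally spaced along
  the annotated membrane circle, average, and divide the background-
  subtracted membrane mean by the background-subtracted lumen mean (lumen =
  central disk at half the annotated radius by default);
* **line profile** — intensities at 1 px spacing along a segment,
  background-subtracted and normalized to the maximum;
* **interface ratio** — for each of (typically five) lines crossing a
  vesicle-vesicle contact, the mean of the 3 samples centered on the peak
  divided by the mean of the 10 samples that follow into the receiver
  lumen; when no clear peak exists (control images) a plateau point stands
  in for the peak.  Per-line ratios are averaged into one data point.

Images are sampled by bilinear interpolation; annotations use 0-based
(row, col) pixel coordinates with pixel centers at integers.  Automatic
vesicle segmentation is out of scope: annotations are inputs, normally the
truth sidecars of the synthetic generator or hand-drawn equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Annotation",
    "PeripheryQuant",
    "InterfaceQuant",
    "UndefinedRatioError",
    "NormalizationError",
    "GeometryError",
    "periphery_ratio",
    "line_profile",
    "interface_ratio",
    "batch_quantify",
]

N_PERIPHERY_POINTS = 30
PEAK_EXCESS = 0.20  # clear peak: max >= (1 + PEAK_EXCESS) * median of lumen pts
PLATEAU_FRAC = 0.02  # plateau: |derivative| <= frac * dynamic range ...
PLATEAU_RUN = 3  # ... for this many consecutive samples
_N_MEMBRANE = 3
_N_LUMEN = 10


class UndefinedRatioError(ValueError):
    """Lumen not brighter than background; ratio has no meaning."""


class NormalizationError(ValueError):
    """Profile contains no signal above background."""


class GeometryError(ValueError):
    """A measurement line is too short for the 3+10-sample rule."""


@dataclass
class Annotation:
    """Measurement geometry for one image (pixel coordinates, 0-based row/col)."""

    vesicles: list[tuple[tuple[float, float], float]] = field(default_factory=list)
    lumen_fraction: float = 0.5  # lumen disk radius as fraction of vesicle radius
    background_region: tuple[int, int, int, int] = (2, 2, 22, 22)  # r0,c0,r1,c1
    lines: list[tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=list
    )

    @classmethod
    def from_truth_dict(cls, d: dict) -> "Annotation":
        """Build from a synthetic-image truth sidecar (shared JSON schema)."""
        return cls(
            vesicles=[(tuple(v["center"]), float(v["radius"])) for v in d["vesicles"]],
            lumen_fraction=float(d.get("lumen_fraction", 0.5)),
            background_region=tuple(d["background_region"]),
            lines=[(tuple(p0), tuple(p1)) for p0, p1 in d.get("lines", [])],
        )


@dataclass(frozen=True)
class PeripheryQuant:
    periphery_samples: np.ndarray  # the 30 sampled intensities
    periphery_mean: float
    lumen_mean: float
    background_mean: float
    ratio: float  # (periphery - background) / (lumen - background)


@dataclass(frozen=True)
class InterfaceQuant:
    per_line: tuple[tuple[float, float, str], ...]  # (membrane, lumen, rule)
    ratio: float  # mean of per-line membrane/lumen
    n_lines: int


def _sample(image: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear interpolation at fractional (row, col) positions."""
    return ndimage.map_coordinates(
        np.asarray(image, float), np.vstack([rows, cols]), order=1, mode="nearest"
    )


def background_mean(image: np.ndarray, region: tuple[int, int, int, int]) -> float:
    """Mean intensity over a rectangular background region (r0, c0, r1, c1)."""
    r0, c0, r1, c1 = region
    return float(np.asarray(image, float)[r0:r1, c0:c1].mean())


def periphery_ratio(
    image: np.ndarray,
    center: tuple[float, float],
    radius: float,
    lumen_fraction: float = 0.5,
    background_region: tuple[int, int, int, int] = (2, 2, 22, 22),
    n_points: int = N_PERIPHERY_POINTS,
    theta0: float = 0.0,
) -> PeripheryQuant:
    """Membrane:lumen intensity ratio from 30 equally spaced periphery points.

    Samples the circle of the annotated radius at angles ``theta0 + k *
    360/n`` deg, averages, and forms ``(periphery - bg) / (lumen - bg)``
    with the lumen mean taken over the central disk of ``lumen_fraction *
    radius``.  ``theta0`` is the sampling phase; rotating image and
    annotation together (phase included) leaves the result unchanged.
    """
    img = np.asarray(image, float)
    h, w = img.shape
    cr, cc = center
    if cr - radius < 0 or cc - radius < 0 or cr + radius > h - 1 or cc + radius > w - 1:
        raise GeometryError("vesicle circle extends outside the frame")
    theta = theta0 + 2 * np.pi * np.arange(n_points) / n_points
    samples = _sample(img, cr + radius * np.sin(theta), cc + radius * np.cos(theta))
    rr, cols = np.mgrid[0:h, 0:w].astype(float)
    lumen_mask = np.hypot(rr - cr, cols - cc) <= lumen_fraction * radius
    lumen = float(img[lumen_mask].mean())
    bg = background_mean(img, background_region)
    if lumen <= bg:
        raise UndefinedRatioError(
            f"lumen mean {lumen:.3g} not above background {bg:.3g}"
        )
    peri = float(samples.mean())
    return PeripheryQuant(
        periphery_samples=samples,
        periphery_mean=peri,
        lumen_mean=lumen,
        background_mean=bg,
        ratio=(peri - bg) / (lumen - bg),
    )


def _profile_positions(
    p0: tuple[float, float], p1: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, float]:
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise GeometryError("zero-length line")
    n = int(np.floor(length)) + 1
    t = np.arange(n) / length  # 1 px spacing along the segment
    rows = p0[0] + t * (p1[0] - p0[0])
    cols = p0[1] + t * (p1[1] - p0[1])
    return rows, cols, length


def raw_line_profile(
    image: np.ndarray,
    segment: tuple[tuple[float, float], tuple[float, float]],
    background_mean: float,
) -> np.ndarray:
    """Background-subtracted intensities at 1 px spacing along a segment."""
    rows, cols, _ = _profile_positions(*segment)
    vals = _sample(np.asarray(image, float), rows, cols) - background_mean
    return np.clip(vals, 0.0, None)


def line_profile(
    image: np.ndarray,
    segment: tuple[tuple[float, float], tuple[float, float]],
    background_mean: float,
    pixel_size: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Max-normalized, background-subtracted profile along a segment.

    Returns ``(positions, values)`` with values in [0, 1]; positions are in
    pixels, or micrometres when ``pixel_size`` (um/px) is given.
    """
    vals = raw_line_profile(image, segment, background_mean)
    peak = vals.max()
    if peak <= 0:
        raise NormalizationError("profile is entirely at or below background")
    positions = np.arange(vals.size, dtype=float)
    if pixel_size is not None:
        positions = positions * pixel_size
    return positions, vals / peak


PLATEAU_HEIGHT = 0.8  # plateau must sit at >= this fraction of the profile max


def _plateau_index(profile: np.ndarray) -> int:
    """First sample (scanning inward) where the signal has levelled off.

    Levelling off: the absolute discrete derivative stays within
    ``PLATEAU_FRAC`` of the profile's dynamic range for ``PLATEAU_RUN``
    consecutive samples, at a height of at least ``PLATEAU_HEIGHT`` of the
    profile maximum (so a flat stretch before the signal rises does not
    qualify).  Falls back to the last feasible index.
    """
    d = np.abs(np.diff(profile))
    thresh = PLATEAU_FRAC * float(np.ptp(profile))
    flat = d <= thresh
    high = profile >= PLATEAU_HEIGHT * profile.max()
    last = profile.size - (_N_MEMBRANE - 1) // 2 - _N_LUMEN - 2
    for i in range(1, max(last, 2)):
        if i + PLATEAU_RUN <= flat.size and np.all(flat[i : i + PLATEAU_RUN]) and high[i]:
            return i
    return max(last, 1)


def _peak_index(profile: np.ndarray) -> int:
    """Global maximum; ties broken at the center of the first maximal run.

    A plateau-topped peak (e.g. an unblurred membrane strip wider than one
    sample) then measures its centerline rather than its leading edge.
    """
    is_max = profile >= profile.max() * (1 - 1e-12)
    start = int(np.argmax(is_max))
    end = start
    while end + 1 < profile.size and is_max[end + 1]:
        end += 1
    return (start + end) // 2


def _quantify_line(profile: np.ndarray, line_id: int) -> tuple[float, float, str]:
    half = (_N_MEMBRANE - 1) // 2
    min_len = 1 + half + (half + 1) + _N_LUMEN  # margin + 3-window + 10 lumen pts
    if profile.size < min_len:
        raise GeometryError(
            f"line {line_id}: profile of {profile.size} samples cannot fit "
            f"the {_N_MEMBRANE}+{_N_LUMEN}-point rule (needs >= {min_len})"
        )
    p = _peak_index(profile)

    def windows(idx: int) -> Optional[tuple[float, float]]:
        m0, m1 = idx - half, idx + half + 1
        l0, l1 = m1, m1 + _N_LUMEN
        if m0 < 0 or l1 > profile.size:
            return None
        return float(profile[m0:m1].mean()), float(profile[l0:l1].mean())

    rule = "peak"
    win = windows(p)
    if win is not None:
        membrane, lumen = win
        lumen_median = float(np.median(profile[p + half + 1 : p + half + 1 + _N_LUMEN]))
        if profile[p] < (1.0 + PEAK_EXCESS) * lumen_median:
            win = None  # maximum not clearly above the lumen: no clear peak
    if win is None:
        rule = "plateau"
        q = _plateau_index(profile)
        win = windows(q)
        if win is None:
            raise GeometryError(
                f"line {line_id}: no admissible plateau window on a "
                f"{profile.size}-sample profile"
            )
        membrane, lumen = win
    else:
        membrane, lumen = win
    if lumen <= 0:
        raise GeometryError(f"line {line_id}: lumen window at or below background")
    return membrane, lumen, rule


def interface_ratio(
    image: np.ndarray,
    lines: Sequence[tuple[tuple[float, float], tuple[float, float]]],
    background_mean: float,
) -> InterfaceQuant:
    """Sender-receiver interface enhancement from lines crossing the contact.

    Each line is oriented from outside the receiver, through the interface,
    into the receiver lumen.  Per line: background-subtract; membrane value
    = mean of the 3 samples centered on the global maximum (or on the
    plateau point when no clear peak exists); lumen value = mean of the 10
    samples immediately following, deeper along the line.  The reported
    ratio is the mean of the per-line membrane/lumen ratios.
    """
    if len(lines) == 0:
        raise ValueError("need at least one measurement line")
    per_line = []
    for i, seg in enumerate(lines):
        profile = raw_line_profile(image, seg, background_mean)
        per_line.append(_quantify_line(profile, i))
    ratio = float(np.mean([m / l for m, l, _ in per_line]))
    return InterfaceQuant(per_line=tuple(per_line), ratio=ratio, n_lines=len(lines))


def batch_quantify(
    items: Sequence[tuple[np.ndarray, Annotation, str, str]],
) -> tuple[pd.DataFrame, list[str]]:
    """Quantify a batch of annotated images into one tidy table.

    ``items`` are ``(image, annotation, condition, image_name)`` tuples.
    Annotations with measurement lines are scored as interfaces, otherwise
    each annotated vesicle gets a periphery row.  Returns the table (columns
    ``image, condition, object_id, ratio, membrane, lumen, background,
    rule``) and a list of error messages for skipped objects.
    """
    rows = []
    errors: list[str] = []
    for image, ann, condition, name in items:
        if ann is None:
            errors.append(f"{name}: missing annotation")
            continue
        bg = background_mean(image, ann.background_region)
        if ann.lines:
            try:
                q = interface_ratio(image, ann.lines, bg)
                rules = {r for _, _, r in q.per_line}
                rows.append(
                    dict(
                        image=name,
                        condition=condition,
                        object_id="interface0",
                        ratio=q.ratio,
                        membrane=float(np.mean([m for m, _, _ in q.per_line])),
                        lumen=float(np.mean([l for _, l, _ in q.per_line])),
                        background=bg,
                        rule="/".join(sorted(rules)),
                    )
                )
            except (ValueError, GeometryError) as exc:
                errors.append(f"{name}: {exc}")
        for j, (center, radius) in enumerate(ann.vesicles if not ann.lines else []):
            try:
                q = periphery_ratio(
                    image,
                    center,
                    radius,
                    lumen_fraction=ann.lumen_fraction,
                    background_region=ann.background_region,
                )
                rows.append(
                    dict(
                        image=name,
                        condition=condition,
                        object_id=f"vesicle{j}",
                        ratio=q.ratio,
                        membrane=q.periphery_mean,
                        lumen=q.lumen_mean,
                        background=q.background_mean,
                        rule="periphery",
                    )
                )
            except (ValueError, GeometryError) as exc:
                errors.append(f"{name}/vesicle{j}: {exc}")
    columns = [
        "image", "condition", "object_id", "ratio",
        "membrane", "lumen", "background", "rule",
    ]
    return pd.DataFrame(rows, columns=columns), errors
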