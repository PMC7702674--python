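"""Skull-roof trait extraction from binary cross-section masks.

Six traits are computed per specimen from eight transverse cross-sections
(two per roofing bone: premaxilla, nasal, frontal, parietal), their
positions along the anteroposterior cranial profile, and three linear skull
dimensions:

* ``c``   — mean bone compactness: bone pixels over pixels inside the outer
  bone boundary, averaged over the eight sections (fraction in [0, 1]).
* ``d``   — thickness integral: the integral over profile positions
  s in [0, 0.5] of relative thickness d_rel = mean local thickness / dia x 100.
* ``ovl`` — mean anteroposterior overlap of the three neighbouring bone
  pairs, from the signed distance between flanking cross-sections:
  ovl[%] = 100 * (2/3 - 2 Delta / (L_A + L_B)).
* ``rfp`` — frontal length / parietal length.
* ``elo`` — cranial elongation l_cran / dia.
* ``dia`` — qualifying skull diameter sqrt(w_cran * h_cran), the size proxy.

Local thickness follows the Hildebrand-Ruegsegger construction in 2D: the
value at a pixel is the diameter of the largest inscribed disc containing
it, computed after morphological filling of interior cavities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

BONES = ("premaxilla", "nasal", "frontal", "parietal")

__all__ = [
    "BONES",
    "SectionMask",
    "CranialProfile",
    "BoneSpan",
    "SkullDimensions",
    "ThicknessProfile",
    "TraitVector",
    "compactness",
    "local_thickness_map",
    "mean_thickness",
    "build_profile",
    "overlap",
    "scalar_traits",
    "thickness_integral",
    "log_compactness",
    "loess_profile",
    "specimen_traits",
    "binarize_otsu",
]


@dataclass
class SectionMask:
    """Binary raster of one bone cross-section (foreground = bone tissue)."""

    raster: np.ndarray
    pixel_size: float
    bone: str = "frontal"
    section_index: int = 1

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster).astype(bool)
        if self.raster.ndim != 2:
            raise ValueError("raster must be 2D")
        if not self.raster.any():
            raise ValueError("empty mask: no foreground pixels")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be strictly positive")
        if self.bone not in BONES:
            raise ValueError(f"bone must be one of {BONES}")
        if self.section_index not in (1, 2):
            raise ValueError("section_index must be 1 or 2")


@dataclass
class CranialProfile:
    """Piecewise-linear anteroposterior profile of the skull roof.

    Landmarks run from the anterior premaxilla limit through the eight
    section intersections to the posterior parietal limit; ``s`` holds the
    normalised cumulative chord length of each landmark in [0, 1].
    """

    landmarks: np.ndarray
    s: np.ndarray
    total_length: float

    def position_mm(self, s: float) -> float:
        return s * self.total_length


@dataclass
class BoneSpan:
    """Anteroposterior extent of one roofing bone on the profile."""

    bone: str
    length_mm: float
    s1: float
    s2: float

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError("bone length must be positive")
        if not self.s1 < self.s2:
            raise ValueError("s1 must precede s2")


@dataclass
class SkullDimensions:
    l_cran: float
    w_cran: float
    h_cran: float

    def __post_init__(self) -> None:
        if min(self.l_cran, self.w_cran, self.h_cran) <= 0:
            raise ValueError("skull dimensions must be strictly positive")


@dataclass
class ThicknessProfile:
    positions: np.ndarray
    d_abs: np.ndarray
    d_rel: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.d_abs = np.asarray(self.d_abs, dtype=float)
        self.d_rel = np.asarray(self.d_rel, dtype=float)
        if not (len(self.positions) == len(self.d_abs) == len(self.d_rel)):
            raise ValueError("profile arrays must share length")
        if np.any(self.d_abs < 0) or np.any(self.d_rel < 0):
            raise ValueError("thickness must be non-negative")


@dataclass
class TraitVector:
    """Per-taxon trait record; missing lists sections absent from input."""

    taxon: str
    c: float
    d: float
    ovl: float
    rfp: float
    elo: float
    dia: float
    c_log: float | None = None
    lifestyle: str = "unknown"
    missing: list[str] = field(default_factory=list)


# -- pixel-level operations ----------------------------------------------

# Hole filling uses 4-connected background (scipy's default cross-shaped
# structuring element): cavities are background regions not 4-connected to
# the raster border.


def _filled(raster: np.ndarray) -> np.ndarray:
    return ndimage.binary_fill_holes(raster)


def compactness(mask: SectionMask) -> float:
    """Bone pixels / pixels inside the filled outer boundary, in (0, 1]."""
    fg = mask.raster
    filled = _filled(fg)
    return float(fg.sum()) / float(filled.sum())


def local_thickness_map(raster: np.ndarray) -> np.ndarray:
    """2D local thickness (pixels) of a binary shape.

    Each foreground pixel gets the diameter of the largest inscribed disc
    containing it.  A disc centred at c with radius EDT(c) (the Euclidean
    distance to the nearest background pixel) covers the pixels strictly
    closer than its radius; processing candidate centres from the largest
    radius down, a single dilation pass per distinct radius assigns every
    still-unlabelled covered pixel.
    """
    fg = np.asarray(raster).astype(bool)
    edt = ndimage.distance_transform_edt(fg)
    out = np.zeros(fg.shape)
    radii = np.unique(edt[fg])[::-1]
    for r in radii:
        if r <= 0:
            continue
        centers = edt == r
        rad = int(math.ceil(r))
        yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
        foot = (yy * yy + xx * xx) < r * r
        covered = ndimage.binary_dilation(centers, structure=foot)
        newly = covered & fg & (out == 0)
        out[newly] = 2.0 * r
    return out


def mean_thickness(mask: SectionMask) -> float:
    """Mean local thickness in mm, after filling interior cavities."""
    filled = _filled(mask.raster)
    lt = local_thickness_map(filled)
    return float(lt[filled].mean()) * mask.pixel_size


def binarize_otsu(gray: np.ndarray) -> np.ndarray:
    """Convenience Otsu binarisation for greyscale section images."""
    from skimage.filters import threshold_otsu

    g = np.asarray(gray, dtype=float)
    return g > threshold_otsu(g)


# -- profile and scalar traits -------------------------------------------


def build_profile(landmarks) -> CranialProfile:
    """Normalised cumulative chord length along an ordered landmark polyline."""
    pts = np.atleast_2d(np.asarray(landmarks, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 landmarks")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("duplicated consecutive landmarks (zero-length segment)")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    return CranialProfile(landmarks=pts, s=cum / total, total_length=float(total))


def overlap(a, b, delta: float) -> float:
    """Anteroposterior overlap [%] of neighbouring bones A (anterior) and B.

    ``delta`` is the SIGNED distance (mm, along the profile) from A's
    posterior cross-section (at 2/3 of L_A) to B's anterior cross-section
    (at 1/3 of L_B), positive when B's section lies posterior to A's.
    100% is a fully centred alignment; 0% is exact abutment of the bone
    limits.  No clamping: gaps give negative values.
    """
    L_a = a.length_mm if isinstance(a, BoneSpan) else float(a)
    L_b = b.length_mm if isinstance(b, BoneSpan) else float(b)
    if L_a + L_b <= 0:
        raise ValueError("bone lengths must sum to a positive value")
    return 100.0 * (2.0 / 3.0 - 2.0 * delta / (L_a + L_b))


def scalar_traits(dims: SkullDimensions, frontal: BoneSpan, parietal: BoneSpan):
    """(dia, elo, rfp) from skull dimensions and frontal/parietal lengths."""
    dia = math.sqrt(dims.w_cran * dims.h_cran)
    elo = dims.l_cran / dia
    rfp = frontal.length_mm / parietal.length_mm
    return dia, elo, rfp


def thickness_integral(profile: ThicknessProfile, upper: float = 0.5,
                       boundary: str = "extrapolate") -> float:
    """Integral of relative thickness over s in [0, upper].

    The measured points are joined by straight lines; to the left of the
    first section the curve is held constant at the first measurement
    (``boundary='extrapolate'``, the default) or the integral starts at the
    first section (``boundary='truncate'``).  The value at ``upper`` is
    linearly interpolated between the flanking sections.
    """
    s = np.asarray(profile.positions, dtype=float)
    d = np.asarray(profile.d_rel, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 measurement positions")
    if np.any(np.diff(s) <= 0):
        raise ValueError("positions must be strictly increasing")
    if s[0] > upper:
        raise ValueError(f"no section at or below s = {upper}")
    # grid of knots restricted to [lo, upper]
    lo = 0.0 if boundary == "extrapolate" else float(s[0])
    if boundary not in ("extrapolate", "truncate"):
        raise ValueError("boundary must be 'extrapolate' or 'truncate'")
    knots = np.concatenate([[lo], s[(s > lo) & (s < upper)], [upper]])
    vals = np.interp(knots, s, d)  # constant beyond the measured range
    return float(np.trapezoid(vals, knots))


def log_compactness(c_percent) -> float:
    """Resolving transform for compactness crowded against 100%.

    c_log = -log10((105 - c) / 105) with c in percent.  The 5% horizontal
    dilation avoids the asymptote at 100%; the transform is strictly
    monotone on [0, 100] and maps 0 to 0.
    """
    c = np.asarray(c_percent, dtype=float)
    if np.any(c > 105) or np.any(c < 0):
        raise ValueError("compactness must lie in [0, 105] percent")
    out = -np.log10((105.0 - c) / 105.0)
    return float(out) if out.ndim == 0 else out


def loess_profile(positions, values, span: float = 0.75, n_grid: int = 101):
    """LOESS (tricube local-linear) smoother on a regular grid over [0, 1].

    Used for the per-lifestyle compactness/thickness profile curves.
    Returns (grid, fitted).
    """
    import statsmodels.api as sm

    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if span * len(x) < 2:
        raise ValueError("span covers fewer points than a local linear fit needs")
    grid = np.linspace(0.0, 1.0, n_grid)
    fitted = sm.nonparametric.lowess(y, x, frac=span, it=0, xvals=grid)
    return grid, fitted


# -- specimen orchestration ----------------------------------------------

_NEIGHBOUR_PAIRS = (("premaxilla", "nasal"), ("nasal", "frontal"),
                    ("frontal", "parietal"))


def specimen_traits(
    taxon: str,
    masks: dict[tuple[str, int], SectionMask],
    profile: CranialProfile,
    spans: dict[str, BoneSpan],
    dims: SkullDimensions,
    lifestyle: str = "unknown",
    boundary: str = "extrapolate",
) -> TraitVector:
    """Full trait vector for one specimen.

    ``masks`` maps (bone, section_index) to its SectionMask; ``spans`` maps
    bone name to its BoneSpan (profile positions of the two sections and the
    bone length).  Missing sections are tolerated: compactness and the
    thickness profile use the available sections and the absent ones are
    recorded in ``missing``.
    """
    missing = [f"{b}{i}" for b in BONES for i in (1, 2) if (b, i) not in masks]

    comp = [compactness(m) for m in masks.values()]
    c = float(np.mean(comp))

    dia, elo, rfp = scalar_traits(dims, spans["frontal"], spans["parietal"])

    # thickness profile over available sections, ordered along the profile
    sec_entries = []
    for (bone, idx), m in masks.items():
        s_pos = spans[bone].s1 if idx == 1 else spans[bone].s2
        sec_entries.append((s_pos, mean_thickness(m)))
    sec_entries.sort()
    pos = np.array([e[0] for e in sec_entries])
    d_abs = np.array([e[1] for e in sec_entries])
    tprof = ThicknessProfile(positions=pos, d_abs=d_abs,
                             d_rel=d_abs / dia * 100.0)
    d = thickness_integral(tprof, boundary=boundary)

    ovls = []
    for ba, bb in _NEIGHBOUR_PAIRS:
        if ba in spans and bb in spans:
            delta = profile.position_mm(spans[bb].s1) - profile.position_mm(spans[ba].s2)
            ovls.append(overlap(spans[ba], spans[bb], delta))
    ovl = float(np.mean(ovls)) if ovls else float("nan")

    return TraitVector(
        taxon=taxon, c=c, d=d, ovl=ovl, rfp=rfp, elo=elo, dia=dia,
        c_log=log_compactness(100.0 * c), lifestyle=lifestyle, missing=missing,
    )
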