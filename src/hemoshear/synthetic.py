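"""Synthetic hemodynamic cohorts and ground-truthed endothelium images.

Two generators make every stage of the package testable without any
measurement data:

* :func:`generate_cohort` draws per-animal hemodynamic records (diameter,
  maximal velocity, hematocrit, whole-blood viscosity, heart rate) from
  truncated normal distributions whose default means and SDs are the
  published male/female diastole/systole group statistics. An optional
  coupling mode draws whole-blood viscosity from the hematocrit regression
  line plus Gaussian noise scaled to a target R².

* :func:`generate_endothelium_image` renders a two-channel 8-bit field of
  elliptical nuclei with nearby Golgi blobs placed at controlled angles to
  a given flow direction over Gaussian background noise, and returns the
  exact ground truth (class, N-G vector, axes) for every cell. Default
  geometry matches the acquisition setup (160 × 160 µm field, 78 nm
  pixels).

Both are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage import draw

from . import defaults
from .errors import DomainError, PackingError
from .polarity import EndotheliumImage

__all__ = ["CohortSpec", "ImageSpec", "generate_cohort", "generate_endothelium_image"]

SEXES = ("male", "female")
PHASES = ("diastole", "systole")


def _table1_diameter() -> dict:
    return {
        ("male", "diastole"): (0.387, 0.05),
        ("male", "systole"): (0.484, 0.05),
        ("female", "diastole"): (0.376, 0.04),
        ("female", "systole"): (0.466, 0.05),
    }


def _table1_vmax() -> dict:
    return {
        ("male", "diastole"): (157.0, 43.0),
        ("male", "systole"): (999.0, 183.0),
        ("female", "diastole"): (167.0, 54.0),
        ("female", "systole"): (1015.0, 258.0),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Distributional spec of a synthetic cohort (defaults: the published
    group means ± SD for 8-week-old mice).

    ``viscosity_coupling`` replaces the independent ηb draw with the
    hematocrit-regression prediction plus Gaussian noise whose SD is set
    so the expected regression R² equals ``coupling_r2``.
    """

    n_per_group: int = 8
    diameter_mm: dict = field(default_factory=_table1_diameter)
    vmax_mm_s: dict = field(default_factory=_table1_vmax)
    hematocrit: dict = field(
        default_factory=lambda: {"male": (0.43, 0.02), "female": (0.43, 0.03)}
    )
    eta_b_cp: dict = field(
        default_factory=lambda: {"male": (4.1, 0.4), "female": (3.9, 0.6)}
    )
    eta_p_cp: dict = field(
        default_factory=lambda: {
            "male": defaults.ETA_P_MALE_CP,
            "female": defaults.ETA_P_FEMALE_CP,
        }
    )
    heart_rate_bpm: dict = field(
        default_factory=lambda: {"male": (455.0, 36.0), "female": (429.0, 62.0)}
    )
    viscosity_coupling: bool = False
    coupling_r2: float = 0.35

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise DomainError("n_per_group must be >= 1")
        for mapping in (self.diameter_mm, self.vmax_mm_s, self.hematocrit,
                        self.eta_b_cp, self.heart_rate_bpm):
            for mean, sd in mapping.values():
                if mean <= 0 or sd < 0:
                    raise DomainError("means must be positive and SDs >= 0")
        if not (0.0 < self.coupling_r2 < 1.0):
            raise DomainError("coupling_r2 must be in (0, 1)")


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    size: int,
    low: float = 0.0,
    high: float = np.inf,
) -> np.ndarray:
    if sd == 0.0:
        return np.full(size, mean)
    a, b = (low - mean) / sd, (high - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    spec: CohortSpec, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort; returns (records, group viscosities).

    ``records`` has one row per animal × phase with columns ``animal_id,
    sex, phase, diameter_mm, vmax_mm_s, hematocrit, eta_b_cP,
    heart_rate_bpm``; per-animal quantities (hematocrit, viscosity, heart
    rate) are shared between the two phases of an animal. ``groups`` maps
    sex to the pooled plasma viscosity. All physiological draws are
    normals truncated at zero (hematocrit also at one).
    """
    rng = np.random.default_rng(seed)
    record_rows = []
    for sex in SEXES:
        n = spec.n_per_group
        ht = _truncated_normal(rng, *spec.hematocrit[sex], n, high=1.0)
        if spec.viscosity_coupling:
            line_cp = (
                defaults.REGRESSION_SLOPE_PA_S * ht
                + defaults.REGRESSION_INTERCEPT_PA_S
            ) / defaults.CP_TO_PA_S
            # noise SD giving an expected regression R² of coupling_r2
            slope_cp = defaults.REGRESSION_SLOPE_PA_S / defaults.CP_TO_PA_S
            signal_sd = slope_cp * spec.hematocrit[sex][1]
            noise_sd = signal_sd * math.sqrt(
                (1.0 - spec.coupling_r2) / spec.coupling_r2
            )
            eta_b = np.maximum(line_cp + rng.normal(0.0, noise_sd, n), 0.1)
        else:
            eta_b = _truncated_normal(rng, *spec.eta_b_cp[sex], n)
        hr = _truncated_normal(rng, *spec.heart_rate_bpm[sex], n)
        for phase in PHASES:
            diameter = _truncated_normal(rng, *spec.diameter_mm[(sex, phase)], n)
            vmax = _truncated_normal(rng, *spec.vmax_mm_s[(sex, phase)], n)
            for i in range(n):
                record_rows.append(
                    {
                        "animal_id": f"{sex[0]}{i + 1:02d}",
                        "sex": sex,
                        "phase": phase,
                        "diameter_mm": diameter[i],
                        "vmax_mm_s": vmax[i],
                        "hematocrit": ht[i],
                        "eta_b_cP": eta_b[i],
                        "heart_rate_bpm": hr[i],
                    }
                )
    records = pd.DataFrame(record_rows)
    groups = pd.DataFrame(
        {"sex": list(SEXES), "eta_p_cP": [spec.eta_p_cp[s] for s in SEXES]}
    )
    return records, groups


# --------------------------------------------------------------------------
# endothelium images
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSpec:
    """Spec of a synthetic two-channel endothelium field.

    Defaults follow the acquisition geometry (160 × 160 µm at 78 nm
    pixels) with nucleus/Golgi sizes and N-G distances typical of mouse
    carotid endothelium. Foreground intensity must exceed the background
    mean by at least 6 background SDs so that any detection failure is a
    pipeline bug rather than an ambiguous image.
    """

    image_size_px: int = 2051
    pixel_size_um: float = defaults.PIXEL_SIZE_UM
    n_cells: int = 25
    #: (dromic, lateral, antidromic), summing to 1
    class_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    ng_length_um: tuple[float, float] = (5.0, 1.0)
    nucleus_major_um: tuple[float, float] = (11.0, 1.5)
    nucleus_minor_um: tuple[float, float] = (5.5, 0.8)
    golgi_area_um2: tuple[float, float] = (12.0, 3.0)
    background_grey: tuple[float, float] = (20.0, 5.0)
    foreground_intensity: float = 200.0
    flow_direction: tuple[float, float] = (1.0, 0.0)
    #: exact per-class cell counts (largest-remainder rounding) instead of
    #: multinomial sampling
    exact_class_counts: bool = True

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.image_size_px < 8:
            raise DomainError("invalid image geometry")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9 or min(self.class_fractions) < 0:
            raise DomainError("class_fractions must be non-negative and sum to 1")
        bg_mean, bg_sd = self.background_grey
        if self.foreground_intensity <= bg_mean + 6 * bg_sd:
            raise DomainError(
                "foreground intensity must exceed background mean + 6 SD"
            )
        if np.hypot(*self.flow_direction) == 0:
            raise DomainError("flow_direction must be non-zero")


def _class_counts(spec: ImageSpec, rng: np.random.Generator) -> np.ndarray:
    fractions = np.asarray(spec.class_fractions)
    if spec.exact_class_counts:
        # largest-remainder rounding to exact totals
        raw = fractions * spec.n_cells
        counts = np.floor(raw).astype(int)
        remainder = spec.n_cells - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:remainder]] += 1
        return counts
    return rng.multinomial(spec.n_cells, fractions)


_CLASS_INTERVALS = {
    "dromic": (0.0, defaults.DROMIC_MAX_DEG),
    "lateral": (defaults.DROMIC_MAX_DEG, defaults.LATERAL_MAX_DEG),
    "antidromic": (defaults.LATERAL_MAX_DEG, 180.0),
}
_CLASS_ORDER = ("dromic", "lateral", "antidromic")


def generate_endothelium_image(
    spec: ImageSpec, seed: int = 0
) -> tuple[EndotheliumImage, pd.DataFrame]:
    """Render one field and return (image, ground-truth table).

    Nuclei are filled ellipses at random in-plane orientation; each Golgi
    is a disk of the drawn area placed at the nucleus centre plus
    ng_length along a direction making the class-drawn angle with the
    flow. Nucleus centres are rejection-sampled with a minimum separation
    that prevents nucleus overlap and nearest-Golgi mispairing; an
    infeasible density raises :class:`PackingError`. N-G lengths are
    truncated at mean ± 2 SD so that a cell's own Golgi is always its
    nearest.
    """
    rng = np.random.default_rng(seed)
    size = spec.image_size_px
    px = spec.pixel_size_um
    field_um = size * px
    bg_mean, bg_sd = spec.background_grey

    counts = _class_counts(spec, rng)
    classes = np.repeat(_CLASS_ORDER, counts)
    classes = classes[rng.permutation(len(classes))]

    def _bounded(params: tuple[float, float], n: int, floor: float) -> np.ndarray:
        # size draws are truncated at mean ± 2 SD to keep the packing
        # geometry (and hence feasibility) bounded
        mean, sd = params
        return _truncated_normal(
            rng, mean, sd, n, low=max(mean - 2 * sd, floor), high=mean + 2 * sd
        )

    ng_mean, ng_sd = spec.ng_length_um
    ng_max = ng_mean + 2 * ng_sd
    majors = _bounded(spec.nucleus_major_um, spec.n_cells, 1e-3)
    minors = np.minimum(_bounded(spec.nucleus_minor_um, spec.n_cells, 1e-3), majors)
    golgi_areas = _bounded(spec.golgi_area_um2, spec.n_cells, 0.5)
    golgi_radii = np.sqrt(golgi_areas / math.pi)

    # minimum centre separation: no nucleus overlap (ellipses fit inside
    # circles of diameter = major axis), and strictly more than twice the
    # largest N-G length so every nucleus is nearest to its own Golgi
    max_major = float(majors.max()) if spec.n_cells else 0.0
    max_golgi_r = float(golgi_radii.max()) if spec.n_cells else 0.0
    min_sep = max(max_major * 1.05, 2.0 * ng_max + 0.5)
    margin = max_major / 2.0 + ng_max + max_golgi_r + 2 * px
    if spec.n_cells and field_um - 2 * margin <= 0:
        raise PackingError("field too small for the requested cell geometry")

    centers: list[tuple[float, float]] = []
    max_attempts = 2000 * max(spec.n_cells, 1)
    attempts = 0
    while len(centers) < spec.n_cells:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed {len(centers)}/{spec.n_cells} cells after "
                f"{max_attempts} attempts; reduce n_cells or cell size"
            )
        attempts += 1
        x, y = rng.uniform(margin, field_um - margin, 2)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_sep**2 for cx, cy in centers):
            centers.append((x, y))

    flow = np.asarray(spec.flow_direction, dtype=float)
    flow = flow / np.linalg.norm(flow)

    nucleus = np.zeros((size, size), dtype=float)
    golgi = np.zeros((size, size), dtype=float)
    truth_rows = []
    for i, (x_um, y_um) in enumerate(centers):
        theta = rng.uniform(*_CLASS_INTERVALS[classes[i]])
        sign = rng.choice([-1.0, 1.0])
        alpha = math.radians(sign * theta)
        direction = np.array(
            [
                flow[0] * math.cos(alpha) - flow[1] * math.sin(alpha),
                flow[0] * math.sin(alpha) + flow[1] * math.cos(alpha),
            ]
        )
        ng_len = float(
            _truncated_normal(
                rng, ng_mean, ng_sd, 1, low=max(ng_mean - 2 * ng_sd, 0.2), high=ng_max
            )[0]
        )
        gx_um, gy_um = x_um + ng_len * direction[0], y_um + ng_len * direction[1]

        orient = rng.uniform(0.0, math.pi)  # nucleus in-plane orientation
        rr, cc = draw.ellipse(
            y_um / px,
            x_um / px,
            (majors[i] / 2.0) / px,
            (minors[i] / 2.0) / px,
            shape=nucleus.shape,
            rotation=orient,
        )
        nucleus[rr, cc] = spec.foreground_intensity
        rr, cc = draw.disk(
            (gy_um / px, gx_um / px), golgi_radii[i] / px, shape=golgi.shape
        )
        golgi[rr, cc] = spec.foreground_intensity

        truth_rows.append(
            {
                "cell_id": i + 1,
                "nucleus_x_um": x_um,
                "nucleus_y_um": y_um,
                "nucleus_major_um": majors[i],
                "nucleus_minor_um": minors[i],
                "nucleus_elongation": majors[i] / minors[i],
                "nucleus_orientation_rad": orient,
                "golgi_x_um": gx_um,
                "golgi_y_um": gy_um,
                "golgi_area_um2": golgi_areas[i],
                "ng_length_um": ng_len,
                "angle_deg": theta,
                "orientation_class": classes[i],
            }
        )

    def _to_uint8(canvas: np.ndarray) -> np.ndarray:
        noisy = canvas + rng.normal(bg_mean, bg_sd, canvas.shape)
        return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    image = EndotheliumImage(
        nucleus_channel=_to_uint8(nucleus),
        golgi_channel=_to_uint8(golgi),
        pixel_size_um=px,
        flow_direction=tuple(flow),
    )
    columns = [
        "cell_id", "nucleus_x_um", "nucleus_y_um", "nucleus_major_um",
        "nucleus_minor_um", "nucleus_elongation", "nucleus_orientation_rad",
        "golgi_x_um", "golgi_y_um", "golgi_area_um2", "ng_length_um",
        "angle_deg", "orientation_class",
    ]
    truth = pd.DataFrame(truth_rows, columns=columns)
    return image, truth
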