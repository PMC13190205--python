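"""Synthetic field-trial generator.

Emulates the study design used throughout the package: a tomato field of
3 acres, each split into 10 zones, each zone represented by 3 sampled
plants (90 plants in total), scored on the six canonical traits.  Each
zone carries one condition class (Healthy / Mild / Severe); a plant's
perceptual trait vector is its class mean plus independent Gaussian
noise clipped to [0, 1].

Class means anchor to the reference trait intensities of healthy and
severely stressed plants (e.g. healthy LC 0.92 vs stressed 0.45, healthy
WI 0.12 vs stressed 0.91); mild-stress means sit at the per-trait
midpoints.  Noise standard deviations grow with severity
(0.05 / 0.10 / 0.16), so stressed zones are not just shifted but also
more heterogeneous - the property that makes within-zone kernel
similarity fall as stress rises.

The module also renders tiny synthetic leaf images with analytically
known area, colour and texture, used to validate the image-trait
extractors against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .encoding import CONDITIONS, TRAIT_CODES, RawTraitRecord

__all__ = [
    "HEALTHY_MEANS",
    "SEVERE_MEANS",
    "FieldDesign",
    "ConditionProfile",
    "balanced_field_design",
    "default_profiles",
    "generate_field",
    "synthetic_leaf_image",
]

#: Reference perceptual intensities per trait, healthy plants.
HEALTHY_MEANS: dict[str, float] = {
    "LC": 0.92,
    "LA": 0.88,
    "TU": 0.90,
    "VP": 0.85,
    "ES": 0.87,
    "WI": 0.12,
}

#: Reference perceptual intensities per trait, severely stressed plants.
SEVERE_MEANS: dict[str, float] = {
    "LC": 0.45,
    "LA": 0.41,
    "TU": 0.39,
    "VP": 0.72,
    "ES": 0.36,
    "WI": 0.91,
}

#: Default trait-noise standard deviations by condition.
DEFAULT_NOISE_SD: dict[str, float] = {"Healthy": 0.05, "Mild": 0.10, "Severe": 0.16}


@dataclass(frozen=True)
class ConditionProfile:
    """Mean intensity per trait and noise sd for one condition class."""

    condition: str
    means: tuple[float, ...]
    noise_sd: float

    def __post_init__(self) -> None:
        if len(self.means) != len(TRAIT_CODES):
            raise ValueError("profile must give one mean per canonical trait")
        if any(not (0.0 <= m <= 1.0) for m in self.means):
            raise ValueError("profile means must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def default_profiles(noise_scale: float = 1.0) -> dict[str, ConditionProfile]:
    """The calibrated condition profiles.

    Healthy and Severe means are the reference healthy/stressed trait
    intensities; Mild means are per-trait midpoints.  ``noise_scale``
    multiplies all three noise sds (used for robustness ablations).
    """
    healthy = tuple(HEALTHY_MEANS[c] for c in TRAIT_CODES)
    severe = tuple(SEVERE_MEANS[c] for c in TRAIT_CODES)
    mild = tuple((a + b) / 2.0 for a, b in zip(healthy, severe))
    means = {"Healthy": healthy, "Mild": mild, "Severe": severe}
    return {
        cond: ConditionProfile(
            condition=cond,
            means=means[cond],
            noise_sd=DEFAULT_NOISE_SD[cond] * noise_scale,
        )
        for cond in CONDITIONS
    }


@dataclass
class FieldDesign:
    """Field layout and zone->condition assignment.

    ``proportions`` gives the Healthy/Mild/Severe share of zones per
    acre (default 60/20/20, with at least one zone of each class);
    ``assignment`` may instead map (acre_index, zone_index) -> condition
    explicitly.
    """

    n_acres: int = 3
    zones_per_acre: int = 10
    plants_per_zone: int = 3
    proportions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    assignment: Mapping[tuple[int, int], str] | None = None

    def __post_init__(self) -> None:
        if min(self.n_acres, self.zones_per_acre, self.plants_per_zone) < 1:
            raise ValueError("all design counts must be >= 1")
        if self.assignment is None:
            if abs(sum(self.proportions) - 1.0) > 1e-9:
                raise ValueError("condition proportions must sum to 1")

    @property
    def n_plants(self) -> int:
        return self.n_acres * self.zones_per_acre * self.plants_per_zone

    def zone_conditions(self, rng: np.random.Generator) -> dict[tuple[int, int], str]:
        """Assign one condition per zone.

        With proportions: per acre, zone counts are the rounded shares
        (each class forced to >= 1 where the acre has >= 3 zones), and
        the per-acre order of conditions is shuffled by ``rng``.
        """
        if self.assignment is not None:
            out = dict(self.assignment)
            for a in range(self.n_acres):
                for z in range(self.zones_per_acre):
                    if (a, z) not in out:
                        raise ValueError(f"assignment is missing zone ({a}, {z})")
            return out
        nz = self.zones_per_acre
        counts = [int(round(p * nz)) for p in self.proportions]
        if nz >= len(CONDITIONS):
            counts = [max(1, c) for c in counts]
        # repair rounding drift against the largest class
        while sum(counts) > nz:
            counts[int(np.argmax(counts))] -= 1
        while sum(counts) < nz:
            counts[int(np.argmin(counts))] += 1
        out = {}
        for a in range(self.n_acres):
            labels = [c for cond, k in zip(CONDITIONS, counts) for c in [cond] * k]
            rng.shuffle(labels)
            for z, cond in enumerate(labels):
                out[(a, z)] = cond
        return out


def balanced_field_design(
    n_acres: int = 3,
    zones_per_acre: int = 10,
    plants_per_zone: int = 3,
) -> FieldDesign:
    """A design with an exactly balanced zone->condition assignment.

    Zones per acre are split as evenly as possible between the three
    conditions, rotating which condition receives the remainder across
    acres, so the field-level class counts are exactly equal whenever
    ``n_acres * zones_per_acre`` is divisible by three (the default
    3 x 10 gives 10 zones, hence 30 plants, per condition).
    """
    base, rem = divmod(zones_per_acre, len(CONDITIONS))
    assignment: dict[tuple[int, int], str] = {}
    for a in range(n_acres):
        counts = [base] * len(CONDITIONS)
        for k in range(rem):
            counts[(a + k) % len(CONDITIONS)] += 1
        labels = [c for cond, k in zip(CONDITIONS, counts) for c in [cond] * k]
        for z, cond in enumerate(labels):
            assignment[(a, z)] = cond
    return FieldDesign(
        n_acres=n_acres,
        zones_per_acre=zones_per_acre,
        plants_per_zone=plants_per_zone,
        assignment=assignment,
    )


def generate_field(
    design: FieldDesign | None = None,
    profiles: Mapping[str, ConditionProfile] | None = None,
    seed: int = 0,
) -> list[RawTraitRecord]:
    """Generate one labelled synthetic field.

    Each plant's trait vector is its zone-condition mean plus iid
    Gaussian noise (condition sd), clipped to [0, 1].  Fully
    reproducible from ``seed``; the default design emits exactly
    3 x 10 x 3 = 90 records.
    """
    design = design or FieldDesign()
    profiles = profiles or default_profiles()
    rng = np.random.default_rng(seed)
    conditions = design.zone_conditions(rng)
    records: list[RawTraitRecord] = []
    for a in range(design.n_acres):
        acre_id = f"A{a + 1}"
        for z in range(design.zones_per_acre):
            zone_id = f"Z{z + 1}"
            cond = conditions[(a, z)]
            prof = profiles[cond]
            for r in range(design.plants_per_zone):
                noise = rng.normal(0.0, prof.noise_sd, size=len(TRAIT_CODES))
                vals = np.clip(np.asarray(prof.means) + noise, 0.0, 1.0)
                records.append(
                    RawTraitRecord(
                        plant_id=f"{acre_id}-{zone_id}-P{r + 1}",
                        zone_id=zone_id,
                        acre_id=acre_id,
                        values={c: float(v) for c, v in zip(TRAIT_CODES, vals)},
                        condition=cond,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Synthetic leaf images


def synthetic_leaf_image(
    canvas: tuple[int, int] = (256, 256),
    center: tuple[float, float] | None = None,
    radius: float = 50.0,
    axes_ratio: float = 1.0,
    color: tuple[int, int, int] = (40, 180, 60),
    background: tuple[int, int, int] = (30, 22, 15),
    noise_sd: float = 0.0,
    n_veins: int = 0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render an elliptical "leaf" with analytically known traits.

    Returns ``(image, mask, truth)`` where ``image`` is uint8 RGB,
    ``mask`` the exact boolean foreground, and ``truth`` holds the
    analytic area (pixels and fraction of canvas), mean colour, noise
    level and vein count.  ``axes_ratio`` is minor/major axis;
    ``noise_sd`` is additive Gaussian pixel noise (0-255 scale) on the
    leaf; ``n_veins`` darker radial lines add ridge-like texture.
    """
    h, w = canvas
    if h < 64 or w < 64:
        raise ValueError("canvas must be at least 64x64")
    if radius <= 0 or axes_ratio <= 0:
        raise ValueError("leaf shape must have positive area")
    cy, cx = center if center is not None else (h / 2.0, w / 2.0)
    yy, xx = np.mgrid[0:h, 0:w]
    ry, rx = radius, radius * axes_ratio
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    if not mask.any():
        raise ValueError("leaf falls entirely outside the canvas")

    rng = np.random.default_rng(seed)
    img = np.empty((h, w, 3), dtype=float)
    img[:] = background
    img[mask] = color
    if n_veins > 0:
        angles = np.linspace(0.0, np.pi, n_veins, endpoint=False)
        t = np.linspace(-1.0, 1.0, int(4 * max(ry, rx)))
        for ang in angles:
            vy = np.clip(np.round(cy + t * ry * np.sin(ang)).astype(int), 0, h - 1)
            vx = np.clip(np.round(cx + t * rx * np.cos(ang)).astype(int), 0, w - 1)
            on = mask[vy, vx]
            img[vy[on], vx[on]] = np.asarray(color) * 0.55
    if noise_sd > 0:
        img[mask] += rng.normal(0.0, noise_sd, size=(int(mask.sum()), 3))
    img = np.clip(img, 0, 255).astype(np.uint8)

    truth = {
        "area_px": int(mask.sum()),
        "area_analytic_px": float(np.pi * ry * rx),
        "area_fraction": float(mask.sum()) / (h * w),
        "mean_color": tuple(float(c) for c in color),
        "noise_sd": float(noise_sd),
        "n_veins": int(n_veins),
        "center": (float(cy), float(cx)),
        "radius": float(radius),
    }
    return img, mask, truth
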