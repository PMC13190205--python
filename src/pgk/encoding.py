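"""Perceptual encoding of raw plant traits.

Raw image-derived trait measurements live in heterogeneous physical units
(pixel counts, index values, sensor readings).  Before any graph can be
built they are mapped onto a common *perceptual intensity* scale in [0, 1]
by min-max normalisation over a reference cohort, and optionally
discretised into the qualitative states ``low`` / ``medium`` / ``high``
that mimic how an agronomist reads a plant at a glance.

The canonical trait set has six members, always in this order::

    LC  Leaf Colour          greenness / vegetation index
    LA  Leaf Area            segmented foreground area
    TU  Texture Uniformity   1 - normalised GLCM entropy
    VP  Vein Prominence      ridge-filter response density
    ES  Edge Sharpness       boundary gradient magnitude
    WI  Wilting Index        compactness loss (1 - solidity)

The order is load-bearing: it fixes the coordinates of the interaction
embedding used by the kernels, so every serialisation carries it
explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_CODES",
    "TRAIT_NAMES",
    "CONDITIONS",
    "STATES",
    "TraitDescriptor",
    "RawTraitRecord",
    "NormalizationModel",
    "PerceptualTraitVector",
    "PerceptualStateVector",
    "default_trait_set",
    "fit_normalization",
    "normalize",
    "discretize",
    "aggregate_zone",
    "read_trait_table",
    "write_trait_table",
]

#: Canonical trait codes, in canonical order.
TRAIT_CODES: tuple[str, ...] = ("LC", "LA", "TU", "VP", "ES", "WI")

TRAIT_NAMES: dict[str, str] = {
    "LC": "Leaf Colour",
    "LA": "Leaf Area",
    "TU": "Texture Uniformity",
    "VP": "Vein Prominence",
    "ES": "Edge Sharpness",
    "WI": "Wilting Index",
}

#: Plant condition classes.
CONDITIONS: tuple[str, ...] = ("Healthy", "Mild", "Severe")

#: Perceptual states, from weakest to strongest expression.
STATES: tuple[str, ...] = ("low", "medium", "high")

#: Default state thresholds (t_low, t_high) splitting [0, 1] into thirds.
DEFAULT_THRESHOLDS: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)


@dataclass(frozen=True)
class TraitDescriptor:
    """One trait in a registry: short code, readable name, position."""

    code: str
    name: str
    index: int


def default_trait_set() -> tuple[TraitDescriptor, ...]:
    """The canonical six-trait registry in canonical order."""
    return tuple(
        TraitDescriptor(code=c, name=TRAIT_NAMES[c], index=i)
        for i, c in enumerate(TRAIT_CODES)
    )


@dataclass
class RawTraitRecord:
    """One plant's raw trait measurements plus its field location.

    ``values`` maps trait code -> raw measurement; all canonical codes
    must be present and finite.  ``condition`` is the optional ground
    truth label (``Healthy`` / ``Mild`` / ``Severe``).
    """

    plant_id: str
    zone_id: str
    acre_id: str
    values: dict[str, float]
    condition: str | None = None

    def validate(self, traits: Sequence[str] = TRAIT_CODES) -> None:
        for code in traits:
            if code not in self.values:
                raise ValueError(
                    f"record for plant {self.plant_id!r} is missing trait {code!r}"
                )
            if not np.isfinite(self.values[code]):
                raise ValueError(
                    f"record for plant {self.plant_id!r} has non-finite value "
                    f"for trait {code!r}"
                )


@dataclass
class NormalizationModel:
    """Per-trait min/max fitted over a reference cohort.

    A trait whose cohort minimum equals its maximum is *degenerate*: it
    carries no contrast, and normalisation maps it to the neutral
    intensity 0.5.
    """

    traits: tuple[str, ...]
    minima: dict[str, float]
    maxima: dict[str, float]

    def degenerate(self, code: str) -> bool:
        return self.maxima[code] == self.minima[code]

    def to_dict(self) -> dict:
        return {
            "traits": list(self.traits),
            "min": {c: self.minima[c] for c in self.traits},
            "max": {c: self.maxima[c] for c in self.traits},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormalizationModel":
        traits = tuple(d["traits"])
        return cls(
            traits=traits,
            minima={c: float(d["min"][c]) for c in traits},
            maxima={c: float(d["max"][c]) for c in traits},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "NormalizationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PerceptualTraitVector:
    """Ordered vector of perceptual intensities p_i in [0, 1].

    ``source`` records whether the vector describes a single plant or a
    zone-level aggregate; ``zone_id`` is carried along so zone
    aggregation can refuse to mix zones.
    """

    owner_id: str
    intensities: np.ndarray
    traits: tuple[str, ...] = TRAIT_CODES
    source: str = "plant"
    zone_id: str | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.traits),):
            raise ValueError(
                f"expected {len(self.traits)} intensities, got shape "
                f"{self.intensities.shape}"
            )

    def intensity(self, code: str) -> float:
        return float(self.intensities[self.traits.index(code)])


@dataclass
class PerceptualStateVector:
    """Discretised perceptual states aligned with a trait vector."""

    owner_id: str
    states: tuple[str, ...]
    thresholds: tuple[float, float]
    traits: tuple[str, ...] = TRAIT_CODES


def fit_normalization(
    records: Iterable[RawTraitRecord],
    traits: Sequence[str] = TRAIT_CODES,
) -> NormalizationModel:
    """Fit per-trait min/max extrema over ``records``.

    Raises ``ValueError`` on an empty collection or when any record is
    missing a trait (the error names the trait and the plant).
    """
    records = list(records)
    if not records:
        raise ValueError("cannot fit a normalisation model on zero records")
    for rec in records:
        rec.validate(traits)
    minima: dict[str, float] = {}
    maxima: dict[str, float] = {}
    for code in traits:
        col = [rec.values[code] for rec in records]
        minima[code] = float(min(col))
        maxima[code] = float(max(col))
    return NormalizationModel(traits=tuple(traits), minima=minima, maxima=maxima)


def normalize(model: NormalizationModel, record: RawTraitRecord) -> PerceptualTraitVector:
    """Map raw values onto perceptual intensities.

    p_i = (x_i - min_i) / (max_i - min_i), clamped to [0, 1] for values
    outside the fitted range (held-out data may exceed the training
    extrema).  Degenerate traits map to the neutral 0.5.
    """
    record.validate(model.traits)
    out = np.empty(len(model.traits))
    for i, code in enumerate(model.traits):
        lo, hi = model.minima[code], model.maxima[code]
        if hi == lo:
            out[i] = 0.5
        else:
            out[i] = np.clip((record.values[code] - lo) / (hi - lo), 0.0, 1.0)
    return PerceptualTraitVector(
        owner_id=record.plant_id,
        intensities=out,
        traits=model.traits,
        source="plant",
        zone_id=record.zone_id,
    )


def discretize(
    vector: PerceptualTraitVector,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> PerceptualStateVector:
    """Assign low/medium/high states by fixed cuts.

    p < t_low -> low; t_low <= p < t_high -> medium; p >= t_high -> high.
    Both interval lower bounds are inclusive, so p == t_low is medium and
    p == t_high is high.
    """
    t_low, t_high = thresholds
    if not (0.0 < t_low < t_high < 1.0):
        raise ValueError(
            f"thresholds must satisfy 0 < t_low < t_high < 1, got {thresholds}"
        )
    states = tuple(
        "low" if p < t_low else ("medium" if p < t_high else "high")
        for p in vector.intensities
    )
    return PerceptualStateVector(
        owner_id=vector.owner_id,
        states=states,
        thresholds=(t_low, t_high),
        traits=vector.traits,
    )


def empirical_thresholds(
    vectors: Sequence[PerceptualTraitVector],
) -> dict[str, tuple[float, float]]:
    """Per-trait empirical tertiles, an alternative to the fixed cuts."""
    if not vectors:
        raise ValueError("need at least one vector to estimate tertiles")
    traits = vectors[0].traits
    mat = np.stack([v.intensities for v in vectors])
    out = {}
    for i, code in enumerate(traits):
        q1, q2 = np.quantile(mat[:, i], [1.0 / 3.0, 2.0 / 3.0])
        out[code] = (float(q1), float(q2))
    return out


def aggregate_zone(vectors: Sequence[PerceptualTraitVector]) -> PerceptualTraitVector:
    """Average plant-level vectors of one zone into a zone-level vector."""
    vectors = list(vectors)
    if not vectors:
        raise ValueError("cannot aggregate an empty collection of vectors")
    zones = {v.zone_id for v in vectors}
    if len(zones) > 1:
        raise ValueError(f"cannot aggregate vectors from mixed zones: {sorted(map(str, zones))}")
    traits = vectors[0].traits
    if any(v.traits != traits for v in vectors):
        raise ValueError("all vectors must share the same trait set")
    mean = np.mean([v.intensities for v in vectors], axis=0)
    zone = vectors[0].zone_id or vectors[0].owner_id
    return PerceptualTraitVector(
        owner_id=str(zone),
        intensities=mean,
        traits=traits,
        source="zone",
        zone_id=vectors[0].zone_id,
    )


# ---------------------------------------------------------------------------
# Trait-table I/O (CSV)

_TABLE_COLUMNS = ["plant_id", "zone_id", "acre_id", *TRAIT_CODES]


def read_trait_table(path: str | Path) -> list[RawTraitRecord]:
    """Read the standard trait-table CSV into records.

    Expected columns: plant_id, zone_id, acre_id, LC, LA, TU, VP, ES, WI
    and optionally condition.  Header required.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table {path} is missing columns: {missing}")
    has_condition = "condition" in df.columns
    records = []
    for _, row in df.iterrows():
        condition = None
        if has_condition and not pd.isna(row["condition"]):
            condition = str(row["condition"])
        records.append(
            RawTraitRecord(
                plant_id=str(row["plant_id"]),
                zone_id=str(row["zone_id"]),
                acre_id=str(row["acre_id"]),
                values={c: float(row[c]) for c in TRAIT_CODES},
                condition=condition,
            )
        )
    return records


def write_trait_table(records: Sequence[RawTraitRecord], path: str | Path) -> None:
    """Write records to the standard trait-table CSV."""
    rows = []
    for rec in records:
        row = {
            "plant_id": rec.plant_id,
            "zone_id": rec.zone_id,
            "acre_id": rec.acre_id,
            **{c: rec.values[c] for c in TRAIT_CODES},
        }
        if rec.condition is not None:
            row["condition"] = rec.condition
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
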