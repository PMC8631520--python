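"""Feature-name registry: the single source of truth for the 314 features.

Names follow the MaZda-style convention used in the clinical radiomics
literature: histogram names like ``Perc.90%``, co-occurrence names like
``S(0,0,1)AngScMom`` (the parenthesized triple is the voxel offset in
(row, column, slice) order, distance folded into the offset), run-length
names like ``Z_GLevNonU`` (direction prefix + statistic), and gradient names
``GrMean`` ... ``GrNonZeros``.

Gray levels are 1-based (1..Ng) throughout, matching the index arithmetic of
the classical co-occurrence / run-length formulas.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import pandas as pd

HISTOGRAM_FEATURES = (
    "Mean",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Perc.01%",
    "Perc.10%",
    "Perc.50%",
    "Perc.90%",
    "Perc.99%",
)

GLCM_STATISTICS = (
    "AngScMom",
    "Contrast",
    "Correlat",
    "SumOfSqs",
    "InvDfMom",
    "SumAverg",
    "SumVarnc",
    "SumEntrp",
    "Entropy",
    "DifVarnc",
    "DifEntrp",
)

#: Base co-occurrence offsets in (row, column, slice) order: the three axes
#: plus the two in-plane diagonals.  Scaled by distances 1..5.
GLCM_BASE_OFFSETS = (
    (0, 0, 1),
    (1, 0, 0),
    (0, 1, 0),
    (1, 1, 0),
    (1, -1, 0),
)

GLCM_DISTANCES = (1, 2, 3, 4, 5)

RLM_STATISTICS = ("RLNonUni", "GLevNonU", "LngREmph", "ShrtREmp", "Fraction")

#: Run directions as (prefix, offset in (row, column, slice) order).
RLM_DIRECTIONS = (
    ("Z", (0, 0, 1)),
    ("Horzl", (0, 1, 0)),
    ("Vertl", (1, 0, 0)),
    ("45dgr", (1, 1, 0)),
    ("135dr", (1, -1, 0)),
)

GRADIENT_FEATURES = ("GrMean", "GrVariance", "GrSkewness", "GrKurtosis", "GrNonZeros")


def glcm_feature_name(offset: tuple[int, int, int], statistic: str) -> str:
    a, b, c = offset
    return f"S({a},{b},{c}){statistic}"


def rlm_feature_name(prefix: str, statistic: str) -> str:
    return f"{prefix}_{statistic}"


@dataclass(frozen=True)
class FeatureInfo:
    name: str
    family: str  # histogram | glcm | rlm | gradient
    statistic: str
    offset: tuple[int, int, int] | None = None
    distance: int | None = None
    direction: str | None = None


def build_registry() -> list[FeatureInfo]:
    """Ordered inventory of the default 314-feature configuration."""
    entries: list[FeatureInfo] = []
    for name in HISTOGRAM_FEATURES:
        entries.append(FeatureInfo(name=name, family="histogram", statistic=name))
    for distance in GLCM_DISTANCES:
        for base in GLCM_BASE_OFFSETS:
            offset = tuple(distance * o for o in base)
            for stat in GLCM_STATISTICS:
                entries.append(
                    FeatureInfo(
                        name=glcm_feature_name(offset, stat),
                        family="glcm",
                        statistic=stat,
                        offset=offset,
                        distance=distance,
                    )
                )
    for prefix, _offset in RLM_DIRECTIONS:
        for stat in RLM_STATISTICS:
            entries.append(
                FeatureInfo(
                    name=rlm_feature_name(prefix, stat),
                    family="rlm",
                    statistic=stat,
                    direction=prefix,
                )
            )
    for name in GRADIENT_FEATURES:
        entries.append(FeatureInfo(name=name, family="gradient", statistic=name))
    return entries


REGISTRY: list[FeatureInfo] = build_registry()
FEATURE_NAMES: tuple[str, ...] = tuple(e.name for e in REGISTRY)


def registry_table() -> pd.DataFrame:
    """The registry as a DataFrame, exportable to CSV for provenance."""
    return pd.DataFrame(
        {
            "name": [e.name for e in REGISTRY],
            "family": [e.family for e in REGISTRY],
            "statistic": [e.statistic for e in REGISTRY],
            "offset": [
                "" if e.offset is None else f"{e.offset[0]},{e.offset[1]},{e.offset[2]}"
                for e in REGISTRY
            ],
            "distance": ["" if e.distance is None else e.distance for e in REGISTRY],
            "direction": ["" if e.direction is None else e.direction for e in REGISTRY],
        }
    )


def registry_hash() -> str:
    """Stable short hash of the feature inventory (embedded in --version)."""
    payload = "\n".join(FEATURE_NAMES).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
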