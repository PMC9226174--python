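"""Canonical per-cell feature schema for multiplexed-IHC cell tables.

Each segmented cell carries 35 node attributes: five optical features for
each of six stained biomarkers (DAPI, PD-L1, CD68, Foxp3, CD8, Pan-CK) plus
five whole-cell morphology features.  The three ``positive*`` attributes per
biomarker are Boolean thresholding calls stored as 0/1; intensities and
morphology are non-negative reals.  Coordinates are pixel units at
0.5 µm/pixel, origin top-left, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BIOMARKERS: tuple[str, ...] = ("dapi", "pdl1", "cd68", "foxp3", "cd8", "panck")

OPTICAL_KINDS: tuple[str, ...] = (
    "positive",
    "positive_nucleus",
    "positive_cytoplasm",
    "nucleus_intensity",
    "cytoplasm_intensity",
)

#: per-biomarker optical kinds that are Boolean thresholding calls
BOOLEAN_KINDS: tuple[str, ...] = ("positive", "positive_nucleus", "positive_cytoplasm")

MORPHOLOGY: tuple[str, ...] = (
    "cell_area",
    "cytoplasm_area",
    "nucleus_area",
    "nucleus_perimeter",
    "nucleus_roundness",
)

COORD_COLUMNS: tuple[str, str] = ("x", "y")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered 35-column node-attribute schema (6 biomarkers x 5 optical + 5 morphology)."""

    biomarkers: tuple[str, ...] = BIOMARKERS
    optical_kinds: tuple[str, ...] = OPTICAL_KINDS
    morphology: tuple[str, ...] = MORPHOLOGY
    header_map: dict[str, str] = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        names = [f"{m}_{k}" for m in self.biomarkers for k in self.optical_kinds]
        names.extend(self.morphology)
        return names

    @property
    def boolean_features(self) -> list[str]:
        return [f"{m}_{k}" for m in self.biomarkers for k in BOOLEAN_KINDS]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def columns(self) -> list[str]:
        """Full table header: two coordinate columns plus the 35 features."""
        return list(COORD_COLUMNS) + self.feature_names

    def feature_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None

    def group_columns(self, group: str) -> list[int]:
        """Feature indices for an ablation group: a biomarker name or 'morphology'."""
        if group == "morphology":
            return [self.feature_names.index(m) for m in self.morphology]
        if group in self.biomarkers:
            return [
                self.feature_names.index(f"{group}_{k}") for k in self.optical_kinds
            ]
        raise KeyError(
            f"unknown feature group {group!r}; expected one of "
            f"{list(self.biomarkers) + ['morphology']}"
        )


#: ablation groups partitioning the 35 features into 7 blocks of 5 columns
FEATURE_GROUPS: tuple[str, ...] = BIOMARKERS + ("morphology",)

DEFAULT_SCHEMA = FeatureSchema()
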