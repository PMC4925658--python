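"""Canonical feature index for regional cortical morphometry tables.

The default parcellation is the Desikan-Killiany-Tourville (DKT) cortical
atlas with 31 structures per hemisphere.  For each (hemisphere, region) five
surface-based measures are tabulated — white surface area (mm^2), gray-matter
volume (mm^3), average cortical thickness (mm), thickness standard deviation
(mm) and integrated rectified mean curvature (mm^-1) — plus, per hemisphere,
the total white-surface area and the cortex mean thickness, giving the
canonical 314-component feature vector (62 regions x 5 measures + 4 globals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: The 31 DKT cortical structures of one hemisphere, alphabetical.
DKT_REGIONS: tuple[str, ...] = (
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "transversetemporal",
)

#: Measure names in canonical order.
MEASURES: tuple[str, ...] = ("Area", "Volume", "Thickness", "ThicknessStd", "MeanCurv")

HEMISPHERES: tuple[str, ...] = ("lh", "rh")

#: Global (whole-hemisphere) entries appended after the regional block of each
#: hemisphere: (pseudo-region name, measure it is reported with).
GLOBAL_ENTRIES: tuple[tuple[str, str], ...] = (
    ("WhiteSurfArea", "Area"),
    ("MeanThickness", "Thickness"),
)

#: Units of each measure, for documentation and reports.
MEASURE_UNITS: dict[str, str] = {
    "Area": "mm^2",
    "Volume": "mm^3",
    "Thickness": "mm",
    "ThicknessStd": "mm",
    "MeanCurv": "mm^-1",
}


def feature_name(hemisphere: str, region: str, measure: str) -> str:
    return f"{hemisphere}_{region}_{measure}"


@dataclass(frozen=True)
class FeatureIndex:
    """Ordered canonical index of morphometric features.

    Ordering is hemisphere-major (lh before rh); within a hemisphere the
    regions are alphabetical with measures in the fixed canonical order, and
    the hemisphere's global entries (WhiteSurfArea, MeanThickness) close the
    block.  The ordering is a pure function of the label set: permuting the
    input regions or measures does not change the resulting index.
    """

    entries: tuple[tuple[str, str, str], ...] = field(default=())

    @classmethod
    def build(
        cls,
        regions: Sequence[str] = DKT_REGIONS,
        measures: Sequence[str] = MEASURES,
        include_global: bool = True,
    ) -> "FeatureIndex":
        regions = sorted(set(regions))
        measures = [m for m in MEASURES if m in set(measures)]
        if not measures:
            raise ValueError("measure list is empty")
        entries: list[tuple[str, str, str]] = []
        for hemi in HEMISPHERES:
            for region in regions:
                for measure in measures:
                    entries.append((hemi, region, measure))
            if include_global:
                for region, measure in GLOBAL_ENTRIES:
                    if measure in measures:
                        entries.append((hemi, region, measure))
        return cls(entries=tuple(entries))

    @classmethod
    def default(cls) -> "FeatureIndex":
        return cls.build()

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return [feature_name(*e) for e in self.entries]

    def positions(self, selector) -> list[int]:
        """Indices of entries for which ``selector(hemi, region, measure)`` is true."""
        return [i for i, e in enumerate(self.entries) if selector(*e)]

    def subset(self, measure: str | None = None, hemisphere: str | None = None) -> "FeatureIndex":
        if hemisphere is not None and hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {hemisphere!r}; expected one of {HEMISPHERES}")
        kept = tuple(
            e
            for e in self.entries
            if (measure is None or e[2] == measure) and (hemisphere is None or e[0] == hemisphere)
        )
        return FeatureIndex(entries=kept)

    def position_of(self, hemisphere: str, region: str, measure: str) -> int:
        return self.entries.index((hemisphere, region, measure))


def validate_unique(names: Iterable[str]) -> None:
    seen = set()
    for n in names:
        if n in seen:
            raise ValueError(f"duplicate feature name {n!r}")
        seen.add(n)
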