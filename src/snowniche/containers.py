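"""Core vocabulary and containers shared across the pipeline.

The study design is a seasonal time series over a mountain watershed:
two sampling locations (an upland hillslope and a riparian floodplain),
three soil depth classes, and four sampling dates bracketing the winter
snowpack — autumn (September), peak snow (March), mid-snowmelt (May),
and post-snowmelt spring (June).  Abundances are always within-sample
relative abundances (proportions).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Location",
    "Depth",
    "Timepoint",
    "Transition",
    "Strategy",
    "TrophicMode",
    "TIMEPOINT_ORDER",
    "TRANSITION_ENDPOINTS",
    "PEAK_TO_STRATEGY",
    "FormatError",
    "AbundanceTable",
]


class FormatError(ValueError):
    """Raised when an input file violates its documented format contract."""


class Location(str, enum.Enum):
    HILLSLOPE = "hillslope"
    FLOODPLAIN = "floodplain"


class Depth(str, enum.Enum):
    """Soil depth class: 0-5 cm, 5-15 cm, and deeper than 15 cm."""

    D0_5 = "D0_5"
    D5_15 = "D5_15"
    D15plus = "D15plus"


class Timepoint(str, enum.Enum):
    SEP = "SEP"
    MAR = "MAR"
    MAY = "MAY"
    JUN = "JUN"


#: Chronological order of the four sampling dates.
TIMEPOINT_ORDER: tuple[Timepoint, ...] = (
    Timepoint.SEP,
    Timepoint.MAR,
    Timepoint.MAY,
    Timepoint.JUN,
)


class Transition(str, enum.Enum):
    """The three consecutive seasonal periods between sampling dates."""

    WINTER = "WINTER"  # SEP -> MAR, under accumulating snowpack
    SNOWMELT = "SNOWMELT"  # MAR -> MAY, the snowmelt period
    SPRING = "SPRING"  # MAY -> JUN, after loss of snow cover


TRANSITION_ENDPOINTS: dict[Transition, tuple[Timepoint, Timepoint]] = {
    Transition.WINTER: (Timepoint.SEP, Timepoint.MAR),
    Transition.SNOWMELT: (Timepoint.MAR, Timepoint.MAY),
    Transition.SPRING: (Timepoint.MAY, Timepoint.JUN),
}


class Strategy(str, enum.Enum):
    """Temporal life strategy of an OTU, named by its peak period."""

    WINTER_ADAPTED = "WINTER_ADAPTED"
    SNOWMELT_SPECIALIST = "SNOWMELT_SPECIALIST"
    SPRING_ADAPTED = "SPRING_ADAPTED"
    FALL = "FALL"
    BACKGROUND = "BACKGROUND"  # synthetic-data only: no planted signal
    UNASSIGNED = "UNASSIGNED"


#: Cluster centroids are labelled by the timepoint at which they peak.
PEAK_TO_STRATEGY: dict[Timepoint, Strategy] = {
    Timepoint.SEP: Strategy.FALL,
    Timepoint.MAR: Strategy.WINTER_ADAPTED,
    Timepoint.MAY: Strategy.SNOWMELT_SPECIALIST,
    Timepoint.JUN: Strategy.SPRING_ADAPTED,
}


class TrophicMode(str, enum.Enum):
    """Fungal functional guild (FUNGuild-style trophic annotation)."""

    AMF = "AMF"  # arbuscular mycorrhizal fungi
    EMF = "EMF"  # ectomycorrhizal fungi
    ENDOPHYTE = "endophyte"
    SAPROTROPH = "saprotroph"
    OTHER = "other"
    UNKNOWN = "unknown"


METADATA_COLUMNS = ("location", "depth", "timepoint", "replicate")


@dataclass
class AbundanceTable:
    """OTU x sample relative-abundance matrix with sample metadata.

    Parameters
    ----------
    data :
        DataFrame of proportions, index = OTU ids, columns = sample ids.
        Each column sums to 1 (within 1e-9) unless the table was
        prevalence-filtered, in which case proportions remain relative to
        the full, unfiltered community.
    metadata :
        DataFrame indexed by sample id with columns ``location``,
        ``depth``, ``timepoint``, ``replicate``.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate OTU ids in abundance table")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate sample ids in abundance table")
        if self.metadata.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        absent = self.data.columns.difference(self.metadata.index)
        if len(absent):
            raise FormatError(
                f"samples without metadata: {sorted(absent)[:5]}"
            )
        vals = self.data.to_numpy()
        if np.isnan(vals).any():
            raise FormatError("abundance table contains missing values")
        if (vals < 0).any():
            raise FormatError("abundance table contains negative values")
        # keep metadata aligned to, and ordered as, the data columns
        self.metadata = self.metadata.loc[self.data.columns]

    @property
    def otu_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def normalize(self) -> "AbundanceTable":
        """Return a copy with each sample (column) rescaled to sum to 1."""
        sums = self.data.sum(axis=0)
        zero = sums[sums == 0]
        if len(zero):
            raise FormatError(
                f"sample(s) with zero total abundance: {list(zero.index)}"
            )
        return AbundanceTable(self.data / sums, self.metadata.copy())

    def strata(self) -> list[tuple[str, str]]:
        """Distinct (location, depth) combinations, in metadata order."""
        seen: dict[tuple[str, str], None] = {}
        for loc, dep in zip(self.metadata["location"], self.metadata["depth"]):
            seen.setdefault((loc, dep))
        return list(seen)

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        ids = list(sample_ids)
        return AbundanceTable(self.data[ids], self.metadata.loc[ids])

    def stratum_samples(self, location: str, depth: str) -> pd.Index:
        m = self.metadata
        return m.index[(m["location"] == location) & (m["depth"] == depth)]

    def subset_otus(self, otu_ids) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(otu_ids)], self.metadata.copy())
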