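"""Fungal functional-guild composition within life strategies.

Each (stratum, strategy) group of fungal OTUs is summarized as the
percent of member OTUs in each trophic mode (AMF, EMF, endophyte,
saprotroph, other).  Percentages are computed over OTUs with a known
guild; members with unknown annotation are counted separately rather
than dropped.  Counting is by OTU richness, not abundance.
"""

from __future__ import annotations

from fractions import Fraction

import pandas as pd

from .containers import TrophicMode

__all__ = ["guild_composition", "GUILD_COLUMNS"]

GUILD_COLUMNS = [
    TrophicMode.AMF.value,
    TrophicMode.EMF.value,
    TrophicMode.ENDOPHYTE.value,
    TrophicMode.SAPROTROPH.value,
    TrophicMode.OTHER.value,
]


def guild_composition(assignment: pd.DataFrame, guilds: pd.Series) -> pd.DataFrame:
    """Percent of member OTUs per trophic mode, per strategy group.

    ``assignment`` is a frame indexed by otu_id with a ``strategy``
    column (one stratum); ``guilds`` maps otu_id -> trophic mode.
    Members absent from ``guilds`` count as unknown.  Percentages are
    exact rationals over known-guild members before conversion to
    float, so they sum to 100 within floating-point rounding; a group
    with no known-guild members gets NaN percentages.
    """
    rows = []
    for strategy in sorted(set(assignment["strategy"])):
        members = assignment.index[assignment["strategy"] == strategy]
        modes = [
            guilds.get(otu, TrophicMode.UNKNOWN.value) for otu in members
        ]
        counts = {g: sum(m == g for m in modes) for g in GUILD_COLUMNS}
        n_unknown = sum(m == TrophicMode.UNKNOWN.value for m in modes)
        n_known = len(members) - n_unknown
        row = {"strategy": strategy, "n_otus": len(members), "n_unknown": n_unknown}
        for g in GUILD_COLUMNS:
            row[f"pct_{g}"] = (
                float(Fraction(100 * counts[g], n_known)) if n_known else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
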