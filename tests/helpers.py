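"""Shared test helpers."""

import numpy as np
import pandas as pd

from snowniche.containers import AbundanceTable


def make_table(values, n_reps: int | None = None, otu_ids=None) -> AbundanceTable:
    """Single-stratum table: one column per timepoint x replicate.

    ``values`` has shape (n_otus, 4 * n_reps) with replicates grouped by
    timepoint in SEP, MAR, MAY, JUN order.
    """
    values = np.asarray(values, float)
    n_otus, n_cols = values.shape
    n_reps = n_cols // 4 if n_reps is None else n_reps
    assert n_cols == 4 * n_reps
    tps = ["SEP", "MAR", "MAY", "JUN"]
    sample_ids, meta = [], []
    for tp in tps:
        for r in range(n_reps):
            sid = f"{tp}.r{r + 1}"
            sample_ids.append(sid)
            meta.append(
                {
                    "sample_id": sid,
                    "location": "hillslope",
                    "depth": "D0_5",
                    "timepoint": tp,
                    "replicate": f"r{r + 1}",
                }
            )
    otu_ids = otu_ids or [f"OTU{i + 1}" for i in range(n_otus)]
    data = pd.DataFrame(values, index=otu_ids, columns=sample_ids)
    return AbundanceTable(data, pd.DataFrame(meta).set_index("sample_id"))
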