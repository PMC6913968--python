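"""Shared fixtures-in-code for MOTU-table tests."""

import pandas as pd

from metasort import MotuTable


def make_table(counts: dict, control_reps=(), aic_motus=("AIC",),
               groups=None) -> MotuTable:
    """counts: {replicate: {motu: n}}; replicate ids '<sample>_r<i>'."""
    df = pd.DataFrame(counts).fillna(0).astype(int)
    reps = []
    for rep in df.columns:
        sample = rep.rsplit("_r", 1)[0]
        reps.append((rep, sample, "L1",
                     (groups or {}).get(rep, "CRUS"), 1,
                     rep in set(control_reps)))
    replicates = pd.DataFrame(
        reps, columns=["id", "sample", "location", "group", "replicate",
                       "is_control"]).set_index("id")
    motus = pd.DataFrame(
        {"is_control_sequence": [m in set(aic_motus) for m in df.index]},
        index=df.index)
    return MotuTable(df, replicates, motus)
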