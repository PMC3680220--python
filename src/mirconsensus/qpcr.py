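"""ddCt relative quantification with dual housekeeping-gene normalization.

Ct values (qPCR cycle thresholds) are converted into fold changes under
the standard assumptions of the ddCt method: amplification efficiency 2
and reference assays (here typically the small nucleolar RNAs SNORD44 and
SNORD48) whose expression is constant across samples.

    dCt(sample)  = Ct_target(sample) - mean(Ct_refs(sample))
    ddCt(sample) = dCt(sample) - dCt(calibrator)
    FC(sample)   = 2 ** (-ddCt(sample))

Technical replicates are averaged (arithmetic mean of Ct) first; the
arithmetic mean over the reference Cts equals the geometric mean of their
linear quantities.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def _validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"sample", "assay", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    ct = table["ct"].astype(float)
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    return table


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    refs: Sequence[str],
    calibrator: str,
) -> pd.Series:
    """Fold change of ``target`` per sample, relative to ``calibrator``.

    ``table`` has one row per technical measurement with columns
    (sample, assay, ct) and optionally a replicate column.  Raises a
    data error naming the sample if the target or a reference assay is
    missing anywhere.
    """
    table = _validate_ct_table(table)
    mean_ct = table.groupby(["sample", "assay"])["ct"].mean().unstack()
    needed = [target, *refs]
    for sample in mean_ct.index:
        absent = [a for a in needed if a not in mean_ct.columns or pd.isna(mean_ct.loc[sample, a])]
        if absent:
            raise ValueError(f"sample {sample!r} is missing assay(s) {absent}")
    if calibrator not in mean_ct.index:
        raise ValueError(f"calibrator sample {calibrator!r} not in table")
    dct = mean_ct[target] - mean_ct[list(refs)].mean(axis=1)
    ddct = dct - dct[calibrator]
    fc = 2.0 ** (-ddct)
    fc.name = target
    return fc
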