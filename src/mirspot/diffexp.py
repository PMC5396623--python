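"""Fold-change differential expression between array groups.

The design has a control group and two perturbation groups (SPARC
overexpression, SPARC underexpression).  A probe is called differentially
expressed in a comparison when the absolute difference of group-mean log2
intensities is at least ``threshold_log2`` (default 1, i.e. a two-fold
change, boundary inclusive).  No variance test is applied at this stage —
the call is a pure effect-size rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .tables import IntensityMatrix


def group_means(matrix: IntensityMatrix, design: pd.Series) -> pd.DataFrame:
    """Per-probe arithmetic mean of available values within each group.

    Missing values are excluded per probe; a probe with no values at all in
    a group gets a missing mean there.
    """
    data = matrix.data
    unknown = set(data.columns) - set(design.index)
    if unknown:
        raise ConfigurationError(f"arrays not present in design: {sorted(unknown)}")
    groups = design.reindex(data.columns)
    return data.T.groupby(groups).mean().T


def call_de(means: pd.DataFrame, threshold_log2: float = 1.0,
            control: str = "control",
            treatments: tuple = ("over", "under")):
    """Two-fold-rule DE table from group means.

    Returns ``(results, excluded)``: ``results`` has one row per probe with a
    complete set of group means — per-comparison delta (treatment minus
    control, log2), fold change ``2**|delta|`` with an up/down direction, a
    boolean call per comparison and ``any_de`` aggregating the comparisons;
    ``excluded`` lists probes dropped because a group mean was missing.
    Rows are sorted by the largest absolute delta, descending.
    """
    if control not in means.columns:
        raise ConfigurationError(f"control group {control!r} absent from design")
    for t in treatments:
        if t not in means.columns:
            raise ConfigurationError(f"comparison group {t!r} absent from design")
    needed = [control, *treatments]
    complete = means[needed].notna().all(axis=1)
    excluded = list(means.index[~complete])
    sub = means.loc[complete, needed]

    out = pd.DataFrame(index=sub.index)
    for g in needed:
        out[f"mean_{g}"] = sub[g]
    calls = []
    for t in treatments:
        delta = sub[t] - sub[control]
        out[f"delta_{t}"] = delta
        out[f"fold_change_{t}"] = 2.0 ** delta.abs()
        out[f"direction_{t}"] = np.where(delta >= 0, "up", "down")
        call = delta.abs() >= threshold_log2
        out[f"de_{t}"] = call
        calls.append(call)
    out["any_de"] = np.logical_or.reduce(calls) if calls else False
    max_abs = out[[f"delta_{t}" for t in treatments]].abs().max(axis=1)
    out = out.loc[max_abs.sort_values(ascending=False, kind="mergesort").index]
    out.index.name = "probe_id"
    return out, excluded
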