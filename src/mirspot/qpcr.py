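"""Relative quantification of qRT-PCR data by the delta-delta-Ct method.

Each sample measures a target assay and a housekeeping reference (U6 for
miRNA, GAPDH for mRNA).  Technical replicates are averaged per (sample,
assay) first; the per-sample delta-Ct is target minus reference; the
delta-delta-Ct is the treated-group mean delta-Ct minus the control-group
mean, and the fold change is ``2**(-ddct)``.  Group significance uses the
classic pooled-variance (Student) unpaired t-test on per-sample delta-Ct.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError

CT_COLUMNS = ["sample_id", "group", "assay", "replicate", "ct"]


@dataclass
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False  # zero pooled variance with unequal means


@dataclass
class QpcrResult:
    assay: str
    reference: str
    delta_ct: pd.Series         # per sample
    group_delta_ct: pd.Series   # per group mean
    delta_delta_ct: float
    fold_change: float
    t_statistic: float
    p_value: float
    degenerate: bool = False


def unpaired_ttest(values_a, values_b) -> TTestResult:
    """Pooled-variance two-sample t-test, two-sided.

    When the pooled variance is exactly zero the statistic is degenerate:
    identical means give ``t=0, p=1``; different means give an infinite
    statistic reported with ``p=0`` and the ``degenerate`` flag set.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ComputationError("each group needs at least two values")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(t=0.0, p=1.0, df=df)
        return TTestResult(t=math.copysign(math.inf, diff), p=0.0, df=df,
                           degenerate=True)
    t = diff / math.sqrt(sp2 * (1 / a.size + 1 / b.size))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), p=p, df=df)


def ddct_fold_change(ct_table: pd.DataFrame, assay: str, reference: str,
                     control_group: str = "control",
                     treated_group: str = "treated") -> QpcrResult:
    """Fold change of ``assay`` relative to ``reference`` between two groups.

    ``ct_table`` needs columns ``sample_id, group, assay, replicate, ct``.
    Samples lacking a reference (or target) measurement are excluded with a
    warning; a group losing all its samples is an error.
    """
    for col in CT_COLUMNS:
        if col not in ct_table.columns:
            raise ComputationError(f"Ct table is missing column {col!r}")
    sub = ct_table[ct_table["assay"].isin([assay, reference])]
    mean_ct = sub.groupby(["sample_id", "assay"])["ct"].mean().unstack()
    groups = ct_table.drop_duplicates("sample_id").set_index("sample_id")["group"]

    have_both = mean_ct.reindex(columns=[assay, reference]).notna().all(axis=1)
    dropped = list(mean_ct.index[~have_both])
    if dropped:
        warnings.warn(f"samples excluded for missing measurements: {dropped}")
    mean_ct = mean_ct[have_both]

    delta_ct = (mean_ct[assay] - mean_ct[reference]).rename("delta_ct")
    sample_groups = groups.reindex(delta_ct.index)
    per_group = {}
    for g in (control_group, treated_group):
        vals = delta_ct[sample_groups == g]
        if vals.empty:
            raise ComputationError(f"group {g!r} has no usable samples")
        per_group[g] = vals
    group_means = pd.Series({g: v.mean() for g, v in per_group.items()})
    ddct = float(group_means[treated_group] - group_means[control_group])
    fc = 2.0 ** (-ddct)

    if len(per_group[control_group]) >= 2 and len(per_group[treated_group]) >= 2:
        tt = unpaired_ttest(per_group[treated_group], per_group[control_group])
        t, p, degenerate = tt.t, tt.p, tt.degenerate
    else:
        t, p, degenerate = float("nan"), float("nan"), False

    return QpcrResult(assay=assay, reference=reference, delta_ct=delta_ct,
                      group_delta_ct=group_means, delta_delta_ct=ddct,
                      fold_change=fc, t_statistic=t, p_value=p,
                      degenerate=degenerate)


def read_ct_table(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", dtype={"sample_id": str, "group": str,
                                              "assay": str})
    for col in CT_COLUMNS:
        if col not in df.columns:
            raise ComputationError(f"Ct table is missing column {col!r}")
    df["ct"] = pd.to_numeric(df["ct"])
    if (df["ct"] <= 0).any() or not np.isfinite(df["ct"]).all():
        raise ComputationError("Ct values must be finite and positive")
    return df
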