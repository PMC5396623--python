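"""Spot-level pre-processing and quality control for spotted miRNA arrays.

The processing chain mirrors standard single-channel spotted-array practice:

1. background subtraction (median foreground - median local background),
2. per-array detection threshold TPT95 = the 95th percentile (nearest rank,
   raw scale) of negative-control spot intensities, log2-transformed,
3. log2 transform with a positive floor so non-positive background-subtracted
   intensities stay finite,
4. qualification of normalization probes: human probes above TPT95 + margin
   in every array whose across-array SD is below ``sd_max``,
5. per-array normalization factor N = 20% trimmed mean of the qualifying
   probe intensities; values are shifted by ``-N + mean(N)`` so every array
   shares the qualifying-probe location while the grand scale is preserved,
6. triplicate averaging with poor-quality spots omitted,
7. detection filtering: keep probes above TPT95 + margin in at least a
   fraction ``min_fraction`` of arrays.

All intensities are log2 fluorescence unless a name says ``raw``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError, QualificationError
from .tables import FLAG_OK, IntensityMatrix


@dataclass
class DetectionThresholds:
    """Per-array log2 detection threshold (TPT95)."""

    tpt95: pd.Series  # index: array_id, values: log2 intensity

    def __post_init__(self):
        if not np.isfinite(self.tpt95.to_numpy(float)).all():
            raise ConsistencyError("TPT95 values must be finite")

    def shifted(self, offsets: pd.Series) -> "DetectionThresholds":
        """Thresholds moved onto another scale (e.g. post-normalization)."""
        return DetectionThresholds(self.tpt95 + offsets.reindex(self.tpt95.index))

    def to_tsv(self, path) -> None:
        self.tpt95.rename("tpt95").rename_axis("array_id").reset_index().to_csv(
            path, sep="\t", index=False
        )


@dataclass
class NormalizationFactors:
    """Per-array trimmed-mean normalization factor N and its grand mean."""

    n: pd.Series  # index: array_id
    grand_mean: float
    qualifying_probes: frozenset

    def to_tsv(self, path) -> None:
        self.n.rename("N").rename_axis("array_id").reset_index().to_csv(
            path, sep="\t", index=False
        )


@dataclass
class QcReport:
    spikes_detected: pd.Series          # per array, count of spikes above threshold
    specificity_deltas: pd.DataFrame    # columns: array_id, set, variant, delta_log2
    replicate_sd: pd.DataFrame          # columns: array_id, probe_id, sd (log2)


def subtract_background(fg_median, bg_median):
    """Background-subtracted raw spot intensity (may be zero or negative)."""
    return np.asarray(fg_median, float) - np.asarray(bg_median, float)


def log2_transform(intensity, floor: float = 1.0):
    """log2 of the intensity after flooring at a positive raw value."""
    if floor <= 0:
        raise ConfigurationError("log2 floor must be positive")
    return np.log2(np.maximum(np.asarray(intensity, float), floor))


def compute_tpt95(negative_intensities, floor: float = 1.0) -> float:
    """Detection threshold from one array's negative-control spots.

    The 95th percentile is taken on the raw scale with the nearest-rank
    convention (sorted index ``ceil(0.95 n)``), then log2-transformed with
    the same floor policy as the data.
    """
    values = np.sort(np.asarray(negative_intensities, float))
    if values.size == 0:
        raise ConfigurationError("no negative-control intensities supplied")
    rank = math.ceil(0.95 * values.size)
    return float(log2_transform(values[rank - 1], floor))


def thresholds_from_spots(spots: pd.DataFrame, annotation: pd.DataFrame,
                          floor: float = 1.0) -> DetectionThresholds:
    """TPT95 per array from a spot table, using unflagged negative controls."""
    neg_ids = set(annotation.loc[annotation["probe_class"] == "negative_control", "probe_id"])
    neg = spots[(spots["probe_id"].isin(neg_ids)) & (spots["flag"] == FLAG_OK)]
    out = {}
    for array_id, sub in neg.groupby("array_id", sort=True):
        out[array_id] = compute_tpt95(
            subtract_background(sub["fg_median"], sub["bg_median"]), floor
        )
    missing = set(spots["array_id"]) - set(out)
    if missing:
        raise ConfigurationError(
            f"arrays without usable negative controls: {sorted(missing)}"
        )
    return DetectionThresholds(pd.Series(out).sort_index())


def spot_log2(spots: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Spot table with a log2 background-subtracted ``value`` column added."""
    out = spots.copy()
    out["value"] = log2_transform(
        subtract_background(out["fg_median"], out["bg_median"]), floor
    )
    return out


def probe_array_means(spots_log2: pd.DataFrame, drop_flagged: bool = True) -> pd.DataFrame:
    """Mean of (unflagged) replicate log2 values per probe per array."""
    df = spots_log2
    if drop_flagged:
        df = df[df["flag"] == FLAG_OK]
    return df.pivot_table(index="probe_id", columns="array_id", values="value",
                          aggfunc="mean")


def select_normalization_probes(matrix: IntensityMatrix,
                                thresholds: DetectionThresholds,
                                margin: float = 1.0,
                                sd_max: float = 1.25) -> frozenset:
    """Probes usable for computing the normalization factor.

    A probe qualifies when its intensity is strictly above TPT95 + margin in
    every array and its across-array sample SD (n-1 denominator) is strictly
    below ``sd_max``.
    """
    if matrix.data.shape[1] < 2:
        raise ConfigurationError("qualification needs at least two arrays")
    data = matrix.data
    thr = thresholds.tpt95.reindex(data.columns)
    if thr.isna().any():
        raise ConsistencyError("thresholds missing for some arrays")
    detected_everywhere = (data.gt(thr + margin, axis=1) & data.notna()).all(axis=1)
    stable = data.std(axis=1, ddof=1) < sd_max
    probes = frozenset(data.index[detected_everywhere & stable])
    if not probes:
        raise QualificationError(
            "no probe qualifies for normalization; relax margin/sd_max"
        )
    return probes


def compute_normalization_factor(array_values, trim: float = 0.20) -> float:
    """Trimmed mean of one array's qualifying-probe log2 intensities.

    ``floor(trim * n)`` values are removed from each tail before averaging.
    """
    values = np.sort(np.asarray(array_values, float))
    if values.size == 0:
        raise ConfigurationError("no qualifying-probe values for this array")
    k = math.floor(trim * values.size)
    trimmed = values[k:values.size - k] if k > 0 else values
    return float(np.mean(trimmed))


def normalization_factors(matrix: IntensityMatrix, probes: frozenset,
                          trim: float = 0.20) -> NormalizationFactors:
    sub = matrix.data.loc[sorted(probes)]
    n = sub.apply(lambda col: compute_normalization_factor(col.dropna(), trim), axis=0)
    return NormalizationFactors(n=n, grand_mean=float(n.mean()),
                                qualifying_probes=probes)


def normalize(matrix: IntensityMatrix, factors: NormalizationFactors) -> IntensityMatrix:
    """Subtract each array's N and re-center by the grand mean of N."""
    n = factors.n.reindex(matrix.data.columns)
    if n.isna().any():
        missing = list(matrix.data.columns[n.isna()])
        raise ConsistencyError(f"normalization factor missing for arrays {missing}")
    data = matrix.data.sub(n, axis=1) + factors.grand_mean
    return matrix.advanced(data, "normalized")


def normalize_spots(spots_log2: pd.DataFrame,
                    factors: NormalizationFactors) -> pd.DataFrame:
    """Apply the per-array normalization to spot-level log2 values."""
    n = spots_log2["array_id"].map(factors.n)
    if n.isna().any():
        missing = sorted(set(spots_log2.loc[n.isna(), "array_id"]))
        raise ConsistencyError(f"normalization factor missing for arrays {missing}")
    out = spots_log2.copy()
    out["value"] = out["value"] - n + factors.grand_mean
    return out


def average_triplicates(spots_log2: pd.DataFrame, stage: str = "averaged") -> IntensityMatrix:
    """Per probe per array mean of unflagged replicate values.

    Probe/array cells whose replicates are all flagged come out missing.
    """
    mat = probe_array_means(spots_log2, drop_flagged=True)
    # reinstate all (probe, array) cells so fully-flagged cells appear as NaN
    all_probes = spots_log2["probe_id"].unique()
    all_arrays = sorted(spots_log2["array_id"].unique())
    mat = mat.reindex(index=all_probes, columns=all_arrays)
    return IntensityMatrix(mat, stage)


def detection_filter(matrix: IntensityMatrix, thresholds: DetectionThresholds,
                     margin: float = 1.0, min_fraction: float = 0.10) -> IntensityMatrix:
    """Keep probes detected in at least ``ceil(min_fraction * K)`` arrays.

    Detection is strict: value > TPT95 + margin.  Thresholds must be on the
    same scale as the matrix (normalize them alongside the data).
    """
    data = matrix.data
    if data.empty:
        raise ConfigurationError("empty matrix")
    thr = thresholds.tpt95.reindex(data.columns)
    if thr.isna().any():
        raise ConsistencyError("thresholds missing for some arrays")
    detected = data.gt(thr + margin, axis=1) & data.notna()
    need = math.ceil(min_fraction * data.shape[1])
    keep = detected.sum(axis=1) >= need
    return matrix.advanced(data.loc[keep], "detected")


def qc_report(spots_log2: pd.DataFrame, annotation: pd.DataFrame,
              thresholds: DetectionThresholds, margin: float = 1.0) -> QcReport:
    """Spike sensitivity, specificity-probe deltas and replicate spread.

    * spikes_detected: per array, how many spike probes average above
      TPT95 + margin (hybridization sensitivity check);
    * specificity_deltas: per array and specificity set, log2 difference of
      the perfect-match probe versus each mismatch / shuffled probe;
    * replicate_sd: per human probe per array, SD of the unflagged
      replicate log2 values (array reproducibility).
    """
    ann = annotation.set_index("probe_id")
    means = probe_array_means(spots_log2, drop_flagged=True)

    spike_ids = ann.index[ann["probe_class"] == "spike"]
    spike_means = means.reindex(spike_ids)
    thr = thresholds.tpt95.reindex(means.columns)
    spikes_detected = (spike_means.gt(thr + margin, axis=1)).sum(axis=0)

    spec_classes = ("specificity_pm", "specificity_mismatch", "specificity_shuffled")
    spec = ann[ann["probe_class"].isin(spec_classes)]
    rows = []
    # specificity probes are grouped per control miRNA via display_name
    for name, group in spec.groupby("display_name"):
        pm = group.index[group["probe_class"] == "specificity_pm"]
        if len(pm) != 1:
            continue
        pm_values = means.loc[pm[0]]
        for probe_id, row in group.iterrows():
            if probe_id == pm[0]:
                continue
            delta = pm_values - means.loc[probe_id]
            for array_id, d in delta.items():
                rows.append({"array_id": array_id, "set": name,
                             "variant": row["probe_class"], "probe_id": probe_id,
                             "delta_log2": d})
    specificity_deltas = pd.DataFrame(
        rows, columns=["array_id", "set", "variant", "probe_id", "delta_log2"]
    )

    human_ids = set(ann.index[ann["probe_class"] == "human"])
    ok = spots_log2[(spots_log2["flag"] == FLAG_OK)
                    & spots_log2["probe_id"].isin(human_ids)]
    rep = (ok.groupby(["array_id", "probe_id"])["value"].std(ddof=1)
             .rename("sd").reset_index())
    return QcReport(spikes_detected=spikes_detected,
                    specificity_deltas=specificity_deltas,
                    replicate_sd=rep)
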