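"""Synthetic spotted-array experiments with known ground truth.

The generator emulates the study design the pipeline was built for: a
custom single-channel array with 1209 human miRNA probes spotted in
triplicate, 96 negative-control probes, 11 spike-in probes, three
specificity-control sets (perfect match / single mismatch / double
mismatch / shuffled) and blank spots padding the layout to 8816 features
per array; three biological replicates each for a control group, a
SPARC-overexpression group and a SPARC-underexpression group.

Signal model (log2 scale, additive):

    log2 intensity = baseline(probe) + array_offset(array)
                     + group_effect(probe, group) + Normal(0, noise_sd)

Undetectable probes sit at the negative-control location instead of a
baseline.  Raw intensities are ``2**log2`` plus an additive background
draw; the emitted foreground median is signal + background and the
background median is the background draw itself, so background subtraction
recovers the signal exactly.  Every output is a pure function of the
configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .tables import FLAG_OK, FLAG_POOR

GROUPS = ("control", "over", "under")

#: per-array feature count of the emulated platform
PLATFORM_FEATURES = 8816


@dataclass
class ArraySimConfig:
    """Parameters of the synthetic array experiment.

    Defaults state the emulated platform: 1209 human probes of which 729
    are detectable and 27 carry planted group effects of at least one log2
    unit (two-fold), in biological triplicate per group.
    """

    n_human_probes: int = 1209
    n_negative: int = 96
    n_spikes: int = 11
    n_specificity_sets: int = 3
    replicates_per_probe: int = 3
    arrays_per_group: int = 3
    groups: tuple = GROUPS
    n_detectable: int = 729
    n_de: int = 27
    de_effect_range: tuple = (1.0, 2.5)   # |log2 effect| of planted DE probes
    baseline_log2_range: tuple = (9.0, 13.0)
    neg_log2_mean: float = 6.0
    neg_log2_sd: float = 0.5
    spike_log2_mean: float = 12.0
    specificity_delta: float = 4.0        # pm minus mismatch/shuffled, log2
    background_mean: float = 100.0
    background_sd: float = 10.0
    array_offset_sd: float = 0.3
    array_offsets: tuple | None = None    # explicit per-array offsets (optional)
    noise_sd: float = 0.25
    flag_probability: float = 0.01
    pad_to_platform: bool = True          # add blank spots up to 8816 features
    detectable_set: tuple | None = None   # explicit probe ids (optional)
    planted_de: dict | None = None        # probe id -> {group: log2 effect}
    seed: int = 20170101

    def validate(self):
        for name in ("n_human_probes", "n_negative", "n_spikes",
                     "replicates_per_probe", "arrays_per_group"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0 <= self.flag_probability <= 1:
            raise ConfigurationError("flag_probability must be in [0, 1]")
        if not 0 <= self.n_detectable <= self.n_human_probes:
            raise ConfigurationError("n_detectable must be within the human panel")
        if not 0 <= self.n_de <= self.n_detectable:
            raise ConfigurationError("n_de must be within the detectable set")
        if self.noise_sd < 0 or self.neg_log2_sd < 0 or self.background_sd < 0:
            raise ConfigurationError("noise_sd/neg_log2_sd/background_sd must be >= 0")
        if self.de_effect_range[0] < 0 or self.de_effect_range[0] > self.de_effect_range[1]:
            raise ConfigurationError("de_effect_range must be 0 <= low <= high")


@dataclass
class GroundTruth:
    """What the generator planted, for exact downstream verification."""

    detectable: frozenset                 # human probe ids
    effects: dict                         # probe id -> {group: log2 effect}
    baselines: pd.Series                  # per human probe log2 baseline
    array_offsets: pd.Series              # per array
    array_groups: pd.Series               # per array
    flagged_spots: pd.DataFrame           # rows of the emitted spot table
    config: ArraySimConfig = field(repr=False, default=None)

    @property
    def de_probes(self) -> frozenset:
        return frozenset(p for p, eff in self.effects.items()
                         if any(abs(e) >= 1.0 for e in eff.values()))


def _probe_layout(config: ArraySimConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_human_probes):
        rows.append((f"hp{i:04d}", f"sim-miR-{i:04d}", "human"))
    for i in range(config.n_negative):
        rows.append((f"neg{i:03d}", f"neg-control-{i:03d}", "negative_control"))
    for i in range(config.n_spikes):
        rows.append((f"spike{i:02d}", f"spike-{i:02d}", "spike"))
    for s in range(config.n_specificity_sets):
        name = f"spec-miR-{s}"
        rows.append((f"spec{s}_pm", name, "specificity_pm"))
        rows.append((f"spec{s}_mm1", name, "specificity_mismatch"))
        rows.append((f"spec{s}_mm2", name, "specificity_mismatch"))
        rows.append((f"spec{s}_shuf", name, "specificity_shuffled"))
    df = pd.DataFrame(rows, columns=["probe_id", "display_name", "probe_class"])
    df["species"] = "hsa"
    return df


def generate_array_experiment(config: ArraySimConfig | None = None):
    """Simulate the full experiment.

    Returns ``(spots, annotation, design, truth)``: a spot table covering
    all arrays, the probe annotation, the array -> group design and the
    planted :class:`GroundTruth`.
    """
    config = config or ArraySimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    annotation = _probe_layout(config)
    human = list(annotation.loc[annotation["probe_class"] == "human", "probe_id"])

    if config.detectable_set is not None:
        detectable = list(config.detectable_set)
        if not set(detectable) <= set(human):
            raise ConfigurationError("detectable_set must be human probes")
    else:
        detectable = sorted(rng.choice(human, size=config.n_detectable, replace=False))

    if config.planted_de is not None:
        effects = {p: dict(e) for p, e in config.planted_de.items()}
        if not set(effects) <= set(human):
            raise ConfigurationError("planted_de must reference human probes")
    else:
        de_probes = sorted(rng.choice(detectable, size=config.n_de, replace=False))
        lo, hi = config.de_effect_range
        effects = {}
        for p in de_probes:
            mag = float(rng.uniform(lo, hi))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            # opposite response under over- vs under-expression
            effects[p] = {"over": sign * mag, "under": -sign * mag}

    arrays, array_groups = [], {}
    for g in config.groups:
        for r in range(1, config.arrays_per_group + 1):
            aid = f"{g}_{r}"
            arrays.append(aid)
            array_groups[aid] = g
    if config.array_offsets is not None:
        if len(config.array_offsets) != len(arrays):
            raise ConfigurationError("array_offsets must match the array count")
        offsets = pd.Series(dict(zip(arrays, map(float, config.array_offsets))))
    else:
        offsets = pd.Series(rng.normal(0.0, config.array_offset_sd, len(arrays)),
                            index=arrays)

    lo_b, hi_b = config.baseline_log2_range
    baselines = pd.Series(rng.uniform(lo_b, hi_b, len(human)), index=human)

    detectable_set = frozenset(detectable)
    rep = config.replicates_per_probe
    n_blank = 0
    if config.pad_to_platform:
        used = len(annotation) * rep
        n_blank = max(0, PLATFORM_FEATURES - used)

    frames = []
    for aid in arrays:
        g = array_groups[aid]
        off = offsets[aid]
        probe_ids, log2_levels = [], []
        for _, row in annotation.iterrows():
            pid, cls, name = row["probe_id"], row["probe_class"], row["display_name"]
            if cls == "human":
                if pid in detectable_set:
                    level = baselines[pid] + effects.get(pid, {}).get(g, 0.0)
                else:
                    level = config.neg_log2_mean
            elif cls == "negative_control":
                level = None  # drawn with its own spread below
            elif cls == "spike":
                level = config.spike_log2_mean
            elif cls == "specificity_pm":
                level = config.spike_log2_mean
            else:  # mismatch / shuffled
                level = config.spike_log2_mean - config.specificity_delta
            probe_ids.append(pid)
            log2_levels.append(level)

        pid_col, repl_col, sig_col = [], [], []
        for pid, level in zip(probe_ids, log2_levels):
            for r in range(1, rep + 1):
                pid_col.append(pid)
                repl_col.append(r)
                if level is None:
                    val = rng.normal(config.neg_log2_mean, config.neg_log2_sd)
                else:
                    val = level + rng.normal(0.0, config.noise_sd) if config.noise_sd else level
                sig_col.append(val + off)
        n_spots = len(pid_col)
        signal_raw = np.exp2(np.asarray(sig_col))
        background = np.clip(
            rng.normal(config.background_mean, config.background_sd, n_spots),
            0.0, None)
        flags = np.where(rng.random(n_spots) < config.flag_probability,
                         FLAG_POOR, FLAG_OK)
        frame = pd.DataFrame({
            "array_id": aid,
            "probe_id": pid_col,
            "replicate_index": repl_col,
            "fg_median": signal_raw + background,
            "bg_median": background,
            "flag": flags,
        })
        if n_blank:
            blank_bg = np.clip(
                rng.normal(config.background_mean, config.background_sd, n_blank),
                0.0, None)
            blank = pd.DataFrame({
                "array_id": aid,
                "probe_id": [f"blank{i:04d}" for i in range(n_blank)],
                "replicate_index": 1,
                "fg_median": blank_bg,
                "bg_median": blank_bg,
                "flag": FLAG_OK,
            })
            frame = pd.concat([frame, blank], ignore_index=True)
        frames.append(frame)

    spots = pd.concat(frames, ignore_index=True)
    if n_blank:
        blanks = pd.DataFrame({
            "probe_id": [f"blank{i:04d}" for i in range(n_blank)],
            "display_name": "blank",
            "probe_class": "blank",
            "species": "none",
        })
        annotation = pd.concat([annotation, blanks], ignore_index=True)

    design = pd.Series(array_groups, name="group").loc[arrays]
    design.index.name = "array_id"
    truth = GroundTruth(
        detectable=detectable_set,
        effects=effects,
        baselines=baselines,
        array_offsets=offsets,
        array_groups=design,
        flagged_spots=spots[spots["flag"] == FLAG_POOR].copy(),
        config=config,
    )
    return spots, annotation, design, truth


def zero_noise_config(**overrides) -> ArraySimConfig:
    """The default experiment with every stochastic nuisance switched off."""
    base = dict(noise_sd=0.0, flag_probability=0.0, array_offset_sd=0.0,
                background_sd=0.0)
    base.update(overrides)
    return ArraySimConfig(**base)


def generate_ct_table(planted_fc: dict, noise_sd: float = 0.1,
                      n_per_group: int = 4, replicates: int = 3,
                      reference: str = "U6", ref_ct_mean: float = 20.0,
                      dct_control: float = 4.0, seed: int = 0) -> pd.DataFrame:
    """Synthetic Ct table with known per-assay fold changes.

    Reference Ct values are drawn around ``ref_ct_mean``; each target's
    control-group Ct sits ``dct_control`` cycles above its reference and the
    treated group is shifted by ``-log2(planted_fc)`` so the delta-delta-Ct
    analysis recovers ``planted_fc`` exactly at zero noise.  Gaussian noise
    of ``noise_sd`` cycles is added per well.
    """
    for assay, fc in planted_fc.items():
        if fc <= 0:
            raise ConfigurationError(f"planted fold change for {assay!r} must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group in ("control", "treated"):
        for s in range(1, n_per_group + 1):
            sample = f"{group}_{s}"
            ref_base = ref_ct_mean + rng.normal(0.0, 0.5)
            for r in range(1, replicates + 1):
                rows.append({"sample_id": sample, "group": group,
                             "assay": reference, "reference_assay": reference,
                             "replicate": r,
                             "ct": ref_base + rng.normal(0.0, noise_sd)})
            for assay, fc in planted_fc.items():
                shift = -np.log2(fc) if group == "treated" else 0.0
                target_base = ref_base + dct_control + shift
                for r in range(1, replicates + 1):
                    rows.append({"sample_id": sample, "group": group,
                                 "assay": assay, "reference_assay": reference,
                                 "replicate": r,
                                 "ct": target_base + rng.normal(0.0, noise_sd)})
    return pd.DataFrame(rows)
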