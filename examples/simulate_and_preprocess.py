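"""Simulate a spotted miRNA array experiment and preprocess it.

Generates the default 8816-feature / 9-array design with known ground
truth, then runs background subtraction, TPT95 thresholds, trimmed-mean
normalization, triplicate averaging and the detection filter.
"""

from mirspot import preprocess, tables
from mirspot.simulate import ArraySimConfig, generate_array_experiment

spots, annotation, design, truth = generate_array_experiment(ArraySimConfig(seed=20170101))
print(f"simulated {len(spots)} spots over {design.size} arrays "
      f"({annotation['probe_class'].eq('human').sum()} human probes in triplicate)")

thresholds = preprocess.thresholds_from_spots(spots, annotation)
print("per-array log2 detection thresholds (TPT95):")
print(thresholds.tpt95.round(2).to_string())

human = set(annotation.loc[annotation["probe_class"] == "human", "probe_id"])
slog = preprocess.spot_log2(spots)
qual = tables.IntensityMatrix(
    preprocess.probe_array_means(slog[slog["probe_id"].isin(human)]), "log2")
probes = preprocess.select_normalization_probes(qual, thresholds)
factors = preprocess.normalization_factors(qual, probes)
print(f"{len(probes)} probes qualify for normalization; "
      f"factors N span {factors.n.min():.2f}..{factors.n.max():.2f} "
      f"(grand mean {factors.grand_mean:.2f})")

normalized = preprocess.normalize_spots(slog, factors)
averaged = preprocess.average_triplicates(normalized[normalized["probe_id"].isin(human)])
detected = preprocess.detection_filter(
    averaged, thresholds.shifted(-factors.n + factors.grand_mean))
print(f"{len(detected.data)} of {len(averaged.data)} human probes pass the "
      f"detection filter (truth planted {len(truth.detectable)} detectable)")
# The detection count matching the planted count shows the TPT95+1 rule
# separates signal from the negative-control floor at this noise level.
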