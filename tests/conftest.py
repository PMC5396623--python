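import io

import pandas as pd
import pytest

from mirspot.simulate import ArraySimConfig, generate_array_experiment


@pytest.fixture
def tiny_spots() -> pd.DataFrame:
    """Hand-written two-array spot table: 2 probes x 3 replicates each."""
    rows = []
    for array in ("a1", "a2"):
        for probe, fg in (("p1", 500.0), ("p2", 1100.0)):
            for rep in (1, 2, 3):
                rows.append({"array_id": array, "probe_id": probe,
                             "replicate_index": rep, "fg_median": fg + 10 * rep,
                             "bg_median": 100.0, "flag": "ok"})
    return pd.DataFrame(rows)


def small_config(**overrides) -> ArraySimConfig:
    """A miniature array design that keeps pipeline tests fast."""
    base = dict(n_human_probes=40, n_negative=24, n_spikes=3,
                n_specificity_sets=1, n_detectable=25, n_de=4,
                pad_to_platform=False, noise_sd=0.0, flag_probability=0.0,
                array_offset_sd=0.0, background_sd=0.0, seed=7)
    base.update(overrides)
    return ArraySimConfig(**base)


@pytest.fixture
def small_experiment():
    return generate_array_experiment(small_config())


def spot_tsv(df: pd.DataFrame) -> io.StringIO:
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return buf
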