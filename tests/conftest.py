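import pytest

from effectbench import (
    Corpus,
    EffectRecord,
    default_calibration,
    generate,
    normalize,
)


@pytest.fixture
def toy_corpus():
    """A small handcrafted corpus covering all three metrics and categories."""
    return Corpus(
        records=[
            EffectRecord("m1", "s1", "r", -0.40, 120, None, "unclassified"),
            EffectRecord("m1", "s2", "r", 0.20, 129, None, "unclassified"),
            EffectRecord("m2", "s1", "d", 0.50, 32, 32, "biomedical"),
            EffectRecord("m2", "s2", "g", -0.30, 30, 19, "psychosocial"),
            EffectRecord("m3", "s1", "g", 0.76, 30, 19, "psychosocial"),
        ],
        provenance="handcrafted fixture",
    )


@pytest.fixture(scope="session")
def synth_corpus():
    """A medium synthetic corpus under the study-like default configuration."""
    return normalize(generate(default_calibration(seed=11, n_meta=400)))


@pytest.fixture(scope="session")
def recovery_setup():
    """A 5e4-record unbiased corpus with one effect per meta-analysis.

    One effect per meta removes the cluster variance of the shared-true-
    effect design so sample quantiles converge at the i.i.d. rate, which is
    what the quartile-recovery tolerance assumes.
    """
    config = default_calibration(seed=11, n_meta=50_000, effects_per_meta=1e-6)
    return config, normalize(generate(config))
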