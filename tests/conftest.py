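import pytest

from reglinkmap.synthetic_data import ScenarioParams, generate_scenario

TINY = dict(
    n_tf=3,
    n_tg=8,
    seq_len_tf=80,
    seq_len_tg=100,
    promoter_len=60,
    motifs_per_tf=2,
    motif_len=8,
    links_per_tf=2,
    n_decoy_seqs=4,
    n_experiments=6,
)


def tiny_params(**overrides) -> ScenarioParams:
    merged = {**TINY, **overrides}
    return ScenarioParams(**merged)


@pytest.fixture(scope="session")
def tiny_identity_scenario():
    """Fully conserved, mutation-free scenario: target copies the source."""
    return generate_scenario(
        tiny_params(
            frac_tf_conserved=1.0,
            frac_tg_conserved=1.0,
            frac_link_conserved=1.0,
            substitution_rate=0.0,
            p_absent=0.0,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def tiny_noisy_scenario():
    return generate_scenario(
        tiny_params(
            frac_link_conserved=0.6,
            substitution_rate=0.05,
            seed=23,
        )
    )
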