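import pytest

from sweepscan import SimConfig, SweepSpec, simulate_dataset


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down two-chromosome dataset with one sweep; fast enough for
    per-test use while keeping the sweep signature detectable."""
    return SimConfig(
        n_g1=20,
        n_g2=20,
        n_snps=400,
        chrom_lengths={"1": 5_000_000, "2": 5_000_000},
        sweep=SweepSpec(chrom="1", pos=2_500_000, freq=0.9, span_bp=400_000),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_ds(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_bundle(small_cfg, tmp_path_factory):
    from sweepscan import write_fixture_bundle

    out = tmp_path_factory.mktemp("bundle")
    return write_fixture_bundle(small_cfg, out)
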