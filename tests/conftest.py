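import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy():
    """Default toy genome: 14-residue cryptic peptide in a 490-nt cassette."""
    from crypticflow.simulate import build_toy_genome

    return build_toy_genome()


@pytest.fixture(scope="session")
def junction_sim():
    """Seeded junction simulation at the default study conditions."""
    from crypticflow.simulate import SpliceSimSpec, simulate_junctions

    return simulate_junctions(SpliceSimSpec(seed=11))


@pytest.fixture(scope="session")
def sim_annotation_index(junction_sim, tmp_path_factory):
    from crypticflow.annotation import build_annotation_index

    gtf = tmp_path_factory.mktemp("ann") / "sim.gtf"
    junction_sim.write_gtf(gtf)
    return build_annotation_index(gtf)


@pytest.fixture(scope="session")
def toy_index(toy, tmp_path_factory):
    from crypticflow.annotation import build_annotation_index

    gtf = tmp_path_factory.mktemp("toyann") / "toy.gtf"
    toy.write_gtf(gtf)
    return build_annotation_index(gtf)
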