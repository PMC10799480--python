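import pytest

from tefuse.model import DomainHit, TEStatus
from tefuse.pipeline import run_pipeline
from tefuse.simulate import SimulationParams, generate_bundle


def make_hit(
    protein_id="p1",
    genome_id="g1",
    pfam_acc="PF90001",
    start=1,
    end=100,
    bitscore=100.0,
    evalue=1e-30,
    status=TEStatus.UNASSIGNED,
):
    return DomainHit(
        protein_id=protein_id,
        genome_id=genome_id,
        pfam_acc=pfam_acc,
        pfam_name="",
        env_start=start,
        env_end=end,
        bitscore=bitscore,
        evalue=evalue,
        te_status=status,
    )


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One synthetic bundle at the standard study scale: 30 genomes over
    4 orders, 10 planted fusion orthogroups spanning the tiers, and 5
    decoys of each of the 8 classes."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_bundle(SimulationParams(seed=11), out)


@pytest.fixture(scope="session")
def default_result(default_bundle):
    return run_pipeline(default_bundle.out_dir)
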