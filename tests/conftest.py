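import numpy as np
import pytest

from smmtax import seqio, synth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def community_dir(tmp_path_factory):
    """Four well-separated 30 kb genomes on disk + lineage map."""
    root = tmp_path_factory.mktemp("community")
    genomes, lineage_map = synth.community(4, 30_000, divergence_knob=0.8, seed=11)
    paths = []
    for rec in genomes:
        path = root / f"{rec.id}.fasta"
        seqio.write_fasta(path, [rec])
        paths.append(str(path))
    return {"paths": paths, "genomes": genomes, "lineage": lineage_map, "root": root}
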