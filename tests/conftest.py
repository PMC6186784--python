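from pathlib import Path

import numpy as np
import pytest

from cleavemap import DetectionParams, NucleotideSequence

REPO_ROOT = Path(__file__).resolve().parents[1]
PARAMS_TSV = REPO_ROOT / "analysis" / "data" / "ne_burden_params.tsv"


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def default_params():
    return DetectionParams()


@pytest.fixture
def random_references(rng):
    """Ten random DNA references of mixed length, seeded."""
    refs = []
    for i in range(10):
        length = int(rng.integers(50, 400))
        residues = "".join(rng.choice(list("ACGT"), size=length))
        refs.append(NucleotideSequence(id=f"ref{i}", residues=residues))
    return refs
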