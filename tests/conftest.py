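import numpy as np
import pandas as pd
import pytest

import thymoclone as tc


def make_sample(counts, frames=None, sequences=None, sample_id="toy", **meta):
    """Build a RepertoireSample from raw read counts."""
    n = len(counts)
    if sequences is None:
        sequences = [f"ACGT{i:04d}" for i in range(n)]
    if frames is None:
        frames = [tc.repertoire.PRODUCTIVE] * n
    df = pd.DataFrame(
        {
            "sequence": sequences,
            "v_gene": ["TRBV1"] * n,
            "d_gene": ["TRBD1"] * n,
            "j_gene": ["TRBJ1-1"] * n,
            "frame_status": frames,
            "read_count": list(counts),
        }
    )
    return tc.RepertoireSample(sample_id=sample_id, clones=df, **meta)


def uniform_exons(n, chromosome="chr1", exon_length=150, spacing=2000):
    starts = np.arange(n) * spacing
    return pd.DataFrame(
        {"chromosome": [chromosome] * n, "start": starts, "end": starts + exon_length}
    )


@pytest.fixture
def toy_sample():
    return make_sample([2, 1, 1])


@pytest.fixture(scope="session")
def male2_tumor():
    """Synthetic oligoclonal tumor with two dominant clones at 76.7%/9.7%."""
    cfg = tc.RepertoireSimConfig(
        n_reads=200_000,
        n_background_clones=10_000,
        expanded_clone_fractions=[0.767, 0.097],
        seed=0,
    )
    return tc.simulate_repertoire(cfg)
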