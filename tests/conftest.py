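import numpy as np
import pandas as pd
import pytest

from cfsubtype.types import SampleFragments


def make_sample(
    fragments,
    sample_id="S0",
    label="LUAD",
    material="tissue",
    total_fragments=None,
):
    """Build a SampleFragments from (region_id, n_cpgs, n_methylated) tuples."""
    frame = pd.DataFrame(
        list(fragments), columns=["region_id", "n_cpgs", "n_methylated"]
    )
    if total_fragments is None:
        total_fragments = max(len(frame), 1)
    return SampleFragments(sample_id, label, material, total_fragments, frame)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_region_samples(rng, n_target, n_other, n_frags=6, cpg_choices=(4, 5, 10)):
    """Random small single-region cohorts whose alphas lie on the 0.01 grid."""
    def cohort(n, label):
        out = []
        for i in range(n):
            k = rng.integers(1, n_frags + 1)
            frags = []
            for _ in range(k):
                nc = int(rng.choice(cpg_choices))
                frags.append(("r", nc, int(rng.integers(0, nc + 1))))
            out.append(make_sample(frags, sample_id=f"{label}{i}", label=label))
        return out
    return cohort(n_target, "LUAD"), cohort(n_other, "LUSC")
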