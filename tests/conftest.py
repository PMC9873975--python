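import logging

import numpy as np
import pandas as pd
import pytest

from cllmeth.datatypes import BetaMatrix
from cllmeth.synthdata import (
    MethylationEffects,
    generate_annotation,
    generate_methylation,
    make_sample_design,
)

logging.getLogger("cllmeth").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def annotation_small():
    return generate_annotation(2000, seed=11)


@pytest.fixture(scope="session")
def design_default():
    return make_sample_design(48, 28, n_mbl=2, seed=11)


@pytest.fixture(scope="session")
def null_methylation(annotation_small, design_default):
    """No injected effects beyond the sex-linked X structure."""
    bm, (meth, unmeth), ledger = generate_methylation(
        annotation_small, design_default,
        MethylationEffects(sex_effect_x=0.25), seed=11)
    return bm, meth, unmeth, ledger


def tiny_beta(values, probe_prefix="cg", sample_prefix="S", **companions):
    """Wrap a 2-D array as a BetaMatrix with generated axis labels."""
    values = np.asarray(values, dtype=float)
    probes = [f"{probe_prefix}{i}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j}" for j in range(values.shape[1])]
    wrap = lambda a: None if a is None else pd.DataFrame(
        np.asarray(a), index=probes, columns=samples)
    return BetaMatrix(pd.DataFrame(values, index=probes, columns=samples),
                      detection_p=wrap(companions.get("detection_p")),
                      bead_count=wrap(companions.get("bead_count")))
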