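import numpy as np
import pandas as pd
import pytest

from oxhmc import core_io, hmc_calling, qc
from oxhmc import synthetic_data as sd


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale simulated dataset shared across test modules."""
    ann, genes = sd.generate_annotation(4000, seed=11)
    truth = sd.generate_truth(
        ann,
        f=0.2,
        tissue_effect=0.05,
        feature_rr={"gene:gene_body": 2.0},
        seed=12,
    )
    data = sd.generate_betas(truth, n_donors={"discovery": 8, "validation": 6}, seed=13)
    return {"ann": ann, "genes": genes, "truth": truth, "data": data}


@pytest.fixture(scope="session")
def small_callset(small_sim):
    data = small_sim["data"]
    filtered, _ = qc.pfilter(data.betas, data.detp)
    masked, _ = qc.mask_probes(filtered, small_sim["ann"])
    pairs = core_io.pair_samples(masked, data.sheet, cohort="discovery")
    delta, meta = hmc_calling.compute_delta_beta(pairs, masked)
    tau = hmc_calling.estimate_threshold(delta)
    return hmc_calling.call_detectable(delta, meta, tau, betas=masked, pairs=pairs)


@pytest.fixture()
def tiny_beta_frame():
    return pd.DataFrame(
        [[0.1, 0.9], [0.4, 0.6]],
        index=["cgA", "cgB"],
        columns=["s1", "s2"],
    )


def make_pairs(donors, tissues=("prefrontal_cortex", "cerebellum")):
    """Explicit pairing helper for hand-built matrices."""
    pairs = []
    for d in donors:
        for t in tissues:
            pairs.append(core_io.SamplePair(d, t, f"{d}_{t}_bs", f"{d}_{t}_ox"))
    return core_io.PairedSampleSet(pairs=pairs)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
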