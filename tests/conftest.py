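import numpy as np
import pytest

from zbind import (
    SyntheticConfig,
    canonical_zscales,
    encode_dataset,
    generate_dataset,
    generate_linear_truth,
)


@pytest.fixture(scope="session")
def zt():
    return canonical_zscales()


def make_linear_problem(
    length: int,
    n: int,
    r2: float,
    sparsity: int = 9,
    effect_scale: float = 1.0,
    seed: int = 11,
):
    """Uniform random peptides with ln(ic50) linear in the z-scale descriptors.

    The noise sd is set from the realized signal variance so the population
    R^2 equals ``r2`` by construction.  Returns (X, y, beta).
    """
    beta = generate_linear_truth(length, sparsity=sparsity, effect_scale=effect_scale, seed=seed)

    def build(noise_sd):
        cfg = SyntheticConfig(
            n_peptides=(n,),
            subset_mean_offsets=(9.0,),
            true_effect_vector=beta,
            noise_sd=noise_sd,
            censor_points_nM=(),
            censor_fractions=(),
            peptide_length=length,
            seed=seed,
        )
        return encode_dataset(generate_dataset(cfg).records, canonical_zscales())

    X, _ = build(0.0)
    signal_var = float(np.var(X @ beta))
    noise_sd = float(np.sqrt(signal_var * (1.0 - r2) / r2))
    X, y = build(noise_sd)
    return X, y, beta
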