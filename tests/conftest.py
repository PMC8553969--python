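import numpy as np
import pandas as pd
import pytest

from canopygwas.simdata import (
    QtlEffectSpec,
    make_snp_panel,
    simulate_magic_population,
    simulate_traits,
)


@pytest.fixture(scope="session")
def small_panel():
    return make_snp_panel(100, n_chromosomes=5, chrom_length_bp=8_000_000)


@pytest.fixture(scope="session")
def small_haplotypes(small_panel):
    return simulate_magic_population(
        165, small_panel, recombination_rate_per_bp=3e-7, seed=42
    )


@pytest.fixture(scope="session")
def planted_traits(small_panel, small_haplotypes):
    """Traits with one heading-specific +10 cm QTL for founder RU."""
    target = small_panel[small_panel["chromosome"] == 1]["snp_id"].iloc[10]
    spec = QtlEffectSpec(target, {"RU": 10.0}, stages={"heading"})
    traits = simulate_traits(
        small_haplotypes, small_panel, [spec], noise_sd=5.0, seed=43
    )
    return traits, spec


def class_means(values: pd.Series, groups: pd.Series):
    """Per-haplotype class means; independent of the effects module."""
    common = values.index.intersection(groups.index)
    return values.loc[common].groupby(groups.loc[common]).mean()
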