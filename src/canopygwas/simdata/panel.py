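"""SNP panel construction."""

from __future__ import annotations

import numpy as np
import pandas as pd

from canopygwas.io_formats import validate_panel


def make_snp_panel(
    n_snps: int,
    n_chromosomes: int = 5,
    chrom_length_bp: int = 40_000_000,
    *,
    spacing: str = "uniform",
    seed: int | None = None,
) -> pd.DataFrame:
    """Build a sorted SNP panel.

    Parameters
    ----------
    n_snps
        Total number of SNPs, split as evenly as possible across chromosomes.
    spacing
        ``"uniform"`` places SNPs on an even grid; ``"random"`` draws
        positions uniformly (without replacement) along each chromosome.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    rng = np.random.default_rng(seed)
    per_chrom = np.full(n_chromosomes, n_snps // n_chromosomes)
    per_chrom[: n_snps % n_chromosomes] += 1
    rows = []
    for chrom in range(1, n_chromosomes + 1):
        k = per_chrom[chrom - 1]
        if k == 0:
            continue
        if spacing == "uniform":
            pos = np.linspace(1, chrom_length_bp, k, dtype=np.int64)
            pos = np.unique(pos)
        elif spacing == "random":
            pos = np.sort(rng.choice(np.arange(1, chrom_length_bp + 1), size=k, replace=False))
        else:
            raise ValueError(f"unknown spacing {spacing!r}")
        for p in pos:
            rows.append((f"chr{chrom}_{int(p)}", chrom, int(p)))
    panel = pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp"])
    return validate_panel(panel)
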