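"""Founder-label mosaic simulator for a MAGIC-style population.

The multi-way funnel is emulated directly as a Markov founder-label
process along each chromosome: breakpoint events arrive as a Poisson
process in base-pair distance, and at each event the label is redrawn
from the configured founder frequencies.  Redrawing from the full
frequency vector (the current founder included) keeps the stationary
label distribution exactly equal to the configured frequencies; the
fraction ``1 - freq[current]`` of events are visible breakpoints.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from canopygwas.constants import FOUNDER_LABELS


def simulate_magic_population(
    n_lines: int,
    panel: pd.DataFrame,
    *,
    recombination_rate_per_bp: float = 1e-7,
    founder_freqs: Sequence[float] | None = None,
    missing_rate: float = 0.0,
    interchrom_gap_bp: float = 1e9,
    seed: int,
) -> pd.DataFrame:
    """Simulate a lines x SNPs matrix of founder-of-origin labels.

    Parameters
    ----------
    n_lines
        Number of inbred mosaic lines to generate.
    panel
        SNP panel with ``snp_id``, ``chromosome``, ``position_bp`` columns,
        sorted by (chromosome, position).
    recombination_rate_per_bp
        Poisson breakpoint intensity along the chromosome.  The default
        1e-7/bp (0.1 per Mb) gives realistic long founder blocks.
    founder_freqs
        Stationary founder frequencies (length 8, sums to 1).  Uniform by
        default.
    missing_rate
        Per-entry probability of masking the label to missing.
    interchrom_gap_bp
        Effective distance inserted between consecutive chromosomes; the
        label process is chained across chromosomes over this gap, so at
        any realistic rate chromosome starts are independent draws, while
        the zero-recombination limit is still a single-founder clone.
    seed
        Required; the whole matrix is a deterministic function of it.

    Returns
    -------
    pandas.DataFrame
        Index ``line_id`` (L001..), columns ``snp_id``; float values in
        1..8 with NaN for missing.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if len(panel) == 0:
        raise ValueError("SNP panel is empty")
    if recombination_rate_per_bp < 0:
        raise ValueError("recombination rate must be non-negative")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")

    freqs = np.full(8, 1 / 8) if founder_freqs is None else np.asarray(founder_freqs, float)
    if freqs.shape != (8,) or not np.isclose(freqs.sum(), 1.0) or (freqs < 0).any():
        raise ValueError("founder_freqs must be 8 non-negative values summing to 1")

    rng = np.random.default_rng(seed)
    labels = np.asarray(FOUNDER_LABELS)

    chroms = panel["chromosome"].to_numpy()
    positions = panel["position_bp"].to_numpy()
    chrom_slices = []
    for chrom in pd.unique(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        chrom_slices.append((idx, positions[idx]))

    n_snps = len(panel)
    out = np.empty((n_lines, n_snps), dtype=np.int8)
    p_gap = 1.0 - np.exp(-recombination_rate_per_bp * interchrom_gap_bp)
    for i in range(n_lines):
        current = rng.choice(labels, p=freqs)
        for c, (idx, pos) in enumerate(chrom_slices):
            if c > 0 and rng.random() < p_gap:
                current = rng.choice(labels, p=freqs)
            gaps = np.diff(pos)
            p_event = 1.0 - np.exp(-recombination_rate_per_bp * gaps)
            events = rng.random(gaps.shape) < p_event
            lab = np.empty(len(pos), dtype=np.int8)
            event_at = np.nonzero(events)[0]
            prev = 0
            for j in event_at:
                lab[prev: j + 1] = current
                current = rng.choice(labels, p=freqs)
                prev = j + 1
            lab[prev:] = current
            out[i, idx] = lab

    hap = pd.DataFrame(
        out.astype(float),
        index=pd.Index([f"L{i + 1:03d}" for i in range(n_lines)], name="line_id"),
        columns=panel["snp_id"].to_numpy(),
    )
    if missing_rate > 0:
        mask = rng.random(hap.shape) < missing_rate
        hap = hap.mask(mask)
    return hap
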