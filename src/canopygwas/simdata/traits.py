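"""Time-course and endpoint trait simulator with planted QTL architecture."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from canopygwas.constants import (
    CODE_TO_LABEL,
    STAGES,
    YEAR_DATS,
    stage_of_dat,
)

#: default per-trait noise standard deviations for endpoint traits
DEFAULT_ENDPOINT_NOISE = {
    "CL": 4.0,
    "PL": 2.0,
    "PN": 2.0,
    "PW": 4.0,
    "SLW": 5.0,
    "SDW": 5.0,
}


@dataclass(frozen=True)
class GrowthCurveParams:
    """Baseline canopy-height template: smooth rise to a peak, then a
    moderate linear decline (stems and panicles drooping)."""

    peak_dat: float = 83.0
    peak_height_cm: float = 100.0
    decline_cm_per_day: float = 0.3


def baseline_canopy_height(dat, params: GrowthCurveParams = GrowthCurveParams()):
    """Baseline CH (cm) at days-after-transplanting ``dat`` (scalar or array)."""
    t = np.asarray(dat, dtype=float)
    u = np.clip(t / params.peak_dat, 0.0, None)
    rise = params.peak_height_cm * (2 * u - u**2)
    fall = params.peak_height_cm - params.decline_cm_per_day * (t - params.peak_dat)
    out = np.where(t <= params.peak_dat, rise, fall)
    return float(out) if np.isscalar(dat) else out


@dataclass(frozen=True)
class QtlEffectSpec:
    """A planted QTL: per-founder trait shifts active in a stage window.

    Parameters
    ----------
    snp_id
        Target SNP; must exist in the panel used for simulation.
    effects_cm
        Mapping founder (code like ``"RU"`` or label 1..8) -> CH shift in cm.
        Unlisted founders have effect 0.
    stages
        Subset of {"tillering", "heading", "maturation"}; outside the
        window the CH effect is 0.  Defaults to all three (constant QTL).
    pleiotropy
        Mapping trait name -> coefficient; a line's shift on that trait is
        ``coefficient * (its CH effect size)``.  Opposite-sign PW/SLW
        coefficients plant the biomass-allocation trade-off.
    """

    snp_id: str
    effects_cm: Mapping[str | int, float]
    stages: frozenset = frozenset(STAGES)
    pleiotropy: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "stages", frozenset(self.stages))
        unknown = self.stages - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        eff = {}
        for key, value in self.effects_cm.items():
            label = CODE_TO_LABEL[key] if isinstance(key, str) else int(key)
            if label not in range(1, 9):
                raise ValueError(f"unknown founder {key!r}")
            if not np.isfinite(value):
                raise ValueError(f"non-finite effect for founder {key!r}")
            eff[label] = float(value)
        object.__setattr__(self, "effects_cm", eff)

    def effect_by_label(self) -> np.ndarray:
        """Length-9 lookup vector indexed by founder label (0 unused)."""
        vec = np.zeros(9)
        for label, value in self.effects_cm.items():
            vec[label] = value
        return vec


def simulate_traits(
    haplotypes: pd.DataFrame,
    panel: pd.DataFrame,
    qtl_specs: Sequence[QtlEffectSpec] = (),
    *,
    growth: GrowthCurveParams = GrowthCurveParams(),
    noise_sd: float = 5.0,
    timepoints_by_year: Mapping[str, Sequence[int]] | None = None,
    seed: int,
    growth_dev_frac: float = 0.5,
    vf_noise_sd: float = 2.0,
    colour_noise_sd: float = 1.5,
    endpoint_noise_sd: Mapping[str, float] | None = None,
    cl_slope: float = 0.85,
    cl_intercept: float = 5.0,
) -> pd.DataFrame:
    """Generate a long-format trait table for every line.

    Canopy height at each grid DAT is ``baseline(t) + sum of active QTL
    effects + u + e`` where ``u`` is a per-(line, year) growth deviation
    carrying ``growth_dev_frac`` of the noise variance and ``e``
    per-observation noise carrying the rest (the marginal per-DAT noise
    s.d. is exactly ``noise_sd`` and the two years stay independent;
    ``growth_dev_frac=0`` gives plain i.i.d. measurement noise).  Culm
    length is an affine function of the
    line's peak-DAT genetic CH plus the same growth deviation, which
    reproduces the strong CH-CL correlation; endpoint yield traits receive
    each QTL's pleiotropy shift; TW is the exact sum PW + SLW.  VF follows
    a logistic rise, leaf colour (−a*) a rise-then-fall template.
    """
    panel_ids = set(panel["snp_id"])
    for spec in qtl_specs:
        if spec.snp_id not in panel_ids:
            raise ValueError(f"QTL target SNP {spec.snp_id!r} is not in the panel")
        if spec.snp_id not in haplotypes.columns:
            raise ValueError(f"QTL target SNP {spec.snp_id!r} is not in the haplotype matrix")

    timepoints_by_year = dict(timepoints_by_year or YEAR_DATS)
    rng = np.random.default_rng(seed)
    lines = haplotypes.index.to_numpy()
    n = len(lines)

    # per-line, per-spec base effect size (cm); missing label -> 0
    spec_effect = np.zeros((len(qtl_specs), n))
    for s, spec in enumerate(qtl_specs):
        labels = haplotypes[spec.snp_id].to_numpy(float)
        ok = np.isfinite(labels)
        vec = spec.effect_by_label()
        spec_effect[s, ok] = vec[labels[ok].astype(int)]

    def stage_effect(year: str, dat: int) -> np.ndarray:
        total = np.zeros(n)
        for s, spec in enumerate(qtl_specs):
            if stage_of_dat_or_none(year, dat, timepoints_by_year) in spec.stages:
                total += spec_effect[s]
        return total

    def pleio(trait: str) -> np.ndarray:
        total = np.zeros(n)
        for s, spec in enumerate(qtl_specs):
            coeff = spec.pleiotropy.get(trait, 0.0)
            if coeff:
                total += coeff * spec_effect[s]
        return total

    rows: list[pd.DataFrame] = []

    def emit(trait, year, dat, values):
        rows.append(
            pd.DataFrame(
                {
                    "line_id": lines,
                    "trait": trait,
                    "year": year,
                    "dat": dat if dat is None else int(dat),
                    "value": values,
                }
            )
        )

    if not 0.0 <= growth_dev_frac <= 1.0:
        raise ValueError("growth_dev_frac must be in [0, 1]")
    u_sd = noise_sd * np.sqrt(growth_dev_frac)
    e_sd = noise_sd * np.sqrt(1.0 - growth_dev_frac)
    genetic_peak: dict[str, np.ndarray] = {}
    growth_dev: dict[str, np.ndarray] = {}
    for year, dats in timepoints_by_year.items():
        u = rng.normal(0.0, u_sd, n) if u_sd > 0 else np.zeros(n)
        growth_dev[year] = u
        peak_dat = min(dats, key=lambda d: abs(d - growth.peak_dat))
        for dat in dats:
            g = baseline_canopy_height(float(dat), growth) + stage_effect(year, dat)
            if dat == peak_dat:
                genetic_peak[year] = g
            e = rng.normal(0.0, e_sd, n) if e_sd > 0 else 0.0
            emit("CH", year, dat, g + u + e)
        for dat in dats:
            vf = 95.0 / (1.0 + np.exp(-0.08 * (dat - 40.0)))
            vf = vf + pleio("VF") + (rng.normal(0.0, vf_noise_sd, n) if vf_noise_sd > 0 else 0.0)
            emit("VF", year, dat, np.clip(vf, 0.0, 100.0))
        for dat in dats:
            colour = 25.0 - 0.004 * (dat - 75.0) ** 2
            colour = colour + pleio("minus_a_star") + (
                rng.normal(0.0, colour_noise_sd, n) if colour_noise_sd > 0 else 0.0
            )
            emit("minus_a_star", year, dat, np.clip(colour, -128.0, 128.0))

    ep_noise = dict(DEFAULT_ENDPOINT_NOISE)
    ep_noise.update(endpoint_noise_sd or {})

    def noise(trait):
        sd = ep_noise[trait]
        return rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)

    for year in timepoints_by_year:
        cl = (cl_slope * (genetic_peak[year] + growth_dev[year])
              + cl_intercept + pleio("CL") + noise("CL"))
        pl = 20.0 + pleio("PL") + noise("PL")
        pn = np.clip(np.rint(12.0 + pleio("PN") + noise("PN")), 0, None)
        pw = 30.0 + pleio("PW") + noise("PW")
        slw = 40.0 + pleio("SLW") + noise("SLW")
        sdw = 45.0 + pleio("SDW") + noise("SDW")
        emit("CL", year, None, cl)
        emit("PL", year, None, pl)
        emit("PN", year, None, pn)
        emit("PW", year, None, pw)
        emit("SLW", year, None, slw)
        emit("TW", year, None, pw + slw)
        emit("SDW", year, None, sdw)

    traits = pd.concat(rows, ignore_index=True)
    traits["dat"] = traits["dat"].astype("Int64")
    return traits


def stage_of_dat_or_none(year, dat, timepoints_by_year):
    """Stage of a DAT on this year's grid, via the standard grids when the
    year matches, else by grid index (grids are 6-point by convention)."""
    if year in YEAR_DATS and tuple(timepoints_by_year[year]) == YEAR_DATS[year]:
        return stage_of_dat(year, dat)
    grid = list(timepoints_by_year[year])
    idx = grid.index(dat)
    from canopygwas.constants import PAIR_STAGES

    if len(grid) == len(PAIR_STAGES):
        return PAIR_STAGES[idx]
    # fall back: first third tillering, middle heading, last maturation
    third = max(len(grid) // 3, 1)
    return ("tillering", "heading", "maturation")[min(idx // third, 2)]
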