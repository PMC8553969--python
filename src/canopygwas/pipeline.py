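"""End-to-end orchestration: simulate -> (render/extract) -> scan -> call -> effects.

Every stage is a pure function of the config plus upstream files, writes
plain-text intermediates carrying the config hash, and can be resumed:
a stage whose meta file matches the current config hash is skipped, and a
mismatching hash refuses to resume.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from canopygwas import io_formats
from canopygwas.constants import DEFAULT_DAT_PAIRS, ENDPOINT_TRAITS, PAIR_STAGES, YEAR_DATS
from canopygwas.effects import (
    build_effect_profiles,
    cluster_qtls,
    effect_correlation,
    effect_matrix,
    haplotype_effect,
    profile_quadratics,
)
from canopygwas.gwas import call_qtls, qtl_table, scan, select_snps
from canopygwas.imaging import measure_plots
from canopygwas.simdata import (
    GrowthCurveParams,
    QtlEffectSpec,
    make_snp_panel,
    render_scene,
    simulate_magic_population,
    simulate_traits,
)

log = logging.getLogger("canopygwas.pipeline")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (see README for the YAML form)."""

    seed: int = 0
    n_lines: int = 165
    n_snps: int = 500
    n_chromosomes: int = 5
    chrom_length_bp: int = 40_000_000
    recombination_rate_per_bp: float = 1e-7
    founder_freqs: Sequence[float] | None = None
    missing_rate: float = 0.0
    qtls: Sequence[Mapping[str, Any]] = field(default_factory=list)
    growth: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 5.0
    years: Mapping[str, Sequence[int]] | None = None
    p_cut: float = 1e-2
    product_cut: float = 1e-5
    merge_gap_bp: int = 2_000_000
    min_class_size: int = 4
    trait: str = "CH"
    name_prefix: str = "qCH"
    imaging: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("p_cut", "product_cut", "merge_gap_bp", "min_class_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def timepoints(self) -> dict[str, tuple[int, ...]]:
        years = self.years or YEAR_DATS
        return {str(y): tuple(int(d) for d in dats) for y, dats in years.items()}

    def dat_pairs(self) -> tuple[tuple[str, int, str, int], ...]:
        """(year1, dat1, year2, dat2) per paired timepoint, grid order."""
        tp = self.timepoints()
        if len(tp) < 2:
            raise ValueError(
                "two-year selection rule (select_snps) requires trait data "
                f"from two years; config has {sorted(tp)}"
            )
        (y1, d1), (y2, d2) = sorted(tp.items())[:2]
        if len(d1) != len(d2):
            raise ValueError("the two years' DAT grids must pair one-to-one")
        if self.years is None:
            return tuple(
                ("2019", a, "2018", b) for a, b in DEFAULT_DAT_PAIRS
            )
        return tuple((y1, a, y2, b) for a, b in zip(d1, d2))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run(config: RunConfig, outdir: str | Path, *, resume: bool = True) -> dict[str, Any]:
    """Execute the full pipeline; returns paths and in-memory artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    artifacts: dict[str, Any] = {"config_hash": chash, "outdir": outdir}
    run_log: dict[str, Any] = {"config_hash": chash, "seed": config.seed, "stages": {}}

    for stage, fn in (
        ("simdata", _stage_simdata),
        ("imaging", _stage_imaging),
        ("gwas", _stage_gwas),
        ("effects", _stage_effects),
    ):
        t0 = time.perf_counter()
        meta_path = outdir / f"{stage}.meta.json"
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            if meta.get("config_hash") != chash:
                raise RuntimeError(
                    f"stage {stage!r}: on-disk intermediates were produced with "
                    f"config hash {meta.get('config_hash')}, current is {chash}; "
                    "refusing to resume (use resume=False or a clean outdir)"
                )
            if resume and all(Path(p).exists() for p in meta.get("outputs", [])):
                log.info("stage %s: up to date, skipping", stage)
                fn(config, outdir, artifacts, load_only=True)
                run_log["stages"][stage] = {"skipped": True}
                continue
        try:
            outputs = fn(config, outdir, artifacts, load_only=False)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        meta_path.write_text(
            json.dumps({"config_hash": chash, "outputs": [str(p) for p in outputs]})
        )
        run_log["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": [str(p) for p in outputs],
        }

    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    return artifacts


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _resolve_qtl_specs(config: RunConfig, panel: pd.DataFrame) -> list[QtlEffectSpec]:
    specs = []
    for entry in config.qtls:
        entry = dict(entry)
        if "snp_id" not in entry:
            chrom, pos = int(entry.pop("chromosome")), int(entry.pop("position_bp"))
            entry["snp_id"] = nearest_snp(panel, chrom, pos)
        specs.append(
            QtlEffectSpec(
                snp_id=entry["snp_id"],
                effects_cm=entry.get("effects_cm", {}),
                stages=frozenset(entry.get("stages", ("tillering", "heading", "maturation"))),
                pleiotropy=entry.get("pleiotropy", {}),
            )
        )
    return specs


def nearest_snp(panel: pd.DataFrame, chromosome: int, position_bp: int) -> str:
    grp = panel[panel["chromosome"] == chromosome]
    if grp.empty:
        raise ValueError(f"no SNPs on chromosome {chromosome}")
    i = (grp["position_bp"] - position_bp).abs().idxmin()
    return str(panel.at[i, "snp_id"])


def _stage_simdata(config, outdir, artifacts, *, load_only):
    chash = config.config_hash()
    paths = {
        "panel": outdir / "panel.tsv",
        "haplotypes": outdir / "haplotypes.tsv",
        "traits": outdir / "traits.csv",
    }
    if load_only:
        artifacts["panel"] = io_formats.read_panel(paths["panel"])
        artifacts["haplotypes"] = io_formats.read_haplotypes(paths["haplotypes"])
        artifacts["traits"] = io_formats.read_traits(paths["traits"])
        return list(paths.values())

    panel = make_snp_panel(config.n_snps, config.n_chromosomes, config.chrom_length_bp)
    hap = simulate_magic_population(
        config.n_lines,
        panel,
        recombination_rate_per_bp=config.recombination_rate_per_bp,
        founder_freqs=config.founder_freqs,
        missing_rate=config.missing_rate,
        seed=config.seed,
    )
    specs = _resolve_qtl_specs(config, panel)
    traits = simulate_traits(
        hap,
        panel,
        specs,
        growth=GrowthCurveParams(**dict(config.growth)),
        noise_sd=config.noise_sd,
        timepoints_by_year=config.timepoints(),
        seed=config.seed + 1,
    )
    comment = f"config_hash: {chash}"
    io_formats.write_panel(panel, paths["panel"], header_comment=comment)
    io_formats.write_haplotypes(hap, paths["haplotypes"], header_comment=comment)
    io_formats.write_traits(traits, paths["traits"], header_comment=comment)
    artifacts.update(panel=panel, haplotypes=hap, traits=traits, qtl_specs=specs)
    return list(paths.values())


def _stage_imaging(config, outdir, artifacts, *, load_only):
    opts = dict(config.imaging)
    if not opts.get("enabled", False):
        artifacts["analysis_traits"] = artifacts["traits"]
        return []
    chash = config.config_hash()
    out_path = outdir / "extracted_traits.csv"
    if load_only:
        artifacts["analysis_traits"] = io_formats.read_traits(out_path)
        return [out_path]

    traits = artifacts["traits"]
    resolution = float(opts.get("resolution_m", 0.01))
    stat = opts.get("stat", "p95")
    cutoff = float(opts.get("fallback_a_cutoff", -10.0))
    scene_dir = outdir / "scenes"
    scene_dir.mkdir(exist_ok=True)

    wide = traits[traits["trait"].isin(["CH", "VF", "minus_a_star"])]
    extracted_rows = []
    scene_seed = config.seed + 1000
    for (year, dat), grp in wide.groupby(["year", "dat"]):
        pivot = grp.pivot_table(index="line_id", columns="trait", values="value")
        plot_values = pd.DataFrame(
            {
                "plot_id": pivot.index,
                "ch_m": pivot["CH"] / 100.0,
                "vf_pct": pivot["VF"].clip(0, 100),
                "minus_a_star": pivot["minus_a_star"],
            }
        ).reset_index(drop=True)
        scene = render_scene(
            plot_values,
            resolution_m=resolution,
            terrain_noise_sd_m=float(opts.get("terrain_noise_sd_m", 0.0)),
            seed=scene_seed,
        )
        scene_seed += 1
        io_formats.write_raster_scene(scene, scene_dir / f"scene_{year}_{dat}")
        measured = measure_plots(
            scene.rgb, scene.dsm, scene.baseline_dsm, scene.layout_frame(),
            stat=stat, fallback_a_cutoff=cutoff,
        )
        for rec in measured.itertuples(index=False):
            extracted_rows.extend(
                [
                    (rec.plot_id, "CH", year, dat, rec.CH_m * 100.0),
                    (rec.plot_id, "VF", year, dat, rec.VF_pct),
                    (rec.plot_id, "minus_a_star", year, dat, rec.minus_a_star),
                ]
            )
    extracted = pd.DataFrame(
        extracted_rows, columns=["line_id", "trait", "year", "dat", "value"]
    )
    extracted["dat"] = extracted["dat"].astype("Int64")
    endpoint = traits[~traits["trait"].isin(["CH", "VF", "minus_a_star"])]
    analysis = pd.concat([extracted, endpoint], ignore_index=True)
    io_formats.write_traits(analysis, out_path, header_comment=f"config_hash: {chash}")
    artifacts["analysis_traits"] = analysis
    return [out_path]


def _stage_gwas(config, outdir, artifacts, *, load_only):
    chash = config.config_hash()
    pairs = config.dat_pairs()
    scan_dir = outdir / "scans"
    qtl_path = outdir / "qtls.tsv"
    scan_paths = [
        scan_dir / f"scan_{config.trait}_{year}_{dat}.tsv"
        for (y1, d1, y2, d2) in pairs
        for year, dat in ((y1, d1), (y2, d2))
    ]
    traits = artifacts.get("analysis_traits", artifacts.get("traits"))
    hap = artifacts["haplotypes"]
    panel = artifacts["panel"]

    if load_only:
        scans = {}
        for i, (y1, d1, y2, d2) in enumerate(pairs):
            s1 = io_formats.read_scan(scan_dir / f"scan_{config.trait}_{y1}_{d1}.tsv")
            s2 = io_formats.read_scan(scan_dir / f"scan_{config.trait}_{y2}_{d2}.tsv")
            scans[i] = (s1, s2)
    else:
        scan_dir.mkdir(exist_ok=True)
        slice_ = traits[traits["trait"] == config.trait]
        by_key = {
            (str(year), int(dat)): grp.set_index("line_id")["value"]
            for (year, dat), grp in slice_.groupby(["year", "dat"])
        }
        scans = {}
        scan_cache: dict[tuple[str, int], pd.DataFrame] = {}
        for i, (y1, d1, y2, d2) in enumerate(pairs):
            for year, dat in ((y1, d1), (y2, d2)):
                key = (year, dat)
                if key not in scan_cache:
                    if key not in by_key:
                        raise ValueError(f"no {config.trait} data for year {year} DAT {dat}")
                    result = scan(by_key[key], hap, panel,
                                  min_class_size=config.min_class_size)
                    scan_cache[key] = result
                    io_formats.write_scan(
                        result.reset_index(),
                        scan_dir / f"scan_{config.trait}_{year}_{dat}.tsv",
                        header_comment=f"config_hash: {chash}",
                    )
            scans[i] = (scan_cache[(y1, d1)], scan_cache[(y2, d2)])

    selections = {
        i: select_snps(s1, s2, p_cut=config.p_cut, product_cut=config.product_cut)
        for i, (s1, s2) in scans.items()
    }
    stage_by_key = {i: PAIR_STAGES[i] if i < len(PAIR_STAGES) else None for i in scans}
    calls = call_qtls(
        selections,
        scans,
        panel,
        merge_gap_bp=config.merge_gap_bp,
        name_prefix=config.name_prefix,
        stage_by_key=stage_by_key,
    )
    if not load_only:
        io_formats.write_qtl_table(
            qtl_table(calls), qtl_path, header_comment=f"config_hash: {chash}"
        )
    artifacts.update(scans=scans, selections=selections, qtl_calls=calls)
    return [*scan_paths, qtl_path]


def _stage_effects(config, outdir, artifacts, *, load_only):
    chash = config.config_hash()
    paths = {
        "profiles": outdir / "effect_profiles.csv",
        "quadratics": outdir / "effect_quadratics.csv",
        "correlations": outdir / "effect_correlations.csv",
        "cluster": outdir / "qtl_cluster.nwk",
    }
    calls = artifacts["qtl_calls"]
    traits = artifacts.get("analysis_traits", artifacts.get("traits"))
    hap = artifacts["haplotypes"]

    if load_only:
        artifacts["effect_profiles"] = io_formats.read_effects(paths["profiles"])
        return [p for p in paths.values() if p.exists()]

    comment = f"config_hash: {chash}"
    profiles = build_effect_profiles(traits, hap, calls, config.trait,
                                     min_n=config.min_class_size)
    io_formats.write_effects(profiles, paths["profiles"], header_comment=comment)
    quads = profile_quadratics(profiles)
    io_formats.write_effects(quads, paths["quadratics"], header_comment=comment)

    # cross-trait haplotype-effect correlations at the peak paired DAT
    corr_rows = []
    pairs = config.dat_pairs()
    peak_idx = min(3, len(pairs) - 1)
    y1, d1, y2, d2 = pairs[peak_idx]
    endpoint = [t for t in ENDPOINT_TRAITS if (traits["trait"] == t).any()]
    for call in calls:
        groups = hap[call.rep_snp_id]
        for year, dat in ((y1, d1), (y2, d2)):
            ch_slice = traits[
                (traits["trait"] == config.trait)
                & (traits["year"] == year)
                & (traits["dat"] == dat)
            ].set_index("line_id")["value"]
            ch_prof = haplotype_effect(ch_slice, groups,
                                       min_n=config.min_class_size)["mean"]
            other_profiles = {}
            for t in endpoint:
                t_slice = traits[
                    (traits["trait"] == t) & (traits["year"] == year)
                ].set_index("line_id")["value"]
                other_profiles[t] = haplotype_effect(
                    t_slice, groups, min_n=config.min_class_size
                )["mean"]
            if "PW" in other_profiles and "SLW" in other_profiles:
                other_profiles["PW/SLW"] = other_profiles["PW"] / other_profiles["SLW"]
            for t, prof in other_profiles.items():
                res = effect_correlation(ch_prof, prof)
                if res is not None:
                    corr_rows.append(
                        (call.name, year, config.trait, t, res.r, res.p, res.n, res.tier)
                    )
    correlations = pd.DataFrame(
        corr_rows, columns=["qtl", "year", "trait_a", "trait_b", "r", "p", "n", "tier"]
    )
    io_formats.write_effects(correlations, paths["correlations"], header_comment=comment)

    outputs = [paths["profiles"], paths["quadratics"], paths["correlations"]]
    if len(calls) >= 2:
        try:
            matrix = effect_matrix(profiles)
            linkage, _order = cluster_qtls(matrix)
            io_formats.write_newick(linkage, list(matrix.index.astype(str)), paths["cluster"])
            outputs.append(paths["cluster"])
        except ValueError as exc:
            log.warning("clustering skipped: %s", exc)
    artifacts.update(effect_profiles=profiles, effect_quadratics=quads,
                     effect_correlations=correlations)
    return outputs
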