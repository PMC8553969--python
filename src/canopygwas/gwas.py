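"""Haplotype-based association scan and the two-year QTL-calling rule.

Each SNP is tested with a tie-corrected Kruskal-Wallis rank-sum test of
the trait values grouped by founder haplotype.  A SNP is selected when it
passes ``p < p_cut`` in both years and the product of the two p-values is
below ``product_cut`` (raw p-values; no multiple-testing adjustment).
Selected SNPs on a chromosome are merged into one QTL while consecutive
selected SNPs are at most ``merge_gap_bp`` apart; the representative SNP
of a QTL minimises the two-year p-value product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from canopygwas.constants import PAIR_STAGES, STAGES

DEFAULT_P_CUT = 1e-2
DEFAULT_PRODUCT_CUT = 1e-5
DEFAULT_MERGE_GAP_BP = 2_000_000
DEFAULT_MIN_CLASS_SIZE = 4


@dataclass(frozen=True)
class TestResult:
    """One Kruskal-Wallis test: statistic, degrees of freedom, p-value.

    ``log10p`` is computed on the log scale (chi-square log-survival) and
    stays finite where ``p`` underflows to the smallest float.
    """

    H: float
    df: int
    p: float
    k: int       # haplotype classes tested
    n: int       # lines tested
    snp_id: str | None = None
    log10p: float = 0.0


def kruskal_wallis(
    values: np.ndarray,
    groups: np.ndarray,
    *,
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
    snp_id: str | None = None,
) -> TestResult | None:
    """Tie-corrected Kruskal-Wallis test of ``values`` grouped by ``groups``.

    Lines with missing values or missing group labels are dropped, then
    classes with fewer than ``min_class_size`` members are excluded.
    Returns ``None`` when fewer than two classes survive.  When all
    surviving values are identical the result is H = 0, p = 1.

    H = [ (12 / (N(N+1))) * sum_i n_i (rbar_i - (N+1)/2)^2 ]
        / [ 1 - sum_t (t^3 - t) / (N^3 - N) ]

    with average ranks for ties and an upper-tail chi-square p-value on
    k - 1 degrees of freedom.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups, dtype=np.float64)
    keep = np.isfinite(values) & np.isfinite(groups)
    values, groups = values[keep], groups[keep]
    if values.size == 0:
        return None

    labels, inverse = np.unique(groups, return_inverse=True)
    counts = np.bincount(inverse)
    keep_class = counts >= min_class_size
    if keep_class.sum() < 2:
        return None
    if not keep_class.all():
        sel = keep_class[inverse]
        values, groups = values[sel], groups[sel]
        labels, inverse = np.unique(groups, return_inverse=True)
        counts = np.bincount(inverse)

    n = values.size
    k = labels.size
    ranks = stats.rankdata(values)
    rank_sums = np.bincount(inverse, weights=ranks)
    h_raw = 12.0 / (n * (n + 1)) * np.sum(rank_sums**2 / counts) - 3.0 * (n + 1)

    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    correction = 1.0 - tie_term / (n**3 - n)
    if correction <= 0:        # all values identical
        return TestResult(0.0, k - 1, 1.0, k, n, snp_id, 0.0)
    h = max(h_raw / correction, 0.0)
    p = float(stats.chi2.sf(h, k - 1))
    log10p = float(stats.chi2.logsf(h, k - 1)) / np.log(10)
    return TestResult(float(h), k - 1, min(max(p, np.nextafter(0, 1)), 1.0), k, n,
                      snp_id, log10p)


def scan(
    values: pd.Series,
    haplotypes: pd.DataFrame,
    panel: pd.DataFrame | None = None,
    *,
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
) -> pd.DataFrame:
    """Kruskal-Wallis test at every SNP of the haplotype matrix.

    Parameters
    ----------
    values
        Trait values indexed by line_id (one trait / year / timepoint).
    haplotypes
        Lines x SNPs founder-label matrix.
    panel
        Optional SNP panel; when given, chromosome and position columns
        are attached to the result.

    Returns
    -------
    pandas.DataFrame
        Indexed by snp_id with columns H, df, k, n, p (NaN rows mark SNPs
        with fewer than two testable classes).  A ``p_bonferroni`` column
        is included for information only; selection uses raw p.
    """
    common = values.index.intersection(haplotypes.index)
    if len(common) == 0:
        raise ValueError("no overlapping line ids between trait values and haplotypes")
    y = values.loc[common].to_numpy(dtype=np.float64)
    hap = haplotypes.loc[common]
    mat = hap.to_numpy(dtype=np.float64)

    records = np.full((hap.shape[1], 6), np.nan)
    for j in range(mat.shape[1]):
        res = kruskal_wallis(y, mat[:, j], min_class_size=min_class_size)
        if res is not None:
            records[j] = (res.H, res.df, res.k, res.n, res.p, res.log10p)
    out = pd.DataFrame(
        records,
        index=pd.Index(hap.columns, name="snp_id"),
        columns=["H", "df", "k", "n", "p", "log10p"],
    )
    n_tests = out["p"].notna().sum()
    out["p_bonferroni"] = np.minimum(out["p"] * max(n_tests, 1), 1.0)
    if panel is not None:
        meta = panel.set_index("snp_id")[["chromosome", "position_bp"]]
        out = meta.join(out, how="right")
    return out


def select_snps(
    scan_year1: pd.DataFrame,
    scan_year2: pd.DataFrame,
    *,
    p_cut: float = DEFAULT_P_CUT,
    product_cut: float = DEFAULT_PRODUCT_CUT,
) -> pd.Index:
    """Two-year SNP selection: p1 < p_cut, p2 < p_cut, p1*p2 < product_cut.

    SNPs missing (untestable) in either year are never selected.
    """
    if not scan_year1.index.equals(scan_year2.index):
        raise ValueError("the two scans were run on different SNP panels")
    p1 = scan_year1["p"]
    p2 = scan_year2["p"]
    ok = p1.notna() & p2.notna()
    log_prod = _log10_product(scan_year1, scan_year2)
    selected = ok & (p1 < p_cut) & (p2 < p_cut) & (log_prod < np.log10(product_cut))
    return scan_year1.index[selected]


def _log10_product(scan_year1: pd.DataFrame, scan_year2: pd.DataFrame) -> pd.Series:
    """log10(p1*p2) per SNP, on the log scale where available (no underflow)."""
    if "log10p" in scan_year1.columns and "log10p" in scan_year2.columns:
        return scan_year1["log10p"] + scan_year2["log10p"]
    with np.errstate(divide="ignore"):
        return np.log10(scan_year1["p"]) + np.log10(scan_year2["p"])


@dataclass
class QtlCall:
    """A called QTL: merged selected SNPs with a representative and flags."""

    name: str
    chromosome: int
    rep_snp_id: str
    rep_position_bp: int
    interval_bp: tuple[int, int]
    p_product: float              # may underflow to 0; see log10_p_product
    log10_p_product: float = float("nan")
    detected: dict[Hashable, bool] = field(default_factory=dict)
    stages: tuple[str, ...] = ()
    snp_ids: tuple[str, ...] = ()


def call_qtls(
    selections: Mapping[Hashable, pd.Index | Sequence[str]],
    scans: Mapping[Hashable, tuple[pd.DataFrame, pd.DataFrame]],
    panel: pd.DataFrame,
    *,
    merge_gap_bp: int = DEFAULT_MERGE_GAP_BP,
    name_prefix: str = "qCH",
    stage_by_key: Mapping[Hashable, str] | None = None,
) -> list[QtlCall]:
    """Merge per-timepoint SNP selections into QTL calls.

    ``selections`` maps a timepoint-pair key to the SNPs selected at that
    pair; ``scans`` maps the same keys to the (year1, year2) scan frames
    used for the selection.  Per chromosome, the union of selected SNPs is
    partitioned into runs with inter-SNP gaps <= ``merge_gap_bp``; each run
    becomes one call.  The representative SNP minimises the two-year
    p-value product over all timepoints (ties: lower position).  The
    result is order-invariant in ``selections``.
    """
    if stage_by_key is None:
        stage_by_key = {
            key: PAIR_STAGES[key] if isinstance(key, (int, np.integer)) else None
            for key in selections
        }
    keys = sorted(selections.keys(), key=repr)

    union: set[str] = set()
    for key in keys:
        union.update(selections[key])
    if not union:
        return []

    meta = panel.set_index("snp_id")
    # best (minimum over timepoints) two-year log10 p-product per SNP
    best_product = pd.Series(np.inf, index=meta.index)
    for key in keys:
        s1, s2 = scans[key]
        prod = _log10_product(s1, s2).reindex(meta.index)
        best_product = np.minimum(best_product, prod.fillna(np.inf))

    selected = meta.loc[sorted(union, key=lambda s: (meta.at[s, "chromosome"],
                                                     meta.at[s, "position_bp"]))]
    calls: list[QtlCall] = []
    for chrom, grp in selected.groupby("chromosome", sort=True):
        pos = grp["position_bp"].to_numpy()
        breaks = np.nonzero(np.diff(pos) > merge_gap_bp)[0]
        run_bounds = np.split(np.arange(len(pos)), breaks + 1)
        for run in run_bounds:
            snps = grp.index.to_numpy()[run]
            run_pos = pos[run]
            products = best_product.loc[snps].to_numpy()
            best = products.min()
            ties = snps[products <= best + 1e-9]
            rep = min(ties, key=lambda s: meta.at[s, "position_bp"])
            detected = {
                key: bool(len(pd.Index(selections[key]).intersection(snps)))
                for key in keys
            }
            stage_flags = tuple(
                stage for stage in STAGES
                if any(detected[key] and stage_by_key.get(key) == stage for key in keys)
            )
            calls.append(
                QtlCall(
                    name="",
                    chromosome=int(chrom),
                    rep_snp_id=str(rep),
                    rep_position_bp=int(meta.at[rep, "position_bp"]),
                    interval_bp=(int(run_pos.min()), int(run_pos.max())),
                    p_product=float(10.0**best) if np.isfinite(best) else float("nan"),
                    log10_p_product=float(best),
                    detected=detected,
                    stages=stage_flags,
                    snp_ids=tuple(snps),
                )
            )

    calls.sort(key=lambda c: (c.chromosome, c.rep_position_bp))
    per_chrom: dict[int, list[QtlCall]] = {}
    for call in calls:
        per_chrom.setdefault(call.chromosome, []).append(call)
    for chrom, chrom_calls in per_chrom.items():
        for i, call in enumerate(chrom_calls, start=1):
            call.name = (
                f"{name_prefix}{chrom}" if len(chrom_calls) == 1
                else f"{name_prefix}{chrom}-{i}"
            )
    return calls


def qtl_table(calls: Sequence[QtlCall]) -> pd.DataFrame:
    """Flatten QTL calls into a table mirroring a per-timepoint flag layout."""
    keys: list = []
    for call in calls:
        for key in call.detected:
            if key not in keys:
                keys.append(key)
    rows = []
    for call in calls:
        row = {
            "name": call.name,
            "chromosome": call.chromosome,
            "rep_snp_id": call.rep_snp_id,
            "rep_position_bp": call.rep_position_bp,
            "interval_start_bp": call.interval_bp[0],
            "interval_end_bp": call.interval_bp[1],
            "p_product": call.p_product,
            "log10_p_product": call.log10_p_product,
            "stages": "+".join(call.stages),
            "n_snps": len(call.snp_ids),
        }
        for key in keys:
            row[f"detected_{key}"] = call.detected.get(key, False)
        rows.append(row)
    return pd.DataFrame(rows)
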