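"""Haplotype-effect profiling, phenology fits, clustering and contrasts.

The haplotype effect of a QTL on a trait is the mean trait value of the
lines carrying each founder haplotype at the QTL's representative SNP;
classes with fewer than four lines are excluded, and each class mean is
also reported as a ratio to the mean over ALL lines (small classes
included in the denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from canopygwas.gwas import kruskal_wallis

DEFAULT_MIN_N = 4


def haplotype_effect(
    values: pd.Series,
    groups: pd.Series,
    *,
    min_n: int = DEFAULT_MIN_N,
) -> pd.DataFrame:
    """Per-haplotype class size, mean and ratio to the population mean.

    Parameters
    ----------
    values
        Trait values indexed by line_id (one trait / year / timepoint).
    groups
        Founder haplotype labels at the QTL's representative SNP, indexed
        by line_id.

    Returns
    -------
    pandas.DataFrame
        Indexed by haplotype label, columns ``n``, ``mean``, ``ratio``.
        Classes with fewer than ``min_n`` lines are absent.  ``ratio`` is
        the class mean divided by the mean over all lines with data
        (including lines in excluded small classes).
    """
    common = values.index.intersection(groups.index)
    vals = values.loc[common].astype(float)
    labs = groups.loc[common].astype(float)
    ok = vals.notna() & labs.notna()
    vals, labs = vals[ok], labs[ok]
    if len(vals) == 0:
        warnings.warn("no usable lines for haplotype effect", stacklevel=2)
        return pd.DataFrame(columns=["n", "mean", "ratio"])
    pop_mean = vals.mean()
    grouped = vals.groupby(labs)
    out = pd.DataFrame({"n": grouped.size(), "mean": grouped.mean()})
    out = out[out["n"] >= min_n]
    if out.empty:
        warnings.warn(f"no haplotype class reaches n >= {min_n}", stacklevel=2)
    out["ratio"] = out["mean"] / pop_mean
    out.index = out.index.astype(int)
    out.index.name = "haplotype"
    return out


def fit_quadratic(dats: Sequence[float], means: Sequence[float]) -> tuple[float, float, float] | None:
    """OLS quadratic fit mean(t) ~ c2*t^2 + c1*t + c0; None with < 3 points.

    With exactly three points the parabola interpolates them.
    """
    dats = np.asarray(dats, dtype=float)
    means = np.asarray(means, dtype=float)
    ok = np.isfinite(dats) & np.isfinite(means)
    if ok.sum() < 3:
        return None
    c2, c1, c0 = np.polyfit(dats[ok], means[ok], 2)
    return float(c2), float(c1), float(c0)


@dataclass(frozen=True)
class EffectCorrelation:
    r: float
    p: float
    n: int
    tier: str  # "**" p<0.01, "*" p<0.05, "" otherwise


def _tier(p: float, *, with_plus: bool = False) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if with_plus and p < 0.1:
        return "+"
    return ""


def effect_correlation(profile_a: pd.Series, profile_b: pd.Series) -> EffectCorrelation | None:
    """Pearson correlation of two per-haplotype effect vectors.

    Computed over the shared haplotype labels; returns ``None`` when
    fewer than three are shared.  The two-sided p-value comes from the
    t-distribution with n - 2 degrees of freedom.
    """
    shared = profile_a.index.intersection(profile_b.index)
    a = profile_a.loc[shared].astype(float)
    b = profile_b.loc[shared].astype(float)
    ok = a.notna() & b.notna()
    a, b = a[ok], b[ok]
    if len(a) < 3:
        return None
    r, p = stats.pearsonr(a, b)
    return EffectCorrelation(float(r), float(p), len(a), _tier(p))


def cluster_qtls(effect_matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Cluster QTLs on correlation distance (1 - Pearson r), average linkage.

    ``effect_matrix`` has one row per QTL and one column per
    (year, DAT) x haplotype entry; missing entries are allowed as long as
    every pair of rows shares at least three non-missing columns.

    Returns the scipy linkage matrix and the leaf order (QTL names).
    """
    if len(effect_matrix) < 2:
        raise ValueError("need at least two QTLs to cluster")
    names = list(effect_matrix.index.astype(str))
    X = effect_matrix.to_numpy(dtype=float)
    m = len(names)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ok = np.isfinite(X[i]) & np.isfinite(X[j])
            if ok.sum() < 3:
                raise ValueError(
                    f"QTL pair ({names[i]}, {names[j]}) shares fewer than 3 entries"
                )
            if X[i][ok].std() == 0 or X[j][ok].std() == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(X[i][ok], X[j][ok])[0, 1])
            dist[i, j] = dist[j, i] = 1.0 - r
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [names[i] for i in hierarchy.leaves_list(linkage)]
    return linkage, order


def allele_class_test(
    values: pd.Series,
    groups: pd.Series,
    class_map: Mapping[int | float, str],
    *,
    min_n: int = DEFAULT_MIN_N,
    alpha: float = 0.05,
) -> dict:
    """Group haplotypes into allele classes and test class differences.

    Returns a dict with per-class stats, a Kruskal-Wallis omnibus result,
    pairwise Wilcoxon rank-sum p-values and compact letter groupings at
    ``alpha`` (no multiplicity correction).
    """
    common = values.index.intersection(groups.index)
    vals = values.loc[common].astype(float)
    labs = groups.loc[common].astype(float)
    classes = labs.map(lambda h: class_map.get(int(h)) if np.isfinite(h) else None)
    ok = vals.notna() & classes.notna()
    vals, classes = vals[ok], classes[ok]

    sizes = classes.value_counts()
    keep = sizes[sizes >= min_n].index
    vals, classes = vals[classes.isin(keep)], classes[classes.isin(keep)]
    class_names = sorted(classes.unique())
    if len(class_names) < 2:
        return {"classes": None, "omnibus": None, "pairwise": None, "letters": None}

    stats_df = pd.DataFrame(
        {
            "n": classes.value_counts().reindex(class_names),
            "mean": vals.groupby(classes).mean().reindex(class_names),
        }
    )
    codes = pd.Categorical(classes, categories=class_names).codes.astype(float)
    omnibus = kruskal_wallis(vals.to_numpy(), codes, min_class_size=min_n)

    pairs = []
    pmat: dict[tuple[str, str], float] = {}
    for i, a in enumerate(class_names):
        for b in class_names[i + 1:]:
            res = stats.mannwhitneyu(
                vals[classes == a], vals[classes == b], alternative="two-sided"
            )
            pairs.append((a, b, float(res.pvalue)))
            pmat[(a, b)] = pmat[(b, a)] = float(res.pvalue)
    pairwise = pd.DataFrame(pairs, columns=["class_a", "class_b", "p"])

    letters = _letter_grouping(stats_df["mean"], pmat, alpha)
    return {"classes": stats_df, "omnibus": omnibus, "pairwise": pairwise, "letters": letters}


def _letter_grouping(means: pd.Series, pmat: Mapping, alpha: float) -> dict[str, str]:
    """Compact letter display from pairwise p-values (means-sorted runs)."""
    order = list(means.sort_values(ascending=False).index)
    runs = []
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and all(
            pmat[(order[a], order[b])] >= alpha
            for a in range(i, j + 2) for b in range(a + 1, j + 2)
        ):
            j += 1
        runs.append((i, j))
    maximal = [r for r in runs if not any(o[0] <= r[0] and r[1] <= o[1] and o != r for o in runs)]
    letters = {name: "" for name in order}
    for letter_idx, (i, j) in enumerate(sorted(set(maximal))):
        letter = chr(ord("a") + letter_idx)
        for k in range(i, j + 1):
            letters[order[k]] += letter
    return letters


@dataclass(frozen=True)
class ContrastResult:
    trait: str
    mean_top: float
    se_top: float
    mean_bottom: float
    se_bottom: float
    ratio: float          # top mean / bottom mean
    p: float | None       # Welch t-test, two-sided
    tier: str             # ** p<0.01, * p<0.05, + p<0.1


def contrast_extremes(
    trait_values: Mapping[str, pd.Series],
    groups: pd.Series,
    top_haplotypes: Sequence[int],
    bottom_haplotypes: Sequence[int],
) -> pd.DataFrame:
    """Compare lines carrying top vs bottom haplotype sets at a QTL.

    For each trait: group means with standard errors, the top/bottom
    ratio of means, and a Welch two-sided t-test with significance tiers
    at 0.01 (**), 0.05 (*) and 0.1 (+).  The p-value is missing when a
    group has fewer than two lines.
    """
    top_set = {int(h) for h in top_haplotypes}
    bottom_set = {int(h) for h in bottom_haplotypes}
    if not top_set or not bottom_set:
        raise ValueError("both haplotype sets must be non-empty")
    labels = groups.astype(float)
    top_lines = labels.index[labels.isin(top_set)]
    bottom_lines = labels.index[labels.isin(bottom_set)]

    rows = []
    for trait, series in trait_values.items():
        a = series.reindex(top_lines).dropna().to_numpy(dtype=float)
        b = series.reindex(bottom_lines).dropna().to_numpy(dtype=float)
        mean_a = float(np.mean(a)) if a.size else float("nan")
        mean_b = float(np.mean(b)) if b.size else float("nan")
        se_a = float(np.std(a, ddof=1) / np.sqrt(a.size)) if a.size > 1 else float("nan")
        se_b = float(np.std(b, ddof=1) / np.sqrt(b.size)) if b.size > 1 else float("nan")
        if a.size >= 2 and b.size >= 2:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            tier = _tier(p, with_plus=True)
        else:
            p, tier = None, ""
        rows.append(
            ContrastResult(trait, mean_a, se_a, mean_b, se_b,
                           mean_a / mean_b if mean_b else float("nan"), p, tier)
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def build_effect_profiles(
    traits: pd.DataFrame,
    haplotypes: pd.DataFrame,
    qtls: Sequence,
    trait: str = "CH",
    *,
    min_n: int = DEFAULT_MIN_N,
) -> pd.DataFrame:
    """Long table of haplotype effects for every QTL x (year, DAT).

    ``qtls`` is a sequence of QtlCall objects (only ``name`` and
    ``rep_snp_id`` are used).  Output columns: qtl, haplotype, year, dat,
    n, mean, ratio.
    """
    slice_ = traits[traits["trait"] == trait]
    rows = []
    for qtl in qtls:
        groups = haplotypes[qtl.rep_snp_id]
        for (year, dat), grp in slice_.groupby(["year", "dat"], dropna=False):
            values = grp.set_index("line_id")["value"]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prof = haplotype_effect(values, groups, min_n=min_n)
            for hap, rec in prof.iterrows():
                rows.append(
                    (qtl.name, int(hap), year, dat, int(rec["n"]),
                     float(rec["mean"]), float(rec["ratio"]))
                )
    out = pd.DataFrame(
        rows, columns=["qtl", "haplotype", "year", "dat", "n", "mean", "ratio"]
    )
    out["dat"] = out["dat"].astype("Int64")
    return out


def profile_quadratics(profiles: pd.DataFrame) -> pd.DataFrame:
    """Quadratic phenology coefficients per (qtl, haplotype, year)."""
    rows = []
    for (qtl, hap, year), grp in profiles.groupby(["qtl", "haplotype", "year"]):
        coeffs = fit_quadratic(grp["dat"].astype(float), grp["mean"])
        if coeffs is not None:
            rows.append((qtl, hap, year, *coeffs))
    return pd.DataFrame(rows, columns=["qtl", "haplotype", "year", "c2", "c1", "c0"])


def effect_matrix(profiles: pd.DataFrame, column: str = "ratio") -> pd.DataFrame:
    """Pivot effect profiles to QTLs x (year, dat, haplotype) for clustering.

    Defaults to the ratio-to-population-mean, which removes the shared
    baseline growth curve that would otherwise dominate every row.
    """
    return profiles.pivot_table(
        index="qtl", columns=["year", "dat", "haplotype"], values=column
    )
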