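"""Group comparisons and correlation analyses.

The statistics mirror a standard microbiome cohort workup:

* Kruskal-Wallis tests compare each feature (taxon relative abundance,
  alpha-diversity metric, phenotype or covariate) among enterotypes, with
  the chi-square approximation and mid-rank tie correction.  Raw p-values
  are reported alongside Benjamini-Hochberg q-values computed within each
  feature family.
* Compact letter displays summarize pairwise Mann-Whitney tests: groups
  sharing a letter were not significantly different at ``alpha`` after BH
  correction of the pairwise p-values.
* Spearman rank correlations describe genus co-occurrence and the
  relationships between butyrate-producing taxa, fecal butyrate content
  and the Buk/But gene copies (log10 scale).

Scalar tests are delegated to scipy.stats; this module owns the
per-feature orchestration, letter assignment and ranking logic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import (
    BUK,
    BUT,
    BUTYRATE,
    RELATIVE,
    AbundanceTable,
    EnterotypeLabels,
    PhenotypeTable,
    TableError,
    normalize_relative,
)
from .model_selection import AlphaDiversity


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H and chi-square p for values split by group labels.

    All-identical values give (H=0, p=1) rather than an error.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (Pearson on mid-ranks) with the t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("spearman needs at least 3 observations")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        raise ValueError("spearman undefined: zero rank variance")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def benjamini_hochberg(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def compact_letters(n_groups: int, significant_pairs) -> list[str]:
    """Greedy insert-and-absorb compact letter display.

    ``significant_pairs`` holds 0-based (i, j) group pairs that differ
    significantly; groups sharing a returned letter are *not* in any such
    pair.
    """
    letter_sets: list[set[int]] = [set(range(n_groups))]
    for i, j in sorted(tuple(sorted(p)) for p in significant_pairs):
        nxt: list[set[int]] = []
        for s in letter_sets:
            if i in s and j in s:
                nxt.append(s - {i})
                nxt.append(s - {j})
            else:
                nxt.append(s)
        # absorb sets contained in another
        letter_sets = []
        for s in sorted(nxt, key=len, reverse=True):
            if s and not any(s <= t for t in letter_sets):
                letter_sets.append(s)
    letter_sets.sort(key=lambda s: min(s))
    out = []
    for g in range(n_groups):
        out.append("".join(chr(ord("a") + idx) for idx, s in enumerate(letter_sets) if g in s))
    return out


def _pairwise_letters(values: np.ndarray, groups: np.ndarray, uniq, alpha: float) -> list[str]:
    pairs = list(combinations(range(len(uniq)), 2))
    pvals = []
    for i, j in pairs:
        a, b = values[groups == uniq[i]], values[groups == uniq[j]]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals.append(1.0)
        else:
            pvals.append(float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue))
    q = benjamini_hochberg(pvals)
    sig = [pairs[idx] for idx in range(len(pairs)) if q[idx] < alpha]
    return compact_letters(len(uniq), sig)


def _features_frame(features) -> tuple[pd.DataFrame, str]:
    """Coerce any supported feature container to (samples x features, family)."""
    if isinstance(features, AbundanceTable):
        t = features if features.unit == RELATIVE else normalize_relative(features)
        return t.data, "taxa"
    if isinstance(features, AlphaDiversity):
        return features.data, "alpha_diversity"
    if isinstance(features, PhenotypeTable):
        return features.data, "phenotype"
    if isinstance(features, pd.DataFrame):
        return features, "features"
    raise TypeError(f"unsupported feature container {type(features).__name__}")


def per_feature_group_tests(features, labels: EnterotypeLabels, alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis + letters for every feature across enterotypes.

    Returns one row per feature with per-group mean, median and SEM,
    the H statistic, raw p, BH q (within this feature family) and the
    compact letter display.  Features for which any group has fewer than
    two non-missing observations are skipped with a warning.
    """
    frame, _family = _features_frame(features)
    lab = labels.to_series().reindex(frame.index)
    if lab.isna().any():
        missing = frame.index[lab.isna()].tolist()
        raise TableError(f"samples without enterotype label: {missing[:5]}")
    groups_all = lab.to_numpy()
    uniq = np.unique(groups_all)
    rows = []
    for feat in frame.columns:
        col = frame[feat].to_numpy(dtype=float)
        ok = np.isfinite(col)
        values, groups = col[ok], groups_all[ok]
        sizes = [np.sum(groups == g) for g in uniq]
        if any(s < 2 for s in sizes):
            warnings.warn(f"feature {feat!r} skipped: a group has < 2 observations")
            continue
        h, p = kruskal_wallis(values, groups)
        if np.ptp(values) == 0:
            letters = ["a"] * len(uniq)
        else:
            letters = _pairwise_letters(values, groups, uniq, alpha)
        row = {"feature_id": feat, "H_statistic": h, "p_value": p}
        for gi, g in enumerate(uniq):
            gv = values[groups == g]
            row[f"mean_ET{g}"] = gv.mean()
            row[f"median_ET{g}"] = float(np.median(gv))
            row[f"sem_ET{g}"] = gv.std(ddof=1) / np.sqrt(len(gv))
            row[f"letter_ET{g}"] = letters[gi]
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature_id") if rows else pd.DataFrame()
    if len(out):
        out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out


@dataclass
class CooccurrenceResult:
    rho: pd.DataFrame  # square, unit diagonal; NaN where undefined
    long: pd.DataFrame  # pair, rho, p, q, undefined flag
    taxa: list[str] = field(default_factory=list)


def cooccurrence_matrix(table: AbundanceTable, top_n: int = 12) -> CooccurrenceResult:
    """Spearman co-occurrence among the ``top_n`` most abundant taxa.

    Taxa are ranked by mean relative abundance.  Constant taxa yield
    undefined correlations, kept as NaN with a flag rather than dropped.
    """
    t = table if table.unit == RELATIVE else normalize_relative(table)
    if top_n > t.n_taxa:
        raise ValueError(f"top_n={top_n} exceeds the {t.n_taxa} available taxa")
    order = t.data.mean(axis=0).sort_values(ascending=False).index[:top_n]
    sub = t.data[order]
    k = len(order)
    rho = np.eye(k)
    records = []
    for i, j in combinations(range(k), 2):
        x, y = sub.iloc[:, i].to_numpy(), sub.iloc[:, j].to_numpy()
        try:
            r, p = spearman(x, y)
            undefined = False
        except ValueError:
            r, p, undefined = np.nan, np.nan, True
        rho[i, j] = rho[j, i] = r
        records.append(
            {"taxon_a": order[i], "taxon_b": order[j], "rho": r, "p_value": p, "undefined": undefined}
        )
    long = pd.DataFrame(records)
    defined = ~long["undefined"]
    long["q_value"] = np.nan
    if defined.any():
        long.loc[defined, "q_value"] = benjamini_hochberg(long.loc[defined, "p_value"].to_numpy())
    rho_df = pd.DataFrame(rho, index=order, columns=order)
    return CooccurrenceResult(rho=rho_df, long=long, taxa=list(order))


@dataclass
class AssociationRanking:
    """Taxon vs butyrate/gene-copy correlation table, ranked by rho."""

    table: pd.DataFrame  # index taxon; rho/p vs butyrate, Buk, But
    gene_correlations: dict  # rho/p of butyrate vs Buk and vs But
    skipped_taxa: list[str] = field(default_factory=list)


def phenotype_association_ranking(
    table: AbundanceTable, phen: PhenotypeTable, candidate_taxa: list[str]
) -> AssociationRanking:
    """Rank candidate butyrate-producer genera by correlation with butyrate.

    For every candidate present in the table, Spearman rho of its relative
    abundance against fecal butyrate and against the log10 Buk and But
    gene copies; plus the two gene-vs-butyrate correlations.  Rows are
    sorted by rho vs butyrate, descending.  Missing candidates are
    reported, not fatal.
    """
    t = table if table.unit == RELATIVE else normalize_relative(table)
    if list(t.sample_ids) != list(phen.sample_ids):
        common = [s for s in t.sample_ids if s in set(phen.sample_ids)]
        t = AbundanceTable(t.data.loc[common], t.unit)
        phen = PhenotypeTable(phen.data.loc[common])
    if t.n_samples < 3:
        raise ValueError("fewer than 3 aligned samples; cannot correlate")
    buty = phen.data[BUTYRATE].to_numpy(dtype=float)
    buk = phen.data[BUK].to_numpy(dtype=float)
    but = phen.data[BUT].to_numpy(dtype=float)
    present = [g for g in candidate_taxa if g in t.data.columns]
    skipped = [g for g in candidate_taxa if g not in t.data.columns]
    rows = []
    for g in present:
        x = t.data[g].to_numpy(dtype=float)
        row = {"taxon": g}
        for name, y in (("butyrate", buty), ("buk", buk), ("but", but)):
            try:
                r, p = spearman(x, y)
            except ValueError:
                r, p = np.nan, np.nan
            row[f"rho_{name}"] = r
            row[f"p_{name}"] = p
        rows.append(row)
    ranking = pd.DataFrame(rows)
    if len(ranking):
        ranking = ranking.sort_values("rho_butyrate", ascending=False).set_index("taxon")
    gene_corr = {}
    for name, y in (("buk", buk), ("but", but)):
        r, p = spearman(buty, y)
        gene_corr[name] = {"rho": r, "p_value": p}
    return AssociationRanking(table=ranking, gene_correlations=gene_corr, skipped_taxa=skipped)
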