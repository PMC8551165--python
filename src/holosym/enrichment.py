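"""Rank-based functional enrichment (Mann-Whitney delta ranks).

Instead of testing only significant genes against a background, every gene
enters with a signed score -log(p) * sign(log2FC) from the differential
expression results (positive = higher in symbiotic samples).  For each
functional class (GO term within its division, or KOG class) a two-sided
Mann-Whitney U test compares the scores of member genes against all other
genes, and the effect is summarized as the *delta rank*: the mean rank of
member genes in the score ordering minus the mean rank of non-members.
Positive delta ranks mean the class is enriched among genes up-regulated in
the symbiotic state.  Because only ranks matter, results are invariant to
any strictly monotone transform of the scores (log base, scaling).

Delta ranks live on a shared, unit-free scale, so enrichment tables from
different species can be compared class-by-class: ``cross_taxa_compare``
joins tables on class ID, reports per-dataset delta ranks and p-values,
flags classes significant in every dataset, and correlates delta ranks
across the shared classes.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("holosym")

GO_DIVISIONS = ("BP", "MF", "CC")
P_FLOOR = 1e-300

#: class sizes at which exact Mann-Whitney enumeration is used
EXACT_MAX = 8


# ---------------------------------------------------------------------------
# Signed gene scores

def signed_scores(de_results: pd.DataFrame, log_base: float = np.e) -> pd.Series:
    """Per-gene signed -log(p) scores from a differential expression table.

    score = -log(p) * sign(log2FoldChange); p is floored at 1e-300 before
    the log.  Genes with missing p-values are excluded.  Ranks downstream
    are identical for any log base.
    """
    p = de_results["pvalue"]
    ok = p.notna()
    pv = p[ok].to_numpy(dtype=float)
    if (pv <= 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    lfc = de_results.loc[ok, "log2FoldChange"].to_numpy(dtype=float)
    score = -np.log(np.maximum(pv, P_FLOOR)) / np.log(log_base) * np.sign(lfc)
    return pd.Series(score, index=de_results.index[ok], name="score")


# ---------------------------------------------------------------------------
# Class maps

def invert_annotations(gene_to_classes: Mapping[str, Sequence[str]] | Mapping[str, str],
                       ) -> dict[str, frozenset[str]]:
    """Turn a gene -> class(es) annotation map into class -> member-gene sets."""
    classes: dict[str, set[str]] = {}
    for gene, anns in gene_to_classes.items():
        if isinstance(anns, str):
            anns = (anns,)
        for c in anns:
            classes.setdefault(c, set()).add(gene)
    return {c: frozenset(m) for c, m in classes.items()}


def merge_similar_classes(class_map: Mapping[str, frozenset[str]],
                          jaccard_threshold: float = 0.75) -> dict[str, frozenset[str]]:
    """Merge near-duplicate classes by member-set similarity (single linkage).

    Classes whose member sets have Jaccard similarity >= the threshold are
    merged transitively (single-linkage closure); the merged class takes
    the union of members and a name concatenated from its parts.
    """
    names = sorted(class_map)
    parent = {n: n for n in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in combinations(names, 2):
        ma, mb = class_map[a], class_map[b]
        union = len(ma | mb)
        if union and len(ma & mb) / union >= jaccard_threshold:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[str]] = {}
    for n in names:
        groups.setdefault(find(n), []).append(n)
    out: dict[str, frozenset[str]] = {}
    for members in groups.values():
        name = ";".join(sorted(members))
        genes = frozenset().union(*(class_map[m] for m in members))
        out[name] = genes
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney machinery

@lru_cache(maxsize=256)
def _combination_matrix(n: int, k: int) -> np.ndarray:
    """All C(n, k) index subsets as a boolean matrix (cached)."""
    idx = np.array(list(combinations(range(n), k)), dtype=np.int64)
    mask = np.zeros((len(idx), n), dtype=bool)
    mask[np.arange(len(idx))[:, None], idx] = True
    return mask

def _exact_mwu_p(ranks: np.ndarray, member_mask: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all member assignments.

    Valid under ties (works on the observed midranks): enumerates every way
    to choose the member set of the same size and computes the two-sided
    tail of the member rank sum, p = 2 * min(P(S <= s), P(S >= s)), capped
    at 1.
    """
    n = len(ranks)
    k = int(member_mask.sum())
    obs = ranks[member_mask].sum()
    sums = _combination_matrix(n, k).astype(float) @ ranks
    # tolerance guards float equality of midrank sums
    eps = 1e-9
    p_le = (sums <= obs + eps).mean()
    p_ge = (sums >= obs - eps).mean()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_mwu_p(scores: np.ndarray, member_mask: np.ndarray) -> float:
    """Two-sided MWU p, normal approximation with tie and continuity correction."""
    if np.all(scores == scores[0]):
        return 1.0  # every observation tied: no evidence either way
    res = stats.mannwhitneyu(scores[member_mask], scores[~member_mask],
                             alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def mwu_enrichment(scores: pd.Series, class_map: Mapping[str, frozenset[str]],
                   min_size: int = 5, max_frac: float = 0.1) -> pd.DataFrame:
    """Per-class Mann-Whitney enrichment on signed gene scores.

    For each class with at least ``min_size`` scored members covering at
    most ``max_frac`` of all scored genes: a two-sided MWU test of member
    vs non-member scores (exact enumeration when both groups have <= 8
    genes, otherwise the tie-corrected normal approximation with continuity
    correction) and the delta rank (mean member rank minus mean non-member
    rank, ranks ascending with ties averaged).  P-values are BH-adjusted
    across the tested classes.

    Genes absent from every class still shape the background ranking.
    """
    genes = np.array(scores.index)
    values = scores.to_numpy(dtype=float)
    n = len(genes)
    if n == 0:
        raise ValueError("empty score table")
    ranks = stats.rankdata(values, method="average")
    gene_pos = {g: i for i, g in enumerate(genes)}

    rows = []
    for class_id in sorted(class_map):
        members = [gene_pos[g] for g in class_map[class_id] if g in gene_pos]
        n_in = len(members)
        if n_in < min_size or n_in > max_frac * n:
            continue
        n_out = n - n_in
        if n_out == 0:
            log.warning("class %s covers every scored gene; skipped", class_id)
            continue
        mask = np.zeros(n, dtype=bool)
        mask[members] = True
        delta = ranks[mask].mean() - ranks[~mask].mean()
        if n_in <= EXACT_MAX and n_out <= EXACT_MAX:
            p = _exact_mwu_p(ranks, mask)
        else:
            p = _normal_mwu_p(values, mask)
        rows.append((class_id, n_in, delta, p))

    out = pd.DataFrame(rows, columns=["class_id", "n_members", "delta_rank", "p_mwu"])
    out = out.set_index("class_id")
    if len(out):
        out["fdr"] = multipletests(out["p_mwu"].to_numpy(), method="fdr_bh")[1]
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def go_enrichment_by_division(scores: pd.Series,
                              gene_to_go: Mapping[str, Sequence[str]],
                              go_divisions: Mapping[str, str],
                              min_size: int = 5,
                              max_frac: float = 0.1) -> dict[str, pd.DataFrame]:
    """Run mwu_enrichment separately per GO division (BP/MF/CC).

    ``go_divisions`` maps GO ID -> division label; terms with unknown
    division are skipped with a warning.
    """
    class_map = invert_annotations(gene_to_go)
    by_div: dict[str, dict[str, frozenset[str]]] = {d: {} for d in GO_DIVISIONS}
    for term, members in class_map.items():
        div = go_divisions.get(term)
        if div not in by_div:
            log.warning("GO term %s has no known division; skipped", term)
            continue
        by_div[div][term] = members
    return {d: mwu_enrichment(scores, cm, min_size, max_frac)
            for d, cm in by_div.items() if cm}


# ---------------------------------------------------------------------------
# Cross-taxon comparison

def cross_taxa_compare(tables: Mapping[str, pd.DataFrame],
                       alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare enrichment tables from different datasets/taxa.

    Inner-joins the tables on class ID, reports each dataset's delta rank
    and MWU p per shared class, flags classes with p < ``alpha`` in every
    dataset, and computes Pearson and Spearman correlations of delta ranks
    over shared classes for each dataset pair.

    Returns (per-class table, correlation table).
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 enrichment tables to compare")
    names = list(tables)
    shared: pd.Index | None = None
    for t in tables.values():
        shared = t.index if shared is None else shared.intersection(t.index)
    if shared is None or shared.empty:
        raise ValueError("no shared class IDs across datasets")
    shared = shared.sort_values()

    joined = pd.DataFrame(index=shared)
    for name in names:
        joined[f"delta_rank_{name}"] = tables[name].loc[shared, "delta_rank"]
        joined[f"p_{name}"] = tables[name].loc[shared, "p_mwu"]
    joined["significant_in_all"] = np.logical_and.reduce(
        [joined[f"p_{name}"] < alpha for name in names])

    corr_rows = []
    for a, b in combinations(names, 2):
        da = joined[f"delta_rank_{a}"]
        db = joined[f"delta_rank_{b}"]
        pear = stats.pearsonr(da, db) if len(shared) > 2 else (np.nan, np.nan)
        spear = stats.spearmanr(da, db) if len(shared) > 2 else (np.nan, np.nan)
        corr_rows.append((a, b, len(shared), pear[0], pear[1], spear[0], spear[1]))
    corr = pd.DataFrame(
        corr_rows,
        columns=["dataset_a", "dataset_b", "n_shared",
                 "pearson_r", "pearson_p", "spearman_rho", "spearman_p"],
    )
    return joined, corr
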