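"""Clone detection from RNA-seq-derived SNP genotypes.

Branching corals propagate asexually by fragmentation, so two sampled
colonies can be the same genet.  Sampling a clone twice would
pseudo-replicate the genetic blocking factor of the expression model, so
clones must be found and deduplicated before differential expression.

The procedure: filter variant calls down to well-covered bi-allelic SNPs,
count pairwise genotype differences across loci (the classic locus-difference
genetic distance), cluster samples by complete linkage, and flag a pair as
clonal when its distance falls far below the background — at most ``tau``
times the median of all pairwise distances.  One member per clone group is
then retained, chosen uniformly at random under a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .io import VariantTable

log = logging.getLogger("holosym")


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids),) * 2:
            raise ValueError("distance matrix shape does not match sample IDs")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0) or (v < 0).any():
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
        self.values = v


@dataclass
class Dendrogram:
    """Agglomerative clustering result: ordered merges with heights."""

    sample_ids: list[str]
    #: each merge: (members of left cluster, members of right cluster, height)
    merges: list[tuple[frozenset[str], frozenset[str], float]]

    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def newick(self) -> str:
        node: dict[frozenset[str], str] = {
            frozenset([s]): s for s in self.sample_ids
        }
        depth: dict[frozenset[str], float] = {frozenset([s]): 0.0 for s in self.sample_ids}
        for left, right, h in self.merges:
            bl = (h - depth[left]) / 2.0
            br = (h - depth[right]) / 2.0
            merged = left | right
            node[merged] = f"({node[left]}:{bl:g},{node[right]}:{br:g})"
            depth[merged] = h
        root = frozenset(self.sample_ids)
        return node[root] + ";"


@dataclass
class CloneReport:
    clone_groups: list[set[str]]
    representatives: dict[frozenset, str]
    removed: set[str]
    threshold: float
    dendrogram: Dendrogram | None = None


# ---------------------------------------------------------------------------

def filter_variants(vt: VariantTable, min_depth: int = 10,
                    min_qual: float = 30.0) -> VariantTable:
    """Keep well-genotyped bi-allelic SNPs.

    A site survives when every sample has depth >= ``min_depth`` and a
    called genotype, site QUAL >= ``min_qual``, there is exactly one
    alternate allele, and both alleles are single bases (boundaries
    inclusive).
    """
    if vt.n_sites == 0:
        raise ValueError("no variant sites to filter")
    covered = (vt.depth >= min_depth).all(axis=1)
    called = (vt.genotypes >= 0).all(axis=(1, 2))
    qual_ok = vt.qual >= min_qual
    biallelic = np.array([len(a) == 1 for a in vt.alt])
    snp = ~vt.is_indel()
    keep = covered & called & qual_ok & biallelic & snp
    n_kept = int(keep.sum())
    log.info("variant filter: input=%d removed=%d retained=%d",
             vt.n_sites, vt.n_sites - n_kept, n_kept)
    if n_kept == 0:
        raise ValueError(
            "variant filtering removed every site; consider relaxing "
            f"min_depth={min_depth} or min_qual={min_qual}"
        )
    return vt.take(keep)


def genetic_distance(vt: VariantTable, proportion: bool = False) -> DistanceMatrix:
    """Pairwise genetic distance: the number of loci with differing genotypes.

    Genotypes are compared as unordered allele pairs (0/1 == 1/0).  With
    ``proportion=True`` the count is divided by the number of loci.
    """
    n = len(vt.samples)
    if n < 2:
        raise ValueError("genetic distance needs at least 2 samples")
    if (vt.genotypes < 0).any():
        raise ValueError("missing genotypes present; run filter_variants first")
    # canonical unordered genotype code: sorted allele pair
    g = np.sort(vt.genotypes, axis=2)
    code = g[:, :, 0] * (g.max() + 2) + g[:, :, 1]  # (sites, samples)
    d = np.zeros((n, n), dtype=float)
    for i, j in combinations(range(n), 2):
        diff = int((code[:, i] != code[:, j]).sum())
        d[i, j] = d[j, i] = diff
    if proportion:
        d /= vt.n_sites
    return DistanceMatrix(list(vt.samples), d)


def hierarchical_cluster(dist: DistanceMatrix) -> Dendrogram:
    """Complete-linkage agglomerative clustering with deterministic ties.

    At every step the pair of clusters with the smallest complete-linkage
    distance merges; exact ties break toward the lexicographically smallest
    pair of cluster labels (a cluster is labelled by its smallest member).
    Merge heights are non-decreasing (complete linkage is monotone).
    """
    ids = list(dist.sample_ids)
    clusters: dict[str, frozenset[str]] = {s: frozenset([s]) for s in ids}
    d = {frozenset([a, b]): dist.values[i, j]
         for (i, a) in enumerate(ids) for (j, b) in enumerate(ids) if i < j}
    merges: list[tuple[frozenset[str], frozenset[str], float]] = []
    while len(clusters) > 1:
        labels = sorted(clusters)
        best = None
        for la, lb in combinations(labels, 2):
            h = d[frozenset([la, lb])]
            key = (h, la, lb)
            if best is None or key < best:
                best = key
        h, la, lb = best
        a, b = clusters.pop(la), clusters.pop(lb)
        new_label = min(la, lb)
        merged = a | b
        # complete linkage: distance to the merged cluster is the max
        for other in clusters:
            pair = frozenset([new_label, other])
            d[pair] = max(d[frozenset([la, other])], d[frozenset([lb, other])])
        clusters[new_label] = merged
        merges.append((a, b, float(h)))
    return Dendrogram(ids, merges)


def call_clones(dist: DistanceMatrix, tau: float = 0.25) -> list[set[str]]:
    """Flag sample pairs as clonal and return clone groups.

    A pair is clonal when its distance is at most ``tau`` times the median
    of all pairwise distances; clone groups are the connected components of
    the flagged pairs.  Needs >= 3 samples so a background median exists;
    errors if every pair is flagged (no background left).
    """
    n = len(dist.sample_ids)
    if n < 3:
        raise ValueError("clone calling needs at least 3 samples for a background")
    iu = np.triu_indices(n, k=1)
    pairwise = dist.values[iu]
    threshold = tau * float(np.median(pairwise))
    flagged = [(i, j) for i, j in zip(*iu) if dist.values[i, j] <= threshold]
    if len(flagged) == len(pairwise):
        raise ValueError("all sample pairs fall below the clone threshold; "
                         "background distance distribution is degenerate")
    # union-find over flagged pairs
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in flagged:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, set[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(dist.sample_ids[i])
    return sorted((g for g in groups.values() if len(g) > 1), key=lambda g: sorted(g))


def deduplicate(clone_groups: list[set[str]], seed: int,
                dist: DistanceMatrix | None = None, tau: float = 0.25) -> CloneReport:
    """Retain one member per clone group, chosen uniformly at random.

    Deterministic given the seed: the same seed always removes the same
    samples.  Samples outside any clone group are untouched.
    """
    rng = np.random.default_rng(seed)
    representatives: dict[frozenset, str] = {}
    removed: set[str] = set()
    for group in sorted((sorted(g) for g in clone_groups)):
        rep = group[rng.integers(len(group))]
        representatives[frozenset(group)] = rep
        removed |= set(group) - {rep}
    threshold = float("nan")
    if dist is not None:
        iu = np.triu_indices(len(dist.sample_ids), k=1)
        threshold = tau * float(np.median(dist.values[iu]))
    return CloneReport(
        clone_groups=[set(g) for g in sorted(sorted(g) for g in clone_groups)],
        representatives=representatives,
        removed=removed,
        threshold=threshold,
    )


def detect_clones(vt: VariantTable, min_depth: int = 10, min_qual: float = 30.0,
                  tau: float = 0.25, seed: int = 0) -> CloneReport:
    """Full clone-detection pipeline: filter -> distance -> cluster -> call -> dedup."""
    filtered = filter_variants(vt, min_depth=min_depth, min_qual=min_qual)
    dist = genetic_distance(filtered)
    dendro = hierarchical_cluster(dist)
    groups = call_clones(dist, tau=tau)
    report = deduplicate(groups, seed=seed, dist=dist, tau=tau)
    report.dendrogram = dendro
    return report
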