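"""Seeded synthetic inputs with the statistical structure each stage assumes.

Every generator is a pure function of its parameters and a seed (identical
seeds give identical outputs, each generator on its own RNG stream) and
returns, alongside the data, a truth record sufficient to score any
downstream stage's recovery:

* ``gen_assembly``          — contig FASTA with lognormal lengths and a target GC
* ``gen_contig_lengths``    — a length table with exact below/above-threshold counts
* ``gen_hit_tables``        — outfmt-6 hit tables with exact database-overlap structure
* ``gen_genotypes``         — a VCF with planted clone pairs and genotyping error
* ``gen_counts``            — NB counts with genet block effects and sparse state effects
* ``gen_class_annotations`` — gene scores with planted shifted functional classes

Default scales emulate the paired coral-branch study design (six genets,
one symbiotic and one aposymbiotic branch each) at sizes where the full
test suite stays fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import OUTFMT6_COLUMNS, ContigRecord, VariantTable

BASES = np.array(list("ACGT"))


@dataclass
class SimTruth:
    """What a generator planted, keyed by kind; enough to score recovery."""

    seed: int
    kind: str
    params: dict = field(default_factory=dict)
    planted: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Assemblies

def gen_assembly(n_contigs: int, length_mu: float = 6.8, length_sigma: float = 0.7,
                 gc_mean: float = 0.42, min_length: int = 100,
                 seed: int = 0) -> tuple[list[ContigRecord], SimTruth]:
    """Random contig set: lognormal lengths, Bernoulli-GC sequences.

    Lengths are drawn from lognormal(length_mu, length_sigma), floored at
    ``min_length`` and rounded to integers; each base is G or C with
    probability ``gc_mean``.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if length_sigma <= 0 or not (0 < gc_mean < 1):
        raise ValueError("invalid length/GC law parameters")
    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        np.round(rng.lognormal(length_mu, length_sigma, n_contigs)).astype(int),
        min_length,
    )
    records = []
    for i, L in enumerate(lengths):
        is_gc = rng.random(L) < gc_mean
        strong = rng.integers(0, 2, L)  # G vs C, A vs T
        codes = np.where(is_gc, 1 + strong, 3 * strong)  # C/G vs A/T
        seq = "".join(BASES[codes])
        records.append(ContigRecord(f"contig{i:07d}", int(L), seq))
    truth = SimTruth(seed, "assembly",
                     params=dict(n_contigs=n_contigs, length_mu=length_mu,
                                 length_sigma=length_sigma, gc_mean=gc_mean),
                     planted=dict(lengths=lengths))
    return records, truth


def gen_contig_lengths(n_short: int, n_long: int, threshold: int = 500,
                       max_length: int = 30000, seed: int = 0,
                       ) -> tuple[dict[str, int], SimTruth]:
    """Length table with exactly ``n_short`` contigs below ``threshold`` bases.

    Used to reproduce length-filter bookkeeping exactly: the short contigs
    get lengths in [100, threshold), the rest in [threshold, max_length].
    """
    rng = np.random.default_rng(seed)
    short = rng.integers(100, threshold, n_short)
    long_ = rng.integers(threshold, max_length + 1, n_long)
    lengths = np.concatenate([short, long_])
    ids = [f"contig{i:07d}" for i in range(n_short + n_long)]
    truth = SimTruth(seed, "contig_lengths",
                     params=dict(n_short=n_short, n_long=n_long, threshold=threshold),
                     planted=dict(n_short=n_short, n_long=n_long))
    return dict(zip(ids, lengths.tolist())), truth


# ---------------------------------------------------------------------------
# Hit tables

def _hit_rows(rng: np.random.Generator, qids: Sequence[str],
              passing: bool) -> pd.DataFrame:
    """Outfmt-6 rows for the given query IDs, passing or failing the
    >=100 bp / >=80% identity parse thresholds."""
    n = len(qids)
    if passing:
        length = rng.integers(100, 2000, n)
        pident = rng.uniform(80.0, 100.0, n)
    else:
        # fail on length, identity, or both
        mode = rng.integers(0, 3, n)
        length = np.where(mode == 1, rng.integers(100, 2000, n), rng.integers(30, 100, n))
        pident = np.where(mode == 0, rng.uniform(80.0, 100.0, n), rng.uniform(40.0, 79.99, n))
    df = pd.DataFrame({
        "qseqid": list(qids),
        "sseqid": [f"ref{int(i):08d}" for i in rng.integers(0, 10**7, n)],
        "pident": np.round(pident, 2),
        "length": length,
        "mismatch": rng.integers(0, 50, n),
        "gapopen": rng.integers(0, 5, n),
        "qstart": 1, "qend": length, "sstart": 1, "send": length,
        "evalue": 10.0 ** rng.uniform(-50, -4, n),
        "bitscore": np.round(rng.uniform(50, 2000, n), 1),
    })
    return df[OUTFMT6_COLUMNS]


def gen_hit_tables(n_holobiont: int, n_holo_ex_overlap: int,
                   n_in_hospite: int, n_in_apo_overlap: int,
                   n_ambiguous: int = 0, n_distractors: int = 100,
                   seed: int = 0) -> tuple[dict[str, pd.DataFrame], SimTruth]:
    """Hit tables whose post-parse membership sets have exact cell counts.

    Builds a contig universe and per-database outfmt-6 tables such that,
    after the >=100 bp / >=80% identity parse:

    * ``n_holobiont`` contigs hit the holobiont database, of which
      ``n_holo_ex_overlap`` also hit the ex-hospite database;
    * ``n_in_hospite`` contigs hit the in-hospite database, of which
      ``n_in_apo_overlap`` also hit the aposymbiotic-cnidarian database;
    * ``n_ambiguous`` contigs sit in both (holobiont minus ex-hospite) and
      (in-hospite minus apo) — the set removed as ambiguous.

    ``n_distractors`` sub-threshold hits per database are added so the
    parse filter has work to do.
    """
    n_coral = n_holobiont - n_holo_ex_overlap   # holobiont \ ex_hospite
    n_sym = n_in_hospite - n_in_apo_overlap     # in_hospite \ apo
    if n_coral < 0 or n_sym < 0:
        raise ValueError("overlap exceeds set size")
    if n_ambiguous > min(n_coral, n_sym):
        raise ValueError("ambiguous overlap exceeds a fraction size")

    # universe layout (disjoint ID blocks):
    #   [0, n_coral)                        coral-only + ambiguous prefix
    #   [n_coral, n_holobiont)              holobiont & ex_hospite
    #   ambiguous = first n_ambiguous of coral block, also in in_hospite
    #   symmetric layout for the symbiont side
    total = n_holobiont + n_sym - n_ambiguous + n_in_apo_overlap
    ids = np.array([f"c{i:08d}" for i in range(total)], dtype=object)
    holo_ids = ids[:n_holobiont]
    holo_ex_ids = ids[n_coral:n_holobiont]
    ambiguous_ids = ids[:n_ambiguous]
    sym_only = ids[n_holobiont:n_holobiont + (n_sym - n_ambiguous)]
    in_ids = np.concatenate([ambiguous_ids, sym_only,
                             ids[n_holobiont + (n_sym - n_ambiguous):]])
    in_apo_ids = ids[n_holobiont + (n_sym - n_ambiguous):]

    rng = np.random.default_rng(seed)
    tables: dict[str, pd.DataFrame] = {}
    for label, members in [("holobiont", holo_ids), ("ex_hospite", holo_ex_ids),
                           ("in_hospite", in_ids), ("apo_cnidarian", in_apo_ids)]:
        parts = [_hit_rows(rng, members, passing=True)]
        if n_distractors:
            dq = rng.choice(ids, size=min(n_distractors, total), replace=False)
            parts.append(_hit_rows(rng, dq, passing=False))
        tables[label] = pd.concat(parts, ignore_index=True)

    truth = SimTruth(
        seed, "hit_tables",
        params=dict(n_holobiont=n_holobiont, n_holo_ex_overlap=n_holo_ex_overlap,
                    n_in_hospite=n_in_hospite, n_in_apo_overlap=n_in_apo_overlap,
                    n_ambiguous=n_ambiguous),
        planted=dict(
            coral_after_ex=set(holo_ids) - set(holo_ex_ids),
            symbiont_after_apo=set(in_ids) - set(in_apo_ids),
            ambiguous=set(ambiguous_ids),
            n_coral_assigned=n_coral,
            n_symbiont_assigned=n_sym,
        ),
    )
    return tables, truth


# ---------------------------------------------------------------------------
# Genotypes

def gen_genotypes(n_samples: int = 6, n_loci: int = 5000,
                  clone_pairs: Sequence[tuple[str, str]] = (("A", "E"),),
                  error_rate: float = 0.005,
                  maf_low: float = 0.1, maf_high: float = 0.5,
                  depth_mean: float = 30.0, frac_low_depth: float = 0.03,
                  frac_low_qual: float = 0.02, frac_indel: float = 0.01,
                  frac_multiallelic: float = 0.01,
                  seed: int = 0) -> tuple[VariantTable, SimTruth]:
    """Genotype matrix with planted clone pairs plus filterable noise sites.

    Samples are colonies labelled A, B, C, ...  Non-clones draw genotypes
    independently per locus under Hardy-Weinberg with allele frequency ~
    Uniform(maf_low, maf_high).  Each clone copies its partner's genotypes
    and then flips one allele per locus with probability ``error_rate``
    (every flip changes the unordered genotype, so the expected clone-pair
    distance is error_rate * n_loci).  A controllable fraction of sites
    gets low depth, low QUAL, indel alleles, or a second alternate allele
    so the variant filters have realistic work.
    """
    if not 0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    samples = [chr(ord("A") + i) for i in range(n_samples)]
    for a, b in clone_pairs:
        if a not in samples or b not in samples:
            raise ValueError(f"clone pair ({a}, {b}) references unknown sample")
    rng = np.random.default_rng(seed)

    maf = rng.uniform(maf_low, maf_high, n_loci)
    gt = (rng.random((n_loci, n_samples, 2)) < maf[:, None, None]).astype(np.int64)
    flips_per_pair = {}
    for a, b in clone_pairs:
        ia, ib = samples.index(a), samples.index(b)
        gt[:, ib, :] = gt[:, ia, :]
        flip = rng.random(n_loci) < error_rate
        which = rng.integers(0, 2, n_loci)
        rows = np.flatnonzero(flip)
        gt[rows, ib, which[rows]] = 1 - gt[rows, ib, which[rows]]
        flips_per_pair[(a, b)] = int(flip.sum())

    depth = rng.poisson(depth_mean, (n_loci, n_samples)).astype(np.int64)
    depth = np.maximum(depth, 10)
    low_dp = rng.random((n_loci, n_samples)) < frac_low_depth
    depth[low_dp] = rng.integers(0, 10, int(low_dp.sum()))

    qual = rng.uniform(30.0, 2000.0, n_loci)
    low_q = rng.random(n_loci) < frac_low_qual
    qual[low_q] = rng.uniform(1.0, 29.99, int(low_q.sum()))

    ref_codes = rng.integers(0, 4, n_loci)
    alt_offsets = rng.integers(1, 4, n_loci)
    ref = [str(BASES[c]) for c in ref_codes]
    alt: list[tuple[str, ...]] = [(str(BASES[(c + o) % 4]),)
                                  for c, o in zip(ref_codes, alt_offsets)]
    indel = rng.random(n_loci) < frac_indel
    multi = (rng.random(n_loci) < frac_multiallelic) & ~indel
    for i in np.flatnonzero(indel):
        ref[i] = ref[i] + "A"
    for i in np.flatnonzero(multi):
        extra = str(BASES[(ref_codes[i] + alt_offsets[i] + 1) % 4])
        alt[i] = alt[i] + (extra,)
        # give the extra allele to one sample so the record is honest
        j = rng.integers(0, n_samples)
        gt[i, j, 1] = 2

    vt = VariantTable(
        samples=samples,
        chrom=np.array([f"contig{i // 50:06d}" for i in range(n_loci)], dtype=object),
        pos=np.array([(i % 50) * 37 + 11 for i in range(n_loci)], dtype=np.int64),
        ref=ref,
        alt=alt,
        qual=qual,
        genotypes=gt,
        depth=depth,
    )
    clean = (~indel & ~multi & ~low_q & ~low_dp.any(axis=1))
    truth = SimTruth(
        seed, "genotypes",
        params=dict(n_samples=n_samples, n_loci=n_loci, error_rate=error_rate,
                    maf_low=maf_low, maf_high=maf_high),
        planted=dict(clone_pairs=[tuple(p) for p in clone_pairs],
                     flips_per_pair=flips_per_pair,
                     n_clean_sites=int(clean.sum())),
    )
    return vt, truth


# ---------------------------------------------------------------------------
# Counts

def gen_counts(n_genes: int = 2000, genets: Sequence[str] = ("A", "B", "C", "D", "F"),
               frac_de: float = 0.0, lfc: float = 2.0, dispersion: float = 0.1,
               genet_sd: float = 0.3, lib_size_sd: float = 0.2,
               base_log2_mean: float = 6.0, base_log2_sd: float = 2.0,
               seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Overdispersed counts under the paired ``~ genet + state`` design.

    Every genet contributes one symbiotic and one aposymbiotic sample.
    K[i, j] ~ NB(mean = s_j * 2^(base_i + genet_effect + lfc * 1[symbiotic]),
    dispersion); exactly ceil(frac_de * n_genes) genes carry the state
    effect ``lfc`` (sign alternating), the rest none.  Genet effects are
    Normal(0, genet_sd) per gene x genet on the log2 scale; library size
    factors s_j are lognormal with sd ``lib_size_sd``.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    samples = [f"{g}_{st}" for g in genets for st in ("sym", "apo")]
    design = pd.DataFrame({
        "sample_id": samples,
        "genet": [g for g in genets for _ in range(2)],
        "state": ["symbiotic", "aposymbiotic"] * len(genets),
    }).set_index("sample_id")

    n_de = int(np.ceil(frac_de * n_genes))
    true_lfc = np.zeros(n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], int)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    true_lfc[de_idx] = lfc * signs

    base = rng.normal(base_log2_mean, base_log2_sd, n_genes)
    genet_eff = rng.normal(0.0, genet_sd, (n_genes, len(genets)))
    s = np.exp(rng.normal(0.0, lib_size_sd, len(samples)))
    s /= np.exp(np.log(s).mean())

    log2_q = (base[:, None]
              + np.repeat(genet_eff, 2, axis=1)
              + true_lfc[:, None] * (design["state"] == "symbiotic").to_numpy(float))
    mu = s[None, :] * np.exp2(np.clip(log2_q, -10, 26))
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)

    genes = [f"gene{i:05d}" for i in range(n_genes)]
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = SimTruth(
        seed, "counts",
        params=dict(n_genes=n_genes, genets=list(genets), frac_de=frac_de,
                    lfc=lfc, dispersion=dispersion, genet_sd=genet_sd),
        planted=dict(de_genes=[genes[i] for i in de_idx],
                     true_lfc=pd.Series(true_lfc, index=genes),
                     size_factors=pd.Series(s, index=samples)),
    )
    return counts_df, design, truth


# ---------------------------------------------------------------------------
# Annotations and scores

def gen_class_annotations(n_genes: int = 5000, n_classes: int = 50,
                          size_mu: float = 3.0, size_sigma: float = 0.6,
                          planted: Sequence[tuple[str, float]] = (),
                          min_size: int = 5,
                          seed: int = 0) -> tuple[dict[str, tuple[str, ...]],
                                                  pd.Series, SimTruth]:
    """Gene scores with planted shifted classes.

    Background scores ~ Normal(0, 1).  Classes (GO:0000001, ...) draw their
    sizes from a lognormal (floored at ``min_size``) and their members
    uniformly without replacement.  Every (class_id, delta) in ``planted``
    adds ``delta`` to its members' scores.

    Returns (gene -> class IDs annotation map, score Series, truth).
    """
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    scores = pd.Series(rng.normal(0.0, 1.0, n_genes), index=genes, name="score")

    class_ids = [f"GO:{i + 1:07d}" for i in range(n_classes)]
    members: dict[str, list[str]] = {}
    for cid in class_ids:
        size = max(min_size, int(np.round(rng.lognormal(size_mu, size_sigma))))
        size = min(size, n_genes)
        members[cid] = [genes[i] for i in rng.choice(n_genes, size, replace=False)]

    planted_map = dict(planted)
    unknown = set(planted_map) - set(class_ids)
    if unknown:
        raise ValueError(f"planted class(es) not generated: {sorted(unknown)}")
    for cid, delta in planted_map.items():
        idx = [int(g[4:]) for g in members[cid]]
        scores.iloc[idx] += delta

    gene_to_classes: dict[str, list[str]] = {g: [] for g in genes}
    for cid, ms in members.items():
        for g in ms:
            gene_to_classes[g].append(cid)
    ann = {g: tuple(cs) for g, cs in gene_to_classes.items() if cs}

    truth = SimTruth(
        seed, "class_annotations",
        params=dict(n_genes=n_genes, n_classes=n_classes),
        planted=dict(shifted_classes=planted_map,
                     class_members={c: frozenset(m) for c, m in members.items()}),
    )
    return ann, scores, truth


# ---------------------------------------------------------------------------
# Recovery scoring

def score_recovery(called: set, truth_set: set) -> dict[str, float]:
    """Sensitivity and false discovery proportion of a called set vs truth."""
    called, truth_set = set(called), set(truth_set)
    tp = len(called & truth_set)
    sens = tp / len(truth_set) if truth_set else float("nan")
    fdp = (len(called) - tp) / len(called) if called else 0.0
    return {"sensitivity": sens, "fdp": fdp,
            "n_called": len(called), "n_true": len(truth_set)}
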