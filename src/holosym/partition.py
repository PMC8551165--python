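"""Partition a holobiont transcriptome assembly into host and symbiont fractions.

A mixed coral + algal-symbiont ("holobiont") de novo assembly contains
contigs from both partners.  Given tabular alignment hits of the contigs
against four reference databases — a cnidarian holobiont database, cultured
*ex hospite* symbiont sequences, *in hospite* symbiont sequences, and
aposymbiotic cnidarian sequences — contigs are assigned by set logic:

* coral    = hits(holobiont)  minus  hits(ex hospite symbiont)
* symbiont = hits(in hospite) minus  hits(aposymbiotic cnidarian)
* contigs landing in both fractions are ambiguous and dropped from both.

Around that core sit the standard cleanup steps of a transcriptome build:
a minimum-length filter, rRNA removal against a SILVA hit set, collapsing
isoforms to the longest representative, annotation-based decontamination,
and N50/L50/GC assembly statistics.  Every removal step is recorded in an
ordered ledger of (step, n_input, n_removed, n_retained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import percent, round_half_up
from .config import RunConfig
from .io import AnnotationRecord, ContigRecord

log = logging.getLogger("holosym")

FRACTIONS = ("coral", "symbiont")

#: recognized hit-table database labels
DB_LABELS = ("holobiont", "ex_hospite", "in_hospite", "apo_cnidarian", "silva")

#: annotation keywords that flag algal contamination in the coral fraction;
#: both the usual spelling and the common transposition are matched
CORAL_CONTAMINANT_KEYWORDS = ("chloroplastic", "chroloplastic", "chlorophyll")

#: source taxa that flag cnidarian contamination in the symbiont fraction
SYMBIONT_CONTAMINANT_TAXA = ("acropora millepora", "nematostella vectensis")


@dataclass
class LedgerStep:
    step: str
    n_input: int
    n_removed: int

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed


@dataclass
class PartitionResult:
    """Disjoint coral/symbiont contig-ID sets plus the removal ledger."""

    coral_ids: set[str]
    symbiont_ids: set[str]
    ambiguous_ids: set[str]
    ledger: list[LedgerStep] = field(default_factory=list)

    def record(self, step: str, n_input: int, n_removed: int) -> None:
        entry = LedgerStep(step, n_input, n_removed)
        self.ledger.append(entry)
        log.info("%s: input=%d removed=%d retained=%d",
                 step, n_input, n_removed, entry.n_retained)

    def ledger_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.step, s.n_input, s.n_removed, s.n_retained) for s in self.ledger],
            columns=["step", "n_input", "n_removed", "n_retained"],
        )


@dataclass(frozen=True)
class AssemblyStats:
    """N50/L50-style summary of a contig set."""

    n_contigs: int
    n50: int
    l50: int
    max_length: int
    mean_length: float
    gc_percent: float | None = None


# ---------------------------------------------------------------------------

def parse_hits(hits: pd.DataFrame, min_aln_len: int = 100,
               min_pident: float = 80.0) -> pd.DataFrame:
    """Keep alignment hits that are long and similar enough to count.

    A hit is retained when its alignment length is at least ``min_aln_len``
    and its percent identity at least ``min_pident`` (both boundaries
    inclusive).  Idempotent; empty in, empty out.
    """
    if hits.empty:
        return hits.copy()
    keep = (hits["length"] >= min_aln_len) & (hits["pident"] >= min_pident)
    return hits.loc[keep].reset_index(drop=True)


def hit_query_ids(hits: pd.DataFrame) -> set[str]:
    """Contig IDs with at least one surviving hit."""
    if hits.empty:
        return set()
    return set(hits["qseqid"].astype(str))


def assign_fractions(holobiont_ids: set[str], ex_hospite_ids: set[str],
                     in_hospite_ids: set[str], apo_ids: set[str]) -> PartitionResult:
    """Set-logic assignment of contigs to coral vs symbiont fractions.

    Coral contigs hit the holobiont database but not the cultured symbiont
    database; symbiont contigs hit the in-hospite symbiont database but not
    the aposymbiotic cnidarian database.  Contigs qualifying for both
    fractions are ambiguous and removed from both.
    """
    coral = set(holobiont_ids) - set(ex_hospite_ids)
    symbiont = set(in_hospite_ids) - set(apo_ids)
    ambiguous = coral & symbiont
    result = PartitionResult(coral - ambiguous, symbiont - ambiguous, ambiguous)
    result.record("coral: holobiont hits minus ex-hospite hits",
                  len(holobiont_ids), len(holobiont_ids) - len(coral))
    result.record("symbiont: in-hospite hits minus aposymbiotic hits",
                  len(in_hospite_ids), len(in_hospite_ids) - len(symbiont))
    result.record("ambiguous contigs removed from coral", len(coral), len(ambiguous))
    result.record("ambiguous contigs removed from symbiont", len(symbiont), len(ambiguous))
    return result


def remove_rrna(fraction_ids: set[str], silva_hit_ids: set[str]) -> tuple[set[str], int]:
    """Drop contigs with a surviving SILVA (rRNA) hit from a fraction."""
    retained = set(fraction_ids) - set(silva_hit_ids)
    n_removed = len(fraction_ids) - len(retained)
    if not retained and fraction_ids:
        log.warning("rRNA removal emptied the fraction (%d contigs removed)", n_removed)
    return retained, n_removed


def length_filter(lengths: Mapping[str, int] | Sequence[ContigRecord],
                  min_len: int = 500) -> tuple[set[str], int, int]:
    """Remove contigs shorter than ``min_len`` bases.

    Returns (retained IDs, n_removed, percent removed rounded half-up to an
    integer).  A contig of exactly ``min_len`` bases is retained.
    """
    if not isinstance(lengths, Mapping):
        lengths = {c.contig_id: c.length for c in lengths}
    ids = np.array(list(lengths.keys()), dtype=object)
    lens = np.fromiter(lengths.values(), dtype=np.int64, count=len(ids))
    keep = lens >= min_len
    retained = set(ids[keep])
    n_removed = int((~keep).sum())
    pct = int(percent(n_removed, len(ids), 0)) if len(ids) else 0
    return retained, n_removed, pct


def collapse_isoforms(lengths: Mapping[str, int] | Sequence[ContigRecord],
                      cluster_map: Mapping[str, str]) -> set[str]:
    """Keep one representative contig per isoform cluster: the longest.

    Length ties break toward the lexicographically smallest contig ID.
    Every contig must appear in ``cluster_map``.
    """
    if not isinstance(lengths, Mapping):
        lengths = {c.contig_id: c.length for c in lengths}
    best: dict[str, tuple[int, str]] = {}
    for cid, length in lengths.items():
        try:
            cluster = cluster_map[cid]
        except KeyError:
            raise KeyError(f"contig {cid!r} missing from cluster map") from None
        # max on (length, reversed-ID order) == longest, ties to smallest ID
        key = (length, _NegStr(cid))
        if cluster not in best or key > (best[cluster][0], _NegStr(best[cluster][1])):
            best[cluster] = (length, cid)
    return {cid for _, cid in best.values()}


class _NegStr(str):
    """String whose ordering is reversed, for 'smallest ID wins' max() keys."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def annotation_cleanup(fraction: str,
                       annotations: Iterable[AnnotationRecord]) -> tuple[set[str], set[str]]:
    """Remove cross-contaminating genes from a fraction by annotation.

    Coral fraction: genes whose description mentions chloroplasts or
    chlorophyll (algal carryover).  Symbiont fraction: genes annotated to
    the cnidarians *Acropora millepora* or *Nematostella vectensis*.
    Returns (retained IDs, removed IDs) over the annotated genes.
    """
    if fraction not in FRACTIONS:
        raise ValueError(f"unknown fraction {fraction!r}; expected one of {FRACTIONS}")
    removed: set[str] = set()
    retained: set[str] = set()
    for ann in annotations:
        if fraction == "coral":
            name = ann.gene_name.lower()
            hit = any(k in name for k in CORAL_CONTAMINANT_KEYWORDS)
        else:
            taxon = (ann.source_taxon or "").strip().lower()
            hit = taxon in SYMBIONT_CONTAMINANT_TAXA
        (removed if hit else retained).add(ann.contig_id)
    return retained, removed


# ---------------------------------------------------------------------------

def assembly_stats(contigs: Sequence[ContigRecord] | Mapping[str, int],
                   require_gc: bool = False) -> AssemblyStats:
    """N50, L50, max/mean length and GC percent of a contig set.

    N50 is the length L such that the contigs of length >= L, taken
    longest-first, cover at least half of the total assembled bases; L50 is
    how many contigs that cover takes.  GC is computed over unambiguous
    bases only (A/C/G/T in numerator and denominator).
    """
    if isinstance(contigs, Mapping):
        lengths = np.asarray(list(contigs.values()), dtype=np.int64)
        seqs: list[str] = []
    else:
        lengths = np.asarray([c.length for c in contigs], dtype=np.int64)
        seqs = [c.sequence for c in contigs if c.sequence is not None]
    if lengths.size == 0:
        raise ValueError("assembly_stats of an empty contig set")
    order = np.sort(lengths)[::-1]
    csum = np.cumsum(order)
    half = csum[-1] / 2.0
    l50 = int(np.searchsorted(csum, half, side="left")) + 1
    n50 = int(order[l50 - 1])

    gc: float | None = None
    if seqs and (len(seqs) == lengths.size):
        gc_count = 0
        acgt_count = 0
        for s in seqs:
            su = s.upper()
            a, c, g, t = su.count("A"), su.count("C"), su.count("G"), su.count("T")
            gc_count += g + c
            acgt_count += a + c + g + t
        if acgt_count == 0:
            raise ValueError("GC requested but sequences contain no unambiguous bases")
        gc = 100.0 * gc_count / acgt_count
    elif require_gc:
        raise ValueError("GC percent requires sequences for every contig")

    return AssemblyStats(
        n_contigs=int(lengths.size),
        n50=n50,
        l50=l50,
        max_length=int(order[0]),
        mean_length=float(lengths.mean()),
        gc_percent=gc,
    )


# ---------------------------------------------------------------------------

def run_partition_pipeline(
    contigs: Sequence[ContigRecord] | Mapping[str, int],
    hit_tables: Mapping[str, pd.DataFrame],
    cluster_map: Mapping[str, str] | None = None,
    annotations: Mapping[str, Sequence[AnnotationRecord]] | None = None,
    config: RunConfig | None = None,
) -> tuple[PartitionResult, dict[str, AssemblyStats]]:
    """Full partition pipeline in fixed order.

    length filter -> per-database hit parsing -> fraction assignment ->
    rRNA removal per fraction -> isoform collapsing -> annotation cleanup,
    emitting the combined ledger and per-fraction assembly statistics.

    ``hit_tables`` maps db labels (see DB_LABELS) to raw outfmt-6 frames;
    missing tables are treated as empty.  ``annotations`` maps fraction name
    to its AnnotationRecords (unannotated contigs are never removed by the
    cleanup step).
    """
    cfg = config or RunConfig()
    if isinstance(contigs, Mapping):
        lengths = dict(contigs)
    else:
        lengths = {c.contig_id: c.length for c in contigs}

    unknown = set(hit_tables) - set(DB_LABELS)
    if unknown:
        raise ValueError(f"unknown hit-table label(s) {sorted(unknown)}")

    retained, n_removed, pct = length_filter(lengths, cfg.min_contig_len)
    lengths = {cid: lengths[cid] for cid in retained}

    empty = pd.DataFrame(columns=["qseqid", "length", "pident"])
    parsed: dict[str, set[str]] = {}
    for label in DB_LABELS:
        table = hit_tables.get(label, empty)
        if label == "silva":
            kept = parse_hits(table, cfg.silva_min_aln_len, cfg.silva_min_pident)
        else:
            kept = parse_hits(table, cfg.min_aln_len, cfg.min_pident)
        parsed[label] = hit_query_ids(kept) & retained

    result = assign_fractions(parsed["holobiont"], parsed["ex_hospite"],
                              parsed["in_hospite"], parsed["apo_cnidarian"])
    result.ledger.insert(0, LedgerStep(
        f"length filter (< {cfg.min_contig_len} bp removed, {pct}%)",
        len(retained) + n_removed, n_removed))

    fractions = {"coral": result.coral_ids, "symbiont": result.symbiont_ids}
    for name in FRACTIONS:
        kept, n_rrna = remove_rrna(fractions[name], parsed["silva"])
        result.record(f"{name}: SILVA rRNA removal", len(fractions[name]), n_rrna)
        fractions[name] = kept

    if cluster_map is not None:
        for name in FRACTIONS:
            frac_lengths = {cid: lengths[cid] for cid in fractions[name]}
            reps = collapse_isoforms(frac_lengths, cluster_map)
            result.record(f"{name}: isoform collapse", len(fractions[name]),
                          len(fractions[name]) - len(reps))
            fractions[name] = reps

    if annotations is not None:
        for name in FRACTIONS:
            anns = [a for a in annotations.get(name, ()) if a.contig_id in fractions[name]]
            _, removed = annotation_cleanup(name, anns)
            result.record(f"{name}: annotation cleanup", len(fractions[name]), len(removed))
            fractions[name] = fractions[name] - removed

    result.coral_ids = fractions["coral"]
    result.symbiont_ids = fractions["symbiont"]
    assert not (result.coral_ids & result.symbiont_ids)

    stats = {}
    for name in FRACTIONS:
        ids = fractions[name]
        if ids:
            stats[name] = assembly_stats({cid: lengths[cid] for cid in ids})
    return result, stats


def read_accounting(n_total: int, n_paired: int, decimals: int = 2) -> float:
    """Percent of retained reads that are paired, half-up rounded."""
    return percent(n_paired, n_total, decimals)
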