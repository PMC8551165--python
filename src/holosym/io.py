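"""Readers and writers for every on-disk format the pipeline touches.

FASTA goes through Biopython; VCF through cyvcf2; everything tabular
(BLAST outfmt-6 hit tables, count matrices, sample designs, annotation
maps, gene score tables) through pandas.  Each reader has a matching
writer and ``write(read(x)) == x`` on valid inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("holosym")

#: canonical column order of a 12-column tabular BLAST (outfmt 6) file
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

STATES = ("symbiotic", "aposymbiotic")


@dataclass(frozen=True)
class ContigRecord:
    """One assembled contig: an ID, its length in bases, optionally the sequence."""

    contig_id: str
    length: int
    sequence: str | None = None

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"contig {self.contig_id!r}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.contig_id!r}: length {self.length} != sequence length "
                f"{len(self.sequence)}"
            )


@dataclass(frozen=True)
class AnnotationRecord:
    """Functional annotation of one gene/contig."""

    contig_id: str
    gene_name: str = ""
    source_taxon: str | None = None
    go_terms: tuple[str, ...] = ()
    kog_class: str | None = None


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ContigRecord]:
    """Read a FASTA file into ContigRecords.

    IDs are the first whitespace-delimited token of each header.  Duplicate
    IDs are an error; an empty file yields an empty list with a warning.
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig ID {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        records.append(ContigRecord(rec.id, len(seq), seq))
    if not records:
        log.warning("no FASTA records in %s", path)
    return records


def write_fasta(records: Iterable[ContigRecord], path: str | Path) -> None:
    seqs = []
    for r in records:
        if r.sequence is None:
            raise ValueError(f"contig {r.contig_id!r} has no sequence to write")
        seqs.append(SeqRecord(Seq(r.sequence), id=r.contig_id, description=""))
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# BLAST tabular hit tables

def read_hit_table(path: str | Path, db_label: str) -> pd.DataFrame:
    """Read a 12-column outfmt-6 TSV, tagging every row with ``db_label``.

    Extra columns beyond 12 are ignored with a warning; malformed rows raise
    with their line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        log.warning("empty hit table %s", path)
        df = pd.DataFrame(columns=OUTFMT6_COLUMNS)
    if df.shape[1] > len(OUTFMT6_COLUMNS):
        log.warning(
            "%s: %d columns, ignoring columns beyond the standard 12",
            path, df.shape[1],
        )
        df = df.iloc[:, : len(OUTFMT6_COLUMNS)]
    if 0 < df.shape[1] < len(OUTFMT6_COLUMNS):
        raise ValueError(f"{path}: expected 12 tab-separated columns, found {df.shape[1]}")
    df.columns = OUTFMT6_COLUMNS
    for col, typ in [("pident", float), ("length", int), ("mismatch", int),
                     ("gapopen", int), ("qstart", int), ("qend", int),
                     ("sstart", int), ("send", int), ("evalue", float),
                     ("bitscore", float)]:
        try:
            df[col] = df[col].astype(typ)
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            lineno = int(bad[0]) + 1 if len(bad) else "?"
            raise ValueError(f"{path}: malformed value in column {col!r} at line {lineno}")
    bad_pident = ~df["pident"].between(0, 100)
    if bad_pident.any():
        lineno = int(df.index[bad_pident][0]) + 1
        raise ValueError(f"{path}: pident outside [0, 100] at line {lineno}")
    df["db"] = db_label
    return df.reset_index(drop=True)


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    hits[OUTFMT6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Counts and design

def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene x sample matrix of non-negative integer counts (genes as rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"{path}: non-integer count values")
        df = df.round().astype(np.int64)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative count values")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_design(path: str | Path) -> pd.DataFrame:
    """Sample design table: sample_id, genet, state in {symbiotic, aposymbiotic}.

    State labels are case-insensitive on read and canonicalized to lowercase.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "genet", "state"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: design needs columns {sorted(required)}")
    df["state"] = df["state"].str.lower().str.strip()
    unknown = set(df["state"]) - set(STATES)
    if unknown:
        raise ValueError(f"{path}: unknown state label(s) {sorted(unknown)}; expected {STATES}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs")
    return df.set_index("sample_id")


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.reset_index().to_csv(path, sep="\t", index=False)


def check_counts_design(counts: pd.DataFrame, design: pd.DataFrame) -> None:
    """Raise if count columns and design sample IDs do not match exactly."""
    if set(counts.columns) != set(design.index):
        raise ValueError(
            "sample-ID mismatch between counts and design: "
            f"counts-only={sorted(set(counts.columns) - set(design.index))}, "
            f"design-only={sorted(set(design.index) - set(counts.columns))}"
        )


# ---------------------------------------------------------------------------
# VCF

@dataclass
class VariantTable:
    """In-memory variant calls: per-site metadata plus genotype/depth arrays.

    ``genotypes`` is (n_sites, n_samples, 2) with allele indices, -1 for
    missing; ``depth`` is (n_sites, n_samples).
    """

    samples: list[str]
    chrom: np.ndarray      # (n_sites,) str
    pos: np.ndarray        # (n_sites,) int, 1-based
    ref: list[str]
    alt: list[tuple[str, ...]]
    qual: np.ndarray       # (n_sites,) float
    genotypes: np.ndarray  # (n_sites, n_samples, 2) int
    depth: np.ndarray      # (n_sites, n_samples) int

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def is_indel(self) -> np.ndarray:
        """Boolean mask of sites where ref or any alt is not a single base."""
        return np.array(
            [len(r) != 1 or any(len(a) != 1 for a in alts)
             for r, alts in zip(self.ref, self.alt)],
            dtype=bool,
        )

    def take(self, mask: np.ndarray) -> "VariantTable":
        idx = np.flatnonzero(mask)
        return VariantTable(
            samples=list(self.samples),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=[self.ref[i] for i in idx],
            alt=[self.alt[i] for i in idx],
            qual=self.qual[idx],
            genotypes=self.genotypes[idx],
            depth=self.depth[idx],
        )


def read_vcf(path: str | Path) -> VariantTable:
    """Read a VCF 4.x file (QUAL, per-sample GT and DP) into a VariantTable."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, pos, ref, alt, qual, gts, dps = [], [], [], [], [], [], []
    for v in vcf:
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(tuple(v.ALT))
        qual.append(v.QUAL if v.QUAL is not None else np.nan)
        gt = np.array([g[:2] for g in v.genotypes], dtype=np.int64)
        gts.append(gt)
        dp = v.format("DP")
        dps.append(
            dp.astype(np.int64).reshape(-1) if dp is not None
            else np.zeros(len(samples), dtype=np.int64)
        )
    vcf.close()
    n = len(pos)
    return VariantTable(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=ref,
        alt=alt,
        qual=np.array(qual, dtype=float),
        genotypes=(np.stack(gts) if n else np.empty((0, len(samples), 2), dtype=np.int64)),
        depth=(np.stack(dps) if n else np.empty((0, len(samples)), dtype=np.int64)),
    )


def write_vcf(vt: VariantTable, path: str | Path) -> None:
    """Write a VariantTable as minimal plain-text VCF 4.2 with GT:DP."""
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">']
    for contig in dict.fromkeys(vt.chrom):  # stable unique order
        lines.append(f"##contig=<ID={contig}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vt.samples))
    for i in range(vt.n_sites):
        cells = [
            str(vt.chrom[i]), str(int(vt.pos[i])), ".", vt.ref[i],
            ",".join(vt.alt[i]) if vt.alt[i] else ".",
            format(float(vt.qual[i]), "g") if np.isfinite(vt.qual[i]) else ".",
            "PASS", ".", "GT:DP",
        ]
        for j in range(len(vt.samples)):
            a, b = vt.genotypes[i, j]
            gt = "./." if a < 0 or b < 0 else f"{a}/{b}"
            cells.append(f"{gt}:{int(vt.depth[i, j])}")
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Annotation maps and gene score tables

def read_go_annotations(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Two-column TSV: gene TAB semicolon-joined GO IDs -> {gene: (GO, ...)}."""
    out: dict[str, tuple[str, ...]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        gene, terms = parts
        out[gene] = tuple(t for t in terms.split(";") if t)
    return out


def write_go_annotations(ann: Mapping[str, Sequence[str]], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{g}\t{';'.join(ts)}\n" for g, ts in ann.items())
    )


def read_kog_annotations(path: str | Path) -> dict[str, str]:
    """Two-column TSV: gene TAB single KOG class."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        out[parts[0]] = parts[1]
    return out


def write_kog_annotations(ann: Mapping[str, str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\t{k}\n" for g, k in ann.items()))


def read_score_table(path: str | Path) -> pd.Series:
    """Gene TAB signed score table -> Series indexed by gene."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"],
                     dtype={"gene": str, "score": float})
    if df["gene"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene IDs")
    return df.set_index("gene")["score"]


def write_score_table(scores: pd.Series, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", header=False)
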