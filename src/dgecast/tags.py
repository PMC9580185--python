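"""Tag catalog construction, raw-read cleaning and tag-to-gene counting.

In NlaIII-anchored DGE library construction, each transcript contributes a
21-nt tag: the CATG recognition site plus the 17 nt immediately 3' of the
3'-most CATG that still has 17 nt downstream (the 3'-most restriction
fragment stays bound to the oligo-dT bead, so it is the one sequenced).
Raw 49-bp reads are reduced to clean tags in five steps — adaptor
trimming, removal of adaptor-only reads, removal of reads with unknown
bases, removal of off-length candidates, and removal of single-copy tags —
then mapped to the catalog allowing at most one mismatch, keeping only
unambiguous assignments, and normalised to transcripts per million (TPM).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

TAG_LEN = 21
SITE = "CATG"
_DOWNSTREAM = TAG_LEN - len(SITE)  # 17 nt sequenced past the restriction site
_BASES = "ACGT"

__all__ = [
    "TagCatalog",
    "CleaningReport",
    "CountTable",
    "build_tag_catalog",
    "clean_tags",
    "map_tags",
    "compute_tpm",
    "library_correlation",
    "read_fasta",
    "read_reads",
]


@dataclass
class TagCatalog:
    """Canonical 21-nt tag per gene, with ambiguity bookkeeping.

    ``entries`` maps each catalog tag to the set of genes carrying it;
    ``ambiguous`` lists tags claimed by two or more genes; genes with no
    qualifying CATG site are collected in ``no_site_genes``.
    """

    entries: dict[str, frozenset[str]]
    ambiguous: frozenset[str]
    no_site_genes: frozenset[str]
    gene_tag: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_tag) | self.no_site_genes


@dataclass
class CleaningReport:
    """Accounting of the five cleaning steps over one read library."""

    input_reads: int = 0
    removed_adaptor_trim: int = 0  # reads where an adaptor hit was trimmed off
    removed_empty: int = 0
    removed_lowq: int = 0
    removed_length: int = 0
    removed_singleton: int = 0
    clean_tags_total: int = 0
    clean_tags_distinct: int = 0

    def check(self) -> None:
        """Every input read is either a clean tag or removed at exactly one step."""
        total = (
            self.clean_tags_total
            + self.removed_empty
            + self.removed_lowq
            + self.removed_length
            + self.removed_singleton
        )
        if total != self.input_reads:
            raise AssertionError(
                f"cleaning report does not reconcile: {total} != {self.input_reads}"
            )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1) + "\n")


@dataclass
class CountTable:
    """Per-gene unambiguous tag counts and TPM for one library."""

    library_id: str
    counts: dict[str, int]
    total_mapped: int
    tpm: dict[str, float]
    mapped_fraction: float | None = None

    @classmethod
    def from_counts(
        cls,
        library_id: str,
        counts: Mapping[str, int],
        mapped_fraction: float | None = None,
    ) -> "CountTable":
        counts = {g: int(c) for g, c in counts.items()}
        if any(c < 0 for c in counts.values()):
            raise ValueError("counts must be non-negative")
        total = sum(counts.values())
        tpm = compute_tpm(counts)
        return cls(library_id, counts, total, tpm, mapped_fraction)

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.counts)
        return pd.DataFrame(
            {
                "gene": genes,
                "count": [self.counts[g] for g in genes],
                "tpm": [self.tpm[g] for g in genes],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, library_id: str | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        if "gene" not in df.columns or "count" not in df.columns:
            raise ValueError(f"{path}: expected columns 'gene' and 'count'")
        counts = dict(zip(df["gene"].astype(str), df["count"].astype(int)))
        return cls.from_counts(library_id or Path(path).stem, counts)


def read_fasta(source) -> list[tuple[str, str]]:
    """Read (gene_id, sequence) pairs from a FASTA path or handle."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(source, "fasta")]


def read_reads(path) -> list[str]:
    """Read raw reads from FASTQ (``.fq``/``.fastq``) or one-per-line text."""
    path = Path(path)
    if path.suffix.lower() in {".fq", ".fastq"}:
        from Bio import SeqIO

        return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def _records(transcriptome) -> list[tuple[str, str]]:
    if isinstance(transcriptome, (str, Path)):
        return read_fasta(str(transcriptome))
    if hasattr(transcriptome, "records"):
        return list(transcriptome.records)
    return [(str(g), str(s)) for g, s in transcriptome]


def canonical_tag(sequence: str) -> str | None:
    """21-nt tag from the 3'-most CATG with >=17 valid nt downstream, or None.

    Windows containing characters outside A/C/G/T (e.g. N) never form tags.
    """
    seq = sequence.upper()
    best = None
    start = seq.find(SITE)
    while start != -1:
        end = start + TAG_LEN
        if end <= len(seq):
            window = seq[start:end]
            if all(b in _BASES for b in window):
                best = window
        start = seq.find(SITE, start + 1)
    return best


def build_tag_catalog(transcriptome) -> TagCatalog:
    """Digest a reference transcriptome into its canonical tag catalog."""
    records = _records(transcriptome)
    if not records:
        raise ValueError("empty transcriptome")
    ids = [g for g, _ in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids: {dupes}")

    entries: dict[str, set[str]] = {}
    gene_tag: dict[str, str] = {}
    no_site: set[str] = set()
    for gene, seq in records:
        tag = canonical_tag(seq)
        if tag is None:
            no_site.add(gene)
        else:
            gene_tag[gene] = tag
            entries.setdefault(tag, set()).add(gene)
    frozen = {t: frozenset(gs) for t, gs in entries.items()}
    ambiguous = frozenset(t for t, gs in frozen.items() if len(gs) > 1)
    return TagCatalog(frozen, ambiguous, frozenset(no_site), gene_tag)


def clean_tags(
    raw_reads: Iterable[str], adaptor: str
) -> tuple[Counter, CleaningReport]:
    """Apply the five cleaning steps to one library of raw reads.

    A read failing several criteria is counted at the first failing step,
    in the order: empty, unknown bases, off-length, singleton.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    adaptor = adaptor.upper()
    report = CleaningReport()
    candidates: Counter = Counter()
    for read in raw_reads:
        report.input_reads += 1
        read = read.strip().upper()
        pos = read.find(adaptor)
        if pos != -1:
            report.removed_adaptor_trim += 1
            candidate = read[:pos]
        else:
            candidate = read
        if not candidate:
            report.removed_empty += 1
        elif any(b not in _BASES for b in candidate):
            report.removed_lowq += 1
        elif len(candidate) != TAG_LEN:
            report.removed_length += 1
        else:
            candidates[candidate] += 1

    clean = Counter()
    for tag, n in candidates.items():
        if n == 1:
            report.removed_singleton += 1
        else:
            clean[tag] = n
    report.clean_tags_total = sum(clean.values())
    report.clean_tags_distinct = len(clean)
    report.check()
    return clean, report


def _neighbors(tag: str):
    for i, cur in enumerate(tag):
        for b in _BASES:
            if b != cur:
                yield tag[:i] + b + tag[i + 1 :]


def map_tags(
    clean_tags: Mapping[str, int], catalog: TagCatalog, library_id: str = "library"
) -> CountTable:
    """Assign clean tags to genes with at most one mismatch, unambiguously.

    An exact catalog hit beats any 1-mismatch hit; at the minimal observed
    distance the set of reachable genes must be a single gene, otherwise
    the tag is discarded (this includes exact hits on catalog-ambiguous
    tags).
    """
    counts = {g: 0 for g in catalog.genes}
    total_clean = 0
    for tag, n in clean_tags.items():
        if len(tag) != TAG_LEN:
            raise ValueError(f"clean tag of length {len(tag)} != {TAG_LEN}: {tag!r}")
        total_clean += n
        hit = catalog.entries.get(tag)
        if hit is None:
            reachable: set[str] = set()
            for nb in _neighbors(tag):
                reachable |= catalog.entries.get(nb, frozenset())
            hit = reachable
        if len(hit) == 1:
            counts[next(iter(hit))] += n
    total = sum(counts.values())
    if total == 0:
        tpm = {g: 0.0 for g in counts}
    else:
        tpm = compute_tpm(counts)
    frac = total / total_clean if total_clean else 0.0
    return CountTable(library_id, counts, total, tpm, mapped_fraction=frac)


def compute_tpm(counts: Mapping[str, int]) -> dict[str, float]:
    """Transcripts per million: count / total mapped tags * 1e6."""
    total = sum(counts.values())
    if total < 1:
        raise ValueError("cannot normalise an all-zero count table")
    return {g: c / total * 1e6 for g, c in counts.items()}


def library_correlation(
    table1: CountTable, table2: CountTable, scale: str = "log2tpm"
) -> float:
    """Pearson correlation of two libraries over the union of their genes.

    Missing genes count as zero. ``scale`` is ``"log2tpm"`` (default,
    log2(TPM+1)) or ``"counts"``.
    """
    genes = sorted(set(table1.counts) | set(table2.counts))
    if scale == "log2tpm":
        v1 = np.log2(np.array([table1.tpm.get(g, 0.0) for g in genes]) + 1.0)
        v2 = np.log2(np.array([table2.tpm.get(g, 0.0) for g in genes]) + 1.0)
    elif scale == "counts":
        v1 = np.array([table1.counts.get(g, 0) for g in genes], dtype=float)
        v2 = np.array([table2.counts.get(g, 0) for g in genes], dtype=float)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if len(genes) < 2 or np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("correlation undefined: need >=2 genes with variance")
    return float(pearsonr(v1, v2)[0])
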