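"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator takes an explicit integer seed and is deterministic given
it; there is no global random state. The generators emulate, at desk
scale, the inputs of a two-condition DGE study: a reference
transcriptome whose genes carry NlaIII CATG tags, a pair of tag libraries
with Poisson count noise and planted fold changes, 49-bp raw reads with
controllable contamination, limma-style DEG tables for three cohorts with
a planted shared/specific overlap structure, gene-set collections with one
planted enriched set, scored interaction edge lists with a planted hub,
and long-format qPCR Ct tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tags import SITE, TAG_LEN, canonical_tag

_BASES = np.array(list("ACGT"))
READ_LEN = 49
#: default 3' adaptor used to fill reads past the 21-nt tag (free parameter
#: of the simulation; real adaptor sequences are instrument-kit specific)
DEFAULT_ADAPTOR = "TCGTATGCCGTCTTCTGCTTG"

NO_SITE = "no-site"

__all__ = [
    "SyntheticTranscriptome",
    "SyntheticLibraryPair",
    "RawReadSet",
    "SyntheticDEGTables",
    "gen_transcriptome",
    "gen_library_pair",
    "gen_raw_reads",
    "gen_deg_tables",
    "gen_gene_sets",
    "gen_edge_list",
    "gen_ct_table",
    "write_fasta",
    "write_fastq",
    "write_reads_txt",
    "DEFAULT_ADAPTOR",
]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _seq_without_site(rng: np.random.Generator, n: int) -> str:
    seq = _rand_seq(rng, n)
    while SITE in seq:
        i = seq.find(SITE)
        seq = seq[:i] + _rand_seq(rng, 1) + seq[i + 1 :]
    return seq


@dataclass
class SyntheticTranscriptome:
    """Reference gene sequences plus the canonical tag each should yield."""

    records: list[tuple[str, str]]
    truth: dict[str, str]  # gene -> 21-nt tag, or the marker "no-site"

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.records]

    def to_fasta(self, path) -> None:
        write_fasta(self.records, path)


@dataclass
class SyntheticLibraryPair:
    """Two tag-count libraries with planted per-gene log2 fold changes."""

    counts1: dict[str, int]
    counts2: dict[str, int]
    depth1: int
    depth2: int
    de_truth: dict[str, float]
    seed: int


@dataclass
class RawReadSet:
    """Raw reads of one library plus the contamination composition."""

    reads: list[str]
    composition: dict[str, int] = field(default_factory=dict)


@dataclass
class SyntheticDEGTables:
    """Three DEG tables with a planted shared/specific membership structure."""

    tables: dict[str, pd.DataFrame]
    planted_membership: dict[str, str]
    directions: dict[str, str] = field(default_factory=dict)


def gen_transcriptome(
    n_genes: int,
    min_len: int = 120,
    max_len: int = 400,
    frac_no_site: float = 0.0,
    frac_shared_tag: float = 0.0,
    seed: int = 0,
) -> SyntheticTranscriptome:
    """Random transcriptome with controlled tag structure.

    About ``frac_no_site`` of genes contain no CATG at all; about
    ``frac_shared_tag`` of genes share their canonical tag pairwise with
    another gene (exercising ambiguity filtering); the remainder carry
    unique tags.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if min_len < TAG_LEN + 4 or max_len < min_len:
        raise ValueError("need max_len >= min_len >= 25")
    if not (0 <= frac_no_site <= 1 and 0 <= frac_shared_tag <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if frac_no_site + frac_shared_tag > 1:
        raise ValueError("frac_no_site + frac_shared_tag must be <= 1")
    rng = np.random.default_rng(seed)

    n_no_site = int(round(frac_no_site * n_genes))
    n_shared = int(round(frac_shared_tag * n_genes))
    if n_shared == 1:  # a tag cannot be shared by fewer than two genes
        n_shared = 2 if n_genes - n_no_site >= 2 else 0
    n_no_site = min(n_no_site, n_genes)
    n_shared = min(n_shared, n_genes - n_no_site)

    width = len(str(n_genes))
    ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    roles = ["no-site"] * n_no_site + ["shared"] * n_shared
    roles += ["unique"] * (n_genes - len(roles))
    rng.shuffle(roles)

    used_17mers: set[str] = set()

    def fresh_17mer() -> str:
        # no CATG may start inside the tag past position 0, else the
        # 3'-most-site rule would pick it instead of the planted site
        while True:
            s = _rand_seq(rng, TAG_LEN - 4)
            if SITE not in ("ATG" + s) and s not in used_17mers:
                used_17mers.add(s)
                return s

    # genes sharing a tag are paired off; an odd leftover joins the last pair
    shared_ids = [g for g, r in zip(ids, roles) if r == "shared"]
    shared_tag_of: dict[str, str] = {}
    for j in range(0, len(shared_ids) - 1, 2):
        t = SITE + fresh_17mer()
        shared_tag_of[shared_ids[j]] = t
        shared_tag_of[shared_ids[j + 1]] = t
    if len(shared_ids) % 2 and shared_ids:
        if len(shared_ids) >= 3:
            shared_tag_of[shared_ids[-1]] = shared_tag_of[shared_ids[-3]]
        else:
            shared_tag_of.pop(shared_ids[0], None)

    records: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    for gene, role in zip(ids, roles):
        length = int(rng.integers(min_len, max_len + 1))
        if role == "no-site" or (role == "shared" and gene not in shared_tag_of):
            records.append((gene, _seq_without_site(rng, length)))
            truth[gene] = NO_SITE
            continue
        tag = shared_tag_of.get(gene) or SITE + fresh_17mer()
        # suffix <= 3 nt so no CATG 3' of the planted site can qualify
        suffix = _seq_without_site(rng, int(rng.integers(0, 4)))
        prefix = _rand_seq(rng, max(1, length - TAG_LEN - len(suffix)))
        seq = prefix + tag + suffix
        assert canonical_tag(seq) == tag
        records.append((gene, seq))
        truth[gene] = tag
    return SyntheticTranscriptome(records, truth)


def gen_library_pair(
    transcriptome: SyntheticTranscriptome,
    depth1: int,
    depth2: int,
    n_de: int,
    de_log2fc: float = 0.0,
    seed: int = 0,
    de_min_expected: float = 0.0,
) -> SyntheticLibraryPair:
    """Poisson tag counts for two libraries with ``n_de`` planted DE genes.

    Baseline relative abundances are log-uniform over four orders of
    magnitude; library-2 expectations of the DE genes are multiplied by
    ``2**de_log2fc``. Counts are per-gene Poisson and the recorded depths
    are the realised totals. ``de_min_expected`` restricts the DE draw to
    genes whose expected library-1 count is at least that value.
    """
    if depth1 < 1 or depth2 < 1:
        raise ValueError("depths must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [g for g in transcriptome.gene_ids if transcriptome.truth[g] != NO_SITE]
    if n_de > len(genes):
        raise ValueError(f"n_de={n_de} exceeds the {len(genes)} tagged genes")

    rel = 10.0 ** rng.uniform(0.0, 4.0, size=len(genes))
    prop = rel / rel.sum()
    mu1 = prop * depth1

    eligible = np.flatnonzero(mu1 >= de_min_expected)
    if n_de > eligible.size:
        raise ValueError(
            f"only {eligible.size} genes reach expected count {de_min_expected}"
        )
    de_idx = rng.choice(eligible, size=n_de, replace=False) if n_de else np.array([], int)
    fc = np.ones(len(genes))
    fc[de_idx] = 2.0**de_log2fc
    mu2 = prop * depth2 * fc

    c1 = rng.poisson(mu1)
    c2 = rng.poisson(mu2)
    counts1 = {g: int(c) for g, c in zip(genes, c1)}
    counts2 = {g: int(c) for g, c in zip(genes, c2)}
    de_truth = {g: 0.0 for g in genes}
    for i in de_idx:
        de_truth[genes[i]] = float(de_log2fc)
    return SyntheticLibraryPair(
        counts1, counts2, int(c1.sum()), int(c2.sum()), de_truth, seed
    )


def _fill_to(read: str, adaptor: str, length: int = READ_LEN) -> str:
    fill = (adaptor * (length // len(adaptor) + 2))[: max(0, length - len(read))]
    return (read + fill)[:length]


def _reads_for_library(
    counts: dict[str, int],
    truth: dict[str, str],
    adaptor: str,
    frac_empty: float,
    frac_lowq: float,
    frac_singleton_noise: float,
    frac_badlen: float,
    rng: np.random.Generator,
) -> RawReadSet:
    tags = []
    for gene, c in counts.items():
        if c == 0:
            continue
        if truth[gene] == NO_SITE:
            raise ValueError(f"gene {gene} has no tag site but count {c}")
        tags.extend([truth[gene]] * c)
    reads = [_fill_to(t, adaptor) for t in tags]
    n_clean = len(reads)
    comp = {"clean": n_clean}

    def n_of(frac: float) -> int:
        return int(rng.binomial(n_clean, frac)) if n_clean and frac > 0 else 0

    comp["empty"] = n_of(frac_empty)
    reads += [_fill_to("", adaptor)] * comp["empty"]

    comp["lowq"] = n_of(frac_lowq)
    for _ in range(comp["lowq"]):
        t = list(tags[rng.integers(0, n_clean)])
        t[rng.integers(0, TAG_LEN)] = "N"
        reads.append(_fill_to("".join(t), adaptor))

    comp["badlen"] = n_of(frac_badlen)
    for _ in range(comp["badlen"]):
        t = tags[rng.integers(0, n_clean)]
        t = t[:-2] if rng.random() < 0.5 else t + _rand_seq(rng, 2)
        reads.append(_fill_to(t, adaptor))

    comp["singleton"] = n_of(frac_singleton_noise)
    seen = set(tags)
    for _ in range(comp["singleton"]):
        while True:
            t = SITE + _rand_seq(rng, TAG_LEN - 4)
            if t not in seen:
                seen.add(t)
                break
        reads.append(_fill_to(t, adaptor))

    order = rng.permutation(len(reads))
    return RawReadSet([reads[i] for i in order], comp)


def gen_raw_reads(
    pair: SyntheticLibraryPair,
    transcriptome: SyntheticTranscriptome,
    adaptor: str = DEFAULT_ADAPTOR,
    frac_empty: float = 0.0,
    frac_lowq: float = 0.0,
    frac_singleton_noise: float = 0.0,
    seed: int = 0,
    frac_badlen: float = 0.0,
) -> tuple[RawReadSet, RawReadSet]:
    """49-bp raw reads realising each library's counts, plus contaminants.

    Contaminant classes: adaptor-only reads (empty), reads with an 'N' in
    the tag (low quality), truncated/elongated tags (off-length), and
    unique random tags occurring once (singletons). Their numbers are
    binomial draws relative to the clean read count and are recorded in
    each :class:`RawReadSet`'s composition.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    for name, f in [
        ("frac_empty", frac_empty),
        ("frac_lowq", frac_lowq),
        ("frac_singleton_noise", frac_singleton_noise),
        ("frac_badlen", frac_badlen),
    ]:
        if not 0 <= f <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    args = (adaptor, frac_empty, frac_lowq, frac_singleton_noise, frac_badlen)
    lib1 = _reads_for_library(pair.counts1, transcriptome.truth, *args, rng)
    lib2 = _reads_for_library(pair.counts2, transcriptome.truth, *args, rng)
    return lib1, lib2


def gen_deg_tables(
    n_genes: int,
    n_castration_only: int,
    n_crpc_shared: int,
    n_crpc_specific: int,
    seed: int = 0,
) -> SyntheticDEGTables:
    """Three limma-style DEG tables with a planted three-way overlap.

    ``castration``: significant for castration-only and shared genes;
    ``crpc_a``: significant for shared and specific genes; ``crpc_b``:
    significant for specific genes only. Directions are drawn once per
    gene and are consistent across tables, so direction-aware
    classification recovers exactly the planted shared and specific sets.
    Significant rows satisfy q < 0.001 and |log2FC| > 1.
    """
    if n_castration_only + n_crpc_shared + n_crpc_specific > n_genes:
        raise ValueError("category sizes exceed the gene universe")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"GENE{i + 1:0{width}d}" for i in range(n_genes)]
    perm = list(rng.permutation(n_genes))
    cast_only = [genes[i] for i in perm[:n_castration_only]]
    shared = [genes[i] for i in perm[n_castration_only : n_castration_only + n_crpc_shared]]
    specific = [
        genes[i]
        for i in perm[
            n_castration_only
            + n_crpc_shared : n_castration_only
            + n_crpc_shared
            + n_crpc_specific
        ]
    ]
    membership = {g: "null" for g in genes}
    membership.update({g: "castration-only" for g in cast_only})
    membership.update({g: "crpc-shared" for g in shared})
    membership.update({g: "crpc-specific" for g in specific})
    directions = {g: ("up" if rng.random() < 0.5 else "down") for g in genes}

    sig_in = {
        "castration": set(cast_only) | set(shared),
        "crpc_a": set(shared) | set(specific),
        "crpc_b": set(specific),
    }
    tables = {}
    for name, sig in sig_in.items():
        rows = []
        for g in genes:
            if g in sig:
                lfc = float(rng.uniform(1.5, 4.0))
                if directions[g] == "down":
                    lfc = -lfc
                p = float(10.0 ** rng.uniform(-8, -4.5))
                q = min(1.0, p * 10)
            else:
                lfc = float(rng.normal(0.0, 0.2))
                p = float(rng.uniform(0.05, 1.0))
                q = min(1.0, p * 1.5)
            rows.append({"gene": g, "log2fc": lfc, "p": p, "q": q})
        tables[name] = pd.DataFrame(rows)
    return SyntheticDEGTables(tables, membership, directions)


def gen_gene_sets(
    n_sets: int,
    set_size: int,
    gene_universe: list[str],
    query: list[str],
    enriched_set_overlap: int,
    seed: int = 0,
) -> tuple[dict[str, tuple[str, frozenset[str]]], str]:
    """Gene-set collection with one set planted to overlap ``query``.

    Returns (sets, target_name): ``sets`` maps name -> (description,
    members), GMT-writable; the target set shares exactly
    ``enriched_set_overlap`` genes with ``query``; the other sets are
    uniform draws from the universe.
    """
    universe = list(dict.fromkeys(gene_universe))
    if set_size > len(universe):
        raise ValueError("set_size exceeds the universe")
    if enriched_set_overlap > set_size:
        raise ValueError("overlap cannot exceed set_size")
    query_in = [g for g in query if g in set(universe)]
    if enriched_set_overlap > len(query_in):
        raise ValueError("overlap exceeds the query genes present in the universe")
    rng = np.random.default_rng(seed)
    non_query = [g for g in universe if g not in set(query_in)]
    if set_size - enriched_set_overlap > len(non_query):
        raise ValueError("not enough non-query genes to fill the target set")

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    target = "SET_TARGET"
    members = list(rng.choice(query_in, size=enriched_set_overlap, replace=False))
    members += list(
        rng.choice(non_query, size=set_size - enriched_set_overlap, replace=False)
    )
    sets[target] = ("planted enriched set", frozenset(members))
    for i in range(n_sets - 1):
        draw = rng.choice(universe, size=set_size, replace=False)
        sets[f"SET_{i + 1:03d}"] = ("random set", frozenset(draw))
    return sets, target


def gen_edge_list(
    n_nodes: int,
    n_edges: int,
    hub_node: str = "HUB",
    hub_degree: int = 35,
    score_range: tuple[float, float] = (0.15, 1.0),
    seed: int = 0,
) -> list[tuple[str, str, float]]:
    """Scored undirected edge list with one node of planted degree.

    ``hub_node`` gets exactly ``hub_degree`` incident edges; the remaining
    edges connect non-hub pairs uniformly without duplicates or
    self-loops; scores are uniform in ``score_range``.
    """
    if hub_degree > n_nodes - 1:
        raise ValueError("hub_degree cannot exceed n_nodes - 1")
    if n_edges < hub_degree:
        raise ValueError("n_edges must be >= hub_degree")
    n_rest = n_nodes - 1
    max_rest_edges = n_rest * (n_rest - 1) // 2
    if n_edges - hub_degree > max_rest_edges:
        raise ValueError("too many edges for the non-hub subgraph")
    rng = np.random.default_rng(seed)
    others = [f"N{i + 1:04d}" for i in range(n_rest)]
    neighbors = rng.choice(n_rest, size=hub_degree, replace=False)
    edges = [(hub_node, others[i]) for i in neighbors]
    pool: set[tuple[int, int]] = set()
    while len(pool) < n_edges - hub_degree:
        i, j = rng.integers(0, n_rest, size=2)
        if i != j:
            pool.add((min(i, j), max(i, j)))
    edges += [(others[i], others[j]) for i, j in sorted(pool)]
    lo, hi = score_range
    scores = rng.uniform(lo, hi, size=len(edges))
    return [(a, b, float(s)) for (a, b), s in zip(edges, scores)]


def gen_ct_table(
    genes: dict[str, float],
    reference_gene: str = "GAPDH",
    n_replicates: int = 3,
    ct_noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format qPCR Ct table with planted fold changes.

    ``genes`` maps gene -> true treated-vs-control fold change; each
    doubling of expression lowers Ct by one cycle. Returns columns
    (gene, group, replicate, ct) including the reference gene at fold 1.
    """
    rng = np.random.default_rng(seed)
    rows = []
    all_genes = dict(genes)
    all_genes[reference_gene] = 1.0
    for gene, fold in all_genes.items():
        base = float(rng.uniform(18, 28))
        for group, f in [("control", 1.0), ("treated", fold)]:
            for rep in range(1, n_replicates + 1):
                ct = base - np.log2(f) + rng.normal(0.0, ct_noise_sd)
                rows.append(
                    {"gene": gene, "group": group, "replicate": rep, "ct": float(ct)}
                )
    return pd.DataFrame(rows)


# -- plain-text writers -------------------------------------------------------


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for gene, seq in records:
            fh.write(f">{gene}\n{seq}\n")


def write_fastq(reads, path) -> None:
    """FASTQ with dummy quality 'I'; 'N' positions get quality '#'."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            qual = "".join("#" if b == "N" else "I" for b in read)
            fh.write(f"@read{i + 1}\n{read}\n+\n{qual}\n")


def write_reads_txt(reads, path) -> None:
    Path(path).write_text("".join(r + "\n" for r in reads))


def write_gmt(sets: dict[str, tuple[str, frozenset[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_edges_tsv(edges, path) -> None:
    pd.DataFrame(edges, columns=["node1", "node2", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )
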