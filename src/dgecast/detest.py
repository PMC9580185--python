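"""Exact two-library tag-count differential expression test.

Tag-count (SAGE/DGE) experiments typically sequence one library per
condition, so per-gene replication is unavailable and differential
expression is assessed with an exact test on the pair of counts.  Under a
Poisson model for tag sampling, the distribution of the count ``y`` of a
gene in library 2 conditional on its count ``x`` in library 1 is

    P(y | x) = (N2/N1)^y * (x + y)! / ( x! y! (1 + N2/N1)^(x + y + 1) )

where ``N1`` and ``N2`` are the total clean-tag counts of the two
libraries.  This is the classical Audic–Claverie statistic.  Writing
``p0 = N1 / (N1 + N2)``, the same distribution is negative binomial with
``r = x + 1`` successes and success probability ``p0``, which is how tail
probabilities are evaluated here.

Genes are called differentially expressed when the Benjamini–Hochberg
adjusted two-sided p-value and the TPM log2 fold change pass the
configured thresholds (defaults ``q <= 0.001`` and ``|log2FC| >= 1``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

from .tags import CountTable

__all__ = [
    "ACTestInput",
    "DEResult",
    "ac_point_prob",
    "ac_pvalue",
    "bh_fdr",
    "call_degs",
    "results_to_frame",
    "write_deg_results",
]

Sided = Literal["two-sided", "greater", "less"]


@dataclass(frozen=True)
class ACTestInput:
    """Counts ``x``, ``y`` of one gene and library sizes ``N1``, ``N2``."""

    x: int
    y: int
    n1: int
    n2: int

    def __post_init__(self) -> None:
        for name in ("x", "y", "n1", "n2"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("library sizes N1, N2 must be >= 1")
        if self.x > self.n1 or self.y > self.n2:
            raise ValueError("gene counts cannot exceed their library size")


@dataclass(frozen=True)
class DEResult:
    """Per-gene test output (library 2 relative to library 1)."""

    gene: str
    x: int
    y: int
    tpm1: float
    tpm2: float
    log2fc: float
    p: float
    q: float
    direction: str  # "up", "down" or "ns"


def _validate_counts(x: int, y: int, n1: int, n2: int) -> None:
    ACTestInput(x, y, n1, n2)


def ac_point_prob(x: int, y: int, n1: int, n2: int) -> float:
    """Probability P(y|x) that the gene is equally expressed in both libraries.

    Evaluated in log space (log-gamma) so counts up to ~1e7 do not
    overflow. Returns a value in (0, 1].
    """
    _validate_counts(x, y, n1, n2)
    logq = np.log(n2) - np.log(n1)
    log1pq = np.log(n1 + n2) - np.log(n1)
    logp = (
        y * logq
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * log1pq
    )
    return float(np.exp(logp))


def _tails(x, y, n1, n2):
    """Lower and upper tail probabilities of y | x (vectorised)."""
    p0 = n1 / (n1 + n2)
    less = nbinom.cdf(y, np.asarray(x) + 1, p0)
    greater = nbinom.sf(np.asarray(y) - 1, np.asarray(x) + 1, p0)
    return less, greater


def ac_pvalue(x: int, y: int, n1: int, n2: int, sided: Sided = "two-sided") -> float:
    """Exact p-value for unequal expression of one gene in two libraries.

    ``greater`` sums P(k|x) over k >= y, ``less`` over k <= y; the
    two-sided value is twice the smaller tail, capped at 1.
    """
    _validate_counts(x, y, n1, n2)
    less, greater = _tails(x, y, n1, n2)
    if sided == "greater":
        return float(greater)
    if sided == "less":
        return float(less)
    if sided == "two-sided":
        return float(min(1.0, 2.0 * min(less, greater)))
    raise ValueError(f"unknown sidedness {sided!r}")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    table1: CountTable,
    table2: CountTable,
    fdr_max: float = 0.001,
    lfc_min: float = 1.0,
    pseudocount: float = 1.0,
    sided: Sided = "two-sided",
) -> list[DEResult]:
    """Test every gene in the union of two count tables.

    p-values come from the exact conditional test on raw counts; the fold
    change is computed on TPM with a pseudocount (zeros would otherwise
    give infinite log ratios); ``direction`` is "up"/"down" only when both
    ``q <= fdr_max`` and ``|log2FC| >= lfc_min`` hold (both thresholds
    inclusive). Results are sorted by q, then |log2FC| descending.
    """
    genes = sorted(set(table1.counts) | set(table2.counts))
    if not genes:
        raise ValueError("empty count tables")
    n1, n2 = table1.total_mapped, table2.total_mapped
    if n1 < 1 or n2 < 1:
        raise ValueError("both libraries must contain at least one mapped tag")
    x = np.array([table1.counts.get(g, 0) for g in genes], dtype=np.int64)
    y = np.array([table2.counts.get(g, 0) for g in genes], dtype=np.int64)

    less, greater = _tails(x, y, n1, n2)
    if sided == "two-sided":
        p = np.minimum(1.0, 2.0 * np.minimum(less, greater))
    elif sided == "greater":
        p = greater
    elif sided == "less":
        p = less
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    q = bh_fdr(p)

    tpm1 = x / n1 * 1e6
    tpm2 = y / n2 * 1e6
    lfc = np.log2((tpm2 + pseudocount) / (tpm1 + pseudocount))

    results = []
    for i, g in enumerate(genes):
        if q[i] <= fdr_max and abs(lfc[i]) >= lfc_min:
            direction = "up" if lfc[i] > 0 else "down"
        else:
            direction = "ns"
        results.append(
            DEResult(
                gene=g,
                x=int(x[i]),
                y=int(y[i]),
                tpm1=float(tpm1[i]),
                tpm2=float(tpm2[i]),
                log2fc=float(lfc[i]),
                p=float(p[i]),
                q=float(q[i]),
                direction=direction,
            )
        )
    results.sort(key=lambda r: (r.q, -abs(r.log2fc), r.gene))
    return results


def results_to_frame(results: Iterable[DEResult]):
    """DEG results as a pandas DataFrame (one row per gene)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "x": r.x,
                "y": r.y,
                "tpm1": r.tpm1,
                "tpm2": r.tpm2,
                "log2fc": r.log2fc,
                "p": r.p,
                "q": r.q,
                "direction": r.direction,
            }
            for r in results
        ]
    )


def write_deg_results(results: Iterable[DEResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
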