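"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths of the implementation: exact
rational arithmetic for the conditional point probability, a plain
multiplicative recurrence for tail sums, a quadratic scan for tag sites
and Hamming matching, and a direct step-up loop for BH adjustment.
"""

from fractions import Fraction
from math import factorial


def exact_point_prob(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Big-rational evaluation of (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1))."""
    q = Fraction(n2, n1)
    return q**y * factorial(x + y) / (factorial(x) * factorial(y) * (1 + q) ** (x + y + 1))


def tail_sums(x: int, y: int, n1: int, n2: int, k_max: int) -> tuple[float, float]:
    """(P(k <= y), P(k >= y)) by summing a multiplicative recurrence.

    P(0|x) = (1+q)^-(x+1); P(k+1) = P(k) * q (x+k+1) / ((k+1)(1+q)).
    """
    q = n2 / n1
    p = (1.0 + q) ** -(x + 1)
    less = p if y >= 0 else 0.0
    greater = p if y <= 0 else 0.0
    for k in range(0, k_max):
        p = p * q * (x + k + 1) / ((k + 1) * (1.0 + q))
        if k + 1 <= y:
            less += p
        if k + 1 >= y:
            greater += p
    return less, greater


def two_sided_p(x: int, y: int, n1: int, n2: int, k_max: int | None = None) -> float:
    if k_max is None:
        mean = (x + 1) * n2 / n1
        k_max = int(max(y, mean) + 20 * (mean**0.5 + 2) + 100)
    less, greater = tail_sums(x, y, n1, n2, k_max)
    return min(1.0, 2.0 * min(less, greater))


def bh_stepup(pvalues):
    """Direct min-over-j>=i of m*p_(j)/j, returned in input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvalues[i] / rank)
        q[i] = running
    return q


def all_site_tags(seq: str, tag_len: int = 21):
    """Every CATG-anchored window of tag_len valid bases, 5' to 3'."""
    seq = seq.upper()
    out = []
    for i in range(len(seq) - 3):
        if seq[i : i + 4] == "CATG" and i + tag_len <= len(seq):
            window = seq[i : i + tag_len]
            if all(b in "ACGT" for b in window):
                out.append(window)
    return out


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def brute_force_assign(tag: str, gene_tags: dict[str, str]) -> str | None:
    """Gene at minimal Hamming distance <= 1, or None on tie/no hit."""
    best, best_genes = 2, []
    for gene, cat_tag in gene_tags.items():
        d = hamming(tag, cat_tag)
        if d < best:
            best, best_genes = d, [gene]
        elif d == best:
            best_genes.append(gene)
    if best <= 1 and len(best_genes) == 1:
        return best_genes[0]
    return None
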