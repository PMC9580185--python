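"""Relative expression from qPCR cycle thresholds by the 2^-ddCt method.

Per replicate, dCt = Ct(gene) - Ct(reference) within its group; ddCt is
the difference of group-mean dCt (treated minus control); the fold change
is 2 ** -ddCt with amplification efficiency fixed at 2. The spread is the
SD of treated-replicate ddCt values around the control mean, reported as
the asymmetric interval 2 ** -(ddCt +/- SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FoldChangeResult", "read_ct_table", "ddct_fold_change", "concordance"]

REQUIRED_COLUMNS = ("gene", "group", "replicate", "ct")


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    fold_change: float  # treated vs control, 2^-ddCt
    ddct: float
    sd_ddct: float
    fold_low: float  # 2^-(ddCt + SD)
    fold_high: float  # 2^-(ddCt - SD)
    n_control: int
    n_treated: int

    @property
    def direction(self) -> str:
        return "up" if self.fold_change > 1.0 else "down"


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["ct"] = pd.to_numeric(df["ct"])
    return df


def _delta_ct(df: pd.DataFrame, gene: str, reference: str, group: str) -> np.ndarray:
    sub = df[df["group"] == group]
    g = sub[sub["gene"] == gene].set_index("replicate")["ct"]
    r = sub[sub["gene"] == reference].set_index("replicate")["ct"]
    if r.empty:
        raise ValueError(f"reference gene {reference!r} missing in group {group!r}")
    if g.empty:
        raise ValueError(f"gene {gene!r} missing in group {group!r}")
    joined = pd.concat([g.rename("gene"), r.rename("ref")], axis=1, join="inner")
    if joined.empty:
        raise ValueError(f"no replicate shared by {gene!r} and {reference!r} in {group!r}")
    return (joined["gene"] - joined["ref"]).to_numpy()


def ddct_fold_change(
    ct: pd.DataFrame,
    gene: str,
    reference_gene: str,
    control_group: str = "control",
    treated_group: str = "treated",
) -> FoldChangeResult:
    """Fold change of ``gene`` (treated vs control) normalised to the reference."""
    dct_c = _delta_ct(ct, gene, reference_gene, control_group)
    dct_t = _delta_ct(ct, gene, reference_gene, treated_group)
    ddct = float(dct_t.mean() - dct_c.mean())
    dev = dct_t - dct_c.mean()
    sd = float(dev.std(ddof=1)) if dev.size > 1 else 0.0
    return FoldChangeResult(
        gene=gene,
        fold_change=float(2.0**-ddct),
        ddct=ddct,
        sd_ddct=sd,
        fold_low=float(2.0 ** -(ddct + sd)),
        fold_high=float(2.0 ** -(ddct - sd)),
        n_control=int(dct_c.size),
        n_treated=int(dct_t.size),
    )


def concordance(qpcr_results, deg_table) -> dict:
    """Fraction of genes whose qPCR direction matches the DEG table's.

    ``deg_table`` is an :class:`~dgecast.integrate.DEGTable` or any object
    with ``up``/``down`` gene sets.
    """
    per_gene = {}
    for r in qpcr_results:
        if r.gene in deg_table.up:
            per_gene[r.gene] = r.direction == "up"
        elif r.gene in deg_table.down:
            per_gene[r.gene] = r.direction == "down"
    if not per_gene:
        raise ValueError("no genes shared between qPCR results and the DEG table")
    n_agree = sum(per_gene.values())
    return {
        "n_compared": len(per_gene),
        "n_concordant": n_agree,
        "fraction_concordant": n_agree / len(per_gene),
        "per_gene": per_gene,
    }
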