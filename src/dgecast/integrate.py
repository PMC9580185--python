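"""Direction-aware intersection of DEG tables across cohorts.

Given three DEG tables — a castration comparison and two CRPC-vs-primary
cohorts — genes are partitioned into castration-dependent DEGs
(significant in the first CRPC cohort and in the castration comparison,
same direction) and castration-independent, CRPC-specific DEGs
(significant in both CRPC cohorts but not regulated by castration in any
direction). A gene touched by castration in either direction is never
CRPC-specific.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "DEGTable",
    "DEGClassification",
    "read_deg_table",
    "deg_table_from_results",
    "harmonize_symbols",
    "classify_degs",
    "venn_counts",
    "write_venn_counts",
]


@dataclass
class DEGTable:
    """Significant rows of one dataset's DEG list.

    ``rows`` is indexed by gene symbol with columns log2fc, p, q,
    direction; only rows passing the thresholds are kept.
    """

    name: str
    rows: pd.DataFrame
    fdr_max: float = 0.001
    lfc_min: float = 1.0

    def genes(self, direction: str | None = None) -> set[str]:
        if direction is None:
            return set(self.rows.index)
        return set(self.rows.index[self.rows["direction"] == direction])

    @property
    def up(self) -> set[str]:
        return self.genes("up")

    @property
    def down(self) -> set[str]:
        return self.genes("down")


def _finalize(name, df, fdr_max, lfc_min) -> DEGTable:
    df = df.copy()
    df["direction"] = np.where(df["log2fc"] > 0, "up", "down")
    # duplicate symbols collapse to the entry with the smallest q
    df = df.sort_values(["q", "p"], kind="stable")
    df = df[~df.index.duplicated(keep="first")]
    return DEGTable(name, df.sort_index(), fdr_max, lfc_min)


def read_deg_table(
    path,
    name: str | None = None,
    columns: dict[str, str] | None = None,
    fdr_max: float = 0.001,
    lfc_min: float = 1.0,
) -> DEGTable:
    """Load a limma/GEO2R-style DEG export and apply strict thresholds.

    ``columns`` maps the roles {"gene", "log2fc", "q"} (and optionally
    "p") to the file's column names; by default those exact names are
    expected. Rows are kept when ``q < fdr_max`` and ``|log2FC| >
    lfc_min`` (both strict); non-numeric rows are skipped with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    colmap = {"gene": "gene", "log2fc": "log2fc", "q": "q", "p": "p"}
    if columns:
        colmap.update(columns)
    missing = [c for r, c in colmap.items() if r != "p" and c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = pd.DataFrame(
        {
            "gene": df[colmap["gene"]].astype(str),
            "log2fc": pd.to_numeric(df[colmap["log2fc"]], errors="coerce"),
            "q": pd.to_numeric(df[colmap["q"]], errors="coerce"),
        }
    )
    out["p"] = (
        pd.to_numeric(df[colmap["p"]], errors="coerce")
        if colmap["p"] in df.columns
        else out["q"]
    )
    bad = out[["log2fc", "q"]].isna().any(axis=1)
    if bad.any():
        log.warning("%s: skipped %d non-numeric rows", path, int(bad.sum()))
        out = out[~bad]
    out = out.set_index("gene")
    kept = out[(out["q"] < fdr_max) & (out["log2fc"].abs() > lfc_min)]
    return _finalize(name or str(path), kept, fdr_max, lfc_min)


def deg_table_from_results(
    results, name: str, fdr_max: float = 0.001, lfc_min: float = 1.0
) -> DEGTable:
    """Build a DEGTable from exact-test DEResults (inclusive thresholds)."""
    rows = [
        {"gene": r.gene, "log2fc": r.log2fc, "p": r.p, "q": r.q}
        for r in results
        if r.q <= fdr_max and abs(r.log2fc) >= lfc_min
    ]
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "p", "q"]).set_index("gene")
    return _finalize(name, df, fdr_max, lfc_min)


def harmonize_symbols(table: DEGTable, ortholog_map: dict[str, str] | None = None) -> DEGTable:
    """Bring symbols into one namespace.

    Without a map, symbols are upper-cased (cross-species symbol-identity
    convention); with a map, source symbols are translated and unmapped
    rows dropped (drop count logged).
    """
    df = table.rows.copy()
    if ortholog_map is None:
        df.index = df.index.str.upper()
    else:
        if len(set(ortholog_map)) != len(ortholog_map):
            raise ValueError("ortholog map has duplicate source keys")
        mapped = df.index.map(ortholog_map.get)
        dropped = int(pd.isna(mapped).sum())
        if dropped:
            log.warning("%s: dropped %d unmapped symbols", table.name, dropped)
        df = df[~pd.isna(mapped)]
        df.index = [ortholog_map[g] for g in df.index]
    return _finalize(table.name, df, table.fdr_max, table.lfc_min)


@dataclass
class DEGClassification:
    """Partition into castration-dependent and CRPC-specific DEG sets."""

    crpc_castration_up: set[str] = field(default_factory=set)
    crpc_castration_down: set[str] = field(default_factory=set)
    crpc_specific_up: set[str] = field(default_factory=set)
    crpc_specific_down: set[str] = field(default_factory=set)
    provenance: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls_name, direction, genes in [
            ("crpc_castration", "up", self.crpc_castration_up),
            ("crpc_castration", "down", self.crpc_castration_down),
            ("crpc_specific", "up", self.crpc_specific_up),
            ("crpc_specific", "down", self.crpc_specific_down),
        ]:
            for g in sorted(genes):
                rows.append(
                    {
                        "gene": g,
                        "class": cls_name,
                        "direction": direction,
                        "provenance": json.dumps(self.provenance.get(g, {}), sort_keys=True),
                    }
                )
        return pd.DataFrame(rows, columns=["gene", "class", "direction", "provenance"])


def classify_degs(
    castration: DEGTable,
    crpc_a: DEGTable,
    crpc_b: DEGTable,
    require_direction_match: bool = True,
    strict_castration_both: bool = False,
) -> DEGClassification:
    """Direction-aware three-table classification.

    Castration-dependent (per direction): genes significant in ``crpc_a``
    and in ``castration`` (same direction when
    ``require_direction_match``; with ``strict_castration_both`` also in
    ``crpc_b``). CRPC-specific (per direction): genes significant in both
    CRPC tables minus every castration DEG of either direction.
    """
    if not len(castration.rows):
        log.warning("empty castration table: specific sets equal the CRPC intersection")
    out = DEGClassification()
    cast_any = castration.genes()

    for direction in ("up", "down"):
        a_dir = crpc_a.genes(direction)
        b_dir = crpc_b.genes(direction)
        if require_direction_match:
            cast_match = castration.genes(direction)
            shared = a_dir & cast_match
            specific = (a_dir & b_dir) - cast_any
        else:
            shared = a_dir & cast_any
            specific = (a_dir & crpc_b.genes()) - cast_any
        if strict_castration_both:
            shared &= b_dir if require_direction_match else crpc_b.genes()
        getattr(out, f"crpc_castration_{direction}").update(shared)
        getattr(out, f"crpc_specific_{direction}").update(specific)
        for g in shared:
            out.provenance[g] = {
                "class": "crpc_castration",
                "direction": direction,
                "tables": sorted(
                    t.name for t in (castration, crpc_a, crpc_b) if g in t.genes()
                ),
            }
        for g in specific:
            out.provenance[g] = {
                "class": "crpc_specific",
                "direction": direction,
                "tables": sorted(t.name for t in (crpc_a, crpc_b) if g in t.genes()),
            }
    return out


def venn_counts(
    castration: DEGTable, crpc_a: DEGTable, crpc_b: DEGTable
) -> dict[str, dict[str, int]]:
    """Seven-region Venn counts of the three tables, per direction."""
    out: dict[str, dict[str, int]] = {}
    names = (castration.name, crpc_a.name, crpc_b.name)
    for direction in ("up", "down"):
        s1, s2, s3 = (t.genes(direction) for t in (castration, crpc_a, crpc_b))
        out[direction] = {
            f"{names[0]}_only": len(s1 - s2 - s3),
            f"{names[1]}_only": len(s2 - s1 - s3),
            f"{names[2]}_only": len(s3 - s1 - s2),
            f"{names[0]}&{names[1]}": len((s1 & s2) - s3),
            f"{names[0]}&{names[2]}": len((s1 & s3) - s2),
            f"{names[1]}&{names[2]}": len((s2 & s3) - s1),
            "all_three": len(s1 & s2 & s3),
        }
    return out


def write_venn_counts(
    classification: DEGClassification,
    castration: DEGTable,
    crpc_a: DEGTable,
    crpc_b: DEGTable,
    path,
) -> dict:
    """Write the per-direction Venn regions plus classification sizes as JSON."""
    payload = {
        "venn": venn_counts(castration, crpc_a, crpc_b),
        "classification": {
            "crpc_castration_up": len(classification.crpc_castration_up),
            "crpc_castration_down": len(classification.crpc_castration_down),
            "crpc_specific_up": len(classification.crpc_specific_up),
            "crpc_specific_down": len(classification.crpc_specific_down),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return payload
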