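"""End-to-end orchestration of the synthetic study on one configuration.

`run_pipeline` drives every stage in order — simulate, tag processing,
exact-test DEG calling, multi-cohort classification, enrichment, network
degree analysis and qPCR concordance — writing plain-text outputs and a
manifest of parameter values and output SHA-256 digests. Rerunning with
the same configuration and seed reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import detest, enrich, integrate, network, qpcr, simulate, tags

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid configuration (caught before any stage runs)."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


_DEFAULTS: dict = {
    "seed": 0,
    "simulate": {
        "n_genes": 300,
        "min_len": 120,
        "max_len": 300,
        "frac_no_site": 0.02,
        "frac_shared_tag": 0.04,
        "depth1": 200_000,
        "depth2": 200_000,
        "n_de": 20,
        "de_log2fc": 2.0,
        "de_min_expected": 50.0,
        "adaptor": simulate.DEFAULT_ADAPTOR,
        "frac_empty": 0.02,
        "frac_lowq": 0.02,
        "frac_singleton_noise": 0.01,
        "frac_badlen": 0.01,
    },
    "detest": {
        "fdr_max": 0.001,
        "lfc_min": 1.0,
        "pseudocount": 1.0,
        "sided": "two-sided",
    },
    "degtables": {
        "n_genes": 400,
        "n_castration_only": 30,
        "n_crpc_shared": 12,
        "n_crpc_specific": 15,
    },
    "classify": {"require_direction_match": True},
    "enrich": {"n_sets": 25, "set_size": 20, "enriched_overlap": 12, "top": 10},
    "network": {
        "n_nodes": 60,
        "n_edges": 150,
        "hub_degree": 35,
        "score_min": 0.15,
        "hub_min_degree": 30,
    },
    "qpcr": {"reference": "GAPDH", "n_replicates": 3, "n_genes": 6},
}


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for key, val in base.items():
        if isinstance(val, dict):
            out[key] = _merge(val, override.get(key, {}) or {})
        else:
            out[key] = override.get(key, val)
    unknown = set(override) - set(base)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    return out


@dataclass
class PipelineConfig:
    """Validated per-stage parameters for a full run."""

    params: dict = field(default_factory=lambda: _merge(_DEFAULTS, {}))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        cfg = cls(_merge(_DEFAULTS, raw))
        cfg.validate()
        return cfg

    @classmethod
    def from_dict(cls, overrides: dict | None = None) -> "PipelineConfig":
        cfg = cls(_merge(_DEFAULTS, overrides or {}))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        p = self.params
        sim = p["simulate"]
        det = p["detest"]
        checks = [
            (0 < det["fdr_max"] <= 1, "detest.fdr_max must lie in (0, 1]"),
            (det["lfc_min"] >= 0, "detest.lfc_min must be >= 0"),
            (det["pseudocount"] > 0, "detest.pseudocount must be positive"),
            (det["sided"] in ("two-sided", "greater", "less"), "bad detest.sided"),
            (sim["n_genes"] >= 1, "simulate.n_genes must be >= 1"),
            (sim["depth1"] >= 1 and sim["depth2"] >= 1, "depths must be >= 1"),
            (
                all(
                    0 <= sim[k] <= 1
                    for k in (
                        "frac_no_site",
                        "frac_shared_tag",
                        "frac_empty",
                        "frac_lowq",
                        "frac_singleton_noise",
                        "frac_badlen",
                    )
                ),
                "simulate fractions must lie in [0, 1]",
            ),
            (0 < p["network"]["score_min"] < 1, "network.score_min must lie in (0, 1)"),
            (p["enrich"]["top"] >= 1, "enrich.top must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and return (and write) the manifest."""
    config.validate()
    p = config.params
    seed = int(p["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    manifest: dict = {"config": p, "stages": [], "summary": {}}
    current = "setup"

    def done(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        outputs.extend(paths)

    try:
        # -- simulate ---------------------------------------------------------
        current = "simulate"
        sim = p["simulate"]
        tx = simulate.gen_transcriptome(
            sim["n_genes"],
            sim["min_len"],
            sim["max_len"],
            sim["frac_no_site"],
            sim["frac_shared_tag"],
            seed=seed,
        )
        fasta = outdir / "transcriptome.fa"
        tx.to_fasta(fasta)
        pair = simulate.gen_library_pair(
            tx,
            sim["depth1"],
            sim["depth2"],
            sim["n_de"],
            sim["de_log2fc"],
            seed=seed + 1,
            de_min_expected=sim["de_min_expected"],
        )
        reads1, reads2 = simulate.gen_raw_reads(
            pair,
            tx,
            adaptor=sim["adaptor"],
            frac_empty=sim["frac_empty"],
            frac_lowq=sim["frac_lowq"],
            frac_singleton_noise=sim["frac_singleton_noise"],
            frac_badlen=sim["frac_badlen"],
            seed=seed + 2,
        )
        fq1, fq2 = outdir / "lib1.fq", outdir / "lib2.fq"
        simulate.write_fastq(reads1.reads, fq1)
        simulate.write_fastq(reads2.reads, fq2)
        done("simulate", fasta, fq1, fq2)

        # -- tags -------------------------------------------------------------
        current = "tags"
        catalog = tags.build_tag_catalog(tx.records)
        t_adaptor = sim["adaptor"]
        tables = []
        for lib_id, fq in [("lib1", fq1), ("lib2", fq2)]:
            clean, report = tags.clean_tags(tags.read_reads(fq), t_adaptor)
            report.to_json(outdir / f"{lib_id}.cleaning.json")
            table = tags.map_tags(clean, catalog, library_id=lib_id)
            table.to_tsv(outdir / f"{lib_id}.counts.tsv")
            tables.append(table)
        r = tags.library_correlation(*tables)
        manifest["summary"]["library_pearson_r_log2tpm"] = round(r, 6)
        done(
            "tags",
            outdir / "lib1.counts.tsv",
            outdir / "lib2.counts.tsv",
            outdir / "lib1.cleaning.json",
            outdir / "lib2.cleaning.json",
        )

        # -- detest -----------------------------------------------------------
        current = "detest"
        det = p["detest"]
        results = detest.call_degs(
            tables[0],
            tables[1],
            fdr_max=det["fdr_max"],
            lfc_min=det["lfc_min"],
            pseudocount=det["pseudocount"],
            sided=det["sided"],
        )
        degs_path = outdir / "degs.tsv"
        detest.write_deg_results(results, degs_path)
        called = [r for r in results if r.direction != "ns"]
        manifest["summary"]["n_degs_called"] = len(called)
        manifest["summary"]["n_planted_de"] = sim["n_de"]
        truth_de = {g for g, fc in pair.de_truth.items() if fc != 0}
        manifest["summary"]["n_planted_recovered"] = sum(
            1 for r in called if r.gene in truth_de
        )
        done("detest", degs_path)

        # -- classify ---------------------------------------------------------
        current = "classify"
        dg = p["degtables"]
        synth = simulate.gen_deg_tables(
            dg["n_genes"],
            dg["n_castration_only"],
            dg["n_crpc_shared"],
            dg["n_crpc_specific"],
            seed=seed + 3,
        )
        table_paths = {}
        for name, df in synth.tables.items():
            path = outdir / f"deg_{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            table_paths[name] = path
        loaded = {
            name: integrate.read_deg_table(path, name=name)
            for name, path in table_paths.items()
        }
        classification = integrate.classify_degs(
            loaded["castration"],
            loaded["crpc_a"],
            loaded["crpc_b"],
            require_direction_match=p["classify"]["require_direction_match"],
        )
        cls_path = outdir / "classification.tsv"
        classification.to_frame().to_csv(cls_path, sep="\t", index=False)
        venn_path = outdir / "venn.json"
        integrate.write_venn_counts(
            classification,
            loaded["castration"],
            loaded["crpc_a"],
            loaded["crpc_b"],
            venn_path,
        )
        manifest["summary"]["crpc_specific_genes"] = len(
            classification.crpc_specific_up | classification.crpc_specific_down
        )
        manifest["summary"]["crpc_castration_genes"] = len(
            classification.crpc_castration_up | classification.crpc_castration_down
        )
        done("classify", *table_paths.values(), cls_path, venn_path)

        # -- enrich -----------------------------------------------------------
        current = "enrich"
        en = p["enrich"]
        query = sorted(
            classification.crpc_specific_up | classification.crpc_specific_down
        )
        universe = sorted(synth.tables["crpc_a"]["gene"].astype(str))
        sets, target = simulate.gen_gene_sets(
            en["n_sets"],
            en["set_size"],
            universe,
            query,
            min(en["enriched_overlap"], len(query), en["set_size"]),
            seed=seed + 4,
        )
        gmt_path = outdir / "genesets.gmt"
        collection = enrich.GeneSetCollection(sets, universe=frozenset(universe))
        enrich.write_gmt(collection, gmt_path)
        enr = enrich.enrichment_test(query, collection)
        top = enrich.top_terms(enr, en["top"])
        enr_path = outdir / "enrichment.tsv"
        enrich.results_to_frame(top).to_csv(enr_path, sep="\t", index=False)
        manifest["summary"]["planted_set_rank"] = (
            next(i for i, r in enumerate(enr, 1) if r.set_name == target)
        )
        done("enrich", gmt_path, enr_path)

        # -- network ----------------------------------------------------------
        current = "network"
        net = p["network"]
        raw_edges = simulate.gen_edge_list(
            net["n_nodes"],
            net["n_edges"],
            hub_node="HUB",
            hub_degree=net["hub_degree"],
            seed=seed + 5,
        )
        edges_path = outdir / "edges.tsv"
        simulate.write_edges_tsv(raw_edges, edges_path)
        edges = network.load_edges(edges_path, score_min=net["score_min"])
        deg_table = network.degree_analysis(edges, hub_min_degree=net["hub_min_degree"])
        deg_path = outdir / "degrees.tsv"
        deg_table.to_frame().to_csv(deg_path, sep="\t", index=False)
        manifest["summary"]["n_hubs"] = len(deg_table.hubs)
        done("network", edges_path, deg_path)

        # -- qpcr -------------------------------------------------------------
        current = "qpcr"
        qp = p["qpcr"]
        ups = [r for r in called if r.direction == "up"][: qp["n_genes"] // 2]
        downs = [r for r in called if r.direction == "down"][: qp["n_genes"] // 2]
        picked = ups + downs
        if picked:
            folds = {r.gene: float(2.0**r.log2fc) for r in picked}
            ct = simulate.gen_ct_table(
                folds,
                reference_gene=qp["reference"],
                n_replicates=qp["n_replicates"],
                seed=seed + 6,
            )
            ct_path = outdir / "ct.tsv"
            ct.to_csv(ct_path, sep="\t", index=False)
            fc = [
                qpcr.ddct_fold_change(ct, g, qp["reference"]) for g in folds
            ]
            deg_table_dge = integrate.deg_table_from_results(
                results, "dge", det["fdr_max"], det["lfc_min"]
            )
            conc = qpcr.concordance(fc, deg_table_dge)
            conc_path = outdir / "qpcr_concordance.json"
            conc_path.write_text(
                json.dumps(
                    {k: v for k, v in conc.items() if k != "per_gene"}, indent=1
                )
                + "\n"
            )
            manifest["summary"]["qpcr_fraction_concordant"] = conc["fraction_concordant"]
            done("qpcr", ct_path, conc_path)
        else:
            manifest["stages"].append("qpcr")
            manifest["summary"]["qpcr_fraction_concordant"] = None

    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage name matters more than type
        (outdir / "FAILED").write_text(f"stage {current}: {exc}\n")
        raise StageError(f"stage {current!r} failed: {exc}") from exc

    manifest["digests"] = {path.name: _sha256(path) for path in sorted(set(outputs))}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n"
    )
    return manifest
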