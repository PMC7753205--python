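"""End-to-end orchestration: simulate or load inputs, run every stage.

The pipeline is configured by a single YAML file; every tunable constant
(significance levels, SNP and expression filters, proximity and block
thresholds) is a config default, never hard-coded in a stage.  Reruns with
the same config and seed are byte-identical; a manifest records the
package version, the seed and the SHA-256 of every input consumed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

import regdiv.allele_counts as ac
import regdiv.classify as cl
from regdiv.crosstab import crosstab as build_crosstab
from regdiv.crosstab import mode_tests, write_crosstab
import regdiv.dupmodes as dm
import regdiv.enrichment as en
import regdiv.simulate as sim

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Inputs, thresholds and the seed for one pipeline run."""

    # input files (omit those a stage should skip)
    f1: str | None = None
    mix_rna: str | None = None
    mix_dna: str | None = None
    vcf: str | None = None
    gff: str | None = None
    hits: str | None = None
    collinearity: str | None = None
    ks: str | None = None
    annotations: str | None = None

    # optional synthetic-data generation (dicts of generator arguments)
    simulate: dict | None = None
    layout: dict | None = None

    # thresholds
    snp_bias_alpha: float = 0.05
    fdr_alpha: float = 0.05
    enrichment_alpha: float = 0.05
    min_snps: int = 2
    expr_bounds: tuple | None = (10.0, 1000.0)
    min_gq: float = 20.0
    min_dp: float = 5.0
    proximal_max_gap: int = 20
    min_anchors: int = 5
    kmeans_k: int = 3
    min_term_size: int = 5
    mix_mode: str = "scale"
    seed: int = 0

    def validate(self) -> None:
        for name in ("snp_bias_alpha", "fdr_alpha", "enrichment_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("min_snps", "proximal_max_gap", "min_anchors", "kmeans_k", "min_term_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.expr_bounds is not None:
            low, high = self.expr_bounds
            if not low < high:
                raise ValueError("expr_bounds must satisfy low < high")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "expr_bounds" in raw and raw["expr_bounds"] is not None:
            raw["expr_bounds"] = tuple(raw["expr_bounds"])
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict:
    """Run every configured stage; returns the manifest dict.

    Any stage error aborts with :class:`PipelineError` naming the stage.
    """
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {
        "package": "regdiv",
        "version": __import__("regdiv").__version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {},
        "outputs": [],
    }

    def out_path(name: str) -> str:
        manifest["outputs"].append(name)
        return os.path.join(out_dir, name)

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name} failed: {exc}") from exc

        return deco

    # --- simulate ----------------------------------------------------------
    dataset = None
    if config.simulate is not None:
        def _simulate():
            args = dict(config.simulate)
            args.setdefault("seed", config.seed)
            ds = sim.simulate_dataset(sim.SimConfig(**args))
            paths = sim.write_fixture_bundle(ds, os.path.join(out_dir, "inputs"))
            config.f1 = paths["f1"]
            config.mix_rna = paths["mix_rna"]
            config.mix_dna = paths["mix_dna"]
            config.vcf = paths["vcf"]
            config.gff = paths["gff"]
            return ds

        dataset = stage("simulate")(_simulate)

        if config.layout is not None:
            def _layout():
                args = dict(config.layout)
                args.setdefault("seed", config.seed)
                args.setdefault("n_genes", len(dataset.truth))
                args.setdefault("gene_ids", list(dataset.truth["gene_id"]))
                layout = sim.simulate_genome_layout(**args)
                paths = sim.write_layout_files(layout, os.path.join(out_dir, "inputs"))
                config.hits = paths["hits"]
                config.ks = paths["ks"]
                return layout, paths["gff"]

            _layout_result = stage("simulate-layout")(_layout)
            layout_gff = _layout_result[1]
        else:
            layout_gff = None
    else:
        layout_gff = None

    input_stage = {
        "mix_dna": "filter-snps",
        "vcf": "filter-snps",
        "f1": "aggregate",
        "mix_rna": "aggregate",
        "gff": "aggregate",
        "hits": "dupmode",
        "collinearity": "dupmode",
        "ks": "dupmode",
        "annotations": "enrich",
    }
    for name, stage_name in input_stage.items():
        path = getattr(config, name)
        if path:
            if not os.path.exists(path):
                raise PipelineError(f"stage {stage_name} failed: missing input {name}: {path}")
            manifest["inputs"][name] = {"path": path, "sha256": _sha256(path)}

    # --- filter-snps -------------------------------------------------------
    def _filter_snps():
        if config.mix_dna is None:
            raise FileNotFoundError("no mixed-DNA control table configured")
        dna = ac.read_ase_table(config.mix_dna)
        if config.vcf:
            variants = ac.filter_variants(config.vcf, config.min_gq, config.min_dp)
            keys = set(zip(variants["contig"].astype(str), variants["position"].astype(int)))
            dna = dna[
                [
                    (c, p) in keys
                    for c, p in zip(dna["contig"].astype(str), dna["position"].astype(int))
                ]
            ]
        flagged = ac.filter_biased_snps(dna, alpha=config.snp_bias_alpha)
        retained = flagged[flagged["retained"]][["contig", "position"]].reset_index(drop=True)
        flagged.to_csv(out_path("snp_bias.tsv"), sep="\t", index=False)
        return retained

    retained = stage("filter-snps")(_filter_snps)

    # --- aggregate ---------------------------------------------------------
    def _aggregate():
        f1 = ac.read_ase_table(config.f1)
        mix = ac.read_ase_table(config.mix_rna)
        genes = dm.read_gff_genes(config.gff)[["gene_id", "chrom", "start", "end"]]
        profiles = ac.aggregate_to_genes(
            f1,
            mix,
            genes,
            min_snps=config.min_snps,
            expr_bounds=config.expr_bounds,
            retained_keys=retained,
        )
        ac.write_profiles(profiles, out_path("profiles.tsv"))
        return profiles

    profiles = stage("aggregate")(_aggregate)

    # --- classify ----------------------------------------------------------
    def _classify():
        calls = cl.classify_all(profiles, alpha=config.fdr_alpha)
        cl.write_calls(calls, out_path("calls.tsv"))
        counts = cl.category_counts(calls)
        counts.rename_axis("category").rename("n_genes").to_csv(
            out_path("category_summary.tsv"), sep="\t"
        )
        return calls

    calls = stage("classify")(_classify)

    # --- dupmode -----------------------------------------------------------
    assignments = None
    dup_gff = layout_gff or config.gff
    if config.hits and dup_gff:
        def _dupmode():
            positions = dm.read_gff_genes(dup_gff)
            hits = dm.read_blast_hits(config.hits)
            if config.collinearity:
                blocks = dm.read_collinearity_file(config.collinearity)
            else:
                blocks = dm.detect_collinearity(
                    positions, hits, min_anchors=config.min_anchors
                )
            ks_table = pd.read_csv(config.ks, sep="\t") if config.ks else None
            out = dm.assign_modes_with_age(
                positions,
                hits,
                blocks,
                ks_table,
                proximal_max_gap=config.proximal_max_gap,
                kmeans_k=config.kmeans_k,
                seed=config.seed,
            )
            dm.write_assignments(out, out_path("modes.tsv"))
            return out

        assignments = stage("dupmode")(_dupmode)

    # --- crosstab ----------------------------------------------------------
    if assignments is not None and len(calls):
        def _crosstab():
            table = build_crosstab(calls, assignments)
            write_crosstab(
                table, out_path("crosstab_counts.tsv"), out_path("crosstab_pct.tsv")
            )
            mode_tests(table).to_csv(out_path("mode_tests.tsv"), sep="\t", index=False)
            return table

        stage("crosstab")(_crosstab)

    # --- enrich ------------------------------------------------------------
    if config.annotations and len(calls):
        def _enrich():
            ann = en.read_annotations(config.annotations)
            universe = list(calls["gene_id"])
            for cat in ("cis_only", "trans_only"):
                query = list(calls.loc[calls["category"] == cat, "gene_id"])
                if not query:
                    logger.info("enrich: no %s genes, skipping", cat)
                    continue
                rows = en.enrich(
                    query,
                    ann,
                    universe,
                    min_term_size=config.min_term_size,
                    alpha=config.enrichment_alpha,
                )
                rows.to_csv(out_path(f"enrichment_{cat}.tsv"), sep="\t", index=False)

        stage("enrich")(_enrich)

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
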