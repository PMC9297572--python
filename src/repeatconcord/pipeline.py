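"""End-to-end orchestration: one YAML config drives simulate -> concordance ->
profile -> overlap -> phylostrata -> consensus -> synteny, writing TSVs and a
run manifest (package version, seed, checksums) that makes a run exactly
reproducible.

All stage outputs are plain TSV/JSON so runs can be diffed; two runs from the
same config and seed produce byte-identical output trees.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import fields as dc_fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classifier_consensus import consensus_report, cross_classification_matrix
from .concordance import (
    binarize_windows,
    cluster_methods,
    coverage_summary,
    pairwise_agreement,
    pattern_abundance,
)
from .gene_overlap import (
    exon_coverage_overlaps,
    fully_contained_overlaps,
    gene_class_map,
    merge_isoforms,
    records_to_frame,
    superfamily_tally,
)
from .genomic_intervals import (
    TEClass,
    make_windows,
    write_bed,
    write_genome_index,
    write_gff3_genes,
)
from .phylostrata import assign_age_classes, repeat_contribution_by_age
from .synteny import detect_lineage_specific_insertions, write_gene_order
from .synthetic_data import (
    ClassProfile,
    GeneFixtureConfig,
    GeneOrderConfig,
    HitTableConfig,
    LabelConfig,
    SimConfig,
    ToolProfile,
    simulate_annotation_suite,
    simulate_gene_fixture,
    simulate_gene_orders,
    simulate_hit_table,
    simulate_labels,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "concordance",
    "profile",
    "overlap",
    "phylostrata",
    "consensus",
    "synteny",
)

__all__ = ["ConfigError", "sim_config_from_dict", "load_config", "run_pipeline", "STAGES"]


class ConfigError(ValueError):
    """A pipeline/simulation config that violates the schema; the message names
    the offending key."""


def _check_keys(d: dict, allowed, context: str) -> None:
    unknown = sorted(set(d) - set(allowed))
    if unknown:
        raise ConfigError(f"unknown key(s) {unknown} under {context!r}")


def _build(cls, d: dict, context: str):
    names = [f.name for f in dc_fields(cls)]
    _check_keys(d, names, context)
    try:
        return cls(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {context!r} section: {exc}") from exc


def sim_config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a YAML-shaped mapping; unknown keys are errors."""
    d = dict(d)
    _check_keys(
        d,
        [f.name for f in dc_fields(SimConfig)],
        "simulate",
    )
    if "seed" not in d:
        raise ConfigError("missing required key 'seed' under 'simulate'")
    kwargs: dict = {"seed": int(d["seed"])}
    if "chrom_lengths" in d:
        cl = d["chrom_lengths"]
        if not isinstance(cl, dict) or not cl:
            raise ConfigError("'chrom_lengths' must be a nonempty mapping")
        kwargs["chrom_lengths"] = {str(k): int(v) for k, v in cl.items()}
    if "class_profiles" in d:
        profs = {}
        for cls_name, sub in d["class_profiles"].items():
            try:
                te_cls = TEClass(cls_name)
            except ValueError:
                raise ConfigError(
                    f"unknown TE class {cls_name!r} under 'class_profiles'"
                ) from None
            profs[te_cls] = _build(
                ClassProfile, dict(sub), f"class_profiles.{cls_name}"
            )
        kwargs["class_profiles"] = profs
    if "tools" in d:
        kwargs["tools"] = [
            _build(ToolProfile, dict(t), f"tools[{i}]")
            for i, t in enumerate(d["tools"])
        ]
    for key, cls in (
        ("genes", GeneFixtureConfig),
        ("hits", HitTableConfig),
        ("labels", LabelConfig),
        ("orders", GeneOrderConfig),
    ):
        if key in d:
            sub = dict(d[key])
            if key == "genes" and "contained_per_superfamily" in sub:
                sub["contained_per_superfamily"] = {
                    tuple(k.split("/", 1)): int(v)
                    for k, v in sub["contained_per_superfamily"].items()
                }
            if key == "hits" and "overlap_fractions" in sub:
                sub["overlap_fractions"] = {
                    TEClass(k): tuple(v) for k, v in sub["overlap_fractions"].items()
                }
            for tup_key in ("species", "proportions", "methods", "flip_rates"):
                if tup_key in sub:
                    sub[tup_key] = tuple(sub[tup_key])
            kwargs[key] = _build(cls, sub, key)
    try:
        return SimConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


_PIPELINE_KEYS = {
    "seed",
    "stages",
    "simulate",
    "concordance",
    "profile",
    "overlap",
    "phylostrata",
    "consensus",
    "synteny",
}


def load_config(path: str | Path) -> dict:
    """Load and schema-check a pipeline YAML config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("pipeline config must be a mapping")
    _check_keys(cfg, _PIPELINE_KEYS, "pipeline config")
    if "seed" not in cfg:
        raise ConfigError("missing required key 'seed'")
    stages = cfg.get("stages", list(STAGES))
    unknown = sorted(set(stages) - set(STAGES))
    if unknown:
        raise ConfigError(f"unknown stage(s) {unknown} under 'stages'")
    cfg["stages"] = [s for s in STAGES if s in stages]
    _check_keys(cfg.get("concordance", {}), {"window", "top_k", "reference", "min_bases"}, "concordance")
    _check_keys(cfg.get("profile", {}), {"window", "classes", "merge_penelope"}, "profile")
    _check_keys(cfg.get("overlap", {}), {"min_frac", "min_count"}, "overlap")
    _check_keys(cfg.get("phylostrata", {}), {"evalue_threshold"}, "phylostrata")
    _check_keys(cfg.get("consensus", {}), {"use_truth"}, "consensus")
    _check_keys(cfg.get("synteny", {}), {"max_gap", "target_families"}, "synteny")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Execute the configured stages in dependency order under ``outdir``.

    Returns the path of the run manifest.  Raises :class:`ConfigError` before
    any stage runs if the config is invalid.
    """
    config_sha = None
    if not isinstance(config, dict):
        config_path = Path(config)
        config_sha = _sha256(config_path)
        config = load_config(config_path)
    else:
        _check_keys(config, _PIPELINE_KEYS, "pipeline config")
        if "seed" not in config:
            raise ConfigError("missing required key 'seed'")
        config = dict(config)
        config.setdefault("stages", list(STAGES))

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_section = dict(config.get("simulate", {}))
    sim_section.setdefault("seed", config["seed"])
    sim_cfg = sim_config_from_dict(sim_section)
    stages = config["stages"]

    t0 = time.perf_counter()

    def stage_done(name: str) -> None:
        logger.info("stage %-12s done at %.2fs", name, time.perf_counter() - t0)

    fixtures = outdir / "fixtures"
    fixtures.mkdir(exist_ok=True)

    suite = simulate_annotation_suite(sim_cfg)
    gene_fx = simulate_gene_fixture(sim_cfg)
    hit_fx = simulate_hit_table(sim_cfg)
    label_fx = simulate_labels(sim_cfg)
    order_fx = simulate_gene_orders(sim_cfg)

    if "simulate" in stages:
        write_genome_index(suite.index, fixtures / "genome_index.tsv")
        write_bed(suite.true_set, fixtures / "true_repeats.bed")
        for aset in suite.tool_sets:
            write_bed(aset, fixtures / f"tool_{aset.source}.bed")
        write_gff3_genes(gene_fx.se_genes, fixtures / "transcripts_single_exon.gff3")
        write_gff3_genes(gene_fx.annotated_genes, fixtures / "genes_annotated.gff3")
        _write_tsv(gene_fx.registry, fixtures / "registry_genes.tsv")
        hit_fx.hit_table.hits.astype(int).to_csv(fixtures / "hit_table.tsv", sep="\t")
        _write_tsv(hit_fx.registry, fixtures / "registry_hits.tsv")
        label_fx.label_table.orders.to_csv(fixtures / "labels.tsv", sep="\t")
        label_fx.truth.to_frame().to_csv(fixtures / "labels_truth.tsv", sep="\t")
        _write_tsv(label_fx.registry, fixtures / "registry_labels.tsv")
        for order in (order_fx.focal, order_fx.out1, order_fx.out2):
            write_gene_order(order, fixtures / f"order_{order.species}.tsv")
        _write_tsv(order_fx.registry, fixtures / "registry_orders.tsv")
        _write_tsv(
            pd.DataFrame(
                [
                    {"te_class": k, "true_bp": v}
                    for k, v in sorted(suite.registry["class_bp"].items())
                ]
            ),
            fixtures / "registry_true_class_bp.tsv",
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {"tool": name, **stats}
                    for name, stats in sorted(suite.registry["tool_stats"].items())
                ]
            ),
            fixtures / "registry_tools.tsv",
        )
        stage_done("simulate")

    cc = config.get("concordance", {})
    if "concordance" in stages:
        grid = make_windows(suite.index, int(cc.get("window", 1000)))
        pm = binarize_windows(suite.tool_sets, grid, min_bases=int(cc.get("min_bases", 1)))
        dendro = cluster_methods(pm)
        _write_tsv(dendro.to_frame(), outdir / "concordance_linkage.tsv")
        patterns = pattern_abundance(pm, top_k=int(cc.get("top_k", 20)))
        _write_tsv(
            pd.DataFrame(
                [
                    {"pattern": "".join(map(str, p.pattern)), "n_windows": p.count}
                    for p in patterns
                ],
                columns=["pattern", "n_windows"],
            ),
            outdir / "concordance_patterns.tsv",
        )
        ref_name = cc.get("reference", suite.tool_sets[0].source)
        by_name = {s.source: s for s in suite.tool_sets}
        if ref_name not in by_name:
            raise ConfigError(f"unknown reference tool {ref_name!r} under 'concordance'")
        ref = by_name[ref_name]
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "method": s.source,
                        "reference": ref_name,
                        "agreement": pairwise_agreement(s, ref),
                    }
                    for s in suite.tool_sets
                    if s.source != ref_name
                ]
            ),
            outdir / "concordance_agreement.tsv",
        )
        _write_tsv(coverage_summary(suite.tool_sets), outdir / "concordance_coverage.tsv")
        stage_done("concordance")

    pc = config.get("profile", {})
    if "profile" in stages:
        from .te_profile import composition_summary, density_profile

        _write_tsv(
            composition_summary(suite.true_set), outdir / "profile_composition.tsv"
        )
        grid5 = make_windows(suite.index, int(pc.get("window", 5000)))
        for cls_name in pc.get("classes", ["DNA", "LINE", "LTR"]):
            df = density_profile(
                suite.true_set,
                grid5,
                cls_name,
                merge_penelope=bool(pc.get("merge_penelope", False)),
            )
            _write_tsv(df, outdir / f"profile_density_{cls_name}.tsv")
        stage_done("profile")

    oc = config.get("overlap", {})
    if "overlap" in stages:
        contained = fully_contained_overlaps(gene_fx.se_genes, gene_fx.repeats)
        merged_genes = merge_isoforms(gene_fx.annotated_genes)
        covered = exon_coverage_overlaps(
            merged_genes, gene_fx.repeats, min_frac=float(oc.get("min_frac", 0.5))
        )
        _write_tsv(records_to_frame(contained), outdir / "overlap_contained.tsv")
        _write_tsv(records_to_frame(covered), outdir / "overlap_coverage.tsv")
        _write_tsv(
            superfamily_tally(contained, min_count=int(oc.get("min_count", 20))),
            outdir / "overlap_superfamily_tally.tsv",
        )
        stage_done("overlap")

    if "phylostrata" in stages:
        assign = assign_age_classes(
            hit_fx.hit_table,
            evalue_threshold=float(
                config.get("phylostrata", {}).get("evalue_threshold", 1e-5)
            ),
        )
        assign.to_frame().to_csv(outdir / "phylostrata_age_classes.tsv", sep="\t")
        contrib = repeat_contribution_by_age(
            assign, hit_fx.overlap_map, n_classes=hit_fx.hit_table.n_species
        )
        _write_tsv(contrib, outdir / "phylostrata_contribution.tsv")
        stage_done("phylostrata")

    if "consensus" in stages:
        lt = label_fx.label_table
        methods = lt.methods
        for a, b in ((methods[0], methods[1]), (methods[0], methods[2])):
            counts, fractions = cross_classification_matrix(lt, a, b)
            counts.to_csv(outdir / f"consensus_cross_{a}_{b}.tsv", sep="\t")
        truth = (
            label_fx.truth
            if bool(config.get("consensus", {}).get("use_truth", True))
            else None
        )
        report = consensus_report(lt, truth=truth)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "method": m,
                        "error_rate": report.error_rates[m],
                        "n_reference": report.n_reference[m],
                        "unanimity_rate": report.unanimity_rate,
                    }
                    for m in methods
                ]
            ),
            outdir / "consensus_report.tsv",
        )
        stage_done("consensus")

    if "synteny" in stages:
        sc = config.get("synteny", {})
        targets = set(sc.get("target_families", [order_fx.target_family]))
        calls = detect_lineage_specific_insertions(
            order_fx.focal,
            order_fx.out1,
            order_fx.out2,
            target_families=targets,
            max_gap=int(sc.get("max_gap", 2)),
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "scaffold": c.scaffold,
                        "gene_ids": ",".join(c.gene_ids),
                        "family": c.family,
                        "left_anchor": c.left_anchor,
                        "right_anchor": c.right_anchor,
                        "supported_by": ",".join(sorted(c.supported_by)),
                    }
                    for c in calls
                ],
                columns=[
                    "scaffold",
                    "gene_ids",
                    "family",
                    "left_anchor",
                    "right_anchor",
                    "supported_by",
                ],
            ),
            outdir / "synteny_insertions.tsv",
        )
        stage_done("synteny")

    outputs = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "package_version": __version__,
        "seed": int(config["seed"]),
        "stages": stages,
        "config_sha256": config_sha,
        "outputs": outputs,
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path
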