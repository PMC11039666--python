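"""End-to-end orchestration: SE calling -> waves -> linking -> CRC -> SNPs.

A single :class:`PipelineConfig` (YAML-serializable) names every input and
threshold; :func:`run_pipeline` executes the stages in order, writes every
intermediate artifact under the output directory, and returns a run report
(also written as ``report.yaml``).  Re-running with an identical config
reproduces the report bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import crc_network, se_calling, se_gene_linking, temporal_waves
from .io_formats import (
    GenomicInterval,
    open_genome,
    read_coverage,
    read_expression,
    read_gene_table,
    read_intervals,
    read_pwm_jaspar,
    read_snp_table,
    read_totals,
)
from .se_calling import SECallConfig
from .temporal_waves import WaveConfig

log = logging.getLogger("sewaves")


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and the offending input."""


@dataclass
class PipelineConfig:
    """All paths and thresholds of one pipeline run."""

    samples: dict[str, dict[str, str]]  # sample_id -> {peaks, coverage}
    genes: str
    expression: str
    totals: str
    out_dir: str
    genome: str = ""
    pwms: str = ""
    snps: str = ""
    amplified: str = ""
    stitch_distance: int = 12_500
    tss_exclusion: int = 2_000
    gene_window: int = 50_000
    stable_cv_max: float = 0.30
    invariance_threshold: float = 200.0
    k: int = 5
    n_init: int = 25
    r_min: float = 0.45
    comparator: str = ">="
    link_stat: str = "r"
    scan_threshold_frac: float = 0.8
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def secall_config(self, amplified: list[GenomicInterval]) -> SECallConfig:
        return SECallConfig(
            stitch_distance=self.stitch_distance,
            tss_exclusion=self.tss_exclusion,
            gene_window=self.gene_window,
            amplified_regions=amplified,
        )

    def wave_config(self) -> WaveConfig:
        return WaveConfig(
            stable_cv_max=self.stable_cv_max,
            invariance_threshold=self.invariance_threshold,
            k=self.k,
            n_init=self.n_init,
            seed=self.seed,
        )


def config_from_bundle(bundle_dir: str | Path, out_dir: str | Path, **overrides) -> PipelineConfig:
    """Build a config from a synthetic bundle's manifest.yaml."""
    bundle = Path(bundle_dir)
    with open(bundle / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    samples = {
        s: {
            "peaks": str(bundle / manifest["peaks"][s]),
            "coverage": str(bundle / manifest["coverage"][s]),
        }
        for s in manifest["samples"]
    }
    cfg = PipelineConfig(
        samples=samples,
        genes=str(bundle / manifest["genes"]),
        expression=str(bundle / manifest["expression"]),
        totals=str(bundle / manifest["totals"]),
        genome=str(bundle / manifest["genome"]),
        pwms=str(bundle / manifest["pwms"]),
        snps=str(bundle / manifest["snps"]),
        amplified=str(bundle / manifest["amplified"]),
        out_dir=str(out_dir),
        seed=int(manifest.get("seed", 0)),
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems = []
    if not cfg.samples:
        problems.append("samples: no samples configured")
    for sample, paths in cfg.samples.items():
        for kind in ("peaks", "coverage"):
            p = paths.get(kind)
            if not p or not Path(p).exists():
                problems.append(f"samples[{sample}].{kind}: missing file {p!r}")
    for name in ("genes", "expression", "totals"):
        p = getattr(cfg, name)
        if not p or not Path(p).exists():
            problems.append(f"{name}: missing file {p!r}")
    for name in ("genome", "pwms", "snps", "amplified"):
        p = getattr(cfg, name)
        if p and not Path(p).exists():
            problems.append(f"{name}: missing file {p!r}")
    for name in ("stitch_distance", "tss_exclusion", "gene_window"):
        if getattr(cfg, name) < 0:
            problems.append(f"{name}: must be >= 0")
    if not (0 < cfg.stable_cv_max < 1):
        problems.append("stable_cv_max: must lie in (0, 1)")
    if cfg.invariance_threshold < 0:
        problems.append("invariance_threshold: must be >= 0")
    if cfg.k < 2:
        problems.append("k: must be >= 2")
    if not (-1 <= cfg.r_min <= 1):
        problems.append("r_min outside [-1, 1]")
    if cfg.comparator not in (">", ">="):
        problems.append(f"comparator: unknown {cfg.comparator!r}")
    if cfg.link_stat not in ("r", "r2"):
        problems.append(f"link_stat: unknown {cfg.link_stat!r}")
    if not (0 < cfg.scan_threshold_frac <= 1):
        problems.append("scan_threshold_frac: must lie in (0, 1]")
    return problems


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}': {exc}") from exc
        return wrapper
    return decorator


def _read_amplified(path: str) -> list[GenomicInterval]:
    if not path:
        return []
    return [p.interval for p in read_intervals(path, format="bed")]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the run report dict."""
    problems = validate_config(cfg)
    if problems:
        raise PipelineError("stage 'validate': " + "; ".join(problems))
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    (out / "se_calls").mkdir(parents=True, exist_ok=True)
    (out / "crc").mkdir(exist_ok=True)

    # --- inputs -------------------------------------------------------------
    @_stage("inputs")
    def _load_inputs():
        genes = read_gene_table(cfg.genes)
        totals = read_totals(cfg.totals)
        coverage = {s: read_coverage(p["coverage"]) for s, p in cfg.samples.items()}
        peaks = {
            s: read_intervals(p["peaks"], format="narrowpeak", sample_id=s)
            for s, p in cfg.samples.items()
        }
        amplified = _read_amplified(cfg.amplified)
        return genes, totals, coverage, peaks, amplified

    genes, totals, coverage, peaks, amplified = _load_inputs()
    log.info("inputs: %d samples, %d genes", len(cfg.samples), len(genes))

    # --- per-sample SE calling ----------------------------------------------
    @_stage("call-se")
    def _call():
        secfg = cfg.secall_config(amplified)
        se_sets: dict[str, list[GenomicInterval]] = {}
        for sample in sorted(cfg.samples):
            ranked, cutoff = se_calling.call_super_enhancers(
                peaks[sample], genes, coverage[sample], None, secfg
            )
            rows = [
                {
                    "chrom": r.interval.chrom,
                    "start": r.interval.start,
                    "end": r.interval.end,
                    "load": r.load,
                    "rank": r.rank,
                    "is_super": r.is_super,
                }
                for r in ranked
            ]
            df = pd.DataFrame(rows)
            df.to_csv(out / "se_calls" / f"{sample}.tsv", sep="\t", index=False,
                      float_format="%.10g")
            se_sets[sample] = [r.interval for r in ranked if r.is_super]
            log.info("call-se[%s]: %d regions, %d SEs, cutoff %.3f",
                     sample, len(ranked), len(se_sets[sample]), cutoff)
        return se_sets

    se_sets = _call()

    # --- master set and profiles --------------------------------------------
    @_stage("waves")
    def _waves():
        master, membership = temporal_waves.build_master_set(se_sets)
        with open(out / "master_se.bed", "w") as fh:
            for se_id, iv in master:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{se_id}\n")
        profiles = temporal_waves.quantify_profiles(master, coverage, totals)
        profiles.to_csv(out / "profiles.tsv", sep="\t", index_label="se_id",
                        float_format="%.10g")
        classification = temporal_waves.classify_profiles(profiles, cfg.wave_config())
        classification.to_csv(out / "classification.tsv", sep="\t",
                              index_label="se_id", float_format="%.10g")
        if "elbow" in classification.attrs:
            classification.attrs["elbow"].to_csv(out / "elbow.tsv", sep="\t", index=False)
            pd.DataFrame(classification.attrs["centroids"]).to_csv(
                out / "centroids.tsv", sep="\t", index=False
            )
        log.info("waves: %d master SEs", len(master))
        return master, membership, profiles, classification

    master, membership, profiles, classification = _waves()
    counts = temporal_waves.partition_summary(classification)

    # --- SE-gene linking ------------------------------------------------------
    @_stage("link")
    def _link():
        expr = read_expression(cfg.expression)
        master_by_id = dict(master)
        dynamic_ids = classification.index[
            classification["class_label"] == "dynamic"
        ]
        ses = [
            se_calling.StitchedEnhancer(
                interval=master_by_id[se_id], constituents=[], se_id=se_id
            )
            for se_id in dynamic_ids
        ]
        assigned = se_calling.assign_genes(ses, genes, cfg.gene_window)
        pairs = [(se.se_id, g.gene_id, dist) for se, g, dist in assigned]
        links = se_gene_linking.link_and_filter(
            profiles, expr, pairs,
            r_min=cfg.r_min, comparator=cfg.comparator, stat=cfg.link_stat,
            classification=classification,
        )
        tf_links, wave_summary = se_gene_linking.restrict_to_tfs(links, genes)
        se_gene_linking.links_table(links).to_csv(
            out / "links.tsv", sep="\t", index=False, float_format="%.10g"
        )
        wave_summary.to_csv(out / "wave_tf_summary.tsv", sep="\t", index=False,
                            float_format="%.10g")
        log.info("link: %d candidate pairs, %d TF links pass",
                 len(links), sum(l.passes for l in tf_links))
        return expr, links, tf_links, wave_summary

    expr, links, tf_links, wave_summary = _link()

    # --- CRC ------------------------------------------------------------------
    crc_summary: dict = {"n_tfs": 0, "n_edges": 0}
    if cfg.genome and cfg.pwms:

        @_stage("crc")
        def _crc():
            genome = open_genome(cfg.genome)
            pwm_list = read_pwm_jaspar(cfg.pwms)
            pwm_by_name = {p.name: p for p in pwm_list}
            symbol_by_gene = {g.gene_id: g.symbol for g in genes}
            master_by_id = dict(master)
            tf_ses: dict[str, list[GenomicInterval]] = {}
            tf_expr: dict[str, float] = {}
            for link in tf_links:
                if not link.passes:
                    continue
                symbol = symbol_by_gene[link.gene_id]
                if symbol not in pwm_by_name:
                    continue
                tf_ses.setdefault(symbol, []).append(master_by_id[link.se_id])
                tf_expr[symbol] = float(expr.loc[link.gene_id].mean())
            if not tf_ses:
                return crc_network.CRCGraph(graph=crc_network.nx.DiGraph())
            crc = crc_network.build_crc(
                tf_ses, genome, pwm_by_name, tf_expr,
                threshold_frac=cfg.scan_threshold_frac,
            )
            (out / "crc" / "leaf.json").write_text(crc_network.serialize_leaf(crc))
            (out / "crc" / "crc.dot").write_text(crc_network.leaf_to_dot(crc))
            crc_network.inward_outward_table(crc).to_csv(
                out / "crc" / "inward_outward.tsv", sep="\t", index=False,
                float_format="%.10g",
            )
            log.info("crc: %d TFs, %d edges", crc.graph.number_of_nodes(),
                     crc.graph.number_of_edges())
            return crc

        crc = _crc()
        crc_summary = {
            "n_tfs": int(crc.graph.number_of_nodes()),
            "n_edges": int(crc.graph.number_of_edges()),
        }

    # --- SNP overlap ----------------------------------------------------------
    n_snp_overlaps = 0
    if cfg.snps:

        @_stage("snp-overlap")
        def _snp():
            snps = read_snp_table(cfg.snps, one_based=True)
            rows = [
                (se_id, iv, str(classification.loc[se_id, "wave_label"]))
                for se_id, iv in master
                if classification.loc[se_id, "class_label"] == "dynamic"
            ]
            overlaps = crc_network.intersect_snps(snps, rows)
            overlaps.to_csv(out / "snp_overlaps.tsv", sep="\t", index=False,
                            float_format="%.10g")
            log.info("snp-overlap: %d rows", len(overlaps))
            return overlaps

        n_snp_overlaps = int(len(_snp()))

    # --- report ---------------------------------------------------------------
    report = {
        "partition": counts,
        "wave_tf_links": {
            str(r.wave_label): {"n_links": int(r.n_links), "n_tf_links": int(r.n_tf_links)}
            for r in wave_summary.itertuples(index=False)
        },
        "n_links_passing": int(sum(l.passes for l in links)),
        "crc": crc_summary,
        "n_snp_overlaps": n_snp_overlaps,
        "parameters": {
            k: v
            for k, v in asdict(cfg).items()
            if k not in ("samples", "out_dir", "log_level")
        },
    }
    with open(out / "report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
    return report
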