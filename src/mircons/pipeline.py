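"""End-to-end orchestration of the synthetic demonstration pipeline.

``run_pipeline`` executes, in dependency order, the stages of the in-silico
workflow: two-color array DE -> top-miRNA selection -> multi-predictor
consensus target prediction -> minimum-site prioritization -> CRE filtering
of a down-regulated gene set, plus the qPCR ddCt stage.  Each stage writes
its outputs before the next starts, and a YAML run manifest records record
counts, output checksums and the seed, so a rerun with the same config is
checksum-identical for every deterministic stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, array_de, cre_scan, io, qpcr_stats, synthetic_data
from . import target_consensus as tc
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

_DEMO_MIRNAS = {
    "miR-17-like": "CAAAGUGCUUACAGUGCAGGUAG",
    "miR-144-like": "UACAGUAUAGAUGAUGUACU",
    "miR-22-like": "AAGCUGCCAGUUGAAGAACUGU",
    "miR-181a-like": "AACAUUCAACGCUGUCGGUGAGU",
    "miR-21-like": "UAGCUUAUCAGACUGAUGUUGA",
}

# the worked composition: a Creb1-like gene carrying 3+1+2+2 = 8 sites
CREB1_LIKE_COUNTS = {
    "Creb1-like": {
        "miR-17-like": 3,
        "miR-144-like": 1,
        "miR-22-like": 2,
        "miR-181a-like": 2,
    }
}


@dataclass
class PipelineConfig:
    """Validated run configuration; unknown keys in YAML are rejected."""

    seed: int = 0
    outdir: str = "mircons_run"
    # stage toggles
    run_de: bool = True
    run_qpcr: bool = True
    run_targets: bool = True
    run_cre: bool = True
    # array DE stage
    n_probes: int = 580
    n_arrays: int = 10
    de_fraction: float = 0.06
    effect_log2: float = 2.0
    alpha: float = 1e-4
    adjust: str = "bonferroni"
    top_n: int = 100
    # qPCR stage
    qpcr_reference: str = "Hprt"
    qpcr_n_per_group: int = 5
    # target stage
    n_genes: int = 50
    utr_length: int = 1000
    consensus_k: int = 5
    min_sites: int = 4
    n_predictors: int = 5
    predictor_sensitivity: float = 1.0
    predictor_false_calls_per_kb: float = 0.0
    predictor_jitter: int = 0
    # CRE stage
    motif: str = cre_scan.CRE_MOTIF
    n_promoters: int = 185
    n_cre_positive: int = 35
    promoter_length: int = 1100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = io.read_yaml(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class RunManifest:
    version: str
    seed: int
    config_hash: str
    stage_counts: dict = field(default_factory=dict)
    output_checksums: dict = field(default_factory=dict)
    wall_time_s: float = 0.0

    def write(self, path) -> None:
        io.write_yaml_atomic(dataclasses.asdict(self), path)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all enabled stages on freshly simulated inputs."""
    t0 = time.monotonic()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(__version__, config.seed, config.config_hash())
    logger.info("pipeline start, seed=%d, outdir=%s", config.seed, out)

    def record(name: str, path: Path):
        manifest.output_checksums[name] = io.sha256_file(path)

    prioritized_genes: list[str] = []

    if config.run_de:
        sim = synthetic_data.simulate_two_color_array(
            n_probes=config.n_probes, n_arrays=config.n_arrays,
            de_fraction=config.de_fraction, effect_log2=config.effect_log2,
            seed=config.seed,
        )
        result, call = array_de.de_analysis(
            sim, adjust=config.adjust, alpha=config.alpha, top_n=config.top_n,
        )
        io.write_table(call.top.assign(rank=call.top["rank"]),
                       out / "de_top.tsv")
        io.write_table(result.table, out / "de_results.tsv")
        manifest.stage_counts["n_significant_mirnas"] = int(len(call.significant))
        manifest.stage_counts["n_top_mirnas"] = int(len(call.top))
        record("de_results.tsv", out / "de_results.tsv")
        record("de_top.tsv", out / "de_top.tsv")
        logger.info("DE stage: %d significant of %d probes",
                    len(call.significant), config.n_probes)

    if config.run_qpcr:
        genes = [config.qpcr_reference] + list(_DEMO_MIRNAS)
        lfc = {config.qpcr_reference: 0.0, "miR-17-like": 1.5, "miR-21-like": 2.0,
               "miR-144-like": 1.0, "miR-22-like": -1.0, "miR-181a-like": 0.0}
        cp_sim = synthetic_data.simulate_cp_table(
            genes, n_per_group=config.qpcr_n_per_group, true_log2fc=lfc,
            reference_gene=config.qpcr_reference, seed=config.seed,
        )
        dcp = qpcr_stats.compute_dcp(cp_sim.to_cp_table())
        table = qpcr_stats.ddct_analysis(dcp)
        io.write_table(table, out / "qpcr_ddct.tsv")
        manifest.stage_counts["n_qpcr_genes"] = int(len(table))
        record("qpcr_ddct.tsv", out / "qpcr_ddct.tsv")

    if config.run_targets:
        utr_sim = synthetic_data.simulate_utr_set(
            n_genes=config.n_genes, utr_length=config.utr_length,
            mirnas=_DEMO_MIRNAS, planted_counts=CREB1_LIKE_COUNTS,
            seed=config.seed,
        )
        io.write_fasta(utr_sim.utr_sequences, out / "utrs.fasta")
        profiles = [
            synthetic_data.PredictorProfile(
                f"predictor{i + 1}", config.predictor_sensitivity,
                config.predictor_false_calls_per_kb, config.predictor_jitter)
            for i in range(config.n_predictors)
        ]
        calls = synthetic_data.simulate_predictor_calls(
            utr_sim, profiles, seed=config.seed)
        tc.write_predictions(calls, out / "predictor_calls.tsv")
        targets = tc.consensus_interactions(calls, k=config.consensus_k)
        prioritized = tc.prioritize_targets(targets, min_sites=config.min_sites)
        io.write_table(prioritized.table, out / "prioritized_genes.tsv")
        io.write_table(prioritized.matrix.reset_index(), out / "site_count_matrix.tsv")
        io.write_bed6([s for t in targets for s in t.sites], out / "consensus_sites.bed")
        prioritized_genes = prioritized.table["gene"].tolist()
        manifest.stage_counts["n_consensus_pairs"] = int(
            sum(t.n_mirnas for t in targets))
        manifest.stage_counts["n_prioritized_genes"] = int(len(prioritized_genes))
        for name in ("utrs.fasta", "predictor_calls.tsv", "prioritized_genes.tsv",
                     "site_count_matrix.tsv", "consensus_sites.bed"):
            record(name, out / name)
        logger.info("target stage: %d prioritized gene(s)", len(prioritized_genes))

    if config.run_cre:
        # the down-regulated gene set: prioritized targets head a list padded
        # to n_promoters; the first n_cre_positive carry planted CRE motifs
        down = prioritized_genes or ["Creb1-like"]
        all_genes = down + [f"down{i + 1:03d}"
                            for i in range(config.n_promoters - len(down))]
        planted = {g: (1 if i < config.n_cre_positive else 0)
                   for i, g in enumerate(all_genes)}
        prom = synthetic_data.simulate_promoters(
            n_genes=config.n_promoters, length=config.promoter_length,
            planted=planted, motif=config.motif, seed=config.seed,
        )
        io.write_fasta(prom.promoter_sequences, out / "promoters.fasta")
        hits = cre_scan.scan_promoters(prom.promoter_sequences, motif=config.motif)
        table = cre_scan.intersect_with_gene_set(hits, set(all_genes))
        io.write_table(table, out / "cre_candidates.tsv")
        io.write_bed6([h for hs in hits.values() for h in hs], out / "cre_hits.bed")
        manifest.stage_counts["n_cre_candidates"] = int(
            len(cre_scan.candidate_genes(table)))
        for name in ("promoters.fasta", "cre_candidates.tsv", "cre_hits.bed"):
            record(name, out / name)

    manifest.wall_time_s = round(time.monotonic() - t0, 3)
    manifest.write(out / "manifest.yaml")
    logger.info("pipeline done in %.1fs", manifest.wall_time_s)
    return manifest
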