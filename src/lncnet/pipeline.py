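"""End-to-end orchestration of the analysis chain.

Stages run in the study's order: differential expression screening ->
coexpression network (hubs, top edges) -> cis-window target intersection ->
over-representation of up-/downregulated network mRNAs -> qPCR validation
and direction concordance. Every stage writes its table under the run
directory; a JSON manifest records the config, thresholds, per-stage record
counts and wall time. The chain is deterministic given inputs and config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cis as cismod
from . import coexpression as coex
from . import diffexpr, enrichment, io as lio, plots, qpcr as qpcrmod
from .containers import LNCRNA, MRNA, ValidationError
from .synthetic import REFERENCE_GENE, SyntheticConfig, write_bundle

log = logging.getLogger(__name__)


class ConfigError(ValidationError):
    """Invalid pipeline configuration (bad paths or thresholds)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs, thresholds and mode flags for a full run."""

    expression: str
    metadata: str
    out_dir: str
    bed: str | None = None
    gmt: str | None = None
    qpcr: str | None = None
    fc_threshold: float = 1.5
    p_de: float = 0.05
    pcc_threshold: float = 0.7
    p_edge: float = 0.05
    min_degree: int = 60
    window_bp: int = 300_000
    top_k: int = 30
    p_enrich: float = 0.05
    correlation_samples: str = "pooled"  # pooled | case | control
    qpcr_test: str = "t"  # t | mann-whitney
    reference_gene: str = REFERENCE_GENE
    seed: int = 0
    figures: bool = True

    def validate(self) -> None:
        for name in ("fc_threshold", "p_de", "pcc_threshold", "p_edge", "p_enrich"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("min_degree", "window_bp", "top_k"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("expression", "metadata", "bed", "gmt", "qpcr"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name} path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def simulate(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the full synthetic input bundle, ready for :func:`run`."""
    return write_bundle(config, out_dir)


def run(config: PipelineConfig) -> Path:
    """Execute the full chain; returns the run directory.

    Any stage failure raises :class:`StageError` after recording the stage
    name in the manifest with ``"incomplete"`` status.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fig_dir = out / "figures"
    if config.figures:
        fig_dir.mkdir(exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("lncnet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "counts": {},
        "status": "incomplete",
    }
    t0 = time.time()
    stage = "setup"
    try:
        stage = "diffexpr"
        matrix = lio.read_expression(config.expression, config.metadata)
        de = diffexpr.moderated_t_test(
            matrix, fc_threshold=config.fc_threshold, p_threshold=config.p_de
        )
        de.to_csv(out / "de_results.csv")
        n_de_lnc = int(((de["is_de"]) & (de["biotype"] == LNCRNA)).sum())
        n_de_mrna = int(((de["is_de"]) & (de["biotype"] == MRNA)).sum())
        log.info(
            "DE screen |FC|>=%g & P<%g: %d DE lncRNAs, %d DE mRNAs of %d probes",
            config.fc_threshold, config.p_de, n_de_lnc, n_de_mrna, len(de),
        )
        manifest["counts"]["de_results"] = len(de)
        manifest["counts"]["de_lnc"] = n_de_lnc
        manifest["counts"]["de_mrna"] = n_de_mrna
        if config.figures:
            plots.volcano_plot(
                de, fig_dir / "volcano.png", config.fc_threshold, config.p_de
            )

        stage = "network"
        network = coex.build_cnc(
            matrix,
            de,
            pcc_threshold=config.pcc_threshold,
            p_threshold=config.p_edge,
            samples=config.correlation_samples,
        )
        hubs = coex.degree_filter(network, config.min_degree)
        nodes = network.nodes.copy()
        nodes["is_hub"] = nodes.index.isin(hubs.index)
        network.edges.to_csv(out / "edges.csv", index=False)
        nodes.to_csv(out / "nodes.csv", index_label="id")
        coex.top_edges(network, config.top_k).to_csv(out / "top_edges.csv", index=False)
        lio.write_network(network, out / "network.sif", "sif")
        lio.write_network(network, out / "network.graphml", "graphml")
        log.info(
            "CNC |PCC|>%g & P<%g: %d edges, %d lncRNA + %d mRNA nodes, %d hubs (degree>%d)",
            config.pcc_threshold, config.p_edge, network.n_edges,
            int((nodes["biotype"] == LNCRNA).sum()),
            int((nodes["biotype"] == MRNA).sum()), len(hubs), config.min_degree,
        )
        manifest["counts"]["edges"] = network.n_edges
        manifest["counts"]["nodes"] = len(nodes)
        manifest["counts"]["hubs"] = len(hubs)

        stage = "cis"
        if config.bed:
            loci = lio.read_bed(config.bed)
            by_id = {l.probe_id: l for l in loci}
            de_ids = de.index[de["is_de"]]
            missing = [p for p in de_ids if p not in by_id]
            if missing:
                log.warning("no locus for %d DE probe(s); skipped", len(missing))
            lnc_loci = [
                by_id[p] for p in de_ids
                if p in by_id and de.loc[p, "biotype"] == LNCRNA
            ]
            mrna_loci = [
                by_id[p] for p in de_ids
                if p in by_id and de.loc[p, "biotype"] == MRNA
            ]
            cis_pairs = cismod.find_cis_pairs(lnc_loci, mrna_loci, config.window_bp)
            cis_pairs.to_csv(out / "cis_pairs.csv", index=False)
            cis_coexp = cismod.intersect_cis_coexpressed(cis_pairs, network)
            cis_coexp.to_csv(out / "cis_coexpressed.csv", index=False)
            cismod.per_lnc_summary(cis_coexp).to_csv(
                out / "cis_summary.csv", index=False
            )
            log.info(
                "cis window <=%d bp: %d candidate pairs, %d also coexpressed",
                config.window_bp, len(cis_pairs), len(cis_coexp),
            )
            manifest["counts"]["cis_pairs"] = len(cis_pairs)
            manifest["counts"]["cis_coexpressed"] = len(cis_coexp)

        stage = "enrichment"
        if config.gmt:
            gene_sets = lio.read_gmt(config.gmt)
            universe = list(matrix.probes_of(MRNA))
            in_network = de.index.isin(network.nodes.index)
            de_net = de[in_network]
            up, down = enrichment.split_by_direction(de_net, biotype=MRNA)
            for name, genes in (("up", up), ("down", down)):
                res = enrichment.ora(genes, universe, gene_sets, config.p_enrich)
                res.to_csv(out / f"enrichment_{name}.csv", index=False)
                n_sig = int(res["significant"].sum()) if len(res) else 0
                log.info(
                    "ORA %sregulated (n=%d): %d/%d sets at P<%g",
                    name, len(genes), n_sig, len(res), config.p_enrich,
                )
                manifest["counts"][f"enrichment_{name}"] = n_sig
                if config.figures:
                    plots.enrichment_bars(
                        res, fig_dir / f"enrichment_{name}.png",
                        title=f"{name}regulated mRNAs",
                    )

        stage = "qpcr"
        if config.qpcr:
            records = lio.read_qpcr(config.qpcr)
            rel = qpcrmod.delta_delta_ct(records, config.reference_gene)
            rel.to_csv(out / "qpcr_relative.csv", index=False)
            compare = qpcrmod.group_compare(rel, method=config.qpcr_test)
            compare.to_csv(out / "qpcr_results.csv", index=False)
            shared = [g for g in compare["gene_id"] if g in de.index]
            if shared:
                array_dir = np.sign(de.loc[shared, "log2fc"]).astype(int)
                qp_dir = compare.set_index("gene_id").loc[shared, "direction"]
                frac, table = qpcrmod.concordance(qp_dir, array_dir)
                table.to_csv(out / "qpcr_concordance.csv", index=False)
                log.info(
                    "qPCR validation: %d genes, %.0f%% direction concordance",
                    len(table), 100 * frac,
                )
                manifest["counts"]["qpcr_genes"] = len(compare)
                manifest["counts"]["qpcr_concordant"] = int(table["concordant"].sum())
            if config.figures:
                plots.qpcr_bars(rel, compare, fig_dir / "qpcr.png")

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["failed_stage"] = stage
        raise StageError(stage, exc) from exc
    finally:
        manifest["wall_time_s"] = round(time.time() - t0, 3)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        root.removeHandler(handler)
        handler.close()
    return out
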