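"""End-to-end assembly pipeline: build/load graph -> prune -> traverse ->
write FASTA (and optionally GFA2/FASTG), with a machine-readable manifest.

This is the library face of the command-line ``assemble`` subcommand;
identical configuration and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import dbg, io_formats
from .consensus import assemble_consensus
from .subtractive import assemble_subtractive

logger = logging.getLogger(__name__)

ALGORITHMS = ("consensus", "subtractive", "unitig")


@dataclass
class RunConfig:
    """Everything one assembly run needs; defaults are the pipeline defaults.

    ``algorithm`` is one of ``consensus`` (coverage-guided walk with the
    bubble rule and sequence-graph output), ``subtractive`` (per-variant
    coverage subtraction) or ``unitig`` (maximal non-branching paths only).
    """

    input_files: list[str] = field(default_factory=list)
    k: int = 31
    algorithm: str = "consensus"
    min_coverage: float = 2
    tip_length: int = 100
    delta_sw: float = 0.8
    as_printed_delta_rule: bool = False
    multiple_contigs: bool = False
    min_contig_length: int = 100
    output_prefix: str = "assembly"
    emit_gfa: bool = False
    emit_fastg: bool = False
    save_graph: Optional[str] = None
    load_graph: Optional[str] = None
    search_budget: int = 1000
    lookahead: int = 64
    max_alt_length: int = 500
    max_k: int = dbg.DEFAULT_MAX_K
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        if self.k % 2 == 0 or not 3 <= self.k <= self.max_k:
            raise ValueError(
                f"k must be odd and in [3, {self.max_k}], got {self.k}"
            )
        if not self.input_files and not self.load_graph:
            raise ValueError("no input reads and no graph to load")
        if not 0 < self.delta_sw <= 1:
            raise ValueError(f"delta_sw must be in (0, 1], got {self.delta_sw}")


def build_or_load_graph(config: RunConfig) -> dbg.DeBruijnGraph:
    if config.load_graph:
        graph = dbg.load_graph(config.load_graph)
        logger.info("loaded graph: k=%d, %d nodes", graph.k, len(graph))
        if config.input_files:
            extra = _build_from_files(config)
            graph = dbg.merge_graphs(graph, extra)
            logger.info("merged with reads: %d nodes", len(graph))
        return graph
    return _build_from_files(config)


def _build_from_files(config: RunConfig) -> dbg.DeBruijnGraph:
    def stream():
        for path in config.input_files:
            yield from io_formats.read_sequences(path)

    graph = dbg.build_graph(stream(), config.k, max_k=config.max_k)
    logger.info("built graph: k=%d, %d nodes", config.k, len(graph))
    return graph


def run_assembly(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict (also written as a
    YAML manifest beside the outputs)."""
    config.validate()
    logging.basicConfig(level=config.log_level)

    graph = build_or_load_graph(config)
    tips, lowcov = dbg.prune_graph(
        graph, max_tip_length=config.tip_length, min_coverage=config.min_coverage
    )
    logger.info("pruned %d tip nodes, %d low-coverage nodes", tips, lowcov)
    if config.save_graph:
        dbg.save_graph(graph, config.save_graph)
        logger.info("graph saved to %s", config.save_graph)

    docs = []
    if config.algorithm == "consensus":
        contigs, docs = assemble_consensus(
            graph,
            min_coverage=config.min_coverage,
            lookahead=config.lookahead,
            multiple_contigs=config.multiple_contigs,
            explore_variants=config.emit_gfa or config.emit_fastg,
            max_alt_length=config.max_alt_length,
        )
    elif config.algorithm == "subtractive":
        contigs = assemble_subtractive(
            graph,
            min_coverage=config.min_coverage,
            delta_sw=config.delta_sw,
            as_printed=config.as_printed_delta_rule,
            search_budget=config.search_budget,
        )
    else:  # unitig
        contigs = dbg.extract_unitigs(graph, min_coverage=config.min_coverage)

    prefix = Path(config.output_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta = prefix.with_suffix(".fa")
    written = io_formats.write_contigs_fasta(
        contigs, fasta, min_length=config.min_contig_length
    )
    outputs = [str(fasta)]
    for i, doc in enumerate(docs, start=1):
        if config.emit_gfa:
            out = Path(f"{prefix}_contig_{i}.gfa")
            io_formats.write_gfa2(doc, out)
            outputs.append(str(out))
        if config.emit_fastg:
            out = Path(f"{prefix}_contig_{i}.fastg")
            io_formats.write_fastg(doc, out)
            outputs.append(str(out))

    summary = {
        "parameters": asdict(config),
        "graph_nodes": len(graph),
        "pruned_tip_nodes": tips,
        "pruned_low_coverage_nodes": lowcov,
        "contigs_total": len(contigs),
        "contigs_written": written,
        "outputs": outputs,
    }
    manifest = Path(f"{prefix}_manifest.yaml")
    with open(manifest, "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    logger.info(
        "%s assembly complete: %d contigs (%d >= %d bp) -> %s",
        config.algorithm, len(contigs), written, config.min_contig_length, fasta,
    )
    return summary
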