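"""End-to-end orchestration: segment files in, comparison + enrichment out.

Runs every stage in order for each sample/condition pair found in the
input directory: CNA calling, cytoband projection, gene-set construction,
subnetwork induction, centrality computation, HBS labeling; then the
cross-sample/cross-condition intersections and per-network GO
over-representation of the HBS members.  All emitted files use fixed
numeric formats, so a pipeline run is byte-deterministic in its inputs.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import cna, compare, genome, network
from .enrich import (
    EnrichmentResult,
    enrich as run_enrichment,
    filter_generic_terms,
    load_annotations,
    load_dag,
    propagate_annotations,
    write_enrichment,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

DEFAULT_BLOCKLIST = (
    "regulation of biological processes",
    "biochemical processes",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of a pipeline run (defaults follow the method)."""

    gain_threshold: float = 0.25
    loss_threshold: float = -0.25
    min_probes: int = 3
    min_samples: int = 2
    channels: frozenset = network.DEFAULT_CHANNELS
    min_score: int = network.DEFAULT_MIN_SCORE
    channel_mode: str = "any"
    protein_coding_only: bool = True
    alpha: float = 0.05
    blocklist: tuple[str, ...] = DEFAULT_BLOCKLIST


@dataclass
class PipelineResult:
    """Everything one run computed, keyed by (sample_id, condition)."""

    call_counts: dict[tuple[str, str], int]
    alterations: dict[tuple[str, str], list[cna.CytobandAlteration]]
    recurrent: dict[str, list[cna.RecurrentCytoband]]  # per condition
    gene_sets: dict[tuple[str, str], genome.GeneSet]
    networks: dict[tuple[str, str], network.Network]
    centralities: dict[tuple[str, str], network.CentralityTable]
    hbs_labels: dict[tuple[str, str], network.HBSLabels]
    hbs_sets: dict[tuple[str, str], compare.HBSSet]
    intersections: dict[str, compare.IntersectionReport]  # per condition
    cross_condition: compare.CrossConditionReport | None
    enrichment: dict[tuple[str, str], list[EnrichmentResult]]

    def hbs_counts(self) -> dict[tuple[str, str], int]:
        return {key: len(s.members) for key, s in self.hbs_sets.items()}


_SEGMENT_FILE = re.compile(r"^(?P<sample>.+)_(?P<condition>pre|post)\.tsv$")


def _discover_segments(input_dir: Path) -> dict[tuple[str, str], Path]:
    seg_dir = input_dir / "segments"
    if not seg_dir.is_dir():
        raise FileNotFoundError(f"no segments/ directory under {input_dir}")
    found: dict[tuple[str, str], Path] = {}
    for path in sorted(seg_dir.glob("*.tsv")):
        m = _SEGMENT_FILE.match(path.name)
        if m:
            found[(m.group("sample"), m.group("condition"))] = path
    if not found:
        raise FileNotFoundError(
            f"no <sample>_<pre|post>.tsv segment files under {seg_dir}"
        )
    return found


def run_pipeline(
    input_dir: str | Path,
    out_dir: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis over a fixture-layout input directory.

    Expects ``cytobands.tsv``, ``genes.tsv``, ``edges.txt``,
    ``segments/<sample>_<condition>.tsv`` and (for enrichment)
    ``ontology_edges.tsv``, ``ontology_names.tsv``, ``annotations.tsv``.
    When ``out_dir`` is given, every stage's tables are written there with
    fixed numeric formatting.
    """
    cfg = config or PipelineConfig()
    input_dir = Path(input_dir)
    cytobands = cna.load_cytobands(input_dir / "cytobands.tsv")
    annotation = genome.load_gene_annotation(input_dir / "genes.tsv")
    interactions = network.load_interactions(
        input_dir / "edges.txt",
        selected_channels=cfg.channels,
        min_score=cfg.min_score,
        mode=cfg.channel_mode,
    )

    segment_files = _discover_segments(input_dir)
    classified: dict[tuple[str, str], list[cna.CNASegment]] = {}
    for (sid, cond), path in segment_files.items():
        segments = cna.parse_segments(path, sample_id=sid, condition=cond)
        classified[(sid, cond)] = cna.classify_all(
            segments, cfg.gain_threshold, cfg.loss_threshold, cfg.min_probes
        )

    all_segments = [s for segs in classified.values() for s in segs]
    call_counts = cna.count_calls(all_segments)

    alterations: dict[tuple[str, str], list[cna.CytobandAlteration]] = {}
    for key, segs in classified.items():
        alterations[key] = cna.segments_to_cytobands(segs, cytobands)

    recurrent: dict[str, list[cna.RecurrentCytoband]] = {}
    for cond in ("pre", "post"):
        pooled = [
            a for (sid, c), alts in alterations.items() if c == cond
            for a in alts
        ]
        if pooled:
            recurrent[cond] = cna.recurrent_cytobands(
                pooled, min_samples=cfg.min_samples
            )

    gene_sets: dict[tuple[str, str], genome.GeneSet] = {}
    networks: dict[tuple[str, str], network.Network] = {}
    centralities: dict[tuple[str, str], network.CentralityTable] = {}
    hbs_labels: dict[tuple[str, str], network.HBSLabels] = {}
    hbs_sets: dict[tuple[str, str], compare.HBSSet] = {}
    for key in sorted(classified):
        gs = genome.build_gene_set(
            alterations[key], annotation, cytobands,
            protein_coding_only=cfg.protein_coding_only,
        )
        gene_sets[key] = gs
        net = network.induce_network(gs, interactions)
        networks[key] = net
        table = network.compute_centralities(net)
        centralities[key] = table
        labels = network.classify_hbs(table)
        hbs_labels[key] = labels
        hbs_sets[key] = compare.HBSSet(
            sample_id=key[0], condition=key[1], members=labels.hbs
        )

    intersections: dict[str, compare.IntersectionReport] = {}
    for cond in ("pre", "post"):
        cond_sets = [s for (sid, c), s in sorted(hbs_sets.items()) if c == cond]
        if len(cond_sets) >= 2:
            intersections[cond] = compare.intersect_hbs(cond_sets, condition=cond)

    pre_sets = [s for (sid, c), s in sorted(hbs_sets.items()) if c == "pre"]
    post_sets = [s for (sid, c), s in sorted(hbs_sets.items()) if c == "post"]
    cross = None
    if pre_sets and post_sets and (
        {s.sample_id for s in pre_sets} == {s.sample_id for s in post_sets}
    ):
        cross = compare.cross_condition_overlap(pre_sets, post_sets)

    enrichment: dict[tuple[str, str], list[EnrichmentResult]] = {}
    dag_path = input_dir / "ontology_edges.tsv"
    if dag_path.exists():
        dag = load_dag(dag_path, input_dir / "ontology_names.tsv"
                       if (input_dir / "ontology_names.tsv").exists()
                       else None)
        raw = load_annotations(input_dir / "annotations.tsv")
        propagated = propagate_annotations(raw, dag)
        universe = sorted(propagated.genes)
        for key, hbs_set in sorted(hbs_sets.items()):
            study = sorted(set(hbs_set.members) & set(universe))
            if not study:
                enrichment[key] = []
                continue
            results = run_enrichment(
                study, universe, propagated, dag, alpha=cfg.alpha
            )
            results, _ = filter_generic_terms(results, cfg.blocklist)
            enrichment[key] = results

    result = PipelineResult(
        call_counts=call_counts,
        alterations=alterations,
        recurrent=recurrent,
        gene_sets=gene_sets,
        networks=networks,
        centralities=centralities,
        hbs_labels=hbs_labels,
        hbs_sets=hbs_sets,
        intersections=intersections,
        cross_condition=cross,
        enrichment=enrichment,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with (out_dir / "call_counts.tsv").open("w") as fh:
        fh.write("sample\tcondition\tcalls\n")
        for (sid, cond), count in sorted(result.call_counts.items()):
            fh.write(f"{sid}\t{cond}\t{count}\n")

    with (out_dir / "cytoband_alterations.tsv").open("w") as fh:
        fh.write("sample\tcondition\tcytoband\tdirection\tn_segments\n")
        for key in sorted(result.alterations):
            for alt in result.alterations[key]:
                fh.write(
                    f"{alt.sample_id}\t{alt.condition}\t{alt.cytoband}\t"
                    f"{alt.direction}\t{len(alt.supporting_segments)}\n"
                )

    with (out_dir / "recurrent_cytobands.tsv").open("w") as fh:
        fh.write("condition\tcytoband\tn_samples\tsamples\tconcordant\n")
        for cond in sorted(result.recurrent):
            for rec in result.recurrent[cond]:
                fh.write(
                    f"{rec.condition}\t{rec.cytoband}\t{len(rec.samples)}\t"
                    f"{','.join(rec.samples)}\t{int(rec.concordant)}\n"
                )

    net_dir = out_dir / "networks"
    net_dir.mkdir(exist_ok=True)
    for key in sorted(result.networks):
        sid, cond = key
        genome_mod_path = net_dir / f"{sid}_{cond}.genes.tsv"
        genome.write_gene_set(result.gene_sets[key], genome_mod_path)
        network.write_edge_list(
            result.networks[key], net_dir / f"{sid}_{cond}.edges.tsv"
        )
        network.write_centrality_table(
            result.centralities[key],
            result.hbs_labels[key],
            net_dir / f"{sid}_{cond}.centrality.tsv",
        )

    if result.intersections and result.cross_condition is not None:
        compare.write_comparison(
            result.intersections,
            result.cross_condition,
            out_dir / "comparison.json",
            out_dir / "comparison.tsv",
        )

    if result.enrichment:
        enr_dir = out_dir / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        for key in sorted(result.enrichment):
            sid, cond = key
            write_enrichment(
                result.enrichment[key], enr_dir / f"{sid}_{cond}.tsv"
            )

    summary = {
        "call_counts": {
            f"{sid}:{cond}": n
            for (sid, cond), n in sorted(result.call_counts.items())
        },
        "hbs_counts": {
            f"{sid}:{cond}": n
            for (sid, cond), n in sorted(result.hbs_counts().items())
        },
        "network_sizes": {
            f"{sid}:{cond}": len(net)
            for (sid, cond), net in sorted(result.networks.items())
        },
    }
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
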