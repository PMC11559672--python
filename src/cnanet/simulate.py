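"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the four input kinds the pipeline consumes — a
genome annotation (cytobands + genes), paired pre/post-chemotherapy CNA
segment profiles per sample, a multi-channel interaction edge file, and an
ontology DAG with gene annotations — while recording exactly what was
planted (altered cytobands, high-centrality regulators, one enriched
term).  Every generator is a pure function of its parameters and seed; the
pseudo-random generator is numpy's PCG64 (via ``numpy.random.default_rng``
and ``SeedSequence`` spawning), which is pinned so emitted files are
byte-stable across runs and platforms.

The interaction generator grows a graph by preferential attachment with a
strong multiplicative attachment bias toward the planted regulators.  The
bias concentrates edges — and with them shortest paths — on the
regulators, so that above-mean degree, betweenness and eigenvector jointly
isolate the planted nodes.  This emulates the topology the pipeline is
meant to detect: a handful of regulators bridging otherwise sparsely
connected neighborhoods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cna import CNASegment, CytobandMap, write_segments
from .genome import GeneAnnotation, write_gene_annotation
from .network import ALL_CHANNELS, DEFAULT_CHANNELS, DEFAULT_MIN_SCORE

__all__ = [
    "RNG_NAME",
    "PROFILES",
    "Genome",
    "ChannelProfile",
    "FixtureProfile",
    "generate_genome",
    "generate_cna_profiles",
    "generate_ppi",
    "generate_annotations",
    "make_end_to_end_fixture",
    "write_cytobands",
    "write_edge_file",
]

RNG_NAME = "numpy.random.Generator(PCG64)"

Seed = "int | np.random.SeedSequence"


@dataclass(frozen=True)
class Genome:
    """A synthetic genome: tiling cytobands plus gene intervals."""

    cytobands: CytobandMap
    genes: tuple[GeneAnnotation, ...]

    @property
    def coding_symbols(self) -> tuple[str, ...]:
        return tuple(g.symbol for g in self.genes if g.biotype == "protein_coding")

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(name for _, _, _, name in self.cytobands.bands)


def generate_genome(
    n_chrom: int = 2,
    cytobands_per_chrom: int = 8,
    genes_per_cytoband: int = 15,
    noncoding_fraction: float = 0.10,
    seed: int | np.random.SeedSequence = 0,
    band_length_range: tuple[int, int] = (800_000, 1_200_000),
    gene_length_range: tuple[int, int] = (2_000, 50_000),
) -> Genome:
    """Build a genome of non-overlapping cytobands with genes placed inside.

    Bands tile each chromosome contiguously (first half "p" arm, second
    "q"); each band carries ``genes_per_cytoband`` genes placed uniformly
    within it, a ``noncoding_fraction`` of which are labeled ``other``.
    Deterministic per seed.
    """
    if min(n_chrom, cytobands_per_chrom, genes_per_cytoband) < 1:
        raise ValueError("all counts must be >= 1")
    if not 0 <= noncoding_fraction < 1:
        raise ValueError(
            f"noncoding_fraction must be in [0, 1), got {noncoding_fraction}"
        )
    if gene_length_range[1] > band_length_range[0]:
        raise ValueError(
            "impossible packing: maximum gene length "
            f"{gene_length_range[1]} exceeds minimum cytoband length "
            f"{band_length_range[0]}"
        )
    rng = np.random.default_rng(seed)
    bands: list[tuple[str, int, int, str]] = []
    genes: list[GeneAnnotation] = []
    counter = 0
    half = cytobands_per_chrom / 2
    for ci in range(1, n_chrom + 1):
        chrom = f"chr{ci}"
        pos = 0
        p_idx = q_idx = 0
        for bi in range(cytobands_per_chrom):
            length = int(rng.integers(band_length_range[0], band_length_range[1] + 1))
            if bi < half:
                p_idx += 1
                name = f"{ci}p{p_idx}"
            else:
                q_idx += 1
                name = f"{ci}q{q_idx}"
            start, end = pos, pos + length
            bands.append((chrom, start, end, name))
            for _ in range(genes_per_cytoband):
                glen = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
                gstart = int(rng.integers(start, end - glen + 1))
                biotype = (
                    "other"
                    if rng.random() < noncoding_fraction
                    else "protein_coding"
                )
                counter += 1
                genes.append(
                    GeneAnnotation(
                        symbol=f"G{counter:04d}",
                        chrom=chrom,
                        start=gstart,
                        end=gstart + glen,
                        biotype=biotype,
                    )
                )
            pos = end
    return Genome(cytobands=CytobandMap(bands=tuple(bands)), genes=tuple(genes))


def write_cytobands(cytobands: CytobandMap, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for chrom, start, end, name in cytobands.bands:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# CNA profiles


def generate_cna_profiles(
    genome: Genome,
    n_samples: int = 3,
    planted_per_condition: int = 6,
    log2_effect: float = 0.5,
    noise_sd: float = 0.05,
    probe_range: tuple[int, int] = (5, 30),
    shared_fraction: float = 0.5,
    discordant_prob: float = 0.1,
    background_segments: int = 5,
    low_probe_segments: int = 2,
    gain_threshold: float = 0.25,
    core_cytobands: Sequence[str] = (),
    sample_ids: Sequence[str] | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[dict[tuple[str, str], list[CNASegment]], dict]:
    """Paired pre/post segment profiles with planted cytoband alterations.

    Per sample and condition, each planted cytoband receives one covering
    segment with mean log2 ~ Normal(+/-log2_effect, noise_sd) and a probe
    count drawn from ``probe_range`` (always passing the probe filter);
    background segments are neutral (Normal(0, noise_sd)) and a couple of
    large-amplitude segments with <= 3 probes exercise the probe filter.
    A ``shared_fraction`` of the planted bands is planted in every sample
    of a condition to exercise recurrence logic (occasionally with a
    flipped direction in one sample, exercising discordance flagging), and
    ``core_cytobands`` are gained in every sample of both conditions.

    Requires ``log2_effect > gain_threshold + 3 * noise_sd`` so planted
    calls survive thresholding by construction.  Returns the per
    (sample, condition) segment lists plus a truth record.
    """
    if not log2_effect > gain_threshold + 3 * noise_sd:
        raise ValueError(
            f"log2_effect {log2_effect} must exceed gain_threshold + 3*noise_sd "
            f"= {gain_threshold + 3 * noise_sd}"
        )
    if not 0 <= shared_fraction <= 1:
        raise ValueError(f"shared_fraction must be in [0, 1], got {shared_fraction}")
    unknown_core = set(core_cytobands) - set(genome.band_names)
    if unknown_core:
        raise ValueError(f"unknown core cytoband(s): {sorted(unknown_core)}")
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"case{i + 1}" for i in range(n_samples)]
    elif len(sample_ids) != n_samples:
        raise ValueError("sample_ids length must equal n_samples")

    candidate_bands = [b for b in genome.band_names if b not in core_cytobands]
    n_shared = round(planted_per_condition * shared_fraction)
    band_interval = {
        name: (chrom, start, end)
        for chrom, start, end, name in genome.cytobands.bands
    }

    # plan planted (sample, condition, band, direction) tuples
    planted: dict[tuple[str, str], list[tuple[str, str]]] = {
        (sid, cond): [] for sid in sample_ids for cond in ("pre", "post")
    }
    truth_entries: list[dict] = []

    for cond in ("pre", "post"):
        shared = list(
            rng.choice(candidate_bands, size=n_shared, replace=False)
        )
        for band in shared:
            direction = "gain" if rng.random() < 0.5 else "loss"
            flip_sample = None
            if rng.random() < discordant_prob and n_samples > 1:
                flip_sample = sample_ids[int(rng.integers(0, n_samples))]
            for sid in sample_ids:
                d = direction
                if sid == flip_sample:
                    d = "loss" if direction == "gain" else "gain"
                planted[(sid, cond)].append((band, d))
        remaining = [b for b in candidate_bands if b not in shared]
        n_private = planted_per_condition - n_shared
        for sid in sample_ids:
            private = list(
                rng.choice(remaining, size=min(n_private, len(remaining)),
                           replace=False)
            )
            for band in private:
                direction = "gain" if rng.random() < 0.5 else "loss"
                planted[(sid, cond)].append((band, direction))
        for sid in sample_ids:
            for band in core_cytobands:
                planted[(sid, cond)].append((band, "gain"))

    profiles: dict[tuple[str, str], list[CNASegment]] = {}
    all_bands = list(genome.band_names)
    for (sid, cond), entries in planted.items():
        rows: list[CNASegment] = []
        for band, direction in entries:
            chrom, bstart, bend = band_interval[band]
            blen = bend - bstart
            start = bstart + int(rng.integers(0, blen // 4 + 1))
            end = bend - int(rng.integers(0, blen // 4 + 1))
            sign = 1.0 if direction == "gain" else -1.0
            rows.append(
                CNASegment(
                    sample_id=sid,
                    condition=cond,
                    chrom=chrom,
                    start=start,
                    end=end,
                    mean_log2=float(rng.normal(sign * log2_effect, noise_sd)),
                    probe_count=int(rng.integers(probe_range[0], probe_range[1] + 1)),
                )
            )
            truth_entries.append(
                {"sample_id": sid, "condition": cond, "cytoband": band,
                 "direction": direction}
            )
        for _ in range(background_segments):
            band = all_bands[int(rng.integers(0, len(all_bands)))]
            chrom, bstart, bend = band_interval[band]
            blen = bend - bstart
            start = bstart + int(rng.integers(0, blen // 2 + 1))
            end = min(bend, start + int(rng.integers(blen // 10 + 1, blen // 2 + 2)))
            rows.append(
                CNASegment(
                    sample_id=sid, condition=cond, chrom=chrom,
                    start=start, end=end,
                    mean_log2=float(rng.normal(0.0, noise_sd)),
                    probe_count=int(rng.integers(probe_range[0], probe_range[1] + 1)),
                )
            )
        for _ in range(low_probe_segments):
            band = all_bands[int(rng.integers(0, len(all_bands)))]
            chrom, bstart, bend = band_interval[band]
            blen = bend - bstart
            start = bstart + int(rng.integers(0, blen // 2 + 1))
            end = min(bend, start + int(rng.integers(blen // 10 + 1, blen // 2 + 2)))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            rows.append(
                CNASegment(
                    sample_id=sid, condition=cond, chrom=chrom,
                    start=start, end=end,
                    mean_log2=float(rng.normal(sign * log2_effect, noise_sd)),
                    probe_count=int(rng.integers(1, 4)),  # fails the > 3 filter
                )
            )
        rows.sort(key=lambda s: (s.chrom, s.start, s.end))
        profiles[(sid, cond)] = rows

    truth = {
        "rng": RNG_NAME,
        "planted_cna": sorted(
            truth_entries,
            key=lambda e: (e["sample_id"], e["condition"], e["cytoband"],
                           e["direction"]),
        ),
        "log2_effect": log2_effect,
        "noise_sd": noise_sd,
        "sample_ids": list(sample_ids),
    }
    return profiles, truth


# ---------------------------------------------------------------------------
# interaction network


@dataclass(frozen=True)
class ChannelProfile:
    """How per-channel scores are drawn for each generated edge.

    With probability ``pass_rate`` an edge is made to pass the confidence
    filter: between ``n_strong[0]`` and ``n_strong[1]`` of the selected
    channels receive a score >= ``min_score``; all other selected channels
    stay below it.  Unselected evidence channels receive noise scores that
    can never qualify an edge.
    """

    pass_rate: float = 0.9
    min_score: int = DEFAULT_MIN_SCORE
    n_strong: tuple[int, int] = (1, 3)
    selected: frozenset = DEFAULT_CHANNELS


def generate_ppi(
    genome: Genome | Sequence[str],
    n_edges: int = 1200,
    n_planted_regulators: int = 5,
    attachment_bias: float = 25.0,
    channel_profile: ChannelProfile | None = None,
    regulators: Sequence[str] | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list[tuple[str, str, dict[str, int]]], dict]:
    """Grow a regulator-dominated interaction network with channel scores.

    Growth is preferential attachment (weight = degree + 1) with the weight
    of each planted regulator multiplied by ``attachment_bias``; the
    regulators start as a clique and absorb most attachments, producing a
    heavy-tailed degree distribution whose top degrees are the planted
    nodes.  Each edge receives per-channel integer scores drawn from
    ``channel_profile``.  Returns (edges, truth) where each edge is
    (node_a, node_b, channel_scores); deterministic per seed.
    """
    nodes = list(genome.coding_symbols) if isinstance(genome, Genome) else list(genome)
    if n_planted_regulators > len(nodes):
        raise ValueError(
            f"{n_planted_regulators} planted regulators requested but only "
            f"{len(nodes)} nodes available"
        )
    if n_edges < len(nodes) - 1:
        raise ValueError(
            f"n_edges={n_edges} cannot connect {len(nodes)} nodes"
        )
    if attachment_bias < 0:
        raise ValueError(f"attachment_bias must be >= 0, got {attachment_bias}")
    profile = channel_profile or ChannelProfile()
    rng = np.random.default_rng(seed)

    if regulators is None:
        regulators = [str(s) for s in rng.choice(nodes, size=n_planted_regulators,
                                                 replace=False)]
    else:
        regulators = list(regulators)
        missing = set(regulators) - set(nodes)
        if missing:
            raise ValueError(f"regulators absent from node list: {sorted(missing)}")
    reg_set = set(regulators)

    edges: list[tuple[str, str]] = []
    edge_set: set[frozenset[str]] = set()
    degree: dict[str, int] = dict.fromkeys(nodes, 0)

    def add_edge(u: str, v: str) -> bool:
        key = frozenset((u, v))
        if u == v or key in edge_set:
            return False
        edges.append((u, v))
        edge_set.add(key)
        degree[u] += 1
        degree[v] += 1
        return True

    for i, u in enumerate(regulators):
        for v in regulators[i + 1:]:
            add_edge(u, v)

    background = [v for v in nodes if v not in reg_set]
    order = list(rng.permutation(background))
    budget = n_edges - len(edges)
    m_base, extra = divmod(max(budget, 0), max(len(order), 1))

    existing = list(regulators)
    for idx, new in enumerate(order):
        m = m_base + (1 if idx < extra else 0)
        m = min(m, len(existing))
        targets: list[str] = []
        candidates = list(existing)
        for _ in range(m):
            weights = np.array(
                [
                    (degree[v] + 1.0)
                    * (attachment_bias if v in reg_set else 1.0)
                    for v in candidates
                ]
            )
            pick = int(rng.choice(len(candidates), p=weights / weights.sum()))
            targets.append(candidates.pop(pick))
        for t in targets:
            add_edge(new, t)
        existing.append(new)

    # top up to the exact edge budget (early nodes saw fewer candidates)
    attempts = 0
    while len(edges) < n_edges and attempts < 50 * n_edges:
        attempts += 1
        weights = np.array(
            [
                (degree[v] + 1.0) * (attachment_bias if v in reg_set else 1.0)
                for v in nodes
            ]
        )
        p = weights / weights.sum()
        u = nodes[int(rng.choice(len(nodes), p=p))]
        v = nodes[int(rng.choice(len(nodes), p=p))]
        add_edge(u, v)

    selected = sorted(profile.selected)
    unselected = [c for c in ALL_CHANNELS if c not in profile.selected]
    scored: list[tuple[str, str, dict[str, int]]] = []
    for u, v in edges:
        scores = dict.fromkeys(ALL_CHANNELS, 0)
        if rng.random() < profile.pass_rate:
            k = int(rng.integers(profile.n_strong[0], profile.n_strong[1] + 1))
            strong = set(rng.choice(selected, size=min(k, len(selected)),
                                    replace=False))
        else:
            strong = set()
        for c in selected:
            if c in strong:
                scores[c] = int(rng.integers(profile.min_score, 1001))
            else:
                scores[c] = int(rng.integers(0, profile.min_score))
        for c in unselected:
            # sparse evidence noise; never qualifies an edge
            scores[c] = int(rng.integers(0, 1001)) if rng.random() < 0.2 else 0
        scored.append((u, v, scores))

    truth = {
        "rng": RNG_NAME,
        "planted_regulators": sorted(regulators),
        "attachment_bias": attachment_bias,
        "n_edges": len(scored),
    }
    return scored, truth


def write_edge_file(
    edges: Sequence[tuple[str, str, dict[str, int]]], path: str | Path
) -> None:
    """Write edges in the multi-channel protein-links-full layout."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein1 protein2 " + " ".join(ALL_CHANNELS) + " combined_score\n")
        for u, v, scores in edges:
            probs_absent = 1.0
            for c in ALL_CHANNELS:
                probs_absent *= 1.0 - scores[c] / 1000.0
            combined = min(999, int(round(1000 * (1.0 - probs_absent))))
            fh.write(
                f"{u} {v} "
                + " ".join(str(scores[c]) for c in ALL_CHANNELS)
                + f" {combined}\n"
            )


# ---------------------------------------------------------------------------
# ontology + annotations


def generate_annotations(
    genes: Sequence[str],
    planted_gene_set: Sequence[str],
    n_terms: int = 50,
    dag_depth: int = 4,
    planted_term_depth: int = 3,
    background_rate: float = 0.08,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[dict[str, list[str]], dict[str, str], dict[str, set[str]], dict]:
    """A random tree-shaped term DAG with one term enriched by construction.

    The planted term sits at ``planted_term_depth`` below the root and is
    directly annotated to every gene of ``planted_gene_set``; every
    non-root term (the planted one included) additionally annotates each
    gene with probability ``background_rate``.  Two shallow terms carry
    deliberately generic names so blocklist filtering can be exercised.

    Returns (parents, names, direct annotations, truth); deterministic per
    seed.
    """
    if not planted_gene_set:
        raise ValueError("planted_gene_set must be nonempty")
    if not 0 < background_rate < 1:
        raise ValueError(f"background_rate must be in (0, 1), got {background_rate}")
    if planted_term_depth > dag_depth:
        raise ValueError(
            f"planted_term_depth {planted_term_depth} exceeds dag_depth {dag_depth}"
        )
    missing = set(planted_gene_set) - set(genes)
    if missing:
        raise ValueError(f"planted genes absent from gene list: {sorted(missing)}")
    if n_terms < planted_term_depth + 3:
        raise ValueError("n_terms too small for the requested DAG shape")
    rng = np.random.default_rng(seed)

    terms = [f"T{i:03d}" for i in range(n_terms)]
    root = terms[0]
    parents: dict[str, list[str]] = {t: [] for t in terms}
    depth = {root: 0}
    # a guaranteed chain down to the planted depth
    for i in range(1, planted_term_depth + 1):
        parents[terms[i]] = [terms[i - 1]]
        depth[terms[i]] = i
    planted_term = terms[planted_term_depth]
    # the planted term stays a leaf: descendants would propagate their own
    # annotations into it and dilute the planted signal
    for t in terms[planted_term_depth + 1:]:
        eligible = [u for u in depth if depth[u] < dag_depth and u != planted_term]
        parent = eligible[int(rng.integers(0, len(eligible)))]
        parents[t] = [parent]
        depth[t] = depth[parent] + 1

    names = {t: f"synthetic process {i}" for i, t in enumerate(terms)}
    names[root] = "biological_process"
    names[planted_term] = "synthetic planted process"
    generic = [t for t in terms if depth[t] == 1 and t != planted_term][:2]
    generic_names = ["regulation of biological processes", "biochemical processes"]
    for t, n in zip(generic, generic_names):
        names[t] = n

    annotations: dict[str, set[str]] = {g: set() for g in genes}
    for g in planted_gene_set:
        annotations[g].add(planted_term)
    for t in terms[1:]:  # root annotates everything via propagation anyway
        for g in genes:
            if rng.random() < background_rate:
                annotations[g].add(t)
    annotations = {g: ts for g, ts in annotations.items() if ts}

    truth = {
        "rng": RNG_NAME,
        "planted_term": planted_term,
        "planted_genes": sorted(planted_gene_set),
        "background_rate": background_rate,
        "generic_terms": {t: names[t] for t in generic},
    }
    return parents, names, annotations, truth


def write_dag(parents: Mapping[str, Sequence[str]], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for child in sorted(parents):
            for parent in sorted(parents[child]):
                fh.write(f"{child}\t{parent}\n")


def write_term_names(names: Mapping[str, str], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for term in sorted(names):
            fh.write(f"{term}\t{names[term]}\n")


def write_annotations(annotations: Mapping[str, set[str]], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# end-to-end fixture


@dataclass(frozen=True)
class FixtureProfile:
    """All generator parameters for one end-to-end fixture size."""

    n_chrom: int = 2
    cytobands_per_chrom: int = 8
    genes_per_cytoband: int = 15
    noncoding_fraction: float = 0.10
    n_samples: int = 3
    planted_per_condition: int = 6
    shared_fraction: float = 0.5
    log2_effect: float = 0.5
    noise_sd: float = 0.05
    probe_range: tuple[int, int] = (5, 30)
    n_edges: int = 1200
    n_planted_regulators: int = 5
    attachment_bias: float = 25.0
    n_terms: int = 50
    dag_depth: int = 4
    planted_term_depth: int = 3
    background_rate: float = 0.08
    n_core_cytobands: int = 2
    planted_set_size: int = 12


PROFILES: dict[str, FixtureProfile] = {
    "small": FixtureProfile(),
    "default": FixtureProfile(
        n_chrom=3,
        cytobands_per_chrom=10,
        genes_per_cytoband=20,
        n_edges=3000,
        n_terms=80,
        planted_per_condition=8,
    ),
}


def make_end_to_end_fixture(
    out_dir: str | Path,
    profile: str | FixtureProfile = "small",
    seed: int = 42,
) -> dict:
    """Emit every pipeline input plus a truth JSON into a directory.

    The generated inputs are internally coordinated: a few "core"
    cytobands are gained in every sample and condition, the planted network
    regulators are protein-coding genes of those core bands (so every
    induced network contains them and is non-degenerate), and the planted
    enriched gene set extends the regulators with further core-band genes.
    Layout::

        cytobands.tsv  genes.tsv  edges.txt
        segments/<sample>_<condition>.tsv
        ontology_edges.tsv  ontology_names.tsv  annotations.tsv
        truth.json

    Returns the truth record; byte-identical output per (profile, seed).
    """
    if isinstance(profile, str):
        try:
            prof = PROFILES[profile]
        except KeyError:
            raise ValueError(
                f"unknown profile {profile!r}; available: {sorted(PROFILES)}"
            ) from None
        profile_name = profile
    else:
        prof, profile_name = profile, "custom"

    ss = np.random.SeedSequence(seed)
    s_genome, s_cna, s_ppi, s_ann, s_pick = ss.spawn(5)

    genome = generate_genome(
        n_chrom=prof.n_chrom,
        cytobands_per_chrom=prof.cytobands_per_chrom,
        genes_per_cytoband=prof.genes_per_cytoband,
        noncoding_fraction=prof.noncoding_fraction,
        seed=s_genome,
    )

    rng = np.random.default_rng(s_pick)
    core = sorted(
        str(b)
        for b in rng.choice(
            genome.band_names, size=prof.n_core_cytobands, replace=False
        )
    )
    core_coding = [
        g.symbol
        for g in genome.genes
        if g.biotype == "protein_coding"
        and genome.cytobands.overlapping(g.chrom, g.start, g.end)
        and set(genome.cytobands.overlapping(g.chrom, g.start, g.end)) & set(core)
    ]
    if len(core_coding) < prof.planted_set_size:
        raise ValueError(
            "core cytobands carry too few protein-coding genes for the "
            "requested planted set"
        )
    regulators = sorted(
        str(g)
        for g in rng.choice(
            core_coding, size=prof.n_planted_regulators, replace=False
        )
    )
    rest = [g for g in core_coding if g not in regulators]
    extra = sorted(
        str(g)
        for g in rng.choice(
            rest, size=prof.planted_set_size - len(regulators), replace=False
        )
    )
    planted_gene_set = sorted(regulators + extra)

    profiles_cna, cna_truth = generate_cna_profiles(
        genome,
        n_samples=prof.n_samples,
        planted_per_condition=prof.planted_per_condition,
        log2_effect=prof.log2_effect,
        noise_sd=prof.noise_sd,
        probe_range=prof.probe_range,
        shared_fraction=prof.shared_fraction,
        core_cytobands=core,
        seed=s_cna,
    )
    edges, ppi_truth = generate_ppi(
        genome,
        n_edges=prof.n_edges,
        n_planted_regulators=prof.n_planted_regulators,
        attachment_bias=prof.attachment_bias,
        regulators=regulators,
        seed=s_ppi,
    )
    parents, names, annotations, ann_truth = generate_annotations(
        genome.coding_symbols,
        planted_gene_set=planted_gene_set,
        n_terms=prof.n_terms,
        dag_depth=prof.dag_depth,
        planted_term_depth=prof.planted_term_depth,
        background_rate=prof.background_rate,
        seed=s_ann,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "segments").mkdir(exist_ok=True)
    write_cytobands(genome.cytobands, out / "cytobands.tsv")
    write_gene_annotation(genome.genes, out / "genes.tsv")
    for (sid, cond), rows in sorted(profiles_cna.items()):
        write_segments(rows, out / "segments" / f"{sid}_{cond}.tsv")
    write_edge_file(edges, out / "edges.txt")
    write_dag(parents, out / "ontology_edges.tsv")
    write_term_names(names, out / "ontology_names.tsv")
    write_annotations(annotations, out / "annotations.tsv")

    truth = {
        "seed": seed,
        "rng": RNG_NAME,
        "profile": profile_name,
        "profile_params": asdict(prof),
        "samples": cna_truth["sample_ids"],
        "core_cytobands": core,
        "planted_cna": cna_truth["planted_cna"],
        "planted_regulators": ppi_truth["planted_regulators"],
        "planted_term": ann_truth["planted_term"],
        "planted_gene_set": planted_gene_set,
        "generic_terms": ann_truth["generic_terms"],
    }
    (out / "truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n"
    )
    return truth
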