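"""Gene Ontology over-representation with true-path propagation and BH FDR.

Annotations are propagated up the term DAG (a gene annotated to a term is
annotated to every ancestor — the true-path rule), each term with at least
one annotated universe gene is tested with the one-sided hypergeometric
upper tail (identical to a one-sided Fisher exact test on the 2x2 table),
and p-values are adjusted with Benjamini-Hochberg over all tested terms.
A blocklist of generic, uninformative terms ("regulation of biological
processes" and the like) can be removed from the result list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OntologyDAG",
    "AnnotationSet",
    "EnrichmentResult",
    "CycleError",
    "load_dag",
    "load_dag_obo",
    "load_annotations",
    "propagate_annotations",
    "enrich",
    "filter_generic_terms",
    "hypergeometric_upper_tail",
    "write_enrichment",
]


class CycleError(ValueError):
    """The term graph contains a cycle (it must be a DAG)."""


@dataclass(frozen=True)
class OntologyDAG:
    """Term DAG given as child -> parents edges, with optional term names."""

    parents: Mapping[str, frozenset[str]]
    names: Mapping[str, str]

    def __post_init__(self) -> None:
        cycle = _find_cycle(self.parents)
        if cycle:
            raise CycleError(f"term graph contains a cycle: {' -> '.join(cycle)}")

    @property
    def terms(self) -> frozenset[str]:
        all_terms = set(self.parents)
        for ps in self.parents.values():
            all_terms |= ps
        return frozenset(all_terms)

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if not self.parents.get(t))

    def ancestors(self, term: str) -> frozenset[str]:
        """All proper ancestors of a term (transitive closure of parents)."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        return frozenset(out)

    def name(self, term: str) -> str:
        return self.names.get(term, term)


def _find_cycle(parents: Mapping[str, frozenset[str]]) -> list[str] | None:
    """Return one cycle as a node list, or None if the graph is acyclic."""
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[str, int] = {}
    stack_path: list[str] = []

    def visit(node: str) -> list[str] | None:
        color[node] = GRAY
        stack_path.append(node)
        for parent in parents.get(node, ()):
            state = color.get(parent, WHITE)
            if state == GRAY:
                i = stack_path.index(parent)
                return stack_path[i:] + [parent]
            if state == WHITE:
                found = visit(parent)
                if found:
                    return found
        stack_path.pop()
        color[node] = BLACK
        return None

    for node in list(parents):
        if color.get(node, WHITE) == WHITE:
            found = visit(node)
            if found:
                return found
    return None


def load_dag(
    edges_path: str | Path, names_path: str | Path | None = None
) -> OntologyDAG:
    """Load a DAG from a child/parent TSV, plus an optional term-name TSV."""
    parents: dict[str, set[str]] = {}
    with Path(edges_path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{edges_path}: line {lineno}: expected 2 fields, "
                    f"got {len(fields)}"
                )
            child, parent = fields[0], fields[1]
            parents.setdefault(child, set()).add(parent)
            parents.setdefault(parent, set())
    names: dict[str, str] = {}
    if names_path is not None:
        with Path(names_path).open() as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                term, _, name = line.partition("\t")
                names[term] = name
    return OntologyDAG(
        parents={t: frozenset(ps) for t, ps in parents.items()}, names=names
    )


def load_dag_obo(path: str | Path) -> OntologyDAG:
    """Minimal OBO reader: id, name and is_a stanza lines only."""
    parents: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    term_id: str | None = None
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.strip()
            if line == "[Term]":
                term_id = None
            elif line.startswith("id: "):
                term_id = line[4:].strip()
                parents.setdefault(term_id, set())
            elif line.startswith("name: ") and term_id:
                names[term_id] = line[6:].strip()
            elif line.startswith("is_a: ") and term_id:
                parent = line[6:].split("!")[0].strip()
                parents[term_id].add(parent)
                parents.setdefault(parent, set())
    return OntologyDAG(
        parents={t: frozenset(ps) for t, ps in parents.items()}, names=names
    )


def load_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """Load a two-column gene/term TSV into a gene -> term-set mapping."""
    raw: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 fields, got {len(fields)}"
                )
            raw.setdefault(fields[0], set()).add(fields[1])
    return {g: frozenset(ts) for g, ts in raw.items()}


@dataclass(frozen=True)
class AnnotationSet:
    """Gene -> term-set mapping; ``propagated`` marks true-path closure."""

    annotations: Mapping[str, frozenset[str]]
    propagated: bool = False

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.annotations)


def propagate_annotations(
    annotations: Mapping[str, frozenset[str]] | AnnotationSet,
    dag: OntologyDAG,
) -> AnnotationSet:
    """Close each gene's term set under the ancestor relation (true-path rule).

    Idempotent: propagating an already propagated set leaves it unchanged.
    Terms missing from the DAG raise a KeyError naming the term.
    """
    if isinstance(annotations, AnnotationSet):
        annotations = annotations.annotations
    closed: dict[str, frozenset[str]] = {}
    for gene, terms in annotations.items():
        full: set[str] = set(terms)
        for term in terms:
            full |= dag.ancestors(term)
        closed[gene] = frozenset(full)
    return AnnotationSet(annotations=closed, propagated=True)


def hypergeometric_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); the enrichment p-value."""
    return float(min(hypergeom.sf(k - 1, N, K, n), 1.0))


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested term: 2x2 counts, exact p and BH-adjusted q."""

    term: str
    name: str
    k: int  # study genes annotated to the term
    n: int  # study size
    K: int  # universe genes annotated to the term
    N: int  # universe size
    p: float
    q: float
    significant: bool


def enrich(
    study: Iterable[str],
    universe: Iterable[str],
    annotations: AnnotationSet,
    dag: OntologyDAG,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided over-representation test for every term annotated in the universe.

    For a term with K annotated universe genes, n study genes of which k are
    annotated, the p-value is the hypergeometric upper tail
    P(X >= k | N, K, n) — exactly the one-sided Fisher exact test on the
    2x2 table.  Terms with K = 0 are never tested; the BH family size is the
    number of tested terms.  Results are sorted by (q, p, term) and flagged
    significant at q < alpha.
    """
    study_set = frozenset(study)
    universe_set = frozenset(universe)
    stray = study_set - universe_set
    if stray:
        raise ValueError(
            f"study genes absent from the universe: {sorted(stray)}"
        )
    if not annotations.propagated:
        raise ValueError(
            "annotations must be propagated (true-path rule) before testing"
        )
    big_n = len(universe_set)
    n = len(study_set)

    term_universe: dict[str, set[str]] = {}
    for gene in universe_set:
        for term in annotations.annotations.get(gene, ()):
            term_universe.setdefault(term, set()).add(gene)

    terms = sorted(term_universe)
    rows = []
    for term in terms:
        annotated = term_universe[term]
        big_k = len(annotated)
        k = len(annotated & study_set)
        p = hypergeometric_upper_tail(k, big_n, big_k, n)
        rows.append((term, k, big_k, p))

    if not rows:
        return []
    pvals = [r[3] for r in rows]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    results = [
        EnrichmentResult(
            term=term,
            name=dag.name(term),
            k=k,
            n=n,
            K=big_k,
            N=big_n,
            p=p,
            q=float(q),
            significant=bool(q < alpha),
        )
        for (term, k, big_k, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.term))
    return results


def filter_generic_terms(
    results: Sequence[EnrichmentResult], blocklist: Iterable[str]
) -> tuple[list[EnrichmentResult], int]:
    """Drop blocklisted terms (by ID or exact name), preserving order.

    Returns the filtered list and the number of removed entries.
    """
    block = frozenset(blocklist)
    kept = [r for r in results if r.term not in block and r.name not in block]
    return kept, len(results) - len(kept)


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("term_id\tname\tk\tn\tK\tN\tp\tq\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.name}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                f"{r.p:.6g}\t{r.q:.6g}\t{int(r.significant)}\n"
            )
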