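"""GO DAG handling and term enrichment (classic Fisher and elim).

Annotations obey the true-path rule: a gene directly annotated to a term
is implicitly annotated to every ancestor reached through ``is_a`` (and,
by default, ``part_of``) edges.  Enrichment of a study set against a
universe is the one-sided hypergeometric test per term ("classic"); the
"elim" variant walks the DAG bottom-up and removes the genes of already
significant children from their ancestors before testing those, which
decorrelates nested terms.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom

_EDGE_KEYS_DEFAULT = ("is_a", "part_of")


@dataclass
class GODag:
    """Ontology terms plus child -> parent edges (acyclic)."""

    terms: dict[str, dict]  # id -> {"name": ..., "namespace": ...}
    parents: dict[str, set[str]]

    def __post_init__(self) -> None:
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    @property
    def roots(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for t, meta in self.terms.items():
            if not self.parents.get(t):
                out.setdefault(meta.get("namespace", "biological_process"), set()).add(t)
        return out

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable upward from ``term`` (excluding itself)."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        acc: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            p = stack.pop()
            if p not in acc:
                acc.add(p)
                stack.extend(self.parents.get(p, ()))
        result = frozenset(acc)
        self._ancestor_cache[term] = result
        return result

    def topological_bottom_up(self) -> list[str]:
        """Terms ordered so every child precedes all of its ancestors."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        return list(nx.topological_sort(g))


@dataclass
class AnnotationMap:
    """Direct gene -> terms plus the propagated term -> genes closure."""

    direct: dict[str, set[str]]
    term_genes: dict[str, set[str]]

    @property
    def annotated_genes(self) -> set[str]:
        return set(self.direct)


def parse_obo(source: str | Path | io.TextIOBase, use_part_of: bool = True) -> GODag:
    """Read an OBO 1.2 ontology into a :class:`GODag`.

    ``source`` may be a path or OBO text.  Obsolete terms are dropped;
    ``is_a`` edges are always followed, ``part_of`` optionally (default on),
    other relationship types are ignored.  Cycles and dangling parent ids
    are rejected.
    """
    if isinstance(source, Path):
        handle: io.TextIOBase = io.StringIO(source.read_text())
    elif isinstance(source, str):
        if "\n" in source:  # OBO text, not a path
            handle = io.StringIO(source)
        else:
            handle = io.StringIO(Path(source).read_text())
    else:
        handle = source
    graph = obonet.read_obo(handle, ignore_obsolete=True)

    wanted = set(_EDGE_KEYS_DEFAULT if use_part_of else ("is_a",))
    terms: dict[str, dict] = {}
    parents: dict[str, set[str]] = {}
    for node, data in graph.nodes(data=True):
        if "name" not in data:
            raise ValueError(f"term {node} referenced as parent but never defined")
        terms[node] = {
            "name": data.get("name", node),
            "namespace": data.get("namespace", "biological_process"),
        }
        parents[node] = set()
    for child, parent, key in graph.edges(keys=True):
        if key in wanted:
            if parent not in terms:
                raise ValueError(f"edge {child} -> {parent} targets unknown term")
            parents[child].add(parent)

    check = nx.DiGraph()
    check.add_nodes_from(terms)
    check.add_edges_from((c, p) for c, ps in parents.items() for p in ps)
    if not nx.is_directed_acyclic_graph(check):
        raise ValueError("ontology contains a cycle")
    return GODag(terms, parents)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a gene/term TSV (two first columns used; header optional)."""
    df = pd.read_csv(path, sep="\t", comment="!", header=None, dtype=str)
    if str(df.iloc[0, 0]).lower() in {"gene", "gene_id"}:
        df = df.iloc[1:]
    direct: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        direct.setdefault(str(gene), set()).add(str(term))
    return direct


def read_gaf(path: str | Path) -> dict[str, set[str]]:
    """Read a GAF 2.x file using the gene symbol (col 2) and term (col 5)."""
    direct: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 5:
            continue
        direct.setdefault(cols[2], set()).add(cols[4])
    return direct


def propagate(dag: GODag, direct: Mapping[str, Iterable[str]]) -> AnnotationMap:
    """Close direct annotations over the DAG (true-path rule)."""
    unknown = sorted(
        {t for ts in direct.values() for t in ts if t not in dag.terms}
    )
    if unknown:
        raise ValueError(f"annotations reference unknown terms: {unknown[:10]}")
    direct_sets = {g: set(ts) for g, ts in direct.items()}
    term_genes: dict[str, set[str]] = {}
    for gene, ts in direct_sets.items():
        closed: set[str] = set()
        for t in ts:
            closed.add(t)
            closed |= dag.ancestors(t)
        for t in closed:
            term_genes.setdefault(t, set()).add(gene)
    return AnnotationMap(direct_sets, term_genes)


def feasible_universe(genes: Iterable[str], ann: AnnotationMap) -> set[str]:
    """Genes usable for enrichment: those carrying >= 1 annotation."""
    return set(genes) & ann.annotated_genes


def classic_fisher(
    study: set[str],
    universe: set[str],
    ann: AnnotationMap,
    dag: GODag,
    min_node_size: int = 10,
    namespace: str | None = "biological_process",
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    For each term with at least ``min_node_size`` annotated genes in the
    universe the p-value is ``P(X >= significant)`` when drawing
    ``|study|`` genes from the universe without replacement.
    """
    study = set(study)
    universe = set(universe)
    if not study:
        raise ValueError("empty study set")
    if not study <= universe:
        raise ValueError("study set must be contained in the universe")
    n_univ, n_study = len(universe), len(study)
    rows = []
    for term, genes in sorted(ann.term_genes.items()):
        if namespace and dag.terms.get(term, {}).get("namespace") != namespace:
            continue
        annotated = len(genes & universe)
        if annotated < max(min_node_size, 1):
            continue
        significant = len(genes & study)
        p = float(hypergeom.sf(significant - 1, n_univ, annotated, n_study))
        meta = dag.terms.get(term, {})
        rows.append(
            (
                term,
                meta.get("name", term),
                meta.get("namespace", "biological_process"),
                annotated,
                significant,
                annotated * n_study / n_univ,
                min(1.0, p),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["term", "name", "namespace", "annotated", "significant", "expected", "p_classic"],
    )


def elim_fisher(
    study: set[str],
    universe: set[str],
    ann: AnnotationMap,
    dag: GODag,
    cutoff: float = 0.01,
    min_node_size: int = 10,
    namespace: str | None = "biological_process",
) -> pd.DataFrame:
    """Classic p plus the elim p from bottom-up gene elimination.

    Terms are visited children-first; when a term's elim p falls below
    ``cutoff`` its (propagated) genes are removed from every ancestor's
    gene set before those ancestors are tested.  A cutoff >= 1 disables
    elimination, reducing elim to classic.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    classic = classic_fisher(study, universe, ann, dag, min_node_size, namespace)
    testable = set(classic["term"])
    study = set(study)
    universe = set(universe)
    n_univ, n_study = len(universe), len(study)

    removed: dict[str, set[str]] = {}
    p_elim: dict[str, float] = {}
    for term in dag.topological_bottom_up():
        if term not in testable:
            continue
        genes = (ann.term_genes[term] - removed.get(term, set())) & universe
        annotated = len(genes)
        significant = len(genes & study)
        p = float(hypergeom.sf(significant - 1, n_univ, annotated, n_study)) if annotated else 1.0
        p_elim[term] = min(1.0, p)
        if cutoff < 1 and p_elim[term] < cutoff:
            eliminated = ann.term_genes[term]
            for anc in dag.ancestors(term):
                removed.setdefault(anc, set()).update(eliminated)

    out = classic.copy()
    out["p_elim"] = [p_elim[t] for t in out["term"]]
    return out


def top_terms(result: pd.DataFrame, n: int = 6, algorithm: str = "classic") -> pd.DataFrame:
    """Best ``n`` terms sorted by p ascending; ties by annotated desc, id asc."""
    if n < 1:
        raise ValueError("n must be >= 1")
    col = {"classic": "p_classic", "elim": "p_elim"}[algorithm]
    if col not in result.columns:
        raise KeyError(f"result has no column {col}")
    ordered = result.sort_values(
        by=[col, "annotated", "term"], ascending=[True, False, True], kind="mergesort"
    )
    return ordered.head(n).reset_index(drop=True)
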