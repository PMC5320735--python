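"""Shared fixtures and independent oracles.

The closure oracle here is deliberately brute force (numpy boolean
matrix products over the raw parent lists) and never calls the graph
traversal code it is used to check.
"""

from __future__ import annotations

import random
import warnings

import numpy as np
import pytest

from txstore import FeatureStore, Organism, init_store, parse_obo
from txstore.fixtures import FixtureSpec, load_bundle, make_toy_project
from txstore.ontology import OntologyGraph, Term

CHAIN_OBO = """format-version: 1.2
ontology: chain

[Term]
id: T:0
name: root

[Term]
id: T:1
name: middle
is_a: T:0

[Term]
id: T:2
name: leaf
is_a: T:1
"""

DIAMOND_OBO = """format-version: 1.2
ontology: diamond

[Term]
id: D:A
name: apex

[Term]
id: D:B
name: left
is_a: D:A

[Term]
id: D:C
name: right
is_a: D:A

[Term]
id: D:D
name: bottom
is_a: D:B
is_a: D:C
"""


# ---------------------------------------------------------------------
# independent closure oracle


def random_dag_parents(seed: int, max_terms: int = 50,
                       max_edges: int = 120) -> dict[int, list[int]]:
    """Random rooted DAG as child -> parent lists; acyclic because
    parents always have smaller indices."""
    rng = random.Random(seed)
    n = rng.randint(2, max_terms)
    parents: dict[int, list[int]] = {0: []}
    n_edges = 0
    for i in range(1, n):
        k = min(i, rng.choice([1, 1, 1, 2, 2, 3]))
        ps = rng.sample(range(i), k)
        if n_edges + len(ps) > max_edges:
            ps = ps[: max(0, max_edges - n_edges)] or [i - 1]
        parents[i] = sorted(set(ps))
        n_edges += len(parents[i])
    return parents


def matrix_closure(parents: dict[int, list[int]]) -> np.ndarray:
    """closure[i, j] True iff j is a proper ancestor of i."""
    n = len(parents)
    adj = np.zeros((n, n), dtype=bool)
    for child, ps in parents.items():
        for p in ps:
            adj[child, p] = True
    closure = adj.copy()
    while True:
        nxt = closure | (closure @ adj)
        if (nxt == closure).all():
            return closure
        closure = nxt


def graph_from_parents(parents: dict[int, list[int]]) -> OntologyGraph:
    g = OntologyGraph(ontology_name="random")
    for i in range(len(parents)):
        g.add_term(Term(term_id=f"R:{i}"))
    for child, ps in parents.items():
        for p in ps:
            g.add_relation(f"R:{child}", "is_a", f"R:{p}")
    return g


# ---------------------------------------------------------------------
# fixtures


@pytest.fixture
def chain_graph():
    return parse_obo(CHAIN_OBO)


@pytest.fixture
def diamond_graph():
    return parse_obo(DIAMOND_OBO)


@pytest.fixture
def store(tmp_path):
    """Fresh store with an organism and the two toy vocabularies
    registered (so term validation is active)."""
    s = init_store(tmp_path / "test.db")
    s.add_organism(Organism(genus="Synthetica", species="exemplaris"))
    s.register_ontology(parse_obo(CHAIN_OBO))
    s.register_ontology(parse_obo(DIAMOND_OBO))
    s.conn.commit()
    return s


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default toy project generated once and loaded through every
    public loader; treated as read-only by tests."""
    root = tmp_path_factory.mktemp("bundle")
    spec = FixtureSpec(seed=1)
    manifest = make_toy_project(spec, root / "files")
    s = init_store(root / "project.db")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = load_bundle(s, root / "files")
    out["store"] = s
    out["dir"] = root / "files"
    out["spec"] = spec
    return out
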