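"""Reading, writing and filtering of food-web data.

Food webs arrive either as two-column edge lists (TSV, ``#`` comments
allowed) or as Ecopath-style diet matrices (CSV, prey in rows, predators in
columns, cells = diet proportions).  All topology is binarised on read: the
analysis operates on the binary, undirected interaction structure, while the
directed prey->predator orientation may be retained for trophic-level
computation.  Per-node attributes (biomass, ecotrophic efficiency, optional
precomputed trophic level) come from a separate CSV.

Conventions
-----------
* Node order is lexicographic by label; every matrix produced downstream
  indexes nodes in this fixed order.
* Self-loops (cannibalism) are dropped on read with a logged warning: they
  would distort node degree and hence the TI index.
* Binarisation keeps any strictly positive diet proportion by default; the
  threshold is configurable because Ecopath exports can carry tiny numerical
  residue.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: an unordered edge, stored as a lexicographically sorted label pair
Edge = tuple[str, str]

ATTRIBUTE_KEYS = ("biomass", "ee", "tl")


def _pair(u: str, v: str) -> Edge:
    """Canonical (sorted) form of an unordered node pair."""
    return (u, v) if u <= v else (v, u)


@dataclass
class FoodWeb:
    """A binary food web: undirected topology plus optional trophic direction.

    Parameters
    ----------
    web_id : str
        Label identifying the web (file stem, model id, ...).
    nodes : list of str
        All node labels, in the fixed (by default lexicographic) order used
        by every matrix computed from this web.
    undirected_edges : set of (str, str)
        Unordered binary interactions, stored as sorted label pairs; no
        self-loops.
    trophic_edges : set of (str, str), optional
        Directed prey -> predator pairs.  When present, the undirected edge
        set equals their symmetrisation.
    attributes : dict
        Per-node mapping with any of the keys ``biomass`` (mass per area,
        >= 0), ``ee`` (ecotrophic efficiency, dimensionless) and ``tl``
        (precomputed trophic level, >= 1).
    """

    web_id: str
    nodes: list[str]
    undirected_edges: set[Edge]
    trophic_edges: set[Edge] | None = None
    attributes: dict[str, dict[str, float]] = field(default_factory=dict)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        web_id: str,
        edges: Iterable[tuple[str, str]],
        *,
        directed: bool = False,
        nodes: Iterable[str] | None = None,
        attributes: Mapping[str, Mapping[str, float]] | None = None,
    ) -> "FoodWeb":
        """Build a web from raw edges, dropping self-loops and duplicates.

        With ``directed=True`` the edges are interpreted as prey->predator
        pairs and kept in :attr:`trophic_edges`; the undirected edge set is
        derived by symmetrisation.
        """
        node_set = set(nodes) if nodes is not None else set()
        undirected: set[Edge] = set()
        trophic: set[Edge] = set()
        dropped_loops = 0
        for u, v in edges:
            u, v = str(u), str(v)
            node_set.update((u, v))
            if u == v:
                dropped_loops += 1
                continue
            undirected.add(_pair(u, v))
            if directed:
                trophic.add((u, v))
        if dropped_loops:
            logger.warning("%s: dropped %d self-loop(s) on read", web_id, dropped_loops)
        web = cls(
            web_id=web_id,
            nodes=sorted(node_set),
            undirected_edges=undirected,
            trophic_edges=trophic if directed else None,
            attributes={k: dict(v) for k, v in attributes.items()} if attributes else {},
        )
        web.validate()
        return web

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError(f"{self.web_id}: duplicate node labels")
        for u, v in self.undirected_edges:
            if u == v:
                raise ValueError(f"{self.web_id}: self-loop {u!r} in undirected edges")
            if u not in node_set or v not in node_set:
                raise ValueError(f"{self.web_id}: edge endpoint missing from node list: {(u, v)}")
        if self.trophic_edges is not None:
            for u, v in self.trophic_edges:
                if u == v:
                    raise ValueError(f"{self.web_id}: self-loop {u!r} in trophic edges")
                if u not in node_set or v not in node_set:
                    raise ValueError(f"{self.web_id}: trophic endpoint missing: {(u, v)}")
            sym = {_pair(u, v) for u, v in self.trophic_edges}
            if sym != self.undirected_edges:
                raise ValueError(f"{self.web_id}: undirected edges are not the symmetrised trophic edges")
        unknown = set(self.attributes) - node_set
        if unknown:
            raise ValueError(f"{self.web_id}: attributes for unknown nodes: {sorted(unknown)}")

    # -- views ------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return len(self.undirected_edges)

    def to_undirected_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.undirected_edges)
        return g

    def to_trophic_graph(self) -> nx.DiGraph:
        if self.trophic_edges is None:
            raise ValueError(f"{self.web_id}: no directed trophic edges available")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.trophic_edges)
        return g

    def attribute_series(self, key: str) -> pd.Series:
        """One attribute as a Series over all nodes (NaN where absent)."""
        return pd.Series(
            {n: self.attributes.get(n, {}).get(key, float("nan")) for n in self.nodes},
            dtype=float,
        ).reindex(self.nodes)

    def with_attributes(self, attributes: Mapping[str, Mapping[str, float]]) -> "FoodWeb":
        """Return a copy with the given per-node attributes merged in."""
        merged = {k: dict(v) for k, v in self.attributes.items()}
        for node, attrs in attributes.items():
            merged.setdefault(node, {}).update(attrs)
        web = dataclasses.replace(self, attributes=merged)
        web.validate()
        return web


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, directed: bool = False) -> FoodWeb:
    """Read a food web from a 2-column TSV edge list.

    Lines starting with ``#`` and blank lines are skipped.  A third column
    (e.g. an interaction weight) is ignored: topology is binary.  Self-loops
    are dropped with a warning and duplicate edges merged.

    Parameters
    ----------
    path : path
        TSV file, one edge per line.
    directed : bool
        Interpret rows as prey->predator pairs and retain them as trophic
        edges; the undirected edge set is derived by symmetrisation.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed edge row at line {lineno}: {raw.rstrip()!r}")
            edges.append((fields[0], fields[1]))
    if not edges:
        raise ValueError(f"{path}: no edges found (empty edge list)")
    return FoodWeb.from_edges(path.stem, edges, directed=directed)


def write_edge_list(web: FoodWeb, path: str | Path, directed: bool = False, header: str | None = None) -> None:
    """Write a web as a TSV edge list (round-trips with :func:`read_edge_list`)."""
    path = Path(path)
    if directed and web.trophic_edges is None:
        raise ValueError(f"{web.web_id}: cannot write directed edges, none present")
    edges = sorted(web.trophic_edges) if directed else sorted(web.undirected_edges)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_diet_matrix(path: str | Path, presence_threshold: float = 0.0) -> FoodWeb:
    """Read an Ecopath-style diet matrix and binarise it.

    The CSV has prey in rows and predators in columns; the first column
    holds the prey labels and the first row the predator labels.  A trophic
    edge prey->predator is created wherever the diet proportion strictly
    exceeds ``presence_threshold`` (default 0: any flow is a link).
    Diagonal entries (cannibalism) are dropped with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0, comment="#")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric diet-matrix cell ({exc})") from exc
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative diet proportion(s)")
    prey_labels = [str(x) for x in df.index]
    pred_labels = [str(x) for x in df.columns]
    nodes = set(prey_labels) | set(pred_labels)
    edges: list[tuple[str, str]] = []
    cannibal = 0
    for prey, row in zip(prey_labels, df.to_numpy()):
        for pred, val in zip(pred_labels, row):
            if pd.isna(val) or val <= presence_threshold:
                continue
            if prey == pred:
                cannibal += 1
                continue
            edges.append((prey, pred))
    if cannibal:
        logger.warning("%s: dropped %d cannibalistic diagonal entrie(s)", path.stem, cannibal)
    web = FoodWeb.from_edges(path.stem, edges, directed=True, nodes=nodes)
    if web.trophic_edges is None:  # edge-less matrix still carries its node set
        web = dataclasses.replace(web, trophic_edges=set())
    return web


def read_node_attributes(path: str | Path, web: FoodWeb) -> FoodWeb:
    """Attach per-node attributes from a CSV to an existing web.

    Expects a header with a node-label column (named ``node`` or simply the
    first column) and any of ``biomass``/``ee``/``tl``.  Values are attached
    as-is; range checks (e.g. dropping unrealistic EE) happen downstream in
    the indicator computation, not on read.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    label_col = "node" if "node" in df.columns else df.columns[0]
    labels = df[label_col].astype(str)
    if labels.duplicated().any():
        dupes = sorted(labels[labels.duplicated()].unique())
        raise ValueError(f"{path}: duplicate node rows: {dupes}")
    unknown = sorted(set(labels) - set(web.nodes))
    if unknown:
        raise ValueError(f"{path}: attribute rows for nodes not in web {web.web_id!r}: {unknown}")
    attrs: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        node_attrs = {}
        for key in ATTRIBUTE_KEYS:
            if key in df.columns and pd.notna(row[key]):
                node_attrs[key] = float(row[key])
        if node_attrs:
            attrs[str(row[label_col])] = node_attrs
    return web.with_attributes(attrs)


def write_node_attributes(web: FoodWeb, path: str | Path, header: str | None = None) -> None:
    """Write the web's attributes as a node/biomass/ee/tl CSV."""
    rows = []
    for node in web.nodes:
        a = web.attributes.get(node, {})
        rows.append({"node": node, **{k: a.get(k, float("nan")) for k in ATTRIBUTE_KEYS}})
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# collection filtering
# ---------------------------------------------------------------------------

def filter_collection(
    webs: Sequence[FoodWeb],
    min_nodes: int = 50,
    exclude_ids: Iterable[str] = (),
) -> list[FoodWeb]:
    """Keep webs with strictly more than ``min_nodes`` nodes, minus exclusions.

    The strict inequality mirrors the "more than 50 nodes" selection rule
    used for EcoBase collections.  ``exclude_ids`` covers manual curation
    such as dropping repeated yearly snapshots of one ecosystem; the order
    of the input is preserved and the operation is idempotent.
    """
    excluded = {str(x) for x in exclude_ids}
    return [w for w in webs if w.n_nodes > min_nodes and w.web_id not in excluded]
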