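"""Trophic levels and bottom-up / top-down classification of asymmetry links.

Prey-averaged trophic level (the Ecopath convention): basal species (no
prey) sit at level 1; every consumer sits one level above the mean level of
its prey.  The definition is a linear system, solved exactly, so feeding
loops are fine as long as every consumer community ultimately draws on basal
production; a closed consumer cycle with no path to a basal species makes
the system singular and is reported as an error naming the cycle.

An asymmetry-graph link running from a lower trophic level to a higher one
is a bottom-up effect (food provision direction); the reverse is top-down
(consumer control).  Links between equal levels are classed "lateral" and
counted in neither.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from asymweb.asymmetry import AsymmetryGraph
from asymweb.io import FoodWeb

logger = logging.getLogger(__name__)

#: two trophic levels closer than this are treated as equal
TL_TOL = 1e-9


class TrophicCycleError(ValueError):
    """Raised when a closed trophic cycle makes prey-averaged levels undefined."""


@dataclass
class TrophicAssignment:
    """Per-node trophic levels with provenance.

    ``method`` is ``"prey-averaged"`` when levels were solved from directed
    trophic edges, ``"provided"`` when they came from a node-attribute file.
    """

    levels: dict[str, float]
    basal_nodes: list[str]
    method: str

    def level(self, node: str) -> float:
        return self.levels[node]


def trophic_levels(web: FoodWeb) -> TrophicAssignment:
    """Solve prey-averaged trophic levels, or adopt provided ``tl`` attributes.

    Directed trophic edges take precedence; if the web has none, precomputed
    ``tl`` node attributes are used (``method="provided"``).  With neither,
    an error is raised.
    """
    if web.trophic_edges is not None:
        return _solve_prey_averaged(web)
    tl = {n: web.attributes.get(n, {}).get("tl") for n in web.nodes}
    provided = {n: float(v) for n, v in tl.items() if v is not None}
    if not provided:
        raise ValueError(
            f"{web.web_id}: no trophic edges and no 'tl' attributes; trophic levels unavailable"
        )
    basal = sorted(n for n, v in provided.items() if abs(v - 1.0) <= TL_TOL)
    return TrophicAssignment(levels=provided, basal_nodes=basal, method="provided")


def _solve_prey_averaged(web: FoodWeb) -> TrophicAssignment:
    nodes = web.nodes
    index = {n: k for k, n in enumerate(nodes)}
    prey: dict[str, list[str]] = {n: [] for n in nodes}
    for u, v in web.trophic_edges:  # u = prey, v = predator
        prey[v].append(u)
    n = len(nodes)
    a = np.eye(n)
    b = np.ones(n)
    for node, plist in prey.items():
        if not plist:
            continue  # basal: TL = 1
        i = index[node]
        w = 1.0 / len(plist)
        for p in plist:
            a[i, index[p]] -= w
    try:
        levels = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        raise TrophicCycleError(_cycle_message(web)) from None
    if not np.all(np.isfinite(levels)) or np.max(np.abs(a @ levels - b)) > 1e-6:
        raise TrophicCycleError(_cycle_message(web))
    level_map = {node: float(levels[index[node]]) for node in nodes}
    basal = sorted(node for node, plist in prey.items() if not plist)
    return TrophicAssignment(levels=level_map, basal_nodes=basal, method="prey-averaged")


def _cycle_message(web: FoodWeb) -> str:
    g = web.to_trophic_graph()
    cycles = [sorted(c) for c in nx.strongly_connected_components(g) if len(c) > 1]
    return (
        f"{web.web_id}: prey-averaged trophic levels are undefined; "
        f"closed trophic cycle(s): {cycles or 'degenerate system'}"
    )


@dataclass
class LinkClassification:
    """Directional classes of asymmetry-graph links plus the three counts."""

    classes: list[tuple[str, str, str]]  # (source, target, class)
    bu_count: int
    td_count: int
    lateral_count: int


def classify_links(ag: AsymmetryGraph, tl: TrophicAssignment) -> LinkClassification:
    """Class each link bottom-up / top-down / lateral by endpoint trophic levels."""
    missing = sorted(n for n in ag.node_order if n not in tl.levels)
    if missing:
        raise ValueError(f"no trophic level for asymmetry-graph node(s): {missing}")
    classes = []
    bu = td = lateral = 0
    for src, tgt, _ in ag.links:
        diff = tl.levels[tgt] - tl.levels[src]
        if diff > TL_TOL:
            cls = "bottom-up"
            bu += 1
        elif diff < -TL_TOL:
            cls = "top-down"
            td += 1
        else:
            cls = "lateral"
            lateral += 1
        classes.append((src, tgt, cls))
    return LinkClassification(classes=classes, bu_count=bu, td_count=td, lateral_count=lateral)


def write_trophic_levels(tl: TrophicAssignment, path, header: str | None = None) -> None:
    """CSV export: node, level, basal flag."""
    import pandas as pd

    basal = set(tl.basal_nodes)
    df = pd.DataFrame(
        {
            "node": list(tl.levels),
            "level": [tl.levels[n] for n in tl.levels],
            "basal": [n in basal for n in tl.levels],
        }
    )
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
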