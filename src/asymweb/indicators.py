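"""The 21 systemic indicators: food-web, asymmetry-graph, combined, non-network.

Eight food-web properties (Nfw, Lfw, Cfw, avDISTfw, Tfw, avTLfw, maxTLfw and
the carnivore/omnivore ratio NCARNfw/Nfw), eight asymmetry-graph properties
(Nag, Lag, COMPag, BUag, TDag, TDag/BUag, Nsoag, Nsiag), two combined ratios
(Nag/Nfw, Lag/Lfw) and three network-independent ecosystem measures
(Shannon diversity Sh, total biomass TB, mean ecotrophic efficiency EE).

Conventions that the raw definitions leave open:

* Connectance uses the undirected pair universe, ``Cfw = Lfw / (N(N-1)/2)``,
  consistent with the pair universe of the asymmetry-link budget.
* Average distance is computed over connected unordered pairs of the
  undirected graph; unreachable pairs are excluded (and logged).
* Transitivity is the global clustering coefficient,
  3 x triangles / connected triples.
* Shannon diversity uses biomass proportions and the natural log.
* "Unrealistic" ecotrophic efficiencies are those outside [0, 1] (Ecopath
  balance requires EE <= 1); they are omitted from the mean with a log entry.
* TDag/BUag is a missing value when BUag = 0 (excluded pairwise downstream).
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from asymweb.asymmetry import AsymmetryGraph, build_asymmetry_graph, asymmetry_matrix, component_count
from asymweb.io import FoodWeb
from asymweb.ti_core import ti_matrix
from asymweb.trophic import LinkClassification, TrophicAssignment, classify_links, trophic_levels

logger = logging.getLogger(__name__)

NAN = float("nan")

#: fixed indicator order used by every exported table (plus a web_id column)
INDICATOR_COLUMNS = [
    "Nfw", "Lfw", "Cfw", "avDISTfw", "Tfw", "avTLfw", "maxTLfw", "carn_ratio",
    "Nag", "Lag", "COMPag", "BUag", "TDag", "td_bu_ratio", "Nsoag", "Nsiag",
    "Nag_over_Nfw", "Lag_over_Lfw",
    "Sh", "TB", "EE",
]


def foodweb_indicators(web: FoodWeb, tl: TrophicAssignment | None) -> dict[str, float]:
    """The eight food-web properties.

    Trophic-level summaries (avTLfw, maxTLfw, carn_ratio) are missing when
    no trophic assignment is available.
    """
    n = web.n_nodes
    if n < 2:
        raise ValueError(f"{web.web_id}: need at least 2 nodes for food-web indicators")
    g = web.to_undirected_graph()
    l = web.n_links
    out = {
        "Nfw": float(n),
        "Lfw": float(l),
        "Cfw": l / (n * (n - 1) / 2),
        "avDISTfw": _mean_distance(g, web.web_id),
        "Tfw": nx.transitivity(g),
    }
    if tl is not None:
        levels = [tl.levels[x] for x in web.nodes if x in tl.levels]
        out["avTLfw"] = float(np.mean(levels)) if levels else NAN
        out["maxTLfw"] = float(np.max(levels)) if levels else NAN
        out["carn_ratio"] = sum(v > 2 + 1e-9 for v in levels) / n
    else:
        out.update({"avTLfw": NAN, "maxTLfw": NAN, "carn_ratio": NAN})
    return out


def _mean_distance(g: nx.Graph, web_id: str) -> float:
    """Mean shortest-path length over connected unordered pairs."""
    n = g.number_of_nodes()
    total_pairs = n * (n - 1) // 2
    dist_sum = 0.0
    reachable = 0
    for comp in nx.connected_components(g):
        k = len(comp)
        if k < 2:
            continue
        sub = g.subgraph(comp)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            dist_sum += sum(lengths.values())
        reachable += k * (k - 1) // 2
    dist_sum /= 2  # each unordered pair counted twice
    if reachable == 0:
        return NAN
    if reachable < total_pairs:
        logger.info("%s: %d unreachable pair(s) excluded from avDISTfw", web_id, total_pairs - reachable)
    return dist_sum / reachable


def asymgraph_indicators(ag: AsymmetryGraph, classes: LinkClassification | None) -> dict[str, float]:
    """The eight asymmetry-graph properties.

    BUag/TDag need link classes (hence trophic levels); they are missing
    when ``classes`` is None.  TDag/BUag is missing when BUag = 0.
    """
    g = ag.to_networkx()
    out = {
        "Nag": float(ag.n_nodes),
        "Lag": float(ag.n_links),
        "COMPag": float(component_count(ag)),
        "Nsoag": float(sum(1 for v in g if g.out_degree(v) > 0 and g.in_degree(v) == 0)),
        "Nsiag": float(sum(1 for v in g if g.in_degree(v) > 0 and g.out_degree(v) == 0)),
    }
    if classes is not None:
        out["BUag"] = float(classes.bu_count)
        out["TDag"] = float(classes.td_count)
        out["td_bu_ratio"] = classes.td_count / classes.bu_count if classes.bu_count else NAN
    else:
        out.update({"BUag": NAN, "TDag": NAN, "td_bu_ratio": NAN})
    return out


def combined_ratios(fw: dict[str, float], ag: dict[str, float]) -> dict[str, float]:
    """Nag/Nfw and Lag/Lfw, the asymmetry-graph compression ratios."""
    return {
        "Nag_over_Nfw": ag["Nag"] / fw["Nfw"] if fw["Nfw"] else NAN,
        "Lag_over_Lfw": ag["Lag"] / fw["Lfw"] if fw["Lfw"] else NAN,
    }


def nonnetwork_indicators(
    web: FoodWeb,
    ee_valid_range: tuple[float, float] = (0.0, 1.0),
) -> dict[str, float]:
    """Shannon diversity (biomass proportions, nats), total biomass, mean EE.

    EE values outside ``ee_valid_range`` are omitted from the mean and
    logged with the node and value.
    """
    biomass = web.attribute_series("biomass").dropna()
    if len(biomass) == 0:
        sh = tb = NAN
    else:
        tb = float(biomass.sum())
        positive = biomass[biomass > 0]
        p = positive / positive.sum()
        sh = float(-(p * np.log(p)).sum()) if len(positive) else NAN
    ee = web.attribute_series("ee").dropna()
    lo, hi = ee_valid_range
    valid = ee[(ee >= lo) & (ee <= hi)]
    for node, val in ee[(ee < lo) | (ee > hi)].items():
        logger.info("%s: omitted unrealistic EE value %s for node %s", web.web_id, val, node)
    mean_ee = float(valid.mean()) if len(valid) else NAN
    return {"Sh": sh, "TB": tb, "EE": mean_ee}


def analyze_web(
    web: FoodWeb,
    t: float = 0.01,
    n_steps: int = 3,
    ee_valid_range: tuple[float, float] = (0.0, 1.0),
) -> dict[str, float]:
    """Run the full per-web pipeline and return all 21 indicators.

    Stages that cannot run (no trophic information, edgeless web, ...) yield
    missing values for their indicators; the rest are still computed.
    """
    record: dict[str, float] = {c: NAN for c in INDICATOR_COLUMNS}
    try:
        tl = trophic_levels(web)
    except ValueError as exc:
        logger.warning("%s: trophic levels unavailable (%s)", web.web_id, exc)
        tl = None
    record.update(foodweb_indicators(web, tl))
    try:
        ti = ti_matrix(web, n=n_steps, normalize=True)
        ag = build_asymmetry_graph(asymmetry_matrix(ti), ti, t=t)
    except ValueError as exc:
        logger.warning("%s: asymmetry graph unavailable (%s)", web.web_id, exc)
        ag = None
    if ag is not None:
        classes = classify_links(ag, tl) if tl is not None else None
        ag_ind = asymgraph_indicators(ag, classes)
        record.update(ag_ind)
        record.update(combined_ratios(record, ag_ind))
    record.update(nonnetwork_indicators(web, ee_valid_range))
    return record


def indicator_table(
    webs: Sequence[FoodWeb],
    t: float = 0.01,
    n_steps: int = 3,
    ee_valid_range: tuple[float, float] = (0.0, 1.0),
) -> pd.DataFrame:
    """One row of the 21 indicators per web; per-web failures leave NaN rows.

    The batch never aborts on a single bad web: the failure is logged, a row
    of missing values is emitted, and processing continues.
    """
    rows = []
    for web in webs:
        record: dict[str, object] = {"web_id": web.web_id}
        try:
            record.update(analyze_web(web, t=t, n_steps=n_steps, ee_valid_range=ee_valid_range))
        except Exception as exc:  # noqa: BLE001 - contract: record and continue
            logger.error("%s: indicator computation failed (%s)", web.web_id, exc)
            record.update({c: NAN for c in INDICATOR_COLUMNS})
        rows.append(record)
    return pd.DataFrame(rows, columns=["web_id"] + INDICATOR_COLUMNS)
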