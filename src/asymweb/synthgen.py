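"""Synthetic food webs: niche-model topology with Ecopath-like attributes.

The classic niche model places every species at a niche value drawn uniform
on (0, 1) and lets it consume every species falling inside a contiguous
feeding range whose beta-distributed width is calibrated so the expected
directed connectance ``L / N^2`` matches a target.  The range centre lies
below the consumer's own niche value, which makes feeding flow predominantly
from low to high niche positions — the structural signature of empirical
food webs (broad resource bases, omnivory, the occasional feeding loop).

On top of the topology, :func:`assign_attributes` draws per-node biomass
from a lognormal whose median decays geometrically with trophic level
(biomass pyramids) and ecotrophic efficiency uniform on a configurable
interval.  Everything is driven by one integer seed, so a given spec always
reproduces the same web bit-for-bit.

These webs emulate the inputs the pipeline expects from Ecopath exports —
binary topology, biomass, EE — not mass-balanced flow models: the
attributes are generative stand-ins, adequate for exercising the indicator
and correlation machinery, not for ecological inference about real systems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from asymweb.io import FoodWeb
from asymweb.trophic import TrophicCycleError, trophic_levels

logger = logging.getLogger(__name__)


@dataclass
class SyntheticWebSpec:
    """Parameters of one synthetic web.

    ``connectance_target`` is the expected directed connectance ``L/N^2``;
    ``basal_fraction`` fixes the share of primary producers (the lowest
    niche positions, which consume nothing), mirroring the roughly constant
    producer fraction of empirical webs that the plain niche model lacks.
    ``biomass_median_basal`` sets the lognormal median at trophic level 1;
    the median is multiplied by ``biomass_tl_decay`` for each additional
    trophic level, and ``biomass_sigma`` is the lognormal shape (natural-log
    scale).  ``ee_interval`` bounds the uniform ecotrophic-efficiency draw.
    """

    n_species: int = 60
    connectance_target: float = 0.15
    basal_fraction: float = 0.2
    seed: int = 0
    biomass_median_basal: float = 100.0
    biomass_sigma: float = 1.0
    biomass_tl_decay: float = 0.1
    ee_interval: tuple[float, float] = (0.0, 1.0)
    max_redraws: int = 500


def niche_model_web(spec: SyntheticWebSpec) -> FoodWeb:
    """Draw one niche-model web satisfying the pipeline's structural needs.

    A draw is accepted only if the web (after removing self-loops) is
    connected, has at least one basal species, has no trophically duplicate
    species (identical prey and predator sets), and admits prey-averaged
    trophic levels.  Rejected draws are redone with fresh randomness, up to
    ``max_redraws`` attempts.
    """
    if not 0 < spec.connectance_target < 1:
        raise ValueError(f"connectance target must be in (0, 1), got {spec.connectance_target}")
    if spec.n_species < 5:
        raise ValueError(f"need at least 5 species, got {spec.n_species}")
    rng = np.random.default_rng(spec.seed)
    for attempt in range(spec.max_redraws):
        web = _draw_niche_web(spec, rng)
        if web is None:
            continue
        return web
    raise RuntimeError(
        f"no admissible niche-model web after {spec.max_redraws} draws "
        f"(n={spec.n_species}, C={spec.connectance_target})"
    )


def _draw_niche_web(spec: SyntheticWebSpec, rng: np.random.Generator) -> FoodWeb | None:
    n = spec.n_species
    # Consumers must compensate for the basal species' empty ranges to hit
    # the target directed connectance L/N^2 on average.  Consumers are the
    # upper (1-f) quantiles of the niche axis, so their mean niche value is
    # (1+f)/2 and E[L] = (1-f)N * (1+f)/2 * 2*c_eff * N = (1-f^2) c_eff N^2.
    f = spec.basal_fraction
    c_eff = spec.connectance_target / (1.0 - f * f)
    if c_eff >= 0.5:
        raise ValueError(
            f"connectance target {spec.connectance_target} unattainable at "
            f"basal fraction {spec.basal_fraction}"
        )
    beta = 1.0 / (2.0 * c_eff) - 1.0
    # The plain niche model yields too few producers relative to empirical
    # webs; fixing the basal fraction (lowest niche positions feed on
    # nothing) is the standard correction and guarantees >= 1 basal species.
    n_basal = max(1, round(spec.basal_fraction * n))
    niche = rng.uniform(0.0, 1.0, size=n)
    rel_width = rng.beta(1.0, beta, size=n)
    prey_sets: list[frozenset] = []
    for _ in range(100):  # trophically duplicate species are redrawn in place
        width = niche * rel_width
        width[np.argsort(niche)[:n_basal]] = 0.0
        centre = rng.uniform(width / 2.0, np.minimum(niche, 1.0 - width / 2.0))
        lo, hi = centre - width / 2.0, centre + width / 2.0
        prey_sets = [
            frozenset(j for j in range(n) if j != i and lo[i] <= niche[j] <= hi[i])
            for i in range(n)
        ]
        pred_sets = [frozenset(i for i in range(n) if j in prey_sets[i]) for j in range(n)]
        roles: dict[tuple, int] = {}
        offenders = []
        for i, role in enumerate(zip(prey_sets, pred_sets)):
            if role in roles:
                offenders.append(i)
            else:
                roles[role] = i
        if not offenders:
            break
        niche[offenders] = rng.uniform(0.0, 1.0, size=len(offenders))
        rel_width[offenders] = rng.beta(1.0, beta, size=len(offenders))
    else:
        return None
    labels = [f"S{i:03d}" for i in range(n)]
    edges = [(labels[j], labels[i]) for i in range(n) for j in prey_sets[i]]
    if not edges:
        return None
    web = FoodWeb.from_edges(f"niche-{spec.seed}", edges, directed=True, nodes=labels)
    if not nx.is_connected(web.to_undirected_graph()):
        return None
    if not any(len(p) == 0 for p in prey_sets):
        return None
    try:
        trophic_levels(web)
    except TrophicCycleError:
        return None
    return web


def assign_attributes(web: FoodWeb, spec: SyntheticWebSpec) -> FoodWeb:
    """Attach seed-deterministic biomass and EE attributes.

    Biomass for a node at trophic level TL is lognormal with median
    ``biomass_median_basal * biomass_tl_decay ** (TL - 1)`` (so with the
    default decay of 0.1 per level the median at TL 3 is 1% of the basal
    median) and shape ``biomass_sigma``; EE is uniform on ``ee_interval``.
    """
    tl = trophic_levels(web)
    rng = np.random.default_rng([spec.seed, 1])
    attrs: dict[str, dict[str, float]] = {}
    lo, hi = spec.ee_interval
    for node in web.nodes:
        median = spec.biomass_median_basal * spec.biomass_tl_decay ** (tl.levels[node] - 1.0)
        attrs[node] = {
            "biomass": float(rng.lognormal(mean=np.log(median), sigma=spec.biomass_sigma)),
            "ee": float(rng.uniform(lo, hi)),
        }
    return web.with_attributes(attrs)


def synthetic_collection(
    n_webs: int = 34,
    seed: int = 0,
    n_species_range: tuple[int, int] = (51, 120),
    connectance_range: tuple[float, float] = (0.05, 0.15),
    **spec_kwargs,
) -> list[FoodWeb]:
    """A collection of attribute-bearing niche webs of varying size.

    Sizes and connectances are drawn uniformly per web, emulating the
    heterogeneity of a curated model collection (every web above the
    50-node selection cut); all randomness descends from ``seed``.
    """
    rng = np.random.default_rng([seed, 2])
    webs = []
    for k in range(n_webs):
        spec = SyntheticWebSpec(
            n_species=int(rng.integers(n_species_range[0], n_species_range[1] + 1)),
            connectance_target=float(rng.uniform(*connectance_range)),
            seed=int(rng.integers(2**31)),
            **spec_kwargs,
        )
        web = assign_attributes(niche_model_web(spec), spec)
        webs.append(replace_web_id(web, f"synth-{seed}-{k:02d}"))
    return webs


def replace_web_id(web: FoodWeb, web_id: str) -> FoodWeb:
    return replace(web, web_id=web_id)


def fixtures() -> dict[str, FoodWeb]:
    """Canonical small webs used throughout the test-suite and docs.

    * ``path-3``: A-B-C chain (trophic A->B->C).
    * ``star-4``: hub ``c`` with leaves ``l1..l3``.
    * ``cycle-4`` / ``complete-4``: fully symmetric graphs whose asymmetry
      matrices vanish identically.
    * ``chain-PHC``: producer -> herbivore -> carnivore.
    * ``toy-8``: an 8-node, 9-link web in the spirit of a small published
      illustration; the exact published topology is not recoverable, so
      this is a synthetic stand-in with the same node and link counts.
    """
    return {
        "path-3": FoodWeb.from_edges("path-3", [("A", "B"), ("B", "C")], directed=True),
        "star-4": FoodWeb.from_edges("star-4", [("c", "l1"), ("c", "l2"), ("c", "l3")]),
        "cycle-4": FoodWeb.from_edges(
            "cycle-4", [("n1", "n2"), ("n2", "n3"), ("n3", "n4"), ("n4", "n1")]
        ),
        "complete-4": FoodWeb.from_edges(
            "complete-4",
            [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")],
        ),
        "chain-PHC": FoodWeb.from_edges("chain-PHC", [("P", "H"), ("H", "C")], directed=True),
        "toy-8": FoodWeb.from_edges(
            "toy-8",
            [
                ("A", "C"), ("B", "C"), ("B", "D"), ("C", "E"), ("D", "E"),
                ("D", "F"), ("E", "G"), ("F", "G"), ("G", "H"),
            ],
            directed=True,
        ),
    }
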