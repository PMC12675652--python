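"""Topological importance: one-step, multi-step and aggregated TI^n effects.

The topological importance index quantifies how strongly one species affects
another purely through the binary, undirected interaction structure.  The
one-step rule splits each node's incoming influence equally among its
neighbours: the effect of ``i`` on an adjacent ``j`` is ``1/D_j`` where
``D_j`` is the degree of ``j``.  Longer-range effects propagate along walks
(matrix powers, so walks may revisit nodes), and ``TI^n`` averages the
``m``-step effects for ``m = 1..n``.  ``n = 3`` is the conventional horizon:
three steps capture most ecologically meaningful indirect effects while
longer chains decay quickly.

Orientation: entry ``(i, j)`` of every matrix here is the effect OF ``i``
ON ``j`` (row acts on column).

Normalisation divides all entries by the grand off-diagonal total, so the
normalised TI^n matrix sums to 1 over ordered pairs.  The choice rescales
every entry by a single positive scalar; the asymmetry graph built
downstream is invariant to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from asymweb.io import FoodWeb


@dataclass
class EffectMatrix:
    """An N x N matrix of pairwise effects with its node order.

    ``values[i, j]`` is the effect of node ``node_order[i]`` on node
    ``node_order[j]``; ``steps`` records the walk-length horizon and
    ``normalized`` whether entries were rescaled to a unit grand total.
    """

    node_order: list[str]
    values: np.ndarray
    steps: int
    normalized: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Square DataFrame view, labels as index and columns."""
        return pd.DataFrame(self.values, index=self.node_order, columns=self.node_order)

    def effect(self, source: str, target: str) -> float:
        i = self.node_order.index(source)
        j = self.node_order.index(target)
        return float(self.values[i, j])


def one_step_effects(web: FoodWeb) -> EffectMatrix:
    """Direct effects: ``effect(i -> j) = 1/degree(j)`` for each edge {i, j}.

    Every node divides the influence it receives equally among its
    neighbours, so each column over a non-isolated node sums to exactly 1.
    Isolated nodes get zero rows and columns.
    """
    nodes = web.nodes
    index = {n: k for k, n in enumerate(nodes)}
    n = len(nodes)
    degree = np.zeros(n)
    for u, v in web.undirected_edges:
        degree[index[u]] += 1
        degree[index[v]] += 1
    m = np.zeros((n, n))
    for u, v in web.undirected_edges:
        i, j = index[u], index[v]
        m[i, j] = 1.0 / degree[j]
        m[j, i] = 1.0 / degree[i]
    return EffectMatrix(node_order=list(nodes), values=m, steps=1)


def multi_step_effects(one_step: EffectMatrix, m: int) -> EffectMatrix:
    """Effects along walks of exactly ``m`` steps: the m-th matrix power.

    Entry ``(i, j)`` sums, over every length-``m`` walk from ``i`` to ``j``
    (revisits allowed), the product of one-step effects along the walk.
    """
    if m < 1:
        raise ValueError(f"step count must be >= 1, got {m}")
    return EffectMatrix(
        node_order=list(one_step.node_order),
        values=np.linalg.matrix_power(one_step.values, m),
        steps=m,
    )


def ti_matrix(
    web: FoodWeb,
    n: int = 3,
    normalize: bool = True,
    aggregate: str = "mean",
) -> EffectMatrix:
    """Pairwise TI^n effects: aggregated 1..n-step walk effects, diagonal zeroed.

    Parameters
    ----------
    web : FoodWeb
    n : int
        Walk-length horizon (default 3).
    normalize : bool
        Divide all entries by the grand off-diagonal total so they sum to 1.
    aggregate : {"mean", "sum"}
        ``"mean"`` is the standard TI definition, ``(1/n) * sum_m M^m``;
        ``"sum"`` is offered for sensitivity checks and differs only by the
        constant factor ``n``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if aggregate not in ("mean", "sum"):
        raise ValueError(f"aggregate must be 'mean' or 'sum', got {aggregate!r}")
    one = one_step_effects(web)
    acc = np.zeros_like(one.values)
    power = np.eye(len(web.nodes))
    for _ in range(n):
        power = power @ one.values
        acc += power
    if aggregate == "mean":
        acc /= n
    np.fill_diagonal(acc, 0.0)
    normalized = False
    if normalize:
        total = acc.sum()
        if total <= 0:
            raise ValueError(f"{web.web_id}: cannot normalize an all-zero TI matrix (edgeless web)")
        acc = acc / total
        normalized = True
    return EffectMatrix(node_order=list(web.nodes), values=acc, steps=n, normalized=normalized)


def node_ti(ti: EffectMatrix, sort: bool = False) -> pd.Series:
    """Per-node importance: the total effect each node exerts on all others.

    Row sums of the TI matrix (the diagonal is already zero).  With
    ``sort=True`` the series is returned descending, the usual view for
    keystone-species ranking.
    """
    s = pd.Series(ti.values.sum(axis=1), index=ti.node_order, name=f"TI{ti.steps}")
    return s.sort_values(ascending=False) if sort else s
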