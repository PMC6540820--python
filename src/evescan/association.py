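"""Host–element evolutionary association statistics.

Three analyses quantify how elements relate to their hosts:

* :func:`pearson_test` — product-moment correlation between per-genome
  element counts and assembly-quality factors (a sanity check that
  apparent abundance differences are not assembly artifacts);
* :func:`association_index` / :func:`ai_permutation_test` — a tip-trait
  association index on a phylogeny whose tips are labelled with host
  states, with a tip-label permutation null.  The index sums, over
  internal nodes, ``(1 - f) / 2**(n - 1)`` where ``n`` is the number of
  descendant tips and ``f`` the frequency of their most common state;
  it is 0 when every clade is host-pure and grows as states mix.  The
  ratio of the observed index to the null mean is near 0 under strong
  host structure and near 1 under none;
* :func:`reconcile` / :func:`reconcile_significance` — event-cost
  cophylogenetic reconciliation mapping the element tree onto the host
  tree by dynamic programming over (element node, host node) pairs,
  with events co-divergence, duplication, host switch and loss, and a
  host-map randomization null for the total cost.

The reconciliation searches all incomparable host branches as switch
targets without enforcing a global timing order, so it is a
deterministic lower-bound event reconstruction rather than a
timing-consistent one; "failure to diverge" is not representable in
this single-association mapping and is always reported as 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats as sps

from .config import DEFAULT_EVENT_COSTS

logger = logging.getLogger(__name__)

INF = float("inf")


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    t_stat: float
    df: int
    p_two_sided: float
    n: int


def pearson_test(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = math.sqrt(float(xc @ xc)), math.sqrt(float(yc @ yc))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        t, p = math.inf, 0.0
    else:
        t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, t_stat=t, df=df, p_two_sided=p, n=n)


# ---------------------------------------------------------------------------
# Association index
# ---------------------------------------------------------------------------

def _tree_struct(tree: dendropy.Tree) -> list[tuple[str, object]]:
    """Postorder node list: ('leaf', label) or ('internal', child idxs)."""
    index: dict[int, int] = {}
    struct: list[tuple[str, object]] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            if node.taxon is None:
                raise ValueError("leaf without a taxon label")
            struct.append(("leaf", node.taxon.label))
        else:
            kids = [index[id(ch)] for ch in node.child_nodes()]
            if len(kids) == 1:  # unifurcation (e.g. an explicit root edge)
                index[id(node)] = kids[0]
                continue
            struct.append(("internal", kids))
        index[id(node)] = len(struct) - 1
    return struct


def _ai_from_struct(struct, states: Mapping[str, str]) -> float:
    counts: list[dict[str, int]] = [dict() for _ in struct]
    ai = 0.0
    for i, (kind, payload) in enumerate(struct):
        if kind == "leaf":
            if payload not in states:
                raise ValueError(f"tip {payload!r} has no host state")
            counts[i] = {states[payload]: 1}
        else:
            acc: dict[str, int] = {}
            for k in payload:
                for s, c in counts[k].items():
                    acc[s] = acc.get(s, 0) + c
                counts[k] = {}
            counts[i] = acc
            n = sum(acc.values())
            f = max(acc.values()) / n
            if n - 1 <= 1020:  # 2**(n-1) would overflow a float beyond this
                ai += (1.0 - f) / (2.0 ** (n - 1))
    return ai


def association_index(tree: dendropy.Tree, states: Mapping[str, str]) -> float:
    """Tip-trait association index; 0 iff every internal node is
    host-pure (all descendant tips share one state)."""
    return _ai_from_struct(_tree_struct(tree), states)


@dataclass
class AiResult:
    ai_observed: float
    null_mean: float
    ai_ratio: float
    p_value: float
    n_permutations: int
    seed: int
    null_values: list[float] = field(default_factory=list, repr=False)


def ai_permutation_test(
    tree: dendropy.Tree,
    states: Mapping[str, str],
    n_perm: int = 1000,
    seed: int = 0,
) -> AiResult:
    """Association index with a tip-label permutation null.

    The null permutes host states across tips without replacement; the
    ratio is observed / null-mean and the one-sided p-value (small
    index = structured) uses the +1 correction so it is never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    struct = _tree_struct(tree)
    tips = [payload for kind, payload in struct if kind == "leaf"]
    obs = _ai_from_struct(struct, states)
    values = [states[t] for t in tips]
    if len(set(values)) < 2:
        raise ValueError("all tips share one state: permutation null degenerate")
    rng = np.random.default_rng(seed)
    null = []
    vals = np.array(values, dtype=object)
    for _ in range(n_perm):
        perm = rng.permutation(len(vals))
        null.append(_ai_from_struct(struct, dict(zip(tips, vals[perm]))))
    null_mean = float(np.mean(null))
    if null_mean > 0:
        ratio = obs / null_mean
    else:
        ratio = 0.0 if obs == 0 else INF
    p = (1 + sum(v <= obs for v in null)) / (n_perm + 1)
    return AiResult(
        ai_observed=obs,
        null_mean=null_mean,
        ai_ratio=ratio,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        null_values=null,
    )


# ---------------------------------------------------------------------------
# Event-cost reconciliation
# ---------------------------------------------------------------------------

@dataclass
class ReconciliationResult:
    counts: dict[str, int]
    total_cost: int
    p_value: float | None = None


class _BinaryTree:
    """Postorder-indexed binary tree for the reconciliation DP."""

    def __init__(self, tree: dendropy.Tree, name: str):
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        if any(len(n.child_nodes()) > 2 for n in tree.preorder_node_iter()):
            logger.warning("%s tree has multifurcations; resolving arbitrarily", name)
            tree.resolve_polytomies()
        self.children: list[tuple[int, int] | None] = []
        self.labels: list[str] = []
        index: dict[int, int] = {}
        for node in tree.postorder_node_iter():
            kids = node.child_nodes()
            if len(kids) == 0:
                if node.taxon is None:
                    raise ValueError(f"{name} tree has an unlabeled tip")
                self.children.append(None)
                self.labels.append(node.taxon.label)
            else:
                self.children.append((index[id(kids[0])], index[id(kids[1])]))
                self.labels.append(f"{name}#{len(self.children) - 1}")
            index[id(node)] = len(self.children) - 1
        self.n = len(self.children)
        self.root = self.n - 1
        self.leaf_index = {
            lab: i for i, lab in enumerate(self.labels) if self.children[i] is None
        }

    def comparability(self) -> np.ndarray:
        """comp[a, b] True iff a and b lie on one root-to-tip path."""
        desc = np.zeros((self.n, self.n), dtype=bool)
        for i in range(self.n):
            desc[i, i] = True
            if self.children[i] is not None:
                l, r = self.children[i]
                desc[i] |= desc[l] | desc[r]
        return desc | desc.T


_CO, _DUP, _SW = "codivergence", "duplication", "host_switch"


def reconcile(
    host_tree: dendropy.Tree,
    eve_tree: dendropy.Tree,
    tip_to_host: Mapping[str, str],
    costs: Mapping[str, int] | None = None,
) -> ReconciliationResult:
    """Minimum-cost mapping of the element tree onto the host tree.

    Post-order dynamic programming over (element node, host node)
    placements with events co-divergence, duplication, host switch
    (target: any host branch incomparable to the source) and loss (one
    per traversed host edge).  Event counts come from one optimal
    backtrace with deterministic tie-breaking (co-divergence preferred
    over duplication over host switch, then lowest host node index).
    """
    if costs is None:
        costs = DEFAULT_EVENT_COSTS
    c_co, c_dup, c_sw, c_loss = (
        costs["codivergence"], costs["duplication"],
        costs["host_switch"], costs["loss"],
    )
    H = _BinaryTree(host_tree, "host")
    P = _BinaryTree(eve_tree, "eve")
    for tip, host in tip_to_host.items():
        if tip in P.leaf_index and host not in H.leaf_index:
            raise ValueError(f"tip {tip!r} maps to unknown host {host!r}")
    incomp = ~H.comparability()

    C = np.full((P.n, H.n), INF)
    IN = np.full((P.n, H.n), INF)
    OUT = np.full((P.n, H.n), INF)

    def fill_in_out(p: int) -> None:
        # IN[p,h]: best placement of p in subtree(h), paying losses down
        for h in range(H.n):  # postorder: children precede parents
            best = C[p, h]
            if H.children[h] is not None:
                l, r = H.children[h]
                best = min(best, IN[p, l] + c_loss, IN[p, r] + c_loss)
            IN[p, h] = best
        cvec = C[p]
        masked = np.where(incomp, cvec[None, :], INF)
        OUT[p] = masked.min(axis=1)

    for p in range(P.n):
        if P.children[p] is None:
            lab = P.labels[p]
            if lab not in tip_to_host:
                raise ValueError(f"element tip {lab!r} has no host mapping")
            C[p, H.leaf_index[tip_to_host[lab]]] = 0.0
        else:
            u, v = P.children[p]
            for h in range(H.n):
                opts = [c_dup + IN[u, h] + IN[v, h]]
                if H.children[h] is not None:
                    a, b = H.children[h]
                    opts.append(c_co + min(IN[u, a] + IN[v, b], IN[u, b] + IN[v, a]))
                opts.append(c_sw + min(IN[u, h] + OUT[v, h], IN[v, h] + OUT[u, h]))
                C[p, h] = min(opts)
        fill_in_out(p)

    total = float(C[P.root].min())
    if not math.isfinite(total):
        raise ValueError("no feasible reconciliation (check the tip mapping)")

    counts = {_CO: 0, _DUP: 0, _SW: 0, "loss": 0, "failure_to_diverge": 0}

    def trace_in(p: int, h: int) -> None:
        """Descend from h to the node where p is actually placed."""
        cur = h
        while C[p, cur] != IN[p, cur]:
            l, r = H.children[cur]
            counts["loss"] += 1
            cur = l if IN[p, l] + c_loss == IN[p, cur] else r
        trace_node(p, cur)

    def trace_out(p: int, h: int) -> None:
        cvec = C[p]
        cands = np.flatnonzero(incomp[h] & (cvec == OUT[p, h]))
        trace_node(p, int(cands[0]))

    def trace_node(p: int, h: int) -> None:
        if P.children[p] is None:
            return
        u, v = P.children[p]
        here = C[p, h]
        if H.children[h] is not None:
            a, b = H.children[h]
            if here == c_co + IN[u, a] + IN[v, b]:
                counts[_CO] += 1
                trace_in(u, a)
                trace_in(v, b)
                return
            if here == c_co + IN[u, b] + IN[v, a]:
                counts[_CO] += 1
                trace_in(u, b)
                trace_in(v, a)
                return
        if here == c_dup + IN[u, h] + IN[v, h]:
            counts[_DUP] += 1
            trace_in(u, h)
            trace_in(v, h)
            return
        counts[_SW] += 1
        if here == c_sw + IN[u, h] + OUT[v, h]:
            trace_in(u, h)
            trace_out(v, h)
        else:
            trace_in(v, h)
            trace_out(u, h)

    root_h = int(np.flatnonzero(C[P.root] == total)[0])
    trace_node(P.root, root_h)
    return ReconciliationResult(counts=counts, total_cost=int(round(total)))


def reconcile_significance(
    host_tree: dendropy.Tree,
    eve_tree: dendropy.Tree,
    tip_to_host: Mapping[str, str],
    costs: Mapping[str, int] | None = None,
    n_rand: int = 100,
    seed: int = 0,
    return_null: bool = False,
):
    """Randomization p-value for the reconciliation total cost.

    The null permutes the host assignments across element tips; the
    p-value is ``(1 + #{null <= observed}) / (n_rand + 1)``.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    obs = reconcile(host_tree, eve_tree, tip_to_host, costs).total_cost
    tips = list(tip_to_host)
    hosts = np.array([tip_to_host[t] for t in tips], dtype=object)
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_rand):
        perm = rng.permutation(len(hosts))
        null.append(
            reconcile(host_tree, eve_tree, dict(zip(tips, hosts[perm])), costs).total_cost
        )
    p = (1 + sum(v <= obs for v in null)) / (n_rand + 1)
    if return_null:
        return p, obs, null
    return p


def tanglegram_export(
    host_tree: dendropy.Tree,
    eve_tree: dendropy.Tree,
    tip_to_host: Mapping[str, str],
    out_dir: str | Path,
    prefix: str = "tanglegram",
) -> dict[str, Path]:
    """Write the paired-tree bundle any cophylogeny plotter can consume.

    Emits the two Newick files plus a two-column (element tip, host
    tip) association TSV.
    """
    if not tip_to_host:
        raise ValueError("empty association map")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "host": out / f"{prefix}.host.nwk",
        "eve": out / f"{prefix}.eve.nwk",
        "assoc": out / f"{prefix}.assoc.tsv",
    }
    paths["host"].write_text(host_tree.as_string(schema="newick", suppress_rooting=True))
    paths["eve"].write_text(eve_tree.as_string(schema="newick", suppress_rooting=True))
    with open(paths["assoc"], "w") as fh:
        fh.write("eve_tip\thost\n")
        for tip, host in tip_to_host.items():
            fh.write(f"{tip}\t{host}\n")
    return paths
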