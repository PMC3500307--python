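"""Ancestral-area reconstruction: MAC parsimony and a bounded-range DEC model.

Two reconstructions of how geographic ranges evolved over a phylogeny:

* **MAC (minimum area change) parsimony** — ancestral ranges are area
  *sets*; the cost of an ancestor-descendant transition is the number of
  area gains plus losses (the symmetric difference of the two sets).
  Branch lengths are ignored.  Implemented as Sankoff dynamic programming
  over all ranges of bounded cardinality, with an augmented DP that tracks
  the gain/loss decomposition across all most-parsimonious reconstructions.

* **DEC (dispersal-extinction-cladogenesis)** — a continuous-time model
  along branches: an occupied range of size ``|S|`` gains a new area at
  rate ``d * |S|`` (uniform dispersal multipliers) and loses each occupied
  area at rate ``e``; a single-area range can be extirpated to the
  (absorbing) null range.  At speciation a single-area range is inherited
  by both daughters; a two-area range {a, b} resolves into one of six
  equally weighted scenarios: ({a},{b}), ({b},{a}), ({a},{a,b}),
  ({a,b},{a}), ({b},{a,b}), ({a,b},{b}).  Ranges at internal nodes are
  capped at ``max_range_size`` areas (2 in the primate analysis).

Ranges are bitmasks over the area list; the null range is the extra state
appended after all occupied ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .tree import Chronogram

__all__ = [
    "AreaSystem",
    "DECParams",
    "MACResult",
    "DECFit",
    "enumerate_states",
    "mac_cost",
    "mac_reconstruct",
    "mac_change_bounds",
    "dec_rate_matrix",
    "dec_loglik",
    "dec_fit",
    "dec_node_ranges",
    "count_dispersals",
    "read_tip_areas",
]

INF = float("inf")


@dataclass(frozen=True)
class AreaSystem:
    """Named geographic areas with a cap on ancestral range size."""

    areas: tuple
    max_range_size: int = 2

    def __post_init__(self):
        if not 2 <= len(self.areas) <= 16:
            raise ValueError("need between 2 and 16 areas")
        if not 1 <= self.max_range_size <= len(self.areas):
            raise ValueError("max_range_size must be in [1, n_areas]")
        if len(set(self.areas)) != len(self.areas):
            raise ValueError("duplicate area names")

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    def mask(self, names) -> int:
        """Bitmask of an area-name collection."""
        if isinstance(names, str):
            names = [names]
        m = 0
        for name in names:
            try:
                m |= 1 << self.areas.index(name)
            except ValueError:
                raise KeyError(f"unknown area {name!r}; areas are {self.areas}")
        return m

    def names(self, mask: int) -> tuple:
        return tuple(a for i, a in enumerate(self.areas) if mask >> i & 1)


@dataclass(frozen=True)
class DECParams:
    d: float  # dispersal rate per source area per Myr
    e: float  # extirpation rate per occupied area per Myr

    def __post_init__(self):
        if self.d < 0 or self.e < 0:
            raise ValueError("rates must be non-negative")


def enumerate_states(sys: AreaSystem) -> list[int]:
    """All non-empty ranges of cardinality <= max_range_size.

    Deterministic order: by cardinality, then by bitmask value.
    """
    states = [
        m
        for m in range(1, 1 << sys.n_areas)
        if bin(m).count("1") <= sys.max_range_size
    ]
    states.sort(key=lambda m: (bin(m).count("1"), m))
    return states


def mac_cost(s: int, t: int) -> int:
    """Number of area gains plus losses between two ranges (|S xor T|)."""
    if s == 0 or t == 0:
        raise ValueError("ranges must be non-empty")
    return bin(s ^ t).count("1")


@dataclass
class MACResult:
    min_total_changes: int
    node_states: dict  # dendropy node -> frozenset of optimal masks
    gains_range: tuple
    losses_range: tuple
    states: list = field(default_factory=list, repr=False)


def _check_tips(tree: Chronogram, tips: dict) -> None:
    missing = [lab for lab in tree.tip_labels if lab not in tips]
    if missing:
        raise ValueError(f"tips without area coding: {sorted(missing)}")
    empty = [lab for lab in tree.tip_labels if tips[lab] == 0]
    if empty:
        raise ValueError(f"tips with empty range: {sorted(empty)}")


def mac_reconstruct(tree: Chronogram, tips: dict, sys: AreaSystem) -> MACResult:
    """Sankoff DP under the area-change cost; multifurcations allowed.

    ``tips`` maps tip label -> range bitmask.  Tip observations may have
    any cardinality; internal states are capped at ``max_range_size``.
    Returns the minimum total change count, the per-node sets of states
    attained by at least one most-parsimonious reconstruction (MPR), and
    the exact (min, max) gain and loss decompositions over all MPRs.
    """
    _check_tips(tree, tips)
    states = enumerate_states(sys)
    t = tree.dendropy_tree
    n_s = len(states)

    up: dict = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            continue
        vec = np.zeros(n_s)
        for child in node.child_nodes():
            if child.is_leaf():
                obs = tips[child.taxon.label]
                vec += np.array([mac_cost(s, obs) for s in states])
            else:
                cvec = up[child]
                vec += np.array(
                    [min(mac_cost(s, u) + cvec[j] for j, u in enumerate(states))
                     for s in states]
                )
        up[node] = vec

    root = t.seed_node
    if root.is_leaf():
        raise ValueError("tree must have at least one internal node")
    global_min = int(up[root].min())

    # down-pass for per-node MPR state sets
    down: dict = {root: np.zeros(n_s)}
    node_states: dict = {}
    for node in t.preorder_node_iter():
        if node.is_leaf():
            node_states[node] = frozenset([tips[node.taxon.label]])
            continue
        total = up[node] + down[node]
        node_states[node] = frozenset(
            s for j, s in enumerate(states) if total[j] == global_min
        )
        # child contributions given this node's state
        contribs = []
        for child in node.child_nodes():
            if child.is_leaf():
                obs = tips[child.taxon.label]
                contribs.append(np.array([mac_cost(s, obs) for s in states]))
            else:
                cvec = up[child]
                contribs.append(
                    np.array(
                        [min(mac_cost(s, u) + cvec[j] for j, u in enumerate(states))
                         for s in states]
                    )
                )
        for child, contrib in zip(node.child_nodes(), contribs):
            if child.is_leaf():
                continue
            rest = up[node] + down[node] - contrib
            down[child] = np.array(
                [
                    min(rest[i] + mac_cost(states[i], u) for i in range(n_s))
                    for u in states
                ]
            )

    gains_range, losses_range = _gain_loss_extremes(tree, tips, states, global_min)
    return MACResult(
        min_total_changes=global_min,
        node_states=node_states,
        gains_range=gains_range,
        losses_range=losses_range,
        states=states,
    )


def _gains(parent: int, child: int) -> int:
    return bin(child & ~parent).count("1")


def _gain_loss_extremes(tree, tips, states, global_min):
    """DP over (state, cost) tracking min/max gains among all MPRs."""
    t = tree.dendropy_tree

    def leaf_options(s, obs):
        return {mac_cost(s, obs): (_gains(s, obs), _gains(s, obs))}

    tab: dict = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            continue
        per_state = []
        for s in states:
            acc = {0: (0, 0)}
            for child in node.child_nodes():
                if child.is_leaf():
                    opts = leaf_options(s, tips[child.taxon.label])
                else:
                    opts = {}
                    for u, sub in zip(states, tab[child]):
                        ec, eg = mac_cost(s, u), _gains(s, u)
                        for c, (gmin, gmax) in sub.items():
                            cc = c + ec
                            if cc > global_min:
                                continue
                            lo, hi = eg + gmin, eg + gmax
                            if cc in opts:
                                olo, ohi = opts[cc]
                                opts[cc] = (min(olo, lo), max(ohi, hi))
                            else:
                                opts[cc] = (lo, hi)
                nxt = {}
                for c1, (a1, b1) in acc.items():
                    for c2, (a2, b2) in opts.items():
                        c = c1 + c2
                        if c > global_min:
                            continue
                        lo, hi = a1 + a2, b1 + b2
                        if c in nxt:
                            olo, ohi = nxt[c]
                            nxt[c] = (min(olo, lo), max(ohi, hi))
                        else:
                            nxt[c] = (lo, hi)
                acc = nxt
            per_state.append(acc)
        tab[node] = per_state

    gmin, gmax = INF, -INF
    for acc in tab[t.seed_node]:
        if global_min in acc:
            lo, hi = acc[global_min]
            gmin, gmax = min(gmin, lo), max(gmax, hi)
    gmin, gmax = int(gmin), int(gmax)
    return (gmin, gmax), (global_min - gmax, global_min - gmin)


def mac_change_bounds(result: MACResult) -> tuple:
    """(min_gains, max_gains, min_losses, max_losses) over all MPRs."""
    return (*result.gains_range, *result.losses_range)


# ---------------------------------------------------------------------------
# DEC


def dec_rate_matrix(sys: AreaSystem, p: DECParams):
    """Anagenetic rate matrix over occupied ranges plus the null range.

    Returns ``(Q, states)`` where ``states`` is ``enumerate_states(sys)``
    and the null range occupies the final row/column.  Rows sum to zero;
    the null range is absorbing.
    """
    states = enumerate_states(sys)
    idx = {s: i for i, s in enumerate(states)}
    n = len(states) + 1  # + null
    null = n - 1
    Q = np.zeros((n, n))
    for s in states:
        i = idx[s]
        size = bin(s).count("1")
        for a in range(sys.n_areas):
            bit = 1 << a
            if not s & bit:  # dispersal into a new area
                target = s | bit
                if target in idx:
                    Q[i, idx[target]] += p.d * size
            else:  # extirpation of an occupied area
                target = s & ~bit
                Q[i, idx[target] if target else null] += p.e
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q, states


def _scenarios(s: int):
    """Equal-weight daughter-range pairs for parent range ``s``."""
    bits = [1 << i for i in range(s.bit_length()) if s >> i & 1]
    if len(bits) == 1:
        return [(s, s)]
    if len(bits) == 2:
        a, b = bits
        return [(a, b), (b, a), (a, s), (s, a), (b, s), (s, b)]
    raise ValueError("parent ranges above two areas are not modelled")


class _DECEngine:
    """Shared machinery: propagators per branch + pruning pass."""

    def __init__(self, tree: Chronogram, tips: dict, sys: AreaSystem):
        _check_tips(tree, tips)
        if not tree.is_binary():
            raise ValueError("DEC requires a binary tree")
        bad = {
            lab: sys.names(m)
            for lab, m in tips.items()
            if bin(m).count("1") > sys.max_range_size
        }
        if bad:
            raise ValueError(
                f"tip ranges exceed max_range_size={sys.max_range_size}: {bad}; "
                "recode the tips or raise max_range_size"
            )
        self.tree, self.tips, self.sys = tree, tips, sys
        self.states = enumerate_states(sys)
        self.idx = {s: i for i, s in enumerate(self.states)}
        self.n = len(self.states) + 1
        self.nodes = list(tree.dendropy_tree.postorder_node_iter())

    def set_params(self, p: DECParams):
        Q, _ = dec_rate_matrix(self.sys, p)
        self._props = {}
        # diagonalize once; fall back to expm if the reconstruction is poor
        use_eig = False
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            longest = max(
                (n.edge.length for n in self.nodes if n.parent_node is not None),
                default=1.0,
            )
            test = (V * np.exp(w * longest)) @ Vinv
            if np.allclose(test.imag, 0, atol=1e-9) and np.allclose(
                test.real, expm(Q * longest), atol=1e-10
            ):
                use_eig = True
                self._eig = (w, V, Vinv)
        except np.linalg.LinAlgError:
            pass
        self._Q = Q
        self._use_eig = use_eig

    def propagator(self, t: float) -> np.ndarray:
        if t == 0:
            return np.eye(self.n)
        key = t
        P = self._props.get(key)
        if P is None:
            if self._use_eig:
                w, V, Vinv = self._eig
                P = ((V * np.exp(w * t)) @ Vinv).real
            else:
                P = expm(self._Q * t)
            np.clip(P, 0.0, None, out=P)
            self._props[key] = P
        return P

    def tip_vector(self, label: str) -> np.ndarray:
        v = np.zeros(self.n)
        v[self.idx[self.tips[label]]] = 1.0
        return v

    def loglik(self, root_prior: str = "uniform", clamp: dict | None = None) -> float:
        """Pruning pass.  ``clamp`` maps node -> state mask to pin."""
        clamp = clamp or {}
        n_occ = len(self.states)
        logscale = 0.0
        partial: dict = {}
        for node in self.nodes:
            if node.is_leaf():
                L = self.tip_vector(node.taxon.label)
            else:
                c1, c2 = node.child_nodes()
                M1 = self.propagator(c1.edge.length) @ partial[c1]
                M2 = self.propagator(c2.edge.length) @ partial[c2]
                L = np.zeros(self.n)
                for s in self.states:
                    scen = _scenarios(s)
                    w = 1.0 / len(scen)
                    acc = 0.0
                    for da, db in scen:
                        acc += M1[self.idx[da]] * M2[self.idx[db]]
                    L[self.idx[s]] = w * acc
                L[-1] = M1[-1] * M2[-1]  # null stays null on both sides
            if node in clamp:
                mask_vec = np.zeros(self.n)
                i = self.idx[clamp[node]]
                mask_vec[i] = L[i]
                L = mask_vec
            m = L.max()
            if m <= 0:
                return -np.inf
            L = L / m
            logscale += np.log(m)
            partial[node] = L
        root = partial[self.nodes[-1]]
        if root_prior == "uniform":
            lik = root[:n_occ].sum() / n_occ
        else:
            raise ValueError(f"unknown root prior {root_prior!r}")
        if lik <= 0:
            return -np.inf
        return float(np.log(lik) + logscale)


def dec_loglik(
    tree: Chronogram,
    tips: dict,
    sys: AreaSystem,
    p: DECParams,
    root_prior: str = "uniform",
) -> float:
    """DEC log-likelihood of the tip ranges on an ultrametric tree.

    Returns ``-inf`` (not an exception) when the data have probability
    zero, e.g. discordant tips with ``d = 0``.
    """
    eng = _DECEngine(tree, tips, sys)
    eng.set_params(p)
    return eng.loglik(root_prior=root_prior)


@dataclass
class DECFit:
    d: float
    e: float
    loglik: float
    converged: bool = True


def dec_fit(
    tree: Chronogram,
    tips: dict,
    sys: AreaSystem,
    bounds=((1e-6, 10.0), (1e-8, 10.0)),
    n_starts: int = 4,
    root_prior: str = "uniform",
) -> DECFit:
    """Maximum-likelihood d and e by bounded quasi-Newton on log rates."""
    eng = _DECEngine(tree, tips, sys)

    def nll(x):
        eng.set_params(DECParams(d=float(np.exp(x[0])), e=float(np.exp(x[1]))))
        ll = eng.loglik(root_prior=root_prior)
        return -ll if np.isfinite(ll) else 1e10

    lb = [np.log(bounds[0][0]), np.log(bounds[1][0])]
    ub = [np.log(bounds[0][1]), np.log(bounds[1][1])]
    starts = [
        np.array([np.log(0.01), np.log(0.01)]),
        np.array([np.log(0.1), np.log(0.01)]),
        np.array([np.log(0.01), np.log(0.1)]),
        np.array([np.log(0.5), np.log(0.5)]),
    ][:n_starts]
    best, best_x, ok = INF, None, False
    for x0 in starts:
        res = minimize(
            nll, x0, method="L-BFGS-B", bounds=list(zip(lb, ub)),
            options={"maxiter": 200},
        )
        if res.fun < best:
            best, best_x, ok = res.fun, res.x, bool(res.success)
    if best_x is None or not np.isfinite(best):
        warnings.warn("DEC optimization failed to converge; using grid best")
        d, e, ll = dec_grid_scan(tree, tips, sys, root_prior=root_prior)
        return DECFit(d=d, e=e, loglik=ll, converged=False)
    return DECFit(
        d=float(np.exp(best_x[0])), e=float(np.exp(best_x[1])),
        loglik=-best, converged=ok,
    )


def dec_grid_scan(
    tree: Chronogram,
    tips: dict,
    sys: AreaSystem,
    n_grid: int = 20,
    bounds=((1e-6, 10.0), (1e-8, 10.0)),
    root_prior: str = "uniform",
):
    """Best (d, e, loglik) over an n_grid x n_grid log-spaced grid."""
    eng = _DECEngine(tree, tips, sys)
    ds = np.geomspace(bounds[0][0], bounds[0][1], n_grid)
    es = np.geomspace(bounds[1][0], bounds[1][1], n_grid)
    best = (None, None, -INF)
    for d in ds:
        for e in es:
            eng.set_params(DECParams(d=float(d), e=float(e)))
            ll = eng.loglik(root_prior=root_prior)
            if ll > best[2]:
                best = (float(d), float(e), ll)
    return best


def dec_node_ranges(
    tree: Chronogram,
    tips: dict,
    sys: AreaSystem,
    p: DECParams,
    window: float = 2.0,
    root_prior: str = "uniform",
) -> dict:
    """Per-internal-node candidate ranges within ``window`` log-units.

    For each internal node the global likelihood is recomputed with each
    candidate state clamped at that node; candidates whose log-likelihood
    falls within ``window`` units of the node's best clamped value are
    returned as ``[(mask, delta_lnL), ...]`` sorted by increasing delta
    (ties by state order).
    """
    eng = _DECEngine(tree, tips, sys)
    eng.set_params(p)
    out = {}
    for node in eng.nodes:
        if node.is_leaf():
            continue
        lls = []
        for s in eng.states:
            ll = eng.loglik(root_prior=root_prior, clamp={node: s})
            lls.append((s, ll))
        best = max(ll for _, ll in lls)
        cands = [
            (s, best - ll) for s, ll in lls
            if np.isfinite(ll) and best - ll <= window
        ]
        cands.sort(key=lambda x: (x[1], eng.idx[x[0]]))
        out[node] = cands
    return out


def count_dispersals(tree: Chronogram, node_ranges: dict) -> list:
    """Dispersal events implied by one best range per node.

    ``node_ranges`` maps every node (internal and tip) to a single range
    bitmask.  An event ``(child_node, area_bit)`` is recorded on branch
    (u, v) for each area in v's range absent from u's; losses at
    cladogenesis are range inheritance, not dispersal.
    """
    events = []
    for node in tree.dendropy_tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        gained = node_ranges[node] & ~node_ranges[parent]
        for i in range(gained.bit_length()):
            if gained >> i & 1:
                events.append((node, 1 << i))
    return events


def read_tip_areas(path, sys: AreaSystem) -> dict:
    """Tip-area CSV ``taxon,areas`` with semicolon-separated area names."""
    import csv

    out = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or row[0].strip().lower() == "taxon":
                continue
            taxon, areas = row[0].strip(), row[1].strip()
            out[taxon] = sys.mask([a.strip() for a in areas.split(";") if a.strip()])
    return out
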