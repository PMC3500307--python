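"""Seeded generators for every input the pipeline consumes.

Chronograms under (piecewise-constant) birth-death processes with
present-day sampling, tip ranges evolved under the DEC process, fossil
species ranges around a known diversity history, and sparse supermatrix
occupancy patterns.  Every generator takes either an integer ``seed`` or
a ``numpy.random.Generator``; integer seeds are combined with a fixed
per-generator stream id, so adding a generator never perturbs the
streams of existing ones, and identical seeds give identical output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .areas import AreaSystem, DECParams, _scenarios, dec_rate_matrix
from .tree import Chronogram, parse_newick

__all__ = [
    "sim_bd_tree",
    "sim_bd_tree_conditioned",
    "sim_dec_tips",
    "sim_species_durations",
    "sim_fossil_ranges",
    "sim_occupancy_matrix",
]

# fixed stream ids, one per generator
_STREAMS = {"bd": 1, "dec": 2, "fossil": 3, "matrix": 4, "durations": 5}


def _rng(seed, stream: str) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class DECSim:
    """Output of :func:`sim_dec_tips`."""

    tips: dict
    node_ranges: dict
    dispersals: list
    start_ranges: dict


@dataclass
class _Lineage:
    born: float  # age Ma (larger = older)
    end: float = 0.0  # death age, split age, or 0 if extant
    fate: str = "extant"  # extant | extinct | split
    children: tuple = ()
    sampled: bool = False


@dataclass
class BDEventLog:
    """Bookkeeping from one birth-death simulation."""

    branching_ages: np.ndarray  # of the reconstructed sampled tree
    n_extant: int
    n_sampled: int
    lineages: list = field(default_factory=list, repr=False)

    def species_durations(self):
        """(origin, end) age pairs, one per lineage segment (budding species)."""
        return [(l.born, l.end) for l in self.lineages]


def _epoch_rates(age, shift_times, lambdas, mus):
    i = int(np.searchsorted(shift_times, age, side="right"))
    return lambdas[i], mus[i]


def sim_bd_tree(
    lambda_,
    mu=0.0,
    rho: float = 1.0,
    age: float = 10.0,
    shift_times=(),
    seed=0,
    max_retries: int = 1000,
    require_both_root_lineages: bool = False,
):
    """Forward birth-death simulation, returning the reconstructed tree.

    ``lambda_`` and ``mu`` are scalars (constant rates) or sequences with
    one entry per epoch, youngest epoch first, with epochs delimited by
    ``shift_times`` (ascending ages, matching
    :class:`~primdiv.shifts.BDShiftModel`).  The process starts with the
    two lineages of the root split at ``age`` Ma; rho-sampling removes
    each extant tip independently at the present.  Resimulates (up to
    ``max_retries``) until at least two sampled tips remain — and, if
    ``require_both_root_lineages``, until both root lineages have sampled
    descendants so the reconstructed root age equals ``age`` exactly.

    Returns ``(Chronogram, BDEventLog)``.
    """
    lambdas = tuple(np.atleast_1d(np.asarray(lambda_, dtype=float)))
    mus_ = np.atleast_1d(np.asarray(mu, dtype=float))
    if len(mus_) == 1 and len(lambdas) > 1:
        mus_ = np.repeat(mus_, len(lambdas))
    mus = tuple(mus_)
    shift_times = tuple(shift_times)
    if len(lambdas) != len(shift_times) + 1:
        raise ValueError("need one lambda per epoch")
    if min(lambdas) <= 0 or min(mus) < 0:
        raise ValueError("need lambda > 0 and mu >= 0")
    rng = _rng(seed, "bd")

    for _ in range(max_retries):
        result = _simulate_once(lambdas, mus, shift_times, rho, age, rng)
        if result is None:
            continue
        newick, log, roots_ok = result
        if require_both_root_lineages and not roots_ok:
            continue
        tree = parse_newick(newick)
        log.branching_ages = tree.internal_node_ages()
        return tree, log
    raise RuntimeError(
        f"no surviving tree in {max_retries} attempts; rates too extinction-heavy?"
    )


def _simulate_once(lambdas, mus, shift_times, rho, root_age, rng):
    alive: list[_Lineage] = [_Lineage(born=root_age), _Lineage(born=root_age)]
    root_pair = tuple(alive)
    all_lineages = list(alive)
    t = root_age  # current age, decreasing to 0
    # piecewise-constant thinning: step epoch by epoch
    while alive and t > 0:
        lam, mu_ = _epoch_rates(t - 1e-12, shift_times, lambdas, mus)
        next_bound = 0.0
        for s in reversed(shift_times):
            if s < t - 1e-12:
                next_bound = s
                break
        total = len(alive) * (lam + mu_)
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        if t - wait <= next_bound:
            t = next_bound
            if next_bound == 0.0:
                break
            continue
        t -= wait
        idx = rng.integers(len(alive))
        lin = alive[idx]
        if rng.random() < lam / (lam + mu_):
            lin.fate, lin.end = "split", t
            kids = (_Lineage(born=t), _Lineage(born=t))
            lin.children = kids
            alive[idx] = kids[0]
            alive.append(kids[1])
            all_lineages.extend(kids)
        else:
            lin.fate, lin.end = "extinct", t
            alive.pop(idx)
    n_extant = len(alive)
    for lin in alive:
        lin.sampled = bool(rng.random() < rho)
    sampled = [l for l in alive if l.sampled]
    if len(sampled) < 2:
        return None

    tip_counter = iter(range(1, len(sampled) + 1))

    def build(lin):
        """(newick fragment, bottom age) of the reconstructed subtree, or None."""
        while lin.fate == "split":
            kept = [c for c in lin.children if _has_sampled(c)]
            if len(kept) == 2:
                (s1, a1), (s2, a2) = build(kept[0]), build(kept[1])
                return (
                    f"({s1}:{lin.end - a1!r},{s2}:{lin.end - a2!r})",
                    lin.end,
                )
            if len(kept) == 1:
                lin = kept[0]
                continue
            return None
        if lin.fate == "extant" and lin.sampled:
            return f"t{next(tip_counter)}", 0.0
        return None

    parts = [build(l) for l in root_pair if _has_sampled(l)]
    parts = [p for p in parts if p is not None]
    roots_ok = len(parts) == 2
    if roots_ok:
        (s1, a1), (s2, a2) = parts
        newick = f"({s1}:{root_age - a1!r},{s2}:{root_age - a2!r});"
    else:
        frag, top = parts[0]
        if not frag.startswith("("):
            return None  # single sampled tip: no tree
        newick = frag + ";"
    log = BDEventLog(
        branching_ages=np.array([]),
        n_extant=n_extant,
        n_sampled=len(sampled),
        lineages=all_lineages,
    )
    return newick, log, roots_ok


def _has_sampled(lin) -> bool:
    stack = [lin]
    while stack:
        l = stack.pop()
        if l.fate == "split":
            stack.extend(l.children)
        elif l.sampled:
            return True
    return False


def sim_bd_tree_conditioned(
    lambda_,
    mu,
    rho,
    n_tips: int,
    age: float,
    rng=None,
    seed=0,
    max_retries: int = 100_000,
) -> Chronogram:
    """Constant-rate tree conditioned on sampled tip count and root age.

    Rejection sampling on the forward simulator: exact tip count for
    n <= 50, within +/-10 percent above that.
    """
    rng = _rng(rng if rng is not None else seed, "bd")
    tol = 0 if n_tips <= 50 else max(1, int(round(0.1 * n_tips)))
    for _ in range(max_retries):
        try:
            tree, _ = sim_bd_tree(
                lambda_, mu, rho, age=age, seed=rng, max_retries=50,
                require_both_root_lineages=True,
            )
        except RuntimeError:
            continue
        if abs(tree.n_tips - n_tips) <= tol:
            return tree
    raise RuntimeError(
        f"could not hit {n_tips} tips at root age {age} in {max_retries} tries"
    )


# ---------------------------------------------------------------------------
# DEC tip simulation


def sim_dec_tips(
    tree: Chronogram,
    d: float,
    e: float,
    sys: AreaSystem,
    seed=0,
    root_range: int | None = None,
    max_branch_retries: int = 200,
):
    """Gillespie simulation of the DEC process along a chronogram.

    Returns a :class:`DECSim` with ``tips`` (tip label -> range bitmask),
    ``node_ranges`` (every dendropy node -> its true range at the node),
    ``dispersals`` (``(node, area_bit)`` anagenetic gains on the branch
    subtending each node) and ``start_ranges`` (the range each branch
    inherited at its parent's cladogenesis, so that per branch the
    logged gains are exactly ``end_range & ~start_range`` plus any
    gained-then-lost areas when e > 0).  Branches whose lineage hits the
    null range are resimulated (bounded retries).
    """
    rng = _rng(seed, "dec")
    Q, states = dec_rate_matrix(sys, DECParams(d=d, e=e))
    idx = {s: i for i, s in enumerate(states)}
    ages = tree.node_ages()
    root = tree.dendropy_tree.seed_node
    if root_range is None:
        root_range = states[rng.integers(len(states))]
    node_ranges = {root: root_range}
    start_ranges: dict = {}
    dispersals = []

    def evolve(state, duration):
        """One branch; returns (end state, gains) or None on null absorption."""
        t, s, gains = 0.0, state, []
        while True:
            i = idx[s]
            rates = Q[i].copy()
            rates[i] = 0.0
            total = rates.sum()
            if total <= 0:
                return s, gains
            wait = rng.exponential(1.0 / total)
            if t + wait > duration:
                return s, gains
            t += wait
            j = rng.choice(len(rates), p=rates / total)
            if j == len(states):  # null range: lineage locally dead
                return None
            new = states[j]
            gained = new & ~s
            if gained:
                gains.append(gained)
            s = new

    for node in tree.dendropy_tree.preorder_node_iter():
        if node is root:
            pass
        else:
            start = node_ranges[node]  # state at the top of the branch
            start_ranges[node] = start
            dur = node.edge.length
            for _ in range(max_branch_retries):
                out = evolve(start, dur)
                if out is not None:
                    break
            else:
                raise RuntimeError(
                    "branch kept hitting the null range; lower e or raise d"
                )
            s_end, gains = out
            node_ranges[node] = s_end
            dispersals.extend((node, g) for g in gains)
        # hand ranges down at cladogenesis
        kids = node.child_nodes()
        if kids:
            scen = _scenarios(node_ranges[node])
            da, db = scen[rng.integers(len(scen))]
            node_ranges[kids[0]], node_ranges[kids[1]] = da, db

    tips = {
        leaf.taxon.label: node_ranges[leaf]
        for leaf in tree.dendropy_tree.leaf_node_iter()
    }
    return DECSim(tips, node_ranges, dispersals, start_ranges)


# ---------------------------------------------------------------------------
# fossil ranges


def sim_species_durations(
    n_species: int = 150,
    old: float = 66.0,
    turnover: float = 0.15,
    pulse_age: float | None = None,
    pulse_kill_frac: float = 0.0,
    seed=0,
):
    """True species durations: uniform origins, exponential lifetimes.

    An optional extinction pulse truncates (with probability
    ``pulse_kill_frac``) every species alive at ``pulse_age``.
    Returns a list of (origin, end) age pairs.
    """
    rng = _rng(seed, "durations")
    origins = rng.uniform(0.0, old, n_species)
    lifetimes = rng.exponential(1.0 / turnover, n_species)
    durations = []
    for o, life in zip(origins, lifetimes):
        end = max(o - life, 0.0)
        if (
            pulse_age is not None
            and o >= pulse_age >= end
            and rng.random() < pulse_kill_frac
        ):
            end = pulse_age
        durations.append((float(o), float(end)))
    return durations


def sim_fossil_ranges(
    durations,
    preservation: float | None = 2.0,
    indet_prob: float = 0.0,
    seed=0,
) -> pd.DataFrame:
    """Occurrence table with per-species (first, last) inside true durations.

    ``preservation`` is the rate (per Myr) of an exponential erosion of
    the observed range at each end; None means perfect preservation
    (observed range = true duration).  With probability ``indet_prob`` a
    species-indeterminate record is added in the same genus, spanning a
    sub-range — material that range pruning should discard.
    """
    rng = _rng(seed, "fossil")
    rows = []
    for i, (origin, end) in enumerate(durations):
        span = origin - end
        if preservation is None:
            first, last = origin, end
        else:
            a = min(rng.exponential(1.0 / preservation), 0.499 * span)
            b = min(rng.exponential(1.0 / preservation), 0.499 * span)
            first, last = origin - a, end + b
        genus = f"Genus{i:04d}"
        rows.append(
            {"genus": genus, "species": f"species{i:04d}",
             "first_ma": first, "last_ma": last}
        )
        if rng.random() < indet_prob:
            mid = 0.5 * (first + last)
            rows.append(
                {"genus": genus, "species": "sp.",
                 "first_ma": first, "last_ma": mid}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# occupancy matrices


def sim_occupancy_matrix(
    n_taxa: int = 40,
    loci=tuple(("locus%d" % i, 400) for i in range(5)),
    fill: float = 0.5,
    backbone_frac: float = 0.0,
    backbone_fill: float = 0.95,
    seed=0,
):
    """Sparse supermatrix: FASTA + partition text + planted presence mask.

    A ``backbone_frac`` fraction of taxa (exemplars with high gene
    completeness, as real supermatrices have) gets presence probability
    ``backbone_fill`` per locus; the rest get ``fill``.  Present cells
    are random nucleotides across the whole locus, absent cells are
    gaps, so realized percent-filled equals the mask's fill fraction.

    Returns ``(fasta_text, partition_text, mask)`` with ``mask`` the
    boolean (taxon x locus) presence grid.
    """
    rng = _rng(seed, "matrix")
    loci = [(name, int(length)) for name, length in loci]
    n_loci = len(loci)
    n_backbone = int(round(backbone_frac * n_taxa))
    probs = np.full((n_taxa, n_loci), fill)
    probs[:n_backbone, :] = backbone_fill
    mask = rng.random((n_taxa, n_loci)) < probs
    # every taxon needs at least one locus to be a valid matrix row
    for i in range(n_taxa):
        if not mask[i].any():
            mask[i, rng.integers(n_loci)] = True

    fasta = io.StringIO()
    bases = np.array(list("ACGT"))
    for i in range(n_taxa):
        fasta.write(f">taxon{i:03d}\n")
        seq = []
        for j, (_, length) in enumerate(loci):
            if mask[i, j]:
                seq.append("".join(bases[rng.integers(0, 4, length)]))
            else:
                seq.append("-" * length)
        fasta.write("".join(seq) + "\n")
    parts = io.StringIO()
    pos = 1
    for name, length in loci:
        parts.write(f"DNA, {name} = {pos}-{pos + length - 1}\n")
        pos += length
    return fasta.getvalue(), parts.getvalue(), mask
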