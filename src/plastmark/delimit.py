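"""Poisson tree processes (PTP / mPTP) species delimitation.

A delimitation of a rooted tree is a set of *species roots*: pairwise
non-ancestral nodes whose subtrees cover all tips. Edges whose parent lies
strictly above every species root form the *speciation* class (this
includes each species root's own stem edge); edges strictly inside a
species root's subtree form that species' *coalescent* class. Branch
lengths within a class are modelled as i.i.d. Exponential draws, so the
profile log-likelihood of a class with ``n`` branches summing to ``s`` is
``n ln(n/s) - n`` at the MLE rate ``n/s``. The ``single`` model pools all
coalescent classes into one rate; the ``multi`` model (mPTP) gives each
species its own coalescent rate.

The ML search is a hill climb over node toggles (split/merge moves) from
both the one-species and the all-split states, followed by a likelihood
ratio test against the single-rate null; an exhaustive enumeration over
all antichain covers serves as the oracle for small trees. MCMC support
values are sampled by a Metropolis walker over the same move set with a
uniform prior, and the Average Support Value (ASV) is the mean MCMC
support of the ML delimitation's species roots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterator

import dendropy
import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateTreeError,
    RootingError,
    SizeError,
    TreeMismatchError,
)

__all__ = [
    "Delimitation",
    "McmcResult",
    "null_loglik",
    "brute_force_ml",
    "ml_delimitation",
    "mcmc_delimitation",
    "asv",
    "MIN_BRANCH_LENGTH",
]

#: Branches shorter than this (substitutions/site) carry no rate information
#: and are excluded from every likelihood (they would otherwise force
#: infinite rate estimates).
MIN_BRANCH_LENGTH = 1e-9

_TIE_TOL = 1e-10


@dataclass(frozen=True)
class Delimitation:
    """A species partition of the tips of a rooted tree.

    ``species_roots`` are the tip-label sets of the species-root clades
    (one per entity); ``lambda_coal`` is per-entity under the multi model
    (``None`` where a species has no coalescent branches).
    """

    species_roots: tuple[frozenset, ...]
    loglik: float
    model: str
    lambda_sp: float | None
    lambda_coal: tuple[float | None, ...]
    null_loglik: float | None = None
    lrt_stat: float | None = None
    lrt_df: int | None = None
    p_value: float | None = None

    @property
    def n_entities(self) -> int:
        return len(self.species_roots)

    @property
    def entities(self) -> tuple[frozenset, ...]:
        return self.species_roots


@dataclass(frozen=True)
class McmcResult:
    """Two-chain Metropolis sample of delimitations on one tree."""

    traces: tuple  # per chain: tuple of sampled states (tuple of clade keys)
    node_support: dict  # clade key (frozenset of tip labels) -> support
    asv: float
    ml: Delimitation
    chain_correlation: float
    seed: int
    steps: int
    chains: int
    burnin: float
    model: str

    def posterior_states(self) -> dict:
        """Post-burn-in pooled state frequencies keyed by sorted clade keys."""
        skip = int(self.burnin * self.steps)
        counts: dict = {}
        for trace in self.traces:
            for state in trace[skip:]:
                counts[state] = counts.get(state, 0) + 1
        total = sum(counts.values())
        return {k: v / total for k, v in counts.items()}


class _TreeIndex:
    """Array view of a rooted tree for fast repeated likelihood evaluation."""

    def __init__(self, tree: dendropy.Tree):
        if not tree.is_rooted:
            raise RootingError("delimitation requires a rooted tree")
        nodes = list(tree.postorder_node_iter())
        self.n = len(nodes)
        self._id = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n, -1, dtype=int)
        self.children: list[list[int]] = [[] for _ in range(self.n)]
        self.is_tip = np.zeros(self.n, dtype=bool)
        self.clade: list[frozenset] = [frozenset()] * self.n
        own_n = np.zeros(self.n, dtype=int)
        own_s = np.zeros(self.n, dtype=float)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = self._id[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                bl = nd.edge.length if nd.edge.length is not None else 0.0
                if bl < 0:
                    raise ValueError("negative branch length")
                if bl >= MIN_BRANCH_LENGTH:
                    own_n[i] = 1
                    own_s[i] = bl
            if nd.is_leaf():
                self.is_tip[i] = True
                self.clade[i] = frozenset([nd.taxon.label])
        for i in range(self.n):  # postorder: children before parents
            if not self.is_tip[i]:
                self.clade[i] = frozenset().union(
                    *(self.clade[c] for c in self.children[i])
                )
        self.root = self.n - 1
        self.own_n, self.own_s = own_n, own_s
        # subtree stats including the node's own stem edge
        self.incl_n = own_n.copy()
        self.incl_s = own_s.copy()
        for i in range(self.n):
            for c in self.children[i]:
                self.incl_n[i] += self.incl_n[c]
                self.incl_s[i] += self.incl_s[c]
        self.total_n = int(self.incl_n[self.root])
        self.total_s = float(self.incl_s[self.root])
        self.internal = [i for i in range(self.n) if not self.is_tip[i]]
        self.n_tips = int(self.is_tip.sum())
        self._finish_stats()

    def _finish_stats(self) -> None:
        """Per-node constants for O(1) toggle deltas in the hill climb.

        ``tc[v]``: profile log-likelihood of node v's coalescent class
        (edges strictly inside v); ``sc_n/sc_s[v]``: the stem edges of v's
        children (what moves between the speciation class and the
        coalescent side when v is toggled); ``dtc[v]``: coalescent-term
        change when v is split into its children.
        """
        n = self.n
        self.tc = np.zeros(n)
        self.sc_n = np.zeros(n, dtype=int)
        self.sc_s = np.zeros(n)
        self.dtc = np.zeros(n)
        for v in range(n):
            cn = int(self.incl_n[v] - self.own_n[v])
            cs = float(self.incl_s[v] - self.own_s[v])
            self.tc[v] = _class_ll(cn, cs)
        for v in range(n):
            if self.is_tip[v]:
                continue
            self.sc_n[v] = sum(self.own_n[c] for c in self.children[v])
            self.sc_s[v] = sum(self.own_s[c] for c in self.children[v])
            self.dtc[v] = sum(self.tc[c] for c in self.children[v]) - self.tc[v]

    def resampled_null(self, rng: np.random.Generator) -> "_TreeIndex":
        """Clone with measurable branch lengths redrawn i.i.d. Exp(1).

        Shares the topology arrays; edges below MIN_BRANCH_LENGTH stay
        excluded, preserving the observed measurable-edge pattern.
        """
        bs = object.__new__(_TreeIndex)
        for name in (
            "n", "parent", "children", "is_tip", "clade", "root",
            "internal", "n_tips", "own_n",
        ):
            setattr(bs, name, getattr(self, name))
        own_s = np.zeros(self.n)
        mask = self.own_n > 0
        own_s[mask] = rng.exponential(1.0, size=int(mask.sum()))
        bs.own_s = own_s
        bs.incl_n = self.incl_n
        incl_s = own_s.copy()
        for i in range(self.n):
            for c in self.children[i]:
                incl_s[i] += incl_s[c]
        bs.incl_s = incl_s
        bs.total_n = self.total_n
        bs.total_s = float(incl_s[self.root])
        bs._finish_stats()
        return bs

    # -- delimitation states -------------------------------------------------
    # A state S is the ancestor-closed set of "speciation nodes": internal
    # nodes lying strictly above every species root. S is empty (one
    # species) or contains the root; species roots are the nodes just below
    # S's lower boundary.

    def species_roots(self, S: frozenset) -> tuple[int, ...]:
        if not S:
            return (self.root,)
        return tuple(
            v
            for v in range(self.n)
            if v not in S and self.parent[v] >= 0 and self.parent[v] in S
        )

    def valid_toggle(self, S: frozenset, v: int) -> bool:
        """Can node v be added to / removed from S keeping closure?"""
        if self.is_tip[v]:
            return False
        if v in S:
            return not any(c in S for c in self.children[v])
        return v == self.root or self.parent[v] in S

    def class_stats(self, S: frozenset):
        """(speciation (n, s), per-species coalescent [(n, s), ...], roots)."""
        roots = self.species_roots(S)
        coal = [
            (
                int(self.incl_n[r] - self.own_n[r]),
                float(self.incl_s[r] - self.own_s[r]),
            )
            for r in roots
        ]
        cn = sum(n for n, _ in coal)
        cs = sum(s for _, s in coal)
        return (self.total_n - cn, self.total_s - cs), coal, roots

    def loglik(self, S: frozenset, model: str) -> float:
        (sn, ss), coal, _ = self.class_stats(S)
        ll = _class_ll(sn, ss)
        if model == "single":
            ll += _class_ll(sum(n for n, _ in coal), sum(s for _, s in coal))
        else:
            for n, s in coal:
                ll += _class_ll(n, s)
        return ll

    def free_params(self, S: frozenset, model: str) -> int:
        (sn, _), coal, _ = self.class_stats(S)
        k = 1 if sn > 0 else 0
        if model == "single":
            k += 1 if sum(n for n, _ in coal) > 0 else 0
        else:
            k += sum(1 for n, _ in coal if n > 0)
        return k

    def delimitation(self, S: frozenset, model: str) -> Delimitation:
        (sn, ss), coal, roots = self.class_stats(S)
        lam_sp = sn / ss if sn > 0 else None
        lam_coal = tuple(n / s if n > 0 else None for n, s in coal)
        if model == "single":
            n = sum(x for x, _ in coal)
            s = sum(x for _, x in coal)
            pooled = n / s if n > 0 else None
            lam_coal = tuple(pooled for _ in coal)
        order = np.argsort([min(self.clade[r]) for r in roots])
        return Delimitation(
            species_roots=tuple(self.clade[roots[i]] for i in order),
            loglik=self.loglik(S, model),
            model=model,
            lambda_sp=lam_sp,
            lambda_coal=tuple(lam_coal[i] for i in order),
        )


def _class_ll(n: int, s: float) -> float:
    """Profile log-likelihood of n exponential branches summing to s."""
    if n == 0:
        return 0.0
    return n * (math.log(n / s) - 1.0)


def _index(tree) -> _TreeIndex:
    return tree if isinstance(tree, _TreeIndex) else _TreeIndex(tree)


def null_loglik(tree) -> tuple[float, float]:
    """Single-class null: all branches one exponential rate.

    Returns ``(loglik, rate)`` with ``loglik = n ln(n/s) - n`` over the n
    branches of length >= MIN_BRANCH_LENGTH summing to s.
    """
    idx = _index(tree)
    if idx.total_n == 0:
        raise DegenerateTreeError(
            "no branches above the minimum measurable length"
        )
    lam = idx.total_n / idx.total_s
    return _class_ll(idx.total_n, idx.total_s), lam


def _enumerate_states(idx: _TreeIndex) -> Iterator[frozenset]:
    """All valid delimitation states (antichain covers of the tips)."""

    def options(v: int) -> list[frozenset]:
        # S-fragments for the subtree of v, given v's parent is in S
        out = [frozenset()]
        if not idx.is_tip[v]:
            for combo in product(*(options(c) for c in idx.children[v])):
                out.append(frozenset([v]).union(*combo))
        return out

    yield frozenset()
    if not idx.is_tip[idx.root]:
        for combo in product(*(options(c) for c in idx.children[idx.root])):
            yield frozenset([idx.root]).union(*combo)


def _state_key(idx: _TreeIndex, S: frozenset) -> tuple:
    return tuple(
        sorted(
            (sorted(idx.clade[r]) for r in idx.species_roots(S)),
        )
    )


def _pick_best(idx: _TreeIndex, states, model: str) -> tuple[frozenset, float]:
    best_S, best_ll, best_k, best_key = None, -math.inf, None, None
    for S in states:
        ll = idx.loglik(S, model)
        k = len(idx.species_roots(S))
        if ll > best_ll + _TIE_TOL:
            better = True
        elif ll >= best_ll - _TIE_TOL:
            key = _state_key(idx, S)
            better = k < best_k or (k == best_k and key < best_key)
        else:
            better = False
        if better:
            best_S, best_ll, best_k = S, ll, k
            best_key = _state_key(idx, S)
    return best_S, best_ll


#: Monte-Carlo resamples for the likelihood-ratio test's null distribution.
LRT_RESAMPLES = 199


def _cheap_best_ll(idx: _TreeIndex, model: str) -> float:
    """Best log-likelihood from plain two-start hill climbs (the screening
    statistic used identically on observed and null-resampled trees)."""
    s1 = _hill_climb(idx, frozenset(), model)
    s2 = _hill_climb(idx, frozenset(idx.internal), model)
    return max(idx.loglik(s1, model), idx.loglik(s2, model))


def _apply_lrt(
    idx: _TreeIndex,
    S: frozenset,
    model: str,
    alpha: float,
    n_boot: int = LRT_RESAMPLES,
):
    """Monte-Carlo LRT of delimitation structure against the one-rate null.

    Under the null all measurable branches are i.i.d. exponential, and the
    log-likelihood *difference* is invariant to rescaling branch lengths,
    so the null distribution of the statistic depends on the topology
    only. The reference is built by redrawing measurable branch lengths
    from Exp(1) on the same topology and re-running the same cheap search;
    p = (1 + #exceedances)/(B + 1). Sampling stops early once rejection at
    ``alpha`` is impossible. Returns (S_final, stat, df, p); df (free rate
    parameters of the alternative minus one) is reported for reference.
    """
    ll_null, _ = null_loglik(idx)
    stat = max(0.0, 2.0 * (_cheap_best_ll(idx, model) - ll_null))
    df = max(0, idx.free_params(S, model) - 1)
    if df == 0 or stat <= _TIE_TOL:
        return frozenset(), stat, df, 1.0
    rng = np.random.default_rng(0)
    exceed = 0
    done = 0
    for _ in range(n_boot):
        bs = idx.resampled_null(rng)
        tb = max(0.0, 2.0 * (_cheap_best_ll(bs, model) - null_loglik(bs)[0]))
        exceed += tb >= stat - 1e-12
        done += 1
        if (1 + exceed) / (n_boot + 1) >= alpha:
            break
    p = (1 + exceed) / (done + 1)
    if p >= alpha:
        return frozenset(), stat, df, p
    return S, stat, df, p


def _finalize(
    idx: _TreeIndex, S: frozenset, model: str, alpha: float | None
) -> Delimitation:
    ll_null, _ = null_loglik(idx)
    stat = df = p = None
    if alpha is not None:
        S, stat, df, p = _apply_lrt(idx, S, model, alpha)
    d = idx.delimitation(S, model)
    return Delimitation(
        species_roots=d.species_roots,
        loglik=d.loglik,
        model=d.model,
        lambda_sp=d.lambda_sp,
        lambda_coal=d.lambda_coal,
        null_loglik=ll_null,
        lrt_stat=stat,
        lrt_df=df,
        p_value=p,
    )


def brute_force_ml(
    tree, model: str = "multi", alpha: float | None = 0.01, max_tips: int = 12
) -> Delimitation:
    """Exhaustive ML delimitation by enumerating every antichain cover.

    Feasible only for small trees (the state count grows quickly with
    balanced shape); ties are broken toward fewer entities.
    """
    idx = _index(tree)
    if idx.n_tips > max_tips:
        raise SizeError(
            f"{idx.n_tips} tips exceeds enumeration bound {max_tips}"
        )
    best_S, _ = _pick_best(idx, _enumerate_states(idx), model)
    return _finalize(idx, best_S, model, alpha)


def _hill_climb(idx: _TreeIndex, S0: frozenset, model: str) -> frozenset:
    """Best-improvement climb over node toggles, O(1) per candidate move.

    Per-species coalescent statistics are per-node constants, so a toggle
    at v only changes the speciation class (by the stem edges of v's
    children) and, for the single model, the pooled coalescent class.
    """
    S = set(S0)
    single = model == "single"
    in_S_children = [0] * idx.n  # children of each node currently in S
    for v in S:
        p = idx.parent[v]
        if p >= 0:
            in_S_children[p] += 1
    # speciation-class and pooled-coalescent stats for the current state
    roots = idx.species_roots(frozenset(S))
    cn = sum(int(idx.incl_n[r] - idx.own_n[r]) for r in roots)
    cs = sum(float(idx.incl_s[r] - idx.own_s[r]) for r in roots)
    sp_n, sp_s = idx.total_n - cn, idx.total_s - cs
    sp_term = _class_ll(sp_n, sp_s)
    coal_term = _class_ll(cn, cs)  # used by the single model only

    while True:
        best_v, best_gain = None, _TIE_TOL
        for v in idx.internal:
            if v in S:
                if in_S_children[v]:
                    continue
                dn, ds = -idx.sc_n[v], -idx.sc_s[v]
                dcoal = -idx.dtc[v]
            else:
                p = idx.parent[v]
                if p >= 0 and p not in S:
                    continue
                dn, ds = idx.sc_n[v], idx.sc_s[v]
                dcoal = idx.dtc[v]
            gain = _class_ll(sp_n + dn, sp_s + ds) - sp_term
            if single:
                gain += _class_ll(cn - dn, cs - ds) - coal_term
            else:
                gain += dcoal
            if gain > best_gain:
                best_v, best_gain = v, gain
        if best_v is None:
            return frozenset(S)
        v = best_v
        if v in S:
            S.discard(v)
            dn, ds = -idx.sc_n[v], -idx.sc_s[v]
            dpar = -1
        else:
            S.add(v)
            dn, ds = idx.sc_n[v], idx.sc_s[v]
            dpar = 1
        p = idx.parent[v]
        if p >= 0:
            in_S_children[p] += dpar
        sp_n += dn
        sp_s += ds
        cn -= dn
        cs -= ds
        sp_term = _class_ll(sp_n, sp_s)
        coal_term = _class_ll(cn, cs)


def _toggled(S: frozenset, v: int) -> frozenset:
    return S - {v} if v in S else S | {v}


def _local_search(idx: _TreeIndex, S0: frozenset, model: str) -> frozenset:
    """Hill climb with escape repair.

    From each local optimum, re-climb from every one-toggle neighbor; on
    small trees (<= 24 internal nodes) also from every two-toggle
    neighbor. Repeats until no escape improves the likelihood.
    """
    deep = len(idx.internal) <= 24
    S = _hill_climb(idx, S0, model)
    ll = idx.loglik(S, model)
    improved = True
    while improved:
        improved = False
        for v in idx.internal:
            if not idx.valid_toggle(S, v):
                continue
            S1 = _toggled(S, v)
            S2 = _hill_climb(idx, S1, model)
            ll2 = idx.loglik(S2, model)
            if ll2 > ll + _TIE_TOL:
                S, ll = S2, ll2
                improved = True
                break
            if not deep:
                continue
            for w in idx.internal:
                if w == v or not idx.valid_toggle(S1, w):
                    continue
                S3 = _hill_climb(idx, _toggled(S1, w), model)
                ll3 = idx.loglik(S3, model)
                if ll3 > ll + _TIE_TOL:
                    S, ll = S3, ll3
                    improved = True
                    break
            if improved:
                break
    return S


def ml_delimitation(
    tree, model: str = "multi", alpha: float | None = 0.01
) -> Delimitation:
    """Heuristic ML delimitation with a likelihood ratio test at ``alpha``.

    Greedy top-down splitting with hill-climbing repair: climb over
    split/merge node toggles from the one-species state and from the fully
    split state, escape local optima by re-climbing from each one-toggle
    neighbor, and keep the better optimum (ties go to fewer entities).
    With ``alpha=None`` the LRT is skipped and the raw ML delimitation is
    returned.
    """
    if model not in ("single", "multi"):
        raise ValueError(f"unknown model {model!r}")
    idx = _index(tree)
    starts = [frozenset(), frozenset(idx.internal)]
    for v in idx.internal:
        # ancestor-closed path root..v: splits exactly along one lineage
        path = []
        u = v
        while u >= 0:
            path.append(u)
            u = int(idx.parent[u])
        starts.append(frozenset(path))
    candidates = {_local_search(idx, S0, model) for S0 in starts}
    best_S, _ = _pick_best(idx, candidates, model)
    return _finalize(idx, best_S, model, alpha)


def mcmc_delimitation(
    tree,
    steps: int,
    chains: int = 2,
    burnin: float = 0.10,
    seed: int = 0,
    model: str = "multi",
    alpha: float | None = 0.01,
) -> McmcResult:
    """Metropolis sampling of delimitations under a uniform prior.

    Each step picks a uniformly random internal node and proposes toggling
    it (merge a species root into its parent's entity, or split an entity
    at that node); invalid toggles leave the chain in place. Acceptance is
    ``min(1, exp(delta loglik))``. Per-node supports are the fraction of
    pooled post-burn-in samples in which the node is a species root, and
    the ASV is their mean over the ML delimitation's species roots.
    """
    if steps < 100:
        raise ConfigurationError(f"steps must be >= 100, got {steps}")
    if not (0.0 <= burnin < 1.0):
        raise ConfigurationError(f"burnin must be in [0, 1), got {burnin}")
    if chains < 1:
        raise ConfigurationError(f"chains must be >= 1, got {chains}")
    idx = _index(tree)
    ml = ml_delimitation(idx, model=model, alpha=alpha)
    internal = idx.internal
    K = len(internal)
    # cached per-state: loglik and the species-root clade keys
    cache: dict = {}

    def state_info(S: frozenset):
        info = cache.get(S)
        if info is None:
            roots = idx.species_roots(S)
            key = tuple(
                idx.clade[r]
                for r in sorted(roots, key=lambda r: min(idx.clade[r]))
            )
            info = (idx.loglik(S, model), key)
            cache[S] = info
        return info

    traces = []
    skip = int(burnin * steps)
    per_chain_counts = []
    for chain in range(chains):
        rng = np.random.default_rng([seed, chain])
        S = frozenset()
        ll, _ = state_info(S)
        trace = []
        counts: dict = {}
        for step in range(steps):
            v = internal[int(rng.integers(K))]
            if idx.valid_toggle(S, v):
                S2 = S - {v} if v in S else S | {v}
                ll2, _ = state_info(S2)
                if ll2 >= ll or rng.random() < math.exp(ll2 - ll):
                    S, ll = S2, ll2
            key = state_info(S)[1]
            trace.append(key)
            if step >= skip:
                counts[key] = counts.get(key, 0) + 1
        traces.append(tuple(trace))
        per_chain_counts.append(counts)

    all_clades = set(idx.clade[i] for i in range(idx.n))
    support_by_chain = []
    for counts in per_chain_counts:
        total = sum(counts.values())
        sup = {c: 0.0 for c in all_clades}
        for state, cnt in counts.items():
            for clade in state:
                sup[clade] += cnt
        support_by_chain.append({c: v / total for c, v in sup.items()})
    pooled_total = sum(sum(c.values()) for c in per_chain_counts)
    node_support = {c: 0.0 for c in all_clades}
    for counts in per_chain_counts:
        for state, cnt in counts.items():
            for clade in state:
                node_support[clade] += cnt
    node_support = {c: v / pooled_total for c, v in node_support.items()}

    if len(support_by_chain) >= 2:
        order = sorted(all_clades, key=lambda c: (len(c), sorted(c)))
        a = np.array([support_by_chain[0][c] for c in order])
        b = np.array([support_by_chain[1][c] for c in order])
        if a.std() == 0 or b.std() == 0:
            corr = 1.0 if np.allclose(a, b) else 0.0
        else:
            corr = float(np.corrcoef(a, b)[0, 1])
    else:
        corr = float("nan")

    asv_value = float(
        np.mean([node_support[c] for c in ml.species_roots])
    )
    return McmcResult(
        traces=tuple(traces),
        node_support=node_support,
        asv=asv_value,
        ml=ml,
        chain_correlation=corr,
        seed=seed,
        steps=steps,
        chains=chains,
        burnin=burnin,
        model=model,
    )


def asv(ml: Delimitation, mcmc: McmcResult) -> float:
    """Average Support Value: mean MCMC support of the ML species roots."""
    missing = [c for c in ml.species_roots if c not in mcmc.node_support]
    if missing:
        raise TreeMismatchError(
            "ML delimitation references clades absent from the MCMC tree"
        )
    return float(np.mean([mcmc.node_support[c] for c in ml.species_roots]))
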