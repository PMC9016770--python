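"""Mk (continuous-time Markov) habitat evolution on a phylogeny.

Three habitat states -- forest (0), intermediate (1), open (2) -- evolve
along branches under a 3x3 rate matrix Q with structure ER (1 free rate),
SYM (3) or ARD (6). Provides Felsenstein-pruning likelihoods, ML fitting
with LRT structure selection, marginal ancestral states, and stochastic
character mapping by joint node-state sampling plus uniformization bridges
along branches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import poisson

from .phylo import Phylogeny
from .selection import lrt

__all__ = [
    "STATES", "TransitionModel", "mk_loglik", "fit_mk",
    "ancestral_marginals", "stochastic_map", "summarize_maps",
    "StochasticMaps", "SimmapSummary", "read_trait_tsv",
]

STATES = ("forest", "intermediate", "open")
N_STATES = 3
_N_FREE = {"ER": 1, "SYM": 3, "ARD": 6}
# off-diagonal fill order for the 6-vector: (row, col)
_ARD_ORDER = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
_SYM_ORDER = [(0, 1), (0, 2), (1, 2)]


def build_q(structure: str, rates) -> np.ndarray:
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(rates < 0):
        raise ValueError("transition rates must be nonnegative")
    Q = np.zeros((3, 3))
    if structure == "ER":
        Q[:] = rates[0]
    elif structure == "SYM":
        for r, (i, j) in zip(rates, _SYM_ORDER):
            Q[i, j] = Q[j, i] = r
    elif structure == "ARD":
        for r, (i, j) in zip(rates, _ARD_ORDER):
            Q[i, j] = r
    else:
        raise ValueError(f"unknown structure {structure!r}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclass
class TransitionModel:
    structure: str
    Q: np.ndarray

    @property
    def n_free(self) -> int:
        return _N_FREE[self.structure]


def read_trait_tsv(path, tree: Phylogeny | None = None) -> dict[str, int]:
    """Read a taxon/habitat TSV; states must be forest|intermediate|open.

    If a tree is given, tip labels and table rows must match exactly.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.strip().lower(): c for c in df.columns}
    if "taxon" not in cols or "habitat" not in cols:
        raise ValueError(f"{path}: expected columns taxon, habitat")
    out = {}
    bad = []
    for _, row in df.iterrows():
        h = str(row[cols["habitat"]]).strip().lower()
        if h not in STATES:
            bad.append((row[cols["taxon"]], h))
        else:
            out[str(row[cols["taxon"]])] = STATES.index(h)
    if bad:
        raise ValueError(f"unrecognized habitat values: {bad[:5]}")
    if tree is not None:
        tips = set(tree.tip_labels)
        missing = tips - set(out)
        extra = set(out) - tips
        if missing or extra:
            raise ValueError(
                f"trait table / tree mismatch; missing={sorted(missing)[:5]}, "
                f"extra={sorted(extra)[:5]}")
    return out


def _node_index(tree: Phylogeny):
    nodes = list(tree.preorder())
    return nodes, {id(n): i for i, n in enumerate(nodes)}


def _tip_partials(tree, tip_states):
    missing = [t.label for t in tree.tips() if t.label not in tip_states]
    if missing:
        raise ValueError(f"tips without states: {missing[:10]}")


def _propagators(Q, nodes, index):
    """P(t) = expm(Q t) for every branch, via one eigendecomposition of Q
    (falls back to expm per branch if Q is defective)."""
    P = {}
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) > 1e10:
            raise np.linalg.LinAlgError
        for node in nodes:
            if node.parent is None:
                continue
            M = (V * np.exp(w * node.length)) @ Vinv
            P[index[id(node)]] = np.clip(M.real, 0.0, 1.0)
    except np.linalg.LinAlgError:
        for node in nodes:
            if node.parent is not None:
                P[index[id(node)]] = expm(Q * node.length)
    return P


def _down_pass(tree, tip_states, Q):
    """Partial likelihoods below each node, rescaled; returns (down, logscale, P)."""
    nodes, index = _node_index(tree)
    down = np.zeros((len(nodes), N_STATES))
    P = _propagators(Q, nodes, index)
    logscale = 0.0
    for node in tree.postorder():
        i = index[id(node)]
        if node.is_tip:
            down[i, tip_states[node.label]] = 1.0
        else:
            part = np.ones(N_STATES)
            for child in node.children:
                ci = index[id(child)]
                part = part * (P[ci] @ down[ci])
            s = part.sum()
            if s <= 0 or not np.isfinite(s):
                return down, -np.inf, P
            logscale += np.log(s)
            down[i] = part / s
    return down, logscale, P


def _root_weights(root_prior, down_root):
    if isinstance(root_prior, str):
        if root_prior == "equal":
            return np.full(N_STATES, 1.0 / N_STATES)
        if root_prior == "fitzjohn":
            s = down_root.sum()
            return down_root / s if s > 0 else np.full(N_STATES, 1.0 / N_STATES)
        raise ValueError(f"unknown root prior {root_prior!r}")
    w = np.asarray(root_prior, dtype=float)
    return w / w.sum()


def mk_loglik(tree: Phylogeny, tip_states: dict, Q: np.ndarray,
              root_prior="equal") -> float:
    """Felsenstein-pruning log-likelihood of tip states under rate matrix Q."""
    _tip_partials(tree, tip_states)
    down, logscale, _ = _down_pass(tree, tip_states, Q)
    if not np.isfinite(logscale):
        return -np.inf
    nodes, index = _node_index(tree)
    prior = _root_weights(root_prior, down[index[id(tree.root)]])
    L = float(prior @ down[index[id(tree.root)]])
    if L <= 0:
        return -np.inf
    return float(np.log(L) + logscale)


def fit_mk(tree: Phylogeny, tip_states: dict, root_prior="equal",
           n_starts: int = 3, seed: int = 0, alpha: float = 0.05):
    """ML fits of ER / SYM / ARD with LRT-based structure selection.

    Returns (best TransitionModel, LRT table DataFrame). ARD is preferred
    only if it beats both simpler structures at the given alpha; otherwise
    SYM if it beats ER; otherwise ER (parameter-parsimony tie-break).
    """
    _tip_partials(tree, tip_states)
    observed = {tip_states[t.label] for t in tree.tips()}
    if len(observed) < 2:
        warnings.warn("single observed state: returning ER with q -> 0")
        model = TransitionModel("ER", build_q("ER", [1e-9]))
        table = pd.DataFrame(
            [{"comparison": "degenerate", "chi2": 0.0, "df": 0, "p": 1.0}])
        return model, table

    rng = np.random.default_rng(seed)
    total_len = sum(n.length for n in tree.preorder())
    q_scale = max(len(tree.tips()) / max(total_len, 1e-9), 1e-3)
    fits = {}
    for structure in ("ER", "SYM", "ARD"):
        nf = _N_FREE[structure]

        def nll(logq, _s=structure):
            try:
                with np.errstate(all="ignore"):
                    ll = mk_loglik(tree, tip_states,
                                   build_q(_s, np.exp(logq)), root_prior)
                return -ll if np.isfinite(ll) else 1e10
            except (ValueError, FloatingPointError):
                return 1e10

        bounds = [(np.log(1e-9), np.log(1e3))] * nf
        best = None
        for i in range(n_starts):
            x0 = np.full(nf, np.log(q_scale))
            if i > 0:
                x0 = x0 + rng.normal(0, 1.0, nf)
            res = minimize(nll, x0, method="Nelder-Mead", bounds=bounds,
                           options={"xatol": 1e-6, "fatol": 1e-8,
                                    "maxiter": 3000})
            if best is None or res.fun < best.fun:
                best = res
        fits[structure] = (-best.fun, np.exp(best.x))

    rows = []
    for null, alt, df in (("ER", "ARD", 5), ("SYM", "ARD", 3), ("ER", "SYM", 2)):
        ll0, ll1 = fits[null][0], fits[alt][0]
        chi2, p = lrt(min(ll0, ll1 + 1e-9), ll1, df)
        rows.append({"comparison": f"{alt} vs {null}", "chi2": chi2,
                     "df": df, "p": p, "logL0": ll0, "logL1": ll1})
    table = pd.DataFrame(rows)
    p_ard_er = table.loc[0, "p"]
    p_ard_sym = table.loc[1, "p"]
    p_sym_er = table.loc[2, "p"]
    if p_ard_er < alpha and p_ard_sym < alpha:
        chosen = "ARD"
    elif p_sym_er < alpha:
        chosen = "SYM"
    else:
        chosen = "ER"
    model = TransitionModel(chosen, build_q(chosen, fits[chosen][1]))
    return model, table


def ancestral_marginals(tree: Phylogeny, tip_states: dict, Q: np.ndarray,
                        root_prior="equal") -> np.ndarray:
    """Marginal state probabilities at internal nodes.

    Rows align with ``tree.internal_nodes()`` order; each row sums to 1.
    Computed by the standard down-pass / up-pass decomposition.
    """
    _tip_partials(tree, tip_states)
    nodes, index = _node_index(tree)
    down, logscale, P = _down_pass(tree, tip_states, Q)
    up = np.zeros((len(nodes), N_STATES))
    ri = index[id(tree.root)]
    up[ri] = _root_weights(root_prior, down[ri])
    for node in tree.preorder():
        i = index[id(node)]
        for child in node.children:
            ci = index[id(child)]
            sib_term = np.ones(N_STATES)
            for sib in node.children:
                if sib is child:
                    continue
                si = index[id(sib)]
                sib_term = sib_term * (P[si] @ down[si])
            at_parent = up[i] * sib_term
            up[ci] = at_parent @ P[ci]
            s = up[ci].sum()
            if s > 0:
                up[ci] /= s
    out = []
    for node in tree.internal_nodes():
        i = index[id(node)]
        m = down[i] * up[i]
        out.append(m / m.sum())
    return np.array(out)


# -- stochastic mapping ------------------------------------------------------


@dataclass
class StochasticMaps:
    """A set of sampled character histories.

    node_states: (n_maps, n_nodes) states at every node, preorder indexing.
    branch_jumps: child-node-index -> (map_ids, counts, times, states) with
    ragged per-map jump records (times measured from the parent end of the
    branch; states are the states entered). Maps without records on a branch
    stay in the parent node's state for the whole branch.
    """

    tree: Phylogeny
    n_maps: int
    node_states: np.ndarray
    branch_jumps: dict = field(default_factory=dict)
    nodes: list = field(default_factory=list)

    def __len__(self) -> int:
        return self.n_maps

    def history(self, m: int) -> dict[int, list[tuple[int, float]]]:
        """Per-branch piecewise-constant history [(state, duration), ...]."""
        _, index = _node_index(self.tree)
        out = {}
        for ci, node in enumerate(self.nodes):
            if node.parent is None:
                continue
            t = node.length
            start = int(self.node_states[m, index[id(node.parent)]])
            recs = self.branch_jumps.get(ci)
            segs = []
            if recs is not None:
                map_ids, offsets, times, states = recs
                j = np.searchsorted(map_ids, m)
                if j < len(map_ids) and map_ids[j] == m:
                    lo, hi = offsets[j], offsets[j + 1]
                    prev_t, prev_s = 0.0, start
                    for tt, ss in zip(times[lo:hi], states[lo:hi]):
                        segs.append((prev_s, float(tt - prev_t)))
                        prev_t, prev_s = tt, int(ss)
                    segs.append((prev_s, float(t - prev_t)))
            if not segs:
                segs = [(start, float(t))]
            out[ci] = segs
        return out

    def __iter__(self):
        for m in range(self.n_maps):
            yield self.history(m)


def _sample_categorical(rng, probs):
    """Row-wise categorical sampling; probs (n, k) rows normalized."""
    c = np.cumsum(probs, axis=1)
    u = rng.random((probs.shape[0], 1)) * c[:, -1:]
    return (u > c).sum(axis=1)


def sample_node_states(tree: Phylogeny, tip_states: dict, Q: np.ndarray,
                       n_maps: int, seed: int, root_prior="equal") -> np.ndarray:
    """Joint draws of states at all nodes, (n_maps, n_nodes) preorder-indexed."""
    _tip_partials(tree, tip_states)
    nodes, index = _node_index(tree)
    down, logscale, P = _down_pass(tree, tip_states, Q)
    if not np.isfinite(logscale):
        raise ValueError("data have zero likelihood under Q")
    rng = np.random.default_rng(seed)
    states = np.zeros((n_maps, len(nodes)), dtype=np.int8)
    ri = index[id(tree.root)]
    w = _root_weights(root_prior, down[ri]) * down[ri]
    states[:, ri] = _sample_categorical(rng, np.tile(w / w.sum(), (n_maps, 1)))
    for node in tree.preorder():
        i = index[id(node)]
        for child in node.children:
            ci = index[id(child)]
            probs = P[ci][states[:, i]] * down[ci][None, :]
            states[:, ci] = _sample_categorical(rng, probs)
    return states


def stochastic_map(tree: Phylogeny, tip_states: dict, Q: np.ndarray,
                   n_maps: int, seed: int, root_prior="equal",
                   nmax_jumps: int = 400) -> StochasticMaps:
    """Sample full character histories conditional on tip states and Q.

    Node states are drawn from their joint conditional distribution; branch
    interiors are filled in by uniformization bridges (jump counts from the
    endpoint-conditioned Poisson mixture, then the virtual-jump chain, then
    uniform order-statistics times; self-jumps are discarded).
    """
    nodes, index = _node_index(tree)
    node_states = sample_node_states(tree, tip_states, Q, n_maps, seed,
                                     root_prior)
    rng = np.random.default_rng(seed + 1)
    omega = float(np.max(-np.diag(Q))) * 1.05 + 1e-12
    R = np.eye(N_STATES) + Q / omega

    branch_jumps = {}
    for ci, node in enumerate(nodes):
        if node.parent is None or node.length <= 0:
            continue
        t = node.length
        pi = index[id(node.parent)]
        a = node_states[:, pi].astype(int)
        b = node_states[:, ci].astype(int)
        mu_pois = omega * t
        nmax = int(poisson.ppf(1.0 - 1e-12, mu_pois)) + 2
        if nmax > nmax_jumps:
            raise RuntimeError(
                f"uniformization cap exceeded (need {nmax} > {nmax_jumps}); "
                "increase nmax_jumps")
        pois = poisson.pmf(np.arange(nmax + 1), mu_pois)
        Rpow = np.zeros((nmax + 1, N_STATES, N_STATES))
        Rpow[0] = np.eye(N_STATES)
        for k in range(1, nmax + 1):
            Rpow[k] = Rpow[k - 1] @ R
        Pt = expm(Q * t)

        # jump-count distribution per endpoint pair, sampled per map
        w_nab = pois[:, None, None] * Rpow          # (n, a, b)
        N = np.zeros(n_maps, dtype=int)
        for s0 in range(N_STATES):
            for s1 in range(N_STATES):
                sel = np.where((a == s0) & (b == s1))[0]
                if sel.size == 0:
                    continue
                wv = w_nab[:, s0, s1]
                tot = wv.sum()
                if tot <= 0:
                    raise RuntimeError("zero-probability endpoint pair")
                cdf = np.cumsum(wv / tot)
                N[sel] = np.searchsorted(cdf, rng.random(sel.size))

        map_ids_all, times_all, states_all, counts_all = [], [], [], []
        for nj in np.unique(N):
            if nj == 0:
                continue
            sel = np.where(N == nj)[0]
            g = sel.size
            chain = np.zeros((g, nj + 1), dtype=int)
            chain[:, 0] = a[sel]
            chain[:, -1] = b[sel]
            for k in range(1, nj):
                prev = chain[:, k - 1]
                probs = R[prev] * Rpow[nj - k][:, b[sel]].T
                chain[:, k] = _sample_categorical(rng, probs)
            jt = np.sort(rng.random((g, nj)), axis=1) * t
            real = chain[:, 1:] != chain[:, :-1]
            for gi, mi in enumerate(sel):
                mask = real[gi]
                if not mask.any():
                    continue
                map_ids_all.append(mi)
                times_all.append(jt[gi][mask])
                states_all.append(chain[gi, 1:][mask])
                counts_all.append(int(mask.sum()))
        if map_ids_all:
            order = np.argsort(map_ids_all, kind="mergesort")
            map_ids = np.asarray(map_ids_all)[order]
            counts = np.asarray(counts_all)[order]
            offsets = np.concatenate([[0], np.cumsum(counts)])
            times = np.concatenate([times_all[o] for o in order])
            states = np.concatenate([states_all[o] for o in order]).astype(np.int8)
            branch_jumps[ci] = (map_ids, offsets, times, states)
    return StochasticMaps(tree=tree, n_maps=n_maps, node_states=node_states,
                          branch_jumps=branch_jumps, nodes=nodes)


@dataclass
class SimmapSummary:
    mean_counts: np.ndarray        # (3, 3) mean transitions, ordered pairs
    time_proportions: np.ndarray   # (3,) share of total tree length per state

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for i, si in enumerate(STATES):
            for j, sj in enumerate(STATES):
                if i != j:
                    rows.append({"from": si, "to": sj,
                                 "mean_count": self.mean_counts[i, j]})
        return pd.DataFrame(rows)


def summarize_maps(maps: StochasticMaps) -> SimmapSummary:
    """Mean transition counts and time-in-state proportions across maps."""
    nodes = maps.nodes
    _, index = _node_index(maps.tree)
    counts = np.zeros((3, 3))
    time_in = np.zeros(3)
    total_len = 0.0
    for ci, node in enumerate(nodes):
        if node.parent is None or node.length <= 0:
            continue
        t = node.length
        total_len += t
        pi = index[id(node.parent)]
        start = maps.node_states[:, pi].astype(int)
        # default: whole branch in the start state
        branch_time = np.zeros((maps.n_maps, 3))
        branch_time[np.arange(maps.n_maps), start] = t
        recs = maps.branch_jumps.get(ci)
        if recs is not None:
            map_ids, offsets, times, states = recs
            for j, m in enumerate(map_ids):
                lo, hi = offsets[j], offsets[j + 1]
                branch_time[m] = 0.0
                prev_t, prev_s = 0.0, start[m]
                for tt, ss in zip(times[lo:hi], states[lo:hi]):
                    branch_time[m, prev_s] += tt - prev_t
                    counts[prev_s, ss] += 1.0 / maps.n_maps
                    prev_t, prev_s = tt, int(ss)
                branch_time[m, prev_s] += t - prev_t
        time_in += branch_time.mean(axis=0)
    return SimmapSummary(mean_counts=counts,
                         time_proportions=time_in / total_len)
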