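"""Independent brute-force oracles used by the tests.

Each oracle re-derives the quantity it checks from first principles
(fine-grid discrete-time integration, dense matrix exponentials, state
enumeration, closed forms) without touching the implementation's solvers.
"""

import numpy as np
from scipy.linalg import expm as dense_expm


def yule_loglik(bt, lam):
    """Closed-form pure-birth (f = 1, unconditioned) log-likelihood."""
    bt = np.sort(np.asarray(bt, dtype=float))[::-1]
    n = bt.size + 1
    ages = np.concatenate([[0.0], bt[::-1]])
    k = np.arange(n, 1, -1)
    total_time = float(k @ np.diff(ages))
    return (n - 2) * np.log(lam) - lam * total_time


def bd_grid_loglik(bt, lam_fn, mu_fn, f, conditioning="crown_survival",
                   h=1e-4):
    """Fine-grid RK4 discrete-time integration of the E/Psi equations."""
    bt = np.sort(np.asarray(bt, dtype=float))[::-1]
    n = bt.size + 1
    T = bt[0]
    ts = np.arange(0.0, T + h, h)

    def fE(t, E):
        return mu_fn(t) - (lam_fn(t) + mu_fn(t)) * E + lam_fn(t) * E * E

    def fG(t, E):
        return 2 * lam_fn(t) * E - (lam_fn(t) + mu_fn(t))

    E = np.empty(ts.size)
    G = np.empty(ts.size)
    E[0], G[0] = 1.0 - f, 0.0
    for i in range(1, ts.size):
        t0, Ev = ts[i - 1], E[i - 1]
        k1 = fE(t0, Ev)
        k2 = fE(t0 + h / 2, Ev + h / 2 * k1)
        k3 = fE(t0 + h / 2, Ev + h / 2 * k2)
        k4 = fE(t0 + h, Ev + h * k3)
        E[i] = Ev + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        g1 = fG(t0, Ev)
        g2 = fG(t0 + h / 2, Ev + h / 2 * k1)
        g3 = fG(t0 + h / 2, Ev + h / 2 * k2)
        g4 = fG(t0 + h, Ev + h * k3)
        G[i] = G[i - 1] + h / 6 * (g1 + 2 * g2 + 2 * g3 + g4)
    ll = n * np.log(f)
    ages = np.concatenate([[0.0], bt[::-1]])
    k = np.arange(n, 1, -1)
    ll += float(k @ np.diff(np.interp(ages, ts, G)))
    ll += float(np.sum(np.log([lam_fn(a) for a in bt[1:]])))
    if conditioning == "crown_survival":
        ll -= 2 * np.log(1 - np.interp(T, ts, E))
    return ll


def dd_matexp_loglik(bt, model, M=80):
    """Dense matrix-exponential solution of the hidden-count master equation
    (unconditioned); independent generator construction."""
    bt = np.sort(np.asarray(bt, dtype=float))[::-1]
    n = bt.size + 1
    v = np.zeros(M + 1)
    v[0] = 1.0
    ages = np.concatenate([bt, [0.0]])
    for i in range(n - 1):
        k = i + 2
        dt = ages[i] - ages[i + 1]
        A = np.zeros((M + 1, M + 1))
        for m in range(M + 1):
            ntot = k + m
            A[m, m] = -(model.lam(ntot) * ntot + model.mu(ntot) * ntot)
            if m < M:
                A[m + 1, m] = model.lam(ntot) * (m + 2 * k)
            if m > 0:
                A[m - 1, m] = model.mu(ntot) * m
        v = dense_expm(A * dt) @ v
        if i < n - 2:
            v = v * np.array([model.lam(k + m) for m in range(M + 1)])
    w = model.f ** n * (1.0 - model.f) ** np.arange(M + 1)
    return float(np.log(v @ w))


def sse_grid_loglik(tree, tip_states, spec, h=2e-4):
    """Literal per-branch discrete-time (RK2 midpoint) integration of the
    SSE E/D system, dual or single inheritance, no rescaling tricks."""
    lam = spec.lambda_by_state()
    mu = spec.mu_by_state()
    Q = spec.q_matrix()
    K = spec.n_states
    cpar, ca, cb, crate = spec.clado_events()
    f = spec.f
    exam_of = np.arange(K) % 3

    def clado_E(E):
        out = np.zeros(K)
        np.add.at(out, cpar, crate * E[ca] * E[cb])
        return out

    def clado_D(E, D):
        out = np.zeros(K)
        np.add.at(out, cpar, crate * (D[ca] * E[cb] + E[ca] * D[cb]))
        return out

    def deriv(E, D):
        dE = mu - (lam + mu) * E + Q @ E + clado_E(E)
        dD = -(lam + mu) * D + Q @ D + clado_D(E, D)
        return dE, dD

    def integrate(E, D, t0, t1):
        t = t0
        while t < t1 - 1e-12:
            step = min(h, t1 - t)
            dE, dD = deriv(E, D)
            Em, Dm = E + 0.5 * step * dE, D + 0.5 * step * dD
            dE2, dD2 = deriv(Em, Dm)
            E, D = E + step * dE2, D + step * dD2
            t += step
        return E, D

    def merge(D1, D2):
        out = np.zeros(K)
        np.add.at(out, cpar, crate * D1[ca] * D2[cb])
        return out

    def descend(node):
        if node.is_tip:
            D = np.where(exam_of == tip_states[node.label], f, 0.0)
            E = np.full(K, 1.0 - f)
        else:
            (D1, E1), (D2, _) = (descend(c) for c in node.children)
            D, E = merge(D1, D2), E1
        if node.parent is not None:
            E, D = integrate(E, D, node.age, node.parent.age)
        return D, E

    D, E = descend(tree.root)
    if spec.root_weighting == "conditional":
        w = D / D.sum()
    else:
        w = np.full(K, 1.0 / K)
    if spec.conditioning:
        L = float(np.sum(w * D / (lam * (1.0 - E) ** 2)))
    else:
        L = float(w @ D)
    return np.log(L)


def mk_enum_loglik(tree, tip_states, Q, root_prior=None):
    """Enumeration over all internal-state assignments (small trees only)."""
    import itertools

    nodes = list(tree.preorder())
    internal = [n for n in nodes if not n.is_tip]
    P = {id(n): dense_expm(Q * n.length) for n in nodes if n.parent is not None}
    if root_prior is None:
        root_prior = np.full(3, 1 / 3)
    total = 0.0
    for assign in itertools.product(range(3), repeat=len(internal)):
        amap = {id(n): s for n, s in zip(internal, assign)}
        p = root_prior[amap[id(tree.root)]]
        for n in nodes:
            if n.parent is None:
                continue
            s_par = amap[id(n.parent)]
            s = tip_states[n.label] if n.is_tip else amap[id(n)]
            p *= P[id(n)][s_par, s]
        total += p
    return np.log(total)


def mk_enum_marginals(tree, tip_states, Q, root_prior=None):
    """Exact marginals by enumeration; rows follow tree.internal_nodes()."""
    import itertools

    nodes = list(tree.preorder())
    internal = [n for n in nodes if not n.is_tip]
    P = {id(n): dense_expm(Q * n.length) for n in nodes if n.parent is not None}
    if root_prior is None:
        root_prior = np.full(3, 1 / 3)
    acc = {id(n): np.zeros(3) for n in internal}
    for assign in itertools.product(range(3), repeat=len(internal)):
        amap = {id(n): s for n, s in zip(internal, assign)}
        p = root_prior[amap[id(tree.root)]]
        for n in nodes:
            if n.parent is None:
                continue
            s_par = amap[id(n.parent)]
            s = tip_states[n.label] if n.is_tip else amap[id(n)]
            p *= P[id(n)][s_par, s]
        for n in internal:
            acc[id(n)][amap[id(n)]] += p
    rows = []
    for n in tree.internal_nodes():
        v = acc[id(n)]
        rows.append(v / v.sum())
    return np.array(rows)
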