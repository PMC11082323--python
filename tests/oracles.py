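"""Independent brute-force oracles used by the test suite.

These deliberately use different algorithms from the package (recursive
kinship instead of the tabular loop, explicit Kronecker mixed-model
equations instead of incremental assembly, two-loop cross-products) so that
agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def kinship_oracle(ped: pd.DataFrame) -> np.ndarray:
    """Additive relationships from the recursive kinship (coancestry) definition.

    f(i, j) for i == j is (1 + F_i)/2 with F_i = f(sire_i, dam_i); for j
    older than i, f(i, j) = (f(sire_i, j) + f(dam_i, j))/2.  A = 2f.
    """
    ids = list(ped["animal"])
    idx = {a: k for k, a in enumerate(ids)}
    sire = [idx.get(s, -1) if s != "0" else -1 for s in ped["sire"]]
    dam = [idx.get(d, -1) if d != "0" else -1 for d in ped["dam"]]
    cache: dict = {}

    def f(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i < j:
            i, j = j, i
        if (i, j) in cache:
            return cache[(i, j)]
        if i == j:
            val = 0.5 * (1.0 + f(sire[i], dam[i]))
        else:
            # i is the younger (later) animal by topological construction
            val = 0.5 * (f(sire[i], j) + f(dam[i], j))
        cache[(i, j)] = val
        return val

    n = len(ids)
    A = np.empty((n, n))
    for i in range(n):
        for j in range(i + 1):
            A[i, j] = A[j, i] = 2.0 * f(i, j)
    return A


def random_pedigree(rng: np.random.Generator, n: int, n_founders: int | None = None) -> pd.DataFrame:
    """A random acyclic pedigree in topological order; some single parents."""
    if n_founders is None:
        n_founders = max(2, n // 4)
    rows = []
    for i in range(n):
        aid = f"a{i:04d}"
        if i < n_founders:
            s = d = "0"
        else:
            choice = rng.random()
            if choice < 0.15:
                s = d = "0"
            elif choice < 0.3:
                s, d = f"a{rng.integers(0, i):04d}", "0"
            else:
                s = f"a{rng.integers(0, i):04d}"
                d = f"a{rng.integers(0, i):04d}"
                if d == s:
                    d = "0"
        rows.append((aid, s, d, "x", 2000 + i // 10))
    return pd.DataFrame(rows, columns=["animal", "sire", "dam", "breed", "birth_year"])


def vanraden_two_loop(M: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Element-by-element VanRaden G."""
    n, m = M.shape
    denom = 2.0 * sum(pk * (1 - pk) for pk in p)
    G = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for k in range(m):
                s += (M[i, k] - 2 * p[k]) * (M[j, k] - 2 * p[k])
            G[i, j] = s / denom
    return G


def mme_kron_oracle(ys, Xs, rec_animals, H_inv, G0, residual):
    """Mixed-model equations from first principles with explicit Z and Kronecker priors."""
    n = H_inv.shape[0]
    Zs = []
    for t in range(2):
        Z = np.zeros((len(ys[t]), n))
        for r, aidx in enumerate(rec_animals[t]):
            Z[r, aidx] = 1.0
        Zs.append(Z)
    W1 = np.hstack([Xs[0], np.zeros((len(ys[0]), Xs[1].shape[1])), Zs[0], np.zeros((len(ys[0]), n))])
    W2 = np.hstack([np.zeros((len(ys[1]), Xs[0].shape[1])), Xs[1], np.zeros((len(ys[1]), n)), Zs[1]])
    W = np.vstack([W1, W2])
    Rinv = np.diag(np.concatenate([np.full(len(ys[0]), 1.0 / residual[0]),
                                   np.full(len(ys[1]), 1.0 / residual[1])]))
    y = np.concatenate(ys)
    C = W.T @ Rinv @ W
    p = Xs[0].shape[1] + Xs[1].shape[1]
    C[p:, p:] += np.kron(np.linalg.inv(G0), H_inv)
    rhs = W.T @ Rinv @ y
    sol = np.linalg.solve(C, rhs)
    return sol[:p], sol[p:].reshape(2, n)


def pearson_r2_brute(a: np.ndarray, b: np.ndarray) -> float:
    """r^2 from the definition, no library correlation call."""
    am, bm = a.mean(), b.mean()
    num = ((a - am) * (b - bm)).sum()
    den = np.sqrt(((a - am) ** 2).sum() * ((b - bm) ** 2).sum())
    return float((num / den) ** 2)
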