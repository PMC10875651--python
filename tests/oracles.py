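"""Independent reference implementations used to cross-check the package.

These deliberately avoid the package's M_S-blocked machinery: the ladder
oracle builds the full dense Hamiltonian by explicit Kronecker products and
diagonalizes it whole; the coupling-fit oracle solves the normal equations
directly instead of using an SVD pseudo-inverse.
"""

from __future__ import annotations

import numpy as np


def _site_operators(spins: list[float]):
    """Dense S_z and S_+ for each site, embedded in the full product space."""
    def sz(s):
        return np.diag(np.arange(s, -s - 1, -1, dtype=float))

    def splus(s):
        m = np.arange(s, -s - 1, -1, dtype=float)
        op = np.zeros((len(m), len(m)))
        for k in range(1, len(m)):
            op[k - 1, k] = np.sqrt(s * (s + 1) - m[k] * (m[k] + 1))
        return op

    dims = [int(2 * s + 1) for s in spins]
    Sz, Sp = [], []
    for i, s in enumerate(spins):
        mats_z, mats_p = [], []
        for k, d in enumerate(dims):
            mats_z.append(sz(s) if k == i else np.eye(d))
            mats_p.append(splus(s) if k == i else np.eye(d))
        z = mats_z[0]
        p = mats_p[0]
        for mz, mp in zip(mats_z[1:], mats_p[1:]):
            z = np.kron(z, mz)
            p = np.kron(p, mp)
        Sz.append(z)
        Sp.append(p)
    return Sz, Sp


def dense_hamiltonian(
    spins: list[float],
    couplings: dict[tuple[int, int], float],
    prefactor: float = -2.0,
) -> np.ndarray:
    """Full Hamiltonian prefactor * sum J_ij S_i.S_j via Kronecker products."""
    Sz, Sp = _site_operators(spins)
    dim = Sz[0].shape[0]
    H = np.zeros((dim, dim))
    for (i, j), J in couplings.items():
        dot = Sz[i] @ Sz[j] + 0.5 * (Sp[i] @ Sp[j].T + Sp[i].T @ Sp[j])
        H += prefactor * J * dot
    return H


def dense_s_squared(spins: list[float]) -> np.ndarray:
    Sz, Sp = _site_operators(spins)
    n = len(spins)
    S2 = np.zeros_like(Sz[0])
    for i in range(n):
        for j in range(n):
            S2 += Sz[i] @ Sz[j] + 0.5 * (Sp[i] @ Sp[j].T + Sp[i].T @ Sp[j])
    return S2


def dense_ladder(
    spins: list[float],
    couplings: dict[tuple[int, int], float],
    prefactor: float = -2.0,
) -> list[tuple[float, float]]:
    """(S, relative energy) per multiplet from brute-force diagonalization.

    Degenerate Zeeman components are collapsed: each multiplet appears once.
    """
    H = dense_hamiltonian(spins, couplings, prefactor)
    S2 = dense_s_squared(spins)
    energies, vectors = np.linalg.eigh(H)
    expect = np.einsum("ij,jk,ki->i", vectors.T, S2, vectors)
    s_values = np.round(2 * (-1 + np.sqrt(1 + 4 * np.maximum(expect, 0))) / 2) / 2
    levels: list[tuple[float, float, int]] = []  # (energy, S, count)
    for e, s in zip(energies - energies[0], s_values):
        if levels and abs(e - levels[-1][0]) < 1e-7 and levels[-1][1] == s:
            levels[-1] = (levels[-1][0], s, levels[-1][2] + 1)
        else:
            levels.append((e, s, 1))
    out = []
    for e, s, count in levels:
        mult = int(2 * s) + 1
        assert count % mult == 0, "incomplete multiplet in dense oracle"
        out.extend([(s, e)] * (count // mult))
    return out


def lande_dimer_ladder(s1: float, s2: float, J: float) -> list[tuple[float, float]]:
    """Closed-form dimer ladder: E(S) = -J[S(S+1) - S1(S1+1) - S2(S2+1)].

    Returned relative to the ground multiplet, sorted ascending,
    as (S, energy) pairs.
    """
    levels = []
    S = abs(s1 - s2)
    while S <= s1 + s2 + 1e-9:
        levels.append((S, -J * (S * (S + 1) - s1 * (s1 + 1) - s2 * (s2 + 1))))
        S += 1
    levels.sort(key=lambda t: t[1])
    e0 = levels[0][1]
    return [(s, e - e0) for s, e in levels]


def normal_equations_fit(
    spins: list[float],
    patterns: list[tuple[int, ...]],
    energies: np.ndarray,
    prefactor: float = -2.0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Least-squares (E0, J_ij) via the normal equations A^T A x = A^T E."""
    n = len(spins)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    rows = []
    for pattern in patterns:
        m = [pattern[i] * spins[i] for i in range(n)]
        rows.append([1.0] + [prefactor * m[i] * m[j] for i, j in pairs])
    A = np.asarray(rows)
    coeffs = np.linalg.solve(A.T @ A, A.T @ np.asarray(energies))
    return coeffs, pairs
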