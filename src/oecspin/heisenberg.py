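"""Exact diagonalization of the isotropic Heisenberg Hamiltonian.

The Hamiltonian convention is

    H = -2 * sum_{i<j} J_ij S_i . S_j

so that J > 0 is ferromagnetic: for a dimer the multiplet energies follow
the Lande interval rule E(S) = -J [S(S+1) - S1(S1+1) - S2(S2+1)] up to a
constant shift, i.e. an antiferromagnetic (J < 0) dimer has a singlet (or
minimal-spin) ground state with a first gap of 2|J| for two spins-1/2.

Because H commutes with total S_z, the product basis |m_1 ... m_N> splits
into blocks of fixed M = sum_i m_i.  Every total-spin-S multiplet places
exactly one state in each block with |M| <= S, so diagonalizing the single
minimal-|M| block (M = 0 for integer total spin, M = 1/2 otherwise) yields
one representative per multiplet and hence the complete spin ladder.
Eigenstates are classified by the expectation of the total-spin-squared
operator; accidental degeneracies are resolved by diagonalizing S^2 within
the degenerate subspace before classification.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .spin_system import SpinCluster, validate_cluster

__all__ = [
    "CONVENTIONS",
    "Multiplet",
    "SpinLadder",
    "GroundStateAnalysis",
    "build_hamiltonian",
    "spin_ladder",
    "analyze_ground_state",
    "sz_basis",
    "sector_hamiltonian",
    "sector_s_squared",
]

#: Hamiltonian prefactor conventions: H = prefactor * sum J_ij S_i.S_j
CONVENTIONS = {"minus2J": -2.0, "minusJ": -1.0, "plusJ": 1.0}

#: Refuse to build Hamiltonians beyond this Hilbert-space dimension.
DEFAULT_DIMENSION_CAP = 1_000_000

#: |<S^2> - S(S+1)| tolerance for assigning a total spin to an eigenstate.
SPIN_CLASSIFICATION_TOL = 1e-6

#: Relative (to ladder span) tolerance for treating levels as degenerate.
DEGENERACY_RTOL = 1e-6
DEGENERACY_ATOL = 1e-9


class DimensionError(ValueError):
    """Hilbert space too large for dense exact diagonalization."""


class ClassificationError(RuntimeError):
    """<S^2> of an eigenstate does not match any S(S+1)."""


def _prefactor(convention: str) -> float:
    try:
        return CONVENTIONS[convention]
    except KeyError:
        raise ValueError(
            f"unknown convention {convention!r}; expected one of "
            f"{sorted(CONVENTIONS)}"
        ) from None


def sz_basis(cluster: SpinCluster) -> dict[Fraction, list[tuple[Fraction, ...]]]:
    """Product basis states grouped by total M = sum_i m_i.

    Returns a mapping from M to the ordered list of m-tuples in that sector.
    """
    site_ms = [
        [site.local_spin - k for k in range(site.multiplicity)]
        for site in cluster.sites
    ]
    sectors: dict[Fraction, list[tuple[Fraction, ...]]] = {}
    for state in itertools.product(*site_ms):
        sectors.setdefault(sum(state), []).append(state)
    return sectors


def _ladder_factor(s: Fraction, m: Fraction, up: bool) -> float:
    """Matrix element sqrt(S(S+1) - m(m+-1)) of S+- acting on |s, m>."""
    target = m + 1 if up else m - 1
    value = s * (s + 1) - m * target
    return math.sqrt(float(value)) if value > 0 else 0.0


def sector_hamiltonian(
    cluster: SpinCluster,
    states: list[tuple[Fraction, ...]],
    convention: str = "minus2J",
) -> np.ndarray:
    """Heisenberg Hamiltonian block for one list of fixed-M basis states."""
    pref = _prefactor(convention)
    weights = {
        pair: pref * cluster.coupling(*pair) for pair in cluster.pairs()
    }
    return _sector_matrix_with_spins(states, weights, list(cluster.spins))


def sector_s_squared(
    cluster: SpinCluster, states: list[tuple[Fraction, ...]]
) -> np.ndarray:
    """Total-spin-squared operator block: sum_i S_i^2 + 2 sum_{i<j} S_i.S_j."""
    weights = {pair: 2.0 for pair in cluster.pairs()}
    mat = _sector_matrix_with_spins(states, weights, list(cluster.spins))
    const = sum(float(s * (s + 1)) for s in cluster.spins)
    return mat + const * np.eye(len(states))


def _sector_matrix_with_spins(
    states: list[tuple[Fraction, ...]],
    pair_weights: dict[tuple[int, int], float],
    spins: list[Fraction],
) -> np.ndarray:
    index = {state: k for k, state in enumerate(states)}
    dim = len(states)
    mat = np.zeros((dim, dim))
    for row, state in enumerate(states):
        for (i, j), w in pair_weights.items():
            if w == 0.0:
                continue
            mat[row, row] += w * float(state[i] * state[j])
            si, sj = spins[i], spins[j]
            mi, mj = state[i], state[j]
            if mi < si and mj > -sj:
                flipped = list(state)
                flipped[i] = mi + 1
                flipped[j] = mj - 1
                col = index.get(tuple(flipped))
                if col is not None:
                    amp = 0.5 * w * _ladder_factor(si, mi, True) * _ladder_factor(
                        sj, mj, False
                    )
                    mat[col, row] += amp
                    mat[row, col] += amp
    return mat


def build_hamiltonian(
    cluster: SpinCluster,
    convention: str = "minus2J",
    dimension_cap: int = DEFAULT_DIMENSION_CAP,
) -> dict[Fraction, np.ndarray]:
    """Hamiltonian matrix blocks indexed by total M_S.

    Each block is real-symmetric in the product basis returned by
    :func:`sz_basis`.  Raises :class:`DimensionError` above ``dimension_cap``.
    """
    cluster = validate_cluster(cluster)
    if cluster.dimension > dimension_cap:
        raise DimensionError(
            f"Hilbert dimension {cluster.dimension} exceeds the cap "
            f"{dimension_cap}; exact dense diagonalization refused"
        )
    return {
        M: sector_hamiltonian(cluster, states, convention)
        for M, states in sz_basis(cluster).items()
    }


@dataclass(frozen=True)
class Multiplet:
    """One total-spin multiplet of the ladder."""

    total_spin: Fraction
    energy: float  # cm^-1, relative to the ground multiplet
    degeneracy: int  # 2S+1

    def __post_init__(self):
        if self.degeneracy != int(2 * self.total_spin) + 1:
            raise ValueError("degeneracy must equal 2S+1")


@dataclass(frozen=True)
class SpinLadder:
    """Complete set of total-spin multiplets, energy-sorted, ground at 0."""

    multiplets: tuple[Multiplet, ...]

    @property
    def ground(self) -> Multiplet:
        return self.multiplets[0]

    @property
    def total_degeneracy(self) -> int:
        return sum(m.degeneracy for m in self.multiplets)

    def lowest(self, total_spin: Fraction) -> Multiplet | None:
        """Lowest multiplet of the given total spin, or None."""
        for m in self.multiplets:
            if m.total_spin == total_spin:
                return m
        return None


@dataclass(frozen=True)
class GroundStateAnalysis:
    """Table-style descriptors of the low-energy ladder.

    ``dE_doublet`` is the energy of the lowest S=1/2 multiplet above the
    ground multiplet; it is None when the ground state itself is a doublet
    (or when no doublet exists in the ladder).
    """

    S_GS: Fraction
    S_ES: Fraction | None
    dE_ES: float | None
    dE_doublet: float | None


def _classify_spins(
    energies: np.ndarray,
    vectors: np.ndarray,
    s2: np.ndarray,
) -> list[Fraction]:
    """Total spin per eigenstate; resolves accidental degeneracies via S^2.

    Eigenvalues closer than the degeneracy tolerance are treated as one
    subspace; S^2 is diagonalized inside it so that accidentally degenerate
    multiplets of different S are separated cleanly.
    """
    span = float(energies[-1] - energies[0]) if len(energies) > 1 else 0.0
    tol = max(DEGENERACY_RTOL * span, DEGENERACY_ATOL)
    spins: list[Fraction] = [Fraction(0)] * len(energies)
    start = 0
    while start < len(energies):
        stop = start + 1
        while stop < len(energies) and energies[stop] - energies[stop - 1] <= tol:
            stop += 1
        block = vectors[:, start:stop]
        s2_block = block.T @ s2 @ block
        if stop - start > 1:
            vals, rot = np.linalg.eigh(s2_block)
        else:
            vals = np.array([s2_block[0, 0]])
        for k, val in enumerate(vals):
            s = Fraction(round(2 * ((-1 + math.sqrt(1 + 4 * max(val, 0.0))) / 2)), 2)
            expected = float(s * (s + 1))
            if abs(val - expected) > SPIN_CLASSIFICATION_TOL:
                raise ClassificationError(
                    f"<S^2> = {val:.10f} does not match any S(S+1) "
                    f"(nearest S = {s}); possible unresolved degeneracy"
                )
            spins[start + k] = s
        start = stop
    return spins


def spin_ladder(
    cluster: SpinCluster,
    convention: str = "minus2J",
    dimension_cap: int = DEFAULT_DIMENSION_CAP,
) -> SpinLadder:
    """Diagonalize the Heisenberg Hamiltonian and return the spin ladder.

    Works in the minimal-|M| sector, which holds exactly one state per
    multiplet.  Energies are returned relative to the ground multiplet.
    """
    cluster = validate_cluster(cluster)
    if cluster.dimension > dimension_cap:
        raise DimensionError(
            f"Hilbert dimension {cluster.dimension} exceeds the cap "
            f"{dimension_cap}; exact dense diagonalization refused"
        )
    sectors = sz_basis(cluster)
    m0 = min(sectors, key=abs)
    states = sectors[m0]
    ham = sector_hamiltonian(cluster, states, convention)
    s2 = sector_s_squared(cluster, states)
    energies, vectors = np.linalg.eigh(ham)
    spins = _classify_spins(energies, vectors, s2)
    ground = energies[0]
    multiplets = tuple(
        Multiplet(
            total_spin=s,
            energy=float(e - ground),
            degeneracy=int(2 * s) + 1,
        )
        for e, s in zip(energies, spins)
    )
    ladder = SpinLadder(multiplets=multiplets)
    if ladder.total_degeneracy != cluster.dimension:
        raise ClassificationError(
            f"multiplet degeneracies sum to {ladder.total_degeneracy}, "
            f"expected Hilbert dimension {cluster.dimension}"
        )
    return ladder


def analyze_ground_state(ladder: SpinLadder) -> GroundStateAnalysis:
    """Extract S_GS, S_ES, the first gap, and the lowest-doublet energy."""
    if not ladder.multiplets:
        raise ValueError("empty spin ladder")
    ground = ladder.ground
    s_es: Fraction | None = None
    de_es: float | None = None
    if len(ladder.multiplets) > 1:
        first_excited = ladder.multiplets[1]
        s_es = first_excited.total_spin
        de_es = first_excited.energy
    half = Fraction(1, 2)
    de_doublet: float | None = None
    if ground.total_spin != half:
        doublet = ladder.lowest(half)
        if doublet is not None:
            de_doublet = doublet.energy
    return GroundStateAnalysis(
        S_GS=ground.total_spin,
        S_ES=s_es,
        dE_ES=de_es,
        dE_doublet=de_doublet,
    )
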