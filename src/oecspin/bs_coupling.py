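"""Exchange-coupling extraction from broken-symmetry determinant energies.

A broken-symmetry (BS) determinant assigns every site its maximal local
projection m_i = +-S_i.  On such a collinear configuration the Heisenberg
Hamiltonian reduces to the Ising expression

    E(pattern) = E0 - 2 * sum_{i<j} J_ij m_i m_j

(the -2 prefactor follows the package-wide convention; see
:mod:`oecspin.heisenberg`).  Given the energies of the high-spin
determinant and of determinants with inverted local spins, the pairwise
couplings J_ij and the baseline E0 are recovered as the least-squares
solution of the resulting linear system, computed via singular value
decomposition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from .heisenberg import CONVENTIONS
from .spin_system import SpinCluster, ValidationError, validate_cluster

__all__ = [
    "HARTREE_TO_CM1",
    "BSDeterminantSet",
    "CouplingFit",
    "enumerate_bs_determinants",
    "ising_energy",
    "extract_couplings",
]

#: CODATA conversion used for Hartree-tagged determinant energies.
HARTREE_TO_CM1 = 219474.63

#: Singular values below this fraction of the largest are truncated.
SV_TRUNCATION = 1e-10

SignPattern = tuple[int, ...]  # +1 (local spin up) / -1 (inverted) per site


def _canonical(pattern: Sequence[int]) -> SignPattern:
    """Canonical representative modulo global inversion: site 1 spin-up."""
    pat = tuple(int(s) for s in pattern)
    if any(s not in (-1, 1) for s in pat):
        raise ValidationError(f"sign pattern {pattern!r} must contain only +-1")
    return pat if pat[0] == 1 else tuple(-s for s in pat)


@dataclass(frozen=True)
class BSDeterminantSet:
    """Sign patterns plus one energy per determinant.

    ``unit`` is either ``"cm-1"`` or ``"hartree"``; Hartree energies are
    converted before fitting.  Patterns are stored canonically (site 1 up)
    and must be pairwise distinct modulo global inversion.
    """

    patterns: tuple[SignPattern, ...]
    energies: tuple[float, ...]
    unit: str = "cm-1"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.unit not in ("cm-1", "hartree"):
            raise ValidationError(
                f"unknown energy unit {self.unit!r} (expected cm-1 or hartree)"
            )
        if len(self.patterns) != len(self.energies):
            raise ValidationError("one energy per pattern required")
        canon = tuple(_canonical(p) for p in self.patterns)
        if len(set(canon)) != len(canon):
            raise ValidationError(
                "patterns must be distinct modulo global inversion"
            )
        n = len(canon[0]) if canon else 0
        if any(len(p) != n for p in canon):
            raise ValidationError("all patterns must have the same length")
        if canon and len(canon) > 2 ** (n - 1):
            raise ValidationError(
                f"at most 2^(N-1) = {2 ** (n - 1)} distinct patterns exist "
                f"for {n} sites"
            )
        if not all(np.isfinite(self.energies)):
            raise ValidationError("energies must be finite")
        object.__setattr__(self, "patterns", canon)
        object.__setattr__(
            self, "energies", tuple(float(e) for e in self.energies)
        )

    def energies_cm1(self) -> np.ndarray:
        scale = HARTREE_TO_CM1 if self.unit == "hartree" else 1.0
        return np.asarray(self.energies) * scale


@dataclass(frozen=True)
class CouplingFit:
    """Result of the SVD least-squares fit of (J_ij, E0)."""

    couplings: dict[tuple[int, int], float]  # 0-based pairs, cm^-1
    offset: float  # E0, cm^-1
    residuals: tuple[float, ...]  # per-determinant misfit, cm^-1
    condition_number: float

    @property
    def rms_residual(self) -> float:
        res = np.asarray(self.residuals)
        return float(np.sqrt(np.mean(res**2))) if res.size else 0.0


def enumerate_bs_determinants(cluster: SpinCluster) -> list[SignPattern]:
    """All 2^(N-1) sign patterns, high-spin (all up) first.

    Patterns are canonical (site 1 spin-up); for a four-site cluster this
    yields the high-spin determinant plus the seven spin-inverted ones.
    """
    n = cluster.n_sites
    if n > 20:
        raise ValidationError(f"{n} sites: pattern enumeration refused (N > 20)")
    patterns = [
        (1,) + tail for tail in itertools.product((1, -1), repeat=n - 1)
    ]
    patterns.sort(key=lambda p: p.count(-1))  # high-spin first, then by flips
    return patterns


def ising_energy(
    cluster: SpinCluster,
    pattern: Sequence[int],
    E0: float = 0.0,
    convention: str = "minus2J",
) -> float:
    """Collinear-determinant energy E0 + pref * sum_{i<j} J_ij m_i m_j.

    With the default convention (pref = -2) this equals the diagonal
    Hamiltonian matrix element of the product basis state with m_i = s_i S_i.
    """
    if len(pattern) != cluster.n_sites:
        raise ValidationError(
            f"pattern length {len(pattern)} != number of sites "
            f"{cluster.n_sites}"
        )
    pref = CONVENTIONS[convention]
    spins = cluster.spins
    total = 0.0
    for i, j in cluster.pairs():
        m_i = pattern[i] * float(spins[i])
        m_j = pattern[j] * float(spins[j])
        total += pref * cluster.coupling(i, j) * m_i * m_j
    return E0 + total


def _design_matrix(
    spins: Sequence[Fraction], patterns: Sequence[SignPattern], pref: float
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    n = len(spins)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    rows = []
    for pattern in patterns:
        m = [pattern[i] * float(spins[i]) for i in range(n)]
        rows.append([1.0] + [pref * m[i] * m[j] for i, j in pairs])
    return np.asarray(rows), pairs


def extract_couplings(
    dets: BSDeterminantSet,
    spins: Sequence[Fraction | float],
    convention: str = "minus2J",
) -> CouplingFit:
    """Least-squares (J_ij, E0) from determinant energies, via SVD.

    The design matrix row for determinant k is
    ``[1, pref*m_i^(k)*m_j^(k) ...]`` over all pairs; the system is solved
    with a truncated-SVD pseudo-inverse (singular values below
    ``1e-10 * sigma_max`` are dropped).  A rank-deficient design — e.g. too
    few or degenerate patterns — raises an error naming the pairs whose
    couplings are not identifiable.
    """
    spins = [Fraction(s) for s in spins]
    if dets.patterns and len(dets.patterns[0]) != len(spins):
        raise ValidationError(
            f"pattern length {len(dets.patterns[0])} != number of spins "
            f"{len(spins)}"
        )
    n_pairs = len(spins) * (len(spins) - 1) // 2
    if len(dets.patterns) < n_pairs + 1:
        raise ValidationError(
            f"need at least {n_pairs + 1} determinants to fit {n_pairs} "
            f"couplings plus an offset, got {len(dets.patterns)}"
        )
    pref = CONVENTIONS[convention]
    design, pairs = _design_matrix(spins, dets.patterns, pref)
    energies = dets.energies_cm1()

    u, sv, vt = np.linalg.svd(design, full_matrices=False)
    keep = sv > SV_TRUNCATION * sv[0]
    if not np.all(keep):
        # Columns with weight in the truncated right-singular vectors are
        # the unidentifiable parameters.
        null_weight = np.abs(vt[~keep]).max(axis=0)
        bad = [
            pairs[k - 1]
            for k in range(1, len(null_weight))
            if null_weight[k] > 1e-8
        ]
        names = ", ".join(f"J({i + 1},{j + 1})" for i, j in bad) or "offset E0"
        raise ValidationError(
            f"rank-deficient determinant set: cannot identify {names}"
        )
    coeffs = vt.T @ ((u.T @ energies) / sv)
    condition = float(sv[0] / sv[-1])
    residuals = energies - design @ coeffs

    couplings = {pair: float(coeffs[k + 1]) for k, pair in enumerate(pairs)}
    return CouplingFit(
        couplings=couplings,
        offset=float(coeffs[0]),
        residuals=tuple(float(r) for r in residuals),
        condition_number=condition,
    )
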