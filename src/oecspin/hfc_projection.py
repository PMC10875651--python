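"""Spin projection coefficients and effective hyperfine couplings.

In an exchange-coupled cluster the hyperfine coupling observed for a
nucleus attached to site i is the on-site (local) coupling alpha_i scaled
by the site's share of the total spin in the coupled ground state:

    A_i = rho_i * alpha_i,      rho_i = <S_iz> / M_S

evaluated in the maximal-M_S component of the ground multiplet.  The
coefficients satisfy sum_i rho_i = 1 exactly, since sum_i <S_iz> = M_S.

For comparison of computed 55Mn couplings with ENDOR experiments a global
empirical scaling factor (1.78 by default) is applied; because the factor
is global it cancels in the A1/A2, A2/A3, A3/A4 ratio criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Sequence

import numpy as np

from .heisenberg import (
    DEGENERACY_ATOL,
    DEGENERACY_RTOL,
    SPIN_CLASSIFICATION_TOL,
    sector_hamiltonian,
    sector_s_squared,
    spin_ladder,
    sz_basis,
)
from .spin_system import SpinCluster, ValidationError, validate_cluster

__all__ = [
    "MN55_SCALING",
    "ProjectionCoefficients",
    "HFCRecord",
    "projection_coefficients",
    "project_hfc",
    "apply_mn_scaling",
    "sort_and_ratio",
]

logger = logging.getLogger(__name__)

#: Empirical scaling applied to computed 55Mn hyperfine couplings.
MN55_SCALING = 1.78


@dataclass(frozen=True)
class ProjectionCoefficients:
    """Per-site spin projection coefficients rho_i of the ground multiplet.

    ``M_S_used`` is the S_z eigenvalue of the analyzed component (the
    maximal one, M_S = S_GS).  ``ambiguous`` flags an accidental degeneracy
    of the ground level beyond its 2S+1 Zeeman components, in which case
    the coefficients of one arbitrary member are reported.
    """

    rho: tuple[float, ...]
    M_S_used: Fraction
    total_spin: Fraction
    ambiguous: bool = False

    def __getitem__(self, site: int) -> float:
        return self.rho[site]

    @property
    def total(self) -> float:
        return float(sum(self.rho))


@dataclass(frozen=True)
class HFCRecord:
    """Nucleus-level hyperfine observables before/after projection.

    ``alpha_iso``/``alpha_aniso`` are on-site values in MHz (inputs from
    quantum chemistry or synthetic); ``A_iso_eff`` is filled in by
    :func:`project_hfc`.  ``attached_site`` is the 0-based index of the Mn
    centre whose projection coefficient applies.  ``eta`` is the nuclear
    quadrupole asymmetry parameter, carried through unchanged.
    """

    nucleus: str
    isotope: str  # "55Mn", "14N", "17O"
    alpha_iso: float
    attached_site: int | None = None
    alpha_aniso: float | None = None
    A_iso_eff: float | None = None
    eta: float | None = None

    def __post_init__(self):
        if self.eta is not None and not (0.0 <= self.eta <= 1.0):
            raise ValidationError(
                f"nucleus {self.nucleus}: eta={self.eta} outside [0, 1]"
            )

    @property
    def A_iso_abs(self) -> float | None:
        return None if self.A_iso_eff is None else abs(self.A_iso_eff)


def projection_coefficients(
    cluster: SpinCluster, convention: str = "minus2J"
) -> ProjectionCoefficients:
    """rho_i = <S_iz>/M_S in the maximal-M_S ground-multiplet component.

    Diagonalizes the M = S_GS sector, picks the lowest state with total
    spin S_GS (resolving accidental degeneracies by diagonalizing S^2 in
    the degenerate subspace first), and evaluates <S_iz> per site.
    Raises for a singlet ground state, where no projection exists.
    """
    cluster = validate_cluster(cluster)
    ladder = spin_ladder(cluster, convention=convention)
    s_gs = ladder.ground.total_spin
    if s_gs == 0:
        raise ValidationError(
            f"cluster {cluster.name!r}: no projection for singlet ground state"
        )
    sectors = sz_basis(cluster)
    states = sectors[s_gs]
    ham = sector_hamiltonian(cluster, states, convention)
    s2 = sector_s_squared(cluster, states)
    energies, vectors = np.linalg.eigh(ham)

    # States of this sector have S >= S_GS; the ground multiplet is the
    # energy minimum among states classified as S = S_GS.
    span = float(energies[-1] - energies[0]) if len(energies) > 1 else 0.0
    tol = max(DEGENERACY_RTOL * span, DEGENERACY_ATOL)
    target = float(s_gs * (s_gs + 1))

    candidates: list[np.ndarray] = []
    start = 0
    while start < len(energies) and not candidates:
        stop = start + 1
        while stop < len(energies) and energies[stop] - energies[stop - 1] <= tol:
            stop += 1
        block = vectors[:, start:stop]
        s2_block = block.T @ s2 @ block
        vals, rot = np.linalg.eigh(s2_block)
        rotated = block @ rot
        for k, val in enumerate(vals):
            if abs(val - target) < max(SPIN_CLASSIFICATION_TOL, 1e-8 * target):
                candidates.append(rotated[:, k])
        start = stop
    if not candidates:
        raise ValidationError(
            f"cluster {cluster.name!r}: no S={s_gs} state found in its "
            f"own M_S sector (classification failure)"
        )
    ambiguous = len(candidates) > 1
    if ambiguous:
        logger.warning(
            "cluster %s: accidentally degenerate ground multiplet; "
            "projection coefficients of one member reported",
            cluster.name,
        )
    vec = candidates[0]
    weights = vec**2
    m_s = float(s_gs)
    rho = []
    for i in range(cluster.n_sites):
        siz = np.array([float(state[i]) for state in states])
        rho.append(float(np.dot(weights, siz)) / m_s)
    return ProjectionCoefficients(
        rho=tuple(rho), M_S_used=s_gs, total_spin=s_gs, ambiguous=ambiguous
    )


def project_hfc(rho: ProjectionCoefficients, record: HFCRecord) -> HFCRecord:
    """Fill in A_iso_eff = rho_site * alpha_iso for the record's site.

    The signed value is retained; reporting layers print |A_iso|.
    """
    if record.attached_site is None:
        raise ValidationError(
            f"nucleus {record.nucleus}: no attached site for projection"
        )
    if not (0 <= record.attached_site < len(rho.rho)):
        raise ValidationError(
            f"nucleus {record.nucleus}: attached site {record.attached_site} "
            f"out of range for {len(rho.rho)} sites"
        )
    return replace(
        record, A_iso_eff=rho[record.attached_site] * record.alpha_iso
    )


def apply_mn_scaling(
    A: float, factor: float = MN55_SCALING, isotope: str = "55Mn"
) -> float:
    """Scale a 55Mn hyperfine coupling by the empirical factor.

    The scaling is specific to 55Mn; for any other isotope the value is
    returned unchanged and a warning is logged.
    """
    if isotope != "55Mn":
        logger.warning(
            "Mn scaling requested for isotope %s: not applied", isotope
        )
        return A
    return A * factor


def sort_and_ratio(
    mn_hfcs: Sequence[float], sites: Sequence[int] | None = None
) -> tuple[tuple[float, ...], tuple[float, ...], tuple[int, ...]]:
    """Descending |A| sort plus successive ratios A1/A2, A2/A3, A3/A4.

    ``sites`` optionally carries the originating Mn site per value (1-based
    in reports); ties in magnitude are broken by site order, keeping the
    sort stable and deterministic.  Returns (sorted magnitudes, ratios,
    site assignment per rank).
    """
    if len(mn_hfcs) != 4:
        raise ValidationError(
            f"expected exactly 4 Mn hyperfine values, got {len(mn_hfcs)}"
        )
    mags = [abs(float(a)) for a in mn_hfcs]
    if sites is None:
        sites = tuple(range(1, 5))
    if len(sites) != 4:
        raise ValidationError("need one site per hyperfine value")
    order = sorted(range(4), key=lambda k: (-mags[k], sites[k]))
    sorted_mags = tuple(mags[k] for k in order)
    sorted_sites = tuple(sites[k] for k in order)
    ratios = tuple(
        sorted_mags[k] / sorted_mags[k + 1] if sorted_mags[k + 1] != 0 else float("inf")
        for k in range(3)
    )
    return sorted_mags, ratios, sorted_sites
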