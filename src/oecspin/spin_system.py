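"""Domain types for exchange-coupled spin clusters.

A :class:`SpinCluster` is the central model instance shared by all analysis
stages: an ordered list of paramagnetic sites (each with an oxidation state
and a local spin quantum number) plus a table of pairwise isotropic exchange
coupling constants J_ij in cm^-1.

Site spins are stored as exact :class:`fractions.Fraction` values so that
half-integer spins such as 3/2 are never floating-point approximations;
energies and couplings are plain floats in cm^-1.

Site indexing is 1-based in files and reports (Mn1..Mn4 convention) and
0-based internally; the conversion is confined to the I/O layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Sequence

__all__ = [
    "SpinSite",
    "SpinCluster",
    "ExperimentalReference",
    "ValidationError",
    "validate_cluster",
    "as_spin",
]

#: Local spin assigned to each Mn oxidation state (high-spin d4 / d3 ions).
MN_OXIDATION_SPINS = {"III": Fraction(2), "IV": Fraction(3, 2)}


class ValidationError(ValueError):
    """Raised when a cluster or site violates a structural invariant."""


def as_spin(value) -> Fraction:
    """Coerce a number to an exact non-negative half-integer Fraction.

    Accepts ints, floats (e.g. 1.5) and strings ("3/2", "1.5", "2").
    Raises :class:`ValidationError` if the value is not a multiple of 1/2.
    """
    try:
        frac = Fraction(value).limit_denominator(1000)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"cannot interpret {value!r} as a spin") from exc
    if Fraction(value) != frac:
        raise ValidationError(f"spin {value!r} is not an exact rational")
    if frac.denominator not in (1, 2):
        raise ValidationError(f"spin {value!r} is not a multiple of 1/2")
    if frac < 0:
        raise ValidationError(f"spin {value!r} is negative")
    return frac


@dataclass(frozen=True)
class SpinSite:
    """One paramagnetic centre of the cluster.

    Parameters
    ----------
    index:
        1-based site ordinal, matching the Mn1..Mn4 labelling of reports.
    label:
        Free-text label, e.g. ``"Mn1"``.
    oxidation_state:
        ``"III"``, ``"IV"`` or ``"other"``.  For Mn sites the oxidation
        state fixes the local spin (III -> S=2, IV -> S=3/2).
    local_spin:
        Non-negative half-integer spin quantum number.
    is_mn:
        Whether the site is a manganese ion (enables the oxidation-state/
        spin consistency check).
    """

    index: int
    label: str
    oxidation_state: str
    local_spin: Fraction
    is_mn: bool = True

    def __post_init__(self):
        object.__setattr__(self, "local_spin", as_spin(self.local_spin))
        if self.oxidation_state not in ("III", "IV", "other"):
            raise ValidationError(
                f"site {self.label}: unknown oxidation state "
                f"{self.oxidation_state!r} (expected III, IV or other)"
            )
        if self.is_mn and self.oxidation_state in MN_OXIDATION_SPINS:
            expected = MN_OXIDATION_SPINS[self.oxidation_state]
            if self.local_spin != expected:
                raise ValidationError(
                    f"site {self.label}: Mn({self.oxidation_state}) requires "
                    f"S={expected}, got S={self.local_spin}"
                )

    @property
    def multiplicity(self) -> int:
        """Dimension 2S+1 of the local Hilbert space."""
        return int(2 * self.local_spin) + 1


@dataclass(frozen=True)
class SpinCluster:
    """An exchange-coupled cluster: sites plus pairwise couplings.

    ``couplings`` maps unordered 0-based site pairs ``(i, j)`` with ``i < j``
    to J_ij in cm^-1.  Pairs not listed are treated as J = 0.
    """

    name: str
    sites: tuple[SpinSite, ...]
    couplings: Mapping[tuple[int, int], float] = field(default_factory=dict)
    metadata: Mapping[str, object] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def spins(self) -> tuple[Fraction, ...]:
        return tuple(site.local_spin for site in self.sites)

    @property
    def dimension(self) -> int:
        """Hilbert-space dimension, Prod(2S_i + 1)."""
        dim = 1
        for site in self.sites:
            dim *= site.multiplicity
        return dim

    def pairs(self) -> list[tuple[int, int]]:
        """All unordered site pairs (i < j), 0-based."""
        n = self.n_sites
        return [(i, j) for i in range(n) for j in range(i + 1, n)]

    def coupling(self, i: int, j: int) -> float:
        """J between 0-based sites i and j (0 if unlisted)."""
        if i == j:
            raise ValidationError("no self-coupling J_ii")
        key = (min(i, j), max(i, j))
        return float(self.couplings.get(key, 0.0))


def validate_cluster(cluster: SpinCluster) -> SpinCluster:
    """Validate invariants and return the cluster with missing pairs as J=0.

    Checks: at least two sites, unique 1-based site indices in order,
    half-integer spins (enforced by :class:`SpinSite`), Hilbert dimension
    > 1, and finite couplings over valid site pairs.
    """
    if cluster.n_sites < 2:
        raise ValidationError(
            f"cluster {cluster.name!r}: need at least 2 sites, "
            f"got {cluster.n_sites}"
        )
    indices = [site.index for site in cluster.sites]
    if len(set(indices)) != len(indices):
        raise ValidationError(
            f"cluster {cluster.name!r}: duplicate site indices {indices}"
        )
    if indices != sorted(indices):
        raise ValidationError(
            f"cluster {cluster.name!r}: site indices must be ascending"
        )
    if cluster.dimension <= 1:
        raise ValidationError(
            f"cluster {cluster.name!r}: Hilbert dimension "
            f"{cluster.dimension} (all sites diamagnetic?)"
        )
    n = cluster.n_sites
    filled: dict[tuple[int, int], float] = {}
    for (i, j), J in cluster.couplings.items():
        if not (0 <= i < j < n):
            raise ValidationError(
                f"cluster {cluster.name!r}: invalid coupling pair ({i}, {j}) "
                f"for {n} sites (expect 0-based, i < j)"
            )
        if not math.isfinite(J):
            raise ValidationError(
                f"cluster {cluster.name!r}: non-finite J for pair ({i}, {j})"
            )
        filled[(i, j)] = float(J)
    for pair in [(i, j) for i in range(n) for j in range(i + 1, n)]:
        filled.setdefault(pair, 0.0)
    return replace(cluster, couplings=filled)


@dataclass(frozen=True)
class ExperimentalReference:
    """Experimental EPR/ENDOR/ESEEM/EDNMR observables for one organism.

    ``mn_hfcs`` are the four fitted 55Mn |A_iso| values in MHz in descending
    order; ``hfc_ratios`` the three successive ratios A1/A2, A2/A3, A3/A4.
    ``o17_aiso`` maps a ligand role (e.g. "exchangeable", "terminal") to an
    |A_iso| in MHz.  ``ea_difference`` is the estimated electron-affinity
    gap EA(S2) - EA(S2-NH3) in kcal/mol.
    """

    organism: str
    mn_hfcs: tuple[float, float, float, float]
    hfc_ratios: tuple[float, float, float]
    n14_aiso: float | None = None
    n14_eta: float | None = None
    o17_aiso: Mapping[str, float] | None = None
    ea_difference: float | None = None
    ammonia_treated: bool = True

    def __post_init__(self):
        if len(self.mn_hfcs) != 4:
            raise ValidationError("mn_hfcs must hold exactly 4 values")
        if list(self.mn_hfcs) != sorted(self.mn_hfcs, reverse=True):
            raise ValidationError("mn_hfcs must be sorted descending")
        if len(self.hfc_ratios) != 3:
            raise ValidationError("hfc_ratios must hold exactly 3 values")
        if any(r < 0 for r in self.hfc_ratios):
            raise ValidationError("hfc_ratios must be non-negative")
        if self.n14_eta is not None and not (0.0 <= self.n14_eta <= 1.0):
            raise ValidationError("n14_eta must lie in [0, 1]")


def mn_cluster(
    name: str,
    valences: Sequence[str],
    couplings_1based: Mapping[tuple[int, int], float],
    metadata: Mapping[str, object] | None = None,
) -> SpinCluster:
    """Build a validated Mn cluster from a valence pattern.

    ``valences`` maps positionally onto sites Mn1..MnN; ``couplings_1based``
    uses the 1-based (i, j) convention of published coupling tables.
    """
    sites = tuple(
        SpinSite(
            index=k + 1,
            label=f"Mn{k + 1}",
            oxidation_state=ox,
            local_spin=MN_OXIDATION_SPINS[ox],
        )
        for k, ox in enumerate(valences)
    )
    couplings = {
        (i - 1, j - 1): float(J) for (i, j), J in couplings_1based.items()
    }
    return validate_cluster(
        SpinCluster(
            name=name,
            sites=sites,
            couplings=couplings,
            metadata=dict(metadata or {}),
        )
    )
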