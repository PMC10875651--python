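"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators make every stage testable without any electronic-structure
computation:

* :func:`simulate_bs_energies` produces broken-symmetry determinant energy
  sets that are exactly Ising-consistent for a known coupling set, plus
  optional Gaussian noise standing in for the unmodelled systematic error
  of quantum-chemical energies relative to the Ising mapping;
* :func:`simulate_onsite_hfcs` draws on-site 55Mn hyperfine parameters
  from the valence- and coordination-dependent ranges characteristic of
  Mn(III)/Mn(IV) ions in oxo-bridged clusters.

All randomness flows through :class:`numpy.random.Generator` seeded with
PCG64, so outputs are reproducible bit-for-bit across platforms for a
given seed.

:func:`published_fixtures` loads the transcribed published tables shipped with
the package: 31 model definitions (29 ammonia-bound S2 variants plus the
untreated S2 and its W2-protonated form S2H), the projected hyperfine
tables, and the experimental reference rows.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .bs_coupling import BSDeterminantSet, enumerate_bs_determinants, ising_energy
from .hfc_projection import HFCRecord
from .spin_system import ExperimentalReference, SpinCluster, ValidationError

__all__ = [
    "SyntheticSpec",
    "HFC_RANGES",
    "simulate_bs_energies",
    "simulate_onsite_hfcs",
    "FixtureBundle",
    "published_fixtures",
]

#: On-site 55Mn hyperfine ranges (MHz) by valence/coordination class:
#: (|alpha_iso| low, high, |alpha_aniso| low, high).  Octahedral Mn(IV)
#: couples within 219-301 MHz with small anisotropy; five-coordinate
#: square-pyramidal Mn(III) sits near 140 MHz and six-coordinate
#: (tetragonally elongated) Mn(III) within 191-231 MHz, both with large
#: anisotropy (141-150 MHz).
HFC_RANGES: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("IV", "octahedral"): (219.0, 301.0, 0.0, 49.0),
    ("III", "square-pyramidal"): (130.0, 150.0, 141.0, 150.0),
    ("III", "octahedral"): (191.0, 231.0, 141.0, 150.0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and noise model for a synthetic determinant set.

    ``couplings`` are the true J_ij (cm^-1, 0-based pairs); ``offset`` the
    baseline energy E0; ``noise_sd`` the standard deviation (cm^-1) of
    additive Gaussian noise.  ``seed`` makes the draw reproducible.
    """

    couplings: Mapping[tuple[int, int], float]
    offset: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    valence_pattern: tuple[str, ...] | None = None
    hfc_ranges: Mapping[tuple[str, str], tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(HFC_RANGES)
    )

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


def simulate_bs_energies(
    spec: SyntheticSpec,
    cluster: SpinCluster,
    convention: str = "minus2J",
) -> BSDeterminantSet:
    """Ising-consistent energies for all 2^(N-1) determinants, plus noise.

    Couplings in ``spec`` override those stored on the cluster, so the same
    geometry can be re-simulated under different ground truths.
    """
    from dataclasses import replace

    truth = replace(cluster, couplings=dict(spec.couplings))
    patterns = enumerate_bs_determinants(cluster)
    rng = np.random.default_rng(spec.seed)
    energies = []
    for pattern in patterns:
        e = ising_energy(truth, pattern, spec.offset, convention)
        if spec.noise_sd > 0:
            e += rng.normal(0.0, spec.noise_sd)
        energies.append(e)
    return BSDeterminantSet(
        patterns=tuple(patterns),
        energies=tuple(energies),
        unit="cm-1",
        metadata={"seed": spec.seed, "noise_sd": spec.noise_sd},
    )


def simulate_onsite_hfcs(
    valence_pattern: Sequence[str],
    coordination: Sequence[str],
    seed: int = 0,
    hfc_ranges: Mapping[tuple[str, str], tuple[float, float, float, float]] | None = None,
) -> list[HFCRecord]:
    """Draw on-site 55Mn hyperfine parameters for a 4-site valence pattern.

    ``coordination`` tags each site ("octahedral" or "square-pyramidal").
    Isotropic couplings are reported negative, the usual sign of the Fermi
    contact term for high-spin Mn ions; magnitudes are uniform draws from
    the class range.
    """
    if len(valence_pattern) != 4:
        raise ValidationError("valence pattern must have 4 sites")
    if len(coordination) != len(valence_pattern):
        raise ValidationError("one coordination tag per site required")
    ranges = dict(HFC_RANGES if hfc_ranges is None else hfc_ranges)
    rng = np.random.default_rng(seed)
    records = []
    for k, (ox, coord) in enumerate(zip(valence_pattern, coordination)):
        try:
            iso_lo, iso_hi, an_lo, an_hi = ranges[(ox, coord)]
        except KeyError:
            raise ValidationError(
                f"site {k + 1}: no hyperfine range for Mn({ox}) with "
                f"{coord!r} coordination"
            ) from None
        alpha_iso = -rng.uniform(iso_lo, iso_hi)
        alpha_aniso = rng.uniform(an_lo, an_hi)
        records.append(
            HFCRecord(
                nucleus=f"Mn{k + 1}",
                isotope="55Mn",
                alpha_iso=float(alpha_iso),
                alpha_aniso=float(alpha_aniso),
                attached_site=k,
            )
        )
    return records


@dataclass(frozen=True)
class FixtureBundle:
    """The transcribed published tables, ready for the pipeline.

    ``models`` maps a model name to its validated :class:`SpinCluster`;
    ``mn_hfcs`` holds per-model projected 55Mn |A_iso| values with their
    site assignment and the printed ratio triple; ``n14``/``o17`` the
    ligand hyperfine tables; ``references`` the experimental rows.
    """

    models: Mapping[str, SpinCluster]
    mn_hfcs: Mapping[str, dict]
    n14: Mapping[str, dict]
    o17: Mapping[str, dict]
    references: tuple[ExperimentalReference, ...]

    def doublet_models(self) -> list[str]:
        """Names of ammonia-bound models reported with a doublet ground state."""
        return [
            name
            for name, cluster in self.models.items()
            if cluster.metadata.get("printed_S_GS") == "1/2"
            and name not in ("S2", "S2H")
        ]

    def ammonia_references(self) -> tuple[ExperimentalReference, ...]:
        return tuple(r for r in self.references if r.ammonia_treated)

    def screening_inputs(self, convention: str = "minus2J"):
        """Assemble per-model screening inputs for the 29 ammonia-bound models.

        Ladders are recomputed from the coupling sets; hyperfine ratios,
        14N asymmetry and 17O couplings come from the transcribed tables
        (absent entries yield not-evaluated criteria downstream).
        """
        from .heisenberg import analyze_ground_state, spin_ladder
        from .hfc_projection import sort_and_ratio
        from .screening import ModelInputs

        inputs = {}
        for name, cluster in self.models.items():
            if name in ("S2", "S2H"):
                continue
            analysis = analyze_ground_state(
                spin_ladder(cluster, convention=convention)
            )
            ratios = None
            mn = self.mn_hfcs.get(name)
            if mn is not None:
                _, ratios, _ = sort_and_ratio(mn["values"], mn["sites"])
            n14 = self.n14.get(name, {})
            o17 = self.o17.get(name)
            o17_clean = (
                {k: v for k, v in o17.items() if v is not None} if o17 else None
            )
            inputs[name] = ModelInputs(
                analysis=analysis,
                mn_ratios=ratios,
                n14_eta=n14.get("nhx_eta"),
                o17_aiso=o17_clean or None,
            )
        return inputs


def _data_root():
    return resources.files("oecspin") / "data"


def _verify_checksums() -> None:
    root = _data_root()
    manifest = json.loads((root / "checksums.json").read_text())
    for rel, expected in manifest.items():
        digest = hashlib.sha256((root / rel).read_bytes()).hexdigest()
        if digest != expected:
            raise ValidationError(
                f"fixture file {rel} fails its transcription checksum"
            )


def published_fixtures(verify: bool = True) -> FixtureBundle:
    """Load the shipped fixture bundle (checksum-guarded transcription)."""
    from .io import model_from_dict

    if verify:
        _verify_checksums()
    root = _data_root()
    models: dict[str, SpinCluster] = {}
    models_dir = root / "models"
    for entry in sorted(models_dir.iterdir(), key=lambda p: p.name):
        if entry.name.endswith(".json"):
            cluster = model_from_dict(json.loads(entry.read_text()))
            models[cluster.name] = cluster

    mn: dict[str, dict] = {}
    for row in csv.DictReader((root / "hfc_mn55.csv").read_text().splitlines()):
        mn[row["model"]] = {
            "values": [float(row[f"A{k}_MHz"]) for k in range(1, 5)],
            "sites": [int(row[f"site{k}"]) for k in range(1, 5)],
            "printed_ratios": (
                float(row["ratio12"]),
                float(row["ratio23"]),
                float(row["ratio34"]),
            ),
        }

    def _opt(value: str) -> float | None:
        return float(value) if value not in ("", None) else None

    n14: dict[str, dict] = {}
    for row in csv.DictReader((root / "hfc_n14.csv").read_text().splitlines()):
        n14[row["model"]] = {
            "nhx_aiso": _opt(row["nhx_aiso_MHz"]),
            "nhx_eta": _opt(row["nhx_eta"]),
            "his332_aiso": _opt(row["his332_aiso_MHz"]),
            "his332_eta": _opt(row["his332_eta"]),
        }

    o17: dict[str, dict] = {}
    for row in csv.DictReader((root / "hfc_o17.csv").read_text().splitlines()):
        o17[row["model"]] = {
            ligand: _opt(row[f"{ligand}_MHz"]) for ligand in ("O5", "W1", "W2")
        }

    refs = []
    for rec in json.loads((root / "references.json").read_text()):
        refs.append(
            ExperimentalReference(
                organism=rec["organism"],
                mn_hfcs=tuple(float(v) for v in rec["mn_hfcs"]),
                hfc_ratios=tuple(float(v) for v in rec["hfc_ratios"]),
                n14_aiso=rec.get("n14_aiso"),
                n14_eta=rec.get("n14_eta"),
                o17_aiso=rec.get("o17_aiso"),
                ea_difference=rec.get("ea_difference"),
                ammonia_treated=rec["ammonia_treated"],
            )
        )
    return FixtureBundle(
        models=models, mn_hfcs=mn, n14=n14, o17=o17, references=tuple(refs)
    )
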