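"""Readers and writers for model, energy, hyperfine and report formats.

File conventions
----------------
* model definition: JSON with keys ``name``, ``sites`` (index, label,
  oxidation_state, local_spin), ``couplings`` (1-based ``i``, ``j``,
  ``J_cm1``) and optional ``metadata``;
* determinant energies: CSV with columns ``pattern`` and ``energy``;
  a leading comment line ``# unit=hartree`` (or ``cm-1``) declares the
  energy unit, defaulting to cm^-1.  Patterns are either sign strings
  ("uddu") or comma-separated local projections ("2,-1.5,-1.5,1.5");
* on-site hyperfine tables: CSV with columns nucleus, isotope,
  attached_site (1-based), alpha_iso_MHz, alpha_aniso_MHz, eta;
* ladders: TSV with S (as a fraction), energy_cm1, degeneracy;
* screening reports: TSV, JSON or plain text with deterministic ordering.

Site indices are 1-based in every file (Mn1..Mn4 convention) and converted
to the package's internal 0-based indexing here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

from .bs_coupling import BSDeterminantSet, CouplingFit
from .heisenberg import CONVENTIONS, SpinLadder
from .hfc_projection import HFCRecord
from .screening import ScreeningReport
from .spin_system import SpinCluster, SpinSite, ValidationError, validate_cluster

__all__ = [
    "RunConfig",
    "read_model",
    "write_model",
    "model_from_dict",
    "model_to_dict",
    "read_bs_energies",
    "read_hfc_table",
    "write_ladder",
    "write_couplings",
    "write_report",
]


class ParseError(ValueError):
    """Raised with file/line context when an input file is malformed."""


@dataclass(frozen=True)
class RunConfig:
    """Runtime configuration shared by the CLI subcommands."""

    convention: str = "minus2J"
    dimension_cap: int = 1_000_000
    degeneracy_rtol: float = 1e-6
    seed: int | None = None
    verbosity: int = 0

    def __post_init__(self):
        if self.convention not in CONVENTIONS:
            raise ValidationError(
                f"unknown convention {self.convention!r}; expected one of "
                f"{sorted(CONVENTIONS)}"
            )
        if self.dimension_cap <= 0 or self.degeneracy_rtol <= 0:
            raise ValidationError("caps and tolerances must be positive")

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "RunConfig":
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def model_from_dict(data: Mapping[str, object]) -> SpinCluster:
    """Build and validate a cluster from parsed model JSON."""
    try:
        sites = tuple(
            SpinSite(
                index=int(site["index"]),
                label=str(site.get("label", f"site{site['index']}")),
                oxidation_state=str(site.get("oxidation_state", "other")),
                local_spin=Fraction(str(site["local_spin"])),
                is_mn=bool(site.get("is_mn", True)),
            )
            for site in data["sites"]
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed site entry: {exc}") from exc
    couplings = {}
    for entry in data.get("couplings", []):
        try:
            i, j = int(entry["i"]), int(entry["j"])
            J = entry["J_cm1"]
            if isinstance(J, str):
                raise ParseError(
                    f"coupling ({i},{j}): J_cm1 must be a number, got {J!r}"
                )
            couplings[(min(i, j) - 1, max(i, j) - 1)] = float(J)
        except (KeyError, TypeError) as exc:
            raise ParseError(f"malformed coupling entry {entry!r}") from exc
    return validate_cluster(
        SpinCluster(
            name=str(data.get("name", "unnamed")),
            sites=sites,
            couplings=couplings,
            metadata=dict(data.get("metadata", {})),
        )
    )


def model_to_dict(cluster: SpinCluster) -> dict:
    """Serialize a cluster to the model JSON structure (1-based pairs)."""
    return {
        "name": cluster.name,
        "sites": [
            {
                "index": site.index,
                "label": site.label,
                "oxidation_state": site.oxidation_state,
                "local_spin": str(site.local_spin),
                "is_mn": site.is_mn,
            }
            for site in cluster.sites
        ],
        "couplings": [
            {"i": i + 1, "j": j + 1, "J_cm1": J}
            for (i, j), J in sorted(cluster.couplings.items())
        ],
        "metadata": dict(cluster.metadata),
    }


def read_model(path: str | Path) -> SpinCluster:
    """Read and validate a model definition file."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}")
    try:
        return model_from_dict(data)
    except (ParseError, ValidationError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_model(cluster: SpinCluster, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(model_to_dict(cluster), indent=1, sort_keys=True) + "\n"
    )


def _parse_pattern(text: str) -> tuple:
    """Sign pattern from 'uudd' / 'abba' or '2,-1.5,-1.5,1.5' notation."""
    text = text.strip()
    letters = {"u": 1, "d": -1, "a": 1, "b": -1}
    if all(c in letters for c in text.lower()) and text:
        return tuple(letters[c] for c in text.lower())
    try:
        values = [float(tok) for tok in text.split(",")]
    except ValueError:
        raise ParseError(f"cannot parse sign pattern {text!r}")
    if any(v == 0 for v in values):
        raise ParseError(f"pattern {text!r} has a zero projection")
    return tuple(1 if v > 0 else -1 for v in values)


def read_bs_energies(path: str | Path) -> BSDeterminantSet:
    """Read a determinant-energy CSV (unit declared via '# unit=...')."""
    path = Path(path)
    unit = "cm-1"
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            decl = line.lstrip("#").strip().replace(" ", "")
            if decl.lower().startswith("unit="):
                unit = decl.split("=", 1)[1].lower()
            continue
        if line.lower().replace(" ", "").startswith("pattern,"):
            continue  # header
        parts = line.rsplit(",", 1)
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 'pattern,energy'")
        try:
            energy = float(parts[1])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: bad energy {parts[1]!r}")
        rows.append((_parse_pattern(parts[0]), energy))
    if not rows:
        raise ParseError(f"{path}: no determinant rows found")
    return BSDeterminantSet(
        patterns=tuple(p for p, _ in rows),
        energies=tuple(e for _, e in rows),
        unit=unit,
    )


def read_hfc_table(path: str | Path) -> list[HFCRecord]:
    """Read an on-site hyperfine CSV into HFCRecords (0-based sites)."""
    import csv

    path = Path(path)
    records = []
    with path.open() as handle:
        for lineno, row in enumerate(csv.DictReader(handle), start=2):
            try:
                attached = row.get("attached_site", "").strip()
                eta = row.get("eta", "").strip()
                aniso = row.get("alpha_aniso_MHz", "").strip()
                records.append(
                    HFCRecord(
                        nucleus=row["nucleus"].strip(),
                        isotope=row["isotope"].strip(),
                        alpha_iso=float(row["alpha_iso_MHz"]),
                        attached_site=int(attached) - 1 if attached else None,
                        alpha_aniso=float(aniso) if aniso else None,
                        eta=float(eta) if eta else None,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no hyperfine rows found")
    return records


def write_ladder(ladder: SpinLadder, path: str | Path) -> None:
    """TSV spin ladder: S as a fraction, energy (1 decimal), degeneracy."""
    lines = ["S\tenergy_cm1\tdegeneracy"]
    for m in ladder.multiplets:
        lines.append(f"{m.total_spin}\t{m.energy:.1f}\t{m.degeneracy}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_couplings(fit: CouplingFit, path: str | Path) -> None:
    """JSON coupling fit (1-based pairs, cm^-1)."""
    payload = {
        "couplings": [
            {"i": i + 1, "j": j + 1, "J_cm1": J}
            for (i, j), J in sorted(fit.couplings.items())
        ],
        "offset_cm1": fit.offset,
        "residuals_cm1": list(fit.residuals),
        "rms_residual_cm1": fit.rms_residual,
        "condition_number": fit.condition_number,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def _outcome_cells(outcome) -> dict:
    value = outcome.value
    if isinstance(value, float):
        value = f"{value:.2f}"
    elif isinstance(value, tuple):
        value = ",".join(f"{v:.2f}" if isinstance(v, float) else str(v) for v in value)
    elif isinstance(value, dict):
        value = ";".join(f"{k}={v}" for k, v in sorted(value.items()))
    dev = "" if outcome.deviation is None else f"{outcome.deviation:.3f}"
    return {
        "criterion": outcome.criterion,
        "status": outcome.status,
        "value": "" if value is None else str(value),
        "reference": "" if outcome.reference is None else str(outcome.reference),
        "deviation": dev,
        "note": outcome.note,
    }


def write_report(
    report: ScreeningReport, path: str | Path, format: str = "tsv"
) -> None:
    """Write a screening report as TSV, JSON or human-readable text.

    Column order and model order are deterministic; the TSV lists one row
    per (model, criterion), models in ranked order.
    """
    path = Path(path)
    ranked = report.ranking()
    by_name = {r.model: r for r in report.reports}
    if format == "tsv":
        cols = ["model", "rank", "verdict", "score", "criterion", "status",
                "value", "reference", "deviation", "note"]
        lines = ["\t".join(cols)]
        for rank, name in enumerate(ranked, start=1):
            r = by_name[name]
            score = "" if r.score is None else f"{r.score:.4f}"
            for outcome in r.outcomes:
                cells = _outcome_cells(outcome)
                lines.append(
                    "\t".join(
                        [name, str(rank), r.verdict, score]
                        + [cells[c] for c in cols[4:]]
                    )
                )
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        payload = {
            "ranking": ranked,
            "provenance": dict(report.provenance),
            "models": {
                name: {
                    "verdict": by_name[name].verdict,
                    "score": by_name[name].score,
                    "outcomes": [
                        _outcome_cells(o) for o in by_name[name].outcomes
                    ],
                }
                for name in ranked
            },
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    elif format == "text":
        lines = ["Screening summary (best first)", "=" * 32]
        for rank, name in enumerate(ranked, start=1):
            r = by_name[name]
            score = "n/a" if r.score is None else f"{r.score:.3f}"
            lines.append(f"{rank:2d}. {name:6s} {r.verdict:10s} score={score}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unknown report format {format!r}")
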