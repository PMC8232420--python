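"""Drug records, tabular I/O, and the descriptor pipeline.

Input drug tables are CSV/TSV with the columns
``id,name,smiles,formula,dili_class,atc_codes,year,peptide_flag,nucleic_acid_flag``
(``atc_codes`` semicolon-separated; ``dili_class`` one of Most/Less/No).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import pandas as pd

from .composition import Composition, amw, h_percent, molecular_weight, parse_formula
from .masses import MassTable
from .structures import (
    DEFAULT_SALT_SMILES,
    ORGANIC_ELEMENTS,
    StandardizationError,
    StandardizationLog,
    exclusion_check,
    parse_smiles,
    standardize,
)

__all__ = [
    "DiliClass",
    "DrugRecord",
    "load_drug_table",
    "records_to_frame",
    "compute_descriptors",
    "DESCRIPTOR_COLUMNS",
]

DESCRIPTOR_COLUMNS = ("AMW", "H_PERCENT", "MW", "N_ATOMS", "MLOGP")


class DiliClass(str, Enum):
    MOST = "Most"
    LESS = "Less"
    NO = "No"

    @classmethod
    def parse(cls, value: str) -> "DiliClass":
        v = str(value).strip().lower()
        for member in cls:
            if member.value.lower() == v:
                return member
        raise ValueError(f"unknown DILI class {value!r} (expected Most/Less/No)")


@dataclass
class DrugRecord:
    """One drug: identifiers, structure, label, annotations."""

    id: str
    name: str = ""
    smiles: str | None = None
    formula: str | None = None
    dili_class: DiliClass | None = None
    atc_codes: list[str] = field(default_factory=list)
    year: int | None = None
    peptide_flag: bool = False
    nucleic_acid_flag: bool = False
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def dili_label(self) -> int | None:
        """Binary label: Most/Less -> 1 (DILI), No -> 0."""
        if self.dili_class is None:
            return None
        return 0 if self.dili_class is DiliClass.NO else 1

    def validate(self) -> None:
        if not self.excluded and self.smiles is None and self.formula is None:
            raise ValueError(
                f"record {self.id!r}: need smiles or formula for a non-excluded drug"
            )


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    s = str(value).strip().lower()
    return s in ("1", "true", "yes", "t", "y")


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def load_drug_table(path: str | Path) -> list[DrugRecord]:
    """Read a drug table; the separator is taken from the extension
    (``.tsv`` -> tab, otherwise comma)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    if "id" not in frame.columns:
        raise ValueError(f"{path}: drug table must have an 'id' column")
    records = []
    for i, row in frame.iterrows():
        raw = row.to_dict()
        cls = _opt_str(raw.get("dili_class"))
        atc_raw = _opt_str(raw.get("atc_codes"))
        year_raw = _opt_str(raw.get("year"))
        try:
            rec = DrugRecord(
                id=str(raw["id"]).strip(),
                name=_opt_str(raw.get("name")) or "",
                smiles=_opt_str(raw.get("smiles")),
                formula=_opt_str(raw.get("formula")),
                dili_class=DiliClass.parse(cls) if cls else None,
                atc_codes=[c.strip() for c in atc_raw.split(";") if c.strip()]
                if atc_raw
                else [],
                year=int(float(year_raw)) if year_raw else None,
                peptide_flag=_parse_bool(raw.get("peptide_flag")),
                nucleic_acid_flag=_parse_bool(raw.get("nucleic_acid_flag")),
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
        records.append(rec)
    return records


def load_smiles_file(path: str | Path) -> list[DrugRecord]:
    """Read a SMILES file: one record per line, ``SMILES<whitespace>id``
    (missing id -> line number)."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split(None, 1)
        smiles = parts[0]
        rec_id = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
        records.append(DrugRecord(id=rec_id, smiles=smiles))
    return records


def records_to_frame(records: list[DrugRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "name": r.name,
                "smiles": r.smiles or "",
                "formula": r.formula or "",
                "dili_class": r.dili_class.value if r.dili_class else "",
                "atc_codes": ";".join(r.atc_codes),
                "year": r.year if r.year is not None else "",
                "peptide_flag": int(r.peptide_flag),
                "nucleic_acid_flag": int(r.nucleic_acid_flag),
            }
        )
    return pd.DataFrame(rows)


def _composition_for(record: DrugRecord, salt_smiles) -> tuple[
    Composition | None, object | None, StandardizationLog | None, str | None
]:
    """Parse + standardize one record.  Returns (composition, molecule,
    audit log, error message); the SMILES path takes precedence."""
    if record.smiles:
        mol = parse_smiles(record.smiles)
        try:
            std, log = standardize(mol, tuple(salt_smiles))
        except StandardizationError as exc:
            return None, None, None, str(exc)
        return std.composition(), std, log, None
    if record.formula:
        return parse_formula(record.formula), None, None, None
    return None, None, None, "no structure"


def compute_descriptors(
    records: list[DrugRecord],
    masses: MassTable | None = None,
    salt_smiles=DEFAULT_SALT_SMILES,
    mlogp: dict[str, float] | None = None,
    compute_mlogp: bool = True,
) -> tuple[pd.DataFrame, list[str], list[DrugRecord]]:
    """Standardize every record and compute the constitutional descriptors.

    Returns ``(table, audit_lines, updated_records)`` where *table* has one
    row per non-excluded drug with columns ``id`` + AMW, H_PERCENT, MW,
    N_ATOMS and MLOGP (NaN when unavailable).  ``mlogp`` supplies precomputed
    values by drug id and always wins over the calculator (pass-through
    mode); excluded drugs get an audit line but no descriptor row.
    """
    table = masses if masses is not None else MassTable.default()
    rows: list[dict] = []
    audit: list[str] = []
    updated: list[DrugRecord] = []

    for rec in records:
        rec.validate()
        comp, molecule, log, err = _composition_for(rec, salt_smiles)
        if err is not None:
            out = replace(rec, excluded=True, exclusion_reason=err)
            audit.append(f"{rec.id}\texcluded: {err}")
            updated.append(out)
            continue

        if molecule is not None:
            excluded, reason = exclusion_check(
                molecule, rec.peptide_flag, rec.nucleic_acid_flag
            )
        else:
            # Formula-only path: apply the metal rule on parsed elements.
            offending = sorted(set(comp.counts) - ORGANIC_ELEMENTS)
            if rec.peptide_flag:
                excluded, reason = True, "peptide annotation"
            elif rec.nucleic_acid_flag:
                excluded, reason = True, "nucleic-acid annotation"
            elif offending:
                excluded, reason = True, "metal-containing: " + ",".join(offending)
            else:
                excluded, reason = False, None

        if excluded:
            out = replace(rec, excluded=True, exclusion_reason=reason)
            audit.append(f"{rec.id}\texcluded: {reason}")
            updated.append(out)
            continue

        mlogp_value = float("nan")
        if mlogp is not None and rec.id in mlogp:
            mlogp_value = float(mlogp[rec.id])
        elif compute_mlogp and molecule is not None:
            from .mlogp import MlogpError, moriguchi_logp

            try:
                mlogp_value = moriguchi_logp(molecule)
            except MlogpError:
                mlogp_value = float("nan")

        rows.append(
            {
                "id": rec.id,
                "AMW": amw(comp, table),
                "H_PERCENT": h_percent(comp),
                "MW": molecular_weight(comp, table),
                "N_ATOMS": comp.total_atoms,
                "MLOGP": mlogp_value,
            }
        )
        audit.append(log.as_line(rec.id) if log is not None else f"{rec.id}\tunchanged")
        updated.append(replace(rec))

    return pd.DataFrame(rows, columns=("id",) + DESCRIPTOR_COLUMNS), audit, updated
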