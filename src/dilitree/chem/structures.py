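"""Structure handling: SMILES parsing, desalting/neutralization, and the
organic-element exclusion rule.

The molecular-graph layer is backed by RDKit (standard organic-subset valence
model) behind a thin :class:`Molecule` wrapper; parse failures always raise,
never return a silently wrong composition.  Composition extraction and all
descriptor arithmetic stay in :mod:`dilitree.chem.composition`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from .composition import Composition

__all__ = [
    "Molecule",
    "SmilesParseError",
    "StandardizationError",
    "StandardizationLog",
    "DEFAULT_SALT_SMILES",
    "ORGANIC_ELEMENTS",
    "parse_smiles",
    "standardize",
    "exclusion_check",
]

#: Elements allowed to remain after standardization; anything else flags the
#: structure as metal-containing and excluded from the analysis.
ORGANIC_ELEMENTS: frozenset[str] = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"}
)

#: Common pharmaceutical counterions removed during desalting (versioned
#: configuration, matched by canonical SMILES).  Both ionic and neutral acid
#: forms are listed where relevant.
DEFAULT_SALT_SMILES: tuple[str, ...] = (
    # halides / hydrohalic acids
    "[F-]", "[Cl-]", "[Br-]", "[I-]", "F", "Cl", "Br", "I",
    # alkali / alkaline-earth and other simple cations
    "[Li+]", "[Na+]", "[K+]", "[Rb+]", "[Cs+]",
    "[Mg+2]", "[Ca+2]", "[Sr+2]", "[Ba+2]", "[Zn+2]", "[Al+3]",
    # ammonium, water
    "[NH4+]", "O",
    # sulfate / bisulfate
    "OS(=O)(=O)O", "OS(=O)(=O)[O-]", "[O-]S(=O)(=O)[O-]",
    # nitrate
    "O[N+](=O)[O-]", "[O-][N+](=O)[O-]",
    # phosphate series
    "OP(=O)(O)O", "[O-]P(=O)(O)O", "[O-]P(=O)([O-])O", "[O-]P(=O)([O-])[O-]",
    # methanesulfonate (mesylate)
    "CS(=O)(=O)O", "CS(=O)(=O)[O-]",
    # p-toluenesulfonate (tosylate)
    "Cc1ccc(S(=O)(=O)O)cc1", "Cc1ccc(S(=O)(=O)[O-])cc1",
    # maleate / fumarate
    "OC(=O)/C=C\\C(=O)O", "OC(=O)/C=C\\C(=O)[O-]", "[O-]C(=O)/C=C\\C(=O)[O-]",
    "OC(=O)/C=C/C(=O)O", "OC(=O)/C=C/C(=O)[O-]", "[O-]C(=O)/C=C/C(=O)[O-]",
    # tartrate
    "OC(=O)C(O)C(O)C(=O)O", "OC(=O)C(O)C(O)C(=O)[O-]",
    "[O-]C(=O)C(O)C(O)C(=O)[O-]",
    # citrate
    "OC(=O)CC(O)(CC(=O)O)C(=O)O", "OC(=O)CC(O)(CC(=O)[O-])C(=O)O",
    "[O-]C(=O)CC(O)(CC(=O)[O-])C(=O)[O-]",
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a valid graph."""


class StandardizationError(ValueError):
    """Raised when standardization cannot produce a parent structure."""


def _rdkit():
    try:
        from rdkit import Chem, RDLogger
    except ImportError as exc:  # pragma: no cover - environment guard
        raise ImportError(
            "the SMILES path requires rdkit; install dilitree[chem] or supply "
            "molecular formulas instead"
        ) from exc
    RDLogger.DisableLog("rdApp.*")
    return Chem


@lru_cache(maxsize=1)
def _canonical_salt_set(salts: tuple[str, ...]) -> frozenset[str]:
    Chem = _rdkit()
    out = set()
    for smi in salts:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # pragma: no cover - list is static and valid
            raise ValueError(f"invalid salt SMILES in configuration: {smi!r}")
        out.add(Chem.MolToSmiles(mol))
    return frozenset(out)


@dataclass(frozen=True)
class Molecule:
    """A parsed molecular graph (possibly multi-component)."""

    mol: object  # rdkit.Chem.Mol

    @property
    def canonical_smiles(self) -> str:
        return _rdkit().MolToSmiles(self.mol)

    @property
    def net_charge(self) -> int:
        return _rdkit().GetFormalCharge(self.mol)

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def components(self) -> list["Molecule"]:
        Chem = _rdkit()
        frags = Chem.GetMolFrags(self.mol, asMols=True, sanitizeFrags=True)
        return [Molecule(f) for f in frags]

    def composition(self) -> Composition:
        """Element counts with implicit hydrogens resolved explicitly."""
        counts: dict[str, int] = {}
        for atom in self.mol.GetAtoms():
            sym = atom.GetSymbol()
            counts[sym] = counts.get(sym, 0) + 1
            nh = atom.GetTotalNumHs()
            if nh:
                counts["H"] = counts.get("H", 0) + nh
        return Composition(counts, self.net_charge)

    def elements(self) -> frozenset[str]:
        return frozenset(self.composition().counts)


def parse_smiles(smiles: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Implicit hydrogen counts follow the standard organic-subset default
    valences, adjusted for formal charge and explicit bonds.  Any input the
    valence model cannot sanitize raises :class:`SmilesParseError` — there is
    no silent fallback.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError("empty SMILES")
    Chem = _rdkit()
    mol = Chem.MolFromSmiles(smiles.strip())
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES {smiles.strip()!r}")
    return Molecule(mol)


@dataclass
class StandardizationLog:
    """Audit record of one standardization: what was removed and changed."""

    removed_components: list[str] = field(default_factory=list)
    kept_component: str | None = None
    discarded_components: list[str] = field(default_factory=list)
    neutralized_sites: int = 0
    multi_component_choice: bool = False

    def as_line(self, drug_id: str = "") -> str:
        parts = []
        if self.removed_components:
            parts.append("removed=" + ",".join(self.removed_components))
        if self.multi_component_choice:
            parts.append("kept_largest=" + (self.kept_component or ""))
            parts.append("discarded=" + ",".join(self.discarded_components))
        if self.neutralized_sites:
            parts.append(f"neutralized_sites={self.neutralized_sites}")
        if not parts:
            parts.append("unchanged")
        prefix = f"{drug_id}\t" if drug_id else ""
        return prefix + ";".join(parts)


# Neutralizes charged atoms that are not part of a zwitterionic pair:
# cations carrying at least one H are deprotonated, anions are protonated.
_NEUTRALIZE_SMARTS = "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"


def _neutralize(mol, Chem) -> tuple[object, int]:
    pattern = Chem.MolFromSmarts(_NEUTRALIZE_SMARTS)
    matches = [idx for (idx,) in mol.GetSubstructMatches(pattern)]
    if not matches:
        return mol, 0
    mol = Chem.RWMol(mol)
    for idx in matches:
        atom = mol.GetAtomWithIdx(idx)
        chg = atom.GetFormalCharge()
        h = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(h - chg)
        atom.UpdatePropertyCache()
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out, len(matches)


def standardize(
    molecule: Molecule, salt_smiles: tuple[str, ...] = DEFAULT_SALT_SMILES
) -> tuple[Molecule, StandardizationLog]:
    """Desalt and neutralize a (possibly multi-component) structure.

    Components whose canonical SMILES is on the salt list are removed; if
    several non-salt components remain, the one with the most heavy atoms is
    kept and the choice is logged; remaining charged sites are neutralized
    where chemically consistent.  Idempotent.

    Raises
    ------
    StandardizationError
        If every component is on the salt list ("no parent structure").
    """
    Chem = _rdkit()
    salt_set = _canonical_salt_set(tuple(salt_smiles))
    log = StandardizationLog()

    components = molecule.components
    parents = []
    for comp in components:
        smi = comp.canonical_smiles
        if smi in salt_set:
            log.removed_components.append(smi)
        else:
            parents.append(comp)

    if not parents:
        raise StandardizationError(
            "no parent structure: all components are on the salt list"
        )

    if len(parents) > 1:
        parents.sort(key=lambda m: m.num_heavy_atoms, reverse=True)
        log.multi_component_choice = True
        log.kept_component = parents[0].canonical_smiles
        log.discarded_components = [p.canonical_smiles for p in parents[1:]]
    parent = parents[0]

    neutral_mol, n_sites = _neutralize(parent.mol, Chem)
    log.neutralized_sites = n_sites
    return Molecule(neutral_mol), log


def exclusion_check(
    molecule: Molecule | None,
    peptide_flag: bool = False,
    nucleic_acid_flag: bool = False,
) -> tuple[bool, str | None]:
    """Return ``(excluded, reason)`` for a standardized structure.

    A drug is excluded if any atom falls outside the organic element set
    (metal rule) or if it carries a peptide / nucleic-acid annotation flag.
    Annotation flags take precedence so the reason is stable even when the
    structure is also inorganic.
    """
    if peptide_flag:
        return True, "peptide annotation"
    if nucleic_acid_flag:
        return True, "nucleic-acid annotation"
    if molecule is not None:
        offending = sorted(molecule.elements() - ORGANIC_ELEMENTS)
        if offending:
            return True, "metal-containing: " + ",".join(offending)
    return False, None
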