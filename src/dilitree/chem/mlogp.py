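"""Moriguchi-style calculated logP.

The lipophilicity feature used at the screening rule's second node is treated
as pluggable and opaque by the rest of the pipeline: precomputed values in an
input column always take precedence.  This module provides a calculator for
when no precomputed column exists, implementing the classic 13-parameter
regression

    logP = -1.041 + 1.244*CX^0.6 - 1.017*NO^0.6 + 0.406*PRX - 0.145*UB^0.9
           + 0.511*HB + 0.268*POL - 2.215*AMP + 0.912*ALK - 0.392*RNG
           - 3.684*QN + 0.474*NO2 + 1.582*NCS + 0.773*BLM

with structural parameters extracted from the molecular graph.  CX, NO, PRX,
UB, QN, NO2, NCS, BLM, ALK and RNG follow the published definitions; HB, POL
and AMP are SMARTS heuristics (their original definitions are partly verbal)
— see the per-term comments.  Unsupported structures raise, never return a
silent default.
"""

from __future__ import annotations

from .structures import Molecule, _rdkit

__all__ = ["moriguchi_logp", "moriguchi_features", "MlogpError", "COEFFICIENTS"]

#: Elements the regression was parameterized for (no B or Si, although the
#: wider pipeline accepts them).
MLOGP_ELEMENTS: frozenset[str] = frozenset(
    {"H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I"}
)

#: Regression coefficients, term name -> weight (intercept under "const").
COEFFICIENTS: dict[str, float] = {
    "const": -1.041,
    "CX": 1.244,    # applied to CX**0.6
    "NO": -1.017,   # applied to NO**0.6
    "PRX": 0.406,
    "UB": -0.145,   # applied to UB**0.9
    "HB": 0.511,
    "POL": 0.268,
    "AMP": -2.215,
    "ALK": 0.912,
    "RNG": -0.392,
    "QN": -3.684,
    "NO2": 0.474,
    "NCS": 1.582,
    "BLM": 0.773,
}

_HALOGEN_WEIGHT = {"F": 0.5, "Cl": 1.0, "Br": 1.5, "I": 2.0}


class MlogpError(ValueError):
    """Raised for structures outside the calculator's applicability domain."""


def _smarts(Chem, pattern: str):
    m = Chem.MolFromSmarts(pattern)
    if m is None:  # pragma: no cover - patterns are static
        raise ValueError(f"bad SMARTS {pattern!r}")
    return m


def moriguchi_features(molecule: Molecule) -> dict[str, float]:
    """Extract the 13 structural parameters of the regression."""
    Chem = _rdkit()
    mol = molecule.mol

    bad = sorted(molecule.elements() - MLOGP_ELEMENTS)
    if bad:
        raise MlogpError(f"unsupported element(s) for calculated logP: {','.join(bad)}")
    if mol.GetNumAtoms() == 0:
        raise MlogpError("empty structure")

    f: dict[str, float] = {}

    # CX: carbons plus halogens, halogens weighted F 0.5 / Cl 1.0 / Br 1.5 / I 2.0.
    cx = 0.0
    n_no = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "C":
            cx += 1.0
        elif sym in _HALOGEN_WEIGHT:
            cx += _HALOGEN_WEIGHT[sym]
        elif sym in ("N", "O"):
            n_no += 1
    f["CX"] = cx
    f["NO"] = float(n_no)

    # PRX: proximity effect of N/O — 2 per directly bonded N/O pair, 1 per
    # pair separated by one atom; a carboxamide O=C-N is counted as 2.
    hetero = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O")]
    prx = 0.0
    if len(hetero) >= 2:
        dm = Chem.GetDistanceMatrix(mol)
        for i, ai in enumerate(hetero):
            for aj in hetero[i + 1:]:
                d = dm[ai][aj]
                if d == 1:
                    prx += 2.0
                elif d == 2:
                    prx += 1.0
        amide = _smarts(Chem, "[OX1]=[CX3][NX3]")
        prx += float(len(mol.GetSubstructMatches(amide)))
    f["PRX"] = prx

    # UB: unsaturated bonds in the kekulized graph (double 1, triple 2),
    # excluding the N=O bonds of nitro groups.
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    nitro = _smarts(Chem, "[$([NX3](=O)=O),$([NX3+](=O)[O-])]")
    nitro_n = {m[0] for m in mol.GetSubstructMatches(nitro)}
    ub = 0.0
    for bond in kek.GetBonds():
        order = bond.GetBondTypeAsDouble()
        if order < 2:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if (a.GetIdx() in nitro_n and b.GetSymbol() == "O") or (
            b.GetIdx() in nitro_n and a.GetSymbol() == "O"
        ):
            continue
        ub += order - 1.0
    f["UB"] = ub

    # HB: dummy for intramolecular hydrogen bonding (heuristic: aromatic
    # ortho donor/acceptor arrangement, e.g. salicylate-like motifs).
    hb_patterns = (
        "[OX2H,NX3;H1,H2]-c:c-[CX3]=[OX1]",
        "[OX2H,NX3;H1,H2]-c:c-[N+](=O)[O-]",
    )
    f["HB"] = float(
        any(mol.HasSubstructMatch(_smarts(Chem, p)) for p in hb_patterns)
    )

    # POL: polar substituents attached to aromatic rings (heuristic: an
    # aromatic-ring neighbor that is a heteroatom/halogen, or a carbon whose
    # other neighbors include one).
    polar_syms = {"N", "O", "S", "P", "F", "Cl", "Br", "I"}
    pol = 0
    for atom in mol.GetAtoms():
        if not atom.GetIsAromatic():
            continue
        for nbr in atom.GetNeighbors():
            if nbr.GetIsAromatic():
                continue
            if nbr.GetSymbol() in polar_syms:
                pol += 1
            elif nbr.GetSymbol() == "C" and any(
                n2.GetSymbol() in polar_syms
                for n2 in nbr.GetNeighbors()
                if n2.GetIdx() != atom.GetIdx()
            ):
                pol += 1
    f["POL"] = float(pol)

    # AMP: amphoteric property — alpha-amino acid 1.0; aminobenzoic or
    # pyridinecarboxylic acid 0.5 (heuristic SMARTS).
    amp = 0.0
    if mol.HasSubstructMatch(
        _smarts(Chem, "[NX3;H2,H1;!$(NC=O)][CX4][CX3](=O)[OX2H1,OX1-]")
    ):
        amp = 1.0
    elif mol.HasSubstructMatch(_smarts(Chem, "[NX3;H2]c1ccccc1")) and mol.HasSubstructMatch(
        _smarts(Chem, "c[CX3](=O)[OX2H1,OX1-]")
    ):
        amp = 0.5
    elif mol.HasSubstructMatch(_smarts(Chem, "n")) and mol.HasSubstructMatch(
        _smarts(Chem, "c[CX3](=O)[OX2H1,OX1-]")
    ):
        amp = 0.5
    f["AMP"] = amp

    # ALK: dummy for pure hydrocarbons with at most one double bond and no
    # triple bond or aromatic ring (alkane/alkene/cycloalkane/cycloalkene).
    elements = molecule.elements()
    is_hydrocarbon = elements <= {"C", "H"}
    has_aromatic = any(a.GetIsAromatic() for a in mol.GetAtoms())
    n_double = sum(
        1 for b in mol.GetBonds() if b.GetBondTypeAsDouble() == 2.0
    )
    n_triple = sum(
        1 for b in mol.GetBonds() if b.GetBondTypeAsDouble() == 3.0
    )
    f["ALK"] = float(
        is_hydrocarbon and not has_aromatic and n_triple == 0 and n_double <= 1
    )

    # RNG: dummy for ring structures other than plain benzenoid carbocycles.
    ring_info = mol.GetRingInfo()
    rng = 0.0
    for ring in ring_info.AtomRings():
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        benzenoid = (
            len(ring) == 6
            and all(a.GetIsAromatic() and a.GetSymbol() == "C" for a in atoms)
        )
        if not benzenoid:
            rng = 1.0
            break
    f["RNG"] = rng

    # QN: quaternary nitrogen 1.0, N-oxide 0.5 (dummy).
    if mol.HasSubstructMatch(_smarts(Chem, "[NX4,NX4+]")):
        f["QN"] = 1.0
    elif mol.HasSubstructMatch(_smarts(Chem, "[NX3+]-[OX1-]")):
        f["QN"] = 0.5
    else:
        f["QN"] = 0.0

    # NO2: number of nitro groups.
    f["NO2"] = float(len(mol.GetSubstructMatches(nitro)))

    # NCS: isothiocyanate 1.0 per group, thiocyanate 0.5 per group.
    ncs = 1.0 * len(mol.GetSubstructMatches(_smarts(Chem, "[NX2]=C=[SX1]")))
    ncs += 0.5 * len(mol.GetSubstructMatches(_smarts(Chem, "[SX2][CX2]#[NX1]")))
    f["NCS"] = ncs

    # BLM: dummy for a beta-lactam ring.
    f["BLM"] = float(mol.HasSubstructMatch(_smarts(Chem, "O=C1CCN1")))

    return f


def moriguchi_logp(molecule: Molecule) -> float:
    """Predicted octanol/water logP for a standardized single-component
    structure.  Raises :class:`MlogpError` on unsupported features."""
    f = moriguchi_features(molecule)
    c = COEFFICIENTS
    return (
        c["const"]
        + c["CX"] * f["CX"] ** 0.6
        + c["NO"] * f["NO"] ** 0.6
        + c["PRX"] * f["PRX"]
        + c["UB"] * f["UB"] ** 0.9
        + c["HB"] * f["HB"]
        + c["POL"] * f["POL"]
        + c["AMP"] * f["AMP"]
        + c["ALK"] * f["ALK"]
        + c["RNG"] * f["RNG"]
        + c["QN"] * f["QN"]
        + c["NO2"] * f["NO2"]
        + c["NCS"] * f["NCS"]
        + c["BLM"] * f["BLM"]
    )
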