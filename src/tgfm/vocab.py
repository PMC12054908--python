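"""OGB-convention categorical vocabularies for atoms and bonds.

Molecular graphs carry 9 categorical features per atom and 3 per bond.  The
code tables below follow the Open Graph Benchmark convention used by the
PCQM4Mv2 dataset, with a trailing ``misc`` bucket where the convention has
one.  Feature values outside a table map to ``misc``.
"""

from __future__ import annotations

from rdkit import Chem

VOCAB_VERSION = "ogb-v2"

_ATOM_FEATURES: dict[str, list] = {
    "atomic_num": list(range(1, 119)) + ["misc"],
    "chirality": [
        "CHI_UNSPECIFIED",
        "CHI_TETRAHEDRAL_CW",
        "CHI_TETRAHEDRAL_CCW",
        "CHI_OTHER",
        "misc",
    ],
    "degree": [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, "misc"],
    "formal_charge": [-5, -4, -3, -2, -1, 0, 1, 2, 3, 4, 5, "misc"],
    "num_h": [0, 1, 2, 3, 4, 5, 6, 7, 8, "misc"],
    "num_radical_e": [0, 1, 2, 3, 4, "misc"],
    "hybridization": ["SP", "SP2", "SP3", "SP3D", "SP3D2", "misc"],
    "is_aromatic": [False, True],
    "is_in_ring": [False, True],
}

_BOND_FEATURES: dict[str, list] = {
    "bond_type": ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC", "misc"],
    "stereo": [
        "STEREONONE",
        "STEREOZ",
        "STEREOE",
        "STEREOCIS",
        "STEREOTRANS",
        "STEREOANY",
    ],
    "is_conjugated": [False, True],
}

ATOM_FEATURE_DIMS: list[int] = [len(v) for v in _ATOM_FEATURES.values()]  # sums to 174
BOND_FEATURE_DIMS: list[int] = [len(v) for v in _BOND_FEATURES.values()]  # sums to 13

# column indices used elsewhere in the package
ATOM_AROMATIC_COL = 7
BOND_TYPE_COL = 0
BOND_CONJUGATED_COL = 2
AROMATIC_BOND_CODE = _BOND_FEATURES["bond_type"].index("AROMATIC")


def _index(table: list, value) -> int:
    try:
        return table.index(value)
    except ValueError:
        return len(table) - 1  # misc bucket


def atom_to_codes(atom: Chem.Atom) -> list[int]:
    """Encode one rdkit atom into the 9 categorical columns."""
    return [
        _index(_ATOM_FEATURES["atomic_num"], atom.GetAtomicNum()),
        _index(_ATOM_FEATURES["chirality"], str(atom.GetChiralTag())),
        _index(_ATOM_FEATURES["degree"], atom.GetTotalDegree()),
        _index(_ATOM_FEATURES["formal_charge"], atom.GetFormalCharge()),
        _index(_ATOM_FEATURES["num_h"], atom.GetTotalNumHs()),
        _index(_ATOM_FEATURES["num_radical_e"], atom.GetNumRadicalElectrons()),
        _index(_ATOM_FEATURES["hybridization"], str(atom.GetHybridization())),
        _index(_ATOM_FEATURES["is_aromatic"], atom.GetIsAromatic()),
        _index(_ATOM_FEATURES["is_in_ring"], atom.IsInRing()),
    ]


def bond_to_codes(bond: Chem.Bond) -> list[int]:
    """Encode one rdkit bond into the 3 categorical columns."""
    return [
        _index(_BOND_FEATURES["bond_type"], str(bond.GetBondType())),
        _index(_BOND_FEATURES["stereo"], str(bond.GetStereo())),
        _index(_BOND_FEATURES["is_conjugated"], bond.GetIsConjugated()),
    ]
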