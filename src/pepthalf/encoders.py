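"""Sequence- and chemistry-derived feature encodings for peptides.

Encoders implemented here:

* amino-acid composition (AAC): 20-dim percent vector;
* dipeptide composition (DPC): 400-dim percent vector over overlapping pairs;
* terminal binary profiles: position-wise one-hot encodings of the first /
  last k residues (k = 5 by default);
* atom composition: percent (or count) of the elements C, H, O, N, S, F,
  Cl, Br in the peptide's molecular formula, obtained either from residue
  formulas (natural peptides) or from a SMILES string (modified peptides);
* physicochemical property panel (length, monoisotopic mass, net charge at
  pH 7, Eisenberg hydrophobicity, aromatic/small/charged percents).

Vector layout is fixed to the alphabetical residue order ACDEFGHIKLMNPQRSTVWY.
Compositions are reported in percent, so AAC, DPC and atom-fraction vectors
each sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import ALPHABET, HalfLifeDataset

_ALPHABET_SET = frozenset(ALPHABET)
#: fixed 400-pair order for DPC vectors
DIPEPTIDES = tuple(a + b for a, b in product(ALPHABET, repeat=2))
#: element order for atom-composition vectors
ELEMENTS = ("C", "H", "O", "N", "S", "F", "Cl", "Br")


class EncodingError(ValueError):
    """A sequence or fragment cannot be encoded."""


class SmilesParseError(ValueError):
    """A SMILES string could not be tokenized; carries the offset."""

    def __init__(self, smiles: str, offset: int, message: str):
        self.offset = offset
        super().__init__(f"cannot parse SMILES at offset {offset} ({message}): {smiles!r}")


@dataclass(frozen=True)
class FeatureVector:
    """A named numeric encoding of one peptide."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.names) != len(values):
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def _check_sequence(sequence: str, min_length: int = 1) -> str:
    sequence = sequence.upper()
    for pos, ch in enumerate(sequence):
        if ch not in _ALPHABET_SET:
            raise EncodingError(
                f"non-standard residue {ch!r} at position {pos + 1}"
            )
    if len(sequence) < min_length:
        raise EncodingError(
            f"sequence of length {len(sequence)} shorter than required {min_length}"
        )
    return sequence


# ---------------------------------------------------------------------------
# composition encoders


def amino_acid_composition(sequence: str) -> FeatureVector:
    """Percent frequency of each of the 20 residues; sums to 100."""
    sequence = _check_sequence(sequence, 1)
    counts = np.array([sequence.count(a) for a in ALPHABET], dtype=float)
    return FeatureVector(tuple(f"AAC_{a}" for a in ALPHABET),
                         100.0 * counts / len(sequence))


def dipeptide_composition(sequence: str) -> FeatureVector:
    """Percent frequency of the 400 overlapping residue pairs; sums to 100."""
    sequence = _check_sequence(sequence, 2)
    counts = dict.fromkeys(DIPEPTIDES, 0)
    for i in range(len(sequence) - 1):
        counts[sequence[i : i + 2]] += 1
    values = 100.0 * np.array([counts[p] for p in DIPEPTIDES], dtype=float) / (
        len(sequence) - 1
    )
    return FeatureVector(tuple(f"DPC_{p}" for p in DIPEPTIDES), values)


def terminal_fragment(sequence: str, end: str, k: int = 5) -> str:
    """First (``end="N"``) or last (``end="C"``) ``k`` residues, N→C order."""
    sequence = _check_sequence(sequence, 1)
    if end not in ("N", "C"):
        raise ValueError(f"end must be 'N' or 'C', got {end!r}")
    if len(sequence) < k:
        raise EncodingError(
            f"sequence of length {len(sequence)} has no {end}-terminal {k}-mer"
        )
    return sequence[:k] if end == "N" else sequence[-k:]


def binary_profile(fragment: str, k: int | None = None) -> FeatureVector:
    """Position-wise one-hot encoding over the 20 residues (20·k dims)."""
    fragment = _check_sequence(fragment, 1)
    if k is not None and len(fragment) != k:
        raise EncodingError(f"fragment length {len(fragment)} != expected {k}")
    k = len(fragment)
    names, values = [], np.zeros(20 * k)
    for pos, ch in enumerate(fragment):
        for j, a in enumerate(ALPHABET):
            names.append(f"P{pos + 1}_{a}")
        values[20 * pos + ALPHABET.index(ch)] = 1.0
    return FeatureVector(tuple(names), values)


# ---------------------------------------------------------------------------
# molecular formulas and atom composition

#: molecular formulas of the free amino acids (C, H, N, O, S)
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "A": {"C": 3, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 7, "N": 1, "O": 2, "S": 1},
    "D": {"C": 4, "H": 7, "N": 1, "O": 4},
    "E": {"C": 5, "H": 9, "N": 1, "O": 4},
    "F": {"C": 9, "H": 11, "N": 1, "O": 2},
    "G": {"C": 2, "H": 5, "N": 1, "O": 2},
    "H": {"C": 6, "H": 9, "N": 3, "O": 2},
    "I": {"C": 6, "H": 13, "N": 1, "O": 2},
    "K": {"C": 6, "H": 14, "N": 2, "O": 2},
    "L": {"C": 6, "H": 13, "N": 1, "O": 2},
    "M": {"C": 5, "H": 11, "N": 1, "O": 2, "S": 1},
    "N": {"C": 4, "H": 8, "N": 2, "O": 3},
    "P": {"C": 5, "H": 9, "N": 1, "O": 2},
    "Q": {"C": 5, "H": 10, "N": 2, "O": 3},
    "R": {"C": 6, "H": 14, "N": 4, "O": 2},
    "S": {"C": 3, "H": 7, "N": 1, "O": 3},
    "T": {"C": 4, "H": 9, "N": 1, "O": 3},
    "V": {"C": 5, "H": 11, "N": 1, "O": 2},
    "W": {"C": 11, "H": 12, "N": 2, "O": 2},
    "Y": {"C": 9, "H": 11, "N": 1, "O": 3},
}


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts of a molecule (C, H, N, O, S and optionally halogens)."""

    counts: dict[str, int]

    def __post_init__(self):
        clean = {el: int(n) for el, n in self.counts.items() if n}
        if any(n < 0 for n in clean.values()):
            raise ValueError(f"negative element count in {clean}")
        if not clean:
            raise ValueError("empty molecular formula")
        unknown = set(clean) - set(ELEMENTS)
        if unknown:
            raise ValueError(f"unsupported element(s) {sorted(unknown)}")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def __str__(self) -> str:
        return "".join(
            f"{el}{self[el] if self[el] != 1 else ''}" for el in ELEMENTS if self[el]
        )


def peptide_molecular_formula(sequence: str) -> MolecularFormula:
    """Molecular formula of an unmodified linear peptide.

    Sum of the free amino-acid formulas minus one water per peptide bond;
    free (uncharged) termini, cysteines as free thiols.
    """
    sequence = _check_sequence(sequence, 1)
    counts: dict[str, int] = {}
    for ch in sequence:
        for el, n in RESIDUE_FORMULAS[ch].items():
            counts[el] = counts.get(el, 0) + n
    n_bonds = len(sequence) - 1
    counts["H"] -= 2 * n_bonds
    counts["O"] -= n_bonds
    return MolecularFormula(counts)


def atom_composition(formula: MolecularFormula, mode: str = "fraction") -> FeatureVector:
    """8-dim atom-composition vector (C, H, O, N, S, F, Cl, Br).

    ``mode="fraction"`` (the modelling default) reports percent of total
    atoms and sums to 100; ``mode="count"`` reports raw counts.
    """
    counts = np.array([formula[el] for el in ELEMENTS], dtype=float)
    if mode == "count":
        values = counts
    elif mode == "fraction":
        values = 100.0 * counts / counts.sum()
    else:
        raise ValueError(f"mode must be 'fraction' or 'count', got {mode!r}")
    return FeatureVector(tuple(f"ATC_{el}" for el in ELEMENTS), values)


# ---------------------------------------------------------------------------
# SMILES handling
#
# A deliberately small SMILES reader: enough to count atoms (with implicit
# hydrogens) in peptide-like structures.  Stereo markers, isotopes and
# charges are accepted and ignored where they do not affect atom counts.

_DEFAULT_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3,
                    "F": 1, "Cl": 1, "Br": 1, "I": 1, "B": 3}
_ORGANIC_TWO = ("Cl", "Br")
_ORGANIC_ONE = set("BCNOSPFI")
_AROMATIC = set("bcnosp")


def smiles_element_counts(smiles: str) -> MolecularFormula:
    """Element counts (including implicit hydrogens) of a SMILES string.

    Implicit hydrogens follow the standard organic-subset convention:
    ``valence - bond order sum`` for aliphatic atoms, with aromatic atoms
    charged one extra bond for the delocalized system.  Bracket atoms carry
    their hydrogen count explicitly.
    """
    if not smiles:
        raise SmilesParseError(smiles, 0, "empty string")
    heavy: list[dict] = []  # {symbol, aromatic, bonds, explicit_h, bracket}
    element_counts: dict[str, int] = {}
    prev: int | None = None  # index of atom awaiting a bond
    pending_bond = 1.0
    stack: list[int | None] = []
    ring_open: dict[str, tuple[int, float]] = {}
    i, n = 0, len(smiles)

    def add_atom(symbol, aromatic, explicit_h, bracket):
        nonlocal prev, pending_bond
        heavy.append(
            {"symbol": symbol, "aromatic": aromatic, "bonds": 0.0,
             "explicit_h": explicit_h, "bracket": bracket}
        )
        idx = len(heavy) - 1
        if prev is not None:
            order = pending_bond
            if order == 1.0 and aromatic and heavy[prev]["aromatic"]:
                order = 1.0  # aromatic-aromatic single counts as sigma bond
            heavy[prev]["bonds"] += order
            heavy[idx]["bonds"] += order
        prev = idx
        pending_bond = 1.0

    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise SmilesParseError(smiles, i, "unclosed bracket")
            body = smiles[i + 1 : j]
            k = 0
            while k < len(body) and body[k].isdigit():  # isotope
                k += 1
            if k >= len(body):
                raise SmilesParseError(smiles, i, "bracket without element")
            if body[k : k + 2] in ("Cl", "Br"):
                sym, aromatic_flag = body[k : k + 2], False
                k += 2
            elif body[k].isupper():
                sym, aromatic_flag = body[k], False
                k += 1
                # two-letter symbols like Se, Si
                if k < len(body) and body[k].islower() and body[k] not in "h@":
                    sym += body[k]
                    k += 1
            elif body[k].islower():
                sym, aromatic_flag = body[k].upper(), True
                k += 1
            else:
                raise SmilesParseError(smiles, i, f"bad bracket atom {body!r}")
            if sym != "H" and sym not in _DEFAULT_VALENCE:
                raise SmilesParseError(smiles, i, f"unsupported element {sym!r}")
            # stereo markers
            while k < len(body) and body[k] == "@":
                k += 1
            h_count = 0
            if k < len(body) and body[k] in "Hh":
                k += 1
                num = ""
                while k < len(body) and body[k].isdigit():
                    num += body[k]
                    k += 1
                h_count = int(num) if num else 1
            # charges (ignored for atom counting)
            while k < len(body) and body[k] in "+-0123456789":
                k += 1
            if k != len(body):
                raise SmilesParseError(smiles, i, f"trailing bracket text {body[k:]!r}")
            add_atom(sym, aromatic_flag, h_count, True)
            i = j + 1
        elif smiles[i : i + 2] in _ORGANIC_TWO:
            add_atom(smiles[i : i + 2], False, None, False)
            i += 2
        elif ch in _ORGANIC_ONE:
            add_atom(ch, False, None, False)
            i += 1
        elif ch in _AROMATIC:
            add_atom(ch.upper(), True, None, False)
            i += 1
        elif ch in "-=#:/\\":
            pending_bond = {"-": 1.0, "=": 2.0, "#": 3.0, ":": 1.0,
                            "/": 1.0, "\\": 1.0}[ch]
            i += 1
        elif ch == "(":
            stack.append(prev)
            i += 1
        elif ch == ")":
            if not stack:
                raise SmilesParseError(smiles, i, "unmatched ')'")
            prev = stack.pop()
            i += 1
        elif ch.isdigit() or ch == "%":
            if ch == "%":
                label = smiles[i + 1 : i + 3]
                i += 3
            else:
                label = ch
                i += 1
            if prev is None:
                raise SmilesParseError(smiles, i, "ring bond before any atom")
            if label in ring_open:
                other, order = ring_open.pop(label)
                order = max(order, pending_bond)
                heavy[other]["bonds"] += order
                heavy[prev]["bonds"] += order
            else:
                ring_open[label] = (prev, pending_bond)
            pending_bond = 1.0
        elif ch == ".":
            prev = None
            i += 1
        else:
            raise SmilesParseError(smiles, i, f"unexpected character {ch!r}")
    if ring_open:
        raise SmilesParseError(smiles, n, f"unclosed ring bond(s) {sorted(ring_open)}")
    if stack:
        raise SmilesParseError(smiles, n, "unclosed branch")

    for atom in heavy:
        element_counts[atom["symbol"]] = element_counts.get(atom["symbol"], 0) + 1
    n_h = 0
    for atom in heavy:
        if atom["bracket"]:
            n_h += atom["explicit_h"]
            continue
        valence = _DEFAULT_VALENCE.get(atom["symbol"])
        if valence is None:
            raise SmilesParseError(smiles, 0, f"no default valence for {atom['symbol']}")
        used = atom["bonds"] + (1 if atom["aromatic"] else 0)
        n_h += max(0, int(round(valence - used)))
    if n_h:
        element_counts["H"] = element_counts.get("H", 0) + n_h
    return MolecularFormula(element_counts)


#: side-chain SMILES fragments, branch off the alpha carbon (G empty, P cyclic)
_SIDE_CHAIN_SMILES = {
    "A": "C", "C": "CS", "D": "CC(=O)O", "E": "CCC(=O)O", "F": "Cc1ccccc1",
    "G": "", "H": "Cc1c[nH]cn1", "I": "C(C)CC", "K": "CCCCN", "L": "CC(C)C",
    "M": "CCSC", "N": "CC(N)=O", "Q": "CCC(N)=O", "R": "CCCNC(=N)N",
    "S": "CO", "T": "C(C)O", "V": "C(C)C", "W": "Cc1c[nH]c2ccccc12",
    "Y": "Cc1ccc(O)cc1",
}


def peptide_to_smiles(sequence: str) -> str:
    """Linear SMILES of an unmodified peptide (free termini, no stereo)."""
    sequence = _check_sequence(sequence, 1)
    parts = []
    for ch in sequence:
        if ch == "P":
            parts.append("N9CCCC9C(=O)")  # pyrrolidine ring, alpha C closes it
        else:
            side = _SIDE_CHAIN_SMILES[ch]
            alpha = f"C({side})" if side else "C"
            parts.append("N" + alpha + "C(=O)")
    return "".join(parts) + "O"


# ---------------------------------------------------------------------------
# physicochemical properties

#: monoisotopic residue masses (peptide-bonded residues), Da
MONOISOTOPIC_RESIDUE_MASS = {
    "A": 71.03711, "C": 103.00919, "D": 115.02694, "E": 129.04259,
    "F": 147.06841, "G": 57.02146, "H": 137.05891, "I": 113.08406,
    "K": 128.09496, "L": 113.08406, "M": 131.04049, "N": 114.04293,
    "P": 97.05276, "Q": 128.05858, "R": 156.10111, "S": 87.03203,
    "T": 101.04768, "V": 99.06841, "W": 186.07931, "Y": 163.06333,
}
WATER_MONOISOTOPIC = 18.010565

#: Eisenberg consensus hydrophobicity scale
EISENBERG_HYDROPHOBICITY = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

_AROMATIC_RESIDUES = set("FWY")
_SMALL_RESIDUES = set("AGSTPCDN")
_NEGATIVE_RESIDUES = set("DE")
_POSITIVE_RESIDUES = set("KR")

PHYSCHEM_NAMES = (
    "length", "molecular_weight", "net_charge", "hydrophobicity",
    "aromatic_percent", "small_percent", "negative_percent", "positive_percent",
)


def physicochemical_properties(sequence: str) -> FeatureVector:
    """Panel of simple physicochemical descriptors of a peptide.

    Net charge at pH 7 uses the coarse convention Asp/Glu −1, Lys/Arg +1,
    His +0.1; hydrophobicity is the mean Eisenberg consensus value.
    """
    sequence = _check_sequence(sequence, 1)
    L = len(sequence)
    mw = sum(MONOISOTOPIC_RESIDUE_MASS[c] for c in sequence) + WATER_MONOISOTOPIC
    charge = sum(
        -1.0 if c in _NEGATIVE_RESIDUES else 1.0 if c in _POSITIVE_RESIDUES
        else 0.1 if c == "H" else 0.0
        for c in sequence
    )
    hydro = float(np.mean([EISENBERG_HYDROPHOBICITY[c] for c in sequence]))
    pct = lambda group: 100.0 * sum(c in group for c in sequence) / L
    values = (L, mw, charge, hydro, pct(_AROMATIC_RESIDUES), pct(_SMALL_RESIDUES),
              pct(_NEGATIVE_RESIDUES), pct(_POSITIVE_RESIDUES))
    return FeatureVector(PHYSCHEM_NAMES, np.array(values, dtype=float))


# ---------------------------------------------------------------------------
# dataset-level encoding and analyses

ENCODERS = {
    "aac": amino_acid_composition,
    "dpc": dipeptide_composition,
    "aac-n5": lambda s: amino_acid_composition(terminal_fragment(s, "N", 5)),
    "aac-c5": lambda s: amino_acid_composition(terminal_fragment(s, "C", 5)),
    "dpc-n5": lambda s: dipeptide_composition(terminal_fragment(s, "N", 5)),
    "dpc-c5": lambda s: dipeptide_composition(terminal_fragment(s, "C", 5)),
    "binary-n5": lambda s: binary_profile(terminal_fragment(s, "N", 5), 5),
    "binary-c5": lambda s: binary_profile(terminal_fragment(s, "C", 5), 5),
    "atom": lambda s: atom_composition(peptide_molecular_formula(s)),
    "physchem": physicochemical_properties,
}


def encode_dataset(ds: HalfLifeDataset, encoder) -> pd.DataFrame:
    """Feature matrix (peptides × features) for a dataset; index = ids."""
    if isinstance(encoder, str):
        encoder = ENCODERS[encoder]
    rows, ids = [], []
    for rec in ds:
        if rec.sequence is None:
            raise EncodingError(f"record {rec.id!r} has no sequence to encode")
        fv = encoder(rec.sequence)
        rows.append(fv.to_series())
        ids.append(rec.id)
    return pd.DataFrame(rows, index=ids)


def feature_halflife_correlations(ds: HalfLifeDataset, encoder) -> pd.DataFrame:
    """Pearson r of each feature against log2 half-life.

    Zero-variance features are flagged ``undefined`` (r = NaN), not zero.
    Returns a frame with columns ``feature, r, undefined`` sorted by input
    feature order.
    """
    if len(ds) < 3:
        raise ValueError(f"need at least 3 records for correlations, got {len(ds)}")
    X = encode_dataset(ds, encoder)
    y = ds.log2_half_lives
    rows = []
    for name in X.columns:
        col = X[name].to_numpy()
        if np.ptp(col) == 0 or np.ptp(y) == 0:
            rows.append((name, np.nan, True))
        else:
            rows.append((name, float(stats.pearsonr(col, y).statistic), False))
    return pd.DataFrame(rows, columns=["feature", "r", "undefined"])


def extreme_group_comparison(ds: HalfLifeDataset, k: int = 20) -> dict[str, pd.Series]:
    """Mean AAC and physicochemical profiles of the k longest- vs k
    shortest-half-life peptides, plus their (long − short) differences.

    Ties in half-life are broken by input order; the two groups are disjoint.
    """
    if len(ds) < 2 * k:
        raise ValueError(f"need at least {2 * k} records for k={k}, got {len(ds)}")
    # one stable descending sort; taking head and tail keeps the groups
    # disjoint even when ties span the boundary
    order = np.argsort([-r.log2_half_life for r in ds], kind="stable")
    long_idx, short_idx = order[:k], order[len(ds) - k :]
    long_ds = HalfLifeDataset([ds[i] for i in sorted(long_idx)])
    short_ds = HalfLifeDataset([ds[i] for i in sorted(short_idx)])
    out = {}
    for label, sub in (("long", long_ds), ("short", short_ds)):
        out[f"{label}_aac"] = encode_dataset(sub, amino_acid_composition).mean()
        out[f"{label}_physchem"] = encode_dataset(sub, physicochemical_properties).mean()
    out["aac_difference"] = out["long_aac"] - out["short_aac"]
    out["physchem_difference"] = out["long_physchem"] - out["short_physchem"]
    return out
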