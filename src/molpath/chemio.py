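"""Compound parsing, featurization, dataset I/O and synthetic fixtures.

Molecules are exchanged as SMILES strings and represented internally in two
parallel forms: a molecular graph (atoms as nodes, bonds as directed edges,
one feature row per heavy atom) for the graph branch of the network, and a
padded character-level token sequence for the text branch.

Datasets are UTF-8 CSV files with columns ``smiles`` and ``labels``, the
latter a semicolon-separated list of integer pathway indices (``"0;5"``),
matching the multi-hot label layout used for pathway-membership tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class TokenizationError(ValueError):
    """Raised on over-length input or characters outside the vocabulary."""


class DatasetFormatError(ValueError):
    """Raised on malformed dataset files; carries offending row numbers."""


# ---------------------------------------------------------------------------
# Molecules and canonicalization
# ---------------------------------------------------------------------------


def _parse(smiles: str) -> Chem.Mol:
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    return mol


def canonicalize_smiles(smiles: str) -> str:
    """Return the canonical form of a SMILES string (idempotent)."""
    return Chem.MolToSmiles(_parse(smiles))


@dataclass(frozen=True)
class Molecule:
    """A parsed compound: original SMILES, canonical form, heavy-atom count."""

    smiles: str
    canonical_smiles: str
    n_atoms: int
    rdkit_mol: Chem.Mol = field(repr=False, compare=False)

    @classmethod
    def from_smiles(cls, smiles: str) -> "Molecule":
        mol = _parse(smiles)
        if mol.GetNumAtoms() == 0:
            raise SmilesParseError(f"SMILES has no heavy atoms: {smiles!r}")
        return cls(
            smiles=smiles,
            canonical_smiles=Chem.MolToSmiles(mol),
            n_atoms=mol.GetNumAtoms(),
            rdkit_mol=mol,
        )


# ---------------------------------------------------------------------------
# Atom featurization
# ---------------------------------------------------------------------------

# Elements common in biological small molecules; anything else falls into
# the trailing "other" bucket.
ELEMENT_VOCAB = (
    "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B",
    "Se", "Si", "Na", "K", "Li", "Ca", "Mg", "Fe", "Zn", "Cu",
)
DEGREE_RANGE = 6        # 0..5 + overflow
NUM_H_RANGE = 5         # 0..4 + overflow
IMPLICIT_VALENCE_RANGE = 7  # 0..6 + overflow
_CHIRAL_TAGS = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)

ATOM_FEATURE_DIM = (
    (len(ELEMENT_VOCAB) + 1)
    + (DEGREE_RANGE + 1)
    + (NUM_H_RANGE + 1)
    + 1  # formal charge, kept as a plain integer
    + (IMPLICIT_VALENCE_RANGE + 1)
    + (len(_CHIRAL_TAGS) + 1)
    + 1  # in ring
    + 1  # aromatic
)


def _onehot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[min(index, size - 1)] = 1.0  # last slot is the overflow bucket
    return v


@dataclass(frozen=True)
class AtomFeatureVector:
    """Concatenation of the eight atom-property blocks used as node input."""

    symbol_onehot: np.ndarray
    degree_onehot: np.ndarray
    num_h_onehot: np.ndarray
    formal_charge: int
    implicit_valence_onehot: np.ndarray
    chiral_onehot: np.ndarray
    in_ring: bool
    aromatic: bool

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.symbol_onehot,
                self.degree_onehot,
                self.num_h_onehot,
                [float(self.formal_charge)],
                self.implicit_valence_onehot,
                self.chiral_onehot,
                [float(self.in_ring)],
                [float(self.aromatic)],
            ]
        )


def atom_features(molecule: Molecule, atom_index: int) -> AtomFeatureVector:
    """Featurize one atom: symbol, degree, attached H, charge, valence,
    chirality, ring membership and aromaticity."""
    if not 0 <= atom_index < molecule.n_atoms:
        raise IndexError(f"atom index {atom_index} out of range for {molecule.n_atoms} atoms")
    atom = molecule.rdkit_mol.GetAtomWithIdx(atom_index)
    symbol = atom.GetSymbol()
    sym_idx = ELEMENT_VOCAB.index(symbol) if symbol in ELEMENT_VOCAB else len(ELEMENT_VOCAB)
    tag = atom.GetChiralTag()
    chiral_idx = _CHIRAL_TAGS.index(tag) if tag in _CHIRAL_TAGS else len(_CHIRAL_TAGS)
    sym = np.zeros(len(ELEMENT_VOCAB) + 1)
    sym[sym_idx] = 1.0
    chiral = np.zeros(len(_CHIRAL_TAGS) + 1)
    chiral[chiral_idx] = 1.0
    return AtomFeatureVector(
        symbol_onehot=sym,
        degree_onehot=_onehot(atom.GetDegree(), DEGREE_RANGE + 1),
        num_h_onehot=_onehot(atom.GetTotalNumHs(), NUM_H_RANGE + 1),
        formal_charge=atom.GetFormalCharge(),
        implicit_valence_onehot=_onehot(atom.GetImplicitValence(), IMPLICIT_VALENCE_RANGE + 1),
        chiral_onehot=chiral,
        in_ring=atom.IsInRing(),
        aromatic=atom.GetIsAromatic(),
    )


# ---------------------------------------------------------------------------
# Molecular graph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MolecularGraph:
    """Node-feature matrix plus a directed edge list (both bond directions)."""

    node_features: np.ndarray  # (n_atoms, ATOM_FEATURE_DIM)
    edges: tuple[tuple[int, int], ...]
    molecule: Molecule

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def edge_array(self) -> np.ndarray:
        """Edges as a (2, E) int array: row 0 sources, row 1 targets."""
        if not self.edges:
            return np.zeros((2, 0), dtype=np.intp)
        return np.asarray(self.edges, dtype=np.intp).T

    def neighbors(self, node: int) -> list[int]:
        return [j for j, i in self.edges if i == node]


def smiles_to_graph(molecule: Molecule) -> MolecularGraph:
    """Build the molecular graph: one feature row per heavy atom in parser
    order, and two directed edges per chemical bond."""
    mol = molecule.rdkit_mol
    feats = np.stack([atom_features(molecule, i).vector for i in range(molecule.n_atoms)])
    edges: list[tuple[int, int]] = []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((a, b))
        edges.append((b, a))
    return MolecularGraph(node_features=feats, edges=tuple(edges), molecule=molecule)


# ---------------------------------------------------------------------------
# SMILES tokenizer (character level with multi-character merges)
# ---------------------------------------------------------------------------

PAD_TOKEN = "<pad>"

_DEFAULT_TOKENS = (
    list("BCNOPSFI")
    + ["Cl", "Br"]
    + list("bcnops")
    + list("0123456789")
    + list("()=#-+/\\.:*~$")
    + ["@", "@@"]
    + [f"%{i}" for i in range(10, 30)]
    + [
        "[nH]", "[NH]", "[N+]", "[NH+]", "[NH2+]", "[NH3+]", "[N-]", "[O-]",
        "[O+]", "[OH+]", "[C@H]", "[C@@H]", "[C@]", "[C@@]", "[S+]", "[s+]",
        "[S-]", "[Na+]", "[K+]", "[Li+]", "[Cl-]", "[Br-]", "[I-]", "[F-]",
        "[Se]", "[se]", "[Si]", "[P+]", "[B-]", "[H]", "[2H]", "[C-]",
        "[CH-]", "[CH2-]", "[cH-]", "[c-]", "[n+]", "[nH+]", "[o+]", "[N]",
        "[O]", "[C]", "[Ca+2]", "[Mg+2]", "[Fe+2]", "[Fe+3]", "[Zn+2]", "[Cu+2]",
    ]
)


@dataclass(frozen=True)
class TokenSequence:
    """Padded integer encoding of a SMILES string."""

    token_ids: np.ndarray  # (max_len,), int
    true_length: int
    vocabulary_id: str

    @property
    def max_len(self) -> int:
        return self.token_ids.shape[0]


class SmilesTokenizer:
    """Character-level tokenizer with a merge table for two-character
    element symbols (Cl, Br), ``@@``, ``%NN`` ring closures, and whole
    bracket atoms (``[nH]`` is one token)."""

    def __init__(self, tokens: list[str] | None = None, max_len: int = 256):
        vocab = list(tokens) if tokens is not None else list(_DEFAULT_TOKENS)
        if PAD_TOKEN in vocab:
            vocab.remove(PAD_TOKEN)
        self.tokens = [PAD_TOKEN] + vocab
        self.index = {t: i for i, t in enumerate(self.tokens)}
        if len(self.index) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        self.max_len = max_len

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def vocab_size(self) -> int:
        return len(self.tokens)

    @property
    def vocabulary_id(self) -> str:
        digest = hashlib.sha256("\x00".join(self.tokens).encode()).hexdigest()
        return digest[:12]

    @staticmethod
    def split(smiles: str) -> list[str]:
        """Split a SMILES string into tokens (no vocabulary lookup)."""
        out: list[str] = []
        i = 0
        n = len(smiles)
        while i < n:
            ch = smiles[i]
            if ch == "[":
                j = smiles.find("]", i)
                if j < 0:
                    raise TokenizationError(f"unterminated bracket atom in {smiles!r}")
                out.append(smiles[i : j + 1])
                i = j + 1
            elif ch == "%" and i + 2 < n + 1 and smiles[i + 1 : i + 3].isdigit():
                out.append(smiles[i : i + 3])
                i += 3
            elif smiles[i : i + 2] in ("Cl", "Br", "@@"):
                out.append(smiles[i : i + 2])
                i += 2
            else:
                out.append(ch)
                i += 1
        return out

    def fit(self, smiles_iter) -> "SmilesTokenizer":
        """Extend the vocabulary with tokens seen in a corpus (in-place)."""
        for s in smiles_iter:
            for tok in self.split(s):
                if tok not in self.index:
                    self.index[tok] = len(self.tokens)
                    self.tokens.append(tok)
        return self

    def tokenize(self, smiles: str, max_len: int | None = None) -> TokenSequence:
        if not smiles:
            raise TokenizationError("empty SMILES string")
        max_len = max_len if max_len is not None else self.max_len
        toks = self.split(smiles)
        if len(toks) > max_len:
            raise TokenizationError(
                f"SMILES has {len(toks)} tokens, exceeding max_len={max_len}: {smiles!r}"
            )
        ids = np.zeros(max_len, dtype=np.intp)
        for pos, tok in enumerate(toks):
            if tok not in self.index:
                raise TokenizationError(f"token {tok!r} not in vocabulary (SMILES {smiles!r})")
            ids[pos] = self.index[tok]
        return TokenSequence(token_ids=ids, true_length=len(toks), vocabulary_id=self.vocabulary_id)

    def detokenize(self, seq: TokenSequence) -> str:
        return "".join(self.tokens[i] for i in seq.token_ids[: seq.true_length])


def tokenize_smiles(smiles: str, max_len: int = 256, tokenizer: SmilesTokenizer | None = None) -> TokenSequence:
    """Tokenize a SMILES string with the default vocabulary."""
    tok = tokenizer if tokenizer is not None else SmilesTokenizer(max_len=max_len)
    return tok.tokenize(smiles, max_len=max_len)


# ---------------------------------------------------------------------------
# Labels and datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelVector:
    """Multi-hot pathway membership: bit p is 1 iff the compound belongs to
    pathway p. All-zero vectors are permitted (no known pathway)."""

    bits: np.ndarray
    label_names: tuple[str, ...]

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.int8)
        if bits.ndim != 1 or len(bits) != len(self.label_names):
            raise ValueError("label bits and names must have equal length")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("label bits must be 0/1")
        object.__setattr__(self, "bits", bits)

    @classmethod
    def from_indices(cls, indices, label_names: tuple[str, ...]) -> "LabelVector":
        bits = np.zeros(len(label_names), dtype=np.int8)
        for idx in indices:
            if not 0 <= idx < len(label_names):
                raise ValueError(f"label index {idx} out of range for {len(label_names)} labels")
            bits[idx] = 1
        return cls(bits=bits, label_names=tuple(label_names))

    @property
    def indices(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.bits)]


@dataclass
class LoadReport:
    """Summary of a dataset load: row counts, rejects, per-label totals."""

    n_rows: int = 0
    n_parsed: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)
    merged_duplicates: list[int] = field(default_factory=list)
    empty_label_rows: list[int] = field(default_factory=list)
    per_label_totals: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


@dataclass
class LabeledDataset:
    """A list of (Molecule, LabelVector) records sharing one label space."""

    records: list[tuple[Molecule, LabelVector]]
    label_names: tuple[str, ...]
    name: str = "dataset"
    load_report: LoadReport | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        seen: set[str] = set()
        for mol, labels in self.records:
            if len(labels.bits) != len(self.label_names):
                raise ValueError(f"label length mismatch for {mol.canonical_smiles}")
            if mol.canonical_smiles in seen:
                raise ValueError(f"duplicate canonical SMILES: {mol.canonical_smiles}")
            seen.add(mol.canonical_smiles)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def label_count(self) -> int:
        return len(self.label_names)

    @property
    def label_matrix(self) -> np.ndarray:
        return np.stack([lv.bits for _, lv in self.records]) if self.records else np.zeros((0, self.label_count), dtype=np.int8)

    @property
    def smiles(self) -> list[str]:
        return [mol.smiles for mol, _ in self.records]

    def subset(self, indices, name: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            records=[self.records[int(i)] for i in indices],
            label_names=self.label_names,
            name=name or f"{self.name}/subset",
        )

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"smiles": mol.smiles, "labels": ";".join(str(i) for i in labels.indices)}
            for mol, labels in self.records
        ]
        pd.DataFrame(rows, columns=["smiles", "labels"]).to_csv(path, index=False)


def read_dataset(
    path: str | Path,
    label_count: int,
    name: str | None = None,
    duplicates: str = "merge",
    on_error: str = "raise",
) -> LabeledDataset:
    """Read a ``smiles,labels`` CSV into a LabeledDataset.

    ``duplicates``: "merge" unions the labels of rows with the same
    canonical SMILES; "error" rejects them. ``on_error``: "raise" aborts
    with all offending row numbers; "skip" drops bad rows into the report.
    The attached :class:`LoadReport` records rejects, merges and per-label
    totals; row numbers count the header as line 1.
    """
    if duplicates not in ("merge", "error"):
        raise ValueError(f"duplicates must be 'merge' or 'error': {duplicates!r}")
    if on_error not in ("raise", "skip"):
        raise ValueError(f"on_error must be 'raise' or 'skip': {on_error!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"smiles", "labels"} - set(df.columns)
    if missing:
        raise DatasetFormatError(f"{path}: missing required columns {sorted(missing)}")
    label_names = tuple(str(i) for i in range(label_count))
    report = LoadReport(n_rows=len(df))
    by_canonical: dict[str, int] = {}
    records: list[tuple[Molecule, LabelVector]] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # header is line 1
        try:
            mol = Molecule.from_smiles(row.smiles)
            raw = str(row.labels).strip()
            if raw:
                indices = []
                for tok in raw.split(";"):
                    try:
                        indices.append(int(tok))
                    except ValueError:
                        raise ValueError(f"non-integer label {tok!r}") from None
                labels = LabelVector.from_indices(indices, label_names)
            else:
                labels = LabelVector(np.zeros(label_count, dtype=np.int8), label_names)
                report.empty_label_rows.append(line_no)
        except (SmilesParseError, ValueError) as exc:
            report.rejected.append((line_no, str(exc)))
            continue
        key = mol.canonical_smiles
        if key in by_canonical:
            if duplicates == "error":
                report.rejected.append((line_no, f"duplicate canonical SMILES {key}"))
                continue
            prev_idx = by_canonical[key]
            prev_mol, prev_labels = records[prev_idx]
            merged = np.maximum(prev_labels.bits, labels.bits)
            records[prev_idx] = (prev_mol, LabelVector(merged, label_names))
            report.merged_duplicates.append(line_no)
        else:
            by_canonical[key] = len(records)
            records.append((mol, labels))
    if report.rejected and on_error == "raise":
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in report.rejected)
        raise DatasetFormatError(f"{path}: {len(report.rejected)} malformed rows ({detail})")
    report.n_parsed = len(records)
    totals = np.zeros(label_count, dtype=int)
    for _, lv in records:
        totals += lv.bits
    report.per_label_totals = {n: int(t) for n, t in zip(label_names, totals)}
    ds = LabeledDataset(records=records, label_names=label_names, name=name or Path(path).stem)
    ds.load_report = report
    return ds


# ---------------------------------------------------------------------------
# Synthetic fixture generator
# ---------------------------------------------------------------------------

# Functional-group decorations; in structural-label mode the first L of
# these act as label markers (label l == "molecule carries decoration l").
MARKER_DECORATIONS = (
    "O", "OC", "N", "N(C)C", "Cl", "F", "Br", "I", "C#N",
    "C(=O)O", "C(=O)N", "S", "SC", "C(F)(F)F", "C=C", "C#C", "C(C)C", "OCC",
)

_RING_TEMPLATES: dict[str, dict[int, str]] = {
    "benzene": {
        0: "c1ccccc1",
        1: "c1ccc({0})cc1",
        2: "c1ccc({0})c({1})c1",
        3: "c1cc({0})c({1})c({2})c1",
    },
    "cyclohexane": {
        0: "C1CCCCC1",
        1: "C1CCC({0})CC1",
        2: "C1CC({0})CC({1})C1",
        3: "C1C({0})C({1})C({2})CC1",
    },
    "pyridine": {
        0: "c1ccncc1",
        1: "c1cc({0})cnc1",
        2: "c1nc({0})cc({1})c1",
    },
    "thiophene": {
        0: "c1ccsc1",
        1: "c1cc({0})sc1",
        2: "c1sc({0})cc1{1}",
    },
    "furan": {
        0: "c1ccoc1",
        1: "c1cc({0})oc1",
        2: "c1oc({0})cc1{1}",
    },
    "cyclopentane": {
        0: "C1CCCC1",
        1: "C1CCC({0})C1",
        2: "C1CC({0})CC1{1}",
    },
}


def _build_chain(rng: np.random.Generator, decorations: list[str]) -> str:
    """A linear alkane of random length with decorations as branches."""
    length = int(rng.integers(3, 9))
    positions = rng.choice(length, size=min(len(decorations), length), replace=False)
    branches = {int(p): d for p, d in zip(positions, decorations)}
    return "".join("C" + (f"({branches[i]})" if i in branches else "") for i in range(length))


def _build_ring(rng: np.random.Generator, family: str, decorations: list[str]) -> str:
    variants = _RING_TEMPLATES[family]
    m = len(decorations)
    if m not in variants:
        return ""
    return variants[m].format(*decorations)


def generate_fixture_dataset(
    n_compounds: int,
    label_count: int,
    seed: int,
    structural_labels: bool = False,
    multi_label_fraction: float = 0.3,
    label_weights: np.ndarray | None = None,
    name: str | None = None,
) -> LabeledDataset:
    """Generate a deterministic synthetic multi-label SMILES dataset.

    Molecules are ring or chain scaffolds carrying 1-3 functional-group
    decorations. With ``structural_labels=False`` labels are drawn from an
    imbalanced categorical distribution independent of structure: each row
    draws ``m`` labels with replacement (``m`` is 1 with probability
    ``1 - multi_label_fraction``, else 2 or 3 in a 7:3 ratio), so the
    marginal P(bit l) is ``1 - (1 - w_l)**m`` averaged over m. With
    ``structural_labels=True``, label ``l`` indicates that decoration
    ``MARKER_DECORATIONS[l]`` is present — a perfectly recoverable task
    used for capacity and transfer experiments.

    Default label weights decay geometrically (``0.85**l``, normalised),
    emulating the strong class imbalance of pathway-membership tables.
    """
    if n_compounds < label_count:
        raise ValueError("n_compounds must be at least label_count")
    if structural_labels and label_count > len(MARKER_DECORATIONS):
        raise ValueError(f"structural labels support at most {len(MARKER_DECORATIONS)} labels")
    if not 0.0 <= multi_label_fraction <= 1.0:
        raise ValueError("multi_label_fraction must be in [0, 1]")
    if label_weights is None:
        label_weights = 0.85 ** np.arange(label_count)
    label_weights = np.asarray(label_weights, dtype=float)
    if len(label_weights) != label_count or (label_weights <= 0).any():
        raise ValueError("label_weights must be positive with one entry per label")
    label_weights = label_weights / label_weights.sum()

    rng = np.random.default_rng(seed)
    label_names = tuple(str(i) for i in range(label_count))
    families = list(_RING_TEMPLATES) + ["chain"]
    records: list[tuple[Molecule, LabelVector]] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 200 * n_compounds
    while len(records) < n_compounds:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("fixture generator exhausted its SMILES template space")
        u = rng.random()
        m = 1 if u >= multi_label_fraction else (2 if rng.random() < 0.7 else 3)
        if structural_labels:
            marker_idx = rng.choice(label_count, size=m, replace=False, p=label_weights)
            decorations = [MARKER_DECORATIONS[int(i)] for i in marker_idx]
            bits = np.zeros(label_count, dtype=np.int8)
            bits[marker_idx] = 1
        else:
            draws = rng.choice(label_count, size=m, replace=True, p=label_weights)
            decorations = [
                MARKER_DECORATIONS[int(i) % len(MARKER_DECORATIONS)]
                for i in rng.integers(0, len(MARKER_DECORATIONS), size=int(rng.integers(1, 4)))
            ]
            bits = np.zeros(label_count, dtype=np.int8)
            bits[draws] = 1
        family = families[int(rng.integers(len(families)))]
        if family == "chain":
            smiles = _build_chain(rng, decorations)
        else:
            smiles = _build_ring(rng, family, decorations)
        if not smiles:
            continue
        try:
            mol = Molecule.from_smiles(smiles)
        except SmilesParseError:
            continue
        if mol.canonical_smiles in seen:
            continue
        seen.add(mol.canonical_smiles)
        records.append((mol, LabelVector(bits, label_names)))
    return LabeledDataset(
        records=records,
        label_names=label_names,
        name=name or f"fixture-n{n_compounds}-L{label_count}-s{seed}",
    )
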