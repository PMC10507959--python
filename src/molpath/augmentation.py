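"""Label-preserving dataset expansion.

Two families of augmentation, both resting on the hypothesis that highly
similar structures share metabolic pathways:

* substitution (methods ``alpha``/``beta``): methoxy groups are replaced by
  hydroxy groups and vice versa, one site at a time; ``alpha`` runs one
  substitution pass, ``beta`` runs three sequential passes with
  accumulation. Carboxylic-acid hydroxyls and ester methoxyls are excluded
  so the edits stay within ether/alcohol chemistry.
* similarity mining (methods ``gamma``/``theta``): compounds from an
  external library whose Morgan-fingerprint Tanimoto similarity to a
  dataset molecule falls within a band ([0.99, 1] for gamma, [0.96, 1] for
  theta) are recruited with that molecule's labels; a recruit matching
  several parents receives the union of their labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import DataStructs, rdFingerprintGenerator

from .chemio import LabeledDataset, LabelVector, Molecule, SmilesParseError

METHOXY_PATTERN = Chem.MolFromSmarts("[CH3;D1][OX2][#6;!$([CX3]=[OX1])]")
HYDROXY_PATTERN = Chem.MolFromSmarts("[OX2H1][#6;!$([CX3]=[OX1])]")

_METHOD_DEFAULTS = {
    "alpha": {"rounds": 1},
    "beta": {"rounds": 3},
    "gamma": {"similarity_range": (0.99, 1.0)},
    "theta": {"similarity_range": (0.96, 1.0)},
}


@dataclass(frozen=True)
class AugmentationSpec:
    method: str
    rounds: int | None = None
    similarity_range: tuple[float, float] | None = None
    library_path: str | None = None

    def __post_init__(self):
        if self.method not in _METHOD_DEFAULTS:
            raise ValueError(f"unknown augmentation method {self.method!r}")
        defaults = _METHOD_DEFAULTS[self.method]
        if self.method in ("alpha", "beta"):
            rounds = self.rounds if self.rounds is not None else defaults["rounds"]
            if rounds < 1:
                raise ValueError("rounds must be >= 1")
            object.__setattr__(self, "rounds", rounds)
        else:
            rng = self.similarity_range if self.similarity_range is not None else defaults["similarity_range"]
            low, high = float(rng[0]), float(rng[1])
            if not (0.0 <= low <= high <= 1.0):
                raise ValueError(f"similarity_range must satisfy 0 <= low <= high <= 1: {rng}")
            object.__setattr__(self, "similarity_range", (low, high))


@dataclass(frozen=True)
class FingerprintConfig:
    radius: int = 2
    n_bits: int = 2048
    counted: bool = False

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.n_bits < 2 or self.n_bits & (self.n_bits - 1):
            raise ValueError(f"n_bits must be a power of two: {self.n_bits}")


@dataclass(frozen=True)
class Fingerprint:
    bits: object = field(repr=False)
    config: FingerprintConfig


def compute_fingerprint(molecule: Molecule, config: FingerprintConfig = FingerprintConfig()) -> Fingerprint:
    """Morgan (circular) fingerprint; binary by default, counted optional."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=config.radius, fpSize=config.n_bits)
    if config.counted:
        fp = gen.GetCountFingerprint(molecule.rdkit_mol)
    else:
        fp = gen.GetFingerprint(molecule.rdkit_mol)
    return Fingerprint(bits=fp, config=config)


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto coefficient |intersection| / |union| in [0, 1]."""
    if fp_a.config != fp_b.config:
        raise ValueError(f"fingerprint configs differ: {fp_a.config} vs {fp_b.config}")
    return float(DataStructs.TanimotoSimilarity(fp_a.bits, fp_b.bits))


# ---------------------------------------------------------------------------
# Substitution (alpha / beta)
# ---------------------------------------------------------------------------


def swap_functional_groups(molecule: Molecule, direction: str) -> list[Molecule]:
    """Single-site methoxy<->hydroxy edits: one product per matching site,
    canonicalized and deduplicated. Empty list when nothing matches."""
    if direction not in ("methoxy_to_hydroxy", "hydroxy_to_methoxy"):
        raise ValueError(f"unknown direction {direction!r}")
    mol = molecule.rdkit_mol
    products: list[Molecule] = []
    seen: set[str] = set()
    if direction == "methoxy_to_hydroxy":
        for match in mol.GetSubstructMatches(METHOXY_PATTERN):
            methyl_idx = match[0]
            edit = Chem.RWMol(mol)
            edit.RemoveAtom(methyl_idx)  # the ether O picks up an implicit H
            _collect(edit, products, seen)
    else:
        for match in mol.GetSubstructMatches(HYDROXY_PATTERN):
            oxygen_idx = match[0]
            edit = Chem.RWMol(mol)
            new_c = edit.AddAtom(Chem.Atom(6))
            edit.AddBond(oxygen_idx, new_c, Chem.BondType.SINGLE)
            _collect(edit, products, seen)
    return products


def _collect(edit: Chem.RWMol, products: list[Molecule], seen: set[str]) -> None:
    try:
        out = edit.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return
    smiles = Chem.MolToSmiles(out)
    if smiles in seen:
        return
    seen.add(smiles)
    products.append(Molecule.from_smiles(smiles))


def augment_substitution(dataset: LabeledDataset, spec: AugmentationSpec) -> LabeledDataset:
    """Expand a dataset with methoxy<->hydroxy variants.

    Every product inherits its parent's labels; a molecule reachable from
    several parents carries the union of their labels. Round r applies both
    swap directions to the molecules produced in round r-1; originals are
    always retained.
    """
    if spec.method not in ("alpha", "beta"):
        raise ValueError(f"augment_substitution requires method alpha or beta, got {spec.method!r}")
    pool: dict[str, tuple[Molecule, np.ndarray]] = {
        mol.canonical_smiles: (mol, labels.bits.copy()) for mol, labels in dataset
    }
    provenance: dict[str, tuple[str, str]] = {}
    frontier = [mol.canonical_smiles for mol, _ in dataset]
    for _ in range(spec.rounds):
        next_frontier: list[str] = []
        for key in frontier:
            parent, parent_bits = pool[key]
            for direction in ("methoxy_to_hydroxy", "hydroxy_to_methoxy"):
                for product in swap_functional_groups(parent, direction):
                    ckey = product.canonical_smiles
                    if ckey in pool:
                        mol0, bits0 = pool[ckey]
                        pool[ckey] = (mol0, np.maximum(bits0, parent_bits))
                    else:
                        pool[ckey] = (product, parent_bits.copy())
                        provenance[ckey] = (key, spec.method)
                        next_frontier.append(ckey)
        frontier = next_frontier
        if not frontier:
            break
    records = [(mol, LabelVector(bits, dataset.label_names)) for mol, bits in pool.values()]
    out = LabeledDataset(records=records, label_names=dataset.label_names,
                         name=f"{dataset.name}+{spec.method}")
    out.provenance = provenance
    return out


# ---------------------------------------------------------------------------
# Similarity mining (gamma / theta)
# ---------------------------------------------------------------------------


def augment_similarity(
    dataset: LabeledDataset,
    library: list[Molecule],
    spec: AugmentationSpec,
    fp_config: FingerprintConfig = FingerprintConfig(),
) -> LabeledDataset:
    """Recruit library compounds whose Tanimoto similarity to any dataset
    molecule lies within the spec's band; recruits inherit the union of
    their parents' labels and duplicates of dataset members are dropped."""
    if spec.method not in ("gamma", "theta"):
        raise ValueError(f"augment_similarity requires method gamma or theta, got {spec.method!r}")
    if not library:
        raise ValueError("library must be non-empty")
    low, high = spec.similarity_range
    dataset_fps = [compute_fingerprint(mol, fp_config).bits for mol, _ in dataset]
    existing = {mol.canonical_smiles for mol, _ in dataset}
    records = list(dataset.records)
    provenance: dict[str, tuple[str, str]] = {}
    recruited: dict[str, tuple[Molecule, np.ndarray]] = {}
    for lib_mol in library:
        key = lib_mol.canonical_smiles
        if key in existing or key in recruited:
            continue
        lib_fp = compute_fingerprint(lib_mol, fp_config).bits
        sims = DataStructs.BulkTanimotoSimilarity(lib_fp, dataset_fps)
        bits = None
        parent = None
        for (ds_mol, ds_labels), sim in zip(dataset.records, sims):
            if low <= sim <= high:
                bits = ds_labels.bits.copy() if bits is None else np.maximum(bits, ds_labels.bits)
                parent = parent or ds_mol.canonical_smiles
        if bits is not None:
            recruited[key] = (lib_mol, bits)
            provenance[key] = (parent, spec.method)
    records += [(mol, LabelVector(bits, dataset.label_names)) for mol, bits in recruited.values()]
    out = LabeledDataset(records=records, label_names=dataset.label_names,
                         name=f"{dataset.name}+{spec.method}")
    out.provenance = provenance
    return out


# ---------------------------------------------------------------------------
# Library I/O and augmented output
# ---------------------------------------------------------------------------


def read_library(path: str | Path) -> list[Molecule]:
    """Compound library: CSV with a ``smiles`` column, or one SMILES per
    line. Unparsable entries are skipped."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        return []
    first = text.splitlines()[0]
    if "smiles" in first.lower().split(","):
        values = pd.read_csv(path, dtype=str, keep_default_na=False)["smiles"].tolist()
    else:
        values = [line.strip() for line in text.splitlines() if line.strip()]
    out = []
    for s in values:
        try:
            out.append(Molecule.from_smiles(s))
        except SmilesParseError:
            continue
    return out


def write_augmented_csv(dataset: LabeledDataset, path: str | Path) -> None:
    """Dataset CSV with provenance columns (parent SMILES and method tag;
    empty for original records)."""
    provenance = getattr(dataset, "provenance", {})
    rows = []
    for mol, labels in dataset:
        parent, method = provenance.get(mol.canonical_smiles, ("", ""))
        rows.append({
            "smiles": mol.smiles,
            "labels": ";".join(str(i) for i in labels.indices),
            "parent_smiles": parent,
            "method": method,
        })
    pd.DataFrame(rows, columns=["smiles", "labels", "parent_smiles", "method"]).to_csv(path, index=False)
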