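"""Multiscale featurization of solute-solvent systems.

Turns SMILES strings into heavy-atom molecular graphs carrying three node-level
and two edge-level feature blocks:

* inherent atomic features -- six element-level physical constants (covalent
  radius, Pauling electronegativity, atomic number, atomic mass, first
  ionization energy, electron affinity), encoded as raw numbers;
* environmental atomic features -- one-hot categorical context of the atom in
  its molecule (valence, H count, formal charge, hybridization, ring and
  aromatic flags) plus optional task-defined marking bits;
* solvent descriptors -- 66 whole-molecule descriptors of the solvent drawn
  from four families (E-state, VSA surface-area contributions, topological,
  connectivity), one vector per solvent;
* bond features -- one-hot bond type plus conjugation/aromaticity/ring bits;
* solvent polarity parameters -- the empirical solvatochromic scales Et(30)
  and the Catalan set (SP, SdP, SA, SB).

Hydrogens are implicit: the graph holds heavy atoms only and hydrogen counts
enter through the environmental block.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class FeaturizationError(ValueError):
    """Raised when a molecule or solvent cannot be featurized."""


# --------------------------------------------------------------------------
# category sets for the environmental one-hot blocks (order is part of the
# feature format and must never change)
# --------------------------------------------------------------------------
VALENCE_CATEGORIES = (0, 1, 2, 3, 4, 5, 6)
H_COUNT_CATEGORIES = (0, 1, 2, 3, 4)
FORMAL_CHARGE_CATEGORIES = (-1, -2, 1, 2, 0)
HYBRIDIZATION_CATEGORIES = ("s", "sp", "sp2", "sp3")
ENV_BASE_LENGTH = (
    len(VALENCE_CATEGORIES)
    + len(H_COUNT_CATEGORIES)
    + len(FORMAL_CHARGE_CATEGORIES)
    + len(HYBRIDIZATION_CATEGORIES)
    + 2
)  # = 23

INHERENT_LENGTH = 6
BOND_LENGTH = 7
N_SOLVENT_DESCRIPTORS = 66
N_POLARITY_PARAMS = 5

HALOGENS = frozenset({"F", "Cl", "Br", "I"})

#: built-in atom-marking rules: name -> predicate on the element symbol
MARKING_RULES: dict[str, object] = {
    "hydrophobic_halogen": lambda symbol: symbol in HALOGENS,
}

_HYB_FROM_RDKIT = {
    Chem.HybridizationType.S: "s",
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}

_BOND_TYPE_INDEX = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


# --------------------------------------------------------------------------
# bundled data files
# --------------------------------------------------------------------------
def _data_text(filename: str) -> str:
    return (resources.files("ngnn") / "data" / filename).read_text(encoding="utf-8")


_PERIODIC: dict[str, np.ndarray] | None = None


def _periodic_table() -> dict[str, np.ndarray]:
    global _PERIODIC
    if _PERIODIC is None:
        table = {}
        rows = csv.DictReader(_data_text("periodic_table.tsv").splitlines(), delimiter="\t")
        for row in rows:
            table[row["symbol"]] = np.array(
                [
                    float(row["covalent_radius"]),
                    float(row["electronegativity"]),
                    float(row["atomic_number"]),
                    float(row["atomic_mass"]),
                    float(row["first_ionization_energy"]),
                    float(row["electron_affinity"]),
                ]
            )
        _PERIODIC = table
    return _PERIODIC


_DESCRIPTOR_REGISTRY: list[tuple[str, str]] | None = None

DESCRIPTOR_REGISTRY_VERSION = "v1"


def descriptor_registry() -> list[tuple[str, str]]:
    """The versioned (family, descriptor-name) list defining the 66-vector."""
    global _DESCRIPTOR_REGISTRY
    if _DESCRIPTOR_REGISTRY is None:
        rows = csv.DictReader(
            _data_text("solvent_descriptors_v1.tsv").splitlines(), delimiter="\t"
        )
        _DESCRIPTOR_REGISTRY = [(r["family"], r["name"]) for r in rows]
        assert len(_DESCRIPTOR_REGISTRY) == N_SOLVENT_DESCRIPTORS
    return _DESCRIPTOR_REGISTRY


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom topology with raw per-atom and per-directed-edge features.

    Every chemical bond appears as two directed edges (i->j and j->i) with
    identical features; atom indices are 0-based and follow the parser's
    canonical atom ranking.
    """

    n_atoms: int
    symbols: tuple[str, ...]
    directed_edges: np.ndarray  # (E, 2) int
    inherent: np.ndarray  # (n, 6) float
    environment: np.ndarray  # (n, 23 + k) float
    bond_features: np.ndarray  # (E, 7) float
    canonical_smiles: str
    applied_rules: tuple[str, ...] = ()

    @property
    def n_custom_flags(self) -> int:
        return self.environment.shape[1] - ENV_BASE_LENGTH

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_atoms, dtype=np.intp)
        if len(self.directed_edges):
            np.add.at(deg, self.directed_edges[:, 0], 1)
        return deg


@dataclass(frozen=True)
class SolventEntry:
    name: str
    aliases: tuple[str, ...]
    smiles: str  # canonical
    polarity: np.ndarray  # (5,): Et30, SP, SdP, SA, SB
    descriptors: np.ndarray  # (66,)
    citation: str


@dataclass(frozen=True)
class DissolvedSample:
    """A solute molecular graph paired with its solvent's feature vectors."""

    solute: MolecularGraph
    solvent_descriptors: np.ndarray  # (66,)
    solvent_polarity: np.ndarray  # (5,)
    target: float
    sample_id: str
    solvent_name: str = ""


# --------------------------------------------------------------------------
# atom-level encoders
# --------------------------------------------------------------------------
def encode_inherent(element_symbol: str) -> np.ndarray:
    """Six tabulated physical constants for an element, in fixed order.

    Any element present in the bundled constants table is usable, whether or
    not it occurred in training data; this is what permits extrapolation to
    unseen elements.
    """
    table = _periodic_table()
    if element_symbol not in table:
        raise FeaturizationError(
            f"element {element_symbol!r} is not in the bundled constants table "
            f"(supported: {', '.join(sorted(table))})"
        )
    return table[element_symbol].copy()


def encode_environment(
    atom_state: Mapping[str, object], custom_flags: Sequence[float] = ()
) -> np.ndarray:
    """One-hot encode an atom's molecular context, custom flags appended last.

    `atom_state` needs keys valence, h_count, formal_charge, hybridization,
    in_ring, aromatic. Out-of-range categories are rejected.
    """

    def onehot(value, categories, field_name):
        vec = np.zeros(len(categories))
        try:
            vec[categories.index(value)] = 1.0
        except ValueError:
            raise FeaturizationError(
                f"{field_name}={value!r} outside the enumerated set {categories}"
            ) from None
        return vec

    blocks = [
        onehot(atom_state["valence"], list(VALENCE_CATEGORIES), "valence"),
        onehot(atom_state["h_count"], list(H_COUNT_CATEGORIES), "h_count"),
        onehot(atom_state["formal_charge"], list(FORMAL_CHARGE_CATEGORIES), "formal_charge"),
        onehot(atom_state["hybridization"], list(HYBRIDIZATION_CATEGORIES), "hybridization"),
        np.array([1.0 if atom_state["in_ring"] else 0.0]),
        np.array([1.0 if atom_state["aromatic"] else 0.0]),
    ]
    flags = np.asarray(custom_flags, dtype=np.float64).reshape(-1)
    if flags.size and not np.isin(flags, (0.0, 1.0)).all():
        raise FeaturizationError("custom flags must be 0/1 bits")
    return np.concatenate(blocks + [flags])


def _encode_bond(bond: Chem.Bond) -> np.ndarray:
    vec = np.zeros(BOND_LENGTH)
    try:
        vec[_BOND_TYPE_INDEX[bond.GetBondType()]] = 1.0
    except KeyError:
        raise FeaturizationError(
            f"unsupported bond type {bond.GetBondType()} between atoms "
            f"{bond.GetBeginAtomIdx()} and {bond.GetEndAtomIdx()}"
        ) from None
    vec[4] = 1.0 if bond.GetIsConjugated() else 0.0
    vec[5] = 1.0 if bond.GetIsAromatic() else 0.0
    vec[6] = 1.0 if bond.IsInRing() else 0.0
    return vec


# --------------------------------------------------------------------------
# molecule-level operations
# --------------------------------------------------------------------------
def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise FeaturizationError(f"not a SMILES string: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparsable SMILES: {smiles!r}")
    return mol


def parse_smiles(smiles: str) -> MolecularGraph:
    """Build the heavy-atom graph with all raw feature blocks populated.

    Atoms are renumbered by the parser's canonical ranking, so any SMILES of
    the same molecule yields the same graph (up to ties between symmetry-
    equivalent atoms). Multi-fragment inputs are rejected: message passing
    over a disconnected solute is undefined here.
    """
    mol = _mol_from_smiles(smiles)
    if len(Chem.GetMolFrags(mol)) > 1:
        raise FeaturizationError(f"multi-fragment solute not supported: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise FeaturizationError(f"no heavy atoms in {smiles!r}")
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    mol = Chem.RenumberAtoms(mol, [int(i) for i in np.argsort(ranks)])

    symbols, inherent, env = [], [], []
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        symbols.append(symbol)
        inherent.append(encode_inherent(symbol))
        hyb = _HYB_FROM_RDKIT.get(atom.GetHybridization())
        if hyb is None:
            raise FeaturizationError(
                f"atom {atom.GetIdx()} ({symbol}) in {smiles!r}: hybridization "
                f"{atom.GetHybridization()} outside (s, sp, sp2, sp3)"
            )
        try:
            env.append(
                encode_environment(
                    {
                        "valence": atom.GetTotalValence(),
                        "h_count": atom.GetTotalNumHs(),
                        "formal_charge": atom.GetFormalCharge(),
                        "hybridization": hyb,
                        "in_ring": atom.IsInRing(),
                        "aromatic": atom.GetIsAromatic(),
                    }
                )
            )
        except FeaturizationError as err:
            raise FeaturizationError(
                f"atom {atom.GetIdx()} ({symbol}) in {smiles!r}: {err}"
            ) from None

    edges, bond_feats = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        feat = _encode_bond(bond)
        edges.extend([(i, j), (j, i)])
        bond_feats.extend([feat, feat])
    if edges:
        order = np.lexsort((np.array(edges)[:, 1], np.array(edges)[:, 0]))
        directed = np.array(edges, dtype=np.intp)[order]
        bonds = np.array(bond_feats)[order]
    else:
        directed = np.empty((0, 2), dtype=np.intp)
        bonds = np.empty((0, BOND_LENGTH))

    return MolecularGraph(
        n_atoms=mol.GetNumAtoms(),
        symbols=tuple(symbols),
        directed_edges=directed,
        inherent=np.array(inherent),
        environment=np.array(env),
        bond_features=bonds,
        canonical_smiles=Chem.MolToSmiles(mol),
    )


def mark_atoms(graph: MolecularGraph, rule_name: str) -> MolecularGraph:
    """Append one custom-flag bit per atom under a registered marking rule.

    Marking lets a task highlight atoms known to matter for its property, e.g.
    hydrophobic halogens for aqueous solubility. Reapplying a rule already on
    the graph is an error (the bit would be duplicated).
    """
    if rule_name not in MARKING_RULES:
        raise FeaturizationError(
            f"unknown marking rule {rule_name!r}; registered: {sorted(MARKING_RULES)}"
        )
    if rule_name in graph.applied_rules:
        raise FeaturizationError(f"marking rule {rule_name!r} already applied")
    predicate = MARKING_RULES[rule_name]
    flags = np.array([[1.0 if predicate(s) else 0.0] for s in graph.symbols])
    return replace(
        graph,
        environment=np.hstack([graph.environment, flags]),
        applied_rules=graph.applied_rules + (rule_name,),
    )


# --------------------------------------------------------------------------
# solvent-level operations
# --------------------------------------------------------------------------
_DESCRIPTOR_CACHE: dict[str, np.ndarray] = {}


def compute_solvent_descriptors(solvent_smiles: str) -> np.ndarray:
    """The 66 whole-molecule solvent descriptors, in registry order.

    One vector per solvent molecule; during "dissolution" it is broadcast to
    every solute atom. Cached per canonical SMILES.
    """
    mol = _mol_from_smiles(solvent_smiles)
    if len(Chem.GetMolFrags(mol)) > 1:
        raise FeaturizationError(
            f"multi-fragment solvent (salt?) not supported: {solvent_smiles!r}"
        )
    canonical = Chem.MolToSmiles(mol)
    if canonical in _DESCRIPTOR_CACHE:
        return _DESCRIPTOR_CACHE[canonical].copy()
    values, failed = [], []
    for _family, name in descriptor_registry():
        try:
            v = float(getattr(Descriptors, name)(mol))
        except Exception:
            v = math.nan
        if not math.isfinite(v):
            failed.append(name)
            v = math.nan
        values.append(v)
    if failed:
        raise FeaturizationError(
            f"solvent {solvent_smiles!r}: descriptor computation failed for {failed}"
        )
    vec = np.array(values)
    _DESCRIPTOR_CACHE[canonical] = vec
    return vec.copy()


class SolventRegistry:
    """Bundled per-solvent polarity parameters plus computed descriptors.

    Entries resolve both by conventional name (case-insensitive, aliases
    included) and by canonical SMILES. Descriptor vectors are computed lazily
    at first lookup and cached.
    """

    version = DESCRIPTOR_REGISTRY_VERSION

    def __init__(self, entries: Iterable[SolventEntry]):
        self._entries: list[SolventEntry] = list(entries)
        self._by_name: dict[str, SolventEntry] = {}
        self._by_smiles: dict[str, SolventEntry] = {}
        for e in self._entries:
            for key in (e.name, *e.aliases):
                self._by_name[key.lower()] = e
            self._by_smiles[e.smiles] = e

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, identifier: str) -> bool:
        try:
            self.lookup(identifier)
            return True
        except FeaturizationError:
            return False

    def lookup(self, identifier: str) -> SolventEntry:
        entry = self._by_name.get(identifier.strip().lower())
        if entry is not None:
            return entry
        try:
            canonical = Chem.MolToSmiles(_mol_from_smiles(identifier))
        except FeaturizationError:
            canonical = None
        if canonical is not None and canonical in self._by_smiles:
            return self._by_smiles[canonical]
        raise FeaturizationError(
            f"solvent {identifier!r} not in registry (names: {', '.join(self.names)})"
        )

    @classmethod
    def default(cls) -> "SolventRegistry":
        global _DEFAULT_REGISTRY
        if _DEFAULT_REGISTRY is None:
            entries = []
            rows = csv.DictReader(_data_text("solvents.tsv").splitlines(), delimiter="\t")
            for row in rows:
                canonical = Chem.MolToSmiles(_mol_from_smiles(row["smiles"]))
                entries.append(
                    SolventEntry(
                        name=row["name"],
                        aliases=tuple(a for a in row["aliases"].split("|") if a),
                        smiles=canonical,
                        polarity=np.array(
                            [float(row[k]) for k in ("et30", "sp", "sdp", "sa", "sb")]
                        ),
                        descriptors=compute_solvent_descriptors(canonical),
                        citation=row["citation"],
                    )
                )
            _DEFAULT_REGISTRY = cls(entries)
        return _DEFAULT_REGISTRY


_DEFAULT_REGISTRY: SolventRegistry | None = None


def lookup_solvent(
    identifier: str,
    registry: SolventRegistry | None = None,
    allow_missing_polarity: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a solvent to its (descriptor, polarity) vectors.

    Unregistered but parseable SMILES get computed descriptors; their polarity
    parameters are unknown, which is an error unless `allow_missing_polarity`
    permits a zero-filled polarity vector.
    """
    registry = registry or SolventRegistry.default()
    try:
        entry = registry.lookup(identifier)
        return entry.descriptors.copy(), entry.polarity.copy()
    except FeaturizationError:
        descriptors = compute_solvent_descriptors(identifier)  # may re-raise
        if not allow_missing_polarity:
            raise FeaturizationError(
                f"solvent {identifier!r}: descriptors computable but polarity "
                "parameters (Et30, SP, SdP, SA, SB) are not tabulated; pass "
                "allow_missing_polarity=True to zero-fill"
            )
        return descriptors, np.zeros(N_POLARITY_PARAMS)


# --------------------------------------------------------------------------
# sample assembly
# --------------------------------------------------------------------------
def build_sample(
    solute_smiles: str,
    solvent_id: str,
    target: float,
    marking_rules: Sequence[str] = (),
    registry: SolventRegistry | None = None,
    sample_id: str = "",
    allow_missing_polarity: bool = False,
) -> DissolvedSample:
    """Compose a fully featurized solute-in-solvent sample."""
    target = float(target)
    if not math.isfinite(target):
        raise FeaturizationError(
            f"sample {sample_id or solute_smiles!r}: non-finite target {target}"
        )
    try:
        graph = parse_smiles(solute_smiles)
        for rule in marking_rules:
            graph = mark_atoms(graph, rule)
        descriptors, polarity = lookup_solvent(
            solvent_id, registry, allow_missing_polarity=allow_missing_polarity
        )
    except FeaturizationError as err:
        raise FeaturizationError(f"sample {sample_id or solute_smiles!r}: {err}") from None
    try:
        solvent_name = (registry or SolventRegistry.default()).lookup(solvent_id).name
    except FeaturizationError:
        solvent_name = solvent_id
    return DissolvedSample(
        solute=graph,
        solvent_descriptors=descriptors,
        solvent_polarity=polarity,
        target=target,
        sample_id=sample_id or graph.canonical_smiles,
        solvent_name=solvent_name,
    )


DATASET_COLUMNS = ("sample_id", "solute_smiles", "solvent", "target")


def load_dataset(
    path,
    marking_rules: Sequence[str] = (),
    registry: SolventRegistry | None = None,
) -> list[DissolvedSample]:
    """Read a dataset CSV (`sample_id,solute_smiles,solvent,target`)."""
    import pandas as pd

    frame = pd.read_csv(path, dtype={"sample_id": str, "solute_smiles": str, "solvent": str})
    if tuple(frame.columns) != DATASET_COLUMNS:
        raise FeaturizationError(
            f"dataset {path}: columns {tuple(frame.columns)} != required {DATASET_COLUMNS}"
        )
    return [
        build_sample(
            row.solute_smiles,
            row.solvent,
            row.target,
            marking_rules=marking_rules,
            registry=registry,
            sample_id=row.sample_id,
        )
        for row in frame.itertuples()
    ]
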