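"""Chemical-space grouping of confirmed hits.

Confirmed enhancers are encoded as circular (Morgan/ECFP-style)
substructure fingerprints — radius 2, folded to 2048 bits by default —
compared by Tanimoto similarity, grouped by single-linkage components
above a similarity threshold, and optionally embedded in 2-D through a
pluggable reducer delegate (PCA fallback, UMAP if available).

The in-repo fingerprint hashes iteratively grown atom neighborhoods
with a platform-stable CRC32 mix; it shares the Morgan construction
but does NOT claim bit-compatibility with RDKit's implementation.  An
RDKit-backed adapter (:func:`rdkit_fingerprint`) is provided for
regenerating toolkit-faithful fingerprints.  Structure input parsing
(SMILES) is delegated to RDKit; aromatic flags are trusted as parsed
and no standardization is applied beyond explicit-hydrogen stripping.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "AtomSpec",
    "BondSpec",
    "Fingerprint",
    "MoleculeGraph",
    "atom_environments",
    "circular_fingerprint",
    "embed_2d",
    "neighbor_groups",
    "rdkit_fingerprint",
    "tanimoto",
    "tanimoto_matrix",
]


class AtomSpec(NamedTuple):
    element: str
    charge: int
    aromatic: bool
    n_hydrogens: int


class BondSpec(NamedTuple):
    i: int
    j: int
    order: float  # 1, 2, 3 or 1.5 for aromatic


@dataclass
class MoleculeGraph:
    """A molecule as an annotated graph (hydrogens implicit)."""

    atoms: list[AtomSpec]
    bonds: list[BondSpec]
    molecule_id: str = ""
    smiles: str | None = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ValueError(f"bond {b} references invalid atoms")

    @classmethod
    def from_smiles(cls, smiles: str, molecule_id: str = "") -> "MoleculeGraph":
        """Parse a SMILES string (via RDKit) into a molecule graph."""
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES for record {molecule_id or smiles!r}")
        atoms = [
            AtomSpec(
                a.GetSymbol(),
                a.GetFormalCharge(),
                a.GetIsAromatic(),
                a.GetTotalNumHs(),
            )
            for a in mol.GetAtoms()
        ]
        bonds = [
            BondSpec(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in mol.GetBonds()
        ]
        return cls(atoms=atoms, bonds=bonds, molecule_id=molecule_id, smiles=smiles)

    def neighbors(self) -> list[list[tuple[float, int]]]:
        """Adjacency as (bond order, neighbor index) lists."""
        adj: list[list[tuple[float, int]]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append((b.order, b.j))
            adj[b.j].append((b.order, b.i))
        return adj


def _stable_hash(obj) -> int:
    """Deterministic 32-bit hash of a nested tuple of primitives."""
    return zlib.crc32(repr(obj).encode("utf-8"))


def atom_environments(mol: MoleculeGraph, radius: int) -> list[list[int]]:
    """Environment identifiers per atom for radii 0..radius.

    Radius-0 identifiers hash the atom's own invariants (element,
    charge, aromaticity, hydrogen count, degree); each further
    iteration hashes the previous identifier together with the sorted
    (bond order, neighbor identifier) multiset, so symmetric atoms get
    identical identifiers at every radius.
    """
    if not mol.atoms:
        raise ValueError("cannot fingerprint an empty molecule")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    adj = mol.neighbors()
    ids = [
        _stable_hash(("atom", a.element, a.charge, a.aromatic, a.n_hydrogens, len(adj[i])))
        for i, a in enumerate(mol.atoms)
    ]
    layers = [list(ids)]
    for r in range(1, radius + 1):
        new_ids = [
            _stable_hash(("env", r, ids[i], tuple(sorted((order, ids[j]) for order, j in adj[i]))))
            for i in range(len(mol.atoms))
        ]
        ids = new_ids
        layers.append(list(ids))
    return layers


@dataclass
class Fingerprint:
    """Folded circular-substructure bit vector for one molecule."""

    bits: np.ndarray
    radius: int
    n_bits: int
    molecule_id: str = ""
    backend: str = "spermscreen"

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.shape != (self.n_bits,):
            raise ValueError("bit vector length must equal n_bits")

    def popcount(self) -> int:
        return int(self.bits.sum())

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()


def circular_fingerprint(
    mol: MoleculeGraph, radius: int = 2, n_bits: int = 2048
) -> Fingerprint:
    """Morgan-style circular fingerprint folded to ``n_bits``.

    Deterministic across runs and platforms, and invariant to atom
    input ordering (neighbor multisets are sorted before hashing).
    """
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    bits = np.zeros(n_bits, dtype=bool)
    for layer in atom_environments(mol, radius):
        for env_id in layer:
            bits[env_id % n_bits] = True
    return Fingerprint(bits=bits, radius=radius, n_bits=n_bits, molecule_id=mol.molecule_id)


def rdkit_fingerprint(
    smiles: str, radius: int = 2, n_bits: int = 2048, molecule_id: str = ""
) -> Fingerprint:
    """Toolkit adapter: RDKit's own Morgan bits (for faithful
    regeneration of published-style chemical-space figures)."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES for record {molecule_id or smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=bool)
    for bit in gen.GetFingerprint(mol).GetOnBits():
        arr[bit] = True
    return Fingerprint(bits=arr, radius=radius, n_bits=n_bits,
                       molecule_id=molecule_id, backend="rdkit")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a & b| / |a | b| in [0, 1].

    Defined as 1 when both fingerprints are empty (with a warning).
    """
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprint lengths differ")
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints defined as 1.0", stacklevel=2)
        return 1.0
    return int(np.logical_and(a.bits, b.bits).sum()) / union


def tanimoto_matrix(fingerprints: Sequence[Fingerprint]) -> np.ndarray:
    """Symmetric pairwise Tanimoto matrix."""
    if not fingerprints:
        return np.zeros((0, 0))
    nb = fingerprints[0].n_bits
    if any(fp.n_bits != nb for fp in fingerprints):
        raise ValueError("fingerprint lengths differ")
    X = np.stack([fp.bits for fp in fingerprints]).astype(np.float64)
    inter = X @ X.T
    pop = X.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    return sim


def neighbor_groups(
    fingerprints: Sequence[Fingerprint], threshold: float = 0.55
) -> np.ndarray:
    """Single-linkage similarity groups.

    Molecules are nodes; edges connect pairs with Tanimoto >= threshold
    (default 0.55, a common medicinal-chemistry similarity heuristic);
    groups are the connected components.  Returns integer labels
    aligned with the input, numbered by order of first appearance, so
    the partition is invariant to input order.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    n = len(fingerprints)
    if n == 0:
        return np.zeros(0, dtype=int)
    sim = tanimoto_matrix(fingerprints)
    ii, jj = np.nonzero(np.triu(sim >= threshold, k=1))
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    # renumber by first appearance for determinism
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        out[i] = remap.setdefault(int(lab), len(remap))
    return out


def embed_2d(
    fingerprints: Sequence[Fingerprint],
    reducer: "str | object" = "pca",
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """2-D embedding of fingerprints through a pluggable delegate.

    ``reducer`` is "pca" (deterministic fallback), "umap", or any
    object with a ``fit_transform`` method.  Returns (coordinates,
    provenance) where provenance records the delegate and seed; the
    reduction algorithm itself is never re-implemented here.
    """
    if len(fingerprints) < 3:
        raise ValueError("need at least 3 fingerprints to embed")
    X = np.stack([fp.bits for fp in fingerprints]).astype(np.float64)
    if reducer == "pca":
        from sklearn.decomposition import PCA

        delegate = PCA(n_components=2, random_state=seed)
        name = "sklearn.decomposition.PCA"
    elif reducer == "umap":
        try:
            import umap
        except ImportError as exc:
            raise ImportError(
                "umap-learn is not installed; install it or use reducer='pca', "
                "or group compounds with neighbor_groups() instead"
            ) from exc
        delegate = umap.UMAP(n_components=2, random_state=seed)
        name = "umap.UMAP"
    elif hasattr(reducer, "fit_transform"):
        delegate, name = reducer, type(reducer).__name__
    else:
        raise ValueError("reducer must be 'pca', 'umap' or expose fit_transform")
    coords = np.asarray(delegate.fit_transform(X), dtype=float)[:, :2]
    provenance = {"delegate": name, "seed": seed, "n_molecules": len(fingerprints)}
    return coords, provenance
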