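"""Structural-key fingerprints as index sets.

Molecules are represented by the set of *on* bits of a binary structural
fingerprint: either the 166 predefined MACCS substructure keys (1-based
indices 1..166; the toolkit's bit 0 is undefined and always dropped) or a
folded Morgan/ECFP circular fingerprint (0-based bit indices).  All
downstream machinery — tokenization, translation, Tanimoto scoring,
lookup-table retrieval — operates on these key sets, never on atoms.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "Backend",
    "KeySet",
    "KeyFrequencyProfile",
    "SmilesParseError",
    "MACCS_NUM_KEYS",
    "mol_from_smiles",
    "canonical_smiles",
    "compute_maccs",
    "compute_ecfp",
    "profile_keys",
    "analyze_bit_degeneracy",
]

logger = logging.getLogger(__name__)

# RDKit warns loudly on every sanitization hiccup; corpus parsing handles
# failures explicitly, so keep the C++ logger quiet.
RDLogger.DisableLog("rdApp.*")

MACCS_NUM_KEYS = 166


class Backend:
    MACCS = "MACCS"
    ECFP = "ECFP"


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


def mol_from_smiles(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def canonical_smiles(smiles: str) -> str:
    return Chem.MolToSmiles(mol_from_smiles(smiles))


@dataclass(frozen=True)
class KeySet:
    """Sorted set of on-bit indices of one molecule's fingerprint.

    For the MACCS backend indices are the 1-based key numbers 1..166; for
    ECFP they are 0-based folded bit positions in ``[0, nbits)``.
    """

    indices: frozenset[int]
    backend: str = Backend.MACCS
    radius: int | None = None
    nbits: int | None = None

    def __post_init__(self):
        idx = frozenset(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if self.backend == Backend.MACCS:
            bad = [i for i in idx if not 1 <= i <= MACCS_NUM_KEYS]
        else:
            if self.nbits is None:
                raise ValueError("ECFP KeySet requires nbits")
            bad = [i for i in idx if not 0 <= i < self.nbits]
        if bad:
            raise ValueError(f"key indices out of range for {self.backend}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(sorted(self.indices))

    def __contains__(self, key: int) -> bool:
        return key in self.indices

    def sorted(self) -> list[int]:
        return sorted(self.indices)

    def _check_same_backend(self, other: "KeySet") -> None:
        if self.backend != other.backend:
            raise ValueError(
                f"backend mismatch: {self.backend} vs {other.backend}"
            )

    def intersection_size(self, other: "KeySet") -> int:
        self._check_same_backend(other)
        return len(self.indices & other.indices)

    def symmetric_difference_size(self, other: "KeySet") -> int:
        self._check_same_backend(other)
        return len(self.indices ^ other.indices)

    def restrict(self, keys: Iterable[int]) -> "KeySet":
        """Intersection with an allowed key list, keeping backend metadata."""
        return KeySet(self.indices & set(keys), self.backend, self.radius, self.nbits)


def compute_maccs(smiles: str) -> KeySet:
    """MACCS keys of a molecule as a :class:`KeySet`.

    The toolkit returns a 167-bit vector whose bit 0 is undefined; only
    keys 1..166 are kept.
    """
    mol = mol_from_smiles(smiles)
    fp = MACCSkeys.GenMACCSKeys(mol)
    on = {i for i in fp.GetOnBits() if i >= 1}
    return KeySet(on, Backend.MACCS)


def compute_ecfp(smiles: str, radius: int = 1, nbits: int = 1024) -> KeySet:
    """Folded Morgan (ECFP) fingerprint on-bits as a :class:`KeySet`."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if nbits <= 0:
        raise ValueError("nbits must be positive")
    mol = mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    return KeySet(set(gen.GetFingerprint(mol).GetOnBits()), Backend.ECFP,
                  radius=radius, nbits=nbits)


def compute_keyset(smiles: str, backend: str = Backend.MACCS,
                   radius: int = 1, nbits: int = 1024) -> KeySet:
    if backend == Backend.MACCS:
        return compute_maccs(smiles)
    if backend == Backend.ECFP:
        return compute_ecfp(smiles, radius=radius, nbits=nbits)
    raise ValueError(f"unknown backend {backend!r}")


@dataclass
class KeyFrequencyProfile:
    """Per-key occurrence counts over a molecule corpus.

    ``counts[k]`` is the number of molecules whose key set contains ``k``;
    normalized frequency is ``counts[k] / n_molecules`` in [0, 1].
    """

    counts: dict[int, int]
    n_molecules: int
    backend: str = Backend.MACCS
    n_skipped: int = 0

    def frequency(self, key: int) -> float:
        if self.n_molecules == 0:
            return 0.0
        return self.counts.get(key, 0) / self.n_molecules

    def count(self, key: int) -> int:
        return self.counts.get(key, 0)


def profile_keys(corpus: Iterable[str], backend: str = Backend.MACCS,
                 radius: int = 1, nbits: int = 1024) -> KeyFrequencyProfile:
    """Occurrence profile of every key over a SMILES corpus.

    Unparseable entries are skipped and logged; an entirely unparseable
    corpus is an error.
    """
    counts: Counter[int] = Counter()
    n_ok = 0
    n_skipped = 0
    for smiles in corpus:
        try:
            ks = compute_keyset(smiles, backend, radius=radius, nbits=nbits)
        except SmilesParseError:
            logger.warning("profile_keys: skipping unparseable SMILES %r", smiles)
            n_skipped += 1
            continue
        n_ok += 1
        counts.update(ks.indices)
    if n_ok == 0:
        raise ValueError("profile_keys: no parseable molecules in corpus")
    return KeyFrequencyProfile(dict(counts), n_ok, backend, n_skipped)


def analyze_bit_degeneracy(corpus: Iterable[str], radius: int = 1,
                           nbits: int = 1024) -> tuple[dict[int, set[str]], float]:
    """Distinct atom-environment fragments folded into each ECFP bit.

    Hash folding maps many circular atom environments onto one bit; the more
    fragments share a bit, the more ambiguous that token is to a translation
    model.  Returns ``(bit -> set of canonical fragment SMILES, mean
    fragments per active bit)`` over the corpus.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    bit_frags: dict[int, set[str]] = {}
    n_ok = 0
    for smiles in corpus:
        try:
            mol = mol_from_smiles(smiles)
        except SmilesParseError:
            logger.warning("analyze_bit_degeneracy: skipping %r", smiles)
            continue
        n_ok += 1
        ao = rdFingerprintGenerator.AdditionalOutput()
        ao.AllocateBitInfoMap()
        gen.GetFingerprint(mol, additionalOutput=ao)
        for bit, envs in ao.GetBitInfoMap().items():
            frags = bit_frags.setdefault(bit, set())
            for atom_idx, rad in envs:
                frags.add(_environment_smiles(mol, atom_idx, rad))
    if n_ok == 0:
        raise ValueError("analyze_bit_degeneracy: no parseable molecules")
    mean = (sum(len(v) for v in bit_frags.values()) / len(bit_frags)) if bit_frags else 0.0
    return bit_frags, mean


def _environment_smiles(mol, atom_idx: int, radius: int) -> str:
    """Canonical SMILES of the atom environment activating one bit."""
    if radius == 0:
        atom = mol.GetAtomWithIdx(atom_idx)
        return atom.GetSmarts()
    env = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom_idx)
    amap: dict[int, int] = {}
    sub = Chem.PathToSubmol(mol, env, atomMap=amap)
    return Chem.MolToSmiles(sub, rootedAtAtom=amap.get(atom_idx, -1), canonical=True)
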