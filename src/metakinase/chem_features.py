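"""Compound featurization: SMILES -> fixed-length binary fingerprints.

The compound tower of the two-tower model consumes either MACCS keys
(167 slots, slot 0 conventionally unused) or extended-connectivity
fingerprints (ECFP, hashed circular environments folded to a fixed bit
length; defaults radius=2, 256 bits).  RDKit does the chemistry; this
module fixes the conventions (canonicalization, vector lengths, failure
policy) and the on-disk formats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

MACCS_NBITS = 167  # slot 0 unused placeholder + 166 structural keys
ECFP_DEFAULT_RADIUS = 2
ECFP_DEFAULT_NBITS = 256

SCHEMES = ("maccs", "ecfp", "ctd", "custom")


class FeaturizationError(ValueError):
    """Raised when a SMILES string cannot be turned into a fingerprint."""

    def __init__(self, smiles: str, reason: str = "unparsable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


@dataclass
class CompoundRecord:
    compound_id: str
    smiles: str
    features: np.ndarray


@dataclass
class FeatureMatrix:
    """Ordered identifiers plus an n x d feature matrix.

    Shared container for compound fingerprints and kinase descriptors;
    rows align with ``ids`` and ``d`` is constant across rows.
    """

    ids: list[str]
    matrix: np.ndarray
    scheme: str = "custom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            self.matrix = self.matrix.reshape(len(self.ids), -1)
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids but {self.matrix.shape[0]} matrix rows"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in FeatureMatrix")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        self._index = {cid: i for i, cid in enumerate(self.ids)}

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def row(self, id_: str) -> np.ndarray:
        try:
            return self.matrix[self._index[id_]]
        except KeyError:
            raise KeyError(f"unknown id {id_!r} in {self.scheme} FeatureMatrix")

    def rows(self, ids: Sequence[str]) -> np.ndarray:
        return np.stack([self.row(i) for i in ids]) if len(ids) else np.empty((0, self.d))

    def __contains__(self, id_: str) -> bool:
        return id_ in self._index

    def save(self, path: str) -> None:
        """Write an .npz archive: ids + matrix + scheme tag."""
        np.savez(
            path,
            ids=np.asarray(self.ids, dtype=object),
            matrix=self.matrix,
            scheme=np.asarray(self.scheme),
        )

    @classmethod
    def load(cls, path: str) -> "FeatureMatrix":
        with np.load(path, allow_pickle=True) as z:
            return cls(
                ids=[str(i) for i in z["ids"]],
                matrix=z["matrix"],
                scheme=str(z["scheme"]),
            )

    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame(self.matrix, index=pd.Index(self.ids, name="id"))
        df.to_csv(path, sep="\t")


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise FeaturizationError(str(smiles), "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(smiles)
    # Round-trip through the canonical SMILES so spelling variants and any
    # input-order-dependent state collapse to one representative molecule.
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    if mol is None:  # pragma: no cover - canonical SMILES always reparses
        raise FeaturizationError(smiles, "canonicalization failed")
    return mol


def compute_maccs(smiles: str) -> np.ndarray:
    """167-slot binary MACCS key fingerprint (slot 0 always 0)."""
    mol = _mol_from_smiles(smiles)
    bv = MACCSkeys.GenMACCSKeys(mol)
    out = np.zeros(MACCS_NBITS, dtype=np.uint8)
    out[list(bv.GetOnBits())] = 1
    return out


def compute_ecfp(
    smiles: str,
    radius: int = ECFP_DEFAULT_RADIUS,
    n_bits: int = ECFP_DEFAULT_NBITS,
) -> np.ndarray:
    """Binary ECFP (Morgan) fingerprint of length ``n_bits``."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    out = np.zeros(n_bits, dtype=np.uint8)
    out[list(bv.GetOnBits())] = 1
    return out


def featurize_smiles(smiles: str, scheme: str = "maccs", **kw) -> np.ndarray:
    if scheme == "maccs":
        return compute_maccs(smiles)
    if scheme == "ecfp":
        return compute_ecfp(smiles, **kw)
    raise ValueError(f"unknown compound featurization scheme {scheme!r}")


def scheme_dim(scheme: str, n_bits: int = ECFP_DEFAULT_NBITS) -> int:
    return MACCS_NBITS if scheme == "maccs" else n_bits


def featurize_compound_table(
    table: pd.DataFrame | Iterable[tuple[str, str]],
    scheme: str = "maccs",
    radius: int = ECFP_DEFAULT_RADIUS,
    n_bits: int = ECFP_DEFAULT_NBITS,
    on_error: str = "strict",
) -> tuple[FeatureMatrix, list[tuple[str, str]]]:
    """Featurize a (compound_id, smiles) table into a FeatureMatrix.

    ``on_error='strict'`` raises on the first bad SMILES; ``'skip'`` drops
    the row and records it in the returned failure list.  Row order is
    preserved.  Returns ``(features, failures)``.
    """
    if on_error not in ("strict", "skip"):
        raise ValueError("on_error must be 'strict' or 'skip'")
    if isinstance(table, pd.DataFrame):
        rows = list(zip(table["compound_id"].astype(str), table["smiles"].astype(str)))
    else:
        rows = [(str(c), str(s)) for c, s in table]
    ids = [c for c, _ in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({c for c in ids if ids.count(c) > 1})
        raise ValueError(f"duplicate compound_id(s): {dupes}")

    kw = {} if scheme == "maccs" else {"radius": radius, "n_bits": n_bits}
    kept_ids: list[str] = []
    vecs: list[np.ndarray] = []
    failures: list[tuple[str, str]] = []
    for cid, smi in rows:
        try:
            vecs.append(featurize_smiles(smi, scheme, **kw))
            kept_ids.append(cid)
        except FeaturizationError as exc:
            if on_error == "strict":
                raise
            log.warning("skipping compound %s: %s", cid, exc)
            failures.append((cid, str(exc)))
    if rows and not kept_ids:
        raise FeaturizationError("<all rows>", "every input row failed featurization")
    d = scheme_dim(scheme, n_bits)
    matrix = np.stack(vecs).astype(float) if vecs else np.empty((0, d))
    fm = FeatureMatrix(ids=kept_ids, matrix=matrix, scheme=scheme,
                       meta={"radius": radius, "n_bits": n_bits} if scheme == "ecfp" else {})
    return fm, failures


def read_compound_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"compound_id", "smiles"} - set(df.columns)
    if missing:
        raise ValueError(f"compound CSV missing column(s) {sorted(missing)}")
    return df
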