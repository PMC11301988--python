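"""Kinase featurization: amino-acid sequence -> 343-dim conjoint-triad descriptor.

The conjoint-triad descriptor maps the 20 standard amino acids into seven
physicochemical classes (dipole moment / side-chain volume clustering) and
counts every overlapping window of three consecutive residues as one of the
7^3 = 343 possible class triads.  Normalized mode divides the counts by the
number of windows (L - 2), giving a length-invariant distribution that sums
to one.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from Bio import SeqIO

from .chem_features import FeatureMatrix

#: The standard seven-class amino-acid partition used by conjoint-triad
#: descriptors (grouped by dipole and side-chain volume).
AA_CLASSES: dict[str, int] = {}
for _cls, _residues in enumerate(
    ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C"), start=1
):
    for _r in _residues:
        AA_CLASSES[_r] = _cls

N_CLASSES = 7
CTD_DIM = N_CLASSES**3  # 343


class SequenceError(ValueError):
    pass


def classify_residue(residue: str) -> int:
    """Class index in 1..7 for a one-letter amino-acid code."""
    try:
        return AA_CLASSES[residue.upper()]
    except KeyError:
        raise SequenceError(f"non-standard residue {residue!r}")


def clean_sequence(sequence: str, mode: str = "strict") -> str:
    """Uppercase and validate a sequence.

    ``strict`` raises on any character outside the 20-letter alphabet;
    ``lenient`` silently drops such characters (X, B, Z, U, gaps, ``*``).
    """
    if mode not in ("strict", "lenient"):
        raise ValueError("mode must be 'strict' or 'lenient'")
    seq = sequence.strip().upper()
    if mode == "strict":
        bad = sorted({c for c in seq if c not in AA_CLASSES})
        if bad:
            raise SequenceError(f"non-standard residue(s) {bad} in sequence")
        return seq
    return "".join(c for c in seq if c in AA_CLASSES)


def triad_index(c1: int, c2: int, c3: int) -> int:
    """0-based descriptor slot for the class triple (c1, c2, c3), each in 1..7."""
    return (c1 - 1) * 49 + (c2 - 1) * 7 + (c3 - 1)


def conjoint_triad(
    sequence: str, normalize: bool = True, mode: str = "strict"
) -> np.ndarray:
    """Conjoint-triad descriptor of a protein sequence.

    Raw mode returns integer counts over the L-2 sliding windows; normalized
    mode (default) divides by L-2 so every descriptor sums to one.
    """
    seq = clean_sequence(sequence, mode)
    L = len(seq)
    if L < 3:
        raise SequenceError(f"sequence too short after cleaning (L={L} < 3)")
    classes = np.array([AA_CLASSES[c] for c in seq]) - 1
    slots = classes[:-2] * 49 + classes[1:-1] * 7 + classes[2:]
    counts = np.bincount(slots, minlength=CTD_DIM).astype(float)
    if normalize:
        counts /= L - 2
    return counts


def featurize_kinase_fasta(
    fasta_path: str, normalize: bool = True, mode: str = "strict"
) -> FeatureMatrix:
    """One 343-dim conjoint-triad row per FASTA record, order preserved."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for record in SeqIO.parse(fasta_path, "fasta"):
        if record.id in ids:
            raise ValueError(f"duplicate FASTA header {record.id!r}")
        try:
            rows.append(conjoint_triad(str(record.seq), normalize, mode))
        except SequenceError as exc:
            raise SequenceError(f"record {record.id!r}: {exc}") from exc
        ids.append(record.id)
    if not ids:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return FeatureMatrix(ids=ids, matrix=np.stack(rows), scheme="ctd")


def featurize_sequences(
    records: Iterable[tuple[str, str]], normalize: bool = True, mode: str = "strict"
) -> FeatureMatrix:
    """In-memory counterpart of :func:`featurize_kinase_fasta`."""
    ids, rows = [], []
    for kid, seq in records:
        ids.append(str(kid))
        rows.append(conjoint_triad(seq, normalize, mode))
    return FeatureMatrix(ids=ids, matrix=np.stack(rows), scheme="ctd")
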