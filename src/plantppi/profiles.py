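"""Per-protein evolutionary profiles and their 20x20 condensation.

A profile is produced either by an external PSI-BLAST search (the
position-specific scoring matrix, PSSM) or by the BLOSUM62
substitution-matrix representation (SMR) used as a search-free
comparator.  Variable-length U x 20 profiles are condensed to a fixed
20 x 20 matrix before feature extraction.
"""

from __future__ import annotations

import os
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import (
    AA_ORDER,
    AMBIGUITY_CODES,
    Profile,
    ProteinRecord,
    parse_ascii_pssm,
    write_fasta,
)


@dataclass
class PsiBlastConfig:
    """How to invoke the external PSI-BLAST program.

    ``iterations`` and ``evalue`` default to the standard profile-search
    settings (3 iterations, 0.001 cutoff).  ``evalue_applies_to``
    selects whether the cutoff is passed as the profile-inclusion
    threshold (``inclusion``, default) or the search E-value
    (``search``).
    """

    db_path: str
    iterations: int = 3
    evalue: float = 0.001
    executable: str = "psiblast"
    evalue_applies_to: str = "inclusion"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")
        if self.evalue_applies_to not in ("inclusion", "search"):
            raise ValueError("evalue_applies_to must be 'inclusion' or 'search'")


@dataclass
class CondensedMatrix:
    """A 20 x 20 condensation of a variable-length profile.

    ``crossproduct`` mode holds the length-normalised Gram matrix
    (P^T P)/U, which is symmetric positive semi-definite;
    ``padtrunc`` holds the first 20 profile rows, zero-padded.
    """

    values: np.ndarray
    mode: str = "crossproduct"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20, 20):
            raise ValueError(f"condensed matrix must be 20x20, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("condensed matrix contains non-finite entries")
        if self.mode not in ("crossproduct", "padtrunc"):
            raise ValueError(f"unknown condensation mode {self.mode!r}")


_BLOSUM62_ROWS: dict[str, np.ndarray] | None = None


def _blosum62_rows() -> dict[str, np.ndarray]:
    global _BLOSUM62_ROWS
    if _BLOSUM62_ROWS is None:
        mat = substitution_matrices.load("BLOSUM62")
        rows = {}
        for aa in AA_ORDER:
            rows[aa] = np.array([mat[aa, bb] for bb in AA_ORDER], dtype=float)
        for code in AMBIGUITY_CODES:
            rows[code] = np.zeros(20)
        _BLOSUM62_ROWS = rows
    return _BLOSUM62_ROWS


def smr_profile(record: ProteinRecord) -> Profile:
    """Encode a sequence as its BLOSUM62 substitution profile.

    Row t is the BLOSUM62 score row of the residue at position t, in the
    canonical column order; ambiguity codes contribute all-zero rows.
    Deterministic and search-free.
    """
    rows = _blosum62_rows()
    values = np.array([rows[aa] for aa in record.sequence], dtype=float)
    return Profile(values=values, source="smr")


def run_psiblast(record: ProteinRecord, cfg: PsiBlastConfig) -> Profile:
    """Run PSI-BLAST for one protein and parse its ASCII PSSM.

    Falls back to :func:`smr_profile` with a warning when the search
    finds no homologs and hence writes no PSSM.
    """
    evalue_flag = (
        "-inclusion_ethresh" if cfg.evalue_applies_to == "inclusion" else "-evalue"
    )
    with tempfile.TemporaryDirectory() as tmp:
        query = Path(tmp) / "query.fasta"
        out_pssm = Path(tmp) / "out.pssm"
        write_fasta([record], query)
        cmd = [
            cfg.executable,
            "-query", str(query),
            "-db", str(cfg.db_path),
            "-num_iterations", str(cfg.iterations),
            evalue_flag, str(cfg.evalue),
            "-out_ascii_pssm", str(out_pssm),
        ]
        try:
            proc = subprocess.run(cmd, capture_output=True, text=True)
        except FileNotFoundError:
            raise RuntimeError(
                f"PSI-BLAST executable not found: {cfg.executable!r}"
            ) from None
        if proc.returncode != 0:
            raise RuntimeError(
                f"PSI-BLAST failed for {record.id} (exit {proc.returncode}): "
                f"{proc.stderr.strip()}"
            )
        if not out_pssm.exists() or os.path.getsize(out_pssm) == 0:
            warnings.warn(
                f"PSI-BLAST produced no PSSM for {record.id} (no hits); "
                "falling back to the BLOSUM62 substitution profile"
            )
            return smr_profile(record)
        profile = parse_ascii_pssm(out_pssm)
    if profile.length != len(record):
        warnings.warn(
            f"PSSM for {record.id} has {profile.length} rows but the sequence "
            f"has {len(record)} residues"
        )
    return profile


def logistic_normalize(profile: Profile) -> Profile:
    """Map each log-odds entry through the logistic function 1/(1+e^-x)."""
    return Profile(values=1.0 / (1.0 + np.exp(-profile.values)), source=profile.source)


def condense(profile: Profile, mode: str = "crossproduct") -> CondensedMatrix:
    """Condense a U x 20 profile into a fixed 20 x 20 matrix.

    ``crossproduct`` (default) computes (P^T P)/U — symmetric, positive
    semi-definite and invariant to reordering of sequence positions.
    ``padtrunc`` keeps the first 20 rows, zero-padding shorter profiles.
    """
    P = profile.values
    if mode == "crossproduct":
        M = (P.T @ P) / P.shape[0]
    elif mode == "padtrunc":
        M = np.zeros((20, 20))
        u = min(20, P.shape[0])
        M[:u, :] = P[:u, :]
    else:
        raise ValueError(f"unknown condensation mode {mode!r}")
    return CondensedMatrix(values=M, mode=mode)
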