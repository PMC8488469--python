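"""Readers and writers for every external format the pipeline touches.

Covers FASTA protein records, labelled pair lists, the PSI-BLAST ASCII
PSSM dialect (``-out_ascii_pssm``), cross-validation reports and ROC
point tables.  The canonical amino-acid column order is PSI-BLAST's
ASCII order (``A R N D C Q E G H I L K M F P S T W Y V``) and is used
for every 20-column matrix in the package.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .evaluation import CVReport

#: Canonical amino-acid order of the PSI-BLAST ASCII PSSM columns.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Tolerated ambiguity codes; mapped to neutral (all-zero) profile rows.
AMBIGUITY_CODES = "BZXU"

_VALID_LETTERS = frozenset(AA_ORDER) | frozenset(AMBIGUITY_CODES)


class FormatError(ValueError):
    """A file does not conform to its declared external format."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid protein id {self.id!r}")
        if len(self.sequence) < 1:
            raise FormatError(f"empty sequence for {self.id}")
        bad = set(self.sequence.upper()) - _VALID_LETTERS
        if bad:
            raise FormatError(
                f"sequence for {self.id} contains invalid letters: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class InteractionPair:
    """A labelled protein pair: 1 = interacting, 0 = non-interacting."""

    id_a: str
    id_b: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise FormatError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class Profile:
    """A U x 20 per-position substitution profile.

    Rows follow sequence positions; columns follow :data:`AA_ORDER`.
    ``source`` records how the profile was obtained: a PSI-BLAST search
    (``pssm``), the BLOSUM62 substitution-matrix representation
    (``smr``), or the synthetic generator (``synthetic``).
    """

    values: np.ndarray
    source: str = "pssm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError(
                f"profile must be U x 20, got shape {self.values.shape}"
            )
        if self.values.shape[0] < 1:
            raise ValueError("profile must have at least one row")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile contains non-finite entries")
        if self.source not in ("pssm", "smr", "synthetic"):
            raise ValueError(f"unknown profile source {self.source!r}")

    @property
    def length(self) -> int:
        return self.values.shape[0]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id}")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapping sequences at 60 columns."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_pair_list(path: str | Path) -> list[InteractionPair]:
    """Read a tab- or comma-separated ``idA  idB  label`` pair list.

    Duplicate rows are kept but trigger a warning.
    """
    pairs: list[InteractionPair] = []
    seen: set[tuple[str, str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected idA, idB, label")
            id_a, id_b, raw = fields[0].strip(), fields[1].strip(), fields[2].strip()
            try:
                label = int(raw)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: label {raw!r} is not an integer"
                ) from None
            if label not in (0, 1):
                raise FormatError(f"{path}:{lineno}: label must be 0 or 1, got {label}")
            key = (id_a, id_b, label)
            if key in seen:
                warnings.warn(f"{path}:{lineno}: duplicate pair {id_a}/{id_b}")
            seen.add(key)
            pairs.append(InteractionPair(id_a, id_b, label))
    return pairs


def write_pair_list(pairs: Iterable[InteractionPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.id_a}\t{p.id_b}\t{p.label}\n")


def parse_ascii_pssm(path: str | Path) -> Profile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into a :class:`Profile`.

    Only the first 20 numeric columns of each position row (the log-odds
    block) are kept; the weighted-percentage block and the trailing
    statistics lines are skipped.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if (
                len(tokens) >= 2
                and tokens[0].isdigit()
                and len(tokens[1]) == 1
                and tokens[1].isalpha()
            ):
                numeric = tokens[2:]
                try:
                    values = [float(t) for t in numeric]
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric score column"
                    ) from None
                if len(values) < 40:
                    raise FormatError(
                        f"{path}:{lineno}: position row has {len(values)} numeric "
                        "columns, expected at least 40"
                    )
                rows.append(values[:20])
    if not rows:
        raise FormatError(f"{path}: no position rows found")
    return Profile(values=np.array(rows, dtype=float), source="pssm")


_PCT_METRICS = ("acc", "pr", "sens", "spec", "mcc")


def _fmt_row(label: str, vals: Sequence[str]) -> str:
    return f"{label:<10}" + "".join(f"{v:>18}" for v in vals)


def write_report(report: "CVReport", path: str | Path) -> None:
    """Write a cross-validation report.

    Emits a machine-readable ``key = value`` block followed by an
    aligned table with one row per fold and an ``Average`` row holding
    mean +/- sample standard deviation per metric (percentages to two
    decimals, AUC to four).
    """
    folds = report.folds
    if not folds:
        raise ValueError("cannot write an empty report")
    lines = ["# five-fold cross-validation report", f"folds = {len(folds)}"]
    for i, m in enumerate(folds, start=1):
        for key in (*_PCT_METRICS, "auc"):
            lines.append(f"fold{i}.{key} = {getattr(m, key):.10g}")
    for key in (*_PCT_METRICS, "auc"):
        lines.append(f"mean.{key} = {report.mean[key]:.10g}")
        lines.append(f"sd.{key} = {report.sd[key]:.10g}")
    lines.append("")

    header = _fmt_row(
        "fold", ["Acc(%)", "PR(%)", "Sens(%)", "Spec(%)", "MCC(%)", "AUC"]
    )
    lines.append(header)
    for i, m in enumerate(folds, start=1):
        vals = [f"{100 * getattr(m, k):.2f}" for k in _PCT_METRICS]
        vals.append(f"{m.auc:.4f}")
        lines.append(_fmt_row(str(i), vals))
    avg = [
        f"{100 * report.mean[k]:.2f} ± {100 * report.sd[k]:.2f}"
        for k in _PCT_METRICS
    ]
    avg.append(f"{report.mean['auc']:.4f} ± {report.sd['auc']:.4f}")
    lines.append(_fmt_row("Average", avg))
    Path(path).write_text("\n".join(lines) + "\n")


def write_roc(points: Iterable[tuple[float, float, float]], path: str | Path) -> None:
    """Write ROC points as CSV ``fpr,tpr,threshold``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fpr", "tpr", "threshold"])
        for fpr, tpr, thr in points:
            writer.writerow([repr(float(fpr)), repr(float(tpr)), repr(float(thr))])


def read_roc(path: str | Path) -> list[tuple[float, float, float]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        return [(float(a), float(b), float(c)) for a, b, c in reader]
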