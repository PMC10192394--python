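"""Sequence and tabular I/O: FASTA, site tables, PSP window extraction,
benchmark construction, and the prediction-table contract.

A PSP(m, n) item is a lysine-centered peptide window with m upstream and
n downstream residues; positions falling outside the protein are padded
with ``*``. All protein coordinates are 1-based and inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .alphabet import SEQUENCE_ALPHABET

log = logging.getLogger(__name__)

#: Labels a PSP item may carry.
LABELS = ("positive", "negative", "functional_positive", "unlabeled")

PREDICTION_COLUMNS = (
    "accession",
    "position",
    "residue",
    "predictor",
    "peptide",
    "score",
    "cutoff",
)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20 standard letters plus B, Z, X."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"{self.accession}: invalid sequence characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PSPItem:
    """A fixed-width peptide window around a candidate lysine.

    ``center`` is the 0-based offset of the central lysine within the
    peptide; None means the midpoint (symmetric PSP(m, m) windows).
    """

    source_accession: str
    position: int  # 1-based index of the central K in the protein
    peptide: str
    label: str = "unlabeled"
    center: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        mid = self.center if self.center is not None else len(self.peptide) // 2
        if not 0 <= mid < len(self.peptide) or self.peptide[mid] != "K":
            found = self.peptide[mid] if 0 <= mid < len(self.peptide) else "?"
            raise ValueError(
                f"{self.source_accession}:{self.position}: central residue is "
                f"{found!r}, not K"
            )

    @property
    def is_positive(self) -> bool:
        return self.label in ("positive", "functional_positive")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file.

    Sequences are uppercased; the rare residues U (selenocysteine) and O
    (pyrrolysine) are mapped to X with a warning. Duplicate accessions or
    a malformed header line raise ValueError.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    accession: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal accession, chunks
        if accession is None:
            return
        seq = "".join(chunks).upper()
        if "U" in seq or "O" in seq:
            log.warning(
                "%s: mapping %d U/O residue(s) to X",
                accession,
                seq.count("U") + seq.count("O"),
            )
            seq = seq.replace("U", "X").replace("O", "X")
        records.append(ProteinRecord(accession, seq))
        accession, chunks = None, []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                accession = line[1:].split()[0] if len(line) > 1 else ""
                if not accession:
                    raise ValueError(f"{path}:{lineno}: header line with no accession")
                if accession in seen:
                    raise ValueError(
                        f"{path}:{lineno}: duplicate accession {accession!r} "
                        f"(first seen on line {seen[accession]})"
                    )
                seen[accession] = lineno
            elif accession is None:
                raise ValueError(
                    f"{path}:{lineno}: sequence data before any '>' header"
                )
            else:
                chunks.append(line)
    flush()
    if not records:
        log.warning("%s: no FASTA records found", path)
    return records


def write_fasta(path: str | Path, records: Iterable[ProteinRecord], width: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def extract_psp(
    protein: ProteinRecord,
    position: int,
    m: int = 30,
    n: int = 30,
    label: str = "unlabeled",
) -> PSPItem:
    """Extract the PSP(m, n) window around a lysine at a 1-based position."""
    seq = protein.sequence
    if not 1 <= position <= len(seq):
        raise ValueError(
            f"{protein.accession}: position {position} outside 1..{len(seq)}"
        )
    centre = seq[position - 1]
    if centre != "K":
        raise ValueError(
            f"{protein.accession}:{position}: residue is {centre!r}, not K"
        )
    start, end = position - 1 - m, position + n
    left = seq[max(start, 0) : position - 1].rjust(m, "*")
    right = seq[position : min(end, len(seq))].ljust(n, "*")
    return PSPItem(protein.accession, position, left + "K" + right, label, center=m)


@dataclass
class BenchmarkResult:
    """Labeled PSP dataset plus the rejected-positive report."""

    items: list[PSPItem]
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["accession", "position", "reason"])
    )

    @property
    def positives(self) -> list[PSPItem]:
        return [it for it in self.items if it.is_positive]

    @property
    def negatives(self) -> list[PSPItem]:
        return [it for it in self.items if it.label == "negative"]


def build_benchmark(
    positives: Sequence[tuple[str, int]] | pd.DataFrame,
    proteome: Sequence[ProteinRecord],
    m: int = 30,
    n: int = 30,
) -> BenchmarkResult:
    """Build a labeled PSP(m, n) benchmark from positive sites and a proteome.

    Every lysine in a positive-bearing protein that is not itself a
    positive site becomes a negative. Exact-duplicate peptides are
    collapsed to a single item, positives winning label conflicts.
    Output is deterministically ordered by (accession, position).
    Positive sites that do not fall on a K (or name an unknown protein)
    go to the rejects report instead of being silently dropped.
    """
    if isinstance(positives, pd.DataFrame):
        pos_pairs = list(zip(positives["accession"], positives["position"].astype(int)))
    else:
        pos_pairs = [(acc, int(pos)) for acc, pos in positives]

    by_acc = {rec.accession: rec for rec in proteome}
    pos_set: set[tuple[str, int]] = set()
    rejects: list[dict] = []
    for acc, pos in pos_pairs:
        rec = by_acc.get(acc)
        if rec is None:
            rejects.append({"accession": acc, "position": pos, "reason": "protein not in proteome"})
        elif not 1 <= pos <= len(rec):
            rejects.append({"accession": acc, "position": pos, "reason": "position out of range"})
        elif rec.sequence[pos - 1] != "K":
            rejects.append(
                {
                    "accession": acc,
                    "position": pos,
                    "reason": f"residue is {rec.sequence[pos - 1]!r}, not K",
                }
            )
        else:
            pos_set.add((acc, pos))

    raw: list[PSPItem] = []
    for acc in sorted({a for a, _ in pos_set}):
        rec = by_acc[acc]
        for i, ch in enumerate(rec.sequence, start=1):
            if ch != "K":
                continue
            label = "positive" if (acc, i) in pos_set else "negative"
            raw.append(extract_psp(rec, i, m, n, label=label))

    # exact-duplicate clearance: one item per peptide, positive beats negative,
    # then first in (accession, position) order.
    raw.sort(key=lambda it: (it.source_accession, it.position))
    best: dict[str, PSPItem] = {}
    for it in raw:
        prev = best.get(it.peptide)
        if prev is None or (it.is_positive and not prev.is_positive):
            best[it.peptide] = it
    items = sorted(best.values(), key=lambda it: (it.source_accession, it.position))
    rej = pd.DataFrame(rejects, columns=["accession", "position", "reason"])
    return BenchmarkResult(items=items, rejects=rej)


# ---------------------------------------------------------------------------
# ELM-dialect site tables and the 7-column prediction table


def read_elm(path: str | Path) -> pd.DataFrame:
    """Read an ELM-dialect site table: tab-separated (accession, position,
    peptide), no header. Returns a DataFrame with those columns.
    """
    path = Path(path)
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            acc, pos_s, pep = parts
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer position {pos_s!r}") from None
            mid = len(pep) // 2
            if len(pep) % 2 == 0 or pep[mid] != "K":
                raise ValueError(
                    f"{path}:{lineno}: peptide is not centered on K"
                )
            rows.append({"accession": acc, "position": pos, "peptide": pep})
    return pd.DataFrame(rows, columns=["accession", "position", "peptide"])


def write_elm(path: str | Path, items: Iterable[PSPItem]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for it in items:
            fh.write(f"{it.source_accession}\t{it.position}\t{it.peptide}\n")


def write_benchmark_table(path: str | Path, items: Iterable[PSPItem]) -> None:
    """Labeled benchmark TSV: accession, position, peptide, label (with header)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("accession\tposition\tpeptide\tlabel\n")
        for it in items:
            fh.write(f"{it.source_accession}\t{it.position}\t{it.peptide}\t{it.label}\n")


def read_benchmark_table(path: str | Path) -> list[PSPItem]:
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "peptide": str, "label": str})
    needed = {"accession", "position", "peptide", "label"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: benchmark table needs columns {sorted(needed)}")
    return [
        PSPItem(r.accession, int(r.position), r.peptide, r.label)
        for r in df.itertuples(index=False)
    ]


def write_predictions(path: str | Path, rows: pd.DataFrame) -> None:
    """Write the 7-column prediction table (tab-separated, header line,
    scores and cutoffs printed with 4 decimals).
    """
    missing = [c for c in PREDICTION_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"prediction table missing columns {missing}")
    out = rows.loc[:, list(PREDICTION_COLUMNS)].copy()
    out["score"] = out["score"].map(lambda v: f"{float(v):.4f}")
    out["cutoff"] = out["cutoff"].map(lambda v: f"{float(v):.4f}")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read back a prediction table written by :func:`write_predictions`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    got = tuple(df.columns)
    if got != PREDICTION_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {PREDICTION_COLUMNS}, got {got}"
        )
    df["position"] = df["position"].astype(int)
    df["score"] = df["score"].astype(float)
    df["cutoff"] = df["cutoff"].astype(float)
    return df
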