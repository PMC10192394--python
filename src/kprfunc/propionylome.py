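"""Post-processing of quantified propionylome site tables.

Covers: mapping modified peptides back to protein coordinates,
localization-probability filtering, peak/trough fold changes across
time points, clock-mutant effect filtering, the acyl-lysine diagnostic
ion mass, and per-position residue enrichment around modified lysines.

A site table is a DataFrame with columns ``accession``, ``position``,
``LP`` (localization probability), and one column per sample intensity
(e.g. WT_CT0, WT_CT6, WT_CT12, WT_CT18, PER0_CT6, PER0_CT18) — a
documented simplification of a MaxQuant "sites" table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .seqio import ProteinRecord

__all__ = [
    "ModifiedPeptide",
    "SiteMatch",
    "map_peptide_to_sites",
    "fold_change",
    "add_fold_changes",
    "filter_cycling",
    "mutant_effect",
    "diagnostic_ion_mz",
    "motif_position_frequencies",
    "read_site_table",
    "write_site_table",
    "PROPIONYL_DELTA",
    "ACETYL_DELTA",
]

# Unimod monoisotopic masses (Da)
LYSINE_RESIDUE_MASS = 128.09496
IMMONIUM_OFFSET = 26.98708  # residue -> immonium (loss of CO, gain of H)
NH3_MASS = 17.02655
PROPIONYL_DELTA = 56.02621
ACETYL_DELTA = 42.01057


@dataclass(frozen=True)
class ModifiedPeptide:
    """A sequenced peptide with modified lysine offsets (1-based)."""

    sequence: str
    modified_offsets: tuple[int, ...]
    modification: str = "propionyl"
    spectral_count: int = 1

    def __post_init__(self) -> None:
        for off in self.modified_offsets:
            if not 1 <= off <= len(self.sequence):
                raise ValueError(f"offset {off} outside peptide of length {len(self.sequence)}")
            if self.sequence[off - 1] != "K":
                raise ValueError(
                    f"offset {off} points at {self.sequence[off - 1]!r}, not K"
                )


@dataclass(frozen=True)
class SiteMatch:
    accession: str
    position: int  # 1-based protein coordinate of the modified K
    ambiguous: bool  # peptide matched more than one location


def map_peptide_to_sites(
    pep: ModifiedPeptide, proteome: Sequence[ProteinRecord]
) -> list[SiteMatch]:
    """Locate a modified peptide in the proteome by exact substring search.

    Every match is returned (all proteins, all occurrences); matches are
    flagged ambiguous when the peptide occurs more than once overall.
    An unmatched peptide yields an empty list — callers should report
    it rather than drop it silently.
    """
    if len(pep.sequence) < 5:
        raise ValueError("peptide too short to map reliably (< 5 residues)")
    hits: list[tuple[str, int]] = []  # (accession, 1-based match start)
    for rec in proteome:
        start = rec.sequence.find(pep.sequence)
        while start != -1:
            hits.append((rec.accession, start + 1))
            start = rec.sequence.find(pep.sequence, start + 1)
    ambiguous = len(hits) > 1
    return [
        SiteMatch(acc, match_start + off - 1, ambiguous)
        for acc, match_start in hits
        for off in pep.modified_offsets
    ]


def fold_change(
    intensities: pd.Series | dict, samples: Sequence[str]
) -> float | None:
    """Peak/trough fold change: max/min intensity over the sample subset.

    Returns None (undefined) when any intensity in the subset is zero or
    missing; such sites are excluded from cycling counts and reported.
    """
    vals = pd.Series(intensities).reindex(list(samples)).astype(float)
    if len(samples) < 2:
        raise ValueError("fold change needs at least 2 samples")
    if vals.isna().any() or (vals <= 0).any():
        return None
    return float(vals.max() / vals.min())


def add_fold_changes(
    table: pd.DataFrame, samples: Sequence[str], column: str = "FC"
) -> pd.DataFrame:
    """Compute per-site fold change over ``samples`` into ``column``."""
    out = table.copy()
    out[column] = [
        fold_change(row, samples) for _, row in table[list(samples)].iterrows()
    ]
    return out


def filter_cycling(
    table: pd.DataFrame, fc_threshold: float = 1.5, column: str = "FC"
) -> pd.DataFrame:
    """Sites whose fold change strictly exceeds the threshold.

    Undefined fold changes (None/NaN) never pass. Row order follows the
    input table, so output is deterministic.
    """
    if column not in table.columns:
        raise ValueError(f"run add_fold_changes first; no {column!r} column")
    fc = pd.to_numeric(table[column], errors="coerce")
    return table[fc > fc_threshold]


def mutant_effect(
    table: pd.DataFrame,
    wt_samples: Sequence[str],
    mutant_samples: Sequence[str],
    threshold: float = 1.2,
    column: str = "mutant_FC",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clock-mutant effect: max over matched time points of the
    larger of WT/mutant and mutant/WT intensity ratios.

    ``wt_samples`` and ``mutant_samples`` pair up positionally (matched
    time points). Returns (annotated table, subset with effect strictly
    above threshold); sites with a zero/missing intensity at every
    matched point get an undefined effect and are excluded.
    """
    if len(wt_samples) != len(mutant_samples) or not wt_samples:
        raise ValueError("wt and mutant sample lists must pair up and be non-empty")
    wt = table[list(wt_samples)].astype(float).to_numpy()
    mu = table[list(mutant_samples)].astype(float).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((wt > 0) & (mu > 0), np.maximum(wt / mu, mu / wt), np.nan)
    effect = np.nanmax(ratio, axis=1) if ratio.size else np.array([])
    out = table.copy()
    out[column] = effect
    return out, out[out[column] > threshold]


def diagnostic_ion_mz(mod_delta_mass: float) -> float:
    """m/z of the acyl-lysine diagnostic ion (immonium minus NH3).

    m/z = K residue mass + modification delta - immonium offset - NH3.
    For the propionyl delta (56.02621 Da) this is 140.1075 at 4 dp.
    """
    if mod_delta_mass < 0:
        raise ValueError("modification delta mass must be non-negative")
    return LYSINE_RESIDUE_MASS + mod_delta_mass - IMMONIUM_OFFSET - NH3_MASS


def motif_position_frequencies(
    positives: Sequence[str], background: Sequence[str]
) -> pd.DataFrame:
    """Per-position residue enrichment around the central lysine.

    Both inputs are equal-length lysine-centered windows. For every
    (offset, residue) observed in the foreground: foreground frequency,
    background frequency, their ratio, and a two-sided binomial p-value
    of the foreground count under the background frequency. Padding
    ``*`` characters are excluded from all counts. Offsets are relative
    to the central K (negative = upstream).
    """
    if not positives or not background:
        raise ValueError("both peptide sets must be non-empty")
    L = len(positives[0])
    if any(len(p) != L for p in positives) or any(len(p) != L for p in background):
        raise ValueError("all peptides must share one window length")
    mid = L // 2
    rows = []
    for j in range(L):
        if j == mid:
            continue
        fg = [p[j] for p in positives if p[j] != "*"]
        bg = [p[j] for p in background if p[j] != "*"]
        if not fg or not bg:
            continue
        n_fg, n_bg = len(fg), len(bg)
        bg_counts = pd.Series(bg).value_counts()
        fg_counts = pd.Series(fg).value_counts()
        for res, k in fg_counts.items():
            f_fg = k / n_fg
            f_bg = bg_counts.get(res, 0) / n_bg
            if f_bg > 0:
                pval = binomtest(int(k), n_fg, f_bg, alternative="two-sided").pvalue
                ratio = f_fg / f_bg
            else:
                pval, ratio = np.nan, np.inf
            rows.append(
                {
                    "offset": j - mid,
                    "residue": res,
                    "fg_freq": f_fg,
                    "bg_freq": f_bg,
                    "ratio": ratio,
                    "p": pval,
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["p", "offset", "residue"], kind="mergesort")
        .reset_index(drop=True)
    )


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read the TSV site table (accession, position, LP, intensities)."""
    df = pd.read_csv(path, sep="\t")
    required = {"accession", "position", "LP"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: site table missing columns {sorted(missing)}")
    df["position"] = df["position"].astype(int)
    df["LP"] = df["LP"].astype(float)
    if ((df["LP"] < 0) | (df["LP"] > 1)).any():
        raise ValueError(f"{path}: LP values outside [0, 1]")
    return df


def write_site_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")
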