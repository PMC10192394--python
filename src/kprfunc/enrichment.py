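"""Hypergeometric term enrichment of a foreground protein/gene set.

For a term t, with N background entities annotated by at least one
term, n of them annotated by t, M foreground entities annotated by at
least one term, and m of those annotated by t:

    E-ratio = (m/M) / (n/N)

The p-value is the hypergeometric upper-tail sum over m' = m..n when
E-ratio >= 1, and the lower-tail sum over m' = 0..m otherwise.
Entities without any annotation never enter N or M. No ontology-graph
propagation is applied. A Benjamini-Hochberg column is available as an
optional extension (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "EnrichmentInput",
    "EnrichmentResult",
    "enrich_term",
    "enrich_set",
    "read_annotation",
]


@dataclass(frozen=True)
class EnrichmentInput:
    N: int  # background entities with >= 1 term
    n: int  # background entities with term t
    M: int  # foreground entities with >= 1 term
    m: int  # foreground entities with term t

    def __post_init__(self) -> None:
        for name in ("N", "n", "M", "m"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} is negative")
        if self.n > self.N:
            raise ValueError(f"n={self.n} exceeds N={self.N}")
        if self.M > self.N:
            raise ValueError(f"M={self.M} exceeds N={self.N}")
        if self.m > min(self.n, self.M):
            raise ValueError(f"m={self.m} exceeds min(n={self.n}, M={self.M})")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    e_ratio: float
    p: float
    tail: str  # "upper" iff e_ratio >= 1, else "lower"
    counts: EnrichmentInput


def enrich_term(inp: EnrichmentInput, term: str = "") -> EnrichmentResult:
    """E-ratio and tail p-value for a single term."""
    if inp.M == 0 or inp.n == 0:
        raise ValueError("enrich_term requires M > 0 and n > 0")
    e_ratio = (inp.m / inp.M) / (inp.n / inp.N)
    if e_ratio >= 1.0:
        # sum_{m'=m}^{n} P(m'); pmf vanishes beyond min(n, M)
        p = float(hypergeom.sf(inp.m - 1, inp.N, inp.n, inp.M))
        tail = "upper"
    else:
        p = float(hypergeom.cdf(inp.m, inp.N, inp.n, inp.M))
        tail = "lower"
    p = min(max(p, 0.0), 1.0)
    return EnrichmentResult(term=term, e_ratio=e_ratio, p=p, tail=tail, counts=inp)


def enrich_set(
    foreground: Iterable[str],
    annotation: Mapping[str, set[str]],
    background: Iterable[str] | None = None,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Enrichment of every term present in the foreground.

    ``annotation`` maps entity -> set of terms. Background defaults to
    all annotated entities in the map; entities with no annotation are
    excluded from both N and M. Results are ranked by p ascending with
    ties broken by term id. Columns: term, m, M, n, N, e_ratio, p, tail
    (plus p_bh when ``bh_correction``, a labeled extension).
    """
    annotated = {e for e, terms in annotation.items() if terms}
    if not annotated:
        raise ValueError("annotation map has no annotated entities")
    bg = annotated if background is None else set(background) & annotated
    fg = set(foreground) & bg
    if not fg:
        raise ValueError("foreground has no annotated entities in the background")
    N, M = len(bg), len(fg)
    term_bg: dict[str, int] = {}
    term_fg: dict[str, int] = {}
    for ent in bg:
        for t in annotation[ent]:
            term_bg[t] = term_bg.get(t, 0) + 1
            if ent in fg:
                term_fg[t] = term_fg.get(t, 0) + 1
    rows = []
    for t in sorted(term_fg):
        res = enrich_term(
            EnrichmentInput(N=N, n=term_bg[t], M=M, m=term_fg[t]), term=t
        )
        rows.append(
            {
                "term": t,
                "m": res.counts.m,
                "M": M,
                "n": res.counts.n,
                "N": N,
                "e_ratio": res.e_ratio,
                "p": res.p,
                "tail": res.tail,
            }
        )
    df = pd.DataFrame(rows).sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read an entity->terms map from 2-column TSV or GAF 2.x.

    GAF is recognized by a ``!gaf-version`` first line or a ``.gaf``
    suffix; only the DB object id (column 2) and GO id (column 5) are
    used, comment lines starting with ``!`` are skipped.
    """
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        is_gaf = path.suffix.lower() == ".gaf" or first.startswith("!gaf-version")
        fh.seek(0)
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            parts = line.split("\t")
            if is_gaf:
                if len(parts) < 5:
                    raise ValueError(f"{path}:{lineno}: GAF line with <5 columns")
                entity, term = parts[1], parts[4]
            else:
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                    )
                entity, term = parts
            if entity and term:
                mapping.setdefault(entity, set()).add(term)
    return mapping
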