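"""Synthetic study generator: proteomes with plantable sequence motifs
around modified lysines, a small functional subset carrying an extra
signal, and quantified intensity tables with known fold changes.

The generator emulates the structure of a propionylation benchmark:
by default 890 proteins carrying 1707 positive sites (every other
lysine in those proteins is a candidate negative), a positional motif
planted around positives (glycine over-represented at +2, lysine at +7
and +8 downstream of the modified residue), a 13-site functional subset
distinguished by a second, disjoint upstream motif, and per-site
intensity series across circadian time points with controllable
peak/trough ratios and clock-mutant effects. All randomness flows from
a single integer seed through one generator in a fixed draw order, so
identical configurations produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import ProteinRecord

__all__ = [
    "SimConfig",
    "SimBenchmark",
    "simulate_benchmark",
    "simulate_functional_subset",
    "simulate_intensity_table",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: General motif around positives: offset -> (residue, plant probability).
DEFAULT_MOTIF: dict[int, tuple[str, float]] = {
    2: ("G", 0.85),
    7: ("K", 0.85),
    8: ("K", 0.85),
}

#: Functional-subset signal, disjoint from the general motif (upstream).
DEFAULT_FUNCTIONAL_MOTIF: dict[int, tuple[str, float]] = {
    -5: ("F", 0.9),
    -4: ("W", 0.9),
    -3: ("Y", 0.9),
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark."""

    n_proteins: int = 890
    n_positives: int = 1707
    length_range: tuple[int, int] = (150, 450)
    background_freqs: Mapping[str, float] | None = None  # default: uniform
    motif: Mapping[int, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF)
    )
    n_functional: int = 13
    functional_motif: Mapping[int, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_FUNCTIONAL_MOTIF)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.n_positives <= 0:
            raise ValueError("counts must be positive")
        if self.length_range[0] < 61 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must be sane and allow 61-mer windows")
        for off, (res, p) in {**self.motif, **self.functional_motif}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"motif probability at offset {off} outside [0, 1]")
            if res not in STANDARD_AA:
                raise ValueError(f"motif residue {res!r} is not a standard residue")

    def probabilities(self) -> np.ndarray:
        if self.background_freqs is None:
            return np.full(len(STANDARD_AA), 1.0 / len(STANDARD_AA))
        p = np.array([self.background_freqs.get(a, 0.0) for a in STANDARD_AA], float)
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")
        return p


@dataclass
class SimBenchmark:
    """Synthetic proteome plus the labeled site table."""

    proteome: list[ProteinRecord]
    sites: pd.DataFrame  # columns: accession, position, label


def _plant(
    seqs: dict[str, np.ndarray],
    positives: Sequence[tuple[str, int]],
    pos_set: set[tuple[str, int]],
    motif: Mapping[int, tuple[str, float]],
    rng: np.random.Generator,
) -> None:
    """Plant motif residues around sites, in site order then offset order.

    Never overwrites the central lysine of any chosen positive site.
    """
    aa_idx = {a: i for i, a in enumerate(STANDARD_AA)}
    for acc, pos in positives:
        seq = seqs[acc]
        for off in sorted(motif):
            res, prob = motif[off]
            tgt = pos + off  # 1-based
            if not 1 <= tgt <= len(seq):
                continue
            if (acc, tgt) in pos_set:
                continue
            if rng.random() < prob:
                seq[tgt - 1] = aa_idx[res]


def simulate_benchmark(cfg: SimConfig | None = None) -> SimBenchmark:
    """Generate the synthetic proteome and labeled positive sites.

    Sequences are drawn from the background frequencies, ``n_positives``
    distinct lysine positions are chosen as positives, and the general
    motif is planted around each at its stated probability. Every other
    lysine in these proteins is an implicit negative (materialized by
    ``seqio.build_benchmark``).
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    probs = cfg.probabilities()
    k_idx = STANDARD_AA.index("K")

    lengths = rng.integers(cfg.length_range[0], cfg.length_range[1] + 1, cfg.n_proteins)
    width = len(str(cfg.n_proteins - 1))
    accs = [f"SYN{str(i).zfill(width)}" for i in range(cfg.n_proteins)]
    seqs: dict[str, np.ndarray] = {
        acc: rng.choice(len(STANDARD_AA), size=int(L), p=probs)
        for acc, L in zip(accs, lengths)
    }
    # every protein must be able to carry a site: force a lysine if absent
    for acc in accs:
        if not (seqs[acc] == k_idx).any():
            seqs[acc][rng.integers(len(seqs[acc]))] = k_idx

    # positives span the proteins (n sites in n_proteins proteins): first one
    # lysine per protein, then the remainder from the leftover candidates
    per_protein = {
        acc: [int(i) + 1 for i in np.flatnonzero(seqs[acc] == k_idx)] for acc in accs
    }
    n_lysines = sum(len(v) for v in per_protein.values())
    if n_lysines < cfg.n_positives:
        raise ValueError(
            f"proteome holds only {n_lysines} lysines; "
            f"cannot place {cfg.n_positives} positive sites"
        )
    positives: list[tuple[str, int]] = []
    covered = (
        accs
        if cfg.n_positives >= cfg.n_proteins
        else [accs[i] for i in sorted(rng.choice(cfg.n_proteins, cfg.n_positives, replace=False))]
    )
    for acc in covered:
        ks = per_protein[acc]
        positives.append((acc, ks[int(rng.integers(len(ks)))]))
    pos_set = set(positives)
    leftover = [
        (acc, p) for acc in accs for p in per_protein[acc] if (acc, p) not in pos_set
    ]
    n_more = cfg.n_positives - len(positives)
    if n_more > 0:
        pick = rng.choice(len(leftover), size=n_more, replace=False)
        positives.extend(leftover[i] for i in pick)
    positives = sorted(positives)
    pos_set = set(positives)

    _plant(seqs, positives, pos_set, cfg.motif, rng)

    proteome = [
        ProteinRecord(acc, "".join(STANDARD_AA[i] for i in seqs[acc])) for acc in accs
    ]
    sites = pd.DataFrame(
        {"accession": [a for a, _ in positives], "position": [p for _, p in positives]}
    )
    sites["label"] = "positive"
    return SimBenchmark(proteome=proteome, sites=sites)


def simulate_functional_subset(
    benchmark: SimBenchmark,
    k: int = 13,
    functional_motif: Mapping[int, tuple[str, float]] | None = None,
    seed: int = 0,
) -> SimBenchmark:
    """Re-label k positives as functional and plant their extra signal.

    Returns a new benchmark whose proteome carries the functional motif
    around the chosen sites and whose site table marks them
    ``functional_positive``. ``k`` may be 0 (no-op relabeling).
    """
    motif = dict(functional_motif) if functional_motif is not None else dict(DEFAULT_FUNCTIONAL_MOTIF)
    n_pos = len(benchmark.sites)
    if k > n_pos:
        raise ValueError(f"k={k} exceeds the {n_pos} available positives")
    rng = np.random.default_rng(seed)
    aa_idx = {a: i for i, a in enumerate(STANDARD_AA)}
    seqs = {
        rec.accession: np.array([aa_idx[c] for c in rec.sequence], dtype=np.intp)
        for rec in benchmark.proteome
    }
    sites = benchmark.sites.reset_index(drop=True).copy()
    pos_set = set(zip(sites["accession"], sites["position"].astype(int)))
    chosen = sorted(rng.choice(n_pos, size=k, replace=False).tolist()) if k else []
    chosen_sites = [
        (sites.loc[i, "accession"], int(sites.loc[i, "position"])) for i in chosen
    ]
    _plant(seqs, chosen_sites, pos_set, motif, rng)
    sites.loc[chosen, "label"] = "functional_positive"
    proteome = [
        ProteinRecord(rec.accession, "".join(STANDARD_AA[i] for i in seqs[rec.accession]))
        for rec in benchmark.proteome
    ]
    return SimBenchmark(proteome=proteome, sites=sites)


def simulate_intensity_table(
    sites: pd.DataFrame,
    true_fc: float | Sequence[float] = 2.0,
    per0_effect: float | Sequence[float] = 1.0,
    noise_sigma: float = 0.1,
    base_intensity: float = 1e6,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site intensities across WT CT0/6/12/18 and per0 CT6/18.

    Each site oscillates as base * fc^(cos(2*pi*(t - peak)/24) / 2) with
    a peak phase drawn from the four sampled CTs, so with zero noise the
    daily max/min ratio is exactly ``true_fc``. The clock-mutant series
    matches WT at the matched time points except the CT6 intensity is
    divided by ``per0_effect``, making the recoverable mutant effect
    exactly that value at sigma 0. Multiplicative log-normal noise
    exp(N(0, sigma^2)) is applied per measurement. LP is 1.0 throughout.
    """
    n = len(sites)
    rng = np.random.default_rng(seed)
    fc = np.broadcast_to(np.asarray(true_fc, dtype=float), (n,)).copy()
    eff = np.broadcast_to(np.asarray(per0_effect, dtype=float), (n,)).copy()
    if (fc < 1).any() or (eff < 1).any():
        raise ValueError("true_fc and per0_effect must be >= 1")
    cts = np.array([0, 6, 12, 18], dtype=float)
    peak = rng.choice(cts, size=n)
    base = base_intensity * rng.lognormal(0.0, 0.5, size=n)
    phase = np.cos(2 * np.pi * (cts[None, :] - peak[:, None]) / 24.0)
    wt = base[:, None] * fc[:, None] ** (phase / 2.0)
    per0 = np.column_stack([wt[:, 1] / eff, wt[:, 3]])  # matched CT6, CT18
    noisy = np.hstack([wt, per0]) * np.exp(
        rng.normal(0.0, noise_sigma, size=(n, 6))
    )
    out = sites.reset_index(drop=True).loc[:, ["accession", "position"]].copy()
    out["LP"] = 1.0
    for i, name in enumerate(
        ["WT_CT0", "WT_CT6", "WT_CT12", "WT_CT18", "PER0_CT6", "PER0_CT18"]
    ):
        out[name] = noisy[:, i]
    out["true_FC"] = fc
    out["true_per0_effect"] = eff
    return out
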