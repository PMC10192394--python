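"""Shared fixtures: synthetic study datasets generated at test time.

The "small" study keeps module tests fast; the "full" study runs the
generator at its default scale (890 proteins / 1707 positives / 13
functional sites) and is shared session-wide by the acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from kprfunc import embedding, seqio, synthdata


@dataclass
class Study:
    """A simulated benchmark with embeddings ready for model training."""

    items: list
    peptides: list[str]
    labels: np.ndarray  # 1 for any positive (functional or not)
    functional: np.ndarray  # boolean mask over items
    scoring_model: embedding.ScoringModel
    X: np.ndarray


def _make_study(cfg: synthdata.SimConfig, k_functional: int, seed: int) -> Study:
    bench = synthdata.simulate_benchmark(cfg)
    if k_functional:
        bench = synthdata.simulate_functional_subset(bench, k=k_functional, seed=seed + 1)
    built = seqio.build_benchmark(bench.sites, bench.proteome)
    func_sites = set(
        zip(
            bench.sites.loc[bench.sites["label"] == "functional_positive", "accession"],
            bench.sites.loc[bench.sites["label"] == "functional_positive", "position"].astype(int),
        )
    )
    items = built.items
    labels = np.array([1 if it.is_positive else 0 for it in items])
    functional = np.array(
        [it.is_positive and (it.source_accession, it.position) in func_sites for it in items]
    )
    model = embedding.ScoringModel(positives=[it.peptide for it in items if it.is_positive])
    X = embedding.embed_dataset([it.peptide for it in items], model)
    return Study(items, [it.peptide for it in items], labels, functional, model, X)


@pytest.fixture(scope="session")
def small_study() -> Study:
    cfg = synthdata.SimConfig(n_proteins=60, n_positives=120, seed=1)
    return _make_study(cfg, k_functional=13, seed=1)


@pytest.fixture(scope="session")
def full_study() -> Study:
    """Generator defaults (seed 1): 890 proteins, 1707 positives, 13 functional."""
    return _make_study(synthdata.SimConfig(seed=1), k_functional=13, seed=1)
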