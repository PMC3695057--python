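"""Shared fixtures and independent oracle implementations.

Oracles here must stay independent of the code paths they check: seed
words are rebuilt with Biopython, site enumeration is exhaustive substring
comparison, BH is the direct step-up formula.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from mirhub.promoter import CountMatrix, build_pwm, score_pvalue_table
from mirhub.synthetic import HubSpec, ScenarioConfig
from mirhub.targets import MiRNASequence, SITE_HIERARCHY

# let-7a mature sequence (miRBase), used for hand-derived word oracles
LET7A = "UGAGGUAGUAGGUUGUAUAGUU"


@pytest.fixture
def let7a() -> MiRNASequence:
    return MiRNASequence("let-7a", LET7A)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def small_config() -> ScenarioConfig:
    """A fast two-hub scenario used across module tests."""
    return ScenarioConfig(
        n_genes=400,
        n_mirnas=10,
        utr_length_mean=400.0,
        utr_length_sd=80.0,
        hubs=[
            HubSpec("cond1", "mir-001", "down", 0.4, 1.0),
            HubSpec("cond2", "mir-002", "up", 0.4, 1.0),
        ],
        rng_seed=7,
    )


@pytest.fixture
def rich_pwm():
    """An information-rich width-10 PWM, calibrated."""
    counts = CountMatrix(
        "rich",
        np.array(
            [
                [20, 0, 0, 0],
                [0, 20, 0, 0],
                [0, 0, 20, 0],
                [20, 0, 0, 0],
                [0, 0, 0, 20],
                [0, 20, 0, 0],
                [0, 0, 20, 0],
                [20, 0, 0, 0],
                [0, 0, 0, 20],
                [0, 20, 0, 0],
            ],
            dtype=float,
        ),
    )
    pwm = build_pwm(counts)
    score_pvalue_table(pwm)
    return pwm


def oracle_site_words(mature: str) -> dict[str, str]:
    """Seed words rebuilt independently with Biopython reverse_complement."""
    dna = mature.upper().replace("U", "T")
    seed7 = Seq(dna[1:8])
    seed6 = Seq(dna[1:7])
    m8 = str(seed7.reverse_complement())
    core = str(seed6.reverse_complement())
    return {"8mer": m8 + "A", "7mer-m8": m8, "7mer-A1": core + "A", "6mer": core}


def oracle_find_sites(mature: str, utr: str, site_types) -> list[tuple[int, str, str]]:
    """Exhaustive-substring site enumeration with hierarchy dedup by locus.

    Returns sorted (start, site_type, word) triples. Each seed-match locus
    (identified by its 6mer-core position) is reported once, as the
    strongest requested type whose word matches there.
    """
    utr = utr.upper().replace("U", "T")
    words = oracle_site_words(mature)
    best: dict[int, tuple[int, str, str]] = {}
    for site_type in SITE_HIERARCHY:  # strongest first
        if site_type not in site_types:
            continue
        word = words[site_type]
        w = len(word)
        for start in range(len(utr) - w + 1):
            if utr[start:start + w] != word:
                continue
            core = start + 1 if site_type in ("8mer", "7mer-m8") else start
            if core not in best:
                best[core] = (start, site_type, word)
    return sorted(best.values())


def oracle_bh(p: np.ndarray) -> np.ndarray:
    """Direct step-up formula: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
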