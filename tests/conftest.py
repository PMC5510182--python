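"""Shared fixtures and independent oracles used across the suite."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from rges import DiseaseSignature, DrugProfile, GeneUniverse, ProfileMeta


@pytest.fixture
def universe4() -> GeneUniverse:
    return GeneUniverse.from_iterable(["g1", "g2", "g3", "g4"])


def make_profile(values: dict[str, float], profile_id: str = "p1",
                 compound: str = "c1", cell: str = "CL1",
                 dose: float = 10.0, time: float = 24.0,
                 quality: bool = True) -> DrugProfile:
    return DrugProfile(
        profile_id,
        pd.Series(values, dtype=float),
        ProfileMeta(compound, cell, dose, time, quality),
    )


def make_signature(up: set[str], down: set[str], universe: GeneUniverse,
                   lfc: float = 2.0) -> DiseaseSignature:
    stats = {g: (lfc, 1e-6) for g in up} | {g: (-lfc, 1e-6) for g in down}
    return DiseaseSignature(frozenset(up), frozenset(down), stats, universe)


# ---------------------------------------------------------------------------
# independent oracles (direct loops / enumeration; no shared code paths)
# ---------------------------------------------------------------------------

def brute_force_es(positions: dict[str, int], geneset: set[str], n: int) -> float:
    """Enrichment score by direct evaluation of both maxima over all j."""
    v = sorted(positions[g] for g in geneset)
    m = len(v)
    a = max(j / m - v[j - 1] / n for j in range(1, m + 1))
    b = max(v[j - 1] / n - (j - 1) / m for j in range(1, m + 1))
    return a if a > b else -b


def brute_force_rges(values: dict[str, float], up: set[str], down: set[str]
                     ) -> tuple[float, float, float]:
    """(es_up, es_down, rges) from first principles: explicit sort + loops."""
    order = sorted(values, key=lambda g: (-values[g], g))
    positions = {g: i + 1 for i, g in enumerate(order)}
    n = len(order)
    es_up = brute_force_es(positions, up, n)
    es_down = brute_force_es(positions, down, n)
    return es_up, es_down, es_up - es_down


def enumerate_mww_p(x, y, alternative: str) -> float:
    """One-sided MWW P by exhaustive enumeration of all rank splits."""
    def u_stat(a, b):
        return sum(1.0 if ai > bj else 0.5 if ai == bj else 0.0
                   for ai in a for bj in b)

    obs = u_stat(x, y)
    combined = list(x) + list(y)
    k = len(x)
    hits = total = 0
    for idx in combinations(range(len(combined)), k):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(len(combined)) if i not in idx]
        u = u_stat(xs, ys)
        total += 1
        if alternative == "greater":
            hits += u >= obs - 1e-12
        else:
            hits += u <= obs + 1e-12
    return hits / total


def random_case(rng: np.random.Generator, n_max: int = 12, m_max: int = 3):
    """Random universe/profile/signature for oracle-equivalence checks."""
    n = int(rng.integers(4, n_max + 1))
    genes = [f"g{i:02d}" for i in range(n)]
    values = {g: float(rng.normal()) for g in genes}
    m_up = int(rng.integers(1, min(m_max, n // 2) + 1))
    m_down = int(rng.integers(1, min(m_max, n - m_up) + 1))
    picked = list(rng.choice(genes, size=m_up + m_down, replace=False))
    return genes, values, set(picked[:m_up]), set(picked[m_up:])
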