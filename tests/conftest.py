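"""Shared fixtures and independent brute-force oracles.

The oracles here recompute sharing statistics and the SH index with plain
python loops over sets and lists, independently of the vectorised
implementation they are used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from polyshare import GenotypeMatrix, PopulationMap

try:  # optional: property tests use hypothesis when present
    from hypothesis import settings

    settings.register_profile("suite", deadline=None, derandomize=True)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


# ---------------------------------------------------------------------------
# the F1 fixture: 4 biallelic SNPs, focal lineage X (x1, x2) plus B and C

F1_RECORDS = [
    ("v1", 1, "A", ["G"], [(0, 1), (0, 0), (0, 0), (0, 1)]),
    ("v2", 2, "C", ["T"], [(0, 1), (0, 0), (0, 1), (0, 0)]),
    ("v3", 3, "G", ["A"], [(1, 1), (1, 1), (0, 1), (0, 1)]),
    ("v4", 4, "T", ["C"], [(0, 1), (0, 0), (0, 0), (0, 0)]),
]
F1_SAMPLES = ["x1", "x2", "b1", "c1"]


@pytest.fixture
def f1_matrix() -> GenotypeMatrix:
    return GenotypeMatrix.from_calls(F1_SAMPLES, F1_RECORDS)


@pytest.fixture
def f1_popmap() -> PopulationMap:
    return PopulationMap(
        assignment={"x1": "X", "x2": "X", "b1": "B", "c1": "C"},
        focal="X",
        clades={"B": "K1", "C": "K1"},
    )


# ---------------------------------------------------------------------------
# random matrices


def random_matrix(
    rng: np.random.Generator,
    n_variants: int | None = None,
    n_samples: int | None = None,
    n_lineages: int = 3,
    p_missing: float = 0.15,
    p_multiallelic: float = 0.2,
    with_depths: bool = False,
) -> tuple[GenotypeMatrix, PopulationMap]:
    V = int(rng.integers(1, 21)) if n_variants is None else n_variants
    S = int(rng.integers(n_lineages, 13)) if n_samples is None else n_samples
    samples = [f"s{i}" for i in range(S)]
    lineages = [f"L{i}" for i in range(n_lineages)]
    # cyclic assignment guarantees every lineage has a sample
    assignment = {s: lineages[i % n_lineages] for i, s in enumerate(samples)}
    records = []
    nucs = "ACGT"
    for v in range(V):
        n_alt = 2 if rng.random() < p_multiallelic else 1
        ref = nucs[rng.integers(0, 4)]
        alts = [n for n in nucs if n != ref][:n_alt]
        n_alleles = 1 + n_alt
        calls = []
        for _ in range(S):
            if rng.random() < p_missing:
                calls.append(None)
            else:
                calls.append(tuple(sorted(rng.integers(0, n_alleles, size=2).tolist())))
        records.append((f"r{v}", v + 1, ref, alts, calls))
    depths = None
    if with_depths:
        depths = rng.integers(-1, 120, size=(V, S)).astype(np.int32)
    matrix = GenotypeMatrix.from_calls(samples, records, depths=depths)
    popmap = PopulationMap(assignment=assignment, focal=lineages[0])
    return matrix, popmap


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_presence(matrix: GenotypeMatrix, popmap: PopulationMap, exclude=()):
    """(variant_key, allele) → set of lineages carrying it (known calls only)."""
    keep = [l for l in popmap.lineages() if l not in set(exclude)]
    presence: dict[tuple, set] = {}
    for i in range(matrix.n_variants):
        key = (matrix.loci[i], int(matrix.positions[i]))
        for s, sample in enumerate(matrix.samples):
            lin = popmap.assignment[sample]
            if lin not in keep:
                continue
            a, b = (int(x) for x in matrix.genotypes[i, s])
            if a < 0:
                continue
            for al in (a, b):
                presence.setdefault((key, al), set()).add(lin)
    return presence


def brute_sharing(matrix: GenotypeMatrix, popmap: PopulationMap, exclude=()):
    """Private/shared/exclusive counts by exhaustive enumeration."""
    keep = [l for l in popmap.lineages() if l not in set(exclude)]
    presence = brute_presence(matrix, popmap, exclude)
    focal = popmap.focal
    private = {l: sum(1 for ls in presence.values() if ls == {l}) for l in keep}
    shared = {
        l: sum(1 for ls in presence.values() if focal in ls and l in ls)
        for l in keep
        if l != focal
    }
    exclusive = {
        l: sum(1 for ls in presence.values() if ls == {focal, l})
        for l in keep
        if l != focal
    }
    focal_total = sum(1 for ls in presence.values() if focal in ls)
    return private, shared, exclusive, focal_total


def brute_clade_sharing(matrix, popmap, clades: dict[str, list[str]], exclude=()):
    presence = brute_presence(matrix, popmap, exclude)
    focal = popmap.focal
    out = {}
    for name, members in clades.items():
        mset = set(members)
        shared = sum(1 for ls in presence.values() if focal in ls and ls & mset)
        excl = sum(
            1
            for ls in presence.values()
            if focal in ls and ls & mset and ls <= (mset | {focal})
        )
        out[name] = (shared, excl)
    return out


def brute_sh(calls_a, calls_b, denominator="either"):
    """SH by direct site-by-site enumeration over python tuples."""
    n_h = n_m = 0
    for ca, cb in zip(calls_a, calls_b, strict=True):
        if ca is None or cb is None:
            continue
        ma, mb = tuple(sorted(ca)), tuple(sorted(cb))
        het_a, het_b = ma[0] != ma[1], mb[0] != mb[1]
        in_h = (het_a or het_b) if denominator == "either" else (het_a and het_b)
        if not in_h:
            continue
        n_h += 1
        if het_a and het_b and ma == mb:
            n_m += 1
    return (None, 0) if n_h == 0 else (n_m / n_h, n_h)


def calls_of_sample(matrix: GenotypeMatrix, s: int):
    out = []
    for i in range(matrix.n_variants):
        a, b = (int(x) for x in matrix.genotypes[i, s])
        out.append(None if a < 0 else (a, b))
    return out


def brute_pairwise_sh(matrix, popmap, denominator="either"):
    """Double loop over intra-lineage pairs."""
    out = {}
    for lin in popmap.lineages():
        members = [i for i, s in enumerate(matrix.samples) if popmap.assignment[s] == lin]
        for i, j in itertools.combinations(members, 2):
            out[(matrix.samples[i], matrix.samples[j])] = brute_sh(
                calls_of_sample(matrix, i), calls_of_sample(matrix, j), denominator
            )
    return out
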