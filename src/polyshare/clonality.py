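"""Pairwise shared-heterozygosity (SH) index and clonemate classification.

For a pair of samples, let H be the SNP sites at which both calls are known
and at least one of the two is heterozygous, and M ⊆ H the sites at which
both calls are heterozygous and identical as allele multisets (so 0/1 ≡ 1/0
but 0/1 ≠ 0/2).  Then SH = |M| / |H|, undefined when H is empty.  Ramets of
one genet carry the same heterozygous sites, so SH near 1 flags clonemates;
sexually produced full sibs segregate and fall well below.  A pair is
classified as clonal when SH exceeds a threshold (default 0.9), strictly.

An alternative denominator — sites heterozygous in *both* samples — is
available via ``denominator="both"`` for sensitivity analysis.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .model import MISSING, GenotypeMatrix, PopulationMap

DENOMINATORS = ("either", "both")


def _as_pairs(calls) -> np.ndarray:
    """Normalise a call series to a (V, 2) int array, -1 missing, sorted."""
    if isinstance(calls, np.ndarray) and calls.ndim == 2 and calls.shape[1] == 2:
        arr = calls.astype(np.int64)
    else:
        arr = np.array(
            [(MISSING, MISSING) if c is None else tuple(c) for c in calls], dtype=np.int64
        ).reshape(-1, 2)
    arr = np.sort(arr, axis=1)
    arr[(arr == MISSING).any(axis=1)] = MISSING
    return arr


def shared_heterozygosity(
    calls_a, calls_b, denominator: str = "either"
) -> tuple[float | None, int]:
    """SH for one pair of equal-length call series over the same variants.

    Returns ``(sh, n_comparable_sites)``; ``sh`` is ``None`` (undefined)
    when no comparable site exists.
    """
    if denominator not in DENOMINATORS:
        raise InputError(f"unknown denominator {denominator!r}")
    a = _as_pairs(calls_a)
    b = _as_pairs(calls_b)
    if len(a) != len(b):
        raise InputError(f"call series length mismatch: {len(a)} vs {len(b)}")
    known = (a[:, 0] != MISSING) & (b[:, 0] != MISSING)
    het_a = a[:, 0] != a[:, 1]
    het_b = b[:, 0] != b[:, 1]
    identical = (a == b).all(axis=1)
    if denominator == "either":
        H = known & (het_a | het_b)
    else:
        H = known & het_a & het_b
    n = int(H.sum())
    if n == 0:
        return None, 0
    m = int((H & het_a & het_b & identical).sum())
    return m / n, n


@dataclass
class PairSH:
    sample_a: str
    sample_b: str
    lineage: str
    sh: float | None
    n_comparable_sites: int
    is_clone: bool


@dataclass
class SHResult:
    """Pairwise SH values with clone classification at a threshold."""

    pairs: list[PairSH] = field(default_factory=list)
    threshold: float = 0.9
    denominator: str = "either"

    def clone_pairs(self) -> list[PairSH]:
        return [p for p in self.pairs if p.is_clone]

    def clone_counts_by_lineage(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.clone_pairs():
            out[p.lineage] = out.get(p.lineage, 0) + 1
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                (p.sample_a, p.sample_b, p.lineage, p.n_comparable_sites, p.sh, p.is_clone)
                for p in self.pairs
            ],
            columns=["sample_a", "sample_b", "lineage", "n_sites", "SH", "is_clone"],
        )

    def to_tsv(self, path: str | os.PathLike, extra_header: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in extra_header or []:
                fh.write(line + "\n")
            fh.write(f"#threshold={self.threshold}\tdenominator={self.denominator}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, na_rep="NA")


def pairwise_sh(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    scope: str = "within_lineage",
    threshold: float = 0.9,
    denominator: str = "either",
) -> SHResult:
    """SH for every unordered sample pair within each lineage (or globally).

    ``scope="within_lineage"`` scores every intra-lineage pair (lineages
    with fewer than two samples contribute none); ``scope="all_pairs"``
    scores every pair, labelling cross-lineage pairs ``"A|B"``.
    """
    if scope not in ("within_lineage", "all_pairs"):
        raise InputError(f"unknown scope {scope!r}")
    _check_threshold(threshold)
    popmap.require_cover(matrix)
    result = SHResult(threshold=threshold, denominator=denominator)
    if scope == "within_lineage":
        pair_iter = (
            (i, j, lin)
            for lin in popmap.lineages()
            for i, j in itertools.combinations(popmap.sample_indices(matrix, lin), 2)
        )
    else:
        lin_of = {s: popmap.assignment[s] for s in matrix.samples}
        def label(i, j):
            la, lb = lin_of[matrix.samples[i]], lin_of[matrix.samples[j]]
            return la if la == lb else f"{la}|{lb}"
        pair_iter = (
            (i, j, label(i, j)) for i, j in itertools.combinations(range(matrix.n_samples), 2)
        )
    g = matrix.genotypes
    for i, j, lin in pair_iter:
        sh, n = shared_heterozygosity(g[:, i, :], g[:, j, :], denominator=denominator)
        result.pairs.append(
            PairSH(
                sample_a=matrix.samples[i],
                sample_b=matrix.samples[j],
                lineage=lin,
                sh=sh,
                n_comparable_sites=n,
                is_clone=sh is not None and sh > threshold,
            )
        )
    return result


def _check_threshold(threshold: float) -> None:
    if not (0.0 <= threshold <= 1.0):
        raise InputError("threshold must be in [0, 1]")


def classify_clones(result: SHResult, threshold: float = 0.9) -> list[PairSH]:
    """Re-classify at ``threshold`` (strict >) and return the clone pairs.

    Pairs with undefined SH are never flagged.  The result's pairs are
    updated in place with the new classification.
    """
    _check_threshold(threshold)
    result.threshold = threshold
    for p in result.pairs:
        p.is_clone = p.sh is not None and p.sh > threshold
    return result.clone_pairs()
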