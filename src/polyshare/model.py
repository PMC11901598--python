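"""In-memory genotype data model.

A :class:`GenotypeMatrix` holds unordered diploid allele calls for a set of
samples at a set of variant sites, together with per-call and per-site read
depths.  Genotypes are stored as a dense ``(n_variants, n_samples, 2)``
integer array of allele indices; phase is discarded on construction and the
two allele indices of every call are kept sorted, so a call is a multiset.
Missing calls are encoded as ``(-1, -1)``; unknown depths as ``-1``.

A :class:`PopulationMap` assigns each sample to a lineage (a species or a
named allopolyploid), optionally groups lineages into clades, and designates
one focal lineage — the taxon whose parentage and reproductive mode are under
study.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError

logger = logging.getLogger("polyshare")

#: Sentinel for a missing allele index or an unknown depth.
MISSING = -1


@dataclass(frozen=True)
class GenotypeCall:
    """One diploid call: an unordered pair of allele indices, or missing.

    ``alleles`` is ``None`` for a missing call, otherwise a sorted pair of
    non-negative allele indices into the owning variant's allele list
    (0 = REF).  ``depth`` is the per-genotype read depth, or ``None``.
    """

    alleles: tuple[int, int] | None
    depth: int | None = None

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]


@dataclass(frozen=True)
class Variant:
    """A read-only view of one site of a :class:`GenotypeMatrix`."""

    locus_id: str
    position: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    calls: tuple[GenotypeCall, ...]
    site_dp: int | None = None

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele, *self.alt_alleles)

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt_alleles)

    @property
    def is_indel(self) -> bool:
        return any(len(a) != 1 for a in self.alleles)

    @property
    def site_depth(self) -> float:
        """Site depth: the VCF site DP if present, else the mean of known
        per-genotype depths, else NaN (unknown)."""
        if self.site_dp is not None:
            return float(self.site_dp)
        known = [c.depth for c in self.calls if c.depth is not None]
        return float(np.mean(known)) if known else float("nan")


def _canonical_pair(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a <= b else (b, a)


class GenotypeMatrix:
    """Samples × variants store of unordered diploid calls.

    Parameters
    ----------
    samples
        Ordered unique sample identifiers.
    loci, positions, ref, alt
        Per-variant metadata: locus id (VCF CHROM), 1-based position, REF
        allele, tuple of ALT alleles.
    genotypes
        ``(V, S, 2)`` int array of allele indices, ``-1`` for missing.  Pairs
        are canonicalised to ascending order; a pair with any ``-1`` becomes
        fully missing.
    depths
        ``(V, S)`` int array of per-genotype depths, ``-1`` unknown.
    site_dp
        ``(V,)`` int array of site-level DP, ``-1`` unknown.
    """

    def __init__(
        self,
        samples: Sequence[str],
        loci: Sequence[str],
        positions: Sequence[int],
        ref: Sequence[str],
        alt: Sequence[Sequence[str]],
        genotypes: np.ndarray,
        depths: np.ndarray | None = None,
        site_dp: np.ndarray | None = None,
    ):
        self.samples = list(samples)
        if len(set(self.samples)) != len(self.samples):
            raise InputError("duplicate sample identifiers")
        self.loci = list(loci)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.ref = list(ref)
        self.alt = [tuple(a) for a in alt]
        g = np.array(genotypes, dtype=np.int16)
        if g.ndim != 3 or g.shape[2] != 2:
            raise InputError("genotypes must have shape (n_variants, n_samples, 2)")
        V, S = g.shape[:2]
        if S != len(self.samples) or V != len(self.loci):
            raise InputError("genotype array shape does not match samples/variants")
        if not (len(self.positions) == len(self.ref) == len(self.alt) == V):
            raise InputError("per-variant metadata lengths disagree")
        # canonicalise: sort pairs, half-calls -> missing
        g = np.sort(g, axis=2)
        half = (g == MISSING).any(axis=2)
        g[half] = MISSING
        self.genotypes = g
        if depths is None:
            depths = np.full((V, S), MISSING, dtype=np.int32)
        self.depths = np.asarray(depths, dtype=np.int32)
        if self.depths.shape != (V, S):
            raise InputError("depths shape does not match genotypes")
        if site_dp is None:
            site_dp = np.full(V, MISSING, dtype=np.int32)
        self.site_dp = np.asarray(site_dp, dtype=np.int32)
        if self.site_dp.shape != (V,):
            raise InputError("site_dp shape does not match variants")
        self._validate_variants()

    def _validate_variants(self) -> None:
        for i, (r, alts) in enumerate(zip(self.ref, self.alt)):
            if not r:
                raise InputError(f"variant {i}: empty REF allele")
            if r in alts:
                raise InputError(f"variant {i}: REF equals an ALT allele")
            if self.positions[i] < 1:
                raise InputError(f"variant {i}: position must be >= 1")
        if self.n_variants:
            n_all = self.n_alleles[:, None, None]
            if (self.genotypes >= n_all).any():
                raise InputError("allele index out of range for its variant")

    # ---- basic properties -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.loci)

    @property
    def n_alleles(self) -> np.ndarray:
        """Number of alleles (REF + ALTs) per variant."""
        return np.array([1 + len(a) for a in self.alt], dtype=np.int64)

    @property
    def is_indel(self) -> np.ndarray:
        return np.array(
            [any(len(x) != 1 for x in (r, *a)) for r, a in zip(self.ref, self.alt)],
            dtype=bool,
        )

    @property
    def known(self) -> np.ndarray:
        """``(V, S)`` mask of non-missing calls."""
        return self.genotypes[:, :, 0] != MISSING

    @property
    def site_mean_depth(self) -> np.ndarray:
        """Per-site depth: site DP where known, else mean of known
        per-genotype depths, else NaN."""
        out = np.where(self.site_dp >= 0, self.site_dp.astype(float), np.nan)
        dp = np.where(self.depths >= 0, self.depths.astype(float), np.nan)
        if self.n_samples:
            import warnings

            with warnings.catch_warnings():
                # all-unknown rows legitimately yield NaN
                warnings.simplefilter("ignore", category=RuntimeWarning)
                call_mean = np.nanmean(dp, axis=1)
        else:
            call_mean = np.full(self.n_variants, np.nan)
        need = np.isnan(out)
        out[need] = call_mean[need]
        return out

    def variant_keys(self) -> list[tuple[str, int]]:
        return list(zip(self.loci, (int(p) for p in self.positions)))

    # ---- views & subsetting ----------------------------------------------

    def variant(self, i: int) -> Variant:
        calls = []
        for s in range(self.n_samples):
            a, b = self.genotypes[i, s]
            dp = int(self.depths[i, s])
            calls.append(
                GenotypeCall(
                    alleles=None if a == MISSING else (int(a), int(b)),
                    depth=None if dp < 0 else dp,
                )
            )
        sdp = int(self.site_dp[i])
        return Variant(
            locus_id=self.loci[i],
            position=int(self.positions[i]),
            ref_allele=self.ref[i],
            alt_alleles=self.alt[i],
            calls=tuple(calls),
            site_dp=None if sdp < 0 else sdp,
        )

    def take(self, indices: Iterable[int] | np.ndarray) -> "GenotypeMatrix":
        """Subset variants by index, preserving order."""
        idx = np.asarray(list(indices) if not isinstance(indices, np.ndarray) else indices)
        idx = idx.astype(np.int64) if idx.size else np.empty(0, dtype=np.int64)
        return GenotypeMatrix(
            samples=self.samples,
            loci=[self.loci[i] for i in idx],
            positions=self.positions[idx],
            ref=[self.ref[i] for i in idx],
            alt=[self.alt[i] for i in idx],
            genotypes=self.genotypes[idx],
            depths=self.depths[idx],
            site_dp=self.site_dp[idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=list(self.loci),
            positions=self.positions.copy(),
            ref=list(self.ref),
            alt=[tuple(a) for a in self.alt],
            genotypes=self.genotypes.copy(),
            depths=self.depths.copy(),
            site_dp=self.site_dp.copy(),
        )

    @classmethod
    def from_calls(
        cls,
        samples: Sequence[str],
        records: Sequence[tuple],
        depths: np.ndarray | None = None,
        site_dp: Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        """Build a matrix from python-level records.

        Each record is ``(locus_id, position, ref, alts, calls)`` where
        ``calls`` is a sequence (one per sample) of ``(a, b)`` pairs or
        ``None`` for missing.
        """
        V, S = len(records), len(samples)
        g = np.full((V, S, 2), MISSING, dtype=np.int16)
        loci, pos, ref, alt = [], [], [], []
        for i, (lid, p, r, alts, calls) in enumerate(records):
            loci.append(lid)
            pos.append(p)
            ref.append(r)
            alt.append(tuple(alts))
            if len(calls) != S:
                raise InputError(f"record {i}: expected {S} calls, got {len(calls)}")
            for s, c in enumerate(calls):
                if c is not None:
                    g[i, s] = _canonical_pair(*c)
        sdp = None
        if site_dp is not None:
            sdp = np.asarray(site_dp, dtype=np.int32)
        return cls(samples, loci, pos, ref, alt, g, depths=depths, site_dp=sdp)

    # ---- equality ---------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.loci == other.loci
            and np.array_equal(self.positions, other.positions)
            and self.ref == other.ref
            and self.alt == other.alt
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.depths, other.depths)
            and np.array_equal(self.site_dp, other.site_dp)
        )

    def __repr__(self) -> str:
        return f"<GenotypeMatrix {self.n_variants} variants x {self.n_samples} samples>"


@dataclass
class PopulationMap:
    """Sample→lineage and lineage→clade assignments with one focal lineage.

    ``assignment`` maps each sample to a lineage label; ``clades`` maps
    lineages to clade labels (lineages may be left unassigned, e.g. the
    focal allopolyploid itself); ``focal`` names the lineage under study.
    """

    assignment: dict[str, str]
    focal: str
    clades: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.focal not in self.assignment.values():
            raise InputError(f"focal lineage {self.focal!r} has no assigned samples")
        unknown = set(self.clades) - set(self.assignment.values())
        if unknown:
            raise InputError(f"clade assignment for unknown lineage(s): {sorted(unknown)}")

    def lineages(self) -> list[str]:
        """Lineage labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lin in self.assignment.values():
            seen.setdefault(lin)
        return list(seen)

    def samples_of(self, lineage: str) -> list[str]:
        return [s for s, l in self.assignment.items() if l == lineage]

    def sample_indices(self, matrix: GenotypeMatrix, lineage: str) -> np.ndarray:
        members = set(self.samples_of(lineage))
        return np.array([i for i, s in enumerate(matrix.samples) if s in members], dtype=np.int64)

    def clade_members(self) -> dict[str, list[str]]:
        """clade label → member lineages (in lineage order)."""
        out: dict[str, list[str]] = {}
        for lin in self.lineages():
            c = self.clades.get(lin)
            if c is not None:
                out.setdefault(c, []).append(lin)
        return out

    def require_cover(self, matrix: GenotypeMatrix) -> None:
        missing = [s for s in matrix.samples if s not in self.assignment]
        if missing:
            raise InputError(f"samples without a lineage assignment: {missing[:5]}")

    def restricted_to(self, lineages: Iterable[str]) -> "PopulationMap":
        keep = set(lineages)
        if self.focal not in keep:
            raise InputError("cannot drop the focal lineage")
        return PopulationMap(
            assignment={s: l for s, l in self.assignment.items() if l in keep},
            focal=self.focal,
            clades={l: c for l, c in self.clades.items() if l in keep},
        )

    def copy(self) -> "PopulationMap":
        return dataclasses.replace(
            self, assignment=dict(self.assignment), clades=dict(self.clades)
        )
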