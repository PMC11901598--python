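"""Per-lineage allele accounting: private, shared and exclusively shared alleles.

The central object is the :class:`AlleleCountTable` — a genpop-style table
keyed by (site, allele state) holding the number of observed allele copies
per lineage.  All sharing statistics are defined on allele *presence*
(copy count > 0):

* an allele is **private** to a lineage when it is present in exactly one
  lineage;
* an allele of the focal lineage is **shared** with lineage L when it is
  present in both;
* it is **exclusively shared** with L when it is additionally absent from
  every other lineage;
* clade-level sharing treats a set of lineages as one unit: shared means
  present in the focal lineage and in at least one member, exclusively
  shared means additionally absent from every lineage outside the clade
  (the focal lineage excepted).

Percentages in the :class:`SharingReport` use the focal lineage's
non-private allele count as denominator, i.e. 100 × count / (total − private),
rounded half-up.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import InputError
from .model import GenotypeMatrix, PopulationMap


def percent(count: int, denominator: int, rounding: int = 2) -> float | None:
    """Half-up-rounded percentage; ``None`` when the denominator is zero."""
    if denominator == 0:
        return None
    q = Decimal(1).scaleb(-rounding)
    return float((Decimal(count) * 100 / Decimal(denominator)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AlleleCountTable:
    """Per-(variant, allele) copy counts per lineage.

    ``counts`` has shape ``(n_variants, max_alleles, n_lineages)``; an
    (variant, allele) slot is a real allele of its variant only where
    ``allele_valid`` is true.  ``variant_keys`` are ``(locus_id, position)``
    pairs identifying the sites.
    """

    counts: np.ndarray
    allele_valid: np.ndarray
    lineages: list[str]
    focal: str
    variant_keys: list[tuple[str, int]]

    def __post_init__(self):
        if self.focal not in self.lineages:
            raise InputError(f"focal lineage {self.focal!r} not in table")

    @property
    def presence(self) -> np.ndarray:
        """(V, A, L) boolean presence (copy count > 0)."""
        return self.counts > 0

    @property
    def observed(self) -> np.ndarray:
        """(V, A) mask of alleles with at least one known copy anywhere."""
        return self.counts.sum(axis=2) > 0

    @property
    def n_entries(self) -> int:
        return int(self.observed.sum())

    def lineage_index(self, lineage: str) -> int:
        try:
            return self.lineages.index(lineage)
        except ValueError:
            raise InputError(f"unknown lineage {lineage!r}") from None

    def entries(self) -> Iterator[tuple[tuple[str, int], int, dict[str, int]]]:
        """Yield ``(variant_key, allele_index, {lineage: copies})`` for every
        observed allele."""
        obs = self.observed
        for v, a in zip(*np.nonzero(obs)):
            yield (
                self.variant_keys[v],
                int(a),
                {lin: int(self.counts[v, a, li]) for li, lin in enumerate(self.lineages)},
            )

    def counts_for(self, variant_key: tuple[str, int], allele: int) -> dict[str, int]:
        v = self.variant_keys.index(variant_key)
        return {lin: int(self.counts[v, allele, li]) for li, lin in enumerate(self.lineages)}


def build_allele_counts(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    exclude: Iterable[str] = (),
) -> AlleleCountTable:
    """Count allele copies per lineage from a genotype matrix.

    Missing calls contribute nothing.  ``exclude`` drops lineages (e.g.
    known hybrids other than the focal) before the table is built; the
    focal lineage cannot be excluded.
    """
    popmap.require_cover(matrix)
    excl = set(exclude)
    if popmap.focal in excl:
        raise InputError("cannot exclude the focal lineage")
    lineages = [l for l in popmap.lineages() if l not in excl]
    V = matrix.n_variants
    max_a = int(matrix.n_alleles.max()) if V else 1
    counts = np.zeros((V, max_a, len(lineages)), dtype=np.int64)
    for li, lin in enumerate(lineages):
        idx = popmap.sample_indices(matrix, lin)
        if idx.size == 0 or V == 0:
            continue
        g = matrix.genotypes[:, idx, :].reshape(V, -1)
        for a in range(max_a):
            counts[:, a, li] = (g == a).sum(axis=1)
    valid = (
        np.arange(max_a)[None, :] < matrix.n_alleles[:, None]
        if V
        else np.zeros((0, max_a), dtype=bool)
    )
    return AlleleCountTable(
        counts=counts,
        allele_valid=valid,
        lineages=lineages,
        focal=popmap.focal,
        variant_keys=matrix.variant_keys(),
    )


# ---------------------------------------------------------------------------
# sharing statistics


def private_alleles(table: AlleleCountTable) -> dict[str, int]:
    """Number of alleles present in exactly one lineage, per lineage."""
    pres = table.presence
    n_present = pres.sum(axis=2)
    return {
        lin: int((pres[:, :, li] & (n_present == 1)).sum())
        for li, lin in enumerate(table.lineages)
    }


def focal_total_alleles(table: AlleleCountTable) -> int:
    """Number of alleles present in the focal lineage."""
    fi = table.lineage_index(table.focal)
    return int(table.presence[:, :, fi].sum())


def shared_alleles(table: AlleleCountTable) -> dict[str, int]:
    """Alleles present in both the focal lineage and L, per non-focal L."""
    pres = table.presence
    fi = table.lineage_index(table.focal)
    return {
        lin: int((pres[:, :, fi] & pres[:, :, li]).sum())
        for li, lin in enumerate(table.lineages)
        if lin != table.focal
    }


def exclusively_shared(table: AlleleCountTable) -> dict[str, int]:
    """Alleles present in the focal lineage and L only, per non-focal L."""
    pres = table.presence
    fi = table.lineage_index(table.focal)
    n_present = pres.sum(axis=2)
    out = {}
    for li, lin in enumerate(table.lineages):
        if lin == table.focal:
            continue
        out[lin] = int((pres[:, :, fi] & pres[:, :, li] & (n_present == 2)).sum())
    return out


def clade_sharing(
    table: AlleleCountTable,
    clades: Mapping[str, Sequence[str]],
    unions: Sequence[Sequence[str]] = (),
) -> dict[str, tuple[int, int]]:
    """Shared / exclusively shared counts for clades and clade unions.

    ``clades`` maps clade label → member lineages (none may contain the
    focal lineage); ``unions`` is a sequence of clade-label groups, each
    treated as one merged clade and reported under a ``+``-joined label.
    """
    pres = table.presence
    fi = table.lineage_index(table.focal)
    focal_pres = pres[:, :, fi]

    def one(members: Sequence[str]) -> tuple[int, int]:
        idx = [table.lineage_index(m) for m in members]
        inside = pres[:, :, idx].any(axis=2)
        outside_idx = [
            li
            for li, lin in enumerate(table.lineages)
            if lin != table.focal and li not in idx
        ]
        outside = (
            pres[:, :, outside_idx].any(axis=2)
            if outside_idx
            else np.zeros_like(inside)
        )
        shared = focal_pres & inside
        return int(shared.sum()), int((shared & ~outside).sum())

    out: dict[str, tuple[int, int]] = {}
    for name, members in clades.items():
        if table.focal in members:
            raise InputError(f"clade {name!r} contains the focal lineage")
        out[name] = one(list(members))
    for group in unions:
        members: list[str] = []
        for cname in group:
            if cname not in clades:
                raise InputError(f"union references unknown clade {cname!r}")
            members.extend(clades[cname])
        out[" + ".join(group)] = one(members)
    return out


# ---------------------------------------------------------------------------
# report


@dataclass
class SharingRow:
    name: str
    kind: str  # "lineage" | "clade" | "union"
    shared: int
    shared_pct: float | None
    exclusive: int
    exclusive_pct: float | None


@dataclass
class SharingReport:
    """Table of shared / exclusively shared allele counts and percentages.

    ``denominator`` is the focal lineage's non-private allele count
    (``focal_total − focal_private``); percentages are half-up rounded.
    Rows are sorted by shared count descending (ties: exclusive count
    descending, then label).
    """

    focal: str
    focal_total: int
    focal_private: int
    rows: list[SharingRow] = field(default_factory=list)
    rounding: int = 2

    @property
    def denominator(self) -> int:
        return self.focal_total - self.focal_private

    def lineage_rows(self) -> list[SharingRow]:
        return [r for r in self.rows if r.kind == "lineage"]

    @classmethod
    def from_counts(
        cls,
        focal: str,
        focal_total: int,
        focal_private: int,
        lineage_counts: Mapping[str, tuple[int, int]],
        clade_counts: Mapping[str, tuple[int, int]] | None = None,
        union_counts: Mapping[str, tuple[int, int]] | None = None,
        rounding: int = 2,
    ) -> "SharingReport":
        """Build a report directly from (shared, exclusive) count pairs —
        e.g. counts transcribed from a published table."""
        report = cls(focal=focal, focal_total=focal_total, focal_private=focal_private, rounding=rounding)
        denom = report.denominator
        groups = [("lineage", lineage_counts), ("clade", clade_counts or {}), ("union", union_counts or {})]
        for kind, mapping in groups:
            rows = [
                SharingRow(
                    name=name,
                    kind=kind,
                    shared=sh,
                    shared_pct=percent(sh, denom, rounding),
                    exclusive=ex,
                    exclusive_pct=percent(ex, denom, rounding),
                )
                for name, (sh, ex) in mapping.items()
            ]
            rows.sort(key=lambda r: (-r.shared, -r.exclusive, r.name))
            report.rows.extend(rows)
        return report

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                (r.name, r.kind, r.shared, r.shared_pct, r.exclusive, r.exclusive_pct)
                for r in self.rows
            ],
            columns=["name", "kind", "shared", "shared_pct", "exclusive", "exclusive_pct"],
        )

    def to_tsv(self, path: str | os.PathLike, extra_header: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in extra_header or []:
                fh.write(line + "\n")
            fh.write(
                f"#focal={self.focal}\tprivate={self.focal_private}\ttotal={self.focal_total}\n"
            )
            self.to_frame().to_csv(fh, sep="\t", index=False)

    def to_markdown(self) -> str:
        def fmt(pct):
            return "–" if pct is None else f"({pct:.{self.rounding}f}%)"

        lines = [
            f"Alleles shared with the focal lineage *{self.focal}* "
            f"({self.focal_private} private of {self.focal_total} total)",
            "",
            "| Group | Shared | | Exclusively shared | |",
            "|---|---|---|---|---|",
        ]
        for r in self.rows:
            lines.append(
                f"| {r.name} | {r.shared:,} | {fmt(r.shared_pct)} | {r.exclusive:,} | {fmt(r.exclusive_pct)} |"
            )
        return "\n".join(lines)


def sharing_report(
    table: AlleleCountTable,
    clades: Mapping[str, Sequence[str]] | None = None,
    unions: Sequence[Sequence[str]] = (),
    rounding: int = 2,
) -> SharingReport:
    """Compute the full sharing report from an allele-count table."""
    priv = private_alleles(table)
    shared = shared_alleles(table)
    excl = exclusively_shared(table)
    lineage_counts = {lin: (shared[lin], excl[lin]) for lin in shared}
    clade_counts: dict[str, tuple[int, int]] = {}
    union_counts: dict[str, tuple[int, int]] = {}
    if clades:
        merged = clade_sharing(table, clades, unions)
        union_labels = {" + ".join(g) for g in unions}
        for name, pair in merged.items():
            (union_counts if name in union_labels else clade_counts)[name] = pair
    return SharingReport.from_counts(
        focal=table.focal,
        focal_total=focal_total_alleles(table),
        focal_private=priv[table.focal],
        lineage_counts=lineage_counts,
        clade_counts=clade_counts,
        union_counts=union_counts,
        rounding=rounding,
    )


def rank_parent_candidates(report: SharingReport) -> list[tuple[str, int, int]]:
    """Rank non-focal lineages as parent candidates of the focal taxon.

    Ordered by shared allele count descending; ties broken by exclusively
    shared count descending, then label.  Returns
    ``[(lineage, shared, exclusive), ...]``.
    """
    rows = sorted(report.lineage_rows(), key=lambda r: (-r.shared, -r.exclusive, r.name))
    return [(r.name, r.shared, r.exclusive) for r in rows]
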