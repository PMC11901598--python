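"""Reading and writing the on-disk formats: VCF v4.x and population maps.

VCF reading goes through cyvcf2 (htslib), so anything htslib accepts —
plain, bgzipped, phased or unphased — is accepted here.  Phase is discarded:
``1|0`` and ``0/1`` both become the unordered pair ``{0, 1}``.  Half-calls
(``0/.``) and non-diploid genotypes are converted to missing with a logged
warning, since every downstream statistic assumes diploid calls.

Writing emits minimal VCF v4.2 text with ``GT:DP`` genotypes, canonical
``a/b`` ordering (``a <= b``), and a site-level ``DP`` INFO field when known.
``read_vcf(write_vcf(m))`` is the identity on the data model.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError, VcfFormatError
from .model import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger("polyshare")

_INT_MISSING = -2147483648  # htslib int sentinel as surfaced by cyvcf2


def _coerce_int(value) -> int | None:
    """Best-effort integer coercion of an htslib DP value.

    DP may surface as int, numpy int, bytes or str (e.g. when the header
    does not declare its type); '.' and htslib sentinels mean unknown.
    """
    if value is None:
        return None
    if isinstance(value, bytes):
        value = value.decode()
    if isinstance(value, (str, np.str_)):
        value = value.strip()
        if value in (".", ""):
            return None
        try:
            return int(float(value))
        except ValueError:
            return None
    try:
        iv = int(value)
    except (TypeError, ValueError):
        return None
    return None if iv == _INT_MISSING else iv


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records are kept as single variants.  Per-genotype ``DP``
    is used when present; the site-level ``DP`` INFO field is stored
    separately and never split across genotypes.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # htslib reports parse failures many ways
        raise VcfFormatError(f"{path}: cannot parse VCF header: {exc}") from exc
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise InputError(f"{path}: duplicate sample identifier in VCF header")

    loci: list[str] = []
    positions: list[int] = []
    ref: list[str] = []
    alt: list[tuple[str, ...]] = []
    gts: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    sdps: list[int] = []
    n_half = n_nondip = 0
    S = len(samples)
    try:
        for rec_no, v in enumerate(vcf, start=1):
            loci.append(v.CHROM)
            positions.append(v.POS)
            ref.append(v.REF)
            alt.append(tuple(v.ALT))
            row = np.full((S, 2), MISSING, dtype=np.int16)
            for s, g in enumerate(v.genotypes):
                alleles = [int(a) for a in g[:-1]]  # last element is phase flag
                if len(alleles) != 2:
                    n_nondip += 1
                    continue
                if min(alleles) < 0:
                    if max(alleles) >= 0:
                        n_half += 1
                    continue
                row[s] = sorted(alleles)
            gts.append(row)
            dp = np.full(S, MISSING, dtype=np.int32)
            try:
                fmt_dp = v.format("DP")
            except KeyError:  # DP not declared in the header
                fmt_dp = None
            if fmt_dp is not None:
                col = np.asarray(fmt_dp).reshape(S, -1)[:, 0]
                for s in range(S):
                    val = _coerce_int(col[s])
                    if val is not None and val >= 0:
                        dp[s] = val
            dps.append(dp)
            sdp = _coerce_int(v.INFO.get("DP"))
            sdps.append(sdp if sdp is not None and sdp >= 0 else MISSING)
    except Exception as exc:
        if isinstance(exc, (InputError, VcfFormatError)):
            raise
        raise VcfFormatError(f"{path}: malformed record near record {len(loci) + 1}: {exc}") from exc

    if n_half:
        logger.warning("%s: %d half-call genotype(s) converted to missing", path, n_half)
    if n_nondip:
        logger.warning("%s: %d non-diploid genotype(s) converted to missing", path, n_nondip)

    V = len(loci)
    genotypes = np.stack(gts) if V else np.empty((0, S, 2), dtype=np.int16)
    depths = np.stack(dps) if V else np.empty((0, S), dtype=np.int32)
    return GenotypeMatrix(
        samples=samples,
        loci=loci,
        positions=positions,
        ref=ref,
        alt=alt,
        genotypes=genotypes,
        depths=depths,
        site_dp=np.asarray(sdps, dtype=np.int32) if V else None,
    )


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | os.PathLike,
    extra_header: Sequence[str] = (),
) -> None:
    """Write a matrix as VCF v4.2 text.

    ``extra_header`` lines (without trailing newline, each starting ``##``)
    are inserted after the source line — used by the CLI for provenance.
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", "##source=polyshare"]
    lines.extend(extra_header)
    for contig in dict.fromkeys(matrix.loci):
        lines.append(f"##contig=<ID={contig}>")
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth at the site">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.samples)
    )
    for i in range(matrix.n_variants):
        alt = ",".join(matrix.alt[i]) if matrix.alt[i] else "."
        sdp = int(matrix.site_dp[i])
        info = f"DP={sdp}" if sdp >= 0 else "."
        cells = []
        for s in range(matrix.n_samples):
            a, b = matrix.genotypes[i, s]
            gt = "./." if a == MISSING else f"{a}/{b}"
            dp = int(matrix.depths[i, s])
            cells.append(f"{gt}:{dp if dp >= 0 else '.'}")
        lines.append(
            f"{matrix.loci[i]}\t{matrix.positions[i]}\t.\t{matrix.ref[i]}\t{alt}"
            f"\t.\t.\t{info}\tGT:DP\t" + "\t".join(cells)
        )
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# population maps

_POPMAP_HEADER = ("sample", "lineage", "clade")


def read_popmap(path: str | os.PathLike) -> PopulationMap:
    """Read a tab-separated population map.

    Format: optional header line ``sample<TAB>lineage<TAB>clade``, one
    directive line ``#focal=<lineage>``, then one line per sample with two
    or three tab-separated fields (clade optional per lineage).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    assignment: dict[str, str] = {}
    clades: dict[str, str] = {}
    focal: str | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#focal="):
                focal = line.split("=", 1)[1].strip()
            continue
        fields = [f.strip() for f in line.split("\t")]
        if tuple(f.lower() for f in fields[:3]) == _POPMAP_HEADER or (
            len(fields) == 2 and fields[0].lower() == "sample"
        ):
            continue
        if len(fields) < 2:
            raise InputError(f"{path}:{lineno}: expected at least sample<TAB>lineage")
        sample, lineage = fields[0], fields[1]
        if sample in assignment:
            raise InputError(f"{path}:{lineno}: sample {sample!r} listed twice")
        assignment[sample] = lineage
        if len(fields) >= 3 and fields[2]:
            clade = fields[2]
            prev = clades.get(lineage)
            if prev is not None and prev != clade:
                raise InputError(
                    f"{path}:{lineno}: lineage {lineage!r} assigned to clades {prev!r} and {clade!r}"
                )
            clades[lineage] = clade
    if focal is None:
        raise InputError(f"{path}: missing '#focal=<lineage>' directive")
    if focal not in assignment.values():
        raise InputError(f"{path}: focal lineage {focal!r} has no samples")
    return PopulationMap(assignment=assignment, focal=focal, clades=clades)


def write_popmap(popmap: PopulationMap, path: str | os.PathLike, extra_header: Iterable[str] = ()) -> None:
    path = Path(path)
    lines = list(extra_header)
    lines.append(f"#focal={popmap.focal}")
    lines.append("sample\tlineage\tclade")
    for sample, lineage in popmap.assignment.items():
        clade = popmap.clades.get(lineage, "")
        lines.append(f"{sample}\t{lineage}\t{clade}")
    path.write_text("\n".join(lines) + "\n")
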