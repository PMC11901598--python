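"""Post-clustering variant filter cascade for GBS SNP matrices.

The cascade mirrors the standard vcftools-style cleanup applied to a
reduced-representation SNP call set before allele-sharing analysis:

1. drop indel records;
2. drop sites below a minor-allele-frequency floor (computed over known
   allele copies only);
3. drop sites whose depth falls outside a closed window — either on the
   site mean depth, or per genotype (masking out-of-window calls);
4. drop sites genotyped in fewer than a minimum number of samples;
5. optional focal-informativeness rules: the site's non-reference alleles
   must be carried by a minimum number of focal individuals, must not be
   carried in every lineage, and the focal lineage must be genotyped at
   the site.

Every stage takes and returns a :class:`~polyshare.model.GenotypeMatrix`
and is idempotent; :func:`apply_filter_cascade` chains them and records a
:class:`FilterLog`.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError
from .model import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger("polyshare")


@dataclass
class FilterConfig:
    """Thresholds for the filter cascade.

    Defaults follow common vcftools practice for GBS data: MAF 0.02, mean
    depth within [10, 300], site genotyped in at least 40 samples, and
    focal-informativeness rules requiring non-reference alleles in at least
    3 focal individuals but not in every lineage.
    """

    maf_min: float = 0.02
    depth_min: int = 10
    depth_max: int = 300
    depth_mode: str = "site_mean"  # or "genotype"
    min_samples_per_site: int = 40
    focal_min_carriers: int = 3
    #: count rule-(a) "carriers" as distinct individuals or as allele copies
    focal_carrier_unit: str = "individuals"  # or "copies"
    drop_ubiquitous: bool = True
    require_focal_presence: bool = True

    def __post_init__(self):
        if not (0.0 <= self.maf_min <= 0.5):
            raise InputError("maf_min must be in [0, 0.5]")
        if self.depth_min > self.depth_max:
            raise InputError("depth_min must be <= depth_max")
        if self.depth_mode not in ("site_mean", "genotype"):
            raise InputError(f"unknown depth_mode {self.depth_mode!r}")
        if self.focal_carrier_unit not in ("individuals", "copies"):
            raise InputError(f"unknown focal_carrier_unit {self.focal_carrier_unit!r}")
        if min(self.min_samples_per_site, self.focal_min_carriers) < 0:
            raise InputError("counts must be >= 0")

    @classmethod
    def no_op(cls) -> "FilterConfig":
        """A configuration under which every stage is the identity."""
        return cls(
            maf_min=0.0,
            depth_min=0,
            depth_max=10**9,
            min_samples_per_site=0,
            focal_min_carriers=0,
            drop_ubiquitous=False,
            require_focal_presence=False,
        )

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "FilterConfig":
        """Load from YAML or flat ``key=value`` / ``key: value`` text."""
        import yaml

        text = Path(path).read_text()
        if "=" in text and ":" not in text:
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, v = line.split("=", 1)
                data[k.strip()] = yaml.safe_load(v.strip())
        else:
            data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise InputError(f"unknown filter config key(s): {sorted(bad)}")
        return cls(**data)


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_removed: int
    n_out: int


@dataclass
class FilterLog:
    stages: list[FilterStage] = field(default_factory=list)
    genotypes_masked: int = 0

    def add(self, name: str, n_in: int, n_out: int) -> None:
        stage = FilterStage(name, n_in, n_in - n_out, n_out)
        if self.stages and self.stages[-1].n_out != n_in:
            raise InputError("filter log stages do not chain")
        self.stages.append(stage)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(s.name, s.n_in, s.n_removed, s.n_out) for s in self.stages],
            columns=["stage", "variants_in", "removed", "variants_out"],
        )

    def to_tsv(self, path: str | os.PathLike, extra_header: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in extra_header or []:
                fh.write(line + "\n")
            fh.write(f"#genotypes_masked={self.genotypes_masked}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# stages


def remove_indels(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Keep only sites where every allele is a single nucleotide."""
    return matrix.take(np.flatnonzero(~matrix.is_indel))


def minor_allele_frequencies(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-site MAF over known allele copies; NaN where no copies are known.

    For a multiallelic site the MAF is the frequency of the second most
    common allele, which reduces to ``min(p, 1-p)`` for biallelic sites.
    """
    V = matrix.n_variants
    out = np.full(V, np.nan)
    if V == 0:
        return out
    g = matrix.genotypes.reshape(V, -1)
    max_a = int(matrix.n_alleles.max())
    counts = np.stack([(g == a).sum(axis=1) for a in range(max_a)], axis=1).astype(float)
    total = counts.sum(axis=1)
    has = total > 0
    freqs = np.divide(counts, total[:, None], out=np.zeros_like(counts), where=total[:, None] > 0)
    freqs.sort(axis=1)
    out[has] = freqs[has, -2] if max_a >= 2 else 0.0
    return out


def filter_maf(matrix: GenotypeMatrix, maf_min: float) -> GenotypeMatrix:
    """Keep sites with minor allele frequency >= ``maf_min`` (closed bound).

    Sites with zero known allele copies are removed.
    """
    maf = minor_allele_frequencies(matrix)
    keep = np.flatnonzero(~np.isnan(maf) & (maf >= maf_min))
    return matrix.take(keep)


def filter_depth(
    matrix: GenotypeMatrix,
    depth_min: int,
    depth_max: int,
    depth_mode: str = "site_mean",
) -> GenotypeMatrix:
    out, _ = _filter_depth(matrix, depth_min, depth_max, depth_mode)
    return out


def _filter_depth(
    matrix: GenotypeMatrix, depth_min: int, depth_max: int, depth_mode: str
) -> tuple[GenotypeMatrix, int]:
    """Depth window filter; returns (matrix, n genotypes masked).

    ``site_mean``: sites whose known mean depth is outside the closed
    window are removed; sites with unknown depth are kept with a warning.
    ``genotype``: calls with known depth outside the window are masked to
    missing, then sites with no remaining calls are removed.
    """
    if depth_mode == "site_mean":
        mean = matrix.site_mean_depth
        unknown = np.isnan(mean)
        if unknown.any():
            logger.warning(
                "depth filter: %d site(s) have unknown depth and were kept", int(unknown.sum())
            )
        keep = unknown | ((mean >= depth_min) & (mean <= depth_max))
        return matrix.take(np.flatnonzero(keep)), 0
    # genotype mode
    out = matrix.copy()
    known_dp = out.depths >= 0
    bad = known_dp & ((out.depths < depth_min) | (out.depths > depth_max)) & out.known
    n_masked = int(bad.sum())
    out.genotypes[bad] = MISSING
    keep = out.known.any(axis=1) if out.n_samples else np.zeros(out.n_variants, dtype=bool)
    return out.take(np.flatnonzero(keep)), n_masked


def filter_site_presence(matrix: GenotypeMatrix, min_samples: int) -> GenotypeMatrix:
    """Keep sites genotyped (non-missing) in at least ``min_samples`` samples."""
    n_called = matrix.known.sum(axis=1)
    return matrix.take(np.flatnonzero(n_called >= min_samples))


def _lineage_carries_alt(matrix: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    """Per-site flag: does any sample in ``idx`` carry a non-reference allele."""
    if idx.size == 0:
        return np.zeros(matrix.n_variants, dtype=bool)
    return (matrix.genotypes[:, idx, :] > 0).any(axis=(1, 2))


def focal_informative_filter(
    matrix: GenotypeMatrix, popmap: PopulationMap, config: FilterConfig
) -> GenotypeMatrix:
    """Keep sites informative about the focal lineage.

    Rules (each controlled by the config):

    a. at least ``focal_min_carriers`` focal individuals (or allele copies,
       per ``focal_carrier_unit``) carry a non-reference allele;
    b. the site's non-reference alleles are NOT carried in every lineage
       (``drop_ubiquitous``);
    c. at least one focal sample is genotyped (``require_focal_presence``).
    """
    popmap.require_cover(matrix)
    focal_idx = popmap.sample_indices(matrix, popmap.focal)
    if focal_idx.size == 0:
        raise InputError(f"focal lineage {popmap.focal!r} has zero samples")
    keep = np.ones(matrix.n_variants, dtype=bool)
    if config.focal_min_carriers > 0:
        fg = matrix.genotypes[:, focal_idx, :]
        if config.focal_carrier_unit == "individuals":
            carriers = (fg > 0).any(axis=2).sum(axis=1)
        else:
            carriers = (fg > 0).sum(axis=(1, 2))
        keep &= carriers >= config.focal_min_carriers
    if config.drop_ubiquitous:
        ubiquitous = np.ones(matrix.n_variants, dtype=bool)
        for lin in popmap.lineages():
            idx = popmap.sample_indices(matrix, lin)
            ubiquitous &= _lineage_carries_alt(matrix, idx)
        keep &= ~ubiquitous
    if config.require_focal_presence:
        keep &= matrix.known[:, focal_idx].any(axis=1)
    return matrix.take(np.flatnonzero(keep))


def apply_filter_cascade(
    matrix: GenotypeMatrix,
    popmap: PopulationMap | None,
    config: FilterConfig,
) -> tuple[GenotypeMatrix, FilterLog]:
    """Run all stages in order: indels → MAF → depth → presence → focal.

    The focal stage requires a population map; pass ``popmap=None`` to run
    only the first four stages (as for a sharing-only analysis).
    """
    log = FilterLog()
    m = matrix

    n_in = m.n_variants
    m = remove_indels(m)
    log.add("remove_indels", n_in, m.n_variants)

    n_in = m.n_variants
    m = filter_maf(m, config.maf_min)
    log.add("maf", n_in, m.n_variants)

    n_in = m.n_variants
    m, n_masked = _filter_depth(m, config.depth_min, config.depth_max, config.depth_mode)
    log.genotypes_masked = n_masked
    log.add("depth", n_in, m.n_variants)

    n_in = m.n_variants
    m = filter_site_presence(m, config.min_samples_per_site)
    log.add("site_presence", n_in, m.n_variants)

    focal_enabled = config.focal_min_carriers > 0 or config.drop_ubiquitous or config.require_focal_presence
    if popmap is not None and focal_enabled:
        n_in = m.n_variants
        m = focal_informative_filter(m, popmap, config)
        log.add("focal_informative", n_in, m.n_variants)
    return m, log
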