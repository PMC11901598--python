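"""Synthetic GBS-like SNP datasets with known population structure.

The generator emulates the statistical setting of an allopolyploid-origin
study: several diploid lineages grouped into clades, one allotetraploid
focal lineage formed from two of the diploid lineages, clonal ramets,
missing genotypes and sequencing-depth noise.

Allele frequencies follow a hierarchical Balding–Nichols (beta) drift
model.  Per locus an ancestral frequency ``p`` is drawn uniformly from
``ancestral_freq_range``; each clade draws its frequency from
``Beta(p(1−Fc)/Fc, (1−p)(1−Fc)/Fc)`` with divergence ``Fc = f_clade``, and
each lineage draws from its clade frequency the same way with
``f_lineage``.  Diploid genotypes are binomial draws of two allele copies
from the lineage frequency.

The allotetraploid focal lineage inherits disomically: every sample draws
two copies from parent A's frequency and two from parent B's, and is then
exported as a pseudo-diploid call (heterozygous iff both allele states
occur among the four copies) — mimicking diploid genotype calling of GBS
reads from a tetraploid.  True dosage is retained in the truth record.

Clonal ramets copy a progenitor genotype with an independent per-site
error (a genotyping error that replaces the call with one of the other two
genotypes).  All randomness flows from one seed through one generator.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .model import MISSING, GenotypeMatrix, PopulationMap

_NUCS = np.array(list("ACGT"))


def default_clades() -> dict[str, list[str]]:
    """Three clades of 3/4/2 diploid lineages, named after the Crocus
    series Verni species whose structure the generator emulates."""
    return {
        "cladeI": ["vernus", "siculus", "neapolitanus"],
        "cladeII": ["heuffelianus", "tommasinianus", "bertiscensis", "kosaninii"],
        "cladeIII": ["etruscus", "ilvensis"],
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Defaults give 5,000 biallelic loci across 9 diploid lineages in three
    clades (8 samples each), an allotetraploid focal lineage of 9 samples
    formed from *vernus* (cladeI) × *heuffelianus* (cladeII), one clonal
    ramet pair in the focal lineage with 0.5% per-site genotyping error,
    10% missing calls, and negative-binomial depths with mean 50.

    The divergence defaults model distinct congeneric species: pairwise
    differentiation ~0.3 within a clade and ~0.5 between clades, which
    reproduces the wide spread of between-species allele-sharing that
    distinguishes a parent from its clade relatives.
    """

    n_loci: int = 5000
    clades: dict[str, list[str]] = field(default_factory=default_clades)
    samples_per_lineage: int | dict[str, int] = 8
    f_clade: float = 0.3
    f_lineage: float = 0.3
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    #: (focal label, parent lineage A, parent lineage B, n focal samples)
    hybrid: tuple[str, str, str, int] = ("bachofenii", "vernus", "heuffelianus", 9)
    #: list of (lineage, n_ramets, per-site error rate)
    clone_spec: list[tuple[str, int, float]] = field(
        default_factory=lambda: [("bachofenii", 1, 0.005)]
    )
    missing_rate: float = 0.1
    depth_model: tuple[float, float] = (50.0, 5.0)  # (mean, dispersion)
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_loci <= 0:
            raise InputError("n_loci must be > 0")
        for name, val in (("f_clade", self.f_clade), ("f_lineage", self.f_lineage)):
            if not (0.0 < val < 1.0):
                raise InputError(f"{name} must be in (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise InputError("ancestral_freq_range must lie within (0, 1)")
        focal, pa, pb, n = self.hybrid
        lineages = self.diploid_lineages()
        if pa == pb:
            raise InputError("hybrid parents must differ")
        for p in (pa, pb):
            if p not in lineages:
                raise InputError(f"hybrid parent {p!r} is not a simulated lineage")
        if focal in lineages:
            raise InputError(f"focal label {focal!r} collides with a diploid lineage")
        for lin, n_ramets, err in self.clone_spec:
            if lin != focal and lin not in lineages:
                raise InputError(f"clone_spec references unknown lineage {lin!r}")
            if not (0.0 <= err <= 1.0):
                raise InputError("clone error rate must be in [0, 1]")
        for name, rate in (("missing_rate", self.missing_rate), ("indel_rate", self.indel_rate)):
            if not (0.0 <= rate <= 1.0):
                raise InputError(f"{name} must be in [0, 1]")

    def diploid_lineages(self) -> list[str]:
        return [lin for members in self.clades.values() for lin in members]

    def n_samples_of(self, lineage: str) -> int:
        if isinstance(self.samples_per_lineage, dict):
            return int(self.samples_per_lineage[lineage])
        return int(self.samples_per_lineage)

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "SimulationConfig":
        import yaml
        from pathlib import Path

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise InputError(f"unknown simulation config key(s): {sorted(bad)}")
        for key in ("ancestral_freq_range", "hybrid", "depth_model"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if "clone_spec" in data:
            data["clone_spec"] = [tuple(c) for c in data["clone_spec"]]
        return cls(**data)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    focal: str
    parents: tuple[str, str]
    clone_pairs: list[tuple[str, str]]
    lineage_freqs: dict[str, np.ndarray]
    hybrid_dosage: np.ndarray  # (V, n_focal) alt copies among the 4 tetraploid copies
    seed: int

    def to_json(self, path: str | os.PathLike) -> None:
        """Write the discrete truth (parents, clone pairs, seed) as JSON;
        the per-locus frequency arrays stay in memory only."""
        payload = {
            "focal": self.focal,
            "parents": list(self.parents),
            "clone_pairs": [list(p) for p in self.clone_pairs],
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def _bn_freq(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    # clip away exact fixation so the next level's beta parameters stay positive
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def _counts_to_pairs(c: np.ndarray) -> np.ndarray:
    """Map alt-copy counts in {0,1,2} to sorted diploid pairs."""
    g = np.empty(c.shape + (2,), dtype=np.int16)
    g[..., 0] = (c == 2).astype(np.int16)
    g[..., 1] = (c >= 1).astype(np.int16)
    return g


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PopulationMap, SimulationTruth]:
    """Generate one dataset: genotype matrix, population map and truth.

    Identical configs (including seed) give identical output.
    """
    rng = np.random.default_rng(config.seed)
    V = config.n_loci
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=V)

    lineage_freqs: dict[str, np.ndarray] = {}
    for clade, members in config.clades.items():
        p_clade = _bn_freq(rng, p_anc, config.f_clade)
        for lin in members:
            lineage_freqs[lin] = _bn_freq(rng, p_clade, config.f_lineage)

    focal, parent_a, parent_b, n_focal = config.hybrid

    samples: list[str] = []
    assignment: dict[str, str] = {}
    columns: list[np.ndarray] = []  # each (V, n, 2)
    alt_counts: dict[str, np.ndarray] = {}  # per-sample alt-copy records for clone errors

    for lin in config.diploid_lineages():
        n = config.n_samples_of(lin)
        c = rng.binomial(2, lineage_freqs[lin][:, None], size=(V, n))
        columns.append(_counts_to_pairs(c))
        names = [f"{lin}_{k + 1}" for k in range(n)]
        samples.extend(names)
        for k, name in enumerate(names):
            assignment[name] = lin
        alt_counts[lin] = c

    # allotetraploid focal lineage: disomic 2+2 inheritance from the parents
    cA = rng.binomial(2, lineage_freqs[parent_a][:, None], size=(V, n_focal))
    cB = rng.binomial(2, lineage_freqs[parent_b][:, None], size=(V, n_focal))
    dosage = cA + cB  # alt copies among 4
    g_focal = np.empty((V, n_focal, 2), dtype=np.int16)
    g_focal[..., 0] = (dosage == 4).astype(np.int16)
    g_focal[..., 1] = (dosage >= 1).astype(np.int16)
    columns.append(g_focal)
    focal_names = [f"{focal}_{k + 1}" for k in range(n_focal)]
    samples.extend(focal_names)
    for name in focal_names:
        assignment[name] = focal

    genotypes = np.concatenate(columns, axis=1)

    # clonal ramets: copy the first sample of the lineage, with per-site error
    clone_pairs: list[tuple[str, str]] = []
    ramet_cols: list[np.ndarray] = []
    for lin, n_ramets, err in config.clone_spec:
        members = [s for s in samples if assignment[s] == lin]
        if not members:
            raise InputError(f"clone_spec lineage {lin!r} has no samples")
        progenitor = members[0]
        pidx = samples.index(progenitor)
        base = genotypes[:, pidx, :].copy()
        base_c = base.sum(axis=1)  # alt copies of the pseudo-diploid call
        for r in range(n_ramets):
            c = base_c.copy()
            flip = rng.random(V) < err
            # replace with one of the two other diploid genotypes
            c[flip] = (c[flip] + 1 + rng.integers(0, 2, size=int(flip.sum()))) % 3
            ramet_cols.append(_counts_to_pairs(c)[:, None, :])
            name = f"{progenitor}_ramet{r + 1}"
            samples.append(name)
            assignment[name] = lin
            clone_pairs.append((progenitor, name))
    if ramet_cols:
        genotypes = np.concatenate([genotypes, *ramet_cols], axis=1)

    S = len(samples)
    # missingness and depths
    miss = rng.random((V, S)) < config.missing_rate
    genotypes = genotypes.copy()
    genotypes[miss] = MISSING
    mean, disp = config.depth_model
    depths = rng.negative_binomial(disp, disp / (disp + mean), size=(V, S)).astype(np.int32)
    depths[miss] = MISSING

    # per-locus metadata: one SNP per GBS locus, random REF/ALT nucleotides
    ref_idx = rng.integers(0, 4, size=V)
    alt_shift = rng.integers(1, 4, size=V)
    ref = _NUCS[ref_idx]
    alt = _NUCS[(ref_idx + alt_shift) % 4]
    loci = [f"loc{i:06d}" for i in range(V)]
    positions = rng.integers(1, 90, size=V)

    matrix = GenotypeMatrix(
        samples=samples,
        loci=loci,
        positions=positions,
        ref=list(ref),
        alt=[(a,) for a in alt],
        genotypes=genotypes,
        depths=depths,
    )
    if config.indel_rate > 0:
        matrix, _ = inject_artifacts(
            matrix, indel_rate=config.indel_rate, missing_rate=0.0, depth_model=None,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    clades = {lin: clade for clade, members in config.clades.items() for lin in members}
    popmap = PopulationMap(assignment=assignment, focal=focal, clades=clades)
    truth = SimulationTruth(
        focal=focal,
        parents=(parent_a, parent_b),
        clone_pairs=clone_pairs,
        lineage_freqs=lineage_freqs,
        hybrid_dosage=dosage,
        seed=config.seed,
    )
    return matrix, popmap, truth


@dataclass
class ArtifactTruth:
    """Which artifacts :func:`inject_artifacts` introduced."""

    indel_keys: list[tuple[str, int]]
    n_masked_calls: int
    depth_model: tuple[float, float] | None


def inject_artifacts(
    matrix: GenotypeMatrix,
    indel_rate: float = 0.0,
    missing_rate: float = 0.0,
    depth_model: tuple[float, float] | None = None,
    seed: int = 0,
) -> tuple[GenotypeMatrix, ArtifactTruth]:
    """Introduce filterable artifacts into a SNP matrix.

    A fraction ``indel_rate`` of variants (rounded to the nearest count)
    has its first ALT allele extended by one base, making the record an
    indel; calls are masked to missing at ``missing_rate``; when
    ``depth_model=(mean, dispersion)`` is given, all per-genotype depths
    are overwritten with negative-binomial draws.  Returns the modified
    matrix and the truth of what was injected.
    """
    for name, rate in (("indel_rate", indel_rate), ("missing_rate", missing_rate)):
        if not (0.0 <= rate <= 1.0):
            raise InputError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    V = out.n_variants

    n_indel = int(round(indel_rate * V))
    indel_idx = np.sort(rng.choice(V, size=n_indel, replace=False)) if n_indel else np.array([], dtype=int)
    keys = []
    for i in indel_idx:
        alts = list(out.alt[i])
        if not alts:
            alts = [out.ref[i] + "A"]
        else:
            alts[0] = alts[0] + "A"
        out.alt[i] = tuple(alts)
        keys.append((out.loci[i], int(out.positions[i])))

    n_masked = 0
    if missing_rate > 0 and out.n_samples:
        mask = rng.random((V, out.n_samples)) < missing_rate
        n_masked = int((mask & out.known).sum())
        out.genotypes[mask] = MISSING

    if depth_model is not None:
        mean, disp = depth_model
        out.depths = rng.negative_binomial(
            disp, disp / (disp + mean), size=(V, out.n_samples)
        ).astype(np.int32)
        out.site_dp = np.full(V, MISSING, dtype=np.int32)

    return out, ArtifactTruth(indel_keys=keys, n_masked_calls=n_masked, depth_model=depth_model)
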