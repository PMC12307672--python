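"""Synthetic fixtures for every stage of the scan pipeline.

Real resequencing panels are large downloads; the generators here emulate
just enough of their statistical structure to exercise the pipeline
end-to-end with known ground truth:

* a biallelic 0/1/2 genotype matrix with shared background allele
  frequencies, planted group-differentiated loci in LD blocks, and
  uniform missingness;
* Dirichlet admixture profiles with a group-specific dominant ancestry
  component (K = 16 by default);
* a rasterized synthetic coastline with sample points placed along it and
  planted relatedness decaying in along-coast distance.

All generators are pure functions of (spec, seed): the same spec and seed
produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .geo import CostGrid, rasterize
from .matrix import MISSING, GenotypeMatrix, LabelSet, VARIANT_COLUMNS

_BASES = "ACGT"


@dataclass
class SimGenotypeSpec:
    """Parameters of the planted-signal genotype simulation.

    Background variants are i.i.d. binomial(2, maf) draws per sample with
    the maf shared across groups, so they carry no group signal. Each of
    ``n_causal_loci`` causal blocks spans ``causal_block_size``
    consecutive variants whose alternate-allele frequency is
    ``causal_freq_pair[0]`` in the first group and ``causal_freq_pair[1]``
    in the second. Within a block each variant copies its left
    neighbour's genotype column with probability ``ld_copy_prob``,
    mimicking tight linkage.
    """

    n_samples_per_group: dict[str, int]
    n_variants: int
    scaffolds: list[tuple[str, int]]
    n_causal_loci: int = 5
    causal_block_size: int = 10
    background_maf_range: tuple[float, float] = (0.05, 0.5)
    causal_freq_pair: tuple[float, float] = (0.05, 0.9)
    ld_copy_prob: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_samples_per_group) < 2:
            raise ValueError("need at least two groups")
        if self.n_causal_loci > 0 and len(self.n_samples_per_group) != 2:
            raise ValueError("causal loci are planted for exactly two groups")
        lo, hi = self.background_maf_range
        if not (0 <= lo <= hi <= 0.5):
            raise ValueError("background_maf_range must be within [0, 0.5]")
        for f in self.causal_freq_pair:
            if not 0 <= f <= 1:
                raise ValueError("causal frequencies must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 <= self.ld_copy_prob <= 1:
            raise ValueError("ld_copy_prob must lie in [0, 1]")
        if self.n_causal_loci * self.causal_block_size > self.n_variants:
            raise ValueError("causal blocks exceed the number of variants")
        if any(length <= 0 for _, length in self.scaffolds):
            raise ValueError("scaffold lengths must be positive")
        if self.n_variants > sum(length for _, length in self.scaffolds):
            raise ValueError("more variants than genome positions")


@dataclass
class TruthSet:
    """Ground truth of a planted-signal simulation."""

    causal_variant_ids: list[str]  # "scaffold:pos" (1-based)
    causal_regions: list[tuple[str, int, int]]  # 0-based half-open bp intervals

    def region_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.causal_regions, columns=["scaffold", "start", "end"])


@dataclass
class SimAdmixtureSpec:
    """Parameters of the Dirichlet admixture-profile simulation.

    Each group's samples put ``dominant_mass`` on one ancestry component
    and spread the remaining mass over the other K-1 components with a
    symmetric Dirichlet(``dirichlet_concentration``) draw.
    """

    K: int = 16
    groups: list[tuple[str, int, float, float, int]] = field(default_factory=list)
    # (label, dominant_component_index, dominant_mass, dirichlet_concentration, n_samples)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if not self.groups:
            raise ValueError("at least one group required")
        for label, k, mass, conc, n in self.groups:
            if not 0 <= k < self.K:
                raise ValueError(f"group {label}: dominant component {k} out of range")
            if not 0 < mass < 1:
                raise ValueError(f"group {label}: dominant_mass must be in (0, 1)")
            if conc <= 0:
                raise ValueError(f"group {label}: concentration must be positive")
            if n < 1:
                raise ValueError(f"group {label}: needs at least one sample")


@dataclass
class SimCoastSpec:
    """Parameters of the synthetic coastline fixture.

    ``coastline_path`` is a polyline in degrees; cells within
    ``coast_width / 2`` of it become coast, the left side land and the
    right side sea. ``n_points`` samples are placed evenly along the
    coastline and their planted pairwise relatedness decays exponentially
    in along-coast distance with scale ``relatedness_decay_length``.
    """

    grid_extent: tuple[float, float, float, float]
    resolution: float
    coastline_path: list[tuple[float, float]]
    coast_width: float
    n_points: int
    relatedness_decay_length: float
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.coast_width < self.resolution:
            raise ValueError("coast_width must be at least one cell")
        if self.n_points < 2:
            raise ValueError("need at least two points")
        if self.relatedness_decay_length <= 0:
            raise ValueError("relatedness_decay_length must be positive")
        if len(self.coastline_path) < 2:
            raise ValueError("coastline polyline needs at least two vertices")


def u_bay_coast_spec(
    coast_width: float = 0.8,
    n_points: int = 40,
    relatedness_decay_length: float = 5.0,
    resolution: float = 0.05,
    seed: int = 0,
) -> SimCoastSpec:
    """Canonical U-shaped bay fixture for isolation-by-distance contrasts.

    Two north-running coastal arms 2 degrees apart joined by a short bay
    bottom: the arm tips are ~2 degrees apart in a straight line but
    ~7.5 degrees apart along the coast, so along-coast decay of
    relatedness is badly approximated by linear distance.
    """
    return SimCoastSpec(
        grid_extent=(-4.0, -3.0, 4.0, 6.0),
        resolution=resolution,
        coastline_path=[
            (-1.0, 3.0),
            (-1.0, 0.0),
            (-0.5, -0.3),
            (0.5, -0.3),
            (1.0, 0.0),
            (1.0, 3.0),
        ],
        coast_width=coast_width,
        n_points=n_points,
        relatedness_decay_length=relatedness_decay_length,
        seed=seed,
    )


def _allocate_positions(
    rng: np.random.Generator, scaffolds: list[tuple[str, int]], n_variants: int
) -> pd.DataFrame:
    """Draw sorted unique 1-based positions, spread proportional to length."""
    scaffolds = sorted(scaffolds)  # lexicographic, matching VCF encoding order
    total = sum(length for _, length in scaffolds)
    counts = [int(np.floor(n_variants * length / total)) for _, length in scaffolds]
    # largest-remainder top-up, deterministic order
    i = 0
    while sum(counts) < n_variants:
        counts[i % len(counts)] += 1
        i += 1
    frames = []
    for (name, length), k in zip(scaffolds, counts):
        if k > length:
            raise ValueError(f"scaffold {name} too short for {k} variants")
        pos = np.sort(rng.choice(length, size=k, replace=False)) + 1
        frames.append(pd.DataFrame({"scaffold": name, "pos": pos}))
    var = pd.concat(frames, ignore_index=True)
    ref_idx = var["pos"].to_numpy() % 4
    var["ref"] = [_BASES[i] for i in ref_idx]
    var["alt"] = [_BASES[(i + 1) % 4] for i in ref_idx]
    return var[list(VARIANT_COLUMNS)]


def _causal_block_starts(var: pd.DataFrame, n_loci: int, block: int) -> list[int]:
    """Evenly spread non-overlapping blocks of consecutive variant indices."""
    starts: list[int] = []
    groups = [g.index.to_numpy() for _, g in var.groupby("scaffold", sort=True)]
    eligible = [g for g in groups if len(g) >= block]
    if not eligible:
        raise ValueError("no scaffold holds a full causal block")
    per = np.zeros(len(eligible), dtype=int)
    for i in range(n_loci):
        per[i % len(eligible)] += 1
    for g, k in zip(eligible, per):
        if k == 0:
            continue
        if k * block > len(g):
            raise ValueError("causal blocks exceed a scaffold's variant count")
        anchors = np.linspace(0, len(g) - block, k).astype(int)
        # enforce non-overlap if linspace collapses anchors
        for j in range(1, k):
            anchors[j] = max(anchors[j], anchors[j - 1] + block)
        starts.extend(int(g[a]) for a in anchors)
    return sorted(starts)


def simulate_genotypes(
    spec: SimGenotypeSpec,
) -> tuple[GenotypeMatrix, LabelSet, TruthSet]:
    """Simulate a labelled genotype matrix with planted discriminative loci."""
    rng = np.random.default_rng(spec.seed)
    groups = list(spec.n_samples_per_group.items())
    sample_ids: list[str] = []
    labels: list[str] = []
    for label, n in groups:
        sample_ids.extend(f"{label}_{i:04d}" for i in range(n))
        labels.extend([label] * n)
    n_samples = len(sample_ids)

    var = _allocate_positions(rng, spec.scaffolds, spec.n_variants)
    maf = rng.uniform(*spec.background_maf_range, size=spec.n_variants)
    values = rng.binomial(2, maf, size=(n_samples, spec.n_variants)).astype(np.int8)

    truth = TruthSet([], [])
    if spec.n_causal_loci > 0:
        starts = _causal_block_starts(var, spec.n_causal_loci, spec.causal_block_size)
        (label_a, n_a), (_label_b, _n_b) = groups
        rows_a = np.arange(n_a)
        rows_b = np.arange(n_a, n_samples)
        f_a, f_b = spec.causal_freq_pair
        for s in starts:
            block = range(s, s + spec.causal_block_size)
            for j in block:
                values[rows_a, j] = rng.binomial(2, f_a, size=len(rows_a))
                values[rows_b, j] = rng.binomial(2, f_b, size=len(rows_b))
            for j in list(block)[1:]:
                if rng.random() < spec.ld_copy_prob:
                    values[:, j] = values[:, j - 1]
            sub = var.iloc[list(block)]
            scaffold = sub["scaffold"].iloc[0]
            if sub["scaffold"].nunique() != 1:
                raise ValueError("causal block crosses a scaffold boundary")
            truth.causal_regions.append(
                (scaffold, int(sub["pos"].min()) - 1, int(sub["pos"].max()))
            )
            truth.causal_variant_ids.extend(
                f"{scaffold}:{p}" for p in sub["pos"].tolist()
            )
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values[mask] = MISSING

    matrix = GenotypeMatrix(values, sample_ids, var)
    label_set = LabelSet(pd.Series(labels, index=sample_ids))
    return matrix, label_set, truth


def simulate_admixture(spec: SimAdmixtureSpec) -> tuple[pd.DataFrame, LabelSet]:
    """Simulate per-sample ancestry proportion rows (Q-matrix).

    Returns a DataFrame indexed by sample id with columns ``q1..qK`` and
    the matching group labels. Every row is nonnegative and sums to 1.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    labels: list[str] = []
    for label, dom, mass, conc, n in spec.groups:
        rest = rng.dirichlet([conc] * (spec.K - 1), size=n) * (1.0 - mass)
        q = np.insert(rest, dom, mass, axis=1)
        rows.append(q)
        ids.extend(f"{label}_{i:04d}" for i in range(n))
        labels.extend([label] * n)
    Q = np.vstack(rows)
    profiles = pd.DataFrame(Q, index=ids, columns=[f"q{k + 1}" for k in range(spec.K)])
    profiles.index.name = "sample"
    return profiles, LabelSet(pd.Series(labels, index=ids))


def simulate_coast(
    spec: SimCoastSpec,
) -> tuple[CostGrid, pd.DataFrame, pd.DataFrame]:
    """Rasterize a synthetic coastline and place samples along it.

    Returns the cost grid, a ``sample, lon, lat`` point table (points
    evenly spaced by arclength along the coastline polyline) and the
    planted pairwise relatedness matrix
    ``r_ij = exp(-d_alongcoast(i, j) / relatedness_decay_length)``
    (optionally perturbed by truncated Gaussian noise).
    """
    rng = np.random.default_rng(spec.seed)
    grid = rasterize(
        np.asarray(spec.coastline_path, dtype=float),
        spec.grid_extent,
        spec.coast_width,
        spec.resolution,
    )
    line = LineString(spec.coastline_path)
    # keep endpoints half a cell inside so every point rasterizes to a coast cell
    margin = spec.resolution / 2
    s = np.linspace(margin, line.length - margin, spec.n_points)
    pts = [line.interpolate(float(si)) for si in s]
    points = pd.DataFrame(
        {
            "sample": [f"pt_{i:03d}" for i in range(spec.n_points)],
            "lon": [p.x for p in pts],
            "lat": [p.y for p in pts],
        }
    )
    d_along = np.abs(s[:, None] - s[None, :])
    rel = np.exp(-d_along / spec.relatedness_decay_length)
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=rel.shape)
        noise = np.triu(noise, 1)
        rel = np.clip(rel + noise + noise.T, 0.0, 1.0)
        np.fill_diagonal(rel, 1.0)
    relatedness = pd.DataFrame(rel, index=points["sample"], columns=points["sample"])
    return grid, points, relatedness


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    matrix: GenotypeMatrix, scaffolds: list[tuple[str, int]], path: str | Path
) -> Path:
    """Write the matrix as a minimal GT-only VCF 4.2 file."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in sorted(scaffolds):
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, v in matrix.variants.iterrows():
            gts = "\t".join(_GT_STR[int(g)] for g in matrix.values[:, j])
            fh.write(
                f"{v['scaffold']}\t{v['pos']}\t.\t{v['ref']}\t{v['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return path


def write_gff(
    scaffolds: list[tuple[str, int]],
    path: str | Path,
    gene_length: int = 2000,
    gene_gap: int = 1000,
) -> Path:
    """Write a GFF3 of genes tiling each scaffold at a fixed pitch."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in sorted(scaffolds):
            start = 1
            i = 0
            while start + gene_length - 1 <= length:
                end = start + gene_length - 1
                gid = f"{name}_g{i:04d}"
                fh.write(
                    f"{name}\tforestscan_sim\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}\n"
                )
                start += gene_length + gene_gap
                i += 1
    return path


def write_fixtures(
    directory: str | Path,
    *,
    genotypes: GenotypeMatrix | None = None,
    labels: LabelSet | None = None,
    truth: TruthSet | None = None,
    scaffolds: list[tuple[str, int]] | None = None,
    admixture: pd.DataFrame | None = None,
    points: pd.DataFrame | None = None,
    relatedness: pd.DataFrame | None = None,
    grid: CostGrid | None = None,
    gene_length: int = 2000,
    gene_gap: int = 1000,
) -> dict[str, Path]:
    """Write the generated objects as the standard file set.

    Produces whichever of ``sim.vcf``, ``genes.gff3``, ``labels.csv``,
    ``qmatrix.csv``, ``coords.csv``, ``relatedness.tsv``, ``grid.asc`` and
    ``truth.csv`` its inputs allow; files round-trip through the readers
    of the other modules.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if genotypes is not None:
        if scaffolds is None:
            raise ValueError("scaffolds (with lengths) required to write VCF/GFF")
        written["vcf"] = write_vcf(genotypes, scaffolds, directory / "sim.vcf")
    if scaffolds is not None:
        written["gff"] = write_gff(
            scaffolds, directory / "genes.gff3", gene_length, gene_gap
        )
    if labels is not None:
        p = directory / "labels.csv"
        pd.DataFrame(
            {"sample": labels.labels.index, "group": labels.labels.values}
        ).to_csv(p, index=False)
        written["labels"] = p
    if truth is not None:
        p = directory / "truth.csv"
        truth.region_frame().to_csv(p, index=False)
        written["truth"] = p
    if admixture is not None:
        p = directory / "qmatrix.csv"
        admixture.to_csv(p)
        written["qmatrix"] = p
    if points is not None:
        p = directory / "coords.csv"
        points.to_csv(p, index=False)
        written["coords"] = p
    if relatedness is not None:
        p = directory / "relatedness.tsv"
        relatedness.to_csv(p, sep="\t")
        written["relatedness"] = p
    if grid is not None:
        p = directory / "grid.asc"
        grid.to_ascii(p)
        written["grid"] = p
    return written
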