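"""Genotype matrices in 0/1/2 dosage encoding.

Every scan in this package consumes a samples x variants integer matrix in
which each biallelic genotype is coded as the dosage of the alternate
allele: homozygous reference = 0, heterozygous = 1, homozygous alternate
= 2. Missing genotypes are carried as a sentinel (:data:`MISSING`, -1) and
must be imputed explicitly before model fitting.

The on-disk form is the classic 012 triplet (``.012``, ``.012.indv``,
``.012.pos``) popularised by vcftools, with missing genotypes written as
``-1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: In-memory and on-disk sentinel for a missing genotype call.
MISSING: int = -1

VARIANT_COLUMNS = ("scaffold", "pos", "ref", "alt")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant coordinates.

    Parameters
    ----------
    values
        ``(n_samples, n_variants)`` integer array with entries in
        ``{0, 1, 2, MISSING}``.
    sample_ids
        Ordered sample identifiers (rows).
    variants
        DataFrame with columns ``scaffold, pos, ref, alt``; ``pos`` is
        1-based as in VCF. Sorted by ``(scaffold, pos)``.
    """

    values: np.ndarray
    sample_ids: list[str]
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x variants)")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match sample_ids")
        if self.values.shape[1] != len(self.variants):
            raise ValueError("column count does not match variant table")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("matrix entries must be in {0, 1, 2, MISSING}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.values == MISSING).any())

    def subset_region(self, scaffold: str, start: int, end: int) -> "GenotypeMatrix":
        """Columns whose 0-based position falls in half-open ``[start, end)``."""
        pos0 = self.variants["pos"].to_numpy() - 1
        mask = (self.variants["scaffold"] == scaffold).to_numpy() & (pos0 >= start) & (pos0 < end)
        if not mask.any():
            raise ValueError(f"no variants in {scaffold}:[{start},{end})")
        return GenotypeMatrix(
            self.values[:, mask], list(self.sample_ids), self.variants.loc[mask]
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Equality on values, sample order and variant coordinates (ref/alt ignored)."""
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
            and self.variants["scaffold"].tolist() == other.variants["scaffold"].tolist()
            and self.variants["pos"].tolist() == other.variants["pos"].tolist()
        )


@dataclass
class LabelSet:
    """Mapping from sample id to class label.

    ``classes`` is the sorted list of distinct labels; class indices used by
    the ensemble module follow this order.
    """

    labels: pd.Series  # index: sample_id, values: label strings

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate sample ids in label table")

    @property
    def classes(self) -> list[str]:
        return sorted(self.labels.unique())

    def for_samples(self, sample_ids: list[str]) -> np.ndarray:
        """Integer class codes aligned to ``sample_ids`` (order of ``classes``)."""
        missing = [s for s in sample_ids if s not in self.labels.index]
        if missing:
            raise KeyError(f"samples without label: {missing[:5]}")
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[self.labels[s]] for s in sample_ids], dtype=np.int64)

    def class_counts(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def read_labels(path: str | Path) -> LabelSet:
    """Read a two-column ``sample,group`` CSV into a :class:`LabelSet`."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns sample,group")
    return LabelSet(pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values))


def write_labels(labels: LabelSet, path: str | Path) -> None:
    pd.DataFrame({"sample": labels.labels.index, "group": labels.labels.values}).to_csv(
        path, index=False
    )


def encode_vcf(vcf_path: str | Path, biallelic_only: bool = True) -> GenotypeMatrix:
    """Encode a multi-sample VCF into a 0/1/2 dosage matrix.

    Diploid GT fields map as 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2; any
    genotype with a missing allele becomes :data:`MISSING`. Phase
    separators are ignored. Multiallelic records are dropped when
    ``biallelic_only`` is set; otherwise the dosage of the first ALT
    allele is counted (other ALT alleles contribute 0).

    Columns are sorted by ``(scaffold, pos)``; duplicate coordinates are
    rejected.
    """
    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise FormatError(f"{vcf_path}: no samples in VCF")
    cols: list[np.ndarray] = []
    meta: list[tuple[str, int, str, str]] = []
    for var in vcf:
        if len(var.ALT) != 1:
            if biallelic_only:
                continue
        alleles = var.genotype.array()[:, :-1]  # last column is the phased flag
        if alleles.shape != (len(sample_ids), 2):
            raise FormatError(f"{vcf_path}: non-diploid GT at {var.CHROM}:{var.POS}")
        dosage = (alleles == 1).sum(axis=1)
        col = np.where((alleles < 0).any(axis=1), MISSING, dosage).astype(np.int8)
        cols.append(col)
        meta.append((var.CHROM, var.POS, var.REF, var.ALT[0] if var.ALT else "."))
    if not cols:
        values = np.empty((len(sample_ids), 0), dtype=np.int8)
        variants = pd.DataFrame(columns=list(VARIANT_COLUMNS))
        variants["pos"] = variants["pos"].astype(int)
        return GenotypeMatrix(values, sample_ids, variants)
    variants = pd.DataFrame(meta, columns=list(VARIANT_COLUMNS))
    values = np.stack(cols, axis=1)
    order = np.lexsort((variants["pos"].to_numpy(), variants["scaffold"].to_numpy()))
    variants = variants.iloc[order]
    values = values[:, order]
    dup = variants.duplicated(subset=["scaffold", "pos"])
    if dup.any():
        first = variants.loc[dup].iloc[0]
        raise FormatError(
            f"{vcf_path}: duplicate variant coordinate {first['scaffold']}:{first['pos']}"
        )
    return GenotypeMatrix(values, sample_ids, variants)


def write_012(matrix: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write the 012 triplet (``prefix``, ``prefix.indv``, ``prefix.pos``).

    Rows of the main file carry a 0-based sample index followed by the
    genotypes, tab separated; missing entries are written as ``-1``.
    """
    prefix = Path(prefix)
    main, indv, pos = prefix, Path(f"{prefix}.indv"), Path(f"{prefix}.pos")
    with open(main, "w") as fh:
        for i in range(matrix.n_samples):
            row = "\t".join(str(int(v)) for v in matrix.values[i])
            fh.write(f"{i}\t{row}\n" if row else f"{i}\n")
    with open(indv, "w") as fh:
        fh.writelines(f"{s}\n" for s in matrix.sample_ids)
    with open(pos, "w") as fh:
        for _, v in matrix.variants.iterrows():
            fh.write(f"{v['scaffold']}\t{v['pos']}\n")
    return main, indv, pos


def read_012(prefix: str | Path) -> GenotypeMatrix:
    """Read a 012 triplet back into a :class:`GenotypeMatrix`.

    REF/ALT alleles are not stored in the triplet and come back as ``"."``.
    """
    prefix = Path(prefix)
    sample_ids = Path(f"{prefix}.indv").read_text().split()
    pos_lines = [ln.split("\t") for ln in Path(f"{prefix}.pos").read_text().splitlines()]
    variants = pd.DataFrame(
        [(sc, int(p), ".", ".") for sc, p in pos_lines], columns=list(VARIANT_COLUMNS)
    )
    rows = []
    for lineno, line in enumerate(Path(prefix).read_text().splitlines(), start=1):
        fields = line.split("\t")
        geno = fields[1:]
        if len(geno) != len(variants):
            raise FormatError(
                f"{prefix}:{lineno}: {len(geno)} genotypes, expected {len(variants)}"
            )
        rows.append([int(g) for g in geno])
    values = (
        np.array(rows, dtype=np.int8)
        if rows and variants.shape[0]
        else np.empty((len(rows), len(variants)), dtype=np.int8)
    )
    if len(rows) != len(sample_ids):
        raise FormatError(f"{prefix}: row count does not match {prefix}.indv")
    return GenotypeMatrix(values, sample_ids, variants)


def impute_for_model(
    matrix: GenotypeMatrix, strategy: str = "most_frequent_per_variant"
) -> GenotypeMatrix:
    """Replace MISSING entries so models never see the sentinel.

    ``most_frequent_per_variant`` substitutes each variant's modal observed
    genotype (ties break toward the smaller dosage; all-missing columns
    fall back to 0 with a warning). ``zero_fill`` substitutes 0
    everywhere. A matrix without missing entries is returned unchanged.
    """
    if strategy not in ("most_frequent_per_variant", "zero_fill"):
        raise ValueError(f"unknown imputation strategy: {strategy}")
    if not matrix.has_missing:
        return matrix
    values = matrix.values.copy()
    miss = values == MISSING
    if strategy == "zero_fill":
        values[miss] = 0
    else:
        # per-column mode over {0,1,2}; argmax breaks ties toward 0
        counts = np.stack([(values == g).sum(axis=0) for g in (0, 1, 2)])
        mode = counts.argmax(axis=0).astype(np.int8)
        all_missing = counts.sum(axis=0) == 0
        if all_missing.any():
            logger.warning(
                "%d all-missing variant columns imputed to 0", int(all_missing.sum())
            )
            mode[all_missing] = 0
        values[miss] = np.broadcast_to(mode, values.shape)[miss]
    logger.info("imputed %d missing genotypes (%s)", int(miss.sum()), strategy)
    return GenotypeMatrix(values, list(matrix.sample_ids), matrix.variants)
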