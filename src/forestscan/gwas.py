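"""Univariate association comparator for the forest scan.

A per-variant Wald test of the genotype dosage coefficient in a linear
probability model of the binary group label, with the top principal
components of the genotype matrix as fixed covariates to absorb
population structure, and a Bonferroni threshold of alpha / n_variants.
This is the classical single-marker GWAS baseline the multivariate forest
scan is contrasted with; it deliberately trades the mixed-model kinship
correction for PC covariates to stay a light-weight comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import GenotypeMatrix, LabelSet
from .windows import RegionSet, overlapping_genes, read_genes, variants_to_genes


@dataclass
class AssociationResult:
    """Per-variant association statistics and the Bonferroni-significant set."""

    table: pd.DataFrame = field(repr=False)  # scaffold,pos,beta,stat,p,monomorphic
    n_tests: int = 0
    alpha: float = 0.05

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.n_tests

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p"] < self.bonferroni_threshold]


def association_scan(
    matrix: GenotypeMatrix,
    labels: LabelSet,
    n_structure_pcs: int = 0,
    alpha: float = 0.05,
) -> AssociationResult:
    """Wald test of dosage on a 0/1 label, per variant.

    The label (coded 0/1 in sorted class order) is regressed on the
    dosage plus an intercept and ``n_structure_pcs`` genotype principal
    components. Monomorphic variants (or variants fully absorbed by the
    covariates) get p = 1 and are flagged.
    """
    if matrix.has_missing:
        raise ValueError("impute the matrix before the association scan")
    y_codes = labels.for_samples(matrix.sample_ids)
    if len(np.unique(y_codes)) != 2:
        raise ValueError("association scan requires exactly two classes")
    y = y_codes.astype(float)
    G = matrix.values.astype(float)
    n, m = G.shape

    C = np.ones((n, 1))
    if n_structure_pcs > 0:
        Gc = G - G.mean(axis=0)
        # PCs of the centred genotype matrix via thin SVD of samples x variants
        u, s, _ = np.linalg.svd(Gc, full_matrices=False)
        pcs = u[:, :n_structure_pcs] * s[:n_structure_pcs]
        C = np.hstack([C, pcs])
    # residualize label and genotypes against the covariates
    Cpinv = np.linalg.pinv(C)
    proj = lambda M: M - C @ (Cpinv @ M)  # noqa: E731
    y_r = proj(y[:, None])[:, 0]
    G_r = proj(G)

    gtg = (G_r**2).sum(axis=0)
    monomorphic = G.std(axis=0) == 0
    absorbed = gtg <= 1e-12
    safe = ~(monomorphic | absorbed)
    beta = np.zeros(m)
    tstat = np.zeros(m)
    p = np.ones(m)
    df = n - C.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough samples for the covariate count")
    gy = G_r.T @ y_r
    beta[safe] = gy[safe] / gtg[safe]
    rss = (y_r**2).sum() - beta**2 * gtg
    sigma2 = np.maximum(rss, 0.0) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / gtg)
        tstat[safe] = beta[safe] / se[safe]
    p[safe] = 2 * stats.t.sf(np.abs(tstat[safe]), df)
    table = matrix.variants[["scaffold", "pos"]].copy()
    table["beta"] = beta
    table["stat"] = tstat
    table["p"] = p
    table["monomorphic"] = monomorphic | absorbed
    return AssociationResult(table=table, n_tests=m, alpha=alpha)


def significant_genes(result: AssociationResult, gff_path) -> set[str]:
    """Genes containing at least one Bonferroni-significant variant."""
    genes = read_genes(gff_path)
    sig = result.significant
    hits = variants_to_genes(sig, genes)
    return {g for g in hits if g}


def compare_scans(
    forest_regions: RegionSet, association: AssociationResult, gff_path
) -> dict:
    """Gene-level overlap between the forest scan and the association scan.

    Returns counts of genes unique to each method and shared, plus the
    per-gene membership table.
    """
    genes = read_genes(gff_path)
    forest_genes: set[str] = set()
    for hit in overlapping_genes(forest_regions.regions, genes):
        forest_genes.update(hit)
    assoc_genes = significant_genes(association, gff_path)
    shared = forest_genes & assoc_genes
    table = pd.DataFrame(
        {
            "gene_id": sorted(forest_genes | assoc_genes),
        }
    )
    table["forest"] = table["gene_id"].isin(forest_genes)
    table["association"] = table["gene_id"].isin(assoc_genes)
    return {
        "n_forest": len(forest_genes),
        "n_association": len(assoc_genes),
        "n_shared": len(shared),
        "forest_only": sorted(forest_genes - assoc_genes),
        "association_only": sorted(assoc_genes - forest_genes),
        "shared": sorted(shared),
        "table": table,
    }
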