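"""MAF filtering, duplicate collapsing, standardization, and LD screening.

MAF is always computed from the stored dosage column and folded at 0.5,
so the allele-coding direction of the input never changes a filtering or
selection decision.  Standardization uses the population (1/n) variance
convention so penalty values are on the same scale as the penalized
regression formulation in :mod:`snplasso.lasso`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from snplasso.core_data import (
    COVARIATE_NAMES,
    GenotypeMatrix,
    PhenotypeReplicates,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class StandardizedDesign:
    """Centered/scaled design for the penalized fit, plus back-transforms.

    ``X`` holds penalized SNP columns, ``Z`` unpenalized covariates, both
    with column mean 0 and 1/n-variance 1; ``y`` is the centered trait.
    Raw matrices and the means/scales are retained so cross-validation and
    bootstrap resampling can re-standardize within subsets of rows.
    """

    X: np.ndarray
    Z: np.ndarray
    y: np.ndarray
    snp_ids: list[str]
    covariate_names: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    z_mean: np.ndarray
    z_scale: np.ndarray
    y_mean: float
    X_raw: np.ndarray | None = None
    Z_raw: np.ndarray | None = None
    y_raw: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]


def compute_maf(column: np.ndarray) -> float:
    """Folded allele frequency min(f, 1-f), f = (sum of dosages)/(2n)."""
    column = np.asarray(column)
    if column.size == 0:
        raise ValueError("empty dosage column")
    f = float(column.sum(dtype=np.int64)) / (2.0 * column.size)
    return min(f, 1.0 - f)


def compute_mafs(g: GenotypeMatrix) -> np.ndarray:
    """Vector of folded MAFs, one per SNP column."""
    f = g.dosages.sum(axis=0, dtype=np.int64) / (2.0 * g.n_samples)
    return np.minimum(f, 1.0 - f)


def filter_by_maf(g: GenotypeMatrix, threshold: float = 0.01) -> GenotypeMatrix:
    """Retain SNPs with folded MAF >= threshold (common variants)."""
    keep = compute_mafs(g) >= threshold
    removed = int((~keep).sum())
    if removed:
        logger.info("MAF filter at %.4g removed %d of %d SNPs", threshold, removed, g.n_snps)
    return g.subset_snps(keep)


def collapse_duplicates(
    g: GenotypeMatrix,
) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Keep one SNP per group of bit-identical dosage columns.

    The first column (input order) of each group is the representative;
    the returned mapping representative -> full member list lets reports
    re-expand collapsed groups.  Only exact identity is merged: flipped
    codings (d vs 2-d) are distinct columns.
    """
    seen: dict[bytes, int] = {}
    keep: list[int] = []
    members: dict[int, list[str]] = {}
    ids = g.snp_ids
    for j in range(g.n_snps):
        key = g.dosages[:, j].tobytes()
        if key in seen:
            members[seen[key]].append(ids[j])
        else:
            seen[key] = j
            keep.append(j)
            members[j] = [ids[j]]
    groups = {ids[j]: mem for j, mem in members.items() if len(mem) > 1}
    if groups:
        logger.info(
            "collapsed %d duplicate columns into %d groups",
            g.n_snps - len(keep),
            len(groups),
        )
    return g.subset_snps(np.array(keep)), groups


def _center_scale(mat: np.ndarray, what: str, names: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = mat.mean(axis=0)
    scale = mat.std(axis=0)  # ddof=0: population variance
    zero = np.flatnonzero(scale == 0.0)
    if zero.size:
        raise ValidationError(
            f"zero-variance {what} column(s): {[names[j] for j in zero[:5]]}"
        )
    return (mat - mean) / scale, mean, scale


def standardize(
    g: GenotypeMatrix, p: PhenotypeReplicates, trait_id: str
) -> StandardizedDesign:
    """Build the standardized penalized design for one trait replicate."""
    if trait_id not in p.traits:
        raise KeyError(f"trait {trait_id!r} not among replicates {p.replicate_ids[:5]}")
    if g.samples != p.samples:
        raise ValidationError("genotype and phenotype samples differ; align first")
    X_raw = g.dosages.astype(float)
    Z_raw = p.covariates.astype(float)
    y_raw = p.traits[trait_id].astype(float)
    X, x_mean, x_scale = _center_scale(X_raw, "SNP", g.snp_ids)
    Z, z_mean, z_scale = _center_scale(Z_raw, "covariate", list(COVARIATE_NAMES))
    y_mean = float(y_raw.mean())
    return StandardizedDesign(
        X=X,
        Z=Z,
        y=y_raw - y_mean,
        snp_ids=list(g.snp_ids),
        covariate_names=list(COVARIATE_NAMES),
        x_mean=x_mean,
        x_scale=x_scale,
        z_mean=z_mean,
        z_scale=z_scale,
        y_mean=y_mean,
        X_raw=X_raw,
        Z_raw=Z_raw,
        y_raw=y_raw,
    )


def standardize_arrays(
    X_raw: np.ndarray,
    Z_raw: np.ndarray,
    y_raw: np.ndarray,
    snp_ids: list[str],
    covariate_names: list[str] = list(COVARIATE_NAMES),
    drop_constant: bool = False,
) -> StandardizedDesign:
    """Standardize raw arrays directly (used on CV folds and bootstrap resamples).

    With ``drop_constant`` SNP columns that are constant within the row
    subset are removed (they cannot be standardized and are reported as
    unselected); a constant covariate column still raises.
    """
    if drop_constant:
        keep = X_raw.std(axis=0) > 0.0
        X_raw = X_raw[:, keep]
        snp_ids = [s for s, k in zip(snp_ids, keep) if k]
    X, x_mean, x_scale = _center_scale(X_raw, "SNP", snp_ids)
    Z, z_mean, z_scale = _center_scale(Z_raw, "covariate", covariate_names)
    y_mean = float(y_raw.mean())
    return StandardizedDesign(
        X=X,
        Z=Z,
        y=y_raw - y_mean,
        snp_ids=list(snp_ids),
        covariate_names=list(covariate_names),
        x_mean=x_mean,
        x_scale=x_scale,
        z_mean=z_mean,
        z_scale=z_scale,
        y_mean=y_mean,
        X_raw=X_raw,
        Z_raw=Z_raw,
        y_raw=y_raw,
    )


def pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (LD r^2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("r^2 undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_screen(
    g: GenotypeMatrix, focal: list[str], threshold: float = 0.1
) -> pd.DataFrame:
    """Best LD partner for each focal SNP against all other panel SNPs.

    Returns a table (focal_id, best_partner, best_r2, above_threshold)
    sorted as given.  Used for interpretation — a causal SNP in high LD
    with a non-causal one can be replaced by it in the selected model.
    """
    ids = g.snp_ids
    pos = {s: j for j, s in enumerate(ids)}
    missing = [s for s in focal if s not in pos]
    if missing:
        raise KeyError(f"focal SNPs not in panel: {missing[:5]}")
    D = g.dosages.astype(float)
    Dc = D - D.mean(axis=0)
    norms = np.sqrt((Dc**2).sum(axis=0))
    if (norms == 0.0).any():
        raise ValueError("panel contains constant SNP columns; filter first")
    rows = []
    for s in focal:
        j = pos[s]
        r = (Dc.T @ Dc[:, j]) / (norms * norms[j])
        r2 = r * r
        r2[j] = -1.0  # exclude self
        k = int(np.argmax(r2))
        rows.append(
            {
                "focal_id": s,
                "best_partner": ids[k],
                "best_r2": float(r2[k]),
                "above_threshold": bool(r2[k] >= threshold),
            }
        )
    return pd.DataFrame(rows)
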