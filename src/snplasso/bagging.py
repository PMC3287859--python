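"""Bootstrap bagging of the stage-1 LASSO: resample model inclusion proportions.

Each of B bootstrap resamples (drawn with replacement at the original
sample size) is treated as a fresh data set: the design is
re-standardized on the resampled rows, the LASSO is refit at the *same
fixed* penalty as the original analysis, and the nonzero support is
recorded.  A SNP's RMIP is the fraction of resamples in which it is
selected — a measure of how stable its selection is under perturbation
of the data.  SNPs monomorphic within a resample cannot enter that
resample's model and count as unselected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from snplasso.core_data import GenotypeMatrix, PhenotypeReplicates
from snplasso.lasso import DEFAULT_TOL, fit_lasso
from snplasso.preprocess import standardize_arrays

logger = logging.getLogger(__name__)


@dataclass
class RmipTable:
    """Per-SNP resample model inclusion proportions at a fixed penalty."""

    lambda_used: float
    n_resamples: int
    rmip: dict[str, float]
    supports: list[set[str]] = field(default_factory=list, repr=False)

    def nonzero(self) -> dict[str, float]:
        return {s: v for s, v in self.rmip.items() if v > 0.0}


def bootstrap_resample(n: int, seed) -> np.ndarray:
    """n indices drawn uniformly with replacement (one bootstrap resample).

    ``seed`` is anything ``numpy.random.default_rng`` accepts (an int or a
    sequence of ints for derived streams); the draw is deterministic in it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.random.default_rng(seed).integers(0, n, size=n)


def bag_lasso(
    g: GenotypeMatrix,
    p: PhenotypeReplicates,
    trait_id: str,
    lam: float,
    B: int = 100,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
) -> RmipTable:
    """B bootstrap refits of the LASSO at fixed ``lam``; returns RMIPs."""
    if lam <= 0:
        raise ValueError("bagging requires a fixed positive lambda")
    if B < 1:
        raise ValueError("B must be >= 1")
    X_raw = g.dosages.astype(float)
    Z_raw = p.covariates.astype(float)
    y_raw = np.asarray(p.traits[trait_id], dtype=float)
    n = g.n_samples

    counts: dict[str, int] = {s: 0 for s in g.snp_ids}
    supports: list[set[str]] = []
    for b in range(B):
        rows = bootstrap_resample(n, seed=[seed, b])
        d_b = standardize_arrays(
            X_raw[rows],
            Z_raw[rows],
            y_raw[rows],
            g.snp_ids,
            drop_constant=True,
        )
        fit = fit_lasso(d_b, lam, tol=tol)
        if not fit.converged:
            warnings.warn(f"resample {b}: LASSO did not converge")
        sup = fit.support
        supports.append(sup)
        for s in sup:
            counts[s] += 1

    return RmipTable(
        lambda_used=lam,
        n_resamples=B,
        rmip={s: counts[s] / B for s in g.snp_ids},
        supports=supports,
    )


def rmip_report(
    t: RmipTable, truth: set[str] | None = None, threshold: float = 0.5
) -> pd.DataFrame:
    """Plot-ready RMIP table: SNPs sorted by descending RMIP.

    Columns: rank, snp_id, rmip, is_truth (when a truth set is given).
    The accompanying summary (attrs) reports the nonzero-RMIP count and,
    with truth, how many true vs. spurious SNPs exceed the threshold.
    """
    items = sorted(t.rmip.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(items) + 1),
            "snp_id": [s for s, _ in items],
            "rmip": [v for _, v in items],
        }
    )
    df.attrs["lambda_used"] = t.lambda_used
    df.attrs["n_resamples"] = t.n_resamples
    df.attrs["n_nonzero"] = int((df["rmip"] > 0).sum())
    if truth is not None:
        df["is_truth"] = df["snp_id"].isin(sorted(truth))
        above = df[df["rmip"] > threshold]
        df.attrs["n_true_above"] = int(above["is_truth"].sum())
        df.attrs["n_spurious_above"] = int((~above["is_truth"]).sum())
    return df
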