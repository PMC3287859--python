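"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.optimize import minimize

from snplasso.core_data import GenotypeMatrix, PhenotypeReplicates, SnpInfo
from snplasso.preprocess import StandardizedDesign, standardize_arrays

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_genotypes(
    rng: np.random.Generator,
    n: int,
    mafs: list[float],
    ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Hardy-Weinberg dosage matrix with given per-SNP allele frequencies."""
    ids = ids or [f"snp{j}" for j in range(len(mafs))]
    dos = np.column_stack([rng.binomial(2, m, size=n) for m in mafs]).astype(np.int8)
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        snps=[SnpInfo(snp_id=i) for i in ids],
        dosages=dos,
    )


def make_phenotypes(
    rng: np.random.Generator, samples: list[str], traits: dict[str, np.ndarray]
) -> PhenotypeReplicates:
    n = len(samples)
    cov = np.column_stack(
        [
            rng.binomial(1, 0.5, n).astype(float),
            np.round(rng.normal(50, 10, n)),
            rng.binomial(1, 0.3, n).astype(float),
        ]
    )
    return PhenotypeReplicates(samples=samples, covariates=cov, traits=traits)


def random_design(
    seed: int, n: int = 40, p: int = 8, q: int = 3, signal: int = 2
) -> StandardizedDesign:
    """Random standardized regression instance with a little planted signal."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    Z = rng.standard_normal((n, q)) if q else np.empty((n, 0))
    beta = np.zeros(p)
    beta[:signal] = rng.normal(0, 1.5, size=signal)
    y = X @ beta + (Z @ rng.normal(0, 0.5, size=q) if q else 0) + rng.standard_normal(n)
    return standardize_arrays(
        X, Z, y, [f"s{j}" for j in range(p)], [f"z{k}" for k in range(q)]
    )


def lasso_objective(d: StandardizedDesign, beta: np.ndarray, gamma: np.ndarray, lam: float) -> float:
    r = d.y - d.X @ beta - (d.Z @ gamma if d.q else 0.0)
    return float(r @ r) / (2 * d.n) + lam * float(np.abs(beta).sum())


def convex_oracle(d: StandardizedDesign, lam: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Generic-solver solution of the penalized objective.

    Split formulation beta = b+ - b- turns the L1 problem into a smooth
    bound-constrained one solved by L-BFGS-B — an independent route that
    shares nothing with the coordinate-descent implementation.
    """
    n, p, q = d.n, d.p, d.q
    W = np.hstack([d.X, d.Z]) if q else d.X
    m = p + q
    pen = np.concatenate([np.full(p, lam), np.zeros(q)])

    def fun(u):
        b = u[:m] - u[m:]
        r = d.y - W @ b
        val = float(r @ r) / (2 * n) + float(pen @ (u[:m] + u[m:]))
        g = -(W.T @ r) / n
        grad = np.concatenate([g + pen, -g + pen])
        return val, grad

    res = minimize(
        fun,
        np.zeros(2 * m),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * m),
        options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12},
    )
    b = res.x[:m] - res.x[m:]
    beta, gamma = b[:p], b[p:]
    return beta, gamma, lasso_objective(d, beta, gamma, lam)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
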