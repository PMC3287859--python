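"""Bidirectional stepwise refinement of the stage-1 candidate model.

Starting from the *full* model (every stage-1 SNP plus Sex/Age/Smoke),
each step evaluates all single-term deletions from the current model and
all single-term additions from the excluded part of the candidate pool,
and applies the move with the lowest information criterion provided it
strictly improves on the current model.  The criterion is the
constants-dropped Gaussian form

    n * ln(RSS / n) + penalty * k,    penalty = 2 (AIC) or ln(n) (BIC)

with k counting all estimated mean parameters including the intercept.
Additions are restricted to the candidate pool, i.e. terms can only be
deleted and subsequently added back — never drawn from outside stage 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from snplasso.lasso import CvResult, cross_validate, select_at
from snplasso.preprocess import StandardizedDesign

logger = logging.getLogger(__name__)

_PENALTY = {"AIC": lambda n: 2.0, "BIC": lambda n: float(np.log(n))}


@dataclass
class StepwiseResult:
    """Final model, search trace, and criterion value of one stepwise run."""

    criterion_name: str
    included_terms: list[str]
    trace: list[tuple[str, str | None, float]]  # (move, term, criterion)
    final_criterion: float

    @property
    def included_set(self) -> set[str]:
        return set(self.included_terms)


def _rss(y: np.ndarray, M: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares of the OLS fit of y on [1, M]; returns (rss, rank)."""
    n = y.size
    D = np.concatenate([np.ones((n, 1)), M], axis=1)
    coef, res, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    r = y - D @ coef
    return float(r @ r), int(rank)


def model_criterion(
    y: np.ndarray, terms: np.ndarray, criterion: str = "AIC"
) -> float:
    """Information criterion of the OLS model of ``y`` on intercept + terms.

    ``terms`` is an n x k design block (k may be 0: intercept-only model).
    Raises on rank deficiency — collinear candidates must be collapsed
    upstream.
    """
    if criterion not in _PENALTY:
        raise ValueError(f"criterion must be AIC or BIC, got {criterion!r}")
    y = np.asarray(y, dtype=float)
    terms = np.asarray(terms, dtype=float)
    if terms.ndim == 1:
        terms = terms[:, None]
    n = y.size
    k = terms.shape[1] + 1  # + intercept
    if n <= k:
        raise ValueError(f"need n > number of parameters, have n={n}, k={k}")
    rss, rank = _rss(y, terms)
    if rank < k:
        raise ValueError(f"rank-deficient design: rank {rank} < {k} parameters")
    if rss <= 0.0:
        raise ValueError("zero residual sum of squares; criterion undefined")
    return n * float(np.log(rss / n)) + _PENALTY[criterion](n) * k


def stepwise_select(
    y: np.ndarray,
    pool: dict[str, np.ndarray],
    criterion: str = "AIC",
    start: list[str] | None = None,
) -> StepwiseResult:
    """Greedy bidirectional search over the candidate pool.

    ``pool`` maps term name -> column; ``start`` defaults to the full
    pool.  Ties never trigger a move (strict improvement required); among
    equal-criterion moves deletions are preferred over additions, then
    pool order decides.  Moves hitting a rank-deficient design are
    skipped with a warning.
    """
    if not pool:
        raise ValueError("candidate pool is empty")
    names = list(pool)
    cols = {t: np.asarray(pool[t], dtype=float).ravel() for t in names}
    current = list(pool) if start is None else list(start)
    unknown = set(current) - set(names)
    if unknown:
        raise ValueError(f"start terms outside pool: {sorted(unknown)[:5]}")

    def crit_of(terms: list[str]) -> float:
        M = (
            np.column_stack([cols[t] for t in terms])
            if terms
            else np.empty((y.size, 0))
        )
        return model_criterion(y, M, criterion)

    cur_crit = crit_of(current)
    trace: list[tuple[str, str | None, float]] = [("start", None, cur_crit)]
    while True:
        best: tuple[float, int, int, str, str] | None = None  # sortable move
        moves: list[tuple[str, str]] = [("drop", t) for t in current]
        moves += [("add", t) for t in names if t not in current]
        for mi, (move, term) in enumerate(moves):
            cand = (
                [t for t in current if t != term]
                if move == "drop"
                else current + [term]
            )
            try:
                c = crit_of(cand)
            except ValueError as exc:
                warnings.warn(f"skipping {move} {term}: {exc}")
                continue
            key = (c, 0 if move == "drop" else 1, mi, move, term)
            if best is None or key < best:
                best = key
        if best is None or best[0] >= cur_crit:
            break
        cur_crit, _, _, move, term = best
        if move == "drop":
            current = [t for t in current if t != term]
        else:
            current = current + [term]
        trace.append((move, term, cur_crit))
    return StepwiseResult(
        criterion_name=criterion,
        included_terms=current,
        trace=trace,
        final_criterion=cur_crit,
    )


def stepwise_pool(
    d: StandardizedDesign, stage1_snps: set[str]
) -> dict[str, np.ndarray]:
    """Candidate pool for stage 2: stage-1 SNP columns + the three covariates."""
    idx = {s: j for j, s in enumerate(d.snp_ids)}
    pool: dict[str, np.ndarray] = {
        s: d.X[:, idx[s]] for s in d.snp_ids if s in stage1_snps
    }
    for k, name in enumerate(d.covariate_names):
        pool[name] = d.Z[:, k]
    return pool


def refine_selection(
    d: StandardizedDesign, stage1_snps: set[str], criterion: str = "AIC"
) -> StepwiseResult:
    """Run stepwise on the stage-1 selection; full stage-1 model is the start."""
    return stepwise_select(d.y, stepwise_pool(d, stage1_snps), criterion)


def two_stage_select(
    d: StandardizedDesign,
    lambda_rule: str = "min",
    criterion: str = "AIC",
    K: int = 10,
    n_repeats: int = 1,
    seed: int = 0,
    cv: CvResult | None = None,
) -> set[str]:
    """Full two-stage procedure: CV -> LASSO selection -> stepwise refinement.

    Returns the final SNP set (covariate membership is not part of the
    selection target).  An empty stage-1 selection short-circuits to an
    empty SNP set — stage 2 then only adjudicates the covariates.
    """
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")
    if cv is None:
        cv = cross_validate(d, K=K, n_repeats=n_repeats, seed=seed)
    lam = cv.lambda_min if lambda_rule == "min" else cv.lambda_1se
    stage1 = select_at(d, lam)
    if not stage1:
        return set()
    result = refine_selection(d, stage1, criterion)
    return result.included_set - set(d.covariate_names)
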