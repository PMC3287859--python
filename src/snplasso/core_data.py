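"""Domain containers and delimited-text I/O for genotype/phenotype data.

Genotypes are additive allele counts (dosages) in {0, 1, 2}; the coding
direction (minor vs. major allele) is *not* assumed — minor allele
frequency is folded downstream, so either coding is acceptable on input.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COVARIATE_NAMES = ("Sex", "Age", "Smoke")


class ValidationError(ValueError):
    """Input data violates a container invariant."""


class ParseError(ValueError):
    """A file does not conform to the expected dialect."""


@dataclass(frozen=True)
class SnpInfo:
    """Identity and annotation for one SNP."""

    snp_id: str
    chromosome: str = ""
    gene: str = ""
    maf_declared: float | None = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValidationError("snp_id must be nonempty")
        if self.maf_declared is not None and not (0.0 <= self.maf_declared <= 0.5):
            raise ValidationError(
                f"declared MAF for {self.snp_id} must lie in [0, 0.5], "
                f"got {self.maf_declared}"
            )


@dataclass
class GenotypeMatrix:
    """n x p dosage matrix with per-SNP metadata; the fixed design."""

    samples: list[str]
    snps: list[SnpInfo]
    dosages: np.ndarray  # (n, p) int8, entries in {0, 1, 2}

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        n, p = self.dosages.shape
        if n != len(self.samples) or p != len(self.snps):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            dupes = [i for i, c in Counter(ids).items() if c > 1]
            raise ValidationError(f"duplicate snp ids: {dupes[:5]}")
        if self.dosages.size and not np.isin(self.dosages, (0, 1, 2)).all():
            bad = np.unique(self.dosages[~np.isin(self.dosages, (0, 1, 2))])
            raise ValidationError(f"dosages outside {{0,1,2}}: {bad[:5]}")
        self.dosages = self.dosages.astype(np.int8, copy=False)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def column(self, snp_id: str) -> np.ndarray:
        j = self.snp_ids.index(snp_id)
        return self.dosages[:, j]

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to SNP columns selected by a boolean/index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[j] for j in keep],
            dosages=self.dosages[:, keep],
        )

    def subset_samples(self, rows: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=[self.samples[i] for i in rows],
            snps=list(self.snps),
            dosages=self.dosages[rows, :],
        )


@dataclass
class PhenotypeReplicates:
    """Covariates (Sex, Age, Smoke) plus one or more trait replicates."""

    samples: list[str]
    covariates: np.ndarray  # (n, 3) float
    traits: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.covariates = np.asarray(self.covariates, dtype=float)
        n = len(self.samples)
        if self.covariates.shape != (n, 3):
            raise ValidationError(
                f"covariates must be (n, 3) for Sex/Age/Smoke, got "
                f"{self.covariates.shape} with n={n}"
            )
        for rid, y in self.traits.items():
            y = np.asarray(y, dtype=float)
            if y.shape != (n,):
                raise ValidationError(f"trait {rid!r} has length {y.shape}, expected {n}")
            if not np.isfinite(y).all():
                raise ValidationError(f"trait {rid!r} contains non-finite values")
            self.traits[rid] = y

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def replicate_ids(self) -> list[str]:
        return list(self.traits)

    def subset_samples(self, rows: np.ndarray) -> "PhenotypeReplicates":
        return PhenotypeReplicates(
            samples=[self.samples[i] for i in rows],
            covariates=self.covariates[rows, :],
            traits={rid: y[rows] for rid, y in self.traits.items()},
        )


@dataclass
class SelectionReport:
    """Selection outcome of one procedure variant across replicates."""

    procedure: str
    selections: dict[str, set[str]]  # replicate id -> selected snp ids
    truth: set[str] | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.selections)

    @property
    def snp_counts(self) -> Counter:
        c: Counter = Counter()
        for sel in self.selections.values():
            c.update(sel)
        return c

    def snp_frequency(self, snp_id: str) -> float:
        return self.snp_counts[snp_id] / self.n_replicates

    @property
    def mean_total_selected(self) -> float:
        return float(np.mean([len(s) for s in self.selections.values()]))

    @property
    def mean_total_correct(self) -> float:
        if self.truth is None:
            raise ValueError("no truth set attached to this report")
        return float(np.mean([len(s & self.truth) for s in self.selections.values()]))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_PLINK_LEAD_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _impute_mode(col: np.ndarray) -> tuple[np.ndarray, int]:
    """Replace NaNs by the per-SNP modal dosage; returns (column, n imputed)."""
    miss = np.isnan(col)
    n_miss = int(miss.sum())
    if n_miss:
        observed = col[~miss].astype(int)
        if observed.size == 0:
            raise ValidationError("column entirely missing; cannot impute")
        mode = Counter(observed.tolist()).most_common(1)[0][0]
        col = col.copy()
        col[miss] = mode
    return col, n_miss


def read_genotypes(path, dialect: str = "delimited") -> GenotypeMatrix:
    """Load a dosage matrix from a delimited or PLINK-.raw-style text file.

    ``delimited``: header row of snp ids, first column sample ids.
    ``plink_raw``: whitespace-separated, lead columns FID IID PAT MAT SEX
    PHENOTYPE, then one ``<snp>_<allele>`` column per SNP; NA allowed.
    Missing dosages are imputed with the per-SNP mode and the total count
    is logged.
    """
    if dialect == "delimited":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        snp_ids = [str(c) for c in df.columns]
        samples = [str(i) for i in df.index]
    elif dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        missing_lead = [c for c in _PLINK_LEAD_COLS if c not in df.columns]
        if missing_lead:
            raise ParseError(f"plink_raw file lacks columns {missing_lead}")
        samples = [str(i) for i in df["IID"]]
        snp_cols = [c for c in df.columns if c not in _PLINK_LEAD_COLS]
        snp_ids = [c.rsplit("_", 1)[0] for c in snp_cols]
        df = df[snp_cols]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    try:
        mat = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"non-numeric dosage entry in {path}: {exc}") from None

    n_imputed = 0
    for j in range(mat.shape[1]):
        mat[:, j], k = _impute_mode(mat[:, j])
        n_imputed += k
    if n_imputed:
        logger.info("imputed %d missing dosages with per-SNP mode", n_imputed)

    if mat.size and not np.isin(mat, (0.0, 1.0, 2.0)).all():
        bad = np.unique(mat[~np.isin(mat, (0.0, 1.0, 2.0))])
        raise ValidationError(f"dosages outside {{0,1,2,NA}} in {path}: {bad[:5]}")

    return GenotypeMatrix(
        samples=samples,
        snps=[SnpInfo(snp_id=s) for s in snp_ids],
        dosages=mat.astype(np.int8),
    )


def write_genotypes(g: GenotypeMatrix, path, dialect: str = "delimited") -> None:
    if dialect == "delimited":
        df = pd.DataFrame(g.dosages, index=g.samples, columns=g.snp_ids)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
    elif dialect == "plink_raw":
        lead = pd.DataFrame(
            {
                "FID": g.samples,
                "IID": g.samples,
                "PAT": 0,
                "MAT": 0,
                "SEX": 0,
                "PHENOTYPE": -9,
            }
        )
        body = pd.DataFrame(g.dosages, columns=[f"{s}_A" for s in g.snp_ids])
        pd.concat([lead, body], axis=1).to_csv(path, sep=" ", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_snp_metadata(path) -> dict[str, SnpInfo]:
    """Sidecar table with columns snp_id, chromosome, gene[, maf]."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    out = {}
    for _, row in df.iterrows():
        out[row["snp_id"]] = SnpInfo(
            snp_id=row["snp_id"],
            chromosome=row.get("chromosome", "") or "",
            gene=row.get("gene", "") or "",
            maf_declared=float(row["maf"]) if "maf" in df.columns else None,
        )
    return out


def read_phenotypes(path) -> PhenotypeReplicates:
    """Delimited table: sample_id, Sex, Age, Smoke, then one trait per column."""
    df = pd.read_csv(path, sep=None, engine="python", index_col="sample_id")
    for c in COVARIATE_NAMES:
        if c not in df.columns:
            raise ParseError(f"phenotype table lacks covariate column {c!r}")
    trait_cols = [c for c in df.columns if c not in COVARIATE_NAMES]
    return PhenotypeReplicates(
        samples=[str(i) for i in df.index],
        covariates=df[list(COVARIATE_NAMES)].to_numpy(dtype=float),
        traits={c: df[c].to_numpy(dtype=float) for c in trait_cols},
    )


def write_phenotypes(p: PhenotypeReplicates, path) -> None:
    df = pd.DataFrame(p.covariates, index=p.samples, columns=list(COVARIATE_NAMES))
    for rid, y in p.traits.items():
        df[rid] = y
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def align_samples(
    g: GenotypeMatrix, p: PhenotypeReplicates
) -> tuple[GenotypeMatrix, PhenotypeReplicates]:
    """Restrict both objects to the shared samples, in genotype-file order.

    Raises ``ValidationError`` if the id sets are disjoint; logs a warning
    when ids are dropped from either side.
    """
    gset, pset = set(g.samples), set(p.samples)
    common = gset & pset
    if not common:
        raise ValidationError("genotype and phenotype sample ids are disjoint")
    dropped_g, dropped_p = len(gset - common), len(pset - common)
    if dropped_g or dropped_p:
        logger.warning(
            "align_samples dropped %d genotype and %d phenotype samples",
            dropped_g,
            dropped_p,
        )
    g_rows = np.array([i for i, s in enumerate(g.samples) if s in common])
    order = [g.samples[i] for i in g_rows]
    p_index = {s: i for i, s in enumerate(p.samples)}
    p_rows = np.array([p_index[s] for s in order])
    return g.subset_samples(g_rows), p.subset_samples(p_rows)
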