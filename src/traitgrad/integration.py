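"""Phenotypic integration: trait correlation matrices, the eigenvalue-variance
integration index, bootstrap confidence intervals, and between-zone matrix
similarity with a permutation null.

The integration index INT of a k-trait Pearson correlation matrix R is the
sample variance (k-1 divisor) of R's eigenvalues.  Because the eigenvalues
of a correlation matrix always average 1, INT has the closed form

    INT = 2 * sum_{i<j} r_ij^2 / (k - 1)

which this module computes alongside the eigen-decomposition route and
asserts they agree.  INT is 0 for independent traits (all eigenvalues 1)
and k when every |r_ij| = 1 (a rank-one +/-1 matrix).

Correlations are computed on log-transformed tree-level means by default,
matching the bootstrap CI which resamples the log-transformed data.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import TreeTraitMatrix, ValidationError


class DegenerateDataError(ValueError):
    """Input data cannot support the requested correlation computation."""


@dataclass(frozen=True)
class CorrelationMatrix:
    """An ordered trait list with a symmetric, unit-diagonal Pearson matrix."""

    trait_names: tuple[str, ...]
    r: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        k = len(self.trait_names)
        if k < 2:
            raise ValidationError("need at least 2 traits")
        if r.shape != (k, k):
            raise ValidationError(f"matrix shape {r.shape} does not match {k} traits")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-10):
            raise ValidationError("correlation matrix must have a unit diagonal")
        if np.any(np.abs(r) > 1 + 1e-10):
            raise ValidationError("correlation coefficients must satisfy |r| <= 1")
        object.__setattr__(self, "trait_names", tuple(self.trait_names))
        object.__setattr__(self, "r", r)

    @property
    def k(self) -> int:
        return len(self.trait_names)

    def offdiagonal(self) -> np.ndarray:
        """Upper-triangle coefficients, row-major: one entry per trait pair."""
        return self.r[np.triu_indices(self.k, 1)]

    def permuted(self, perm: tuple[int, ...]) -> "CorrelationMatrix":
        """Simultaneous row/column reordering (a trait relabelling)."""
        idx = np.asarray(perm)
        return CorrelationMatrix(
            tuple(self.trait_names[i] for i in perm), self.r[np.ix_(idx, idx)]
        )

    @classmethod
    def from_upper_triangle(
        cls, trait_names: list[str] | tuple[str, ...], coefficients
    ) -> "CorrelationMatrix":
        """Build from the k(k-1)/2 upper-triangle coefficients in row-major
        order — the layout in which published trait-correlation tables are
        printed, so a table can be typed in verbatim."""
        names = tuple(trait_names)
        k = len(names)
        coefficients = np.asarray(coefficients, dtype=float)
        if coefficients.size != k * (k - 1) // 2:
            raise ValidationError(
                f"expected {k * (k - 1) // 2} coefficients for {k} traits, "
                f"got {coefficients.size}"
            )
        r = np.eye(k)
        r[np.triu_indices(k, 1)] = coefficients
        r = r + r.T - np.eye(k)
        return cls(names, r)

    @classmethod
    def read_upper_triangle_csv(cls, path) -> "CorrelationMatrix":
        """Read the two-column CSV written by :meth:`write_upper_triangle_csv`:
        header ``trait_a,trait_b,r``, pairs in row-major upper-triangle order."""
        df = pd.read_csv(path)
        for col in ("trait_a", "trait_b", "r"):
            if col not in df.columns:
                raise ValidationError(f"missing column {col!r} in matrix CSV")
        names: list[str] = []
        for t in itertools.chain(df["trait_a"], df["trait_b"]):
            if t not in names:
                names.append(t)
        return cls.from_upper_triangle(names, df["r"].to_numpy())

    def write_upper_triangle_csv(self, path) -> None:
        rows = [
            (self.trait_names[i], self.trait_names[j], self.r[i, j])
            for i, j in itertools.combinations(range(self.k), 2)
        ]
        pd.DataFrame(rows, columns=["trait_a", "trait_b", "r"]).to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.trait_names, columns=self.trait_names)


@dataclass(frozen=True)
class IntegrationResult:
    """INT point estimate with percentile bootstrap CI and resampling metadata."""

    zone: str
    integration: float
    ci_low: float
    ci_high: float
    B: int
    seed: int
    n_individuals: int
    n_skipped: int = 0
    ci_excludes_estimate: bool = False


@dataclass(frozen=True)
class SimilarityResult:
    """Element-wise Pearson similarity of two correlation matrices with a
    trait-relabelling permutation p-value."""

    pair: tuple[str, str]
    index: float
    p_value: float
    n_permutations: int
    exact: bool


def _log_zone_frame(
    m: TreeTraitMatrix, zone: str, traits, log_transform: bool
) -> pd.DataFrame:
    df = m.zone_frame(zone, list(traits))
    if log_transform:
        if (df <= 0).any().any():
            raise DegenerateDataError(
                "log transform requires strictly positive trait values"
            )
        df = np.log(df)
    return df


def _pairwise_pearson(df: pd.DataFrame, min_pairs: int = 3) -> np.ndarray:
    """Pairwise-complete Pearson correlations of a trees-by-traits frame."""
    for trait in df.columns:
        col = df[trait].dropna()
        if col.nunique() <= 1:
            raise DegenerateDataError(f"trait {trait!r} is constant; correlation undefined")
    counts = df.notna().astype(int)
    pair_n = counts.T @ counts
    k = df.shape[1]
    iu = np.triu_indices(k, 1)
    if (pair_n.to_numpy()[iu] < min_pairs).any():
        raise DegenerateDataError(
            f"need at least {min_pairs} complete observation pairs for every trait pair"
        )
    r = df.corr(method="pearson", min_periods=min_pairs).to_numpy()
    if np.isnan(r).any():
        raise DegenerateDataError("correlation undefined for at least one trait pair")
    return r


def correlation_matrix(
    m: TreeTraitMatrix,
    zone: str,
    traits: list[str] | tuple[str, ...],
    log_transform: bool = True,
) -> CorrelationMatrix:
    """Pearson trait-correlation matrix for one zone's tree-level means.

    Correlations are pairwise-complete (each pair uses trees measured for
    both traits, minimum 3).  ``log_transform=True`` (default) correlates
    log-transformed means, consistent with the bootstrap CI.
    """
    df = _log_zone_frame(m, zone, traits, log_transform)
    return CorrelationMatrix(tuple(traits), _pairwise_pearson(df))


def integration_index(R: CorrelationMatrix) -> float:
    """Variance of the eigenvalues of R (k-1 divisor).

    Computed by eigen-decomposition and by the closed form
    2*sum(r_ij^2)/(k-1); the two routes are asserted to agree.
    """
    eigenvalues = np.linalg.eigvalsh(R.r)
    by_eigen = float(np.var(eigenvalues, ddof=1))
    closed_form = float(2.0 * np.sum(R.offdiagonal() ** 2) / (R.k - 1))
    if not math.isclose(by_eigen, closed_form, rel_tol=1e-9, abs_tol=1e-10):
        raise AssertionError(
            f"eigenvalue variance {by_eigen} disagrees with closed form {closed_form}"
        )
    return by_eigen


def mean_r_squared(R: CorrelationMatrix) -> float:
    """Mean squared off-diagonal coefficient, each unordered pair once."""
    return float(np.mean(R.offdiagonal() ** 2))


def _resample_integration(values: np.ndarray, rng: np.random.Generator) -> float | None:
    """INT of one bootstrap resample of rows, or None if degenerate."""
    n = values.shape[0]
    idx = rng.integers(0, n, size=n)
    sample = values[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        if np.any(np.nanstd(sample, axis=0) == 0):
            return None
        df = pd.DataFrame(sample)
        if np.isnan(sample).any():
            r = df.corr(min_periods=3).to_numpy()
        else:
            r = np.corrcoef(sample, rowvar=False)
    if np.isnan(r).any():
        return None
    k = r.shape[1]
    return float(2.0 * np.sum(r[np.triu_indices(k, 1)] ** 2) / (k - 1))


def integration_ci(
    m: TreeTraitMatrix,
    zone: str,
    traits: list[str] | tuple[str, ...],
    B: int = 10_000,
    seed: int = 0,
    log_transform: bool = True,
    confidence: float = 0.95,
) -> IntegrationResult:
    """INT with a percentile bootstrap CI from resampling individuals.

    Trees (rows) are resampled with replacement B times; INT is recomputed
    on each replicate's correlation matrix of log-transformed values.
    Degenerate replicates (a constant trait) are skipped and counted; more
    than 10% skipped raises :class:`DegenerateDataError`.
    """
    if B < 100:
        warnings.warn(f"B={B} is very small; CI bounds will be unstable", stacklevel=2)
    R = correlation_matrix(m, zone, traits, log_transform)
    point = integration_index(R)
    values = _log_zone_frame(m, zone, traits, log_transform).to_numpy()
    rng = np.random.default_rng(seed)
    replicates: list[float] = []
    n_skipped = 0
    for _ in range(B):
        rep = _resample_integration(values, rng)
        if rep is None:
            n_skipped += 1
        else:
            replicates.append(rep)
    if n_skipped > 0.10 * B:
        raise DegenerateDataError(
            f"{n_skipped}/{B} bootstrap replicates degenerate; data too sparse"
        )
    tail = (1.0 - confidence) / 2.0
    lo, hi = np.quantile(replicates, [tail, 1.0 - tail])
    return IntegrationResult(
        zone=zone,
        integration=point,
        ci_low=float(lo),
        ci_high=float(hi),
        B=B,
        seed=seed,
        n_individuals=values.shape[0],
        n_skipped=n_skipped,
        ci_excludes_estimate=not (lo <= point <= hi),
    )


def _offdiag_pearson(a: CorrelationMatrix, b: CorrelationMatrix) -> float:
    x, y = a.offdiagonal(), b.offdiagonal()
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError(
            "matrix similarity undefined: off-diagonal coefficients have zero variance"
        )
    return float(np.corrcoef(x, y)[0, 1])


def matrix_similarity(
    R1: CorrelationMatrix,
    R2: CorrelationMatrix,
    exhaustive: bool | None = None,
    n_permutations: int = 9_999,
    seed: int = 0,
    pair: tuple[str, str] = ("matrix_1", "matrix_2"),
) -> SimilarityResult:
    """Similarity of two trait-correlation matrices over the same traits.

    The index is the Pearson correlation between the two vectors of
    k(k-1)/2 off-diagonal coefficients.  The two-sided p-value permutes
    the trait labels of ``R2``: all k! relabellings are enumerated when
    k <= 7 (exact, identity included), Monte Carlo otherwise.
    """
    if R1.trait_names != R2.trait_names:
        raise ValidationError(
            f"trait lists differ: {R1.trait_names} vs {R2.trait_names}"
        )
    observed = _offdiag_pearson(R1, R2)
    k = R1.k
    if exhaustive is None:
        exhaustive = k <= 7
    x = R1.offdiagonal()
    threshold = abs(observed) - 1e-12
    if exhaustive:
        count = total = 0
        for perm in itertools.permutations(range(k)):
            y = R2.permuted(perm).offdiagonal()
            total += 1
            if abs(np.corrcoef(x, y)[0, 1]) >= threshold:
                count += 1
        p = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = 1  # identity permutation
        for _ in range(n_permutations):
            perm = tuple(rng.permutation(k))
            y = R2.permuted(perm).offdiagonal()
            if abs(np.corrcoef(x, y)[0, 1]) >= threshold:
                count += 1
        p = count / (n_permutations + 1)
        n_used = n_permutations + 1
    return SimilarityResult(
        pair=pair, index=observed, p_value=p, n_permutations=n_used, exact=exhaustive
    )
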