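"""Linear and mixed linear trait models and their Hamiltonians.

The ensemble Q(beta, X) over model parameters is defined through a Hamiltonian
H with Q proportional to exp(-H) (the Boltzmann factor).  For the fixed-effects
linear model Y = X beta + eps,

    H(beta, X) = (Y - X beta)' V^{-1} (Y - X beta),

with V block diagonal, fixed at the per-accession sample variances of the
trait.  For the mixed linear model Y = X beta + Z u + eps with Z_i = X_i, the
marginal covariance is

    V = sum_i x_i x_i' sigma_{j(i)}^2 + sigma^2 I = X S X' + sigma^2 I,

where x_i is the i-th design row, j(i) the accession of observation i, and
S = sum_i x_i x_i' sigma_{j(i)}^2.  Its Hamiltonian is the exact negative
multivariate-normal log density

    H = 1/2 (Y - X beta)' V^{-1} (Y - X beta) + n/2 ln(2 pi) + 1/2 ln|V|,

which, unlike the linear-model sum of squared errors, may be negative.
Note the linear-model H carries no factor 1/2: its stationary ensemble over
beta is Gaussian with covariance (1/2)(X' V^{-1} X)^{-1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from minegwas.genomatrix import DesignMatrix

_TWO_PI = 2.0 * np.pi


def _as_array(X) -> np.ndarray:
    """Accept a DesignMatrix or a plain 2-D array."""
    if isinstance(X, DesignMatrix):
        return X.values
    return np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class TraitData:
    """One quantitative-trait observation per plant with field structure."""

    y: np.ndarray
    plant_ids: list[str]
    accession_ids: list[str]
    year: np.ndarray | None = None
    block: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if not np.isfinite(self.y).all():
            raise ValueError("trait vector contains non-finite values")
        n = len(self.y)
        if len(self.plant_ids) != n or len(self.accession_ids) != n:
            raise ValueError("plant/accession labels must match y length")
        if self.year is not None:
            self.year = np.asarray(self.year)
        if self.block is not None:
            self.block = np.asarray(self.block)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def accessions(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.accession_ids:
            seen.setdefault(a, None)
        return list(seen)

    def accession_index(self) -> np.ndarray:
        """Per-observation index into :meth:`accessions` order."""
        order = {a: i for i, a in enumerate(self.accessions)}
        return np.asarray([order[a] for a in self.accession_ids])

    @classmethod
    def from_table(cls, df, trait: str) -> "TraitData":
        """Build from a phenotype table with plant_id, accession_id, year, block."""
        return cls(
            y=df[trait].to_numpy(float),
            plant_ids=[str(v) for v in df["plant_id"]],
            accession_ids=[str(v) for v in df["accession_id"]],
            year=df["year"].to_numpy() if "year" in df else None,
            block=df["block"].to_numpy() if "block" in df else None,
        )


@dataclass
class LinearParams:
    """Chromosomal-region effects beta for the fixed-effects linear model."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.isfinite(self.beta).all():
            raise ValueError("beta contains non-finite values")


@dataclass
class MixedParams:
    """beta plus per-accession scale sigma_acc (sqrt variance components)
    and residual scale sigma_resid, all in trait units."""

    beta: np.ndarray
    sigma_acc: np.ndarray
    sigma_resid: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.sigma_acc = np.asarray(self.sigma_acc, dtype=float)
        if np.any(self.sigma_acc < 0):
            raise ValueError("sigma_acc must be nonnegative")
        if not self.sigma_resid > 0:
            raise ValueError("sigma_resid must be positive")


class CovStructure:
    """Symmetric positive-definite observation covariance V with a cached
    Cholesky factorization.  Diagonal forms keep O(n) storage."""

    def __init__(self, matrix=None, diag=None, form: str = "fixed_blockdiag"):
        if (matrix is None) == (diag is None):
            raise ValueError("provide exactly one of matrix / diag")
        self.form = form
        if diag is not None:
            self.diag = np.asarray(diag, dtype=float)
            if np.any(self.diag <= 0):
                raise ValueError("diagonal V requires positive entries")
            self.matrix = None
        else:
            M = np.asarray(matrix, dtype=float)
            if not np.allclose(M, M.T, atol=1e-10):
                raise ValueError("V must be symmetric")
            self.matrix = M
            self.diag = None
            try:
                self._cho = cho_factor(M)
            except np.linalg.LinAlgError as e:  # pragma: no cover
                raise np.linalg.LinAlgError(f"V is not positive definite: {e}")

    # -- factories ----------------------------------------------------------

    @classmethod
    def identity(cls, n: int) -> "CovStructure":
        return cls(diag=np.ones(n))

    @classmethod
    def from_diagonal(cls, d) -> "CovStructure":
        return cls(diag=d)

    # -- linear algebra -----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.diag) if self.diag is not None else self.matrix.shape[0]

    def dense(self) -> np.ndarray:
        return np.diag(self.diag) if self.diag is not None else self.matrix

    def solve(self, b: np.ndarray) -> np.ndarray:
        if self.diag is not None:
            return (b.T / self.diag).T
        return cho_solve(self._cho, b)

    def quad(self, r: np.ndarray) -> float:
        """r' V^{-1} r."""
        return float(r @ self.solve(r))

    def logdet(self) -> float:
        if self.diag is not None:
            return float(np.log(self.diag).sum())
        c, _ = self._cho
        return float(2.0 * np.log(np.diag(c)).sum())


# ---------------------------------------------------------------------------
# operations


def v_fixed(td: TraitData, floor: float = 1e-6) -> CovStructure:
    """Diagonal V fixed at each observation's accession sample variance.

    Accessions with fewer than 2 observations, or sample variance below
    ``floor``, take max(pooled within-accession variance, floor).  When every
    accession is a singleton the global sample variance is used (with a
    warning in the log).
    """
    import logging

    acc_idx = td.accession_index()
    n_acc = acc_idx.max() + 1
    var = np.full(n_acc, np.nan)
    ss, dof = 0.0, 0
    for a in range(n_acc):
        ya = td.y[acc_idx == a]
        if len(ya) >= 2:
            var[a] = ya.var(ddof=1)
            ss += ((ya - ya.mean()) ** 2).sum()
            dof += len(ya) - 1
    if dof > 0:
        pooled = ss / dof
    else:
        pooled = td.y.var(ddof=1) if td.n_obs >= 2 else 1.0
        logging.getLogger(__name__).warning(
            "v_fixed: all accessions singleton; using global sample variance"
        )
    fallback = max(pooled, floor)
    var = np.where(np.isnan(var) | (var < floor), fallback, var)
    return CovStructure(diag=var[acc_idx], form="fixed_blockdiag")


def hamiltonian_linear(lp: LinearParams, X, td: TraitData, V: CovStructure) -> float:
    """(Y - X beta)' V^{-1} (Y - X beta): the V-weighted sum of squared errors."""
    Xa = _as_array(X)
    if Xa.shape != (td.n_obs, len(lp.beta)):
        raise ValueError(
            f"shape mismatch: X {Xa.shape}, y {td.n_obs}, beta {len(lp.beta)}"
        )
    r = td.y - Xa @ lp.beta
    return V.quad(r)


def v_mixed(mp: MixedParams, X, accession_index: np.ndarray) -> CovStructure:
    """Mixed-model marginal covariance V = X S X' + sigma^2 I with
    S = sum_i x_i x_i' sigma_{j(i)}^2 (sum over observation rows)."""
    Xa = _as_array(X)
    s2 = mp.sigma_acc[accession_index] ** 2          # per-observation variance
    S = Xa.T @ (s2[:, None] * Xa)
    V = Xa @ S @ Xa.T
    V[np.diag_indices_from(V)] += mp.sigma_resid**2
    return CovStructure(matrix=0.5 * (V + V.T), form="mixed_dense")


def hamiltonian_mixed(mp: MixedParams, X, td: TraitData,
                      V: CovStructure | None = None) -> float:
    """Negative log density of N(X beta, V) at Y; can be negative."""
    Xa = _as_array(X)
    if V is None:
        V = v_mixed(mp, Xa, td.accession_index())
    r = td.y - Xa @ mp.beta
    n = td.n_obs
    return 0.5 * V.quad(r) + 0.5 * n * np.log(_TWO_PI) + 0.5 * V.logdet()


def log_ensemble_prob(h: float) -> float:
    """log Q up to the normalization Omega(X), which cancels in every
    Metropolis ratio and is never computed: simply -H."""
    if not np.isfinite(h):
        raise ValueError("Hamiltonian must be finite")
    return -h


def predict(beta: np.ndarray, X_cand) -> np.ndarray:
    """Model-predicted trait values X_cand @ beta, one per candidate row."""
    Xa = _as_array(X_cand)
    beta = np.asarray(beta, dtype=float)
    if Xa.shape[1] != len(beta):
        raise ValueError(f"X has {Xa.shape[1]} columns but beta has {len(beta)}")
    return Xa @ beta
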