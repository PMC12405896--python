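"""Feature selection from the model ensemble.

Three filters identify significant chromosomal-region effects:

* **linear projection** — with n < p some beta directions are unconstrained by
  the data and wander during the random walk.  Eigendecomposing X' V^{-1} X
  and zeroing the rotated beta components whose eigenvalues are near zero
  removes the wandering without changing the fitted values X beta.
* **Bayesian interval** — a region is kept only when the 95% equal-tailed
  interval of its sampled effect excludes zero.
* **Benjamini–Hochberg** — z = ensemble mean / ensemble standard deviation per
  region, two-sided normal p-values, FDR-controlling step-up rule.  (The
  literal per-p variant of the procedure box is available behind a flag.)

Regions passing all filters are kept.  A one-column-at-a-time GLS regression
is included as the overfitting-prone negative control, and a likelihood-ratio
machinery compares a pooled (no-year) fit against separate per-year fits via
ensemble Hamiltonians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from minegwas.mcmc import Ensemble
from minegwas.models import CovStructure, TraitData, _as_array


# ---------------------------------------------------------------------------
# domain types


@dataclass
class FeatureReport:
    """Per-bin survival status under each filter."""

    bin_labels: list[str]
    kept_projection: np.ndarray
    kept_bayes: np.ndarray
    kept_bh: np.ndarray
    z_scores: np.ndarray | None = None
    p_values: np.ndarray | None = None
    interval_low: np.ndarray | None = None
    interval_high: np.ndarray | None = None
    model: str = "linear"

    def __post_init__(self) -> None:
        n = len(self.bin_labels)
        for name in ("kept_projection", "kept_bayes", "kept_bh"):
            m = np.asarray(getattr(self, name), dtype=bool)
            if len(m) != n:
                raise ValueError(f"{name} length {len(m)} != {n} bins")
            setattr(self, name, m)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "bin": self.bin_labels,
            "kept_projection": self.kept_projection,
            "kept_bayes": self.kept_bayes,
            "kept_bh": self.kept_bh,
        })
        if self.z_scores is not None:
            df["z"] = self.z_scores
            df["p"] = self.p_values
        if self.interval_low is not None:
            df["q2.5"] = self.interval_low
            df["q97.5"] = self.interval_high
        df["kept_all"] = self.kept_projection & self.kept_bayes & self.kept_bh
        return df


@dataclass
class LrtResult:
    """-2 ln Lambda comparison of pooled vs per-year model fits."""

    lambda_stat: float
    df: int
    h_noyear: float
    h_years: list[float]
    resample_histogram: np.ndarray
    frac_below_zero: float


# ---------------------------------------------------------------------------
# filters


def linear_projection(e: Ensemble, X, V: CovStructure,
                      rel_tol: float = 1e-10) -> Ensemble:
    """Project each sampled beta onto the data-constrained eigen-directions.

    Eigendecomposes X' V^{-1} X, zeroes rotated components whose eigenvalue is
    below ``rel_tol`` times the largest, and rotates back.  Fitted values
    X beta are unchanged because the removed directions lie (numerically) in
    the null space of X.
    """
    Xa = _as_array(X)
    M = Xa.T @ V.solve(Xa)
    M = 0.5 * (M + M.T)
    eigval, eigvec = np.linalg.eigh(M)
    order = np.argsort(eigval)[::-1]
    eigval, rot = eigval[order], eigvec[:, order]
    keep = eigval >= rel_tol * max(float(eigval[0]), 0.0)
    beta_star = e.beta @ rot                 # rotate each sample
    beta_star[:, ~keep] = 0.0
    beta_p = beta_star @ rot.T               # rotate back
    samples = e.samples.copy()
    samples[:, : e.n_beta] = beta_p
    return Ensemble(
        samples=samples,
        hamiltonians=e.hamiltonians.copy(),
        model=e.model,
        n_beta=e.n_beta,
        n_sigma=e.n_sigma,
        traces=dict(e.traces),
        config=e.config,
        accession_ids=e.accession_ids,
    )


def bayesian_interval(e: Ensemble, level: float = 0.95) -> np.ndarray:
    """Keep a parameter only if its equal-tailed ensemble interval excludes 0.

    Quantiles use the sorted-sample index convention: the q-quantile is the
    value at (1-based) index ceil(q * M) of the ascending sort.
    """
    M = e.n_samples
    if M < 40:
        raise ValueError("need an ensemble of at least 40 samples")
    q = (1.0 - level) / 2.0
    lo_i = max(ceil(q * M), 1) - 1
    hi_i = max(ceil((1.0 - q) * M), 1) - 1
    srt = np.sort(e.beta, axis=0)
    lo, hi = srt[lo_i], srt[hi_i]
    removed = (lo < 0) & (hi > 0)
    return ~removed


def interval_bounds(e: Ensemble, level: float = 0.95):
    M = e.n_samples
    q = (1.0 - level) / 2.0
    lo_i = max(ceil(q * M), 1) - 1
    hi_i = max(ceil((1.0 - q) * M), 1) - 1
    srt = np.sort(e.beta, axis=0)
    return srt[lo_i], srt[hi_i]


def benjamini_hochberg(e: Ensemble, alpha: float = 0.05,
                       literal: bool = False):
    """z = ensemble mean / sd per region, two-sided normal p, BH at ``alpha``.

    Returns (kept mask, z, p).  ``literal=True`` applies the plain per-p
    comparison p_(k) <= (k/m) alpha without the step-up closure (keeps a
    subset of the step-up survivors).  Zero-variance parameters are excluded
    with a warning.
    """
    import logging

    mean = e.beta.mean(axis=0)
    sd = e.beta.std(axis=0, ddof=1)
    ok = sd > 0
    if not ok.all():
        logging.getLogger(__name__).warning(
            "benjamini_hochberg: %d zero-variance parameter(s) excluded",
            int((~ok).sum()),
        )
    z = np.zeros_like(mean)
    z[ok] = mean[ok] / sd[ok]
    p = np.ones_like(mean)
    p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    kept = np.zeros(len(mean), dtype=bool)
    if ok.any():
        if literal:
            m = int(ok.sum())
            order = np.argsort(p[ok])
            ranks = np.empty(m)
            ranks[order] = np.arange(1, m + 1)
            kept[ok] = p[ok] <= ranks / m * alpha
        else:
            kept[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
    return kept, z, p


def intersect_filters(fr: FeatureReport):
    """AND of the three masks plus all 7 Venn region counts."""
    a, b, c = fr.kept_projection, fr.kept_bayes, fr.kept_bh
    if not (len(a) == len(b) == len(c)):
        raise ValueError("filter mask lengths differ")
    venn = {
        "projection_only": int((a & ~b & ~c).sum()),
        "bayes_only": int((~a & b & ~c).sum()),
        "bh_only": int((~a & ~b & c).sum()),
        "projection_bayes": int((a & b & ~c).sum()),
        "projection_bh": int((a & ~b & c).sum()),
        "bayes_bh": int((~a & b & c).sum()),
        "all": int((a & b & c).sum()),
    }
    return a & b & c, venn


def one_at_a_time(X, td: TraitData, V: CovStructure, alpha: float = 0.05):
    """Single-column GLS regressions (with intercept), BH across columns.

    The classical negative control: fitting each chromosomal region alone
    dramatically overfits relative to the joint-model filters.
    Returns (kept mask, z, p).
    """
    import logging

    Xa = _as_array(X)
    y = td.y
    n, p = Xa.shape
    z = np.zeros(p)
    pv = np.ones(p)
    ok = np.ones(p, dtype=bool)
    ones = np.ones(n)
    for j in range(p):
        xj = Xa[:, j]
        if np.allclose(xj, xj[0]):
            ok[j] = False
            logging.getLogger(__name__).warning(
                "one_at_a_time: constant column %d excluded", j
            )
            continue
        A = np.column_stack([ones, xj])
        WA = V.solve(A)
        AtWA = A.T @ WA
        coef = np.linalg.solve(AtWA, WA.T @ y)
        cov = np.linalg.inv(AtWA)
        se = np.sqrt(cov[1, 1])
        z[j] = coef[1] / se
        pv[j] = 2.0 * stats.norm.sf(abs(z[j]))
    kept = np.zeros(p, dtype=bool)
    if ok.any():
        kept[ok] = multipletests(pv[ok], alpha=alpha, method="fdr_bh")[0]
    return kept, z, pv


def lrt_year_effect(e_noyear: Ensemble, e_years: list[Ensemble],
                    df: int = 2, n_draws: int = 1_000, rng=None) -> LrtResult:
    """-2 ln Lambda = 2 (H_noyear - sum_y H_year) from final Hamiltonians.

    Positive values favor the per-year model.  Because any single MCMC run's
    terminal Hamiltonian is noisy, the statistic is also resampled: each draw
    picks one stored Hamiltonian uniformly from every ensemble; the fraction
    of draws below zero votes for the no-year-effect hypothesis.
    """
    if len(e_years) < 2:
        raise ValueError("need at least two per-year ensembles")
    models = {e.model for e in [e_noyear, *e_years]}
    if len(models) != 1:
        raise ValueError(f"model tags differ across ensembles: {models}")
    if rng is None:
        rng = np.random.default_rng(0)
    h0 = float(e_noyear.hamiltonians[-1])
    hy = [float(e.hamiltonians[-1]) for e in e_years]
    stat = 2.0 * (h0 - sum(hy))
    draws = np.empty(n_draws)
    h0s = e_noyear.hamiltonians
    hys = [e.hamiltonians for e in e_years]
    for t in range(n_draws):
        s = rng.choice(h0s) - sum(rng.choice(h) for h in hys)
        draws[t] = 2.0 * s
    frac = float((draws < 0).mean())
    return LrtResult(stat, df, h0, hy, draws, frac)


# ---------------------------------------------------------------------------
# convenience: run every filter and assemble the report


def select_features(e: Ensemble, X, V: CovStructure,
                    bin_labels: list[str] | None = None,
                    alpha: float = 0.05, level: float = 0.95) -> FeatureReport:
    """Apply all three filters and intersect.

    The projection is a transform of the ensemble, not itself a mask; its
    selection is realized as the interval test applied to the *projected*
    ensemble, while the Bayesian-interval and BH filters run on the raw
    ensemble.  A region must survive all three.
    """
    labels = bin_labels or [f"bin{j}" for j in range(e.n_beta)]
    proj = linear_projection(e, X, V)
    kept_proj = bayesian_interval(proj, level=level)
    kept_bayes = bayesian_interval(e, level=level)
    kept_bh, z, p = benjamini_hochberg(e, alpha=alpha)
    lo, hi = interval_bounds(e, level=level)
    return FeatureReport(
        bin_labels=labels,
        kept_projection=kept_proj,
        kept_bayes=kept_bayes,
        kept_bh=kept_bh,
        z_scores=z,
        p_values=p,
        interval_low=lo,
        interval_high=hi,
        model=e.model,
    )
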