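"""Customized Metropolis sampler with a dynamic stepwidth adjuster.

One *sweep* is p single-parameter update attempts with the parameter index
drawn uniformly at random — a visit to every parameter on average once.  The
chain runs ``n_equil_sweeps`` of equilibration (burn-in, with the stepwidth
adjuster active), then ``n_accumulate`` blocks of ``n_decorr_sweeps``
decorrelation sweeps, storing one parameter vector per block.

The stepwidth S_i is multiplied every ``adjust_every`` sweeps by a factor f_i
chosen from the windowed acceptance rate r_i:

* r_i inside [r_min, r_max], or S_{i-1} outside [S_min, S_max]  ->  f = 1
* first drop below r_min                                         ->  f = 2/3
* first rise above r_max                                         ->  f = 3/2
* out of range on the same side twice                            ->  f = f_{i-1}
* range crossed (below -> above or above -> below)               ->  f = 1/f_{i-1}

with S_min = E_S * S_bar and S_max = S_bar / E_S, S_bar the running mean of
past stepwidths.  Acceptance that is too low means steps are too large, so the
stepwidth shrinks; too high grows it.  Betas and sigmas carry separate
adjuster states.

The linear-model Hamiltonian is updated incrementally per move (rank-1
residual update with cached V^{-1}-weighted columns); the mixed model reuses
its Cholesky factorization while only beta moves and refactorizes when a sigma
moves.  Stored Hamiltonians are re-synchronized against a full recomputation
at every accumulation store and every adjuster update.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from minegwas.genomatrix import DesignMatrix
from minegwas.models import (
    CovStructure,
    TraitData,
    _as_array,
    v_fixed,
)

logger = logging.getLogger(__name__)

_TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# configuration and adjuster state


@dataclass
class McmcConfig:
    """Sampler settings; defaults follow the full-scale runs (Ne near 10^4,
    1,000 decorrelation sweeps between each of 1,000 stored vectors)."""

    n_equil_sweeps: int = 10_000
    n_decorr_sweeps: int = 1_000
    n_accumulate: int = 1_000
    stepwidth_init: dict = field(default_factory=lambda: {"beta": 0.1, "sigma": 0.05})
    r_min: float = 0.3
    r_max: float = 0.7
    e_s: float = 1e-5
    adjust_every: int = 1_000
    rate_window: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.r_min < self.r_max < 1.0):
            raise ValueError("need 0 < r_min < r_max < 1")
        if not (1e-6 <= self.e_s <= 1e-4):
            raise ValueError("E_S must lie in [1e-6, 1e-4]")
        for name in ("n_equil_sweeps", "n_decorr_sweeps", "n_accumulate",
                     "adjust_every", "rate_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class StepwidthState:
    """Adjuster state for one parameter class."""

    s_current: float
    f_prev: float = 1.0
    s_history_sum: float = 0.0
    s_history_n: int = 0
    r_prev: float | None = None

    def __post_init__(self) -> None:
        if not self.s_current > 0:
            raise ValueError("stepwidth must be positive")
        if self.s_history_n == 0:
            self.s_history_sum = self.s_current
            self.s_history_n = 1

    @property
    def s_mean(self) -> float:
        return self.s_history_sum / self.s_history_n


def adjust_stepwidth(st: StepwidthState, r_i: float, cfg: McmcConfig) -> StepwidthState:
    """One adjuster update; pure function of (state, windowed acceptance rate)."""
    if not (0.0 <= r_i <= 1.0):
        raise ValueError("acceptance rate must be in [0, 1]")
    s_bar = st.s_mean
    s_min, s_max = cfg.e_s * s_bar, s_bar / cfg.e_s
    in_band = s_min <= st.s_current <= s_max
    prev_in_range = st.r_prev is None or cfg.r_min <= st.r_prev <= cfg.r_max

    if cfg.r_min <= r_i <= cfg.r_max or not in_band:
        f = 1.0
    elif r_i < cfg.r_min:
        if prev_in_range:
            f = 2.0 / 3.0
        elif st.r_prev < cfg.r_min:
            f = st.f_prev
        else:
            f = 1.0 / st.f_prev
    else:  # r_i > r_max
        if prev_in_range:
            f = 3.0 / 2.0
        elif st.r_prev > cfg.r_max:
            f = st.f_prev
        else:
            f = 1.0 / st.f_prev

    s_new = f * st.s_current
    return StepwidthState(
        s_current=s_new,
        f_prev=f,
        s_history_sum=st.s_history_sum + s_new,
        s_history_n=st.s_history_n + 1,
        r_prev=r_i,
    )


# ---------------------------------------------------------------------------
# elementary Metropolis operations


def propose_update(params: np.ndarray, k: int, stepwidth: float, rng,
                   sigma_indices=()) -> tuple[np.ndarray, bool]:
    """beta_k' = beta_k + stepwidth * U(-1, 1); only component k changes.

    Returns (proposal, valid); a proposal driving any sigma component negative
    is flagged invalid (and counts as a rejection in the chain).
    """
    if not 0 <= k < len(params):
        raise IndexError(f"parameter index {k} out of range")
    out = np.array(params, dtype=float, copy=True)
    out[k] += stepwidth * rng.uniform(-1.0, 1.0)
    valid = not (k in set(sigma_indices) and out[k] < 0.0)
    return out, valid


def accept_step(h_current: float, h_proposed: float, rng) -> bool:
    """Metropolis rule: accept with probability min(1, exp(h_current - h_proposed))."""
    if h_proposed <= h_current:
        return True
    return rng.random() < np.exp(h_current - h_proposed)


# ---------------------------------------------------------------------------
# ensemble container


@dataclass
class Ensemble:
    """M accepted parameter vectors with their Hamiltonians and run traces.

    ``samples`` stacks the flat parameter vectors row-wise; for the mixed
    model the layout is [beta (n_beta), sigma_acc (n_sigma), sigma_resid].
    """

    samples: np.ndarray
    hamiltonians: np.ndarray
    model: str                    # {"linear", "mixed"}
    n_beta: int
    n_sigma: int = 0
    traces: dict = field(default_factory=dict)
    config: McmcConfig | None = None
    accession_ids: list[str] | None = None

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def beta(self) -> np.ndarray:
        return self.samples[:, : self.n_beta]

    @property
    def sigma_acc(self) -> np.ndarray:
        if self.model != "mixed":
            raise AttributeError("linear-model ensemble has no sigma_acc")
        return self.samples[:, self.n_beta : self.n_beta + self.n_sigma]

    @property
    def sigma_resid(self) -> np.ndarray:
        if self.model != "mixed":
            raise AttributeError("linear-model ensemble has no sigma_resid")
        return self.samples[:, -1]

    def save(self, path_prefix: str) -> None:
        """Write <prefix>.npz (arrays) and <prefix>.json (config sidecar)."""
        np.savez(
            f"{path_prefix}.npz",
            samples=self.samples,
            hamiltonians=self.hamiltonians,
            **{f"trace_{k}": np.asarray(v) for k, v in self.traces.items()},
        )
        sidecar = {
            "model": self.model,
            "n_beta": self.n_beta,
            "n_sigma": self.n_sigma,
            "config": asdict(self.config) if self.config else None,
            "accession_ids": self.accession_ids,
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path_prefix: str) -> "Ensemble":
        arrays = np.load(f"{path_prefix}.npz")
        with open(f"{path_prefix}.json") as fh:
            sidecar = json.load(fh)
        traces = {
            k[len("trace_"):]: arrays[k] for k in arrays.files if k.startswith("trace_")
        }
        cfg = McmcConfig(**sidecar["config"]) if sidecar.get("config") else None
        return cls(
            samples=arrays["samples"],
            hamiltonians=arrays["hamiltonians"],
            model=sidecar["model"],
            n_beta=sidecar["n_beta"],
            n_sigma=sidecar.get("n_sigma", 0),
            traces=traces,
            config=cfg,
            accession_ids=sidecar.get("accession_ids"),
        )


# ---------------------------------------------------------------------------
# model cores: incremental Hamiltonian bookkeeping


class _LinearCore:
    """H = r' V^{-1} r with rank-1 residual updates.

    Caches V^{-1} X and the per-column quadratic terms so one single-parameter
    move costs O(n).
    """

    n_sigma = 0

    def __init__(self, X: np.ndarray, y: np.ndarray, V: CovStructure,
                 beta0: np.ndarray):
        self.X = X
        self.y = y
        self.V = V
        self.WX = V.solve(X)                       # V^{-1} X
        self.colquad = np.einsum("ij,ij->j", X, self.WX)
        self.beta = np.array(beta0, dtype=float)
        self.r = y - X @ self.beta
        self.h = V.quad(self.r)
        self.n_params = X.shape[1]

    def param_class(self, k: int) -> int:
        return 0  # all betas

    def delta_h(self, k: int, delta: float):
        s1 = self.WX[:, k] @ self.r
        dh = -2.0 * delta * s1 + delta * delta * self.colquad[k]
        return dh, True

    def apply(self, k: int, delta: float, dh: float) -> None:
        self.beta[k] += delta
        self.r -= delta * self.X[:, k]
        self.h += dh

    def full_h(self) -> float:
        r = self.y - self.X @ self.beta
        return self.V.quad(r)

    def resync(self) -> None:
        self.r = self.y - self.X @ self.beta
        self.h = self.V.quad(self.r)

    def flat_params(self) -> np.ndarray:
        return self.beta.copy()


class _MixedCore:
    """H = 1/2 r' V^{-1} r + (n/2) ln 2 pi + 1/2 ln|V|, V = X S X' + s^2 I.

    Beta moves reuse the cached Cholesky factorization of V (O(n) each);
    sigma moves rebuild V and refactorize (O(n^3)).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, acc_idx: np.ndarray,
                 beta0: np.ndarray, sigma_acc0: np.ndarray, sigma_resid0: float,
                 update_sigmas: bool = True):
        self.X = X
        self.y = y
        self.acc_idx = acc_idx
        self.n, self.p = X.shape
        self.n_acc = int(acc_idx.max()) + 1
        self.beta = np.array(beta0, dtype=float)
        self.sigma_acc = np.array(sigma_acc0, dtype=float)
        self.sigma_resid = float(sigma_resid0)
        self.update_sigmas = update_sigmas
        self.n_sigma = (self.n_acc + 1) if update_sigmas else 0
        self.n_params = self.p + self.n_sigma
        self.r = y - X @ self.beta
        self._refresh_v()

    # -- V cache ------------------------------------------------------------

    def _build_v(self, sigma_acc: np.ndarray, sigma_resid: float) -> np.ndarray:
        s2 = sigma_acc[self.acc_idx] ** 2
        S = self.X.T @ (s2[:, None] * self.X)
        V = self.X @ S @ self.X.T
        V[np.diag_indices_from(V)] += sigma_resid**2
        return 0.5 * (V + V.T)

    def _refresh_v(self) -> None:
        V = self._build_v(self.sigma_acc, self.sigma_resid)
        self._cho = cho_factor(V)
        c, _ = self._cho
        self.logdet = float(2.0 * np.log(np.diag(c)).sum())
        self.B = cho_solve(self._cho, self.X)       # V^{-1} X
        self.colquad = np.einsum("ij,ij->j", self.X, self.B)
        self.quad = float(self.r @ cho_solve(self._cho, self.r))
        self.h = self._h_from(self.quad, self.logdet)

    def _h_from(self, quad: float, logdet: float) -> float:
        return 0.5 * quad + 0.5 * self.n * np.log(_TWO_PI) + 0.5 * logdet

    # -- moves --------------------------------------------------------------

    def param_class(self, k: int) -> int:
        return 0 if k < self.p else 1

    def delta_h(self, k: int, delta: float):
        if k < self.p:
            s1 = self.B[:, k] @ self.r
            dq = -2.0 * delta * s1 + delta * delta * self.colquad[k]
            return 0.5 * dq, True
        # sigma move: full refactorization of the proposed V
        j = k - self.p
        if j < self.n_acc:
            new = self.sigma_acc[j] + delta
            if new < 0:
                return np.inf, False
            sig_acc = self.sigma_acc.copy()
            sig_acc[j] = new
            sig_res = self.sigma_resid
        else:
            sig_res = self.sigma_resid + delta
            if sig_res <= 0:
                return np.inf, False
            sig_acc = self.sigma_acc
        V = self._build_v(sig_acc, sig_res)
        try:
            cho = cho_factor(V)
        except np.linalg.LinAlgError:
            return np.inf, False
        c, _ = cho
        logdet = float(2.0 * np.log(np.diag(c)).sum())
        quad = float(self.r @ cho_solve(cho, self.r))
        dh = self._h_from(quad, logdet) - self.h
        self._pending = (cho, logdet, quad)
        return dh, True

    def apply(self, k: int, delta: float, dh: float) -> None:
        if k < self.p:
            self.beta[k] += delta
            self.r -= delta * self.X[:, k]
            self.quad += 2.0 * dh - 0.0  # dh = 0.5 * dq
            self.h += dh
            return
        j = k - self.p
        if j < self.n_acc:
            self.sigma_acc[j] += delta
        else:
            self.sigma_resid += delta
        cho, logdet, quad = self._pending
        self._cho, self.logdet, self.quad = cho, logdet, quad
        self.B = cho_solve(self._cho, self.X)
        self.colquad = np.einsum("ij,ij->j", self.X, self.B)
        self.h = self._h_from(self.quad, self.logdet)

    def full_h(self) -> float:
        r = self.y - self.X @ self.beta
        V = self._build_v(self.sigma_acc, self.sigma_resid)
        cho = cho_factor(V)
        c, _ = cho
        logdet = float(2.0 * np.log(np.diag(c)).sum())
        return self._h_from(float(r @ cho_solve(cho, r)), logdet)

    def resync(self) -> None:
        self.r = self.y - self.X @ self.beta
        self._refresh_v()

    def flat_params(self) -> np.ndarray:
        if self.update_sigmas:
            return np.concatenate(
                [self.beta, self.sigma_acc, [self.sigma_resid]]
            )
        return self.beta.copy()


# ---------------------------------------------------------------------------
# the chain


def run_chain(model: str, X, td: TraitData, cfg: McmcConfig, *,
              V: CovStructure | None = None, init: np.ndarray | None = None,
              sigma_init: tuple[np.ndarray, float] | None = None,
              update_sigmas: bool = True, rng=None) -> Ensemble:
    """Run the customized Metropolis sampler and return the ensemble.

    Parameters
    ----------
    model : "linear" or "mixed"
    X : DesignMatrix or array, one row per observation of ``td``
    V : observation covariance for the linear model (default: ``v_fixed(td)``)
    init : optional initial beta (default i.i.d. uniform(-0.1, 0.1))
    sigma_init : optional (sigma_acc, sigma_resid) start for the mixed model
        (default: trait overall sample standard deviation for every component)
    update_sigmas : mixed model only; freeze variance components when False
    """
    Xa = _as_array(X)
    n, p = Xa.shape
    if n != td.n_obs:
        raise ValueError(f"X has {n} rows but trait has {td.n_obs} observations")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    beta0 = rng.uniform(-0.1, 0.1, size=p) if init is None else np.asarray(init, float)
    if model == "linear":
        if V is None:
            V = v_fixed(td)
        core = _LinearCore(Xa, td.y, V, beta0)
        acc_ids = td.accessions
    elif model == "mixed":
        acc_idx = td.accession_index()
        sd = td.y.std(ddof=1) if td.n_obs >= 2 else 1.0
        if sigma_init is None:
            sigma_acc0 = np.full(int(acc_idx.max()) + 1, sd)
            sigma_resid0 = sd
        else:
            sigma_acc0, sigma_resid0 = sigma_init
            sigma_acc0 = np.asarray(sigma_acc0, float)
        core = _MixedCore(Xa, td.y, acc_idx, beta0, sigma_acc0, sigma_resid0,
                          update_sigmas=update_sigmas)
        acc_ids = td.accessions
    else:
        raise ValueError(f"unknown model {model!r}")

    if not np.isfinite(core.h):
        raise ValueError("non-finite Hamiltonian at initialization")

    n_params = core.n_params
    n_classes = 2 if (model == "mixed" and update_sigmas) else 1
    steps = [
        StepwidthState(cfg.stepwidth_init["beta"]),
        StepwidthState(cfg.stepwidth_init.get("sigma", 0.05)),
    ][:n_classes]

    total_sweeps = cfg.n_equil_sweeps + cfg.n_accumulate * cfg.n_decorr_sweeps
    h_trace = np.empty(total_sweeps)
    rate_trace = np.zeros((total_sweeps, n_classes))
    step_trace = np.empty((total_sweeps, n_classes))
    attempts = np.zeros((total_sweeps, n_classes), dtype=np.int64)
    accepts = np.zeros((total_sweeps, n_classes), dtype=np.int64)

    samples = np.empty((cfg.n_accumulate, len(core.flat_params())))
    hams = np.empty(cfg.n_accumulate)
    stored = 0
    next_store_sweep = cfg.n_equil_sweeps + cfg.n_decorr_sweeps

    if model == "mixed" and update_sigmas:
        # class of each flat parameter index, cached once
        cls_of = np.zeros(n_params, dtype=np.int64)
        cls_of[p:] = 1
    else:
        cls_of = np.zeros(n_params, dtype=np.int64)

    step_now = np.array([s.s_current for s in steps])

    for sweep in range(total_sweeps):
        ks = rng.integers(0, n_params, size=n_params)
        us = rng.uniform(-1.0, 1.0, size=n_params)
        coin = rng.random(size=n_params)
        for t in range(n_params):
            k = int(ks[t])
            c = cls_of[k]
            delta = step_now[c] * us[t]
            attempts[sweep, c] += 1
            dh, valid = core.delta_h(k, delta)
            if not valid:
                continue
            if dh <= 0.0 or coin[t] < np.exp(-dh):
                core.apply(k, delta, dh)
                accepts[sweep, c] += 1
        h_trace[sweep] = core.h
        step_trace[sweep] = step_now
        a = attempts[sweep]
        rate_trace[sweep] = np.where(a > 0, accepts[sweep] / np.maximum(a, 1), 0.0)

        in_equil = sweep < cfg.n_equil_sweeps
        if (sweep + 1) % cfg.adjust_every == 0:
            full = core.full_h()
            if not np.isclose(core.h, full, rtol=1e-6, atol=1e-8):
                logger.warning(
                    "incremental Hamiltonian drift at sweep %d (%.3g vs %.3g); "
                    "resynchronized", sweep, core.h, full,
                )
            core.resync()
            h_trace[sweep] = core.h
            if in_equil:
                lo = max(0, sweep + 1 - cfg.rate_window)
                att = attempts[lo : sweep + 1].sum(axis=0)
                acc = accepts[lo : sweep + 1].sum(axis=0)
                for c in range(n_classes):
                    r_i = acc[c] / att[c] if att[c] > 0 else 0.0
                    steps[c] = adjust_stepwidth(steps[c], r_i, cfg)
                step_now = np.array([s.s_current for s in steps])

        if not in_equil and (sweep + 1) == next_store_sweep:
            core.resync()  # guarantees stored H equals full recomputation
            samples[stored] = core.flat_params()
            hams[stored] = core.h
            stored += 1
            next_store_sweep += cfg.n_decorr_sweeps

    assert stored == cfg.n_accumulate
    n_sigma = (core.n_acc + 1) if (model == "mixed" and update_sigmas) else 0
    return Ensemble(
        samples=samples,
        hamiltonians=hams,
        model=model,
        n_beta=p,
        n_sigma=max(0, n_sigma - 1),
        traces={
            "hamiltonian": h_trace,
            "acceptance_rate": rate_trace,
            "stepwidth": step_trace,
        },
        config=cfg,
        accession_ids=acc_ids,
    )


# ---------------------------------------------------------------------------
# diagnostics


def diagnostics(e: Ensemble, slope_tol: float = 1e-3,
                out_prefix: str | None = None, plot: bool = False) -> dict:
    """Equilibration report from the run traces.

    Fits a least-squares line to the last quartile of the Hamiltonian trace;
    the run is flagged non-equilibrated when |slope| exceeds ``slope_tol``
    per sweep.  Optionally writes traces as TSV and a diagnostic figure.
    """
    h = np.asarray(e.traces["hamiltonian"], dtype=float)
    if h.size == 0:
        raise ValueError("empty trace")
    q = h[3 * len(h) // 4 :]
    x = np.arange(len(q), dtype=float)
    if len(q) >= 2:
        slope = float(np.polyfit(x, q, 1)[0])
    else:
        slope = 0.0
    report = {
        "h_slope_last_quartile": slope,
        "equilibrated": bool(abs(slope) <= slope_tol),
        "final_hamiltonian": float(h[-1]),
        "final_acceptance_rate": np.asarray(e.traces["acceptance_rate"])[-1].tolist(),
        "final_stepwidth": np.asarray(e.traces["stepwidth"])[-1].tolist(),
    }
    if out_prefix is not None:
        import pandas as pd

        rate = np.atleast_2d(np.asarray(e.traces["acceptance_rate"]))
        step = np.atleast_2d(np.asarray(e.traces["stepwidth"]))
        df = pd.DataFrame({"sweep": np.arange(len(h)), "hamiltonian": h})
        for c in range(rate.shape[1]):
            df[f"acc_rate_class{c}"] = rate[:, c]
            df[f"stepwidth_class{c}"] = step[:, c]
        df.to_csv(f"{out_prefix}_traces.tsv", sep="\t", index=False)
        if plot:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, axes = plt.subplots(3, 1, figsize=(8, 9), sharex=True)
            axes[0].plot(h)
            axes[0].set_ylabel("Hamiltonian")
            for c in range(rate.shape[1]):
                axes[1].plot(rate[:, c], label=f"class {c}")
                axes[2].plot(step[:, c], label=f"class {c}")
            axes[1].set_ylabel("acceptance rate")
            axes[2].set_ylabel("stepwidth")
            axes[2].set_yscale("log")
            axes[2].set_xlabel("sweep")
            axes[1].legend()
            fig.tight_layout()
            fig.savefig(f"{out_prefix}_traces.png", dpi=100)
            plt.close(fig)
    return report
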