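"""Synthetic genotypes, field panels and traits with the models' structure.

The generator emulates a highly selfing diploid panel: biallelic SNPs at a
mean spacing of 2–3 kb along chromosomes, per-accession genotypes with excess
homozygosity F = s/(2 - s) from the selfing rate (default 0.85), accessions
replicated in randomized blocks, and traits generated under the fixed-effects
or mixed linear model with a handful of causal chromosomal bins.

Effect sizes are specified in residual-standard-deviation units per causal
*column*: the true beta for causal bin j is e_j * sigma_resid / sd(X_j), so an
effect of 1.0 moves the trait by one residual sd per sd of bin dosage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from minegwas.genomatrix import (
    DesignMatrix,
    VariantTable,
    bin_variants,
    build_design_matrix,
    expand_to_plants,
    join_chromosomes,
)
from minegwas.models import TraitData, v_mixed, MixedParams


@dataclass
class SimConfig:
    """Study-condition knobs for the generator."""

    n_accessions: int = 60
    n_chrom: int = 2
    snps_per_chrom: int = 150
    mean_snp_spacing_bp: int = 2_500
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    selfing_rate: float = 0.85
    n_causal_bins: int = 10
    effect_sizes: list[float] | None = None   # residual-sd units; default 0.5–2.0
    sigma_acc_max: float = 0.5                # per-accession scale ~ U(0, max)*resid
    sigma_resid: float = 1.0
    replicates_per_accession: int = 2
    n_blocks: int = 3
    n_years: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_accessions", "n_chrom", "snps_per_chrom",
                     "mean_snp_spacing_bp", "replicates_per_accession",
                     "n_blocks", "n_years"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.selfing_rate <= 1.0):
            raise ValueError("selfing_rate must be in [0, 1]")
        if self.effect_sizes is None:
            self.effect_sizes = list(
                np.linspace(0.5, 2.0, self.n_causal_bins)
            )
        if len(self.effect_sizes) != self.n_causal_bins:
            raise ValueError("effect_sizes length must equal n_causal_bins")

    @property
    def inbreeding_coefficient(self) -> float:
        s = self.selfing_rate
        return s / (2.0 - s)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(cfg: SimConfig, rng=None,
                       vcf_path: str | None = None) -> VariantTable:
    """Draw a biallelic SNP table; optionally also write it as VCF 4.2.

    Genotype frequencies per SNP follow the inbreeding-adjusted law
    P(RR) = f^2 + F f(1-f), P(Rr) = 2 f (1-f)(1-F), P(rr) = (1-f)^2 + F f(1-f)
    with F = s/(2-s); SNPs are independent across sites.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_acc = cfg.n_accessions
    F = cfg.inbreeding_coefficient
    lo, hi = cfg.allele_freq_range

    chroms, positions = [], []
    for c in range(cfg.n_chrom):
        gaps = rng.integers(1, 2 * cfg.mean_snp_spacing_bp,
                            size=cfg.snps_per_chrom)
        pos = np.cumsum(gaps)
        chroms.extend([f"Chr{c + 1:02d}"] * cfg.snps_per_chrom)
        positions.extend(int(v) for v in pos)

    n_snps = len(positions)
    f = rng.uniform(lo, hi, size=n_snps)
    p_rr = f**2 + F * f * (1 - f)
    p_het = 2 * f * (1 - f) * (1 - F)
    u = rng.random((n_acc, n_snps))
    ref_count = np.where(u < p_rr, 2, np.where(u < p_rr + p_het, 1, 0)).astype(np.int8)

    vt = VariantTable(
        accession_ids=[f"ACC{i:04d}" for i in range(n_acc)],
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ref_count=ref_count,
        missing_mask=np.zeros((n_acc, n_snps), dtype=bool),
    )
    if vcf_path is not None:
        write_vcf(vt, vcf_path)
    return vt


_GT = {2: "0/0", 1: "0/1", 0: "1/1"}


def write_vcf(vt: VariantTable, path) -> None:
    """Write a VariantTable as a plain-text VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=minegwas-simgen\n")
        for c in vt.chromosomes:
            maxpos = int(vt.pos[vt.chrom == c].max())
            fh.write(f"##contig=<ID={c},length={maxpos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vt.accession_ids) + "\n"
        )
        for s in range(vt.n_snps):
            gts = [
                "./." if vt.missing_mask[i, s] else _GT[int(vt.ref_count[i, s])]
                for i in range(vt.n_accessions)
            ]
            fh.write(
                f"{vt.chrom[s]}\t{vt.pos[s]}\tsnp{s}\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def design_from_config(cfg: SimConfig, rng=None,
                       min_span_bp: int = 50_000) -> tuple[VariantTable, DesignMatrix]:
    """Genotypes -> bins -> accession-level design matrix, per chromosome then
    joined genome-wide."""
    vt = simulate_genotypes(cfg, rng=rng)
    bins = bin_variants(vt, min_span_bp=min_span_bp)
    dm = build_design_matrix(vt, bins)
    per_chrom = []
    for c in vt.chromosomes:
        cols = [j for j, b in enumerate(dm.bins) if b.chrom == c]
        per_chrom.append(
            DesignMatrix(dm.row_ids, [dm.bins[j] for j in cols],
                         dm.values[:, cols], dm.level)
        )
    return vt, join_chromosomes(per_chrom)


# ---------------------------------------------------------------------------
# field layout and traits


def field_layout(cfg: SimConfig, accession_ids: list[str], rng=None) -> pd.DataFrame:
    """Randomized-block plant table: each accession appears
    ``replicates_per_accession`` times in each of ``n_blocks`` blocks per year,
    order randomized within block."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    pid = 0
    for year in range(1, cfg.n_years + 1):
        for block in range(1, cfg.n_blocks + 1):
            accs = np.repeat(accession_ids, cfg.replicates_per_accession)
            rng.shuffle(accs)
            for a in accs:
                rows.append(
                    {"plant_id": f"P{pid:05d}", "accession_id": a,
                     "year": year, "block": block}
                )
                pid += 1
    return pd.DataFrame(rows)


def simulate_traits(cfg: SimConfig, X: DesignMatrix, model: str = "linear",
                    rng=None, layout: pd.DataFrame | None = None):
    """Generate a trait under Y = X beta + eps (linear) or with the
    mixed-model accession covariance added; returns (TraitData, truth dict).

    ``X`` is the accession-level design matrix; plants are laid out by
    :func:`field_layout` unless a layout table is passed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    if cfg.n_causal_bins > X.n_bins:
        raise ValueError("more causal bins requested than design columns")
    if layout is None:
        layout = field_layout(cfg, list(X.row_ids), rng=rng)
    plant_map = dict(zip(layout["plant_id"], layout["accession_id"]))
    Xp = expand_to_plants(X, plant_map)

    causal = np.sort(
        rng.choice(X.n_bins, size=cfg.n_causal_bins, replace=False)
    )
    beta = np.zeros(X.n_bins)
    col_sd = Xp.values[:, causal].std(axis=0, ddof=1)
    col_sd = np.where(col_sd > 0, col_sd, 1.0)
    beta[causal] = np.asarray(cfg.effect_sizes) * cfg.sigma_resid / col_sd

    n = Xp.n_rows
    mean = Xp.values @ beta
    y = mean + rng.normal(0.0, cfg.sigma_resid, size=n)
    truth = {
        "causal_bins": causal.tolist(),
        "causal_labels": [X.bins[j].label for j in causal],
        "beta": beta,
        "sigma_resid": cfg.sigma_resid,
        "model": model,
    }
    td_probe = TraitData(
        y=y, plant_ids=list(Xp.row_ids),
        accession_ids=[plant_map[p] for p in Xp.row_ids],
        year=layout.set_index("plant_id").loc[Xp.row_ids, "year"].to_numpy(),
        block=layout.set_index("plant_id").loc[Xp.row_ids, "block"].to_numpy(),
    )
    if model == "mixed":
        sigma_acc = rng.uniform(
            0.0, cfg.sigma_acc_max * cfg.sigma_resid,
            size=len(X.row_ids),
        )
        mp = MixedParams(beta=beta, sigma_acc=sigma_acc,
                         sigma_resid=cfg.sigma_resid)
        acc_idx = td_probe.accession_index()
        # accession order in TraitData follows first appearance; remap
        order = {a: i for i, a in enumerate(td_probe.accessions)}
        sig_in_order = np.empty_like(sigma_acc)
        for a, s in zip(X.row_ids, sigma_acc):
            sig_in_order[order[a]] = s
        mp = MixedParams(beta=beta, sigma_acc=sig_in_order,
                         sigma_resid=cfg.sigma_resid)
        V = v_mixed(mp, Xp.values, acc_idx)
        L = np.linalg.cholesky(V.dense())
        y = Xp.values @ beta + L @ rng.standard_normal(n)
        td_probe.y = y
        truth["sigma_acc"] = sig_in_order
    elif model != "linear":
        raise ValueError(f"unknown model {model!r}")
    return td_probe, truth


# ---------------------------------------------------------------------------
# power / false-positive-rate study


def power_fpr_study(cfg: SimConfig, n_replicates: int = 10,
                    pipeline=None, mcmc_cfg=None, alpha: float = 0.05,
                    level: float = 0.95, seed: int | None = None) -> pd.DataFrame:
    """Repeated simulate-fit-filter rounds: per replicate the trait is drawn
    fresh on a fixed design matrix, the linear-model ensemble is fitted, the
    Bayesian-interval and BH filters are applied, and survivors are compared
    to the true causal bins.

    power = detected causal bins / n_causal; FPR = non-causal survivors /
    non-causal bins.  ``pipeline(X, td, rep_seed) -> kept mask`` may replace
    the default fit+filter stage.
    """
    from minegwas.mcmc import McmcConfig, run_chain
    from minegwas.featselect import bayesian_interval, benjamini_hochberg

    if seed is None:
        seed = cfg.seed
    master = np.random.default_rng(seed)
    _, X = design_from_config(cfg, rng=np.random.default_rng(seed))

    if mcmc_cfg is None:
        mcmc_cfg = McmcConfig(
            n_equil_sweeps=1_500, n_decorr_sweeps=10, n_accumulate=300,
            adjust_every=100, rate_window=100, seed=seed,
        )

    def default_pipeline(X, td, rep_seed):
        cfg_r = McmcConfig(**{**mcmc_cfg.__dict__, "seed": rep_seed})
        Xp = expand_to_plants(X, dict(zip(td.plant_ids, td.accession_ids)))
        e = run_chain("linear", Xp, td, cfg_r)
        kept_b = bayesian_interval(e, level=level)
        kept_bh, _, _ = benjamini_hochberg(e, alpha=alpha)
        return kept_b & kept_bh

    if pipeline is None:
        pipeline = default_pipeline

    rows = []
    for rep in range(n_replicates):
        rep_seed = int(master.integers(2**31 - 1))
        rng = np.random.default_rng(rep_seed)
        td, truth = simulate_traits(cfg, X, model="linear", rng=rng)
        kept = pipeline(X, td, rep_seed)
        causal = np.zeros(X.n_bins, dtype=bool)
        causal[truth["causal_bins"]] = True
        n_causal = int(causal.sum())
        detected = int((kept & causal).sum())
        false_pos = int((kept & ~causal).sum())
        n_null = int((~causal).sum())
        rows.append({
            "replicate": rep,
            "seed": rep_seed,
            "power": detected / n_causal if n_causal else np.nan,
            "fpr": false_pos / n_null if n_null else np.nan,
            "n_detected": detected,
            "n_false_pos": false_pos,
            "n_kept": int(kept.sum()),
        })
    return pd.DataFrame(rows)
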