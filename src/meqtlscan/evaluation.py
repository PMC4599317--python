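"""Simulation studies of the scan's statistical operating characteristics.

Each study generates cohorts with the synthetic generator, runs the full
scan machinery, and measures calibration (type-I error, p-value
uniformity), false-discovery control at the q-value threshold, effect-size
recovery (confidence-interval coverage and bias), and how well the two-PC
surrogate tracks the true simulated cell composition.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .preprocess import beta_to_m, cell_surrogate
from .scan import CisMeQTLScanner
from .simulate import blood_config, simulate_dataset

__all__ = [
    "null_calibration",
    "fdr_study",
    "recovery_study",
    "surrogate_recovery",
]


def _scan_dataset(dataset, q_threshold: float = 0.05):
    cfg = dataset.config
    m = beta_to_m(dataset.beta)
    surrogate = cell_surrogate(m, cfg.reference_probe_ids)
    manifest = cfg.probe_manifest()
    manifest = manifest[~manifest["probe_id"].isin(cfg.reference_probe_ids)]
    scanner = CisMeQTLScanner(q_threshold=q_threshold)
    scanner.fit(
        m, dataset.genotypes, covariates=dataset.covariates, surrogate=surrogate,
        snp_manifest=cfg.snp_manifest(), probe_manifest=manifest,
    )
    return scanner


def null_calibration(n_pairs: int = 2000, n_samples: int = 350,
                     seed: int = 0) -> dict:
    """Type-I error and p-value uniformity on an all-null scan.

    No effects are planted, so every raw LRT p-value is a null draw; the
    study reports the fraction below 0.05 (with its binomial Monte-Carlo
    standard error) and a Kolmogorov-Smirnov test against U(0, 1).
    """
    probes_per_snp = 100
    n_snps = int(np.ceil(n_pairs / probes_per_snp))
    cfg = blood_config(n_samples=n_samples, n_snps=n_snps,
                       probes_per_snp=probes_per_snp, seed=seed)
    dataset = simulate_dataset(cfg, annotation=False)
    scanner = _scan_dataset(dataset)
    p = scanner.results_["p"].to_numpy()[:n_pairs]
    frac = float((p < 0.05).mean())
    return {
        "n_pairs": int(p.size),
        "frac_p_lt_05": frac,
        "mc_se": float(np.sqrt(0.05 * 0.95 / p.size)),
        "ks_p": float(stats.kstest(p, "uniform").pvalue),
        "p_values": p,
    }


def fdr_study(n_replicates: int = 50, n_true: int = 10, n_pairs: int = 50,
              delta: float = 1.0, n_samples: int = 350, maf: float = 0.3,
              noise_sd: float = 0.5, q_threshold: float = 0.05,
              seed: int = 0) -> dict:
    """Realized false-discovery proportion and power of the q < threshold rule.

    Each replicate scans ``n_pairs`` SNP-CpG pairs of which ``n_true`` carry
    a planted effect of ``delta`` M units per allele; the FDP (false
    discoveries over all discoveries, 0 when none) is averaged over
    replicates.
    """
    probes_per_snp = n_pairs // 5
    effects = {(i, j): delta for i in range(5) for j in range(n_true // 5)}
    fdps, detected = [], []
    for rep in range(n_replicates):
        cfg = blood_config(
            n_samples=n_samples, n_snps=5, probes_per_snp=probes_per_snp,
            effects=effects, noise_sd=noise_sd, maf_range=(maf, maf),
            seed=seed + rep,
        )
        dataset = simulate_dataset(cfg, annotation=False)
        scanner = _scan_dataset(dataset, q_threshold)
        truth = set(dataset.truth.true_effects)
        called = set(map(tuple, scanner.significant_[["snp_id", "probe_id"]].to_numpy()))
        false = len(called - truth)
        fdps.append(false / len(called) if called else 0.0)
        detected.append(len(called & truth) / len(truth))
    fdps = np.asarray(fdps)
    return {
        "n_replicates": n_replicates,
        "mean_fdp": float(fdps.mean()),
        "fdp_mc_se": float(fdps.std(ddof=1) / np.sqrt(n_replicates)),
        "mean_detection_rate": float(np.mean(detected)),
        "all_true_detected": bool(np.all(np.asarray(detected) == 1.0)),
    }


def recovery_study(n_replicates: int = 100, delta: float = 0.5,
                   n_samples: int = 350, maf: float = 0.3,
                   noise_sd: float = 0.5, seed: int = 0) -> dict:
    """Coverage of the planted effect by each fit's 95 % confidence interval,
    and the mean bias of the genotype coefficient."""
    covered, estimates = [], []
    for rep in range(n_replicates):
        cfg = blood_config(
            n_samples=n_samples, n_snps=1, probes_per_snp=1,
            effects={(0, 0): delta}, noise_sd=noise_sd,
            maf_range=(maf, maf), seed=seed + rep,
        )
        dataset = simulate_dataset(cfg, annotation=False)
        scanner = _scan_dataset(dataset)
        row = scanner.results_.iloc[0]
        tcrit = stats.t.ppf(0.975, int(row["n_used"]) - 7)
        lo = row["coef"] - tcrit * row["coef_se"]
        hi = row["coef"] + tcrit * row["coef_se"]
        covered.append(lo <= delta <= hi)
        estimates.append(row["coef"])
    return {
        "n_replicates": n_replicates,
        "coverage": float(np.mean(covered)),
        "mean_bias": float(np.mean(estimates) - delta),
    }


def surrogate_recovery(n_samples: int = 350, seed: int = 0) -> dict:
    """First canonical correlation between the two surrogate PCs and the true
    cell-composition matrix, plus the panel variance the PCs explain."""
    from sklearn.cross_decomposition import CCA

    cfg = blood_config(n_samples=n_samples, n_snps=2, probes_per_snp=20, seed=seed)
    dataset = simulate_dataset(cfg, annotation=False)
    m = beta_to_m(dataset.beta)
    surrogate = cell_surrogate(m, cfg.reference_probe_ids)
    X = surrogate.frame().to_numpy()
    Y = dataset.truth.true_compositions.to_numpy()
    U, V = CCA(n_components=2).fit_transform(X, Y)
    first_cc = float(np.corrcoef(U[:, 0], V[:, 0])[0, 1])
    return {
        "n_samples": n_samples,
        "first_canonical_correlation": first_cc,
        "variance_explained_top2": float(surrogate.variance_explained.sum()),
    }
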