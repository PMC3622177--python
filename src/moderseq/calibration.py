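"""Operating characteristics of the moderated DE test on synthetic data.

The deposited study data are not public, so the DE core is validated by
its statistical behaviour instead: type-I error on null simulations,
realized false-discovery proportion and sensitivity with spiked-in DE
genes, and recovery of the prior degrees of freedom from a hierarchical
variance simulation.  Simulations use 5,000-gene replicates (10,000 for
the prior-df recovery), sized so the whole battery runs in well under a
minute on one core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .de_moderated import LogExpression, de_test, fit_variance_model
from .synthetic_data import CountSimConfig, simulate_counts, substream


def null_type1_error(n_seeds: int = 20, n_genes: int = 5000, base_seed: int = 0,
                     reference: str = "t", alpha: float = 0.05) -> np.ndarray:
    """Fraction of null genes with p < alpha, per seeded replicate."""
    rates = []
    for i in range(n_seeds):
        cfg = CountSimConfig(n_genes=n_genes, pi_de=0.0, seed=base_seed + i)
        expr, _ = simulate_counts(cfg)
        res = de_test(expr, reference=reference)
        rates.append(float(np.mean(res["p"] < alpha)))
    return np.asarray(rates)


def fdp_and_sensitivity(n_seeds: int = 20, n_genes: int = 5000,
                        base_seed: int = 0, pi_de: float = 0.02,
                        lfc_dist: tuple[float, float] = (2.0, 0.5),
                        reference: str = "t",
                        min_lfc: float = 2.0, min_mean: float = 100.0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Realized FDP among calls and sensitivity for strong true DE genes.

    Strong genes are those with true |log2fc| >= ``min_lfc`` and true mean
    count >= ``min_mean`` (averaged over conditions).
    """
    fdps, sens = [], []
    for i in range(n_seeds):
        cfg = CountSimConfig(n_genes=n_genes, pi_de=pi_de, lfc_dist=lfc_dist,
                             seed=base_seed + i)
        expr, truth = simulate_counts(cfg)
        res = de_test(expr, reference=reference)
        called = (res["call"] != "ns").to_numpy()
        is_de = truth["is_de"].to_numpy()
        fdps.append(float(np.mean(~is_de[called])) if called.any() else 0.0)
        strong = (is_de & (np.abs(truth["true_lfc"]) >= min_lfc)
                  & (truth["true_mean"] >= min_mean)).to_numpy()
        if strong.any():
            sens.append(float(np.mean(called[strong])))
    return np.asarray(fdps), np.asarray(sens)


def d0_recovery(n_genes: int = 10_000, true_d0: float = 4.0,
                s0_sq: float = 0.05, d_g: float = 2.0, seed: int = 0) -> float:
    """Estimate d0 from a flat-trend hierarchical variance simulation.

    s_g^2 ~ sigma_g^2 chi2_{d_g}/d_g with 1/sigma_g^2 ~ chi2_{d0}/(d0 s0^2);
    a well-behaved estimator should recover d0 from the excess spread of
    log sample variances.
    """
    rng = substream(seed, "d0-recovery")
    sigma_sq = s0_sq * true_d0 / rng.chisquare(true_d0, n_genes)
    s2 = sigma_sq * rng.chisquare(d_g, n_genes) / d_g
    x = pd.DataFrame(np.zeros((n_genes, 4)), columns=["a1", "a2", "b1", "b2"])
    le = LogExpression(x, pd.Series(rng.uniform(0.0, 10.0, n_genes)),
                       pd.Series(["c1", "c1", "c2", "c2"], index=x.columns), 0.25)
    return fit_variance_model(le, s2, d_g).d0
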