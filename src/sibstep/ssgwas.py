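"""Single-step GWAS: SNP effects back-solved from genomic breeding values.

Given GEBVs u for the genotyped animals and the genomic relationship
G = Z Z' / d with d = sum 2 p (1 - p), the SNP-effect vector is

    a = Z' G^-1 u / d

which reproduces u exactly (Z a = u) when G is unblended.  Per-SNP
sampling variances propagate the prediction-error covariance of u through
this linear map, giving z-scores and two-sided normal p-values.  SNPs
significant in every cross-validation run (p < 1e-5 by default) form the
pre-selected panel that is fed back into ssGBLUP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .genomic import GenotypeMatrix, allele_frequencies, centred_scores

__all__ = [
    "GWASResult",
    "backsolve_snp_effects",
    "snp_pvalues",
    "snp_effect_variances",
    "gwas_scan",
    "preselect_snps",
    "refit_with_panel",
]


@dataclass
class GWASResult:
    """Per-SNP effects and significance for one evaluation run."""

    table: pd.DataFrame  # snp_id, effect, se, z, p
    run: int = 0

    def significant(self, threshold: float = 1e-5) -> np.ndarray:
        t = self.table
        return t.loc[t["p"] < threshold, "snp_id"].to_numpy()


def backsolve_snp_effects(
    u_geno: np.ndarray, G: np.ndarray, Z_centred: np.ndarray, denom: float
) -> np.ndarray:
    """a = Z' G^-1 u / d.

    ``G`` is the (possibly blended) genomic relationship among the same
    animals ``Z_centred`` is built from; monomorphic SNPs enter with an
    all-zero centred column and get effect 0.
    """
    u_geno = np.asarray(u_geno, float)
    if Z_centred.shape[0] != len(u_geno) or G.shape != (len(u_geno),) * 2:
        raise ValueError("dimension mismatch between u, G and Z")
    Ginv_u = linalg.solve(G, u_geno, assume_a="pos")
    return (Z_centred.T @ Ginv_u) / denom


def snp_effect_variances(
    G: np.ndarray,
    Z_centred: np.ndarray,
    denom: float,
    pev: np.ndarray,
    sigma_g: float,
) -> np.ndarray:
    """Sampling variance of each back-solved SNP effect.

    var(a_hat) propagates var(u_hat) = sigma_g G - PEV through the linear
    map T = Z' G^-1 / d, i.e. var(a_i) = t_i' (sigma_g G - PEV) t_i.
    Non-positive values (numerical, or blended-G artefacts) are flagged by
    returning 0.
    """
    B = linalg.solve(G, Z_centred, assume_a="pos")  # columns: G^-1 z_i
    S = sigma_g * G - pev
    S = (S + S.T) / 2.0
    v = np.einsum("ij,ij->j", B, S @ B) / denom**2
    return np.maximum(v, 0.0)


def snp_pvalues(effects: np.ndarray, variances: np.ndarray) -> pd.DataFrame:
    """Two-sided normal p-values; zero-variance SNPs get p = 1, flagged."""
    effects = np.asarray(effects, float)
    se = np.sqrt(variances)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, effects / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    flagged = se <= 0
    p[flagged] = 1.0
    return pd.DataFrame({"effect": effects, "se": se, "z": z, "p": p, "flagged": flagged})


def gwas_scan(
    panel: GenotypeMatrix,
    u_geno: np.ndarray,
    G_star: np.ndarray,
    pev: np.ndarray,
    sigma_g: float,
    run: int = 0,
) -> GWASResult:
    """Full back-solve + p-value pass over a genotyped panel.

    Monomorphic SNPs are carried with effect 0 and p = 1 so the output is
    positionally aligned with the panel.
    """
    p_freq = allele_frequencies(panel)
    Z, keep, denom = centred_scores(panel, p_freq)
    eff_k = backsolve_snp_effects(u_geno, G_star, Z, denom)
    var_k = snp_effect_variances(G_star, Z, denom, pev, sigma_g)
    tab_k = snp_pvalues(eff_k, var_k)

    m = panel.n_snps
    out = pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "effect": np.zeros(m),
            "se": np.zeros(m),
            "z": np.zeros(m),
            "p": np.ones(m),
            "flagged": ~keep,
        }
    )
    out.loc[keep, ["effect", "se", "z", "p", "flagged"]] = tab_k.to_numpy()
    return GWASResult(out, run=run)


def preselect_snps(
    run_pvalues: list[pd.Series | dict],
    threshold: float = 1e-5,
    rule: str = "intersection",
) -> np.ndarray:
    """SNPs significant across cross-validation runs.

    ``rule='intersection'`` (default) keeps a SNP only if p < threshold in
    every supplied run; ``'union'`` keeps SNPs significant in any run.
    Returns sorted SNP ids.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    sets = []
    for run in run_pvalues:
        s = pd.Series(run)
        sets.append(set(s.index[s < threshold]))
    if not sets:
        return np.asarray([], dtype=object)
    if rule == "intersection":
        sel = set.intersection(*sets)
    elif rule == "union":
        sel = set.union(*sets)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return np.asarray(sorted(sel), dtype=object)


def refit_with_panel(
    selected_ids,
    panel: GenotypeMatrix,
    data: pd.DataFrame,
    ped,
    spec,
    varcomp,
    fold_plan,
    h2: float | None = None,
    tau: float = 0.95,
    omega: float = 0.05,
):
    """Re-run the ssGBLUP evaluation protocol on a reduced SNP panel.

    An empty selection falls back to the full panel with a warning.  The
    returned CVResult is labelled ``ssGWAS``.
    """
    import warnings

    from .evaluation import cross_validate
    from .mixed_model import make_kinship_inverse

    selected_ids = np.asarray(selected_ids, dtype=object)
    if len(selected_ids) == 0:
        warnings.warn("empty SNP selection: falling back to the full panel")
        sub = panel
    else:
        sub = panel.subset_snps(selected_ids)
    K_inv, logdet_K, _ = make_kinship_inverse(ped, sub, "H", tau=tau, omega=omega)
    res = cross_validate(data, ped, K_inv, logdet_K, spec, varcomp, fold_plan, h2=h2)
    res.label = dict(res.label, method="ssGWAS")
    return res
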