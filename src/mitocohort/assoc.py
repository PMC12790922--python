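"""mtDNA-nDNA association scan.

Per-sample heteroplasmic levels (VAF, 0 for non-carriers) of common
mtDNA variants are the continuous phenotype; nuclear genotype dosages
(0/1/2) are the exposure. Nuclear variants pass sample/variant call
rate >= 0.9, MAF > 5% and Hardy-Weinberg exact p >= 1e-6 filters; the
scan is ordinary least squares of phenotype on dosage with the top
genotype principal components and sex as covariates, a two-sided Wald
t-test on the dosage coefficient and Benjamini-Hochberg q-values within
each per-mtDNA-variant scan. Significance follows two thresholds
divided by the number of mtDNA phenotypes tested: q < 0.05/n_mt
(primary, as published; a Bonferroni-on-p switch is provided) and
p < 5e-8/n_mt (stringent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mitocohort.mt_variants import MtVariantCall


@dataclass
class GenotypeMatrix:
    """Dosage matrix, samples x variants; missing entries are NaN."""

    samples: list[str]
    variant_ids: list[str]
    dosages: np.ndarray  # float array (n_samples, n_variants), values 0/1/2/NaN

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variant_ids)):
            raise ValueError("dosage matrix shape does not match labels")


@dataclass(frozen=True)
class AssociationResult:
    mt_variant: str
    ndna_variant: str
    beta: float
    se: float
    t_stat: float
    p_value: float
    q_value: float
    significant_primary: bool
    significant_stringent: bool


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test (no mid-p correction).

    Sums the probabilities of all heterozygote counts, conditional on
    the observed allele counts, that are no more probable than the
    observed one. Log-gamma arithmetic keeps it exact to double
    precision for cohort-scale counts.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0:
            raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_Aa  # minor-allele copies (labelling is symmetric)
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0
    hets = range(rare % 2, rare + 1, 2)  # parity fixed by allele count

    def logp(h: int) -> float:
        # P(het = h | allele counts) up to a shared constant
        hom_r = (rare - h) // 2
        hom_c = (2 * n - rare - h) // 2
        return (
            h * math.log(2)
            - math.lgamma(h + 1)
            - math.lgamma(hom_r + 1)
            - math.lgamma(hom_c + 1)
        )

    lps = np.array([logp(h) for h in hets])
    lps -= lps.max()
    probs = np.exp(lps)
    probs /= probs.sum()
    p_obs = probs[list(hets).index(n_Aa)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def filter_genotypes(
    gmat: GenotypeMatrix,
    min_variant_call_rate: float = 0.9,
    min_sample_call_rate: float = 0.9,
    min_maf: float = 0.05,
    min_hwe_p: float = 1e-6,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Sample call-rate filter first, then per-variant call rate, MAF
    (on non-missing dosages) and HWE exact-test filters. Returns the
    filtered matrix and a drop log (id, axis, reason)."""
    d = gmat.dosages
    drops: list[tuple[str, str, str]] = []

    sample_cr = 1 - np.isnan(d).mean(axis=1)
    keep_s = sample_cr > min_sample_call_rate
    for s, ok in zip(gmat.samples, keep_s):
        if not ok:
            drops.append((s, "sample", "call_rate"))
    if not keep_s.any():
        raise ValueError("all samples dropped by call-rate filter")
    d = d[keep_s]
    samples = [s for s, ok in zip(gmat.samples, keep_s) if ok]

    keep_v = np.ones(d.shape[1], dtype=bool)
    for j, vid in enumerate(gmat.variant_ids):
        col = d[:, j]
        obs = col[~np.isnan(col)]
        if obs.size / d.shape[0] <= min_variant_call_rate:
            drops.append((vid, "variant", "call_rate"))
            keep_v[j] = False
            continue
        af = obs.mean() / 2 if obs.size else 0.0
        maf = min(af, 1 - af)
        if maf <= min_maf:
            drops.append((vid, "variant", "maf"))
            keep_v[j] = False
            continue
        n_aa = int((obs == 2).sum())
        n_Aa = int((obs == 1).sum())
        n_AA = int((obs == 0).sum())
        if hwe_exact_p(n_AA, n_Aa, n_aa) < min_hwe_p:
            drops.append((vid, "variant", "hwe"))
            keep_v[j] = False

    out = GenotypeMatrix(
        samples=samples,
        variant_ids=[v for v, ok in zip(gmat.variant_ids, keep_v) if ok],
        dosages=d[:, keep_v],
    )
    log = pd.DataFrame(drops, columns=["id", "axis", "reason"])
    return out, log


def select_mt_phenotypes(
    calls: Sequence[MtVariantCall],
    samples: Sequence[str],
    min_freq: float = 0.05,
) -> pd.DataFrame:
    """Phenotype vectors for common mtDNA variants.

    One column per mtDNA variant carried by >= ``min_freq`` of
    ``samples`` (the unrelated set, supplied externally); entries are
    the per-sample heteroplasmic level (VAF), 0.0 for non-carriers.
    """
    sset = {s: i for i, s in enumerate(samples)}
    by_var: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for c in calls:
        if c.sample_id not in sset:
            continue
        vid = f"m.{c.pos}{c.ref}>{c.alt}"
        if vid not in by_var:
            by_var[vid] = np.zeros(len(samples))
            counts[vid] = 0
        by_var[vid][sset[c.sample_id]] = c.vaf
        counts[vid] += 1
    keep = {v: col for v, col in by_var.items() if counts[v] / len(samples) >= min_freq}
    return pd.DataFrame(keep, index=list(samples))


def genotype_pca(gmat: GenotypeMatrix, k: int = 12) -> np.ndarray:
    """Top-k principal-component scores of the dosage matrix.

    Missing dosages are mean-imputed for the PCA only; columns are
    standardized; each component's sign is fixed so its largest-
    magnitude loading is positive.
    """
    d = gmat.dosages.copy()
    col_mean = np.nanmean(d, axis=0)
    nan_idx = np.where(np.isnan(d))
    d[nan_idx] = np.take(col_mean, nan_idx[1])
    d -= d.mean(axis=0)
    sd = d.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance variant column; filter before PCA")
    d /= sd
    if k == 0:
        return np.empty((d.shape[0], 0))
    u, s, vt = np.linalg.svd(d, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    scores = u[:, :k] * s[:k]
    for j in range(k):
        if vt[j, np.argmax(np.abs(vt[j]))] < 0:
            scores[:, j] *= -1
    return scores


def significance_thresholds(
    alpha: float = 0.05, gw: float = 5e-8, n_mt: int = 93
) -> tuple[float, float]:
    """(primary, stringent) thresholds: alpha/n_mt and gw/n_mt."""
    if n_mt < 1:
        raise ValueError("n_mt must be >= 1")
    return alpha / n_mt, gw / n_mt


def glm_scan(
    phenotype: np.ndarray,
    gmat: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    mt_variant: str = "mt_phenotype",
    n_mt: int = 93,
    alpha: float = 0.05,
    gw: float = 5e-8,
    bonferroni_on_p: bool = False,
) -> list[AssociationResult]:
    """Per-nuclear-variant OLS of phenotype on dosage + covariates.

    Covariates (typically PC1..PC12 and sex) and an intercept are
    residualized out of both phenotype and dosages, which makes the
    per-variant slope, its standard error (df = n - n_covariates - 2)
    and Wald t identical to the full-design OLS fit, at a fraction of
    the cost. Missing dosages are mean-imputed per variant. Variants
    collinear with the covariates (or constant) yield NaN results
    flagged rather than dropped; BH q-values are computed over the
    valid tests of this scan.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if covariates is None:
        covariates = np.empty((n, 0))
    X = np.column_stack([np.ones(n), covariates])
    q_cov = np.linalg.matrix_rank(X)
    if q_cov < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    qmat, _ = np.linalg.qr(X)
    resid = lambda v: v - qmat @ (qmat.T @ v)

    y_r = resid(y)
    d = gmat.dosages.copy()
    col_mean = np.nanmean(d, axis=0)
    nan_idx = np.where(np.isnan(d))
    d[nan_idx] = np.take(col_mean, nan_idx[1])
    d_r = d - qmat @ (qmat.T @ d)

    ss_d = (d_r**2).sum(axis=0)
    df = n - X.shape[1] - 1
    if df < 1:
        raise ValueError("not enough samples for the design")
    valid = ss_d > 1e-10 * n

    beta = np.full(d.shape[1], np.nan)
    se = np.full(d.shape[1], np.nan)
    beta[valid] = (d_r[:, valid] * y_r[:, None]).sum(axis=0) / ss_d[valid]
    rss = (y_r**2).sum() - beta[valid] ** 2 * ss_d[valid]
    rss = np.maximum(rss, 0.0)
    se[valid] = np.sqrt(rss / df / ss_d[valid])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)

    q = np.full_like(p, np.nan)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]

    thr_primary, thr_stringent = significance_thresholds(alpha, gw, n_mt)
    out = []
    for j, vid in enumerate(gmat.variant_ids):
        stat_primary = p[j] if bonferroni_on_p else q[j]
        out.append(
            AssociationResult(
                mt_variant=mt_variant,
                ndna_variant=vid,
                beta=float(beta[j]),
                se=float(se[j]),
                t_stat=float(t[j]),
                p_value=float(p[j]),
                q_value=float(q[j]),
                significant_primary=bool(
                    valid[j] and not np.isnan(stat_primary) and stat_primary < thr_primary
                ),
                significant_stringent=bool(valid[j] and p[j] < thr_stringent),
            )
        )
    return out
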