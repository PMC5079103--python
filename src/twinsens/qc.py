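"""Per-SNP quality control and ancestry principal components.

QC filters each variant on call rate, minor-allele frequency (computed
from called genotypes only) and the Hardy-Weinberg exact test.
Monomorphic variants get HWE p = 1 (a single attainable configuration)
and are instead removed by the MAF criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.linalg import svds

from .config import QcThresholds
from .genotypes import GenotypeDataset


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (no mid-p correction).  Symmetric in the two homozygote counts.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("all genotype counts are zero")

    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0  # monomorphic: only one configuration exists

    # heterozygote count shares parity with the rare-allele count
    het_values = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # unnormalized log-probabilities of each attainable het count
    log_probs = np.empty(len(het_values), dtype=float)
    from scipy.special import gammaln

    for idx, het in enumerate(het_values):
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        log_probs[idx] = (
            het * np.log(2.0)
            - gammaln(hom_r + 1) - gammaln(het + 1) - gammaln(hom_c + 1)
        )
    log_probs -= log_probs.max()
    probs = np.exp(log_probs)
    probs /= probs.sum()

    obs = n_het
    p_obs = probs[het_values == obs][0]
    # tolerance guards ties against floating-point noise
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


@dataclass
class QcReport:
    """Per-variant QC statistics and pass/fail reasons."""

    table: pd.DataFrame  # variant_id, call_rate, maf, hwe_p, passed, reasons


def snp_qc(
    dataset: GenotypeDataset, thresholds: QcThresholds
) -> tuple[GenotypeDataset, QcReport]:
    """Filter variants on call rate, MAF and HWE exact p.

    Retains exactly the variants with call rate >= ``min_call_rate``,
    MAF >= ``min_maf`` and HWE p >= ``min_hwe_p``.
    """
    if dataset.n_variants == 0:
        raise ValueError("dataset has no variants")
    thresholds.validate()

    call_rate = dataset.call_rate()
    maf = dataset.minor_allele_frequency()
    hwe_p = np.empty(dataset.n_variants)
    for j in range(dataset.n_variants):
        counts = dataset.genotype_counts(j)
        hwe_p[j] = hwe_exact_test(*counts) if sum(counts) > 0 else 1.0
    maf = np.where(np.isnan(maf), 0.0, maf)

    reasons = []
    passed = np.ones(dataset.n_variants, dtype=bool)
    for j in range(dataset.n_variants):
        why = []
        if call_rate[j] < thresholds.min_call_rate:
            why.append("call_rate")
        if maf[j] < thresholds.min_maf:
            why.append("maf")
        if hwe_p[j] < thresholds.min_hwe_p:
            why.append("hwe")
        passed[j] = not why
        reasons.append(",".join(why))

    report = QcReport(table=pd.DataFrame({
        "variant_id": dataset.variants["variant_id"],
        "call_rate": call_rate,
        "maf": maf,
        "hwe_p": hwe_p,
        "passed": passed,
        "reasons": reasons,
    }))
    return dataset.subset_variants(np.flatnonzero(passed)), report


@dataclass
class PcMatrix:
    """Principal-component scores with explained-variance fractions."""

    scores: np.ndarray  # (n_samples, k)
    explained_variance_ratio: np.ndarray
    samples: list[str]

    def as_frame(self) -> pd.DataFrame:
        k = self.scores.shape[1]
        return pd.DataFrame(
            self.scores, index=self.samples,
            columns=[f"pc{i + 1}" for i in range(k)],
        )


def compute_pcs(dataset: GenotypeDataset, k: int) -> PcMatrix:
    """Top-``k`` principal components of the standardized dosage matrix.

    Missing dosages are imputed to the per-variant mean before
    standardization; zero-variance variants contribute nothing.
    Components are ordered by explained variance.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = dataset.dosage.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X -= col_mean
    sd = X.std(axis=0, ddof=0)
    nz = sd > 0
    X[:, nz] /= sd[nz]
    X[:, ~nz] = 0.0

    max_rank = min(dataset.n_samples, dataset.n_variants)
    if k > max_rank:
        raise ValueError(f"k={k} exceeds max rank {max_rank}")

    if k < max_rank - 1 and max_rank > 20:
        U, S, _ = svds(X, k=k, random_state=0)
        order = np.argsort(S)[::-1]
        U, S = U[:, order], S[order]
    else:
        U, S, _ = np.linalg.svd(X, full_matrices=False)
        U, S = U[:, :k], S[:k]

    total_var = float(np.sum(X**2))
    evr = (S**2) / total_var if total_var > 0 else np.zeros(k)
    return PcMatrix(scores=U * S, explained_variance_ratio=evr,
                    samples=list(dataset.samples))
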