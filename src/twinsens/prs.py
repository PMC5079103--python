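"""Clumping + thresholding polygenic environmental-sensitivity scores.

Index SNPs are chosen greedily by ascending discovery p-value; variants on
the same chromosome within ``window_kb`` of an index and with dosage
r^2 above the cutoff are removed.  Scores at each p-value threshold are
effect-size-weighted effect-allele counts over the retained SNPs, with
missing dosages imputed to twice the effect-allele frequency, then
standardized column-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ClumpParameters, validate_thresholds
from .genotypes import GenotypeDataset

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def pairwise_r2(dataset: GenotypeDataset, i: int, j: int) -> float:
    """Squared Pearson correlation of dosages over jointly called samples."""
    gi, gj = dataset.dosage[:, i], dataset.dosage[:, j]
    ok = ~(np.isnan(gi) | np.isnan(gj))
    gi, gj = gi[ok], gj[ok]
    if len(gi) < 2 or np.ptp(gi) == 0 or np.ptp(gj) == 0:
        raise ValueError(
            f"zero-variance variant in r2({i},{j}) over complete cases")
    r = np.corrcoef(gi, gj)[0, 1]
    return float(r * r)


def clump_variants(
    sumstats: pd.DataFrame,
    reference: GenotypeDataset,
    params: ClumpParameters | None = None,
) -> list[str]:
    """Greedy p-value-informed LD clumping; returns retained variant ids.

    Ties on p are broken by smaller genomic position, then lexicographic
    id, for determinism.  Summary-statistic variants absent from the
    reference are excluded with a warning.
    """
    params = (params or ClumpParameters()).validate()
    idx = reference.variant_index()

    ss = sumstats.dropna(subset=[params.p_field]).copy()
    absent = [v for v in ss["variant_id"] if v not in idx]
    if absent:
        warnings.warn(
            f"{len(absent)} sumstat variants absent from reference; excluded")
        ss = ss[ss["variant_id"].isin(idx)]

    ss = ss.sort_values(
        [params.p_field, "position", "variant_id"],
        kind="mergesort").reset_index(drop=True)

    chrom = ss["chromosome"].astype(str).to_numpy()
    pos = ss["position"].to_numpy(dtype=float)
    vids = ss["variant_id"].to_numpy()
    cols = np.array([idx[v] for v in vids])
    window_bp = params.window_kb * 1000.0

    # pre-standardized dosage matrix for fast r^2 (mean-imputed missing)
    G = reference.dosage[:, cols].copy()
    mu = np.nanmean(G, axis=0)
    nan_mask = np.isnan(G)
    G[nan_mask] = np.take(mu, np.nonzero(nan_mask)[1])
    G -= G.mean(axis=0)
    sd = G.std(axis=0)
    pos_sd = sd > 0
    G[:, pos_sd] /= sd[pos_sd]
    nS = G.shape[0]

    alive = np.ones(len(ss), dtype=bool)
    retained: list[str] = []
    for k in range(len(ss)):
        if not alive[k]:
            continue
        retained.append(vids[k])
        alive[k] = False
        near = alive & (chrom == chrom[k]) & (np.abs(pos - pos[k]) <= window_bp)
        if near.any() and pos_sd[k]:
            r = (G[:, near].T @ G[:, k]) / nS
            kill = np.zeros(len(ss), dtype=bool)
            kill[np.flatnonzero(near)] = (r * r) > params.r2_threshold
            alive &= ~kill
    return retained


@dataclass
class ScoreMatrix:
    """Per-individual polygenic scores at each p-value threshold.

    ``scores`` columns are labelled by the threshold cutoffs themselves
    and are standardized (mean 0, SD 1); ``raw_means``/``raw_sds`` keep
    the back-transformation, ``snp_counts`` the SNPs per threshold.
    """

    scores: pd.DataFrame
    snp_counts: dict[str, int]
    raw_means: dict[str, float] = field(default_factory=dict)
    raw_sds: dict[str, float] = field(default_factory=dict)

    @property
    def thresholds(self) -> list[str]:
        return list(self.scores.columns)


def _format_threshold(t: float) -> str:
    return np.format_float_positional(t, trim="-")


def compute_scores(
    dataset: GenotypeDataset,
    sumstats: pd.DataFrame,
    retained: list[str],
    thresholds,
) -> ScoreMatrix:
    """Weighted effect-allele count per individual at each threshold.

    Alleles are aligned by matching the summary-statistic effect/other
    alleles to the dataset's; a swapped orientation flips the dosage
    (g -> 2 - g).  Unresolvable allele mismatches are dropped with a
    warning.  Missing dosages are imputed to 2 x effect-allele frequency.
    """
    thresholds = validate_thresholds(thresholds)
    idx = dataset.variant_index()
    ss = sumstats.set_index("variant_id")

    cols, weights, pvals = [], [], []
    dropped = []
    for vid in retained:
        if vid not in idx or vid not in ss.index:
            dropped.append(vid)
            continue
        row = ss.loc[vid]
        v = dataset.variants.iloc[idx[vid]]
        g = dataset.dosage[:, idx[vid]].copy()
        eaf = np.nanmean(g) / 2.0 if np.any(~np.isnan(g)) else 0.0
        g[np.isnan(g)] = 2.0 * eaf
        if (row["effect_allele"] == v["effect_allele"]
                and row["other_allele"] == v["other_allele"]):
            pass
        elif (row["effect_allele"] == v["other_allele"]
                and row["other_allele"] == v["effect_allele"]):
            g = 2.0 - g
        else:
            dropped.append(vid)
            continue
        if np.isnan(row["beta"]) or np.isnan(row[("p")]):
            dropped.append(vid)
            continue
        cols.append(g)
        weights.append(float(row["beta"]))
        pvals.append(float(row["p"]))
    if dropped:
        warnings.warn(f"{len(dropped)} retained variants dropped "
                      "(absent or allele mismatch)")

    G = (np.column_stack(cols) if cols
         else np.empty((dataset.n_samples, 0)))
    w = np.asarray(weights)
    p = np.asarray(pvals)

    data = {}
    counts, means, sds = {}, {}, {}
    for t in thresholds:
        label = _format_threshold(t)
        sel = p < t
        counts[label] = int(sel.sum())
        if counts[label] == 0:
            warnings.warn(f"no SNPs pass threshold {label}; zero scores")
            raw = np.zeros(dataset.n_samples)
        else:
            raw = G[:, sel] @ w[sel]
        mu, sd = float(raw.mean()), float(raw.std())
        means[label], sds[label] = mu, sd
        data[label] = (raw - mu) / sd if sd > 0 else raw - mu
    scores = pd.DataFrame(data, index=list(dataset.samples))
    return ScoreMatrix(scores=scores, snp_counts=counts,
                       raw_means=means, raw_sds=sds)
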