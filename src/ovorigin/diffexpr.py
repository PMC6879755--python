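"""Negative-binomial differential expression for two labeled groups.

Counts are normalized by median-of-ratios size factors, per-gene dispersions
are estimated by method of moments and shrunk halfway toward a monotone
mean-dispersion trend, and each gene is tested with a Wald test on the group
coefficient of an NB GLM with log link. This is a desk-scale NB Wald test in
the DESeq2 family, defined and calibration-tested on its own terms rather
than reproducing any particular implementation bit for bit.

Fold changes are oriented "B vs A": ``nb_test_two_groups(counts, ann, A, B)``
reports log2(mean_B / mean_A), so genes enriched in A carry negative log2fc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CANONICAL_GROUPS, CountMatrix, SampleAnnotation, ValidationError

DISPERSION_FLOOR = 1e-8
#: Pseudo-mean added (on the normalized-count scale) inside the group-mean
#: estimates so fold changes stay finite when one group is all zero.
MEAN_PRIOR = 0.5

DE_COLUMNS = ["gene", "log2fc", "pvalue", "padj", "base_mean"]


def _as_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Per sample, the factor is the median over genes (restricted to genes
    positive in every sample, i.e. with a positive geometric mean) of
    count / geometric-mean-count; the factors are then divided by their own
    geometric mean so they are centred at 1.
    """
    frame = _as_frame(counts)
    values = frame.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(values)
    log_geomean = logc.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValidationError(
            "no gene has positive counts in every sample; median-of-ratios is "
            "undefined (consider a pseudo-reference fallback)"
        )
    ratios = values[usable] / np.exp(log_geomean[usable, None])
    factors = np.median(ratios, axis=0)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=frame.columns, name="size_factor")


def compute_logcpm(
    counts: CountMatrix | pd.DataFrame, prior: float = 0.5
) -> pd.DataFrame:
    """log2 counts-per-million with a pseudo-count prior.

    ``logCPM_gi = log2((c_gi + prior) / (L_i + 2 * prior) * 1e6)`` with
    ``L_i`` the library size (column sum).
    """
    if prior <= 0:
        raise ValidationError(f"prior must be positive, got {prior}")
    frame = _as_frame(counts).astype(float)
    libsize = frame.sum(axis=0)
    if (libsize <= 0).any():
        bad = libsize.index[libsize <= 0][0]
        raise ValidationError(f"sample {bad!r} has library size 0")
    return np.log2((frame + prior) / (libsize + 2.0 * prior) * 1e6)


def adjust_bh(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries are excluded from m."""
    arr = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(arr)
    if ((arr[ok] < 0) | (arr[ok] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    if ok.sum() > 0:
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    return out


def _fit_dispersion_trend(phi_hat: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Monotone (non-increasing) trend ``phi(mu) = a1 / mu + a0`` fit by NNLS."""
    ok = (mu > 0) & np.isfinite(phi_hat)
    if ok.sum() < 2:
        return np.full_like(mu, np.nanmedian(np.where(ok, phi_hat, np.nan)))
    design = np.column_stack([1.0 / mu[ok], np.ones(ok.sum())])
    coef, _ = scipy.optimize.nnls(design, phi_hat[ok])
    with np.errstate(divide="ignore"):
        trend = coef[0] / mu + coef[1]
    return np.where(mu > 0, trend, coef[1])


def estimate_dispersions(
    q: np.ndarray, group_idx: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene NB dispersion from normalized counts ``q`` (genes x samples).

    Method of moments on the within-group pooled variance (var = mu + phi *
    mu**2 solved for phi), floored at :data:`DISPERSION_FLOOR`, then shrunk
    halfway toward the mean-dispersion trend. Returns (phi, grand mean of q).
    """
    n_total = sum(idx.size for idx in group_idx)
    ss = np.zeros(q.shape[0])
    for idx in group_idx:
        sub = q[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    dof = n_total - len(group_idx)
    var = ss / max(dof, 1)
    mu = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_hat = (var - mu) / mu**2
    phi_hat = np.where(mu > 0, phi_hat, 0.0)
    phi_hat = np.clip(phi_hat, DISPERSION_FLOOR, None)
    trend = _fit_dispersion_trend(phi_hat, mu)
    phi = 0.5 * phi_hat + 0.5 * np.clip(trend, DISPERSION_FLOOR, None)
    return np.clip(phi, DISPERSION_FLOOR, None), mu


def _nb_group_mean(
    c: np.ndarray, sf: np.ndarray, phi: np.ndarray, n_iter: int = 30
) -> np.ndarray:
    """Vectorized Newton solve of the NB score equation for each gene's mean.

    Solves ``sum_i (c_i - sf_i * m) / (1 + phi * sf_i * m) = 0`` for m >= 0
    (the NB MLE of the group mean with size-factor offsets and fixed phi).
    """
    m = c.sum(axis=1) / sf.sum()
    m = np.clip(m, 0.0, None)
    for _ in range(n_iter):
        mu = sf[None, :] * m[:, None]
        denom = 1.0 + phi[:, None] * mu
        f = ((c - mu) / denom).sum(axis=1)
        fprime = -(sf[None, :] * (1.0 + phi[:, None] * c) / denom**2).sum(axis=1)
        step = np.where(fprime != 0, f / fprime, 0.0)
        new = m - step
        m = np.where(new > 0, new, m / 2.0)
        if np.max(np.abs(step)) < 1e-12:
            break
    return m


def nb_test_two_groups(
    counts: CountMatrix,
    group_a: str,
    group_b: str,
    size_factors: pd.Series | None = None,
    annotation: SampleAnnotation | None = None,
    mean_prior: float = MEAN_PRIOR,
) -> pd.DataFrame:
    """NB Wald test of ``group_b`` vs ``group_a``; returns a DE table.

    Columns: gene, log2fc (B relative to A), pvalue, padj (BH within this
    comparison), base_mean (mean normalized count over both groups). Genes
    with zero counts everywhere get NaN p-values and log2fc 0.
    """
    ann = annotation or counts.annotation
    samples_a = [s for s in counts.sample_ids if ann.group_of(s) == group_a]
    samples_b = [s for s in counts.sample_ids if ann.group_of(s) == group_b]
    for name, samples in ((group_a, samples_a), (group_b, samples_b)):
        if len(samples) < 2:
            raise ValidationError(f"group {name!r} has {len(samples)} samples (< 2)")
    used = samples_a + samples_b
    frame = counts.counts[used]
    if size_factors is None:
        size_factors = estimate_size_factors(frame)
    sf = size_factors.loc[used].to_numpy(dtype=float)
    c = frame.to_numpy(dtype=float)
    q = c / sf[None, :]

    idx_a = np.arange(len(samples_a))
    idx_b = np.arange(len(samples_a), len(used))
    phi, _ = estimate_dispersions(q, [idx_a, idx_b])

    m_a = _nb_group_mean(c[:, idx_a], sf[idx_a], phi)
    m_b = _nb_group_mean(c[:, idx_b], sf[idx_b], phi)
    # pseudo-mean keeps the fold change finite and the Wald weights positive
    ma, mb = m_a + mean_prior, m_b + mean_prior
    beta = np.log(mb) - np.log(ma)
    log2fc = beta / np.log(2.0)

    def _weight_sum(m: np.ndarray, idx: np.ndarray) -> np.ndarray:
        mu = sf[idx][None, :] * m[:, None]
        return (mu / (1.0 + phi[:, None] * mu)).sum(axis=1)

    se = np.sqrt(1.0 / _weight_sum(ma, idx_a) + 1.0 / _weight_sum(mb, idx_b))
    z = beta / se
    pvalue = 2.0 * scipy.stats.norm.sf(np.abs(z))

    all_zero = c.sum(axis=1) == 0
    log2fc[all_zero] = 0.0
    pvalue[all_zero] = np.nan
    padj = adjust_bh(pvalue)

    return pd.DataFrame(
        {
            "gene": frame.index,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "base_mean": q.mean(axis=1),
        }
    ).reset_index(drop=True)


def _canonical_pair(x: str, y: str) -> tuple[str, str]:
    """Orientation "later vs earlier" in canonical group order: (B, A)."""
    order = {g: i for i, g in enumerate(CANONICAL_GROUPS)}
    ix, iy = order.get(x, len(order)), order.get(y, len(order))
    return (x, y) if ix > iy else (y, x)


@dataclass
class PairwiseDESet:
    """DE tables for the six ordered comparisons of the four groups.

    Tables are stored under canonical (B, A) orientation keys; ``get(b, a)``
    returns either orientation, negating log2fc when flipping (p-values are
    orientation-invariant).
    """

    tables: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)

    def add(self, group_b: str, group_a: str, table: pd.DataFrame) -> None:
        self.tables[(group_b, group_a)] = table

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.tables)

    def get(self, group_b: str, group_a: str) -> pd.DataFrame:
        """DE table oriented ``group_b vs group_a``."""
        if (group_b, group_a) in self.tables:
            return self.tables[(group_b, group_a)]
        if (group_a, group_b) in self.tables:
            flipped = self.tables[(group_a, group_b)].copy()
            flipped["log2fc"] = -flipped["log2fc"]
            return flipped
        raise KeyError(f"no comparison between {group_b!r} and {group_a!r}")

    def comparisons_for(self, target: str) -> dict[str, pd.DataFrame]:
        """All "target vs other" tables, keyed by the other group."""
        others = sorted({g for pair in self.tables for g in pair if g != target})
        return {other: self.get(target, other) for other in others}


def run_all_pairs(
    counts: CountMatrix,
    groups: tuple[str, ...] = CANONICAL_GROUPS,
    size_factors: pd.Series | None = None,
) -> PairwiseDESet:
    """All six pairwise NB tests with shared size factors and per-pair BH.

    Size factors are estimated once on all samples of the requested groups;
    BH is applied within each comparison separately.
    """
    present = set(counts.groups())
    absent = [g for g in groups if g not in present]
    if absent:
        raise ValidationError(f"groups missing from the data: {absent}")
    used = [s for s in counts.sample_ids if counts.annotation.group_of(s) in groups]
    if size_factors is None:
        size_factors = estimate_size_factors(counts.counts[used])
    out = PairwiseDESet()
    for x, y in combinations(groups, 2):
        b, a = _canonical_pair(x, y)
        out.add(b, a, nb_test_two_groups(counts, a, b, size_factors=size_factors))
    return out
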