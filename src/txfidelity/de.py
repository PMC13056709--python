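"""Exact negative-binomial two-group differential expression.

The test conditions on each gene's total count T across both groups and
enumerates the conditional distribution of one group's sum under the null of
equal per-unit-mass expression: P(a | T) is proportional to
``f_NB(a; nA*mu, phi/nA) * f_NB(T-a; nB*mu, phi/nB)`` with ``mu = T/(nA+nB)``
and ``nA``, ``nB`` the groups' effective size-factor masses.  The two-sided
p-value sums all outcomes whose conditional probability does not exceed the
observed one (minimum-likelihood method).  With phi = 0 the negative binomial
collapses to Poisson and the conditional law is exactly binomial(T, nA/(nA+nB)).

Per-gene dispersions are method-of-moments estimates on size-factor-normalized
counts, shrunk toward the across-gene mean (sSeq-style).  Fold changes are
log2 ratios of pseudocounted normalized group means; multiplicity is handled
by Benjamini-Hochberg across the genes that survive the low-expression filter
(average occurrence >= 1 count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, ValidationError

#: Below this per-group scaled dispersion the NB pmf is evaluated in its
#: Poisson limit (avoids catastrophic cancellation in gammaln at huge r).
_POISSON_PHI = 1e-8
#: Relative slack absorbing floating-point ties in the minimum-likelihood sum.
_TIE_SLACK = 1e-12


@dataclass
class DEConfig:
    alpha: float = 0.05
    min_mean_count: float = 1.0
    pseudocount: float = 1.0
    shrinkage_weight: float | None = None  # None => n_genes_used (w = 1/2)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if self.shrinkage_weight is not None and self.shrinkage_weight < 0:
            raise ValidationError("shrinkage_weight must be >= 0")


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Per-cell depth factors: depth / median depth of nonzero-depth cells.

    Zero-depth cells get NaN (unusable) factors.
    """
    depths = counts.depths().astype(float)
    nonzero = depths > 0
    if not nonzero.any():
        raise ValidationError("all-zero count matrix has no size factors")
    med = np.median(depths[nonzero])
    factors = depths / med
    factors[~nonzero] = np.nan
    return factors


def filter_low_expression(counts: CountMatrix, min_mean_count: float = 1.0) -> np.ndarray:
    """Gene mask: kept iff total count / n_cells >= min_mean_count."""
    totals = np.asarray(counts.values.sum(axis=1)).ravel()
    return totals / counts.n_cells >= min_mean_count


def estimate_dispersion(
    counts: CountMatrix,
    groups: tuple,
    shrinkage_weight: float | None = None,
    sf: np.ndarray | None = None,
) -> np.ndarray:
    """Shrunken per-gene NB dispersions from two cell groups.

    Method-of-moments on normalized counts y = x / s: with Var(x|s) =
    s*mu + phi*(s*mu)^2, E[var(y)] ~= mu * mean(1/s) + phi * mu^2, so
    ``phi_hat = max(0, (s2 - m * mean(1/s)) / m^2)`` with ``s2`` the pooled
    within-group variance and ``m`` the across-cell mean.  Raw estimates are
    shrunk toward the across-gene mean dispersion xi with weight
    ``w = shrinkage_weight / (shrinkage_weight + n_genes)``; the default
    weight equals the gene count (w = 1/2).
    """
    mask_a, mask_b = (np.asarray(m) for m in groups)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValidationError("each group needs >= 2 cells for dispersion estimation")
    if sf is None:
        sf = size_factors(counts)
    if np.isnan(sf).any():
        raise ValidationError("zero-depth cells must be removed before dispersion")

    dense = np.asarray(counts.values.todense(), dtype=float) / sf[None, :]
    inv_mean = float(np.mean(1.0 / sf))
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    var_a = dense[:, mask_a].var(axis=1, ddof=1)
    var_b = dense[:, mask_b].var(axis=1, ddof=1)
    pooled_var = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    mean_all = dense[:, mask_a | mask_b].mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(
            mean_all > 0,
            (pooled_var - mean_all * inv_mean) / np.maximum(mean_all, 1e-300) ** 2,
            0.0,
        )
    raw = np.maximum(raw, 0.0)
    used = mean_all > 0
    xi = float(raw[used].mean()) if used.any() else 0.0
    n_used = int(used.sum())
    sw = float(n_used if shrinkage_weight is None else shrinkage_weight)
    w = sw / (sw + n_used) if (sw + n_used) > 0 else 0.0
    return np.maximum((1.0 - w) * raw + w * xi, 0.0)


def _nb_logpmf(k: np.ndarray, mean: np.ndarray, phi: np.ndarray, lgam_k1: np.ndarray) -> np.ndarray:
    """Elementwise NB(mean, phi) log-pmf with a Poisson branch for tiny phi."""
    out = np.empty(len(k), dtype=float)
    pois = phi < _POISSON_PHI
    if pois.any():
        m = mean[pois]
        out[pois] = k[pois] * np.log(m) - m - lgam_k1[pois]
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        m = mean[nb]
        kk = k[nb]
        out[nb] = (
            gammaln(kk + r)
            - gammaln(r)
            - lgam_k1[nb]
            + r * np.log(r / (r + m))
            + kk * np.log(m / (r + m))
        )
    return out


def exact_nb_test(
    sum_a: int, sum_b: int, n_a_eff: float, n_b_eff: float, phi: float
) -> float:
    """Two-sided exact NB test p-value for one gene (scalar reference path).

    ``n_a_eff`` / ``n_b_eff`` are the groups' effective size-factor masses.
    T = 0 returns 1 by convention.
    """
    if min(n_a_eff, n_b_eff) <= 0:
        raise ValidationError("effective masses must be positive")
    if not np.isfinite(phi) or phi < 0:
        raise ValidationError("dispersion must be finite and >= 0")
    if min(sum_a, sum_b) < 0:
        raise ValidationError("group sums must be >= 0")
    total = int(sum_a + sum_b)
    if total == 0:
        return 1.0
    a = np.arange(total + 1, dtype=float)
    mu = total / (n_a_eff + n_b_eff)
    lgam = gammaln(np.arange(total + 2, dtype=float) + 1.0)
    log_w = _nb_logpmf(
        a,
        np.full(total + 1, n_a_eff * mu),
        np.full(total + 1, phi / n_a_eff),
        lgam[: total + 1],
    ) + _nb_logpmf(
        total - a,
        np.full(total + 1, n_b_eff * mu),
        np.full(total + 1, phi / n_b_eff),
        lgam[: total + 1][::-1],
    )
    log_w -= log_w.max()
    w = np.exp(log_w)
    denom = w.sum()
    observed = w[int(sum_a)]
    p = w[w <= observed * (1.0 + _TIE_SLACK)].sum() / denom
    return float(min(max(p, 0.0), 1.0))


def exact_nb_test_batch(
    sums_a: np.ndarray,
    sums_b: np.ndarray,
    n_a_eff: float,
    n_b_eff: float,
    phi: np.ndarray,
    chunk_support: int = 4_000_000,
) -> np.ndarray:
    """Vectorized exact NB test over genes sharing the two group masses.

    Enumerates every gene's conditional support in concatenated blocks and
    reduces per-gene with segment sums; numerically identical to calling
    :func:`exact_nb_test` gene by gene.
    """
    sums_a = np.asarray(sums_a, dtype=np.int64)
    sums_b = np.asarray(sums_b, dtype=np.int64)
    phi = np.asarray(phi, dtype=float)
    totals = sums_a + sums_b
    p_out = np.ones(len(sums_a), dtype=float)
    live = np.flatnonzero(totals > 0)
    if len(live) == 0:
        return p_out

    # Per-gene log-weights are built recursively along the support:
    #   w(a)/w(a-1) = [fA(a)/fA(a-1)] * [fB(T-a)/fB(T-a+1)]
    # so one log + a segmented cumsum replaces two gammaln sweeps.  The
    # conditional pmf is log-concave (a product of log-concave NB pmfs), so
    # enumeration can be restricted to a window around the conditional mode
    # that always contains the observed point; the excluded tail mass is
    # below ~1e-13 and only perturbs p at that absolute scale.
    n_tot = n_a_eff + n_b_eff
    mu = totals[live] / n_tot
    m_a = n_a_eff * mu
    m_b = n_b_eff * mu
    phi_a = phi[live] / n_a_eff
    phi_b = phi[live] / n_b_eff
    pois_a = phi_a < _POISSON_PHI
    pois_b = phi_b < _POISSON_PHI
    with np.errstate(divide="ignore"):
        r_a = np.where(pois_a, np.inf, 1.0 / np.maximum(phi_a, 1e-300))
        r_b = np.where(pois_b, np.inf, 1.0 / np.maximum(phi_b, 1e-300))
    q_a = np.where(pois_a, 0.0, np.log(m_a / (np.where(pois_a, 1.0, r_a) + m_a)))
    q_b = np.where(pois_b, 0.0, np.log(m_b / (np.where(pois_b, 1.0, r_b) + m_b)))

    # window: conditional mean +/- (16 sd + 64), widened to cover the
    # observation with the same margin on its far side
    t_f = totals[live].astype(float)
    var_a = m_a * (1.0 + phi_a * m_a)
    var_b = m_b * (1.0 + phi_b * m_b)
    cond_sd = np.sqrt(var_a * var_b / (var_a + var_b))
    center = t_f * (n_a_eff / n_tot)
    margin = 16.0 * cond_sd + 64.0
    win_lo = np.minimum(center - margin, sums_a[live] - margin)
    win_hi = np.maximum(center + margin, sums_a[live] + margin)
    win_lo = np.clip(np.floor(win_lo), 0, totals[live]).astype(np.int64)
    win_hi = np.clip(np.ceil(win_hi), 0, totals[live]).astype(np.int64)

    # anchor log-weight at the window start (per-gene scalars via gammaln)
    lo_f = win_lo.astype(float)
    log_w_anchor = _nb_logpmf(lo_f, m_a, phi_a, gammaln(lo_f + 1.0)) + _nb_logpmf(
        t_f - lo_f, m_b, phi_b, gammaln(t_f - lo_f + 1.0)
    )

    # per-gene constants for the unified ratio
    #   w(a)/w(a-1) = [(ca0 + ca1*a) * (T-a+1)] / [a * (cb0 + cb1*(T-a))] * e^q
    ca0 = np.where(pois_a, m_a, r_a - 1.0)
    ca1 = np.where(pois_a, 0.0, 1.0)
    cb0 = np.where(pois_b, m_b, r_b)
    cb1 = np.where(pois_b, 0.0, 1.0)
    q_const = q_a - q_b

    # chunk genes so concatenated windows stay below chunk_support
    seg_len_all = win_hi - win_lo + 1
    boundaries = [0]
    acc = 0
    for i, s in enumerate(seg_len_all):
        acc += int(s)
        if acc > chunk_support:
            boundaries.append(i)
            acc = int(s)
    boundaries.append(len(live))

    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        if lo == hi:
            continue
        idx = live[lo:hi]
        seg_len = seg_len_all[lo:hi]
        offsets = np.concatenate([[0], np.cumsum(seg_len)])
        starts = offsets[:-1]
        total_len = int(offsets[-1])
        gene_of = np.repeat(np.arange(hi - lo), seg_len)
        a = (
            np.arange(total_len) - starts[gene_of] + win_lo[lo:hi][gene_of]
        ).astype(float)
        t_rep = t_f[lo:hi][gene_of]

        # a == win_lo rows are placeholders overwritten by the anchor
        a_safe = np.maximum(a, 1.0)
        num = (ca0[lo:hi][gene_of] + ca1[lo:hi][gene_of] * a_safe) * (
            t_rep - a_safe + 1.0
        )
        den = a_safe * (cb0[lo:hi][gene_of] + cb1[lo:hi][gene_of] * (t_rep - a_safe))
        log_ratio = np.log(num / den) + q_const[lo:hi][gene_of]
        log_ratio[starts] = 0.0
        cum = np.cumsum(log_ratio)
        log_w = cum - cum[starts][gene_of] + log_w_anchor[lo:hi][gene_of]

        seg_max = np.maximum.reduceat(log_w, starts)
        w = np.exp(log_w - seg_max[gene_of])
        denom = np.add.reduceat(w, starts)
        obs = w[starts + (sums_a[idx] - win_lo[lo:hi])]
        incl = w * (w <= obs[gene_of] * (1.0 + _TIE_SLACK))
        numer = np.add.reduceat(incl, starts)
        p_out[idx] = np.clip(numer / denom, np.finfo(float).tiny, 1.0)
    return p_out


def log2_fold_change(mean_target, mean_baseline, pseudocount: float = 1.0):
    """log2((mean_target + pc) / (mean_baseline + pc)); always finite."""
    return np.log2(
        (np.asarray(mean_target, float) + pseudocount)
        / (np.asarray(mean_baseline, float) + pseudocount)
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    counts: CountMatrix,
    target_cells,
    baseline_cells,
    config: DEConfig | None = None,
) -> pd.DataFrame:
    """Full two-group DE for target vs baseline cell sets.

    Pipeline: low-expression filter on the union of the two groups, size
    factors from the union, shrunken dispersions, exact NB test per gene,
    pseudocounted log2 fold change of normalized group means, BH across the
    retained genes.  Returns a DataFrame with columns gene_id, mean_target,
    mean_baseline, log2fc, p_raw, p_adj, significant (gene order preserved).
    """
    config = config or DEConfig()
    target_cells = list(target_cells)
    baseline_cells = list(baseline_cells)
    if not target_cells or not baseline_cells:
        raise ValidationError("both cell groups must be non-empty")
    overlap = set(target_cells) & set(baseline_cells)
    if overlap:
        raise ValidationError(f"groups overlap on {len(overlap)} cells")

    union = counts.subset_cells(np.array(target_cells + baseline_cells, dtype=object))
    depths = union.depths()
    usable = depths > 0
    if (~usable).any():
        warnings.warn(f"dropping {int((~usable).sum())} zero-depth cells", stacklevel=2)
        union = union.subset_cells(usable)
    n_t = len(target_cells)
    mask_t = np.zeros(union.n_cells, dtype=bool)
    mask_t[np.isin(union.cell_ids, np.array(target_cells, dtype=object))] = True
    mask_b = ~mask_t
    if mask_t.sum() == 0 or mask_b.sum() == 0:
        raise ValidationError("a group became empty after dropping zero-depth cells")
    del n_t

    gene_mask = filter_low_expression(union, config.min_mean_count)
    if not gene_mask.any():
        raise ValidationError("no genes pass the low-expression filter")
    sub = union.subset_genes(gene_mask)

    sf = size_factors(sub)
    phi = estimate_dispersion(sub, (mask_t, mask_b), config.shrinkage_weight, sf=sf)

    csr = sub.values.tocsr()
    sums_t = np.asarray(csr[:, mask_t].sum(axis=1)).ravel().astype(np.int64)
    sums_b = np.asarray(csr[:, mask_b].sum(axis=1)).ravel().astype(np.int64)
    n_t_eff = float(sf[mask_t].sum())
    n_b_eff = float(sf[mask_b].sum())

    p_raw = exact_nb_test_batch(sums_t, sums_b, n_t_eff, n_b_eff, phi)

    inv_sf = 1.0 / sf
    mean_t = (csr[:, mask_t] @ inv_sf[mask_t]) / mask_t.sum()
    mean_b = (csr[:, mask_b] @ inv_sf[mask_b]) / mask_b.sum()
    l2fc = log2_fold_change(mean_t, mean_b, config.pseudocount)
    p_adj = bh_adjust(p_raw)

    return pd.DataFrame(
        {
            "gene_id": sub.gene_ids,
            "mean_target": mean_t,
            "mean_baseline": mean_b,
            "log2fc": l2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": p_adj < config.alpha,
        }
    )
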