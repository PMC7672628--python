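"""Negative-binomial GLM differential expression between consecutive stages.

Model per gene: ``log E(count_ij) = beta_stage(i) + offset_j`` with
``offset_j = log(effective library size)`` and NB variance
``mu + phi mu^2``. Because the stage factor saturates the design, the
likelihood factorizes over stages, so each stage coefficient is a
one-dimensional NB mean fit (Fisher scoring). A consecutive-stage
contrast is tested by a likelihood-ratio test of the model that merges
the two stages against the one that keeps them separate; the statistic
2*delta(logLik) is referred to chi-square(1).

Dispersion is estimated once on the full stage model: a common value by
maximizing the summed Cox-Reid adjusted profile likelihood (APL), then a
moderated per-gene value maximizing ``APL_g + prior_n * mean(APL)`` —
per-gene evidence shrunk toward the common value with a prior weight
equivalent to ``prior_n`` genes.

Multiple testing is controlled per contrast with Benjamini-Hochberg;
genes are called up (FDR < 0.05 and log2FC > 1), down (log2FC < -1),
unchanged (significant but |log2FC| <= 1) or not significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2

from .design import consecutive_contrasts, contrast_name, order_stages
from .normalize import effective_lib_sizes, tmm_factors

_MIN_PHI = 1e-8
_BETA_FLOOR = -50.0


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Row sums of the NB log-likelihood; exact Poisson at phi == 0."""
    mu = np.maximum(mu, 1e-300)
    phi = np.asarray(phi, dtype=float)
    if np.all(phi < 1e-12):
        return (y * np.log(mu) - mu - gammaln(y + 1.0)).sum(axis=-1)
    inv = 1.0 / phi
    ll = (
        gammaln(y + inv)
        - gammaln(inv)
        - gammaln(y + 1.0)
        + y * np.log(phi * mu / (1.0 + phi * mu))
        - inv * np.log1p(phi * mu)
    )
    return ll.sum(axis=-1)


def _fit_means(
    y: np.ndarray, offsets: np.ndarray, phi
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized single-coefficient NB fit with offsets, per gene (row).

    Returns (beta, loglik, weight_sum, converged); ``weight_sum`` is the
    Fisher information term sum(mu / (1 + phi mu)) used for the Cox-Reid
    adjustment. With phi == 0 the MLE is closed form (Poisson).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    offsets = np.asarray(offsets, dtype=float)
    G = y.shape[0]
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (G,)).copy()
    sy = y.sum(axis=1)
    se = np.exp(offsets).sum()

    beta = np.where(sy > 0, np.log(np.maximum(sy, 0.5) / se), _BETA_FLOOR)
    converged = np.ones(G, dtype=bool)
    poisson = phi < 1e-12
    active = (~poisson) & (sy > 0)
    phi_a = phi[active, None]
    b = beta[active]
    ya = y[active]
    for _ in range(100):
        if b.size == 0:
            break
        mu = np.exp(b[:, None] + offsets)
        resid = (ya - mu) / (1.0 + phi_a * mu)
        score = resid.sum(axis=1)
        info = (mu * (1.0 + phi_a * ya) / (1.0 + phi_a * mu) ** 2).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break
    else:
        mu = np.exp(b[:, None] + offsets)
        resid = (ya - mu) / (1.0 + phi_a * mu)
        bad = np.abs(resid.sum(axis=1)) > 1e-4 * np.maximum(ya.sum(axis=1), 1.0)
        idx = np.flatnonzero(active)
        converged[idx[bad]] = False
    beta[active] = b

    mu_all = np.exp(beta[:, None] + offsets)
    ll = np.empty(G)
    if poisson.any():
        ll[poisson] = _nb_loglik(y[poisson], mu_all[poisson], 0.0)
    if (~poisson).any():
        ll[~poisson] = _nb_loglik(y[~poisson], mu_all[~poisson], phi[~poisson, None])
    wsum = (mu_all / (1.0 + phi[:, None] * mu_all)).sum(axis=1)
    return beta, ll, wsum, converged


def _group_indices(sheet: pd.DataFrame, columns) -> dict[str, np.ndarray]:
    cols = list(columns)
    groups: dict[str, np.ndarray] = {}
    for stage in order_stages(sheet["stage"]):
        ids = sheet.loc[sheet["stage"] == stage, "sample_id"]
        groups[stage] = np.array([cols.index(s) for s in ids])
    return groups


def _apl(
    y: np.ndarray, groups: dict[str, np.ndarray], offsets: np.ndarray, phi: float
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per gene at dispersion phi."""
    total = np.zeros(y.shape[0])
    for idx in groups.values():
        _, ll, wsum, _ = _fit_means(y[:, idx], offsets[idx], phi)
        total += ll - 0.5 * np.log(np.maximum(wsum, 1e-12))
    return total


@dataclass
class DispersionEstimate:
    """Common NB dispersion and moderated per-gene dispersions."""

    common: float
    tagwise: pd.Series
    prior_n: float


def estimate_dispersion(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    offsets: np.ndarray | None = None,
    prior_n: float = 10.0,
    grid_points: int = 21,
    grid_span: float = 10.0,
) -> DispersionEstimate:
    """Estimate common + moderated per-gene NB dispersion on the stage model.

    The per-gene grid spans ``common * 2**(+/- grid_span)``; each gene
    maximizes its own APL plus ``prior_n`` times the mean APL over genes
    (quadratic interpolation between grid points), clamped at 1e-8.
    """
    y = counts.to_numpy(dtype=float)
    if y.sum() == 0:
        raise ValueError("all-zero count matrix")
    if offsets is None:
        offsets = np.log(y.sum(axis=0))
    groups = _group_indices(sheet, counts.columns)
    if max(len(ix) for ix in groups.values()) < 2:
        raise ValueError("dispersion estimation needs >=2 replicates in a stage")

    expressed = y.sum(axis=1) > 0
    ye = y[expressed]

    def neg_sum_apl(log_phi: float) -> float:
        return -float(_apl(ye, groups, offsets, 10.0**log_phi).sum())

    res = minimize_scalar(
        neg_sum_apl, bounds=(-8.0, 1.3), method="bounded",
        options={"xatol": 1e-3},
    )
    common = float(10.0 ** res.x)

    lo = max(np.log2(common) - grid_span, np.log2(_MIN_PHI))
    hi = np.log2(common) + grid_span
    grid = 2.0 ** np.linspace(lo, hi, grid_points)
    apl = np.stack([_apl(ye, groups, offsets, p) for p in grid], axis=1)
    crit = apl + prior_n * apl.mean(axis=0)

    best = np.argmax(crit, axis=1)
    log_grid = np.log2(grid)
    phi_e = grid[best].astype(float)
    interior = (best > 0) & (best < grid_points - 1)
    if interior.any():
        i = best[interior]
        rows = np.flatnonzero(interior)
        y0 = crit[rows, i - 1]
        y1 = crit[rows, i]
        y2 = crit[rows, i + 1]
        denom = y0 - 2.0 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        step = log_grid[1] - log_grid[0]
        phi_e[rows] = 2.0 ** (log_grid[i] + shift * step)
    phi_e = np.clip(phi_e, _MIN_PHI, None)

    tagwise = np.full(y.shape[0], common)
    tagwise[expressed] = phi_e
    return DispersionEstimate(
        common=common,
        tagwise=pd.Series(tagwise, index=counts.index, name="dispersion"),
        prior_n=prior_n,
    )


@dataclass
class GLMFit:
    """A fitted per-gene NB GLM with a stage-factor design."""

    coefficients: pd.Series  # natural-log stage coefficients
    loglik: float
    df: int
    converged: bool
    dispersion: float

    def stage_effects(self) -> pd.Series:
        """Stage effects relative to the first stage (treatment coding)."""
        return self.coefficients - self.coefficients.iloc[0]


def fit_nb_glm(
    y,
    stages,
    offsets,
    dispersion: float,
) -> GLMFit:
    """Fit ``log E(count) = beta_stage + offset`` for one gene.

    ``stages`` gives each sample's stage label; the model is the saturated
    stage-means model, so each coefficient is that stage's NB mean on the
    offset scale.
    """
    y = np.asarray(y, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    stages = list(stages)
    try:
        ordered = order_stages(stages)
    except ValueError:  # arbitrary group labels (e.g. a pooled reduced model)
        ordered = list(dict.fromkeys(stages))
    betas, lls, conv = {}, 0.0, True
    for stage in ordered:
        idx = np.array([i for i, s in enumerate(stages) if s == stage])
        b, ll, _, ok = _fit_means(y[None, idx], offsets[idx], dispersion)
        betas[stage] = float(b[0])
        lls += float(ll[0])
        conv &= bool(ok[0])
    coef = pd.Series(betas)
    return GLMFit(
        coefficients=coef,
        loglik=lls,
        df=len(coef),
        converged=conv,
        dispersion=dispersion,
    )


def lrt(full: GLMFit, reduced: GLMFit) -> tuple[float, float]:
    """Likelihood-ratio test of nested fits: 2*delta(logLik) vs chi-square."""
    ddf = full.df - reduced.df
    if ddf <= 0:
        raise ValueError("reduced model must have fewer parameters than full")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        raise ValueError(f"negative LRT statistic {stat}; fits are inconsistent")
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, ddf))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_genes(
    results: pd.DataFrame,
    fdr: float = 0.05,
    lfc_up: float = 1.0,
    lfc_down: float = -1.0,
) -> pd.DataFrame:
    """Attach up/down/unchanged/not_significant calls to a DE table.

    up: FDR < threshold and logFC > lfc_up; down: FDR < threshold and
    logFC < lfc_down; unchanged: significant but between the bounds;
    not_significant otherwise.
    """
    out = results.copy()
    sig = out["fdr"] < fdr
    call = np.where(
        sig & (out["logFC"] > lfc_up),
        "up",
        np.where(
            sig & (out["logFC"] < lfc_down),
            "down",
            np.where(sig, "unchanged", "not_significant"),
        ),
    )
    out["call"] = call
    return out


def _shrunken_logfc(
    y: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    elib: np.ndarray,
    prior_count: float = 0.125,
) -> np.ndarray:
    """log2 FC of group abundances with a library-proportional prior count."""
    prior = prior_count * elib / elib.mean()
    num_a = y[:, idx_a].sum(axis=1) + prior[idx_a].sum()
    num_b = y[:, idx_b].sum(axis=1) + prior[idx_b].sum()
    ab_a = num_a / elib[idx_a].sum()
    ab_b = num_b / elib[idx_b].sum()
    return np.log2(ab_b / ab_a)


def run_consecutive_contrasts(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    fdr: float = 0.05,
    lfc: float = 1.0,
    dispersion: DispersionEstimate | None = None,
    prior_n: float = 10.0,
    prior_count: float = 0.125,
) -> pd.DataFrame:
    """Full DE analysis: TMM offsets, dispersion, six consecutive LRTs.

    Returns a long-format table with one row per gene per contrast:
    ``gene_id, contrast, logFC, LR, pvalue, fdr, converged, call``.
    BH adjustment is applied within each contrast.
    """
    factors = tmm_factors(counts)
    elib = effective_lib_sizes(counts, factors).to_numpy()
    offsets = np.log(elib)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, sheet, offsets=offsets, prior_n=prior_n)
    phi = dispersion.tagwise.reindex(counts.index).to_numpy()
    y = counts.to_numpy(dtype=float)
    groups = _group_indices(sheet, counts.columns)

    per_stage = {
        stage: _fit_means(y[:, idx], offsets[idx], phi)
        for stage, idx in groups.items()
    }
    frames = []
    for a, b in consecutive_contrasts(list(groups)):
        ia, ib = groups[a], groups[b]
        both = np.concatenate([ia, ib])
        _, ll_merged, _, conv_m = _fit_means(y[:, both], offsets[both], phi)
        ll_full = per_stage[a][1] + per_stage[b][1]
        stat = 2.0 * (ll_full - ll_merged)
        if stat.min() < -1e-6:
            raise ValueError("negative LRT statistic; numerical failure")
        stat = np.maximum(stat, 0.0)
        pval = chi2.sf(stat, 1)
        converged = per_stage[a][3] & per_stage[b][3] & conv_m
        frame = pd.DataFrame(
            {
                "gene_id": counts.index,
                "contrast": contrast_name(a, b),
                "logFC": _shrunken_logfc(y, ia, ib, elib, prior_count),
                "LR": stat,
                "pvalue": pval,
                "fdr": bh_adjust(pval),
                "converged": converged,
            }
        )
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    table = call_genes(table, fdr=fdr, lfc_up=lfc, lfc_down=-lfc)
    table.loc[~table["converged"], "call"] = "not_converged"
    return table


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
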