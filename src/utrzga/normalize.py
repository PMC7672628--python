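"""Count-matrix loading, TMM normalization and stage profiles.

TMM (trimmed mean of M-values) estimates a relative scaling factor per
sample against a reference sample: per-gene log2 count-fraction ratios
(M-values) are doubly trimmed — by M and by average abundance (A) — and
the factor is 2 to the precision-weighted mean of the surviving M-values.
Factors are rescaled so their geometric mean is 1; the effective library
size is ``library_size * factor`` and normalized expression is counts per
million on the effective library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .design import STAGES, order_stages, stage_rank


def read_counts(counts_path, samples_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and cross-validate a count matrix TSV and its sample sheet.

    The matrix must be genes x samples with non-negative integers; every
    matrix column must appear in the sheet (and vice versa) and every stage
    name must be one of the seven known stages.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t")
    required = {"sample_id", "stage", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    unknown_stage = set(sheet["stage"]) - set(STAGES)
    if unknown_stage:
        raise ValueError(f"unknown stage name(s) {sorted(unknown_stage)}")
    sheet_ids = list(sheet["sample_id"])
    extra = [c for c in counts.columns if c not in set(sheet_ids)]
    if extra:
        raise ValueError(f"count columns not in sample sheet: {extra}")
    absent = [s for s in sheet_ids if s not in set(counts.columns)]
    if absent:
        raise ValueError(f"sample sheet rows without count columns: {absent}")
    counts = counts[sheet_ids]
    if not np.issubdtype(counts.to_numpy().dtype, np.number):
        raise ValueError("count matrix contains non-numeric entries")
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("count matrix contains negative entries")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("count matrix contains non-integer entries")
    counts = counts.astype(np.int64)
    counts.index.name = "gene_id"
    return counts, sheet


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    ref: str | None = None,
) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean rescaled to 1).

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean across samples, unless ``ref`` names one explicitly.
    Genes with a zero count in the sample or the reference are excluded
    pairwise.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        zero = list(counts.columns[lib == 0])
        raise ValueError(f"sample(s) with zero library size: {zero}")
    if mat.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="tmm_factor")

    with np.errstate(invalid="ignore"):
        q75 = np.quantile(mat, 0.75, axis=0) / lib
    if ref is None:
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = list(counts.columns).index(ref)
    r = mat[:, ref_idx]
    nr = lib[ref_idx]

    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        x = mat[:, j]
        n = lib[j]
        keep = (x > 0) & (r > 0)
        if not keep.any():
            raise ValueError(
                f"sample {counts.columns[j]!r} shares no expressed genes "
                f"with reference {counts.columns[ref_idx]!r}"
            )
        xk, rk = x[keep], r[keep]
        m = np.log2((xk / n) / (rk / nr))
        a = 0.5 * np.log2((xk / n) * (rk / nr))
        w = (n - xk) / (n * xk) + (nr - rk) / (nr * rk)

        cnt = len(m)
        lo_m = np.floor(cnt * logratio_trim) + 1
        hi_m = cnt + 1 - lo_m
        lo_a = np.floor(cnt * abs_trim) + 1
        hi_a = cnt + 1 - lo_a
        rm, ra = rankdata(m), rankdata(a)
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if sel.any() and w[sel].sum() > 0:
            f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
        else:
            f = 0.0
        factors[j] = 2.0**f

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


@dataclass
class NormalizationResult:
    """TMM factors plus normalized (CPM) and log2 matrices."""

    factors: pd.Series
    cpm: pd.DataFrame
    log2: pd.DataFrame
    pseudocount: float
    logratio_trim: float = 0.30
    abs_trim: float = 0.05


def normalize_and_log(
    counts: pd.DataFrame,
    factors: pd.Series,
    pseudocount: float = 1.0,
) -> NormalizationResult:
    """CPM on effective library sizes, and log2(CPM + pseudocount).

    A zero count maps to log2(pseudocount); with the default pseudocount of
    1 that is exactly 0.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("zero library size")
    elib = lib * factors.reindex(counts.columns)
    cpm = counts.div(elib, axis=1) * 1e6
    log2 = np.log2(cpm + pseudocount)
    return NormalizationResult(
        factors=factors, cpm=cpm, log2=log2, pseudocount=pseudocount
    )


def effective_lib_sizes(counts: pd.DataFrame, factors: pd.Series) -> pd.Series:
    """Library size times TMM factor, aligned to the count columns."""
    return counts.sum(axis=0).astype(float) * factors.reindex(counts.columns)


def stage_profile(
    log2_matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    stages: tuple[str, ...] = STAGES,
) -> pd.DataFrame:
    """Per-gene mean log2 expression per stage, columns in stage order."""
    present = set(sheet["stage"])
    missing = [s for s in stages if s not in present]
    if missing:
        raise ValueError(f"stage(s) missing from sample sheet: {missing}")
    cols = {}
    for stage in order_stages(stages):
        ids = sheet.loc[sheet["stage"] == stage, "sample_id"]
        cols[stage] = log2_matrix[list(ids)].mean(axis=1)
    return pd.DataFrame(cols)
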