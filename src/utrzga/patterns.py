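"""Temporal-archetype classification and 2^-ddCt relative quantification.

A gene's six consecutive-stage DE calls plus its log2 stage profile are
mapped onto the maternal-to-zygotic-transition archetypes: activation at
the zygote (1st, minor ZGA wave), activation between EGK.I and EGK.VI
(2nd, major wave), post-ZGA activation (EGK.VIII onward), maternal
clearance (downregulation only), constitutive expression, or too lowly
expressed to classify. The earliest upregulation call decides the wave.

The qPCR-style module computes 2^-ddCt fold changes relative to a
reference gene (e.g. GAPDH) and a reference stage (oocyte), with a
Welch t-test on the per-replicate dCt values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import CONTRASTS, STAGES, contrast_name

PRIMARY_LABELS = (
    "zga1_activated",
    "zga2_activated",
    "post_zga_activated",
    "maternal_decay",
    "constitutive",
    "low_expressed",
)

#: contrast -> activation wave implied by an "up" call at that contrast
_WAVE_OF_CONTRAST = {
    contrast_name("oocyte", "zygote"): "zga1_activated",
    contrast_name("zygote", "EGK.I"): "zga2_activated",
    contrast_name("EGK.I", "EGK.III"): "zga2_activated",
    contrast_name("EGK.III", "EGK.VI"): "zga2_activated",
    contrast_name("EGK.VI", "EGK.VIII"): "post_zga_activated",
    contrast_name("EGK.VIII", "EGK.X"): "post_zga_activated",
}

_DECLINE_CONTRASTS = (
    contrast_name("EGK.VI", "EGK.VIII"),
    contrast_name("EGK.VIII", "EGK.X"),
)


@dataclass
class PatternLabel:
    """One gene's temporal archetype with supporting evidence."""

    gene_id: str
    label: str
    decline_flag: bool
    evidence: tuple[str, ...]  # contrast:call pairs that drove the label


def classify_temporal_pattern(
    gene_id: str,
    calls: dict[str, str],
    profile,
    min_expr_log2: float = 1.0,
) -> PatternLabel:
    """Classify one gene from its six contrast calls and stage profile.

    Rule order: (1) ``low_expressed`` if no stage reaches ``min_expr_log2``
    on the log2 scale; (2) the earliest contrast called ``up`` sets the
    activation wave; (3) otherwise any ``down`` call means maternal decay;
    (4) otherwise constitutive. The decline flag marks a significant drop
    at either of the last two transitions and is set independently.
    """
    missing = [c for c in CONTRASTS if c not in calls]
    if missing:
        raise ValueError(f"gene {gene_id}: missing contrast(s) {missing}")
    profile = np.asarray(profile, dtype=float)
    decline = any(calls[c] == "down" for c in _DECLINE_CONTRASTS)
    evidence = tuple(f"{c}:{calls[c]}" for c in CONTRASTS if calls[c] not in
                     ("not_significant", "not_converged"))

    if np.nanmax(profile) < min_expr_log2:
        return PatternLabel(gene_id, "low_expressed", False, evidence)
    for c in CONTRASTS:
        if calls[c] == "up":
            return PatternLabel(gene_id, _WAVE_OF_CONTRAST[c], decline, evidence)
    if any(calls[c] == "down" for c in CONTRASTS):
        return PatternLabel(gene_id, "maternal_decay", decline, evidence)
    return PatternLabel(gene_id, "constitutive", decline, evidence)


def classify_all(
    de_table: pd.DataFrame,
    profiles: pd.DataFrame,
    min_expr_log2: float = 1.0,
) -> pd.DataFrame:
    """Classify every gene from a long-format DE table and stage profiles.

    Returns a table indexed by gene: ``label, decline_flag, evidence``.
    """
    calls = de_table.pivot(index="gene_id", columns="contrast", values="call")
    rows = []
    for gene_id in profiles.index:
        if gene_id not in calls.index:
            raise ValueError(f"gene {gene_id} missing from DE table")
        lab = classify_temporal_pattern(
            gene_id,
            calls.loc[gene_id].to_dict(),
            profiles.loc[gene_id].to_numpy(),
            min_expr_log2=min_expr_log2,
        )
        rows.append(
            {
                "gene_id": lab.gene_id,
                "label": lab.label,
                "decline_flag": lab.decline_flag,
                "evidence": ";".join(lab.evidence),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def _dct(table: pd.DataFrame, gene: str, ref_gene: str, stage: str) -> pd.Series:
    """Per-replicate delta-Ct (target minus reference gene) at one stage."""
    sub = table[table["stage"] == stage]
    tgt = sub[sub["gene"] == gene].set_index("replicate")["ct"]
    ref = sub[sub["gene"] == ref_gene].set_index("replicate")["ct"]
    if tgt.empty:
        raise ValueError(f"no Ct rows for gene {gene!r} at stage {stage!r}")
    if ref.empty:
        raise ValueError(f"no Ct rows for reference gene {ref_gene!r} at stage {stage!r}")
    common = tgt.index.intersection(ref.index)
    if common.empty:
        raise ValueError(f"no shared replicates for {gene!r}/{ref_gene!r} at {stage!r}")
    return (tgt.loc[common] - ref.loc[common]).sort_index()


@dataclass
class DdctResult:
    """2^-ddCt fold changes of one gene at one stage vs the reference stage."""

    gene: str
    stage: str
    folds: pd.Series  # per test-stage replicate
    mean_fold: float
    p_value: float  # Welch t-test on delta-Ct replicates vs reference stage


def delta_delta_ct(
    table: pd.DataFrame,
    gene: str,
    stage: str,
    ref_gene: str = "GAPDH",
    ref_stage: str = "oocyte",
    equal_var: bool = False,
) -> DdctResult:
    """Relative quantification by the 2^-ddCt method.

    ``table`` columns: gene, stage, replicate, ct. Per test replicate:
    ddCt = (Ct_gene - Ct_refgene) - mean over reference-stage replicates of
    the same difference; fold = 2^-ddCt. The t-test (Welch by default)
    compares the per-replicate delta-Ct values between the two stages.
    """
    required = {"gene", "stage", "replicate", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    if not np.isfinite(table["ct"]).all() or (table["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    dct_test = _dct(table, gene, ref_gene, stage)
    dct_ref = _dct(table, gene, ref_gene, ref_stage)
    ddct = dct_test - dct_ref.mean()
    folds = 2.0 ** (-ddct)
    if stage == ref_stage or len(dct_test) < 2 or len(dct_ref) < 2:
        p = float("nan") if stage != ref_stage else 1.0
    else:
        p = float(stats.ttest_ind(dct_test, dct_ref, equal_var=equal_var).pvalue)
    return DdctResult(
        gene=gene,
        stage=stage,
        folds=folds,
        mean_fold=float(folds.mean()),
        p_value=p,
    )


def ddct_table(
    table: pd.DataFrame,
    genes=None,
    ref_gene: str = "GAPDH",
    ref_stage: str = "oocyte",
) -> pd.DataFrame:
    """2^-ddCt fold changes for every (gene, stage) pair present in ``table``."""
    if genes is None:
        genes = [g for g in table["gene"].unique() if g != ref_gene]
    rows = []
    stages = [s for s in STAGES if s in set(table["stage"])]
    for g in genes:
        for s in stages:
            res = delta_delta_ct(table, g, s, ref_gene=ref_gene, ref_stage=ref_stage)
            rows.append(
                {"gene": g, "stage": s, "mean_fold": res.mean_fold, "p_value": res.p_value}
            )
    return pd.DataFrame(rows)
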