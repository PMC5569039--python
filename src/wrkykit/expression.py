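"""Relative qPCR expression (2^-ddCt), Dunnett testing and FPKM-based calls.

The qPCR route: per-replicate dCt against a reference gene, ddCt against the
control condition's mean dCt, fold change 2^-ddCt (per-condition value is the
arithmetic mean of replicate-level fold changes), then Dunnett many-to-one
tests of each condition's dCt replicates against the control.  Calls: up if
fold change > 1.5 and p < 0.05; down if fold change <= 0.66 and p < 0.05.

The RNA-seq route: FPKM = count * 1e9 / (length * sample total); genes with
mean FPKM > 10 in either arm are valid; fold change = mean(treated) /
mean(control); the "deviation probability" is the seeded-bootstrap fraction
of replicate resamples whose fold change stays beyond the relevant
threshold; calls need fold change >= 1.5 (or <= 0.66) and probability >= 0.8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UP_THRESHOLD = 1.5
DOWN_THRESHOLD = 0.66
ALPHA = 0.05
FPKM_VALIDITY = 10.0
DEVIATION_PROB = 0.8
DEFAULT_DUNNETT_DRAWS = 200_000


@dataclass
class RelativeExpression:
    gene_id: str
    condition: str
    rq: float  # mean over replicate-level 2^-ddCt
    ddct_replicates: list[float] = field(default_factory=list)
    dct_replicates: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class DECall:
    gene_id: str
    condition: str
    fold_change: float
    call: str  # up | down | unchanged
    p_value: Optional[float] = None
    deviation_probability: Optional[float] = None


def ddct(
    table: pd.DataFrame,
    reference_gene: str,
    control_condition: str,
) -> list[RelativeExpression]:
    """Per-gene, per-condition relative expression by the 2^-ddCt method.

    ``table`` columns: gene, condition, replicate, ct.  A replicate missing
    its reference Ct is dropped with a notice; a gene/condition with no
    usable replicates is omitted.
    """
    required = {"gene", "condition", "replicate", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    ref = table[table["gene"] == reference_gene]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    if control_condition not in set(table["condition"]):
        raise ValueError(f"control condition {control_condition!r} absent from table")
    ref_ct = {
        (row.condition, row.replicate): row.ct for row in ref.itertuples()
    }
    out: list[RelativeExpression] = []
    for gene, sub in table[table["gene"] != reference_gene].groupby("gene", sort=True):
        dct: dict[str, list[float]] = {}
        for row in sub.itertuples():
            key = (row.condition, row.replicate)
            if key not in ref_ct or pd.isna(ref_ct[key]) or pd.isna(row.ct):
                logger.info(
                    "gene %s %s rep %s: missing reference Ct; replicate dropped",
                    gene, row.condition, row.replicate,
                )
                continue
            dct.setdefault(row.condition, []).append(row.ct - ref_ct[key])
        if control_condition not in dct or not dct[control_condition]:
            logger.info("gene %s: no usable control replicates; omitted", gene)
            continue
        control_mean = float(np.mean(dct[control_condition]))
        for condition in sorted(dct):
            dd = [v - control_mean for v in dct[condition]]
            rq = float(np.mean([2.0 ** (-x) for x in dd]))
            out.append(RelativeExpression(gene, condition, rq, dd, dct[condition]))
    return out


def dunnett_test(
    control: Sequence[float],
    treatments: Sequence[Sequence[float]],
    n_draws: int = DEFAULT_DUNNETT_DRAWS,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Two-sided Dunnett many-to-one p-values by seeded Monte Carlo.

    Uses the pooled within-group variance; the null distribution of
    ``max_j |T_j|`` is sampled from the joint law of the studentized group
    mean contrasts (correlated normals over a shared chi-square).
    """
    control = np.asarray(control, dtype=float)
    groups = [np.asarray(t, dtype=float) for t in treatments]
    if len(control) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 replicates")
    k = len(groups)
    n0 = len(control)
    ns = np.array([len(g) for g in groups])
    df = int(n0 + ns.sum()) - (k + 1)
    ss = float(((control - control.mean()) ** 2).sum()) + sum(
        float(((g - g.mean()) ** 2).sum()) for g in groups
    )
    s2 = ss / df
    diffs = np.array([g.mean() - control.mean() for g in groups])
    if s2 == 0.0:
        logger.warning("dunnett_test: zero pooled variance (degenerate input)")
        return np.where(diffs == 0.0, 1.0, 0.0)
    se = np.sqrt(s2 * (1.0 / ns + 1.0 / n0))
    tstats = diffs / se
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_draws) / np.sqrt(n0)
    zi = rng.standard_normal((n_draws, k)) / np.sqrt(ns)
    w = rng.chisquare(df, n_draws)
    tnull = (zi - z0[:, None]) / (
        np.sqrt(w / df)[:, None] * np.sqrt(1.0 / ns + 1.0 / n0)
    )
    max_abs = np.abs(tnull).max(axis=1)
    return np.array([float(np.mean(max_abs >= abs(t))) for t in tstats])


def call_de_qpcr(
    results: pd.DataFrame,
    up_threshold: float = UP_THRESHOLD,
    down_threshold: float = DOWN_THRESHOLD,
    alpha: float = ALPHA,
) -> list[DECall]:
    """Apply the qPCR thresholds: up iff rq > up and p < alpha; down iff
    rq <= down and p < alpha; otherwise unchanged.

    ``results`` columns: gene, condition, rq, p_value.
    """
    calls = []
    for row in results.itertuples():
        if row.rq > up_threshold and row.p_value < alpha:
            call = "up"
        elif row.rq <= down_threshold and row.p_value < alpha:
            call = "down"
        else:
            call = "unchanged"
        calls.append(DECall(row.gene, row.condition, row.rq, call, p_value=row.p_value))
    return calls


def qpcr_pipeline(
    table: pd.DataFrame,
    reference_gene: str,
    control_condition: str,
    n_draws: int = DEFAULT_DUNNETT_DRAWS,
    seed: Optional[int] = None,
    up_threshold: float = UP_THRESHOLD,
    down_threshold: float = DOWN_THRESHOLD,
    alpha: float = ALPHA,
) -> tuple[list[RelativeExpression], list[DECall]]:
    """ddct -> Dunnett (dCt replicates vs control) -> threshold calls."""
    rel = ddct(table, reference_gene, control_condition)
    rows = []
    by_gene: dict[str, dict[str, RelativeExpression]] = {}
    for r in rel:
        by_gene.setdefault(r.gene_id, {})[r.condition] = r
    for gene in sorted(by_gene):
        conds = by_gene[gene]
        if control_condition not in conds:
            continue
        others = sorted(c for c in conds if c != control_condition)
        if not others:
            continue
        pvals = dunnett_test(
            conds[control_condition].dct_replicates,
            [conds[c].dct_replicates for c in others],
            n_draws=n_draws,
            seed=seed,
        )
        for c, p in zip(others, pvals):
            rows.append((gene, c, conds[c].rq, float(p)))
    results = pd.DataFrame(rows, columns=["gene", "condition", "rq", "p_value"])
    return rel, call_de_qpcr(results, up_threshold, down_threshold, alpha)


# ---------------------------------------------------------------------------
# FPKM route
# ---------------------------------------------------------------------------


def fpkm(counts: pd.DataFrame) -> pd.DataFrame:
    """Add an ``fpkm`` column: count * 1e9 / (length * sample total count).

    ``counts`` columns: gene, sample, count, length.
    """
    required = {"gene", "sample", "count", "length"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    if (counts["length"] <= 0).any():
        raise ValueError("gene lengths must be > 0")
    totals = counts.groupby("sample")["count"].transform("sum")
    if (totals <= 0).any():
        raise ValueError("every sample must have a positive total count")
    out = counts.copy()
    out["fpkm"] = out["count"] * 1e9 / (out["length"] * totals)
    return out


def call_de_fpkm(
    control: pd.DataFrame,
    treated: pd.DataFrame,
    validity: float = FPKM_VALIDITY,
    up_threshold: float = UP_THRESHOLD,
    down_threshold: float = DOWN_THRESHOLD,
    prob_threshold: float = DEVIATION_PROB,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> tuple[list[DECall], list[str]]:
    """FPKM-rule calls over two replicate matrices (rows genes, cols reps).

    Returns (calls for valid genes, invalid gene ids).  A gene is valid iff
    its mean FPKM exceeds ``validity`` in either arm.  The deviation
    probability is the fraction of paired replicate resamples whose fold
    change stays beyond the threshold on the side indicated by the observed
    fold change.
    """
    if control.shape[1] < 2 or treated.shape[1] < 2:
        raise ValueError("need at least 2 replicates per arm")
    rng = np.random.default_rng(seed)
    calls: list[DECall] = []
    invalid: list[str] = []
    genes = [g for g in control.index if g in set(treated.index)]
    for gene in genes:
        c = control.loc[gene].to_numpy(dtype=float)
        t = treated.loc[gene].to_numpy(dtype=float)
        mc, mt = float(c.mean()), float(t.mean())
        if mc <= validity and mt <= validity:
            invalid.append(gene)
            continue
        fc = _fold(mt, mc)
        bc = c[rng.integers(0, len(c), size=(n_boot, len(c)))].mean(axis=1)
        bt = t[rng.integers(0, len(t), size=(n_boot, len(t)))].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            bfc = np.where(bc > 0, bt / bc, np.where(bt > 0, np.inf, 1.0))
        prob_up = float(np.mean(bfc >= up_threshold))
        prob_down = float(np.mean(bfc <= down_threshold))
        if fc >= up_threshold:
            prob = prob_up
            call = "up" if prob >= prob_threshold else "unchanged"
        elif fc <= down_threshold:
            prob = prob_down
            call = "down" if prob >= prob_threshold else "unchanged"
        else:
            prob = prob_up if fc > 1.0 else prob_down
            call = "unchanged"
        calls.append(DECall(gene, "treated_vs_control", fc, call, deviation_probability=prob))
    return calls, invalid


def _fold(mt: float, mc: float) -> float:
    if mc == 0.0:
        return float("inf") if mt > 0 else 1.0
    return mt / mc
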