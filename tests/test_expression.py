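"""2^-ddCt arithmetic, Dunnett Monte Carlo vs oracles, FPKM rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wrkykit.expression import (
    DECall,
    call_de_fpkm,
    call_de_qpcr,
    ddct,
    dunnett_test,
    fpkm,
    qpcr_pipeline,
)


def _ct_table(rows):
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])


# ---------------------------------------------------------------------------
# ddct
# ---------------------------------------------------------------------------


def test_rq_identity_when_dct_equals_control():
    rows = []
    for rep in (1, 2, 3):
        rows += [("ACT", "0h", rep, 20.0), ("ACT", "2h", rep, 20.0)]
        rows += [("g", "0h", rep, 25.0), ("g", "2h", rep, 25.0)]
    out = {(r.gene_id, r.condition): r for r in ddct(_ct_table(rows), "ACT", "0h")}
    assert out[("g", "2h")].rq == pytest.approx(1.0)
    assert out[("g", "0h")].rq == pytest.approx(1.0)


def test_rq_doubles_for_minus_one_ddct():
    rows = []
    for rep in (1, 2):
        rows += [("ACT", "0h", rep, 20.0), ("ACT", "2h", rep, 20.0)]
        rows += [("g", "0h", rep, 25.0), ("g", "2h", rep, 24.0)]
    out = {(r.gene_id, r.condition): r for r in ddct(_ct_table(rows), "ACT", "0h")}
    assert out[("g", "2h")].rq == pytest.approx(2.0)


def test_missing_reference_replicate_dropped():
    rows = [
        ("ACT", "0h", 1, 20.0), ("ACT", "0h", 2, 20.0),
        ("g", "0h", 1, 25.0), ("g", "0h", 2, 25.5), ("g", "0h", 3, 27.0),
    ]
    out = ddct(_ct_table(rows), "ACT", "0h")
    assert len(out[0].dct_replicates) == 2  # rep 3 lacked a reference Ct


def test_gene_without_control_omitted():
    rows = [
        ("ACT", "0h", 1, 20.0), ("ACT", "0h", 2, 20.0),
        ("ACT", "2h", 1, 20.0), ("ACT", "2h", 2, 20.0),
        ("g", "2h", 1, 24.0), ("g", "2h", 2, 24.0),
    ]
    assert ddct(_ct_table(rows), "ACT", "0h") == []


def test_missing_reference_gene_raises():
    with pytest.raises(ValueError, match="reference gene"):
        ddct(_ct_table([("g", "0h", 1, 25.0)]), "ACT", "0h")


@given(st.floats(-5, 5))
@settings(max_examples=30, deadline=None)
def test_ddct_shift_invariance(shift):
    """Adding a constant to every Ct of one replicate cancels out."""
    rows, shifted = [], []
    for rep in (1, 2, 3):
        for gene, ct in (("ACT", 20.0), ("g", 24.0 + rep * 0.3)):
            rows.append((gene, "0h", rep, ct))
            delta = shift if rep == 2 else 0.0
            shifted.append((gene, "0h", rep, ct + delta))
    base = ddct(_ct_table(rows), "ACT", "0h")
    moved = ddct(_ct_table(shifted), "ACT", "0h")
    assert moved[0].rq == pytest.approx(base[0].rq)
    assert moved[0].ddct_replicates == pytest.approx(base[0].ddct_replicates)


def test_rq_tolerance_under_noise():
    """True 4-fold induction with sigma 0.1: mean rq stays in [3.4, 4.7]."""
    from wrkykit.simulate import gen_ct_table

    rqs = []
    for seed in range(100):
        table, _ = gen_ct_table({"g": {"2h": 4.0}}, sigma=0.1, seed=seed)
        out = {(r.gene_id, r.condition): r for r in ddct(table, "ACT", "0h")}
        rqs.append(out[("g", "2h")].rq)
    assert 3.4 <= float(np.mean(rqs)) <= 4.7
    assert all(3.0 <= r <= 5.3 for r in rqs)


# ---------------------------------------------------------------------------
# Dunnett
# ---------------------------------------------------------------------------


def pooled_t_pvalue(control, treatment):
    """Closed-form two-sided pooled two-sample t-test (k=1 oracle)."""
    c, t = np.asarray(control, float), np.asarray(treatment, float)
    df = len(c) + len(t) - 2
    s2 = (((c - c.mean()) ** 2).sum() + ((t - t.mean()) ** 2).sum()) / df
    tval = (t.mean() - c.mean()) / np.sqrt(s2 * (1 / len(c) + 1 / len(t)))
    return 2 * stats.t.sf(abs(tval), df)


@pytest.mark.parametrize("trial", range(5))
def test_single_group_matches_t_test(trial):
    rng = np.random.default_rng(600 + trial)
    c = rng.normal(0, 1, 4)
    t = rng.normal(rng.uniform(0, 2), 1, 5)
    (p,) = dunnett_test(c, [t], n_draws=200_000, seed=trial)
    assert p == pytest.approx(pooled_t_pvalue(c, t), abs=0.005)


@pytest.mark.parametrize("trial", range(5))
def test_matches_scipy_dunnett(trial):
    rng = np.random.default_rng(700 + trial)
    c = rng.normal(0, 1, 4)
    groups = [rng.normal(mu, 1, 4) for mu in (0.0, 1.0, 2.5)]
    p = dunnett_test(c, groups, n_draws=200_000, seed=trial)
    ref = stats.dunnett(*groups, control=c).pvalue
    assert p == pytest.approx(ref, abs=0.005)


def test_degenerate_zero_variance():
    c = [1.0, 1.0, 1.0]
    p = dunnett_test(c, [[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]], seed=0)
    assert p[0] == 1.0 and p[1] == 0.0


def test_monotone_in_mean_difference():
    c = [0.0, 0.1, -0.1]
    ps = []
    for mu in (0.2, 0.8, 1.6, 3.0):
        (p,) = dunnett_test(c, [[mu, mu + 0.1, mu - 0.1]], n_draws=50_000, seed=1)
        ps.append(p)
    assert ps == sorted(ps, reverse=True)


def test_requires_two_replicates():
    with pytest.raises(ValueError):
        dunnett_test([1.0], [[1.0, 2.0]])


def test_type_I_error_rate():
    """Null data: familywise rejection rate at alpha=0.05 within [0.03, 0.07]."""
    rng = np.random.default_rng(20240903)
    rejections = 0
    n_sims = 1000
    for i in range(n_sims):
        c = rng.normal(0, 1, 3)
        groups = [rng.normal(0, 1, 3) for _ in range(3)]
        p = dunnett_test(c, groups, n_draws=20_000, seed=i)
        rejections += bool((p < 0.05).any())
    assert 0.03 <= rejections / n_sims <= 0.07


# ---------------------------------------------------------------------------
# qPCR calls
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "rq,p,expected",
    [
        (1.6, 0.01, "up"),
        (0.60, 0.01, "down"),
        (1.6, 0.20, "unchanged"),
        (0.66, 0.01, "down"),   # down threshold is non-strict
        (1.5, 0.01, "unchanged"),  # up threshold is strict
        (1.0, 0.5, "unchanged"),
        (1.6, 0.05, "unchanged"),  # alpha is strict
    ],
)
def test_qpcr_thresholds(rq, p, expected):
    df = pd.DataFrame([("g", "2h", rq, p)], columns=["gene", "condition", "rq", "p_value"])
    (call,) = call_de_qpcr(df)
    assert call.call == expected


def test_up_down_disjoint():
    rng = np.random.default_rng(31)
    df = pd.DataFrame(
        [("g%d" % i, "2h", rng.uniform(0.1, 3.0), rng.uniform(0, 1)) for i in range(50)],
        columns=["gene", "condition", "rq", "p_value"],
    )
    calls = call_de_qpcr(df)
    ups = {c.gene_id for c in calls if c.call == "up"}
    downs = {c.gene_id for c in calls if c.call == "down"}
    assert not (ups & downs)


def test_qpcr_parameter_recovery():
    """Fold 4, sigma 0.2, n=3: up-call rate >= 0.9; fold 1: <= 0.1."""
    from wrkykit.simulate import gen_ct_table

    def rate(fold):
        ups = 0
        n = 200
        for seed in range(n):
            table, _ = gen_ct_table({"g": {"2h": fold}}, sigma=0.2, seed=seed)
            _, calls = qpcr_pipeline(table, "ACT", "0h", n_draws=10_000, seed=seed)
            ups += calls[0].call == "up"
        return ups / n

    assert rate(4.0) >= 0.9
    assert rate(1.0) <= 0.1


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------


def _counts(rows):
    return pd.DataFrame(rows, columns=["gene", "sample", "count", "length"])


def test_fpkm_arithmetic():
    out = fpkm(_counts([("g", "s", 100, 1000)]))
    assert out["fpkm"].iloc[0] == pytest.approx(1e6)


def test_fpkm_scale_invariance():
    rows = [("g1", "s", 100, 1000), ("g2", "s", 300, 500)]
    base = fpkm(_counts(rows))["fpkm"]
    doubled = fpkm(_counts([(g, s, 2 * c, l) for g, s, c, l in rows]))["fpkm"]
    assert doubled.tolist() == pytest.approx(base.tolist())


def test_fpkm_hand_oracle():
    rows = [
        ("g1", "s1", 10, 2000), ("g2", "s1", 40, 500), ("g3", "s1", 50, 1000),
    ]
    out = fpkm(_counts(rows))
    total = 100
    assert out["fpkm"].tolist() == pytest.approx(
        [10 * 1e9 / (2000 * total), 40 * 1e9 / (500 * total), 50 * 1e9 / (1000 * total)]
    )


def test_fpkm_errors():
    with pytest.raises(ValueError, match="length"):
        fpkm(_counts([("g", "s", 5, 0)]))
    with pytest.raises(ValueError, match="total"):
        fpkm(_counts([("g", "s", 0, 100)]))


def _arm(values):
    return pd.DataFrame(
        {f"r{i+1}": col for i, col in enumerate(np.asarray(values).T)},
        index=[f"g{j+1}" for j in range(np.asarray(values).shape[0])],
    )


def test_fpkm_call_up_tight_replicates():
    control = _arm([[100.0, 102.0, 98.0]])
    treated = _arm([[200.0, 205.0, 195.0]])
    (call,), invalid = call_de_fpkm(control, treated, seed=0)
    assert call.call == "up"
    assert call.deviation_probability >= 0.99
    assert invalid == []


def test_fpkm_validity_filter():
    control = _arm([[5.0, 5.0, 5.0]])
    treated = _arm([[5.0, 5.0, 5.0]])
    calls, invalid = call_de_fpkm(control, treated, seed=0)
    assert calls == [] and invalid == ["g1"]


def test_fpkm_identical_arms_unchanged():
    control = _arm([[50.0, 52.0, 48.0]])
    (call,), _ = call_de_fpkm(control, control.copy(), seed=0)
    assert call.fold_change == pytest.approx(1.0)
    assert call.call == "unchanged"


def test_fpkm_zero_control_infinite_fold():
    control = _arm([[0.0, 0.0, 0.0]])
    treated = _arm([[50.0, 60.0, 55.0]])
    (call,), _ = call_de_fpkm(control, treated, seed=0)
    assert np.isinf(call.fold_change)
    assert call.call == "up"


def test_fpkm_needs_two_replicates():
    with pytest.raises(ValueError):
        call_de_fpkm(_arm([[1.0]]), _arm([[1.0]]))
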