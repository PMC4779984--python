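"""Nested ANOVA and variance-component estimation.

The implementation is cross-checked against an independent brute-force
oracle that forms sums of squares from explicitly computed group means
with plain Python loops, and solves the same EMS system.
"""

import numpy as np
import pandas as pd
import pytest

from cqplan import (CqDataset, EstimabilityError, SimulationSpec,
                    estimate_components, nested_anova, simulate_stratum)

# ---------------------------------------------------------------- oracle --


def brute_force_nested(df: pd.DataFrame):
    """Independent method-of-moments oracle (loops and dicts only)."""
    df = df[df["cq"].notna()]
    y = {(r.rna_rep, r.rt_rep, r.qpcr_rep): r.cq for r in df.itertuples()}
    exts = sorted({i for i, _, _ in y})
    grand = sum(y.values()) / len(y)

    ss_s = ss_rt = ss_q = 0.0
    n_i, n_ij = {}, {}
    for i in exts:
        vals_i = [v for (ii, _, _), v in y.items() if ii == i]
        n_i[i] = len(vals_i)
        mean_i = sum(vals_i) / len(vals_i)
        ss_s += len(vals_i) * (mean_i - grand) ** 2
        rts = sorted({j for (ii, j, _) in y if ii == i})
        for j in rts:
            vals_ij = [v for (ii, jj, _), v in y.items() if ii == i and jj == j]
            n_ij[(i, j)] = len(vals_ij)
            mean_ij = sum(vals_ij) / len(vals_ij)
            ss_rt += len(vals_ij) * (mean_ij - mean_i) ** 2
            ss_q += sum((v - mean_ij) ** 2 for v in vals_ij)

    a = len(exts)
    b = len(n_ij)
    n = len(y)
    ms_s, ms_rt, ms_q = ss_s / (a - 1), ss_rt / (b - a), ss_q / (n - b)
    sum_nij2_over_ni = sum(
        sum(n_ij[(i, j)] ** 2 for (ii, j) in n_ij if ii == i) / n_i[i]
        for i in exts
    )
    c1 = (n - sum_nij2_over_ni) / (b - a)
    c2 = (sum_nij2_over_ni - sum(v**2 for v in n_ij.values()) / n) / (a - 1)
    c3 = (n - sum(v**2 for v in n_i.values()) / n) / (a - 1)

    vq = ms_q
    vrt = (ms_rt - ms_q) / c1
    vs = (ms_s - ms_q - c2 * vrt) / c3
    return dict(ss=(ss_s, ss_rt, ss_q), c=(c1, c2, c3),
                components=(vs, vrt, vq), mu=grand)


# ----------------------------------------------------------------- tests --


def test_balanced_ems_coefficients(balanced_stratum):
    """4 extractions x 4 RTs x 3 qPCRs gives the textbook (3, 3, 12)."""
    t = nested_anova(balanced_stratum)
    assert (t.c1, t.c2, t.c3) == (3.0, 3.0, 12.0)
    assert t.df == {"sampling": 3, "rt": 12, "qpcr": 32}


def test_unbalanced_ems_coefficients_hand_checked(unbalanced_stratum):
    """Extractions with (2, 3) RTs, 2 wells each: c1=2, c2=2, c3=4.8."""
    t = nested_anova(unbalanced_stratum)
    assert t.c1 == pytest.approx(2.0)
    assert t.c2 == pytest.approx(2.0)
    assert t.c3 == pytest.approx(4.8)


def test_matches_brute_force_oracle(unbalanced_stratum, balanced_stratum):
    for ds in (unbalanced_stratum, balanced_stratum):
        t = nested_anova(ds)
        oracle = brute_force_nested(ds.data)
        assert t.ss["sampling"] == pytest.approx(oracle["ss"][0], abs=1e-10)
        assert t.ss["rt"] == pytest.approx(oracle["ss"][1], abs=1e-10)
        assert t.ss["qpcr"] == pytest.approx(oracle["ss"][2], abs=1e-10)
        assert (t.c1, t.c2, t.c3) == pytest.approx(oracle["c"])
        vc = estimate_components(ds, truncate=False)
        assert vc.raw["sampling"] == pytest.approx(oracle["components"][0])
        assert vc.raw["rt"] == pytest.approx(oracle["components"][1])
        assert vc.raw["qpcr"] == pytest.approx(oracle["components"][2])
        assert vc.mu == pytest.approx(oracle["mu"])


def test_missing_records_change_ems_coefficients(balanced_stratum):
    """Complete-case analysis recomputes coefficients from realized sizes."""
    df = balanced_stratum.data.copy()
    df.loc[df.index[:2], "cq"] = np.nan  # knock out 2 wells of RT (1,1)
    t = nested_anova(CqDataset(df))
    assert t.n_obs == 46
    assert t.c1 != 3.0
    oracle = brute_force_nested(df)
    assert (t.c1, t.c2, t.c3) == pytest.approx(oracle["c"])


def test_constant_cq_gives_zero_components():
    df = simulate_stratum(SimulationSpec(
        mu=25.0, sd_sampling=0, sd_rt=0, sd_qpcr=0, seed=0))
    t = nested_anova(df)
    assert all(s == 0.0 for s in t.ss.values())
    vc = estimate_components(df)
    assert (vc.var_sampling, vc.var_rt, vc.var_qpcr) == (0.0, 0.0, 0.0)
    assert vc.mu == pytest.approx(25.0)


def test_balanced_equivalence_closed_form():
    """Generic unbalanced path equals the balanced closed form to 1e-10."""
    ds = simulate_stratum(SimulationSpec(
        mu=24, sd_sampling=0.6, sd_rt=0.5, sd_qpcr=0.25, seed=9,
        n_sampling=5, n_rt=3, n_qpcr=4))
    y = (ds.data.sort_values(["rna_rep", "rt_rep", "qpcr_rep"])["cq"]
         .to_numpy().reshape(5, 3, 4))
    ms_q = ((y - y.mean(2, keepdims=True)) ** 2).sum() / (5 * 3 * (4 - 1))
    m_ij, m_i = y.mean(2), y.mean((1, 2))
    ms_rt = 4 * ((m_ij - m_i[:, None]) ** 2).sum() / (5 * (3 - 1))
    ms_s = 12 * ((m_i - y.mean()) ** 2).sum() / (5 - 1)
    closed = (
        (ms_s - ms_rt) / 12.0,
        (ms_rt - ms_q) / 4.0,
        ms_q,
    )
    vc = estimate_components(ds, truncate=False)
    assert vc.raw["sampling"] == pytest.approx(closed[0], abs=1e-10)
    assert vc.raw["rt"] == pytest.approx(closed[1], abs=1e-10)
    assert vc.raw["qpcr"] == pytest.approx(closed[2], abs=1e-10)


def test_permutation_invariance(balanced_stratum):
    """Replicate indices are nominal: renumbering changes nothing."""
    rng = np.random.default_rng(0)
    df = balanced_stratum.data.copy()
    # remap rna_rep globally, rt_rep within extraction, qpcr_rep within RT
    rna_map = dict(zip([1, 2, 3, 4], rng.permutation([1, 2, 3, 4])))
    df["rt_rep"] = df.groupby("rna_rep")["rt_rep"].transform(
        lambda s: s.map(dict(zip(sorted(s.unique()),
                                 rng.permutation(sorted(s.unique()))))))
    df["rna_rep"] = df["rna_rep"].map(rna_map)
    a, b = estimate_components(balanced_stratum), estimate_components(CqDataset(df))
    assert a.var_sampling == pytest.approx(b.var_sampling)
    assert a.var_rt == pytest.approx(b.var_rt)
    assert a.var_qpcr == pytest.approx(b.var_qpcr)


def test_truncation_only_on_negative_raw():
    """Truncation fires iff the raw moment solution is negative."""
    # tiny upstream noise, big well noise -> negative sampling estimates common
    hits = 0
    for seed in range(30):
        ds = simulate_stratum(SimulationSpec(
            mu=24, sd_sampling=0.0, sd_rt=0.05, sd_qpcr=0.8, seed=seed))
        vc = estimate_components(ds)
        raw = estimate_components(ds, truncate=False)
        for lv in ("sampling", "rt", "qpcr"):
            if lv in vc.truncated:
                assert raw.raw[lv] < 0
                hits += 1
            else:
                assert raw.raw[lv] >= 0
    assert hits > 0  # scenario does produce truncations


def test_zero_df_levels_flagged(balanced_stratum):
    single_ext = CqDataset(
        balanced_stratum.data[balanced_stratum.data["rna_rep"] == 1])
    t = nested_anova(single_ext)
    assert "sampling" in t.non_estimable
    vc = estimate_components(single_ext)
    assert np.isnan(vc.var_sampling)
    assert np.isfinite(vc.var_rt) and np.isfinite(vc.var_qpcr)


def test_empty_stratum_raises():
    with pytest.raises(EstimabilityError):
        nested_anova(pd.DataFrame(
            {"rna_rep": [], "rt_rep": [], "qpcr_rep": [], "cq": []}))


def test_estimates_converge_with_design_size():
    """RMSE of component estimates shrinks as the design grows."""
    truth = np.array([0.45, 0.73, 0.32]) ** 2
    rmse = {}
    for dims, tag in [((4, 4, 3), "small"), ((12, 12, 6), "large")]:
        errs = []
        for r in range(40):
            ds = simulate_stratum(SimulationSpec(
                mu=24, sd_sampling=0.45, sd_rt=0.73, sd_qpcr=0.32,
                n_sampling=dims[0], n_rt=dims[1], n_qpcr=dims[2],
                seed=1000 * (dims[0]) + r))
            vc = estimate_components(ds, truncate=False)
            est = np.array([vc.raw["sampling"], vc.raw["rt"], vc.raw["qpcr"]])
            errs.append(est - truth)
        rmse[tag] = np.sqrt((np.array(errs) ** 2).mean(0))
    assert (rmse["large"] < rmse["small"]).all()
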