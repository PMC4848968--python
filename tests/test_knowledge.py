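"""Flag probabilities, class-imbalance correction, alteration, curation,
regime assignment and side-chain entropy."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mutddg.knowledge import (
    alter_ddg,
    build_tables,
    compute_delta_n,
    curate_dataset,
    entropy_sum,
    estimate_probability,
    load_default_tables,
    lookup_flags,
    side_chain_entropy,
)
from mutddg.synth import SyntheticDatasetSpec, make_labeled_dataset, make_peptide


def toy_table():
    rows = [
        # exact duplicate pair
        dict(protein="P1", chain="A", position=1, wt="A", mt="G", ddg=1.2, ph=7.0),
        dict(protein="P1", chain="A", position=1, wt="A", mt="G", ddg=1.2, ph=7.0),
        # pH outlier
        dict(protein="P1", chain="A", position=2, wt="L", mt="P", ddg=2.0, ph=3.0),
        # consistent repeat group (spread 0.05 < 0.1)
        dict(protein="P2", chain="A", position=5, wt="V", mt="A", ddg=0.50, ph=7.0),
        dict(protein="P2", chain="A", position=5, wt="V", mt="A", ddg=0.55, ph=7.0),
        # singleton
        dict(protein="P3", chain="A", position=9, wt="K", mt="E", ddg=-0.3, ph=6.5),
    ]
    return pd.DataFrame(rows)


def test_curation_hand_trace():
    curated, audit = curate_dataset(toy_table())
    assert len(curated) == 3
    assert audit["duplicates_removed"] == 1
    assert audit["ph_removed"] == 1
    assert audit["fused_away"] == 1
    fused = curated[(curated["protein"] == "P2")]["ddg"].iloc[0]
    assert fused == pytest.approx(0.525)


def test_curation_identity_on_clean_table():
    df = toy_table().iloc[[0, 3, 5]].reset_index(drop=True)
    df["ph"] = 7.0
    curated, audit = curate_dataset(df)
    assert len(curated) == 3
    assert audit["inconsistent_removed"] == 0
    assert curated["ddg"].tolist() == df["ddg"].tolist()


def test_curation_drops_inconsistent_group():
    df = pd.DataFrame(
        [
            dict(protein="P", chain="A", position=1, wt="A", mt="G", ddg=0.5, ph=7.0),
            dict(protein="P", chain="A", position=1, wt="A", mt="G", ddg=1.0, ph=7.0),
        ]
    )
    curated, audit = curate_dataset(df)
    assert len(curated) == 0
    assert audit["inconsistent_removed"] == 2


def test_curation_missing_column():
    with pytest.raises(ValueError, match="missing required column"):
        curate_dataset(pd.DataFrame([{"protein": "P"}]))


def test_delta_n_reconstruction():
    ddg = [1.5] * 652 + [0.5] * 610
    assert compute_delta_n(ddg) == pytest.approx(0.069, abs=0.001)


def test_delta_n_balanced_and_antisymmetric():
    assert compute_delta_n([1.5] * 10 + [0.5] * 10) == 0.0
    a = compute_delta_n([1.5] * 7 + [0.5] * 3)
    b = compute_delta_n([1.5] * 3 + [0.5] * 7)
    assert math.log(1 + a) == pytest.approx(-math.log(1 + b), rel=1e-12)


def test_delta_n_empty_subset():
    with pytest.raises(ValueError):
        compute_delta_n([2.0, 3.0])


@pytest.mark.parametrize(
    "m_large,m_total,dn,expected",
    [
        (50, 100, 0.0, 0.5),
        (51, 91, 0.069, 0.599),  # back-calculated Ala wild-type entry
        (3, 4, 0.069, 0.5),      # sparse category rule
        (100, 100, 0.5, 1.0),    # clipped at 1
    ],
)
def test_estimate_probability(m_large, m_total, dn, expected):
    assert estimate_probability(m_large, m_total, dn) == pytest.approx(
        expected, abs=0.0005
    )


def test_estimate_probability_validates():
    with pytest.raises(ValueError):
        estimate_probability(5, 3)


@settings(max_examples=100, derandomize=True)
@given(st.integers(5, 200), st.integers(0, 200))
def test_estimate_probability_monotone(m_total, m_large):
    m_large = min(m_large, m_total)
    p1 = estimate_probability(m_large, m_total, 0.0)
    assert p1 == pytest.approx(m_large / m_total)
    if m_large < m_total:
        assert estimate_probability(m_large + 1, m_total, 0.0) >= p1


@pytest.mark.parametrize(
    "ddg,probs,expected",
    [
        (0.8, (0.5, 0.5, 0.5), 0.8),   # no-alteration identity
        (0.6, (1.0, 1.0, 1.0), 1.2),
        (2.0, (0.0, 0.0, 0.0), 4.0),
        (2.0, (0.5, 0.5, 0.5), 2.0),
    ],
)
def test_alter_ddg(ddg, probs, expected):
    assert alter_ddg(ddg, probs) == pytest.approx(expected)


def test_alter_ddg_linear_within_branches():
    probs = (0.3, 0.6, 0.9)
    for lo, hi in ((0.2, 0.8), (1.2, 1.8)):
        f_lo = alter_ddg(lo, probs)
        f_mid = alter_ddg((lo + hi) / 2, probs)
        f_hi = alter_ddg(hi, probs)
        assert f_mid == pytest.approx((f_lo + f_hi) / 2, rel=1e-12)


def test_alter_ddg_rejects_bad_input():
    with pytest.raises(ValueError):
        alter_ddg(-0.1, (0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        alter_ddg(0.5, (1.5, 0.5, 0.5))


def test_build_tables_balanced_fixed_point():
    """Everything-at-0.5 data is a fixed point of the raw and altered
    probabilities, up to per-category binomial error (3.5 sigma)."""
    spec = SyntheticDatasetSpec(n=2000)
    df = make_labeled_dataset(spec, seed=11)
    t = build_tables(df)
    counts = {"wt": t.counts_wt, "mt": t.counts_mt, "loc": t.counts_loc, "sse": t.counts_sse}
    for flag, raw, prime in (
        ("wt", t.p_wt, t.pprime_wt),
        ("mt", t.p_mt, t.pprime_mt),
        ("loc", t.p_loc, t.pprime_loc),
        ("sse", t.p_sse, t.pprime_sse),
    ):
        for cat, p in raw.items():
            tol = 3.5 * math.sqrt(0.25 / max(counts[flag][cat], 1))
            assert p == pytest.approx(0.5, abs=max(tol, 1e-9)), (flag, cat)
        for cat, p in prime.items():
            tol = 3.5 * math.sqrt(0.25 / max(counts[flag][cat], 1))
            assert p == pytest.approx(0.5, abs=max(tol, 0.02)), (flag, cat)


def test_build_tables_degenerate_category():
    df = make_labeled_dataset(SyntheticDatasetSpec(n=400), seed=2)
    # force one wild-type category to be always-large
    df.loc[df.index[:50], "wt"] = "W"
    df.loc[df.index[:50], "ddg"] = 2.5
    df = df[(df["wt"] != "W") | (df.index < 50)]
    t = build_tables(df)
    assert t.p_wt["W"] == pytest.approx(1.0, abs=1e-9) or t.p_wt["W"] == 1.0


def test_build_tables_order_invariance():
    df = make_labeled_dataset(SyntheticDatasetSpec(n=500), seed=3)
    t1 = build_tables(df)
    t2 = build_tables(df.sample(frac=1.0, random_state=9).reset_index(drop=True))
    assert t1.p_wt == t2.p_wt
    assert t1.pprime_sse == t2.pprime_sse


def test_lookup_flags_printed_values():
    """L->G in a buried helix pair: mean of the bundled altered probabilities
    (0.80, 0.69, 0.70, 0.53) = 0.68 -> large regime."""
    f = lookup_flags("L", "G", "B-B", "HH")
    assert f.p_wt == pytest.approx(0.80)
    assert f.p_mt == pytest.approx(0.69)
    assert f.p_loc == pytest.approx(0.70)
    assert f.p_sse == pytest.approx(0.53)
    assert f.combined == pytest.approx(0.68)
    assert f.regime == "large"


def test_lookup_flags_small_case():
    f = lookup_flags("K", "Q", "E-E", "CC")
    assert f.combined == pytest.approx((0.20 + 0.30 + 0.29 + 0.45) / 4)
    assert f.regime == "small"


def test_boundary_probability_is_large():
    from mutddg.knowledge import FlagProbabilities

    f = FlagProbabilities(0.5, 0.5, 0.5, 0.5)
    assert f.combined == 0.5
    assert f.regime == "large"


def test_unknown_code_falls_back_to_half(caplog):
    import logging

    with caplog.at_level(logging.WARNING):
        f = lookup_flags("L", "G", "Z-Z", "HH")
    assert f.p_loc == 0.5
    assert any("unknown" in r.message for r in caplog.records)


@pytest.mark.parametrize(
    "rsasa,R,expected",
    [(0.0, 7, 0.0), (1.0, 3, math.log(3)), (0.5, 9, math.log(5))],
)
def test_side_chain_entropy(rsasa, R, expected):
    assert side_chain_entropy(rsasa, R) == pytest.approx(expected)


def test_side_chain_entropy_validates():
    with pytest.raises(ValueError):
        side_chain_entropy(0.5, 0)


def test_entropy_sum_polyalanine_zero():
    pep = make_peptide("AAAAA", "helix")
    assert entropy_sum(pep) == 0.0


def test_entropy_sum_single_contribution():
    """Adding one flexible residue raises Ssum by exactly its own term."""
    from mutddg.knowledge import site_entropy

    pep = make_peptide("AARAA", "helix")
    total = entropy_sum(pep)
    site = site_entropy(pep, "A", 3)
    assert total == pytest.approx(site)
    assert total >= 0.0
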