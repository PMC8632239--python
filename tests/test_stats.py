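"""Rank tests, exact tests, group comparison and the gain metric."""

import subprocess
import textwrap

import numpy as np
import pytest

from navmargin.behavior import TrialRecord
from navmargin.margins import ZONE_CODES, MarginPlaneMap, classify_points, summarize_plane
from navmargin.stats import (
    compare_groups,
    compute_gain,
    fisher_exact_rxc,
    kruskal_wallis,
    steel_dwass_critchlow_fligner,
)


def test_kruskal_wallis_hand_value():
    """Three separated triples: H = 7.2 by the hand rank formula."""
    H, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert H == pytest.approx(7.2, abs=1e-9)
    assert 0 < p < 0.05


def test_kruskal_wallis_degenerate():
    H, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0], [2.0]])
    assert (H, p) == (0.0, 1.0)


def test_kruskal_wallis_validation():
    with pytest.raises(ValueError):
        kruskal_wallis([[1.0]])
    with pytest.raises(ValueError):
        kruskal_wallis([[1.0], []])


def test_sdcf_identical_samples_p_near_one():
    P = steel_dwass_critchlow_fligner([[1, 2, 3, 4]] * 3)
    assert np.all(P >= 0.99)
    assert np.allclose(P, P.T)
    assert np.all(np.diag(P) == 1.0)


def test_sdcf_extreme_group_most_significant():
    g = [[1.0, 2, 3, 4], [2.0, 3, 4, 5], [50.0, 51, 52, 53]]
    P = steel_dwass_critchlow_fligner(g)
    assert P[0, 2] < P[0, 1]
    assert P[1, 2] < P[0, 1]


def test_sdcf_validation():
    with pytest.raises(ValueError, match="3 groups"):
        steel_dwass_critchlow_fligner([[1, 2], [3, 4]])
    with pytest.raises(ValueError, match=">= 2"):
        steel_dwass_critchlow_fligner([[1.0], [2, 3], [4, 5]])


def test_fisher_2x2_matches_classical():
    from scipy.stats import fisher_exact

    for table in ([[3, 1], [1, 3]], [[8, 2], [1, 5]], [[10, 0], [0, 10]]):
        ours = fisher_exact_rxc(table)
        ref = fisher_exact(table).pvalue
        assert ours == pytest.approx(ref, abs=1e-10)


def test_fisher_identical_columns_p_one():
    assert fisher_exact_rxc([[2, 2, 2], [3, 3, 3]]) == pytest.approx(1.0)


def test_fisher_degenerate_margin():
    assert fisher_exact_rxc([[0, 0], [3, 4]]) == 1.0


def test_fisher_2x3_matches_r_reference():
    """Freeman-Halton p agrees with R's fisher.test on 2 x 3 tables."""
    tables = [[[5, 1, 2], [2, 6, 4]], [[1, 3, 5], [4, 2, 0]], [[7, 2, 0], [2, 3, 6]]]
    script = textwrap.dedent(
        """
        tabs <- list(matrix(c(5,2,1,6,2,4),2), matrix(c(1,4,3,2,5,0),2),
                     matrix(c(7,2,2,3,0,6),2))
        for (t in tabs) cat(fisher.test(t)$p.value, "\n")
        """
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    ).stdout.split()
    for table, ref in zip(tables, out):
        assert fisher_exact_rxc(table) == pytest.approx(float(ref), abs=1e-6)


def _record(sid, setting, pairs, preset="S1", portion="superior", rep=0):
    d_ica = np.array([[p[0] for p in pairs]])
    d_tumor = np.array([[p[1] for p in pairs]])
    pm = MarginPlaneMap(
        grid=np.zeros(d_ica.shape + (3,)),
        d_tumor=d_tumor,
        d_ica=d_ica,
        zone=classify_points(d_ica, d_tumor),
    )
    from navmargin.margins import PointerPose

    return TrialRecord(
        surgeon_id=sid,
        preset_id=preset,
        setting=setting,
        portion=portion,
        replicate=rep,
        summary=summarize_plane(pm),
        pose=PointerPose(tip=[0, 0, 0], shaft_axis=[1, 0, 0]),
    )


GREEN = (5.0, 7.0)
RED = (-1.0, 7.0)
Y1 = (5.0, -1.0)


def test_compare_groups_duplicated_map_degenerate():
    """All records identical: every p-value is 1 and means equal the map."""
    records = [
        _record(s, setting, [GREEN, GREEN, Y1], rep=r)
        for s in range(2)
        for setting in ("unguided", "tumor_guided", "carotid_guided")
        for r in range(2)
    ]
    cmp = compare_groups(records)
    for code in ZONE_CODES:
        assert cmp.zone_tests[code]["p"] == pytest.approx(1.0)
    for setting in cmp.settings:
        assert cmp.zone_means["G"][setting] == pytest.approx(200.0 / 3.0)
        assert cmp.zone_means["Y1"][setting] == pytest.approx(100.0 / 3.0)
    for flag in ("intratumoral", "ica_damaged"):
        assert cmp.flag_tables[flag]["p"] == pytest.approx(1.0)


def test_compare_groups_hand_built_means():
    records = [
        _record(0, "unguided", [RED, GREEN]),
        _record(0, "unguided", [GREEN, GREEN]),
        _record(0, "tumor_guided", [GREEN, GREEN]),
        _record(0, "tumor_guided", [GREEN, GREEN]),
        _record(0, "carotid_guided", [GREEN, GREEN]),
        _record(0, "carotid_guided", [GREEN, Y1]),
    ]
    cmp = compare_groups(records)
    assert cmp.zone_means["R"]["unguided"] == pytest.approx(25.0)
    assert cmp.zone_means["G"]["unguided"] == pytest.approx(75.0)
    assert cmp.zone_means["G"]["tumor_guided"] == pytest.approx(100.0)
    assert cmp.zone_means["G"]["carotid_guided"] == pytest.approx(75.0)
    assert cmp.flag_tables["ica_damaged"]["table"].tolist() == [[1, 0, 0], [1, 2, 2]]


def test_compare_groups_means_sum_to_100(models):
    from navmargin.behavior import simulate_study

    records = simulate_study({"S2": models["S2"]}, n_surgeons=3, seed=4)
    cmp = compare_groups(records)
    for setting in cmp.settings:
        total = sum(cmp.zone_means[code][setting] for code in ZONE_CODES)
        assert total == pytest.approx(100.0, abs=0.1)


def test_compare_groups_order_invariant():
    records = [
        _record(s, setting, [GREEN, RED] if s % 2 else [GREEN, GREEN])
        for s in range(4)
        for setting in ("unguided", "tumor_guided", "carotid_guided")
    ]
    a = compare_groups(records)
    b = compare_groups(records[::-1])
    for code in ZONE_CODES:
        assert a.zone_tests[code]["p"] == pytest.approx(b.zone_tests[code]["p"])
        assert a.zone_means[code] == b.zone_means[code]


def test_compare_groups_missing_setting_warns():
    records = [
        _record(0, "unguided", [GREEN]),
        _record(0, "unguided", [GREEN], rep=1),
        _record(0, "tumor_guided", [GREEN]),
        _record(0, "tumor_guided", [GREEN], rep=1),
    ]
    with pytest.warns(UserWarning, match="zero records"):
        cmp = compare_groups(records)
    assert "carotid_guided" not in cmp.settings


def test_gain_hand_computed():
    """Two surgeons improving 0.5->0.8 and 0.6->0.9: gains 30% and 30%."""
    records = []
    for sid, (u_clear, g_clear) in enumerate([(5, 8), (6, 9)]):
        for i in range(10):
            records.append(_record(sid, "unguided", [GREEN] if i < u_clear else [Y1], rep=i))
            records.append(_record(sid, "tumor_guided", [GREEN] if i < g_clear else [Y1], rep=i))
    gain = compute_gain(records)
    assert gain.per_surgeon[0]["clear_margin"] == pytest.approx(30.0)
    assert gain.per_surgeon[1]["clear_margin"] == pytest.approx(30.0)
    assert gain.mean_clear_margin == pytest.approx(30.0)
    assert gain.range_clear_margin == (pytest.approx(30.0), pytest.approx(30.0))


def test_gain_zero_when_identical():
    records = []
    for setting in ("unguided", "tumor_guided"):
        for i in range(4):
            records.append(_record(0, setting, [GREEN, Y1], rep=i))
    gain = compute_gain(records)
    assert gain.mean_clear_margin == pytest.approx(0.0)
    assert gain.mean_carotid_spared == pytest.approx(0.0)


def test_gain_excludes_incomplete_surgeon():
    records = [
        _record(0, "unguided", [GREEN]),
        _record(0, "tumor_guided", [GREEN]),
        _record(1, "tumor_guided", [GREEN]),
    ]
    with pytest.warns(UserWarning, match="lacks"):
        gain = compute_gain(records)
    assert list(gain.per_surgeon) == [0]
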