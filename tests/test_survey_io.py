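import io
import textwrap

import numpy as np
import pandas as pd
import pytest

from lichencoda import (BlankSeries, ElementPanel, aggregate_replicates,
                        clr_matrix, compute_lod, compositional_pca,
                        group_geometric_means, harmonize_units,
                        normalize_to_reference, read_concentrations,
                        replace_below_lod, write_concentrations)
from lichencoda.survey_io import SchemaError, ValidationError
from lichencoda.datasets import PANEL


def _csv(text):
    return io.StringIO(textwrap.dedent(text))


SMALL = """\
    sample_id,group,Co,Cu,Cr,Fe,Ni,Zn,Ti
    a,G1,1,2,3,0.1,5,6,7
    abis,G1,1.1,2.2,3.3,0.11,5.5,6.6,7.7
    b,G1,2,3,4,0.2,6,7,8
    c,G2,4,5,6,0.4,8,9,10
    d,G2,1,1,1,1,1,1,1
    e,G2,9,8,7,0.6,5,4,3
    """


def test_roundtrip_preserves_everything(survey, tmp_path):
    p = tmp_path / "t.csv"
    write_concentrations(survey, p)
    back = read_concentrations(p, survey.panel)
    assert back.sample_ids == survey.sample_ids
    assert (back.groups.values == survey.groups.values).all()
    np.testing.assert_allclose(back.values.values, survey.values.values)
    assert any(s.endswith("bis") for s in back.sample_ids)


def test_read_validation_errors():
    panel = PANEL
    with pytest.raises(SchemaError):
        read_concentrations(_csv("""\
            sample_id,group,Co,Cu,Cr,Fe,Zn,Ti
            a,G,1,1,1,1,1,1
            """), panel)                      # Ni column missing
    with pytest.raises(ValidationError, match="duplicate"):
        read_concentrations(_csv("""\
            sample_id,group,Co,Cu,Cr,Fe,Ni,Zn,Ti
            a,G,1,1,1,1,1,1,1
            a,G,2,2,2,2,2,2,2
            """), panel)
    with pytest.raises(ValidationError, match="non-positive"):
        read_concentrations(_csv("""\
            sample_id,group,Co,Cu,Cr,Fe,Ni,Zn,Ti
            a,G,1,1,-1,1,1,1,1
            """), panel)


def test_single_row_all_ones_accepted():
    t = read_concentrations(_csv("""\
        sample_id,group,Co,Cu,Cr,Fe,Ni,Zn,Ti
        only,G,1,1,1,1,1,1,1
        """), PANEL)
    assert t.n_samples == 1
    assert (t.values.values == 1).all()


def test_lod_token_flagged_and_replaced():
    t = read_concentrations(_csv("""\
        sample_id,group,Co,Cu,Cr,Fe,Ni,Zn,Ti
        a,G,<LOD,2,3,0.1,5,6,7
        b,G,1,2,3,0.1,5,6,7
        """), PANEL)
    assert t.below_lod.loc["a", "Co"]
    fixed = replace_below_lod(t, {"Co": 0.2}, fraction=0.65)
    assert fixed.values.loc["a", "Co"] == pytest.approx(0.13)
    # fraction = 1 boundary: the cell equals the LOD exactly
    full = replace_below_lod(t, {"Co": 0.2}, fraction=1.0)
    assert full.values.loc["a", "Co"] == pytest.approx(0.2)
    # replacement never pushes the table minimum below fraction * min(LOD)
    floor = min(0.65 * 0.2, t.values.values[~t.below_lod.values].min())
    assert fixed.values.values.min() >= floor - 1e-12
    with pytest.raises(ValidationError):
        replace_below_lod(t, {}, fraction=0.5)
    # a table without flags is returned unchanged
    clean = read_concentrations(_csv(SMALL), PANEL)
    same = replace_below_lod(clean, {"Co": 0.2})
    np.testing.assert_allclose(same.values.values, clean.values.values)


def test_harmonize_units_converts_and_is_idempotent(survey):
    h1 = harmonize_units(survey)
    # sample 1: Fe 0.19 %w/w -> 1900 ug/g
    assert h1.values.loc["1", "Fe"] == pytest.approx(1900.0)
    # already-ug/g columns untouched
    assert h1.values.loc["1", "Ni"] == survey.values.loc["1", "Ni"]
    h2 = harmonize_units(h1)
    np.testing.assert_allclose(h2.values.values, h1.values.values)


def test_pca_invariant_to_unit_harmonization(survey):
    raw = compositional_pca(clr_matrix(survey.values))
    harm = compositional_pca(clr_matrix(harmonize_units(survey).values))
    np.testing.assert_allclose(raw.var_explained, harm.var_explained,
                               atol=1e-10)


def test_compute_lod():
    assert compute_lod(BlankSeries("Co", (1.0, 1.0, 1.0))) == 0.0
    lod = compute_lod(BlankSeries("Co", (0, 0, 0, 0, 1)))
    assert lod == pytest.approx(3 * 0.4472136, rel=1e-5)  # n-1 denominator
    double = compute_lod(BlankSeries("Co", (0, 0, 0, 0, 2)))
    assert double == pytest.approx(2 * lod)
    with pytest.raises(ValidationError):
        BlankSeries("Co", (1.0,))


class TestAggregateReplicates:
    def test_geometric_mean_is_orderless(self):
        for order in (("4", "16"), ("16", "4")):
            vals = pd.DataFrame(
                {e: [float(order[0]), float(order[1])] for e in PANEL.names},
                index=["s", "sbis"])
            from lichencoda import ConcentrationTable
            t = ConcentrationTable(vals, pd.Series(["G", "G"],
                                   index=vals.index), PANEL)
            m = aggregate_replicates(t, "geometric_mean")
            assert m.values.loc["s", "Co"] == pytest.approx(8.0)

    def test_row_counts_on_bundled_survey(self, survey):
        assert aggregate_replicates(survey, "keep_all").n_samples == 39
        assert aggregate_replicates(survey, "geometric_mean").n_samples == 34
        assert aggregate_replicates(survey, "first").n_samples == 34

    def test_singletons_unchanged(self, survey):
        m = aggregate_replicates(survey, "geometric_mean")
        np.testing.assert_allclose(m.values.loc["27"].values,
                                   survey.values.loc["27"].values)

    def test_mixed_group_replicates_rejected(self):
        from lichencoda import ConcentrationTable
        vals = pd.DataFrame(1.0, index=["x", "xbis"], columns=list(PANEL.names))
        t = ConcentrationTable(vals, pd.Series(["G1", "G2"], index=vals.index),
                               PANEL)
        with pytest.raises(ValidationError, match="group"):
            aggregate_replicates(t, "geometric_mean")

    def test_commutes_with_harmonize(self, survey):
        a = aggregate_replicates(harmonize_units(survey), "geometric_mean")
        b = harmonize_units(aggregate_replicates(survey, "geometric_mean"))
        np.testing.assert_allclose(a.values.values, b.values.values,
                                   rtol=1e-12)


def test_group_geometric_means(survey):
    t = read_concentrations(_csv("""\
        sample_id,group,Co,Cu,Cr,Fe,Ni,Zn,Ti
        a,G,1,1,1,1,1,1,1
        b,G,100,100,100,100,100,100,100
        """), PANEL)
    gm = group_geometric_means(t)
    np.testing.assert_allclose(gm.loc["G"].values, 10.0)
    # log-space oracle on the bundled survey
    h = harmonize_units(survey)
    gm = group_geometric_means(h)
    oracle = np.exp(np.log(h.values).groupby(h.groups.values).mean())
    np.testing.assert_allclose(gm.values, oracle.loc[gm.index].values,
                               rtol=1e-12)


def test_normalize_to_reference(harmonized):
    r = normalize_to_reference(harmonized)
    assert "Ti/Ti" not in r.columns and r.shape[1] == 6
    one = harmonized.values.loc["1"]
    assert r.loc["1", "Ni/Ti"] == pytest.approx(one["Ni"] / one["Ti"])
    # uniform composition -> all ratios 1; row scaling cancels
    t = read_concentrations(_csv("""\
        sample_id,group,Co,Cu,Cr,Fe,Ni,Zn,Ti
        u,G,5,5,5,5,5,5,5
        """), PANEL)
    assert (normalize_to_reference(t).values == 1).all()
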