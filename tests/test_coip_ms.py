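import numpy as np
import pandas as pd
import pytest

from swisig.coip_ms import (
    dimethyl_ratios,
    enrichment_test,
    impute_missing,
    normalize_peptides,
    significance_curve,
    top3_quantify,
)


def _pep_table(rows):
    return pd.DataFrame(
        rows, columns=["protein", "peptide", "condition", "replicate", "intensity"]
    )


class TestTop3:
    def test_four_peptides_sum_of_top_three(self):
        t = _pep_table(
            [("P1", f"p{i}", "IP", 1, v) for i, v in enumerate([10.0, 8.0, 5.0, 2.0])]
        )
        out = top3_quantify(t)
        assert out.loc[0, "top3"] == 23.0
        assert out.loc[0, "evidence"] == 4

    def test_two_peptides_partial_sum(self):
        t = _pep_table([("P1", "a", "IP", 1, 7.0), ("P1", "b", "IP", 1, 3.0)])
        out = top3_quantify(t)
        assert out.loc[0, "top3"] == 10.0
        assert out.loc[0, "evidence"] == 2

    def test_missing_peptides_excluded(self):
        t = _pep_table(
            [("P1", "a", "IP", 1, 5.0), ("P1", "b", "IP", 1, np.nan),
             ("P1", "a", "IgG", 1, np.nan), ("P1", "b", "IgG", 1, np.nan)]
        )
        out = top3_quantify(t)
        assert len(out) == 1  # IgG replicate entirely missing -> absent
        assert out.loc[0, "condition"] == "IP"

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        rows = []
        for prot in ("A", "B", "C"):
            for cond in ("IP", "IgG"):
                for rep in (1, 2):
                    for k in range(int(rng.integers(1, 7))):
                        rows.append((prot, f"{prot}{k}", cond, rep,
                                     float(rng.uniform(1, 100))))
        t = _pep_table(rows)
        out = top3_quantify(t).set_index(["protein", "condition", "replicate"])
        for (prot, cond, rep), grp in t.groupby(["protein", "condition", "replicate"]):
            want = sum(sorted(grp["intensity"], reverse=True)[:3])
            assert out.loc[(prot, cond, rep), "top3"] == pytest.approx(want)

    def test_top3_bounded_by_total(self):
        rng = np.random.default_rng(1)
        rows = [("P", f"p{k}", "IP", 1, float(v))
                for k, v in enumerate(rng.uniform(0, 50, 10))]
        t = _pep_table(rows)
        assert top3_quantify(t).loc[0, "top3"] <= t["intensity"].sum()

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            top3_quantify(_pep_table([("P", "a", "IP", 1, -1.0)]))


class TestNormalizePeptides:
    def _table(self, seed=0, scale_rep2=1.0):
        rng = np.random.default_rng(seed)
        rows = []
        for k in range(60):
            base = rng.uniform(10, 20)
            rows.append(("P%d" % (k // 3), f"pep{k}", "IP", 1, 2.0 ** base))
            rows.append(("P%d" % (k // 3), f"pep{k}", "IP", 2, 2.0 ** base * scale_rep2))
        return _pep_table(rows)

    def test_global_scaling_removed(self):
        out = normalize_peptides(self._table(scale_rep2=4.0))
        rep1 = out[out["replicate"] == 1]["log_intensity"]
        rep2 = out[out["replicate"] == 2]["log_intensity"]
        assert rep1.median() == pytest.approx(rep2.median(), abs=1e-9)
        # the x4 replicate was shifted down by 2 log2 units (relative to raw)
        raw2 = np.log2(self._table(scale_rep2=4.0)[lambda d: d["replicate"] == 2]["intensity"])
        assert (raw2.to_numpy() - rep2.to_numpy()).mean() == pytest.approx(1.0, abs=1e-6)

    def test_already_aligned_unchanged(self):
        # identical replicates: medians equal, so log2 values pass through
        t = self._table(scale_rep2=1.0)
        out = normalize_peptides(t)
        assert np.allclose(out["log_intensity"], np.log2(t["intensity"]), atol=1e-12)

    def test_missing_values_untouched(self):
        t = self._table()
        t.loc[3, "intensity"] = np.nan
        out = normalize_peptides(t)
        assert np.isnan(out.loc[3, "log_intensity"])
        assert out["log_intensity"].isna().sum() == 1


class TestImputation:
    def _matrix(self, seed=0, n=2000, missing_frac=0.3):
        rng = np.random.default_rng(seed)
        data = rng.normal(20, 2, size=(n, 4))
        mask = rng.uniform(size=(n, 4)) < missing_frac
        data[mask] = np.nan
        df = pd.DataFrame(data, columns=["IP_1", "IP_2", "IgG_1", "IgG_2"],
                          index=[f"P{i}" for i in range(n)])
        return df

    GROUPS = {"IP_1": "IP", "IP_2": "IP", "IgG_1": "IgG", "IgG_2": "IgG"}

    def test_peptide_level_moments(self):
        # ~1e5 imputed draws: mean mu - 1.8 sd, width 0.3 sd
        m = self._matrix(n=80_000, missing_frac=0.35)
        imp = impute_missing(m, self.GROUPS, level="peptide", seed=1)
        col = "IP_1"
        observed = m.loc[imp.index, col].dropna()
        mu, sd = observed.mean(), observed.std(ddof=1)
        drawn = imp.loc[m.loc[imp.index, col].isna(), col]
        assert len(drawn) > 1e4
        assert drawn.mean() == pytest.approx(mu - 1.8 * sd, abs=0.01 * sd)
        assert drawn.std(ddof=1) == pytest.approx(0.3 * sd, abs=0.01 * sd)

    def test_protein_level_moments(self):
        m = self._matrix(seed=2, n=80_000, missing_frac=0.35)
        imp = impute_missing(m, self.GROUPS, level="protein", seed=3)
        col = "IgG_2"
        observed = m.loc[imp.index, col].dropna()
        mu, sd = observed.mean(), observed.std(ddof=1)
        drawn = imp.loc[m.loc[imp.index, col].isna(), col]
        assert drawn.mean() == pytest.approx(mu - 2.5 * sd, abs=0.01 * sd)
        assert drawn.std(ddof=1) == pytest.approx(0.2 * sd, abs=0.01 * sd)

    def test_single_evidence_per_group_dropped(self):
        m = pd.DataFrame(
            {"IP_1": [20.0, 20.0], "IP_2": [np.nan, 21.0],
             "IgG_1": [19.0, 19.0], "IgG_2": [np.nan, 18.0]},
            index=["lonely", "kept"],
        )
        imp = impute_missing(m, self.GROUPS, level="protein", seed=0)
        assert "lonely" not in imp.index
        assert "kept" in imp.index

    def test_same_seed_identical_draws(self):
        m = self._matrix(n=500)
        a = impute_missing(m, self.GROUPS, level="protein", seed=9)
        b = impute_missing(m, self.GROUPS, level="protein", seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_imputed_values_below_observed_mean(self):
        m = self._matrix(n=5000)
        imp = impute_missing(m, self.GROUPS, level="peptide", seed=4)
        for col in m.columns:
            mu = m.loc[imp.index, col].dropna().mean()
            drawn = imp.loc[m.loc[imp.index, col].isna(), col]
            assert (drawn < mu).all()


class TestEnrichmentTest:
    DESIGN = {"IP_1": "IP", "IP_2": "IP", "IP_3": "IP",
              "IgG_1": "IgG", "IgG_2": "IgG", "IgG_3": "IgG"}

    def _quant(self, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.normal(20, 1, size=(300, 6))
        data[:10, :3] += 3.0  # enriched block in IP columns
        return pd.DataFrame(data, columns=list(self.DESIGN),
                            index=[f"P{i}" for i in range(300)])

    def test_planted_enrichment_detected(self):
        res = enrichment_test(self._quant(), self.DESIGN)
        top10 = res.nsmallest(10, "p_adj").index
        assert sum(t in {f"P{i}" for i in range(10)} for t in top10) >= 9
        assert (res.loc[[f"P{i}" for i in range(10)], "log2fc"] > 2).all()

    def test_swapping_labels_negates_log2fc(self):
        q = self._quant()
        res_ip = enrichment_test(q, self.DESIGN, test_group="IP")
        res_igg = enrichment_test(q, self.DESIGN, test_group="IgG")
        assert np.allclose(res_ip["log2fc"], -res_igg["log2fc"], atol=1e-12)

    def test_fully_observed_independent_of_imputation_seed(self):
        from swisig.coip_ms import impute_missing

        q = self._quant()
        groups = dict(self.DESIGN)
        a = enrichment_test(impute_missing(q, groups, seed=1), self.DESIGN)
        b = enrichment_test(impute_missing(q, groups, seed=2), self.DESIGN)
        pd.testing.assert_frame_equal(a, b)


class TestSignificanceCurve:
    def _results(self, lfc, padj):
        return pd.DataFrame({"log2fc": lfc, "p_adj": padj})

    def test_at_fc0_never_significant(self):
        res = self._results([1.0, -1.0, 5.0], [1e-30, 1e-30, 1e-30])
        out = significance_curve(res, fc0=1.0, s0=0.5)
        assert not out.loc[0, "significant"]
        assert not out.loc[1, "significant"]
        assert out.loc[2, "significant"]

    def test_large_fc_threshold_relaxes_to_p0(self):
        # with the curve constant held fixed, the p threshold approaches p0
        # as |log2fc| grows: 0.049 makes it in the limit, 0.051 never does
        res = self._results([50.0, 50.0, 0.5], [0.049, 0.051, 0.001])
        out = significance_curve(res, s0=0.1)
        assert out.loc[0, "significant"]
        assert not out.loc[1, "significant"]  # above p0 even at huge FC
        assert not out.loc[2, "significant"]  # below fc0

    def test_monotone_in_abs_fc_at_fixed_p(self):
        lfc = np.linspace(1.01, 6, 40)
        res = self._results(lfc, np.full(40, 0.01))
        out = significance_curve(res)
        sig = out["significant"].to_numpy()
        assert (np.diff(sig.astype(int)) >= 0).all()

    def test_empty_input(self):
        out = significance_curve(self._results([], []))
        assert out.empty


class TestDimethylRatios:
    def _psms(self, rows):
        return pd.DataFrame(rows, columns=["protein", "psm", "heavy_sn", "light_sn"])

    def test_control_zero_imputes_denominator_one(self):
        # total experimental S/N of 8 against an absent control: log2(8/1) = 3
        rows = [("P1", f"p{k}", 1.0, 0.0) for k in range(8)]
        out = dimethyl_ratios(self._psms(rows), experimental_channel="heavy",
                              min_sn_sum=1.0)
        assert out.loc[0, "log2_ratio"] == pytest.approx(3.0)  # log2(8/1)
        assert bool(out.loc[0, "control_imputed"])

    def test_seven_psms_dropped(self):
        rows = [("P1", f"p{k}", 20.0, 5.0) for k in range(7)]
        out = dimethyl_ratios(self._psms(rows))
        assert out.empty

    def test_low_sn_psm_excluded_before_totals(self):
        rows = [("P1", f"p{k}", 20.0, 10.0) for k in range(8)]
        rows.append(("P1", "bad", 5.0, 4.0))  # sum 9 < 10
        out = dimethyl_ratios(self._psms(rows))
        assert out.loc[0, "n_psms"] == 8
        assert out.loc[0, "experimental_sn"] == pytest.approx(160.0)
        assert out.loc[0, "log2_ratio"] == pytest.approx(1.0)  # log2(160/80)

    def test_totals_match_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(12):
            for k in range(int(rng.integers(4, 15))):
                rows.append((f"P{i}", f"P{i}_p{k}",
                             float(rng.gamma(2, 20)), float(rng.gamma(2, 20))))
        psms = self._psms(rows)
        out = dimethyl_ratios(psms).set_index("protein")
        for prot, grp in psms.groupby("protein"):
            ok = grp[(grp["heavy_sn"] + grp["light_sn"]) >= 10]
            if len(ok) < 8:
                assert prot not in out.index
            else:
                assert out.loc[prot, "experimental_sn"] == pytest.approx(ok["heavy_sn"].sum())
                assert out.loc[prot, "control_sn"] == pytest.approx(ok["light_sn"].sum())

    def test_channel_assignment_respected(self):
        rows = [("P1", f"p{k}", 40.0, 10.0) for k in range(8)]
        heavy = dimethyl_ratios(self._psms(rows), experimental_channel="heavy")
        light = dimethyl_ratios(self._psms(rows), experimental_channel="light")
        assert heavy.loc[0, "log2_ratio"] == pytest.approx(2.0)
        assert light.loc[0, "log2_ratio"] == pytest.approx(-2.0)

    def test_bad_channel_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            dimethyl_ratios(self._psms([("P", "a", 1.0, 1.0)]),
                            experimental_channel="medium")
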