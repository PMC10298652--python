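"""ANOVA, Dunnett contrasts, QTL calling, correlations and summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from il_toolkit.model import ValidationError
from il_toolkit.phenotypes import (
    call_qtls,
    correlation_matrix,
    derive_shape,
    dunnett_adjusted_p,
    dunnett_test,
    location_summary,
    two_way_anova,
)

COLS = ["location", "block", "line", "replicate", "trait", "value"]


def long_table(groups, trait="FW", location="Loc"):
    rows = []
    for line, values in groups.items():
        for i, v in enumerate(values):
            rows.append((location, 1 + i % 2, line, i, trait, float(v)))
    return pd.DataFrame(rows, columns=COLS)


class TestDeriveShape:
    def test_oval_control_fruit(self):
        # length/diameter of a large oval melon -> moderately elongated
        assert round(derive_shape(215.08, 154.72), 2) == 1.39
        assert round(derive_shape(231.08, 152.36), 2) == 1.52

    def test_round_fruit_identity(self):
        assert derive_shape(150.0, 150.0) == 1.0

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValidationError, match="FD"):
            derive_shape(100.0, 0.0)


class TestTwoWayAnova:
    def test_one_way_f_equals_t_squared(self, rng):
        a, b = rng.normal(10, 2, 8), rng.normal(12, 2, 9)
        df = long_table({"PS": a, "IL1": b})
        res = two_way_anova(df, "FW")
        t, _ = sps.ttest_ind(a, b)
        assert res.table.loc["line", "F"] == pytest.approx(t**2, rel=1e-10)
        assert res.label == "1L"

    def test_identical_cell_means_give_zero_f(self):
        rows = []
        for loc in ("L1", "L2"):
            for line in ("PS", "IL1"):
                for i, v in enumerate((9.0, 11.0)):
                    rows.append((loc, 1, line, i, "FW", v))
        res = two_way_anova(pd.DataFrame(rows, columns=COLS), "FW")
        for term in ("location", "line", "location:line"):
            assert res.table.loc[term, "F"] == pytest.approx(0.0, abs=1e-12)

    def test_balanced_type_iii_matches_closed_form(self, rng):
        # textbook two-way SS from cell means on a balanced layout
        locs, lines, n = ["L1", "L2", "L3"], ["PS", "IL1", "IL2", "IL3"], 5
        rows = []
        y = {}
        for loc in locs:
            for line in lines:
                vals = rng.normal(10 + hash((loc, line)) % 5, 2, n)
                y[(loc, line)] = vals
                rows += [(loc, 1, line, i, "FW", v) for i, v in enumerate(vals)]
        df = pd.DataFrame(rows, columns=COLS)
        res = two_way_anova(df, "FW")

        grand = np.mean([v for vals in y.values() for v in vals])
        m_loc = {l: np.mean([y[(l, g)] for g in lines]) for l in locs}
        m_line = {g: np.mean([y[(l, g)] for l in locs]) for g in lines}
        ss_loc = n * len(lines) * sum((m_loc[l] - grand) ** 2 for l in locs)
        ss_line = n * len(locs) * sum((m_line[g] - grand) ** 2 for g in lines)
        ss_int = n * sum(
            (y[(l, g)].mean() - m_loc[l] - m_line[g] + grand) ** 2
            for l in locs for g in lines
        )
        ss_res = sum(((y[(l, g)] - y[(l, g)].mean()) ** 2).sum()
                     for l in locs for g in lines)
        assert res.table.loc["location", "sum_sq"] == pytest.approx(ss_loc, rel=1e-8)
        assert res.table.loc["line", "sum_sq"] == pytest.approx(ss_line, rel=1e-8)
        assert res.table.loc["location:line", "sum_sq"] == pytest.approx(
            ss_int, rel=1e-8
        )
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(ss_res, rel=1e-8)
        # orthogonality: term SS + residual = total SS in balanced designs
        total = ((df["value"] - grand) ** 2).sum()
        assert res.table["sum_sq"].sum() == pytest.approx(total, rel=1e-8)

    def test_empty_cell_error_names_cell(self, rng):
        rows = [("L1", 1, "PS", i, "FW", v) for i, v in enumerate(rng.normal(10, 1, 4))]
        rows += [("L1", 1, "IL1", i, "FW", v) for i, v in enumerate(rng.normal(10, 1, 4))]
        rows += [("L2", 1, "PS", i, "FW", v) for i, v in enumerate(rng.normal(10, 1, 4))]
        with pytest.raises(ValidationError, match="IL1"):
            two_way_anova(pd.DataFrame(rows, columns=COLS), "FW")


class TestDunnett:
    def test_single_il_reduces_to_student_t(self, rng):
        df = long_table({"PS": rng.normal(10, 2, 10), "IL1": rng.normal(11, 2, 6)})
        res = dunnett_test(df, "FW", "PS")
        row = res.table.loc["IL1"]
        assert abs(row.p_adjusted - row.p_unadjusted) < 1e-6

    def test_bonferroni_dominance_random_inputs(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 8))
            groups = {"PS": rng.normal(0, 1, int(rng.integers(4, 12)))}
            for i in range(k):
                groups[f"IL{i}"] = rng.normal(
                    rng.normal(0, 1), 1, int(rng.integers(3, 10))
                )
            res = dunnett_test(long_table(groups), "FW", "PS")
            assert (
                res.table.p_adjusted
                <= np.minimum(1.0, k * res.table.p_unadjusted) + 1e-10
            ).all()
            assert (res.table.p_adjusted >= res.table.p_unadjusted - 1e-12).all()

    def test_adjusted_p_monotone_in_t_and_k(self):
        lam3 = np.full(3, np.sqrt(0.5))
        ps = [dunnett_adjusted_p(t, lam3, 20) for t in (1.0, 1.5, 2.0, 3.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        for t in (1.0, 2.0):
            p_by_k = [
                dunnett_adjusted_p(t, np.full(k, np.sqrt(0.5)), 20)
                for k in (1, 2, 4, 8)
            ]
            assert all(a <= b + 1e-12 for a, b in zip(p_by_k, p_by_k[1:]))

    def test_agrees_with_scipy_reference(self, rng):
        ctrl = rng.normal(0, 1, 10)
        ils = [rng.normal(0.8, 1, 6) for _ in range(4)]
        ref = sps.dunnett(*ils, control=ctrl, random_state=1)
        groups = {"PS": ctrl, **{f"IL{i}": v for i, v in enumerate(ils)}}
        mine = dunnett_test(long_table(groups), "FW", "PS")
        assert np.allclose(mine.table.p_adjusted, ref.pvalue, atol=2e-3)

    def test_percent_diff_convention(self):
        df = long_table({"PS": [10.0, 10.0, 10.0], "IL1": [6.0, 6.0, 6.1]})
        res = dunnett_test(df, "FW", "PS")
        assert res.table.loc["IL1", "percent_diff"] == pytest.approx(
            100 * (np.mean([6.0, 6.0, 6.1]) - 10.0) / 10.0
        )

    def test_zero_pooled_variance_rejected(self):
        df = long_table({"PS": [10.0, 10.0], "IL1": [5.0, 5.0]})
        with pytest.raises(ValidationError, match="variance"):
            dunnett_test(df, "FW", "PS")


class TestCallQtls:
    def _results(self, pvals_by_loc, pct=10.0):
        out = {}
        for loc, pvals in pvals_by_loc.items():
            table = pd.DataFrame(
                {
                    "n": 10,
                    "mean": 11.0,
                    "diff": 1.0,
                    "t": 2.0,
                    "p_unadjusted": list(pvals.values()),
                    "p_adjusted": list(pvals.values()),
                    "percent_diff": [
                        pct if isinstance(pct, float) else pct[il]
                        for il in pvals
                    ],
                },
                index=pd.Index(list(pvals.keys()), name="line"),
            )
            from il_toolkit.phenotypes import DunnettResult

            out[loc] = DunnettResult(loc, "FW", "PS", 10.0, 10, 20, 1.0, table)
        return out

    def test_single_location_significance_not_called(self):
        res = self._results(
            {"L1": {"IL1": 0.01}, "L2": {"IL1": 0.5}, "L3": {"IL1": 0.9}}
        )
        calls = call_qtls(res)
        assert not calls[0].called and calls[0].n_significant == 1

    def test_two_of_two_locations_called(self):
        res = self._results({"L1": {"IL1": 0.01}, "L2": {"IL1": 0.02}})
        assert call_qtls(res)[0].called

    def test_discordant_signs_blocked_unless_disabled(self):
        res = self._results(
            {"L1": {"IL1": 0.01}, "L2": {"IL1": 0.02}},
            pct={"IL1": 10.0},
        )
        res["L2"].table.loc["IL1", "percent_diff"] = -10.0
        assert not call_qtls(res)[0].called
        assert call_qtls(res, require_concordant=False)[0].called

    def test_invariant_to_location_ordering(self):
        res = self._results(
            {"L1": {"IL1": 0.01, "IL2": 0.5},
             "L2": {"IL1": 0.02, "IL2": 0.01},
             "L3": {"IL1": 0.9, "IL2": 0.03}}
        )
        a = call_qtls(dict(sorted(res.items())))
        b = call_qtls(dict(sorted(res.items(), reverse=True)))
        assert [(c.il, c.called, c.n_significant) for c in a] == [
            (c.il, c.called, c.n_significant) for c in b
        ]


class TestCorrelations:
    def _pheno(self, rng, rho=0.7, n=100):
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([10, 10], cov, size=n)
        rows = []
        for i, (x, y) in enumerate(xy):
            rows.append(("Loc", 1, f"L{i}", 1, "FW", x))
            rows.append(("Loc", 1, f"L{i}", 1, "SSC", y))
        return pd.DataFrame(rows, columns=COLS)

    def test_self_correlation_is_one(self, rng):
        out = correlation_matrix(self._pheno(rng))["Loc"]
        assert out.r.loc["FW", "FW"] == 1.0

    def test_ratio_with_constant_denominator(self, rng):
        rows = []
        for i in range(30):
            fl = float(rng.normal(200, 20))
            rows.append(("Loc", 1, f"L{i}", 1, "FL", fl))
            rows.append(("Loc", 1, f"L{i}", 1, "FS", fl / 150.0))
        out = correlation_matrix(pd.DataFrame(rows, columns=COLS))["Loc"]
        assert out.r.loc["FS", "FL"] == pytest.approx(1.0)

    def test_estimate_within_sampling_error(self, rng):
        out = correlation_matrix(self._pheno(rng, rho=0.7, n=100))["Loc"]
        r = out.r.loc["FW", "SSC"]
        se = (1 - 0.7**2) / np.sqrt(100)
        assert abs(r - 0.7) < 3 * se

    def test_constant_trait_reported_na(self, rng):
        df = self._pheno(rng)
        extra = df[df.trait == "FW"].copy()
        extra["trait"] = "FF"
        extra["value"] = 2.0
        out = correlation_matrix(pd.concat([df, extra]))["Loc"]
        assert pd.isna(out.r.loc["FF", "FW"])
        assert not out.significant.loc["FF", "FW"]


class TestLocationSummary:
    def test_hand_computed_mean_and_sd(self):
        df = long_table({"PS": [1.0, 2.0, 3.0]})
        out = location_summary(df, "PS", "FW")
        assert out.loc["Loc", "mean"] == 2.0
        assert out.loc["Loc", "sd"] == pytest.approx(1.0)
        assert out.loc["Loc", "n"] == 3

    def test_single_record_sd_is_na(self):
        df = long_table({"PS": [5.0]})
        out = location_summary(df, "PS", "FW")
        assert pd.isna(out.loc["Loc", "sd"])

    def test_agrees_with_two_pass_recomputation(self, rng):
        vals = rng.normal(1e6, 1.0, 100_000)  # large mean stresses cancellation
        df = long_table({"PS": vals})
        out = location_summary(df, "PS", "FW")
        mean = vals.sum() / len(vals)
        sd = np.sqrt(((vals - mean) ** 2).sum() / (len(vals) - 1))
        assert out.loc["Loc", "mean"] == pytest.approx(mean, rel=1e-12)
        assert out.loc["Loc", "sd"] == pytest.approx(sd, rel=1e-9)
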