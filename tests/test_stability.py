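import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coloboot as cb
from coloboot.stability import ReplicateResult, replicate_archive


class TestBootstrapP:
    @pytest.mark.parametrize(
        "coefs,expected",
        [
            ([0.5, 1.2, 2.0], 0.0),      # unanimous sign
            ([-1.0, 1.0], 0.5),          # even split
            ([3.0, 1.0, 2.0, -1.0], 0.25),  # one of four on minority side
            ([-3.0, -1.0, -2.0, 1.0], 0.25),
            ([1.0], 0.0),
        ],
    )
    def test_definitional_values(self, coefs, expected):
        assert cb.bootstrap_p(coefs) == pytest.approx(expected)

    def test_exact_zeros_count_to_minority(self):
        assert cb.bootstrap_p([2.0, 1.0, 0.0]) == pytest.approx(1.0 / 3.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cb.bootstrap_p([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=50))
    def test_bounded(self, coefs):
        p = cb.bootstrap_p(coefs)
        assert 0.0 <= p <= 1.0


def _fake_replicates(n_selected, total, coef=1.0, term="t"):
    reps = []
    for i in range(total):
        sel = i < n_selected
        reps.append(
            ReplicateResult(
                index=i, seed=i,
                selected={term: sel},
                coefs={f"{term}:Yes": coef} if sel else {},
                converged=True,
            )
        )
    return reps


class TestStabilityPct:
    @pytest.mark.parametrize("k,B,expected", [(37, 40, 92.5), (0, 10, 0.0), (8, 8, 100.0)])
    def test_arithmetic(self, k, B, expected):
        assert cb.stability_pct(_fake_replicates(k, B), "t") == expected

    def test_unknown_term(self):
        with pytest.raises(KeyError):
            cb.stability_pct(_fake_replicates(1, 2), "other")


class TestSummarizeCoefficients:
    def test_single_replicate_degenerate(self):
        reps = _fake_replicates(1, 5, coef=2.2)
        assert cb.summarize_coefficients(reps, "t:Yes") == (2.2, 2.2, 2.2)

    def test_linear_interpolation_quantiles(self):
        reps = []
        for i, c in enumerate([1.0, 2.0, 3.0, 4.0]):
            reps.append(ReplicateResult(i, i, {"t": True}, {"t:Yes": c}, True))
        mean, lo, hi = cb.summarize_coefficients(reps, "t:Yes")
        assert mean == 2.5
        # sort-and-interpolate oracle: q at h = (n-1) q
        vals = [1.0, 2.0, 3.0, 4.0]

        def interp_q(q):
            h = (len(vals) - 1) * q
            f = int(np.floor(h))
            return vals[f] + (h - f) * (vals[min(f + 1, 3)] - vals[f])

        assert lo == pytest.approx(interp_q(0.025))
        assert hi == pytest.approx(interp_q(0.975))
        assert 1.0 <= lo <= hi <= 4.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=30))
    def test_mean_within_range(self, coefs):
        reps = [
            ReplicateResult(i, i, {"t": True}, {"t:Yes": c}, True)
            for i, c in enumerate(coefs)
        ]
        mean, lo, hi = cb.summarize_coefficients(reps, "t:Yes")
        assert min(coefs) - 1e-12 <= mean <= max(coefs) + 1e-12
        assert lo <= hi

    def test_never_selected_rejected(self):
        with pytest.raises(ValueError):
            cb.summarize_coefficients(_fake_replicates(0, 3), "t:Yes")


class TestBootstrapReplicate:
    def test_seed_determinism(self, small_dataset):
        terms = ["teat_dry_wiped", "premilking_teat_disinfection"]
        r1 = cb.bootstrap_replicate(small_dataset, "log_tbc", terms, 99)
        r2 = cb.bootstrap_replicate(small_dataset, "log_tbc", terms, 99)
        assert r1 == r2

    def test_record_resample_same_size_as_original(self, small_dataset):
        """A replicate equals backward elimination on the documented
        same-size with-replacement row resample."""
        terms = ["teat_dry_wiped"]
        seed = 123
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, small_dataset.n, size=small_dataset.n)
        assert len(idx) == small_dataset.n
        manual = cb.backward_step(small_dataset.subset(idx), "log_tbc", terms)
        selected, coefs = cb.record_selection(manual)
        rep = cb.bootstrap_replicate(small_dataset, "log_tbc", terms, seed)
        assert rep.selected == selected
        assert rep.coefs == coefs

    def test_farm_mode_runs(self, small_dataset):
        rep = cb.bootstrap_replicate(
            small_dataset, "log_tbc", ["teat_dry_wiped"], 7, mode="farm"
        )
        assert rep.converged


class TestRunStability:
    def test_single_replicate(self, small_dataset):
        reps = cb.run_stability(small_dataset, "log_tbc", ["teat_dry_wiped"],
                                n_boot=1, master_seed=3)
        assert len(reps) == 1

    def test_master_seed_reproducible(self, small_dataset):
        kw = dict(n_boot=8, master_seed=55)
        r1 = cb.run_stability(small_dataset, "log_tbc", ["teat_dry_wiped"], **kw)
        r2 = cb.run_stability(small_dataset, "log_tbc", ["teat_dry_wiped"], **kw)
        assert r1 == r2

    def test_invalid_b(self, small_dataset):
        with pytest.raises(ValueError):
            cb.run_stability(small_dataset, "log_tbc", ["teat_dry_wiped"], n_boot=0)


class TestSelectInfluential:
    def _row(self, term, stability, p):
        return {
            "term": term, "level": "Yes", "label": f"{term}:Yes",
            "n_at_level": 10, "stability": stability, "n_selected": 1,
            "n_coef": 1, "mean_coef": 1.0, "bci_low": 0.5, "bci_high": 1.5,
            "boot_p": p,
        }

    def test_thresholds_strict(self):
        df = pd.DataFrame(
            [
                self._row("kept", 92.5, 0.01),
                self._row("low_stability", 9.7, 0.001),
                self._row("boundary_stability", 10.0, 0.001),
                self._row("boundary_p", 50.0, 0.025),
            ]
        )
        out = cb.select_influential(df)
        assert set(out["term"]) == {"kept"}

    def test_whole_term_kept_together(self):
        rows = [self._row("m", 40.0, 0.5), self._row("m", 40.0, 0.001)]
        rows[1]["level"] = "Robot"
        out = cb.select_influential(pd.DataFrame(rows))
        assert len(out) == 2  # both levels ride along once one qualifies

    def test_empty(self):
        assert cb.select_influential(pd.DataFrame()).empty


@pytest.fixture(scope="module")
def run(small_dataset):
    terms = ["teat_dry_wiped", "milking_system"]
    reps = cb.run_stability(small_dataset, "log_tbc", terms,
                            n_boot=30, master_seed=17)
    return small_dataset, terms, reps


class TestSummaries:
    def test_shared_stability_across_levels(self, run):
        ds, terms, reps = run
        summ = cb.summarize_stability(reps, ds, terms)
        for _, grp in summ.groupby("term"):
            assert grp["stability"].nunique() == 1

    def test_replicate_order_invariance(self, run):
        ds, terms, reps = run
        s1 = cb.summarize_stability(reps, ds, terms)
        s2 = cb.summarize_stability(list(reversed(reps)), ds, terms)
        pd.testing.assert_frame_equal(s1, s2)

    def test_archive_matches_replicates(self, run):
        ds, terms, reps = run
        arch = replicate_archive(reps)
        assert arch["replicate"].nunique() == len(reps)
        n_coefs = sum(len(r.coefs) for r in reps if r.coefs)
        assert int(arch["selected"].sum()) == n_coefs


class TestModelObject:
    def test_fit_end_to_end(self, small_dataset):
        model = cb.ColostrumStabilityModel(
            small_dataset, "log_tbc", terms=["teat_dry_wiped", "milking_system"]
        )
        res = model.fit(n_boot=25, seed=5)
        assert len(res.replicates) == 25
        assert not res.summary_frame.empty
        # planted 2-log-unit effect should dominate selection
        row = res.summary_frame[res.summary_frame.term == "teat_dry_wiped"]
        assert row.iloc[0]["stability"] > 50
        table = res.summary_table()
        assert list(table.columns) == [
            "Variable", "N", "Stability (%)", "Mean coefficient",
            "95% bootstrap confidence interval", "Bootstrap P-value",
        ]
        assert "Bootstrap stability selection" in res.summary()

    def test_b_equals_one_degenerate_stability(self, small_dataset):
        model = cb.ColostrumStabilityModel(small_dataset, "log_tbc",
                                           terms=["teat_dry_wiped"])
        res = model.fit(n_boot=1, seed=2)
        assert set(res.summary_frame["stability"]) <= {0.0, 100.0}

    def test_plots_return_figures(self, small_dataset, tmp_path):
        model = cb.ColostrumStabilityModel(small_dataset, "log_tbc",
                                           terms=["teat_dry_wiped"])
        res = model.fit(n_boot=10, seed=4)
        fig = res.plot_coefficient_distributions()
        fig.savefig(tmp_path / "coef.png")
        fig2 = res.plot_stability_vs_p()
        fig2.savefig(tmp_path / "sp.png")
        assert (tmp_path / "coef.png").stat().st_size > 0
        assert (tmp_path / "sp.png").stat().st_size > 0
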