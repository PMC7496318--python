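import itertools

import numpy as np
import pandas as pd
import pytest

import segmorph as sm
from segmorph.exceptions import DataError, InvalidArgumentError
from segmorph.simulate import SEGMENTS, measurements_to_frame
from segmorph.stats import correlation_decay_summary

from conftest import spawn_seeds


def _iid_table(effects, n=25, seed=0, sd=0.01):
    """Gaussian relative positions; ``effects`` maps species -> shift."""
    rng = np.random.default_rng(seed)
    rows = []
    for sp, shift in effects.items():
        for i in range(n):
            for j, seg in enumerate(SEGMENTS):
                rows.append((sp, f"{sp}_{i}", seg, 0.1 * (j + 1) + shift + rng.normal(0, sd), 1000.0))
    return pd.DataFrame(rows, columns=["species", "larva_id", "segment", "p", "body_length_um"])


class TestAnova:
    def test_detects_strong_species_shift(self):
        tab = _iid_table({"a": 0.0, "b": 0.05}, n=100, seed=1)
        aov = sm.fit_interaction_anova(tab)
        assert aov.loc["species", "PR(>F)"] < 1e-6
        assert set(aov.index) == {"species", "segment", "species:segment", "Residual"}

    def test_power_at_moderate_shift(self):
        hits = 0
        for s in spawn_seeds(123, 20):
            tab = _iid_table({"a": 0.0, "b": 0.05, "c": 0.0}, n=100, seed=s)
            aov = sm.fit_interaction_anova(tab)
            hits += aov.loc["species", "PR(>F)"] < 0.05
        assert hits == 20

    def test_zero_residual_variance_flagged(self):
        tab = _iid_table({"a": 0.0, "b": 0.0}, n=5, sd=0.0)
        with pytest.warns(UserWarning, match="zero residual variance"):
            sm.fit_interaction_anova(tab)

    def test_missing_cells_refused(self):
        tab = _iid_table({"a": 0.0, "b": 0.0}, n=5)
        tab = tab[~((tab.species == "a") & (tab.segment == "A3"))]
        with pytest.raises(DataError, match="cell"):
            sm.fit_interaction_anova(tab)


class TestTukey:
    def test_identical_cohorts_no_differences(self, noiseless_profile):
        ms = []
        for sp in ("a", "b", "c"):
            rng_shift = 0.0
            for m in sm.simulate_cohort(sm.SpeciesProfile(sp), 10, seed=3):
                ms.append(m)
        tab = sm.relative_positions(measurements_to_frame(ms))
        # same profile, same seed => same draws per species
        mat = sm.tukey_pairwise(tab)
        assert mat.total == 0

    def test_overwhelming_separation_detected(self):
        tab = _iid_table({"a": 0.0, "b": 0.10}, n=50, sd=0.01)  # 10 within-group sds
        mat = sm.tukey_pairwise(tab)
        assert mat.total == 8  # every segment

    def test_matches_tabulated_q_critical_values(self):
        # balanced 3-group one-way instances vs classical q_{0.05}(3, df)
        q_table = {12: 3.773, 24: 3.532, 27: 3.506, 57: 3.403}  # standard published values
        rng = np.random.default_rng(2)
        for df_resid, q in q_table.items():
            n = df_resid // 3 + 1
            tab = _iid_table({"a": 0.0, "b": 0.004, "c": 0.012}, n=n, seed=int(rng.integers(2**31)))
            tab = tab[tab.segment == "A1"]
            groups = {sp: g["p"].to_numpy() for sp, g in tab.groupby("species")}
            mse = np.mean([g.var(ddof=1) for g in groups.values()])
            hsd = q * np.sqrt(mse / n)
            mat = sm.tukey_pairwise(tab).indicators["A1"]
            for a, b in itertools.combinations(groups, 2):
                expect = abs(groups[a].mean() - groups[b].mean()) > hsd
                assert mat.loc[a, b] == expect

    def test_consistency_identities(self, small_rel):
        mat = sm.tukey_pairwise(small_rel)
        pc = mat.pair_counts()
        assert mat.total == pc["n_differing_segments"].sum()
        assert mat.per_species_counts().sum() == 2 * mat.total
        assert mat.per_segment_counts().sum() == mat.total


class TestTTestBonferroni:
    def test_identical_no_differences(self):
        tab = _iid_table({"a": 0.0, "b": 0.0}, n=30, seed=5)
        assert sm.ttest_bonferroni(tab).total == 0

    def test_global_correction_factor(self):
        # moderate effect: raw p ~ 1e-3 is significant alone but not after
        # multiplying by (pairs x segments)
        rng = np.random.default_rng(0)
        from scipy import stats as sps

        for _ in range(20):
            x = rng.normal(0, 1, 40)
            y = rng.normal(0.8, 1, 40)
            p_raw = sps.ttest_ind(x, y, equal_var=False).pvalue
            if 1e-4 < p_raw < 0.04:
                break
        rows = []
        for sp_idx in range(12):
            data = x if sp_idx else y
            for i, v in enumerate(data):
                for j, seg in enumerate(SEGMENTS):
                    val = 0.1 * (j + 1) + (v * 0.01 if j == 0 else rng.normal(0, 0.01))
                    rows.append((f"sp{sp_idx}", f"sp{sp_idx}_{i}", seg, val, 1000.0))
        tab = pd.DataFrame(rows, columns=["species", "larva_id", "segment", "p", "body_length_um"])
        # factor is 66 pairs x 8 segments = 528: the marginal pair cannot survive
        mat = sm.ttest_bonferroni(tab)
        assert not mat.indicators["A1"].loc["sp0", "sp1"]

    def test_huge_separation_survives_correction(self):
        tab = _iid_table({f"sp{k}": (0.10 if k == 0 else 0.0) for k in range(12)}, n=30, seed=7)
        mat = sm.ttest_bonferroni(tab)
        assert mat.indicators["A1"].loc["sp0", "sp1"]

    def test_agreement_with_tukey_on_clear_and_null_effects(self):
        tab = _iid_table({"a": 0.0, "b": 0.0, "c": 0.08, "d": 0.08}, n=40, seed=9)
        t1 = sm.tukey_pairwise(tab)
        t2 = sm.ttest_bonferroni(tab)
        agree = total = 0
        for seg in SEGMENTS:
            m1, m2 = t1.indicators[seg], t2.indicators[seg]
            for a, b in itertools.combinations(m1.index, 2):
                agree += m1.loc[a, b] == m2.loc[a, b]
                total += 1
        assert agree / total >= 0.90


class TestCounting:
    def test_printed_correction_arithmetic(self):
        # the "corrected" count divides by the number of segments
        fake = {s: pd.DataFrame(False, index=["a", "b"], columns=["a", "b"]) for s in SEGMENTS}
        m = sm.PairwiseDifferenceMatrix(fake, alpha=0.05, method="tukey")
        assert sm.count_and_correct(m)["corrected_total"] == 0
        assert 410 / 8 == pytest.approx(51.25)
        assert 269 / 7 == pytest.approx(38.43, abs=0.01)

    def test_zero_segments_invalid(self):
        fake = {s: pd.DataFrame(False, index=["a", "b"], columns=["a", "b"]) for s in SEGMENTS}
        m = sm.PairwiseDifferenceMatrix(fake, alpha=0.05, method="tukey")
        with pytest.raises(InvalidArgumentError):
            sm.count_and_correct(m, n_segments=0)

    def test_removing_a8_changes_only_a8_entries(self, small_rel):
        full = sm.tukey_pairwise(small_rel)
        no_a8 = sm.tukey_pairwise(small_rel[small_rel.segment != "A8"])
        for seg in SEGMENTS[:7]:
            assert full.indicators[seg].equals(no_a8.indicators[seg])
        assert "A8" not in no_a8.indicators


class TestWithinSpeciesCorrelations:
    def test_zero_variance_reported_undefined(self):
        rows = []
        for i in range(10):
            L = 900 + 20 * i
            for j, seg in enumerate(SEGMENTS):
                rows.append(("sp", f"l{i}", seg, 0.1 * (j + 1), L))
        tab = pd.DataFrame(rows, columns=["species", "larva_id", "segment", "p", "body_length_um"])
        with pytest.warns(UserWarning, match="zero variance"):
            prof = sm.within_species_correlations(tab)
        assert prof["r"].isna().all()

    def test_shared_additive_shift_gives_perfect_correlation(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(30):
            shift = rng.normal(0, 0.01)
            for j, seg in enumerate(SEGMENTS):
                rows.append(("sp", f"l{i}", seg, 0.1 * (j + 1) + shift, 1000.0))
        tab = pd.DataFrame(rows, columns=["species", "larva_id", "segment", "p", "body_length_um"])
        prof = sm.within_species_correlations(tab)
        assert np.allclose(prof["r"], 1.0)

    def test_decay_with_distance_on_default_generator(self):
        df = measurements_to_frame(sm.simulate_cohort(sm.SpeciesProfile("sp"), 5000, seed=21))
        prof = sm.within_species_correlations(sm.relative_positions(df))
        adj = prof[prof.separation == 1]["r"].mean()
        far = prof[prof.separation == 4]["r"].mean()
        assert adj > far

    def test_decay_summary_splits_a8(self, small_rel):
        prof = sm.within_species_correlations(small_rel)
        summ = correlation_decay_summary(prof)
        assert set(summ.columns) >= {"separation", "involves_a8", "mean_r", "ci95_low", "ci95_high"}
        assert (summ["n"] > 0).all()


class TestLengthAnalyses:
    def test_exact_linear_relationship(self, small_rel):
        summ = sm.species_summary(small_rel)
        lengths = summ.per_species["mean_length_um"]
        species = list(lengths.index)
        fake = {}
        # counts exactly proportional to |delta length| cannot be integers in
        # general; instead check the regression on a constructed matrix whose
        # pair counts follow a perfect linear rule via a monotone assignment
        pairs = list(itertools.combinations(species, 2))
        deltas = {pr: abs(lengths[pr[0]] - lengths[pr[1]]) for pr in pairs}
        ranked = sorted(pairs, key=lambda pr: deltas[pr])
        # build indicator stacks: pair k differs at exactly its rank count (0..8 capped)
        counts = {pr: min(8, int(np.floor(8 * deltas[pr] / max(deltas.values())))) for pr in pairs}
        for si, seg in enumerate(SEGMENTS):
            mat = pd.DataFrame(False, index=species, columns=species)
            for pr in pairs:
                if counts[pr] > si:
                    mat.loc[pr[0], pr[1]] = mat.loc[pr[1], pr[0]] = True
            fake[seg] = mat
        m = sm.PairwiseDifferenceMatrix(fake, alpha=0.05, method="tukey", species=species)
        out = sm.length_analyses(summ, m)
        # counts are a monotone step function of |delta length|: strong fit
        assert out["length_vs_differences"]["r_squared"] > 0.5

    def test_all_counts_equal_warns_r2_zero(self, small_rel):
        summ = sm.species_summary(small_rel)
        species = list(summ.per_species.index)
        fake = {s: pd.DataFrame(False, index=species, columns=species) for s in SEGMENTS}
        m = sm.PairwiseDifferenceMatrix(fake, alpha=0.05, method="tukey", species=species)
        with pytest.warns(UserWarning, match="equal"):
            out = sm.length_analyses(summ, m)
        assert out["length_vs_differences"]["r_squared"] == 0.0

    def test_wilcoxon_p_one_on_symmetric_toy(self):
        # two direction groups with interleaved equal-rank lengths
        rows = []
        lengths = {"a": 900, "b": 950, "c": 1000, "d": 1050}
        shifts = {"a": 0.02, "b": -0.02, "c": 0.02, "d": -0.02}
        rng = np.random.default_rng(0)
        for sp in lengths:
            for i in range(10):
                for j, seg in enumerate(SEGMENTS):
                    rows.append((sp, f"{sp}{i}", seg, 0.1 * (j + 1) + shifts[sp] + rng.normal(0, 1e-4), lengths[sp]))
        tab = pd.DataFrame(rows, columns=["species", "larva_id", "segment", "p", "body_length_um"])
        summ = sm.species_summary(tab)
        mat = sm.tukey_pairwise(tab)
        out = sm.length_analyses(summ, mat)
        # groups {a,c} vs {b,d} have interleaved lengths: exact two-sided p = 1... or close
        assert out["direction_vs_length"]["p_value"] > 0.6

    def test_null_slope_p_roughly_uniform(self, small_rel):
        # counts shuffled independently of length: p < 0.05 should be rare
        summ = sm.species_summary(small_rel)
        species = list(summ.per_species.index)
        hits = 0
        n_rep = 100
        for s in spawn_seeds(7, n_rep):
            rng = np.random.default_rng(s)
            fake = {}
            cnt = {pr: rng.integers(0, 9) for pr in itertools.combinations(species, 2)}
            for si, seg in enumerate(SEGMENTS):
                mat = pd.DataFrame(False, index=species, columns=species)
                for pr, c in cnt.items():
                    if c > si:
                        mat.loc[pr[0], pr[1]] = mat.loc[pr[1], pr[0]] = True
                fake[seg] = mat
            m = sm.PairwiseDifferenceMatrix(fake, alpha=0.05, method="tukey", species=species)
            out = sm.length_analyses(summ, m)
            hits += out["length_vs_differences"]["slope_p"] < 0.05
        assert hits / n_rep <= 0.12
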