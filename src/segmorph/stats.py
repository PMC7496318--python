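"""Frequentist comparisons of relative segment position between species.

Implements the study's statistical battery: the species x segment
interaction ANOVA, all-pairs Tukey HSD per segment (harmonic-mean
Tukey-Kramer convention, matching the classical HSD routine), Welch
t-tests with a global Bonferroni correction as the cross-check, the
difference-counting bookkeeping with the per-segment correction, the
within-species correlation-versus-distance analysis, and the
body-length analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .exceptions import DataError, InvalidArgumentError
from .simulate import SEGMENTS

__all__ = [
    "fit_interaction_anova",
    "tukey_pairwise",
    "ttest_bonferroni",
    "count_and_correct",
    "within_species_correlations",
    "correlation_decay_summary",
    "length_analyses",
    "PairwiseDifferenceMatrix",
]


@dataclass
class PairwiseDifferenceMatrix:
    """Per-segment indicators of significant species-pair differences.

    ``indicators`` maps segment -> symmetric boolean DataFrame (species x
    species, diagonal False).  Aggregates (pair counts, totals, per-species
    involvement, per-segment counts) are derived properties so the
    consistency identities hold by construction.
    """

    indicators: dict
    alpha: float
    method: str
    species: list = field(default_factory=list)

    def __post_init__(self):
        for seg, mat in self.indicators.items():
            if not (mat.values == mat.values.T).all():
                raise DataError(f"indicator matrix for {seg} is not symmetric")
            if np.diag(mat.values).any():
                raise DataError(f"indicator matrix for {seg} has a non-empty diagonal")
        if not self.species and self.indicators:
            first = next(iter(self.indicators.values()))
            self.species = list(first.index)

    @property
    def segments(self):
        return list(self.indicators)

    def pair_counts(self):
        """Count of differing segments per unordered species pair."""
        rows = []
        for a, b in itertools.combinations(self.species, 2):
            c = sum(int(self.indicators[seg].loc[a, b]) for seg in self.indicators)
            rows.append((a, b, c))
        return pd.DataFrame(rows, columns=["species_a", "species_b", "n_differing_segments"])

    @property
    def total(self):
        """Total significant (segment, species-pair) differences."""
        return int(self.pair_counts()["n_differing_segments"].sum())

    def per_species_counts(self):
        """Number of differences involving each species (sums to 2x total)."""
        counts = {sp: 0 for sp in self.species}
        pc = self.pair_counts()
        for _, row in pc.iterrows():
            counts[row["species_a"]] += row["n_differing_segments"]
            counts[row["species_b"]] += row["n_differing_segments"]
        return pd.Series(counts).sort_values(ascending=False)

    def per_segment_counts(self):
        return pd.Series(
            {seg: int(np.triu(self.indicators[seg].values, 1).sum()) for seg in self.indicators}
        )

    def n_pairs_all_segments(self):
        """Number of species pairs differing at every segment."""
        pc = self.pair_counts()
        return int((pc["n_differing_segments"] == len(self.indicators)).sum())

    def corrected_total(self, n_segments=None):
        n = n_segments if n_segments is not None else len(self.indicators)
        if n == 0:
            raise InvalidArgumentError("n_segments must be positive")
        return self.total / n


def fit_interaction_anova(table):
    """Fixed-effects ANOVA: p ~ species + segment + species:segment.

    Type-I (sequential) sums of squares in the stated order, matching the
    classical ``lm``/``aov`` treatment.

    Returns
    -------
    DataFrame
        Rows species, segment, species:segment, Residual; columns df,
        sum_sq, mean_sq, F, PR(>F).
    """
    cells = table.groupby(["species", "segment"]).size()
    n_species = table["species"].nunique()
    n_segments = table["segment"].nunique()
    if len(cells) < n_species * n_segments or (cells < 2).any():
        bad = cells[cells < 2] if len(cells) == n_species * n_segments else "missing cells"
        raise DataError(f"every species x segment cell needs >= 2 observations; problem: {bad}")
    model = smf.ols("p ~ C(species) + C(segment) + C(species):C(segment)", data=table).fit()
    aov = sm.stats.anova_lm(model, typ=1)
    aov = aov.rename(
        index={
            "C(species)": "species",
            "C(segment)": "segment",
            "C(species):C(segment)": "species:segment",
        }
    )
    aov["mean_sq"] = aov["sum_sq"] / aov["df"]
    total_ss = float(aov["sum_sq"].sum())
    if aov.loc["Residual", "sum_sq"] <= 1e-12 * max(total_ss, 1e-30):
        warnings.warn("zero residual variance: F statistics undefined")
    return aov


def _groups_by_segment(table, min_n=2):
    for seg, sub in table.groupby("segment"):
        groups = {sp: grp["p"].to_numpy() for sp, grp in sub.groupby("species")}
        small = [sp for sp, x in groups.items() if len(x) < min_n]
        if small:
            warnings.warn(f"segment {seg}: excluding species with < {min_n} larvae: {small}")
            for sp in small:
                groups.pop(sp)
        yield seg, groups


def tukey_pairwise(table, alpha=0.05):
    """All-pairs Tukey HSD per segment.

    For each segment a one-way layout across species is formed; the pooled
    within-group mean square and the studentized-range quantile give a
    single honestly-significant-difference threshold.  Unbalanced groups
    use the harmonic mean of the group sizes (the convention of the
    classical HSD routine).
    """
    indicators = {}
    species = sorted(table["species"].unique())
    for seg, groups in _groups_by_segment(table):
        names = sorted(groups)
        k = len(names)
        if k < 2:
            raise DataError(f"segment {seg}: need >= 2 species")
        ns = np.array([len(groups[sp]) for sp in names])
        means = np.array([groups[sp].mean() for sp in names])
        df_resid = int(ns.sum() - k)
        mse = sum(((groups[sp] - groups[sp].mean()) ** 2).sum() for sp in names) / df_resid
        n_h = k / np.sum(1.0 / ns)  # harmonic mean group size
        q_crit = sps.studentized_range.ppf(1 - alpha, k, df_resid)
        hsd = q_crit * np.sqrt(mse / n_h)
        mat = pd.DataFrame(False, index=names, columns=names)
        for i, j in itertools.combinations(range(k), 2):
            sig = abs(means[i] - means[j]) > hsd
            mat.iloc[i, j] = mat.iloc[j, i] = bool(sig)
        indicators[seg] = mat.reindex(index=species, columns=species, fill_value=False)
    return PairwiseDifferenceMatrix(indicators, alpha=alpha, method="tukey", species=species)


def ttest_bonferroni(table, alpha=0.05, equal_var=False):
    """Welch t-tests per (segment, species pair) with global Bonferroni.

    The correction multiplies every p-value by (number of species pairs x
    number of segments), i.e. the correction spans both multiple species
    and multiple segments, and caps at 1.
    """
    species = sorted(table["species"].unique())
    segs = sorted(table["segment"].unique(), key=lambda s: SEGMENTS.index(s) if s in SEGMENTS else 99)
    n_pairs = len(species) * (len(species) - 1) // 2
    factor = n_pairs * len(segs)
    indicators = {}
    for seg, groups in _groups_by_segment(table):
        names = sorted(groups)
        mat = pd.DataFrame(False, index=names, columns=names)
        for a, b in itertools.combinations(names, 2):
            t = sps.ttest_ind(groups[a], groups[b], equal_var=equal_var)
            p_adj = min(1.0, t.pvalue * factor)
            sig = p_adj < alpha
            mat.loc[a, b] = mat.loc[b, a] = bool(sig)
        indicators[seg] = mat.reindex(index=species, columns=species, fill_value=False)
    return PairwiseDifferenceMatrix(indicators, alpha=alpha, method="ttest_bonferroni", species=species)


def count_and_correct(matrix, n_segments=None):
    """Aggregate a difference matrix into corrected totals and rankings.

    The corrected total divides the overall count of significant
    (segment, pair) differences by the number of segments, making counts
    comparable between analyses with different numbers of segments (e.g.
    after end removal).
    """
    n = n_segments if n_segments is not None else len(matrix.indicators)
    if not n:
        raise InvalidArgumentError("n_segments must be positive")
    return {
        "total": matrix.total,
        "n_segments": n,
        "corrected_total": matrix.total / n,
        "n_pairs_all_segments": matrix.n_pairs_all_segments(),
        "per_species": matrix.per_species_counts(),
        "per_segment": matrix.per_segment_counts(),
        "pair_counts": matrix.pair_counts(),
    }


def within_species_correlations(table, min_n=3):
    """Pearson correlations of relative positions between segment pairs.

    For every species and every unordered segment pair, the correlation is
    computed across individuals; the pair's anatomical distance is the
    absolute difference of the species' mean positions.  Pairs involving
    the most posterior segment (A8) are flagged.

    Returns
    -------
    DataFrame
        Columns ``species, seg_a, seg_b, r, p_value, distance, separation,
        involves_a8``.
    """
    rows = []
    for sp, sub in table.groupby("species"):
        wide = sub.pivot_table(index="larva_id", columns="segment", values="p")
        segs = [s for s in SEGMENTS if s in wide.columns]
        wide = wide[segs].dropna()
        if len(wide) < min_n:
            warnings.warn(f"species {sp}: fewer than {min_n} individuals, skipped")
            continue
        means = wide.mean()
        for a, b in itertools.combinations(segs, 2):
            xa, xb = wide[a].to_numpy(), wide[b].to_numpy()
            tol = 1e-12
            if xa.std() <= tol * max(1.0, abs(xa.mean())) or xb.std() <= tol * max(1.0, abs(xb.mean())):
                warnings.warn(f"species {sp}: zero variance in {a} or {b}; correlation undefined")
                r, pval = np.nan, np.nan
            else:
                res = sps.pearsonr(xa, xb)
                r, pval = float(res.statistic), float(res.pvalue)
            rows.append(
                (
                    sp, a, b, r, pval,
                    abs(means[a] - means[b]),
                    abs(SEGMENTS.index(a) - SEGMENTS.index(b)),
                    a == "A8" or b == "A8",
                )
            )
    return pd.DataFrame(
        rows, columns=["species", "seg_a", "seg_b", "r", "p_value", "distance", "separation", "involves_a8"]
    )


def correlation_decay_summary(profile):
    """Across-species averages of correlation by segment separation.

    Splits pairs by whether they involve A8, mirroring the comparison that
    shows A8 shifting more independently than the other segments.

    Returns
    -------
    DataFrame
        Columns ``separation, involves_a8, mean_r, ci95_low, ci95_high, n``.
    """
    rows = []
    valid = profile.dropna(subset=["r"])
    for (sep, a8), grp in valid.groupby(["separation", "involves_a8"]):
        x = grp["r"].to_numpy()
        m = x.mean()
        if len(x) > 1:
            half = sps.t.ppf(0.975, len(x) - 1) * x.std(ddof=1) / np.sqrt(len(x))
        else:
            half = np.nan
        rows.append((sep, a8, m, m - half, m + half, len(x)))
    return pd.DataFrame(rows, columns=["separation", "involves_a8", "mean_r", "ci95_low", "ci95_high", "n"])


def length_analyses(summary, matrix, pca=None):
    """Body-length analyses.

    1. Least-squares regression of the per-pair count of differing
       segments on the absolute difference in mean body length (R^2 and
       slope p-value);
    2. Wilcoxon rank-sum comparing mean body lengths of species grouped by
       their majority shift direction (anterior vs posterior);
    3. Pearson test of PC1 scores against body length (if ``pca`` given,
       its stored test is reported).

    Returns a dict.
    """
    lengths = summary.per_species["mean_length_um"]
    if len(lengths) < 3:
        raise InvalidArgumentError("need >= 3 species")
    pc = matrix.pair_counts()
    x = np.array([abs(lengths[a] - lengths[b]) for a, b in zip(pc["species_a"], pc["species_b"])])
    y = pc["n_differing_segments"].to_numpy(dtype=float)
    if np.all(y == y[0]):
        warnings.warn("all pair counts equal; regression R^2 is 0 by construction")
        reg = {"r_squared": 0.0, "slope": 0.0, "slope_p": np.nan, "n_pairs": len(y)}
    else:
        fit = sps.linregress(x, y)
        reg = {
            "r_squared": float(fit.rvalue ** 2),
            "slope": float(fit.slope),
            "slope_p": float(fit.pvalue),
            "n_pairs": len(y),
        }
    # majority shift direction per species
    maj = (
        summary.per_segment.groupby("species")["direction"]
        .agg(lambda d: "posterior" if (d == "posterior").sum() * 2 >= len(d) else "anterior")
    )
    grp_a = lengths[maj == "anterior"]
    grp_p = lengths[maj == "posterior"]
    if len(grp_a) and len(grp_p):
        w = sps.mannwhitneyu(grp_a, grp_p, alternative="two-sided", method="exact")
        wilcoxon = {"statistic": float(w.statistic), "p_value": float(w.pvalue)}
    else:
        wilcoxon = {"statistic": np.nan, "p_value": np.nan}
    out = {"length_vs_differences": reg, "direction_vs_length": wilcoxon}
    if pca is not None:
        out["pc1_vs_length"] = {"r": pca.pc1_length_test[0], "p_value": pca.pc1_length_test[1]}
    return out
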