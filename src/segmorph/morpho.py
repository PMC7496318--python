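"""Relative-position morphometrics.

Turns raw belt-border measurements into the study's derived quantities:
relative segment positions (anterior belt border / body length),
end-removal renormalisations, per-species summaries with deviations from
the across-species mean, coefficients of variation, belt width metrics,
and a PCA of mean-centred segment positions.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DataError, InvalidArgumentError
from .simulate import SEGMENTS

__all__ = [
    "relative_positions",
    "remove_end",
    "species_summary",
    "coefficient_of_variation",
    "belt_metrics",
    "pca_segments",
    "PCAResult",
    "SpeciesSummary",
]

_MEAS_COLS = ["species", "larva_id", "segment", "x_anterior_um", "x_posterior_um", "body_length_um"]


def _check_measurements(df):
    missing = [c for c in _MEAS_COLS if c not in df.columns]
    if missing:
        raise DataError(f"measurement table is missing columns {missing}")
    if (df["body_length_um"] <= 0).any():
        raise InvalidArgumentError("body_length_um must be positive")


def relative_positions(measurements):
    """Relative segment position: anterior belt border / body length.

    Parameters
    ----------
    measurements : DataFrame
        Tidy table with one row per (larva, segment).

    Returns
    -------
    DataFrame
        Columns ``species, larva_id, segment, p, body_length_um``.
    """
    _check_measurements(measurements)
    out = measurements[["species", "larva_id", "segment"]].copy()
    out["p"] = measurements["x_anterior_um"] / measurements["body_length_um"]
    out["body_length_um"] = measurements["body_length_um"]
    return out


def remove_end(measurements, end):
    """Recompute relative positions after removing a terminal region.

    ``end="a8tail"`` removes the region from A8's anterior border to the
    posterior tip: the truncated body length is the distance to A8's
    border and positions of A1..A7 are rescaled to it.  ``end="ht"``
    removes the head + thorax: the origin moves to A1's anterior border
    and positions of A2..A8 are rescaled to the remaining length.
    """
    _check_measurements(measurements)
    end = end.lower().replace("+", "")
    if end not in ("a8tail", "ht"):
        raise InvalidArgumentError("end must be 'a8tail' or 'ht'")
    wide = measurements.pivot_table(
        index=["species", "larva_id"], columns="segment", values="x_anterior_um"
    )[SEGMENTS]
    length = measurements.groupby(["species", "larva_id"])["body_length_um"].first()
    length = length.reindex(wide.index)
    if end == "a8tail":
        denom = wide["A8"]
        if (denom <= 0).any():
            raise InvalidArgumentError("degenerate denominator: A8 border at or before the anterior tip")
        p = wide[SEGMENTS[:7]].div(denom, axis=0)
    else:
        origin = wide["A1"]
        denom = length - origin
        if (denom <= 0).any():
            raise InvalidArgumentError("degenerate denominator: A1 border at or beyond the posterior tip")
        p = wide[SEGMENTS[1:]].sub(origin, axis=0).div(denom, axis=0)
    out = p.reset_index().melt(id_vars=["species", "larva_id"], var_name="segment", value_name="p")
    out["body_length_um"] = out.set_index(["species", "larva_id"]).index.map(length)
    out["_seg"] = out["segment"].map({s: i for i, s in enumerate(SEGMENTS)})
    out = out.sort_values(["species", "larva_id", "_seg"]).drop(columns="_seg")
    return out.reset_index(drop=True)


@dataclass
class SpeciesSummary:
    """Per-(species, segment) means, CIs and deviations from the grand mean.

    ``per_segment`` columns: ``mean_p, ci95_low, ci95_high, deviation,
    direction, magnitude, n``; the grand mean is the unweighted mean of
    species means, so deviations average to zero across species within
    each segment.  ``per_species`` carries mean body length with its CI
    and the total deviation (sum of |deviation| over segments).
    """

    per_segment: pd.DataFrame
    per_species: pd.DataFrame

    @property
    def species(self):
        return list(self.per_species.index)


def _t_ci(x, level=0.95):
    x = np.asarray(x, dtype=float)
    n = len(x)
    m = x.mean()
    if n < 2:
        return m, np.nan, np.nan
    half = sps.t.ppf(0.5 + level / 2, n - 1) * x.std(ddof=1) / np.sqrt(n)
    return m, m - half, m + half


def species_summary(table, min_n=2):
    """Summarise a relative-position table per species and segment.

    Species with fewer than ``min_n`` larvae are excluded with a warning.
    Confidence intervals are t-based; the deviation of a species at a
    segment is its mean minus the unweighted across-species grand mean.
    """
    counts = table.groupby("species")["larva_id"].nunique()
    small = counts[counts < min_n].index.tolist()
    if small:
        warnings.warn(f"excluding species with < {min_n} larvae: {small}")
        table = table[~table["species"].isin(small)]
    if table.empty:
        raise DataError("no species left to summarise")
    rows = []
    for (sp, seg), grp in table.groupby(["species", "segment"]):
        m, lo, hi = _t_ci(grp["p"])
        rows.append((sp, seg, m, lo, hi, len(grp)))
    per = pd.DataFrame(rows, columns=["species", "segment", "mean_p", "ci95_low", "ci95_high", "n"])
    grand = per.groupby("segment")["mean_p"].mean().rename("grand_mean_p")
    per = per.join(grand, on="segment")
    per["deviation"] = per["mean_p"] - per["grand_mean_p"]
    per["direction"] = np.where(per["deviation"] >= 0, "posterior", "anterior")
    per["magnitude"] = per["deviation"].abs()

    lengths = table.groupby(["species", "larva_id"])["body_length_um"].first().reset_index()
    lrows = []
    for sp, grp in lengths.groupby("species"):
        m, lo, hi = _t_ci(grp["body_length_um"])
        lrows.append((sp, m, lo, hi))
    per_species = pd.DataFrame(lrows, columns=["species", "mean_length_um", "length_ci95_low", "length_ci95_high"])
    per_species = per_species.set_index("species")
    per_species["total_deviation"] = per.groupby("species")["magnitude"].sum()
    return SpeciesSummary(per_segment=per, per_species=per_species)


def coefficient_of_variation(table, min_n=2):
    """Within-species CV of relative position, per segment.

    Returns
    -------
    (DataFrame, Series)
        Per-(species, segment) CV table and the across-species mean CV per
        segment.
    """
    counts = table.groupby("species")["larva_id"].nunique()
    small = counts[counts < min_n].index.tolist()
    if small:
        warnings.warn(f"excluding species with < {min_n} larvae: {small}")
        table = table[~table["species"].isin(small)]
    g = table.groupby(["species", "segment"])["p"]
    cv = (g.std(ddof=1) / g.mean()).rename("cv").reset_index()
    mean_cv = cv.groupby("segment")["cv"].mean()
    return cv, mean_cv


def belt_metrics(measurements):
    """Relative posterior-border positions and relative belt widths."""
    _check_measurements(measurements)
    out = measurements[["species", "larva_id", "segment"]].copy()
    out["p_posterior"] = measurements["x_posterior_um"] / measurements["body_length_um"]
    out["width"] = (measurements["x_posterior_um"] - measurements["x_anterior_um"]) / measurements["body_length_um"]
    if (out["width"] <= 0).any():
        raise InvalidArgumentError("belt widths must be positive (ordering invariant violated)")
    return out


@dataclass
class PCAResult:
    """PCA of mean-centred relative segment positions.

    ``loadings`` has one column per component (rows = segments); ``scores``
    one row per observation; ``variance_explained`` sums to 1 over the
    retained rank.  ``pc1_segment_tests`` and ``pc1_length_test`` hold
    Pearson correlation tests of PC1 scores against each segment's
    relative position and against body length.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_explained: np.ndarray
    rank: int
    pc1_segment_tests: pd.DataFrame
    pc1_length_test: tuple


def pca_segments(table, level="individual"):
    """PCA of the individuals x segments matrix of mean-centred positions.

    ``level="species"`` instead decomposes the species-means matrix.  No
    variance scaling is applied.  The PC1 sign is fixed so its loading on
    A8 is positive, which makes downstream correlation tests reproducible.
    """
    wide = table.pivot_table(index=["species", "larva_id"], columns="segment", values="p")
    segs = [s for s in SEGMENTS if s in wide.columns]
    wide = wide[segs].dropna()
    if level == "species":
        wide = wide.groupby(level="species").mean()
    elif wide.shape[0] <= wide.shape[1]:
        raise InvalidArgumentError("need more observations than segments for PCA")
    if wide.shape[0] < 2:
        raise InvalidArgumentError("need at least two observations for PCA")
    X = wide.to_numpy()
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2 / (X.shape[0] - 1)
    rank = int((s > s[0] * 1e-12).sum()) if s[0] > 0 else 0
    var_explained = var / var.sum() if var.sum() > 0 else var
    # sign convention: loading of PC1 on the last (most posterior) segment >= 0
    flip = np.where(Vt[:, -1] < 0, -1.0, 1.0)
    Vt = Vt * flip[:, None]
    scores = Xc @ Vt.T
    pcs = [f"PC{i + 1}" for i in range(Vt.shape[0])]
    loadings = pd.DataFrame(Vt.T, index=segs, columns=pcs)
    scores_df = pd.DataFrame(scores, index=wide.index, columns=pcs)
    tests = []
    for j, seg in enumerate(segs):
        if scores[:, 0].std() == 0 or X[:, j].std() == 0 or len(X) < 3:
            r, pval = np.nan, np.nan
        else:
            res = sps.pearsonr(scores[:, 0], X[:, j])
            r, pval = float(res.statistic), float(res.pvalue)
        tests.append((seg, r, pval))
    seg_tests = pd.DataFrame(tests, columns=["segment", "r", "p_value"])
    length_test = (np.nan, np.nan)
    if "body_length_um" in table.columns:
        if level == "individual":
            lengths = table.groupby(["species", "larva_id"])["body_length_um"].first().reindex(wide.index)
        else:
            lengths = table.groupby("species")["body_length_um"].mean().reindex(wide.index)
        lvals = lengths.to_numpy(dtype=float)
        if len(lvals) >= 3 and np.std(lvals) > 0 and scores[:, 0].std() > 0:
            lt = sps.pearsonr(scores[:, 0], lvals)
            length_test = (float(lt.statistic), float(lt.pvalue))
    return PCAResult(
        loadings=loadings,
        scores=scores_df,
        variance_explained=var_explained,
        rank=rank,
        pc1_segment_tests=seg_tests,
        pc1_length_test=length_test,
    )
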