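"""Synthetic data with the statistical structure of the larval study.

This module generates every input the downstream stages consume: random
ultrametric trees, multivariate Brownian trait histories with per-branch
rate multipliers, individual-level larval cohorts whose within-species
noise has correlations that decay with inter-segment distance, and
rendered dark-field images with pixel-level ground truth.

The cohort model: a larva's nine inter-boundary spans (anterior tip to
A1, A1 to A2, ..., A8 to posterior tip) are the species' mean spans
perturbed by (i) independent multiplicative per-span noise and (ii) a
smooth low-frequency axial field (a Gaussian process with a squared-
exponential kernel along the body axis).  The smooth field is what makes
neighbouring segments co-vary more than distant ones, the structure the
within-species correlation analyses assume.  Spans are renormalised to
the larva's drawn body length, so relative positions are invariant to
overall size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, RenderResolutionError
from .ratemodel import BranchRateModel, draw_branch_rates
from .trees import Phylogeny

__all__ = [
    "SpeciesProfile",
    "TraitHistory",
    "LarvaMeasurement",
    "simulate_tree",
    "evolve_traits",
    "simulate_cohort",
    "simulate_study",
    "simulate_null_positions",
    "render_larva_image",
    "default_species_profiles",
    "measurements_to_frame",
    "frame_to_measurements",
    "STUDY_SPECIES",
]

SEGMENTS = [f"A{i}" for i in range(1, 9)]

#: the 12 study species, ordered roughly along the phylogeny
STUDY_SPECIES = [
    "D. melanogaster", "D. simulans", "D. sechellia", "D. yakuba",
    "D. santomea", "D. erecta", "D. ananassae", "D. pseudoobscura",
    "D. persimilis", "D. willistoni", "D. mojavensis", "D. virilis",
]

#: grand-mean relative anterior-border positions of A1..A8
_BASE_BOUNDARIES = np.array([0.29, 0.37, 0.45, 0.53, 0.61, 0.68, 0.755, 0.835])

# fraction of the local inter-boundary span occupied by a denticle belt
BELT_WIDTH_FRACTION = 0.35


@dataclass
class SpeciesProfile:
    """Generative parameters for one species' larval cohort.

    ``mean_boundaries`` are the mean relative anterior-border positions of
    A1..A8 (fractions of body length, strictly increasing).
    ``segment_noise_sd`` is the s.d. of independent log-perturbations of
    each inter-boundary span; ``smooth_noise_scale`` is the amplitude of
    the smooth axial field that induces distance-decaying correlations.
    """

    species_id: str
    mean_boundaries: np.ndarray = field(default_factory=lambda: _BASE_BOUNDARIES.copy())
    mean_length: float = 1000.0
    length_cv: float = 0.07
    segment_noise_sd: float = 0.02
    smooth_noise_scale: float = 0.025
    smooth_length_scale: float = 0.25
    # the terminal regions (head+thorax, A8+tail) are the most variable in
    # real larvae; their spans get scaled-up per-span noise.  The A7->A8
    # span also gets extra independent noise, which makes the A8 border
    # shift more independently of the other segments (tail-span noise, by
    # contrast, moves every relative position together).  Factors multiply
    # segment_noise_sd, so a noiseless profile stays noiseless.
    head_noise_factor: float = 1.5
    tail_noise_factor: float = 6.0
    a8_border_noise_factor: float = 8.0

    def __post_init__(self):
        b = np.asarray(self.mean_boundaries, dtype=float)
        if b.shape != (8,):
            raise InvalidArgumentError("mean_boundaries must have 8 entries (A1..A8)")
        if np.any(np.diff(b) <= 0) or b[0] <= 0 or b[-1] >= 1:
            raise InvalidArgumentError("mean_boundaries must be strictly increasing within (0, 1)")
        if self.mean_length <= 0:
            raise InvalidArgumentError("mean_length must be positive")
        if self.length_cv < 0 or self.segment_noise_sd < 0 or self.smooth_noise_scale < 0:
            raise InvalidArgumentError("noise parameters must be non-negative")
        self.mean_boundaries = b


@dataclass
class TraitHistory:
    """A realised trait history on a tree: node states and true branch rates."""

    tree: Phylogeny
    node_states: np.ndarray          # (n_nodes, n_traits)
    branch_rates_true: np.ndarray    # (n_branches,) or (n_branches, n_traits)
    sigma2_true: np.ndarray          # (n_traits, n_traits)
    n_rejections: int = 0

    @property
    def tip_states(self):
        return self.node_states[: self.tree.n_tips]

    def tip_frame(self):
        return pd.DataFrame(self.tip_states, index=self.tree.tip_labels, columns=SEGMENTS[: self.node_states.shape[1]])


@dataclass
class LarvaMeasurement:
    """One larva's belt-border distances (µm from the anterior tip) and length."""

    species: str
    larva_id: str
    x_anterior: np.ndarray   # (8,) anterior borders of A1..A8
    x_posterior: np.ndarray  # (8,) posterior borders of the belts
    body_length: float

    def __post_init__(self):
        self.x_anterior = np.asarray(self.x_anterior, dtype=float)
        self.x_posterior = np.asarray(self.x_posterior, dtype=float)
        seq = np.empty(16)
        seq[0::2] = self.x_anterior
        seq[1::2] = self.x_posterior
        if self.x_anterior[0] <= 0 or seq[-1] >= self.body_length or np.any(np.diff(seq) <= 0):
            raise InvalidArgumentError(
                f"larva {self.larva_id!r}: belt borders must be strictly increasing within (0, body_length)"
            )

    @property
    def relative_anterior(self):
        return self.x_anterior / self.body_length


def simulate_tree(n_taxa, seed, labels=None):
    """Simulate a random rooted binary ultrametric tree of unit depth.

    Coalescent-style construction: lineages merge in random pairs at
    exponentially spaced heights; heights are rescaled so the root sits at
    depth 1.0.
    """
    if n_taxa < 2:
        raise InvalidArgumentError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"sp{i + 1}" for i in range(n_taxa)]
    n_nodes = 2 * n_taxa - 1
    parent = np.full(n_nodes, -1, dtype=int)
    height = np.zeros(n_nodes)
    active = list(range(n_taxa))
    t = 0.0
    nxt = n_taxa
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        height[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    scale = height[n_nodes - 1]
    height /= scale
    blen = np.zeros(n_nodes)
    for v in range(n_nodes - 1):
        blen[v] = height[parent[v]] - height[v]
    return Phylogeny(parent, blen, labels, ultrametric_tol=1e-9)


def evolve_traits(tree, sigma2, rate_model=None, root_state=None, seed=0, max_rejections=10_000,
                  branch_rates=None):
    """Evolve traits on a tree under Brownian motion with branch rates.

    Child state = parent state + a Gaussian increment with covariance
    ``t_b * r_b * sigma2``.  Because relative positions are fractions, any
    increment that would leave (0, 1) is rejected and redrawn for the whole
    branch; the rejection count is recorded on the returned history.

    ``branch_rates`` (in ``tree.branch_nodes`` order; shape ``(B,)`` or
    ``(B, n_traits)``) overrides the rate-model draw with given true rates.
    """
    sigma2 = np.atleast_2d(np.asarray(sigma2, dtype=float))
    p = sigma2.shape[0]
    eig = np.linalg.eigvalsh(sigma2)
    if eig.min() < -1e-10 * max(1.0, abs(eig).max()):
        raise InvalidArgumentError("sigma2 must be positive semi-definite")
    if root_state is None:
        root_state = _BASE_BOUNDARIES[:p].copy()
    root_state = np.atleast_1d(np.asarray(root_state, dtype=float))
    if np.any(root_state <= 0) or np.any(root_state >= 1):
        raise InvalidArgumentError("root_state components must lie in (0, 1)")
    if rate_model is None:
        rate_model = BranchRateModel("strict")
    rng = np.random.default_rng(seed)
    if branch_rates is not None:
        rates = np.asarray(branch_rates, dtype=float)
        if np.any(rates <= 0):
            raise InvalidArgumentError("branch_rates must be positive")
    else:
        rates = draw_branch_rates(tree, rate_model, rng, n_traits=p)
    pos = {v: i for i, v in enumerate(tree.branch_nodes)}
    # scale-free square root of sigma2 (PSD-safe)
    w, U = np.linalg.eigh(sigma2)
    sqrt_sig = U * np.sqrt(np.clip(w, 0.0, None))
    states = np.zeros((tree.n_nodes, p))
    states[tree.root] = root_state
    rejections = 0
    for v in tree.preorder():
        if v == tree.root:
            continue
        t_b = tree.branch_length[v]
        r_b = rates[pos[v]]
        sd_scale = np.sqrt(t_b * r_b)  # scalar, or per-trait for per-segment rates
        parent_state = states[tree.parent[v]]
        for _ in range(max_rejections):
            if np.ndim(sd_scale) == 0:
                cand = parent_state + sd_scale * (sqrt_sig @ rng.standard_normal(p))
            else:
                # per-segment rates: independent increments per trait
                cand = parent_state + np.sqrt(np.diag(sigma2)) * sd_scale * rng.standard_normal(p)
            if np.all((cand > 0) & (cand < 1)):
                states[v] = cand
                break
            rejections += 1
        else:
            states[v] = np.clip(cand, 1e-6, 1 - 1e-6)
    return TraitHistory(tree, states, rates, sigma2, n_rejections=rejections)


def segment_correlation_matrix(n_segments=8, length_scale=2.0):
    """Squared-exponential correlation across segment indices.

    Neighbouring segments' trait increments are highly correlated and the
    correlation decays with index separation — the coordination structure
    the rate-correlation analyses probe.
    """
    idx = np.arange(n_segments)
    return np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / length_scale) ** 2)


def _smooth_field_chol(midpoints, length_scale):
    d = midpoints[:, None] - midpoints[None, :]
    K = np.exp(-0.5 * (d / length_scale) ** 2)
    K[np.diag_indices_from(K)] += 1e-10
    return np.linalg.cholesky(K)


def _spans_from_boundaries(boundaries):
    knots = np.concatenate([[0.0], boundaries, [1.0]])
    return np.diff(knots)


def simulate_cohort(profile, n_individuals, seed):
    """Simulate a species cohort of individually measured larvae.

    Returns a list of :class:`LarvaMeasurement` with absolute distances in
    micrometers; belt posterior borders sit at a fixed fraction
    (:data:`BELT_WIDTH_FRACTION`) of the local inter-boundary span.
    """
    if n_individuals < 0:
        raise InvalidArgumentError("n_individuals must be >= 0")
    rng = np.random.default_rng(seed)
    mean_spans = _spans_from_boundaries(profile.mean_boundaries)
    mids = np.concatenate([[0.0], profile.mean_boundaries, [1.0]])
    mids = 0.5 * (mids[:-1] + mids[1:])
    chol = _smooth_field_chol(mids, profile.smooth_length_scale) if profile.smooth_noise_scale > 0 else None
    # lognormal body length with the requested CV
    if profile.length_cv > 0:
        s_len = np.sqrt(np.log1p(profile.length_cv ** 2))
        mu_len = np.log(profile.mean_length) - 0.5 * s_len ** 2
    span_sd = np.full(9, profile.segment_noise_sd)
    span_sd[0] *= profile.head_noise_factor
    span_sd[7] *= profile.a8_border_noise_factor
    span_sd[8] *= profile.tail_noise_factor
    out = []
    for i in range(n_individuals):
        L = profile.mean_length if profile.length_cv == 0 else float(np.exp(rng.normal(mu_len, s_len)))
        spans = mean_spans.copy()
        if profile.segment_noise_sd > 0:
            spans = spans * np.exp(rng.normal(0.0, 1.0, size=9) * span_sd)
        if chol is not None:
            g = profile.smooth_noise_scale * (chol @ rng.standard_normal(9))
            spans = spans * np.exp(g)
        spans = spans / spans.sum()
        bounds = np.cumsum(spans)[:8]            # relative anterior borders of A1..A8
        local = spans[1:9]                        # span posterior to each boundary
        xa = bounds * L
        xp = (bounds + BELT_WIDTH_FRACTION * local) * L
        out.append(
            LarvaMeasurement(
                species=profile.species_id,
                larva_id=f"{profile.species_id}_{i:04d}",
                x_anterior=xa,
                x_posterior=xp,
                body_length=L,
            )
        )
    return out


def default_species_profiles():
    """Profiles for the 12 study species.

    Mean boundary offsets emulate the qualitative between-species pattern:
    deviations grow toward the posterior, one cactophilic species has a
    markedly anterior-shifted A8 border (long tail region), one species a
    posterior-shifted A8 border (short tail region), and one species sits
    near the across-species mean.  Mean lengths span the observed range of
    first-instar larvae.
    """
    # per-species additive offsets to the base boundaries (A1..A8), built
    # from two components: a posterior-growing gradient (the dominant
    # axis of between-species variation) and a "shape" component with
    # sign changes along the body, so that neighbouring segments can
    # shift in opposite directions in some species
    grad = np.linspace(0.2, 1.0, 8)
    shape = np.array([0.5, 0.2, -0.3, -0.5, -0.2, 0.2, 0.4, 0.1])
    comps = {
        "D. melanogaster": (0.006, 0.003),
        "D. simulans": (0.002, -0.004),
        "D. sechellia": (-0.014, 0.004),
        "D. yakuba": (0.008, -0.003),
        "D. santomea": (0.010, 0.005),
        "D. erecta": (-0.013, -0.005),
        "D. ananassae": (0.000, 0.001),
        "D. pseudoobscura": (0.009, 0.006),
        "D. persimilis": (0.016, -0.006),   # posterior-shifted A8: short A8+tail
        "D. willistoni": (0.004, -0.008),
        "D. mojavensis": (-0.020, 0.006),   # anterior-shifted A8: long A8+tail
        "D. virilis": (-0.006, 0.007),
    }
    offs = {sp: a * grad + b * shape for sp, (a, b) in comps.items()}
    lengths = {
        "D. melanogaster": 1000.0, "D. simulans": 990.0, "D. sechellia": 1120.0,
        "D. yakuba": 1010.0, "D. santomea": 1150.0, "D. erecta": 960.0,
        "D. ananassae": 1000.0, "D. pseudoobscura": 880.0, "D. persimilis": 870.0,
        "D. willistoni": 980.0, "D. mojavensis": 900.0, "D. virilis": 1080.0,
    }
    return [
        SpeciesProfile(sp, _BASE_BOUNDARIES + offs[sp], mean_length=lengths[sp])
        for sp in STUDY_SPECIES
    ]


def simulate_study(profiles=None, n_range=(105, 145), seed=0):
    """Simulate the full multi-species study as a tidy measurement table.

    Cohort sizes are drawn uniformly from ``n_range`` (inclusive), matching
    the study's 105-145 individuals per species.
    """
    if profiles is None:
        profiles = default_species_profiles()
    rng = np.random.default_rng(seed)
    frames = []
    for k, prof in enumerate(profiles):
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        cohort = simulate_cohort(prof, n, seed=int(rng.integers(2 ** 31)))
        frames.append(measurements_to_frame(cohort))
    return pd.concat(frames, ignore_index=True)


def simulate_null_positions(n_species, n_larvae, seed, noise_sd=0.01):
    """Relative-position table with i.i.d. Gaussian noise and no effects.

    Every observation is the grand-mean boundary plus independent noise —
    the null that matches the linear model's error assumptions exactly.
    Used to calibrate the interaction ANOVA; the cohort generator, by
    design, has within-larva correlations that violate i.i.d. errors.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_species):
        sp = f"sp{s + 1}"
        noise = rng.normal(0.0, noise_sd, size=(n_larvae, 8))
        for i in range(n_larvae):
            for j, seg in enumerate(SEGMENTS):
                rows.append((sp, f"{sp}_{i:04d}", seg, _BASE_BOUNDARIES[j] + noise[i, j]))
    return pd.DataFrame(rows, columns=["species", "larva_id", "segment", "p"])


def measurements_to_frame(measurements):
    """Tidy CSV dialect: one row per (larva, segment)."""
    rows = []
    for m in measurements:
        for j, seg in enumerate(SEGMENTS):
            rows.append(
                (m.species, m.larva_id, seg, m.x_anterior[j], m.x_posterior[j], m.body_length)
            )
    return pd.DataFrame(
        rows,
        columns=["species", "larva_id", "segment", "x_anterior_um", "x_posterior_um", "body_length_um"],
    )


def frame_to_measurements(df):
    """Inverse of :func:`measurements_to_frame`."""
    out = []
    seg_order = {s: i for i, s in enumerate(SEGMENTS)}
    for (sp, lid), grp in df.groupby(["species", "larva_id"], sort=False):
        grp = grp.sort_values("segment", key=lambda s: s.map(seg_order))
        out.append(
            LarvaMeasurement(
                species=sp,
                larva_id=lid,
                x_anterior=grp["x_anterior_um"].to_numpy(),
                x_posterior=grp["x_posterior_um"].to_numpy(),
                body_length=float(grp["body_length_um"].iloc[0]),
            )
        )
    return out


def render_larva_image(measurement, width_px=1000, rotation_deg=0.0, noise_sd=0.03, seed=0):
    """Render a synthetic dark-field image of a measured larva.

    The body is a bright elongated region on a dark background with eight
    brighter transverse bands at the measurement's belt borders and a
    tapered anterior (head) end.  Ground truth is returned in canonical
    (unrotated, anterior-left) pixel coordinates.

    Returns
    -------
    (LarvaImage, BeltAnnotation)
    """
    from .imaging import BeltAnnotation, LarvaImage

    if width_px < 200:
        raise InvalidArgumentError("width_px must be >= 200")
    m = measurement
    c0 = 0.05 * width_px
    c1 = 0.95 * width_px
    px_per_um = (c1 - c0) / m.body_length
    belts_px = [
        (c0 + a * px_per_um, c0 + p * px_per_um) for a, p in zip(m.x_anterior, m.x_posterior)
    ]
    for a, p in belts_px:
        if p - a < 1.0:
            raise RenderResolutionError(
                f"belt would occupy {p - a:.2f} px (< 1 px) at width_px={width_px}"
            )
    height = max(64, width_px // 5)
    img = np.full((height, width_px), 0.02, dtype=float)
    cy = height / 2.0
    cols = np.arange(width_px, dtype=float)
    u = (cols - c0) / (c1 - c0)  # 0..1 along the body
    half = np.full(width_px, 0.30 * height)
    inside = (u >= 0) & (u <= 1)
    # anterior taper (head): thinner over the first 15% of the body;
    # posterior taper over the last 6%
    head = inside & (u < 0.15)
    half[head] *= 0.35 + 0.65 * (u[head] / 0.15) ** 0.8
    tail = inside & (u > 0.94)
    half[tail] *= np.sqrt(np.clip(1 - ((u[tail] - 0.94) / 0.06) ** 2, 0.05, 1.0))
    half[~inside] = 0.0
    rowidx = np.arange(height, dtype=float)[:, None]
    body = np.abs(rowidx - cy) < half[None, :]
    img[body] = 0.35
    band_cols = np.zeros(width_px, dtype=bool)
    for a, p in belts_px:
        band_cols[(cols >= a) & (cols < p)] = True
    img[body & band_cols[None, :]] = 0.90
    if rotation_deg:
        from skimage import transform

        img = transform.rotate(img, rotation_deg, resize=True, order=1, preserve_range=True, cval=0.02)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    annotation = BeltAnnotation(c0, c1, belts_px)
    return LarvaImage(img, pixel_size_um=1.0 / px_per_um), annotation


def write_larva_image(image, annotation, path):
    """Write a rendered image as 16-bit grayscale TIFF/PNG + JSON ground truth.

    The ground-truth sidecar is ``<path>.json``.
    """
    from skimage import io as skio

    arr = np.clip(image.pixels, 0.0, 1.0)
    skio.imsave(str(path), (arr * 65535).astype(np.uint16), check_contrast=False)
    annotation.to_json(str(path) + ".json")
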