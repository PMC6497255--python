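"""Synthetic vascular trees and aging cohorts with known ground truth.

The growth model is a stochastic branching random walk on the image grid:
tips advance in unit steps while their heading diffuses with standard
deviation ``tau`` per step (controlling tortuosity), and at the end of each
segment a tip either bifurcates into two children — deflected by 20-40
degrees each side, with child widths obeying the Murray-type cubed-sum rule
``w_parent**3 = w_child1**3 + w_child2**3`` — or terminates.  Centerlines
are rendered as discs of radius ``w / 2``, and the true topology (number of
bifurcations and endpoints) plus per-branch geometry are recorded so every
downstream measurement can be checked against ground truth.

The cohort simulator draws participants whose generative parameters vary
linearly with age.  Default slopes emulate the decline in bifurcation
number reported for aging retinal microvasculature: an expected measured
bifurcation count (j2) near 74 at age 20 falling to about 31 at age 88,
with heading noise (hence tortuosity) held age-constant so tortuosity
traits act as programmed nulls.  Traits in the cohort table are measured by
running the actual image pipeline on each rendered map, never copied from
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk

from .tracking import count_junctions, crossing_number_map, extract_branches, skeletonize
from .traits import (
    FRACTAL_NAMES,
    TORTUOSITY_NAMES,
    TRAIT_NAMES,
    aggregate_tortuosity,
    anchor_points,
    class_traits,
    fractal_traits,
    tortuosity_basis,
)
from .vesselmap import VesselMap

__all__ = [
    "GrowthConfig",
    "GroundTruth",
    "CohortConfig",
    "grow_vessel_tree",
    "simulate_cohort",
    "measure_map",
]

#: traits the cohort simulator measures by default (sampled tortuosity,
#: junction counts, and one fractal scale) — enough for age-trend work
#: while keeping per-image cost low
DEFAULT_MEASURE = ("t1", "t3", "t5", "j1", "j2", "j3", "f3")

COVARIATE_NAMES = ("sbp", "dbp", "waist", "hip", "weight", "height", "bmi", "imt")


@dataclass
class GrowthConfig:
    """Parameters of the branching random-walk growth model.

    ``shape`` is (rows, cols); the default matches the 565x584 analysis
    raster.  ``p_bif`` is the per-step bifurcation probability, so segments
    between bifurcations have mean length ``min_segment + 1 / p_bif`` steps.
    ``bifurcation_budget`` optionally fixes the exact number of bifurcations
    placed (tips terminate instead of branching once it is spent), which
    gives direct control of the true junction count.
    """

    shape: tuple[int, int] = (584, 565)
    p_bif: float = 0.02
    tau: float = 0.05
    w0: float = 6.0
    width_split_range: tuple[float, float] = (0.4, 0.6)
    branch_angle_deg: tuple[float, float] = (20.0, 40.0)
    min_segment: int = 6
    escape_steps: int = 12
    max_steps: int = 30000
    n_roots: int = 4
    seed: int | None = None
    bifurcation_budget: int | None = None
    min_width: float = 1.0
    #: probability that a tip about to run into an existing vessel stops
    #: short of it instead of crossing; the complement produces the
    #: projection crossings that register as the phantom trait j3
    avoidance: float = 0.85

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("GrowthConfig.seed is mandatory for reproducibility")
        if not (0.0 <= self.p_bif <= 0.05):
            raise ValueError(f"p_bif must lie in [0, 0.05], got {self.p_bif}")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.w0 < 2:
            raise ValueError("root width w0 must be >= 2 px")
        if self.shape[0] < 1 or self.shape[1] < 1:
            raise ValueError(f"degenerate image shape {self.shape}")


@dataclass
class GroundTruth:
    """True morphometry of one generated tree."""

    n_bifurcations: int
    n_endpoints: int
    branch_arc_chord: list[float] = field(default_factory=list)
    branch_widths: list[float] = field(default_factory=list)
    centerlines: list[np.ndarray] = field(default_factory=list)


def _segment_walk(
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    n_steps: int,
    tau: float,
    shape: tuple[int, int],
    straight_prefix: int = 0,
) -> tuple[np.ndarray, float, bool]:
    """Walk up to ``n_steps`` unit steps; stop when leaving the image.

    The first ``straight_prefix`` steps carry no heading noise: right after
    a bifurcation this lets the two children clear the parent tube before
    wandering, so forks render as clean Y junctions instead of braids.
    Returns (points including start, final heading, hit_border).  Headings
    are rounded to 1e-6 rad before use so the integer-lattice rendering is
    reproducible across platforms.
    """
    dtheta = rng.normal(0.0, tau, size=n_steps) if tau > 0 else np.zeros(n_steps)
    if straight_prefix > 0:
        dtheta[:straight_prefix] = 0.0
    headings = np.round(heading + np.cumsum(dtheta), 6)
    # heading 0 points down-image (+row); positive angles turn toward +col
    steps = np.column_stack([np.cos(headings), np.sin(headings)])
    pts = start + np.cumsum(steps, axis=0)
    inside = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] <= shape[0] - 1)
        & (pts[:, 1] >= 0)
        & (pts[:, 1] <= shape[1] - 1)
    )
    first_out = len(pts) if inside.all() else int(np.argmax(~inside))
    pts = pts[:first_out]
    hit_border = first_out < n_steps
    final_heading = float(headings[first_out - 1]) if first_out > 0 else heading
    return np.vstack([start, pts]), final_heading, hit_border


def _root_states(
    rng: np.random.Generator, n_roots: int, shape: tuple[int, int]
) -> list[tuple[np.ndarray, float]]:
    """Roots on the image border, headed inward with some spread."""
    h, w = shape
    states = []
    for _ in range(n_roots):
        side = rng.integers(4)
        if side == 0:  # top edge, heading down
            pos, base = np.array([0.0, rng.uniform(0.1, 0.9) * (w - 1)]), 0.0
        elif side == 1:  # bottom edge, heading up
            pos, base = np.array([h - 1.0, rng.uniform(0.1, 0.9) * (w - 1)]), math.pi
        elif side == 2:  # left edge, heading right
            pos, base = np.array([rng.uniform(0.1, 0.9) * (h - 1), 0.0]), math.pi / 2
        else:  # right edge, heading left
            pos, base = np.array([rng.uniform(0.1, 0.9) * (h - 1), w - 1.0]), -math.pi / 2
        states.append((pos, base + rng.uniform(-0.5, 0.5)))
    return states


def grow_vessel_tree(config: GrowthConfig) -> tuple[VesselMap, GroundTruth]:
    """Grow a stochastic vascular tree and render it as a binary map."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)

    # Tip queue entries: (position, heading, width, straight-prefix, fork id
    # of the bifurcation that spawned the tip, or -1 for roots).  FIFO
    # processing makes budgeted growth breadth-first, i.e. roughly balanced
    # trees.
    queue: list[tuple[np.ndarray, float, float, int, int]] = [
        (pos, heading, float(config.w0), 0, -1)
        for pos, heading in _root_states(rng, config.n_roots, shape)
    ]
    budget = config.bifurcation_budget
    steps_left = config.max_steps
    # Ground truth describes the *rendered* tree: a spawned bifurcation
    # whose children never draw (step cap, border, instant collision) is not
    # a visible fork, so fork bookkeeping counts rendered children.
    fork_children: list[int] = []
    n_term = 0
    rendered_roots = 0
    truth = GroundTruth(n_bifurcations=0, n_endpoints=0)
    centerlines: list[tuple[np.ndarray, float]] = []
    lo_ang, hi_ang = (math.radians(a) for a in config.branch_angle_deg)
    # inflated footprint of vessels grown so far, for collision steering
    occupied = np.zeros(shape, dtype=bool)

    while queue and steps_left > 0:
        pos, heading, width, straight, fork_id = queue.pop(0)
        may_branch = config.p_bif > 0 and (budget is None or budget > 0)
        if config.p_bif > 0:
            # geometric segment length whether or not this tip may still
            # branch, so branch-length statistics do not depend on budget
            length = config.min_segment + int(rng.geometric(config.p_bif))
        else:
            length = steps_left  # non-branching tips run to the border
        length = min(length, steps_left)
        pts, heading, hit_border = _segment_walk(
            rng, pos, heading, length, config.tau, shape, straight_prefix=straight
        )
        # Collision steering: a tip heading into an existing vessel usually
        # stops a caliber short of it; with probability 1 - avoidance it
        # crosses, which later registers as a projection crossing (j3).
        collided = False
        skip = max(straight, int(round(width)) + 3)
        if len(pts) > skip + 1:
            rr = np.round(pts[skip:, 0]).astype(int)
            cc = np.round(pts[skip:, 1]).astype(int)
            hits = occupied[np.clip(rr, 0, shape[0] - 1), np.clip(cc, 0, shape[1] - 1)]
            if hits.any() and rng.random() < config.avoidance:
                first = skip + int(np.argmax(hits))
                cut = max(first - (int(round(width)) + 3), 2)
                pts = pts[:cut]
                collided = True
                hit_border = False
        steps_left -= max(len(pts) - 1, 0)
        rendered = len(pts) >= 2
        if rendered:
            _stamp_footprint(occupied, pts, max(int(round(width / 2.0)), 1) + 2)
            centerlines.append((pts, width))
            chord = float(np.linalg.norm(pts[-1] - pts[0]))
            seg = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
            truth.branch_arc_chord.append(seg / chord if chord > 0 else math.nan)
            truth.branch_widths.append(width)
            truth.centerlines.append(pts)
            if fork_id >= 0:
                fork_children[fork_id] += 1
            else:
                rendered_roots += 1

        end = pts[-1]
        lam = rng.uniform(*config.width_split_range)
        w1 = width * lam ** (1.0 / 3.0)
        w2 = width * (1.0 - lam) ** (1.0 / 3.0)
        can_branch = (
            may_branch
            and not hit_border
            and not collided
            and min(w1, w2) >= config.min_width
            and rendered
        )
        if can_branch:
            if budget is not None:
                budget -= 1
            fid = len(fork_children)
            fork_children.append(0)
            d1, d2 = rng.uniform(lo_ang, hi_ang), rng.uniform(lo_ang, hi_ang)
            queue.append((end.copy(), heading + d1, w1, config.escape_steps, fid))
            queue.append((end.copy(), heading - d2, w2, config.escape_steps, fid))
        elif rendered:
            n_term += 1

    # Visible forks have both children drawn; a fork with neither child
    # drawn is just where its parent's vessel ends (an endpoint); a fork
    # with one child is a pass-through and contributes neither.
    truth.n_bifurcations = sum(1 for c in fork_children if c == 2)
    truth.n_endpoints = (
        n_term + rendered_roots + sum(1 for c in fork_children if c == 0)
    )

    pixels = _render_centerlines(centerlines, shape)
    vmap = VesselMap(image_id=f"synthetic-{config.seed}", pixels=pixels)
    return vmap, truth


def _stamp_footprint(occupied: np.ndarray, pts: np.ndarray, radius: int) -> None:
    """Mark a tube footprint (centerline inflated by ``radius``) as occupied."""
    h, w = occupied.shape
    rr = np.round(pts[:, 0]).astype(int)
    cc = np.round(pts[:, 1]).astype(int)
    k = np.arange(-radius, radius + 1)
    dr = np.repeat(k, k.size)
    dc = np.tile(k, k.size)
    drr = np.clip(rr[None, :] + dr[:, None], 0, h - 1)
    dcc = np.clip(cc[None, :] + dc[:, None], 0, w - 1)
    occupied[drr.ravel(), dcc.ravel()] = True


def _render_centerlines(
    centerlines: Sequence[tuple[np.ndarray, float]], shape: tuple[int, int]
) -> np.ndarray:
    """Stamp each centerline with discs of radius width/2 (union of tubes)."""
    canvas = np.zeros(shape, dtype=bool)
    by_radius: dict[int, list[np.ndarray]] = {}
    for pts, width in centerlines:
        r = max(int(round(width / 2.0)), 1)
        by_radius.setdefault(r, []).append(pts)
    for r, groups in by_radius.items():
        scatter = np.zeros(shape, dtype=bool)
        pts = np.vstack(groups)
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, shape[0] - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, shape[1] - 1)
        scatter[rr, cc] = True
        canvas |= ndimage.binary_dilation(scatter, structure=disk(r))
    return canvas


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortConfig:
    """An aging cohort whose vessel morphology is generated, not observed.

    ``j2_young`` and ``j2_old`` give (age, expected measured j2) anchors;
    the per-participant bifurcation budget follows the line through them,
    mapped through the measurement calibration
    ``measured_j2 = gain * budget + bias`` (render/skeleton artifacts make
    the skeleton-counted j2 exceed the number of true bifurcations by a
    stable linear amount; the gain/bias defaults come from a one-time
    regression of measured j2 on the programmed budget under the default
    growth parameters).  ``tau_slope`` defaults to zero, making all
    tortuosity traits programmed nulls.
    """

    n: int = 300
    age_range: tuple[float, float] = (20.3, 88.4)
    sex_ratio: float = 0.5
    j2_young: tuple[float, float] = (20.0, 74.0)
    j2_old: tuple[float, float] = (88.0, 31.0)
    measurement_gain: float = 1.42
    measurement_bias: float = -7.8
    budget_sd: float = 6.0
    tau0: float = 0.05
    tau_slope: float = 0.0
    tau_sd: float = 0.01
    images_per_participant: int = 1
    shape: tuple[int, int] = (584, 565)
    p_bif: float = 0.02
    w0: float = 6.0
    n_roots: int = 4
    seed: int | None = None
    measure: tuple[str, ...] = DEFAULT_MEASURE
    full_traits: bool = False
    return_images: bool = False

    def budget_line(self) -> tuple[float, float]:
        """(intercept, slope) of the expected bifurcation count vs age."""
        (a0, y0), (a1, y1) = self.j2_young, self.j2_old
        slope = (y1 - y0) / (a1 - a0)
        return y0 - slope * a0, slope

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("CohortConfig.seed is mandatory for reproducibility")
        if self.n < 4:
            raise ValueError("cohort needs n >= 4 participants for any statistics")


def measure_map(
    pixels: np.ndarray, measure: Iterable[str] = DEFAULT_MEASURE
) -> dict[str, float]:
    """Measure a subset of Total-class traits on one binary map.

    Runs the real pipeline (skeleton, crossing numbers, branch tracing) but
    computes only the requested traits; sampled tortuosity skips contour
    smoothing, which keeps cohort simulation fast.  Use
    :func:`retimorph.traits.class_traits` for the full 25-trait set.
    """
    want = set(measure)
    out: dict[str, float] = {}
    need_smoothed = any(
        name in want for name in TORTUOSITY_NAMES if name == "t15" or int(name[1:]) % 2 == 0
    )
    need_tort = any(name in want for name in TORTUOSITY_NAMES)
    if need_smoothed:
        full = class_traits(pixels)
        return {name: full[name] for name in TRAIT_NAMES if name in want}

    skel = skeletonize(pixels)
    cn = crossing_number_map(skel)
    if {"j1", "j2", "j3"} & want:
        j = count_junctions(skel, cn=cn)
        out.update({"j1": float(j.j1), "j2": float(j.j2), "j3": float(j.j3)})
    if need_tort:
        per_branch = []
        for b in extract_branches(skel, cn=cn):
            anchors = anchor_points(b.points)
            if b.closed or len(anchors) < 5:
                continue
            basis = tortuosity_basis(anchors, "sampled")
            row = dict.fromkeys(TORTUOSITY_NAMES, math.nan)
            t2 = float(np.sum(np.abs(basis.kappa) * basis.ds))
            t3 = float(np.sum(basis.kappa**2 * basis.ds))
            row["t3"], row["t5"] = t2, t3
            row["t7"] = t2 / basis.arc if basis.arc > 0 else math.nan
            row["t9"] = t3 / basis.arc if basis.arc > 0 else math.nan
            if basis.chord > 1e-9:
                row["t1"] = basis.arc / basis.chord
                row["t11"] = t2 / basis.chord
                row["t13"] = t3 / basis.chord
            per_branch.append(row)
        agg = aggregate_tortuosity(per_branch)
        out.update({k: v for k, v in agg.items() if k in want})
    if set(FRACTAL_NAMES) & want:
        frac = fractal_traits(pixels)
        out.update({k: v for k, v in frac.items() if k in want})
    return {k: out.get(k, math.nan) for k in measure}


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[tuple[VesselMap, GroundTruth]], pd.DataFrame]:
    """Simulate an aging cohort of vessel maps plus its cohort table.

    Every row of the returned table corresponds to one image and carries
    participant id, age, sex, the eight cardiovascular/anthropometric
    covariates, the generated ground truth, and the pipeline-measured
    traits.  When ``return_images`` is False (the default) the image list
    is empty and only the table is kept, which bounds memory for large
    cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    b0, b1 = config.budget_line()
    rows = []
    images: list[tuple[VesselMap, GroundTruth]] = []
    for i in range(config.n):
        age = float(rng.uniform(*config.age_range))
        sex = int(rng.random() < config.sex_ratio)
        target_j2 = b0 + b1 * age
        budget_mu = (target_j2 - config.measurement_bias) / config.measurement_gain
        budget_i = max(int(round(budget_mu + rng.normal(0.0, config.budget_sd))), 0)
        tau_i = max(
            config.tau0
            + config.tau_slope * (age - np.mean(config.age_range))
            + rng.normal(0.0, config.tau_sd),
            0.0,
        )
        covs = _covariates(rng, age, sex, config.age_range)
        for k in range(config.images_per_participant):
            child_seed = int(rng.integers(2**31))
            gcfg = GrowthConfig(
                shape=config.shape,
                p_bif=config.p_bif,
                tau=tau_i,
                w0=config.w0,
                n_roots=config.n_roots,
                seed=child_seed,
                bifurcation_budget=budget_i,
            )
            vmap, truth = grow_vessel_tree(gcfg)
            vmap.image_id = f"P{i:04d}_I{k}"
            traits = (
                class_traits(vmap.pixels)
                if config.full_traits
                else measure_map(vmap.pixels, config.measure)
            )
            row = {
                "participant_id": f"P{i:04d}",
                "image_id": vmap.image_id,
                "age": age,
                "sex": sex,
                **covs,
                "true_bifurcations": truth.n_bifurcations,
                "true_endpoints": truth.n_endpoints,
            }
            row.update(traits)
            rows.append(row)
            if config.return_images:
                images.append((vmap, truth))
    return images, pd.DataFrame(rows)


def _covariates(
    rng: np.random.Generator, age: float, sex: int, age_range: tuple[float, float]
) -> dict[str, float]:
    """Eight cardiovascular/anthropometric covariates with age correlation.

    Each covariate is mu + sigma * (rho * z_age + sqrt(1 - rho^2) * eps),
    with z_age the standardized age, so its population correlation with age
    is approximately rho.  Magnitudes are ordinary adult clinic values.
    """
    lo, hi = age_range
    z_age = (age - (lo + hi) / 2.0) / ((hi - lo) / math.sqrt(12.0))

    def draw(mu: float, sigma: float, rho: float, sex_shift: float = 0.0) -> float:
        eps = rng.normal()
        return mu + sex_shift * sex + sigma * (rho * z_age + math.sqrt(1 - rho**2) * eps)

    height = draw(162.0, 7.0, -0.15, sex_shift=12.0)
    weight = draw(66.0, 11.0, 0.05, sex_shift=8.0)
    out = {
        "sbp": draw(122.0, 14.0, 0.45),
        "dbp": draw(76.0, 9.0, 0.20),
        "waist": draw(88.0, 11.0, 0.25),
        "hip": draw(100.0, 9.0, 0.10),
        "weight": weight,
        "height": height,
        "bmi": weight / (height / 100.0) ** 2,
        "imt": draw(0.68, 0.12, 0.50),
    }
    return out
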