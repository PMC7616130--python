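"""Seeded synthetic-cohort generators.

Each generator is a pure function of (params, seed) and emulates the
statistical structure one analysis stage assumes:

* ``generate_arbor`` — 2D random-walk axon arbors with Poisson numbers of
  side branches per order and an optional looping main shaft.
* ``generate_growth_cone_image`` — two-channel growth-cone phantoms with a
  tubulin-rich central disc and an actin-rich periphery plus filopodial
  spokes, over noisy background.
* ``generate_force_curve`` — Hertzian approach curves for a spherical tip,
  with the indentation/deflection coupling solved self-consistently.
* ``generate_granule_kymograph`` / ``generate_granule_movie`` — RNA-granule
  transport with stationary / anterograde / retrograde populations imaged
  at 2 frames/s for 60 s.
* ``generate_cohort`` — writes a full per-condition on-disk dataset
  (SWC + TIFF + TSV + sidecar JSON) with a manifest for exact replay.

The per-order branch means ``mean_branches_per_order[k-1]`` (k >= 2)
parametrise the expected number of order-k side-branch *chains* attached to
order-(k-1) branches; there is always exactly one primary shaft.  Because
every side chain splits its parent chain into two segments, the per-order
*segment* counts seen by the arbor analysis obey N_k = a_k + a_{k+1} where
a_k is the number of order-k chains.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .arbor import ArborTree
from . import arbor as _arbor
from .afm import ForceCurve
from .kymo import Kymograph

__all__ = [
    "ArborParams",
    "GrowthConeImageParams",
    "ForceCurveParams",
    "GranuleMovieParams",
    "CohortConfig",
    "generate_arbor",
    "generate_growth_cone_image",
    "generate_force_curve",
    "generate_granule_kymograph",
    "generate_granule_movie",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# Parameter blocks


@dataclass
class ArborParams:
    """Arbor generator settings.

    ``mean_branches_per_order`` gives (λ1, λ2, λ3, ...): λ1 is the single
    primary shaft (at least one is always generated), λk (k>=2) the mean
    number of order-k side branches.  Lengths are per-order normal draws
    (µm), truncated at one step.
    """

    mean_branches_per_order: tuple[float, ...] = (1.0, 4.0, 3.0)
    length_mean_um: tuple[float, ...] = (80.0, 20.0, 8.0)
    length_sd_um: tuple[float, ...] = (15.0, 8.0, 3.0)
    loop_probability: float = 0.0
    loop_branch_suppression: float = 0.15
    heading_noise_deg: float = 12.0
    step_um: float = 2.0

    def validate(self) -> None:
        lam = self.mean_branches_per_order
        if any(l < 0 for l in lam):
            raise ValueError("branch means must be nonnegative")
        if len(self.length_mean_um) < len(lam) or len(self.length_sd_um) < len(lam):
            raise ValueError("need a length mean/sd per order")
        if any(m <= 0 for m in self.length_mean_um):
            raise ValueError("length means must be positive")
        if not 0.0 <= self.loop_probability <= 1.0:
            raise ValueError("loop_probability must be in [0, 1]")
        if self.step_um <= 0:
            raise ValueError("step_um must be positive")


@dataclass
class GrowthConeImageParams:
    image_size_px: int = 128
    pixel_size_um: float = 0.1
    central_radius_um: float = 2.0
    peripheral_width_um: float = 1.5
    tubulin_level: float = 400.0
    actin_level: float = 400.0
    background_level: float = 100.0
    gaussian_noise_sd: float = 5.0
    poisson_noise: bool = True
    n_filopodia: int = 8
    filopodia_length_um: float = 1.0

    def validate(self) -> None:
        if self.image_size_px < 8 or self.pixel_size_um <= 0:
            raise ValueError("invalid field geometry")
        reach = (self.central_radius_um + self.peripheral_width_um
                 + self.filopodia_length_um)
        if 2 * reach >= self.image_size_px * self.pixel_size_um:
            raise ValueError("growth cone geometry exceeds the field of view")
        if min(self.tubulin_level, self.actin_level, self.background_level) < 0:
            raise ValueError("levels must be nonnegative")


@dataclass
class ForceCurveParams:
    """Hertz-curve generator; probe defaults match a soft pre-calibrated
    live-cell cantilever (k = 0.07 N/m, spherical tip R = 70 nm) ramped to
    roughly 200 nm of indentation."""

    E_true_pa: float = 10_000.0
    nu: float = 0.5
    R_m: float = 70e-9
    k_n_per_m: float = 0.07
    z_contact_m: float = 0.0
    pre_contact_m: float = 200e-9
    ramp_depth_m: float = 220e-9
    n_samples: int = 200
    force_noise_sd_n: float = 0.0
    baseline_slope_n_per_m: float = 0.0
    sampling_rate_hz: float = 250.0
    site_height_m: float = 400e-9

    def validate(self) -> None:
        if self.E_true_pa < 0:
            raise ValueError("E_true must be nonnegative")
        if not 0.0 <= self.nu < 0.5 + 1e-9:
            raise ValueError("Poisson ratio must be in [0, 0.5]")
        if self.R_m <= 0 or self.k_n_per_m <= 0:
            raise ValueError("probe radius and spring constant must be positive")
        if self.n_samples < 50:
            raise ValueError("need at least 50 samples")


@dataclass
class GranuleMovieParams:
    axon_length_um: float = 25.0
    density_per_um: float = 0.2
    frac_stationary: float = 0.5
    frac_anterograde: float = 0.3
    frac_retrograde: float = 0.2
    speed_mean_um_s: float = 0.8
    speed_sd_um_s: float = 0.2
    fps: float = 2.0
    duration_s: float = 60.0
    pixel_size_um: float = 0.1
    psf_sigma_px: float = 1.0
    signal_level: float = 100.0
    background_level: float = 20.0
    gaussian_noise_sd: float = 5.0
    position_jitter_um: float = 0.03
    min_spacing_um: float = 0.0

    def validate(self) -> None:
        fr = self.frac_stationary + self.frac_anterograde + self.frac_retrograde
        if abs(fr - 1.0) > 1e-9:
            raise ValueError("population fractions must sum to 1")
        n_frames = self.fps * self.duration_s
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError("fps * duration must give an integral frame count")
        if self.axon_length_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("invalid geometry")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))


@dataclass
class CohortConfig:
    """A multi-condition synthetic study.

    ``effects`` maps a condition label to per-stage effect knobs:
    ``branch_multipliers`` (per-order multipliers on the arbor λs),
    ``loop_probability``, ``actin_scale``, ``tubulin_scale``,
    ``modulus_scale`` and ``granule`` overrides (dict of GranuleMovieParams
    fields).  Conditions without an entry use the base parameters.
    """

    conditions: tuple[str, ...] = ("control",)
    n_per_condition: int = 5
    seed: int = 0
    arbor: ArborParams = field(default_factory=ArborParams)
    image: GrowthConeImageParams = field(default_factory=GrowthConeImageParams)
    force: ForceCurveParams = field(default_factory=ForceCurveParams)
    granule: GranuleMovieParams = field(default_factory=GranuleMovieParams)
    curves_per_cell: int = 10
    effects: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        self.arbor.validate()
        self.image.validate()
        self.force.validate()
        self.granule.validate()


# ---------------------------------------------------------------------------
# Arbors


def _random_walk(rng: np.random.Generator, start: np.ndarray, heading: float,
                 length_um: float, step_um: float, noise_deg: float,
                 turn_per_step_deg: float = 0.0) -> np.ndarray:
    n = max(int(round(length_um / step_um)), 2)
    headings = heading + np.cumsum(
        np.radians(rng.normal(turn_per_step_deg, noise_deg, size=n)))
    steps = step_um * np.column_stack([np.cos(headings), np.sin(headings)])
    return start + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


class _Chain:
    """Skeleton chain: a run of nodes of one intended order.

    ``n_steps`` edges of ``step`` µm; ``attachments`` is a sorted list of
    (node_index, child_chain_index) with node_index in 1..n_steps-1.
    """

    __slots__ = ("order", "n_steps", "attachments", "parent")

    def __init__(self, order: int, n_steps: int, parent=None):
        self.order = order
        self.n_steps = n_steps
        self.attachments: list[tuple[int, int]] = []
        self.parent = parent   # (chain_idx, node_idx) or None


def _skeleton_greedy_counts(chains: list[_Chain], step: float):
    """Replicate the order-minimising continuation rule on the skeleton.

    Returns chain counts per assigned order, or None when a tie cannot be
    resolved with at least one step of length margin (caller should
    re-draw the placement).
    """
    # subtree branch points of chain i from attachment slot t onwards
    def tail_bp(i: int, t: int) -> int:
        c = chains[i]
        return (len(c.attachments) - t
                + sum(tail_bp(child, 0) for _, child in c.attachments[t:]))

    reject = []

    def tail_immediate_len(i: int, t: int) -> float:
        c = chains[i]
        start = c.attachments[t - 1][0] if t > 0 else 0
        nxt = c.attachments[t][0] if t < len(c.attachments) else c.n_steps
        return (nxt - start) * step

    counts: dict[int, int] = {}

    def walk(i: int, t: int, order: int, new_chain: bool) -> None:
        if new_chain:
            counts[order] = counts.get(order, 0) + 1
        c = chains[i]
        if t >= len(c.attachments):
            return
        _, child = c.attachments[t]
        bp_child = len(chains[child].attachments) + sum(
            tail_bp(g, 0) for _, g in chains[child].attachments)
        bp_tail = tail_bp(i, t + 1)
        if bp_child != bp_tail:
            child_wins = bp_child > bp_tail
        else:
            len_child = tail_immediate_len(child, 0)
            len_tail = tail_immediate_len(i, t + 1)
            if abs(len_child - len_tail) < 0.5 * step:
                reject.append(True)
                return
            child_wins = len_child > len_tail
        if child_wins:
            walk(child, 0, order, False)
            walk(i, t + 1, order + 1, True)
        else:
            walk(i, t + 1, order, False)
            walk(child, 0, order + 1, True)

    walk(0, 0, 1, True)
    return None if reject else counts


def generate_arbor(params: ArborParams, condition_effect=None, seed: int = 0,
                   return_truth: bool = False):
    """Generate a single synthetic arbor as an :class:`ArborTree`.

    ``condition_effect`` is a per-order multiplier sequence applied to the
    branch means (entry k scales λ_{k+1}); omitted entries default to 1.

    Side branches are attached one at a time, and a placement is only
    accepted if the greedy order-minimising assignment (replicated on the
    chain skeleton) reproduces the intended labels — so the ground truth
    is exactly what the arbor analysis will report.  Draws that cannot be
    placed anywhere are dropped; the truth table records realised counts.
    With ``return_truth`` the per-order side-chain counts and looping flag
    are returned alongside the tree.
    """
    params.validate()
    lam = list(params.mean_branches_per_order)
    if condition_effect is not None:
        eff = list(condition_effect)
        if any(e < 0 for e in eff):
            raise ValueError("effect multipliers must be nonnegative")
        for i, e in enumerate(eff[: len(lam)]):
            lam[i] = lam[i] * e
    rng = np.random.default_rng(seed)
    step = params.step_um

    looping = rng.random() < params.loop_probability
    if looping:
        # a looping axon fails to enter the branching stage: its higher-order
        # branching is strongly suppressed
        lam = [lam[0]] + [l * params.loop_branch_suppression for l in lam[1:]]

    def draw_steps(order: int) -> int:
        length = rng.normal(params.length_mean_um[order - 1],
                            params.length_sd_um[order - 1])
        return max(int(round(length / step)), 2)

    chains: list[_Chain] = [_Chain(1, draw_steps(1))]
    truth_counts: dict[int, int] = {}
    intended: dict[int, int] = {1: 1}

    for k in range(2, len(lam) + 1):
        mean_k = lam[k - 1]
        placed = 0
        n_target = int(rng.poisson(mean_k)) if mean_k > 0 else 0
        for _ in range(n_target):
            parents_k = [i for i, c in enumerate(chains) if c.order == k - 1]
            if not parents_k:
                break
            accepted = False
            for _attempt in range(40):
                pi = int(rng.choice(parents_k))
                pc = chains[pi]
                # proximal 60% of the parent chain, interior nodes only
                hi_node = max(int(0.6 * pc.n_steps), 1)
                free = [j for j in range(1, min(hi_node, pc.n_steps - 1) + 1)
                        if all(j != a for a, _ in pc.attachments)]
                if not free:
                    continue
                node = int(rng.choice(free))
                child = _Chain(k, draw_steps(k), parent=(pi, node))
                chains.append(child)
                pc.attachments.append((node, len(chains) - 1))
                pc.attachments.sort()
                got = _skeleton_greedy_counts(chains, step)
                want = dict(intended)
                want[k] = want.get(k, 0) + 1
                if got == want:
                    intended = want
                    accepted = True
                    break
                pc.attachments = [(a, c) for a, c in pc.attachments
                                  if c != len(chains) - 1]
                chains.pop()
            if accepted:
                placed += 1
        truth_counts[k] = placed

    # realise geometry: random walks chain by chain (parents first)
    xs: list[np.ndarray] = []
    parents: list[int] = []
    node_ids: list[list[int]] = []   # per chain, node indices incl. start
    for ci, c in enumerate(chains):
        turn_per_step = 0.0
        if c.parent is None:
            start = np.zeros(2)
            heading = rng.uniform(0, 2 * np.pi)
            if looping:
                turn_per_step = float(rng.choice([-1.0, 1.0])
                                      * rng.uniform(310.0, 420.0)) / c.n_steps
            xs.append(start)
            parents.append(-1)
            ids = [0]
            anchor = 0
        else:
            p_chain, p_node = c.parent
            anchor = node_ids[p_chain][p_node]
            prev = xs[node_ids[p_chain][p_node - 1]]
            here = xs[anchor]
            base = math.atan2(here[1] - prev[1], here[0] - prev[0])
            heading = base + float(rng.choice([-1.0, 1.0])) * math.radians(
                rng.uniform(40.0, 90.0))
            start = here
            ids = [anchor]
        pts = _random_walk(rng, start, heading, c.n_steps * step, step,
                           params.heading_noise_deg, turn_per_step)
        for pt in pts[1:]:
            xs.append(pt)
            parents.append(ids[-1])
            ids.append(len(xs) - 1)
        node_ids.append(ids)

    n = len(xs)
    coords = np.asarray(xs)
    df = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "type": np.full(n, 2),
        "x": coords[:, 0],
        "y": coords[:, 1],
        "z": np.zeros(n),
        "radius": np.full(n, 0.3),
        "parent": np.array([p + 1 if p >= 0 else -1 for p in parents]),
    })
    tree = ArborTree(df)
    if return_truth:
        return tree, {"chain_counts": truth_counts, "looping": looping,
                      "chains_per_order": intended}
    return tree


# ---------------------------------------------------------------------------
# Growth-cone images


def generate_growth_cone_image(params: GrowthConeImageParams, seed: int = 0):
    """Two-channel growth-cone phantom.

    Returns ``(channels, masks)``: channels is ``{"tubulin": img, "actin":
    img}`` (float counts), masks is ``{"tubulin": central disc, "actin":
    annulus + filopodial spokes}`` as booleans.  Noise (Poisson shot noise,
    then additive Gaussian read noise) is applied last.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.image_size_px
    px = params.pixel_size_um
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    r_um = np.hypot(yy - cy, xx - cx) * px

    central = r_um <= params.central_radius_um
    r_out = params.central_radius_um + params.peripheral_width_um
    annulus = (r_um > params.central_radius_um) & (r_um <= r_out)

    spokes = np.zeros((n, n), bool)
    angles = rng.uniform(0, 2 * np.pi) + np.linspace(
        0, 2 * np.pi, params.n_filopodia, endpoint=False)
    for a in angles:
        for t in np.linspace(0.0, params.filopodia_length_um, 40):
            r = (r_out + t) / px
            i, j = int(round(cy + r * np.sin(a))), int(round(cx + r * np.cos(a)))
            if 0 <= i < n and 0 <= j < n:
                spokes[i, j] = True
    actin_mask = annulus | spokes
    masks = {"tubulin": central, "actin": actin_mask}

    channels = {}
    for name, level, mask in (("tubulin", params.tubulin_level, central),
                              ("actin", params.actin_level, actin_mask)):
        img = np.full((n, n), float(params.background_level))
        img[mask] += level
        if params.poisson_noise:
            img = rng.poisson(img).astype(float)
        if params.gaussian_noise_sd > 0:
            img = img + rng.normal(0.0, params.gaussian_noise_sd, img.shape)
        channels[name] = np.clip(img, 0.0, None)
    return channels, masks


# ---------------------------------------------------------------------------
# Force curves


def hertz_force(delta_m: np.ndarray | float, E_pa: float, nu: float,
                R_m: float) -> np.ndarray | float:
    """Spherical-indenter Hertz law F = (4/3) E/(1-ν²) √R δ^{3/2}."""
    d = np.maximum(delta_m, 0.0)
    return (4.0 / 3.0) * E_pa / (1.0 - nu ** 2) * np.sqrt(R_m) * d ** 1.5


def _solve_force(z_rel: np.ndarray, E: float, nu: float, R: float,
                 k: float, tol: float = 1e-15, max_iter: int = 100) -> np.ndarray:
    """Self-consistent F with δ = z_rel − F/k (fixed-point, tol in metres)."""
    F = hertz_force(z_rel, E, nu, R)
    for _ in range(max_iter):
        delta = z_rel - F / k
        F_new = hertz_force(delta, E, nu, R)
        if np.max(np.abs((z_rel - F_new / k) - delta)) < tol:
            F = F_new
            break
        F = 0.5 * (F + F_new)  # damped to guarantee convergence
    return F


def generate_force_curve(params: ForceCurveParams, seed: int = 0,
                         return_truth: bool = False):
    """Synthetic approach (extension) force curve.

    Pre-contact samples carry the baseline (plus optional linear drift);
    past contact the force solves the Hertz law self-consistently with the
    cantilever deflection subtracted from the piezo travel.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    z0 = params.z_contact_m - params.pre_contact_m
    z = np.linspace(z0, params.z_contact_m + params.ramp_depth_m, params.n_samples)
    z_rel = z - params.z_contact_m
    F = np.zeros_like(z)
    post = z_rel > 0
    if params.E_true_pa > 0:
        F[post] = _solve_force(z_rel[post], params.E_true_pa, params.nu,
                               params.R_m, params.k_n_per_m)
    baseline = params.baseline_slope_n_per_m * (z - z[0])
    force = F + baseline
    if params.force_noise_sd_n > 0:
        force = force + rng.normal(0.0, params.force_noise_sd_n, force.shape)
    curve = ForceCurve(
        z_m=z, force_N=force, k=params.k_n_per_m, R=params.R_m, nu=params.nu,
        sampling_rate_hz=params.sampling_rate_hz,
        site_height_m=params.site_height_m,
    )
    if return_truth:
        delta = np.where(post, z_rel - F / params.k_n_per_m, 0.0)
        return curve, {"z_contact_m": params.z_contact_m, "delta_m": delta,
                       "force_clean_n": F}
    return curve


# ---------------------------------------------------------------------------
# Granule kymographs / movies


def _granule_tracks(params: GranuleMovieParams, rng: np.random.Generator):
    """Ground-truth positions (granules x frames, µm); NaN when out of field."""
    n_frames = params.n_frames
    lam = params.density_per_um * params.axon_length_um
    n = int(rng.poisson(lam))
    classes = rng.choice(
        ["stationary", "anterograde", "retrograde"], size=n,
        p=[params.frac_stationary, params.frac_anterograde, params.frac_retrograde],
    )
    # granules centred closer than ~3 PSF sigmas to the field edge cannot be
    # localised; keep placement and the visibility bound inside that margin
    margin = 3.0 * params.psf_sigma_px * params.pixel_size_um
    lo_um, hi_um = margin, params.axon_length_um - margin
    if params.min_spacing_um > 0 and n > 0:
        # sequential placement with rejection keeps granules resolvable
        x0 = []
        for _ in range(n):
            for _attempt in range(200):
                c = rng.uniform(lo_um, hi_um)
                if all(abs(c - o) >= params.min_spacing_um for o in x0):
                    break
            x0.append(c)
        x0 = np.array(x0)
    else:
        x0 = rng.uniform(lo_um, hi_um, size=n)
    speeds = np.clip(rng.normal(params.speed_mean_um_s, params.speed_sd_um_s, n),
                     0.05, None)
    v = np.where(classes == "stationary", 0.0,
                 np.where(classes == "anterograde", speeds, -speeds))
    t = np.arange(n_frames) / params.fps
    pos = x0[:, None] + v[:, None] * t[None, :]
    if n:
        pos = pos + rng.normal(0.0, params.position_jitter_um, pos.shape)
    in_field = (pos >= lo_um) & (pos <= hi_um)
    # once a granule leaves the field it stays gone (no re-entry bookkeeping)
    for i in range(n):
        out = np.flatnonzero(~in_field[i])
        if out.size:
            in_field[i, out[0]:] = False
    pos = np.where(in_field, pos, np.nan)
    rows = []
    for i in range(n):
        frames = np.flatnonzero(in_field[i])
        for f in frames:
            rows.append((i, classes[i], abs(v[i]), int(f), pos[i, f]))
    truth = pd.DataFrame(rows, columns=["track_id", "class", "speed_um_s",
                                        "frame", "position_um"])
    return pos, truth


def generate_granule_kymograph(params: GranuleMovieParams, seed: int = 0):
    """Render a kymograph (time x position) plus the ground-truth track table."""
    params.validate()
    rng = np.random.default_rng(seed)
    pos_um, truth = _granule_tracks(params, rng)
    n_frames = params.n_frames
    n_cols = int(round(params.axon_length_um / params.pixel_size_um))
    grid = np.arange(n_cols)
    img = np.full((n_frames, n_cols), float(params.background_level))
    sig = params.psf_sigma_px
    for i in range(pos_um.shape[0]):
        for f in range(n_frames):
            x = pos_um[i, f]
            if np.isnan(x):
                continue
            xc = x / params.pixel_size_um
            lo = max(int(xc - 4 * sig), 0)
            hi = min(int(xc + 4 * sig) + 1, n_cols)
            img[f, lo:hi] += params.signal_level * np.exp(
                -0.5 * ((grid[lo:hi] - xc) / sig) ** 2)
    img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if params.gaussian_noise_sd > 0:
        img += rng.normal(0.0, params.gaussian_noise_sd, img.shape)
    kymo = Kymograph(data=np.clip(img, 0.0, None), dt_s=1.0 / params.fps,
                     dx_um=params.pixel_size_um, growth_cone_side="right")
    return kymo, truth


def generate_granule_movie(params: GranuleMovieParams, seed: int = 0,
                           height_px: int = 24):
    """Small time-lapse movie (frames, H, W) with granules on a straight
    horizontal axon at mid-height; returns (movie, path_xy, truth)."""
    params.validate()
    rng = np.random.default_rng(seed)
    pos_um, truth = _granule_tracks(params, rng)
    n_frames = params.n_frames
    w = int(round(params.axon_length_um / params.pixel_size_um))
    h = height_px
    y0 = (h - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    movie = np.full((n_frames, h, w), float(params.background_level))
    sig = params.psf_sigma_px
    for i in range(pos_um.shape[0]):
        for f in range(n_frames):
            x = pos_um[i, f]
            if np.isnan(x):
                continue
            xc = x / params.pixel_size_um
            movie[f] += params.signal_level * np.exp(
                -0.5 * (((xx - xc) ** 2 + (yy - y0) ** 2) / sig ** 2))
    movie = rng.poisson(np.clip(movie, 0, None)).astype(float)
    if params.gaussian_noise_sd > 0:
        movie += rng.normal(0.0, params.gaussian_noise_sd, movie.shape)
    path_xy = np.array([[0.0, y0], [w - 1.0, y0]])
    return np.clip(movie, 0.0, None), path_xy, truth


# ---------------------------------------------------------------------------
# Cohort writer


def _sub_seed(master: int, *keys) -> int:
    """Stable per-item seed derived from the master seed and string keys."""
    h = hashlib.sha256(("|".join([str(master), *map(str, keys)])).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2 ** 31)


def _apply_overrides(obj, overrides: dict):
    from dataclasses import replace
    valid = {k: v for k, v in overrides.items() if hasattr(obj, k)}
    unknown = set(overrides) - set(valid)
    if unknown:
        raise ValueError(f"unknown parameter overrides: {sorted(unknown)}")
    return replace(obj, **{k: (tuple(v) if isinstance(getattr(obj, k), tuple) else v)
                           for k, v in valid.items()})


def generate_cohort(config: CohortConfig, out_dir: str | Path,
                    overwrite: bool = False,
                    stages: tuple[str, ...] = ("arbor", "image", "afm", "kymo")) -> dict:
    """Write a complete synthetic cohort to ``out_dir``.

    Layout: ``<out>/<condition>/{arbors,images,afm,kymo}/...`` plus
    ``manifest.json`` recording the seed, per-item sub-seeds and parameters.
    Re-running with the same config reproduces identical files.
    """
    config.validate()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "conditions": list(config.conditions),
        "n_per_condition": config.n_per_condition,
        "stages": list(stages),
        "base_params": {
            "arbor": asdict(config.arbor),
            "image": asdict(config.image),
            "force": asdict(config.force),
            "granule": asdict(config.granule),
        },
        "effects": config.effects,
        "items": [],
    }
    for cond in config.conditions:
        eff = config.effects.get(cond, {})
        arbor_params = _apply_overrides(config.arbor,
                                        {"loop_probability":
                                         eff.get("loop_probability",
                                                 config.arbor.loop_probability)})
        branch_mult = eff.get("branch_multipliers")
        img_params = _apply_overrides(config.image, {
            "actin_level": config.image.actin_level * eff.get("actin_scale", 1.0),
            "tubulin_level": config.image.tubulin_level * eff.get("tubulin_scale", 1.0),
        })
        force_params = _apply_overrides(config.force, {
            "E_true_pa": config.force.E_true_pa * eff.get("modulus_scale", 1.0),
        })
        gran_params = _apply_overrides(config.granule, eff.get("granule", {}))

        cdir = out / cond
        for sub in ("arbors", "images", "afm", "kymo"):
            (cdir / sub).mkdir(parents=True, exist_ok=True)
        for i in range(config.n_per_condition):
            item = {"condition": cond, "index": i}
            if "arbor" in stages:
                s = _sub_seed(config.seed, cond, "arbor", i)
                tree = generate_arbor(arbor_params, branch_mult, seed=s)
                p = cdir / "arbors" / f"{cond}_{i:03d}.swc"
                _arbor.write_swc(tree, p)
                item["arbor"] = {"seed": s, "file": str(p.relative_to(out))}
            if "image" in stages:
                s = _sub_seed(config.seed, cond, "image", i)
                channels, gt = generate_growth_cone_image(img_params, seed=s)
                files = {}
                for ch, img in channels.items():
                    p = cdir / "images" / f"{cond}_{i:03d}_{ch}.tif"
                    tifffile.imwrite(p, np.clip(img, 0, 65535).astype(np.uint16))
                    files[ch] = str(p.relative_to(out))
                for ch, m in gt.items():
                    p = cdir / "images" / f"{cond}_{i:03d}_{ch}_mask.tif"
                    tifffile.imwrite(p, m.astype(np.uint8))
                meta = {"pixel_size_um": img_params.pixel_size_um}
                mp = cdir / "images" / f"{cond}_{i:03d}_meta.json"
                mp.write_text(json.dumps(meta))
                item["image"] = {"seed": s, "files": files}
            if "afm" in stages:
                curves = []
                for c in range(config.curves_per_cell):
                    s = _sub_seed(config.seed, cond, "afm", i, c)
                    curve = generate_force_curve(force_params, seed=s)
                    base = cdir / "afm" / f"{cond}_{i:03d}_{c:02d}"
                    pd.DataFrame({"z_m": curve.z_m, "force_N": curve.force_N}
                                 ).to_csv(base.with_suffix(".tsv"), sep="\t",
                                          index=False)
                    base.with_suffix(".json").write_text(json.dumps({
                        "k": curve.k, "R": curve.R, "nu": curve.nu,
                        "sampling_rate": curve.sampling_rate_hz,
                        "site_height_m": force_params.site_height_m,
                        "cell_id": f"{cond}_{i:03d}", "condition": cond,
                    }))
                    curves.append({"seed": s,
                                   "file": str(base.with_suffix(".tsv").relative_to(out))})
                item["afm"] = curves
            if "kymo" in stages:
                s = _sub_seed(config.seed, cond, "kymo", i)
                kymo, truth = generate_granule_kymograph(gran_params, seed=s)
                p = cdir / "kymo" / f"{cond}_{i:03d}.tif"
                tifffile.imwrite(p, np.clip(kymo.data, 0, 65535).astype(np.uint16))
                (cdir / "kymo" / f"{cond}_{i:03d}.json").write_text(json.dumps({
                    "dt_s": kymo.dt_s, "dx_um": kymo.dx_um,
                    "growth_cone_side": kymo.growth_cone_side,
                    "axon_length_um": gran_params.axon_length_um,
                }))
                item["kymo"] = {"seed": s, "file": str(p.relative_to(out)),
                                "n_truth_tracks": int(truth["track_id"].nunique())}
            manifest["items"].append(item)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
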