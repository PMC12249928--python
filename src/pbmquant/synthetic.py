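"""Seeded generators for trajectories, assay imagery, and Ct tables.

Every generator emulates one acquisition mode of a photobiomodulation
wound-healing study and emits its ground truth alongside the data, so the
downstream estimators can be tested for parameter recovery without any
real microscopy. Defaults mirror the study design: time-lapse sampling
every 10 min, 37 points per track (a 6 h observation window).

Seeding: each generator derives an independent stream from
``(seed, generator-name)`` via :func:`child_rng`, so adding one generator
to a pipeline never perturbs another's output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GenerationError, ParameterError
from .io import CtTable, ImageStack, TrajectoryTable

#: study acquisition defaults: δt = 10 min, 36 steps -> 37 points over 6 h
DEFAULT_DELTA_T = 10.0
DEFAULT_N_STEPS = 36


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Independent RNG stream for (seed, name), stable across runs."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# trajectories


@dataclass(frozen=True)
class MotilityModelParams:
    """Parameters of one simulated motility cohort.

    model
        ``brownian``  — i.i.d. Gaussian steps, std ``step_sigma`` μm per
        axis per step (implied D = step_sigma²/(2 δt));
        ``prw``       — persistent random walk: per-axis Ornstein–Uhlenbeck
        velocity with persistence time P and stationary mean speed
        ``speed``;
        ``ballistic`` — straight-line motion at ``speed`` in a per-track
        random direction;
        ``stationary``— no motion.
    """

    model: Literal["brownian", "prw", "ballistic", "stationary"]
    step_sigma: float = 1.0
    speed: float = 0.5
    persistence_time: float = 30.0
    delta_t: float = DEFAULT_DELTA_T
    n_steps: int = DEFAULT_N_STEPS
    n_tracks: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("brownian", "prw", "ballistic", "stationary"):
            raise ParameterError(f"unknown motility model {self.model!r}")
        if self.delta_t <= 0:
            raise ParameterError("delta_t must be > 0")
        if self.n_steps < 2:
            raise ParameterError("n_steps must be >= 2")
        if self.step_sigma < 0 or self.speed < 0:
            raise ParameterError("step_sigma and speed must be >= 0")
        if self.model == "prw" and self.persistence_time <= 0:
            raise ParameterError("persistence_time must be > 0 for prw")
        if self.n_tracks < 1:
            raise ParameterError("n_tracks must be >= 1")


def simulate_tracks(params: MotilityModelParams) -> TrajectoryTable:
    """Simulate ``n_tracks`` tracks of ``n_steps + 1`` points from the origin.

    The PRW scheme is the exact discrete-time Ornstein–Uhlenbeck update

        v[k+1] = a·v[k] + σ_v·sqrt(1 − a²)·η,   a = exp(−δt/P)

    per axis, with σ_v = speed·sqrt(2/π) so that the stationary mean speed
    E|v| (Rayleigh) equals ``speed``; positions integrate v·δt. This is a
    modelling choice of the generator — the study only measures motility,
    it does not posit a motion model.
    """
    rng = child_rng(params.seed, "tracks")
    n_pts = params.n_steps + 1
    rows = []
    for k in range(params.n_tracks):
        if params.model == "stationary":
            xy = np.zeros((n_pts, 2))
        elif params.model == "brownian":
            steps = rng.normal(0.0, params.step_sigma, size=(params.n_steps, 2))
            xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        elif params.model == "ballistic":
            theta = rng.uniform(0, 2 * np.pi)
            v = params.speed * np.array([np.cos(theta), np.sin(theta)])
            xy = np.arange(n_pts)[:, None] * (v * params.delta_t)[None, :]
        else:  # prw
            a = np.exp(-params.delta_t / params.persistence_time)
            sigma_v = params.speed * np.sqrt(2.0 / np.pi)
            v = rng.normal(0.0, sigma_v, size=2)  # stationary start
            xy = np.zeros((n_pts, 2))
            for i in range(params.n_steps):
                xy[i + 1] = xy[i] + v * params.delta_t
                v = a * v + sigma_v * np.sqrt(1 - a * a) * rng.normal(size=2)
        rows.append(
            pd.DataFrame(
                {
                    "track_id": f"track{k:04d}",
                    "frame": np.arange(n_pts),
                    "t": np.arange(n_pts) * params.delta_t,
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                }
            )
        )
    return TrajectoryTable(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# scratch-assay frames


@dataclass(frozen=True)
class ScratchSceneParams:
    """A healing scratch assay: textured cell lawn with a clean gap band.

    ``wound_fraction_per_frame`` is the exact area fraction of the wound in
    each successive frame; fractions must be non-increasing (a healing
    series) unless ``allow_nonmonotone`` is set.
    """

    height: int = 256
    width: int = 256
    wound_fraction_per_frame: tuple[float, ...] = (0.30, 0.20, 0.10)
    gap_orientation: Literal["vertical", "horizontal"] = "vertical"
    cell_texture_scale: float = 3.0
    texture_amplitude: float = 60.0
    background: float = 40.0
    noise_sigma: float = 4.0
    seed: int = 0
    allow_nonmonotone: bool = False

    def __post_init__(self) -> None:
        fr = np.asarray(self.wound_fraction_per_frame, dtype=float)
        if fr.size == 0:
            raise ParameterError("need at least one frame")
        if ((fr < 0) | (fr > 1)).any():
            raise ParameterError("wound fractions must lie in [0, 1]")
        if not self.allow_nonmonotone and (np.diff(fr) > 1e-12).any():
            raise ParameterError(
                "wound fractions must be non-increasing (healing); "
                "set allow_nonmonotone=True to override"
            )
        if self.height < 8 or self.width < 8:
            raise ParameterError("scene too small")


def _band_mask(h: int, w: int, fraction: float, orientation: str) -> np.ndarray:
    """Centred band covering exactly round(fraction·h·w) pixels.

    Full rows/columns plus one partially filled edge line, so the planted
    area matches the requested fraction to the nearest pixel.
    """
    if orientation == "horizontal":
        return _band_mask(w, h, fraction, "vertical").T
    target = int(round(fraction * h * w))
    mask = np.zeros((h, w), dtype=bool)
    n_full = target // h
    rem = target - n_full * h
    c0 = (w - n_full) // 2
    mask[:, c0 : c0 + n_full] = True
    if rem:
        mask[:rem, c0 + n_full if c0 + n_full < w else c0 - 1] = True
    return mask


def render_scratch_frames(
    params: ScratchSceneParams,
) -> tuple[ImageStack, np.ndarray]:
    """Render the scratch series; returns (stack, wound masks).

    The lawn is spatially correlated texture (smoothed white noise,
    correlation length ``cell_texture_scale`` px) riding on ``background``;
    the wound band is texture-free. Gaussian read noise ``noise_sigma``
    is added everywhere. Masks are the exact planted wound regions,
    shape (frames, h, w), dtype bool.
    """
    rng = child_rng(params.seed, "scratch")
    h, w = params.height, params.width
    frames, masks = [], []
    for frac in params.wound_fraction_per_frame:
        mask = _band_mask(h, w, float(frac), params.gap_orientation)
        texture = ndimage.gaussian_filter(
            rng.normal(size=(h, w)), params.cell_texture_scale
        )
        sd = texture.std()
        if sd > 0:
            texture = texture / sd * params.texture_amplitude
        img = params.background + np.where(mask, 0.0, np.abs(texture))
        img = img + rng.normal(0.0, params.noise_sigma, size=(h, w))
        frames.append(np.clip(img, 0, None))
        masks.append(mask)
    stack = ImageStack(np.stack(frames)[..., None].astype(np.float64))
    return stack, np.stack(masks)


# ---------------------------------------------------------------------------
# fluorescence fields


@dataclass(frozen=True)
class FluorescenceSceneParams:
    """A 3-channel immunofluorescence field with planted ground truth.

    Channel 0: nuclei (uniform disks). Channel 1: proliferation marker
    (the planted positive subset of nuclei, bright). Channel 2: adhesion
    puncta (elongated Gaussian spots of axis ratio ``puncta_axis_ratio``).
    """

    height: int = 256
    width: int = 256
    n_nuclei: int = 100
    positive_fraction: float = 0.4
    nucleus_radius: float = 5.0
    nucleus_intensity: float = 200.0
    marker_intensity: float = 180.0
    n_puncta: int = 25
    puncta_intensity: float = 150.0
    puncta_sigma: float = 2.0
    puncta_axis_ratio: float = 3.0
    background: float = 0.0
    noise_sigma: float = 0.0
    min_separation: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.positive_fraction <= 1:
            raise ParameterError("positive_fraction must be in [0, 1]")
        if self.nucleus_radius <= 0 or self.puncta_sigma <= 0:
            raise ParameterError("object sizes must be > 0")
        if self.puncta_axis_ratio < 1:
            raise ParameterError("puncta_axis_ratio must be >= 1")
        if self.n_nuclei < 0 or self.n_puncta < 0:
            raise ParameterError("object counts must be >= 0")


def _place_centers(
    rng: np.random.Generator,
    n: int,
    h: int,
    w: int,
    margin: float,
    min_sep: float,
    max_tries: int = 20000,
) -> np.ndarray:
    """Rejection-sample n centers with pairwise distance >= min_sep."""
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"could not place {n} non-overlapping objects in {h}x{w}"
            )
        c = np.array(
            [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
        )
        if all(np.hypot(*(c - p)) >= min_sep for p in centers):
            centers.append(c)
    return np.array(centers).reshape(n, 2)


def render_fluorescence_field(
    params: FluorescenceSceneParams,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render one field; returns (3-channel 1-frame stack, ground-truth table).

    The truth table has one row per planted object:
    ``object (nucleus|punctum), y, x, size, positive, angle_deg``.
    ``size`` is the nucleus radius or the punctum major-axis sigma.
    """
    rng = child_rng(params.seed, "fluorescence")
    h, w = params.height, params.width
    yy, xx = np.mgrid[0:h, 0:w]
    nuclei = np.zeros((h, w))
    marker = np.zeros((h, w))
    puncta = np.zeros((h, w))
    truth_rows = []

    r = params.nucleus_radius
    sep = params.min_separation if params.min_separation is not None else 2 * r + 2
    if params.n_nuclei:
        centers = _place_centers(rng, params.n_nuclei, h, w, r + 1, sep)
        n_pos = int(round(params.positive_fraction * params.n_nuclei))
        positive = np.zeros(params.n_nuclei, dtype=bool)
        positive[rng.choice(params.n_nuclei, size=n_pos, replace=False)] = True
        for (cy, cx), pos in zip(centers, positive):
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            nuclei[disk] = params.nucleus_intensity
            if pos:
                marker[disk] = params.marker_intensity
            truth_rows.append(
                dict(object="nucleus", y=cy, x=cx, size=r, positive=bool(pos),
                     angle_deg=0.0)
            )

    if params.n_puncta:
        smaj = params.puncta_sigma * params.puncta_axis_ratio
        smin = params.puncta_sigma
        sep_p = 6 * smaj
        pc = _place_centers(rng, params.n_puncta, h, w, 3 * smaj, sep_p)
        for cy, cx in pc:
            ang = rng.uniform(0, np.pi)
            ca, sa = np.cos(ang), np.sin(ang)
            u = (xx - cx) * ca + (yy - cy) * sa
            v = -(xx - cx) * sa + (yy - cy) * ca
            puncta += params.puncta_intensity * np.exp(
                -0.5 * ((u / smaj) ** 2 + (v / smin) ** 2)
            )
            truth_rows.append(
                dict(object="punctum", y=cy, x=cx, size=smaj, positive=False,
                     angle_deg=np.degrees(ang))
            )

    img = np.stack([nuclei, marker, puncta], axis=-1) + params.background
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
    stack = ImageStack(
        np.clip(img, 0, None)[None, ...],
        channel_names=["nuclei", "marker", "puncta"],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["object", "y", "x", "size", "positive", "angle_deg"]
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Ct tables


@dataclass(frozen=True)
class CtSceneParams:
    """Simulated two-condition qPCR experiment with known log2 fold changes.

    ``genes`` must contain ``reference_gene``; ``true_log2_fold`` is aligned
    with ``genes`` (treated vs control) and the reference gene's entry must
    be 0. Target Ct in the treated condition is shifted by −log2fold cycles
    (one PCR cycle per twofold), replicate noise is Gaussian with sd
    ``ct_noise_sd``.
    """

    genes: tuple[str, ...] = ("Gapdh", "Col1a1", "Acta2", "Fn1")
    reference_gene: str = "Gapdh"
    true_log2_fold: tuple[float, ...] = (0.0, 1.0, 0.5, -0.5)
    base_ct: float = 24.0
    reference_ct: float = 18.0
    ct_noise_sd: float = 0.0
    n_replicates: int = 3
    n_samples: int = 3
    conditions: tuple[str, str] = ("control", "treated")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_samples < 1:
            raise ParameterError("n_replicates and n_samples must be >= 1")
        if len(self.true_log2_fold) != len(self.genes):
            raise ParameterError("true_log2_fold must match genes")
        if self.reference_gene not in self.genes:
            raise ParameterError(
                f"reference gene {self.reference_gene!r} missing from gene list"
            )
        ref_fold = dict(zip(self.genes, self.true_log2_fold))[self.reference_gene]
        if ref_fold != 0:
            raise ParameterError("reference gene must have true_log2_fold = 0")
        if self.ct_noise_sd < 0:
            raise ParameterError("ct_noise_sd must be >= 0")


def simulate_ct_table(params: CtSceneParams) -> tuple[CtTable, pd.DataFrame]:
    """Simulate the Ct table; returns (table, truth).

    Truth has columns ``gene, true_log2_fold, true_fold``.
    """
    rng = child_rng(params.seed, "ct")
    control, treated = params.conditions
    rows = []
    for cond in params.conditions:
        for s in range(params.n_samples):
            sample = f"{cond}_{s + 1}"
            gene_ct = {}
            for gene, lf in zip(params.genes, params.true_log2_fold):
                base = (
                    params.reference_ct
                    if gene == params.reference_gene
                    else params.base_ct
                )
                shift = -lf if cond == treated else 0.0
                gene_ct[gene] = base + shift
            for gene, ct0 in gene_ct.items():
                for _ in range(params.n_replicates):
                    ct = ct0 + (
                        rng.normal(0.0, params.ct_noise_sd)
                        if params.ct_noise_sd > 0
                        else 0.0
                    )
                    rows.append(
                        dict(sample=sample, condition=cond, gene=gene, ct=ct)
                    )
    truth = pd.DataFrame(
        {
            "gene": list(params.genes),
            "true_log2_fold": list(params.true_log2_fold),
            "true_fold": [2.0 ** lf for lf in params.true_log2_fold],
        }
    )
    return CtTable(pd.DataFrame(rows)), truth
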