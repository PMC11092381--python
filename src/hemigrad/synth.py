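"""Synthetic multi-site cohorts with planted gradient asymmetry.

The generator emulates the statistical structure the downstream analyses
assume, with full ground truth:

* a smooth **latent gradient** ``g`` over homotopic pairs drives the FC
  structure through a squared-exponential kernel
  ``K[i,j] = exp(-(g_i - g_j)^2 / (2 l^2))``, mirrored across hemispheres
  so that, with all offsets zero, the population FC satisfies ``LL == RR``
  and ``LR == RL.T`` exactly at the covariance level;
* **asymmetry** is planted as a latent-position offset of the *left*
  member of selected pairs (baseline offsets delta for everyone, an extra
  group effect Delta for MDD subjects, and per-subject jitter), which
  perturbs all of that region's edge weights through the kernel — the
  asymmetry index must then re-emerge through the entire pipeline
  (time series -> FC -> embedding -> alignment -> AI);
* **site effects** are an additive offset plus a multiplicative scale on
  Fisher-z edges, matching ComBat's location/scale model;
* **BDI-II** scores depend linearly on a sparse subset of the per-subject
  latent asymmetry features plus Gaussian noise, scaled to a target
  in-sample R² (default 0.3), then shifted/clipped to the 0-63 range;
* covariates (age, sex, mean FD) and per-volume motion traces are
  sampled from plausible resting-state distributions.

Each subject's correlation matrix is projected to the nearest symmetric
positive-definite matrix (eigenvalue clipping, unit-diagonal rescale)
before multivariate-normal sampling. Time series are temporally white;
see the methods note for what that does and does not emulate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parcellation import Parcellation, make_parcellation
from .prep import MotionTrace

DEFAULT_SITES = ("UTO", "COI", "HKH", "KUT")

# Group-effect magnitude on the latent left-position offset, calibrated so
# that the downstream AI group difference lands near Cohen's d ~ 0.5 at the
# default noise settings (see docs/methods.md).
DEFAULT_GROUP_EFFECT = 0.065


class SimulationError(RuntimeError):
    """Raised when a subject's covariance cannot be made positive definite."""


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    latent_gradient: np.ndarray          # n_pairs, in [-1, 1]
    asym_offsets: np.ndarray             # n_pairs baseline left offsets (delta)
    group_effect: np.ndarray             # n_pairs extra offsets for MDD (Delta)
    site_shift: dict                     # site -> (additive offset, scale > 0)
    bdi_weights: np.ndarray              # n_pairs, >= 80% exactly zero
    fc_noise_sd: float = 0.05
    subject_asym_sd: float = 0.04
    bdi_r2: float = 0.3
    length_scale: float = 0.5
    inter_strength: float = 0.6
    homotopic_boost: float = 0.2
    # bilateral distributed components (hub-like structure beyond the
    # single smooth gradient); n_pairs x r loadings, may be empty
    extra_loadings: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("latent_gradient", "asym_offsets", "group_effect", "bdi_weights"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.latent_gradient)
        if self.extra_loadings is None:
            object.__setattr__(self, "extra_loadings", np.zeros((n, 0)))
        else:
            V = np.asarray(self.extra_loadings, dtype=float).reshape(n, -1)
            object.__setattr__(self, "extra_loadings", V)
        for name in ("asym_offsets", "group_effect", "bdi_weights"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per pair")
        for site, (off, scale) in self.site_shift.items():
            if scale <= 0:
                raise ValueError(f"site {site!r} scale factor must be positive")
        nz = np.count_nonzero(self.bdi_weights)
        if nz > 0.2 * n:
            raise ValueError("bdi_weights must be >= 80% exactly zero")
        if self.fc_noise_sd < 0 or self.subject_asym_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if not 0.0 <= self.bdi_r2 < 1.0:
            raise ValueError("bdi_r2 must be in [0, 1)")

    @property
    def n_pairs(self) -> int:
        return len(self.latent_gradient)

    def to_json(self) -> str:
        d = {
            "latent_gradient": self.latent_gradient.tolist(),
            "asym_offsets": self.asym_offsets.tolist(),
            "group_effect": self.group_effect.tolist(),
            "site_shift": {k: list(v) for k, v in self.site_shift.items()},
            "bdi_weights": self.bdi_weights.tolist(),
            "fc_noise_sd": self.fc_noise_sd,
            "subject_asym_sd": self.subject_asym_sd,
            "bdi_r2": self.bdi_r2,
            "length_scale": self.length_scale,
            "inter_strength": self.inter_strength,
            "homotopic_boost": self.homotopic_boost,
            "extra_loadings": self.extra_loadings.tolist(),
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["site_shift"] = {k: tuple(v) for k, v in d["site_shift"].items()}
        return cls(**d)


@dataclass
class SubjectRecord:
    """One simulated (or loaded) participant."""

    subject_id: str
    group: str
    site: str
    age: float
    sex: str
    mean_fd: float
    bdi: int
    timeseries: np.ndarray               # timepoints x regions
    tr: float = 2.5
    motion: MotionTrace | None = None
    latent_asym: np.ndarray | None = None  # ground-truth per-pair left offset

    def __post_init__(self) -> None:
        ts = np.asarray(self.timeseries, dtype=float)
        if ts.ndim != 2 or ts.shape[0] < 2:
            raise ValueError("timeseries must be 2-D with >= 2 timepoints")
        if not np.isfinite(ts).all():
            raise ValueError("timeseries contains non-finite entries")
        if self.group not in ("MDD", "HC"):
            raise ValueError("group must be 'MDD' or 'HC'")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.mean_fd < 0:
            raise ValueError("mean_fd must be nonnegative")
        if self.bdi < 0:
            raise ValueError("bdi must be nonnegative")
        self.timeseries = ts


@dataclass
class CohortDataset:
    """Subjects + parcellation (+ ground truth, when synthetic)."""

    subjects: list
    parcellation: Parcellation
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        n_reg = self.parcellation.n_regions
        for s in self.subjects:
            if s.timeseries.shape[1] != n_reg:
                raise ValueError(
                    f"subject {s.subject_id}: {s.timeseries.shape[1]} regions, "
                    f"parcellation has {n_reg}"
                )

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def groups(self) -> list:
        return [s.group for s in self.subjects]

    @property
    def sites(self) -> list:
        return [s.site for s in self.subjects]

    def phenotypes(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "site": [s.site for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
                "mean_fd": [s.mean_fd for s in self.subjects],
                "bdi": [s.bdi for s in self.subjects],
            }
        )

    def covariate_matrix(self) -> np.ndarray:
        """Age, sex (M=1), mean FD as a subjects x 3 design block."""
        ph = self.phenotypes()
        return np.column_stack(
            [
                ph["age"].to_numpy(float),
                (ph["sex"] == "M").to_numpy(float),
                ph["mean_fd"].to_numpy(float),
            ]
        )


def default_ground_truth(
    parcellation: Parcellation,
    sites=DEFAULT_SITES,
    seed: int = 0,
    effect_networks: tuple = ("DefaultMode", "SalienceVentralAttention"),
    group_effect_size: float = DEFAULT_GROUP_EFFECT,
    baseline_asym_sd: float = 0.02,
    fc_noise_sd: float = 0.05,
    subject_asym_sd: float = 0.04,
    bdi_r2: float = 0.3,
    bdi_sparsity: float = 0.1,
    site_offset_sd: float = 0.03,
    site_scale_range: tuple = (0.9, 1.1),
    n_extra_components: int = 5,
    extra_strength: float = 0.5,
    calibrate_effects: bool = True,
) -> GroundTruth:
    """Study-condition defaults for the ground truth.

    Group asymmetry effects are planted in ``effect_networks`` (default:
    default-mode and salience/ventral-attention systems, falling back to
    the first two network labels if those names are absent); baseline
    (group-independent) asymmetry offsets are drawn for every pair.
    """
    rng = np.random.default_rng(seed)
    n_pairs = parcellation.n_pairs
    nets = parcellation.pair_networks
    available = list(dict.fromkeys(nets))
    chosen = [n for n in effect_networks if n in available]
    if not chosen:
        chosen = available[: min(2, len(available))]
    affected = np.isin(nets, chosen)
    latent = np.linspace(-1.0, 1.0, n_pairs)
    asym = rng.normal(0.0, baseline_asym_sd, n_pairs)
    # effect direction alternates in short runs across affected pairs:
    # disorders shift some regions leftward and others rightward, and a
    # sign-balanced planting avoids a first-order amplitude change of the
    # left-hemisphere spectrum that would bleed into unaffected pairs
    # (run length 4 keeps enough local coherence for the shifted regions
    # to actually move in the embedding)
    signs = np.where((np.cumsum(affected) // 4) % 2 == 0, -1.0, 1.0)
    group = np.where(affected, group_effect_size * signs, 0.0)
    site_shift = {
        s: (
            float(rng.normal(0.0, site_offset_sd)),
            float(rng.uniform(*site_scale_range)),
        )
        for s in sites
    }
    n_w = max(1, int(round(bdi_sparsity * n_pairs)))
    w = np.zeros(n_pairs)
    idx = rng.choice(n_pairs, size=n_w, replace=False)
    w[idx] = rng.normal(0.0, 1.0, n_w)
    # equal-norm random directions: distributed (hub-like) structure that
    # varies by region without making any region systematically weak
    # under unit-diagonal normalization
    if n_extra_components > 0:
        U = rng.standard_normal((n_pairs, n_extra_components))
        U /= np.linalg.norm(U, axis=1, keepdims=True)
        V = extra_strength * U
    else:
        V = np.zeros((n_pairs, 0))
    def build(ge):
        return GroundTruth(
            latent_gradient=latent,
            asym_offsets=asym,
            group_effect=ge,
            site_shift=site_shift,
            bdi_weights=w,
            fc_noise_sd=fc_noise_sd,
            subject_asym_sd=subject_asym_sd,
            bdi_r2=bdi_r2,
            extra_loadings=V,
        )

    truth = build(group)
    if calibrate_effects and affected.any() and group_effect_size != 0:
        # equalize the downstream (noise-free) AI response across planted
        # pairs: the same latent shift moves different pairs by very
        # different amounts in the embedding, so per-pair magnitudes are
        # rescaled toward the mean response (two fixed-point iterations,
        # latent shifts capped at 3x the nominal effect size)
        ge = group.astype(float).copy()
        target = None
        cap = 2.0 * abs(group_effect_size)
        for _ in range(3):
            resp = np.linalg.norm(deterministic_ai_shift(truth), axis=1)
            if target is None:
                target = resp[affected].mean()
            # damped fixed point: responses interact, undamped updates
            # oscillate
            scale = (target / np.maximum(resp[affected], target / 8.0)) ** 0.6
            ge[affected] = np.clip(ge[affected] * scale, -cap, cap)
            # keep shifted left positions inside the latent range (edge
            # regions respond weakly and would otherwise be boosted off
            # the grid, leaving them without strong partners); the cap on
            # ge itself also limits the smearing of a pair's template
            # profile across its shifted and unshifted positions
            total = latent[affected] + asym[affected] + ge[affected]
            total = np.clip(total, -1.1, 1.1)
            ge[affected] = total - latent[affected] - asym[affected]
            truth = build(ge)
    return truth


def deterministic_ai_shift(truth: GroundTruth, cfg=None) -> np.ndarray:
    """Noise-free group AI difference map implied by the planted effects.

    Runs the population (infinite-data) pipeline — kernel correlation,
    Fisher z, embedding, template alignment, AI — with and without the
    group effect and returns the per-pair G1-G3 AI difference. Used to
    calibrate planted effects and to reason about propagation.
    """
    from .gradients import GradientConfig, embed_block, procrustes_align

    cfg = cfg or GradientConfig()
    n = truth.n_pairs

    def intra_blocks(off):
        C = population_correlation(truth, off)
        z = np.arctanh(np.clip(C, -0.999999, 0.999999))
        np.fill_diagonal(z, 0.0)
        return z[:n, :n], z[n:, n:]

    LL_hc, RR_hc = intra_blocks(truth.asym_offsets)
    template = embed_block((LL_hc + RR_hc) / 2.0, cfg).scores

    def ai(LL, RR):
        aL = procrustes_align(embed_block(LL, cfg).scores, template)
        aR = procrustes_align(embed_block(RR, cfg).scores, template)
        return (aL - aR)[:, :3]

    LL_m, RR_m = intra_blocks(truth.asym_offsets + truth.group_effect)
    return ai(LL_m, RR_m) - ai(LL_hc, RR_hc)


def _kernel(x: np.ndarray, y: np.ndarray, length_scale: float) -> np.ndarray:
    d = x[:, None] - y[None, :]
    return np.exp(-(d**2) / (2.0 * length_scale**2))


def population_correlation(truth: GroundTruth, left_offset: np.ndarray | None = None) -> np.ndarray:
    """Noise- and site-free region correlation matrix for given offsets.

    Regions are ordered [all L pairs, all R pairs] by pair index. With
    ``left_offset`` zero the matrix satisfies the mirror property
    LL == RR and LR == RL.T exactly.
    """
    g = truth.latent_gradient
    gl = g if left_offset is None else g + left_offset
    h = truth.homotopic_boost
    eye = np.eye(truth.n_pairs)
    # homotopic boost = shared per-pair signal (adds h to all three block
    # diagonals); distributed components = shared bilateral low-rank term
    # V V^T in every block; both constructions keep the matrix PSD
    E = truth.extra_loadings @ truth.extra_loadings.T
    K_LL = _kernel(gl, gl, truth.length_scale) + h * eye + E
    K_RR = _kernel(g, g, truth.length_scale) + h * eye + E
    K_LR = truth.inter_strength * _kernel(gl, g, truth.length_scale) + h * eye + E
    S = np.block([[K_LL, K_LR], [K_LR.T, K_RR]])
    d = np.sqrt(np.diag(S))
    C = S / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def nearest_spd_correlation(C: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to SPD and rescale to unit diagonal."""
    C = (C + C.T) / 2.0
    evals, evecs = np.linalg.eigh(C)
    floor = max(eps * evals.max(), 1e-12)
    evals = np.clip(evals, floor, None)
    P = (evecs * evals) @ evecs.T
    d = np.sqrt(np.diag(P))
    if np.any(d <= 0) or not np.isfinite(d).all():
        raise SimulationError("covariance projection produced a bad diagonal")
    P = P / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    return (P + P.T) / 2.0


def _subject_correlation(
    truth: GroundTruth, left_offset: np.ndarray, site: str, rng: np.random.Generator
) -> np.ndarray:
    C = population_correlation(truth, left_offset)
    off, scale = truth.site_shift[site]
    z = np.arctanh(np.clip(C, -0.999999, 0.999999))
    noise = rng.normal(0.0, truth.fc_noise_sd, C.shape)
    noise = (noise + noise.T) / np.sqrt(2.0)
    z = off + scale * z + noise
    C2 = np.tanh(z)
    np.fill_diagonal(C2, 1.0)
    return nearest_spd_correlation(C2)


def _motion_trace(rng: np.random.Generator, n_vol: int, tr: float) -> MotionTrace:
    fd = np.abs(rng.normal(0.10, 0.04, n_vol))
    spikes = rng.random(n_vol) < 0.02
    fd = fd + spikes * rng.exponential(0.4, n_vol)
    dvars = np.abs(rng.normal(30.0, 8.0, n_vol)) + spikes * 40.0
    return MotionTrace(fd=fd, dvars=dvars, tr=tr)


def simulate_cohort(
    truth: GroundTruth,
    parcellation: Parcellation,
    n_mdd: int,
    n_hc: int,
    sites=DEFAULT_SITES,
    n_timepoints: int = 240,
    seed: int = 0,
    tr: float = 2.5,
    with_motion: bool = True,
) -> CohortDataset:
    """Draw a full multi-site cohort with planted effects.

    Each subject's time series is sampled i.i.d. in time from a zero-mean
    multivariate normal whose correlation encodes the latent gradient,
    the subject's realized left-hemisphere offsets, the site shift and
    edge noise. Identical inputs and seed reproduce the dataset
    bit-for-bit.
    """
    if n_mdd < 1 or n_hc < 1:
        raise ValueError("subject counts must be positive")
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    if truth.n_pairs != parcellation.n_pairs:
        raise ValueError("ground truth and parcellation disagree on n_pairs")
    n_regions = parcellation.n_regions
    if n_timepoints < 2 * n_regions:
        warnings.warn(
            f"n_timepoints={n_timepoints} < 2 x {n_regions} regions; FC "
            "estimates will be noisy",
            stacklevel=2,
        )
    sites = list(sites)
    unknown = set(sites) - set(truth.site_shift)
    if unknown:
        raise ValueError(f"sites without a declared shift: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    groups = ["MDD"] * n_mdd + ["HC"] * n_hc
    # round-robin within group keeps every site populated by both groups
    site_of = [sites[i % len(sites)] for i in range(n_mdd)] + [
        sites[i % len(sites)] for i in range(n_hc)
    ]
    n_total = n_mdd + n_hc
    offsets = np.empty((n_total, truth.n_pairs))
    subjects: list[SubjectRecord] = []
    records = []
    for i, (grp, site) in enumerate(zip(groups, site_of)):
        a = truth.asym_offsets + (grp == "MDD") * truth.group_effect
        a = a + rng.normal(0.0, truth.subject_asym_sd, truth.n_pairs)
        offsets[i] = a
        C = _subject_correlation(truth, a, site, rng)
        try:
            L = np.linalg.cholesky(C + 1e-10 * np.eye(n_regions))
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise SimulationError(
                f"subject {i}: correlation not positive definite after projection"
            ) from exc
        ts = rng.standard_normal((n_timepoints, n_regions)) @ L.T
        motion = _motion_trace(rng, n_timepoints, tr) if with_motion else None
        mean_fd = float(motion.fd.mean()) if motion else float(abs(rng.normal(0.12, 0.05)))
        age = float(np.clip(rng.normal(43.0, 11.0), 18.0, 80.0))
        sex = "M" if rng.random() < 0.5 else "F"
        records.append((grp, site, age, sex, mean_fd, ts, motion))
    # BDI from the sparse linear model on latent asymmetry features
    signal = offsets @ truth.bdi_weights
    sig_sd = signal.std()
    eps = rng.standard_normal(n_total)
    if truth.bdi_r2 > 0 and sig_sd > 0:
        latent = np.sqrt(truth.bdi_r2) * (signal - signal.mean()) / sig_sd
        latent = latent + np.sqrt(1.0 - truth.bdi_r2) * eps
    else:
        latent = eps
    bdi = np.clip(np.round(12.0 + 8.0 * latent), 0, 63).astype(int)
    for i, (grp, site, age, sex, mean_fd, ts, motion) in enumerate(records):
        subjects.append(
            SubjectRecord(
                subject_id=f"sub-{i:04d}",
                group=grp,
                site=site,
                age=age,
                sex=sex,
                mean_fd=mean_fd,
                bdi=int(bdi[i]),
                timeseries=ts,
                tr=tr,
                motion=motion,
                latent_asym=offsets[i].copy(),
            )
        )
    return CohortDataset(subjects=subjects, parcellation=parcellation, ground_truth=truth)


def true_ai_features(dataset: CohortDataset) -> np.ndarray:
    """Subjects x pairs matrix of realized latent left offsets."""
    rows = []
    for s in dataset.subjects:
        if s.latent_asym is None:
            raise ValueError(f"subject {s.subject_id} carries no ground truth")
        rows.append(s.latent_asym)
    return np.stack(rows)


def simulate_feature_cohort(
    n_subjects: int,
    n_features: int,
    r2: float,
    seed: int = 0,
    sites=DEFAULT_SITES,
    sparsity: float = 0.1,
    site_offset_sd: float = 0.2,
):
    """Feature-level cohort for prediction benchmarks.

    Draws standard-normal AI-like features, adds per-site offsets, and
    builds a BDI-like score from a sparse linear signal at exact in-sample
    R² ``r2`` (``r2 = 0`` gives a pure-noise target). Returns
    ``(features DataFrame, bdi, site labels)``.
    """
    if not 0.0 <= r2 < 1.0:
        raise ValueError("r2 must be in [0, 1)")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_subjects, n_features))
    sites = list(sites)
    site_lab = np.array([sites[i % len(sites)] for i in range(n_subjects)])
    offsets = {s: rng.normal(0.0, site_offset_sd) for s in sites}
    Xs = X + np.array([offsets[s] for s in site_lab])[:, None]
    eps = rng.standard_normal(n_subjects)
    if r2 > 0:
        k = max(1, int(round(sparsity * n_features)))
        w = np.zeros(n_features)
        w[rng.choice(n_features, size=k, replace=False)] = rng.normal(0, 1, k)
        s = X @ w
        latent = np.sqrt(r2) * (s - s.mean()) / s.std() + np.sqrt(1 - r2) * eps
    else:
        latent = eps
    bdi = np.clip(np.round(12.0 + 8.0 * latent), 0, 63)
    cols = [f"f{j:03d}" for j in range(n_features)]
    ids = [f"sub-{i:04d}" for i in range(n_subjects)]
    return pd.DataFrame(Xs, index=ids, columns=cols), bdi, site_lab


__all__ = [
    "GroundTruth",
    "SubjectRecord",
    "CohortDataset",
    "SimulationError",
    "DEFAULT_SITES",
    "DEFAULT_GROUP_EFFECT",
    "make_parcellation",
    "default_ground_truth",
    "population_correlation",
    "nearest_spd_correlation",
    "simulate_cohort",
    "true_ai_features",
    "simulate_feature_cohort",
]
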