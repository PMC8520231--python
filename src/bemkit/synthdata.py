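"""Synthetic inputs for every pipeline stage, with recorded ground truth.

The study this package models compares four groups of brain myeloid cells
(sham/irradiated x control/CSF-1R-inhibitor chow) against published
reference populations (monocyte vs microglia; embryonic vs adult
microglia).  The primary data are not deposited, so each assay here has a
generator that emulates its input's statistical structure:

* reference bulk count matrices with planted directional signature genes,
* a study count matrix whose groups are mixtures of two reference
  expression profiles (the engrafted-macrophage group sits between the
  monocyte and microglia profiles),
* star-shaped binary cell masks with a known process count for Sholl
  analysis,
* flow-event tables with bead-calibration populations and a monotone
  size -> scatter map,
* novel-object-recognition trial tables with a configured preference.

Replicate noise is multiplicative log-normal with its mean correction
(``exp(sigma*z - sigma^2/2)``), so the expectation of every generated
value equals its configured mean and the zero-dispersion limit is exact.
A single global seed expands into independent per-stream child seeds, so
adding one generator does not perturb the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk, line
from skimage.morphology import dilation, footprint_rectangle

from .containers import CountMatrix

__all__ = [
    "child_rng",
    "RefSimConfig",
    "SignatureTruth",
    "StudyMixConfig",
    "MorphTruth",
    "FlowSimConfig",
    "gen_reference_counts",
    "gen_study_counts",
    "gen_radiation_study",
    "gen_cell_mask",
    "gen_flow_events",
    "gen_nor_trials",
]

STUDY_GROUPS = ("Sham+Control", "WBRT+Control", "Sham+CSF1Ri", "WBRT+CSF1Ri")


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for a named stream under one global seed."""
    return np.random.default_rng([int(seed), zlib.crc32(stream.encode())])


def _lognormal_noise(means: np.ndarray, dispersion: float, rng: np.random.Generator, size) -> np.ndarray:
    if dispersion == 0.0:
        return np.broadcast_to(means, size).copy()
    z = rng.standard_normal(size)
    return means * np.exp(dispersion * z - dispersion**2 / 2.0)


# ---------------------------------------------------------------------------
# reference and study count matrices


@dataclass
class RefSimConfig:
    """Two-population (or staged) reference dataset with planted signatures.

    ``n_sig_a`` genes are elevated ``effect_fc``-fold in population A,
    ``n_sig_b`` in population B; all other genes share a common mean.
    When ``stages`` is set the generator emits one population per stage:
    A-genes are elevated only in the first stage and B-genes only in the
    last, emulating development-resolved references where early- and
    late-specific gene lists exist.
    """

    n_genes: int = 2000
    n_sig_a: int = 100
    n_sig_b: int = 100
    effect_fc: float = 4.0
    n_reps: int = 4
    dispersion: float = 0.2
    seed: int = 0
    name_a: str = "monocyte"
    name_b: str = "microglia"
    baseline_log_mean: float = np.log(100.0)
    baseline_log_sd: float = 0.5
    stages: tuple[str, ...] | None = None

    def validate(self) -> None:
        if self.n_sig_a + self.n_sig_b > self.n_genes:
            raise ValueError("n_sig_a + n_sig_b exceeds n_genes")
        if self.effect_fc < 1:
            raise ValueError("effect_fc must be >= 1 (1 is the no-effect null)")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.stages is not None and len(self.stages) < 2:
            raise ValueError("stages needs >= 2 labels")


@dataclass
class SignatureTruth:
    """Ground truth of a generated reference: which genes are planted where."""

    up_in_a: set[str]
    up_in_b: set[str]
    baseline_means: pd.Series
    effect_fc: float

    def __post_init__(self):
        if self.up_in_a & self.up_in_b:
            raise ValueError("up_in_a and up_in_b must be disjoint")

    @property
    def profile_a(self) -> pd.Series:
        """Expected per-gene expression of population A."""
        mult = pd.Series(1.0, index=self.baseline_means.index)
        mult[list(self.up_in_a)] = self.effect_fc
        return self.baseline_means * mult

    @property
    def profile_b(self) -> pd.Series:
        mult = pd.Series(1.0, index=self.baseline_means.index)
        mult[list(self.up_in_b)] = self.effect_fc
        return self.baseline_means * mult


def gen_reference_counts(config: RefSimConfig) -> tuple[CountMatrix, SignatureTruth]:
    config.validate()
    rng = child_rng(config.seed, "reference")
    genes = pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene_id")
    baseline = pd.Series(
        np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)),
        index=genes,
    )
    up_a = set(genes[: config.n_sig_a])
    up_b = set(genes[config.n_sig_a : config.n_sig_a + config.n_sig_b])
    truth = SignatureTruth(up_a, up_b, baseline, config.effect_fc)

    populations = list(config.stages) if config.stages else [config.name_a, config.name_b]
    profiles: dict[str, pd.Series] = {}
    if config.stages:
        for i, stage in enumerate(populations):
            if i == 0:
                profiles[stage] = truth.profile_a
            elif i == len(populations) - 1:
                profiles[stage] = truth.profile_b
            else:
                profiles[stage] = baseline
    else:
        profiles[config.name_a] = truth.profile_a
        profiles[config.name_b] = truth.profile_b

    cols, data, labels = [], [], {}
    for pop in populations:
        mean = profiles[pop].to_numpy()[:, None]
        vals = _lognormal_noise(mean, config.dispersion, rng, (config.n_genes, config.n_reps))
        for r in range(config.n_reps):
            sid = f"{pop}_r{r + 1}"
            cols.append(sid)
            data.append(vals[:, r])
            labels[sid] = pop
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    return CountMatrix(values, pd.Series(labels)), truth


@dataclass
class StudyMixConfig:
    """Four-group study whose expected expression blends two reference profiles.

    ``mixture_fractions[g]`` is the fraction pi of the population-A profile
    in group g; expected expression is ``pi * A + (1 - pi) * B`` per gene.
    The default places the engrafted-macrophage group (irradiated +
    depleted/repopulated) halfway between profiles while the three
    microglia groups stay at the B profile.
    """

    group_names: tuple[str, ...] = STUDY_GROUPS
    mixture_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "Sham+Control": 0.0,
            "WBRT+Control": 0.0,
            "Sham+CSF1Ri": 0.0,
            "WBRT+CSF1Ri": 0.5,
        }
    )
    n_reps: int = 4
    dispersion: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for g in self.group_names:
            if g not in self.mixture_fractions:
                raise ValueError(f"mixture_fractions missing group {g!r}")
            pi = self.mixture_fractions[g]
            if not 0.0 <= pi <= 1.0:
                raise ValueError(f"mixture_fractions[{g!r}]={pi} outside [0, 1]")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")


def gen_study_counts(truth: SignatureTruth, config: StudyMixConfig) -> tuple[CountMatrix, StudyMixConfig]:
    config.validate()
    rng = child_rng(config.seed, "study")
    prof_a = truth.profile_a
    prof_b = truth.profile_b
    genes = prof_a.index
    cols, data, labels = [], [], {}
    for g in config.group_names:
        pi = config.mixture_fractions[g]
        mean = (pi * prof_a + (1.0 - pi) * prof_b).to_numpy()[:, None]
        vals = _lognormal_noise(mean, config.dispersion, rng, (len(genes), config.n_reps))
        for r in range(config.n_reps):
            sid = f"{g}_r{r + 1}"
            cols.append(sid)
            data.append(vals[:, r])
            labels[sid] = g
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    return CountMatrix(values, pd.Series(labels)), config


def gen_radiation_study(
    n_genes: int = 2000,
    n_up: int = 117,
    n_down: int = 87,
    effect_fc: float = 4.0,
    n_reps: int = 4,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[CountMatrix, dict[str, set[str]]]:
    """Study matrix with a radiation response present only on control diet.

    ``n_up`` genes go up and ``n_down`` down ``effect_fc``-fold in the
    irradiated control-diet group relative to sham; the two
    depleted/repopulated (CSF-1Ri) groups stay at the sham profile,
    emulating a radiation transcriptional signature that depletion and
    repopulation erases.  Returns the matrix and the planted
    ``{"up": ..., "down": ...}`` gene sets.
    """
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down exceeds n_genes")
    if effect_fc <= 1:
        raise ValueError("effect_fc must be > 1")
    rng = child_rng(seed, "radiation_study")
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene_id")
    baseline = np.exp(rng.normal(np.log(100.0), 0.5, n_genes))
    up = set(genes[:n_up])
    down = set(genes[n_up : n_up + n_down])
    wbrt_ctrl = baseline.copy()
    wbrt_ctrl[:n_up] *= effect_fc
    wbrt_ctrl[n_up : n_up + n_down] /= effect_fc
    means = {
        "Sham+Control": baseline,
        "WBRT+Control": wbrt_ctrl,
        "Sham+CSF1Ri": baseline,
        "WBRT+CSF1Ri": baseline,
    }
    cols, data, labels = [], [], {}
    for g in STUDY_GROUPS:
        vals = _lognormal_noise(means[g][:, None], dispersion, rng, (n_genes, n_reps))
        for r in range(n_reps):
            sid = f"{g}_r{r + 1}"
            cols.append(sid)
            data.append(vals[:, r])
            labels[sid] = g
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    return CountMatrix(values, pd.Series(labels)), {"up": up, "down": down}


# ---------------------------------------------------------------------------
# cell masks for Sholl analysis


@dataclass
class MorphTruth:
    """Star-shaped cell: ``ray_count`` straight processes of ``ray_length_um``."""

    ray_count: int
    ray_length_um: float
    center: tuple[int, int]
    pixel_size_um: float = 1.0
    soma_radius_um: float = 4.0

    def validate(self) -> None:
        if self.ray_count < 0:
            raise ValueError("ray_count must be >= 0")
        if self.ray_length_um <= 0:
            raise ValueError("ray_length_um must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


def gen_cell_mask(truth: MorphTruth, image_shape: tuple[int, int], seed: int = 0) -> np.ndarray:
    """Binary mask: soma disk plus ``ray_count`` radial processes.

    Rays are evenly spaced in angle with a seeded random rotation and
    drawn a few pixels wide.  The soma is excluded from the intersection
    ground truth (Sholl counts processes, not the cell body).
    """
    truth.validate()
    rng = child_rng(seed, "mask")
    h, w = image_shape
    cy, cx = truth.center
    ray_px = truth.ray_length_um / truth.pixel_size_um
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError("center outside image")
    if cy - ray_px < 1 or cy + ray_px > h - 2 or cx - ray_px < 1 or cx + ray_px > w - 2:
        raise ValueError("rays exceed image bounds")
    mask = np.zeros(image_shape, dtype=bool)
    offset = rng.uniform(0, 2 * np.pi)
    for k in range(truth.ray_count):
        theta = offset + 2 * np.pi * k / truth.ray_count
        ey = int(round(cy + ray_px * np.sin(theta)))
        ex = int(round(cx + ray_px * np.cos(theta)))
        rr, cc = line(cy, cx, ey, ex)
        mask[rr, cc] = True
    if truth.ray_count:
        mask = dilation(mask, footprint_rectangle((3, 3)))
        # dilation pushes ray tips past the nominal length; clip to it
        yy, xx = np.mgrid[0:h, 0:w]
        mask &= np.hypot(yy - cy, xx - cx) <= ray_px + 0.5
    rr, cc = disk((cy, cx), max(truth.soma_radius_um / truth.pixel_size_um, 1.5), shape=image_shape)
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# flow events


@dataclass
class FlowSimConfig:
    """Flow-synaptometry run: calibration beads plus a particle-size mixture.

    Scatter follows a monotone log-linear size map
    ``FSC = scatter_scale * size**scatter_exponent`` with multiplicative
    log-normal noise; only monotonicity matters for gating correctness.
    Fluorescence per particle class is centred on ``mfi_per_class``.
    """

    bead_sizes: tuple[float, ...] = (1.0, 2.0, 3.0, 6.0)
    particle_size_distribution: dict[float, float] = field(
        default_factory=lambda: {0.5: 0.2, 1.5: 0.3, 2.0: 0.3, 5.0: 0.2}
    )
    mfi_per_class: dict[float, float] = field(
        default_factory=lambda: {0.5: 100.0, 1.5: 500.0, 2.0: 600.0, 5.0: 200.0}
    )
    n_events: int = 100_000
    n_beads_per_class: int = 2000
    scatter_scale: float = 1000.0
    scatter_exponent: float = 1.5
    scatter_cv: float = 0.05
    mfi_cv: float = 0.1
    channel: str = "FITC_A"
    seed: int = 0

    def validate(self) -> None:
        if len(self.bead_sizes) != len(set(self.bead_sizes)) or list(self.bead_sizes) != sorted(
            self.bead_sizes
        ):
            raise ValueError("bead_sizes must be strictly increasing")
        if not self.particle_size_distribution:
            raise ValueError("particle_size_distribution is empty")
        total = sum(self.particle_size_distribution.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"particle_size_distribution fractions sum to {total}, not 1")
        if self.n_events <= 0:
            raise ValueError("n_events must be > 0")
        missing = set(self.particle_size_distribution) - set(self.mfi_per_class)
        if missing:
            raise ValueError(f"mfi_per_class missing sizes {sorted(missing)}")

    def expected_scatter(self, size_um) -> np.ndarray:
        return self.scatter_scale * np.asarray(size_um, dtype=float) ** self.scatter_exponent


def gen_flow_events(config: FlowSimConfig) -> pd.DataFrame:
    """Event table: event_id, FSC_A, SSC_A, fluorescence, bead_class, true_size_um.

    ``bead_class`` holds the nominal bead size for calibration events and
    is empty for particles; ``true_size_um`` is simulation ground truth.
    """
    config.validate()
    rng = child_rng(config.seed, "flow")
    sizes = np.array(list(config.particle_size_distribution))
    fracs = np.array([config.particle_size_distribution[s] for s in sizes])
    particle_sizes = rng.choice(sizes, size=config.n_events, p=fracs)
    bead_sizes = np.repeat(config.bead_sizes, config.n_beads_per_class)
    all_sizes = np.concatenate([particle_sizes, bead_sizes])
    n = all_sizes.size
    fsc = _lognormal_noise(config.expected_scatter(all_sizes), config.scatter_cv, rng, n)
    ssc = _lognormal_noise(0.5 * config.expected_scatter(all_sizes), config.scatter_cv, rng, n)
    mfi_mean = np.empty(n)
    mfi_mean[: config.n_events] = [config.mfi_per_class[s] for s in particle_sizes]
    mfi_mean[config.n_events :] = 50.0  # dim bead autofluorescence
    fluor = np.clip(rng.normal(mfi_mean, config.mfi_cv * mfi_mean), 0, None)
    bead_class = np.concatenate(
        [np.full(config.n_events, "", dtype=object), bead_sizes.astype(str).astype(object)]
    )
    return pd.DataFrame(
        {
            "event_id": np.arange(n),
            "FSC_A": fsc,
            "SSC_A": ssc,
            config.channel: fluor,
            "bead_class": bead_class,
            "true_size_um": all_sizes,
        }
    )


# ---------------------------------------------------------------------------
# behavior trials


def gen_nor_trials(
    n_mice: int,
    preference_effect: float,
    total_time_mean: float = 30.0,
    total_time_sd: float = 8.0,
    di_sd: float = 0.0,
    group: str = "group",
    seed: int = 0,
) -> pd.DataFrame:
    """Novel-object-recognition trials with a configured mean preference.

    Each mouse gets a total exploration time (normal, clipped at zero) and
    a discrimination index ``preference_effect + noise`` clipped to
    [-1, 1]; novel/familiar times are back-computed so the planted index
    is exact when ``di_sd`` and ``total_time_sd`` are zero.
    """
    if not -1.0 <= preference_effect <= 1.0:
        raise ValueError("preference_effect must lie in [-1, 1]")
    if total_time_mean < 0 or total_time_sd < 0 or di_sd < 0:
        raise ValueError("time distribution parameters must be non-negative")
    rng = child_rng(seed, "nor")
    totals = np.clip(rng.normal(total_time_mean, total_time_sd, n_mice), 0, None)
    dis = np.clip(preference_effect + (rng.standard_normal(n_mice) * di_sd if di_sd else 0.0), -1, 1)
    dis = np.broadcast_to(dis, (n_mice,))
    return pd.DataFrame(
        {
            "mouse_id": [f"m{i + 1:03d}" for i in range(n_mice)],
            "group": group,
            "T_novel": totals * (1 + dis) / 2,
            "T_familiar": totals * (1 - dis) / 2,
        }
    )
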