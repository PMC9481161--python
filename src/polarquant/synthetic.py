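"""Seeded synthetic-data generators with known ground truth.

Every generator is a pure function of its spec (the seed is part of the
spec), so identical specs give bit-identical outputs, and each artifact
carries ground-truth annotations sufficient to score the downstream analysis
without re-inspecting pixels.

The generators emulate the statistical structure the analysis assumes, not
microscope physics: cells are axis-aligned rods (rectangles with semicircular
caps) so pole anchors are exact, noise is Gaussian, reversals are
instantaneous direction flips, and the coupled GTPase assay assumes ideal
1:1 NADH-per-GTP regeneration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cooccurrence import PresenceAbsenceMatrix
from .kinetics import AbsorbanceTrace

__all__ = [
    "PlacementError",
    "SnapshotPopulationSpec",
    "TrackSpec",
    "CoupledAssaySpec",
    "MalachitePlateSpec",
    "PresenceAbsenceSpec",
    "gen_snapshot_scene",
    "gen_timelapse",
    "gen_coupled_trace",
    "gen_malachite_plate",
    "gen_presence_absence",
]

PATTERN_CLASSES = ("unipolar", "bipolar_asymmetric", "bipolar_symmetric", "diffuse")

#: Default target ranges for the intended asymmetry index per pattern class.
#: They sit well inside the classification bins (>0.9 / 0.2..0.9 / <0.2) so
#: that modest measurement noise does not move a cell across a bin boundary,
#: and the bipolar-asymmetric upper end keeps the bright cluster small enough
#: to fit inside the pole cap.
DEFAULT_OMEGA_RANGES = {
    "unipolar": (0.95, 1.0),
    "bipolar_asymmetric": (0.25, 0.75),
    "bipolar_symmetric": (0.0, 0.15),
}

_OMEGA_BIN_BOUNDS = {
    "unipolar": (0.9, 1.0),
    "bipolar_asymmetric": (0.2, 0.9),
    "bipolar_symmetric": (0.0, 0.2),
}


class PlacementError(ValueError):
    """Scene too small to place the requested cells without overlap."""


def _rod_mask(length: int, width: int) -> np.ndarray:
    """Boolean (width, length) mask of a horizontal rod with semicircular caps.

    Pixels are half-open unit squares; a pixel belongs to the rod when its
    center lies within width/2 of the central axis segment.
    """
    r = width / 2.0
    yy, xx = np.mgrid[0:width, 0:length] + 0.5
    xc = np.clip(xx, r, length - r)
    return np.hypot(yy - width / 2.0, xx - xc) <= r + 1e-9


def _tip_pixels(mask: np.ndarray, tip: tuple[float, float], n: int) -> np.ndarray:
    """The n rod pixels nearest a pole tip (deterministic tie-break)."""
    rr, cc = np.nonzero(mask)
    d = np.hypot(rr + 0.5 - tip[0], cc + 0.5 - tip[1])
    order = np.lexsort((cc, rr, d))
    if n > len(order):
        raise PlacementError(f"cluster of {n} px does not fit in a "
                             f"{mask.shape[1]}x{mask.shape[0]} cell")
    return np.column_stack([rr[order[:n]], cc[order[:n]]])


@dataclass(frozen=True)
class SnapshotPopulationSpec:
    """Population of rod cells with 0-2 polar clusters of controlled asymmetry."""

    n_cells: int
    pattern_mixture: dict = field(default_factory=lambda: {"unipolar": 1.0})
    cell_length_px: int = 30
    cell_width_px: int = 8
    cytoplasm_mean: float = 100.0
    cytoplasm_sd: float = 5.0
    cluster_intensity_factor: float = 3.0
    cluster_size_px: int = 6
    omega_target_range: dict = field(
        default_factory=lambda: dict(DEFAULT_OMEGA_RANGES))
    noise_sd: float = 0.0
    seed: int = 0
    image_shape: tuple[int, int] | None = None
    margin_px: int = 6

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        unknown = set(self.pattern_mixture) - set(PATTERN_CLASSES)
        if unknown:
            raise ValueError(f"unknown pattern classes {sorted(unknown)}")
        total = sum(self.pattern_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("pattern_mixture probabilities must sum to 1")
        if self.cluster_intensity_factor < 1:
            raise ValueError("cluster_intensity_factor must be >= 1")
        if self.cluster_size_px < 3:
            raise ValueError("cluster_size_px must be >= 3 to be detectable")
        if self.cytoplasm_mean * self.cluster_intensity_factor <= (
                self.cytoplasm_mean + 2 * self.cytoplasm_sd):
            raise ValueError("cluster intensity not detectable above cytoplasm")
        for cls, (lo, hi) in self.omega_target_range.items():
            blo, bhi = _OMEGA_BIN_BOUNDS[cls]
            inside = (lo > blo and hi <= bhi) if cls != "bipolar_symmetric" \
                else (lo >= blo and hi < bhi)
            if not (lo <= hi and inside):
                raise ValueError(f"omega_target_range for {cls} outside its bin")


def _cluster_design(omega: float, spec: SnapshotPopulationSpec
                    ) -> tuple[int, float, int, float]:
    """Sizes and pixel values for two clusters realizing a target omega.

    The dim pole gets a minimum-size cluster at the full cluster intensity;
    the bright pole's cluster grows in size (value fine-tuned continuously)
    so that the raw cluster-sum ratio matches (1-omega)/(1+omega) exactly.
    """
    v_base = spec.cytoplasm_mean * spec.cluster_intensity_factor
    s2 = max(3, spec.cluster_size_px // 2)
    f2 = s2 * v_base
    f1 = f2 * (1.0 + omega) / (1.0 - omega) if omega < 1 else float("inf")
    s1 = max(3, round(f1 / v_base))
    return s1, f1 / s1, s2, v_base


def gen_snapshot_scene(spec: SnapshotPopulationSpec
                       ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Non-overlapping rods on a grid with per-cell intended class and omega.

    Returns (label image uint16, fluorescence image float64, ground truth).
    Clusters intended as detectable exceed the cytoplasm mean by more than
    two cytoplasmic standard deviations and span >= 3 px by construction;
    diffuse cells receive no cluster pixels.
    """
    rng = np.random.default_rng(spec.seed)
    L, W, m = spec.cell_length_px, spec.cell_width_px, spec.margin_px
    slot_h, slot_w = W + 2 * m, L + 2 * m
    if spec.image_shape is not None:
        H, Wi = spec.image_shape
        nrows, ncols = H // slot_h, Wi // slot_w
        if nrows * ncols < spec.n_cells:
            raise PlacementError(
                f"image {spec.image_shape} fits only {nrows * ncols} cells, "
                f"{spec.n_cells} requested")
        shape = spec.image_shape
    else:
        ncols = max(1, math.ceil(math.sqrt(spec.n_cells * slot_h / slot_w)))
        nrows = math.ceil(spec.n_cells / ncols)
        shape = (nrows * slot_h + m, ncols * slot_w + m)

    mask = _rod_mask(L, W)
    classes = list(spec.pattern_mixture)
    probs = [spec.pattern_mixture[c] for c in classes]
    assigned = rng.choice(len(classes), size=spec.n_cells, p=probs)

    labels = np.zeros(shape, dtype=np.uint16)
    fluor = np.zeros(shape, dtype=float)
    truth_rows = []
    tip_left, tip_right = (W / 2.0, 0.5), (W / 2.0, L - 0.5)

    for i in range(spec.n_cells):
        cls = classes[assigned[i]]
        row, col = divmod(i, ncols)
        r0, c0 = m + row * slot_h, m + col * slot_w
        cell_fluor = spec.cytoplasm_mean + rng.normal(0.0, spec.cytoplasm_sd, mask.shape)

        if cls == "diffuse":
            omega = float("nan")
            n1 = n2 = 0
        else:
            bright_right = bool(rng.integers(0, 2))
            bright_tip = tip_right if bright_right else tip_left
            dim_tip = tip_left if bright_right else tip_right
            if cls == "unipolar":
                omega = 1.0
                s1 = spec.cluster_size_px
                v1 = spec.cytoplasm_mean * spec.cluster_intensity_factor
                pix1 = _tip_pixels(mask, bright_tip, s1)
                cell_fluor[pix1[:, 0], pix1[:, 1]] = v1
                n1, n2 = s1, 0
            else:
                lo, hi = spec.omega_target_range[cls]
                omega = float(rng.uniform(lo, hi))
                s1, v1, s2, v2 = _cluster_design(omega, spec)
                pix1 = _tip_pixels(mask, bright_tip, s1)
                pix2 = _tip_pixels(mask, dim_tip, s2)
                if len(np.intersect1d(pix1[:, 0] * mask.shape[1] + pix1[:, 1],
                                      pix2[:, 0] * mask.shape[1] + pix2[:, 1])):
                    raise PlacementError("pole clusters overlap; cell too short "
                                         "for the requested asymmetry")
                cell_fluor[pix1[:, 0], pix1[:, 1]] = v1
                cell_fluor[pix2[:, 0], pix2[:, 1]] = v2
                n1, n2 = s1, s2

        sub = (slice(r0, r0 + W), slice(c0, c0 + L))
        labels[sub][mask] = i + 1
        fluor[sub][mask] = cell_fluor[mask]
        truth_rows.append({"cell_id": i + 1, "pattern": cls, "omega": omega,
                           "cluster_px_pole1": n1, "cluster_px_pole2": n2})

    if spec.noise_sd > 0:
        fluor = fluor + rng.normal(0.0, spec.noise_sd, shape)
        fluor = np.clip(fluor, 0.0, None)
    return labels, fluor, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class TrackSpec:
    """Moving rod cells with Poisson reversals and role-linked pole clusters.

    ``pole_fluorescence_rule`` maps the pole role to the cluster pixel
    intensity at that pole (<= 0 means no cluster); the default emulates a
    protein clustered at the lagging pole only. Pole fluorescence identities
    swap instantaneously at reversals (lag of 0 frames).
    """

    n_cells: int
    frame_interval_s: float = 30.0
    duration_s: float = 900.0
    speed_mean: float = 2.0            # px per interval
    speed_sd: float = 0.3
    reversal_rate: float = 0.1         # events per minute (Poisson)
    pole_fluorescence_rule: dict = field(
        default_factory=lambda: {"leading": 0.0, "lagging": 300.0})
    cell_length_px: int = 30
    cell_width_px: int = 8
    cytoplasm_mean: float = 100.0
    cytoplasm_sd: float = 5.0
    cluster_size_px: int = 4
    noise_sd: float = 0.0
    seed: int = 0
    margin_px: int = 6

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.frame_interval_s <= 0 or self.duration_s <= 0:
            raise ValueError("frame_interval_s and duration_s must be positive")
        if self.reversal_rate < 0:
            raise ValueError("reversal_rate must be >= 0")
        if set(self.pole_fluorescence_rule) != {"leading", "lagging"}:
            raise ValueError("pole_fluorescence_rule must map 'leading' and 'lagging'")


def gen_timelapse(spec: TrackSpec
                  ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, dict[int, list[int]]]:
    """Time-lapse of cells gliding along their long axis in separate lanes.

    Returns (fluorescence stack, label stack, per-frame ground truth, true
    reversal frames per cell). The ground-truth table carries the exact
    centroid, outgoing direction (+1 toward increasing x / pole b) and the
    raw Poisson event count per cell; ``reversal_frames`` lists, per cell,
    the first frame moving in each new direction.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration_s / spec.frame_interval_s)) + 1
    n_int = n_frames - 1
    L, W, m = spec.cell_length_px, spec.cell_width_px, spec.margin_px
    mask = _rod_mask(L, W)

    dirs = np.empty((spec.n_cells, n_int), dtype=int)
    xs = np.zeros((spec.n_cells, n_frames))
    reversal_frames: dict[int, list[int]] = {}
    raw_event_counts = {}
    for c in range(spec.n_cells):
        d = 1 if rng.integers(0, 2) else -1
        # Poisson reversal process: exponential interarrival times
        events = []
        if spec.reversal_rate > 0:
            t = rng.exponential(60.0 / spec.reversal_rate)
            while t < spec.duration_s:
                events.append(t)
                t += rng.exponential(60.0 / spec.reversal_rate)
        raw_event_counts[c + 1] = len(events)
        flips = np.zeros(n_int, dtype=int)
        for t in events:
            k = min(n_int - 1, int(t // spec.frame_interval_s) + 1)
            flips[k] += 1
        seq = []
        for k in range(n_int):
            if flips[k] % 2:
                d = -d
            seq.append(d)
        dirs[c] = seq
        speeds = np.abs(rng.normal(spec.speed_mean, spec.speed_sd, n_int)) \
            if spec.speed_sd > 0 else np.full(n_int, spec.speed_mean)
        xs[c, 1:] = np.cumsum(dirs[c] * speeds)
        reversal_frames[c + 1] = [k for k in range(1, n_int)
                                  if dirs[c, k] != dirs[c, k - 1]]

    x_min, x_max = xs.min(), xs.max()
    width = int(math.ceil(x_max - x_min)) + L + 4 * m
    height = spec.n_cells * (W + 2 * m) + m
    x_off = 2 * m - x_min

    fluor = np.zeros((n_frames, height, width))
    labels = np.zeros((n_frames, height, width), dtype=np.uint16)
    truth_rows = []
    rule = spec.pole_fluorescence_rule
    tip_left, tip_right = (W / 2.0, 0.5), (W / 2.0, L - 0.5)

    cyto = spec.cytoplasm_mean + rng.normal(
        0.0, spec.cytoplasm_sd, (spec.n_cells, W, L)) if spec.cytoplasm_sd > 0 \
        else np.full((spec.n_cells, W, L), spec.cytoplasm_mean)

    for f in range(n_frames):
        for c in range(spec.n_cells):
            r0 = m + c * (W + 2 * m)
            c0 = int(round(xs[c, f] + x_off))
            d = dirs[c, f] if f < n_int else dirs[c, n_int - 1]
            lead_tip, lag_tip = (tip_right, tip_left) if d > 0 else (tip_left, tip_right)
            cell = cyto[c].copy()
            f_lead = f_lag = 0.0
            if rule["leading"] > 0:
                pix = _tip_pixels(mask, lead_tip, spec.cluster_size_px)
                cell[pix[:, 0], pix[:, 1]] = rule["leading"]
                f_lead = rule["leading"] * spec.cluster_size_px
            if rule["lagging"] > 0:
                pix = _tip_pixels(mask, lag_tip, spec.cluster_size_px)
                cell[pix[:, 0], pix[:, 1]] = rule["lagging"]
                f_lag = rule["lagging"] * spec.cluster_size_px
            sub = (slice(r0, r0 + W), slice(c0, c0 + L))
            labels[f][sub][mask] = c + 1
            fluor[f][sub][mask] = cell[mask]
            truth_rows.append({
                "cell_id": c + 1, "frame": f,
                "x": xs[c, f] + x_off + L / 2.0, "y": r0 + W / 2.0,
                "direction": int(d), "f_leading": f_lead, "f_lagging": f_lag,
                "raw_event_count": raw_event_counts[c + 1],
            })

    if spec.noise_sd > 0:
        fluor = np.clip(fluor + rng.normal(0.0, spec.noise_sd, fluor.shape), 0.0, None)
    return fluor, labels, pd.DataFrame(truth_rows), reversal_frames


@dataclass(frozen=True)
class CoupledAssaySpec:
    """Regenerative coupled GTPase assay trace with known turnover.

    A340(t) = a340_start - turnover-implied NADH consumption * epsilon * l
    - background_rate * t + noise, with ideal 1:1 NADH-per-GTP coupling.
    """

    enzyme_conc: float                  # µM
    true_turnover: float                # GTP per enzyme per hour
    epsilon_340: float = 6220.0         # M^-1 cm^-1
    path_length: float = 0.5            # cm
    a340_start: float = 0.8
    duration_s: float = 3600.0
    sample_interval_s: float = 15.0
    noise_sd: float = 0.0
    background_rate: float = 0.0        # absorbance per second
    seed: int = 0
    condition: str = ""
    replicate: int = 0

    def __post_init__(self):
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be positive")
        if self.true_turnover < 0:
            raise ValueError("true_turnover must be >= 0")
        drop = (self._signal_slope() + self.background_rate) * self.duration_s
        if self.a340_start - drop < 0:
            raise ValueError("parameters drive A340 below 0 within the run")

    def _signal_slope(self) -> float:
        # A340 decline per second due to GTP hydrolysis (1 NADH per GTP)
        nadh_M_per_s = self.true_turnover * self.enzyme_conc * 1e-6 / 3600.0
        return nadh_M_per_s * self.epsilon_340 * self.path_length


def gen_coupled_trace(spec: CoupledAssaySpec) -> AbsorbanceTrace:
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.duration_s + spec.sample_interval_s / 2,
                      spec.sample_interval_s)
    a340 = spec.a340_start - (spec._signal_slope() + spec.background_rate) * times
    if spec.noise_sd > 0:
        a340 = a340 + rng.normal(0.0, spec.noise_sd, times.shape)
    return AbsorbanceTrace(times=times, a340=a340, condition=spec.condition,
                           replicate=spec.replicate)


@dataclass(frozen=True)
class MalachitePlateSpec:
    """Malachite-green endpoint plate with a known linear response."""

    standard_concs: tuple = (0.0, 5.0, 10.0, 25.0, 50.0, 100.0)   # Pi µM
    true_slope: float = 0.01            # A590 per µM Pi
    true_intercept: float = 0.05
    sample_true_pi: tuple = ()          # µM
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        concs = np.asarray(self.standard_concs, dtype=float)
        if len(concs) < 2 or not np.all(np.diff(concs) > 0) or concs[0] != 0.0:
            raise ValueError("standard_concs must be strictly increasing and include 0")
        if self.true_slope <= 0:
            raise ValueError("true_slope must be positive")


def gen_malachite_plate(spec: MalachitePlateSpec
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standards and samples tables; the samples table carries the true Pi."""
    rng = np.random.default_rng(spec.seed)
    concs = np.asarray(spec.standard_concs, dtype=float)
    a_std = spec.true_intercept + spec.true_slope * concs
    if spec.noise_sd > 0:
        a_std = a_std + rng.normal(0.0, spec.noise_sd, a_std.shape)
    standards = pd.DataFrame({
        "well": [f"S{i + 1}" for i in range(len(concs))],
        "pi_uM": concs, "a590": a_std})
    pis = np.asarray(spec.sample_true_pi, dtype=float)
    a_smp = spec.true_intercept + spec.true_slope * pis
    if spec.noise_sd > 0 and len(pis):
        a_smp = a_smp + rng.normal(0.0, spec.noise_sd, a_smp.shape)
    samples = pd.DataFrame({
        "well": [f"X{i + 1}" for i in range(len(pis))],
        "a590": a_smp, "pi_uM_true": pis})
    return standards, samples


@dataclass(frozen=True)
class PresenceAbsenceSpec:
    """Boolean genomes x genes matrix with controllable profile similarity.

    For each gene, every genome matches the reference gene's presence value
    with probability ``co_occurrence_prob`` (scalar or per-gene mapping) and
    takes the complementary value otherwise; the reference profile itself is
    Bernoulli(``reference_prevalence``).
    """

    n_genomes: int
    gene_names: tuple = ("romR", "romX", "romY", "mglA", "mglB")
    reference_gene: str = "romR"
    co_occurrence_prob: float | dict = 0.9
    reference_prevalence: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.reference_gene not in self.gene_names:
            raise ValueError("reference_gene must be among gene_names")
        probs = self._probs()
        if any(not 0 <= p <= 1 for p in probs.values()):
            raise ValueError("co_occurrence_prob values must be in [0, 1]")
        if not 0 <= self.reference_prevalence <= 1:
            raise ValueError("reference_prevalence must be in [0, 1]")

    def _probs(self) -> dict:
        if isinstance(self.co_occurrence_prob, dict):
            return {g: self.co_occurrence_prob.get(g, 1.0) for g in self.gene_names}
        return {g: float(self.co_occurrence_prob) for g in self.gene_names}


_TAXA = (
    ("Myxococcota", "Myxococcia", "Myxococcales"),
    ("Myxococcota", "Polyangia", "Polyangiales"),
    ("Pseudomonadota", "Deltaproteobacteria", "Bdellovibrionales"),
    ("Bacteroidota", "Cytophagia", "Cytophagales"),
    ("Bacillota", "Bacilli", "Bacillales"),
)


def gen_presence_absence(spec: PresenceAbsenceSpec) -> PresenceAbsenceMatrix:
    rng = np.random.default_rng(spec.seed)
    ref = rng.random(spec.n_genomes) < spec.reference_prevalence
    probs = spec._probs()
    cols = {}
    for g in spec.gene_names:
        if g == spec.reference_gene:
            cols[g] = ref.copy()
        else:
            match = rng.random(spec.n_genomes) < probs[g]
            cols[g] = np.where(match, ref, ~ref)
    genomes = pd.Index([f"G{i + 1:05d}" for i in range(spec.n_genomes)], name="genome")
    taxa = pd.DataFrame(
        [_TAXA[i % len(_TAXA)] for i in range(spec.n_genomes)],
        columns=["phylum", "class", "order"], index=genomes)
    return PresenceAbsenceMatrix(values=pd.DataFrame(cols, index=genomes), taxa=taxa)
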