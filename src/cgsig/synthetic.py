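"""Synthetic multiplexed-IHC cohorts with class-dependent spatial structure.

The generator emulates HALO-style per-cell tables from tumor micro-array
cores: Pan-CK-positive tumor cells clustered in Gaussian nests, immune cells
(CD8 / CD68 / Foxp3) placed at a class-dependent radial distance from the
nests, stromal cells uniform, and right-censored overall-survival times drawn
inside class-defined windows.  Prognostic classes differ through three
effect-size knobs: the immune-infiltration proximity scale (shorter-survival
classes keep immune cells far from tumor nests), a nucleus-morphology mean
shift, and a DAPI nucleus-intensity shift.  Setting all three to
class-constant values yields exchangeable classes (a null generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cell_table_io import CellTable, PatientRecord
from .schema import DEFAULT_SCHEMA, FeatureSchema

# survival windows (months) per class, chosen so labels are consistent with
# the 24/48-month binary and 12/60-month ternary binning thresholds
BINARY_WINDOWS = ((0.0, 23.5), (48.5, 88.0))
TERNARY_WINDOWS = ((0.0, 11.5), (12.5, 59.5), (60.5, 88.0))

_STAGES = ("IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IIIC")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults mirror a gastric-cancer TMA setting: 7,000-13,000 cells per
    3,000 px (1.5 mm at 0.5 µm/px) core image, two prognostic classes of
    equal prevalence, and strong spatial/morphological class effects.
    """

    n_patients: int = 60
    cells_per_image: tuple[int, int] = (7000, 13000)
    image_side: float = 3000.0
    class_proportions: tuple[float, ...] = (0.5, 0.5)
    n_nests: int = 5
    nest_radius: float = 150.0
    proximity_scale: tuple[float, ...] = (240.0, 30.0)
    morph_shift: tuple[float, ...] = (0.6, 0.0)
    intensity_shift: tuple[float, ...] = (0.35, 0.0)
    noise_sd: float = 0.08
    censoring_rate: float = 0.2
    tumor_frac: float = 0.40
    cd8_frac: float = 0.12
    cd68_frac: float = 0.08
    foxp3_frac: float = 0.05
    nest_centers: tuple[tuple[float, float], ...] | None = None
    survival_windows: tuple[tuple[float, float], ...] | None = None
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.class_proportions)

    def windows(self) -> tuple[tuple[float, float], ...]:
        if self.survival_windows is not None:
            return self.survival_windows
        if self.n_classes == 2:
            return BINARY_WINDOWS
        if self.n_classes == 3:
            return TERNARY_WINDOWS
        raise ValueError("survival_windows must be given for n_classes not in {2,3}")

    def validate(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if min(self.class_proportions) < 0:
            raise ValueError("class proportions must be non-negative")
        if self.n_patients <= 0 or self.n_nests <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.cells_per_image
        if lo <= 0 or hi < lo:
            raise ValueError("cells_per_image must be a positive range")
        # ~4 px^2 per cell is an upper packing bound for nucleated cells
        if self.image_side**2 < 4 * hi:
            raise ValueError("image_side too small for the requested cell count")
        for name in ("proximity_scale", "morph_shift", "intensity_shift"):
            if len(getattr(self, name)) != self.n_classes:
                raise ValueError(f"{name} needs one value per class")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")
        if len(self.windows()) != self.n_classes:
            raise ValueError("one survival window per class required")


@dataclass
class SyntheticCohort:
    tables: list[CellTable]
    patients: list[PatientRecord]
    true_labels: dict[str, int]
    config: SimulationConfig = field(repr=False, default=None)


def _clipped_normal(rng, mean, sd, size, low=0.0):
    return np.clip(rng.normal(mean, sd, size), low, None)


def generate_image(
    config: SimulationConfig,
    class_label: int,
    rng: np.random.Generator,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    return_info: bool = False,
):
    """Generate one synthetic cell table for a patient of the given class.

    Returns the :class:`CellTable`, and with ``return_info=True`` also a dict
    holding nest centers and the per-cell type codes (0 tumor, 1 CD8, 2 CD68,
    3 Foxp3, 4 stromal) for downstream verification.
    """
    config.validate()
    side = config.image_side
    n = int(rng.integers(config.cells_per_image[0], config.cells_per_image[1] + 1))

    if config.nest_centers is not None:
        centers = np.asarray(config.nest_centers, dtype=float)
    else:
        centers = rng.uniform(0.15 * side, 0.85 * side, size=(config.n_nests, 2))

    fracs = np.array(
        [config.tumor_frac, config.cd8_frac, config.cd68_frac, config.foxp3_frac]
    )
    if fracs.sum() > 1.0:
        raise ValueError("cell-type fractions exceed 1")
    counts = np.floor(fracs * n).astype(int)
    n_stromal = n - counts.sum()
    cell_type = np.repeat(np.arange(5), np.append(counts, n_stromal))

    coords = np.empty((n, 2))
    # tumor cells: Gaussian nests
    tumor = cell_type == 0
    which = rng.integers(0, len(centers), tumor.sum())
    coords[tumor] = centers[which] + rng.normal(
        0.0, config.nest_radius / 2.0, (tumor.sum(), 2)
    )
    # immune cells: radial placement beyond the nest boundary at the
    # class-specific proximity scale (exponential radial offset)
    immune = (cell_type >= 1) & (cell_type <= 3)
    n_imm = int(immune.sum())
    which = rng.integers(0, len(centers), n_imm)
    theta = rng.uniform(0.0, 2.0 * np.pi, n_imm)
    radial = config.nest_radius + rng.exponential(
        config.proximity_scale[class_label], n_imm
    )
    coords[immune] = centers[which] + radial[:, None] * np.column_stack(
        [np.cos(theta), np.sin(theta)]
    )
    # stromal cells: uniform background
    coords[cell_type == 4] = rng.uniform(0.0, side, (n_stromal, 2))
    np.clip(coords, 0.0, side - 1.0, out=coords)

    feats = np.zeros((n, schema.n_features))
    col = schema.feature_index
    noise = config.noise_sd

    marker_of_type = {1: "cd8", 2: "cd68", 3: "foxp3"}
    positive = {m: np.zeros(n, dtype=bool) for m in schema.biomarkers}
    positive["dapi"][:] = True
    positive["panck"] = tumor
    for tcode, marker in marker_of_type.items():
        positive[marker] = cell_type == tcode
    # PD-L1 expression concentrates on tumor and macrophages
    p_pdl1 = np.where(tumor | (cell_type == 2), 0.15, 0.03)
    positive["pdl1"] = rng.random(n) < p_pdl1

    for marker in schema.biomarkers:
        pos = positive[marker]
        feats[:, col(f"{marker}_positive")] = pos
        feats[:, col(f"{marker}_positive_nucleus")] = pos & (rng.random(n) < 0.85)
        feats[:, col(f"{marker}_positive_cytoplasm")] = pos & (rng.random(n) < 0.90)
        nuc = np.where(pos, 0.70, 0.15)
        cyt = np.where(pos, 0.60, 0.10)
        feats[:, col(f"{marker}_nucleus_intensity")] = _clipped_normal(
            rng, nuc, noise, n
        )
        feats[:, col(f"{marker}_cytoplasm_intensity")] = _clipped_normal(
            rng, cyt, noise, n
        )
    # class effect on the nuclear counterstain
    feats[:, col("dapi_nucleus_intensity")] = _clipped_normal(
        rng, 0.45 + config.intensity_shift[class_label], noise, n
    )

    shift = config.morph_shift[class_label]
    tumor_bump = np.where(tumor, 1.0, 0.0)  # tumor cells run larger
    morph = {
        "cell_area": (120.0, 20.0),
        "cytoplasm_area": (70.0, 15.0),
        "nucleus_area": (50.0, 10.0),
        "nucleus_perimeter": (25.0, 4.0),
        "nucleus_roundness": (0.85, 0.05),
    }
    for name, (mu, sd) in morph.items():
        class_mu = mu + shift * sd + tumor_bump * sd
        if name == "nucleus_roundness":
            feats[:, col(name)] = np.clip(rng.normal(class_mu, sd, n), 0.0, 1.0)
        else:
            feats[:, col(name)] = _clipped_normal(rng, class_mu, sd, n)

    table = CellTable("unknown", coords, feats, schema)
    if return_info:
        return table, {"nest_centers": centers, "cell_type": cell_type}
    return table


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full cohort: one image per patient plus survival outcomes."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    windows = config.windows()
    tables, patients, labels = [], [], {}
    classes = rng.choice(config.n_classes, size=config.n_patients,
                         p=np.asarray(config.class_proportions))
    for i, cls in enumerate(classes):
        pid = f"P{i + 1:04d}"
        table = generate_image(config, int(cls), rng)
        table.patient_id = pid
        lo, hi = windows[cls]
        os_months = float(rng.uniform(lo, hi))
        event = int(rng.random() >= config.censoring_rate)
        stage = _draw_stage(rng, int(cls), config.n_classes)
        tables.append(table)
        patients.append(PatientRecord(pid, os_months, event, stage))
        labels[pid] = int(cls)
    return SyntheticCohort(tables, patients, labels, config)


def _draw_stage(rng: np.random.Generator, cls: int, n_classes: int) -> str:
    """TNM stage loosely anti-correlated with the survival class."""
    w = np.linspace(2.0, 0.5, len(_STAGES)) if cls == n_classes - 1 else (
        np.linspace(0.5, 2.0, len(_STAGES)) if cls == 0
        else np.ones(len(_STAGES)))
    return str(rng.choice(_STAGES, p=w / w.sum()))


def acceptance_cohort_config(seed: int = 0, n_patients: int = 60) -> SimulationConfig:
    """Scaled-down cohort preset used for end-to-end evaluation runs.

    Keeps the default strong class effects but shrinks each core to
    ~1,100-1,400 cells on a 1,200 px field so that the whole
    simulate-build-train-evaluate chain runs in minutes on one CPU.
    """
    return replace(
        SimulationConfig(),
        n_patients=n_patients,
        cells_per_image=(1100, 1400),
        image_side=1200.0,
        seed=seed,
    )


def simulate_two_group_survival(
    n: int,
    hazard_ratio: float,
    censoring_rate: float,
    rng: np.random.Generator,
    baseline_scale: float = 40.0,
):
    """Exponential two-group survival data with a known hazard ratio.

    Group 1 hazard = ``hazard_ratio`` x group 0 hazard; independent
    exponential censoring calibrated so roughly ``censoring_rate`` of
    subjects are censored.  Returns (times, events, group).
    """
    group = rng.integers(0, 2, n)
    lam = (1.0 / baseline_scale) * np.where(group == 1, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / lam)
    if censoring_rate <= 0:
        return t_event, np.ones(n, dtype=int), group
    # P(censored | lam_i) = lam_c / (lam_c + lam_i); bisect for the mean rate
    lo, hi = 1e-9, 1e3
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(mid / (mid + lam)) < censoring_rate:
            lo = mid
        else:
            hi = mid
    t_cens = rng.exponential(1.0 / lo, n)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    return times, events, group
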