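"""Synthetic study generator with known ground truth.

Every input the analysis pipeline consumes can be produced here: multi-slice
tensor phantoms emulating a rodent brain slab with hippocampal subfields
(CA1, CA2/3, DG/hilus on each hemisphere), striatum, cortex and — for
stroke conditions — an infarct; noisy diffusion-weighted stacks under the
mono-exponential tensor model with Rician magnitude noise; fluorescence
fields with seeded glial-marker blobs; and behavioral score tables.

Condition semantics (the study design being emulated):

* ``intact`` / ``sham`` / ``KO_sham`` — baseline tissue everywhere.
* ``MCAO`` — infarct present with elevated MD (default ×1.5 of cortex) and
  reduced MD in the ipsilateral CA2/3 (default ×0.90), the signature of
  glial hypertrophy after stroke.
* ``KO_MCAO`` — infarct present, but the hippocampal MD effect is absent
  (multiplier 1.0): the knockout abolishes the neuroinflammatory response
  while leaving the infarct itself untouched.

Defaults are chosen to be desk-scale yet realistic for fixed ex-vivo
tissue: baseline MD around 3e-4 mm²/s (within the conventional 0–5e-4
display window), SNR 30 on the b=0 signal, 3% between-subject coefficient
of variation on region MDs.  All randomness flows from explicit integer
seeds through ``numpy.random.SeedSequence`` so identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ihc_quant import IHCField
from .image_io import (
    DWIStack,
    GradientTable,
    ImageGrid,
    LabelMap,
    ScalarMap,
    default_gradient_table,
)
from .tensor_fit import TensorVolume, matrices_to_tensor_elements, tensor_elements_to_matrices

__all__ = [
    "PhantomSpec",
    "Subject",
    "CONDITIONS",
    "HIPPOCAMPAL_REGIONS",
    "make_phantom",
    "simulate_dwi",
    "simulate_cohort",
    "simulate_ihc_field",
    "simulate_ihc_cohort",
    "simulate_behavior",
]

CONDITIONS = ("intact", "sham", "MCAO", "KO_sham", "KO_MCAO")
INFARCT_CONDITIONS = ("MCAO", "KO_MCAO")
HIPPOCAMPAL_REGIONS = ("DG_hilus", "hippocampus_CA23", "hippocampus_CA1")

#: baseline region mean diffusivities, mm^2/s (fixed ex-vivo tissue scale)
DEFAULT_REGION_MD = {
    "cortex": 3.2e-4,
    "striatum_ipsi": 3.1e-4,
    "striatum_contra": 3.1e-4,
    "hippocampus_CA1_ipsi": 3.0e-4,
    "hippocampus_CA1_contra": 3.0e-4,
    "hippocampus_CA23_ipsi": 3.0e-4,
    "hippocampus_CA23_contra": 3.0e-4,
    "DG_hilus_ipsi": 2.9e-4,
    "DG_hilus_contra": 2.9e-4,
    "infarct": 3.2e-4,  # base; the infarct multiplier is applied on top
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject.

    ``region_md`` maps region name to baseline MD (mm²/s); ``region_fa``
    optionally assigns a fractional anisotropy (axially symmetric tensor
    along ``principal_direction``) to a region, default isotropic.
    ``infarct_multiplier`` (> 1) scales infarct MD in stroke conditions;
    ``ca23_multiplier`` (< 1 for wild-type stroke) scales the ipsilateral
    CA2/3 MD under ``MCAO``; under ``KO_MCAO`` the knockout multiplier
    (default 1.0) is used instead.
    """

    grid: ImageGrid = field(default_factory=lambda: ImageGrid((64, 64, 5)))
    condition: str = "intact"
    region_md: dict = field(default_factory=lambda: dict(DEFAULT_REGION_MD))
    region_fa: dict = field(default_factory=dict)
    principal_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    infarct_multiplier: float = 1.5
    ca23_multiplier: float = 0.90
    ko_ca23_multiplier: float = 1.0
    table: GradientTable = field(default_factory=default_gradient_table)
    s0: float = 1000.0
    snr: float | None = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if any(v <= 0 for v in self.region_md.values()):
            raise ValueError("all baseline MDs must be > 0")
        if self.infarct_multiplier <= 0 or self.ca23_multiplier <= 0:
            raise ValueError("multipliers must be > 0")
        if self.s0 <= 0:
            raise ValueError("S0 must be > 0")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("SNR must be > 0 (or None for noiseless)")


@dataclass
class Subject:
    """One simulated subject: raw data plus the ground truth it was built
    from."""

    subject_id: str
    condition: str
    stack: DWIStack
    labels: LabelMap
    truth_md: ScalarMap
    truth_tensors: TensorVolume


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

def _region_masks(grid: ImageGrid, condition: str) -> dict[str, np.ndarray]:
    """Deterministic 2D region geometry, replicated across slices.

    The ipsilateral hemisphere is x < nx/2.  Specialized regions are carved
    out of a cortical ellipse; an overlap between two specialized regions is
    a configuration error.
    """
    nx, ny, _ = grid.shape
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = nx / 2.0, ny / 2.0
    brain = ((x - cx) / (0.45 * nx)) ** 2 + ((y - cy) / (0.42 * ny)) ** 2 <= 1.0

    def band(x0, x1, y0, y1):
        return (
            (x >= x0 * nx) & (x < x1 * nx) & (y >= y0 * ny) & (y < y1 * ny) & brain
        )

    masks: dict[str, np.ndarray] = {}
    # hippocampal subfields: mirrored triplets of bands (lateral→medial:
    # CA1, CA2/3, DG/hilus)
    masks["hippocampus_CA1_ipsi"] = band(0.15, 0.25, 0.25, 0.40)
    masks["hippocampus_CA23_ipsi"] = band(0.25, 0.35, 0.25, 0.40)
    masks["DG_hilus_ipsi"] = band(0.35, 0.45, 0.25, 0.40)
    masks["DG_hilus_contra"] = band(0.55, 0.65, 0.25, 0.40)
    masks["hippocampus_CA23_contra"] = band(0.65, 0.75, 0.25, 0.40)
    masks["hippocampus_CA1_contra"] = band(0.75, 0.85, 0.25, 0.40)
    masks["striatum_ipsi"] = band(0.18, 0.32, 0.55, 0.75)
    masks["striatum_contra"] = band(0.68, 0.82, 0.55, 0.75)
    if condition in INFARCT_CONDITIONS:
        masks["infarct"] = (
            ((x - 0.13 * nx) ** 2 + (y - 0.50 * ny) ** 2 <= (0.055 * nx) ** 2) & brain
        )

    taken = np.zeros((nx, ny), dtype=bool)
    for name, m in masks.items():
        if np.any(m & taken):
            raise ValueError(f"region geometry conflict: {name!r} overlaps another region")
        taken |= m
    masks["cortex"] = brain & ~taken
    return masks


def _condition_multipliers(spec: PhantomSpec) -> dict[str, float]:
    mult = {name: 1.0 for name in spec.region_md}
    if spec.condition in INFARCT_CONDITIONS:
        mult["infarct"] = spec.infarct_multiplier
    if spec.condition == "MCAO":
        mult["hippocampus_CA23_ipsi"] = spec.ca23_multiplier
    elif spec.condition == "KO_MCAO":
        mult["hippocampus_CA23_ipsi"] = spec.ko_ca23_multiplier
    return mult


def _axisymmetric_tensor(md: float, fa: float, direction) -> np.ndarray:
    """Axially symmetric tensor with given MD and FA along ``direction``."""
    e = np.asarray(direction, dtype=float)
    e = e / np.linalg.norm(e)
    if not 0.0 <= fa < 1.0:
        raise ValueError(f"FA must be in [0, 1), got {fa}")
    # λ1 = MD(1+2δ), λ2 = λ3 = MD(1-δ) gives FA = 3δ/sqrt(3+6δ²)
    delta = fa / np.sqrt(3.0 - 2.0 * fa**2)
    lam_par = md * (1.0 + 2.0 * delta)
    lam_perp = md * (1.0 - delta)
    return lam_perp * np.eye(3) + (lam_par - lam_perp) * np.outer(e, e)


def make_phantom(spec: PhantomSpec) -> tuple[LabelMap, TensorVolume, ScalarMap]:
    """Build the label map, ground-truth tensor volume and truth MD map.

    Fully deterministic given the spec (including its seed).  Every legend
    region occupies at least 20 voxels; the truth MD map equals each
    region's baseline MD times its condition multiplier.
    """
    grid = spec.grid
    masks2d = _region_masks(grid, spec.condition)
    mult = _condition_multipliers(spec)

    legend = {name: i + 1 for i, name in enumerate(sorted(masks2d))}
    labels = np.zeros(grid.shape, dtype=np.int32)
    md_truth = np.full(grid.shape, np.nan)
    d = np.zeros(grid.shape + (6,), dtype=float)
    mask = np.zeros(grid.shape, dtype=bool)

    nz = grid.shape[2]
    for name, m2d in masks2d.items():
        n_vox = int(m2d.sum()) * nz
        if n_vox < 20:
            raise ValueError(f"region {name!r} occupies only {n_vox} voxels (< 20)")
        md = spec.region_md[name] * mult.get(name, 1.0)
        fa = float(spec.region_fa.get(name, 0.0))
        tensor = _axisymmetric_tensor(md, fa, spec.principal_direction)
        elems = matrices_to_tensor_elements(tensor)
        m3d = np.repeat(m2d[:, :, None], nz, axis=2)
        labels[m3d] = legend[name]
        md_truth[m3d] = md
        d[m3d] = elems
        mask |= m3d

    lm = LabelMap(grid, labels, legend)
    tv = TensorVolume(
        grid=grid,
        d=d,
        ln_s0=np.where(mask, np.log(spec.s0), 0.0),
        residual_rms=np.zeros(grid.shape),
        mask=mask,
    )
    truth_md = ScalarMap(grid, md_truth, name="MD", units="mm^2/s")
    return lm, tv, truth_md


# ---------------------------------------------------------------------------
# DWI simulation
# ---------------------------------------------------------------------------

def simulate_dwi(
    truth: TensorVolume,
    table: GradientTable | None = None,
    s0: float = 1000.0,
    snr: float | None = 30.0,
    seed: int = 0,
    noise: str = "rician",
) -> DWIStack:
    """Forward-simulate a DWI stack from a ground-truth tensor volume.

    Noiseless signal: ``S_i = S0 * exp(-b_i g_i^T D g_i)`` (zero outside
    the tissue mask).  With finite ``snr``, noise of scale
    ``sigma = S0 / snr`` is added — Rician by default (the magnitude of the
    complex signal with i.i.d. Gaussian parts, the physically appropriate
    model for magnitude MR images), or plain Gaussian (clipped at 0) for
    debugging.  ``snr=None`` disables noise.
    """
    if table is None:
        table = default_gradient_table()
    if noise not in ("rician", "gaussian"):
        raise ValueError("noise must be 'rician' or 'gaussian'")
    mats = truth.as_matrices()  # (..., 3, 3)
    g = table.bvecs  # (m, 3)
    b = table.bvals
    # adc per voxel per measurement: g_i^T D g_i
    adc = np.einsum("mi,...ij,mj->...m", g, mats, g)
    signal = s0 * np.exp(-b * adc)
    signal[~truth.mask] = 0.0
    if snr is not None and np.isfinite(snr):
        sigma = s0 / snr
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        if noise == "rician":
            e1 = rng.normal(0.0, sigma, signal.shape)
            e2 = rng.normal(0.0, sigma, signal.shape)
            signal = np.sqrt((signal + e1) ** 2 + e2**2)
        else:
            signal = np.clip(signal + rng.normal(0.0, sigma, signal.shape), 0.0, None)
    return DWIStack(truth.grid, table, signal)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(
    n_per_group: dict[str, int],
    template: PhantomSpec | None = None,
    base_seed: int = 0,
    between_subject_cv: float = 0.03,
) -> list[Subject]:
    """Simulate a cohort: ``n_per_group`` maps condition to subject count.

    Each subject gets a deterministic child seed of ``base_seed``, a
    subject-specific multiplicative jitter on every region MD (normal with
    the given coefficient of variation; 0 disables it), and an independent
    noise realization.  Ground truth travels with each subject.
    """
    if template is None:
        template = PhantomSpec()
    for cond, n in n_per_group.items():
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r}")
        if n < 1:
            raise ValueError(f"count for {cond!r} must be >= 1")
    total = sum(n_per_group.values())
    children = np.random.SeedSequence(base_seed).spawn(total)
    subjects: list[Subject] = []
    i = 0
    # canonical (sorted) condition order: output independent of dict order
    for cond in sorted(n_per_group):
        for j in range(n_per_group[cond]):
            ss = children[i]
            rng = np.random.default_rng(ss)
            jitter = {
                name: md * max(float(rng.normal(1.0, between_subject_cv)), 0.1)
                for name, md in template.region_md.items()
            } if between_subject_cv > 0 else dict(template.region_md)
            spec = replace(template, condition=cond, region_md=jitter)
            lm, tv, truth_md = make_phantom(spec)
            noise_seed = int(ss.generate_state(1, np.uint32)[0] % (2**31))
            stack = simulate_dwi(
                tv, spec.table, s0=spec.s0, snr=spec.snr, seed=noise_seed
            )
            subjects.append(
                Subject(f"{cond}_{j:02d}", cond, stack, lm, truth_md, tv)
            )
            i += 1
    return subjects


# ---------------------------------------------------------------------------
# fluorescence fields
# ---------------------------------------------------------------------------

#: baseline glial blob density, blobs per mm^2, per marker
DEFAULT_IHC_DENSITY = {"GFAP": 120.0, "Iba1": 120.0}
#: density multiplier in the affected region for wild-type stroke groups
DEFAULT_IHC_EFFECT = 2.0


def _ihc_density(group: str, region: str, base: float, effect: float) -> float:
    """Group × region density rule: wild-type stroke doubles glial density
    in CA2/3; the knockout stroke group stays at baseline."""
    if region == "hippocampus_CA23" and group in ("MCAO", "WT-MCAO"):
        return base * effect
    return base


def simulate_ihc_field(
    region: str = "hippocampus_CA23",
    group: str = "sham",
    density_per_marker: dict[str, float] | None = None,
    blob_radius_um: tuple[float, float] = (6.0, 1.5),
    pixel_size_um: float = 1.5,
    field_shape: tuple[int, int] = (400, 400),
    seed: int = 0,
    subject_id: str = "",
    effect_multiplier: float = DEFAULT_IHC_EFFECT,
    background: tuple[float, float] = (10.0, 2.0),
    foreground: tuple[float, float] = (200.0, 10.0),
) -> tuple[IHCField, dict[str, float]]:
    """One synthetic fluorescence field plus its exact truth coverage.

    Marker blobs (disks with normally distributed radius, mean/sd in µm)
    are dropped by a seeded Poisson process at the group- and
    region-dependent density; pixel intensities are background plus bright
    blob populations.  Returns the field and, per marker, the exact
    rasterized percent coverage of the blob union.  A configuration whose
    truth coverage exceeds 95% raises (almost certainly a misconfiguration).
    """
    h, w = field_shape
    area_mm2 = h * w * (pixel_size_um * 1e-3) ** 2
    if area_mm2 < 0.28:
        raise ValueError(
            f"field area {area_mm2:.3f} mm^2 is below the 0.28 mm^2 reporting minimum"
        )
    if density_per_marker is None:
        density_per_marker = dict(DEFAULT_IHC_DENSITY)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    yy, xx = np.mgrid[0:h, 0:w]
    channels: dict[str, np.ndarray] = {}
    truth: dict[str, float] = {}
    for marker, base_density in density_per_marker.items():
        density = _ihc_density(group, region, base_density, effect_multiplier)
        n_blobs = rng.poisson(density * area_mm2)
        mask = np.zeros((h, w), dtype=bool)
        for _ in range(n_blobs):
            cy_, cx_ = rng.uniform(0, h), rng.uniform(0, w)
            r_um = max(float(rng.normal(*blob_radius_um)), 1.0)
            r_px = r_um / pixel_size_um
            mask |= (yy - cy_) ** 2 + (xx - cx_) ** 2 <= r_px**2
        coverage = 100.0 * mask.sum() / mask.size
        if coverage > 95.0:
            raise ValueError(
                f"truth coverage {coverage:.1f}% > 95% for {marker}; "
                "density is likely misconfigured"
            )
        img = rng.normal(*background, (h, w))
        img[mask] = rng.normal(*foreground, int(mask.sum()))
        channels[marker] = np.clip(img, 0.0, None)
        truth[marker] = coverage
    # DAPI: sparse nuclei, carried for diagnostics but unused in coverage
    dapi = rng.normal(*background, (h, w))
    n_nuclei = rng.poisson(50 * area_mm2)
    for _ in range(n_nuclei):
        cy_, cx_ = rng.uniform(0, h), rng.uniform(0, w)
        dapi[(yy - cy_) ** 2 + (xx - cx_) ** 2 <= (3.0 / pixel_size_um) ** 2] = 150.0
    channels["DAPI"] = np.clip(dapi, 0.0, None)
    fld = IHCField(
        channels, pixel_size_um, region=region, subject_id=subject_id, group=group
    )
    return fld, truth


def simulate_ihc_cohort(
    n_per_group: dict[str, int],
    regions=HIPPOCAMPAL_REGIONS,
    base_seed: int = 0,
    **field_kwargs,
) -> tuple[list[IHCField], pd.DataFrame]:
    """Fields for every subject × region, with a truth-coverage table."""
    total = sum(n_per_group.values()) * len(regions)
    children = np.random.SeedSequence(base_seed).spawn(total)
    fields: list[IHCField] = []
    rows = []
    i = 0
    for group in sorted(n_per_group):
        n = n_per_group[group]
        for j in range(n):
            sid = f"{group}_{j:02d}"
            for region in regions:
                seed = int(children[i].generate_state(1, np.uint32)[0] % (2**31))
                fld, truth = simulate_ihc_field(
                    region=region, group=group, seed=seed, subject_id=sid, **field_kwargs
                )
                fields.append(fld)
                for marker, cov in truth.items():
                    rows.append((sid, group, region, marker, cov))
                i += 1
    truth_df = pd.DataFrame(
        rows, columns=["subject_id", "group", "region", "marker", "truth_coverage"]
    )
    return fields, truth_df


# ---------------------------------------------------------------------------
# behavior tables
# ---------------------------------------------------------------------------

def simulate_behavior(
    group_effects: dict[str, tuple[float, float]],
    n_per_group: dict[str, int],
    noise_sd: tuple[float, float] = (8.0, 1.5),
    seed: int = 0,
    day: int = 7,
) -> pd.DataFrame:
    """Behavioral score table: freezing percent (0–100) and 21-point
    neurological score per subject.

    ``group_effects`` maps group name to (freezing mean, neuro-score mean);
    draws are normal with the given SDs, clipped to the valid ranges
    (scores rounded to integers).  Out-of-range means are rejected.
    """
    for g, (fm, nm) in group_effects.items():
        if not 0.0 <= fm <= 100.0:
            raise ValueError(f"group {g!r}: freezing mean {fm} outside [0, 100]")
        if not 0.0 <= nm <= 21.0:
            raise ValueError(f"group {g!r}: neuro-score mean {nm} outside [0, 21]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for g in sorted(n_per_group):
        n = n_per_group[g]
        fm, nm = group_effects[g]
        for j in range(n):
            freezing = float(np.clip(rng.normal(fm, noise_sd[0]), 0.0, 100.0))
            neuro = int(np.clip(round(rng.normal(nm, noise_sd[1])), 0, 21))
            rows.append((f"{g}_{j:02d}", g, freezing, neuro, day))
    return pd.DataFrame(
        rows, columns=["subject", "group", "freezing_percent", "neuro_score", "day"]
    )
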