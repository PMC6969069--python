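"""Seeded synthetic-data generators for the CIN analysis pipeline.

Four generators produce every input the downstream stages consume, each with
the statistical structure the analysis assumes and with exact ground truth:

* :func:`generate_field` — fluorescence fields of Hoechst-like nuclei with a
  configurable micronucleus rate per cell, bright apoptotic/mitotic bodies
  and border-clipped nuclei, plus a per-object ground-truth table that acts
  as the geometric oracle for detection tests.
* :func:`generate_spread_set` — mitotic-spread populations with a modal
  chromosome count, a tetraploid-shifted subpopulation and per-spread
  cohesion-defect annotations.
* :func:`generate_cna_matrix` — gene x sample thresholded copy-number codes
  in the cBioPortal convention {-2, -1, 0, 1, 2}.
* :func:`generate_survival_cohort` — two-group survival cohorts where a
  hidden expression cutpoint multiplies the hazard of the low-expression
  group.

All generators are deterministic given their spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from scipy import optimize

from .io import FieldImage

GT_COLUMNS = [
    "object_id",
    "kind",
    "cx_um",
    "cy_um",
    "diameter_um",
    "mean_intensity",
    "owner_id",
    "border",
]

SPREAD_COLUMNS = [
    "spread_id",
    "condition",
    "replicate",
    "chromosome_count",
    "defective_chromosomes",
    "severity",
    "severe_spread",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping placement cannot be satisfied."""


# ---------------------------------------------------------------------------
# field specs and low-level rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic fluorescence field.

    Lengths are micrometres, intensities are arbitrary units on the 16-bit
    scale. Nuclei are ellipses with mildly random axis ratio; micronuclei are
    circles placed just outside the owner's nuclear boundary but inside its
    cell-body radius; apoptotic/mitotic cells are rendered as uniformly
    bright nucleus-sized bodies so the intensity filter is exercised.
    """

    image_size: tuple[int, int] = (1200, 1200)  # (H, W) pixels
    pixel_size: float = 0.323  # um/pixel (20x objective, 16-bit camera)
    n_cells: int = 100
    nucleus_diameter: tuple[float, float] = (15.0, 1.5)  # mean, sd (um)
    nucleus_axis_ratio: tuple[float, float] = (0.85, 1.0)  # minor/major range
    mn_rate: float = 0.02  # expected micronuclei per cell (Poisson)
    mn_diameter: tuple[float, float] = (2.5, 0.4)  # mean, sd (um)
    mn_diameter_range: tuple[float, float] = (1.5, 3.5)  # hard truncation (um)
    mn_offset: tuple[float, float] = (1.0, 6.0)  # um outside nuclear edge
    apoptotic_fraction: float = 0.0
    apoptotic_diameter: tuple[float, float] = (9.0, 0.8)
    apoptotic_intensity: float = 63000.0
    border_fraction: float = 0.0
    border_margin: float = 30.0  # um; defines the GT border flag
    background_intensity: tuple[float, float] = (3000.0, 150.0)  # mean, noise sd
    foreground_intensity: tuple[float, float] = (30000.0, 300.0)
    blur_sigma_px: float = 0.5  # edge softness of rendered objects
    max_retries: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("nucleus_diameter", "mn_diameter", "apoptotic_diameter"):
            mean, _sd = getattr(self, name)
            if mean <= 0:
                raise ValueError(f"{name} mean must be > 0")
        for name in ("apoptotic_fraction", "border_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mn_rate < 0:
            raise ValueError("mn_rate must be >= 0")
        if not (0 < self.nucleus_axis_ratio[0] <= self.nucleus_axis_ratio[1] <= 1.0):
            raise ValueError("nucleus_axis_ratio must satisfy 0 < lo <= hi <= 1")
        if self.mn_offset[0] <= 0 or self.mn_offset[1] < self.mn_offset[0]:
            raise ValueError("mn_offset must be an increasing positive range")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FieldSpec":
        raw = yaml.safe_load(Path(path).read_text())
        for key, value in raw.items():
            if isinstance(value, list):
                raw[key] = tuple(value)
        return cls(**raw)


@dataclass(frozen=True)
class SceneObject:
    """One renderable object: an ellipse (ratio < 1) or circle in um space."""

    cx_um: float
    cy_um: float
    diameter_um: float  # equivalent circular diameter (area-preserving)
    intensity: float
    axis_ratio: float = 1.0  # minor/major, <= 1
    angle: float = 0.0  # radians, major-axis orientation
    kind: str = "nucleus"  # nucleus | micronucleus | apoptotic_body
    owner_id: int | None = None


def _object_mask_indices(
    obj: SceneObject, shape: tuple[int, int], pixel_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices covered by the object's ellipse, clipped to the image."""
    h, w = shape
    r_eq = obj.diameter_um / 2.0
    # area-preserving ellipse: rx * ry = r_eq^2, ratio = ry / rx
    rx = r_eq / math.sqrt(obj.axis_ratio)
    ry = r_eq * math.sqrt(obj.axis_ratio)
    cx_px, cy_px = obj.cx_um / pixel_size, obj.cy_um / pixel_size
    rmax_px = rx / pixel_size + 1.5
    r0 = max(0, int(math.floor(cy_px - rmax_px)))
    r1 = min(h, int(math.ceil(cy_px + rmax_px)) + 1)
    c0 = max(0, int(math.floor(cx_px - rmax_px)))
    c1 = min(w, int(math.ceil(cx_px + rmax_px)) + 1)
    if r0 >= r1 or c0 >= c1:
        return np.array([], dtype=int), np.array([], dtype=int)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    dx = (cols - cx_px) * pixel_size
    dy = (rows - cy_px) * pixel_size
    ca, sa = math.cos(obj.angle), math.sin(obj.angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    inside = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    return rows[inside], cols[inside]


def render_scene(
    objects: list[SceneObject],
    image_size: tuple[int, int],
    pixel_size: float,
    background: tuple[float, float] = (3000.0, 0.0),
    foreground_noise_sd: float = 0.0,
    blur_sigma_px: float = 0.5,
    border_margin: float = 30.0,
    seed: int = 0,
) -> tuple[FieldImage, pd.DataFrame]:
    """Rasterize objects onto a noisy background; return image + ground truth.

    Ground-truth diameters and centroids are recomputed from the rendered
    pixel set (so they agree with any brute-force pixel scan of the image),
    and the recorded mean intensity is measured on the blurred, noise-free
    render over the object's own pixels.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    bg_mean, bg_sd = background
    value = np.full((h, w), float(bg_mean))
    masks: list[tuple[np.ndarray, np.ndarray]] = []
    for obj in objects:
        rr, cc = _object_mask_indices(obj, (h, w), pixel_size)
        value[rr, cc] = obj.intensity
        masks.append((rr, cc))

    if blur_sigma_px > 0:
        value = ndi.gaussian_filter(value, blur_sigma_px)

    noisy = value
    if bg_sd > 0 or foreground_noise_sd > 0:
        sd_map = np.full((h, w), float(bg_sd))
        for rr, cc in masks:
            sd_map[rr, cc] = foreground_noise_sd
        noisy = value + rng.standard_normal((h, w)) * sd_map
    pixels = np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)

    rows = []
    hx, wx = (h - 1) * pixel_size, (w - 1) * pixel_size
    for oid, (obj, (rr, cc)) in enumerate(zip(objects, masks), start=1):
        if rr.size == 0:
            continue
        area_um2 = rr.size * pixel_size**2
        cx = cc.mean() * pixel_size
        cy = rr.mean() * pixel_size
        edge_dist = min(cx, cy, wx - cx, hx - cy)
        rows.append(
            {
                "object_id": oid,
                "kind": obj.kind,
                "cx_um": cx,
                "cy_um": cy,
                "diameter_um": math.sqrt(4.0 * area_um2 / math.pi),
                "mean_intensity": float(value[rr, cc].mean()),
                "owner_id": obj.owner_id,
                "border": bool(edge_dist <= border_margin),
            }
        )
    gt = pd.DataFrame(rows, columns=GT_COLUMNS)
    return FieldImage(pixels=pixels, pixel_size=pixel_size), gt


# ---------------------------------------------------------------------------
# field generation
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, lo, hi):
    """One draw from N(mean, sd) truncated to [lo, hi] by resampling."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def generate_field(spec: FieldSpec) -> tuple[FieldImage, pd.DataFrame]:
    """Generate one calibrated field and its ground-truth object table.

    Placement uses rejection sampling: nuclei never overlap, each
    micronucleus is rendered 1-to-a-few um outside its owner's nuclear
    boundary (inside the owner's cell-body radius) and clear of every other
    object. A spec too dense to satisfy within ``max_retries`` raises
    :class:`PlacementError` naming the limiting parameter.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    ps = spec.pixel_size
    hx, wx = (h - 1) * ps, (w - 1) * ps

    n = spec.n_cells
    objects: list[SceneObject] = []
    if n == 0:
        return render_scene(
            objects,
            spec.image_size,
            ps,
            background=spec.background_intensity,
            foreground_noise_sd=spec.foreground_intensity[1],
            blur_sigma_px=spec.blur_sigma_px,
            border_margin=spec.border_margin,
            seed=spec.seed + 1,
        )

    n_border = int(round(spec.border_fraction * n))
    is_border = np.zeros(n, bool)
    is_border[rng.choice(n, size=n_border, replace=False)] = True
    is_apoptotic = rng.random(n) < spec.apoptotic_fraction

    # geometry draws (one stream, fixed order -> determinism)
    fg_mean = spec.foreground_intensity[0]
    cells = []
    for i in range(n):
        if is_apoptotic[i]:
            # +/- 2 sd truncation keeps bright bodies clearly nucleus-sized
            am, asd = spec.apoptotic_diameter
            d = _truncated_normal(rng, am, asd, am - 2 * asd, am + 2 * asd)
            ratio, angle, intensity, kind = 1.0, 0.0, spec.apoptotic_intensity, "apoptotic_body"
        else:
            mean, sd = spec.nucleus_diameter
            d = _truncated_normal(rng, mean, sd, max(2.0, mean - 3 * sd), mean + 3 * sd)
            ratio = rng.uniform(*spec.nucleus_axis_ratio)
            angle = rng.uniform(0.0, math.pi)
            intensity, kind = fg_mean, "nucleus"
        cells.append((d, ratio, angle, intensity, kind))

    # rejection-sampled centres; semi-major axis bounds the footprint
    placed: list[tuple[float, float, float]] = []  # (cx, cy, semi-major)
    pad = 2.0  # um clearance between nuclear boundaries
    for i, (d, ratio, angle, intensity, kind) in enumerate(cells):
        a = (d / 2.0) / math.sqrt(ratio)
        ok = False
        for _ in range(spec.max_retries):
            if is_border[i]:
                edge = rng.integers(4)
                depth = rng.uniform(min(2 * ps, spec.border_margin), spec.border_margin)
                along = rng.uniform(a, (hx if edge < 2 else wx) - a)
                if edge == 0:
                    cx, cy = depth, along
                elif edge == 1:
                    cx, cy = wx - depth, along
                elif edge == 2:
                    cx, cy = along, depth
                else:
                    cx, cy = along, hx - depth
            else:
                lo = spec.border_margin + pad
                if lo + a >= min(wx, hx) - lo - a:
                    raise PlacementError(
                        "interior region too small: border_margin + nucleus_diameter "
                        "exceed image_size"
                    )
                cx = rng.uniform(lo + a, wx - lo - a)
                cy = rng.uniform(lo + a, hx - lo - a)
            if all(
                math.hypot(cx - px_, cy - py_) >= a + pa + pad
                for px_, py_, pa in placed
            ):
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place cell {i + 1}/{n} after {spec.max_retries} retries; "
                "n_cells is too large for image_size given nucleus_diameter"
            )
        placed.append((cx, cy, a))
        objects.append(
            SceneObject(cx, cy, d, intensity, ratio, angle, kind, owner_id=None)
        )

    # micronuclei: Poisson(mn_rate) per non-apoptotic cell, placed outside the
    # owner boundary, clear of all other nuclei and micronuclei
    mn_objects: list[SceneObject] = []
    d_lo, d_hi = spec.mn_diameter_range
    for i, (d, ratio, angle, intensity, kind) in enumerate(cells):
        if kind != "nucleus":
            continue
        k = rng.poisson(spec.mn_rate)
        cx0, cy0, a0 = placed[i]
        for _ in range(k):
            md = _truncated_normal(rng, *spec.mn_diameter, d_lo, d_hi)
            mr = md / 2.0
            done = False
            for _try in range(spec.max_retries):
                off = rng.uniform(*spec.mn_offset)
                theta = rng.uniform(0.0, 2 * math.pi)
                mx = cx0 + (a0 + off + mr) * math.cos(theta)
                my = cy0 + (a0 + off + mr) * math.sin(theta)
                if not (mr <= mx <= wx - mr and mr <= my <= hx - mr):
                    continue
                clear = True
                for j, (pxj, pyj, paj) in enumerate(placed):
                    if j == i:
                        continue
                    # stay farther from every other nucleus boundary than from
                    # the owner's, so cell-body ownership is unambiguous
                    if math.hypot(mx - pxj, my - pyj) < paj + (off + mr) + 2 * mr + pad:
                        clear = False
                        break
                if clear and all(
                    math.hypot(mx - o.cx_um, my - o.cy_um)
                    >= mr + o.diameter_um / 2 + 0.5
                    for o in mn_objects
                ):
                    done = True
                    break
            if done:
                mn_objects.append(
                    SceneObject(
                        mx, my, md, fg_mean, 1.0, 0.0, "micronucleus", owner_id=i + 1
                    )
                )

    objects.extend(mn_objects)
    return render_scene(
        objects,
        spec.image_size,
        ps,
        background=spec.background_intensity,
        foreground_noise_sd=spec.foreground_intensity[1],
        blur_sigma_px=spec.blur_sigma_px,
        border_margin=spec.border_margin,
        seed=spec.seed + 1,
    )


def write_ground_truth(gt: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    gt.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# mitotic spreads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DefectModel:
    """Per-spread cohesion-defect distribution.

    A spread is defective with probability ``defect_rate``. Defective spreads
    are severe (cohesion lost, chromatids scattered) with probability
    ``p_severe``; otherwise the number of affected chromosomes is drawn from
    a zero-truncated Poisson with mean ``mean_defective`` (capped at the
    spread's chromosome count) and the per-chromosome severity label is
    'moderate' with probability ``p_moderate``, else 'mild'.
    """

    defect_rate: float = 0.0
    mean_defective: float = 3.0
    p_moderate: float = 0.3
    p_severe: float = 0.0

    def validate(self) -> None:
        for name in ("defect_rate", "p_moderate", "p_severe"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_defective < 0:
            raise ValueError("mean_defective must be >= 0")


@dataclass(frozen=True)
class SpreadPopulationSpec:
    """Population of mitotic spreads with count noise and defect structure."""

    n_spreads: int = 100
    modal_count: int = 45
    count_noise: dict[int, float] = field(default_factory=lambda: {0: 1.0})
    tetraploid_fraction: float = 0.0
    defect_model: DefectModel = field(default_factory=DefectModel)
    condition: str = "synthetic"
    n_replicates: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_spreads < 1:
            raise ValueError("n_spreads must be >= 1")
        if self.modal_count < 1:
            raise ValueError("modal_count must be >= 1")
        if not 0.0 <= self.tetraploid_fraction <= 1.0:
            raise ValueError("tetraploid_fraction must lie in [0, 1]")
        total = sum(self.count_noise.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("count_noise probabilities must sum to 1")
        if min(self.count_noise.values()) < 0:
            raise ValueError("count_noise probabilities must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        self.defect_model.validate()


def _zero_truncated_poisson(rng, lam: float) -> int:
    if lam <= 0:
        return 1
    for _ in range(1000):
        k = rng.poisson(lam)
        if k >= 1:
            return int(k)
    return 1


def generate_spread_set(spec: SpreadPopulationSpec) -> pd.DataFrame:
    """Draw a seeded spread population as a table (one row per spread)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    offsets = np.array(sorted(spec.count_noise), dtype=int)
    probs = np.array([spec.count_noise[o] for o in offsets], dtype=float)
    probs = probs / probs.sum()

    rows = []
    for i in range(spec.n_spreads):
        base = spec.modal_count
        if rng.random() < spec.tetraploid_fraction:
            base = 2 * spec.modal_count
        count = int(base + rng.choice(offsets, p=probs))
        count = max(1, count)
        defective, severity, severe = 0, "mild", False
        dm = spec.defect_model
        if rng.random() < dm.defect_rate:
            if rng.random() < dm.p_severe:
                severe = True
                defective = count  # whole-spread loss; count-level unreliable
            else:
                defective = min(count, _zero_truncated_poisson(rng, dm.mean_defective))
                severity = "moderate" if rng.random() < dm.p_moderate else "mild"
        rows.append(
            {
                "spread_id": i + 1,
                "condition": spec.condition,
                "replicate": 1 + i % spec.n_replicates,
                "chromosome_count": count,
                "defective_chromosomes": defective,
                "severity": severity,
                "severe_spread": severe,
            }
        )
    return pd.DataFrame(rows, columns=SPREAD_COLUMNS)


# ---------------------------------------------------------------------------
# CNA matrices
# ---------------------------------------------------------------------------

CNA_CODES = np.array([-2, -1, 0, 1, 2])


def generate_cna_matrix(
    n_genes: int,
    n_samples: int,
    code_probs,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Draw a gene x sample thresholded copy-number matrix.

    ``code_probs`` is an (n_genes, 5) array of per-gene probabilities over the
    codes (-2, -1, 0, 1, 2); each row must sum to 1. Entries are independent
    across genes and samples.
    """
    probs = np.atleast_2d(np.asarray(code_probs, dtype=float))
    if probs.shape[0] == 1:
        probs = np.repeat(probs, n_genes, axis=0)
    if probs.shape != (n_genes, 5):
        raise ValueError("code_probs must have shape (n_genes, 5)")
    if np.any(probs < 0) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("each gene's code probabilities must be >= 0 and sum to 1")
    rng = np.random.default_rng(seed)
    data = np.empty((n_genes, n_samples), dtype=int)
    for g in range(n_genes):
        data[g] = rng.choice(CNA_CODES, size=n_samples, p=probs[g])
    genes = gene_ids or [f"GENE{g + 1:03d}" for g in range(n_genes)]
    samples = [f"S{s + 1:04d}" for s in range(n_samples)]
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=samples)


def deletion_code_probs(p_deletion, p_deep_fraction: float = 0.5) -> np.ndarray:
    """Per-gene code probabilities carrying a given total deletion mass.

    ``p_deletion`` (scalar or per-gene vector) is split between deep (-2) and
    shallow (-1) losses; the remainder is diploid (0).
    """
    p = np.atleast_1d(np.asarray(p_deletion, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("deletion probabilities must lie in [0, 1]")
    out = np.zeros((p.size, 5))
    out[:, 0] = p * p_deep_fraction
    out[:, 1] = p * (1 - p_deep_fraction)
    out[:, 2] = 1.0 - p
    return out


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

SURVIVAL_COLUMNS = ["sample", "expression", "time_months", "event"]


def generate_survival_cohort(
    n: int,
    cutpoint_percentile: float,
    hazard_ratio: float,
    censor_rate: float,
    seed: int = 0,
    baseline_hazard: float = 0.03,
) -> pd.DataFrame:
    """Draw a cohort with an expression change-point in the hazard.

    Expression is standard normal; patients below the empirical
    ``cutpoint_percentile`` of expression have their exponential event hazard
    multiplied by ``hazard_ratio``. Censoring is independent exponential with
    its rate calibrated so the expected censored fraction equals
    ``censor_rate`` (0 disables censoring). Times are months;
    ``baseline_hazard`` is the high-expression event rate per month
    (0.03/month puts median survival near two years, a typical solid-tumour
    cohort scale).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < cutpoint_percentile < 100:
        raise ValueError("cutpoint_percentile must lie in (0, 100)")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    expression = rng.normal(0.0, 1.0, n)
    threshold = np.percentile(expression, cutpoint_percentile)
    low = expression < threshold
    rates = np.where(low, baseline_hazard * hazard_ratio, baseline_hazard)
    times = rng.exponential(1.0 / rates)
    events = np.ones(n, dtype=int)
    if censor_rate > 0:
        # P(censored | rate l, censor rate m) = m / (l + m); solve mean = target
        def _mean_censor(mu):
            return float(np.mean(mu / (rates + mu))) - censor_rate

        mu = optimize.brentq(_mean_censor, 1e-10, 1e6)
        censor_times = rng.exponential(1.0 / mu, n)
        events = (times <= censor_times).astype(int)
        times = np.minimum(times, censor_times)
    return pd.DataFrame(
        {
            "sample": [f"P{i + 1:04d}" for i in range(n)],
            "expression": expression,
            "time_months": times,
            "event": events,
        },
        columns=SURVIVAL_COLUMNS,
    )
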