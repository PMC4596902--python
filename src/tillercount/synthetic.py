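"""Seeded synthetic bunch photographs with ground truth.

The generator emulates the acquisition protocol the pipeline was designed
for: a grass bunch cut at 5 cm, the fresh tips painted white with a roller,
photographed from ~150 cm perpendicular to the soil with a ~50 x 50 cm field
of view.  A scene is a soil-like background (correlated grey noise with
near-equal R/G/B reflectance plus a linear illumination gradient) carrying

* shoot tips — bright near-white filled ellipses whose eccentricity follows
  a species profile (round stems vs the flattened-stem habit),
* leaf fragments — long thin bright ribbons (cut leaves also catch paint),
* debris — small irregular bright blobs, mostly under the 200 px filter.

Everything is drawn from one seeded ``numpy`` generator, so scenes are
bit-reproducible, and every object is recorded in a ground-truth register
with the true tiller count O = number of tips.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from . import classify, imaging, morphometry

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesProfile",
    "SPECIES_PROFILES",
    "SceneSpec",
    "GroundTruth",
    "render_scene",
    "label_objects_against_truth",
    "generate_dataset",
    "simulate_study",
]


@dataclass(frozen=True)
class SpeciesProfile:
    """Shape statistics of painted tip cross-sections for one habit.

    ``tip_diameter_px`` is the range of the equivalent diameter of a tip
    blob after roller painting (the paint spreads beyond the stem section),
    chosen so every tip clears the 200 px area filter;
    ``tip_eccentricity`` controls how flattened the elliptical section is.
    """

    name: str
    tip_diameter_px: tuple[float, float] = (18.0, 30.0)
    tip_eccentricity: tuple[float, float] = (0.0, 0.55)
    flattened_stem: bool = False


#: Habit profiles: round thick stems, round thin stems, and the
#: flattened-stem habit (cocksfoot-like) with strongly eccentric sections.
SPECIES_PROFILES = {
    "round_thick": SpeciesProfile("round_thick"),
    "round_thin": SpeciesProfile("round_thin", tip_diameter_px=(18.0, 24.0)),
    "flattened": SpeciesProfile(
        "flattened", tip_eccentricity=(0.55, 0.85), flattened_stem=True
    ),
}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic bunch photograph.

    Defaults emulate the stated acquisition: ~50 cm field of view at
    0.33 mm/px (~1500 px), soil with equal R/G/B reflectance, and white
    paint well separated in intensity from the soil.  ``seed`` is mandatory.
    """

    seed: int
    size: tuple[int, int] = (1500, 1500)
    species: str = "round_thick"
    n_tips: int = 150
    n_leaf_fragments: int = 25
    n_debris: int = 40
    soil_mean: float = 90.0
    soil_amplitude: float = 16.0
    soil_corr_px: float = 6.0
    soil_speckle_density: float = 5e-4
    soil_speckle_contrast: tuple[float, float] = (25.0, 55.0)
    tip_intensity: tuple[float, float] = (238.0, 255.0)
    leaf_intensity: tuple[float, float] = (205.0, 245.0)
    debris_intensity: tuple[float, float] = (185.0, 235.0)
    illumination_gradient: float = 10.0
    mm_per_px: float = 0.33
    overlap_prob: float = 0.02

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_tips < 0:
            raise ValueError("n_tips must be >= 0")
        if self.species not in SPECIES_PROFILES:
            raise ValueError(f"unknown species profile {self.species!r}")
        if min(self.tip_intensity) <= self.soil_mean + 3 * self.soil_amplitude:
            raise ValueError(
                "tip intensity range too close to soil range for segmentation"
            )


@dataclass
class GroundTruth:
    """Register of every rendered object plus per-class label rasters."""

    objects: pd.DataFrame  # id, cls, row, col, axis_a, axis_b, angle
    tip_map: np.ndarray  # 0 = background, k = tip id
    leaf_map: np.ndarray
    debris_map: np.ndarray

    @property
    def O(self) -> int:
        """True tiller count: number of rendered shoot tips."""
        return int((self.objects["cls"] == classify.SHOOT).sum())


def _soil_background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.size
    noise = rng.standard_normal((h, w))
    noise = ndimage.gaussian_filter(noise, spec.soil_corr_px)
    sd = noise.std()
    if sd > 0:
        noise *= spec.soil_amplitude / (3.0 * sd)  # amplitude ~ 3 sigma
    theta = rng.uniform(0, 2 * math.pi)
    rr, cc = np.meshgrid(np.linspace(-0.5, 0.5, h), np.linspace(-0.5, 0.5, w),
                         indexing="ij")
    gradient = spec.illumination_gradient * (rr * math.cos(theta) + cc * math.sin(theta))
    grey = spec.soil_mean + noise + gradient
    # punctate soil texture (stones, organic flecks): a few-pixel bright
    # speckles that anchor the automatic threshold above the soil bulk but
    # always fall below the small-object filter
    n_speckles = int(spec.soil_speckle_density * h * w)
    if n_speckles:
        sr = rng.integers(1, h - 1, n_speckles)
        sc = rng.integers(1, w - 1, n_speckles)
        lift = rng.uniform(*spec.soil_speckle_contrast, n_speckles)
        for dr, dc, frac in ((0, 0, 1.0), (0, 1, 0.6), (1, 0, 0.6)):
            np.maximum.at(grey, (sr + dr, sc + dc), spec.soil_mean + frac * lift)
    # near-equal reflectance in all three bands: sub-level per-channel offsets
    offsets = rng.uniform(-0.8, 0.8, size=3)
    return np.stack([grey + o for o in offsets], axis=-1)


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    a: float,
    b: float,
    angle: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rows/cols inside the rotated ellipse (semi-axes a, b, angle radians)."""
    r0, c0 = center
    rad = max(a, b) + 2
    rlo, rhi = int(max(0, r0 - rad)), int(min(shape[0], r0 + rad + 1))
    clo, chi = int(max(0, c0 - rad)), int(min(shape[1], c0 + rad + 1))
    rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi), indexing="ij")
    dr, dc = rr - r0, cc - c0
    u = dr * math.cos(angle) + dc * math.sin(angle)
    v = -dr * math.sin(angle) + dc * math.cos(angle)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc[inside], inside


def _ribbon_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    length: float,
    width: float,
    angle: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Rows/cols inside a rotated rectangle (a straight cut-leaf ribbon)."""
    r0, c0 = center
    rad = length / 2 + 2
    rlo, rhi = int(max(0, r0 - rad)), int(min(shape[0], r0 + rad + 1))
    clo, chi = int(max(0, c0 - rad)), int(min(shape[1], c0 + rad + 1))
    rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi), indexing="ij")
    dr, dc = rr - r0, cc - c0
    u = dr * math.cos(angle) + dc * math.sin(angle)
    v = -dr * math.sin(angle) + dc * math.cos(angle)
    inside = (np.abs(u) <= length / 2) & (np.abs(v) <= width / 2)
    return rr[inside], cc[inside]


def _place_centers(
    rng: np.random.Generator,
    n: int,
    radii: np.ndarray,
    shape: tuple[int, int],
    overlap_prob: float,
    max_attempts: int = 400,
) -> np.ndarray:
    """Rejection-sample object centres with a limited-overlap budget.

    Two objects may touch/overlap only when an ``overlap_prob`` coin accepts
    it; otherwise centres keep a clearance of the two radii plus 2 px.
    """
    h, w = shape
    centers: list[tuple[float, float]] = []
    for i in range(n):
        margin = radii[i] + 2
        for attempt in range(max_attempts):
            r0 = rng.uniform(margin, h - margin)
            c0 = rng.uniform(margin, w - margin)
            ok = True
            for j, (rj, cj) in enumerate(centers):
                d = math.hypot(r0 - rj, c0 - cj)
                if d < radii[i] + radii[j] + 2:
                    # allow a touching/merged pair with small probability,
                    # but never a near-total overlap
                    if d > 0.8 * max(radii[i], radii[j]) and rng.random() < overlap_prob:
                        continue
                    ok = False
                    break
            if ok:
                centers.append((r0, c0))
                break
        else:
            raise ValueError(
                f"cannot place object {i + 1}/{n} within the overlap budget; "
                "use a larger image or fewer objects"
            )
    return np.array(centers).reshape(n, 2)


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic bunch photograph and its ground truth.

    Deterministic given ``spec.seed``; the returned image is ``(H, W, 3)``
    uint8 and the ground truth records every object with its class and the
    painted raster of each class.
    """
    rng = np.random.default_rng(spec.seed)
    profile = SPECIES_PROFILES[spec.species]
    h, w = spec.size
    img = _soil_background(spec, rng)
    tip_map = np.zeros((h, w), dtype=np.int32)
    leaf_map = np.zeros((h, w), dtype=np.int32)
    debris_map = np.zeros((h, w), dtype=np.int32)
    records: list[dict] = []

    # --- shoot tips -------------------------------------------------------
    d_eq = rng.uniform(*profile.tip_diameter_px, size=spec.n_tips)
    ecc = rng.uniform(*profile.tip_eccentricity, size=spec.n_tips)
    # semi-axes at fixed equivalent diameter: a*b = (d/2)^2, b = a*sqrt(1-e^2)
    shape_ratio = (1.0 - ecc**2) ** 0.25
    a_ax = (d_eq / 2.0) / shape_ratio
    b_ax = (d_eq / 2.0) * shape_ratio
    centers = _place_centers(rng, spec.n_tips, a_ax, (h, w), spec.overlap_prob)
    angles = rng.uniform(0, math.pi, size=spec.n_tips)
    next_id = 1
    for i in range(spec.n_tips):
        rr, cc, _ = _ellipse_mask((h, w), tuple(centers[i]), a_ax[i], b_ax[i], angles[i])
        base = rng.uniform(*spec.tip_intensity)
        paint = np.clip(base + rng.normal(0, 2.5, size=rr.size), 0, 255)
        for ch in range(3):
            img[rr, cc, ch] = np.maximum(img[rr, cc, ch], paint)
        tip_map[rr, cc] = next_id
        records.append(
            dict(id=next_id, cls=classify.SHOOT, row=centers[i, 0], col=centers[i, 1],
                 axis_a=a_ax[i], axis_b=b_ax[i], angle=angles[i]))
        next_id += 1

    # --- leaf fragments ---------------------------------------------------
    for _ in range(spec.n_leaf_fragments):
        length = rng.uniform(45, 130)
        width = rng.uniform(4.0, 9.0)
        angle = rng.uniform(0, math.pi)
        r0 = rng.uniform(length / 2 + 2, h - length / 2 - 2)
        c0 = rng.uniform(length / 2 + 2, w - length / 2 - 2)
        rr, cc = _ribbon_mask((h, w), (r0, c0), length, width, angle)
        keep = tip_map[rr, cc] == 0  # paint never covers a tip raster
        rr, cc = rr[keep], cc[keep]
        base = rng.uniform(*spec.leaf_intensity)
        paint = np.clip(base + rng.normal(0, 3.0, size=rr.size), 0, 255)
        for ch in range(3):
            img[rr, cc, ch] = np.maximum(img[rr, cc, ch], paint)
        leaf_map[rr, cc] = next_id
        records.append(dict(id=next_id, cls="leaf", row=r0, col=c0,
                            axis_a=length / 2, axis_b=width / 2, angle=angle))
        next_id += 1

    # --- debris -----------------------------------------------------------
    for _ in range(spec.n_debris):
        d = rng.uniform(6.0, 17.0)
        a = d / 2 * rng.uniform(0.8, 1.6)
        b = (d / 2) ** 2 / a
        angle = rng.uniform(0, math.pi)
        r0 = rng.uniform(a + 2, h - a - 2)
        c0 = rng.uniform(a + 2, w - a - 2)
        rr, cc, _ = _ellipse_mask((h, w), (r0, c0), a, b, angle)
        keep = (tip_map[rr, cc] == 0) & (leaf_map[rr, cc] == 0)
        rr, cc = rr[keep], cc[keep]
        base = rng.uniform(*spec.debris_intensity)
        paint = np.clip(base + rng.normal(0, 4.0, size=rr.size), 0, 255)
        for ch in range(3):
            img[rr, cc, ch] = np.maximum(img[rr, cc, ch], paint)
        debris_map[rr, cc] = next_id
        records.append(dict(id=next_id, cls="debris", row=r0, col=c0,
                            axis_a=a, axis_b=b, angle=angle))
        next_id += 1

    image = np.clip(img, 0, 255).round().astype(np.uint8)
    objects = pd.DataFrame(
        records, columns=["id", "cls", "row", "col", "axis_a", "axis_b", "angle"]
    )
    return image, GroundTruth(objects, tip_map, leaf_map, debris_map)


def label_objects_against_truth(
    objects: imaging.LabeledObjects, truth: GroundTruth
) -> list[str]:
    """Class of each segmented object by majority overlap with the truth
    rasters (shoot / leaf / debris); objects overlapping nothing (pure soil
    artefacts) count as debris."""
    labels = []
    for oid in objects.ids:
        r, c = objects.pixels(oid)
        counts = {
            classify.SHOOT: int((truth.tip_map[r, c] > 0).sum()),
            "leaf": int((truth.leaf_map[r, c] > 0).sum()),
            "debris": int((truth.debris_map[r, c] > 0).sum()),
        }
        cls = max(counts, key=counts.get)
        labels.append(cls if counts[cls] > 0 else "debris")
    return labels


def _segment_and_describe(
    image: np.ndarray, truth: GroundTruth, *, min_area: int = 200,
    opening_radius: int = 1,
) -> tuple[pd.DataFrame, int]:
    """Segment one scene and return its feature table with truth classes."""
    grey = imaging.to_blue_band(image)
    threshold, mask = imaging.max_contrast_threshold(grey)
    objects = imaging.open_and_label(mask, min_area=min_area,
                                     opening_radius=opening_radius)
    feats = morphometry.compute_feature_table(objects)
    truth_cls = label_objects_against_truth(objects, truth)
    kept = feats["id"].to_numpy() - 1  # compute_feature_table may drop rows
    feats = feats.assign(truth_cls=[truth_cls[i] for i in kept])
    feats["class"] = np.where(
        feats["truth_cls"] == classify.SHOOT, classify.SHOOT, classify.NON_SHOOT
    )
    return feats, threshold


@dataclass
class StudyData:
    """In-memory synthetic study: scenes, truth counts and object tables."""

    specs: list[SceneSpec]
    images: list[np.ndarray]
    truths: list[GroundTruth]
    feature_tables: list[pd.DataFrame]  # with truth_cls / class columns
    training: pd.DataFrame  # ~20 % of objects, pooled
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def O(self) -> np.ndarray:
        return np.array([t.O for t in self.truths], dtype=int)


def simulate_study(
    n_images: int,
    seed: int,
    *,
    o_range: tuple[int, int] = (15, 356),
    species: str = "round_thick",
    train_fraction: float = 0.20,
    template: SceneSpec | None = None,
) -> StudyData:
    """Generate a seeded study: scenes with O ~ U[o_range] plus a pooled
    ~``train_fraction`` labelled object sample (mirroring a hand-labelled
    training set of ~20 % of segmented objects)."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    root = np.random.default_rng(seed)
    specs, images, truths, tables, manifest = [], [], [], [], []
    for k in range(n_images):
        o_true = int(root.integers(o_range[0], o_range[1] + 1))
        scene_seed = int(root.integers(0, 2**31 - 1))
        base = template if template is not None else SceneSpec(seed=scene_seed,
                                                               species=species)
        spec = replace(base, seed=scene_seed, n_tips=o_true, species=species)
        image, truth = render_scene(spec)
        feats, threshold = _segment_and_describe(image, truth)
        specs.append(spec)
        images.append(image)
        truths.append(truth)
        tables.append(feats)
        manifest.append(dict(image=f"scene_{k:03d}.png", O=truth.O,
                             seed=scene_seed, species=species,
                             threshold=threshold, n_objects=len(feats)))
    pooled = pd.concat(
        [t.assign(image=m["image"]) for t, m in zip(tables, manifest)],
        ignore_index=True,
    )
    n_train = max(2, int(round(train_fraction * len(pooled))))
    idx = root.choice(len(pooled), size=n_train, replace=False)
    training = pooled.iloc[np.sort(idx)].reset_index(drop=True)
    return StudyData(specs, images, truths, tables, training,
                     pd.DataFrame(manifest))


def generate_dataset(
    out_dir: str | Path,
    n_images: int,
    seed: int,
    *,
    o_range: tuple[int, int] = (15, 356),
    species: str = "round_thick",
    train_fraction: float = 0.20,
    template: SceneSpec | None = None,
) -> StudyData:
    """Write a synthetic dataset to disk: scene PNGs, a truth CSV and a
    labelled training CSV in the morphometry feature schema."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(n_images, seed, o_range=o_range, species=species,
                           train_fraction=train_fraction, template=template)
    for name, image in zip(study.manifest["image"], study.images):
        iio.imwrite(out / name, image)
    study.manifest[["image", "O", "seed", "species"]].to_csv(
        out / "truth.csv", index=False
    )
    cols = morphometry.FEATURE_COLUMNS + ["class", "image"]
    study.training[cols].to_csv(out / "training.csv", index=False)
    return study
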