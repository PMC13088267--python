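"""Synthetic tissue sections with the statistical structure the analysis assumes.

Real slide images are not distributed with the package, so every
downstream stage is exercised on generated data: per-pixel refractive
index (RI) fields clustered near 1.27 for healthy and 1.37 for cancerous
epithelium, thicknesses drawn from the 0.3-1 µm range of dewaxed
nominal-2-µm sections, rendered to sRGB through the slide forward model
(:mod:`noscolor.slide`), plus simulated pathologist calls and labelled
tiles for the agreement and screening statistics.

The generator is deliberately minimal: it reproduces the colour statistics
(class-conditional RI/thickness distributions, sensor noise) but none of
the real histomorphology — glands, nuclei, spatial textures — so passing
results demonstrate the pipeline's statistical behaviour, not clinical
performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import truncnorm
from skimage.color import rgb2lab

from .errors import CapacityError, InputError
from .metrics import LabPointCloud
from .slide import SlideConfig, simulate_glass_color, simulate_slide_color

__all__ = [
    "CLASSES", "SectionSpec", "Fields", "RenderedSection", "TileSet",
    "sample_fields", "render_section", "make_labeled_tiles",
    "make_train_test_tiles", "simulate_raters", "NearestCentroidTileModel",
    "baseline_tile_classifier", "sample_region_clouds",
]

#: class codes used in region maps
CLASSES = ("background", "healthy", "cancerous")
_CODE = {name: i for i, name in enumerate(CLASSES)}

#: RI truncation bounds for tissue (air/water to dense protein)
RI_BOUNDS = (1.0, 1.6)


@dataclass(frozen=True)
class SectionSpec:
    """Recipe for one synthetic section.

    Defaults encode the study conditions: healthy RI ~ N(1.27, 0.02²),
    cancerous RI ~ N(1.37, 0.02²) truncated to [1.0, 1.6]; thickness
    uniform on 0.3-1.0 µm; additive sensor noise of 0.01 sRGB units.
    """

    height: int = 128
    width: int = 128
    layout: str = "split"          # "split" (healthy|cancerous) or a class name
    ri_model: dict = field(default_factory=lambda: {
        "healthy": (1.27, 0.02), "cancerous": (1.37, 0.02)})
    thickness_model_um: dict = field(default_factory=lambda: {
        "healthy": (0.3, 1.0), "cancerous": (0.3, 1.0)})
    cavity_thickness_nm: float = 111.0
    illuminant: str = "D65"
    noise_sd: float = 0.01
    smoothing_sigma_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise InputError("section dimensions must be positive")
        if self.layout != "split" and self.layout not in _CODE:
            raise InputError(f"unknown layout {self.layout!r}")
        for cls, (mu, sd) in self.ri_model.items():
            if cls not in _CODE:
                raise InputError(f"unknown class {cls!r} in ri_model")
            if not (RI_BOUNDS[0] <= mu <= RI_BOUNDS[1]) or sd < 0:
                raise InputError(f"invalid RI model for {cls!r}")
        for cls, (lo, hi) in self.thickness_model_um.items():
            if lo < 0 or hi < lo:
                raise InputError(f"invalid thickness range for {cls!r}")
        if self.noise_sd < 0 or self.smoothing_sigma_px < 0:
            raise InputError("noise/smoothing parameters must be >= 0")

    def region_map(self) -> np.ndarray:
        """Per-pixel class codes (0 background, 1 healthy, 2 cancerous)."""
        m = np.zeros((self.height, self.width), dtype=np.int8)
        if self.layout == "split":
            half = self.width // 2
            m[:, :half] = _CODE["healthy"]
            m[:, half:] = _CODE["cancerous"]
        else:
            m[:, :] = _CODE[self.layout]
        return m

    def slide_config(self) -> SlideConfig:
        return SlideConfig(cavity_thickness_nm=self.cavity_thickness_nm,
                           illuminant=self.illuminant)


@dataclass(frozen=True)
class Fields:
    """Per-pixel ground-truth physical fields."""

    ri: np.ndarray
    thickness_um: np.ndarray
    region: np.ndarray


def sample_fields(spec: SectionSpec,
                  rng: np.random.Generator | None = None) -> Fields:
    """Draw the per-pixel RI and thickness fields of a section.

    RI is truncated-normal per class (bounds ``RI_BOUNDS``); thickness is
    uniform per class; background pixels carry RI 1 and thickness 0.
    Optional Gaussian smoothing (``smoothing_sigma_px``) adds spatial
    correlation.  Fully deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    region = spec.region_map()
    ri = np.full(region.shape, 1.0)
    thickness = np.zeros(region.shape)
    for cls, (mu, sd) in spec.ri_model.items():
        mask = region == _CODE[cls]
        n = int(mask.sum())
        if n == 0:
            continue
        if sd == 0:
            draws = np.full(n, mu)
        else:
            a, b = (RI_BOUNDS[0] - mu) / sd, (RI_BOUNDS[1] - mu) / sd
            draws = truncnorm.rvs(a, b, loc=mu, scale=sd, size=n,
                                  random_state=rng)
        ri[mask] = draws
    for cls, (lo, hi) in spec.thickness_model_um.items():
        mask = region == _CODE[cls]
        n = int(mask.sum())
        if n:
            thickness[mask] = rng.uniform(lo, hi, size=n)
    if spec.smoothing_sigma_px > 0:
        tissue = region != _CODE["background"]
        for arr in (ri, thickness):
            sm = gaussian_filter(arr, spec.smoothing_sigma_px)
            arr[tissue] = sm[tissue]
    return Fields(ri, thickness, region)


@dataclass(frozen=True)
class RenderedSection:
    """RGB rendering plus the ground truth it was rendered from."""

    rgb: np.ndarray
    fields: Fields
    spec: SectionSpec
    mode: str
    provenance: dict = field(default_factory=dict)

    @property
    def truth(self) -> np.ndarray:
        return self.fields.region


def _point_color(config: SlideConfig, mode: str, ri: float,
                 thickness_nm: float) -> np.ndarray:
    fn = simulate_slide_color if mode == "nos" else simulate_glass_color
    return fn(config, ri, thickness_nm).srgb.as_array()


def _build_lut(config: SlideConfig, mode: str, ri_range, th_range_nm,
               lut_size: int):
    ri_ax = np.linspace(ri_range[0], ri_range[1], lut_size)
    th_ax = np.linspace(th_range_nm[0], th_range_nm[1], lut_size)
    table = np.empty((lut_size, lut_size, 3))
    for i, r in enumerate(ri_ax):
        for j, t in enumerate(th_ax):
            table[i, j] = _point_color(config, mode, float(r), float(t))
    return ri_ax, th_ax, table


def _bilinear(ri_ax, th_ax, table, ri, th):
    def frac_index(ax, v):
        idx = np.clip(np.searchsorted(ax, v) - 1, 0, ax.size - 2)
        step = ax[idx + 1] - ax[idx]
        return idx, np.clip((v - ax[idx]) / step, 0.0, 1.0)

    i, fi = frac_index(ri_ax, ri)
    j, fj = frac_index(th_ax, th)
    c00 = table[i, j]
    c10 = table[i + 1, j]
    c01 = table[i, j + 1]
    c11 = table[i + 1, j + 1]
    fi, fj = fi[..., None], fj[..., None]
    return ((1 - fi) * (1 - fj) * c00 + fi * (1 - fj) * c10
            + (1 - fi) * fj * c01 + fi * fj * c11)


def render_section(spec: SectionSpec, fields: Fields | None = None,
                   mode: str = "nos", lut_size: int = 64,
                   rng: np.random.Generator | None = None) -> RenderedSection:
    """Render a section's fields to a noisy sRGB image.

    Per-pixel colour comes from the forward model via a bilinear lookup
    table over (RI, thickness) at ``lut_size × lut_size`` resolution
    (``lut_size=None`` evaluates every pixel exactly); the worst-case LUT
    colour error over a pixel sample is reported in the provenance record.
    Background pixels take the exact bare-slide colour; additive Gaussian
    sensor noise (spec.noise_sd, sRGB units) is applied and clipped.
    """
    if mode not in ("nos", "glass"):
        raise InputError(f"unknown rendering mode {mode!r}")
    if fields is None:
        fields = sample_fields(spec)
    if fields.region.shape != (spec.height, spec.width):
        raise InputError("fields do not match the spec dimensions")
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    config = spec.slide_config()

    tissue = fields.region != _CODE["background"]
    rgb = np.empty((spec.height, spec.width, 3))
    rgb[~tissue] = _point_color(config, mode, 1.0, 0.0)

    provenance: dict = {"mode": mode, "seed": spec.seed, "lut_size": lut_size}
    if tissue.any():
        ri = fields.ri[tissue]
        th = fields.thickness_um[tissue] * 1000.0
        if lut_size is None:
            rgb[tissue] = np.array([
                _point_color(config, mode, float(r), float(t))
                for r, t in zip(ri, th)])
        else:
            eps = 1e-9
            ri_rng = (ri.min(), max(ri.max(), ri.min() + eps))
            th_rng = (th.min(), max(th.max(), th.min() + eps))
            ri_ax, th_ax, table = _build_lut(config, mode, ri_rng, th_rng,
                                             lut_size)
            rgb[tissue] = _bilinear(ri_ax, th_ax, table, ri, th)
            # audit the interpolation error on a pixel subsample
            check = rng.choice(ri.size, size=min(16, ri.size), replace=False)
            errs = []
            for idx in check:
                exact = _point_color(config, mode, float(ri[idx]),
                                     float(th[idx]))
                approx = rgb[tissue][idx]
                pair = rgb2lab(np.stack([exact, approx])[None, :, :])
                errs.append(float(np.linalg.norm(pair[0, 0] - pair[0, 1])))
            provenance["lut_max_delta_e"] = max(errs)

    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0)
    return RenderedSection(rgb, fields, spec, mode, provenance)


def sample_region_clouds(section: RenderedSection, cls: str, n_regions: int,
                         region_px: int, rng: np.random.Generator,
                         max_tries: int = 2000) -> list[LabPointCloud]:
    """Sample non-overlapping class-pure square regions as CIELAB clouds."""
    from .metrics import extract_lab_cloud

    region = section.truth
    code = _CODE[cls]
    taken: list[tuple[int, int]] = []
    clouds: list[LabPointCloud] = []
    tries = 0
    while len(clouds) < n_regions:
        tries += 1
        if tries > max_tries:
            raise CapacityError(
                f"could not place {n_regions} non-overlapping {region_px}px "
                f"regions of class {cls!r}")
        r = int(rng.integers(0, region.shape[0] - region_px + 1))
        c = int(rng.integers(0, region.shape[1] - region_px + 1))
        if not np.all(region[r:r + region_px, c:c + region_px] == code):
            continue
        if any(abs(r - r0) < region_px and abs(c - c0) < region_px
               for r0, c0 in taken):
            continue
        taken.append((r, c))
        clouds.append(extract_lab_cloud(section.rgb, (r, c), region_px))
    return clouds


@dataclass(frozen=True)
class TileSet:
    """Class-pure tiles with labels (1 = cancerous) and subject ids."""

    tiles: tuple
    labels: np.ndarray
    subjects: np.ndarray

    def __len__(self) -> int:
        return len(self.tiles)


def make_labeled_tiles(base_spec: SectionSpec, n_per_class: int,
                       tile_px: int, seed: int, n_subjects: int = 2,
                       mode: str = "nos", lut_size: int = 32) -> TileSet:
    """Render class-pure tiles from per-subject synthetic sections.

    Each "subject" is an independently seeded rendering; tiles are carved
    without overlap on a raster grid.  Raises
    :class:`~noscolor.errors.CapacityError` if the sections cannot hold the
    requested count.
    """
    if n_per_class < 0 or tile_px <= 0 or n_subjects <= 0:
        raise InputError("invalid tile request")
    rng = np.random.default_rng(seed)
    subject_seeds = rng.integers(0, 2 ** 31 - 1, size=n_subjects)
    tiles: list[np.ndarray] = []
    labels: list[int] = []
    subjects: list[int] = []
    if n_per_class == 0:
        return TileSet((), np.array([], dtype=int), np.array([], dtype=int))
    per_subject = -(-n_per_class // n_subjects)  # ceil
    per_row = max(1, base_spec.width // tile_px)
    per_col = max(1, base_spec.height // tile_px)
    if per_row * per_col < per_subject:
        raise CapacityError(
            f"section {base_spec.height}x{base_spec.width} holds at most "
            f"{per_row * per_col} tiles of {tile_px}px, need {per_subject} "
            "per subject")
    for cls in ("healthy", "cancerous"):
        remaining = n_per_class
        for s_idx, s_seed in enumerate(subject_seeds):
            if remaining == 0:
                break
            spec = replace(base_spec, layout=cls, seed=int(s_seed) + _CODE[cls])
            section = render_section(spec, mode=mode, lut_size=lut_size)
            take = min(per_subject, remaining)
            count = 0
            for r in range(per_col):
                for c in range(per_row):
                    if count == take:
                        break
                    tiles.append(section.rgb[r * tile_px:(r + 1) * tile_px,
                                             c * tile_px:(c + 1) * tile_px])
                    labels.append(1 if cls == "cancerous" else 0)
                    subjects.append(s_idx)
                    count += 1
            remaining -= count
        if remaining:
            raise CapacityError(f"could only place {n_per_class - remaining} "
                                f"of {n_per_class} {cls} tiles")
    return TileSet(tuple(tiles), np.asarray(labels), np.asarray(subjects))


def make_train_test_tiles(base_spec: SectionSpec, n_train_per_class: int,
                          n_test_per_class: int, tile_px: int, seed: int,
                          n_subjects_train: int = 2, n_subjects_test: int = 2,
                          mode: str = "nos", lut_size: int = 32,
                          ) -> tuple[TileSet, TileSet]:
    """Patient-level split: train and test tiles from disjoint subject seeds."""
    train = make_labeled_tiles(base_spec, n_train_per_class, tile_px,
                               seed=seed * 2 + 1,
                               n_subjects=n_subjects_train, mode=mode,
                               lut_size=lut_size)
    test = make_labeled_tiles(base_spec, n_test_per_class, tile_px,
                              seed=seed * 2 + 2,
                              n_subjects=n_subjects_test, mode=mode,
                              lut_size=lut_size)
    return train, test


def simulate_raters(truth, confusion_model: dict, seed: int):
    """Two conditionally independent categorical raters given true classes.

    *confusion_model* maps each true class to a dict of call probabilities
    (rows must sum to 1).  Returns two aligned call arrays.
    """
    truth = list(truth)
    rng = np.random.default_rng(seed)
    for cls, row in confusion_model.items():
        p = np.array(list(row.values()), dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise InputError(f"call probabilities for {cls!r} must sum to 1")

    def one_rater():
        calls = []
        for t in truth:
            row = confusion_model[t]
            options = list(row.keys())
            probs = np.array(list(row.values()), dtype=float)
            calls.append(options[rng.choice(len(options), p=probs / probs.sum())])
        return np.array(calls)

    return one_rater(), one_rater()


def _tile_features(tiles) -> np.ndarray:
    feats = []
    for tile in tiles:
        lab = rgb2lab(np.asarray(tile))
        flat = lab.reshape(-1, 3)
        feats.append(np.r_[flat.mean(axis=0), flat.std(axis=0)])
    return np.asarray(feats)


class NearestCentroidTileModel:
    """Nearest-centroid classifier on mean/SD CIELAB tile features.

    The continuous score of a tile is the difference between its distances
    to the negative and positive class centroids in standardised feature
    space (higher = more cancer-like), suitable for ROC analysis.
    """

    def fit(self, tiles, labels) -> "NearestCentroidTileModel":
        y = np.asarray(labels)
        if len(set(y.tolist())) < 2:
            raise InputError("training set must contain both classes")
        x = _tile_features(tiles)
        self.mu_ = x.mean(axis=0)
        self.sd_ = np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
        z = (x - self.mu_) / self.sd_
        self.centroids_ = {c: z[y == c].mean(axis=0) for c in (0, 1)}
        return self

    def scores(self, tiles) -> np.ndarray:
        z = (_tile_features(tiles) - self.mu_) / self.sd_
        d0 = np.linalg.norm(z - self.centroids_[0], axis=1)
        d1 = np.linalg.norm(z - self.centroids_[1], axis=1)
        return d0 - d1


def baseline_tile_classifier(train_tiles, train_labels, test_tiles,
                             method: str = "centroid") -> np.ndarray:
    """Continuous cancer scores for test tiles from a shallow colour baseline.

    ``method="centroid"`` uses :class:`NearestCentroidTileModel`;
    ``method="logistic"`` fits scikit-learn logistic regression on the same
    features and returns positive-class probabilities.
    """
    if method == "centroid":
        model = NearestCentroidTileModel().fit(train_tiles, train_labels)
        return model.scores(test_tiles)
    if method == "logistic":
        from sklearn.linear_model import LogisticRegression

        y = np.asarray(train_labels)
        if len(set(y.tolist())) < 2:
            raise InputError("training set must contain both classes")
        x = _tile_features(train_tiles)
        clf = LogisticRegression(max_iter=1000).fit(x, y)
        return clf.predict_proba(_tile_features(test_tiles))[:, 1]
    raise InputError(f"unknown classifier method {method!r}")
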