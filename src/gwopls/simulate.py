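"""Synthetic UV-Vis blend-oil datasets with known ground truth.

Real quaternary blend-oil spectra show strongly overlapping absorption
bands in the visible region (peaks near 427, 452 and 478 nm from
triglycerides, fatty acids and fat-soluble vitamins), a noisy ultraviolet
region below ~350 nm, and compositions in which one bulk oil spans the
full 0-100% range while a minor, expensive oil stays below ~10%.  The
generator emulates that statistical structure — Beer-Lambert linear mixing
of Gaussian-peak pure-component spectra plus heteroscedastic noise — while
planting a known informative-wavelength mask so selector recovery can be
scored, which no laboratory dataset allows.

The pure spectra are NOT physically measured oil spectra; they are
collinear-but-distinguishable stand-ins sharing the visible peak cluster
with small per-component shifts, so that no single wavelength identifies a
component on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import SpectrumSet, TargetVector

__all__ = [
    "PureComponentSpec",
    "NoiseSpec",
    "MixtureDesign",
    "SyntheticDataset",
    "default_components",
    "make_wavelength_grid",
    "pure_spectrum",
    "generate_mixture_design",
    "generate_dataset",
    "split_train_predict",
    "default_benchmark_dataset",
]


@dataclass(frozen=True)
class PureComponentSpec:
    """Gaussian-peak model of one pure component's absorbance spectrum.

    ``peaks`` is a list of (center nm, width nm, height) triplets; the
    spectrum is their sum plus a flat ``baseline`` offset.
    """

    name: str
    peaks: tuple[tuple[float, float, float], ...]
    baseline: float = 0.0

    def validate(self, grid: np.ndarray) -> None:
        for center, width, height in self.peaks:
            if not (grid[0] <= center <= grid[-1]):
                raise ValueError(f"{self.name}: peak center {center} off-grid")
            if width <= 0:
                raise ValueError(f"{self.name}: non-positive peak width")
            if height < 0:
                raise ValueError(f"{self.name}: negative peak height")


@dataclass(frozen=True)
class NoiseSpec:
    """Heteroscedastic measurement noise: Gaussian with sd ``base_sd``
    everywhere except inside ``uv_region`` where it is multiplied by
    ``uv_sd_multiplier`` (detector noise is worst in the deep UV).

    The default 0.02 AU base noise is clearly visible against peak heights
    of ~0.5-0.9 AU — mimicking instrument noise one can see on a plotted
    oil spectrum — and is large enough that carrying uninformative
    channels measurably degrades a PLS model, so wavelength selection has
    something real to find."""

    base_sd: float = 0.02
    uv_region: tuple[float, float] = (200.0, 350.0)
    uv_sd_multiplier: float = 5.0

    def __post_init__(self) -> None:
        if self.uv_sd_multiplier < 1:
            raise ValueError("uv_sd_multiplier must be >= 1")
        if self.base_sd < 0:
            raise ValueError("base_sd must be non-negative")

    def sd_profile(self, grid: np.ndarray) -> np.ndarray:
        sd = np.full(grid.shape, self.base_sd)
        lo, hi = self.uv_region
        sd[(grid >= lo) & (grid <= hi)] *= self.uv_sd_multiplier
        return sd


@dataclass(frozen=True)
class MixtureDesign:
    """Quaternary composition design.

    The bulk component spans ``bulk_range`` on a grid of ``bulk_step``; the
    minor component spans ``minor_range`` on ``minor_step``; the remainder
    is split randomly between the two filler components subject to their
    caps.  Every row sums to exactly 100 (% g/g).
    """

    n_samples: int = 102
    bulk_range: tuple[float, float] = (0.0, 100.0)
    bulk_step: float = 2.0
    minor_range: tuple[float, float] = (0.0, 10.0)
    minor_step: float = 0.2
    filler_caps: tuple[float, float] = (98.0, 96.0)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if sum(self.filler_caps) + self.bulk_range[1] < 100:
            raise ValueError("ranges cannot reach a 100% total")


@dataclass
class SyntheticDataset:
    """A generated dataset: spectra, per-component targets, the planted
    informative-wavelength mask, and the composition matrix."""

    spectra: SpectrumSet
    targets: dict[str, TargetVector]
    informative_mask: np.ndarray
    compositions: np.ndarray
    component_names: list[str]
    params: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.spectra.n_samples


def make_wavelength_grid(low: float, high: float, step: float) -> np.ndarray:
    """Inclusive arithmetic wavelength grid, e.g. (200, 800, 1) -> 601
    points."""
    if step <= 0:
        raise ValueError("step must be positive")
    if low >= high:
        raise ValueError("low must be below high")
    n = int(round((high - low) / step)) + 1
    return low + step * np.arange(n)


def pure_spectrum(spec: PureComponentSpec, grid: np.ndarray) -> np.ndarray:
    """Evaluate one component's noise-free spectrum on a grid."""
    spec.validate(grid)
    out = np.full(grid.shape, spec.baseline)
    for center, width, height in spec.peaks:
        out += height * np.exp(-((grid - center) ** 2) / (2.0 * width**2))
    return out


def default_components() -> list[PureComponentSpec]:
    """Four collinear-but-distinguishable pure components.

    All share the visible peak cluster near 427/452/478 nm with a few-nm
    per-component shift and differing heights, plus component-specific UV
    features, so the mixture problem is genuinely ill-conditioned at single
    wavelengths.  Baseline offsets are nearly equal across components: the
    between-component information lives in the absorption bands, and the
    featureless red tail (>~520 nm) stays genuinely uninformative.
    """
    return [
        PureComponentSpec(
            "soybean",
            ((427.0, 8.0, 0.90), (452.0, 7.0, 0.70), (478.0, 8.0, 0.45),
             (262.0, 25.0, 0.50)),
            baseline=0.020,
        ),
        PureComponentSpec(
            "sunflower",
            ((425.0, 9.0, 0.60), (455.0, 8.0, 0.80), (480.0, 9.0, 0.30),
             (240.0, 20.0, 0.60), (310.0, 15.0, 0.20)),
            baseline=0.021,
        ),
        PureComponentSpec(
            "peanut",
            ((429.0, 8.0, 0.75), (450.0, 7.0, 0.50), (476.0, 7.0, 0.60),
             (281.0, 22.0, 0.40)),
            baseline=0.022,
        ),
        PureComponentSpec(
            "sesame",
            ((430.0, 10.0, 0.50), (454.0, 9.0, 0.65), (481.0, 8.0, 0.55),
             (230.0, 18.0, 0.70), (296.0, 12.0, 0.35)),
            baseline=0.019,
        ),
    ]


def _snap(values: np.ndarray, step: float, lo: float, hi: float) -> np.ndarray:
    snapped = lo + step * np.round((values - lo) / step)
    return np.clip(snapped, lo, hi)


def generate_mixture_design(design: MixtureDesign, seed: int) -> np.ndarray:
    """Draw quaternary compositions (columns: bulk, filler1, filler2,
    minor), each row summing to 100% g/g."""
    rng = np.random.default_rng(seed)
    n = design.n_samples
    b_lo, b_hi = design.bulk_range
    m_lo, m_hi = design.minor_range

    bulk = _snap(rng.uniform(b_lo, b_hi, n), design.bulk_step, b_lo, b_hi)
    minor = _snap(rng.uniform(m_lo, m_hi, n), design.minor_step, m_lo, m_hi)
    minor = np.minimum(minor, 100.0 - bulk)  # keep the row feasible

    remainder = 100.0 - bulk - minor
    frac = rng.uniform(0.0, 1.0, n)
    f1 = frac * remainder
    f2 = remainder - f1
    cap1, cap2 = design.filler_caps
    # shift any excess over a filler cap onto the other filler
    over1 = np.maximum(f1 - cap1, 0.0)
    f1 -= over1
    f2 += over1
    over2 = np.maximum(f2 - cap2, 0.0)
    f2 -= over2
    f1 += over2
    comp = np.column_stack([bulk, f1, f2, minor])
    if np.any(comp < -1e-9) or np.any(np.abs(comp.sum(axis=1) - 100.0) > 1e-9):
        raise ValueError("infeasible design ranges")
    return np.clip(comp, 0.0, None)


def generate_dataset(
    components: list[PureComponentSpec] | None = None,
    design: MixtureDesign | None = None,
    noise: NoiseSpec | None = None,
    grid: np.ndarray | None = None,
    seed: int = 0,
    cnr_threshold: float = 3.0,
) -> SyntheticDataset:
    """Generate a full synthetic dataset.

    Absorbance is the Beer-Lambert mixture
    ``sum_c (fraction_c / 100) * pure_spectrum_c`` plus heteroscedastic
    Gaussian noise.  The planted informative mask flags wavelengths whose
    between-component spectral contrast (max minus min of the pure spectra)
    exceeds ``cnr_threshold`` times the local noise sd.
    """
    components = components if components is not None else default_components()
    design = design or MixtureDesign()
    noise = noise or NoiseSpec()
    if grid is None:
        grid = make_wavelength_grid(200.0, 800.0, 1.0)

    pures = np.array([pure_spectrum(c, grid) for c in components])
    comp = generate_mixture_design(design, seed)
    if comp.shape[1] != len(components):
        raise ValueError("design width does not match component count")

    clean = (comp / 100.0) @ pures
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x50EC]))
    sd = noise.sd_profile(grid)
    absorbance = clean + rng.standard_normal(clean.shape) * sd

    contrast = pures.max(axis=0) - pures.min(axis=0)
    informative = contrast >= cnr_threshold * np.maximum(sd, 1e-12)

    names = [c.name for c in components]
    spectra = SpectrumSet(wavelengths=grid, absorbance=absorbance)
    targets = {
        name: TargetVector(comp[:, i], name) for i, name in enumerate(names)
    }
    return SyntheticDataset(
        spectra=spectra,
        targets=targets,
        informative_mask=informative.astype(np.int8),
        compositions=comp,
        component_names=names,
        params={
            "seed": seed,
            "n_samples": design.n_samples,
            "n_wavelengths": int(grid.size),
            "base_sd": noise.base_sd,
            "uv_region": list(noise.uv_region),
            "uv_sd_multiplier": noise.uv_sd_multiplier,
            "cnr_threshold": cnr_threshold,
        },
    )


def split_train_predict(
    dataset: SyntheticDataset, train_fraction: float = 0.5, seed: int = 0
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Disjoint, exhaustive seeded split into training and prediction
    sets; the default halves a 102-sample set into 51/51."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    n = dataset.n_samples
    n_train = int(round(train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError("split would leave an empty set")
    perm = np.random.default_rng(seed).permutation(n)
    parts = []
    for idx in (np.sort(perm[:n_train]), np.sort(perm[n_train:])):
        parts.append(
            SyntheticDataset(
                spectra=dataset.spectra.take_samples(idx),
                targets={k: v.take(idx) for k, v in dataset.targets.items()},
                informative_mask=dataset.informative_mask,
                compositions=dataset.compositions[idx],
                component_names=dataset.component_names,
                params=dict(dataset.params),
            )
        )
    return parts[0], parts[1]


def default_benchmark_dataset(
    seed: int = 0,
    n_samples: int = 102,
    step: float = 1.0,
) -> SyntheticDataset:
    """The default study conditions: 102 quaternary samples on the
    200-800 nm grid.  ``step`` coarsens the grid (e.g. 5 nm -> 121
    channels) for reduced-scale benchmarking."""
    grid = make_wavelength_grid(200.0, 800.0, step)
    return generate_dataset(
        design=MixtureDesign(n_samples=n_samples), grid=grid, seed=seed
    )
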