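"""Synthetic library of left-ventricular CRL strain fields with infarcts.

The generator is a phenomenological stand-in for a library of forward
finite-element simulations of infarcted rodent hearts: it reproduces the
statistical structure that the segmentation networks must learn — a
contiguous infarct occupying 5-60% of the LV wall whose contraction is
depressed in proportion to its stiffness, surrounded by a smooth border
zone, on top of level-dependent healthy end-systolic strain baselines —
without solving any mechanics.

Geometry is a polar grid of four short-axis levels (base, mid, apical,
apex) by ``n_theta`` angular bins; every cell is treated as equal wall
area.  Infarct size and regional stiffness are Latin-hypercube sampled
(size fraction in [0.05, 0.60] of the wall, stiffness multiplier within
+/-30% of the mean), infarct centers are uniform over levels and angle,
and the region is grown from its center by geodesic distance until the
requested area is reached.  Inside the region each strain component is
attenuated toward zero with a severity that increases with the stiffness
multiplier; the border zone is a sigmoid in distance.  A smooth angular
modulation and a spatially correlated noise field provide within-example
variability, and four base parameter sets emulate hearts at 1-4 weeks
after infarction.

The high-fidelity domain variant additionally smooths the fields, biases
their amplitude and adds extra correlated noise, emulating the less exact
strain quantification obtained from human cine CMR.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import h5py
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import qmc

LEVELS = ("base", "mid", "apical", "apex")
COMPONENTS = ("CC", "RR", "LL")


def lhs_sample(n: int, bounds, seed=None) -> np.ndarray:
    """Latin hypercube sample: n points, one per stratum per dimension.

    ``bounds`` is a sequence of (low, high) pairs, one per dimension.
    """
    bounds = list(bounds)
    if not bounds:
        raise ValueError("bounds must be non-empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("each bound must satisfy low < high")
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    unit = sampler.random(n)
    return qmc.scale(unit, lo, hi)


@dataclass(frozen=True)
class InfarctSpec:
    """Sampled infarct geometry and stiffness for one example."""

    center_level: str
    center_angle: float
    size_fraction: float
    stiffness_multiplier: float

    def __post_init__(self):
        if self.center_level not in LEVELS:
            raise ValueError(f"unknown level {self.center_level!r}")
        if not 0.0 < self.size_fraction < 1.0:
            raise ValueError("size_fraction must be in (0, 1)")
        if not 0.7 - 1e-9 <= self.stiffness_multiplier <= 1.3 + 1e-9:
            raise ValueError("stiffness_multiplier must lie within +/-30% of 1")


@dataclass
class GeneratorConfig:
    """Defaults reproduce the library's size and sampling bounds."""

    n_examples: int = 592
    n_base_models: int = 4
    n_theta: int = 64
    size_bounds: tuple = (0.05, 0.60)
    stiffness_bounds: tuple = (0.7, 1.3)
    # healthy end-systolic baselines per level (base, mid, apical, apex);
    # circumferential and longitudinal shortening are negative, radial
    # thickening positive, magnitudes growing slightly toward the apex
    healthy_cc: tuple = (-0.11, -0.12, -0.13, -0.14)
    healthy_rr: tuple = (0.24, 0.26, 0.28, 0.30)
    healthy_ll: tuple = (-0.13, -0.14, -0.15, -0.16)
    # per-base-model amplitude scale, emulating 1-4 weeks post-MI phenotypes
    base_model_scales: tuple = (1.0, 0.95, 0.9, 0.85)
    angular_variation: float = 0.05
    # attenuation severity s = s0 + s1 * (multiplier - lo) / (hi - lo)
    severity_intercept: float = 0.55
    severity_slope: float = 0.40
    cc_bulge: float = 0.0
    border_zone_width: float = 0.12   # radians of geodesic distance
    level_spacing: float = 0.5        # inter-level geodesic distance, radians
    noise_amplitude: float = 0.015
    noise_correlation: float = 2.0    # angular bins
    hf_smooth_sigma: float = 2.0      # angular bins
    hf_amplitude_bias: float = 0.85
    hf_noise_amplitude: float = 0.025
    seed: int = 0

    def healthy_baseline(self, base_model_id: int) -> np.ndarray:
        """(4 levels, 3 components) healthy strain table for one base model."""
        scale = self.base_model_scales[(base_model_id - 1) % self.n_base_models]
        return scale * np.stack(
            [np.array(self.healthy_cc), np.array(self.healthy_rr),
             np.array(self.healthy_ll)], axis=1)

    def severity(self, stiffness_multiplier: float) -> float:
        lo, hi = self.stiffness_bounds
        t = (stiffness_multiplier - lo) / (hi - lo)
        return self.severity_intercept + self.severity_slope * t

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "GeneratorConfig":
        d = json.loads(s)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass
class StrainExample:
    """CRL strain profiles on the 4-level polar grid plus infarct mask."""

    strains: np.ndarray      # (4 levels, 3 components, n_theta)
    mask: np.ndarray         # (4 levels, n_theta) binary
    spec: InfarctSpec
    base_model_id: int
    domain: str              # "low_fidelity" | "high_fidelity"
    seed: int

    @property
    def mask_fraction(self) -> float:
        return float(self.mask.mean())


def sample_infarct_specs(config: GeneratorConfig) -> list[InfarctSpec]:
    """LHS-drawn size/stiffness, centers uniform over levels x angle."""
    samples = lhs_sample(config.n_examples,
                         [config.size_bounds, config.stiffness_bounds],
                         seed=config.seed)
    rng = np.random.default_rng(config.seed)
    levels = rng.integers(0, len(LEVELS), size=config.n_examples)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=config.n_examples)
    return [
        InfarctSpec(center_level=LEVELS[levels[i]],
                    center_angle=float(angles[i]),
                    size_fraction=float(samples[i, 0]),
                    stiffness_multiplier=float(samples[i, 1]))
        for i in range(config.n_examples)
    ]


def _geodesic_distance(config: GeneratorConfig, center_level: int,
                       center_angle: float) -> np.ndarray:
    """Distance from the infarct center to every (level, angle) cell."""
    theta = (np.arange(config.n_theta) + 0.5) * 2.0 * np.pi / config.n_theta
    dtheta = np.abs(theta - center_angle)
    dtheta = np.minimum(dtheta, 2.0 * np.pi - dtheta)
    dlevel = config.level_spacing * np.abs(
        np.arange(len(LEVELS))[:, None] - center_level)
    return np.sqrt(dtheta[None, :] ** 2 + dlevel ** 2)


def _grow_mask(config: GeneratorConfig, spec: InfarctSpec):
    """Region-grow by geodesic distance until the target cell count."""
    d = _geodesic_distance(config, LEVELS.index(spec.center_level),
                           spec.center_angle)
    n_cells = d.size
    target = max(1, int(round(spec.size_fraction * n_cells)))
    order = np.argsort(d, axis=None, kind="stable")
    mask = np.zeros(n_cells, dtype=np.uint8)
    mask[order[:target]] = 1
    threshold = d.reshape(-1)[order[target - 1]]
    return mask.reshape(d.shape), d, float(threshold)


def _correlated_noise(rng, shape, sigma, amplitude):
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = gaussian_filter1d(noise, sigma, axis=-1, mode="wrap")
        # renormalize so the amplitude is a standard deviation
        noise /= max(noise.std(), 1e-12)
    return amplitude * noise


def generate_strain_example(spec: InfarctSpec, config: GeneratorConfig,
                            domain: str = "low_fidelity",
                            seed: int = 0,
                            base_model_id: int = 1) -> StrainExample:
    """Synthesize one example: healthy baseline, infarct attenuation,
    border zone, correlated noise and (for the high-fidelity domain) the
    human-CMR-like smoothing/bias shift."""
    if domain not in ("low_fidelity", "high_fidelity"):
        raise ValueError(f"unknown domain {domain!r}")
    rng = np.random.default_rng(seed)
    mask, dist, threshold = _grow_mask(config, spec)

    baseline = config.healthy_baseline(base_model_id)  # (4, 3)
    theta = (np.arange(config.n_theta) + 0.5) * 2.0 * np.pi / config.n_theta
    phase = 2.0 * np.pi * (base_model_id - 1) / max(config.n_base_models, 1)
    angmod = 1.0 + config.angular_variation * np.sin(theta + phase)

    strains = baseline[:, :, None] * angmod[None, None, :]  # (4, 3, n_theta)

    # attenuation weight: ~1 deep inside the infarct, 0.5 at its edge,
    # decaying to 0 through the border zone
    severity = config.severity(spec.stiffness_multiplier)
    if config.border_zone_width > 0:
        w = 1.0 / (1.0 + np.exp((dist - threshold) / config.border_zone_width))
    else:
        w = (dist <= threshold).astype(float)
    strains = strains * (1.0 - severity * w[:, None, :])
    if config.cc_bulge:
        strains[:, 0, :] += config.cc_bulge * w

    strains = strains + _correlated_noise(
        rng, strains.shape, config.noise_correlation, config.noise_amplitude)

    if domain == "high_fidelity":
        if config.hf_smooth_sigma > 0:
            strains = gaussian_filter1d(strains, config.hf_smooth_sigma,
                                        axis=-1, mode="wrap")
        strains = strains * config.hf_amplitude_bias
        strains = strains + _correlated_noise(
            rng, strains.shape, config.noise_correlation,
            config.hf_noise_amplitude)

    return StrainExample(strains=strains.astype(np.float64), mask=mask,
                         spec=spec, base_model_id=base_model_id,
                         domain=domain, seed=seed)


@dataclass
class Library:
    examples: list
    config: GeneratorConfig

    def __len__(self):
        return len(self.examples)

    @property
    def manifest(self) -> pd.DataFrame:
        rows = []
        for i, ex in enumerate(self.examples):
            rows.append({
                "example_id": i,
                "base_model_id": ex.base_model_id,
                "domain": ex.domain,
                "seed": ex.seed,
                **asdict(ex.spec),
            })
        return pd.DataFrame(rows)


def build_library(config: GeneratorConfig,
                  domain: str = "low_fidelity") -> Library:
    """Generate the full library, cycling examples over the base models."""
    specs = sample_infarct_specs(config)
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=config.n_examples)
    examples = [
        generate_strain_example(
            spec, config, domain=domain, seed=int(seeds[i]),
            base_model_id=(i % config.n_base_models) + 1)
        for i, spec in enumerate(specs)
    ]
    return Library(examples=examples, config=config)


# -- persistence ---------------------------------------------------------------

def save_library(path, lib: Library) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = lib.config.to_json()
        f.create_dataset("strains",
                         data=np.stack([e.strains for e in lib.examples]))
        f.create_dataset("masks",
                         data=np.stack([e.mask for e in lib.examples]))
        man = lib.manifest
        for col in man.columns:
            data = man[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            f.create_dataset(f"manifest/{col}", data=data)


def load_library(path) -> Library:
    with h5py.File(path, "r") as f:
        config = GeneratorConfig.from_json(f.attrs["config"])
        strains = f["strains"][()]
        masks = f["masks"][()]
        man = {k: f[f"manifest/{k}"][()] for k in f["manifest"]}
    n = strains.shape[0]
    examples = []
    for i in range(n):
        spec = InfarctSpec(
            center_level=man["center_level"][i].decode(),
            center_angle=float(man["center_angle"][i]),
            size_fraction=float(man["size_fraction"][i]),
            stiffness_multiplier=float(man["stiffness_multiplier"][i]),
        )
        examples.append(StrainExample(
            strains=strains[i], mask=masks[i], spec=spec,
            base_model_id=int(man["base_model_id"][i]),
            domain=man["domain"][i].decode(), seed=int(man["seed"][i])))
    return Library(examples=examples, config=config)
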