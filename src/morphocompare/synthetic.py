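"""Synthetic morphometric datasets with the full crossed study design.

The generator emulates the structure of a repeated-measurement morphometric
study: several species, each sampled at several sites (populations), each
population holding a fixed set of individuals, every individual measured by
every measurer several times.  Signal and noise are controllable:

* population-level mean-shape displacement (the biological signal the
  separative-power analyses should detect);
* per-individual shape variation around the population mean (isotropic
  Gaussian in unit-centroid-size shape space);
* a fixed systematic landmark offset per measurer ("measurer bias", the
  source of the measurer effect / centroid ghosting);
* independent digitization noise per repeat (the source of imperfect
  repeatability);
* allometric scaling of linear measurements with standard length, M ~ SL^b.

Distance variables (truss/caliper modes) are derived from the same body
landmark geometry: each variable is an inter-landmark distance of a perturbed
configuration, scaled by SL^b.  Caliper mode inflates measurer bias and
repeat noise, emulating measurement on the fish itself rather than on a
static image.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datasets import DistanceDataset, LandmarkDataset


class InvalidDesignError(ValueError):
    """A design with non-positive counts or an impossible request."""


@dataclass(frozen=True)
class DesignSpec:
    """Cardinalities of the crossed measurement design.

    Defaults reproduce the study design: 3 species x 3 populations x
    30 individuals x 3 measurers x 3 repeats, 11 body landmarks, 7 scale
    landmarks, 16 distance variables.
    """

    n_species: int = 3
    n_populations: int = 3
    n_individuals: int = 30
    n_measurers: int = 3
    n_repeats: int = 3
    n_landmarks_body: int = 11
    n_landmarks_scale: int = 7
    n_distance_vars: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_species", "n_populations", "n_individuals",
                     "n_measurers", "n_repeats", "n_landmarks_body",
                     "n_landmarks_scale", "n_distance_vars"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise InvalidDesignError(f"{name} must be a positive integer, got {v!r}")

    @property
    def n_records(self) -> int:
        """Records per generated dataset: one per (species, population,
        individual, measurer, repeat) cell."""
        return (self.n_species * self.n_populations * self.n_individuals
                * self.n_measurers * self.n_repeats)


@dataclass(frozen=True)
class EffectSpec:
    """Signal and noise magnitudes, in unit-centroid-size shape units.

    ``population_shift`` displaces population mean shapes along fixed
    orthonormal directions; ``individual_sd`` is the per-coordinate SD of
    individual shapes around their population mean; ``measurer_bias`` is the
    norm of a fixed per-measurer landmark offset; ``repeat_noise`` is the
    per-coordinate SD of independent digitization noise; linear measurements
    scale as SL**allometry_exponent_b with SL drawn log-uniformly from
    ``sl_range`` (mm).
    """

    population_shift: float = 0.012
    individual_sd: float = 0.02
    measurer_bias: float = 0.004
    repeat_noise: float = 0.007
    allometry_exponent_b: float = 1.1
    sl_range: tuple[float, float] = (60.0, 135.0)
    species_shift: float = 0.08

    def __post_init__(self) -> None:
        for name in ("population_shift", "individual_sd", "measurer_bias",
                     "repeat_noise", "species_shift"):
            if getattr(self, name) < 0:
                raise InvalidDesignError(f"{name} must be nonnegative")
        lo, hi = self.sl_range
        if not (0 < lo < hi):
            raise InvalidDesignError("sl_range must be positive with min < max")


# Per-method digitization error profiles (shape units), chosen once to
# realize the study condition of method noise ordered TRA >> TRU ~ GMS >> GMB
# (image-based landmarks most precise, caliper-on-fish least).  See the
# methods note for the rationale behind the magnitudes.
METHOD_EFFECTS: dict[str, EffectSpec] = {
    "GMB": EffectSpec(measurer_bias=0.004, repeat_noise=0.005),
    "GMS": EffectSpec(measurer_bias=0.020, repeat_noise=0.010),
    "TRU": EffectSpec(measurer_bias=0.012, repeat_noise=0.014),
    # TRA is TRU's profile passed through the caliper inflation factors
    "TRA": EffectSpec(measurer_bias=0.012, repeat_noise=0.014),
}

#: caliper-mode inflation of (measurer_bias, repeat_noise) relative to truss
CALIPER_BIAS_INFLATION = 6.0
CALIPER_NOISE_INFLATION = 2.0

BODY_LANDMARK_NAMES = [
    "tip_of_snout", "occiput", "dorsal_fin_base", "upper_caudal_base",
    "lower_caudal_base", "anal_fin_base", "pelvic_fin_base",
    "pectoral_fin_base", "lower_head", "opercle_posterior", "eye",
]

SCALE_LANDMARK_NAMES = [
    "left_cranial_edge", "cranial_end", "right_cranial_edge",
    "left_caudal_edge", "focus", "right_caudal_edge", "caudal_peak",
]

# fish-body outline, digitization order as in BODY_LANDMARK_NAMES
_BODY_TEMPLATE = np.array([
    [0.00, 0.50], [0.28, 0.63], [0.55, 0.67], [0.95, 0.58], [0.95, 0.42],
    [0.68, 0.37], [0.45, 0.33], [0.25, 0.37], [0.10, 0.40], [0.22, 0.50],
    [0.08, 0.55],
])

# cycloid-scale polygon (focus interior)
_SCALE_TEMPLATE = np.array([
    [-0.45, 0.35], [0.00, 0.55], [0.45, 0.35],
    [-0.40, -0.25], [0.00, 0.05], [0.40, -0.25], [0.00, -0.55],
])

# "characteristic" scale shape (pronounced caudal peak and waist), emulating
# species whose scales are easier to landmark consistently
_SCALE_TEMPLATE_CHARACTERISTIC = np.array([
    [-0.50, 0.40], [0.00, 0.62], [0.50, 0.40],
    [-0.30, -0.30], [0.00, 0.10], [0.30, -0.30], [0.00, -0.80],
])

# 16 inter-landmark distances on the 11 body landmarks: a truss ladder along
# the body plus head measurements
TRUSS_PAIRS = [
    (0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, 8), (8, 0),
    (1, 7), (2, 6), (2, 7), (3, 5), (3, 6), (0, 9), (9, 10),
]


def _unit_shape(pts: np.ndarray) -> np.ndarray:
    """Center a configuration and scale it to unit centroid size."""
    pts = pts - pts.mean(axis=0)
    return pts / np.sqrt((pts ** 2).sum())


def _resolve_template(template: str, design: DesignSpec) -> tuple[np.ndarray, list[str], str]:
    if template == "body":
        base, names, method = _BODY_TEMPLATE, BODY_LANDMARK_NAMES, "GMB"
        k = design.n_landmarks_body
    elif template == "scale":
        base, names, method = _SCALE_TEMPLATE, SCALE_LANDMARK_NAMES, "GMS"
        k = design.n_landmarks_scale
    elif template == "scale_characteristic":
        base, names, method = _SCALE_TEMPLATE_CHARACTERISTIC, SCALE_LANDMARK_NAMES, "GMS"
        k = design.n_landmarks_scale
    else:
        raise InvalidDesignError(f"unknown template {template!r}")
    if k > len(base):
        raise InvalidDesignError(
            f"template {template!r} provides {len(base)} landmarks, {k} requested")
    return _unit_shape(base[:k].astype(float)), names[:k], method


def _orthonormal_directions(rng: np.random.Generator, dim: int, n: int) -> np.ndarray:
    """n fixed orthonormal directions in a dim-dimensional shape space."""
    raw = rng.standard_normal((dim, max(n, 1)))
    q, _ = np.linalg.qr(raw)
    return q[:, :n].T  # (n, dim)


def _true_shapes(rng: np.random.Generator, base: np.ndarray,
                 design: DesignSpec, effects: EffectSpec):
    """Draw species templates, population means, individual true shapes and SLs.

    Returns per-(species, population, individual) arrays so that the same
    individual keeps its shape and SL across measurers and repeats.
    """
    k = base.shape[0]
    dim = 2 * k
    species_dirs = _orthonormal_directions(rng, dim, design.n_species)
    pop_dirs = _orthonormal_directions(rng, dim, design.n_populations)
    shapes = np.empty((design.n_species, design.n_populations,
                       design.n_individuals, k, 2))
    sls = np.empty((design.n_species, design.n_populations, design.n_individuals))
    lo, hi = effects.sl_range
    for s in range(design.n_species):
        sp_template = base + effects.species_shift * species_dirs[s].reshape(k, 2)
        for p in range(design.n_populations):
            pop_mean = sp_template + effects.population_shift * pop_dirs[p].reshape(k, 2)
            shapes[s, p] = pop_mean + effects.individual_sd * rng.standard_normal(
                (design.n_individuals, k, 2))
            sls[s, p] = np.exp(rng.uniform(math.log(lo), math.log(hi),
                                           design.n_individuals))
    return shapes, sls


def _measurer_offsets(rng: np.random.Generator, k: int, n_measurers: int,
                      magnitude: float) -> np.ndarray:
    """One fixed landmark-offset vector per measurer, with norm = magnitude."""
    raw = rng.standard_normal((n_measurers, k, 2))
    norms = np.sqrt((raw ** 2).sum(axis=(1, 2), keepdims=True))
    return magnitude * raw / norms


def _design_labels(design: DesignSpec) -> pd.DataFrame:
    rows = []
    for s, p, i, m, r in itertools.product(
            range(design.n_species), range(design.n_populations),
            range(design.n_individuals), range(design.n_measurers),
            range(design.n_repeats)):
        sp = f"sp{s + 1}"
        site = f"site{p + 1}"
        rows.append((sp, site, f"{sp}-{site}-i{i + 1:02d}", f"M{m + 1}", r + 1))
    return pd.DataFrame(rows, columns=["species", "site", "individual",
                                       "measurer", "repeat"])


def generate_landmarks(design: DesignSpec, effects: EffectSpec | None = None,
                       template: str = "body") -> LandmarkDataset:
    """Generate a labelled landmark dataset under the crossed design.

    Each individual has a fixed true shape (population mean plus isotropic
    individual variation); every record is that shape plus the measurer's
    fixed offset plus independent per-repeat digitization noise, scaled by
    the individual's SL (so centroid size carries the size signal).
    """
    if effects is None:
        effects = METHOD_EFFECTS["GMB" if template == "body" else "GMS"]
    base, names, method = _resolve_template(template, design)
    k = base.shape[0]
    rng = np.random.default_rng(design.seed)
    shapes, sls = _true_shapes(rng, base, design, effects)
    offsets = _measurer_offsets(rng, k, design.n_measurers, effects.measurer_bias)

    coords = np.empty((design.n_records, k, 2))
    row = 0
    for s in range(design.n_species):
        for p in range(design.n_populations):
            for i in range(design.n_individuals):
                true = shapes[s, p, i]
                sl = sls[s, p, i]
                for m in range(design.n_measurers):
                    observed_mean = true + offsets[m]
                    for _ in range(design.n_repeats):
                        noise = effects.repeat_noise * rng.standard_normal((k, 2))
                        coords[row] = sl * (observed_mean + noise)
                        row += 1
    return LandmarkDataset(_design_labels(design), coords, names, method)


def _distance_pairs(design: DesignSpec) -> list[tuple[int, int]]:
    k = _BODY_TEMPLATE.shape[0]
    if design.n_distance_vars <= len(TRUSS_PAIRS):
        return TRUSS_PAIRS[: design.n_distance_vars]
    extra = [p for p in itertools.combinations(range(k), 2) if p not in TRUSS_PAIRS]
    pairs = TRUSS_PAIRS + extra
    if design.n_distance_vars > len(pairs):
        raise InvalidDesignError(
            f"at most {len(pairs)} distance variables available")
    return pairs[: design.n_distance_vars]


def generate_distances(design: DesignSpec, effects: EffectSpec | None = None,
                       mode: str = "truss",
                       bias_inflation: float = CALIPER_BIAS_INFLATION,
                       noise_inflation: float = CALIPER_NOISE_INFLATION,
                       ) -> DistanceDataset:
    """Generate a labelled distance dataset (truss or caliper mode).

    Variables are inter-landmark distances of a perturbed body configuration,
    scaled by SL**b, so they inherit the population/individual/measurer/repeat
    structure of the landmark generator.  Caliper mode multiplies measurer
    bias and repeat noise by the inflation factors (defaults > 1); with both
    factors at 1 the two modes are identical.
    """
    if mode not in ("truss", "caliper"):
        raise InvalidDesignError(f"mode must be 'truss' or 'caliper', got {mode!r}")
    if effects is None:
        effects = METHOD_EFFECTS["TRU"]
    if mode == "caliper":
        effects = replace(effects,
                          measurer_bias=effects.measurer_bias * bias_inflation,
                          repeat_noise=effects.repeat_noise * noise_inflation)
    base, _, _ = _resolve_template("body", replace(design, n_landmarks_body=11))
    k = base.shape[0]
    pairs = _distance_pairs(design)
    rng = np.random.default_rng(design.seed)
    shapes, sls = _true_shapes(rng, base, design, effects)
    offsets = _measurer_offsets(rng, k, design.n_measurers, effects.measurer_bias)

    ii = np.array([a for a, _ in pairs])
    jj = np.array([b for _, b in pairs])
    b_exp = effects.allometry_exponent_b

    values = np.empty((design.n_records, len(pairs)))
    sl_col = np.empty(design.n_records)
    row = 0
    for s in range(design.n_species):
        for p in range(design.n_populations):
            for i in range(design.n_individuals):
                true = shapes[s, p, i]
                sl = sls[s, p, i]
                for m in range(design.n_measurers):
                    observed_mean = true + offsets[m]
                    for _ in range(design.n_repeats):
                        cfg = observed_mean + effects.repeat_noise * \
                            rng.standard_normal((k, 2))
                        d = np.sqrt(((cfg[ii] - cfg[jj]) ** 2).sum(axis=1))
                        values[row] = d * sl ** b_exp
                        sl_col[row] = sl
                        row += 1
    names = [f"d{a + 1}_{b + 1}" for a, b in pairs]
    method = "TRU" if mode == "truss" else "TRA"
    return DistanceDataset(_design_labels(design), sl_col,
                           pd.DataFrame(values, columns=names), method)


def generate_method_suite(design: DesignSpec,
                          scale_template: str = "scale",
                          ) -> dict[str, LandmarkDataset | DistanceDataset]:
    """All four method datasets for one design, with per-method error profiles."""
    return {
        "GMB": generate_landmarks(design, METHOD_EFFECTS["GMB"], "body"),
        "GMS": generate_landmarks(design, METHOD_EFFECTS["GMS"], scale_template),
        "TRU": generate_distances(design, METHOD_EFFECTS["TRU"], "truss"),
        "TRA": generate_distances(design, METHOD_EFFECTS["TRA"], "caliper"),
    }


def measurement_count(dataset: LandmarkDataset | DistanceDataset) -> int:
    """Number of recorded measurements, counting each landmark or distance
    variable as one measurement per record (the study's bookkeeping)."""
    if isinstance(dataset, LandmarkDataset):
        return dataset.n_records * dataset.n_landmarks
    return dataset.n_records * len(dataset.variable_names)
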