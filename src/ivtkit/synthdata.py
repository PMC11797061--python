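"""Seeded generators for every input the analysis modules consume.

Each generator returns its outputs together with a :class:`SyntheticTruth`
record holding the ground-truth parameters, so that parameter-recovery tests
can compare estimates with what generated the data.  Regenerating with the
same parameters and seed reproduces outputs bit-identically (all randomness
flows through ``numpy.random.default_rng(seed)``).

What is emulated, and what is not:

* SHAPE counts - Poisson coverage and binomial per-base mutation counts with
  an NAI rate elevation proportional to the true reactivity over a constant
  DMSO background.  No read-level artifacts (PCR duplicates, alignment
  bias, overdispersion beyond Poisson).
* Dose-response - 4PL-shaped optical densities with Gaussian noise and an
  optional fraction of gross outliers.
* Endpoint dilution - single-hit infection: a well receiving a mean of m
  infectious units is infected with probability 1 - e^(-m); the titer is
  expressed in CCID50 units (one CCID50 = ln 2 infectious units), so the
  infected proportion is exactly 1/2 at the dilution matching the titer.
* Dot blot - intensities linear in log10(amount) with multiplicative noise.
* Reporter-cell images - non-overlapping constant-intensity disks on a flat
  (optionally noisy) background; no cell morphology, clumping or focus
  variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose_response import DoseResponseDataset, eval_4pl
from .exceptions import FormatError, ParameterError, PlacementError
from .shape import MutationCountTable
from .titer import DilutionAssay

# Reactivity distributions for structured profiles.  Paired nucleotides are
# conformationally constrained and draw low reactivities; unpaired ones are
# flexible and draw high reactivities.  Gamma shapes/scales chosen to mimic
# typical normalized SHAPE profiles (paired mean 0.04, unpaired mean 0.8).
PAIRED_GAMMA = (2.0, 0.02)
UNPAIRED_GAMMA = (4.0, 0.2)

PHI6_STANDARD_PG = (500.0, 250.0, 125.0, 63.0, 31.0, 16.0)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every generator output."""

    kind: str
    params: dict
    seed: int


# ---------------------------------------------------------------------------
# SHAPE
# ---------------------------------------------------------------------------


def _parse_dotbracket(dotbracket: str) -> np.ndarray:
    """Return a boolean per-position array, True where paired."""
    if len(dotbracket) < 10:
        raise FormatError("dot-bracket string must have length >= 10")
    paired = np.zeros(len(dotbracket), dtype=bool)
    stack: list[int] = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced ')' at position {i + 1}")
            j = stack.pop()
            paired[i] = paired[j] = True
        elif ch != ".":
            raise FormatError(f"invalid character {ch!r} at position {i + 1}")
    if stack:
        raise FormatError(f"unclosed '(' at position {stack[-1] + 1}")
    return paired


def random_hairpin_structure(length: int, seed: int) -> str:
    """A random valid dot-bracket string: hairpins interleaved with loops."""
    if length < 10:
        raise ParameterError("structure length must be >= 10")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    n = 0
    while n < length:
        stem = int(rng.integers(3, 9))
        loop = int(rng.integers(3, 7))
        linker = int(rng.integers(1, 6))
        if n + 2 * stem + loop + linker > length:
            parts.append("." * (length - n))
            break
        parts.append("(" * stem + "." * loop + ")" * stem + "." * linker)
        n += 2 * stem + loop + linker
    return "".join(parts)


def gen_structured_reactivity(
    dotbracket: str, seed: int
) -> tuple[np.ndarray, SyntheticTruth]:
    """True reactivity profile driven by a secondary structure.

    Paired positions draw Gamma(2, 0.02) reactivities, unpaired positions
    Gamma(4, 0.2); all values nonnegative.
    """
    paired = _parse_dotbracket(dotbracket)
    rng = np.random.default_rng(seed)
    profile = np.empty(paired.size)
    # draw in position order so the profile is invariant to pairing layout
    for i, is_paired in enumerate(paired):
        shape, scale = PAIRED_GAMMA if is_paired else UNPAIRED_GAMMA
        profile[i] = rng.gamma(shape, scale)
    truth = SyntheticTruth(
        kind="structured_reactivity",
        params={
            "dotbracket": dotbracket,
            "paired_gamma": PAIRED_GAMMA,
            "unpaired_gamma": UNPAIRED_GAMMA,
            "profile": profile.copy(),
        },
        seed=seed,
    )
    return profile, truth


def gen_shape_counts(
    truth_profile: np.ndarray,
    coverage_mean: float = 50_000.0,
    background_rate: float = 0.002,
    sensitivity: float = 0.02,
    n_replicates: int = 3,
    seed: int = 0,
    rna_id: str = "synthetic",
    background_jitter_sd: float = 0.0,
) -> tuple[list[tuple[MutationCountTable, MutationCountTable]], SyntheticTruth]:
    """Paired NAI/DMSO count tables per replicate.

    Coverage is Poisson with the stated mean; DMSO mutation counts are
    binomial at the background rate (constant across positions by default,
    with optional per-position jitter); NAI counts are binomial at
    ``background + sensitivity * reactivity``.
    """
    profile = np.asarray(truth_profile, dtype=float)
    if np.any(profile < 0):
        raise ParameterError("true reactivities must be nonnegative")
    if background_rate < 0:
        raise ParameterError("background rate must be >= 0")
    max_rate = background_rate + sensitivity * profile.max()
    if max_rate > 1.0:
        raise ParameterError(
            f"NAI mutation rate {max_rate:.3f} exceeds 1 at the most reactive position"
        )
    rng = np.random.default_rng(seed)
    n = profile.size
    background = np.full(n, background_rate)
    if background_jitter_sd > 0:
        background = np.clip(
            background + rng.normal(0.0, background_jitter_sd, size=n), 0.0, 1.0
        )
    nai_rate = np.clip(background + sensitivity * profile, 0.0, 1.0)

    pairs = []
    for rep in range(1, n_replicates + 1):
        cov_nai = rng.poisson(coverage_mean, size=n)
        cov_dmso = rng.poisson(coverage_mean, size=n)
        mut_nai = rng.binomial(cov_nai, nai_rate)
        mut_dmso = rng.binomial(cov_dmso, background)
        pairs.append(
            (
                MutationCountTable(rna_id, "NAI", rep, cov_nai, mut_nai),
                MutationCountTable(rna_id, "DMSO", rep, cov_dmso, mut_dmso),
            )
        )
    truth = SyntheticTruth(
        kind="shape_counts",
        params={
            "profile": profile.copy(),
            "coverage_mean": coverage_mean,
            "background_rate": background_rate,
            "sensitivity": sensitivity,
            "n_replicates": n_replicates,
        },
        seed=seed,
    )
    return pairs, truth


# ---------------------------------------------------------------------------
# dose response
# ---------------------------------------------------------------------------


def gen_dose_response(
    kd: float,
    top: float,
    slope: float,
    concentrations,
    noise_sd: float = 0.05,
    outlier_fraction: float = 0.0,
    outlier_scale: float = 10.0,
    n_replicates: int = 4,
    seed: int = 0,
    group: str = "synthetic",
) -> tuple[DoseResponseDataset, SyntheticTruth]:
    """4PL-shaped optical densities with Gaussian noise and gross outliers.

    OD = 4PL(c; 0, top, kd, slope) + N(0, noise_sd); a random subset of
    exactly round(outlier_fraction * N) points is additionally displaced by
    +/- outlier_scale * noise_sd (random sign), which makes injected
    outliers gross relative to the curve while keeping their magnitude tied
    to the noise level.  The displaced indices are recorded in the truth.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if kd <= 0:
        raise ParameterError("Kd must be strictly positive")
    if np.any(concentrations <= 0):
        raise ParameterError("concentrations must be strictly positive")
    if not 0 <= outlier_fraction < 0.5:
        raise ParameterError("outlier fraction must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    conc = np.tile(concentrations, n_replicates)
    replicate = np.repeat(np.arange(1, n_replicates + 1), concentrations.size)
    clean = eval_4pl(conc, 0.0, top, kd, slope)
    od = clean + rng.normal(0.0, noise_sd, size=conc.size)
    n_out = int(round(outlier_fraction * conc.size))
    idx = np.sort(rng.choice(conc.size, size=n_out, replace=False))
    if n_out:
        signs = rng.choice([-1.0, 1.0], size=n_out)
        od[idx] = od[idx] + signs * outlier_scale * noise_sd
    dataset = DoseResponseDataset(
        group=group, concentration=conc, od=od, replicate=replicate,
        blank_corrected=True,
    )
    truth = SyntheticTruth(
        kind="dose_response",
        params={
            "kd": kd, "top": top, "slope": slope, "bottom": 0.0,
            "noise_sd": noise_sd, "outlier_indices": idx,
            "outlier_scale": outlier_scale, "n_replicates": n_replicates,
        },
        seed=seed,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# endpoint dilution
# ---------------------------------------------------------------------------


def gen_dilution_assay(
    true_log10_titer: float,
    dilution_exponents,
    wells_per_dilution: int = 8,
    seed: int = 0,
) -> tuple[DilutionAssay, SyntheticTruth]:
    """Single-hit dilution-infection outcomes.

    With the titer T expressed as log10 CCID50 and exponent x, a well is
    infected with probability 1 - exp(-ln 2 * 10^(T - x)): the infected
    proportion crosses 1/2 exactly at x = T, which makes the Spearman-Karber
    estimate approximately unbiased for T.
    """
    exponents = np.asarray(dilution_exponents, dtype=float)
    steps = np.diff(exponents)
    if exponents.size < 2 or np.any(steps <= 0) or not np.allclose(
        steps, steps[0], rtol=0, atol=1e-9
    ):
        raise ParameterError("exponents must be strictly increasing, equally spaced")
    if wells_per_dilution < 1:
        raise ParameterError("wells_per_dilution must be >= 1")
    rng = np.random.default_rng(seed)
    p = 1.0 - np.exp(-np.log(2.0) * 10.0 ** (true_log10_titer - exponents))
    infected = rng.binomial(wells_per_dilution, p)
    assay = DilutionAssay(
        exponents=exponents,
        wells_total=np.full(exponents.size, wells_per_dilution),
        wells_infected=infected,
    )
    truth = SyntheticTruth(
        kind="dilution_assay",
        params={
            "log10_titer": true_log10_titer,
            "wells_per_dilution": wells_per_dilution,
            "infection_probabilities": p,
        },
        seed=seed,
    )
    return assay, truth


# ---------------------------------------------------------------------------
# dot blot
# ---------------------------------------------------------------------------


def gen_dotblot(
    standard_amounts=PHI6_STANDARD_PG,
    curve_params: tuple[float, float] = (10.0, 40.0),
    noise_sd: float = 0.0,
    unknown_amounts=(),
    seed: int = 0,
) -> tuple[dict, SyntheticTruth]:
    """Dot-blot intensities for a standard dilution series plus unknowns.

    Intensity follows the log-linear model a + b * log10(amount) with
    multiplicative Gaussian noise of fractional SD ``noise_sd``; unknowns
    are generated from the same curve.  The default standard series is the
    bacteriophage Phi6 dsRNA dilution [500, 250, 125, 63, 31, 16] pg.
    """
    standards = np.asarray(standard_amounts, dtype=float)
    unknowns = np.asarray(unknown_amounts, dtype=float)
    if np.any(standards <= 0) or np.any(unknowns <= 0):
        raise ParameterError("amounts must be strictly positive")
    a, b = curve_params
    if b <= 0:
        raise ParameterError("intensity must increase with amount (b > 0)")
    rng = np.random.default_rng(seed)

    def intensities(amounts):
        clean = a + b * np.log10(amounts)
        if np.any(clean <= 0):
            raise ParameterError("curve parameters give non-positive intensity")
        return clean * (1.0 + rng.normal(0.0, noise_sd, size=amounts.size))

    table = {
        "standard_amounts": standards,
        "standard_intensities": intensities(standards),
        "unknown_intensities": intensities(unknowns) if unknowns.size else np.array([]),
    }
    truth = SyntheticTruth(
        kind="dotblot",
        params={
            "intercept": a, "slope": b, "noise_sd": noise_sd,
            "unknown_amounts": unknowns.copy(),
        },
        seed=seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# reporter-cell images
# ---------------------------------------------------------------------------


def _rasterize_disk(shape, center, radius_px):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def gen_cell_image(
    n_pass: int,
    n_fail_small: int = 0,
    n_fail_dim: int = 0,
    image_shape: tuple[int, int] = (512, 512),
    pixel_size: float = 1.0,
    background_noise_sd: float = 0.0,
    seed: int = 0,
    background_level: float = 100.0,
    pass_intensity: tuple[float, float] = (600.0, 2000.0),
    dim_intensity: float = 250.0,
    pass_area_um2: tuple[float, float] = (200.0, 700.0),
    small_area_um2: tuple[float, float] = (40.0, 100.0),
    max_tries: int = 2000,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Disk-shaped fluorescent cells on a (optionally noisy) background.

    ``n_pass`` disks satisfy both counting gates (area within 150-800 um^2
    with margin, mean intensity >= 400); ``n_fail_small`` disks are bright
    but below the area gate; ``n_fail_dim`` disks have valid area but mean
    intensity below 400 (yet above typical segmentation thresholds, so they
    are segmented and then rejected by the gate).  Objects are placed
    without overlap by rejection sampling; a :class:`PlacementError` is
    raised after bounded retries.
    """
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be positive")
    rng = np.random.default_rng(seed)
    image = np.full(image_shape, background_level, dtype=float)
    occupied = np.zeros(image_shape, dtype=bool)

    specs = []
    for _ in range(n_pass):
        area = rng.uniform(*pass_area_um2)
        specs.append((area, rng.uniform(*pass_intensity)))
    for _ in range(n_fail_small):
        area = rng.uniform(*small_area_um2)
        specs.append((area, rng.uniform(*pass_intensity)))
    for _ in range(n_fail_dim):
        area = rng.uniform(*pass_area_um2)
        specs.append((area, dim_intensity))

    for area_um2, intensity in specs:
        radius_px = np.sqrt(area_um2 / np.pi) / pixel_size
        margin = int(np.ceil(radius_px)) + 2
        placed = False
        for _ in range(max_tries):
            center = (
                rng.integers(margin, image_shape[0] - margin),
                rng.integers(margin, image_shape[1] - margin),
            )
            disk = _rasterize_disk(image_shape, center, radius_px)
            halo = _rasterize_disk(image_shape, center, radius_px + 2)
            if not np.any(occupied & halo):
                image[disk] = intensity
                occupied |= halo
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place a disk of {area_um2:.0f} um^2 after {max_tries} tries"
            )
    if background_noise_sd > 0:
        image = image + rng.normal(0.0, background_noise_sd, size=image_shape)
    truth = SyntheticTruth(
        kind="cell_image",
        params={
            "n_pass": n_pass,
            "n_fail_small": n_fail_small,
            "n_fail_dim": n_fail_dim,
            "pixel_size": pixel_size,
        },
        seed=seed,
    )
    return image, truth
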