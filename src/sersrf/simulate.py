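"""Simulation of SERS-like spectral datasets.

Two-stage generative model for surface-enhanced Raman scattering (SERS)
classification data with known ground truth:

1. A library of twelve *single spectra* is drawn on a fixed wavenumber grid
   (300-1700 cm^-1, 1 cm^-1 resolution, 1401 variables).  Each single
   spectrum is a constant baseline plus i.i.d. Gaussian noise
   (N(200, 50^2) per point) with 3-10 Gaussian bands added, each band
   having a random center, width (5-20 cm^-1, the Gaussian's standard
   deviation) and peak amplitude (1000-10000 a.u.).

2. Composed SERS spectra are convex combinations of 2-5 single spectra.
   Single spectra 1 and 2 are *characteristic*: spectrum 1 may only occur
   in group 1 and spectrum 2 only in group 2; spectra 3-12 are shared
   background.  A fraction ``f`` of each group's spectra contains its
   characteristic single spectrum with mixing weight ``w ~ U(0.1, 0.8)``;
   the rest of the mass (and all non-characteristic spectra) is split over
   background singles.  Finally every composed spectrum is normalized by
   its intensity sum, so each row sums to one.

The bands of single spectra 1 and 2 are the ground-truth important
variables; a variable belongs to a band iff it lies within
``band_extent_k`` standard deviations of the band center (default 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WAVENUMBER_MIN",
    "WAVENUMBER_MAX",
    "N_VARIABLES",
    "spectral_grid",
    "Band",
    "SingleSpectrum",
    "Composition",
    "SimulationConfig",
    "SersDataset",
    "simulate_single_spectrum",
    "build_library",
    "compose_spectrum",
    "vector_normalize",
    "band_membership",
    "simulate_replicate",
    "simulate_study",
    "write_dataset",
    "read_dataset",
]

WAVENUMBER_MIN = 300.0
WAVENUMBER_MAX = 1700.0
N_VARIABLES = 1401

N_SINGLE_SPECTRA = 12
CHARACTERISTIC_IDS = (1, 2)
BACKGROUND_IDS = tuple(range(3, 13))


def spectral_grid() -> np.ndarray:
    """The fixed wavenumber grid: 300..1700 cm^-1 inclusive, step 1."""
    return np.arange(WAVENUMBER_MIN, WAVENUMBER_MAX + 1.0, 1.0)


@dataclass(frozen=True)
class Band:
    """One Gaussian spectral band.

    ``width`` is the standard deviation of the Gaussian in cm^-1 and
    ``amplitude`` its peak height, so the band contributes
    ``amplitude * exp(-(x - center)^2 / (2 width^2))`` to the spectrum.
    """

    center: float
    width: float
    amplitude: float

    def curve(self, wavenumbers: np.ndarray) -> np.ndarray:
        d = wavenumbers - self.center
        return self.amplitude * np.exp(-(d * d) / (2.0 * self.width * self.width))


@dataclass
class SingleSpectrum:
    """A baseline+noise spectrum with its band list."""

    id: int
    intensities: np.ndarray
    bands: list[Band]
    baseline_mean: float = 200.0
    noise_sd: float = 50.0

    @property
    def characteristic(self) -> bool:
        return self.id in CHARACTERISTIC_IDS


@dataclass(frozen=True)
class Composition:
    """Recipe for one composed SERS spectrum."""

    contributing_ids: tuple[int, ...]
    proportions: tuple[float, ...]
    group: int
    contains_characteristic: bool
    w: float | None = None

    def __post_init__(self):
        if not np.isclose(sum(self.proportions), 1.0, atol=1e-9):
            raise ValueError("composition proportions must sum to 1")
        if len(self.contributing_ids) != len(self.proportions):
            raise ValueError("ids and proportions length mismatch")
        if len(set(self.contributing_ids)) != len(self.contributing_ids):
            raise ValueError("contributing ids must be distinct")
        other_char = 2 if self.group == 1 else 1
        if other_char in self.contributing_ids:
            raise ValueError(
                f"group {self.group} spectrum may not contain single spectrum {other_char}"
            )


@dataclass
class SimulationConfig:
    """All constants of the generative model.

    Defaults are the stated full-scale study conditions: 500 spectra per
    group, 50 replicates per value of ``f``.
    """

    f: float = 0.8
    n_replicates: int = 50
    n_per_group: int = 500
    n_bands_range: tuple[int, int] = (3, 10)
    width_range: tuple[float, float] = (5.0, 20.0)
    amplitude_range: tuple[float, float] = (1000.0, 10000.0)
    baseline_mean: float = 200.0
    noise_sd: float = 50.0
    w_range: tuple[float, float] = (0.1, 0.8)
    n_components_range: tuple[int, int] = (2, 5)
    band_extent_k: float = 2.0
    background_weights: str = "rescaled-uniform"  # or "dirichlet"
    noise_mode: str = "per-spectrum"  # or "library"
    seed: int = 0

    def __post_init__(self):
        if self.f < 0 or self.f > 1:
            raise ValueError("f must be in [0, 1]")
        n_char = self.f * self.n_per_group
        if abs(n_char - round(n_char)) > 1e-9:
            raise ValueError("f * n_per_group must be integral")
        if self.band_extent_k <= 0:
            raise ValueError("band_extent_k must be positive")
        if self.background_weights not in ("rescaled-uniform", "dirichlet"):
            raise ValueError("unknown background_weights rule")
        if self.noise_mode not in ("per-spectrum", "library"):
            raise ValueError("noise_mode must be 'per-spectrum' or 'library'")


@dataclass
class SersDataset:
    """One simulated replicate: normalized spectra, labels, ground truth."""

    spectra: np.ndarray  # (n, 1401), rows sum to 1
    labels: np.ndarray  # (n,) in {1, 2}
    compositions: list[Composition]
    f: float
    replicate_id: int
    char_band_mask: np.ndarray  # (1401,) bool: variable in a characteristic band
    band_masks: dict[int, list[np.ndarray]]  # single-spectrum id -> per-band masks

    @property
    def n_spectra(self) -> int:
        return self.spectra.shape[0]

    @property
    def characteristic_band_masks(self) -> list[np.ndarray]:
        """Per-band masks of the bands of single spectra 1 and 2.

        Empty in the null scenario (f=0), where no spectrum contains a
        characteristic band and sensitivity is undefined.
        """
        if self.f == 0:
            return []
        return [m for sid in CHARACTERISTIC_IDS for m in self.band_masks[sid]]


def simulate_single_spectrum(
    grid: np.ndarray,
    rng: np.random.Generator,
    *,
    spectrum_id: int = 0,
    baseline_mean: float = 200.0,
    noise_sd: float = 50.0,
    n_bands_range: tuple[int, int] = (3, 10),
    width_range: tuple[float, float] = (5.0, 20.0),
    amplitude_range: tuple[float, float] = (1000.0, 10000.0),
    n_bands: int | None = None,
) -> SingleSpectrum:
    """Draw one single spectrum: baseline noise plus Gaussian bands.

    ``n_bands`` overrides the random band count (test hook; 0 gives a pure
    baseline spectrum).
    """
    intensities = rng.normal(baseline_mean, noise_sd, size=grid.shape[0])
    if n_bands is None:
        n_bands = int(rng.integers(n_bands_range[0], n_bands_range[1] + 1))
    bands = []
    for _ in range(n_bands):
        center = rng.uniform(grid[0], grid[-1])
        width = rng.uniform(*width_range)
        amplitude = rng.uniform(*amplitude_range)
        band = Band(center, width, amplitude)
        intensities += band.curve(grid)
        bands.append(band)
    return SingleSpectrum(
        id=spectrum_id,
        intensities=intensities,
        bands=bands,
        baseline_mean=baseline_mean,
        noise_sd=noise_sd,
    )


def build_library(
    grid: np.ndarray, rng: np.random.Generator, config: SimulationConfig | None = None
) -> list[SingleSpectrum]:
    """Draw the library of 12 single spectra (ids 1..12).

    Ids 1 and 2 are the characteristic spectra of groups 1 and 2; ids 3-12
    are shared background.
    """
    config = config or SimulationConfig()
    return [
        simulate_single_spectrum(
            grid,
            rng,
            spectrum_id=sid,
            baseline_mean=config.baseline_mean,
            noise_sd=config.noise_sd,
            n_bands_range=config.n_bands_range,
            width_range=config.width_range,
            amplitude_range=config.amplitude_range,
        )
        for sid in range(1, N_SINGLE_SPECTRA + 1)
    ]


def compose_spectrum(
    library: Sequence[SingleSpectrum], composition: Composition
) -> np.ndarray:
    """Weighted sum of the contributing single spectra (not normalized)."""
    by_id = {s.id: s for s in library}
    out = np.zeros_like(library[0].intensities)
    for sid, prop in zip(composition.contributing_ids, composition.proportions):
        if sid not in by_id:
            raise KeyError(f"unknown single spectrum id {sid}")
        out += prop * by_id[sid].intensities
    return out


def vector_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Divide each intensity by the spectrum's intensity sum.

    Works on one spectrum or a matrix of row spectra.  Note this is
    sum (L1) normalization, as the simulation framework defines
    "vector normalization", not the L2 convention.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    sums = spectrum.sum(axis=-1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("cannot normalize a spectrum with non-positive sum")
    return spectrum / sums


def band_membership(
    bands: Sequence[Band], grid: np.ndarray, band_extent_k: float = 2.0
) -> list[np.ndarray]:
    """Boolean mask per band: |wavenumber - center| <= k * width.

    Masks are implicitly clipped at the grid edges.
    """
    if band_extent_k <= 0:
        raise ValueError("band_extent_k must be positive")
    return [np.abs(grid - b.center) <= band_extent_k * b.width for b in bands]


def _library_band_masks(
    library: Sequence[SingleSpectrum], grid: np.ndarray, band_extent_k: float
) -> tuple[dict[int, list[np.ndarray]], np.ndarray]:
    masks = {
        s.id: band_membership(s.bands, grid, band_extent_k) for s in library
    }
    char = np.zeros(grid.shape[0], dtype=bool)
    for sid in CHARACTERISTIC_IDS:
        for m in masks[sid]:
            char |= m
    return masks, char


def _background_split(rng: np.random.Generator, k: int, mass: float, rule: str) -> np.ndarray:
    """Split ``mass`` over ``k`` background spectra."""
    if rule == "dirichlet":
        w = rng.dirichlet(np.ones(k))
    else:
        u = rng.uniform(0.0, 1.0, size=k)
        while u.sum() <= 0:  # pragma: no cover - probability zero
            u = rng.uniform(0.0, 1.0, size=k)
        w = u / u.sum()
    return w * mass


def _draw_composition(
    rng: np.random.Generator, group: int, with_char: bool, config: SimulationConfig
) -> Composition:
    bg_ids = np.array(BACKGROUND_IDS)
    if with_char:
        w = rng.uniform(*config.w_range)
        n_bg = int(rng.integers(config.n_components_range[0] - 1,
                                config.n_components_range[1]))  # 1..4
        ids = rng.choice(bg_ids, size=n_bg, replace=False)
        props = _background_split(rng, n_bg, 1.0 - w, config.background_weights)
        char_id = CHARACTERISTIC_IDS[group - 1]
        return Composition(
            contributing_ids=(char_id, *ids.tolist()),
            proportions=(w, *props.tolist()),
            group=group,
            contains_characteristic=True,
            w=w,
        )
    n_bg = int(rng.integers(config.n_components_range[0],
                            config.n_components_range[1] + 1))  # 2..5
    ids = rng.choice(bg_ids, size=n_bg, replace=False)
    props = _background_split(rng, n_bg, 1.0, config.background_weights)
    return Composition(
        contributing_ids=tuple(ids.tolist()),
        proportions=tuple(props.tolist()),
        group=group,
        contains_characteristic=False,
    )


def _compose_fresh_noise(
    band_curves: dict[int, np.ndarray],
    composition: Composition,
    rng: np.random.Generator,
    baseline_mean: float,
    noise_sd: float,
) -> np.ndarray:
    """Weighted band curves plus a fresh baseline-noise realization.

    Summing independently re-realized single spectra with weights p_i
    gives baseline noise N(mean, sd^2 * sum(p_i^2)); drawing that
    directly is distributionally identical and avoids sharing one frozen
    noise vector across spectra (which would leak class information into
    every variable).
    """
    out = np.zeros_like(next(iter(band_curves.values())))
    sq = 0.0
    for sid, prop in zip(composition.contributing_ids, composition.proportions):
        out += prop * band_curves[sid]
        sq += prop * prop
    out += rng.normal(baseline_mean, noise_sd * np.sqrt(sq), size=out.shape)
    return out


def simulate_replicate(
    library: Sequence[SingleSpectrum],
    config: SimulationConfig,
    replicate_id: int,
    rng: np.random.Generator,
) -> SersDataset:
    """Compose one replicate of ``2 * n_per_group`` normalized SERS spectra.

    Exactly ``round(f * n_per_group)`` spectra per group contain the
    group's characteristic single spectrum (an exact count, not Bernoulli
    draws, so the null scenario f=0 is exact).  With the default
    ``noise_mode="per-spectrum"`` each composed spectrum receives its own
    baseline-noise realization on top of the library's fixed band
    structure; ``noise_mode="library"`` instead combines the fixed
    single-spectrum vectors verbatim (their noise is then shared by every
    spectrum containing them).
    """
    grid = spectral_grid()
    n_char = int(round(config.f * config.n_per_group))
    band_curves = {
        s.id: sum((b.curve(grid) for b in s.bands), np.zeros(grid.shape[0]))
        for s in library
    }
    compositions: list[Composition] = []
    rows = []
    labels = []
    for group in (1, 2):
        for i in range(config.n_per_group):
            comp = _draw_composition(rng, group, i < n_char, config)
            compositions.append(comp)
            if config.noise_mode == "per-spectrum":
                rows.append(
                    _compose_fresh_noise(
                        band_curves, comp, rng, config.baseline_mean, config.noise_sd
                    )
                )
            else:
                rows.append(compose_spectrum(library, comp))
            labels.append(group)
    spectra = vector_normalize(np.vstack(rows))
    band_masks, char_mask = _library_band_masks(library, grid, config.band_extent_k)
    if config.f == 0:  # null scenario: no characteristic signal in the data
        char_mask = np.zeros_like(char_mask)
    return SersDataset(
        spectra=spectra,
        labels=np.array(labels),
        compositions=compositions,
        f=config.f,
        replicate_id=replicate_id,
        char_band_mask=char_mask,
        band_masks=band_masks,
    )


def replicate_rng(config: SimulationConfig, replicate_id: int) -> np.random.Generator:
    """Deterministic per-replicate generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, 1, replicate_id]))


def library_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, 0]))


def simulate_study(
    config: SimulationConfig,
) -> tuple[list[SingleSpectrum], list[SersDataset]]:
    """Library plus ``n_replicates`` independently reproducible replicates.

    The single-spectrum library is fixed once per master seed, so the same
    characteristic bands are shared by every replicate and f value.
    """
    grid = spectral_grid()
    library = build_library(grid, library_rng(config), config)
    datasets = [
        simulate_replicate(library, config, r, replicate_rng(config, r))
        for r in range(1, config.n_replicates + 1)
    ]
    return library, datasets


# ---------------------------------------------------------------------------
# dataset I/O: wide CSV + JSON metadata


def write_dataset(dataset: SersDataset, out_dir: str | Path, stem: str | None = None) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"replicate_{dataset.replicate_id:03d}"
    grid = spectral_grid().astype(int)
    df = pd.DataFrame(dataset.spectra, columns=[str(w) for w in grid])
    df.insert(0, "group", dataset.labels)
    df.insert(0, "id", np.arange(1, dataset.n_spectra + 1))
    csv_path = out_dir / f"{stem}.csv"
    df.to_csv(csv_path, index=False)
    meta = {
        "f": dataset.f,
        "replicate_id": dataset.replicate_id,
        "compositions": [
            {
                "contributing_ids": list(c.contributing_ids),
                "proportions": list(c.proportions),
                "group": c.group,
                "contains_characteristic": c.contains_characteristic,
                "w": c.w,
            }
            for c in dataset.compositions
        ],
        "char_band_mask": dataset.char_band_mask.astype(int).tolist(),
        "band_masks": {
            str(sid): [m.astype(int).tolist() for m in masks]
            for sid, masks in dataset.band_masks.items()
        },
    }
    meta_path = out_dir / f"{stem}.meta.json"
    meta_path.write_text(json.dumps(meta))
    return csv_path, meta_path


def read_dataset(csv_path: str | Path, meta_path: str | Path | None = None) -> SersDataset:
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.parent / (csv_path.stem + ".meta.json")
    df = pd.read_csv(csv_path)
    labels = df["group"].to_numpy()
    spectra = df.drop(columns=["id", "group"]).to_numpy(dtype=float)
    meta_path = Path(meta_path)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        compositions = [
            Composition(
                contributing_ids=tuple(c["contributing_ids"]),
                proportions=tuple(c["proportions"]),
                group=c["group"],
                contains_characteristic=c["contains_characteristic"],
                w=c["w"],
            )
            for c in meta["compositions"]
        ]
        char_mask = np.array(meta["char_band_mask"], dtype=bool)
        band_masks = {
            int(sid): [np.array(m, dtype=bool) for m in masks]
            for sid, masks in meta["band_masks"].items()
        }
        return SersDataset(
            spectra=spectra,
            labels=labels,
            compositions=compositions,
            f=meta["f"],
            replicate_id=meta["replicate_id"],
            char_band_mask=char_mask,
            band_masks=band_masks,
        )
    return SersDataset(
        spectra=spectra,
        labels=labels,
        compositions=[],
        f=float("nan"),
        replicate_id=-1,
        char_band_mask=np.zeros(spectra.shape[1], dtype=bool),
        band_masks={},
    )
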