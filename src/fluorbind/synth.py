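"""Synthetic titration spectra with the statistical structure the fits assume.

The generator emulates what a steady-state fluorimeter records during a
manual quenching titration of a tryptophan-bearing protein: a smooth emission
band near 340 nm whose intensity drops, and whose maximum red-shifts by a few
nm, as the quencher concentration grows; an acceptor absorption band
overlapping the donor emission; and a resonance-light-scattering intensity
curve that stays flat below an aggregation onset and rises linearly above it.

Four quenching laws are supported, matching the analysis equations they are
meant to exercise:

``simple_static``
    F₀/F = 1 + Ksv·[Q] (linear Stern-Volmer).
``accessible_fraction``
    F = F₀·(1 − fa·ka·[Q]/(1 + ka·[Q])) (modified Stern-Volmer with an
    accessible fraction fa and effective constant ka).
``two_regime``
    Stern-Volmer with slope Ksv₁ up to a split concentration and Ksv₂ above
    it; F₀/F is kept continuous at the split so that F remains nonincreasing.
``hill``
    (F₀ − F)/F = K_A·[Q]ⁿ (double-log / Hill-type law with n binding sites).

Noise is additive Gaussian on intensities with standard deviation
``noise_sd``·(band amplitude), drawn reproducibly from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .rls import RlsCurve
from .spectra import Spectrum, TitrationSeries

MECHANISMS = ("simple_static", "accessible_fraction", "two_regime", "hill")


@dataclass
class BandModel:
    """Gaussian emission band.

    ``center`` and ``width`` (the Gaussian sigma) are in nm, ``amplitude`` in
    arbitrary fluorescence units, ``shift_rate`` in nm per concentration unit
    (linear red shift of the band center with quencher concentration).
    """

    center: float = 340.0
    width: float = 15.0
    amplitude: float = 100.0
    shift_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be nonnegative")


@dataclass
class GeneratorConfig:
    """Full description of a synthetic quenching titration.

    ``quencher_grid`` must be nondecreasing and start at exactly 0 (the
    reference point). Which of ``ksv``/``fa``/``ka``/``n_hill``/``split`` are
    required depends on ``mechanism``; see the module docstring for the laws.
    ``ksv`` (and ``ka``) are in the reciprocal of ``unit``.
    """

    band: BandModel
    quencher_grid: np.ndarray
    mechanism: str = "simple_static"
    unit: str = "M"
    ksv: float | tuple[float, float] | None = None
    split: float | None = None
    fa: float | None = None
    ka: float | None = None
    n_hill: float | None = None
    noise_sd: float = 0.0
    seed: int = 0
    excitation: float | None = 295.0

    def __post_init__(self) -> None:
        self.quencher_grid = np.asarray(self.quencher_grid, dtype=float)
        if self.quencher_grid.size == 0 or self.quencher_grid[0] != 0.0:
            raise ValueError("quencher_grid must start at exactly 0")
        if np.any(np.diff(self.quencher_grid) < 0):
            raise ValueError("quencher_grid must be nondecreasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}; "
                             f"choose from {MECHANISMS}")
        need = {
            "simple_static": ("ksv",),
            "accessible_fraction": ("fa", "ka"),
            "two_regime": ("ksv", "split"),
            "hill": ("ka", "n_hill"),
        }[self.mechanism]
        missing = [p for p in need if getattr(self, p) is None]
        if missing:
            raise ValueError(
                f"mechanism {self.mechanism!r} requires parameters {missing}")
        if self.mechanism == "two_regime":
            if np.ndim(self.ksv) != 1 or len(self.ksv) != 2:
                raise ValueError("two_regime requires ksv as a (Ksv1, Ksv2) pair")
        elif self.mechanism == "simple_static" and np.ndim(self.ksv) != 0:
            raise ValueError("simple_static requires a scalar ksv")


def _grid_array(grid) -> np.ndarray:
    """Accept either an explicit wavelength array or a (lo, hi, step) tuple."""
    if isinstance(grid, tuple) and len(grid) == 3:
        lo, hi, step = grid
        return np.arange(lo, hi + 0.5 * step, step, dtype=float)
    return np.asarray(grid, dtype=float)


def gen_emission_band(band: BandModel, grid, concentration: float = 0.0,
                      excitation: float | None = None) -> Spectrum:
    """Sample the (possibly red-shifted) Gaussian band on a wavelength grid.

    The effective center is ``band.center + band.shift_rate * concentration``;
    the grid must cover that center ± 3 widths or the band would be truncated,
    which is refused.
    """
    lam = _grid_array(grid)
    center = band.center + band.shift_rate * concentration
    lo_need, hi_need = center - 3 * band.width, center + 3 * band.width
    if lam[0] > lo_need or lam[-1] < hi_need:
        raise ValueError(
            f"wavelength grid [{lam[0]}, {lam[-1]}] nm too narrow: band at "
            f"{center:.2f} nm with width {band.width} nm needs coverage of "
            f"[{lo_need:.2f}, {hi_need:.2f}] nm"
        )
    y = band.amplitude * np.exp(-((lam - center) ** 2) / (2.0 * band.width ** 2))
    return Spectrum(lam, y, kind="emission", excitation=excitation)


def _quench_scales(cfg: GeneratorConfig) -> np.ndarray:
    """F/F₀ at each grid concentration for the configured mechanism."""
    q = cfg.quencher_grid
    if cfg.mechanism == "simple_static":
        return 1.0 / (1.0 + float(cfg.ksv) * q)
    if cfg.mechanism == "accessible_fraction":
        quenched = cfg.fa * cfg.ka * q / (1.0 + cfg.ka * q)
        if np.any(quenched >= 1.0):
            raise ValueError(
                "unphysical accessible-fraction request: fa·ka[Q]/(1+ka[Q]) "
                f"reaches {quenched.max():.3g} ≥ 1 (fluorescence would vanish "
                "or go negative)"
            )
        return 1.0 - quenched
    if cfg.mechanism == "two_regime":
        k1, k2 = cfg.ksv
        s = float(cfg.split)
        ratio = np.where(q <= s, 1.0 + k1 * q, 1.0 + k1 * s + k2 * (q - s))
        return 1.0 / ratio
    # hill
    return 1.0 / (1.0 + cfg.ka * np.power(q, cfg.n_hill, where=q > 0,
                                          out=np.zeros_like(q)))


def gen_quenching_titration(cfg: GeneratorConfig,
                            grid=(280.0, 420.0, 1.0)) -> TitrationSeries:
    """Generate a full quenching titration series from a generator config.

    Each titration point is the band of ``cfg.band`` scaled by the F/F₀ ratio
    of the configured mechanism (and red-shifted via ``band.shift_rate``),
    with seeded Gaussian noise of sd ``noise_sd``·amplitude added per sample.
    The zero-concentration point is the unquenched reference.
    """
    scales = _quench_scales(cfg)
    rng = np.random.default_rng(cfg.seed)
    spectra = []
    for c, scale in zip(cfg.quencher_grid, scales):
        s = gen_emission_band(cfg.band, grid, concentration=c,
                              excitation=cfg.excitation)
        y = s.intensities * scale
        if cfg.noise_sd > 0:
            y = y + rng.normal(0.0, cfg.noise_sd * cfg.band.amplitude, y.shape)
        spectra.append(Spectrum(s.wavelengths, y, kind="emission",
                                excitation=cfg.excitation))
    return TitrationSeries(cfg.quencher_grid.copy(), spectra, unit=cfg.unit)


def gen_absorption_spectrum(shape: str, params: dict, grid) -> Spectrum:
    """Generate an acceptor molar-extinction trace (M⁻¹cm⁻¹).

    ``shape="flat"`` takes ``eps0``; ``shape="gaussian"`` takes ``center``,
    ``width`` and ``eps_max``. Negative extinction parameters are refused.
    """
    lam = _grid_array(grid)
    if shape == "flat":
        eps0 = float(params["eps0"])
        if eps0 < 0:
            raise ValueError("extinction must be nonnegative")
        y = np.full_like(lam, eps0)
    elif shape == "gaussian":
        center, width, eps_max = (float(params["center"]), float(params["width"]),
                                  float(params["eps_max"]))
        if eps_max < 0:
            raise ValueError("extinction must be nonnegative")
        if width <= 0:
            raise ValueError("absorption band width must be positive")
        y = eps_max * np.exp(-((lam - center) ** 2) / (2.0 * width ** 2))
    else:
        raise ValueError(f"unknown absorption shape {shape!r}")
    return Spectrum(lam, y, kind="absorption")


def gen_rls_series(cciac: float, baseline: float, slope: float, grid,
                   noise_sd: float = 0.0, seed: int = 0,
                   unit: str = "mM",
                   readout_wavelength: float | None = None) -> RlsCurve:
    """Hinge-shaped RLS intensity curve: flat at ``baseline`` below the
    aggregation onset ``cciac``, rising with ``slope`` above it.

    ``cciac`` must lie strictly inside the concentration grid.
    """
    q = np.asarray(grid, dtype=float)
    if not (q.min() < cciac < q.max()):
        raise ValueError(
            f"cciac {cciac} must lie strictly inside the concentration grid "
            f"[{q.min()}, {q.max()}]"
        )
    intensity = baseline + slope * np.clip(q - cciac, 0.0, None)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd * baseline, q.shape)
    return RlsCurve(q, intensity, readout_wavelength=readout_wavelength,
                    unit=unit)


def gen_rls_titration(cciac: float, baseline: float, slope: float, grid,
                      scan=(300.0, 420.0, 2.0), noise_sd: float = 0.0,
                      seed: int = 0, unit: str = "mM") -> TitrationSeries:
    """Δλ=0 scan series whose per-point intensity follows the RLS hinge.

    Convenience for end-to-end pipeline tests: each titration point is a
    broad flat-topped scan scaled so that the readout at any wavelength
    reproduces :func:`gen_rls_series`.
    """
    curve = gen_rls_series(cciac, baseline, slope, grid, noise_sd=noise_sd,
                           seed=seed, unit=unit)
    lam = _grid_array(scan)
    spectra = [Spectrum(lam, np.full_like(lam, v), kind="rls", delta_lambda=0.0)
               for v in curve.intensities]
    return TitrationSeries(np.asarray(grid, dtype=float), spectra, unit=unit)


# ---------------------------------------------------------------------------
# Flat key=value config round-trip (mirrors GeneratorConfig)


def save_config(cfg: GeneratorConfig, path: str | Path) -> None:
    lines = [
        f"mechanism={cfg.mechanism}",
        f"unit={cfg.unit}",
        f"band.center={cfg.band.center}",
        f"band.width={cfg.band.width}",
        f"band.amplitude={cfg.band.amplitude}",
        f"band.shift_rate={cfg.band.shift_rate}",
        "quencher_grid=" + ",".join(repr(float(c)) for c in cfg.quencher_grid),
        f"noise_sd={cfg.noise_sd}",
        f"seed={cfg.seed}",
    ]
    for name in ("ksv", "split", "fa", "ka", "n_hill", "excitation"):
        val = getattr(cfg, name)
        if val is None:
            continue
        if name == "ksv" and np.ndim(val) == 1:
            lines.append(f"ksv={val[0]!r},{val[1]!r}")
        else:
            lines.append(f"{name}={float(val)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> GeneratorConfig:
    kv: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    band = BandModel(center=float(kv["band.center"]), width=float(kv["band.width"]),
                     amplitude=float(kv["band.amplitude"]),
                     shift_rate=float(kv["band.shift_rate"]))
    ksv = None
    if "ksv" in kv:
        parts = [float(p) for p in kv["ksv"].split(",")]
        ksv = parts[0] if len(parts) == 1 else (parts[0], parts[1])
    return GeneratorConfig(
        band=band,
        quencher_grid=np.array([float(p) for p in kv["quencher_grid"].split(",")]),
        mechanism=kv["mechanism"],
        unit=kv.get("unit", "M"),
        ksv=ksv,
        split=float(kv["split"]) if "split" in kv else None,
        fa=float(kv["fa"]) if "fa" in kv else None,
        ka=float(kv["ka"]) if "ka" in kv else None,
        n_hill=float(kv["n_hill"]) if "n_hill" in kv else None,
        noise_sd=float(kv.get("noise_sd", 0.0)),
        seed=int(float(kv.get("seed", 0))),
        excitation=float(kv["excitation"]) if "excitation" in kv else None,
    )
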