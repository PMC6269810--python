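"""End-to-end orchestration of a binary/ternary binding analysis.

``run_analysis`` drives the full chain on one system — dilution corrections,
Stern-Volmer / modified Stern-Volmer / double-log fits per excitation
wavelength, REES, synchronous slopes, RLS onset and FRET — and writes one CSV
per result table plus a plain-text summary and a run log recording every
decision (splits, unphysical flags, skipped stages). Given the same config
and fixtures the report is byte-identical. Every table row carries a
``provenance`` column naming the operation that produced it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import conformation, fret, quenching, rls
from .spectra import TitrationSeries, correct_series_dilution, read_spectrum, read_titration
from .units import per_concentration_to_per_molar


@dataclass
class AnalysisConfig:
    """Paths and constants for one system's analysis.

    Manifest paths may be None (stage skipped when ``allow_missing``).
    The concentration unit is declared by each manifest; it is never assumed.
    """

    label: str = "system"
    manifest_em280: str | None = None
    manifest_em295: str | None = None
    manifest_em305: str | None = None
    manifest_sync15: str | None = None
    manifest_sync60: str | None = None
    manifest_rls: str | None = None
    donor_emission: str | None = None
    acceptor_absorption: str | None = None
    phi: float | None = None
    k2: float = 2.0 / 3.0
    n_ri: float = 1.336
    tau0: float = quenching.DEFAULT_TAU0
    diffusion_limit: float = quenching.DIFFUSION_LIMIT
    two_regime: bool = False
    readout: str | float = "peak"
    rls_readout_nm: float | None = None
    rls_f_threshold: float = 4.0
    allow_missing: bool = True


_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}

_FLOAT_FIELDS = {"phi", "k2", "n_ri", "tau0", "diffusion_limit",
                 "rls_readout_nm", "rls_f_threshold"}
_BOOL_FIELDS = {"two_regime", "allow_missing"}


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Read a flat ``key=value`` config file mirroring :class:`AnalysisConfig`.

    Relative paths are resolved against the config file's directory.
    """
    path = Path(path)
    kwargs: dict = {}
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if not sep or not hasattr(AnalysisConfig, "__dataclass_fields__") or \
                key not in AnalysisConfig.__dataclass_fields__:
            raise ValueError(f"{path}: unknown config key {key!r}")
        if key in _FLOAT_FIELDS:
            kwargs[key] = float(value)
        elif key in _BOOL_FIELDS:
            kwargs[key] = _BOOL[value.lower()]
        elif key == "readout":
            kwargs[key] = value if value == "peak" else float(value)
        elif key == "label":
            kwargs[key] = value
        else:  # a path
            kwargs[key] = str((path.parent / value).resolve())
    return AnalysisConfig(**kwargs)


@dataclass
class Report:
    """Result bundle of one system: named tables, a run log and a failure
    ledger (stages that could not run)."""

    label: str
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)
    unit: str | None = None

    @property
    def ok(self) -> bool:
        return not self.failures


def _quenching_rows(cfg: AnalysisConfig, label_ex: str,
                    series: TitrationSeries, report: Report) -> list[dict]:
    rows = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sv = quenching.stern_volmer_fit(series, readout=cfg.readout,
                                        tau0=cfg.tau0,
                                        two_regime=cfg.two_regime)
        msv = quenching.modified_stern_volmer_fit(series, readout=cfg.readout,
                                                  two_regime=cfg.two_regime)
        dl = quenching.double_log_fit(series, readout=cfg.readout)
    for w in caught:
        report.log.append(f"{label_ex}: {w.message}")

    mech = quenching.classify_mechanism(
        per_concentration_to_per_molar(sv.kq, series.unit),
        cfg.diffusion_limit)
    if isinstance(msv, quenching.TwoRegimeAccessibility):
        fa1, fa2 = msv.low.fa, msv.high.fa
        msv_r1, msv_r2 = msv.low.r, msv.high.r
        report.log.append(f"{label_ex}: modified-SV split after index "
                          f"{msv.split_index} (c={msv.split_concentration:g})")
    else:
        fa1, fa2, msv_r1, msv_r2 = msv.fa, None, msv.r, None
    if sv.n_regimes == 2:
        report.log.append(f"{label_ex}: Stern-Volmer split at "
                          f"c={sv.regime_split:g} ({series.unit})")
    rows.append({
        "excitation": label_ex, "unit": series.unit,
        "ksv1": sv.ksv, "ksv2": sv.ksv2,
        "kq1": sv.kq, "kq2": sv.kq2,
        "n1": dl.n, "n2": None,
        "f1": fa1, "f2": fa2,
        "r_sv1": sv.r, "r_sv2": sv.r2,
        "r_msv1": msv_r1, "r_msv2": msv_r2,
        "r_doublelog": dl.r,
        "log_ka": dl.log_ka,
        "mechanism": mech,
        "provenance": "stern_volmer_fit+modified_stern_volmer_fit+double_log_fit",
    })
    return rows


def run_analysis(cfg: AnalysisConfig, outdir: str | Path | None = None) -> Report:
    """Run every configured stage; see the module docstring for outputs.

    With ``allow_missing`` absent inputs skip their stage (noted in the
    report); otherwise, or on a hard stage failure, the failure ledger is
    populated and the report's ``ok`` flag drops.
    """
    report = Report(label=cfg.label)

    def _load(manifest, kind="emission"):
        if manifest is None:
            return None
        series = read_titration(manifest, kind=kind)
        if report.unit is None:
            report.unit = series.unit
        elif series.unit != report.unit:
            raise ValueError(f"mixed concentration units across manifests: "
                             f"{report.unit} vs {series.unit}")
        return correct_series_dilution(series)

    def _stage(name, fn):
        try:
            fn()
        except FileNotFoundError as exc:
            if cfg.allow_missing:
                report.log.append(f"{name}: skipped (missing input: {exc})")
            else:
                report.failures.append(f"{name}: {exc}")
        except Exception as exc:  # noqa: BLE001 — ledgered, not swallowed
            report.failures.append(f"{name}: {exc}")

    series_cache: dict[str, TitrationSeries | None] = {}

    def quench_stage():
        rows = []
        for label_ex, manifest in (("280", cfg.manifest_em280),
                                   ("295", cfg.manifest_em295)):
            if manifest is None:
                report.log.append(f"quenching@{label_ex}: no manifest; skipped")
                continue
            series = _load(manifest)
            series_cache[label_ex] = series
            rows.extend(_quenching_rows(cfg, label_ex, series, report))
        if rows:
            report.tables["quenching"] = pd.DataFrame(rows)
        elif not cfg.allow_missing:
            raise FileNotFoundError("no quenching manifests configured")
        else:
            report.log.append("quenching: section absent")

    def rees_stage():
        if cfg.manifest_em295 is None or cfg.manifest_em305 is None:
            report.log.append("rees: needs 295 and 305 nm series; skipped")
            return
        s295 = series_cache.get("295") or _load(cfg.manifest_em295)
        s305 = _load(cfg.manifest_em305)
        rows = []
        for point, idx in (("native", 0), ("complex", len(s295) - 1)):
            res = conformation.rees(s295.spectra[idx], s305.spectra[idx])
            rows.append({"point": point,
                         "lam_max_295": res.lam_max_295,
                         "lam_max_305": res.lam_max_305,
                         "rees_nm": res.rees, "provenance": "rees"})
        report.tables["rees"] = pd.DataFrame(rows)

    def sync_stage():
        rows = []
        for manifest in (cfg.manifest_sync15, cfg.manifest_sync60):
            if manifest is None:
                continue
            series = _load(manifest, kind="synchronous")
            res = conformation.synchronous_slope(series)
            rows.append({"delta_lambda": res.delta_lambda, "slope": res.slope,
                         "r": res.r, "residual_rms": res.residual_rms,
                         "lam_max_shift": res.lam_max_shift,
                         "unit": res.unit, "provenance": "synchronous_slope"})
        if rows:
            report.tables["synchronous"] = pd.DataFrame(rows)
        else:
            report.log.append("synchronous: section absent")

    def rls_stage():
        if cfg.manifest_rls is None:
            report.log.append("rls: section absent")
            return
        series = _load(cfg.manifest_rls, kind="rls")
        curve = rls.extract_rls_curve(series, cfg.rls_readout_nm)
        res = rls.detect_cciac(curve, f_threshold=cfg.rls_f_threshold)
        if res is None:
            report.log.append("rls: no aggregation onset detected")
            report.tables["rls"] = pd.DataFrame([{
                "cciac": None, "baseline": None, "slope_above": None,
                "unit": curve.unit, "provenance": "detect_cciac"}])
        else:
            report.tables["rls"] = pd.DataFrame([{
                "cciac": res.cciac, "baseline": res.baseline,
                "slope_above": res.slope_above, "unit": res.unit,
                "provenance": "detect_cciac"}])

    def fret_stage():
        if cfg.donor_emission is None or cfg.acceptor_absorption is None:
            report.log.append("fret: donor/acceptor spectra absent; skipped")
            return
        if cfg.phi is None:
            raise ValueError("fret: donor quantum yield phi must be configured")
        donor = read_spectrum(cfg.donor_emission, kind="emission")
        acceptor = read_spectrum(cfg.acceptor_absorption, kind="absorption")
        src = series_cache.get("295") or series_cache.get("280")
        if src is None:
            report.log.append("fret: no titration to take F/F0 from; skipped")
            return
        from .spectra import peak_intensity
        f0 = peak_intensity(src.spectra[0])
        f = peak_intensity(src.spectra[-1])
        consts = fret.FretConstants(phi=cfg.phi, k2=cfg.k2, n_ri=cfg.n_ri)
        res = fret.fret_analysis(donor, acceptor, f=f, f0=f0, constants=consts)
        report.tables["fret"] = pd.DataFrame([{
            "j_cm3_per_M": res.j, "e": res.e, "r0_nm": res.r0, "r_nm": res.r,
            "phi": cfg.phi, "k2": cfg.k2, "n_ri": cfg.n_ri,
            "provenance": "fret_analysis"}])

    for name, fn in (("quenching", quench_stage), ("rees", rees_stage),
                     ("synchronous", sync_stage), ("rls", rls_stage),
                     ("fret", fret_stage)):
        _stage(name, fn)

    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: Report, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in sorted(report.tables):
        report.tables[name].to_csv(outdir / f"{name}.csv", index=False)
    lines = [f"system: {report.label}", f"unit: {report.unit}",
             f"tables: {', '.join(sorted(report.tables)) or 'none'}",
             f"status: {'ok' if report.ok else 'partial'}"]
    for f in report.failures:
        lines.append(f"FAILED {f}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    (outdir / "run_log.txt").write_text("\n".join(report.log) + "\n")


def compare_systems(reports: list[Report]) -> pd.DataFrame:
    """Side-by-side comparison of ≥2 system reports: regime counts, headline
    quenching parameters and C_CIAC (with rank order). Refuses mixed units."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    units = {r.unit for r in reports if r.unit is not None}
    if len(units) > 1:
        raise ValueError(f"incompatible concentration units across reports: "
                         f"{sorted(units)}")
    rows = []
    for r in reports:
        row: dict = {"system": r.label}
        q = r.tables.get("quenching")
        if q is not None and len(q):
            first = q.iloc[0]
            row["n_regimes"] = 2 if pd.notna(first.get("ksv2")) else 1
            for col in ("ksv1", "ksv2", "n1", "f1", "mechanism"):
                row[col] = first.get(col)
        rl = r.tables.get("rls")
        row["cciac"] = rl.iloc[0]["cciac"] if rl is not None and len(rl) else None
        rows.append(row)
    df = pd.DataFrame(rows)
    if df["cciac"].notna().any():
        df["cciac_rank"] = df["cciac"].rank(method="min")
    return df
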