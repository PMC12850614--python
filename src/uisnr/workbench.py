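"""End-to-end experiment orchestration: config, pipeline, manifest, report.

``run_experiment`` executes the full chain on a synthetic phantom:

    phantom -> dipole shell -> per-B0 (dielectrics -> random basis ->
    noise covariance -> uiSNR maps at N and N - dN) -> convergence mask
    -> piecewise power-law fits -> adjacent-field effective exponents ->
    per-tissue tables,

writing maps (NIfTI-1), tables (CSV), optional basis dumps (HDF5) and a
JSON manifest sufficient to reproduce the run bit-for-bit. Everything is
deterministic given the seed and solver settings.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .basis_noise import (FieldBasis, NoiseCovariance, build_basis,
                          noise_covariance, save_basis)
from .dipole_cloud import (DipoleCloud, build_circumferential_shell,
                           build_shell)
from .em_fields import SolverSettings, VIEProblem
from .errors import ConfigError
from .phantom import (FieldSpec, OrganSpec, VoxelModel, assign_dielectrics,
                      make_sphere_phantom, make_torso_phantom, save_model)
from .scaling_analysis import (FitSettings, ScalingFit, TissueStats,
                               piecewise_fit, tissue_statistics)
from .tissues import GAMMA_OVER_2PI_1H, builtin_tissue
from .uisnr_core import (ConvergenceMask, UiSNRConstants, UiSNRMap,
                         convergence_mask, uisnr_map)


@dataclass
class RunConfig:
    """Complete description of one pipeline run (SI units)."""

    phantom: dict[str, Any]
    d_min_m: float
    d_max_m: float
    B0_list_T: Sequence[float]
    n_basis: int
    seed: int
    end_margin_m: float | None = None
    gamma_over_2pi_Hz_per_T: float = GAMMA_OVER_2PI_1H
    solver: SolverSettings = field(default_factory=SolverSettings)
    fit: FitSettings = field(default_factory=FitSettings)
    low_regime_T: Sequence[float] | None = None
    high_regime_T: Sequence[float] | None = None
    convergence_threshold_pct: float = 1.0
    delta_n: int | None = None
    interpolate_dielectrics: bool = False
    output_dir: str | None = None
    save_basis_files: bool = False

    def __post_init__(self):
        b0 = [float(b) for b in self.B0_list_T]
        if sorted(b0) != b0:
            raise ConfigError("B0 list must be sorted ascending")
        if len(set(b0)) != len(b0):
            raise ConfigError("B0 list has duplicates")
        self.B0_list_T = b0
        if self.n_basis < 1:
            raise ConfigError("n_basis must be >= 1")
        for regime in (self.low_regime_T, self.high_regime_T):
            if regime is not None:
                unknown = set(float(b) for b in regime) - set(b0)
                if unknown:
                    raise ConfigError(f"regime fields {sorted(unknown)} "
                                      "not in the B0 list")
        if not (0 < self.d_min_m < self.d_max_m):
            raise ConfigError("require 0 < d_min < d_max")

    @property
    def effective_delta_n(self) -> int:
        """dN for the convergence check; default mirrors a 1/30 ratio."""
        if self.delta_n is not None:
            return int(self.delta_n)
        return max(1, round(self.n_basis / 30))

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        if "solver" in raw and isinstance(raw["solver"], Mapping):
            raw["solver"] = SolverSettings(**raw["solver"])
        if "fit" in raw and isinstance(raw["fit"], Mapping):
            raw["fit"] = FitSettings(**raw["fit"])
        try:
            return cls(**raw)
        except TypeError as err:
            raise ConfigError(str(err)) from err

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["B0_list_T"] = list(self.B0_list_T)
        return d


def build_phantom(config: RunConfig) -> VoxelModel:
    """Instantiate the phantom described by ``config.phantom``."""
    spec = dict(config.phantom)
    kind = spec.pop("kind", None)
    if kind == "sphere":
        return make_sphere_phantom(
            radius=float(spec["radius_m"]),
            voxel_size=float(spec["voxel_size_m"]),
            tissue=builtin_tissue(spec.get("tissue", "saline")),
            margin=float(spec["margin_m"]) if "margin_m" in spec else None)
    if kind == "torso":
        organs = [OrganSpec(tissue=builtin_tissue(o["tissue"]),
                            center=tuple(o["center_m"]),
                            semiaxes=tuple(o["semiaxes_m"]))
                  for o in spec.get("organs", [])]
        return make_torso_phantom(
            rx=float(spec["rx_m"]), ry=float(spec["ry_m"]),
            length=float(spec["length_m"]),
            voxel_size=float(spec["voxel_size_m"]),
            body_tissue=builtin_tissue(spec.get("body_tissue", "muscle")),
            fat_tissue=builtin_tissue(spec.get("fat_tissue", "fat")),
            fat_thickness=float(spec.get("fat_thickness_m", 0.0)),
            organs=organs,
            margin=float(spec["margin_m"]) if "margin_m" in spec else None)
    raise ConfigError(f"unknown phantom kind {kind!r}")


def build_cloud(model: VoxelModel, config: RunConfig) -> DipoleCloud:
    if config.end_margin_m is not None:
        return build_circumferential_shell(model, config.d_min_m,
                                           config.d_max_m,
                                           config.end_margin_m)
    return build_shell(model, config.d_min_m, config.d_max_m)


@dataclass
class RunResult:
    """In-memory output bundle of :func:`run_experiment`."""

    config: RunConfig
    model: VoxelModel
    cloud: DipoleCloud
    maps: dict[float, UiSNRMap]
    maps_prev: dict[float, UiSNRMap]
    mask: ConvergenceMask
    fit_low: ScalingFit | None
    fit_high: ScalingFit | None
    stats_low: TissueStats | None
    stats_high: TissueStats | None
    interval_table: pd.DataFrame | None
    manifest: dict[str, Any]
    bases: dict[float, FieldBasis] | None = None
    psis: dict[float, NoiseCovariance] | None = None


def _interval_table(maps: Mapping[float, UiSNRMap],
                    mask: np.ndarray) -> pd.DataFrame:
    """Adjacent-field factors and effective exponents, per-voxel means."""
    b0s = sorted(maps)
    rows = []
    for lo, hi in zip(b0s, b0s[1:]):
        s_lo = maps[lo].values[mask]
        s_hi = maps[hi].values[mask]
        ok = np.isfinite(s_lo) & np.isfinite(s_hi) & (s_lo > 0) & (s_hi > 0)
        ratio = s_hi[ok] / s_lo[ok]
        exps = np.log(ratio) / np.log(hi / lo)
        rows.append({"interval": f"{lo:g}-{hi:g} T",
                     "B0_low_T": lo, "B0_high_T": hi,
                     "mean_factor": float(ratio.mean()) if ok.any()
                     else np.nan,
                     "mean_effective_exponent": float(exps.mean())
                     if ok.any() else np.nan,
                     "n_voxels": int(ok.sum())})
    return pd.DataFrame(rows)


def run_experiment(config: RunConfig, *, keep_bases: bool = False
                   ) -> RunResult:
    """Execute the full pipeline; see the module docstring for stages.

    With fewer than 2 field strengths the fit stage is rejected with a
    :class:`ConfigError` recorded in the manifest, but maps and mask are
    still produced (partial pipeline).
    """
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "version": __version__,
        "stages": {},
        "solver_residuals": {},
    }

    def _stage(name):
        t0 = time.perf_counter()

        def done(status="ok", **extra):
            manifest["stages"][name] = {
                "status": status,
                "wall_s": round(time.perf_counter() - t0, 3), **extra}
        return done

    done = _stage("phantom")
    model = build_phantom(config)
    done(n_body_voxels=int(model.body_mask.sum()),
         grid=list(model.shape))

    done = _stage("shell")
    cloud = build_cloud(model, config)
    done(n_shell_voxels=cloud.n_shell_voxels, n_dipoles=cloud.n_dipoles)

    n = config.n_basis
    n_prev = max(1, n - config.effective_delta_n)
    maps: dict[float, UiSNRMap] = {}
    maps_prev: dict[float, UiSNRMap] = {}
    bases: dict[float, FieldBasis] = {}
    psis: dict[float, NoiseCovariance] = {}
    constants = UiSNRConstants()
    body = model.body_mask

    for b0 in config.B0_list_T:
        done = _stage(f"fields_B0={b0:g}T")
        spec = FieldSpec(B0=b0,
                         gamma_over_2pi=config.gamma_over_2pi_Hz_per_T)
        diel = assign_dielectrics(model, spec,
                                  interpolate=config.interpolate_dielectrics)
        basis = build_basis(model, cloud, n, spec, config.solver,
                            config.seed, diel=diel)
        psi = noise_covariance(basis, diel)
        problem = VIEProblem(diel, config.solver)
        res = problem.residual(basis.e_fields[0],
                               _incident_of(basis, model, cloud, spec))
        manifest["solver_residuals"][f"{b0:g}"] = res
        maps[b0] = uisnr_map(basis, psi, spec, constants, n_use=n,
                             reduced=True, body_mask=body)
        maps_prev[b0] = uisnr_map(basis, psi, spec, constants,
                                  n_use=n_prev, reduced=True,
                                  body_mask=body)
        if keep_bases or config.save_basis_files:
            bases[b0] = basis
            psis[b0] = psi
        done(frequency_Hz=spec.frequency, n_basis=n)

    done = _stage("convergence_mask")
    mask = convergence_mask({b0: (maps[b0], maps_prev[b0])
                             for b0 in config.B0_list_T},
                            threshold=config.convergence_threshold_pct,
                            body_mask=body)
    done(n_converged=int(mask.mask.sum()), delta_n=config.effective_delta_n)

    fit_low = fit_high = stats_low = stats_high = None
    interval = None
    done = _stage("fits")
    if len(config.B0_list_T) < 2:
        done(status="rejected: need >= 2 field strengths for fitting")
    else:
        snr_by_b0 = {b0: maps[b0].values for b0 in config.B0_list_T}
        low = config.low_regime_T or [b for b in config.B0_list_T
                                      if b <= 3.0]
        high = config.high_regime_T or [b for b in config.B0_list_T
                                        if b >= 5.0]
        if len(low) >= 2 and len(high) >= 2:
            fit_low, fit_high = piecewise_fit(snr_by_b0, low, high,
                                              config.fit)
            stats_low = tissue_statistics(fit_low, model, mask)
            stats_high = tissue_statistics(fit_high, model, mask)
            done(low_regime=list(low), high_regime=list(high))
        else:
            done(status="rejected: regimes need >= 2 fields each")
        interval = _interval_table(maps, mask.mask)

    if config.output_dir is not None:
        _write_outputs(config, model, cloud, maps, mask, fit_low, fit_high,
                       stats_low, stats_high, interval, manifest,
                       bases if config.save_basis_files else None)

    return RunResult(config=config, model=model, cloud=cloud, maps=maps,
                     maps_prev=maps_prev, mask=mask, fit_low=fit_low,
                     fit_high=fit_high, stats_low=stats_low,
                     stats_high=stats_high, interval_table=interval,
                     manifest=manifest,
                     bases=bases if (keep_bases or config.save_basis_files)
                     else None,
                     psis=psis if (keep_bases or config.save_basis_files)
                     else None)


def _incident_of(basis: FieldBasis, model: VoxelModel, cloud: DipoleCloud,
                 spec: FieldSpec) -> np.ndarray:
    """Recompute the incident E of the first element (residual audit)."""
    from .em_fields import incident_fields

    return incident_fields(cloud, basis.excitations[0], model,
                           spec.frequency).E


def _save_map_nifti(m: UiSNRMap, model: VoxelModel, path: Path) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] *= model.voxel_size * 1e3
    affine[:3, 3] = model.origin * 1e3
    img = nib.Nifti1Image(np.asarray(m.values, dtype=np.float64), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def _write_outputs(config, model, cloud, maps, mask, fit_low, fit_high,
                   stats_low, stats_high, interval, manifest,
                   bases) -> None:
    import nibabel as nib

    out = Path(config.output_dir)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    (out / "tables").mkdir(exist_ok=True)
    save_model(model, out / "maps" / "labels.nii.gz",
               out / "tables" / "tissues.csv")
    for b0, m in maps.items():
        _save_map_nifti(m, model,
                        out / "maps" / f"uisnr_B0_{b0:g}T_N{m.n_basis_used}"
                        ".nii.gz")
    affine = np.eye(4)
    affine[:3, :3] *= model.voxel_size * 1e3
    affine[:3, 3] = model.origin * 1e3
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine),
             str(out / "maps" / "convergence_mask.nii.gz"))
    for name, fit in (("low", fit_low), ("high", fit_high)):
        if fit is not None:
            nib.save(nib.Nifti1Image(fit.alpha, affine),
                     str(out / "maps" / f"alpha_{name}.nii.gz"))
    for name, stats in (("low", stats_low), ("high", stats_high)):
        if stats is not None:
            stats.table.to_csv(out / "tables" / f"exponents_{name}.csv",
                               index=False)
    if interval is not None:
        interval.to_csv(out / "tables" / "interval_exponents.csv",
                        index=False)
    if bases:
        (out / "basis").mkdir(exist_ok=True)
        for b0, basis in bases.items():
            save_basis(basis, out / "basis" / f"basis_B0_{b0:g}T.h5",
                       settings=config.solver)
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)


def save_map_snapshots(result: RunResult, out_dir: str | Path) -> list[Path]:
    """Log-scale mid-coronal uiSNR map snapshots, one PNG per B0.

    Requires matplotlib (optional dependency); maps are shown on a
    log10 color scale with air masked out.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    j_mid = result.model.shape[1] // 2
    for b0, m in sorted(result.maps.items()):
        vals = m.values[:, j_mid, :]
        fig, ax = plt.subplots(figsize=(4, 4))
        with np.errstate(divide="ignore", invalid="ignore"):
            img = ax.imshow(np.log10(vals).T, origin="lower",
                            cmap="viridis")
        fig.colorbar(img, ax=ax, label="log10 uiSNR (reduced units)")
        ax.set_title(f"B0 = {b0:g} T, N = {m.n_basis_used}")
        path = out_dir / f"uisnr_log_B0_{b0:g}T.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written


def report(result: RunResult, snapshot_dir: str | Path | None = None
           ) -> str:
    """Human-readable summary: exponent tables in mean +/- std layout.

    With ``snapshot_dir`` set, log-scale map snapshots are written
    there and listed at the end of the summary.
    """
    lines = []
    n_conv = int(result.mask.mask.sum())
    n_body = int(result.model.body_mask.sum())
    lines.append(f"uisnr run: {len(result.maps)} field strengths, "
                 f"N = {result.config.n_basis} bases, seed = "
                 f"{result.config.seed}")
    lines.append(f"convergence (<= {result.mask.threshold:g}% change over "
                 f"last {result.mask.delta_n} bases): "
                 f"{n_conv}/{n_body} body voxels")
    center = tuple(s // 2 for s in result.model.shape)
    if result.fit_low is not None and result.fit_high is not None \
            and result.model.body_mask[center]:
        lines.append(
            f"center-voxel fitted exponents: low-field regime "
            f"{result.fit_low.alpha[center]:.2f}, high-field regime "
            f"{result.fit_high.alpha[center]:.2f}")
    if n_conv == 0:
        lines.append("no converged voxels; per-tissue exponent "
                     "statistics withheld")
        return "\n".join(lines)
    for name, stats in (("low-field regime", result.stats_low),
                        ("high-field regime", result.stats_high)):
        if stats is None:
            continue
        lines.append(f"\nScaling exponent alpha, {name}:")
        lines.append(f"  {'tissue':<16} {'alpha':>14} {'voxels':>8}")
        for _, r in stats.table.iterrows():
            if r.n_voxels:
                lines.append(f"  {r.tissue:<16} "
                             f"{r.mean_alpha:7.2f} ± {r.std_alpha:4.2f}"
                             f" {int(r.n_voxels):>8}")
            else:
                lines.append(f"  {r.tissue:<16} {'(no voxels)':>14}"
                             f" {0:>8}")
    if result.interval_table is not None:
        lines.append("\nAdjacent-interval uiSNR factors "
                     "(mean within mask):")
        lines.append(f"  {'interval':<14} {'factor':>8} {'exponent':>9}")
        for _, r in result.interval_table.iterrows():
            lines.append(f"  {r.interval:<14} {r.mean_factor:8.2f} "
                         f"{r.mean_effective_exponent:9.2f}")
    if snapshot_dir is not None:
        for path in save_map_snapshots(result, snapshot_dir):
            lines.append(f"snapshot: {path}")
    return "\n".join(lines)
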