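"""Batch orchestration: segment -> expand -> solve, reports and provenance.

A :class:`RunConfig` describes one batch: input TIFF stacks, whether the
channel holds elastic sensor beads (stress is computed; material required)
or nuclei (shape statistics only), segmentation parameters, expansion
degree and the force statistic.  :func:`run_batch` executes the chain per
image and writes label maps, coefficient tables, stress maps, a per-object
report CSV and a provenance JSON.  Per-object failures are flagged in the
report, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .imgseg import (
    Image3D, SegParams, voronoi_otsu_label, filter_labels, label_stats,
)
from .shape import (
    SHExpansion, extract_surface, fit_sh, max_degree, power_spectrum,
    equivalent_radius, align_shape, deformation_parameter, expansions_to_frame,
)
from .elastic import (
    MaterialParams, stress_map, total_force, compression_axis, FORCE_STATISTICS,
)

__all__ = ["RunConfig", "run_batch", "process_image", "summarize"]

logger = logging.getLogger("beadforce")


@dataclass
class RunConfig:
    """Configuration of one batch run.

    ``channel`` is "bead" (stress and force computed; ``material``
    mandatory) or "nucleus" (deformation statistics only; stress
    computation forbidden).  ``r0_policy`` is "infer" (volume-conserving
    radius from c00) or a fixed undeformed radius in um.  The doublet
    filter flags objects with r0 >= 2 * doublet_r_typical as fused pairs.
    """

    inputs: list = dc_field(default_factory=list)
    channel: str = "bead"
    voxel_size: tuple = (0.5, 0.5, 0.5)
    seg: SegParams = dc_field(default_factory=SegParams)
    lmax: int | None = None
    material: MaterialParams | None = None
    r0_policy: str | float = "infer"
    force_statistic: str = "abs_radial"
    doublet_r_typical: float | None = None
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.channel not in ("bead", "nucleus"):
            raise ValueError("channel must be 'bead' or 'nucleus'")
        if self.channel == "bead" and self.material is None:
            raise ValueError("bead runs require MaterialParams")
        if self.channel == "nucleus" and self.material is not None:
            raise ValueError("nucleus runs forbid stress computation; drop material")
        if self.force_statistic not in FORCE_STATISTICS:
            raise ValueError(f"unknown force statistic {self.force_statistic!r}")
        if self.lmax is None:
            # embryo-scale beads are well described at degree 6; nuclei at
            # micron resolution need ~9 (both clipped by the overfit guard)
            self.lmax = 6 if self.channel == "bead" else 9

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seg"] = asdict(self.seg)
        d["material"] = asdict(self.material) if self.material else None
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ObjectResult:
    """Everything computed for one segmented object."""

    label_id: int
    expansion: SHExpansion | None = None
    aligned: SHExpansion | None = None
    deformation: float = np.nan
    axis: np.ndarray | None = None
    force_N: float = np.nan
    net_force_N: float = np.nan
    smap: object = None
    flags: list = dc_field(default_factory=list)


def _report_row(res: ObjectResult, stats_row: pd.Series | None, lmax: int) -> dict:
    row = {
        "label_id": res.label_id,
        "volume_um3": np.nan, "sphericity": np.nan,
        "centroid_x_um": np.nan, "centroid_y_um": np.nan, "centroid_z_um": np.nan,
        "r0_um": np.nan, "D": res.deformation,
        "axis_x": np.nan, "axis_y": np.nan, "axis_z": np.nan,
        "force_N": res.force_N, "net_force_N": res.net_force_N,
        "residual_rms_um": np.nan,
        "flags": ";".join(res.flags),
    }
    if stats_row is not None:
        row["volume_um3"] = stats_row["volume_um3"]
        row["sphericity"] = stats_row["sphericity"]
        row["centroid_x_um"] = stats_row["centroid_x_um"]
        row["centroid_y_um"] = stats_row["centroid_y_um"]
        row["centroid_z_um"] = stats_row["centroid_z_um"]
    if res.expansion is not None:
        row["r0_um"] = equivalent_radius(res.expansion)
        row["residual_rms_um"] = res.expansion.residual_rms
        P = power_spectrum(res.expansion)
        for l in range(lmax + 1):
            row[f"P{l}_um2"] = P[l] if l < len(P) else np.nan
    else:
        for l in range(lmax + 1):
            row[f"P{l}_um2"] = np.nan
    if res.axis is not None:
        row["axis_x"], row["axis_y"], row["axis_z"] = res.axis
    return row


def process_image(image: Image3D, config: RunConfig):
    """Segment one image and analyze every surviving label.

    Returns ``(report DataFrame, list of ObjectResult, LabelMap3D)``.
    Objects that fail a stage keep a report row whose flags state the
    reason; the batch never aborts on a single object.
    """
    t0 = time.perf_counter()
    labels = voronoi_otsu_label(image, config.seg)
    labels = filter_labels(labels, config.seg)
    stats = label_stats(labels).set_index("label_id", drop=False)
    results: list[ObjectResult] = []
    solve_times: list[float] = []
    for lid in range(1, labels.n_labels + 1):
        res = ObjectResult(label_id=lid)
        results.append(res)
        try:
            surface = extract_surface(labels, lid)
        except ValueError as exc:
            res.flags.append(f"surface_failed: {exc}")
            continue
        lmax = config.lmax
        admissible = max_degree(len(surface.points))
        if admissible < lmax:
            lmax = admissible
            res.flags.append("overfit_guard")
        if lmax < 0:
            res.flags.append("surface_failed: too few points for any fit")
            continue
        exp = fit_sh(surface, lmax)
        res.expansion = exp
        res.flags.extend(exp.flags)
        r0 = equivalent_radius(exp)
        if config.doublet_r_typical is not None and r0 >= 2.0 * config.doublet_r_typical:
            res.flags.append("doublet")
            continue
        if exp.lmax >= 2:
            aligned, _ = align_shape(exp)
            res.aligned = aligned
            res.deformation = deformation_parameter(aligned)
            axis, degen = compression_axis(exp)
            res.axis = None if degen else axis
            if degen:
                res.flags.append("degenerate_quadrupole")
        if config.channel == "bead":
            t_solve = time.perf_counter()
            r0_solve = r0 if config.r0_policy == "infer" else float(config.r0_policy)
            smap = stress_map(exp, config.material, r0_override=r0_solve)
            fr = total_force(smap, config.force_statistic)
            res.smap = smap
            res.force_N = fr.force
            res.net_force_N = float(np.linalg.norm(fr.net_vector))
            solve_times.append(time.perf_counter() - t_solve)
    rows = [
        _report_row(r, stats.loc[r.label_id] if r.label_id in stats.index else None,
                    config.lmax)
        for r in results
    ]
    columns = list(_report_row(ObjectResult(label_id=0), None, config.lmax))
    report = pd.DataFrame(rows, columns=columns)
    if config.channel == "nucleus":
        report = report.drop(columns=["force_N", "net_force_N"])
    if solve_times:
        logger.info(
            "solved %d beads, median %.3f s/bead", len(solve_times),
            float(np.median(solve_times)),
        )
    logger.info("image processed in %.2f s", time.perf_counter() - t0)
    return report, results, labels


def run_batch(config: RunConfig):
    """Process every input image and write all artifacts.

    Returns the concatenated report.  Artifacts per image: 16-bit label
    TIFF, long-form coefficient CSV + JSON metadata, per-bead stress map
    CSVs, a report CSV, and one provenance JSON for the whole batch.
    """
    outdir = Path(config.output_dir or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    all_reports = []
    for path in sorted(str(p) for p in config.inputs):
        path = Path(path)
        try:
            values = tifffile.imread(path)
        except (OSError, ValueError) as exc:
            raise RuntimeError(f"cannot read image {path}: {exc}") from exc
        image = Image3D(np.asarray(values, dtype=float), np.asarray(config.voxel_size))
        logger.info("processing %s", path.name)
        report, results, labels = process_image(image, config)
        report.insert(0, "image", path.stem)
        all_reports.append(report)

        stem = outdir / path.stem
        tifffile.imwrite(f"{stem}_labels.tif", labels.labels.astype(np.uint16))
        exps = [r.expansion for r in results if r.expansion is not None]
        expansions_to_frame(exps).to_csv(f"{stem}_coeffs.csv", index=False)
        meta = {
            str(e.label_id): {
                "center_um": list(map(float, e.center)),
                "lmax": e.lmax,
                "normalization": e.normalization,
                "residual_rms_um": e.residual_rms,
                "n_points": e.n_points,
            }
            for e in exps
        }
        with open(f"{stem}_coeffs_meta.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
        for r in results:
            if r.smap is None:
                continue
            TH, PH = np.meshgrid(r.smap.theta, r.smap.phi, indexing="ij")
            pd.DataFrame({
                "theta_rad": TH.ravel(), "phi_rad": PH.ravel(),
                "radial_deformation_um": r.smap.radial_deformation.ravel(),
                "radial_traction_Pa": r.smap.radial_traction.ravel(),
            }).to_csv(f"{stem}_stressmap_{r.label_id:03d}.csv", index=False)
        report.to_csv(f"{stem}_report.csv", index=False)

    full = (
        pd.concat(all_reports, ignore_index=True)
        if all_reports else pd.DataFrame()
    )
    provenance = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "beadforce": __version__,
            "numpy": np.__version__,
        },
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True, default=str)
    full.to_csv(outdir / "report.csv", index=False)
    return full


def summarize(
    reports: pd.DataFrame,
    group_key: str,
    d_threshold: float = 0.2,
    n_axis_bins: int = 6,
) -> pd.DataFrame:
    """Grouped deformation / force statistics.

    Per group: object count, median and IQR of D, fraction with
    D > ``d_threshold``, median and IQR of force (when present), and
    counts of the compression-axis polar angle (angle to z, 0..90 deg)
    in ``n_axis_bins`` equal bins.  Empty groups are omitted with a
    warning.
    """
    if reports.empty:
        raise ValueError("empty report table")
    rows = []
    edges = np.linspace(0.0, 90.0, n_axis_bins + 1)
    for key, grp in reports.groupby(group_key, sort=True):
        d = grp["D"].dropna()
        if len(d) == 0:
            logger.warning("group %r has no valid objects; omitted", key)
            continue
        row = {
            group_key: key,
            "n": len(d),
            "D_median": d.median(),
            "D_iqr": d.quantile(0.75) - d.quantile(0.25),
            f"frac_D_gt_{d_threshold}": float((d > d_threshold).mean()),
        }
        if "force_N" in grp:
            f = grp["force_N"].dropna()
            row["force_median_N"] = f.median() if len(f) else np.nan
            row["force_iqr_N"] = (
                f.quantile(0.75) - f.quantile(0.25) if len(f) else np.nan
            )
        az = grp[["axis_x", "axis_y", "axis_z"]].dropna()
        if len(az):
            polar = np.degrees(np.arccos(np.clip(np.abs(az["axis_z"]), 0, 1)))
            counts, _ = np.histogram(polar, bins=edges)
        else:
            counts = np.zeros(n_axis_bins, dtype=int)
        for i in range(n_axis_bins):
            row[f"axis_{int(edges[i])}_{int(edges[i + 1])}_deg"] = int(counts[i])
        rows.append(row)
    return pd.DataFrame(rows)
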