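"""Rasterized triage maps, area fractions, and the replicated study.

An environment is evaluated on a square lattice clipped to its incident
region. Every lattice point gets a triage label, a destination-option
count and — on higher-order points — the per-point maxima of the two
benefit/harm ratios. Area fractions are lattice point-count fractions;
spatial medians/IQRs are taken over the higher-order points.

The full study draws 50 random geographies per (CSC count, PSC count)
combination and aggregates across-replicate medians and IQRs of every
per-environment statistic, reproducing the design of the abstract-
geometry simulation experiments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import destination_sets as ds
from .environments import (
    CSC,
    GEO,
    Disc,
    Environment,
    PolygonRegion,
    generate_random_environment,
    replicate_rng,
)
from .errors import ValidationError

log = logging.getLogger(__name__)

#: per-environment statistics aggregated across replicates
STAT_NAMES = (
    "triage_fraction",
    "higher_order_fraction",
    "bhr_psc_median",
    "bhr_csc_median",
    "frac_bhr_psc_ge_2",
    "dominates_fraction",
)


# ---------------------------------------------------------------------------
# raster grid
# ---------------------------------------------------------------------------


def raster_grid(
    region: Disc | PolygonRegion, step: float
) -> tuple[np.ndarray, np.ndarray]:
    """Square lattice of pitch ``step`` clipped to the region.

    Lattice nodes sit at integer multiples of ``step``; a node is kept iff
    it lies inside (or on the boundary of) the region. Points are returned
    row-major (y ascending, then x ascending) — a fixed, deterministic
    order. Returns (xs, ys) coordinate arrays.
    """
    if step <= 0:
        raise ValidationError(f"grid step must be positive, got {step}")
    if step >= region.diameter:
        raise ValidationError(
            f"grid step {step} is not smaller than the region diameter "
            f"{region.diameter}"
        )
    xmin, ymin, xmax, ymax = region.bounds
    kx = np.arange(math.ceil(xmin / step - 1e-9), math.floor(xmax / step + 1e-9) + 1)
    ky = np.arange(math.ceil(ymin / step - 1e-9), math.floor(ymax / step + 1e-9) + 1)
    gx, gy = np.meshgrid(kx * step, ky * step)  # row-major: y varies slowest
    xs, ys = gx.ravel(), gy.ravel()
    keep = region.contains(xs, ys)
    return xs[keep], ys[keep]


# ---------------------------------------------------------------------------
# per-environment evaluation
# ---------------------------------------------------------------------------


@dataclass
class RasterField:
    """Per-lattice-point triage classification and benefit/harm maxima.

    ``bhr_psc_max``/``bhr_csc_max`` are NaN outside the higher-order
    region (and ``bhr_csc_max`` also where every option dominates direct
    CSC transport); ``dominates`` flags points with at least one
    harm-free option.
    """

    x: np.ndarray
    y: np.ndarray
    label: np.ndarray
    option_count: np.ndarray
    bhr_psc_max: np.ndarray
    bhr_csc_max: np.ndarray
    dominates: np.ndarray
    step: float

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class EnvironmentSummary:
    """Area fractions and spatial BHR statistics of one environment.

    Fractions are relative to the whole incident region. BHR statistics
    are NaN ("absent") when the environment has no higher-order points;
    the BHR_CSC statistics additionally exclude dominance-flagged points.
    """

    triage_fraction: float
    higher_order_fraction: float
    dominates_fraction: float
    bhr_psc_median: float
    bhr_psc_iqr_lo: float
    bhr_psc_iqr_hi: float
    bhr_csc_median: float
    bhr_csc_iqr_lo: float
    bhr_csc_iqr_hi: float
    frac_bhr_psc_ge_2: float
    n_points: int
    n_higher: int


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    if values.size == 0:
        return (float("nan"),) * 3
    lo, med, hi = np.percentile(values, [25.0, 50.0, 75.0])
    return float(med), float(lo), float(hi)


def _evaluate_on_grid(
    env: Environment, xs: np.ndarray, ys: np.ndarray, step: float
) -> RasterField:
    """Vectorized classification + BHR evaluation of fixed lattice points."""
    m = len(xs)
    provider = env.travel_time
    cscs, pscs = env.cscs, env.pscs

    t_csc = provider.times_to_centers(xs, ys, cscs)  # (m, k)
    d_csc = t_csc.min(axis=1)

    label = np.full(m, int(ds.RegionLabel.UNCONDITIONAL_CSC), dtype=np.int8)
    option_count = np.ones(m, dtype=np.int16)
    bhr_psc_max = np.full(m, np.nan)
    bhr_csc_max = np.full(m, np.nan)
    dominates = np.zeros(m, dtype=bool)

    if pscs:
        d_psc = provider.times_to_centers(xs, ys, pscs)  # (m, p)
        transfer = provider.center_matrix(pscs, cscs).min(axis=1)  # (p,)
        adm = ds.admissible_matrix(d_csc, d_psc, transfer)
        option_count = (1 + adm.sum(axis=1)).astype(np.int16)
        label = np.minimum(option_count, 3).astype(np.int8)

        higher = option_count >= 3
        if higher.any():
            rows = np.nonzero(higher)[0]
            d_h = d_psc[rows]
            adm_h = adm[rows]
            via_h = d_h + transfer[None, :]
            d_csc_h = d_csc[rows]

            d_masked = np.where(adm_h, d_h, np.inf)
            j1 = np.argmin(d_masked, axis=1)  # nearest admissible PSC
            ar = np.arange(len(rows))
            d1 = d_h[ar, j1]
            via1 = via_h[ar, j1]

            others = adm_h.copy()
            others[ar, j1] = False
            with np.errstate(invalid="ignore", divide="ignore"):
                b_psc = (via1[:, None] - via_h) / (d_h - d1[:, None])
            b_psc = np.where(others, b_psc, -np.inf)
            bhr_psc_max[rows] = b_psc.max(axis=1)

            # both ratios apply to the additionally considered PSCs only,
            # i.e. admissible options beyond the nearest PSC
            denom = d_h + env.dido + transfer[None, :] - d_csc_h[:, None]
            dom_entry = others & (denom <= 0)
            defined = others & (denom > 0)
            with np.errstate(invalid="ignore", divide="ignore"):
                b_csc = (d_csc_h[:, None] - d_h) / denom
            b_csc = np.where(defined, b_csc, -np.inf)
            have = defined.any(axis=1)
            csc_max = b_csc.max(axis=1)
            bhr_csc_max[rows[have]] = csc_max[have]
            dominates[rows] = dom_entry.any(axis=1)

    return RasterField(
        x=xs, y=ys, label=label, option_count=option_count,
        bhr_psc_max=bhr_psc_max, bhr_csc_max=bhr_csc_max,
        dominates=dominates, step=step,
    )


def summarize_field(field: RasterField) -> EnvironmentSummary:
    m = len(field)
    higher = field.label == int(ds.RegionLabel.HIGHER_ORDER)
    n_higher = int(higher.sum())
    triage = float((field.label != int(ds.RegionLabel.UNCONDITIONAL_CSC)).mean())
    ho_frac = float(higher.mean())
    dom_frac = float(field.dominates[higher].mean()) if n_higher else float("nan")

    psc_vals = field.bhr_psc_max[higher]
    psc_med, psc_lo, psc_hi = _quartiles(psc_vals)
    frac_ge2 = float((psc_vals >= 2.0).mean()) if n_higher else float("nan")

    # dominance-flagged points are excluded from the BHR_CSC statistics
    csc_mask = higher & ~field.dominates & ~np.isnan(field.bhr_csc_max)
    csc_med, csc_lo, csc_hi = _quartiles(field.bhr_csc_max[csc_mask])

    return EnvironmentSummary(
        triage_fraction=triage,
        higher_order_fraction=ho_frac,
        dominates_fraction=dom_frac,
        bhr_psc_median=psc_med,
        bhr_psc_iqr_lo=psc_lo,
        bhr_psc_iqr_hi=psc_hi,
        bhr_csc_median=csc_med,
        bhr_csc_iqr_lo=csc_lo,
        bhr_csc_iqr_hi=csc_hi,
        frac_bhr_psc_ge_2=frac_ge2,
        n_points=m,
        n_higher=n_higher,
    )


def evaluate_environment(
    env: Environment, step: float
) -> tuple[RasterField, EnvironmentSummary]:
    """Rasterize, classify and score one environment.

    ``step`` is the lattice pitch in the environment's coordinate unit
    (minutes in abstract mode, degrees in geo mode).
    """
    xs, ys = raster_grid(env.region, step)
    field = _evaluate_on_grid(env, xs, ys, step)
    return field, summarize_field(field)


# ---------------------------------------------------------------------------
# replicated study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComboSummary:
    """Across-replicate median and IQR of each statistic for one
    (CSC count, PSC count) combination."""

    n_csc: int
    n_psc: int
    radius: float
    dido: float
    n_replicates: int
    stats: dict  # stat name -> (median, iqr_lo, iqr_hi)


@dataclass
class StudyResult:
    combos: list[ComboSummary]
    per_environment: pd.DataFrame  # one row per simulated environment

    def summary_frame(self) -> pd.DataFrame:
        """Long-format table: n_csc,n_psc,radius,dido,reps,stat,median,iqr_lo,iqr_hi."""
        rows = []
        for c in self.combos:
            for stat, (med, lo, hi) in c.stats.items():
                rows.append(
                    {
                        "n_csc": c.n_csc, "n_psc": c.n_psc, "radius": c.radius,
                        "dido": c.dido, "reps": c.n_replicates, "stat": stat,
                        "median": med, "iqr_lo": lo, "iqr_hi": hi,
                    }
                )
        return pd.DataFrame(rows)


def _nan_quartiles(values: np.ndarray) -> tuple[float, float, float]:
    vals = values[~np.isnan(values)]
    return _quartiles(vals)


def run_simulation_study(
    n_csc_values: Sequence[int],
    n_psc_values: Sequence[int],
    radius: float,
    dido: float = 60.0,
    reps: int = 50,
    step: float | None = None,
    seed: int = 0,
) -> StudyResult:
    """Replicated random-geography study over CSC x PSC combinations.

    For each combination, ``reps`` independent environments are drawn
    (each from its own reproducible stream keyed by ``seed`` and the
    combination/replicate indices), evaluated on a lattice of pitch
    ``step`` (default radius/100), and summarized by across-replicate
    medians and IQRs.
    """
    if reps < 1:
        raise ValidationError(f"reps must be >= 1, got {reps}")
    if step is None:
        step = radius / 100.0
    region = Disc(radius)
    xs, ys = raster_grid(region, step)  # shared by all replicates
    log.info(
        "study: %d x %d combinations, %d reps, %d lattice points each",
        len(n_csc_values), len(n_psc_values), reps, len(xs),
    )

    records = []
    combos: list[ComboSummary] = []
    for n_csc in n_csc_values:
        for n_psc in n_psc_values:
            for rep in range(reps):
                rng = replicate_rng(seed, n_csc, n_psc, rep)
                env = generate_random_environment(
                    n_csc, n_psc, radius, dido=dido, rng=rng
                )
                field = _evaluate_on_grid(env, xs, ys, step)
                s = summarize_field(field)
                records.append(
                    {
                        "n_csc": n_csc, "n_psc": n_psc, "radius": radius,
                        "dido": dido, "rep": rep,
                        "triage_fraction": s.triage_fraction,
                        "higher_order_fraction": s.higher_order_fraction,
                        "bhr_psc_median": s.bhr_psc_median,
                        "bhr_csc_median": s.bhr_csc_median,
                        "frac_bhr_psc_ge_2": s.frac_bhr_psc_ge_2,
                        "dominates_fraction": s.dominates_fraction,
                    }
                )
            block = pd.DataFrame(records[-reps:])
            stats = {
                name: _nan_quartiles(block[name].to_numpy())
                for name in STAT_NAMES
            }
            combos.append(
                ComboSummary(n_csc, n_psc, radius, dido, reps, stats)
            )
            log.info(
                "combo (%d CSC, %d PSC): median triage fraction %.3f",
                n_csc, n_psc, stats["triage_fraction"][0],
            )
    return StudyResult(combos=combos, per_environment=pd.DataFrame(records))


# ---------------------------------------------------------------------------
# range report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RangeReport:
    """Extrema of combination medians plus pooled BHR statistics."""

    triage_fraction_min: float
    triage_fraction_max: float
    higher_order_fraction_min: float
    higher_order_fraction_max: float
    frac_bhr_psc_ge_2_min: float
    frac_bhr_psc_ge_2_max: float
    pooled_bhr_psc_median: float
    pooled_bhr_psc_iqr: tuple[float, float]
    pooled_bhr_csc_median: float
    pooled_bhr_csc_iqr: tuple[float, float]

    def __str__(self) -> str:
        return (
            f"median triage-region fraction across combinations: "
            f"{self.triage_fraction_min:.1%} .. {self.triage_fraction_max:.1%}\n"
            f"median higher-order fraction across combinations: "
            f"{self.higher_order_fraction_min:.1%} .. {self.higher_order_fraction_max:.1%}\n"
            f"median fraction of higher-order area with BHR_PSC >= 2: "
            f"{self.frac_bhr_psc_ge_2_min:.1%} .. {self.frac_bhr_psc_ge_2_max:.1%}\n"
            f"pooled spatial-median BHR_PSC: {self.pooled_bhr_psc_median:.2f} "
            f"(IQR {self.pooled_bhr_psc_iqr[0]:.2f}-{self.pooled_bhr_psc_iqr[1]:.2f})\n"
            f"pooled spatial-median BHR_CSC: {self.pooled_bhr_csc_median:.2f} "
            f"(IQR {self.pooled_bhr_csc_iqr[0]:.2f}-{self.pooled_bhr_csc_iqr[1]:.2f})"
        )


def range_report(study: StudyResult) -> RangeReport:
    """Extrema over combinations of the median statistics, and pooled
    medians/IQRs of per-environment spatial medians over all
    environments (equal weight per environment)."""
    if not study.combos:
        raise ValidationError("empty study")

    def combo_medians(name: str) -> np.ndarray:
        vals = np.array([c.stats[name][0] for c in study.combos])
        return vals[~np.isnan(vals)]

    tf = combo_medians("triage_fraction")
    ho = combo_medians("higher_order_fraction")
    g2 = combo_medians("frac_bhr_psc_ge_2")
    per_env = study.per_environment
    psc_med, psc_lo, psc_hi = _nan_quartiles(per_env["bhr_psc_median"].to_numpy())
    csc_med, csc_lo, csc_hi = _nan_quartiles(per_env["bhr_csc_median"].to_numpy())
    return RangeReport(
        triage_fraction_min=float(tf.min()),
        triage_fraction_max=float(tf.max()),
        higher_order_fraction_min=float(ho.min()),
        higher_order_fraction_max=float(ho.max()),
        frac_bhr_psc_ge_2_min=float(g2.min()) if g2.size else float("nan"),
        frac_bhr_psc_ge_2_max=float(g2.max()) if g2.size else float("nan"),
        pooled_bhr_psc_median=psc_med,
        pooled_bhr_psc_iqr=(psc_lo, psc_hi),
        pooled_bhr_csc_median=csc_med,
        pooled_bhr_csc_iqr=(csc_lo, csc_hi),
    )


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

_LABEL_NAMES = {int(v): v.name for v in ds.RegionLabel}
_LABEL_VALUES = {v.name: int(v) for v in ds.RegionLabel}


def field_frame(field: RasterField) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x": field.x,
            "y": field.y,
            "label": [_LABEL_NAMES[int(v)] for v in field.label],
            "option_count": field.option_count,
            "bhr_psc_max": field.bhr_psc_max,
            "bhr_csc_max": field.bhr_csc_max,
            "dominates": field.dominates.astype(int),
        }
    )


def write_raster(field: RasterField, path: str | Path) -> None:
    field_frame(field).to_csv(path, index=False)


def read_raster(path: str | Path, step: float | None = None) -> RasterField:
    df = pd.read_csv(path)
    return RasterField(
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        label=np.array([_LABEL_VALUES[s] for s in df["label"]], dtype=np.int8),
        option_count=df["option_count"].to_numpy(np.int16),
        bhr_psc_max=df["bhr_psc_max"].to_numpy(float),
        bhr_csc_max=df["bhr_csc_max"].to_numpy(float),
        dominates=df["dominates"].to_numpy(bool),
        step=step if step is not None else float("nan"),
    )


def write_geojson(field: RasterField, path: str | Path) -> None:
    """Point FeatureCollection mirroring the raster CSV (geo mode: x=lon,
    y=lat)."""
    import json

    feats = []
    for i in range(len(field)):
        props = {
            "label": _LABEL_NAMES[int(field.label[i])],
            "option_count": int(field.option_count[i]),
            "bhr_psc_max": None if math.isnan(field.bhr_psc_max[i]) else float(field.bhr_psc_max[i]),
            "bhr_csc_max": None if math.isnan(field.bhr_csc_max[i]) else float(field.bhr_csc_max[i]),
            "dominates": bool(field.dominates[i]),
        }
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(field.x[i]), float(field.y[i])]},
                "properties": props,
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def write_outputs(
    field: RasterField | None,
    study: StudyResult | None,
    out_dir: str | Path,
    env: Environment | None = None,
    figures: bool = False,
) -> list[Path]:
    """Write raster/summary CSVs (plus optional GeoJSON and figures) into
    ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    written: list[Path] = []
    if field is not None:
        p = out / "raster.csv"
        write_raster(field, p)
        written.append(p)
        if env is not None and env.mode == GEO:
            g = out / "raster.geojson"
            write_geojson(field, g)
            written.append(g)
        if figures:
            from .viz import plot_field

            fig = plot_field(field)
            p = out / "map.png"
            fig.savefig(p, dpi=150)
            written.append(p)
    if study is not None:
        p = out / "summary.csv"
        study.summary_frame().to_csv(p, index=False)
        written.append(p)
        q = out / "per_environment.csv"
        study.per_environment.to_csv(q, index=False)
        written.append(q)
        r = out / "range_report.txt"
        r.write_text(str(range_report(study)) + "\n")
        written.append(r)
        if figures:
            from .viz import plot_study

            fig = plot_study(study)
            p = out / "study.png"
            fig.savefig(p, dpi=150)
            written.append(p)
    return written
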