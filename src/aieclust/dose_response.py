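"""Dose–response aggregation, significance annotation, onset detection and
the end-to-end simulated plate experiment.

Per-well quantifications are normalised to the untreated (dose 0) wells of
the same dye and time point, compared to control with a Welch two-sided
t-test (no multiple-testing correction; each condition is annotated
independently), and summarised as a dose–response table. A hinge regression
in log-concentration detects the onset concentration of an
aggregation-induced fluorescence rise. `run_experiment` composes the
synthetic membrane, emission, rendering and quantification modules into a
reproducible plate simulation with an AIE arm and a proximity-insensitive
conventional-dye arm measured from the same labelled receptor sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._rng import (
    STAGE_DISRUPTION,
    STAGE_FOOTPRINT,
    STAGE_LABELING,
    STAGE_RECEPTORS,
    STAGE_RENDER_AIE,
    STAGE_RENDER_CONV,
    as_generator,
    derive_seed,
)
from .aie_optics import EmissionField, aie_emission, conventional_emission, render_image
from .config import ExperimentConfig
from .quantify import compute_snr, mean_masked_intensity, segment_cells
from .synthetic_membrane import (
    apply_disruption,
    sample_cell_footprint,
    sample_receptors_clustered,
    sample_receptors_csr,
)

__all__ = [
    "WellRecord",
    "OnsetResult",
    "normalize_to_control",
    "compare_to_control",
    "detect_onset",
    "fit_hill",
    "run_experiment",
    "ExperimentResult",
]


@dataclass
class WellRecord:
    """One well's condition and measured quantities."""

    cell_model: str  # "clustered" | "dispersed"
    dye: str  # "AIE" | "conventional"
    dose: float  # ug/mL
    time: float  # h
    replicate: int  # >= 1
    mean_intensity: float  # photons / px over the pooled cell ROI
    snr: float

    def __post_init__(self):
        if self.dose < 0 or self.time < 0:
            raise ValueError("dose and time must be >= 0")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")


@dataclass
class OnsetResult:
    onset_concentration: float
    onset_index: int
    detected: bool
    slope: float
    slope_se: float


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([vars(r) for r in records])


def compare_to_control(treated, control) -> tuple[float, str]:
    """Welch two-sided t-test of treated vs control replicate values.

    Returns (p_value, stars) with "**" for p < 0.01, "*" for p < 0.05.
    Degenerate zero-variance groups: identical means give p = 1, distinct
    means p = 0.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("need >= 2 replicates per group (variance undefined)")
    if treated.std(ddof=1) == 0 and control.std(ddof=1) == 0:
        p = 1.0 if treated.mean() == control.mean() else 0.0
    else:
        p = float(stats.ttest_ind(treated, control, equal_var=False).pvalue)
    stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
    return p, stars


def normalize_to_control(records) -> pd.DataFrame:
    """Normalise well intensities to the dose-0 wells of each (dye, time)
    stratum and aggregate per condition.

    Returns a table with one row per (cell_model, dye, dose, time):
    n, mean_norm, sd_norm, p_value, stars. Control rows have mean_norm = 1
    by construction. Raises if any stratum lacks a dose-0 control.
    """
    df = _records_frame(records)
    required = {"cell_model", "dye", "dose", "time", "replicate", "mean_intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records are missing fields: {sorted(missing)}")
    rows = []
    for (model, dye, time), stratum in df.groupby(["cell_model", "dye", "time"], sort=True):
        ctrl = stratum[stratum["dose"] == 0.0]["mean_intensity"].to_numpy()
        if len(ctrl) == 0:
            raise ValueError(f"no dose-0 control in stratum (dye={dye}, time={time})")
        denom = float(ctrl.mean())
        if denom <= 0:
            raise ValueError(f"non-positive control mean in stratum (dye={dye}, time={time})")
        norm_ctrl = ctrl / denom
        for dose, cond in stratum.groupby("dose", sort=True):
            vals = cond["mean_intensity"].to_numpy() / denom
            if len(vals) >= 2 and len(norm_ctrl) >= 2:
                p, stars = compare_to_control(vals, norm_ctrl)
            else:
                p, stars = float("nan"), ""
            rows.append(
                {
                    "cell_model": model,
                    "dye": dye,
                    "dose": float(dose),
                    "time": float(time),
                    "n": int(len(vals)),
                    "mean_norm": float(vals.mean()),
                    "sd_norm": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "p_value": p,
                    "stars": stars,
                }
            )
    return pd.DataFrame(rows)


def detect_onset(concentrations, intensities, noise_sd: float | None = None) -> OnsetResult:
    """Detect the onset concentration of an intensity rise by hinge
    regression in log-concentration.

    The model is y = a + s * max(0, log c - log c_k), fitted by least
    squares for every candidate breakpoint c_k among the tested
    concentrations (all but the last); the breakpoint minimising the
    residual sum of squares is selected, and a rise is declared detected
    only if the fitted slope exceeds twice its standard error (computed
    from the residuals, or from `noise_sd` when the noise level is known).
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if c.ndim != 1 or c.shape != y.shape:
        raise ValueError("concentrations and intensities must be matched 1D series")
    if len(c) < 4:
        raise ValueError("onset detection needs at least 4 points")
    if np.any(np.diff(c) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive (log scale)")
    x = np.log10(c)
    n = len(x)
    best = None
    for k in range(n - 1):
        z = np.maximum(0.0, x - x[k])
        X = np.column_stack([np.ones(n), z])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        if best is None or rss < best[0] - 1e-12 * (1 + abs(best[0])):
            sigma2 = noise_sd**2 if noise_sd is not None else rss / max(n - 2, 1)
            cov = sigma2 * np.linalg.inv(X.T @ X)
            best = (rss, k, float(beta[1]), float(np.sqrt(max(cov[1, 1], 0.0))))
    _, k, slope, se = best
    detected = slope > 2.0 * se
    return OnsetResult(
        onset_concentration=float(c[k]),
        onset_index=int(k),
        detected=bool(detected),
        slope=slope,
        slope_se=se,
    )


def _hill_curve(d, emax, ec50, hill):
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(d > 0, d**hill / (d**hill + ec50**hill), 0.0)
    return 1.0 - emax * frac


def fit_hill(doses, mean_norm) -> dict:
    """Fit mean_norm(dose) = 1 - Emax * d^h / (d^h + ec50^h) by weighted
    least squares; returns {'emax', 'ec50', 'hill'}."""
    d = np.asarray(doses, dtype=float)
    y = np.asarray(mean_norm, dtype=float)
    if len(d) < 4:
        raise ValueError("Hill fit needs at least 4 dose levels")
    pos = d[d > 0]
    p0 = (max(1.0 - y.min(), 1e-3), float(np.median(pos)), 1.0)
    popt, _ = optimize.curve_fit(
        _hill_curve,
        d,
        y,
        p0=p0,
        bounds=([0.0, 1e-6, 0.2], [1.5, 1e5, 5.0]),
        maxfev=20000,
    )
    return {"emax": float(popt[0]), "ec50": float(popt[1]), "hill": float(popt[2])}


@dataclass
class ExperimentResult:
    wells: pd.DataFrame  # one row per (dose, time, replicate, dye)
    table: pd.DataFrame  # normalized dose-response table
    config: ExperimentConfig

    def write(self, out_dir) -> None:
        """Write wells.csv and doseresponse.csv into out_dir."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        self.wells.to_csv(os.path.join(out_dir, "wells.csv"), index=False)
        self.table.to_csv(os.path.join(out_dir, "doseresponse.csv"), index=False)


def _center_offset(footprint, optics) -> np.ndarray:
    rows, cols = optics.image_shape
    w, h = footprint.bounding_box
    return np.array(
        [(cols * optics.pixel_size - w) / 2.0, (rows * optics.pixel_size - h) / 2.0]
    )


def _shifted(em: EmissionField, offset) -> EmissionField:
    return EmissionField(
        positions=em.positions + offset,
        emissive=em.emissive,
        brightness=em.brightness,
        labeled=em.labeled,
    )


def simulate_well(
    config: ExperimentConfig,
    dose: float,
    time: float,
    *,
    seed_key: tuple[int, int, int],
) -> dict:
    """Simulate every imaged cell of one well and pool the quantification.

    Returns per-dye pooled mean intensity (sum of masked photons over summed
    masked area across the well's cells) and the mean per-cell SNR, for the
    AIE and conventional arms rendered from the same labelled receptor sets.
    The ROI of each cell is segmented on the conventional (proximity-
    insensitive) channel, which marks the cell area regardless of
    clustering state, and applied to both channels.
    """
    di, ti, rep = seed_key
    sums = {"AIE": 0.0, "conventional": 0.0}
    area = 0
    snrs = {"AIE": [], "conventional": []}
    n_skipped = 0
    for cell in range(config.cells_per_well):
        ms = config.master_seed
        fp = sample_cell_footprint(
            derive_seed(ms, di, ti, rep, cell, STAGE_FOOTPRINT),
            mean_radius=config.footprint.mean_radius_nm,
            irregularity=config.footprint.irregularity,
            n_vertices=config.footprint.n_vertices,
        )
        rec_seed = derive_seed(ms, di, ti, rep, cell, STAGE_RECEPTORS)
        if config.cell_model == "clustered":
            field = sample_receptors_clustered(fp, config.cluster, rec_seed)
        else:
            field = sample_receptors_csr(
                fp, config.csr_intensity_per_um2, rec_seed, hardcore=config.cluster.hardcore
            )
        field = apply_disruption(
            field, dose, time, config.disruption,
            derive_seed(ms, di, ti, rep, cell, STAGE_DISRUPTION),
        )
        lab_rng = as_generator(derive_seed(ms, di, ti, rep, cell, STAGE_LABELING))
        labeled = lab_rng.random(len(field)) < config.labeling_efficiency
        em_aie = aie_emission(field, config.aie, labeled=labeled)
        em_conv = conventional_emission(
            field, config.conventional_brightness, labeled=labeled
        )
        offset = _center_offset(fp, config.optics)
        img_aie = render_image(
            _shifted(em_aie, offset), config.optics, noise_on=True,
            rng_seed=derive_seed(ms, di, ti, rep, cell, STAGE_RENDER_AIE),
        )
        img_conv = render_image(
            _shifted(em_conv, offset), config.optics, noise_on=True,
            rng_seed=derive_seed(ms, di, ti, rep, cell, STAGE_RENDER_CONV),
        )
        mask = segment_cells(img_conv, config.segmentation)
        if mask.area_px == 0:
            n_skipped += 1
            continue
        area += mask.area_px
        for dye, img in (("AIE", img_aie), ("conventional", img_conv)):
            sums[dye] += float(img.pixels[mask.mask].sum())
            snrs[dye].append(compute_snr(img, mask))
    if area == 0:
        raise RuntimeError(
            f"no cell could be segmented in well (dose={dose}, time={time}, rep={rep})"
        )
    if n_skipped:
        warnings.warn(f"{n_skipped} cell(s) skipped (empty segmentation) in one well")
    return {
        dye: {
            "mean_intensity": sums[dye] / area,
            "snr": float(np.mean(snrs[dye])),
            "n_cells": config.cells_per_well - n_skipped,
        }
        for dye in ("AIE", "conventional")
    }


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full simulated plate experiment defined by `config`.

    For every (dose, time, replicate) a well of `cells_per_well` cells is
    simulated (footprint -> receptors -> disruption -> labelling -> AIE and
    conventional emission -> rendering -> segmentation -> quantification),
    and the per-well records are normalised and annotated. Fully
    deterministic given (config, master_seed).
    """
    rows = []
    for di, dose in enumerate(config.doses):
        for ti, time in enumerate(config.times):
            for rep in range(1, config.replicates + 1):
                well = simulate_well(config, dose, time, seed_key=(di, ti, rep))
                for dye in ("AIE", "conventional"):
                    rows.append(
                        {
                            "cell_model": config.cell_model,
                            "dye": dye,
                            "dose": dose,
                            "time": time,
                            "replicate": rep,
                            "mean_intensity": well[dye]["mean_intensity"],
                            "snr": well[dye]["snr"],
                            "n_cells": well[dye]["n_cells"],
                        }
                    )
    wells = pd.DataFrame(rows)
    table = normalize_to_control(wells)
    return ExperimentResult(wells=wells, table=table, config=config)
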