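"""Batch analysis over many structures and ensemble statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.optimize import curve_fit

from .axis import compute_axis
from .frame import build_frame
from .records import GeometryRecord
from .stacking import find_stacking_pairs
from .structure import (TailTable, assign_domains, expand_crystal,
                        identify_components, load_structure, pair_bases)
from .superhelix import bp_per_turn, compare_frames, fit_superhelix

log = logging.getLogger("ncpgeom")

__all__ = ["SurveyConfig", "NormalFit", "batch_analyze", "analyze_one",
           "fit_normal", "correlate"]


@dataclass
class SurveyConfig:
    smoothing_window: int = 3
    fit_window: int = 129
    pair_cutoff: float = 80.0
    expand_com_distance: float = 100.0
    tail_table: TailTable | None = None
    strict_domains: bool = False
    mass_weighted: bool = True


def _row_from_geometry(entry_id: str, geom, config: SurveyConfig) -> dict:
    """One survey row from anything exposing base pairs + globular COM."""
    ax = compute_axis(geom, smoothing_window=config.smoothing_window)
    sh = fit_superhelix(ax, window=config.fit_window)
    frame = build_frame(geom, sh=sh, mass_weighted=config.mass_weighted)
    comp = compare_frames(sh, frame, ax)
    row = {
        "id": entry_id,
        "bp_count": len(geom.base_pairs),
        "sh_radius": sh.radius, "sh_pitch": sh.pitch,
        "bp_per_turn": bp_per_turn(sh), "sh_rmsd": sh.rmsd,
        "handedness": sh.handedness,
        "centre_distance": comp.centre_distance,
        "dyad_axis_angle": comp.dyad_axis_angle,
        "axis_normal_angle": comp.axis_normal_angle,
        "dna_centroid_com_distance": comp.dna_centroid_com_distance,
        "warnings": "",
    }
    stack_cols = ["stack_dist", "stack_rise", "stack_shift", "stack_phi",
                  "stack_delta", "stack_tilt", "stack_tilt_dir", "stack_class"]
    source = getattr(geom, "source", None)
    if source is not None and getattr(source, "cell", None) is not None:
        placements = expand_crystal(geom, config.expand_com_distance)
        pairs = find_stacking_pairs(placements, frames=frame,
                                    dist_cutoff=config.pair_cutoff)
        if pairs:
            p = pairs[0].params
            for col, val in zip(stack_cols, [p.dist, p.rise, p.shift, p.phi_deg,
                                             p.delta_deg, p.tilt_deg,
                                             p.tilt_direction_deg, p.orientation]):
                row[col] = val
            row["n_pairs"] = len(pairs)
        else:
            row.update({c: np.nan for c in stack_cols[:-1]})
            row["stack_class"] = None
            row["n_pairs"] = 0
    else:
        row.update({c: np.nan for c in stack_cols[:-1]})
        row["stack_class"] = None
        row["n_pairs"] = np.nan
        row["warnings"] = "no unit cell"
    return row


def analyze_one(path: str | Path, config: SurveyConfig | None = None) -> list[dict]:
    """Full pipeline on one file (PDB/mmCIF or geometry-record JSON)."""
    config = config or SurveyConfig()
    path = Path(path)
    if path.suffix == ".json":
        rec = GeometryRecord.load(path)
        return [_row_from_geometry(rec.record_id, rec, config)]
    model = load_structure(path)
    rows = []
    ncps = identify_components(model)
    for k, ncp in enumerate(ncps):
        assign_domains(ncp, config.tail_table, strict=config.strict_domains)
        pair_bases(ncp)
        entry_id = path.stem if len(ncps) == 1 else f"{path.stem}:{k}"
        rows.append(_row_from_geometry(entry_id, ncp, config))
    return rows


def batch_analyze(paths, config: SurveyConfig | None = None) -> pd.DataFrame:
    """Survey table over many inputs; per-entry failures are logged, not fatal.

    Raises RuntimeError only when every input fails.
    """
    config = config or SurveyConfig()
    rows, failures = [], []
    for path in paths:
        try:
            rows.extend(analyze_one(path, config))
        except Exception as exc:   # noqa: BLE001 - batch survives bad entries
            log.warning("failed on %s: %s", path, exc)
            failures.append((str(path), str(exc)))
    if not rows:
        raise RuntimeError(f"all {len(failures)} inputs failed: {failures}")
    table = pd.DataFrame(rows).sort_values("id").reset_index(drop=True)
    table.attrs["failures"] = failures
    return table


@dataclass
class NormalFit:
    mean: float
    sd: float
    n: int
    method: str = "mle"


def fit_normal(values, method: str = "mle", bins: int = 20) -> NormalFit:
    """Normal fit of a value series: MLE by default, histogram curve fit
    (`method="histogram"`) as the binned alternative."""
    v = np.asarray([x for x in np.asarray(values, float) if np.isfinite(x)])
    if len(v) < 2:
        raise ValueError("need at least 2 finite values")
    if method == "mle":
        mu, sd = sstats.norm.fit(v)
        return NormalFit(float(mu), float(sd), len(v), "mle")
    counts, edges = np.histogram(v, bins=bins, density=True)
    mids = 0.5 * (edges[:-1] + edges[1:])
    p0 = [v.mean(), max(v.std(), 1e-6)]
    popt, _ = curve_fit(lambda x, m, s: sstats.norm.pdf(x, m, abs(s)),
                        mids, counts, p0=p0, maxfev=5000)
    return NormalFit(float(popt[0]), float(abs(popt[1])), len(v), "histogram")


def correlate(table: pd.DataFrame, x: str, y: str):
    """Pearson correlation of two survey columns (missing rows dropped).

    Returns (clean two-column DataFrame, r, n_dropped).
    """
    sub = table[[x, y]].apply(pd.to_numeric, errors="coerce")
    clean = sub.dropna()
    dropped = len(sub) - len(clean)
    if len(clean) < 3:
        raise ValueError("need at least 3 complete pairs")
    r = float(sstats.pearsonr(clean[x], clean[y])[0])
    return clean.reset_index(drop=True), r, dropped
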