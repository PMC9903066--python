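"""High-level pipeline steps: simulate → compensate → fit → analyze.

These functions tie the modules together behind plain DataFrames so the CLI
stays a thin argument-parsing layer and scripted use needs no CLI at all.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import io as tio
from .compensation import ErrorModel, apply_compensation, estimate_error_model
from .fitting import FitOptions, fit_chip
from .synthetic import (
    NoiseModel,
    TimelapseDataset,
    simulate_compensation_boards,
    simulate_timelapse,
)
from .timelapse import (
    summaries_to_frame,
    summarize_groups,
    trajectories_from_fits,
    transient_metrics,
)

__all__ = [
    "simulate_run",
    "boards_to_table",
    "compensate_table",
    "fit_table",
    "analyze_fits",
]

logger = logging.getLogger(__name__)

FIT_COLUMNS = [
    "chip_id",
    "time_min",
    "r_series_ohm",
    "r_barrier_ohm",
    "q_cpe",
    "alpha",
    "cost",
    "converged",
    "flags",
    "teer_ohm_cm2",
]


def simulate_run(config: tio.RunConfig) -> tuple[TimelapseDataset, pd.DataFrame, pd.DataFrame]:
    """Simulate a configured experiment.

    Returns the timelapse dataset, the board-spectra table and the plate-map
    table.  Board noise uses a seed offset from the plate seed so boards and
    chips never share noise draws.
    """
    grid = config.grid.build()
    layout = config.build_layout()
    condition_map = config.build_condition_map()
    comp = simulate_compensation_boards(
        parasitics=config.parasitics.build(),
        loads=config.loads_ohm,
        grid=grid,
        noise=NoiseModel(sigma_rel=config.board_sigma_rel, seed=config.seed + 1_000_003),
    )
    dataset = simulate_timelapse(
        layout=layout,
        condition_map=condition_map,
        schedule=config.schedule.build(),
        chip_params_base=config.chip_base.build(),
        parasitics=config.parasitics.build(),
        noise=config.build_noise(),
        chip_cv=config.chip_cv,
        grid=grid,
    )
    board_rows = []
    for i, (load, spec) in enumerate(zip(comp.loads, comp.spectra)):
        board_rows.append(
            pd.DataFrame(
                {
                    "plate_id": config.plate_id,
                    "chip_id": f"board{i + 1}",
                    "time_min": 0.0,
                    "frequency_hz": spec.grid.values,
                    "z_real_ohm": spec.z.real,
                    "z_imag_ohm": spec.z.imag,
                }
            )
        )
    boards = pd.concat(board_rows, ignore_index=True)
    plate_map = pd.DataFrame(
        [
            {"chip_id": cid, "kind": kind, "dose_ng_ml": dose}
            for cid, (kind, dose) in sorted(condition_map.items())
        ]
    )
    return dataset, boards, plate_map


def boards_to_table(config: tio.RunConfig) -> pd.DataFrame:
    _, boards, _ = simulate_run(config)
    return boards


def compensate_table(
    spectra: pd.DataFrame, model: ErrorModel, load_range: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Apply the inverse error map to every (chip, time) block.

    Invalid (ill-conditioned) points are dropped from the output rows.
    """
    frames = []
    for chip_id, time_min, spec in tio.table_to_spectra(spectra):
        comp = apply_compensation(spec, model, load_range=load_range)
        ok = comp.valid
        frames.append(
            pd.DataFrame(
                {
                    "plate_id": spectra["plate_id"].iloc[0],
                    "chip_id": chip_id,
                    "time_min": time_min,
                    "frequency_hz": comp.grid.values[ok],
                    "z_real_ohm": comp.z.real[ok],
                    "z_imag_ohm": comp.z.imag[ok],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def fit_table(spectra: pd.DataFrame, options: FitOptions | None = None) -> pd.DataFrame:
    """Fit every (chip, time) spectrum and tabulate the results."""
    if options is None:
        options = FitOptions()
    rows = []
    for chip_id, time_min, spec in tio.table_to_spectra(spectra):
        res = fit_chip(spec, options)
        rows.append(
            {
                "chip_id": chip_id,
                "time_min": time_min,
                "r_series_ohm": res.params.r_series,
                "r_barrier_ohm": res.params.r_barrier,
                "q_cpe": res.params.q_cpe,
                "alpha": res.params.alpha,
                "cost": res.cost,
                "converged": res.converged,
                "flags": ";".join(res.flags),
                "teer_ohm_cm2": res.teer,
            }
        )
    return pd.DataFrame(rows, columns=FIT_COLUMNS).sort_values(
        ["chip_id", "time_min"], ignore_index=True
    )


def analyze_fits(
    fits: pd.DataFrame, plate_map: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Relative trajectories, group summaries and transient metrics.

    Returns three tidy tables keyed by chip or condition.
    """
    condition_map = {
        str(r.chip_id): (str(r.kind), float(r.dose_ng_ml))
        for r in plate_map.itertuples()
    }
    trajectories = trajectories_from_fits(fits)
    unmapped = [t.chip_id for t in trajectories if t.chip_id not in condition_map]
    if unmapped:
        raise ValueError(f"fit table contains unmapped chips: {unmapped}")

    rel_rows = []
    metric_rows = []
    from .timelapse import normalize_to_baseline  # local to avoid cycle noise

    for traj in trajectories:
        kind, dose = condition_map[traj.chip_id]
        try:
            rel = normalize_to_baseline(traj)
        except ValueError as exc:
            logger.warning("analysis excluding chip: %s", exc)
            continue
        for t, v, ok in zip(rel.times_h, rel.teer, rel.valid):
            rel_rows.append(
                {
                    "chip_id": traj.chip_id,
                    "kind": kind,
                    "dose_ng_ml": dose,
                    "time_h": float(t),
                    "rel_teer": float(v),
                    "converged": bool(ok),
                }
            )
        try:
            m = transient_metrics(rel)
        except ValueError:
            continue
        metric_rows.append(
            {
                "chip_id": traj.chip_id,
                "kind": kind,
                "dose_ng_ml": dose,
                "time_of_nadir_h": m.time_of_nadir_h,
                "nadir": m.nadir,
                "endpoint_recovery": m.endpoint_recovery,
            }
        )

    summaries = summarize_groups(trajectories, condition_map)
    return (
        pd.DataFrame(rel_rows),
        summaries_to_frame(summaries),
        pd.DataFrame(metric_rows),
    )
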