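"""End-to-end orchestration: simulate/load -> stabilize -> quantify -> stats.

``run_pipeline`` executes the full single-AZ analysis on a pair of
recordings (a spontaneous one and an evoked one with its stimulus
protocol), writes every intermediate artifact (TIFF, CSV) plus a JSON
report, and logs every resolved parameter and seed.  Stage failures abort
with the stage name; artifacts produced so far are retained.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .events import (QuantalEventDetector, StimProtocol, per_az_counts)
from .quantify import (AZSet, baseline_correct, detect_az_rois, extract_traces,
                       inter_roi_distances)
from .simulate import MovieStack, SimConfig, generate_confocal, generate_movie
from .stabilize import stabilize
from .stats import (build_survival_curve, compare_aic, fit_survival)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("azping")


@dataclass
class PipelineConfig:
    """Resolved configuration of one end-to-end run.

    With ``simulate=True`` the input recordings are generated from
    ``sim`` (the evoked recording re-uses the same AZ field and appends the
    stimulus protocol); otherwise ``spont_movie`` / ``evoked_movie`` /
    ``marker`` must point at existing TIFF files.
    """

    outdir: str = "azping_out"
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    spont_movie: str | None = None
    evoked_movie: str | None = None
    marker: str | None = None
    prominence_threshold: float = 15.0
    background_offset: tuple[int, int] = (0, 0)
    k_sd: float = 4.0
    consec: int = 3
    smooth_width: int = 5
    n_stimuli: int = 36
    stim_rate_hz: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not self.simulate:
            for name in ("spont_movie", "evoked_movie", "marker"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"config error before any compute: missing {name} ({p})"
                    )


def _auto_background_offset(az: AZSet, movie: MovieStack) -> tuple[int, int]:
    """Pick a global offset that moves all masks into a dark image corner."""
    h, w = movie.data.shape[1:]
    r = int(np.ceil(az.radius_px)) + 1
    xs, ys = az.centers[:, 0], az.centers[:, 1]
    for dx, dy in ((-(int(xs.min()) - r), -(int(ys.min()) - r)),
                   (w - 1 - r - int(xs.max()), 0),
                   (0, h - 1 - r - int(ys.max()))):
        cand_x, cand_y = xs + dx, ys + dy
        if (cand_x.min() >= r and cand_x.max() < w - r
                and cand_y.min() >= r and cand_y.max() < h - r):
            return int(dx), int(dy)
    return 0, 0


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return the report dictionary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {"parameters": _config_dict(config)}
    log.info("parameters: %s", report["parameters"])

    stage = "simulate/load"
    try:
        if config.simulate:
            sim_spont = dataclasses.replace(config.sim, stim_times=[],
                                            seed=config.seed)
            protocol = StimProtocol.regular(config.n_stimuli,
                                            config.stim_rate_hz, start=1.0)
            n_evoked_frames = int(
                (protocol.stim_times[-1] + 2.0) / config.sim.frame_interval
            )
            sim_evoked = dataclasses.replace(
                config.sim, stim_times=protocol.stim_times.tolist(),
                n_frames=n_evoked_frames, seed=config.seed,
            )
            spont, truth = generate_movie(sim_spont)
            evoked, truth_ev = generate_movie(sim_evoked)
            marker = generate_confocal(sim_spont, truth)
            pio.write_movie(outdir / "spont.tif", spont)
            pio.write_movie(outdir / "evoked.tif", evoked)
            pio.write_marker(outdir / "marker.tif", marker)
            truth.events.to_csv(outdir / "truth_spont_events.csv", index=False)
            truth_ev.events.to_csv(outdir / "truth_evoked_events.csv",
                                   index=False)
        else:
            spont = pio.read_movie(config.spont_movie)
            evoked = pio.read_movie(config.evoked_movie)
            marker = pio.read_marker(config.marker)
            protocol = StimProtocol.regular(config.n_stimuli,
                                            config.stim_rate_hz, start=1.0)

        stage = "stabilize"
        spont_stab, spont_shifts = stabilize(spont)
        evoked_stab, evoked_shifts = stabilize(evoked)
        pd.DataFrame(spont_shifts.shifts, columns=["dx", "dy"]).to_csv(
            outdir / "shifts_spont.csv", index=False)
        pd.DataFrame(evoked_shifts.shifts, columns=["dx", "dy"]).to_csv(
            outdir / "shifts_evoked.csv", index=False)

        stage = "detect ROIs"
        # marker rendered/acquired at confocal pixel size; rescale centers
        az_conf = detect_az_rois(marker.data, config.prominence_threshold,
                                 pixel_size=marker.pixel_size)
        ratio = marker.pixel_size / spont.pixel_size
        az = AZSet(az_conf.centers * ratio, pixel_size=spont.pixel_size)
        pd.DataFrame(
            {"id": az.ids, "x_px": az.centers[:, 0], "y_px": az.centers[:, 1]}
        ).to_csv(outdir / "roi_coordinates.csv", index=False)
        distances = inter_roi_distances(az)
        np.savetxt(outdir / "distances_um.csv", distances, delimiter=",")

        stage = "quantify"
        offset = tuple(config.background_offset)
        if offset == (0, 0):
            offset = _auto_background_offset(az, spont_stab)
        log.info("background offset: %s", offset)
        detector = QuantalEventDetector(k_sd=config.k_sd, consec=config.consec,
                                        smooth_width=config.smooth_width)
        traces_sp = baseline_correct(extract_traces(spont_stab, az, offset))
        traces_ev = baseline_correct(extract_traces(evoked_stab, az, offset))

        stage = "detect events"
        ev_spont = detector.detect(traces_sp, distances, mode="spontaneous")
        ev_evoked = detector.detect(traces_ev, distances, mode="evoked",
                                    protocol=protocol)
        events = pd.concat([ev_spont, ev_evoked], ignore_index=True)
        events.to_csv(outdir / "events.csv", index=False)

        stage = "count"
        counts = per_az_counts(events, az)
        counts.to_csv(outdir / "counts.csv", index=False)
        report["n_spontaneous_events"] = int(len(ev_spont))
        report["n_evoked_events"] = int(len(ev_evoked))
        report["n_rois"] = int(len(az))
        report["responding_fraction"] = (
            float(counts["responded"].mean()) if len(counts) else float("nan")
        )

        stage = "survival"
        spont_ids = counts.loc[counts["n_spont"] > 0, "roi_id"].tolist()
        if spont_ids:
            curve = build_survival_curve(spont_ids, ev_evoked,
                                         evoked_stab.n_frames)
            pd.DataFrame({"frame": curve.t,
                          "surviving_fraction": curve.surviving_fraction}
                         ).to_csv(outdir / "survival_curve.csv", index=False)
            fit_exp = fit_survival(curve, model="exp")
            fit_pl = fit_survival(curve, model="exp_plateau")
            sel = compare_aic(fit_exp, fit_pl)
            report["survival"] = {
                "exp": dataclasses.asdict(fit_exp),
                "exp_plateau": dataclasses.asdict(fit_pl),
                "selected_model": sel.winner,
                "delta_aic": sel.delta_aic,
            }
        else:
            report["survival"] = None

        pio.save_json(outdir / "report.json", report)
        log.info("pipeline complete")
        return report
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        log.error("stage '%s' failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    sim = d.get("sim", {})
    for key, val in list(sim.items()):
        if isinstance(val, np.ndarray):
            sim[key] = val.tolist()
    d["background_offset"] = list(d["background_offset"])
    return d
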