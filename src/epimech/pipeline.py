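"""Run configuration and the stage-chaining pipeline.

The pipeline chains: synthesise (or load) a tissue network -> three-fold
restriction -> tension inference -> shear stress -> channel densities and
planar polarity -> conditional and local correlations -> optional
simulated ablation. Every run writes its resolved configuration and a log
of per-stage junction accounting next to the outputs; all CSV/JSON
outputs carry a schema version.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ablation as abl
from . import inference, network, quantify, shear, stats, synth

SCHEMA_VERSION = 1

__all__ = ["RunConfig", "ValidationError", "PipelineError", "run_pipeline"]


class ValidationError(ValueError):
    pass


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run."""

    seed: int = 0
    network_json: str | None = None  # load instead of synthesising
    synthetic: synth.SyntheticConfig = field(default_factory=synth.SyntheticConfig)
    orientation: network.OrientationScheme = field(
        default_factory=network.OrientationScheme
    )
    bin_size: int = 10
    min_junctions_per_cell: int = 4
    n_null: int = 500
    ablate: bool = False
    ablation_duration_s: float = 20.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(doc)
        if "synthetic" in kwargs and isinstance(kwargs["synthetic"], dict):
            syn_known = {f.name for f in dataclasses.fields(synth.SyntheticConfig)}
            syn_unknown = set(kwargs["synthetic"]) - syn_known
            if syn_unknown:
                raise ValidationError(
                    f"unknown synthetic config keys: {sorted(syn_unknown)}"
                )
            kwargs["synthetic"] = synth.SyntheticConfig(**kwargs["synthetic"])
        if "orientation" in kwargs and isinstance(kwargs["orientation"], dict):
            kwargs["orientation"] = network.OrientationScheme(**kwargs["orientation"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the pipeline stages and write results to ``outdir``.

    Returns the output directory. A failing stage raises
    :class:`PipelineError` naming the stage; outputs of completed stages
    are retained.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump({"schema_version": SCHEMA_VERSION, **config.to_dict()}, fh)
    log: dict = {"schema_version": SCHEMA_VERSION, "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                res = fn()
            except Exception as err:  # noqa: BLE001 - named-stage abort
                log["stages"][name] = {"status": "failed", "error": str(err)}
                _write_log(out, log)
                raise PipelineError(name, err) from err
            log["stages"][name] = {"status": "ok", **(res or {})}
            _write_log(out, log)
            return res

        return deco

    state: dict = {}

    @stage("network")
    def _network():
        if config.network_json is not None:
            net = network.TissueNetwork.from_json(config.network_json)
            truth = None
        else:
            cfg = dataclasses.replace(config.synthetic, seed=config.seed)
            net, truth = synth.generate_equilibrium_network(cfg)
            state["syncfg"] = cfg
        state["net"], state["truth"] = net, truth
        net.to_json(out / "network.json")
        return {"cells": len(net.cells), "junctions": len(net.junctions)}

    @stage("restrict")
    def _restrict():
        restricted = network.restrict_threefold(state["net"])
        state["restricted"] = restricted
        return {
            "cells_kept": len(restricted.cells),
            "junctions_excluded": len(restricted.excluded),
        }

    @stage("infer")
    def _infer():
        inf = inference.infer_tensions(state["restricted"])
        state["tensions"] = inf
        net = state["net"]
        rows = []
        for jid, t in sorted(inf.tensions.items()):
            j = net.junctions[jid]
            rows.append(
                {
                    "junction_id": jid,
                    "cell_a": j.cells[0],
                    "cell_b": j.cells[1],
                    "T": t,
                    "length_px": j.length,
                    "angle_deg": j.angle,
                }
            )
        pd.DataFrame(rows).to_csv(out / "tensions.csv", index=False)
        with open(out / "tensions_meta.json", "w") as fh:
            json.dump(
                {
                    "schema_version": SCHEMA_VERSION,
                    "lambda": inf.lambda_,
                    "normalization": inf.normalization,
                    "n_components": inf.n_components,
                    "excluded": {str(k): v for k, v in sorted(inf.excluded.items())},
                },
                fh,
                indent=1,
            )
        total = len(state["net"].junctions)
        return {
            "junctions_with_tension": len(inf.tensions),
            "junctions_excluded": len(inf.excluded),
            "accounted": len(inf.tensions) + len(inf.excluded) == total,
        }

    @stage("shear")
    def _shear():
        estimates, excluded = shear.compute_shear(
            state["restricted"], state["tensions"]
        )
        state["shear"] = estimates
        shear.shear_table(estimates, excluded).to_csv(out / "shear.csv", index=False)
        return {"eligible": len(estimates), "excluded": len(excluded)}

    @stage("quantify")
    def _quantify():
        truth = state["truth"]
        if truth is None:
            return {"skipped": "no synthetic ground truth; densities not assigned"}
        dens = synth.assign_intensities(state["net"], truth, state["syncfg"])
        angles = {
            jid: state["net"].junctions[jid].angle for jid in dens["myosin"]
        }
        profile = quantify.polarity_profile(dens["myosin"], angles, mode="DV/AP")
        ratio = quantify.vinc_ecad_ratio(dens["vinculin"], dens["ecadherin"])
        state["densities"], state["ratio"] = dens, ratio
        rows = [
            {
                "junction_id": jid,
                "channel": ch,
                "density": d,
                "angle_deg": angles[jid],
                "length_px": state["net"].junctions[jid].length,
            }
            for ch, dd in dens.items()
            for jid, d in sorted(dd.items())
        ]
        pd.DataFrame(rows).to_csv(out / "densities.csv", index=False)
        with open(out / "polarity.json", "w") as fh:
            json.dump(
                {
                    "schema_version": SCHEMA_VERSION,
                    "mode": profile.mode,
                    "ald": profile.ald.tolist(),
                    "counts": profile.counts.tolist(),
                    "pcp": profile.pcp,
                    "relative_intensity": profile.relative_intensity.tolist(),
                },
                fh,
                indent=1,
            )
        return {"junctions_quantified": len(dens["myosin"]), "pcp": profile.pcp}

    @stage("correlate")
    def _correlate():
        if state["truth"] is None:
            return {"skipped": "no densities"}
        inf = state["tensions"]
        net = state["net"]
        jids = sorted(set(inf.tensions) & set(state["ratio"]))
        t = np.array([inf.tensions[j] for j in jids])
        r = np.array([state["ratio"][j] for j in jids])
        lens = np.array([net.junctions[j].length for j in jids])
        cond = stats.conditional_correlation(r, t, lens, bin_size=config.bin_size)
        cond.table.to_csv(out / "conditional_correlation.csv", index=False)
        loc = stats.local_correlation(
            state["restricted"],
            {j: inf.tensions[j] for j in jids},
            {j: state["ratio"][j] for j in jids},
            min_junctions=config.min_junctions_per_cell,
            n_null=config.n_null,
            seed=config.seed,
        )
        report = {
            "schema_version": SCHEMA_VERSION,
            "conditional_median_r": cond.median,
            "conditional_n_bins": int(len(cond.table)),
            "local_median_r": loc.median,
            "local_null_band_95": list(loc.null_band(0.95)),
            "local_mannwhitney_p": loc.mannwhitney_p(),
            "n_cells": len(loc.cell_ids),
        }
        with open(out / "correlation.json", "w") as fh:
            json.dump(report, fh, indent=1)
        return {"conditional_median_r": cond.median, "local_median_r": loc.median}

    if config.ablate:

        @stage("ablate")
        def _ablate():
            truth = state["truth"]
            if truth is None:
                return {"skipped": "ablation requires a synthetic tissue"}
            inf = state["tensions"]
            eligible = [
                jid
                for jid in sorted(inf.tensions)
                if not state["net"].junctions[jid].is_boundary
            ]
            rng = np.random.default_rng(config.seed + 7)
            target = int(rng.choice(eligible))
            event = synth.simulate_ablation(
                state["net"],
                truth,
                target,
                state["syncfg"],
                duration_s=config.ablation_duration_s,
            )
            vel = abl.recoil_velocity(event)
            selected, skipped = abl.select_shear_increase(
                state["restricted"], inf, target
            )
            tracks = []
            for vid, tr in event.tracks.items():
                for f, t_s in enumerate(event.times):
                    tracks.append(
                        {"t": t_s, "vertex": vid, "x": tr[f, 0], "y": tr[f, 1]}
                    )
            pd.DataFrame(tracks).to_csv(out / "ablation_tracks.csv", index=False)
            event.densities.to_csv(out / "ablation_densities.csv", index=False)
            with open(out / "ablation.json", "w") as fh:
                json.dump(
                    {
                        "schema_version": SCHEMA_VERSION,
                        "ablated_junction": target,
                        "released_tension": event.released_tension,
                        "recoil_velocity_px_per_s": vel,
                        "shear_increase_junctions": selected,
                        "skipped": {str(k): v for k, v in skipped.items()},
                    },
                    fh,
                    indent=1,
                )
            return {"ablated_junction": target, "recoil_velocity": vel}

    return out


def _write_log(out: Path, log: dict) -> None:
    with open(out / "log.json", "w") as fh:
        json.dump(log, fh, indent=1)
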