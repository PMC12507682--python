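"""End-to-end pipeline: partition -> time-course fit -> metabolism -> report.

All randomness flows from the single config seed (stage seeds are spawned
deterministically from it) and the report records it.  Every output file is
re-parseable by the package's own readers.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .cli_io import (
    PipelineConfig,
    TimeCourse,
    read_images,
    read_timecourse,
    write_images,
    write_json,
    write_timecourse,
)
from .flux_model import build_model, quasi_equilibrium, retrograde_nonvesicular_share
from .metabolism_ms import (
    fit_monoexponential_by_replicate,
    fraction_bifunctional_total,
    fraction_supplied,
    read_species_table,
    transport_metabolism_ratio,
)
from .model_fitting import mc_uncertainty
from .signal_partition import partition_image
from .synthetic_data import (
    GroundTruth,
    NoiseSpec,
    gen_images,
    gen_ms_table,
    gen_timecourse,
    two_rectangles,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@_stage("generate")
def _generate(config: PipelineConfig, outdir: Path, seeds):
    syn = config.synthetic
    rates = dict(syn.rates) if syn.rates else None
    truth = GroundTruth(
        **({"rate_params": rates} if rates else {}),
        initial_state=dict(syn.initial_state),
        k_met=syn.k_met,
        content_decay_rate=syn.content_decay_rate,
        seed=int(seeds[0]),
    )
    model = build_model(config.preset)
    noise = NoiseSpec(sd_fraction=syn.sd_fraction, n_fields=syn.n_fields,
                      timepoints=tuple(syn.timepoints))
    tc = gen_timecourse(truth, model, noise)
    write_timecourse(tc, outdir / "timecourse.csv")
    imgs = gen_images(two_rectangles(), {"ER": 100.0, "PM": 200.0}, seed=int(seeds[1]))
    write_images(outdir / "images.tif", imgs.lipid, imgs.prob_maps)
    table = gen_ms_table(truth, seed=int(seeds[2]))
    table.to_csv(outdir / "ms_table.csv", index=False)
    write_json(
        {
            "rate_params": truth.rate_params,
            "initial_state": truth.initial_state,
            "k_met": truth.k_met,
            "content_decay_rate": truth.content_decay_rate,
            "seed": truth.seed,
            "image_fractions": imgs.true_fractions,
        },
        outdir / "ground_truth.json",
    )
    return tc, imgs, table, truth


@_stage("partition")
def _partition(lipid, prob_maps, config: PipelineConfig, outdir: Path):
    result = partition_image(lipid, prob_maps, threshold=config.threshold)
    result.to_frame().to_csv(outdir / "partition.csv", index=False)
    write_json(result.to_dict(), outdir / "partition.json")
    return result


@_stage("fit")
def _fit(config: PipelineConfig, tc: TimeCourse, outdir: Path, seed, x0=None,
         content_decay_rate: float = 0.0):
    model = build_model(config.preset)
    fit = mc_uncertainty(model, tc, n_mc=config.n_mc, seed=int(seed),
                         n_starts=config.n_starts, x0=x0,
                         content_decay_rate=content_decay_rate if model.content_decay else 0.0)
    write_json(fit.to_dict(), outdir / "fit.json")
    return model, fit


@_stage("metabolism")
def _metabolism(table, outdir: Path):
    supplied = fraction_supplied(table)
    bif_total = fraction_bifunctional_total(table)
    supplied.to_csv(outdir / "fraction_supplied.csv", index=False)
    bif_total.to_csv(outdir / "fraction_bifunctional.csv", index=False)
    met = fit_monoexponential_by_replicate(table)
    write_json(met.to_dict(), outdir / "metabolism.json")
    return supplied, bif_total, met


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and write a report bundle to ``config.outdir``.

    Returns the machine-readable summary (also written as ``summary.json``).
    Reruns with the same config and seed produce byte-identical summaries.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)

    if config.synthetic is not None:
        tc, imgs, table, truth = _generate(config, outdir, seeds)
        lipid, prob_maps = imgs.lipid, imgs.prob_maps
    else:
        if not (config.timecourse and config.ms_table):
            raise PipelineError("config", "need synthetic block or timecourse+ms_table paths")
        tc = read_timecourse(config.timecourse)
        table = read_species_table(config.ms_table)
        lipid = prob_maps = None
        if config.images:
            lipid, prob_maps = read_images(config.images)
        truth = None

    partition = _partition(lipid, prob_maps, config, outdir) if lipid is not None else None
    model, fit = _fit(config, tc, outdir, seeds[3],
                      x0=truth.initial_state if truth is not None else None,
                      content_decay_rate=truth.content_decay_rate if truth is not None else 0.0)
    supplied, bif_total, met = _metabolism(table, outdir)

    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "preset": config.preset,
        "rates": {k: [float(m), float(s)] for k, (m, s) in fit.summary.items()},
        "objective_value": fit.objective_value,
    }
    if "k_PM_ER" in fit.point_estimate and "k_ER_PM" in fit.point_estimate:
        summary["quasi_equilibrium_K"] = quasi_equilibrium(fit.point_estimate)
    if "k_PM_Endo" in fit.point_estimate:
        summary["nonvesicular_share"] = retrograde_nonvesicular_share(fit.point_estimate)
    if met.fitted:
        summary["k_met"] = met.k_met
        ratio, ratio_sd = transport_metabolism_ratio(fit, met)
        summary["transport_metabolism_ratio"] = [ratio, ratio_sd]
    if partition is not None:
        summary["partition_fractions"] = partition.fractions
    if truth is not None:
        summary["truth_rates"] = truth.rate_params
    write_json(summary, outdir / "summary.json")

    report = [f"lipoflux {__version__}", f"seed: {config.seed}", f"preset: {config.preset}", ""]
    report.append("fitted rate constants (MC mean +/- s.d., min^-1):")
    for name, (m, s) in sorted(fit.summary.items()):
        report.append(f"  {name:14s} {m:.4f} +/- {s:.4f}")
    if "nonvesicular_share" in summary:
        report.append(f"non-vesicular retrograde share: {100 * summary['nonvesicular_share']:.1f}%")
    if "quasi_equilibrium_K" in summary:
        report.append(f"quasi-equilibrium K (k_PM_ER/k_ER_PM): {summary['quasi_equilibrium_K']:.2f}")
    if met.fitted:
        report.append(f"k_met: {met.k_met:.4f} +/- {met.se:.4f} min^-1")
        report.append(f"transport/metabolism ratio: {summary['transport_metabolism_ratio'][0]:.1f}")
    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    return summary
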