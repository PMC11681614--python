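"""End-to-end analysis pipeline.

Orchestrates the workflow used to characterise the enzyme: regime
partition → apparent fits → global fits, plus the optional pH-profile,
binding, burst, and product-inhibition stages when their inputs are
configured.  Each stage's failure is captured in the report without
stopping independent stages; the run is deterministic given the
configuration and inputs.
"""

from __future__ import annotations

import logging
from typing import Optional

from . import io as kio
from .fit_engine import (fit_apparent, global_fit, partition_regimes,
                         product_inhibition_analysis)
from .ligand_binding import fit_kd
from .ph_ionization import fit_bell, fit_single_ionization
from .presteady_state import active_site_titration, fit_burst

log = logging.getLogger("ssadhkin")

__all__ = ["run_pipeline"]


def _guard(report: kio.Report, name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                report.warnings.append(f"stage {name} failed: {exc}")
                report.add_stage(name, {"error": str(exc)})
                log.warning("stage %s failed: %s", name, exc)
                return True
            return False

    return _Ctx()


def run_pipeline(config: kio.RunConfig,
                 rate_dataset=None,
                 ph_series=None,
                 quench_titration=None,
                 traces=None,
                 product_dataset=None) -> kio.Report:
    """Run the configured stages and collect a consolidated report.

    Inputs may be passed in memory or read from the paths in ``config``;
    in-memory arguments take precedence.  Stages without input are
    skipped silently.
    """
    report = kio.Report()
    report.provenance["seed"] = config.seed

    if rate_dataset is None and config.rate_csv:
        rate_dataset, rejects = kio.read_rate_csv(config.rate_csv)
        report.add_input("rates", config.rate_csv)
        if rejects:
            report.warnings.append(f"{len(rejects)} rejected rate rows")
            report.add_stage("rate_rejects", {"rejects": rejects})
    if ph_series is None and config.ph_csv:
        ph_series = kio.read_ph_csv(config.ph_csv)
        report.add_input("ph", config.ph_csv)
    if quench_titration is None and config.quench_csv:
        quench_titration = kio.read_quench_csv(config.quench_csv)
        report.add_input("quench", config.quench_csv)
    if traces is None and config.trace_csvs:
        traces = [kio.read_trace_csv(p) for p in config.trace_csvs]
        for i, p in enumerate(config.trace_csvs):
            report.add_input(f"trace{i}", p)

    if rate_dataset is not None:
        with _guard(report, "partition"):
            regimes = partition_regimes(rate_dataset, config.sub_max_um,
                                        config.inhib_min_um)
            report.add_stage("partition", {
                "subinhibitory_n": len(regimes["subinhibitory"]),
                "inhibitory_n": len(regimes["inhibitory"]),
            })
        with _guard(report, "apparent"):
            sub = regimes["subinhibitory"]
            apparent = fit_apparent(sub, fixed="ssa", model="eq1")
            report.add_stage("apparent", {
                str(level): {"vmax": p.vmax, "km": p.km}
                for level, p in apparent.items()})
        with _guard(report, "global"):
            if config.regime in ("auto", "full"):
                data, model = rate_dataset, config.model
            elif config.regime == "sub":
                data, model = regimes["subinhibitory"], "eq3"
            elif config.regime == "inhib":
                data, model = regimes["inhibitory"], "eq4"
            else:
                raise ValueError(f"unknown regime {config.regime!r}")
            gfit = global_fit(data, model=model, n_starts=config.n_starts,
                              seed=config.seed, weighting=config.weighting,
                              sub_max=config.sub_max_um,
                              inhib_min=config.inhib_min_um)
            report.add_stage("global", gfit.to_dict())
            log.info("global %s fit: rss=%.4g aic=%.4g", model,
                     gfit.rss, gfit.aic)

    if ph_series is not None:
        with _guard(report, "ph"):
            if ph_series.kind == "kcat_over_km":
                fit = fit_bell(ph_series, bell_form=config.bell_form)
            else:
                fit = fit_single_ionization(ph_series,
                                            direction=config.direction)
            report.add_stage("ph", fit.to_dict())

    if quench_titration is not None:
        with _guard(report, "binding"):
            bfit = fit_kd(quench_titration)
            report.add_stage("binding", bfit.to_dict())

    if traces is not None:
        with _guard(report, "burst"):
            bursts = [fit_burst(tr) for tr in traces]
            payload = {"bursts": [{
                "enzyme_um": b.enzyme_um, "amplitude_um": b.amplitude_um,
                "lambda_per_s": b.lambda_per_s,
                "steady_rate_um_per_s": b.steady_rate_um_per_s,
            } for b in bursts]}
            if len(bursts) >= 3:
                line = active_site_titration(bursts)
                payload["titration"] = {"slope": line.slope,
                                        "intercept_um": line.intercept_um,
                                        "r2": line.r2}
            report.add_stage("burst", payload)

    if product_dataset is not None:
        with _guard(report, "product_inhibition"):
            pres = product_inhibition_analysis(product_dataset)
            report.add_stage("product_inhibition", pres.to_dict())

    if config.out_json:
        report.to_json(config.out_json)
    return report
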