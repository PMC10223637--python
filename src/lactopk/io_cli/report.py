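"""End-to-end report orchestration: derive -> simulate -> metrics -> files."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

from ..metrics import DEFAULT_CONSTANTS, LactationConstants, infant_dose_report
from ..milk_transfer import derive_milk_transfer
from ..pk_engine import Regimen, build_model, simulate_to_steady_state
from ..population import PopulationSpec, population_simulate
from .config import ConfigError, DrugConfig, apply_effective

__all__ = ["run_report"]

logger = logging.getLogger("lactopk.report")


def _format_summary(config: DrugConfig, transfer, report=None) -> str:
    lines = [
        f"drug: {config.name}",
        f"CLsec = {transfer.clsec:.2f} mL/h",
        f"CLre = {transfer.clre:.2f} mL/h",
        f"Pmilk = {transfer.pmilk:.4g}",
        f"fu_skim = {transfer.fu_skim:.4f}",
        f"fu_milk_total = {transfer.fu_milk_total:.4f}",
        f"M/P (closed form, steady state) = {transfer.mp_ss:.4g}",
    ]
    if report is not None:
        lines += [
            f"M/P (simulated AUC ratio) = {report.mp_ratio:.4g}",
            f"DID_ave = {report.did_ave:.4g} mg/kg/day (RID {report.rid_ave:.3g}%)",
            f"DID_max = {report.did_max:.4g} mg/kg/day (RID {report.rid_max:.3g}%)",
        ]
        if report.rid_therapeutic_ave is not None:
            lines += [
                f"RID_therapeutic_ave = {report.rid_therapeutic_ave:.3g}%",
                f"RID_therapeutic_max = {report.rid_therapeutic_max:.3g}%",
            ]
    return "\n".join(lines) + "\n"


def run_report(
    config: DrugConfig,
    regimen: Optional[Regimen] = None,
    *,
    outdir: Optional[Path] = None,
    dry_run: bool = False,
    use_effective: bool = False,
    population_n: int = 0,
    seed: int = 0,
    method: str = "lsoda",
    n_out: int = 200,
    constants: LactationConstants = DEFAULT_CONSTANTS,
) -> dict:
    """Run the full workflow for one drug and optionally write report files.

    Returns a dict with the derived transfer parameters and, unless
    ``dry_run``, the steady-state interval simulation, the infant-dose
    report and (if ``population_n`` > 0) the population percentile bands.
    """
    if use_effective:
        config = apply_effective(config)
    transfer = derive_milk_transfer(config.physchem)
    logger.info(
        "%s: CLsec=%.2f mL/h CLre=%.2f mL/h Pmilk=%.4g fu_skim=%.4f "
        "fu_milk_total=%.4f M/P_ss=%.4g (physchem provenance: %s)",
        config.name, transfer.clsec, transfer.clre, transfer.pmilk,
        transfer.fu_skim, transfer.fu_milk_total, transfer.mp_ss,
        config.provenance.get("physchem", "unspecified"),
    )
    result = {"config": config, "transfer": transfer}
    if dry_run:
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / "summary.txt").write_text(_format_summary(config, transfer))
        return result

    if config.maternal_pk is None:
        raise ConfigError(f"{config.name}: maternal PK parameters required to simulate")
    if regimen is None:
        regimen = config.default_regimen()
    if regimen.interval is None:
        raise ConfigError("report needs a periodic regimen")
    model = build_model(config.physchem, config.maternal_pk, transfer)
    ev = regimen.events[0]
    sim = simulate_to_steady_state(
        model, (ev.amount, regimen.interval, ev.route, ev.duration),
        n_out=n_out, method=method,
    )
    logger.info("%s: steady state after %d cycles (converged=%s)",
                config.name, sim.n_cycles, sim.ss_flag)
    report = infant_dose_report(
        sim,
        daily_maternal_dose=regimen.daily_dose,
        therapeutic_dose=config.therapeutic_infant_dose,
        constants=constants,
    )
    result.update({"sim": sim, "report": report})

    if population_n > 0:
        spec = PopulationSpec(n=population_n, seed=seed)
        n_cycles = sim.n_cycles or 1
        full = Regimen.periodic(ev.amount, regimen.interval, n_cycles, ev.route, ev.duration)
        pop = population_simulate(
            spec, model, full, t_end=n_cycles * regimen.interval,
            n_out=min(2000, n_out * n_cycles), method=method,
        )
        result["population"] = pop

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sim.to_frame().to_csv(outdir / "profile.csv", index=False)
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "name": config.name,
                    "mp_ratio": report.mp_ratio,
                    "did_ave_mg_kg_day": report.did_ave,
                    "did_max_mg_kg_day": report.did_max,
                    "rid_ave_pct": report.rid_ave,
                    "rid_max_pct": report.rid_max,
                    "rid_therapeutic_ave_pct": report.rid_therapeutic_ave,
                    "rid_therapeutic_max_pct": report.rid_therapeutic_max,
                }
            ]
        ).to_csv(outdir / "metrics.csv", index=False)
        (outdir / "summary.txt").write_text(_format_summary(config, transfer, report))
        if "population" in result:
            result["population"].to_frame().to_csv(outdir / "population.csv", index=False)
    return result
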