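"""End-to-end driver: compose enrollment, costing, effects, ICER and
uncertainty analysis for one or more program years and emit tables,
machine-readable CSVs and (optionally) figures.

Every figure written has a CSV twin containing exactly the plotted
values; all results are usable from the CSVs alone, so plotting is
optional and headless-safe.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .cea import classify_wtp, icer
from .effects import DalyConfig, daly_per_death
from .enrollment import ProjectionConfig, annual_totals, project_enrollment
from .ledger import aggregate_ledger, format_ledger_table, personnel_share, write_ledger_csv
from .scenario import perspective_costs_from_values, point_values, scale_up_model
from .uncertainty import ceac, mean_icer, percentile_ci, run_psa, tornado, tornado_frame

log = logging.getLogger("mhealth_cea")

#: 2015 per-capita gross national income for the study setting (USD),
#: the reference willingness-to-pay threshold.
GNI_PER_CAPITA_2015 = 6080.0


@dataclass
class RunConfig:
    """Configuration for a full pipeline run; serialized into the output
    directory for provenance."""

    years: Sequence[int] = (1, 2, 3, 4, 5)
    discount_rate: float = 0.03
    life_expectancy: float = 66.0
    daly_form: str = "continuous"
    monthly_growth: float = 0.10
    coverage_cap: float = 0.60
    wtp_grid: Sequence[float] = field(
        default_factory=lambda: list(np.arange(0.0, 8000.1, 250.0))
    )
    n_iter: int = 1000
    seed: int = 42
    gni_per_capita: float = GNI_PER_CAPITA_2015
    output_dir: Optional[str] = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        bad = [y for y in self.years if y not in (1, 2, 3, 4, 5)]
        if bad:
            raise ValueError(f"invalid program years {bad}")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.daly_form not in ("continuous", "discrete"):
            raise ValueError("daly_form must be 'continuous' or 'discrete'")

    def daly_config(self) -> DalyConfig:
        return DalyConfig(
            discount_rate=self.discount_rate,
            life_expectancy=self.life_expectancy,
            discounting_form=self.daly_form,  # type: ignore[arg-type]
        )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return a bundle of DataFrames.

    Deterministic given ``config.seed``.  When ``config.output_dir`` is
    set, every table is written as CSV (plus figures if requested) and
    the config itself is archived as YAML.
    """
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    daly_cfg = config.daly_config()
    factor = daly_per_death(daly_cfg)
    log.info("DALY factor (%s, r=%.2f, L=%.0f): %.3f per death averted",
             config.daly_form, config.discount_rate, config.life_expectancy, factor)

    # Cost ledger -----------------------------------------------------------
    ledger = synthetic.generate_cost_ledger(config.discount_rate)
    ledger_by_cat = aggregate_ledger(ledger, by="category")
    pers_pct, _ = personnel_share(ledger)
    log.info("ledger grand total %.2f; personnel share %d%%",
             ledger_by_cat.attrs["grand_total"], pers_pct)

    # Enrollment ------------------------------------------------------------
    observed = synthetic.generate_enrollment_series(years=2, growth=config.monthly_growth)
    proj_cfg = ProjectionConfig(
        monthly_growth=config.monthly_growth, coverage_cap=config.coverage_cap
    )
    series = project_enrollment(observed, proj_cfg, horizon_months=36)
    enrollment = annual_totals(series, proj_cfg.annual_pregnancies)

    # Cost per registered user (cumulative program cost over cumulative users)
    by_year_cost = {y: float(v) for y, v in ledger.total_by_year().items()}
    cum_cost = np.cumsum([by_year_cost[y] for y in (1, 2, 3, 4, 5)])
    cum_users = np.cumsum([synthetic.USERS_BY_YEAR[y] for y in (1, 2, 3, 4, 5)])
    cost_per_user = pd.DataFrame(
        {
            "year": [1, 2, 3, 4, 5],
            "annual_cost": [by_year_cost[y] for y in (1, 2, 3, 4, 5)],
            "annual_users": [synthetic.USERS_BY_YEAR[y] for y in (1, 2, 3, 4, 5)],
            "annual_cost_per_user": [
                by_year_cost[y] / synthetic.USERS_BY_YEAR[y] for y in (1, 2, 3, 4, 5)
            ],
            "cumulative_cost_per_user": cum_cost / cum_users,
        }
    ).set_index("year")

    # Per-year deterministic ICERs and PSA ----------------------------------
    model = scale_up_model(daly_cfg)
    icer_rows, ceac_frames, psa_frames, tornado_frames = [], [], [], []
    for year in config.years:
        specs, _truth = synthetic.generate_parameter_table(year, seed=config.seed)
        points = point_values(specs)
        pc = perspective_costs_from_values(points)
        dalys = points["lives_saved"] * factor
        det = icer(pc.societal, dalys)
        det_per_life = icer(pc.societal, points["lives_saved"])
        draws = run_psa(specs, model, n_iter=config.n_iter, seed=config.seed + year)
        m_icer = mean_icer(draws)
        try:
            ci_lo, ci_hi, _ = percentile_ci(draws)
        except ValueError:  # too few consistent-sign draws for the tails
            ci_lo = ci_hi = float("nan")
        curve = ceac(draws, config.wtp_grid)
        prob_at_gni = ceac(draws, [config.gni_per_capita]).probability[0]
        icer_rows.append(
            {
                "year": year,
                "users": points["users"],
                "lives_saved": points["lives_saved"],
                "dalys_averted": dalys,
                "delta_cost_program": pc.program,
                "delta_cost_health_system": pc.health_system,
                "delta_cost_user": pc.user,
                "delta_cost_societal": pc.societal,
                "icer_per_life": det_per_life.icer,
                "icer_per_daly": det.icer,
                "wtp_class": classify_wtp(det.icer, config.gni_per_capita),
                "psa_mean_icer_per_daly": m_icer,
                "psa_icer_ci_low": ci_lo,
                "psa_icer_ci_high": ci_hi,
                "prob_ce_at_gni": float(prob_at_gni),
            }
        )
        cf = curve.to_frame()
        cf.insert(0, "year", year)
        ceac_frames.append(cf)
        pf = pd.DataFrame(
            {
                "year": year,
                "iteration": np.arange(config.n_iter),
                "delta_cost": draws.delta_cost,
                "delta_dalys": draws.delta_effect,
            }
        )
        psa_frames.append(pf)
        tf = tornado_frame(tornado(specs, model))
        tf.insert(0, "year", year)
        tornado_frames.append(tf)
        log.info("year %d: ICER %.1f USD/DALY (PSA mean %.1f, CI %.1f-%.1f), "
                 "P(CE at GNI) = %.2f", year, det.icer, m_icer, ci_lo, ci_hi, prob_at_gni)

    results = {
        "ledger": ledger,
        "ledger_by_category": ledger_by_cat,
        "enrollment_series": series.to_frame(),
        "enrollment_annual": enrollment,
        "cost_per_user": cost_per_user,
        "icer_table": pd.DataFrame(icer_rows).set_index("year"),
        "ceac": pd.concat(ceac_frames, ignore_index=True),
        "psa_draws": pd.concat(psa_frames, ignore_index=True),
        "tornado": pd.concat(tornado_frames, ignore_index=True),
    }

    if outdir:
        _write_outputs(results, config, outdir)
    return results


def _write_outputs(results: dict, config: RunConfig, outdir: Path) -> None:
    write_ledger_csv(results["ledger"], outdir / "cost_ledger.csv")
    (outdir / "cost_table.txt").write_text(format_ledger_table(results["ledger"]) + "\n")
    for key in ("enrollment_series", "enrollment_annual", "cost_per_user",
                "icer_table", "ceac", "psa_draws", "tornado"):
        df = results[key]
        df.to_csv(outdir / f"{key}.csv", index=df.index.name is not None)
    cfg = {
        k: ([float(x) for x in v] if isinstance(v, (tuple, list, np.ndarray)) else v)
        for k, v in vars(config).items()
    }
    (outdir / "run_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    summary = results["icer_table"].reset_index().to_dict("records")
    (outdir / "results.json").write_text(json.dumps(summary, indent=2, default=float))
    if config.make_plots:
        _write_plots(results, outdir)


def _write_plots(results: dict, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    for year, grp in results["psa_draws"].groupby("year"):
        ax.scatter(grp["delta_dalys"], grp["delta_cost"], s=4, alpha=0.4, label=f"year {year}")
    ax.set_xlabel("incremental DALYs averted")
    ax.set_ylabel("incremental cost (USD)")
    ax.legend()
    fig.savefig(outdir / "ce_plane.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    for year, grp in results["ceac"].groupby("year"):
        ax.plot(grp["wtp"], grp["probability"], label=f"year {year}")
    ax.set_xlabel("willingness to pay (USD/DALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.legend()
    fig.savefig(outdir / "ceac.png", dpi=120)
    plt.close(fig)

    last = results["tornado"]["year"].max()
    tf = results["tornado"].query("year == @last").iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 5))
    base = (tf["icer_at_low"] + tf["icer_at_high"]) / 2
    ax.barh(tf["parameter"], tf["icer_at_high"] - tf["icer_at_low"], left=tf["icer_at_low"])
    ax.set_xlabel("ICER (USD/DALY)")
    fig.tight_layout()
    fig.savefig(outdir / "tornado.png", dpi=120)
    plt.close(fig)
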