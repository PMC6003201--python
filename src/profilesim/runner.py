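"""Scenario grid, Monte-Carlo replication and result persistence.

The grid sweeps one parameter per scenario around a common baseline
(K=50 providers, 10% average mortality, 20% true outliers, H=2, two-sided
outliers, all volumes 1000, P(nmin)=0.5):

1. number of providers K in {10, 20, 30, 40, 50}
2. average mortality p in {0.03, 0.10, 0.20}
3. true-outlier fraction in {0.08, 0.20, 0.40}
4. outlier shift H in {1, 2, 3, 4}
5. outlier sides S in {1, 2}
6. smaller provider volume in {500, 1000}
7. at min volume 500, P(outlier is small) in {0.5, 1}

Replicates are independent units: each replicate's seed derives
deterministically from (master seed, scenario, design point, replicate index),
so any execution order — or a resumed run — reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assignment import AssignedCohort, draw_assignment_model, fill_quotas
from .casemix import CaseMixConfig
from .metrics import confusion, performance, summarize
from .methods import METHOD_NAMES, ClassificationResult, run_all_methods
from .outcome import (
    IncidenceError,
    OutcomeModel,
    ProviderTruth,
    ScenarioSpec,
    allocate_provider_truth,
    calibrate_intercept,
    draw_outcomes,
)

logger = logging.getLogger(__name__)

BASELINE = ScenarioSpec()


def scenario_grid() -> dict[int, list[ScenarioSpec]]:
    """The seven one-parameter-at-a-time sweeps around the baseline."""
    return {
        1: [replace(BASELINE, K=k, scenario=1) for k in (10, 20, 30, 40, 50)],
        2: [replace(BASELINE, p_bar=p, scenario=2) for p in (0.03, 0.10, 0.20)],
        3: [replace(BASELINE, p_out=p, scenario=3) for p in (0.08, 0.20, 0.40)],
        4: [replace(BASELINE, H=h, scenario=4) for h in (1.0, 2.0, 3.0, 4.0)],
        5: [replace(BASELINE, S=s, scenario=5) for s in (1, 2)],
        6: [replace(BASELINE, min_volume=v, scenario=6) for v in (500, 1000)],
        7: [
            replace(BASELINE, min_volume=500, p_nmin=p, scenario=7)
            for p in (0.5, 1.0)
        ],
    }


@dataclass
class ReplicateResult:
    """Everything produced by one data-generation + six-method pass."""

    spec: ScenarioSpec
    truth: ProviderTruth
    results: dict[str, ClassificationResult]
    failures: dict[str, str]
    gamma00: float
    incidence: float
    n_truth_redraws: int

    def measures(self) -> pd.DataFrame:
        """Per-method confusion-derived measures for this replicate."""
        rows = []
        for name, res in self.results.items():
            c = confusion(self.truth.classes, res.labels)
            perf = performance(c)
            rows.append({
                "method": name,
                **{k: (np.nan if v is None else v) for k, v in perf.items()},
                "n_flagged": int(res.flagged.sum()),
                "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
            })
        return pd.DataFrame(rows)


def replicate_seed(master_seed: int, scenario: int, point: int, rep: int):
    """Injective, order-independent seed for one replicate."""
    return np.random.SeedSequence(master_seed, spawn_key=(scenario, point, rep))


def run_replicate(
    spec: ScenarioSpec,
    seed,
    methods=METHOD_NAMES,
    casemix: CaseMixConfig | None = None,
    outcome_model: OutcomeModel | None = None,
    rule: str = "model_sd",
    max_truth_redraws: int = 10,
) -> ReplicateResult:
    """Generate one dataset under ``spec`` and apply the requested methods.

    Deterministic given the seed; all methods see the identical dataset.
    If the per-provider minimum-incidence rule cannot be met by redrawing
    outcomes, the random intercepts are redrawn and the intercept recalibrated
    (never the cohort itself), which is logged.
    """
    casemix = casemix or CaseMixConfig()
    outcome_model = outcome_model or OutcomeModel()
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_model, s_truth, s_fill, s_out, s_redraw = root.spawn(5)

    amodel = draw_assignment_model(spec.K, s_model)
    truth = allocate_provider_truth(spec, s_truth)
    cohort = fill_quotas(amodel, casemix, truth.volumes, s_fill)
    cohort.volumes = truth.volumes

    n_redraws = 0
    for attempt in range(max_truth_redraws + 1):
        gamma00 = calibrate_intercept(cohort, truth, outcome_model.beta, spec.p_bar)
        model = dataclasses.replace(outcome_model, gamma00=gamma00)
        try:
            y = draw_outcomes(cohort, truth, model, s_out if attempt == 0 else s_redraw.spawn(1)[0])
            break
        except IncidenceError:
            n_redraws += 1
            logger.info("redrawing random intercepts (attempt %d)", n_redraws)
            truth = truth.redraw_alpha(s_redraw.spawn(1)[0])
    else:
        raise IncidenceError(
            f"minimum incidence unattainable after {max_truth_redraws} "
            "random-intercept redraws"
        )

    results, failures = run_all_methods(cohort, y, methods=methods, rule=rule)
    return ReplicateResult(
        spec=spec,
        truth=truth,
        results=results,
        failures=failures,
        gamma00=gamma00,
        incidence=float(np.mean(y)),
        n_truth_redraws=n_redraws,
    )


def run_design_point(
    spec: ScenarioSpec,
    replications: int,
    master_seed: int,
    point: int = 0,
    methods=METHOD_NAMES,
    casemix: CaseMixConfig | None = None,
    outcome_model: OutcomeModel | None = None,
    rule: str = "model_sd",
    keep_replicates: bool = False,
):
    """Monte-Carlo replication at one design point.

    Returns ``(summary, records, failure_counts)``: the tidy per-method
    summary (see :func:`profilesim.metrics.summarize`), the per-replicate
    measure records, and per-method failed-fit counts.
    """
    if replications < 1:
        raise ValueError("replications must be >= 1")
    scen = spec.scenario or 0
    frames = []
    fail_counts: dict[str, int] = {m: 0 for m in methods}
    for rep in range(replications):
        seed = replicate_seed(master_seed, scen, point, rep)
        res = run_replicate(
            spec, seed, methods=methods, casemix=casemix,
            outcome_model=outcome_model, rule=rule,
        )
        df = res.measures()
        df.insert(0, "replicate", rep)
        frames.append(df)
        for m in res.failures:
            fail_counts[m] += 1
    records = pd.concat(frames, ignore_index=True)
    summary = summarize(records)
    summary["n_failed"] = summary["method"].map(fail_counts)
    return summary, records, fail_counts


def run_scenario(
    scenario: int,
    replications: int,
    master_seed: int,
    out_dir=None,
    methods=METHOD_NAMES,
    casemix: CaseMixConfig | None = None,
    rule: str = "model_sd",
    keep_replicates: bool = False,
    points=None,
) -> pd.DataFrame:
    """Run every design point of one scenario and optionally persist CSVs.

    ``points`` optionally restricts to a subset of design-point indices
    (seeding stays tied to the absolute index, so partial runs reproduce the
    corresponding rows of a full run).  The combined summary gains
    ``scenario`` and design-point parameter columns, mirroring the
    appendix-table layout (method x measure rows with means and
    5th/95th-percentile bounds).
    """
    grid = scenario_grid()
    if scenario not in grid:
        raise ValueError(f"scenario must be one of {sorted(grid)}")
    out = []
    for point, spec in enumerate(grid[scenario]):
        if points is not None and point not in points:
            continue
        summary, records, _ = run_design_point(
            spec, replications, master_seed, point=point, methods=methods,
            casemix=casemix, rule=rule, keep_replicates=keep_replicates,
        )
        for k, v in spec.to_dict().items():
            summary[k] = v
        summary["point"] = point
        out.append(summary)
        if out_dir is not None and keep_replicates:
            path = Path(out_dir)
            path.mkdir(parents=True, exist_ok=True)
            records.to_csv(
                path / f"scenario{scenario}_point{point}_replicates.csv",
                index=False,
            )
    combined = pd.concat(out, ignore_index=True)
    if out_dir is not None:
        path = Path(out_dir)
        path.mkdir(parents=True, exist_ok=True)
        combined.to_csv(path / f"scenario{scenario}_summary.csv", index=False)
        manifest = {
            "scenario": scenario,
            "replications": replications,
            "master_seed": master_seed,
            "methods": list(methods),
            "rule": rule,
            "version": __version__,
            "design_points": [s.to_dict() for s in grid[scenario]],
        }
        (path / f"scenario{scenario}_manifest.json").write_text(
            json.dumps(manifest, indent=2)
        )
    return combined
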