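"""Repeated-run orchestration and performance measurement.

A configuration is judged over many independent seeded runs: the reported
mutant is the best run's solution, stability is the mean/SD of the best
solutions' growth rates, and two accuracies count how often runs end with a
trustworthy QP.  "Valid" follows a residual criterion: a run's best solution
counts as valid when its MOMA solution's worst constraint violation is below
``validity_tolerance`` (default 0.001); "optimal" counts runs whose solver
status is optimal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .bat import BatConfig, BatRunResult, run_batmoma
from .model_io import MetabolicModel
from .solvers import FluxDistribution, OPTIMAL, reference_flux


@dataclass
class RunSummary:
    """Statistics over one batch of runs (one row of a K-sweep table)."""

    max_knockouts: int
    n_runs: int
    mean_growth: float
    sd_growth: float
    valid_accuracy: float
    optimal_accuracy: float
    best_run: int
    best_production: float
    best_knockouts: tuple[str, ...]


def run_batch(model: MetabolicModel, target: str, config: BatConfig,
              n_runs: int, base_seed: int,
              reference: FluxDistribution | None = None) -> list[BatRunResult]:
    """Run the search ``n_runs`` times with seeds base_seed..base_seed+n-1.

    The parsimonious wild-type reference is computed once and shared, so all
    runs measure distance from the same wild type.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if reference is None:
        reference = reference_flux(model)
    return [
        run_batmoma(model, target, replace(config, rng_seed=base_seed + k),
                    reference=reference)
        for k in range(n_runs)
    ]


def summarize(records: Sequence[BatRunResult],
              validity_tolerance: float = 0.001) -> RunSummary:
    """Mean/SD of best growth rates plus valid/optimal run fractions.

    SD uses the sample (n-1) denominator; a single record gives SD 0.
    """
    if not records:
        raise ValueError("no run records to summarize")
    growths = np.array([r.best_fitness.growth_rate for r in records])
    productions = np.array([r.best_fitness.production_rate for r in records])
    valid = sum(
        1 for r in records
        if r.best_fitness.residual is not None
        and r.best_fitness.residual < validity_tolerance
    )
    optimal = sum(1 for r in records if r.best_fitness.solver_status == OPTIMAL)
    best = int(np.argmax(productions))
    return RunSummary(
        max_knockouts=max(1, max(len(r.best_units) for r in records)),
        n_runs=len(records),
        mean_growth=float(np.mean(growths)),
        sd_growth=float(np.std(growths, ddof=1)) if len(records) > 1 else 0.0,
        valid_accuracy=valid / len(records),
        optimal_accuracy=optimal / len(records),
        best_run=best,
        best_production=float(productions[best]),
        best_knockouts=records[best].best_units,
    )


def write_summary_tsv(summaries: Sequence[RunSummary], path: str | Path) -> None:
    """K-sweep table: one row per maximum-knockout budget."""
    lines = ["max_ko\tn_runs\tmean_growth\tsd_growth\tvalid_accuracy\t"
             "optimal_accuracy\tbest_production\tbest_knockouts"]
    for s in summaries:
        lines.append(
            f"{s.max_knockouts}\t{s.n_runs}\t{s.mean_growth:.6f}\t{s.sd_growth:.6f}\t"
            f"{s.valid_accuracy * 100:.1f}%\t{s.optimal_accuracy * 100:.1f}%\t"
            f"{s.best_production:.4f}\t{','.join(s.best_knockouts) or '-'}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_knockout_table_tsv(records: Sequence[BatRunResult],
                             path: str | Path) -> None:
    """Best-solution table: knocked-out enzymes, genes, production, growth."""
    lines = ["run\tko_number\treactions\tgenes\tproduction\tgrowth"]
    for i, r in enumerate(records):
        genes = ";".join(",".join(g) for g in r.best_genes)
        lines.append(
            f"{i}\t{len(r.best_units)}\t{','.join(r.best_units) or '-'}\t"
            f"{genes or '-'}\t{r.best_fitness.production_rate:.4f}\t"
            f"{r.best_fitness.growth_rate:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
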