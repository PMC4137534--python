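"""End-to-end orchestration: rank -> top-m -> optimize -> report.

Each grid cell (statistic x algorithm x m) gets its own seed derived from
the master seed by a stable hash of the cell key, so removing one cell from
the grid never changes another cell's numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import __version__
from .classifier import CVFitnessEvaluator
from .io_data import ExpressionDataset
from .optimizers import ALGORITHMS, OptimizerConfig, decode, run_optimizer
from .ranking import METHODS, rank_genes

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    statistics: list[str] = field(default_factory=lambda: list(METHODS))
    algorithms: list[str] = field(default_factory=lambda: list(ALGORITHMS))
    top_m: list[int] = field(default_factory=lambda: [10, 50, 100])
    k: int = 5
    n_folds: int = 5
    seed: int = 0
    repeats: int = 1
    snr_denominator: str = "sum"
    signed_ranking: bool = False
    f_rank: str = "ascending"
    optimizer: dict = field(default_factory=dict)  # OptimizerConfig overrides

    def validate(self) -> None:
        if not self.statistics or not self.algorithms or not self.top_m:
            raise ValueError("need at least one statistic, algorithm and m value")
        for s in self.statistics:
            if s not in METHODS:
                raise ValueError(f"unknown statistic {s!r}; expected one of {METHODS}")
        for a in self.algorithms:
            if a not in ALGORITHMS:
                raise ValueError(f"unknown algorithm {a!r}; expected one of {ALGORITHMS}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def cell_seed(master_seed: int, stat: str, algo: str, m: int, repeat: int = 0) -> int:
    """Stable per-cell seed derived from the master seed and the cell key."""
    key = f"{master_seed}:{stat}:{algo}:{m}:{repeat}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:8], "big") % (2**31)


def _run_cell(
    ds: ExpressionDataset, cfg: PipelineConfig, stat: str, algo: str, m: int
) -> dict:
    if m > ds.n_genes:
        raise ValueError(
            f"top-m {m} exceeds the {ds.n_genes} genes in the dataset"
        )
    ranking = rank_genes(
        ds, stat, m,
        snr_denominator=cfg.snr_denominator,
        signed=cfg.signed_ranking,
        f_rank=cfg.f_rank,
    )
    sub = ds.subset_genes(ranking.top_m)

    repeat_rows = []
    for rep in range(cfg.repeats):
        seed = cell_seed(cfg.seed, stat, algo, m, rep)
        evaluator = CVFitnessEvaluator(sub, k=cfg.k, n_folds=cfg.n_folds, seed=seed)
        ocfg = OptimizerConfig(algorithm=algo, dim=m, **cfg.optimizer)
        result = run_optimizer(ocfg, lambda pos: evaluator(decode(pos)), seed)
        best_mask = decode(result.best_position)
        best = evaluator.fitness_result(best_mask)
        repeat_rows.append(
            {
                "seed": seed,
                "best_fitness": result.best_fitness,
                "fold_accuracies": best.fold_accuracies,
                "selected_genes": [sub.gene_ids[i] for i in best_mask],
                "n_selected": int(best_mask.size),
                "evaluations": result.evaluations,
                "unique_masks": evaluator.evaluations,
                "final_trace_value": result.trace[-1],
            }
        )

    headline = max(repeat_rows, key=lambda r: r["best_fitness"])
    cell = {
        "statistic": stat,
        "algorithm": algo,
        "m": m,
        "best_fitness": headline["best_fitness"],
        "mean_fitness_over_repeats": float(
            np.mean([r["best_fitness"] for r in repeat_rows])
        ),
        "fold_accuracies": headline["fold_accuracies"],
        "selected_genes": headline["selected_genes"],
        "n_selected": headline["n_selected"],
        "evaluations": headline["evaluations"],
        "seed": headline["seed"],
        "repeats": repeat_rows if cfg.repeats > 1 else None,
    }
    if cfg.repeats == 1:
        del cell["repeats"]
    return cell


def run_pipeline(ds: ExpressionDataset, cfg: PipelineConfig) -> dict:
    """Run the full (statistic x algorithm x m) grid and collect a report.

    Any stage error aborts that grid cell, is recorded in the cell, and
    does not stop the remaining cells.
    """
    cfg.validate()
    ds.check_valid()
    cells = []
    for stat in cfg.statistics:
        for algo in cfg.algorithms:
            for m in cfg.top_m:
                logger.info("cell %s x %s x m=%d", stat, algo, m)
                try:
                    cells.append(_run_cell(ds, cfg, stat, algo, m))
                except Exception as exc:  # recorded, not swallowed
                    logger.error("cell %s/%s/%d failed: %s", stat, algo, m, exc)
                    cells.append(
                        {
                            "statistic": stat,
                            "algorithm": algo,
                            "m": m,
                            "error": f"{type(exc).__name__}: {exc}",
                        }
                    )
    config_echo = asdict(cfg)
    return {
        "config": config_echo,
        "dataset": {
            "n_genes": ds.n_genes,
            "n_samples": ds.n_samples,
            "class_names": list(ds.class_names),
            "class_sizes": [ds.n1, ds.n2],
        },
        "version": __version__,
        "cells": cells,
    }


def write_report_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_report_tsv(report: dict, path) -> None:
    """Flat per-cell table; error cells carry the message in the last column."""
    cols = [
        "statistic", "algorithm", "m", "best_fitness", "n_selected",
        "evaluations", "seed", "selected_genes", "error",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for cell in report["cells"]:
            row = []
            for c in cols:
                v = cell.get(c, "")
                if c == "selected_genes" and v != "":
                    v = ",".join(v)
                row.append(str(v))
            fh.write("\t".join(row) + "\n")
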