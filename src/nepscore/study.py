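"""Cohort-study protocol: simulate preset cohorts, score them, classify.

This is the validation workflow for the score family on in-silico
tissues: three adjacency levels (random / weak / strong) of either the
self-preference or the cross-preference family are generated on shared
scaffolds at equal cell-type abundances, every image is scored, and a
random forest is asked to tell cohorts apart from the per-image NEP
feature vectors.  Because abundances match across cohorts, any
classification signal must come from tissue architecture.

The default problem size (field 600, ~550-600 cells per image, 30 images
per cohort, 300 permutations) is a scaled-down version of the cohort
design the simulators target; pass ``SimParams(f=1000)`` and more images
for full-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .benchmark import BenchmarkReport, run_benchmark
from .cell_table import CellTable
from .scores import score_images
from .simulate import (
    AdjacencySpec,
    SimParams,
    SimulatedTissue,
    cohort_to_table,
    make_scaffolds,
    preset_spec,
    simulate_cohort,
)

#: scaled-down default: ~580-cell images, desk-scale runtimes
DEFAULT_STUDY_PARAMS = SimParams(f=600.0)


@dataclass
class CohortStudy:
    """Simulated cohorts plus their long-format score table."""

    tissues: dict[str, list[SimulatedTissue]]  # cohort label -> tissues
    specs: dict[str, AdjacencySpec]
    cells: CellTable
    scores: pd.DataFrame
    params: SimParams
    seed: int
    levels: dict[str, str] = field(default_factory=dict)  # level -> cohort label

    def cohort_of_image(self) -> dict[str, str]:
        out = {}
        for label, tissues in self.tissues.items():
            for t in tissues:
                out[t.image_id] = label
        return out


def run_cohort_study(
    kind: str = "self",
    levels: tuple[str, ...] = ("random", "weak", "strong"),
    n_images: int = 30,
    params: SimParams = DEFAULT_STUDY_PARAMS,
    seed: int = 0,
    scores: tuple[str, ...] = ("cozi_z", "total_z"),
    n_perm: int = 300,
    abundance: str = "ab0_0.25",
) -> CohortStudy:
    """Simulate and score one cohort family on shared scaffolds."""
    scaffolds = make_scaffolds(n_images, params, seed)
    specs = {}
    tissues = {}
    level_of = {}
    for level in levels:
        spec = preset_spec(kind, level, abundance)
        specs[spec.cohort_label] = spec
        tissues[spec.cohort_label] = simulate_cohort(
            spec, n_images, params, seed, scaffolds=scaffolds
        )
        level_of[level] = spec.cohort_label
    all_cells = pd.concat(
        [cohort_to_table(ts).df for ts in tissues.values()], ignore_index=True
    )
    cells = CellTable(all_cells)
    score_table = score_images(cells, scores=scores, n_perm=n_perm, seed=seed)
    return CohortStudy(
        tissues=tissues, specs=specs, cells=cells, scores=score_table,
        params=params, seed=seed, levels=level_of,
    )


def compare_levels(
    study: CohortStudy,
    level_a: str,
    level_b: str,
    score_name: str = "cozi_z",
    n_repeats: int = 20,
    seed: int = 0,
    with_baselines: bool = False,
) -> BenchmarkReport:
    """Classify two cohorts of a study; returns the benchmark report with
    the ground-truth cosine similarity attached (truth = H_a - H_b)."""
    a, b = study.levels[level_a], study.levels[level_b]
    reports = run_benchmark(
        study.scores,
        study.cohort_of_image(),
        [(a, b)],
        score_name,
        study.cells.label_set,
        truth=study.specs,
        n_repeats=n_repeats,
        seed=seed,
        cells_df=study.cells.df if with_baselines else None,
        with_baselines=with_baselines,
    )
    return reports[(a, b)]
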