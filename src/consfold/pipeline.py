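"""End-to-end two-round consensus refinement protocol.

Round structure (per consensus round): consensus distance extraction ->
RAPDF weighting -> cutoff-limited constraint sets -> restrained annealing
builds per set -> Cartesian relaxation -> sequential four-term filter ->
iterative density clustering -> centroid selection.  The centroids of the
first round become the input ensemble of the second; the second round's
centroids are the final models.

All randomness derives from one seed through per-stage spawned streams,
so a run is reproducible end to end.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator

from consfold.clustering import iterative_density_cluster, select_top
from consfold.consensus import (
    attach_rapdf_weights,
    compile_constraint_sets,
    extract_consensus,
)
from consfold.modelbuild import (
    BuildConfig,
    build_conformations,
    relax,
    sequential_filter,
    stage_removals,
    train_torsion_prior,
)
from consfold.rapdf import RAPDFTable, score_model, train_rapdf
from consfold.structcore import Ensemble, Model
from consfold.synthetic import make_rapdf_training


class PipelineConfig(BaseModel):
    """Every stated protocol parameter in one declarative object."""

    window: float = 0.5
    min_support: int = 4
    cutoffs: tuple[float, ...] = (12.0, 16.0, 20.0)
    rounds: int = 50
    models_per_round: int = 20
    keep_fraction: float = Field(default=0.5, gt=0.0, le=1.0)
    cluster_threshold: float = 2.0
    min_density: int = 2
    top_k: int = 5
    consensus_rounds: int = 2
    relax_steps: int = 30
    t_start: float = 4.0
    t_end: float = 0.05
    anneal_steps: int | None = None
    n_training: int = 10
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.rounds < 1 or self.models_per_round < 1 or self.top_k < 0:
            raise ValueError("counts must be positive")
        if self.consensus_rounds < 1:
            raise ValueError("consensus_rounds must be >= 1")
        return self


@dataclass
class RoundReport:
    constraints_per_set: dict[float, int]
    conformations_generated: int
    conformations_filtered: int
    cluster_sizes: list[int]
    n_outliers: int
    centroid_labels: list[str]
    centroid_scores: list[float | None]


@dataclass
class PipelineReport:
    seed: int
    config: dict
    rounds: list[RoundReport] = field(default_factory=list)
    final_labels: list[str] = field(default_factory=list)

    @property
    def conformations_generated(self) -> int:
        return sum(r.conformations_generated for r in self.rounds)

    def write(self, path: str | Path) -> None:
        lines = ["stage\tround\tkey\tvalue"]
        lines.append(f"config\t-\tseed\t{self.seed}")
        for k, v in self.config.items():
            lines.append(f"config\t-\t{k}\t{v}")
        for i, r in enumerate(self.rounds, start=1):
            for cutoff, n in r.constraints_per_set.items():
                lines.append(f"consensus\t{i}\tconstraints_cutoff_{cutoff:g}\t{n}")
            lines.append(f"build\t{i}\tconformations_generated\t{r.conformations_generated}")
            lines.append(f"filter\t{i}\tconformations_filtered\t{r.conformations_filtered}")
            lines.append(f"cluster\t{i}\tcluster_sizes\t"
                         f"{','.join(map(str, r.cluster_sizes))}")
            lines.append(f"cluster\t{i}\tn_outliers\t{r.n_outliers}")
            for lbl, sc in zip(r.centroid_labels, r.centroid_scores):
                lines.append(f"centroid\t{i}\t{lbl}\t{sc}")
        lines.append(f"final\t-\tmodels\t{','.join(self.final_labels)}")
        Path(path).write_text("\n".join(lines) + "\n")


class PipelineError(RuntimeError):
    """Raised when a stage yields an empty survivor set."""


def _log(stage: str, msg: str) -> None:
    print(f"[consfold:{stage}] {msg}", file=sys.stderr)


def dry_run(config: PipelineConfig) -> PipelineReport:
    """Planned per-stage counts without building any model."""
    report = PipelineReport(seed=config.seed, config=config.model_dump())
    generated = len(config.cutoffs) * config.rounds * config.models_per_round
    kept = generated - sum(stage_removals(generated, config.keep_fraction))
    for _ in range(config.consensus_rounds):
        report.rounds.append(RoundReport(
            constraints_per_set={c: 0 for c in config.cutoffs},
            conformations_generated=generated,
            conformations_filtered=kept,
            cluster_sizes=[],
            n_outliers=0,
            centroid_labels=[],
            centroid_scores=[],
        ))
    return report


def run_pipeline(initial_ensemble: Ensemble, config: PipelineConfig,
                 table: RAPDFTable | None = None, prior=None,
                 ) -> tuple[PipelineReport, list[Model]]:
    """Run the full multi-round protocol and return (report, final models).

    The RAPDF table and torsion prior default to ones trained on a
    synthetic corpus derived from the pipeline seed.  Any stage left with
    no survivors aborts with a stage-named :class:`PipelineError`.
    """
    if len(initial_ensemble) < config.min_support:
        raise PipelineError(
            f"input: ensemble of {len(initial_ensemble)} models is smaller "
            f"than min_support {config.min_support}")
    root = np.random.SeedSequence(config.seed)
    if table is None or prior is None:
        corpus = make_rapdf_training(config.n_training,
                                     seed=int(root.generate_state(1)[0] % 2 ** 31))
        table = table or train_rapdf(corpus)
        prior = prior or train_torsion_prior(corpus)

    report = PipelineReport(seed=config.seed, config=config.model_dump())
    ensemble = initial_ensemble
    final_models: list[Model] = list(initial_ensemble)

    for rnd in range(1, config.consensus_rounds + 1):
        constraints = extract_consensus(ensemble, window=config.window,
                                        min_support=config.min_support)
        if not constraints:
            raise PipelineError(f"consensus (round {rnd}): no consensus distances")
        weighted = attach_rapdf_weights(constraints, table,
                                        ensemble_size=len(ensemble),
                                        min_support=config.min_support,
                                        sequence=ensemble.sequence)
        sets = compile_constraint_sets(weighted, cutoffs=config.cutoffs,
                                       source=f"round{rnd}")
        _log("consensus", f"round {rnd}: {len(constraints)} consensus distances, "
             f"set sizes {[len(s) for s in sets]}")

        built: list[Model] = []
        for set_idx, cset in enumerate(sets):
            seed = int(np.random.SeedSequence(
                [config.seed, rnd, set_idx]).generate_state(1)[0] % 2 ** 31)
            bc = BuildConfig(rounds=config.rounds,
                             models_per_round=config.models_per_round,
                             t_start=config.t_start, t_end=config.t_end,
                             steps=config.anneal_steps, seed=seed)
            sub = build_conformations(ensemble.sequence, cset, prior, bc)
            for m in sub:
                m.label = f"r{rnd}c{cset.cutoff:g}_{m.label}"
            built.extend(sub.models)
        if not built:
            raise PipelineError(f"build (round {rnd}): no conformations")
        _log("build", f"round {rnd}: {len(built)} conformations")

        relaxed = [relax(m, steps=config.relax_steps) for m in built]
        pool = Ensemble(relaxed, ensemble.sequence)

        filtered = sequential_filter(pool, table, keep_fraction=config.keep_fraction)
        if len(filtered) == 0:
            raise PipelineError(f"filter (round {rnd}): no survivors")
        _log("filter", f"round {rnd}: {len(filtered)} survive of {len(pool)}")

        result = iterative_density_cluster(filtered,
                                           rmsd_threshold=config.cluster_threshold,
                                           min_density=config.min_density)
        if result.n_clusters == 0:
            raise PipelineError(f"cluster (round {rnd}): all models removed "
                                "as outliers")
        centroids = select_top(result, config.top_k)
        # small ensembles can yield fewer clusters than the next round's
        # quorum needs: fill remaining slots with the densest non-centroid
        # survivors, in cluster-rank order
        want = min(config.top_k, int((result.assignments >= 0).sum()))
        if len(centroids) < want:
            chosen = set(result.centroids[:config.top_k])
            extras = [i for rank, members in enumerate(result.clusters)
                      for i in sorted(members,
                                      key=lambda x: (-result.densities[x], x))
                      if i not in chosen]
            for i in extras:
                if len(centroids) >= want:
                    break
                centroids.append(filtered[i])
                chosen.add(i)
        _log("cluster", f"round {rnd}: sizes {[len(c) for c in result.clusters]}, "
             f"{len(centroids)} selected")

        scores = [score_model(m, table).rapdf_normalized for m in centroids]
        report.rounds.append(RoundReport(
            constraints_per_set={s.cutoff: len(s) for s in sets},
            conformations_generated=len(built),
            conformations_filtered=len(filtered),
            cluster_sizes=[len(c) for c in result.clusters],
            n_outliers=int((result.assignments == -1).sum()),
            centroid_labels=[m.label for m in centroids],
            centroid_scores=scores,
        ))
        final_models = centroids
        if rnd < config.consensus_rounds:
            if len(centroids) < config.min_support:
                raise PipelineError(
                    f"select (round {rnd}): only {len(centroids)} models for the "
                    f"next round (min_support {config.min_support})")
            ensemble = Ensemble(centroids, ensemble.sequence)

    report.final_labels = [m.label for m in final_models]
    return report, final_models
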