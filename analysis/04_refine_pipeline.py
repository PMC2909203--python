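#!/usr/bin/env python
"""Run the full two-round consensus refinement protocol on the hairpin
ensemble and measure recovery against the known source fold.

The production protocol is 3 cutoff sets x 50 rounds x 20 models = 3000
conformations per consensus round; here the same protocol runs at desk
scale (1 cutoff set, 8 models per round) so the whole two-round run takes
seconds.  Requires 01 to have run.
"""

from pathlib import Path

from consfold import PipelineConfig, dry_run, read_ensemble, read_pdb, run_pipeline, write_pdb
from consfold.structcore import ca_rmsd

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "refined"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ens = read_ensemble(BASE / "inputs" / "hairpin_ensemble.pdb")
    native = read_pdb(BASE / "inputs" / "hairpin_native.pdb")

    planned = dry_run(PipelineConfig())
    print(f"production protocol would build "
          f"{planned.rounds[0].conformations_generated} conformations per "
          f"consensus round; running the desk-scale equivalent")

    cfg = PipelineConfig(cutoffs=(20.0,), rounds=1, models_per_round=12,
                         cluster_threshold=6.0, min_density=1,
                         consensus_rounds=2, anneal_steps=50, n_training=5,
                         seed=SEED)
    report, finals = run_pipeline(ens, cfg)
    report.write(OUT / "pipeline_report.tsv")
    for i, m in enumerate(finals, start=1):
        write_pdb(m, OUT / f"final_{i}.pdb")

    best_in = min(ca_rmsd(native, m) for m in ens)
    rows = ["model\tca_rmsd_to_native"]
    for m in finals:
        rows.append(f"{m.label}\t{ca_rmsd(native, m):.3f}")
    (OUT / "recovery.tsv").write_text("\n".join(rows) + "\n")
    best_out = min(ca_rmsd(native, m) for m in finals)
    print(f"best input model:    {best_in:.2f} A CA RMSD to source")
    print(f"best final centroid: {best_out:.2f} A CA RMSD to source")
    print("note: the final models concentrate near the ensemble-consensus "
          "conformation, whose distance to the source is set by the input "
          "noise level (see docs/methods.md)")


if __name__ == "__main__":
    main()
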